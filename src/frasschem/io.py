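"""Readers and writers for the plain-text formats the pipelines exchange.

CSV/TSV for plate, feature, library and CFU tables; MGF for MS2 spectra
(keyed by feature id in the TITLE field); newick for dendrograms; JSON
for configuration, layouts, manifests and reports.  All floating-point
report output keeps full precision (repr round trip).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf

from .dereplication import CompoundRecord, Feature, SampleLayout, Spectrum
from .growth import CFU_COLUMNS
from .plate import PLATE_COLUMNS
from .trees import Node, read_newick, write_newick  # re-exported  # noqa: F401


def read_table(
    path: str | Path,
    required: list[str],
    numeric: list[str] = (),
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited table, checking schema and numeric parsability.

    Unknown columns are preserved; decimal and scientific notation are
    both accepted in numeric fields.  Errors name the missing column or
    the first offending row.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = coerced
    return df


# -- plates -----------------------------------------------------------------

def read_plate_csv(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return read_table(
        path, required=PLATE_COLUMNS,
        numeric=["conc_a", "conc_b", "replicate", "fluorescence"], sep=sep,
    )


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


# -- CFU tables -------------------------------------------------------------

def read_cfu_csv(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return read_table(
        path, required=CFU_COLUMNS,
        numeric=["replicate", "cfu_initial", "cfu_final"], sep=sep,
    )


# -- feature tables ---------------------------------------------------------

def features_to_frame(features: list[Feature]) -> pd.DataFrame:
    """Flatten a feature list into a wide table.

    One intensity column per sample/replicate key and one ``ms2:<sample>``
    flag column per sample seen in the MS/MS run.
    """
    int_cols = sorted({k for f in features for k in f.intensities})
    ms2_cols = sorted({k for f in features for k in f.has_ms2})
    rows = []
    for f in features:
        row = {"feature_id": f.feature_id, "mz": f.mz, "rt": f.rt}
        for c in int_cols:
            row[c] = f.intensities.get(c, 0.0)
        for c in ms2_cols:
            row[f"ms2:{c}"] = bool(f.has_ms2.get(c, False))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_features(
    df: pd.DataFrame, spectra: dict[str, Spectrum] | None = None
) -> list[Feature]:
    required = ["feature_id", "mz", "rt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s) {missing}")
    ms2_cols = [c for c in df.columns if c.startswith("ms2:")]
    int_cols = [c for c in df.columns if c not in required + ms2_cols]
    spectra = spectra or {}
    feats = []
    for _, row in df.iterrows():
        fid = str(row["feature_id"])
        feats.append(Feature(
            feature_id=fid, mz=float(row["mz"]), rt=float(row["rt"]),
            intensities={c: float(row[c]) for c in int_cols if row[c] > 0},
            has_ms2={c[4:]: bool(row[c]) for c in ms2_cols if row[c]},
            ms2_spectrum=spectra.get(fid),
        ))
    return feats


def read_features_csv(
    path: str | Path,
    spectra_path: str | Path | None = None,
    sep: str = ",",
) -> list[Feature]:
    df = read_table(path, required=["feature_id", "mz", "rt"],
                    numeric=["mz", "rt"], sep=sep)
    spectra = read_mgf(spectra_path) if spectra_path else None
    return frame_to_features(df, spectra)


def write_features_csv(features: list[Feature], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, index=False)


# -- MS2 spectra ------------------------------------------------------------

def write_mgf(features: list[Feature], path: str | Path) -> None:
    """Write the MS2 spectra of a feature list, TITLE = feature id."""
    entries = []
    for f in features:
        if not f.ms2_spectrum:
            continue
        mzs, ints = zip(*f.ms2_spectrum)
        entries.append({
            "m/z array": np.array(mzs), "intensity array": np.array(ints),
            "params": {"title": f.feature_id, "pepmass": f.mz},
        })
    mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> dict[str, Spectrum]:
    """Read an MGF file into a title-keyed dict of stick spectra."""
    out: dict[str, Spectrum] = {}
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            title = entry["params"]["title"]
            out[title] = list(
                zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
            )
    return out


# -- compound libraries -----------------------------------------------------

LIBRARY_COLUMNS = ["name", "family", "monoisotopic_mass", "is_polyene",
                   "reference_rt", "standard_available"]


def read_library_csv(
    path: str | Path,
    spectra_path: str | Path | None = None,
    sep: str = ",",
) -> list[CompoundRecord]:
    """Read a compound library; reference spectra come from an optional
    MGF whose titles are ``<name>::standard|library|analog``."""
    df = read_table(path, required=["name", "family", "monoisotopic_mass"],
                    numeric=["monoisotopic_mass"], sep=sep)
    spectra = read_mgf(spectra_path) if spectra_path else {}
    records = []
    for _, row in df.iterrows():
        name = str(row["name"])
        ref_rt = row.get("reference_rt")
        records.append(CompoundRecord(
            name=name, family=str(row["family"]),
            monoisotopic_mass=float(row["monoisotopic_mass"]),
            is_polyene=bool(row.get("is_polyene", False)),
            reference_rt=None if pd.isna(ref_rt) else float(ref_rt),
            standard_available=bool(row.get("standard_available", False)),
            standard_spectrum=spectra.get(f"{name}::standard"),
            library_spectrum=spectra.get(f"{name}::library"),
            analog_spectrum=spectra.get(f"{name}::analog"),
        ))
    return records


def write_library_csv(library: list[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame([
        {
            "name": c.name, "family": c.family,
            "monoisotopic_mass": c.monoisotopic_mass,
            "is_polyene": c.is_polyene, "reference_rt": c.reference_rt,
            "standard_available": c.standard_available,
        }
        for c in library
    ]).to_csv(path, index=False)


# -- sample layouts and JSON reports ---------------------------------------

def write_layout(layout: SampleLayout, path: str | Path) -> None:
    write_json({"replicates": layout.replicates, "msms_run": layout.msms_run}, path)


def read_layout(path: str | Path) -> SampleLayout:
    d = json.loads(Path(path).read_text())
    return SampleLayout(replicates=d["replicates"], msms_run=d.get("msms_run", {}))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Node):
        from .trees import to_newick
        return to_newick(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
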