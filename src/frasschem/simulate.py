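"""Synthetic-data generators with known ground truth.

Every generator draws from a substream of a single root seed (via
``numpy`` seed sequences keyed by a per-generator constant), so repeated
runs are byte-identical and adding one generator call never shifts the
draws of another.  Noiseless settings invert the corresponding analysis
operations exactly, which the test-suite round trips rely on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dereplication as derep
from .chemodiversity import cophenetic_matrix, upgma
from .dereplication import (
    AdductSpec, CompoundRecord, DEFAULT_ADDUCTS, Feature, SampleLayout,
    theoretical_mz,
)
from .plate import PLATE_COLUMNS, bliss_expected
from .trees import Node

# substream ids: one per generator, fanned out from the root seed
_PLATE, _FEATURES, _TREES, _CFU = 11, 13, 17, 19


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

@dataclass
class PlateSimSpec:
    """Ground truth for one simulated compound-pair plate.

    True fractional inhibitions of the solo compounds, the true Bliss
    excess of the combination, the replicate count (seven biological
    replicates by default, as in the assay being emulated), and a noise
    level expressed as a fraction of the control dynamic range.
    """

    fi_a_true: float = 0.4
    fi_b_true: float = 0.4
    b_true: float = 0.0
    n_replicates: int = 7
    noise_sd: float = 0.02
    ic_mean: float = 12000.0
    mc_mean: float = 2000.0
    compound_a: str = "A"
    compound_b: str = "B"
    conc_a: float = 15.0
    conc_b: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mc_mean >= self.ic_mean:
            raise ValueError("mc_mean must be below ic_mean")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


def simulate_plate(spec: PlateSimSpec) -> pd.DataFrame:
    """Simulate one plate: controls, solo arms, and the combination.

    Fluorescence of a well with true inhibition f is drawn
    ``Normal(ic_mean - f*(ic_mean - mc_mean), noise_sd*(ic_mean - mc_mean))``;
    the combination's true FI is ``bliss_expected(fi_a, fi_b) - b_true``.
    """
    rng = _rng(spec.seed, _PLATE)
    rng_range = spec.ic_mean - spec.mc_mean
    sd = spec.noise_sd * rng_range

    def fluor(fi_true: float, n: int) -> np.ndarray:
        mean = spec.ic_mean - fi_true * rng_range
        vals = mean + (rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n))
        if (vals < 0).any():
            raise ValueError(
                "simulated fluorescence went negative; lower the true FI "
                "or the noise level"
            )
        return vals

    fi_ab_true = bliss_expected(spec.fi_a_true, spec.fi_b_true) - spec.b_true
    n = spec.n_replicates
    rows = []

    def add(role, comp_a, conc_a, comp_b, conc_b, fi_true):
        for rep, f in enumerate(fluor(fi_true, n), start=1):
            rows.append({
                "well_id": f"{role[:2].upper()}{comp_a or ''}{comp_b or ''}-{rep}",
                "role": role, "compound_a": comp_a, "conc_a": conc_a,
                "compound_b": comp_b, "conc_b": conc_b,
                "replicate": rep, "fluorescence": f,
            })

    add("medium_control", "", None, "", None, 1.0)
    add("inoculum_control", "", None, "", None, 0.0)
    add("solvent_control", "", None, "", None, 0.0)
    add("treatment", spec.compound_a, spec.conc_a, "", None, spec.fi_a_true)
    add("treatment", spec.compound_b, spec.conc_b, "", None, spec.fi_b_true)
    add("treatment", spec.compound_a, spec.conc_a, spec.compound_b, spec.conc_b,
        fi_ab_true)
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


# ---------------------------------------------------------------------------
# LC-MS feature tables
# ---------------------------------------------------------------------------

def _pseudo_spectrum(name: str, mass: float, n_fragments: int = 6) -> list:
    """Deterministic stick MS2 spectrum for a compound (keyed by its name)."""
    r = np.random.default_rng(zlib.crc32(name.encode()))
    mzs = np.sort(r.uniform(50.0, mass, size=n_fragments))
    ints = r.uniform(0.1, 1.0, size=n_fragments)
    return [(float(m), float(i)) for m, i in zip(mzs, ints)]


def default_library() -> list[CompoundRecord]:
    """A compact reference library spanning the compound families of the
    gallery metabolome: actinomycins, angucyclinones, nactins, polyene
    macrolides, PTM macrolactams, cycloheximide and piericidin.

    Monoisotopic masses are approximate literature values; two compounds
    carry commercial standards (reference RT + spectrum), the rest carry
    library spectra, and the filipin analog fungichromin carries an
    analog-standard spectrum only.
    """
    entries = [
        # name, family, mass, polyene, std, ref_rt
        ("actinomycin D", "actinomycins", 1254.6285, False, True, 6.50),
        ("actinomycin X2", "actinomycins", 1268.6077, False, True, 6.10),
        ("STA-21", "angucyclinones", 306.0892, False, False, None),
        ("rubiginone B2", "angucyclinones", 308.1049, False, False, None),
        ("cycloheximide", "cycloheximide", 281.1627, False, False, None),
        ("monactin", "nactins", 750.4554, False, False, None),
        ("dinactin", "nactins", 764.4711, False, False, None),
        ("filipin III", "polyene macrolides", 654.3979, True, False, None),
        ("fungichromin", "polyene macrolides", 670.3928, True, False, None),
        ("alteramide A", "PTMs", 510.2730, False, False, None),
        ("piericidin A", "piericidins", 415.2723, False, False, None),
    ]
    lib = []
    for name, family, mass, poly, std, ref_rt in entries:
        spec = _pseudo_spectrum(name, mass)
        lib.append(CompoundRecord(
            name=name, family=family, monoisotopic_mass=mass, is_polyene=poly,
            reference_rt=ref_rt, standard_available=std,
            standard_spectrum=spec if std else None,
            library_spectrum=None if std else spec,
            analog_spectrum=(
                _pseudo_spectrum("filipin III", 654.3979) if name == "fungichromin"
                else None
            ),
        ))
    return lib


@dataclass
class Spike:
    """One compound spiked into a set of samples with a set of adducts."""

    compound: str
    samples: list[str]
    base_intensity: float = 5e6
    adducts: tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M+NH4]+")


@dataclass
class FeatureSimSpec:
    """Ground truth for a simulated LC-MS feature table.

    Spiked compounds appear with a co-eluting adduct series, truncated
    Gaussian mass error (capped at 3 ppm) and RT jitter (capped at
    0.03 min), in three technical LC-MS replicates plus one LC-MS/MS run
    per sample; decoy features are kept at least 20 ppm away from every
    library adduct mass, and blank contaminants appear in the blanks.
    """

    library: list[CompoundRecord] = field(default_factory=default_library)
    spike_plan: list[Spike] | None = None
    samples: list[str] = field(default_factory=lambda: ["S1", "S2", "S3", "S4"])
    blanks: list[str] = field(
        default_factory=lambda: ["blank_methanol", "blank_medium"]
    )
    ppm_error_sd: float = 1.0
    ppm_error_max: float = 3.0
    rt_jitter_sd: float = 0.01
    rt_jitter_max: float = 0.03
    n_decoys: int = 500
    n_blank_contaminants: int = 50
    n_technical_replicates: int = 3
    intensity_cv: float = 0.2
    decoy_min_ppm: float = 20.0
    adducts: tuple[AdductSpec, ...] = DEFAULT_ADDUCTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_plan is None:
            # default: each library compound into two samples, round-robin
            self.spike_plan = []
            for i, comp in enumerate(self.library):
                s = [self.samples[i % len(self.samples)],
                     self.samples[(i + 1) % len(self.samples)]]
                self.spike_plan.append(Spike(comp.name, s))
        known = {c.name for c in self.library}
        for sp in self.spike_plan:
            if sp.compound not in known:
                raise ValueError(f"spike references unknown compound {sp.compound!r}")
            unknown = set(sp.samples) - set(self.samples)
            if unknown:
                raise ValueError(f"spike into unknown sample ids {sorted(unknown)}")


def _trunc_normal(rng, sd: float, cap: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size=size), -cap, cap)


def simulate_features(
    spec: FeatureSimSpec,
) -> tuple[list[Feature], SampleLayout, dict]:
    """Simulate an aligned feature table plus its ground-truth manifest.

    Returns the feature list, the sample layout (technical replicate and
    MS/MS-run intensity keys per sample) and a manifest recording every
    true (feature, compound, adduct) assignment, the decoy ids and the
    blank-contaminant ids.
    """
    rng = _rng(spec.seed, _FEATURES)
    layout = SampleLayout(
        replicates={
            s: [f"{s}/r{k}" for k in range(1, spec.n_technical_replicates + 1)]
            for s in spec.samples
        },
        msms_run={s: f"{s}/msms" for s in spec.samples},
    )
    lib_by_name = {c.name: c for c in spec.library}
    adducts_by_label = {a.label: a for a in spec.adducts}
    theo = [
        theoretical_mz(c.monoisotopic_mass, a)
        for c in spec.library for a in spec.adducts
    ]
    theo = np.array(sorted(theo))

    features: list[Feature] = []
    manifest: dict = {"spiked": [], "decoys": [], "contaminants": []}
    fid = iter(f"F{i:05d}" for i in range(1, 10 ** 5))

    def intensity(base: float) -> float:
        if spec.intensity_cv == 0:
            return base
        return float(base * rng.lognormal(0.0, spec.intensity_cv))

    for spike in spec.spike_plan:
        comp = lib_by_name[spike.compound]
        true_rt = (
            comp.reference_rt if comp.reference_rt is not None
            else float(rng.uniform(1.0, 13.0))
        )
        for ai, label in enumerate(spike.adducts):
            add = adducts_by_label[label]
            tmz = theoretical_mz(comp.monoisotopic_mass, add)
            ppm = float(_trunc_normal(rng, spec.ppm_error_sd, spec.ppm_error_max, 1)[0])
            jit = float(_trunc_normal(rng, spec.rt_jitter_sd, spec.rt_jitter_max, 1)[0])
            intensities = {}
            has_ms2 = {}
            for s in spike.samples:
                for key in layout.replicates[s]:
                    intensities[key] = intensity(spike.base_intensity)
                intensities[layout.msms_run[s]] = intensity(spike.base_intensity)
                if ai == 0:  # MS2 triggered on the primary (protonated) ion
                    has_ms2[s] = True
            feature = Feature(
                feature_id=next(fid),
                mz=tmz * (1.0 + ppm * 1e-6),
                rt=true_rt + jit,
                intensities=intensities,
                has_ms2=has_ms2,
                ms2_spectrum=(
                    (comp.standard_spectrum or comp.library_spectrum)
                    if ai == 0 else None
                ),
            )
            features.append(feature)
            manifest["spiked"].append({
                "feature_id": feature.feature_id, "compound": comp.name,
                "adduct": label, "samples": list(spike.samples),
                "true_rt": true_rt, "theoretical_mz": tmz, "ppm_error": ppm,
            })

    def random_far_mz() -> float:
        while True:
            mz = float(rng.uniform(200.0, 2000.0))
            i = np.searchsorted(theo, mz)
            near = theo[max(0, i - 1):i + 1]
            if near.size == 0 or (np.abs(mz - near) / near * 1e6).min() >= spec.decoy_min_ppm:
                return mz

    all_rep_keys = [k for s in spec.samples for k in layout.replicates[s]]
    for _ in range(spec.n_decoys):
        n_cols = int(rng.integers(1, len(all_rep_keys) + 1))
        cols = list(rng.choice(all_rep_keys, size=n_cols, replace=False))
        feature = Feature(
            feature_id=next(fid), mz=random_far_mz(),
            rt=float(rng.uniform(0.5, 16.0)),
            intensities={c: intensity(2e6) for c in cols},
        )
        features.append(feature)
        manifest["decoys"].append(feature.feature_id)

    for _ in range(spec.n_blank_contaminants):
        intensities = {b: intensity(3e6) for b in spec.blanks}
        for key in rng.choice(all_rep_keys, size=2, replace=False):
            intensities[str(key)] = intensity(3e6)
        feature = Feature(
            feature_id=next(fid), mz=random_far_mz(),
            rt=float(rng.uniform(0.5, 16.0)), intensities=intensities,
        )
        features.append(feature)
        manifest["contaminants"].append(feature.feature_id)

    return features, layout, manifest


# ---------------------------------------------------------------------------
# dendrogram pairs
# ---------------------------------------------------------------------------

@dataclass
class TreePairSimSpec:
    """A pair of leaf-matched ultrametric trees with controlled discordance.

    ``discordance`` is the fraction of leaves involved in random label
    transpositions applied to the second tree's underlying distance
    matrix (0 reproduces the first tree exactly).
    """

    n_leaves: int = 12
    discordance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 4:
            raise ValueError("need at least 4 leaves")
        if not 0.0 <= self.discordance <= 1.0:
            raise ValueError("discordance must lie in [0, 1]")


def _random_ultrametric(rng, labels: list[str]) -> pd.DataFrame:
    """Random ultrametric distance matrix from random agglomeration."""
    clusters: list[Node] = [Node.leaf(l) for l in labels]
    heights = np.sort(rng.uniform(0.1, 1.0, size=len(labels) - 1))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = Node.merge(clusters[i], clusters[j], float(h))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return cophenetic_matrix(clusters[0])


def simulate_tree_pair(spec: TreePairSimSpec) -> tuple[Node, Node, dict]:
    """Simulate two leaf-matched dendrograms and the applied perturbation.

    The first tree is the UPGMA of a random ultrametric matrix; the
    second is the UPGMA of the same matrix after the discordance-
    controlled leaf-label transpositions.  The truth dict records the
    transpositions applied.
    """
    rng = _rng(spec.seed, _TREES)
    labels = [f"T{i:02d}" for i in range(spec.n_leaves)]
    U = _random_ultrametric(rng, labels)
    left = upgma(U)

    n_swaps = int(round(spec.discordance * spec.n_leaves))
    perm = {l: l for l in labels}
    swaps = []
    for _ in range(n_swaps):
        a, b = rng.choice(labels, size=2, replace=False)
        perm[a], perm[b] = perm[b], perm[a]
        swaps.append((str(a), str(b)))
    permuted = U.rename(index=perm, columns=perm)
    permuted = permuted.loc[labels, labels]
    right = upgma(permuted)
    return left, right, {"transpositions": swaps}


# ---------------------------------------------------------------------------
# CFU tables
# ---------------------------------------------------------------------------

@dataclass
class CfuPlan:
    """True growth of one organism under one treatment."""

    organism: str
    treatment: str
    fold_change: float
    initial_cfu: float = 1000.0

    def __post_init__(self) -> None:
        if self.fold_change < 0:
            raise ValueError("true fold change must be >= 0")
        if self.initial_cfu <= 0:
            raise ValueError("initial CFU must be > 0")


def default_cfu_plans() -> list[CfuPlan]:
    """Plans emulating the frass competition assay: the entomopathogen
    grows freely alone but is suppressed by either antagonist
    streptomycete, while the streptomycetes are barely affected."""
    return [
        CfuPlan("M_anisopliae", "alone", 15.0),
        CfuPlan("M_anisopliae", "+S_padanus", 1.0),
        CfuPlan("M_anisopliae", "+S_scopuliridis", 1.2),
        CfuPlan("M_anisopliae", "no_frass", 1.0),
        CfuPlan("S_padanus", "alone", 60.0),
        CfuPlan("S_padanus", "+M_anisopliae", 55.0),
        CfuPlan("S_padanus", "no_frass", 1.0),
    ]


def simulate_cfu(
    plans: list[CfuPlan] | None = None,
    dispersion: float = 0.25,
    n_replicates: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a CFU table with lognormal replicate noise around each
    plan's true fold change (eight biological replicates by default)."""
    plans = plans if plans is not None else default_cfu_plans()
    rng = _rng(seed, _CFU)
    rows = []
    for plan in plans:
        for rep in range(1, n_replicates + 1):
            noise = rng.lognormal(0.0, dispersion) if dispersion > 0 else 1.0
            rows.append({
                "organism": plan.organism, "treatment": plan.treatment,
                "replicate": rep, "cfu_initial": plan.initial_cfu,
                "cfu_final": plan.initial_cfu * plan.fold_change * noise,
            })
    return pd.DataFrame(rows)
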