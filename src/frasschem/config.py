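"""Pipeline configuration.

Collects the tolerances and thresholds used across the analysis stages:
mass accuracy (ppm), retention-time co-elution window (minutes), the
presence/absence intensity cutoff, the Bliss-excess classification
threshold, the significance level, and the tanglegram entanglement
exponent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


#: proton mass used for adduct arithmetic, in Da
PROTON_MASS = 1.007276466


@dataclass
class PipelineConfig:
    """Shared knobs for every stage, with assay-standard defaults.

    Parameters
    ----------
    ppm_tol:
        Maximum absolute mass accuracy error for a feature/library match,
        in parts per million (inclusive bound).
    rt_tol_min:
        Retention-time window for adduct co-elution and reference-RT
        matching, in minutes (inclusive bound).
    intensity_threshold:
        Peak intensity strictly above which a feature counts as present
        when binarizing a feature table.
    b_threshold:
        Absolute Bliss excess at or beyond which a significant pair is
        called synergistic/antagonistic.
    alpha:
        Significance level for the interaction t-test.
    entanglement_L:
        Exponent applied to per-leaf position differences in the
        entanglement score.
    adducts:
        Positive-mode adduct labels considered during dereplication.
    seed:
        Root seed for the synthetic-data generators.
    """

    ppm_tol: float = 5.0
    rt_tol_min: float = 0.1
    intensity_threshold: float = 1e6
    b_threshold: float = 0.08
    alpha: float = 0.05
    entanglement_L: float = 1.5
    adducts: list[str] = field(
        default_factory=lambda: ["[M+H]+", "[M+Na]+", "[M+NH4]+", "[M+K]+", "[M+2H]2+"]
    )
    seed: int = 0
    use_solvent_control: bool = False
    pseudoreplication: str = "cross"  # "cross" (all-pairs) or "paired"
    ms2_similarity_min: float = 0.7
    ms2_min_matched: int = 4
    ms2_analog_similarity_min: float = 0.5
    fragment_tol_da: float = 0.02

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "rt_tol_min", "intensity_threshold", "b_threshold",
                     "entanglement_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.pseudoreplication not in ("cross", "paired"):
            raise ValueError("pseudoreplication must be 'cross' or 'paired'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
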