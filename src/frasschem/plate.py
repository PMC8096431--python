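"""Bliss-independence interaction analysis of resazurin plate assays.

The resazurin viability readout gives one fluorescence value per well.
Growth inhibition of a treatment is expressed as the fractional inhibition

    FI = 1 - (T_F - MC_F) / (IC_F - MC_F)

where ``T_F`` is the treatment fluorescence, ``MC_F`` the mean of the
medium (sterility) controls and ``IC_F`` the mean of the inoculum
controls.  Under Bliss independence two inhibitors acting independently
combine to an expected inhibition ``E = FI_A + FI_B - FI_A*FI_B``; the
Bliss excess ``b = E - FI_AB`` measures the departure of the observed
combination from that null, and pairs with ``b >= 0.08`` (``<= -0.08``)
at ``p <= 0.05`` are called synergistic (antagonistic).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

ROLES = ("treatment", "inoculum_control", "medium_control", "solvent_control")

PLATE_COLUMNS = [
    "well_id", "role", "compound_a", "conc_a", "compound_b", "conc_b",
    "replicate", "fluorescence",
]


class DegenerateControlsError(ValueError):
    """Inoculum- and medium-control means coincide; FI is undefined."""


class MissingControlsError(ValueError):
    """The plate lacks one or more required control roles."""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compute_fi(t_f: float, mc_f_mean: float, ic_f_mean: float) -> float:
    """Fractional inhibition of a treatment well.

    The value is deliberately not clipped: FI < 0 indicates growth
    stimulation relative to the inoculum control and FI > 1 fluorescence
    below the sterile-medium background; both propagate into downstream
    means and the Bliss excess.
    """
    if ic_f_mean == mc_f_mean:
        raise DegenerateControlsError(
            "inoculum-control mean equals medium-control mean "
            f"({ic_f_mean!r}); fractional inhibition is undefined"
        )
    return 1.0 - (t_f - mc_f_mean) / (ic_f_mean - mc_f_mean)


def percent_inhibition(fi: float) -> float:
    """Fractional inhibition expressed in percent."""
    if not math.isfinite(fi):
        raise ValueError(f"FI must be finite, got {fi!r}")
    return fi * 100.0


def bliss_expected(fi_a: float, fi_b: float) -> float:
    """Expected combined inhibition of two independently acting compounds."""
    return fi_a + fi_b - fi_a * fi_b


def all_pairs_expected(fi_reps_a: list[float], fi_reps_b: list[float]) -> list[float]:
    """Bliss expectations over the full replicate cross product.

    Row-major order: the first compound's replicates vary in the outer
    loop.  Length is ``len(fi_reps_a) * len(fi_reps_b)``.
    """
    if not fi_reps_a or not fi_reps_b:
        raise ValueError("both replicate lists must be non-empty")
    return [bliss_expected(a, b) for a, b in itertools.product(fi_reps_a, fi_reps_b)]


def bliss_excess(e_bliss_mean: float, fi_ab_mean: float) -> float:
    """Bliss excess b = mean expected minus mean observed combined FI."""
    return e_bliss_mean - fi_ab_mean


def interaction_test(
    e_bliss_values: list[float], fi_ab_reps: list[float]
) -> tuple[float, float]:
    """Welch two-sided t-test comparing expected vs observed combination FI.

    Degenerate cases: two constant, equal samples give ``(0.0, 1.0)``;
    two constant samples whose means differ only within floating-point
    noise are rejected as irresolvable.
    """
    e = np.asarray(e_bliss_values, dtype=float)
    o = np.asarray(fi_ab_reps, dtype=float)
    if e.size < 2 or o.size < 2:
        raise ValueError("need at least 2 values in each sample for a t-test")
    if e.std() == 0.0 and o.std() == 0.0:
        diff = abs(e.mean() - o.mean())
        if diff == 0.0:
            return 0.0, 1.0
        if diff < np.finfo(float).eps * max(1.0, abs(e.mean())):
            raise ValueError(
                "both samples are constant and differ only within machine epsilon"
            )
        return math.copysign(math.inf, e.mean() - o.mean()), 0.0
    t, p = stats.ttest_ind(e, o, equal_var=False)
    return float(t), float(p)


def classify_interaction(
    b: float,
    p: float,
    b_threshold: float = 0.08,
    alpha: float = 0.05,
) -> str:
    """Label a pair synergistic / additive / antagonistic / indeterminate.

    Significant pairs (p <= alpha) are called by the sign and size of the
    Bliss excess; non-significant pairs are additive when |b| is within
    the threshold and indeterminate otherwise (a large but unsupported
    excess is left uncalled rather than silently labelled additive).
    """
    if b_threshold <= 0 or not 0 < alpha < 1:
        raise ValueError("thresholds must be positive and alpha in (0, 1)")
    if p <= alpha:
        if b >= b_threshold:
            return "synergistic"
        if b <= -b_threshold:
            return "antagonistic"
        return "additive"
    return "additive" if abs(b) <= b_threshold else "indeterminate"


# ---------------------------------------------------------------------------
# whole-plate pipeline
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    """Analysis of one compound pair at one concentration combination."""

    pair_key: tuple[str, float, str, float]
    fi_a_mean: float
    fi_b_mean: float
    fi_ab_mean: float
    e_bliss_values: list[float] = field(repr=False)
    e_bliss_mean: float = 0.0
    bliss_excess_b: float = 0.0
    t_stat: float = 0.0
    p_value: float = 1.0
    label: str = "additive"

    def to_dict(self) -> dict:
        a, ca, b, cb = self.pair_key
        return {
            "compound_a": a, "conc_a": ca, "compound_b": b, "conc_b": cb,
            "fi_a_mean": self.fi_a_mean, "fi_b_mean": self.fi_b_mean,
            "fi_ab_mean": self.fi_ab_mean, "e_bliss_mean": self.e_bliss_mean,
            "bliss_excess_b": self.bliss_excess_b, "t_stat": self.t_stat,
            "p_value": self.p_value, "label": self.label,
            "n_expected_values": len(self.e_bliss_values),
        }


def validate_plate(plate: pd.DataFrame) -> None:
    """Check the plate table schema and control/replication invariants."""
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing required columns: {missing}")
    bad_roles = set(plate["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    absent = [r for r in ("inoculum_control", "medium_control")
              if not (plate["role"] == r).any()]
    if absent:
        raise MissingControlsError(f"plate lacks control roles: {absent}")
    treat = plate[plate["role"] == "treatment"]
    if (treat["compound_a"].fillna("") == "").any():
        raise ValueError("every treatment row must name at least one compound")
    if (plate["fluorescence"] < 0).any():
        raise ValueError("fluorescence must be nonnegative")
    counts = treat.groupby(
        ["compound_a", "conc_a", "compound_b", "conc_b"], dropna=False
    ).size()
    low = counts[counts < 2]
    if len(low):
        raise ValueError(f"treatment groups with <2 replicates: {list(low.index)}")


def _normalize(plate: pd.DataFrame) -> pd.DataFrame:
    plate = plate.copy()
    for col in ("compound_a", "compound_b"):
        plate[col] = plate[col].fillna("").astype(str)
    for col in ("conc_a", "conc_b"):
        plate[col] = pd.to_numeric(plate[col], errors="coerce")
    plate["fluorescence"] = pd.to_numeric(plate["fluorescence"])
    return plate


def run_interaction_pipeline(
    plate: pd.DataFrame, config: PipelineConfig | None = None
) -> list[InteractionResult]:
    """Analyse every compound pair on a plate.

    Solo-compound FI replicates are pooled per (compound, concentration)
    and crossed into the Bliss expectation for each pair group present.
    Solvent-control wells are summarized for QC only (they may substitute
    for the inoculum control via ``config.use_solvent_control``) and never
    enter pair classification.
    """
    config = config or PipelineConfig()
    plate = _normalize(plate)
    validate_plate(plate)

    mc_mean = plate.loc[plate["role"] == "medium_control", "fluorescence"].mean()
    ic_role = "solvent_control" if config.use_solvent_control else "inoculum_control"
    ic_rows = plate.loc[plate["role"] == ic_role, "fluorescence"]
    if ic_rows.empty:
        raise MissingControlsError(f"plate lacks control roles: ['{ic_role}']")
    ic_mean = ic_rows.mean()
    if ic_mean == mc_mean:
        raise DegenerateControlsError(
            f"mean fluorescence of '{ic_role}' equals that of 'medium_control'"
        )

    treat = plate[plate["role"] == "treatment"].copy()
    treat["fi"] = [
        compute_fi(f, mc_mean, ic_mean) for f in treat["fluorescence"]
    ]

    def solo_key(comp, conc):
        return (comp, conc)

    solo: dict[tuple, pd.DataFrame] = {}
    pairs: dict[tuple, pd.DataFrame] = {}
    for key, grp in treat.groupby(
        ["compound_a", "conc_a", "compound_b", "conc_b"], dropna=False, sort=True
    ):
        comp_a, conc_a, comp_b, conc_b = key
        grp = grp.sort_values("replicate")
        if comp_b == "" or (isinstance(comp_b, float) and pd.isna(comp_b)):
            solo[solo_key(comp_a, conc_a)] = grp
        else:
            pairs[(comp_a, conc_a, comp_b, conc_b)] = grp

    results = []
    for (comp_a, conc_a, comp_b, conc_b), grp in sorted(pairs.items()):
        try:
            fi_a = solo[solo_key(comp_a, conc_a)]["fi"].tolist()
            fi_b = solo[solo_key(comp_b, conc_b)]["fi"].tolist()
        except KeyError as exc:
            raise ValueError(
                f"pair ({comp_a}@{conc_a}, {comp_b}@{conc_b}) lacks a "
                f"solo-compound group for {exc.args[0]}"
            ) from None
        fi_ab = grp["fi"].tolist()
        if config.pseudoreplication == "paired":
            n = min(len(fi_a), len(fi_b))
            e_vals = [bliss_expected(fi_a[i], fi_b[i]) for i in range(n)]
        else:
            e_vals = all_pairs_expected(fi_a, fi_b)
        e_mean = float(np.mean(e_vals))
        b = bliss_excess(e_mean, float(np.mean(fi_ab)))
        t, p = interaction_test(e_vals, fi_ab)
        label = classify_interaction(b, p, config.b_threshold, config.alpha)
        results.append(InteractionResult(
            pair_key=(comp_a, float(conc_a), comp_b, float(conc_b)),
            fi_a_mean=float(np.mean(fi_a)), fi_b_mean=float(np.mean(fi_b)),
            fi_ab_mean=float(np.mean(fi_ab)), e_bliss_values=e_vals,
            e_bliss_mean=e_mean, bliss_excess_b=b, t_stat=t, p_value=p,
            label=label,
        ))
    return results


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
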