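"""Rule-based LC-MS feature dereplication against a compound library.

Features are matched to library compounds through a configurable
positive-mode adduct list at a ±ppm mass tolerance, supported by adduct
co-elution within a retention-time window, and confirmed at
identification levels 1-3:

* level 1 — retention time and MS2 both match a commercial standard;
* level 2 — MS2 matches a literature/library spectrum;
* level 3 — MS2 is similar to the spectrum of an analog standard.

Environmental (field) samples carry extra evidence requirements: a hit
must appear in the MS/MS run and in all three LC-MS technical replicates;
when MS2 was not triggered in a given sample the hit survives only on
mass/RT agreement plus either two co-eluting adducts or an independently
accepted family member in the same sample, and a compound with no MS2 in
any environmental sample is never accepted.  Polyene macrolides, which
ionize poorly, are instead accepted on an adduct-count pattern across
technical replicates (>=2 adducts in one replicate, >=1 in two others).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PROTON_MASS, PipelineConfig

Spectrum = list[tuple[float, float]]


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode adduct: label, total mass shift (Da) and charge."""

    label: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


DEFAULT_ADDUCTS = (
    AdductSpec("[M+H]+", PROTON_MASS, 1),
    AdductSpec("[M+Na]+", 22.989218, 1),
    AdductSpec("[M+NH4]+", 18.033823, 1),
    AdductSpec("[M+K]+", 38.963158, 1),
    AdductSpec("[M+2H]2+", 2 * PROTON_MASS, 2),
)


@dataclass
class CompoundRecord:
    """A reference compound: identity, family and available evidence."""

    name: str
    family: str
    monoisotopic_mass: float
    is_polyene: bool = False
    reference_rt: float | None = None
    standard_available: bool = False
    standard_spectrum: Spectrum | None = None
    library_spectrum: Spectrum | None = None
    analog_spectrum: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: monoisotopic mass must be > 0")
        if self.reference_rt is not None and not self.standard_available:
            raise ValueError(
                f"{self.name}: reference RT requires an available standard"
            )


@dataclass
class Feature:
    """One aligned LC-MS feature with per-sample intensities."""

    feature_id: str
    mz: float
    rt: float
    intensities: dict[str, float] = field(default_factory=dict)
    has_ms2: dict[str, bool] = field(default_factory=dict)
    ms2_spectrum: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: m/z must be > 0")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError(f"{self.feature_id}: intensities must be >= 0")


@dataclass
class SampleLayout:
    """Maps biological samples to their LC-MS replicate intensity columns.

    ``replicates[sample]`` lists the intensity keys of that sample's
    technical LC-MS replicates; ``msms_run[sample]`` (optional) names the
    intensity key of the separate LC-MS/MS run.
    """

    replicates: dict[str, list[str]]
    msms_run: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.replicates)


@dataclass
class Candidate:
    """A (feature, compound, adduct) mass match awaiting confirmation."""

    feature: Feature
    compound: CompoundRecord
    adduct: AdductSpec
    theoretical_mz: float
    ppm_error: float


# ---------------------------------------------------------------------------
# mass arithmetic and matching
# ---------------------------------------------------------------------------

def theoretical_mz(mass: float, adduct: AdductSpec) -> float:
    """m/z of an adduct ion of a neutral monoisotopic mass."""
    if mass <= 0:
        raise ValueError("monoisotopic mass must be > 0")
    mz = (mass + adduct.mass_shift) / adduct.charge
    if mz <= 0:
        raise ValueError(f"nonpositive m/z for adduct {adduct.label}")
    return mz


def ppm_error(observed_mz: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return (observed_mz - theoretical) / theoretical * 1e6


def match_features(
    features: list[Feature],
    library: list[CompoundRecord],
    adducts: tuple[AdductSpec, ...] = DEFAULT_ADDUCTS,
    ppm_tol: float = 5.0,
) -> list[Candidate]:
    """All (feature, compound, adduct) matches within |ppm| <= ppm_tol.

    Bounds are inclusive; one candidate per matching triple.
    """
    if not library:
        raise ValueError("compound library is empty")
    out = []
    for feat in features:
        for comp in library:
            for add in adducts:
                tmz = theoretical_mz(comp.monoisotopic_mass, add)
                err = ppm_error(feat.mz, tmz)
                if abs(err) <= ppm_tol:
                    out.append(Candidate(feat, comp, add, tmz, err))
    return out


def coeluting_adducts(
    candidate: Candidate,
    candidates: list[Candidate],
    rt_tol: float = 0.1,
) -> list[str]:
    """Distinct adducts of the candidate's compound co-eluting with it.

    Returns the sorted labels of every adduct of the same compound whose
    matched feature lies within ±rt_tol minutes (inclusive) of the
    candidate's retention time; the candidate's own adduct is included
    and counts toward any "at least two adducts" requirement.
    """
    labels = set()
    for other in candidates:
        if other.compound.name != candidate.compound.name:
            continue
        if abs(other.feature.rt - candidate.feature.rt) <= rt_tol:
            labels.add(other.adduct.label)
    labels.add(candidate.adduct.label)
    return sorted(labels)


# ---------------------------------------------------------------------------
# MS2 similarity
# ---------------------------------------------------------------------------

def spectral_similarity(
    spec_a: Spectrum, spec_b: Spectrum, frag_tol: float = 0.02
) -> float:
    """Cosine similarity of two stick spectra with sqrt-scaled intensities.

    Fragment pairs within ``frag_tol`` Da are matched greedily in order of
    decreasing intensity product, each fragment used at most once; the
    matched products are normalized by the full spectral norms, so the
    score lies in [0, 1] and is symmetric in its arguments.
    """
    if not spec_a or not spec_b:
        raise ValueError("spectra must be non-empty")
    wa = [(mz, math.sqrt(i)) for mz, i in spec_a]
    wb = [(mz, math.sqrt(i)) for mz, i in spec_b]
    na = math.sqrt(sum(w * w for _, w in wa))
    nb = math.sqrt(sum(w * w for _, w in wb))
    if na == 0 or nb == 0:
        return 0.0
    pairs = [
        (ia * ib, min(mza, mzb), max(mza, mzb), i, j)
        for i, (mza, ia) in enumerate(wa)
        for j, (mzb, ib) in enumerate(wb)
        if abs(mza - mzb) <= frag_tol
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    for prod, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += prod
    return min(score / (na * nb), 1.0)


def count_matched_fragments(
    spec_a: Spectrum, spec_b: Spectrum, frag_tol: float = 0.02
) -> int:
    """Number of greedily matched fragment pairs (same matching as above)."""
    if not spec_a or not spec_b:
        return 0
    pairs = [
        (ia * ib, min(mza, mzb), max(mza, mzb), i, j)
        for i, (mza, ia) in enumerate(spec_a)
        for j, (mzb, ib) in enumerate(spec_b)
        if abs(mza - mzb) <= frag_tol
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    n = 0
    for _, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n += 1
    return n


# ---------------------------------------------------------------------------
# identification levels and validation rules
# ---------------------------------------------------------------------------

@dataclass
class Ms2Evidence:
    """MS2/RT comparison of a candidate against its compound's references."""

    rt_match: bool = False
    standard_similarity: float = 0.0
    standard_matched: int = 0
    library_similarity: float = 0.0
    library_matched: int = 0
    analog_similarity: float = 0.0


def evaluate_ms2(
    candidate: Candidate, config: PipelineConfig | None = None
) -> Ms2Evidence:
    """Score a candidate's MS2 spectrum against every available reference."""
    config = config or PipelineConfig()
    comp = candidate.compound
    ev = Ms2Evidence()
    if comp.reference_rt is not None:
        ev.rt_match = abs(candidate.feature.rt - comp.reference_rt) <= config.rt_tol_min
    spec = candidate.feature.ms2_spectrum
    if not spec:
        return ev
    tol = config.fragment_tol_da
    if comp.standard_spectrum:
        ev.standard_similarity = spectral_similarity(spec, comp.standard_spectrum, tol)
        ev.standard_matched = count_matched_fragments(spec, comp.standard_spectrum, tol)
    if comp.library_spectrum:
        ev.library_similarity = spectral_similarity(spec, comp.library_spectrum, tol)
        ev.library_matched = count_matched_fragments(spec, comp.library_spectrum, tol)
    if comp.analog_spectrum:
        ev.analog_similarity = spectral_similarity(spec, comp.analog_spectrum, tol)
    return ev


def assign_id_level(
    candidate: Candidate,
    evidence: Ms2Evidence,
    config: PipelineConfig | None = None,
) -> int | None:
    """Identification level from MS2/RT evidence, or None when MS2 fails.

    ``None`` means the candidate proceeds to the no-MS2 evidence rules
    (environmental contexts) or is rejected (culture extracts).
    """
    config = config or PipelineConfig()
    comp = candidate.compound
    if (
        comp.standard_available
        and evidence.rt_match
        and evidence.standard_similarity >= config.ms2_similarity_min
        and evidence.standard_matched >= config.ms2_min_matched
    ):
        return 1
    if (
        evidence.library_similarity >= config.ms2_similarity_min
        and evidence.library_matched >= config.ms2_min_matched
    ):
        return 2
    if evidence.analog_similarity >= config.ms2_analog_similarity_min:
        return 3
    return None


@dataclass
class EnvironmentalEvidence:
    """Per-sample presence evidence for an environmental-context hit."""

    in_msms_run: bool
    n_lcms_replicates: int      # technical replicates the feature is detected in
    n_technical_replicates: int = 3
    ms2_in_sample: bool = False
    ms2_in_any_sample: bool = False
    rt_ppm_ok: bool = True
    n_coeluting_adducts: int = 1
    family_member_present: bool = False


def validate_environmental(
    candidate: Candidate,
    evidence: EnvironmentalEvidence,
    allow_nonstandard_replicates: bool = False,
) -> bool:
    """Accept or reject an environmental hit for one sample.

    With MS2 triggered in the sample, acceptance requires presence in the
    MS/MS run and in all three LC-MS technical replicates.  Without MS2 in
    this sample (but with MS2 somewhere among the environmental samples),
    mass and RT agreement plus either two co-eluting adducts or a
    same-family compound in the sample suffice.  A compound with no MS2 in
    any environmental sample is rejected outright.
    """
    if evidence.n_technical_replicates != 3 and not allow_nonstandard_replicates:
        raise ValueError(
            f"expected 3 LC-MS technical replicates, got "
            f"{evidence.n_technical_replicates}; pass "
            "allow_nonstandard_replicates=True to override"
        )
    if not evidence.ms2_in_any_sample:
        return False
    if evidence.ms2_in_sample:
        return (
            evidence.in_msms_run
            and evidence.n_lcms_replicates == evidence.n_technical_replicates
        )
    return evidence.rt_ppm_ok and (
        evidence.n_coeluting_adducts >= 2 or evidence.family_member_present
    )


def validate_polyene(
    candidate: Candidate | None,
    adduct_counts_per_replicate: list[int],
    rt_ppm_ok: bool = True,
) -> bool:
    """Relaxed acceptance rule for polyene macrolides.

    Requires mass/RT agreement, at least two distinct adducts in one
    technical replicate, and at least one adduct in two *other*
    replicates.
    """
    if candidate is not None and not candidate.compound.is_polyene:
        raise ValueError(
            f"{candidate.compound.name} is not a polyene; rule does not apply"
        )
    if not rt_ppm_ok:
        return False
    counts = list(adduct_counts_per_replicate)
    if not counts or max(counts) < 2:
        return False
    anchor = counts.index(max(counts))
    others = counts[:anchor] + counts[anchor + 1:]
    return sum(1 for c in others if c >= 1) >= 2


# ---------------------------------------------------------------------------
# full annotation pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnnotationHit:
    """A confirmed (or rejected) feature annotation with its evidence."""

    feature_id: str
    compound: str
    family: str
    adduct: str
    ppm_error: float
    matched_adducts: list[str]
    id_level: int | str          # 1, 2, 3 or "rejected"
    context: str
    sample_evidence: dict[str, dict] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.id_level in (1, 2, 3)

    def to_dict(self) -> dict:
        d = {
            "feature_id": self.feature_id, "compound": self.compound,
            "family": self.family, "adduct": self.adduct,
            "ppm_error": self.ppm_error,
            "matched_adducts": ";".join(self.matched_adducts),
            "id_level": self.id_level, "context": self.context,
        }
        return d


def _detected(feature: Feature, key: str, threshold: float) -> bool:
    return feature.intensities.get(key, 0.0) > threshold


def annotate(
    features: list[Feature],
    library: list[CompoundRecord],
    adducts: tuple[AdductSpec, ...] = DEFAULT_ADDUCTS,
    config: PipelineConfig | None = None,
    context: str = "culture_extract",
    layout: SampleLayout | None = None,
    detection_threshold: float = 0.0,
) -> list[AnnotationHit]:
    """Run the full dereplication pipeline on a feature table.

    Deterministic: candidates are evaluated in a fixed order, and
    family-member co-detection considers only hits already accepted on
    stronger evidence (single pass, decreasing evidence order), so no
    circular bootstrapping can occur.
    """
    config = config or PipelineConfig()
    if context not in ("culture_extract", "environmental"):
        raise ValueError(f"unknown context: {context}")
    candidates = match_features(features, library, adducts, config.ppm_tol)
    candidates.sort(key=lambda c: (c.compound.name, c.feature.feature_id, c.adduct.label))

    # pre-compute co-elution and MS2 evidence per candidate
    coelution = {
        id(c): coeluting_adducts(c, candidates, config.rt_tol_min) for c in candidates
    }
    ms2_ev = {id(c): evaluate_ms2(c, config) for c in candidates}
    base_level = {
        id(c): assign_id_level(c, ms2_ev[id(c)], config) for c in candidates
    }

    if context == "culture_extract":
        hits = []
        for c in candidates:
            level = base_level[id(c)]
            hits.append(AnnotationHit(
                feature_id=c.feature.feature_id, compound=c.compound.name,
                family=c.compound.family, adduct=c.adduct.label,
                ppm_error=c.ppm_error, matched_adducts=coelution[id(c)],
                id_level=level if level is not None else "rejected",
                context=context,
            ))
        return hits

    if layout is None:
        raise ValueError("environmental context requires a SampleLayout")

    # global rule: MS2 somewhere among the environmental samples, per compound
    ms2_any: dict[str, bool] = {}
    for c in candidates:
        if c.feature.ms2_spectrum and any(c.feature.has_ms2.values()):
            ms2_any[c.compound.name] = True

    # replicate-level adduct counts per (compound, sample) for the polyene rule
    def polyene_counts(comp_name: str, sample: str) -> list[int]:
        counts = []
        for rep_key in layout.replicates[sample]:
            adds = {
                c.adduct.label
                for c in candidates
                if c.compound.name == comp_name
                and _detected(c.feature, rep_key, detection_threshold)
            }
            counts.append(len(adds))
        return counts

    # first pass: hits standing on their own evidence (MS2-based)
    accepted_families: dict[str, set[str]] = {s: set() for s in layout.samples}
    deferred = []
    hits: list[AnnotationHit] = []

    def evaluate(c: Candidate, family_ok: dict[str, bool]) -> AnnotationHit:
        level = base_level[id(c)]
        sample_ev = {}
        accepted_samples = []
        per_sample_level: dict[str, int] = {}
        for sample in layout.samples:
            reps = layout.replicates[sample]
            n_det = sum(_detected(c.feature, r, detection_threshold) for r in reps)
            msms_key = layout.msms_run.get(sample)
            in_msms = (
                _detected(c.feature, msms_key, detection_threshold)
                if msms_key is not None
                else bool(c.feature.has_ms2.get(sample, False))
            )
            ms2_here = bool(c.feature.has_ms2.get(sample, False)) and bool(
                c.feature.ms2_spectrum
            )
            ev = EnvironmentalEvidence(
                in_msms_run=in_msms,
                n_lcms_replicates=n_det,
                n_technical_replicates=len(reps),
                ms2_in_sample=ms2_here,
                ms2_in_any_sample=ms2_any.get(c.compound.name, False),
                rt_ppm_ok=abs(c.ppm_error) <= config.ppm_tol,
                n_coeluting_adducts=len(coelution[id(c)]),
                family_member_present=family_ok.get(sample, False),
            )
            if c.compound.is_polyene:
                ok = ev.ms2_in_any_sample and validate_polyene(
                    c, polyene_counts(c.compound.name, sample), ev.rt_ppm_ok
                )
            else:
                ok = validate_environmental(c, ev, allow_nonstandard_replicates=True)
            sample_ev[sample] = {
                "in_msms_run": ev.in_msms_run,
                "n_lcms_replicates": ev.n_lcms_replicates,
                "ms2_match": ms2_here and level is not None,
                "family_member_present": ev.family_member_present,
                "accepted": ok,
            }
            if ok:
                accepted_samples.append(sample)
                if ms2_here and level is not None:
                    per_sample_level[sample] = level
                else:
                    # no MS2 in this sample: level 2 with a reference
                    # spectrum available, otherwise 3
                    has_ref = bool(
                        c.compound.standard_spectrum or c.compound.library_spectrum
                    )
                    per_sample_level[sample] = 2 if has_ref else 3
        if accepted_samples:
            final_level: int | str = min(per_sample_level.values())
        else:
            final_level = "rejected"
        return AnnotationHit(
            feature_id=c.feature.feature_id, compound=c.compound.name,
            family=c.compound.family, adduct=c.adduct.label,
            ppm_error=c.ppm_error, matched_adducts=coelution[id(c)],
            id_level=final_level, context="environmental",
            sample_evidence=sample_ev,
        )

    for c in candidates:
        needs_family = base_level[id(c)] is None and len(coelution[id(c)]) < 2
        if needs_family:
            deferred.append(c)
            continue
        hit = evaluate(c, {})
        hits.append(hit)
        if hit.accepted:
            for sample, ev in hit.sample_evidence.items():
                if ev["accepted"]:
                    accepted_families[sample].add(hit.family)

    # second pass: candidates that can only stand on family co-detection
    for c in deferred:
        family_ok = {
            s: c.compound.family in accepted_families[s] for s in layout.samples
        }
        hits.append(evaluate(c, family_ok))

    hits.sort(key=lambda h: (h.compound, h.feature_id, h.adduct))
    return hits


def hits_to_frame(hits: list[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame([h.to_dict() for h in hits])
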