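"""Mass matching, adduct co-elution, MS2 similarity and evidence rules."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from frasschem.config import PROTON_MASS, PipelineConfig
from frasschem.dereplication import (
    AdductSpec, Candidate, CompoundRecord, DEFAULT_ADDUCTS,
    EnvironmentalEvidence, Feature, annotate, assign_id_level,
    coeluting_adducts, evaluate_ms2, match_features, ppm_error,
    spectral_similarity, theoretical_mz, validate_environmental,
    validate_polyene,
)
from frasschem.simulate import FeatureSimSpec, default_library, simulate_features

MH = AdductSpec("[M+H]+", PROTON_MASS, 1)
MNA = AdductSpec("[M+Na]+", 22.989218, 1)
M2H = AdductSpec("[M+2H]2+", 2 * PROTON_MASS, 2)


def _compound(name="cmpd", mass=500.0, **kw):
    return CompoundRecord(name=name, family="test", monoisotopic_mass=mass, **kw)


def _feature(fid, mz, rt=5.0, **kw):
    return Feature(feature_id=fid, mz=mz, rt=rt, **kw)


# ---------------------------------------------------------------------------
# mass arithmetic
# ---------------------------------------------------------------------------

def test_theoretical_mz():
    assert theoretical_mz(500.0, MH) == pytest.approx(501.007276466)
    assert theoretical_mz(500.0, M2H) == pytest.approx((500 + 2 * PROTON_MASS) / 2)
    assert theoretical_mz(500.0, AdductSpec("[M]+", 0.0, 1)) == 500.0
    with pytest.raises(ValueError):
        theoretical_mz(-1.0, MH)


@pytest.mark.parametrize("obs, theo, expected", [
    (500.0, 500.0, 0.0),
    (500.0025, 500.0, 5.0),
    (499.9975, 500.0, -5.0),
])
def test_ppm_error(obs, theo, expected):
    assert ppm_error(obs, theo) == pytest.approx(expected)


def test_match_features_tolerance_and_boundary():
    comp = _compound(mass=500.0)
    tmz = theoretical_mz(500.0, MH)
    exact = _feature("f1", tmz)
    near = _feature("f2", tmz * (1 + 4.5e-6))
    outside = _feature("f3", tmz * (1 + 6e-6))
    hits = match_features([exact, near, outside], [comp], (MH,), ppm_tol=5)
    assert [c.feature.feature_id for c in hits] == ["f1", "f2"]
    assert hits[0].ppm_error == pytest.approx(0.0, abs=1e-9)
    # the bound is inclusive: a tolerance equal to the feature's own error
    # still admits it
    err = abs(ppm_error(near.mz, tmz))
    assert [c.feature.feature_id
            for c in match_features([near], [comp], (MH,), ppm_tol=err)] == ["f2"]


def test_match_features_empty_library_errors():
    with pytest.raises(ValueError):
        match_features([], [], (MH,))


def test_coeluting_adducts_window():
    comp = _compound(mass=500.0)
    f_h = _feature("h", theoretical_mz(500.0, MH), rt=5.00)
    f_na_near = _feature("na", theoretical_mz(500.0, MNA), rt=5.05)
    f_na_far = _feature("na2", theoretical_mz(500.0, MNA), rt=5.15)
    cands = match_features([f_h, f_na_near], [comp], (MH, MNA))
    primary = next(c for c in cands if c.feature.feature_id == "h")
    assert coeluting_adducts(primary, cands, rt_tol=0.1) == ["[M+H]+", "[M+Na]+"]
    cands_far = match_features([f_h, f_na_far], [comp], (MH, MNA))
    primary = next(c for c in cands_far if c.feature.feature_id == "h")
    assert coeluting_adducts(primary, cands_far, rt_tol=0.1) == ["[M+H]+"]


# ---------------------------------------------------------------------------
# spectral similarity
# ---------------------------------------------------------------------------

def _optimal_cosine(spec_a, spec_b, tol):
    """Exhaustive optimal fragment assignment (sqrt-scaled cosine)."""
    wa = [(mz, np.sqrt(i)) for mz, i in spec_a]
    wb = [(mz, np.sqrt(i)) for mz, i in spec_b]
    na = np.sqrt(sum(w * w for _, w in wa))
    nb = np.sqrt(sum(w * w for _, w in wb))
    gain = np.zeros((len(wa), len(wb)))
    for i, (mza, ia) in enumerate(wa):
        for j, (mzb, ib) in enumerate(wb):
            if abs(mza - mzb) <= tol:
                gain[i, j] = ia * ib
    rows, cols = linear_sum_assignment(-gain)
    return gain[rows, cols].sum() / (na * nb)


def test_spectral_similarity_identity_and_disjoint():
    spec = [(100.0, 1.0), (200.0, 0.5), (300.0, 0.2)]
    assert spectral_similarity(spec, spec) == pytest.approx(1.0)
    other = [(150.0, 1.0), (250.0, 1.0)]
    assert spectral_similarity(spec, other) == 0.0
    with pytest.raises(ValueError):
        spectral_similarity([], spec)


def test_spectral_similarity_matches_optimal_assignment_oracle(rng):
    grid = np.arange(100, 1000, 1.0)  # spacing >> tolerance: unambiguous matching
    for _ in range(50):
        n_a, n_b = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        a = [(float(m), float(rng.uniform(0.1, 1)))
             for m in rng.choice(grid, size=n_a, replace=False)]
        b = [(float(m + rng.uniform(-0.01, 0.01)), float(rng.uniform(0.1, 1)))
             for m in rng.choice(grid, size=n_b, replace=False)]
        got = spectral_similarity(a, b, frag_tol=0.02)
        want = _optimal_cosine(a, b, 0.02)
        assert got == pytest.approx(want, abs=1e-9)
        assert got == pytest.approx(spectral_similarity(b, a, frag_tol=0.02), abs=1e-12)


def test_spectral_similarity_agrees_with_matchms(rng):
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import CosineGreedy

    for _ in range(10):
        mzs = np.sort(rng.choice(np.arange(100, 900, 2.0), size=8, replace=False))
        ia = rng.uniform(0.1, 1.0, size=8)
        ib = rng.uniform(0.1, 1.0, size=8)
        a = list(zip(mzs.tolist(), ia.tolist()))
        b = list(zip(mzs.tolist(), ib.tolist()))
        # feed sqrt-scaled intensities so both sides score the same quantity
        sa = matchms.Spectrum(mz=mzs, intensities=np.sqrt(ia), metadata_harmonization=False)
        sb = matchms.Spectrum(mz=mzs, intensities=np.sqrt(ib), metadata_harmonization=False)
        ref = float(CosineGreedy(tolerance=0.02).pair(sa, sb)["score"])
        assert spectral_similarity(a, b) == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# identification levels
# ---------------------------------------------------------------------------

def _candidate_with_spectrum(comp, rt=5.0, spectrum=None):
    feat = _feature("f", theoretical_mz(comp.monoisotopic_mass, MH), rt=rt)
    feat.ms2_spectrum = spectrum
    return Candidate(feat, comp, MH, feat.mz, 0.0)


SPEC = [(100.0, 1.0), (150.0, 0.8), (220.0, 0.6), (330.0, 0.4), (410.0, 0.2)]


def test_assign_level_1_requires_rt_and_standard_ms2():
    comp = _compound(standard_available=True, reference_rt=5.0,
                     standard_spectrum=SPEC)
    cand = _candidate_with_spectrum(comp, rt=5.05, spectrum=SPEC)
    assert assign_id_level(cand, evaluate_ms2(cand)) == 1
    # outside the RT window the standard match degrades below level 1
    cand_far = _candidate_with_spectrum(comp, rt=5.5, spectrum=SPEC)
    assert assign_id_level(cand_far, evaluate_ms2(cand_far)) != 1


def test_assign_level_2_library_spectrum():
    comp = _compound(library_spectrum=SPEC)
    cand = _candidate_with_spectrum(comp, spectrum=SPEC)
    assert assign_id_level(cand, evaluate_ms2(cand)) == 2


def test_assign_level_3_analog_only():
    comp = _compound(analog_spectrum=SPEC)
    cand = _candidate_with_spectrum(comp, spectrum=SPEC)
    assert assign_id_level(cand, evaluate_ms2(cand)) == 3


def test_assign_level_none_without_ms2():
    comp = _compound(library_spectrum=SPEC)
    cand = _candidate_with_spectrum(comp, spectrum=None)
    assert assign_id_level(cand, evaluate_ms2(cand)) is None


# ---------------------------------------------------------------------------
# environmental and polyene validation
# ---------------------------------------------------------------------------

def _env(**kw):
    defaults = dict(in_msms_run=True, n_lcms_replicates=3,
                    ms2_in_sample=True, ms2_in_any_sample=True)
    defaults.update(kw)
    return EnvironmentalEvidence(**defaults)


def test_environmental_ms2_present_needs_all_replicates():
    assert validate_environmental(None, _env())
    assert not validate_environmental(None, _env(n_lcms_replicates=2))
    assert not validate_environmental(None, _env(in_msms_run=False))


def test_environmental_no_ms2_anywhere_is_never_real():
    ev = _env(ms2_in_sample=False, ms2_in_any_sample=False,
              n_coeluting_adducts=3)
    assert not validate_environmental(None, ev)


def test_environmental_ms2_elsewhere_adduct_or_family_route():
    base = dict(ms2_in_sample=False, ms2_in_any_sample=True)
    assert validate_environmental(None, _env(**base, n_coeluting_adducts=2))
    assert validate_environmental(None, _env(**base, family_member_present=True))
    assert not validate_environmental(None, _env(**base, n_coeluting_adducts=1))
    assert not validate_environmental(
        None, _env(**base, n_coeluting_adducts=2, rt_ppm_ok=False))


def test_environmental_replicate_count_guard():
    with pytest.raises(ValueError, match="technical replicates"):
        validate_environmental(None, _env(n_technical_replicates=2))
    assert validate_environmental(
        None, _env(n_technical_replicates=2, n_lcms_replicates=2),
        allow_nonstandard_replicates=True,
    )


@pytest.mark.parametrize("counts, accepted", [
    ([2, 1, 1], True),
    ([2, 1, 0], False),
    ([1, 1, 1], False),
    ([2, 2, 1], True),
    ([3, 0, 0], False),
])
def test_polyene_adduct_patterns(counts, accepted):
    assert validate_polyene(None, counts) is accepted


def test_polyene_requires_rt_ppm_and_polyene_compound():
    assert not validate_polyene(None, [2, 1, 1], rt_ppm_ok=False)
    comp = _compound(is_polyene=False)
    cand = _candidate_with_spectrum(comp)
    with pytest.raises(ValueError, match="not a polyene"):
        validate_polyene(cand, [2, 1, 1])


def test_accepted_polyene_has_at_least_four_adduct_observations():
    for counts in itertools.product(range(4), repeat=3):
        if validate_polyene(None, list(counts)):
            assert sum(counts) >= 4


# ---------------------------------------------------------------------------
# pipeline properties
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_sim():
    spec = FeatureSimSpec(seed=7, n_decoys=50, n_blank_contaminants=10)
    return spec, *simulate_features(spec)


def test_annotation_deterministic(small_sim):
    spec, features, layout, _ = small_sim
    h1 = annotate(features, spec.library, context="environmental", layout=layout)
    h2 = annotate(features, spec.library, context="environmental", layout=layout)
    assert [(h.feature_id, h.compound, h.id_level) for h in h1] == \
           [(h.feature_id, h.compound, h.id_level) for h in h2]


def test_annotation_monotone_in_ppm_tolerance(small_sim):
    spec, features, layout, _ = small_sim
    accepted = {}
    for tol in (2.0, 5.0, 10.0):
        cfg = PipelineConfig(ppm_tol=tol)
        hits = annotate(features, spec.library, config=cfg,
                        context="environmental", layout=layout)
        accepted[tol] = {(h.feature_id, h.compound) for h in hits if h.accepted}
    assert accepted[2.0] <= accepted[5.0] <= accepted[10.0]


def test_spiked_recall_and_decoy_rejection(small_sim):
    spec, features, layout, manifest = small_sim
    hits = annotate(features, spec.library, context="environmental", layout=layout)
    accepted = {h.feature_id: h for h in hits if h.accepted}
    for item in manifest["spiked"]:
        assert item["feature_id"] in accepted
        assert accepted[item["feature_id"]].compound == item["compound"]
    assert not set(manifest["decoys"]) & set(accepted)


def test_culture_context_requires_ms2(small_sim):
    spec, features, layout, manifest = small_sim
    hits = annotate(features, spec.library, context="culture_extract")
    by_id = {}
    for h in hits:
        by_id.setdefault(h.feature_id, []).append(h)
    primary = [m for m in manifest["spiked"] if m["adduct"] == "[M+H]+"]
    for m in primary:  # MS2-carrying ions are confirmed
        assert any(h.accepted for h in by_id[m["feature_id"]])
    for fid in manifest["decoys"]:  # decoys never even match
        assert fid not in by_id
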