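"""Scoring and matching logic: weighted-cosine MS/MS score against
independent oracles (hand arithmetic, exhaustive assignment, matchms),
trapezoidal RT score properties, pairing and candidate-search windows."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metannot import (
    FragmentPeak,
    LibraryRecord,
    MatchParameters,
    Ms1Feature,
    MsmsSpectrum,
    PeakTable,
    align_fragments,
    annotate,
    find_candidates,
    pair_ms2_to_features,
    ppm_error,
    score_integrate,
    score_msms,
    score_rt,
    spectrum_abundance,
    write_annotations,
)
from metannot.annotation import forward_reverse_cosine

from conftest import weighted_cosine_oracle


def _spectrum(peaks, precursor=300.0, rt=60.0, polarity="negative", sid="s"):
    return MsmsSpectrum(
        spectrum_id=sid, precursor_mz=precursor, rt=rt, polarity=polarity,
        peaks=tuple(FragmentPeak(m, i) for m, i in peaks),
    )


# ---------------------------------------------------------------------------
# score_integrate / score_rt
# ---------------------------------------------------------------------------

def test_integrated_score_worked_example():
    """0.8 x 0.9606 + 0.2 x 1 = 0.96848 (full precision, no rounding)."""
    assert score_integrate(0.9606, 1.0, 0.8, 0.2) == pytest.approx(0.96848, abs=1e-12)


@pytest.mark.parametrize(
    "msms, rt, wm, wr, expected",
    [
        (0.42, 0.99, 1.0, 0.0, 0.42),     # MS/MS-only weighting
        (0.5, 0.5, 0.8, 0.2, 0.5),        # equal scores are a fixed point
        (0.7, None, 0.8, 0.2, 0.7),       # absent RT collapses onto MS/MS
    ],
)
def test_integrated_score_cases(msms, rt, wm, wr, expected):
    assert score_integrate(msms, rt, wm, wr) == pytest.approx(expected)


@pytest.mark.parametrize(
    "delta, expected",
    [(0.0, 1.0), (29.999, 1.0), (30.0, 1.0), (45.0, 0.5), (60.0, 0.0),
     (75.0, 0.0)],
)
def test_rt_trapezoid(delta, expected):
    assert score_rt(100.0 + delta, 100.0, 30.0, 60.0) == pytest.approx(expected)


def test_rt_score_absent_library_rt():
    assert score_rt(100.0, None, 30.0, 60.0) is None


@given(
    d1=st.floats(0, 200, allow_nan=False),
    d2=st.floats(0, 200, allow_nan=False),
)
@settings(max_examples=200, derandomize=True)
def test_rt_score_monotone_nonincreasing(d1, d2):
    lo, hi = sorted([d1, d2])
    s_lo = score_rt(100.0 + lo, 100.0, 30.0, 60.0)
    s_hi = score_rt(100.0 + hi, 100.0, 30.0, 60.0)
    assert 0.0 <= s_hi <= s_lo <= 1.0


def test_rt_score_continuous_at_knots():
    for knot in (30.0, 60.0):
        below = score_rt(100.0 + knot - 1e-9, 100.0, 30.0, 60.0)
        at = score_rt(100.0 + knot, 100.0, 30.0, 60.0)
        above = score_rt(100.0 + knot + 1e-9, 100.0, 30.0, 60.0)
        assert at == pytest.approx(below, abs=1e-6)
        assert at == pytest.approx(above, abs=1e-6)


@given(
    a=st.floats(0, 1), b=st.floats(0, 1),
    c=st.floats(0, 1), d=st.floats(0, 1),
)
@settings(max_examples=200, derandomize=True)
def test_integrated_score_monotone(a, b, c, d):
    lo_m, hi_m = sorted([a, b])
    lo_r, hi_r = sorted([c, d])
    assert score_integrate(hi_m, hi_r, 0.8, 0.2) >= score_integrate(
        lo_m, lo_r, 0.8, 0.2
    ) - 1e-12


# ---------------------------------------------------------------------------
# spectrum_abundance / pairing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "intensities, expected",
    [
        (range(1, 6), 15.0),          # fewer than ten: sum all
        (range(1, 13), 75.0),         # twelve peaks: sum of the ten largest
        ((), 0.0),
    ],
)
def test_spectrum_abundance_top_ten(intensities, expected):
    peaks = [(100.0 + i, float(x)) for i, x in enumerate(intensities)]
    s = _spectrum(peaks) if peaks else _spectrum([(100.0, 0.0)])
    if not peaks:
        s = MsmsSpectrum("e", 300.0, 60.0, "negative", ())
    assert spectrum_abundance(s) == pytest.approx(expected)


def _feature(mz=385.1118, rt=77.0, fid="M386T77"):
    return Ms1Feature(feature_id=fid, mz=mz, rt=rt, intensities={"s1": 1.0})


def _table(*features, polarity="negative"):
    return PeakTable(features=tuple(features), sample_ids=("s1",),
                     polarity=polarity)


def test_pairing_within_windows():
    s = _spectrum([(100, 1.0)], precursor=385.1118, rt=76.2)
    paired = pair_ms2_to_features([s], _table(_feature()), MatchParameters())
    assert paired == {"M386T77": s}


def test_pairing_outside_rt_window():
    s = _spectrum([(100, 1.0)], precursor=385.1118, rt=86.0)  # dRT = 9 s
    assert pair_ms2_to_features([s], _table(_feature()), MatchParameters()) == {}


def test_pairing_picks_most_abundant():
    weak = _spectrum([(100 + i, 100.0) for i in range(10)],
                     precursor=385.1118, rt=76.5, sid="weak")
    strong = _spectrum([(100 + i, 500.0) for i in range(10)],
                       precursor=385.1118, rt=77.5, sid="strong")
    paired = pair_ms2_to_features(
        [weak, strong], _table(_feature()), MatchParameters()
    )
    assert paired["M386T77"].spectrum_id == "strong"


def test_pairing_polarity_mismatch():
    s = _spectrum([(100, 1.0)], polarity="positive")
    with pytest.raises(ValueError, match="polarity"):
        pair_ms2_to_features([s], _table(_feature()), MatchParameters())


def _record(precursor, cid="C1", rt=76.2, peaks=((100.0, 1.0),)):
    return LibraryRecord(
        compound_id=cid, compound_name=cid, precursor_mz=precursor,
        rt=rt, polarity="negative",
        spectrum=_spectrum(peaks, precursor=precursor, rt=rt, sid=cid),
    )


def test_find_candidates_ppm_window():
    lib = [_record(385.1118, "exact"), _record(385.1215, "off")]
    # (385.1215 - 385.1118)/385.1118 * 1e6 = 25.19 ppm > 25
    assert abs(ppm_error(385.1118, 385.1215)) > 25.0
    hits = find_candidates(_feature(), lib, MatchParameters())
    assert [r.compound_id for r in hits] == ["exact"]


def test_find_candidates_empty_library():
    assert find_candidates(_feature(), [], MatchParameters()) == []


# ---------------------------------------------------------------------------
# fragment alignment + MS/MS score
# ---------------------------------------------------------------------------

def test_align_within_tolerance():
    lib = _spectrum([(100.0, 1.0)])
    exp = _spectrum([(100.0005, 1.0)])
    (pair,) = align_fragments(exp, lib, 10.0)
    assert pair.exp_peak is not None
    assert pair.ppm_error == pytest.approx(5.0, abs=0.01)


def test_align_outside_tolerance():
    lib = _spectrum([(100.0, 1.0)])
    exp = _spectrum([(100.002, 1.0)])  # 20 ppm
    (pair,) = align_fragments(exp, lib, 10.0)
    assert pair.exp_peak is None


def test_align_empty_experimental():
    lib = _spectrum([(100.0, 1.0), (200.0, 0.5)])
    exp = MsmsSpectrum("e", 300.0, 60.0, "negative", ())
    pairs = align_fragments(exp, lib, 10.0)
    assert len(pairs) == 2
    assert all(p.exp_peak is None for p in pairs)


def test_msms_score_identical_spectrum(two_peak_lib):
    aligned = align_fragments(two_peak_lib, two_peak_lib, 10.0)
    assert score_msms(aligned, two_peak_lib) == pytest.approx(1.0)


def test_msms_score_disjoint():
    lib = _spectrum([(100.0, 1.0)])
    exp = _spectrum([(300.0, 1.0)])
    aligned = align_fragments(exp, lib, 10.0)
    assert score_msms(aligned, exp) == 0.0


def test_msms_score_two_peak_fixture(two_peak_lib, two_peak_exp):
    """Both cosines match the independent hand-built vector arithmetic:
    lib (100*1.0, 200*0.5) vs exp (100.0005*0.8, 200.001*0.6) ~ 0.9806."""
    expected = weighted_cosine_oracle(
        [100.0, 200.0], [1.0, 0.5], [100.0005, 200.001], [0.8, 0.6]
    )
    assert expected == pytest.approx(0.9806, abs=5e-4)
    aligned = align_fragments(two_peak_exp, two_peak_lib, 10.0)
    fwd, rev = forward_reverse_cosine(aligned, two_peak_exp)
    assert fwd == pytest.approx(expected, abs=1e-9)
    assert rev == pytest.approx(expected, abs=1e-9)
    assert score_msms(aligned, two_peak_exp) == pytest.approx(expected, abs=1e-9)


def test_msms_score_against_matchms(two_peak_lib, two_peak_exp):
    """The forward component agrees with matchms CosineGreedy at
    mz_power = intensity_power = 1 (an independent implementation)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import CosineGreedy

    def to_matchms(s):
        return matchms.Spectrum(
            mz=np.array([p.mz for p in s.peaks]),
            intensities=np.array([p.intensity for p in s.peaks]),
            metadata={"precursor_mz": s.precursor_mz},
            metadata_harmonization=False,
        )

    sim = CosineGreedy(tolerance=0.01, mz_power=1.0, intensity_power=1.0)
    ref = float(sim.pair(to_matchms(two_peak_lib), to_matchms(two_peak_exp))["score"])
    aligned = align_fragments(two_peak_exp, two_peak_lib, 10.0)
    fwd, _ = forward_reverse_cosine(aligned, two_peak_exp)
    assert fwd == pytest.approx(ref, abs=1e-9)


def _exhaustive_forward(lib, exp, tol_ppm):
    """Brute-force maximum forward cosine over all one-to-one assignments
    of library peaks to experimental peaks within tolerance."""
    L, E = lib.peaks, exp.peaks
    wl = [p.mz * p.intensity for p in L]
    we = [p.mz * p.intensity for p in E]
    denom = np.sqrt(sum(w * w for w in wl) * sum(w * w for w in we))
    best = 0.0
    idx_e = list(range(len(E))) + [None] * len(L)
    for perm in itertools.permutations(idx_e, len(L)):
        if any(
            j is not None
            and abs((E[j].mz - L[i].mz) / L[i].mz * 1e6) > tol_ppm
            for i, j in enumerate(perm)
        ):
            continue
        used = [j for j in perm if j is not None]
        if len(used) != len(set(used)):
            continue
        dot = sum(wl[i] * we[j] for i, j in enumerate(perm) if j is not None)
        best = max(best, dot / denom if denom else 0.0)
    return best


def test_greedy_alignment_matches_exhaustive_oracle():
    """On well-separated random fixtures the greedy alignment attains the
    assignment-optimal forward cosine (spectra of <= 6 peaks)."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n_lib = int(rng.integers(2, 6))
        lib_mz = np.sort(rng.uniform(100, 900, n_lib))
        while np.any(np.diff(lib_mz) < 1.0):  # well separated vs 10 ppm tol
            lib_mz = np.sort(rng.uniform(100, 900, n_lib))
        lib = _spectrum([(m, i) for m, i in
                         zip(lib_mz, rng.uniform(0.1, 1.0, n_lib))])
        keep = rng.random(n_lib) < 0.7
        exp_mz = lib_mz[keep] * (1 + rng.normal(0, 3, keep.sum()) / 1e6)
        extra = rng.uniform(100, 900, 2)
        exp = _spectrum(
            [(m, i) for m, i in zip(
                np.concatenate([exp_mz, extra]),
                rng.uniform(0.1, 1.0, keep.sum() + 2),
            )]
        )
        aligned = align_fragments(exp, lib, 10.0)
        fwd, _ = forward_reverse_cosine(aligned, exp)
        assert fwd == pytest.approx(_exhaustive_forward(lib, exp, 10.0), abs=1e-9)


def test_msms_score_scale_invariance(two_peak_lib, two_peak_exp):
    """Scaling all intensities of one spectrum leaves the cosine unchanged."""
    scaled = _spectrum([(p.mz, p.intensity * 7.5) for p in two_peak_exp.peaks])
    a1 = align_fragments(two_peak_exp, two_peak_lib, 10.0)
    a2 = align_fragments(scaled, two_peak_lib, 10.0)
    assert score_msms(a2, scaled) == pytest.approx(
        score_msms(a1, two_peak_exp), abs=1e-12
    )


def test_msms_score_symmetric_under_role_swap(two_peak_lib, two_peak_exp):
    a = align_fragments(two_peak_exp, two_peak_lib, 10.0)
    b = align_fragments(two_peak_lib, two_peak_exp, 10.0)
    assert score_msms(a, two_peak_exp) == pytest.approx(
        score_msms(b, two_peak_lib), abs=1e-9
    )


def test_msms_score_bounds_random():
    rng = np.random.default_rng(13)
    for _ in range(30):
        lib = _spectrum([(m, i) for m, i in zip(
            np.sort(rng.uniform(60, 1200, 8)), rng.uniform(0, 1, 8))])
        exp = _spectrum([(m, i) for m, i in zip(
            np.sort(rng.uniform(60, 1200, 8)), rng.uniform(0, 1, 8))])
        aligned = align_fragments(exp, lib, 10.0)
        s = score_msms(aligned, exp)
        assert 0.0 <= s <= 1.0


# ---------------------------------------------------------------------------
# full annotate()
# ---------------------------------------------------------------------------

def test_annotate_worked_example_shape():
    """A close library match within the RT plateau is retained at rank 1
    with score_integrate = 0.8 * score_msms + 0.2 * 1."""
    peaks = [(138.975, 0.2), (181.0506, 1.0), (223.0612, 0.45)]
    rec = _record(385.1118, "GLCSIN", rt=76.2, peaks=peaks)
    exp = _spectrum(
        [(m * (1 + 3e-6), i * 0.95) for m, i in peaks],
        precursor=385.1118, rt=76.2,
    )
    results = annotate(_table(_feature()), [exp], [rec])
    assert len(results) == 1
    r = results[0]
    assert r.rank == 1
    assert r.score_rt == 1.0
    assert r.score_msms > 0.99
    assert r.score_integrate == pytest.approx(0.8 * r.score_msms + 0.2)


def test_annotate_discards_below_msms_cutoff():
    rec = _record(385.1118, "C1", peaks=[(100.0, 1.0)])
    exp = _spectrum([(300.0, 1.0)], precursor=385.1118, rt=76.2)  # disjoint
    assert annotate(_table(_feature()), [exp], [rec]) == []


def test_annotate_empty_library():
    exp = _spectrum([(100.0, 1.0)], precursor=385.1118, rt=76.2)
    assert annotate(_table(_feature()), [exp], []) == []


def test_annotate_rt_fallback_flag():
    rec = LibraryRecord(
        compound_id="norts", compound_name="norts", precursor_mz=385.1118,
        rt=None, polarity="negative",
        spectrum=_spectrum([(100.0, 1.0)], precursor=385.1118),
    )
    exp = _spectrum([(100.0, 1.0)], precursor=385.1118, rt=76.2)
    (r,) = annotate(_table(_feature()), [exp], [rec])
    assert r.rt_fallback
    assert r.score_rt is None
    assert r.score_integrate == pytest.approx(r.score_msms)


def test_annotate_deterministic_output(tmp_path, small_library):
    from metannot import FixtureSpec, make_synthetic_experiment

    spec = FixtureSpec(seed=11, n_compounds=12, n_decoy_features=4)
    table, spectra, _ = make_synthetic_experiment(small_library, spec)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_annotations(annotate(table, spectra, small_library), p1)
    write_annotations(annotate(table, spectra, small_library), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_match_parameters_weight_renormalization():
    with pytest.warns(UserWarning, match="renormalizing"):
        p = MatchParameters(weight_msms=2.0, weight_rt=0.5)
    assert p.weight_msms + p.weight_rt == pytest.approx(1.0)
    assert p.weight_msms == pytest.approx(0.8)
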