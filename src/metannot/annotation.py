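"""Candidate annotation of MS1 features against a spectral library.

The pipeline: pair each MS1 feature with its most abundant co-eluting
MS2 spectrum, find library candidates by precursor m/z, align fragments
within a ppm tolerance, and score each candidate on three axes:

* ``score_msms`` — mean of the forward and reverse m/z-weighted cosine
  similarities between library and experimental fragment vectors
  (w = intensity x m/z, the NIST-style composite dot product).  The
  forward match spans the union of library and experimental peaks; the
  reverse match is restricted to library peaks that found an
  experimental counterpart.
* ``score_rt`` — a trapezoidal retention-time agreement score: 1 below
  the minimum tolerance, 0 above the maximum, linear in between.
* ``score_integrate`` — the user-weighted linear combination of the two.

Candidates below the MS/MS or integrated cutoff are discarded; survivors
are ranked per feature by descending integrated score.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectral_io import (
    FragmentPeak,
    LibraryRecord,
    Ms1Feature,
    MsmsSpectrum,
    PeakTable,
)

logger = logging.getLogger(__name__)


def ppm_error(observed: float, reference: float) -> float:
    """Relative mass deviation in parts per million: (obs - ref)/ref * 1e6."""
    return (observed - reference) / reference * 1e6


@dataclass
class MatchParameters:
    """All tolerances, weights, and cutoffs governing an annotation run.

    Defaults are the tool's standard operating point for a QTOF platform:
    MS2 spectra attach to MS1 features within +-8 s and +-20 ppm; library
    candidates within +-25 ppm of the feature m/z; fragments align at
    10 ppm; the RT trapezoid ramps from 1 to 0 between 30 s and 60 s;
    the integrated score weights MS/MS 0.8 and RT 0.2; both the MS/MS
    score and the integrated score must reach 0.6; fragments outside
    50-1250 Th are ignored.
    """

    ms2_ms1_rt_tol: float = 8.0          # s
    ms2_ms1_mz_tol_ppm: float = 20.0
    ms1_mz_tol_ppm: float = 25.0
    fragment_tol_ppm: float = 10.0
    rt_tol_min: float = 30.0             # s
    rt_tol_max: float = 60.0             # s
    weight_msms: float = 0.8
    weight_rt: float = 0.2
    msms_score_cutoff: float = 0.6
    integrate_score_cutoff: float = 0.6
    msms_mass_range: tuple[float, float] = (50.0, 1250.0)
    use_rt: bool = True
    use_msms: bool = True

    def __post_init__(self):
        for name in ("ms2_ms1_rt_tol", "ms2_ms1_mz_tol_ppm", "ms1_mz_tol_ppm",
                     "fragment_tol_ppm", "rt_tol_min", "rt_tol_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rt_tol_min > self.rt_tol_max:
            raise ValueError("rt_tol_min must be <= rt_tol_max")
        if self.weight_msms < 0 or self.weight_rt < 0:
            raise ValueError("score weights must be >= 0")
        total = self.weight_msms + self.weight_rt
        if total == 0:
            raise ValueError("at least one score weight must be positive")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"score weights sum to {total:g}; renormalizing to 1",
                stacklevel=2,
            )
            self.weight_msms /= total
            self.weight_rt /= total
        lo, hi = self.msms_mass_range
        if lo >= hi:
            raise ValueError("msms_mass_range must be (low, high) with low < high")

    @classmethod
    def from_yaml(cls, path) -> "MatchParameters":
        """Load parameters from a YAML mapping mirroring the field names."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "msms_mass_range" in data:
            data["msms_mass_range"] = tuple(data["msms_mass_range"])
        return cls(**data)


@dataclass(frozen=True)
class AlignedFragmentPair:
    """A library fragment and, if one matched within tolerance, its
    experimental counterpart with the signed ppm error."""

    lib_peak: FragmentPeak
    exp_peak: FragmentPeak | None = None
    ppm_error: float | None = None


@dataclass(frozen=True)
class AnnotationResult:
    """One candidate annotation for a feature, fully scored."""

    feature_id: str
    compound_id: str
    compound_name: str
    score_msms: float
    score_rt: float | None
    score_integrate: float
    precursor_ppm_error: float
    aligned: tuple[AlignedFragmentPair, ...] = ()
    rank: int = 1
    rt_fallback: bool = False  # True when library RT was absent with use_rt on


def spectrum_abundance(s: MsmsSpectrum) -> float:
    """Cumulative intensity of the ten most intense fragment ions.

    Used to pick the representative MS2 spectrum when several co-elute
    with one feature; spectra with fewer than ten peaks sum them all.
    """
    if not s.peaks:
        return 0.0
    intens = sorted((p.intensity for p in s.peaks), reverse=True)
    return float(sum(intens[:10]))


def pair_ms2_to_features(
    spectra: Sequence[MsmsSpectrum],
    table: PeakTable,
    params: MatchParameters,
) -> dict[str, MsmsSpectrum]:
    """Attach to each MS1 feature its qualifying MS2 spectrum.

    A spectrum qualifies when its precursor lies within
    ``ms2_ms1_mz_tol_ppm`` of the feature m/z and its RT within
    ``ms2_ms1_rt_tol`` seconds of the feature RT.  Of several qualifying
    spectra the most abundant (top-ten cumulative intensity) wins, ties
    broken by spectrum id for determinism.  Features with no qualifying
    spectrum are absent from the returned map.
    """
    bad = {s.polarity for s in spectra} - {table.polarity}
    if bad:
        raise ValueError(
            f"polarity mismatch: table is {table.polarity}, spectra include {sorted(bad)}"
        )
    paired: dict[str, MsmsSpectrum] = {}
    for feat in table.features:
        best = None
        best_key = None
        for s in spectra:
            if abs(s.rt - feat.rt) > params.ms2_ms1_rt_tol:
                continue
            if abs(ppm_error(s.precursor_mz, feat.mz)) > params.ms2_ms1_mz_tol_ppm:
                continue
            key = (-spectrum_abundance(s), s.spectrum_id)
            if best_key is None or key < best_key:
                best, best_key = s, key
        if best is not None:
            paired[feat.feature_id] = best
    return paired


def find_candidates(
    feature: Ms1Feature,
    library: Sequence[LibraryRecord],
    params: MatchParameters,
) -> list[LibraryRecord]:
    """Library records whose precursor lies within ``ms1_mz_tol_ppm`` of
    the feature m/z, sorted by absolute ppm error (ties by compound id)."""
    hits = []
    for rec in library:
        err = ppm_error(feature.mz, rec.precursor_mz)
        if abs(err) <= params.ms1_mz_tol_ppm:
            hits.append((abs(err), rec.compound_id, rec))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [rec for _, _, rec in hits]


def align_fragments(
    exp: MsmsSpectrum,
    lib: MsmsSpectrum,
    fragment_tol_ppm: float,
) -> tuple[AlignedFragmentPair, ...]:
    """Greedy one-to-one fragment alignment.

    Library peaks are processed in descending intensity order; each takes
    the nearest (by ppm) unused experimental peak within tolerance.
    Unmatched library peaks are returned with ``exp_peak=None``.  Pairs
    come back in ascending library m/z order.
    """
    used = [False] * len(exp.peaks)
    assignment: dict[int, tuple[int, float]] = {}
    order = sorted(
        range(len(lib.peaks)),
        key=lambda i: (-lib.peaks[i].intensity, lib.peaks[i].mz),
    )
    for li in order:
        lp = lib.peaks[li]
        best_j, best_err = None, None
        for j, ep in enumerate(exp.peaks):
            if used[j]:
                continue
            err = ppm_error(ep.mz, lp.mz)
            if abs(err) > fragment_tol_ppm:
                continue
            if best_err is None or abs(err) < abs(best_err):
                best_j, best_err = j, err
        if best_j is not None:
            used[best_j] = True
            assignment[li] = (best_j, best_err)
    pairs = []
    for li, lp in enumerate(lib.peaks):
        if li in assignment:
            j, err = assignment[li]
            pairs.append(AlignedFragmentPair(lp, exp.peaks[j], err))
        else:
            pairs.append(AlignedFragmentPair(lp))
    return tuple(pairs)


def _weight(peak: FragmentPeak) -> float:
    return peak.intensity * peak.mz


def forward_reverse_cosine(
    aligned: Sequence[AlignedFragmentPair],
    exp: MsmsSpectrum,
) -> tuple[float, float]:
    """Forward and reverse m/z-weighted cosine similarities.

    Forward: cosine over the union of library peaks and all experimental
    peaks; a peak unmatched on the other side contributes zero there.
    Reverse: cosine restricted to library peaks that matched.  Either
    similarity is 0 when its vectors have zero norm.
    """
    dot = sum(
        _weight(p.lib_peak) * _weight(p.exp_peak)
        for p in aligned
        if p.exp_peak is not None
    )
    lib_norm2 = sum(_weight(p.lib_peak) ** 2 for p in aligned)
    # unmatched experimental peaks widen the forward denominator: the
    # union vector spans all library peaks plus all experimental peaks
    exp_norm2 = sum(_weight(ep) ** 2 for ep in exp.peaks)

    if lib_norm2 == 0 or exp_norm2 == 0:
        forward = 0.0
    else:
        forward = dot / np.sqrt(lib_norm2 * exp_norm2)

    rev_lib2 = sum(
        _weight(p.lib_peak) ** 2 for p in aligned if p.exp_peak is not None
    )
    rev_exp2 = sum(
        _weight(p.exp_peak) ** 2 for p in aligned if p.exp_peak is not None
    )
    if rev_lib2 == 0 or rev_exp2 == 0:
        reverse = 0.0
    else:
        reverse = dot / np.sqrt(rev_lib2 * rev_exp2)
    return float(min(forward, 1.0)), float(min(reverse, 1.0))


def score_msms(
    aligned: Sequence[AlignedFragmentPair],
    exp: MsmsSpectrum,
) -> float:
    """MS/MS similarity: mean of forward and reverse weighted cosines."""
    forward, reverse = forward_reverse_cosine(aligned, exp)
    return (forward + reverse) / 2.0


def score_rt(
    rt_exp: float,
    rt_lib: float | None,
    rt_tol_min: float,
    rt_tol_max: float,
) -> float | None:
    """Trapezoidal retention-time agreement score.

    1 when |dRT| < rt_tol_min, 0 when |dRT| > rt_tol_max, and the linear
    ramp 1 - (|dRT| - min)/(max - min) in between (both knots fall in the
    linear branch).  ``None`` when the library RT is absent, signalling
    the caller to fall back to MS/MS-only scoring.
    """
    if rt_lib is None:
        return None
    delta = abs(rt_exp - rt_lib)
    if delta < rt_tol_min:
        return 1.0
    if delta > rt_tol_max:
        return 0.0
    if rt_tol_max == rt_tol_min:
        return 1.0  # degenerate trapezoid: single knee, |delta| == knot
    return 1.0 - (delta - rt_tol_min) / (rt_tol_max - rt_tol_min)


def score_integrate(
    msms: float,
    rt: float | None,
    weight_msms: float,
    weight_rt: float,
) -> float:
    """Weighted linear combination of the MS/MS and RT scores.

    With an absent RT score the weights collapse onto the MS/MS score.
    """
    total = weight_msms + weight_rt
    if total <= 0:
        raise ValueError("weights must have positive sum")
    if rt is None:
        return msms
    return (weight_msms * msms + weight_rt * rt) / total


def annotate(
    table: PeakTable,
    spectra: Sequence[MsmsSpectrum],
    library: Sequence[LibraryRecord],
    params: MatchParameters | None = None,
) -> list[AnnotationResult]:
    """Full annotation pass over an MS1 peak table.

    For each feature with a paired MS2 spectrum, every library candidate
    within the precursor tolerance is fragment-aligned and scored;
    candidates failing the MS/MS cutoff or the integrated cutoff are
    dropped; the rest are ranked per feature by descending integrated
    score, ties broken by smaller |precursor ppm error| then compound id.
    Features without MS2 yield no annotations.
    """
    if params is None:
        params = MatchParameters()
    lib_bad = {r.polarity for r in library} - {table.polarity}
    if lib_bad:
        raise ValueError(
            f"polarity mismatch: table is {table.polarity}, library includes {sorted(lib_bad)}"
        )
    paired = pair_ms2_to_features(spectra, table, params)
    lo, hi = params.msms_mass_range
    n_candidates = 0

    results: list[AnnotationResult] = []
    for feat in table.features:
        exp = paired.get(feat.feature_id)
        if exp is None:
            continue
        exp_r = exp.restrict_mass_range(lo, hi).normalized()
        per_feature: list[AnnotationResult] = []
        for rec in find_candidates(feat, library, params):
            n_candidates += 1
            lib_r = rec.spectrum.restrict_mass_range(lo, hi).normalized()
            aligned = align_fragments(exp_r, lib_r, params.fragment_tol_ppm)
            s_msms = score_msms(aligned, exp_r) if params.use_msms else 1.0
            if params.use_msms and s_msms < params.msms_score_cutoff:
                continue
            s_rt = (
                score_rt(exp.rt, rec.rt, params.rt_tol_min, params.rt_tol_max)
                if params.use_rt
                else None
            )
            fallback = params.use_rt and s_rt is None
            s_int = score_integrate(s_msms, s_rt, params.weight_msms, params.weight_rt)
            if s_int < params.integrate_score_cutoff:
                continue
            per_feature.append(
                AnnotationResult(
                    feature_id=feat.feature_id,
                    compound_id=rec.compound_id,
                    compound_name=rec.compound_name,
                    score_msms=s_msms,
                    score_rt=s_rt,
                    score_integrate=s_int,
                    precursor_ppm_error=ppm_error(feat.mz, rec.precursor_mz),
                    aligned=aligned,
                    rt_fallback=fallback,
                )
            )
        per_feature.sort(
            key=lambda r: (
                -r.score_integrate,
                abs(r.precursor_ppm_error),
                r.compound_id,
            )
        )
        for rank, res in enumerate(per_feature, start=1):
            results.append(dataclasses.replace(res, rank=rank))
    logger.info(
        "annotate: %d features, %d paired with MS2, %d candidates scored, %d retained",
        len(table.features),
        len(paired),
        n_candidates,
        len(results),
    )
    return results
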