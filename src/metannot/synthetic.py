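"""Synthetic fixtures for every pipeline stage.

The generators emulate a QTOF untargeted-metabolomics run: a standards
library of compounds with 5-20 fragments each in the 50-1250 Th window,
an experiment in which each selected compound yields one MS1 feature and
one MS2 spectrum perturbed by ppm jitter, RT jitter, and multiplicative
intensity noise, plus decoy features with no library counterpart; and a
two-group quantification table with known injected log2 fold changes on
designated metabolites over a log-normal abundance background.

Every generator draws from its own RNG stream derived from
``FixtureSpec.seed`` via ``numpy`` SeedSequence spawn keys (library = 0,
experiment = 1, quant = 2), so adding a generator never perturbs the
output of an existing one and all outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffstats import QuantTable
from .spectral_io import (
    FragmentPeak,
    LibraryRecord,
    Ms1Feature,
    MsmsSpectrum,
    PeakTable,
    synthesize_feature_id,
    write_msp,
)

_STREAM_LIBRARY = 0
_STREAM_EXPERIMENT = 1
_STREAM_QUANT = 2


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study.

    Noise defaults reflect a well-behaved QTOF acquisition: 5 ppm mass
    jitter (instruments are specified to ~10-25 ppm windows), 2 s RT
    jitter against 30-60 s tolerances, 5% multiplicative fragment-
    intensity noise, six biological replicates per group, and 0.3 log2
    units of between-sample abundance noise.
    """

    seed: int = 0
    n_compounds: int = 50
    n_features: int | None = None        # None = one feature per compound
    n_decoy_features: int = 10
    fragment_count_range: tuple[int, int] = (5, 20)
    intensity_noise_sd: float = 0.05
    rt_jitter_sd: float = 2.0            # s
    ppm_jitter_sd: float = 5.0
    group_effect_log2fc: Mapping[str, float] = field(default_factory=dict)
    n_samples_per_group: int = 6
    n_metabolites: int = 200
    quant_noise_sd_log2: float = 0.3
    polarity: str = "negative"
    mass_range: tuple[float, float] = (50.0, 1250.0)

    def __post_init__(self):
        for name in ("intensity_noise_sd", "rt_jitter_sd", "ppm_jitter_sd",
                     "quant_noise_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.fragment_count_range
        if not (1 <= lo <= hi):
            raise ValueError("fragment_count_range must satisfy 1 <= low <= high")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


def make_synthetic_library(
    spec: FixtureSpec,
    msp_path=None,
) -> list[LibraryRecord]:
    """Generate a synthetic standards library.

    Precursor m/z uniform in a margin inside the instrument mass window,
    fragment m/z strictly below the precursor (a product ion cannot
    outweigh its singly-charged precursor), intensities normalised to
    base peak 1, retention times uniform over a 15-minute gradient.
    Optionally writes the library to ``msp_path``.
    """
    rng = spec.rng(_STREAM_LIBRARY)
    lo, hi = spec.mass_range
    records = []
    for i in range(spec.n_compounds):
        precursor = float(rng.uniform(lo + 70.0, hi - 50.0))
        n_frag = int(rng.integers(spec.fragment_count_range[0],
                                  spec.fragment_count_range[1] + 1))
        frag_mz = rng.uniform(lo, precursor - 1.0, size=n_frag)
        frag_int = rng.uniform(0.01, 1.0, size=n_frag)
        frag_int[int(rng.integers(n_frag))] = 1.0  # guarantee a base peak
        rt = float(rng.uniform(30.0, 900.0))
        cid = f"CPD{i + 1:04d}"
        spectrum = MsmsSpectrum(
            spectrum_id=cid,
            precursor_mz=precursor,
            rt=rt,
            polarity=spec.polarity,
            peaks=tuple(
                FragmentPeak(float(m), float(x))
                for m, x in zip(frag_mz, frag_int)
            ),
        ).normalized()
        records.append(
            LibraryRecord(
                compound_id=cid,
                compound_name=f"Synthetic compound {i + 1}",
                precursor_mz=precursor,
                spectrum=spectrum,
                rt=rt,
                polarity=spec.polarity,
                provenance={"synthetic": True},
            )
        )
    if msp_path is not None:
        write_msp(records, msp_path)
    return records


def make_synthetic_experiment(
    library: Sequence[LibraryRecord],
    spec: FixtureSpec,
) -> tuple[PeakTable, list[MsmsSpectrum], pd.DataFrame]:
    """Generate one experiment consistent with a library.

    Each selected compound yields an MS1 feature (precursor m/z with
    Gaussian ppm jitter, RT with Gaussian jitter) and an MS2 spectrum
    (fragment m/z jittered in ppm, intensities scaled by 1 + Gaussian
    noise, truncated at zero).  Decoy features are drawn at least
    100 ppm away from every library precursor and carry random fragment
    spectra, so they can pair with MS2 but match nothing.

    Returns (peak table, MS2 spectra, truth table); truth maps each
    feature id to its generating compound id (empty string for decoys).
    """
    if not library:
        raise ValueError("make_synthetic_experiment needs a non-empty library")
    rng = spec.rng(_STREAM_EXPERIMENT)
    n = spec.n_features if spec.n_features is not None else len(library)
    chosen = [library[i % len(library)] for i in range(n)]

    sample_ids = ("S1", "S2", "S3")
    features: list[Ms1Feature] = []
    spectra: list[MsmsSpectrum] = []
    truth_rows = []
    used_ids: set[str] = set()

    def unique_id(mz: float, rt: float) -> str:
        base = synthesize_feature_id(mz, rt)
        fid, k = base, 1
        while fid in used_ids:
            k += 1
            fid = f"{base}_{k}"
        used_ids.add(fid)
        return fid

    for rec in chosen:
        mz = rec.precursor_mz * (1.0 + rng.normal(0.0, spec.ppm_jitter_sd) / 1e6)
        rt = max(0.0, (rec.rt or 0.0) + rng.normal(0.0, spec.rt_jitter_sd))
        fid = unique_id(mz, rt)
        features.append(
            Ms1Feature(
                feature_id=fid,
                mz=mz,
                rt=rt,
                intensities={
                    s: float(rng.lognormal(10.0, 1.0)) for s in sample_ids
                },
            )
        )
        jittered = []
        for p in rec.spectrum.peaks:
            pm = p.mz * (1.0 + rng.normal(0.0, spec.ppm_jitter_sd) / 1e6)
            pi = max(0.0, p.intensity * (1.0 + rng.normal(0.0, spec.intensity_noise_sd)))
            jittered.append(FragmentPeak(pm, pi))
        # MS2 precursor and RT stay well inside the +-20 ppm / +-8 s
        # pairing window around the feature
        spectra.append(
            MsmsSpectrum(
                spectrum_id=f"scan_{fid}",
                precursor_mz=mz * (1.0 + rng.normal(0.0, 1.0) / 1e6),
                rt=max(0.0, rt + rng.normal(0.0, 1.0)),
                polarity=spec.polarity,
                peaks=tuple(jittered),
            ).normalized()
        )
        truth_rows.append((fid, rec.compound_id))

    lib_mz = np.array([r.precursor_mz for r in library])
    lo, hi = spec.mass_range
    for _ in range(spec.n_decoy_features):
        while True:
            mz = float(rng.uniform(lo + 70.0, hi - 50.0))
            if np.min(np.abs(mz - lib_mz) / lib_mz) * 1e6 > 100.0:
                break
        rt = float(rng.uniform(30.0, 900.0))
        fid = unique_id(mz, rt)
        features.append(
            Ms1Feature(
                feature_id=fid,
                mz=mz,
                rt=rt,
                intensities={s: float(rng.lognormal(9.0, 1.0)) for s in sample_ids},
            )
        )
        n_frag = int(rng.integers(5, 12))
        spectra.append(
            MsmsSpectrum(
                spectrum_id=f"scan_{fid}",
                precursor_mz=mz,
                rt=rt,
                polarity=spec.polarity,
                peaks=tuple(
                    FragmentPeak(float(m), float(x))
                    for m, x in zip(
                        rng.uniform(lo, mz - 1.0, size=n_frag),
                        rng.uniform(0.05, 1.0, size=n_frag),
                    )
                ),
            ).normalized()
        )
        truth_rows.append((fid, ""))

    table = PeakTable(
        features=tuple(features),
        sample_ids=sample_ids,
        polarity=spec.polarity,
    )
    truth = pd.DataFrame(truth_rows, columns=["feature_id", "compound_id"])
    return table, spectra, truth


def make_synthetic_quant(spec: FixtureSpec) -> tuple[QuantTable, pd.Series]:
    """Generate a two-group quantification table with injected effects.

    Baseline abundances are log-normal: per-metabolite log2 means
    uniform in [10, 20], per-sample Gaussian noise of
    ``quant_noise_sd_log2`` log2 units.  Metabolites named in
    ``group_effect_log2fc`` get half the effect subtracted from group
    "control" and half added to group "treated".  Returns the table and
    the truth Series of injected log2 fold changes (0 for nulls).
    """
    rng = spec.rng(_STREAM_QUANT)
    metabolites = [f"MET{i + 1:04d}" for i in range(spec.n_metabolites)]
    effects = pd.Series(0.0, index=metabolites)
    for met, eff in spec.group_effect_log2fc.items():
        if met not in effects.index:
            raise ValueError(f"unknown metabolite in group_effect_log2fc: {met}")
        effects[met] = eff

    n = spec.n_samples_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"trt_{i + 1}" for i in range(n)]
    groups = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}

    base = rng.uniform(10.0, 20.0, size=spec.n_metabolites)
    shift = effects.to_numpy() / 2.0
    log2_means = np.concatenate(
        [
            np.tile((base - shift)[:, None], (1, n)),
            np.tile((base + shift)[:, None], (1, n)),
        ],
        axis=1,
    )
    noise = rng.normal(0.0, spec.quant_noise_sd_log2, size=log2_means.shape)
    values = pd.DataFrame(
        np.exp2(log2_means + noise), index=metabolites, columns=samples
    )
    return QuantTable(values=values, groups=groups), effects
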