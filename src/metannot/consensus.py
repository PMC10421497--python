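"""Consensus MS2 library construction from replicate acquisitions.

A standards library is built by acquiring many MS2 spectra per compound
(across collision energies), clustering them by spectral similarity, and
collapsing the dominant cluster into one consensus spectrum per compound
and polarity.  Similarity is the same m/z-weighted cosine ("dot product",
DP) used for annotation, and replicate clusters are merged only while
their average DP stays strictly above the threshold (default 0.8).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation import align_fragments, forward_reverse_cosine
from .spectral_io import FragmentPeak, LibraryRecord, MsmsSpectrum

logger = logging.getLogger(__name__)

#: Replicate count below which a compound is flagged as under-replicated.
MIN_REPLICATES = 16


@dataclass
class ReplicateSet:
    """Replicate MS2 acquisitions of one compound in one polarity."""

    compound_id: str
    polarity: str
    spectra: list[MsmsSpectrum]
    compound_name: str | None = None
    rt_values: list[float] = field(default_factory=list)

    def __post_init__(self):
        bad = {s.polarity for s in self.spectra} - {self.polarity}
        if bad:
            raise ValueError(
                f"{self.compound_id}: replicate polarity mismatch {sorted(bad)}"
            )
        if not self.rt_values:
            self.rt_values = [s.rt for s in self.spectra]
        if self.compound_name is None:
            self.compound_name = self.compound_id


@dataclass(frozen=True)
class ConsensusSpectrum:
    """A consensus MS2 spectrum plus provenance of its construction."""

    spectrum: MsmsSpectrum
    n_members: int
    dp_threshold_used: float
    rt_consensus: float

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def pairwise_dp(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    fragment_tol_ppm: float = 10.0,
) -> float:
    """m/z-weighted cosine similarity between two spectra.

    Identical to the forward component of the annotation MS/MS score
    (single code path), with ``a`` in the library role.
    """
    aligned = align_fragments(b.normalized(), a.normalized(), fragment_tol_ppm)
    forward, _ = forward_reverse_cosine(aligned, b.normalized())
    return forward


def cluster_spectra(
    spectra: Sequence[MsmsSpectrum],
    dp_threshold: float = 0.8,
    fragment_tol_ppm: float = 10.0,
) -> list[list[MsmsSpectrum]]:
    """Average-linkage agglomerative clustering on 1 - DP distance.

    Clusters are merged only while the average pairwise DP stays strictly
    above ``dp_threshold`` (a pair at exactly the threshold stays
    separate).  Singletons are allowed.  Clusters are returned largest
    first (ties by first-occurring member, so the result is invariant to
    input order as a set of sets).
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cluster_spectra needs at least one spectrum")
    if len(spectra) == 1:
        return [[spectra[0]]]

    n = len(spectra)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_dp(spectra[i], spectra[j], fragment_tol_ppm)
            dist[i, j] = dist[j, i] = max(d, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    # strict DP > threshold: merge only at distance strictly below 1 - thr
    cut = (1.0 - dp_threshold) - 1e-12
    labels = fcluster(z, t=cut, criterion="distance")

    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    return [[spectra[i] for i in g] for g in ordered]


def build_consensus(
    cluster: Sequence[MsmsSpectrum],
    fragment_tol_ppm: float = 10.0,
    min_presence: float = 0.5,
    dp_threshold: float = 0.8,
) -> ConsensusSpectrum:
    """Collapse a cluster of replicate spectra into one consensus spectrum.

    Pooled fragments are grouped greedily along the m/z axis at
    ``fragment_tol_ppm``; a consensus peak is emitted when its fragment
    appears in at least ``min_presence`` of the members, with
    intensity-weighted mean m/z and mean member intensity (an absent
    member contributes 0 to the mean).  The result is renormalised to
    base peak 1.
    """
    cluster = [s.normalized() for s in cluster]
    if not cluster:
        raise ValueError("cannot build a consensus from an empty cluster")
    n_members = len(cluster)

    pooled = sorted(
        (p.mz, p.intensity, m)
        for m, s in enumerate(cluster)
        for p in s.peaks
    )
    groups: list[list[tuple[float, float, int]]] = []
    for item in pooled:
        if groups:
            g = groups[-1]
            mean_mz = sum(mz * it for mz, it, _ in g) / max(
                sum(it for _, it, _ in g), 1e-300
            )
            if abs(item[0] - mean_mz) / mean_mz * 1e6 <= fragment_tol_ppm:
                g.append(item)
                continue
        groups.append([item])

    peaks = []
    for g in groups:
        members = {m for _, _, m in g}
        if len(members) / n_members < min_presence:
            continue
        w = sum(it for _, it, _ in g)
        mz = sum(mz * it for mz, it, _ in g) / max(w, 1e-300)
        intensity = sum(it for _, it, _ in g) / n_members
        peaks.append(FragmentPeak(mz, intensity))
    template = cluster[0]
    spectrum = MsmsSpectrum(
        spectrum_id=f"consensus_{template.spectrum_id}",
        precursor_mz=float(median(s.precursor_mz for s in cluster)),
        rt=float(median(s.rt for s in cluster)),
        polarity=template.polarity,
        peaks=tuple(peaks),
        metadata={"n_members": n_members},
    ).normalized()
    return ConsensusSpectrum(
        spectrum=spectrum,
        n_members=n_members,
        dp_threshold_used=dp_threshold,
        rt_consensus=float(median(s.rt for s in cluster)),
    )


def build_library(
    replicates: Sequence[ReplicateSet],
    dp_threshold: float = 0.8,
    fragment_tol_ppm: float = 10.0,
    min_presence: float = 0.5,
) -> list[LibraryRecord]:
    """Build one consensus library record per compound.

    Replicates are clustered at ``dp_threshold``; the largest cluster is
    collapsed to the consensus spectrum; the record RT is the median of
    all replicate RTs.  A warning is emitted for compounds with fewer
    than 16 replicate spectra.
    """
    records = []
    for rep in replicates:
        if not rep.spectra:
            warnings.warn(f"{rep.compound_id}: no replicate spectra; skipped",
                          stacklevel=2)
            continue
        if len(rep.spectra) < MIN_REPLICATES:
            warnings.warn(
                f"{rep.compound_id}: only {len(rep.spectra)} replicate spectra "
                f"(recommended >= {MIN_REPLICATES})",
                stacklevel=2,
            )
        clusters = cluster_spectra(rep.spectra, dp_threshold, fragment_tol_ppm)
        consensus = build_consensus(
            clusters[0], fragment_tol_ppm, min_presence, dp_threshold
        )
        energies = sorted(
            {
                str(s.metadata.get("collision_energy", s.metadata.get("CE", "")))
                for s in rep.spectra
                if s.metadata.get("collision_energy") or s.metadata.get("CE")
            }
        )
        precursor = float(median(s.precursor_mz for s in rep.spectra))
        records.append(
            LibraryRecord(
                compound_id=rep.compound_id,
                compound_name=rep.compound_name or rep.compound_id,
                precursor_mz=precursor,
                spectrum=consensus.spectrum,
                rt=float(median(rep.rt_values)) if rep.rt_values else None,
                polarity=rep.polarity,
                provenance={
                    "n_members": consensus.n_members,
                    "n_replicates": len(rep.spectra),
                    "dp_threshold": dp_threshold,
                    "collision_energies": ",".join(energies),
                },
            )
        )
    logger.info("build_library: %d compounds -> %d records",
                len(replicates), len(records))
    return records
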