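"""Domain types and file I/O for LC-MS annotation.

Reads and writes the text formats an untargeted-metabolomics annotation
run touches: MGF (Mascot generic format) for experimental MS2 spectra,
MSP (NIST text format) for spectral libraries, and CSV for MS1 peak
tables and annotation output.

All retention times are held internally in **seconds**; minute-valued
inputs are converted at the parsing boundary.  All fragment intensities
in library records are normalised so the base peak equals 1.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POLARITIES = ("positive", "negative")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class FragmentPeak(NamedTuple):
    """A single product-ion peak: m/z in Th, non-negative intensity."""

    mz: float
    intensity: float


def _clean_peaks(peaks: Iterable[FragmentPeak]) -> tuple[FragmentPeak, ...]:
    """Sort by m/z and merge exact-duplicate m/z values by summing intensity."""
    merged: dict[float, float] = {}
    for p in peaks:
        if p.mz <= 0:
            raise ValueError(f"fragment m/z must be positive, got {p.mz}")
        if p.intensity < 0:
            raise ValueError(f"fragment intensity must be >= 0, got {p.intensity}")
        merged[p.mz] = merged.get(p.mz, 0.0) + p.intensity
    return tuple(FragmentPeak(mz, i) for mz, i in sorted(merged.items()))


@dataclass(frozen=True)
class MsmsSpectrum:
    """An MS2 (product-ion) spectrum.

    Parameters
    ----------
    spectrum_id : opaque identifier (e.g. the MGF TITLE).
    precursor_mz : m/z of the fragmented precursor ion, in Th.
    rt : retention time in seconds (>= 0).
    polarity : ``"positive"`` or ``"negative"`` ionisation mode.
    peaks : fragment peaks; stored sorted by ascending m/z with
        exact-duplicate m/z merged by intensity summation.
    metadata : free-form key/value map (collision energy, title, ...).
    """

    spectrum_id: str
    precursor_mz: float
    rt: float
    polarity: str = "positive"
    peaks: tuple[FragmentPeak, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if self.rt < 0:
            raise ValueError("rt must be >= 0")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        object.__setattr__(self, "peaks", _clean_peaks(self.peaks))

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def normalized(self) -> "MsmsSpectrum":
        """Rescale intensities so the base (most intense) peak equals 1."""
        if not self.peaks:
            return self
        top = max(p.intensity for p in self.peaks)
        if top == 0 or top == 1.0:
            return self
        return replace(
            self,
            peaks=tuple(FragmentPeak(p.mz, p.intensity / top) for p in self.peaks),
        )

    def restrict_mass_range(self, low: float, high: float) -> "MsmsSpectrum":
        """Drop fragments outside the [low, high] m/z window."""
        kept = tuple(p for p in self.peaks if low <= p.mz <= high)
        return self if len(kept) == len(self.peaks) else replace(self, peaks=kept)


@dataclass(frozen=True)
class Ms1Feature:
    """A detected LC-MS feature: id, m/z (Th), RT (s), per-sample intensities."""

    feature_id: str
    mz: float
    rt: float
    intensities: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if self.rt < 0:
            raise ValueError("feature rt must be >= 0")


@dataclass(frozen=True)
class PeakTable:
    """An MS1 peak table: ordered features plus the sample-column order."""

    features: tuple[Ms1Feature, ...]
    sample_ids: tuple[str, ...]
    polarity: str = "positive"

    def __post_init__(self):
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        seen = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature id {f.feature_id!r}")
            seen.add(f.feature_id)
            extra = set(f.intensities) - set(self.sample_ids)
            if extra:
                raise ValueError(
                    f"feature {f.feature_id!r} has unknown sample ids {sorted(extra)}"
                )


@dataclass(frozen=True)
class LibraryRecord:
    """One spectral-library entry: compound identity + consensus MS2 spectrum.

    ``rt`` may be ``None`` (public-library records often lack retention
    times); RT scoring is then skipped for the record.  The stored
    spectrum is always normalised to base peak 1.
    """

    compound_id: str
    compound_name: str
    precursor_mz: float
    spectrum: MsmsSpectrum
    rt: float | None = None
    polarity: str = "positive"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if self.rt is not None and self.rt < 0:
            raise ValueError("rt, if present, must be >= 0")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        object.__setattr__(self, "spectrum", self.spectrum.normalized())


def synthesize_feature_id(mz: float, rt_seconds: float) -> str:
    """``M<round mz>T<round rt>`` naming convention, e.g. M386T77."""
    return f"M{round(mz)}T{round(rt_seconds)}"


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def _parse_polarity_from_charge(charge: str) -> str | None:
    charge = charge.strip()
    if charge.endswith("-"):
        return "negative"
    if charge.endswith("+") or charge.rstrip("0123456789") == "":
        return "positive"
    return None


def read_mgf(
    path,
    rt_in_minutes: bool = False,
    default_polarity: str = "positive",
) -> list[MsmsSpectrum]:
    """Parse an MGF file into MS2 spectra.

    One :class:`MsmsSpectrum` per ``BEGIN IONS``/``END IONS`` block.
    ``PEPMASS`` maps to the precursor m/z and ``RTINSECONDS`` to the
    retention time; ``RTINMINUTES``, or ``rt_in_minutes=True`` applied to
    ``RTINSECONDS``-free dialects, converts minutes to seconds.  Ion mode
    is taken from the ``CHARGE`` sign when present, else
    ``default_polarity``.

    Raises
    ------
    FormatError
        On a block missing PEPMASS or containing a non-numeric peak line;
        the message names the offending line number.
    """
    path = Path(path)
    spectra: list[MsmsSpectrum] = []
    in_block = False
    block_start = 0
    params: dict[str, str] = {}
    peaks: list[FragmentPeak] = []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper() == "BEGIN IONS":
                in_block = True
                block_start = lineno
                params, peaks = {}, []
                continue
            if line.upper() == "END IONS":
                if "PEPMASS" not in params:
                    raise FormatError(
                        f"{path.name}: block starting at line {block_start} "
                        "has no PEPMASS"
                    )
                precursor = float(params["PEPMASS"].split()[0])
                if "RTINSECONDS" in params:
                    rt = float(params["RTINSECONDS"])
                    if rt_in_minutes:
                        rt *= 60.0
                elif "RTINMINUTES" in params:
                    rt = float(params["RTINMINUTES"]) * 60.0
                else:
                    rt = 0.0
                polarity = default_polarity
                if "CHARGE" in params:
                    polarity = (
                        _parse_polarity_from_charge(params["CHARGE"])
                        or default_polarity
                    )
                if not peaks:
                    logger.warning(
                        "%s: spectrum block at line %d has no peaks",
                        path.name,
                        block_start,
                    )
                spectra.append(
                    MsmsSpectrum(
                        spectrum_id=params.get("TITLE", f"scan_{len(spectra) + 1}"),
                        precursor_mz=precursor,
                        rt=rt,
                        polarity=polarity,
                        peaks=tuple(peaks),
                        metadata={
                            k: v
                            for k, v in params.items()
                            if k not in ("PEPMASS", "RTINSECONDS", "RTINMINUTES")
                        },
                    )
                )
                in_block = False
                continue
            if not in_block:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
                params[key.strip().upper()] = value.strip()
            else:
                fields = line.split()
                try:
                    mz = float(fields[0])
                    inten = float(fields[1]) if len(fields) > 1 else 0.0
                except (ValueError, IndexError) as exc:
                    raise FormatError(
                        f"{path.name}: non-numeric peak line {lineno}: {line!r}"
                    ) from exc
                peaks.append(FragmentPeak(mz, inten))

    if in_block:
        raise FormatError(
            f"{path.name}: block starting at line {block_start} has no END IONS"
        )
    if not spectra:
        warnings.warn(f"{path.name}: MGF file contains no spectra", stacklevel=2)
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path) -> None:
    """Write spectra as MGF (RTINSECONDS dialect, 6-decimal peaks)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"RTINSECONDS={s.rt:.4f}\n")
            fh.write("CHARGE=1-\n" if s.polarity == "negative" else "CHARGE=1+\n")
            for key, value in s.metadata.items():
                if key.upper() in ("TITLE", "PEPMASS", "RTINSECONDS", "CHARGE"):
                    continue
                fh.write(f"{key.upper()}={value}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

_MSP_RT_KEYS = ("RETENTIONTIME", "RT", "RETENTION_TIME")
_MSP_PRECURSOR_KEYS = ("PRECURSORMZ", "PRECURSOR_MZ", "PRECURSOR M/Z")
_MSP_POLARITY_KEYS = ("ION_MODE", "IONMODE", "POLARITY")


def _msp_polarity(value: str) -> str:
    v = value.strip().lower()
    if v in ("negative", "neg", "n", "-"):
        return "negative"
    return "positive"


def read_msp(path, default_polarity: str = "positive") -> list[LibraryRecord]:
    """Parse a NIST-style MSP library file.

    One :class:`LibraryRecord` per ``Name:`` entry.  Peak intensities are
    normalised to base peak 1 on load.  Entries lacking a precursor m/z
    are skipped with a warning; a ``Num Peaks`` count that disagrees with
    the actual number of peak lines is a :class:`FormatError`.
    """
    path = Path(path)
    records: list[LibraryRecord] = []

    entries: list[tuple[int, dict[str, str], list[FragmentPeak], int | None]] = []
    headers: dict[str, str] = {}
    peaks: list[FragmentPeak] = []
    declared: int | None = None
    entry_start: int | None = None
    reading_peaks = False

    def flush():
        nonlocal headers, peaks, declared, entry_start, reading_peaks
        if entry_start is not None:
            entries.append((entry_start, headers, peaks, declared))
        headers, peaks, declared, entry_start = {}, [], None, None
        reading_peaks = False

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            key_part, sep, value_part = line.partition(":")
            is_header = sep == ":" and not line[0].isdigit()
            if is_header:
                key = key_part.strip().upper()
                if key == "NAME":
                    flush()
                    entry_start = lineno
                if entry_start is None:
                    raise FormatError(
                        f"{path.name}: header line {lineno} outside any entry"
                    )
                if key == "NUM PEAKS":
                    declared = int(value_part.strip())
                    reading_peaks = True
                else:
                    headers[key] = value_part.strip()
            else:
                if entry_start is None or not reading_peaks:
                    raise FormatError(
                        f"{path.name}: unexpected peak line {lineno} "
                        "(no preceding 'Num Peaks:')"
                    )
                fields = line.replace(";", " ").split()
                try:
                    peaks.append(FragmentPeak(float(fields[0]), float(fields[1])))
                except (ValueError, IndexError) as exc:
                    raise FormatError(
                        f"{path.name}: non-numeric peak line {lineno}: {line!r}"
                    ) from exc
    flush()

    for start, headers, peaks, declared in entries:
        if declared is not None and declared != len(peaks):
            raise FormatError(
                f"{path.name}: entry at line {start} declares "
                f"{declared} peaks but has {len(peaks)}"
            )
        precursor = None
        for k in _MSP_PRECURSOR_KEYS:
            if k in headers:
                precursor = float(headers[k])
                break
        if precursor is None:
            warnings.warn(
                f"{path.name}: entry at line {start} lacks PrecursorMZ; skipped",
                stacklevel=2,
            )
            continue
        rt = None
        for k in _MSP_RT_KEYS:
            if k in headers:
                rt = float(headers[k])
                break
        polarity = default_polarity
        for k in _MSP_POLARITY_KEYS:
            if k in headers:
                polarity = _msp_polarity(headers[k])
                break
        name = headers.get("NAME", f"entry_{start}")
        compound_id = headers.get("DB#", headers.get("ID", name))
        spectrum = MsmsSpectrum(
            spectrum_id=compound_id,
            precursor_mz=precursor,
            rt=rt if rt is not None else 0.0,
            polarity=polarity,
            peaks=tuple(peaks),
            metadata={
                k: v for k, v in headers.items() if k not in ("NAME", "DB#", "ID")
            },
        ).normalized()
        provenance = {}
        if "COMMENTS" in headers:
            provenance["comments"] = headers["COMMENTS"]
        records.append(
            LibraryRecord(
                compound_id=compound_id,
                compound_name=name,
                precursor_mz=precursor,
                spectrum=spectrum,
                rt=rt,
                polarity=polarity,
                provenance=provenance,
            )
        )
    if not records:
        warnings.warn(f"{path.name}: MSP file contains no usable entries",
                      stacklevel=2)
    return records


def write_msp(records: Sequence[LibraryRecord], path) -> None:
    """Write library records as NIST-style MSP (6-decimal peaks).

    Provenance (replicate count, collision energies, clustering
    threshold) is embedded in a ``Comments:`` field.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"Name: {r.compound_name}\n")
            fh.write(f"ID: {r.compound_id}\n")
            fh.write(f"PrecursorMZ: {r.precursor_mz:.6f}\n")
            if r.rt is not None:
                fh.write(f"RetentionTime: {r.rt:.4f}\n")
            fh.write(f"Ion_mode: {r.polarity}\n")
            if r.provenance:
                parts = [f"{k}={v}" for k, v in sorted(r.provenance.items())]
                fh.write(f"Comments: {'; '.join(parts)}\n")
            fh.write(f"Num Peaks: {len(r.spectrum.peaks)}\n")
            for p in r.spectrum.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# CSV peak table / annotation output
# ---------------------------------------------------------------------------

_ID_COLUMNS = ("feature_id", "id", "feature", "alignment id", "name")
_MZ_COLUMNS = ("mz", "m/z", "mzmed", "average mz")
_RT_COLUMNS = ("rt", "rtmed", "rt (min)", "rt(min)", "average rt", "retention time")


def _find_column(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def read_peak_table(path, polarity: str, rt_unit: str = "auto") -> PeakTable:
    """Read an MS1 peak table from CSV.

    The table needs an m/z column, an RT column, and at least one sample
    column; a feature-id column is used when present, else ids are
    synthesized as ``M<round mz>T<round rt>``.  With ``rt_unit="auto"``
    an RT column whose values are all <= 30 is treated as minutes and
    converted to seconds (LC runs are minutes-scale; tolerance arithmetic
    is seconds-scale); pass ``"seconds"`` or ``"minutes"`` to override.
    """
    df = pd.read_csv(path)
    if df.columns.empty:
        raise FormatError(f"{path}: no header row")
    id_col = _find_column(df.columns, _ID_COLUMNS)
    mz_col = _find_column(df.columns, _MZ_COLUMNS)
    rt_col = _find_column(df.columns, _RT_COLUMNS)
    if mz_col is None or rt_col is None:
        raise FormatError(f"{path}: could not locate m/z and RT columns")

    sample_cols = [c for c in df.columns if c not in (id_col, mz_col, rt_col)]
    if not sample_cols:
        raise FormatError(f"{path}: peak table has no sample columns")

    for col, label in ((mz_col, "m/z"), (rt_col, "RT")):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric {label} at file row {row}")
    mz = df[mz_col].astype(float)
    rt = df[rt_col].astype(float)

    if rt_unit == "minutes" or (rt_unit == "auto" and len(rt) and rt.max() <= 30):
        rt = rt * 60.0
    elif rt_unit not in ("auto", "seconds", "minutes"):
        raise ValueError(f"unknown rt_unit {rt_unit!r}")

    features = []
    for i in range(len(df)):
        fid = (
            str(df[id_col].iloc[i])
            if id_col is not None
            else synthesize_feature_id(mz.iloc[i], rt.iloc[i])
        )
        intens = {s: float(df[s].iloc[i]) for s in sample_cols}
        features.append(
            Ms1Feature(feature_id=fid, mz=float(mz.iloc[i]), rt=float(rt.iloc[i]),
                       intensities=intens)
        )
    try:
        return PeakTable(
            features=tuple(features),
            sample_ids=tuple(str(s) for s in sample_cols),
            polarity=polarity,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


ANNOTATION_COLUMNS = (
    "feature_id",
    "compound_id",
    "compound_name",
    "precursor_mz_error_ppm",
    "score_msms",
    "score_rt",
    "score_integrate",
    "rank",
)


def write_annotations(results, path) -> None:
    """Write annotation results as CSV with a deterministic ordering.

    Rows are sorted by feature id, then descending integrated score;
    ``rank`` is the per-feature rank already carried by each result.
    """
    rows = sorted(results, key=lambda r: (r.feature_id, -r.score_integrate, r.rank))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.feature_id,
                    r.compound_id,
                    r.compound_name,
                    f"{r.precursor_ppm_error:.4f}",
                    f"{r.score_msms:.6f}",
                    "" if r.score_rt is None else f"{r.score_rt:.6f}",
                    f"{r.score_integrate:.6f}",
                    r.rank,
                ]
            )
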