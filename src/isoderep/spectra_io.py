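"""Peak lists, spectra, delimited-text I/O and cross-spectrum peak matching.

Peak lists are exported centroid tables (m/z, intensity) as CSV/TSV, one
file per spectrum. Sample-set manifests are YAML files mapping experiment
roles (control / labeled_admin / labeled_ref / parent_ref / fractions) to
peak-list paths; see :func:`read_manifest`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Peak",
    "Spectrum",
    "PeaklistDialect",
    "PeaklistParseError",
    "read_peaklist",
    "write_peaklist",
    "match_peaks",
    "PeakMatchResult",
    "read_manifest",
]

#: Two peaks closer than this (Th) are considered the same centroid.
MZ_DEDUP_TOL = 1e-6


class Peak(NamedTuple):
    """A single centroided peak."""

    mz: float
    intensity: float


class PeaklistParseError(ValueError):
    """A peak-list file could not be parsed; carries the offending line."""

    def __init__(self, message: str, path: object = None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


@dataclass
class Spectrum:
    """A centroided spectrum: sorted, deduplicated peaks plus metadata."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size and (self.mz <= 0).any():
            raise ValueError("all m/z values must be positive")
        if self.intensity.size and (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self._dedup()

    def _dedup(self) -> None:
        # Merge centroids closer than MZ_DEDUP_TOL, summing intensities.
        if self.mz.size < 2:
            return
        close = np.diff(self.mz) < MZ_DEDUP_TOL
        if not close.any():
            return
        group = np.concatenate([[0], np.cumsum(~close)])
        n = group[-1] + 1
        mz = np.zeros(n)
        inten = np.zeros(n)
        np.add.at(inten, group, self.intensity)
        # Intensity-weighted centroid m/z, falling back to mean for zero rows.
        wsum = np.zeros(n)
        np.add.at(wsum, group, self.intensity * self.mz)
        cnt = np.bincount(group, minlength=n)
        msum = np.zeros(n)
        np.add.at(msum, group, self.mz)
        with np.errstate(invalid="ignore", divide="ignore"):
            mz = np.where(inten > 0, wsum / inten, msum / cnt)
        self.mz = mz
        self.intensity = inten

    @classmethod
    def from_peaks(
        cls,
        sample_id: str,
        peaks: Iterable[tuple],
        polarity: str = "negative",
        metadata: Optional[dict] = None,
    ) -> "Spectrum":
        pk = list(peaks)
        mz = np.array([p[0] for p in pk], dtype=float)
        inten = np.array([p[1] for p in pk], dtype=float)
        return cls(sample_id, mz, inten, polarity, metadata or {})

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def relative_intensity(self) -> np.ndarray:
        """Intensities normalised to total ion intensity (non-destructive)."""
        tot = self.total_intensity
        if tot == 0:
            return np.zeros_like(self.intensity)
        return self.intensity / tot

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class PeaklistDialect:
    """Column mapping for delimited peak lists.

    ``sep=None`` sniffs the delimiter. With ``header=False`` the first two
    columns are taken as m/z and intensity.
    """

    mz_column: str = "mz"
    intensity_column: str = "intensity"
    sep: Optional[str] = None
    header: bool = True


DEFAULT_DIALECT = PeaklistDialect()


def read_peaklist(
    path,
    dialect: PeaklistDialect = DEFAULT_DIALECT,
    sample_id: Optional[str] = None,
    polarity: str = "negative",
) -> Spectrum:
    """Read one delimited peak list into a sorted, deduplicated Spectrum."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=dialect.sep,
            engine="python",
            header=0 if dialect.header else None,
            comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise PeaklistParseError("empty peak list", path)
    except csv.Error as exc:  # sniffer failure on blank/one-token files
        raise PeaklistParseError(f"cannot parse delimited text ({exc})", path)
    if dialect.header:
        missing = [
            c for c in (dialect.mz_column, dialect.intensity_column) if c not in df.columns
        ]
        if missing:
            raise PeaklistParseError(
                f"missing column(s) {missing}; found {list(df.columns)}", path, line=1
            )
        raw = df[[dialect.mz_column, dialect.intensity_column]]
    else:
        if df.shape[1] < 2:
            raise PeaklistParseError(
                f"need at least 2 columns, found {df.shape[1]}", path, line=1
            )
        raw = df.iloc[:, :2]
        raw.columns = [dialect.mz_column, dialect.intensity_column]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~raw.isna().all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        line = row + (2 if dialect.header else 1)
        raise PeaklistParseError(
            f"non-numeric value {raw.iloc[row].tolist()!r}", path, line=line
        )
    numeric = numeric.dropna()
    if numeric.empty:
        raise PeaklistParseError("peak list has no data rows", path)
    return Spectrum(
        sample_id=sample_id or path.stem,
        mz=numeric[dialect.mz_column].to_numpy(),
        intensity=numeric[dialect.intensity_column].to_numpy(),
        polarity=polarity,
        metadata={"source_path": str(path)},
    )


def write_peaklist(spectrum: Spectrum, path, dialect: PeaklistDialect = DEFAULT_DIALECT) -> None:
    """Write a spectrum back to delimited text (m/z to 1e-6, 6-sig-digit intensity)."""
    path = Path(path)
    sep = dialect.sep if dialect.sep is not None else ","
    df = pd.DataFrame(
        {
            dialect.mz_column: [f"{m:.6f}" for m in spectrum.mz],
            dialect.intensity_column: [f"{i:.6g}" for i in spectrum.intensity],
        }
    )
    df.to_csv(path, sep=sep, index=False, header=dialect.header)


@dataclass
class PeakMatchResult:
    """Outcome of one-to-one peak matching between two spectra."""

    matches: list[tuple[int, int, float]]  # (index in a, index in b, delta mz)
    unmatched_a: list[int]
    unmatched_b: list[int]


def match_peaks(a: Spectrum, b: Spectrum, tol_mz: float) -> PeakMatchResult:
    """Greedy one-to-one matching by smallest |Δm/z| within ``tol_mz``.

    Every peak is used at most once; the output partitions both inputs.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be positive")
    pairs: list[tuple[float, int, int]] = []
    bmz = b.mz
    for i, m in enumerate(a.mz):
        lo = int(np.searchsorted(bmz, m - tol_mz, side="left"))
        hi = int(np.searchsorted(bmz, m + tol_mz, side="right"))
        for j in range(lo, hi):
            pairs.append((abs(float(bmz[j]) - float(m)), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j, float(b.mz[j] - a.mz[i])))
    matches.sort()
    return PeakMatchResult(
        matches=matches,
        unmatched_a=[i for i in range(len(a)) if i not in used_a],
        unmatched_b=[j for j in range(len(b)) if j not in used_b],
    )


def read_manifest(path) -> dict:
    """Read a YAML sample-set manifest into a role -> paths mapping.

    Expected layout (paths relative to the manifest's directory)::

        control: [control_1.csv, control_2.csv]
        labeled_admin:
          parenteral: [liver_iv_1.csv, ...]
          oral: [liver_po_1.csv, ...]
        labeled_ref: [dbpcx_1.csv]
        parent_ref: [bpcx_1.csv]
        fractions:
          "100% CH3OH": fraction_100.csv
          "25% CH3OH": fraction_25.csv
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PeaklistParseError("manifest must be a YAML mapping", path)
    base = path.parent

    def _resolve(v):
        if isinstance(v, str):
            return str((base / v) if not Path(v).is_absolute() else Path(v))
        if isinstance(v, list):
            return [_resolve(x) for x in v]
        if isinstance(v, dict):
            return {k: _resolve(x) for k, x in v.items()}
        raise PeaklistParseError(f"unexpected manifest entry {v!r}", path)

    return {role: _resolve(v) for role, v in data.items()}
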