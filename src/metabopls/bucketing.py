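"""Spectral bucketing and constant-sum normalization.

A 1D 1H-NMR spectrum is reduced to fixed-width integration windows
("buckets", here 0.01 ppm by default).  Regions without usable signal or
contaminated by solvent/contaminant peaks (water, ethanol) are excluded,
and each reduced spectrum is normalized to a constant sum so that profiles
are comparable across samples of different total signal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BucketGrid",
    "BucketTable",
    "PAPER_EXCLUSIONS",
    "read_spectrum",
    "read_manifest",
    "bin_spectrum",
    "build_bucket_table",
    "normalize_constant_sum",
]

#: Default exclusion windows (ppm): signal-free low field, two ethanol
#: contaminant regions, residual water, and the signal-free region above
#: 8.3 ppm.
PAPER_EXCLUSIONS: list[tuple[float, float]] = [
    (0.0, 0.6),
    (1.1, 1.23),
    (3.62, 3.7),
    (4.54, 5.0),
    (8.3, 20.0),
]

_EPS = 1e-9


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files (names the offending line)."""


@dataclass
class Spectrum:
    """One sample's 1D spectrum: a ppm axis and matching intensities."""

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError(
                f"sample {self.sample_id!r}: ppm and intensity lengths differ "
                f"({self.ppm.size} vs {self.intensity.size})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite intensities")
        # store ascending internally
        if self.ppm.size and not np.all(np.diff(self.ppm) > 0):
            order = np.argsort(self.ppm, kind="stable")
            self.ppm = self.ppm[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.ppm) <= 0):
                raise ValueError(f"sample {self.sample_id!r}: duplicate ppm values")

    def __len__(self) -> int:
        return self.ppm.size


@dataclass(frozen=True)
class BucketGrid:
    """Bucketing layout: width, analysed range and exclusion windows.

    Buckets tile ``[lo, hi)`` as half-open intervals ``[b, b + width)``
    anchored at the lower range bound.  A bucket that intersects any
    exclusion window is dropped whole.
    """

    width_ppm: float = 0.01
    range_ppm: tuple[float, float] = (0.0, 10.0)
    exclusions: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(PAPER_EXCLUSIONS)
    )

    def __post_init__(self) -> None:
        if self.width_ppm <= 0:
            raise ValueError("bucket width must be positive")
        lo, hi = self.range_ppm
        if not lo < hi:
            raise ValueError("range lower bound must be below upper bound")
        merged = _merge_intervals(self.exclusions)
        object.__setattr__(self, "exclusions", merged)

    @property
    def edges(self) -> np.ndarray:
        lo, hi = self.range_ppm
        n = int(np.floor((hi - lo) / self.width_ppm + _EPS))
        return lo + self.width_ppm * np.arange(n + 1)

    def retained_mask(self) -> np.ndarray:
        """Boolean mask over buckets: True where no exclusion overlaps."""
        starts = self.edges[:-1]
        keep = np.ones(starts.size, dtype=bool)
        for elo, ehi in self.exclusions:
            overlap = (starts < ehi - _EPS) & (starts + self.width_ppm > elo + _EPS)
            keep &= ~overlap
        return keep


def _merge_intervals(
    intervals: tuple[tuple[float, float], ...] | list[tuple[float, float]],
) -> tuple[tuple[float, float], ...]:
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for a, b in ivs:
        if not a < b:
            raise ValueError(f"degenerate exclusion interval [{a}, {b})")
    merged: list[tuple[float, float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return tuple(merged)


@dataclass
class BucketTable:
    """Samples-by-buckets intensity matrix with ppm bin labels.

    Bin centers are stored high-field last, i.e. descending ppm, following
    the NMR plotting convention used in output tables.
    """

    sample_ids: list[str]
    groups: list[str | None]
    bin_centers_ppm: np.ndarray
    matrix: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_centers_ppm = np.asarray(self.bin_centers_ppm, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if len(self.sample_ids) != n or len(self.groups) != n:
            raise ValueError("sample_ids/groups length must match matrix rows")
        if self.bin_centers_ppm.size != p:
            raise ValueError("bin_centers length must match matrix columns")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.groups], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{c:.3f}" for c in self.bin_centers_ppm],
        )
        df.insert(0, "group", self.groups)
        return df

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# normalized={self.normalized}\n")
            self.to_frame().to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "BucketTable":
        normalized = False
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "normalized=True" in line:
                        normalized = True
                    continue
                lines.append(line)
        df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
        groups = df.pop("group").tolist()
        return cls(
            sample_ids=[str(s) for s in df.index],
            groups=groups,
            bin_centers_ppm=df.columns.astype(float).to_numpy(),
            matrix=df.to_numpy(dtype=float),
            normalized=normalized,
        )


def _parse_number(token: str) -> float:
    return float(token)


def read_spectrum(path, sample_id: str | None = None, group: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) delimited text file.

    Accepts comma-, tab- or whitespace-delimited values; a single header
    line is tolerated.  Errors name the offending line number.
    """
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in line.replace(",", " ").replace("\t", " ").split() if t]
            if len(tokens) < 2:
                raise SpectrumFormatError(f"{path}: line {lineno}: expected two columns")
            try:
                x, y = _parse_number(tokens[0]), _parse_number(tokens[1])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric value in {tokens[:2]}"
                ) from None
            ppm.append(x)
            intensity.append(y)
    if len(ppm) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")
    arr = np.asarray(ppm)
    if np.unique(arr).size != arr.size:
        dup = arr[np.where(np.diff(np.sort(arr)) == 0)[0][0]]
        raise SpectrumFormatError(f"{path}: duplicate ppm value {dup}")
    if sample_id is None:
        sample_id = str(path)
    return Spectrum(sample_id=sample_id, ppm=arr, intensity=np.asarray(intensity), group=group)


def read_manifest(path) -> dict[str, str]:
    """Read a (sample_id, group) manifest; returns sample_id -> group."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in line.replace(",", " ").replace("\t", " ").split() if t]
            if len(tokens) < 2:
                raise ValueError(f"{path}: line {lineno}: expected sample_id and group")
            if lineno == 1 and tokens[0].lower() in {"sample_id", "sample", "id"}:
                continue
            out[tokens[0]] = tokens[1]
    if not out:
        raise ValueError(f"{path}: empty manifest")
    return out


def bin_spectrum(spec: Spectrum, grid: BucketGrid) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a spectrum to bucket sums on ``grid``.

    Returns ``(bin_centers, bin_values)`` with centers descending.  The
    bucket value is the plain sum of the point intensities falling in the
    half-open bucket interval; buckets touching an exclusion are dropped.
    """
    lo, hi = grid.range_ppm
    edges = grid.edges
    n_buckets = edges.size - 1
    keep = grid.retained_mask()
    if not keep.any():
        raise ValueError("bucket grid configuration retains no buckets")
    idx = np.floor((spec.ppm - lo) / grid.width_ppm + _EPS).astype(int)
    inside = (idx >= 0) & (idx < n_buckets) & (spec.ppm >= lo) & (spec.ppm < hi)
    values = np.bincount(idx[inside], weights=spec.intensity[inside], minlength=n_buckets)
    centers = edges[:-1] + grid.width_ppm / 2.0
    order = np.argsort(-centers[keep], kind="stable")
    return centers[keep][order], values[keep][order]


def build_bucket_table(specs: list[Spectrum], grid: BucketGrid) -> BucketTable:
    """Bin every spectrum on the same grid and stack into a BucketTable."""
    if not specs:
        raise ValueError("no spectra supplied")
    centers = None
    rows = []
    for spec in specs:
        c, v = bin_spectrum(spec, grid)
        if centers is None:
            centers = c
        rows.append(v)
    return BucketTable(
        sample_ids=[s.sample_id for s in specs],
        groups=[s.group for s in specs],
        bin_centers_ppm=centers,
        matrix=np.vstack(rows),
        normalized=False,
    )


def normalize_constant_sum(table: BucketTable) -> BucketTable:
    """Divide each row by its own sum so every spectrum sums to 1."""
    sums = table.matrix.sum(axis=1)
    bad = np.where(sums <= 0)[0]
    if bad.size:
        raise ValueError(
            f"sample {table.sample_ids[bad[0]]!r} has non-positive total intensity"
        )
    return replace(table, matrix=table.matrix / sums[:, None], normalized=True)
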