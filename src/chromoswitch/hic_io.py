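"""Binned contact maps, per-bin tracks, and their text I/O.

Conventions
-----------
Bin counting is *inclusive fence-post*: an interval [start, end] with bin
size ``w`` (where end - start is divisible by w) contains
``(end - start) / w + 1`` bins.  This differs from the usual half-open
convention and is chosen so that chr14:20.5-106.1 Mb at 100 kb yields 857
bins.  Internal bin indices are 0-based; emitted BED/bedGraph intervals are
0-based half-open per those formats.

A :class:`ContactMap` stores contact *probabilities*: a symmetric matrix in
[0, 1] with unit diagonal and unit first off-diagonal (adjacent loci are
assumed always in contact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenomicBinning",
    "ContactMap",
    "BinTrack",
    "make_binning",
    "normalize_to_probability",
    "coarsen",
    "read_triplet",
    "write_triplet",
    "read_dense",
    "write_dense",
    "write_bintrack_bedgraph",
    "write_intervals_bed",
    "from_cooler",
]

DENSE_FMT = "%.6g"  # 6 significant digits for dense matrix text


@dataclass(frozen=True)
class GenomicBinning:
    """A uniform binning of one genomic interval (inclusive fence-post)."""

    chrom: str
    start: int
    end: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        span = self.end - self.start
        if span % self.bin_size != 0:
            raise ValueError(
                f"span {span} bp is not divisible by bin_size {self.bin_size} bp; "
                "refusing to truncate silently"
            )

    @property
    def n_bins(self) -> int:
        return (self.end - self.start) // self.bin_size + 1

    def bin_start(self, i: int) -> int:
        """bp coordinate of the left edge of bin ``i`` (0-based)."""
        if not 0 <= i < self.n_bins:
            raise IndexError(f"bin {i} out of range [0, {self.n_bins})")
        return self.start + i * self.bin_size


def make_binning(chrom: str, start: int, end: int, bin_size: int) -> GenomicBinning:
    """Construct a :class:`GenomicBinning` (validates divisibility)."""
    return GenomicBinning(chrom, start, end, bin_size)


def _default_binning(n: int) -> GenomicBinning:
    return GenomicBinning("chrU", 0, n - 1, 1)


@dataclass
class ContactMap:
    """Symmetric contact-probability matrix with its genomic binning."""

    binning: GenomicBinning
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.binning.n_bins
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match binning "
                f"({n} bins)"
            )

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    def validate(self, atol: float = 1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("contact map is not symmetric")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("contact probabilities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("diagonal must equal 1")
        if not np.allclose(np.diag(v, 1), 1.0, atol=atol):
            raise ValueError("first off-diagonal must equal 1 (adjacent contact)")


@dataclass
class BinTrack:
    """One scalar per bin; missing bins are NaN, never dropped."""

    binning: GenomicBinning
    values: np.ndarray
    name: str = "track"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.binning.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != n_bins {self.binning.n_bins}"
            )


def normalize_to_probability(
    raw: np.ndarray, binning: GenomicBinning | None = None
) -> ContactMap:
    """Normalize a raw symmetric count/probability matrix to a ContactMap.

    The matrix is divided by the mean of its first off-diagonal (so adjacent
    loci have unit contact probability), clipped at 1, and the diagonal and
    first off-diagonal are fixed to 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {raw.shape}")
    if not np.allclose(raw, raw.T, rtol=1e-8, atol=1e-10):
        raise ValueError("input matrix is not symmetric")
    if raw.min() < 0:
        raise ValueError("input matrix has negative entries")
    off1 = np.diag(raw, 1)
    scale = off1.mean()
    if scale <= 0:
        raise ValueError("mean of the first off-diagonal is zero; cannot normalize")
    v = np.minimum(raw / scale, 1.0)
    n = v.shape[0]
    idx = np.arange(n)
    v[idx, idx] = 1.0
    v[idx[:-1], idx[:-1] + 1] = 1.0
    v[idx[:-1] + 1, idx[:-1]] = 1.0
    if binning is None:
        binning = _default_binning(n)
    cmap = ContactMap(binning, v)
    cmap.validate()
    return cmap


def block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a square matrix by ``factor`` (trailing partial blocks
    are averaged over the entries present)."""
    n = values.shape[0]
    m = -(-n // factor)  # ceil
    out = np.empty((m, m), dtype=float)
    for a in range(m):
        ia = slice(a * factor, min((a + 1) * factor, n))
        for b in range(m):
            ib = slice(b * factor, min((b + 1) * factor, n))
            out[a, b] = values[ia, ib].mean()
    return out


def coarsen(cmap: ContactMap, factor: int) -> ContactMap:
    """Coarsen a contact map by block-mean aggregation, then re-normalize."""
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor > cmap.n_bins:
        raise ValueError(f"factor {factor} exceeds n_bins {cmap.n_bins}")
    if factor == 1:
        return ContactMap(cmap.binning, cmap.values.copy())
    coarse = block_mean(cmap.values, factor)
    m = coarse.shape[0]
    b = cmap.binning
    new_size = b.bin_size * factor
    new_binning = GenomicBinning(b.chrom, b.start, b.start + (m - 1) * new_size, new_size)
    return normalize_to_probability(coarse, new_binning)


# ---------------------------------------------------------------------------
# text I/O


def _write_header(fh, header: str | None) -> None:
    if header:
        for line in header.rstrip("\n").split("\n"):
            fh.write(f"# {line}\n" if not line.startswith("#") else line + "\n")


def write_triplet(cmap: ContactMap, path, header: str | None = None) -> None:
    """Write the upper triangle (incl. diagonal) as '*i j value*' lines."""
    v = cmap.values
    n = cmap.n_bins
    with open(path, "w") as fh:
        _write_header(fh, header)
        for i in range(n):
            for j in range(i, n):
                if v[i, j] != 0.0:
                    fh.write(f"{i} {j} {float(v[i, j])!r}\n")


def read_triplet(path, binning: GenomicBinning | None = None) -> ContactMap:
    """Read '*i j value*' triplet text into a symmetric ContactMap.

    Bins are 0-based; either triangle (or both) may be present.  Out-of-range
    indices and non-numeric values raise.
    """
    entries = []
    max_idx = -1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'i j value', got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
                val = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric field in {line!r}") from exc
            if i < 0 or j < 0:
                raise ValueError(f"{path}:{ln}: negative bin index")
            entries.append((i, j, val))
            max_idx = max(max_idx, i, j)
    if binning is None:
        if max_idx < 0:
            raise ValueError(f"{path}: no data lines")
        binning = _default_binning(max_idx + 1)
    n = binning.n_bins
    v = np.zeros((n, n))
    for i, j, val in entries:
        if i >= n or j >= n:
            raise ValueError(f"bin index ({i},{j}) out of range for {n} bins")
        v[i, j] = val
        v[j, i] = val
    return ContactMap(binning, v)


def write_dense(values: np.ndarray | ContactMap, path, header: str | None = None,
                fmt: str = DENSE_FMT) -> None:
    """Write a matrix as whitespace-separated text (6 significant digits)."""
    if isinstance(values, ContactMap):
        values = values.values
    with open(path, "w") as fh:
        _write_header(fh, header)
        np.savetxt(fh, np.asarray(values, dtype=float), fmt=fmt)


def read_dense(path, binning: GenomicBinning | None = None) -> ContactMap:
    """Read a dense whitespace-separated symmetric matrix into a ContactMap."""
    v = np.loadtxt(path, comments="#")
    v = np.atleast_2d(v)
    if v.shape[0] != v.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({v.shape})")
    if binning is None:
        binning = _default_binning(v.shape[0])
    return ContactMap(binning, v)


def read_dense_matrix(path) -> np.ndarray:
    """Read a dense matrix as a bare array (for restraint fields etc.)."""
    return np.atleast_2d(np.loadtxt(path, comments="#"))


def write_bintrack_bedgraph(track: BinTrack, path, header: str | None = None) -> None:
    """Write a per-bin track as bedGraph (0-based half-open); NaN bins skipped."""
    b = track.binning
    with open(path, "w") as fh:
        _write_header(fh, header)
        for i, val in enumerate(track.values):
            if np.isnan(val):
                continue
            s = b.bin_start(i)
            fh.write(f"{b.chrom}\t{s}\t{s + b.bin_size}\t{val:.6g}\n")


def write_intervals_bed(binning: GenomicBinning, intervals, path,
                        names=None, header: str | None = None) -> None:
    """Write bin-index intervals [i, j] (inclusive bins) as BED lines."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        for k, (i, j) in enumerate(intervals):
            s = binning.bin_start(int(i))
            e = binning.bin_start(int(j)) + binning.bin_size
            name = names[k] if names is not None else f"iv{k}"
            fh.write(f"{binning.chrom}\t{s}\t{e}\t{name}\n")


def from_cooler(uri: str) -> ContactMap:
    """Import a cooler-format matrix as a ContactMap (optional adapter)."""
    try:
        import cooler  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the cooler package is required for from_cooler(); install cooler"
        ) from exc
    clr = cooler.Cooler(uri)  # pragma: no cover
    chrom = clr.chromnames[0]  # pragma: no cover
    mat = np.nan_to_num(clr.matrix(balance=False).fetch(chrom))  # pragma: no cover
    return normalize_to_probability(mat)  # pragma: no cover
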