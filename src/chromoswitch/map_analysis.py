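"""Contact-map analyses: difference matrices and stage clustering, P(s)
scaling, A/B compartment profiles, and insulation-score TAD boundaries.

The map-difference statistic between two time frames I, J is

    Delta^{I,J} = sum_{ij} |P^I_ij - P^J_ij| / sum_{ij} P^I_ij

restricted to a genomic-distance range filter (total, local < 2 Mb, or
non-local > 2 Mb).  Note the normalization makes it genuinely asymmetric;
a symmetrized copy (mean of the two directions) is used for clustering and
a min-max normalized copy for visualization only.

Compartments follow the standard eigenvector pipeline: observed/expected
enhancement, ICE matrix balancing, Pearson correlation matrix, PCA; A is
assigned to positive PC1 after fixing the sign against a reference profile.
TAD boundaries use the Crane insulation score (sliding off-diagonal square,
log2 ratio to the chromosome mean) with the delta-vector zero-crossing rule
and a boundary-strength threshold of 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit

from .hic_io import BinTrack, ContactMap, GenomicBinning, coarsen

__all__ = [
    "DeltaMatrix", "StageClustering", "PsCurve", "CompartmentProfile",
    "InsulationResult", "delta_matrix", "cluster_stages", "ps_curve",
    "oe_enhance", "ice_normalize", "compartment_profile", "insulation",
    "boundary_overlap", "tad_size_series",
]

LOCAL_RANGE_BP = 2_000_000  # local/non-local split at 2 Mb
COMPARTMENT_COARSEN_FACTOR = 10  # 100 kb -> 1 Mb for compartment calling


# ---------------------------------------------------------------------------
# Delta matrices and stage clustering


@dataclass
class DeltaMatrix:
    values: np.ndarray        # asymmetric, exactly as defined
    symmetrized: np.ndarray   # mean of the two directions (for clustering)
    normalized: np.ndarray    # min-max rescaled symmetrized copy (plots only)
    range_filter: str


def _range_mask(binning: GenomicBinning, range_filter: str) -> np.ndarray:
    n = binning.n_bins
    idx = np.arange(n)
    sep_bp = np.abs(idx[:, None] - idx[None, :]) * binning.bin_size
    off = sep_bp > 0
    if range_filter == "total":
        return off
    if range_filter == "local":
        return off & (sep_bp < LOCAL_RANGE_BP)
    if range_filter == "nonlocal":
        return sep_bp > LOCAL_RANGE_BP
    raise ValueError(f"unknown range filter {range_filter!r}")


def delta_matrix(maps: Sequence[ContactMap], range_filter: str = "total") -> DeltaMatrix:
    """Pairwise contact-map differences over a genomic-distance filter."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    binning = maps[0].binning
    mask = _range_mask(binning, range_filter)
    if not mask.any():
        raise ValueError(f"range filter {range_filter!r} selects no pairs")
    stack = np.stack([m.values for m in maps])
    if any(m.binning != binning for m in maps[1:]):
        raise ValueError("maps do not share a binning")
    t = len(maps)
    vals = np.zeros((t, t))
    sums = np.array([stack[i][mask].sum() for i in range(t)])
    for i in range(t):
        for j in range(i + 1, t):
            num = np.abs(stack[i][mask] - stack[j][mask]).sum()
            vals[i, j] = num / sums[i]
            vals[j, i] = num / sums[j]
    sym = 0.5 * (vals + vals.T)
    rng_ = sym.max() - sym.min()
    norm = (sym - sym.min()) / rng_ if rng_ > 0 else np.zeros_like(sym)
    return DeltaMatrix(vals, sym, norm, range_filter)


@dataclass
class StageClustering:
    labels: np.ndarray       # frame -> stage (0-based, temporally ordered)
    n_stages: int
    linkage_local: np.ndarray
    linkage_nonlocal: np.ndarray

    def stage_frames(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.labels == s)


def _condensed(sym: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(sym, k=1)
    return sym[iu]


class StageCountError(ValueError):
    """Requested stage count cannot be realized contiguously."""

    def __init__(self, requested: int, nearest: int):
        self.requested = requested
        self.nearest = nearest
        super().__init__(
            f"no cut of the local/non-local trees yields {requested} "
            f"contiguous stages; nearest feasible stage count is {nearest}")


def cluster_stages(delta_local: DeltaMatrix, delta_nonlocal: DeltaMatrix,
                   n_stages: int = 7) -> StageClustering:
    """Reduce the time series to contiguous stages from the two Delta trees.

    Both symmetrized matrices are clustered with average linkage; frames are
    grouped into one stage only when they co-cluster in *both* trees, and
    stage membership must be temporally contiguous.  The two trees are cut
    at the (smallest) cluster counts whose joint contiguous-run count equals
    ``n_stages``; if no cut pair achieves that, a :class:`StageCountError`
    suggests the nearest feasible stage count.
    """
    t = delta_local.symmetrized.shape[0]
    if delta_nonlocal.symmetrized.shape[0] != t:
        raise ValueError("local and non-local matrices cover different frames")
    if not 1 <= n_stages <= t:
        raise ValueError(f"n_stages must lie in [1, {t}]")
    zl = linkage(_condensed(delta_local.symmetrized), method="average")
    zn = linkage(_condensed(delta_nonlocal.symmetrized), method="average")
    cuts_l = [fcluster(zl, t=k, criterion="maxclust").astype(np.int64)
              for k in range(1, t + 1)]
    cuts_n = [fcluster(zn, t=k, criterion="maxclust").astype(np.int64)
              for k in range(1, t + 1)]
    feasible = {}
    for kl in range(t):
        for kn in range(t):
            combined = cuts_l[kl] * (t + 1) + cuts_n[kn]
            runs = 1 + int(np.count_nonzero(np.diff(combined)))
            if runs == n_stages:
                labels = np.zeros(t, dtype=int)
                labels[1:] = np.cumsum(np.diff(combined) != 0)
                return StageClustering(labels, n_stages, zl, zn)
            feasible.setdefault(runs, (kl, kn))
    nearest = min(feasible, key=lambda r: (abs(r - n_stages), r))
    raise StageCountError(n_stages, nearest)


# ---------------------------------------------------------------------------
# P(s) scaling


@dataclass
class PsCurve:
    s: np.ndarray           # genomic separations (bins)
    ps: np.ndarray          # mean contact probability at each s
    exponent: float         # fitted log-log slope over fit_range
    fit_range: tuple        # (s_min, s_max) in bins


def ps_curve(cmap: ContactMap, fit_range: tuple = (5, 50)) -> PsCurve:
    """Mean P(s) by genomic separation and its power-law exponent.

    The exponent is the least-squares slope of log P vs log s over
    ``fit_range`` (inclusive, in bins), which must span at least a decade.
    """
    s_min, s_max = fit_range
    n = cmap.n_bins
    if s_max / s_min < 10 - 1e-9:
        raise ValueError("fit range must span at least one decade of s")
    if s_max > n - 1:
        raise ValueError(f"fit range exceeds map support (max s = {n - 1})")
    v = cmap.values
    s_vals = np.arange(1, n)
    ps = np.array([np.diag(v, k).mean() for k in s_vals])
    sel = (s_vals >= s_min) & (s_vals <= s_max)
    if np.any(ps[sel] <= 0):
        raise ValueError("zero contact probability within the fit range")
    slope = np.polyfit(np.log(s_vals[sel]), np.log(ps[sel]), 1)[0]
    return PsCurve(s_vals, ps, float(slope), (s_min, s_max))


# ---------------------------------------------------------------------------
# compartments


def oe_enhance(cmap: ContactMap) -> np.ndarray:
    """Observed/expected enhancement: P_ij / mean(P at separation |i-j|)."""
    v = cmap.values
    n = v.shape[0]
    expected = np.array([np.diag(v, k).mean() for k in range(n)])
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    exp_mat = expected[sep]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp_mat > 0, v / exp_mat, 0.0)
    return oe


def ice_normalize(matrix: np.ndarray, tol: float = 1e-5,
                  max_iters: int = 500) -> np.ndarray:
    """Iterative correction: rescale to (near-)equal row sums.

    All-zero rows are dropped with a warning and re-inserted as NaN.
    """
    m = np.asarray(matrix, dtype=float).copy()
    n = m.shape[0]
    zero_rows = np.flatnonzero(m.sum(axis=1) == 0)
    keep = np.setdiff1d(np.arange(n), zero_rows)
    if zero_rows.size:
        warnings.warn(f"{zero_rows.size} all-zero rows dropped before ICE "
                      "and re-inserted as missing")
        m = m[np.ix_(keep, keep)]
    bias = np.ones(m.shape[0])
    for _ in range(max_iters):
        s = m.sum(axis=1)
        rel = s / s.mean()
        if np.max(np.abs(rel - 1)) < tol:
            break
        m = m / np.sqrt(np.outer(rel, rel))
    else:
        raise RuntimeError(f"ICE did not balance within {max_iters} iterations")
    if zero_rows.size:
        out = np.full((n, n), np.nan)
        out[np.ix_(keep, keep)] = m
        return out
    return m


@dataclass
class CompartmentProfile:
    pc1: BinTrack                   # zero-mean PC1 per (coarse) bin
    labels: np.ndarray              # 'A' where PC1 > 0, 'B' otherwise
    sign_reference: str = "none"

    def __post_init__(self) -> None:
        vals = self.pc1.values
        lab = np.where(vals > 0, "A", "B")
        lab = np.where(np.isnan(vals), "NA", lab)
        if not np.array_equal(lab, self.labels):
            raise ValueError("labels inconsistent with PC1 sign")


def _reference_vector(reference, n: int) -> Optional[np.ndarray]:
    if reference is None:
        return None
    if isinstance(reference, BinTrack):
        ref = reference.values
    elif isinstance(reference, CompartmentProfile):
        ref = reference.pc1.values
    else:
        ref = np.asarray(reference)
        if ref.dtype.kind in "US":  # A/B label strings
            ref = np.where(ref == "A", 1.0, -1.0)
        ref = ref.astype(float)
    if ref.shape[0] != n:
        raise ValueError("reference length does not match profile bins")
    return ref


def compartment_profile(cmap: ContactMap, reference=None,
                        coarsen_factor: int = 1,
                        sign_reference_name: str = "reference",
                        ice_tol: float = 1e-5) -> CompartmentProfile:
    """A/B compartment profile: O/E -> ICE -> correlation matrix -> PC1.

    The map should be at (or is coarsened to, via ``coarsen_factor``) the
    compartment resolution, conventionally 1 Mb.  PCA is computed on the
    Pearson-correlation matrix of the balanced O/E map (covariance-based,
    no column standardization).  If a ``reference`` per-bin vector/track/
    label array is given, the PC1 sign is flipped to correlate positively
    with it; A is assigned where PC1 > 0.
    """
    if coarsen_factor > 1:
        cmap = coarsen(cmap, coarsen_factor)
    oe = oe_enhance(cmap)
    balanced = ice_normalize(oe, tol=ice_tol)
    n = balanced.shape[0]
    if np.nanstd(balanced) < 1e-9:
        # no enhancement structure at all (e.g. a pure power-law map):
        # the profile is identically zero rather than amplified noise
        track = BinTrack(cmap.binning, np.zeros(n), name="PC1")
        return CompartmentProfile(track, np.array(["B"] * n), "none")
    good = ~np.isnan(balanced).all(axis=1)
    sub = balanced[np.ix_(good, good)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr)
    centered = corr - corr.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc_dir = eigvecs[:, -1]
    scores = centered @ pc_dir
    pc1 = np.full(n, np.nan)
    pc1[good] = scores - scores.mean()
    ref = _reference_vector(reference, n)
    sign_ref = "none"
    if ref is not None:
        m = good & ~np.isnan(ref)
        if np.nanstd(pc1[m]) > 0 and np.nanstd(ref[m]) > 0:
            c = np.corrcoef(pc1[m], ref[m])[0, 1]
            if c < 0:
                pc1 = -pc1
        sign_ref = sign_reference_name
    track = BinTrack(cmap.binning, pc1, name="PC1")
    labels = np.where(pc1 > 0, "A", "B")
    labels = np.where(np.isnan(pc1), "NA", labels)
    return CompartmentProfile(track, labels, sign_ref)


# ---------------------------------------------------------------------------
# insulation score and TAD boundaries


@dataclass
class InsulationResult:
    score: BinTrack            # log2 insulation per bin (NaN near edges)
    delta: np.ndarray          # left-minus-right flanking mean of the score
    boundaries: np.ndarray     # boundary bin indices
    window_bins: int


def insulation(cmap: ContactMap, window_bins: int = 5,
               strength_threshold: float = 0.1) -> InsulationResult:
    """Crane-style insulation score and TAD boundary calls.

    Per bin, the mean contact level in the ``window x window`` square
    strictly off-diagonal (upstream x downstream of the bin) is taken and
    log2-normalized by its chromosome-wide mean.  The delta vector is the
    mean score over the ``window`` bins to the left minus to the right;
    a boundary is called where delta crosses zero downward and the nearest
    left local maximum minus right local minimum of delta exceeds the
    strength threshold.  Bins within a window of the map edge get no score.
    Boundary calls are invariant to uniform scaling of the map.
    """
    n = cmap.n_bins
    w = window_bins
    if 2 * w + 1 > n:
        raise ValueError(f"window {w} too large for {n} bins")
    v = cmap.values
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = v[i - w:i, i + 1:i + w + 1].mean()
    mean_raw = np.nanmean(raw)
    if mean_raw <= 0:
        raise ValueError("insulation undefined: zero mean contact level")
    with np.errstate(divide="ignore"):
        score = np.log2(raw / mean_raw)
    delta = np.full(n, np.nan)
    for i in range(n):
        left = score[max(i - w, 0):i]
        right = score[i + 1:i + 1 + w]
        if left.size and right.size and not (
                np.isnan(left).all() or np.isnan(right).all()):
            delta[i] = np.nanmean(left) - np.nanmean(right)
    boundaries = []
    valid = np.flatnonzero(~np.isnan(delta))
    for a, b in zip(valid[:-1], valid[1:]):
        if not (delta[a] >= 0 > delta[b]):
            continue
        if delta[a] == 0 and (a == valid[0] or delta[a - 1] <= 0):
            continue  # flat zero run, not a crossing
        # strength: nearest local max of delta left of the crossing minus
        # nearest local min right of it
        k = a
        while k - 1 >= valid[0] and not np.isnan(delta[k - 1]) and delta[k - 1] >= delta[k]:
            k -= 1
        left_max = delta[k]
        k = b
        while k + 1 <= valid[-1] and not np.isnan(delta[k + 1]) and delta[k + 1] <= delta[k]:
            k += 1
        right_min = delta[k]
        if left_max - right_min > strength_threshold:
            boundaries.append(a if score[a] <= score[b] else b)
    track = BinTrack(cmap.binning, score, name="insulation")
    return InsulationResult(track, delta, np.asarray(boundaries, dtype=int), w)


def boundary_overlap(ref: Sequence[int], query: Sequence[int],
                     tol_bins: int = 1):
    """Count boundary matches within a bin tolerance (greedy one-to-one).

    Returns ``(n_overlap, n_overlap/len(ref), n_overlap/len(query))``.
    """
    ref = sorted(int(b) for b in ref)
    query = sorted(int(b) for b in query)
    used = [False] * len(query)
    n_ol = 0
    for rb in ref:
        best, best_d = -1, tol_bins + 1
        for qi, qb in enumerate(query):
            if used[qi]:
                continue
            d = abs(qb - rb)
            if d < best_d:
                best, best_d = qi, d
        if best >= 0 and best_d <= tol_bins:
            used[best] = True
            n_ol += 1
    f_ref = n_ol / len(ref) if ref else float("nan")
    f_query = n_ol / len(query) if query else float("nan")
    return n_ol, f_ref, f_query


# ---------------------------------------------------------------------------
# TAD size relaxation


@dataclass
class TadSizeSeries:
    times: np.ndarray          # tau units
    mean_size_mb: np.ndarray   # NaN where a frame had < 2 boundaries
    tau_r: float               # exponential relaxation time (NaN if degenerate)
    y0: float
    y_inf: float
    degenerate: bool
    sd_band: np.ndarray        # per-frame standard deviation of TAD sizes


def tad_size_series(boundaries_per_frame: Sequence[Sequence[int]],
                    binning: GenomicBinning,
                    times: Sequence[float]) -> TadSizeSeries:
    """Mean inter-boundary distance (Mb) per frame, with an exponential fit
    y(t) = y_inf + (y0 - y_inf) exp(-t / tau_r)."""
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 time points")
    mb_per_bin = binning.bin_size / 1e6
    means = np.full(times.size, np.nan)
    sds = np.full(times.size, np.nan)
    for k, bnd in enumerate(boundaries_per_frame):
        bnd = np.sort(np.asarray(bnd, dtype=float))
        if bnd.size < 2:
            continue  # flagged missing
        sizes = np.diff(bnd) * mb_per_bin
        means[k] = sizes.mean()
        sds[k] = sizes.std()
    ok = ~np.isnan(means)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 frames have >= 2 boundaries")
    y = means[ok]
    t = times[ok]
    if np.allclose(y, y[0]):
        return TadSizeSeries(times, means, float("nan"), y[0], y[0], True, sds)

    def model(tt, y_inf, dy, tau_r):
        return y_inf + dy * np.exp(-tt / tau_r)

    try:
        span = max(t.max() - t.min(), 1e-9)
        popt, _ = curve_fit(
            model, t, y, p0=[y[-1], y[0] - y[-1], span / 3],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000)
        y_inf, dy, tau_r = popt
        return TadSizeSeries(times, means, float(tau_r), float(y_inf + dy),
                             float(y_inf), False, sds)
    except RuntimeError:
        return TadSizeSeries(times, means, float("nan"), y[0], y[-1], True, sds)
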