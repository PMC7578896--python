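"""Paired synthetic cell-state contact maps with known ground truth.

Real two-state Hi-C inputs (e.g. an embryonic stem cell vs. a terminally
differentiated fibroblast) show three structural signatures that the
analysis stack keys on: a power-law distance decay P(s) ~ s^a whose exponent
differs between states (roughly -1.5 in the stem-cell-like state vs -1.0 in
the fractal-globule-like differentiated state), block TADs of ~9-10 bins
whose boundaries are shared between states, and a plaid compartment pattern
driven by an A/B label vector, with a fraction of whole compartment blocks
switching identity between the states.

The generator composes these multiplicatively on the power-law backbone:

    f_ij = min(1, c * s^a * m_comp(i,j) * m_tad(i,j)),   s = |i - j|

with m_comp = 1 +/- plaid_strength for same/different labels and
m_tad = 1 + tad_strength inside a TAD.  The prefactor c is set so the
backbone value at s = 2 is 0.5 before clipping.  Adjacent bins have
f = 1 by convention.

This is a statistical stand-in for experimental maps, not a mechanistic
model: there is no read noise, coverage bias, or replicate structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMap, GenomicBinning

__all__ = [
    "SyntheticStateSpec",
    "StatePair",
    "make_ab_labels",
    "make_tad_boundaries",
    "make_target_map",
    "make_state_pair",
]

#: contact-probability decay exponents typical of the two cell states
ESC_EXPONENT = -1.5
DIFFERENTIATED_EXPONENT = -1.0

#: mean TAD size in bins (~0.9-1.0 Mb at 100 kb resolution)
DEFAULT_MEAN_TAD_BINS = 9

#: mean compartment block size in bins
DEFAULT_MEAN_COMPARTMENT_BINS = 20

#: emulated map resolution (bp per bin)
BIN_SIZE_BP = 100_000


def synthetic_binning(n_bins: int) -> GenomicBinning:
    """The binning synthetic maps are generated on (100 kb resolution)."""
    return GenomicBinning("chrS", 0, (n_bins - 1) * BIN_SIZE_BP, BIN_SIZE_BP)


@dataclass(frozen=True)
class SyntheticStateSpec:
    """Full recipe for one synthetic cell-state target map."""

    n_bins: int
    decay_exponent: float
    tad_boundaries: tuple
    ab_labels: tuple
    plaid_strength: float = 0.0
    tad_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if len(self.ab_labels) != self.n_bins:
            raise ValueError("ab_labels length must equal n_bins")
        if any(lab not in ("A", "B") for lab in self.ab_labels):
            raise ValueError("labels must be 'A' or 'B'")
        bnd = np.asarray(self.tad_boundaries, dtype=int)
        if bnd.size and (np.any(np.diff(bnd) <= 0) or bnd.min() <= 0
                         or bnd.max() >= self.n_bins):
            raise ValueError("tad_boundaries must be strictly increasing within "
                             "(0, n_bins)")
        if not 0.0 <= self.plaid_strength < 1.0:
            raise ValueError("plaid_strength must lie in [0, 1)")
        if self.tad_strength < 0:
            raise ValueError("tad_strength must be >= 0")


@dataclass(frozen=True)
class StatePair:
    """Two state specs plus the per-bin compartment switch class."""

    spec_start: SyntheticStateSpec
    spec_end: SyntheticStateSpec
    switch_class: tuple  # per bin: 'A->B', 'B->A', 'A->A', 'B->B'

    def __post_init__(self) -> None:
        for lab_s, lab_e, cls in zip(
            self.spec_start.ab_labels, self.spec_end.ab_labels, self.switch_class
        ):
            if cls != f"{lab_s}->{lab_e}":
                raise ValueError("switch_class inconsistent with label vectors")

    def bins_of_class(self, cls: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.switch_class) if c == cls],
                        dtype=int)


def make_ab_labels(n_bins: int, mean_block_bins: int, seed: int) -> tuple:
    """Alternating A/B runs with geometric block lengths of the given mean."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mean_block_bins < 1:
        raise ValueError("mean_block_bins must be >= 1")
    rng = np.random.default_rng(seed)
    p = 1.0 / mean_block_bins
    labels: list[str] = []
    current = rng.choice(["A", "B"])
    while len(labels) < n_bins:
        run = rng.geometric(p) if p < 1.0 else 1
        labels.extend([current] * run)
        current = "A" if current == "B" else "B"
    return tuple(labels[:n_bins])


def make_tad_boundaries(n_bins: int, mean_tad_bins: int = DEFAULT_MEAN_TAD_BINS,
                        seed: int = 0, jitter: float = 0.25) -> tuple:
    """TAD boundary bin indices; sizes uniform in mean*(1 +/- jitter) bins."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not 0 <= jitter < 1:
        raise ValueError("jitter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lo = max(int(np.ceil(mean_tad_bins * (1 - jitter))), 2)
    hi = max(int(np.floor(mean_tad_bins * (1 + jitter))), lo)
    boundaries = []
    pos = 0
    while True:
        pos += int(rng.integers(lo, hi + 1))
        if pos >= n_bins - 1:
            break
        boundaries.append(pos)
    return tuple(boundaries)


def _tad_ids(n_bins: int, boundaries) -> np.ndarray:
    """Label each bin with the index of its TAD (boundary bin starts a TAD)."""
    ids = np.zeros(n_bins, dtype=int)
    for b in boundaries:
        ids[b:] += 1
    return ids


def make_target_map(spec: SyntheticStateSpec) -> ContactMap:
    """Build the contact-probability map encoded by a state spec."""
    n = spec.n_bins
    a = spec.decay_exponent
    c = 0.5 / 2.0**a  # backbone value 0.5 at s = 2, before clipping
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        backbone = c * s**a
    lab = np.array([0 if x == "A" else 1 for x in spec.ab_labels])
    same_comp = lab[:, None] == lab[None, :]
    m_comp = np.where(same_comp, 1.0 + spec.plaid_strength, 1.0 - spec.plaid_strength)
    tid = _tad_ids(n, spec.tad_boundaries)
    same_tad = tid[:, None] == tid[None, :]
    m_tad = np.where(same_tad, 1.0 + spec.tad_strength, 1.0)
    v = np.minimum(1.0, backbone * m_comp * m_tad)
    v[idx, idx] = 1.0
    v[idx[:-1], idx[:-1] + 1] = 1.0
    v[idx[:-1] + 1, idx[:-1]] = 1.0
    cmap = ContactMap(synthetic_binning(n), v)
    cmap.validate()
    return cmap


def make_state_pair(
    n_bins: int,
    exponents: tuple = (ESC_EXPONENT, DIFFERENTIATED_EXPONENT),
    switch_fraction: float = 0.3,
    plaid_strength: float = 0.3,
    tad_strength: float = 1.0,
    mean_block_bins: int = DEFAULT_MEAN_COMPARTMENT_BINS,
    mean_tad_bins: int = DEFAULT_MEAN_TAD_BINS,
    seed: int = 0,
):
    """Generate a start/end state pair with shared TAD boundaries.

    The end-state labels are obtained by flipping a random ``switch_fraction``
    of the start state's compartment *blocks* (whole blocks, not single bins),
    mirroring the observation that compartment switching happens in TAD-sized
    units.

    Returns ``(StatePair, ContactMap_start, ContactMap_end)``.
    """
    if not 0.0 <= switch_fraction <= 1.0:
        raise ValueError("switch_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sub = rng.integers(2**31, size=4)
    labels_start = make_ab_labels(n_bins, mean_block_bins, int(sub[0]))
    boundaries = make_tad_boundaries(n_bins, mean_tad_bins, int(sub[1]))

    # enumerate maximal runs (blocks) of the start labels
    blocks = []
    run_start = 0
    for i in range(1, n_bins + 1):
        if i == n_bins or labels_start[i] != labels_start[i - 1]:
            blocks.append((run_start, i))
            run_start = i
    # flip whole blocks, in random order, until the switched-bin fraction
    # reaches the requested one (block granularity limits the precision)
    order = rng.permutation(len(blocks))
    target_bins = switch_fraction * n_bins
    labels_end = list(labels_start)
    flipped = 0
    for k in order:
        if flipped >= target_bins:
            break
        lo, hi = blocks[k]
        if flipped + (hi - lo) - target_bins > 0.5 * (hi - lo) \
                and switch_fraction < 1.0:
            continue  # overshoot by more than half a block: skip this one
        for i in range(lo, hi):
            labels_end[i] = "A" if labels_end[i] == "B" else "B"
        flipped += hi - lo
    labels_end = tuple(labels_end)

    spec_start = SyntheticStateSpec(
        n_bins, exponents[0], boundaries, labels_start,
        plaid_strength, tad_strength, int(sub[2]))
    spec_end = SyntheticStateSpec(
        n_bins, exponents[1], boundaries, labels_end,
        plaid_strength, tad_strength, int(sub[3]))
    switch_class = tuple(
        f"{a}->{b}" for a, b in zip(labels_start, labels_end)
    )
    pair = StatePair(spec_start, spec_end, switch_class)
    return pair, make_target_map(spec_start), make_target_map(spec_end)
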