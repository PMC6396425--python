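"""Binned contact matrices: vanilla-coverage normalization, expected-by-
distance profiles, and observed/expected transforms.

The matrix is stored as sparse upper-triangular triplets (i <= j). Bins
whose symmetric coverage marginal is zero are flagged excluded and drop out
of every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactMatrix",
    "vc_normalize",
    "expected_by_distance",
    "observed_over_expected",
]


@dataclass
class ContactMatrix:
    """Sparse upper-triangular binned contact map on one chromosome."""

    bin_size: int
    n_bins: int
    chrom: str
    bins_i: np.ndarray
    bins_j: np.ndarray
    values: np.ndarray
    norm_vector: np.ndarray | None = None
    expected: np.ndarray | None = None
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bins_i = np.asarray(self.bins_i, dtype=np.int64)
        self.bins_j = np.asarray(self.bins_j, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (self.bins_i.shape == self.bins_j.shape == self.values.shape):
            raise ValueError("triplet arrays must share a shape")
        if np.any(self.bins_i > self.bins_j):
            raise ValueError("entries must satisfy i <= j (upper triangle)")
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.bins_j.size and self.bins_j.max() >= self.n_bins:
            raise ValueError("bin index beyond n_bins")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_dense(self) -> np.ndarray:
        """Dense upper-triangular array (including the diagonal)."""
        dense = np.zeros((self.n_bins, self.n_bins))
        dense[self.bins_i, self.bins_j] = self.values
        return dense

    def included_mask(self) -> np.ndarray:
        if self.excluded is None:
            return np.ones(self.n_bins, dtype=bool)
        return ~self.excluded


def vc_normalize(matrix: ContactMatrix) -> ContactMatrix:
    """Vanilla-coverage normalization.

    The normalization vector is the full symmetric coverage marginal of
    each bin; each entry is divided by the product of its two bins'
    marginals and the result rescaled so total normalized mass equals the
    total raw mass. Bins with marginal zero are flagged excluded.
    """
    if matrix.total <= 0:
        raise ValueError("cannot normalize an all-zero matrix")
    marg = np.zeros(matrix.n_bins)
    np.add.at(marg, matrix.bins_i, matrix.values)
    off = matrix.bins_i != matrix.bins_j
    np.add.at(marg, matrix.bins_j[off], matrix.values[off])
    excluded = marg == 0
    vi = marg[matrix.bins_i]
    vj = marg[matrix.bins_j]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where((vi > 0) & (vj > 0), matrix.values / (vi * vj), 0.0)
    scale = matrix.total / vals.sum()
    return replace(
        matrix,
        values=vals * scale,
        norm_vector=marg,
        excluded=excluded,
        expected=None,
    )


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean normalized contact per diagonal distance d = j - i.

    The mean at each distance runs over all included bin pairs at that
    distance, counting structural zeros between included bins. Returns an
    array of length ``n_bins`` and stores it on the matrix.
    """
    included = matrix.included_mask()
    sums = np.zeros(matrix.n_bins)
    d = matrix.bins_j - matrix.bins_i
    np.add.at(sums, d, matrix.values)
    # number of included bin pairs at each distance
    inc_idx = np.flatnonzero(included)
    n_pairs = np.zeros(matrix.n_bins)
    for dist in range(matrix.n_bins):
        if dist == 0:
            n_pairs[0] = inc_idx.size
        else:
            # pairs (i, i+dist) with both included
            n_pairs[dist] = np.count_nonzero(
                included[: matrix.n_bins - dist] & included[dist:]
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(n_pairs > 0, sums / n_pairs, 0.0)
    matrix.expected = expected
    return expected


def observed_over_expected(matrix: ContactMatrix) -> ContactMatrix:
    """O/E transform: each normalized entry divided by the expected value
    at its diagonal. Entries at distances with expected 0, or touching an
    excluded bin, are undefined and omitted."""
    if matrix.expected is None:
        expected_by_distance(matrix)
    expected = matrix.expected
    included = matrix.included_mask()
    d = matrix.bins_j - matrix.bins_i
    defined = (expected[d] > 0) & included[matrix.bins_i] & included[matrix.bins_j]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = matrix.values[defined] / expected[d[defined]]
    return replace(
        matrix,
        bins_i=matrix.bins_i[defined],
        bins_j=matrix.bins_j[defined],
        values=oe,
        expected=expected,
    )
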