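"""Contact-matrix I/O, balancing and summary profiles.

The central object is :class:`ContactMatrix`: a dense, symmetric,
non-negative bin x bin frequency matrix on a circular genome binning, with
an explicit mask of excluded (low-coverage) bins.  Operations here cover
SCN balancing, distance-decay curves, cross-condition log-ratio maps and
the short-range interaction frequency/proportion profiles used to
characterize how a bin interacts with its genomic neighbourhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .errors import DimensionError, EmptyMatrixError, MatrixFormatError

__all__ = [
    "ContactMatrix",
    "DecayProfile",
    "RatioMatrix",
    "ShortRangeProfile",
    "read_matrix",
    "read_sparse_triplets",
    "scn_normalize",
    "distance_decay",
    "log_ratio_map",
    "short_range_frequency",
    "short_range_proportion",
]

_SYM_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact-frequency matrix.

    ``mask`` is a boolean vector, ``True`` for excluded bins; masked rows
    and columns are kept all-zero so downstream sums need no special
    casing.
    """

    binning: GenomeBinning
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.binning.n_bins
        if self.values.shape != (n, n):
            raise DimensionError(
                f"matrix shape {self.values.shape} != binning ({n}, {n})"
            )
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contact matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("contact matrix contains negative values")
        if np.max(np.abs(self.values - self.values.T)) > _SYM_TOL * max(
            1.0, float(np.max(np.abs(self.values)))
        ):
            raise ValueError("contact matrix is not symmetric; use read_matrix")
        self.values[self.mask, :] = 0.0
        self.values[:, self.mask] = 0.0

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    @property
    def unmasked(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)

    def copy(self) -> "ContactMatrix":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass
class DecayProfile:
    """Mean contact frequency as a function of circular bin separation."""

    distances: np.ndarray  # bin separations 0..floor(n/2)
    mean_frequency: np.ndarray
    binning: GenomeBinning

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "separation_bp": self.distances * self.binning.bin_size,
                "mean_frequency": self.mean_frequency,
            }
        )


@dataclass
class RatioMatrix:
    """log2 ratio of two contact matrices (condition A over condition B)."""

    binning: GenomeBinning
    values: np.ndarray
    pseudocount: float
    mask: np.ndarray


@dataclass
class ShortRangeProfile:
    """Per-bin short-range interaction summaries.

    ``per_bin_frequency[i, d]`` is the average of the two flanking contacts
    of bin ``i`` at separation ``d`` (upstream/downstream mean);
    ``per_bin_proportion[i]`` is the fraction of bin ``i``'s total contacts
    that fall within ``window`` bp.  Either field may be ``None`` depending
    on which summary produced the profile.
    """

    window: int
    per_bin_frequency: np.ndarray | None = None
    per_bin_proportion: np.ndarray | None = None


def read_matrix(path, binning: GenomeBinning) -> ContactMatrix:
    """Read a dense whitespace-delimited n x n contact matrix.

    An optional leading header row and/or first column of bin start
    coordinates is detected and stripped.  Asymmetric input is symmetrized
    as ``(M + M.T) / 2`` with a warning.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    raw = df.to_numpy()
    n = binning.n_bins

    def to_float(a):
        try:
            return a.astype(float)
        except (TypeError, ValueError):
            return None

    values = to_float(raw)
    if raw.shape == (n + 1, n + 1):
        # a leading row+column of bin coordinates (possibly textual)
        stripped = to_float(raw[1:, 1:])
        if stripped is not None:
            values = stripped
    elif values is None:
        # textual header row and/or coordinate column
        for cand in (raw[1:, :], raw[:, 1:], raw[1:, 1:]):
            stripped = to_float(cand)
            if stripped is not None:
                values = stripped
                break
    if values is None:
        raise MatrixFormatError(f"non-numeric entries in {path}")
    if values.shape[0] != values.shape[1]:
        raise MatrixFormatError(f"matrix in {path} is not square: {values.shape}")
    if values.shape != (n, n):
        raise DimensionError(
            f"matrix in {path} has {values.shape[0]} bins, binning expects {n}"
        )
    if np.any(values < 0):
        raise ValueError(f"negative contact frequencies in {path}")
    asym = np.max(np.abs(values - values.T))
    if asym > _SYM_TOL * max(1.0, float(np.max(np.abs(values)))):
        warnings.warn(
            f"input matrix asymmetric (max |M - M.T| = {asym:.3g}); "
            "symmetrizing as (M + M.T)/2",
            stacklevel=2,
        )
        values = (values + values.T) / 2.0
    return ContactMatrix(binning=binning, values=values)


def read_sparse_triplets(path, binning: GenomeBinning) -> ContactMatrix:
    """Read a cooler-style sparse triplet table ``bin1 bin2 count``."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] != 3:
        raise MatrixFormatError("triplet file must have 3 columns")
    n = binning.n_bins
    i = df.iloc[:, 0].to_numpy(dtype=int)
    j = df.iloc[:, 1].to_numpy(dtype=int)
    c = df.iloc[:, 2].to_numpy(dtype=float)
    if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
        raise DimensionError("triplet bin index out of range")
    if np.any(c < 0):
        raise ValueError("negative counts in triplet file")
    values = np.zeros((n, n))
    np.add.at(values, (i, j), c)
    upper = np.triu(values, 1)
    lower = np.tril(values, -1)
    # entries given on one side only are mirrored; duplicated pairs averaged
    off = np.where((upper > 0) & (lower.T > 0), (upper + lower.T) / 2,
                   upper + lower.T)
    values = np.diag(np.diag(values)) + off + off.T
    return ContactMatrix(binning=binning, values=values)


def write_matrix(M: ContactMatrix, path) -> None:
    np.savetxt(path, M.values, fmt="%.8g", delimiter="\t")


def scn_normalize(
    M: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
    min_coverage_quantile: float = 0.01,
) -> ContactMatrix:
    """Balance a raw matrix by sequential component normalization (SCN).

    Rows and then columns of the unmasked submatrix are iteratively divided
    by their Euclidean (L2) norms until the largest relative entry change
    drops below ``tol``.  A final ``(W + W.T)/2`` restores exact symmetry.
    Bins whose raw coverage (row sum) falls below the
    ``min_coverage_quantile`` quantile — and all-zero bins — are masked
    before balancing and stay zero in the output.
    """
    values = M.values
    row_sums = values.sum(axis=1)
    mask = M.mask.copy()
    alive = row_sums[~mask]
    if alive.size:
        cutoff = np.quantile(alive, min_coverage_quantile)
        mask |= row_sums < cutoff
    mask |= row_sums <= 0
    keep = np.flatnonzero(~mask)
    if keep.size == 0:
        raise EmptyMatrixError("all bins masked during SCN normalization")

    W = values[np.ix_(keep, keep)].astype(float)
    converged = False
    for _ in range(max_iter):
        prev = W.copy()
        rn = np.linalg.norm(W, axis=1)
        rn[rn == 0] = 1.0
        W = W / rn[:, None]
        cn = np.linalg.norm(W, axis=0)
        cn[cn == 0] = 1.0
        W = W / cn[None, :]
        denom = np.maximum(np.abs(prev), 1e-300)
        if np.max(np.abs(W - prev) / denom) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SCN did not converge to tol={tol} within {max_iter} iterations",
            stacklevel=2,
        )
    W = (W + W.T) / 2.0

    out = np.zeros_like(values)
    out[np.ix_(keep, keep)] = W
    return ContactMatrix(binning=M.binning, values=out, mask=mask, normalized=True)


def distance_decay(M: ContactMatrix) -> DecayProfile:
    """Mean contact frequency per circular separation s = 0..floor(n/2).

    The mean at separation ``s`` is taken over pairs ``(i, i+s)`` with both
    bins unmasked, walking the full circle.
    """
    n = M.n_bins
    smax = n // 2
    good = ~M.mask
    if not good.any():
        raise EmptyMatrixError("all bins masked")
    idx = np.arange(n)
    mean_freq = np.empty(smax + 1)
    for s in range(smax + 1):
        j = (idx + s) % n
        sel = good & good[j]
        mean_freq[s] = M.values[idx[sel], j[sel]].mean() if sel.any() else np.nan
    return DecayProfile(
        distances=np.arange(smax + 1), mean_frequency=mean_freq, binning=M.binning
    )


def log_ratio_map(
    M_a: ContactMatrix, M_b: ContactMatrix, pseudocount: float | None = None
) -> RatioMatrix:
    """log2((A + pc) / (B + pc)) map between two normalized matrices.

    The default pseudocount is the smallest positive entry across the two
    matrices, giving a symmetric diverging scale without swamping weak
    contacts.  The union of the masks is applied (masked rows/cols are 0).
    """
    if M_a.binning != M_b.binning:
        raise DimensionError("ratio map requires identical binnings")
    mask = M_a.mask | M_b.mask
    if pseudocount is None:
        pooled = np.concatenate([M_a.values.ravel(), M_b.values.ravel()])
        positive = pooled[pooled > 0]
        pseudocount = float(positive.min()) if positive.size else 1.0
    if pseudocount <= 0 and (np.any(M_a.values == 0) or np.any(M_b.values == 0)):
        raise ValueError("pseudocount must be > 0 when zero entries are present")
    values = np.log2((M_a.values + pseudocount) / (M_b.values + pseudocount))
    values[mask, :] = 0.0
    values[:, mask] = 0.0
    return RatioMatrix(
        binning=M_a.binning, values=values, pseudocount=pseudocount, mask=mask
    )


def short_range_frequency(
    M: ContactMatrix, max_distance: int = 1_000_000
) -> ShortRangeProfile:
    """Average flanking contact frequency of each bin per separation.

    ``per_bin_frequency[i, d]`` averages the upstream and downstream
    contacts of bin ``i`` at separation ``d`` bins; ``d = 0`` is the
    self-contact.  Rows of masked bins are zero.
    """
    binning = M.binning
    if max_distance > binning.genome_length / 2:
        raise ValueError("max_distance exceeds half the genome length")
    dmax = max_distance // binning.bin_size
    n = M.n_bins
    idx = np.arange(n)
    freq = np.zeros((n, dmax + 1))
    freq[:, 0] = np.diag(M.values)
    for d in range(1, dmax + 1):
        up = M.values[idx, (idx - d) % n]
        down = M.values[idx, (idx + d) % n]
        freq[:, d] = (up + down) / 2.0
    freq[M.mask, :] = 0.0
    return ShortRangeProfile(window=max_distance, per_bin_frequency=freq)


def short_range_proportion(M: ContactMatrix, window: int) -> ShortRangeProfile:
    """Fraction of each bin's contacts within ``window`` bp.

    Self-contacts are excluded from both numerator and denominator.  Bins
    with no contacts at all (or masked) get NaN.
    """
    binning = M.binning
    if window > binning.genome_length / 2:
        raise ValueError("window exceeds half the genome length")
    w = window // binning.bin_size
    sep = binning.separation_matrix()
    off_diag = sep > 0
    near = off_diag & (sep <= w)
    totals = np.where(off_diag, M.values, 0.0).sum(axis=1)
    near_sums = np.where(near, M.values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(totals > 0, near_sums / totals, np.nan)
    prop[M.mask] = np.nan
    return ShortRangeProfile(window=window, per_bin_proportion=prop)
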