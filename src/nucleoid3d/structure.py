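"""3D chromosome models: I/O, distance summaries, fallback embedding.

A :class:`Structure3D` holds one 3D point per (unmasked) genome bin, as
produced by external reconstruction programs from normalized contact
matrices.  Distances between points — D(i, j) — feed the compactness
metrics and the macrodomain distance summaries.  A classical
multidimensional-scaling embedding is provided as plumbing so the whole
pipeline can run on synthetic data without any external modelling tool; it
makes no attempt to reproduce any particular reconstruction algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .binning import GenomeBinning
from .contact_matrix import ContactMatrix
from .errors import DimensionError, EmbeddingError, MatrixFormatError

__all__ = [
    "Structure3D",
    "MacrodomainMap",
    "DistanceSummary",
    "read_structure",
    "write_xyz",
    "read_macrodomains_bed",
    "pairwise_distance_distribution",
    "macrodomain_distances",
    "fallback_embedding",
]


@dataclass
class Structure3D:
    """One 3D coordinate per bin, in arbitrary model units.

    ``present`` lists the bin indices that actually have coordinates (all
    bins by default); masked bins of the source matrix are simply absent.
    """

    binning: GenomeBinning
    coords: np.ndarray
    label: str = ""
    present: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DimensionError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.present is None:
            self.present = np.arange(self.binning.n_bins)
        self.present = np.asarray(self.present, dtype=int)
        if self.coords.shape[0] != self.present.size:
            raise DimensionError(
                f"{self.coords.shape[0]} points for {self.present.size} bins"
            )

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def distances(self) -> np.ndarray:
        """Full pairwise Euclidean distance matrix D(i, j) between points."""
        return squareform(pdist(self.coords))


@dataclass
class MacrodomainMap:
    """Named base-pair intervals (Ori, Ter, Left, Right, NS-left, NS-right).

    Intervals are 0-based half-open and may wrap the origin; they must not
    overlap.
    """

    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (s, e) in self.intervals.items():
            if s == e:
                raise ValueError(f"empty interval for {name}")

    def bins(self, binning: GenomeBinning) -> dict[str, np.ndarray]:
        out = {
            name: binning.bins_in_interval(s, e)
            for name, (s, e) in self.intervals.items()
        }
        all_bins = np.concatenate(list(out.values())) if out else np.array([])
        if all_bins.size != np.unique(all_bins).size:
            raise ValueError("macrodomain intervals overlap")
        return out


@dataclass
class DistanceSummary:
    """Histogram of pairwise distances and per-domain-pair mean distances."""

    hist_edges: np.ndarray | None = None
    hist_counts: np.ndarray | None = None
    class_means: dict[tuple[str, str], float] = field(default_factory=dict)
    class_distances: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def means_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, m, self.class_distances[(a, b)].size)
            for (a, b), m in self.class_means.items()
        ]
        return pd.DataFrame(rows, columns=["domain_a", "domain_b", "mean_distance", "n_pairs"])


def read_structure(path, binning: GenomeBinning) -> Structure3D:
    """Read a 3D model from an XYZ-style or PDB-like CA-trace file.

    XYZ lines are ``x y z`` or ``index x y z`` (reordered by index).
    PDB-like files are read from their ATOM/HETATM records.
    """
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if any(ln.startswith(("ATOM", "HETATM")) for ln in lines):
        coords = []
        for ln in lines:
            if ln.startswith(("ATOM", "HETATM")):
                try:
                    coords.append(
                        [float(ln[30:38]), float(ln[38:46]), float(ln[46:54])]
                    )
                except ValueError as exc:
                    raise MatrixFormatError(f"bad ATOM record in {path}") from exc
        arr = np.asarray(coords)
    else:
        rows = []
        for ln in lines:
            parts = ln.split()
            if len(parts) not in (3, 4):
                raise MatrixFormatError(
                    f"expected 3 or 4 columns per line in {path}, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise MatrixFormatError(f"non-numeric coordinate in {path}") from exc
        arr = np.asarray(rows)
        if arr.shape[1] == 4:
            arr = arr[np.argsort(arr[:, 0]), 1:]
    if arr.shape[0] != binning.n_bins:
        raise DimensionError(
            f"{arr.shape[0]} points in {path}, binning expects {binning.n_bins}"
        )
    return Structure3D(binning=binning, coords=arr, label=path)


def write_xyz(s: Structure3D, path) -> None:
    with open(path, "w") as fh:
        for b, (x, y, z) in zip(s.present, s.coords):
            fh.write(f"{b}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_macrodomains_bed(path) -> MacrodomainMap:
    """Read named macrodomain intervals from a BED file (chrom start end name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise MatrixFormatError("macrodomain BED needs 4 columns (chrom start end name)")
    intervals = {
        str(r[3]): (int(r[1]), int(r[2])) for r in df.itertuples(index=False)
    }
    return MacrodomainMap(intervals=intervals)


def pairwise_distance_distribution(s: Structure3D, n_hist_bins: int = 50) -> DistanceSummary:
    """Histogram of all unordered pairwise distances in the model."""
    if s.n_points < 2:
        raise ValueError("need at least two points")
    d = pdist(s.coords)
    counts, edges = np.histogram(d, bins=n_hist_bins)
    return DistanceSummary(hist_edges=edges, hist_counts=counts)


def macrodomain_distances(s: Structure3D, domains: MacrodomainMap) -> DistanceSummary:
    """Distance sets between and within macrodomains.

    For two distinct domains the class holds all cross distances (the "OT",
    "OL", ... classes); within one domain it holds all unordered intra
    pairs.  A single-bin domain has no intra pairs; its intra mean is NaN.
    """
    dom_bins = domains.bins(s.binning)
    pos_of = {int(b): k for k, b in enumerate(s.present)}
    summary = DistanceSummary()
    D = s.distances()
    names = list(dom_bins)
    for name, bins in dom_bins.items():
        if bins.size == 0:
            raise ValueError(f"macrodomain {name} maps to no bins")
    for ai, a in enumerate(names):
        for b in names[ai:]:
            rows = np.array([pos_of[int(x)] for x in dom_bins[a] if int(x) in pos_of])
            cols = np.array([pos_of[int(x)] for x in dom_bins[b] if int(x) in pos_of])
            if a == b:
                if rows.size < 2:
                    vals = np.array([])
                else:
                    sub = D[np.ix_(rows, rows)]
                    vals = sub[np.triu_indices(rows.size, k=1)]
            else:
                vals = D[np.ix_(rows, cols)].ravel()
            key = (a, b)
            summary.class_distances[key] = vals
            summary.class_means[key] = float(vals.mean()) if vals.size else float("nan")
    return summary


def fallback_embedding(
    M: ContactMatrix, alpha: float = 1.0, seed: int = 0, pseudocount: float = 0.0
) -> Structure3D:
    """Embed a contact matrix in 3D by classical metric scaling.

    Target distances are ``D_ij = (1 / (M_ij + pseudocount)) ** alpha``
    (stronger contact = closer), embedded by eigendecomposition of the
    double-centred squared-distance matrix.  Deterministic given ``seed``
    (the seed fixes the sign convention of the principal axes).  Masked
    bins are dropped; the returned structure covers unmasked bins only.

    This is generic plumbing for synthetic round-trips; it is not a
    reconstruction method of its own.
    """
    keep = M.unmasked
    if keep.size < 4:
        raise EmbeddingError("need at least 4 unmasked bins")
    W = M.values[np.ix_(keep, keep)] + pseudocount
    off = W[~np.eye(keep.size, dtype=bool)]
    if np.any(off <= 0):
        raise EmbeddingError("matrix has non-positive off-diagonal entries; add a pseudocount")
    if np.ptp(off) <= 1e-12 * np.max(off):
        raise EmbeddingError("degenerate matrix: all contacts equal")
    with np.errstate(divide="ignore"):
        D = (1.0 / W) ** alpha
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    from scipy.linalg import eigh

    vals, vecs = eigh(B, subset_by_index=(n - 3, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.sum(vals > 0) < 2:
        raise EmbeddingError("matrix does not admit a 2D/3D metric embedding")
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    # deterministic sign convention: largest-magnitude loading positive
    for k in range(3):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return Structure3D(binning=M.binning, coords=coords, present=keep, label="cmds-embedding")
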