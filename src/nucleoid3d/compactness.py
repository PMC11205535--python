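"""Global and Local Compactness of 3D chromosome models.

Both metrics compare pairwise distances in the model, D(i, j), with
distances d(i, j) on an idealized "unfolded" reference of identical
backbone contour length:

* **Global Compactness**  GC = -log2( sum_{i!=j} D(i,j) / sum_{i!=j} d(i,j) )
  where the reference is a circle carrying the bins at angular spacings
  proportional to the model's backbone segment lengths and d(i, j) is the
  chord distance.  The circle radius is set so that the reference polygon
  (the chain of adjacent-bin chords) has the same contour length as the
  model backbone; a model that is itself a uniform ring therefore scores
  exactly GC = 0, and any folding of the ring pushes GC above 0.

* **Local Compactness**  LC_i = -log2( sum_j D(i,j) / sum_j d(i,j) ),
  j running over the window [i - t, i + t] (t = thr / bin_size, wrapping
  on a circular genome), with the reference a straight line whose
  consecutive spacings equal the model's backbone segment lengths inside
  the window.  Equally spaced collinear points score LC = 0; local folding
  raises LC.

Both are dimensionless and invariant under rigid motions and uniform
scaling (numerator and denominator scale together).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import DimensionError
from .structure import Structure3D

__all__ = [
    "CompactnessProfile",
    "global_compactness",
    "local_compactness",
    "lc_multiscale",
    "lc_log_ratio",
]


@dataclass
class CompactnessProfile:
    """Scalar GC plus per-bin LC values at one or more scales."""

    gc: float
    lc: np.ndarray  # (n_scales, n_points)
    scales: np.ndarray  # base-pair thresholds, ascending
    label: str = ""

    def to_frame(self, structure: Structure3D | None = None) -> pd.DataFrame:
        bins = (
            structure.present
            if structure is not None
            else np.arange(self.lc.shape[1])
        )
        rows = []
        for si, scale in enumerate(self.scales):
            for b, v in zip(bins, self.lc[si]):
                rows.append((int(scale), int(b), v))
        return pd.DataFrame(rows, columns=["scale_bp", "bin", "lc"])


def _backbone_segments(coords: np.ndarray, closed: bool = True) -> np.ndarray:
    """Lengths of consecutive backbone segments (closing edge if closed)."""
    diffs = np.diff(coords, axis=0)
    seg = np.linalg.norm(diffs, axis=1)
    if closed:
        seg = np.append(seg, np.linalg.norm(coords[0] - coords[-1]))
    return seg


def _circle_reference_chords(coords: np.ndarray) -> np.ndarray:
    """Pairwise chord distances on the equal-contour reference circle.

    Bins sit on a circle at angles proportional to the cumulative backbone
    length; the radius is chosen so the reference polygon perimeter equals
    the model contour length.
    """
    seg = _backbone_segments(coords, closed=True)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero backbone contour length (all points coincident)")
    theta = 2.0 * np.pi * np.concatenate(([0.0], np.cumsum(seg[:-1]))) / total
    dtheta = 2.0 * np.pi * seg / total
    perimeter_unit = np.sum(2.0 * np.sin(dtheta / 2.0))  # radius-1 polygon
    radius = total / perimeter_unit
    half = np.abs(theta[:, None] - theta[None, :]) / 2.0
    return 2.0 * radius * np.abs(np.sin(half))


def global_compactness(s: Structure3D) -> float:
    """GC of a 3D model against its equal-contour reference circle."""
    if s.n_points < 3:
        raise ValueError("need at least 3 points")
    coords = s.coords
    d_ref = _circle_reference_chords(coords)
    D_sum = 2.0 * pdist(coords).sum()  # ordered pairs; factor cancels anyway
    d_sum = d_ref.sum()
    return float(-np.log2(D_sum / d_sum))


def local_compactness(s: Structure3D, thr: int) -> np.ndarray:
    """Per-bin LC at one genomic scale ``thr`` (base pairs).

    The window half-width in bins is ``t = thr // bin_size``; on a
    circular binning windows wrap, on a linear one they truncate at the
    chromosome ends.  Within the window the reference line reproduces the
    model's own backbone segment lengths, so only folding (not stretching)
    changes LC.
    """
    t = thr // s.binning.bin_size
    n = s.n_points
    if t < 1:
        raise ValueError("thr smaller than one bin")
    circular = s.binning.circular
    if circular and t >= n / 2:
        raise ValueError("local window must span less than half the genome")
    seg = _backbone_segments(s.coords, closed=circular)
    coords = s.coords
    lc = np.empty(n)
    for i in range(n):
        if circular:
            offsets = np.arange(-t, t + 1)
            idx = (i + offsets) % n
        else:
            lo, hi = max(0, i - t), min(n - 1, i + t)
            idx = np.arange(lo, hi + 1)
        # cumulative backbone position along the window path
        pos = np.zeros(idx.size)
        for k in range(1, idx.size):
            pos[k] = pos[k - 1] + seg[idx[k - 1] % seg.size]
        center = int(np.flatnonzero(idx == i)[0])
        others = np.flatnonzero(idx != i)
        D = np.linalg.norm(coords[idx[others]] - coords[i], axis=1)
        d = np.abs(pos[others] - pos[center])
        lc[i] = -np.log2(D.sum() / d.sum())
    return lc


def lc_multiscale(s: Structure3D, scales) -> CompactnessProfile:
    """LC profiles over several genomic scales plus the model's GC.

    Scales are sorted ascending in the output regardless of input order.
    """
    scales = np.asarray(sorted(int(x) for x in scales))
    if scales.size == 0:
        raise ValueError("empty scale list")
    lc = np.vstack([local_compactness(s, int(thr)) for thr in scales])
    return CompactnessProfile(
        gc=global_compactness(s), lc=lc, scales=scales, label=s.label
    )


def lc_log_ratio(a: CompactnessProfile, b: CompactnessProfile) -> np.ndarray:
    """Elementwise log2(LC_a / LC_b) across scales and bins.

    Entries where either LC is <= 0 (the ratio has no meaningful log) are
    returned as NaN.
    """
    if a.lc.shape != b.lc.shape or not np.array_equal(a.scales, b.scales):
        raise DimensionError("compactness profiles have different scales/shape")
    out = np.full(a.lc.shape, np.nan)
    ok = (a.lc > 0) & (b.lc > 0)
    out[ok] = np.log2(a.lc[ok] / b.lc[ok])
    return out
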