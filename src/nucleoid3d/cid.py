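"""Directionality index and chromosome interaction domain (CID) boundaries.

The directionality index (DI) of a bin contrasts its summed upstream and
downstream contacts within a genomic window; sign changes of the DI along
the chromosome mark CID boundaries, the bacterial analogue of TAD
boundaries.  This module computes DI profiles, calls boundaries from sign
alternation, compares boundary sets between conditions, and extracts genes
residing at boundary bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .contact_matrix import ContactMatrix
from .errors import DimensionError

__all__ = [
    "DIProfile",
    "BoundarySet",
    "DifferentialBoundaries",
    "directionality_index",
    "call_cid_boundaries",
    "compare_boundaries",
    "boundary_genes",
    "read_genes_gff3",
    "boundaries_to_bed",
]


@dataclass
class DIProfile:
    """Per-bin directionality index with the audit sums it derives from."""

    di: np.ndarray
    window: int
    upstream_sum: np.ndarray  # A
    downstream_sum: np.ndarray  # B
    expected: np.ndarray  # E = (A + B) / 2
    binning: GenomeBinning


@dataclass
class BoundarySet:
    """Ordered CID boundary bins for one condition.

    On a circular genome each boundary starts one domain, so the number of
    CIDs equals the number of boundaries.
    """

    boundaries: np.ndarray
    binning: GenomeBinning
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(sorted(set(int(b) for b in self.boundaries)))
        n = self.binning.n_bins
        if self.boundaries.size and (
            self.boundaries.min() < 0 or self.boundaries.max() >= n
        ):
            raise ValueError("boundary bin index out of range")

    @property
    def n_cids(self) -> int:
        return int(self.boundaries.size)


@dataclass
class DifferentialBoundaries:
    """Matched and condition-unique boundaries between two boundary sets."""

    matched: list[tuple[int, int]]
    unique_to_a: np.ndarray
    unique_to_b: np.ndarray
    tolerance_bins: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("matched", a, b) for a, b in self.matched]
        rows += [("unique_to_a", a, -1) for a in self.unique_to_a]
        rows += [("unique_to_b", -1, b) for b in self.unique_to_b]
        return pd.DataFrame(rows, columns=["category", "bin_a", "bin_b"])


def directionality_index(M: ContactMatrix, window: int = 100_000) -> DIProfile:
    """Directionality index per bin.

    With ``A``/``B`` the summed contacts over ``w = window / bin_size``
    upstream/downstream bins and ``E = (A + B) / 2``::

        DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

    DI is 0 wherever ``A == B`` or ``E == 0``.  The window should be
    matched to the expected domain scale: sensitivity is best when the
    window is around half the typical domain size, so that one of the two
    sums crosses a boundary for every bin inside a domain.
    """
    binning = M.binning
    w = window // binning.bin_size
    n = M.n_bins
    if w < 1:
        raise ValueError("window smaller than one bin")
    if w >= n / 2:
        raise ValueError("DI window must span less than half the genome")
    idx = np.arange(n)
    A = np.zeros(n)
    B = np.zeros(n)
    for d in range(1, w + 1):
        A += M.values[idx, (idx - d) % n]
        B += M.values[idx, (idx + d) % n]
    E = (A + B) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = (A - E) ** 2 / E + (B - E) ** 2 / E
    di = np.sign(B - A) * chi
    di[(A == B) | (E == 0)] = 0.0
    di[M.mask] = 0.0
    return DIProfile(
        di=di, window=window, upstream_sum=A, downstream_sum=B, expected=E,
        binning=binning,
    )


def _sign_runs(order: np.ndarray, signs: np.ndarray) -> list[tuple[int, list[int]]]:
    """Compress an ordered (bin, sign) sequence into maximal same-sign runs."""
    runs: list[tuple[int, list[int]]] = []
    for b, s in zip(order, signs):
        if runs and runs[-1][0] == s:
            runs[-1][1].append(int(b))
        else:
            runs.append((int(s), [int(b)]))
    return runs


def _merge_circular(runs: list[tuple[int, list[int]]]) -> list[tuple[int, list[int]]]:
    """Merge adjacent same-sign runs, treating the list as circular."""
    merged: list[tuple[int, list[int]]] = []
    for s, bins in runs:
        if merged and merged[-1][0] == s:
            merged[-1][1].extend(bins)
        else:
            merged.append((s, list(bins)))
    if len(merged) > 1 and merged[0][0] == merged[-1][0]:
        # wrap-around merge: the last run precedes the first
        s, bins = merged.pop()
        merged[0] = (merged[0][0], bins + merged[0][1])
    return merged


def call_cid_boundaries(di: DIProfile, min_run: int = 3) -> BoundarySet:
    """Call CID boundaries from DI sign alternation.

    Zero-DI bins are skipped.  The remaining bins are compressed into
    maximal sign runs along the circular genome; runs shorter than
    ``min_run`` bins are treated as noise and discarded (their neighbours
    then merge).  A boundary is placed at the first bin of each surviving
    positive run that follows a negative run — the start of a new domain of
    downstream-biased contacts.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    nz = np.flatnonzero(di.di != 0)
    if nz.size == 0:
        return BoundarySet(boundaries=np.array([], dtype=int), binning=di.binning)
    runs = _merge_circular(_sign_runs(nz, np.sign(di.di[nz])))
    while True:
        kept = [r for r in runs if len(r[1]) >= min_run]
        merged = _merge_circular(kept)
        if merged == runs:
            break
        runs = merged
    if len(runs) < 2:
        return BoundarySet(boundaries=np.array([], dtype=int), binning=di.binning)
    boundaries = []
    for k, (s, bins) in enumerate(runs):
        prev_sign = runs[k - 1][0]
        if s > 0 and prev_sign < 0:
            boundaries.append(bins[0])
    return BoundarySet(boundaries=np.array(boundaries, dtype=int), binning=di.binning)


def compare_boundaries(
    a: BoundarySet, b: BoundarySet, tolerance_bins: int = 1
) -> DifferentialBoundaries:
    """Greedy nearest matching of two boundary sets under circular distance.

    Candidate pairs within ``tolerance_bins`` are matched closest-first;
    every boundary ends up either in one matched pair or in the
    condition-unique remainder.
    """
    if a.binning != b.binning:
        raise DimensionError("boundary sets use different binnings")
    pairs = []
    for i in a.boundaries:
        for j in b.boundaries:
            d = int(a.binning.bin_distance(i, j))
            if d <= tolerance_bins:
                pairs.append((d, int(i), int(j)))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            matched.append((i, j))
            used_a.add(i)
            used_b.add(j)
    unique_a = np.array([i for i in a.boundaries if i not in used_a], dtype=int)
    unique_b = np.array([j for j in b.boundaries if j not in used_b], dtype=int)
    return DifferentialBoundaries(
        matched=sorted(matched),
        unique_to_a=unique_a,
        unique_to_b=unique_b,
        tolerance_bins=tolerance_bins,
    )


def read_genes_gff3(path) -> pd.DataFrame:
    """Load gene intervals from GFF3 into a 0-based half-open table."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.start - 1, feat.end, feat.strand))
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])


def boundary_genes(
    bset: BoundarySet, annotation: pd.DataFrame
) -> list[str]:
    """Genes overlapping any boundary bin span (strand-agnostic).

    ``annotation`` needs columns ``gene_id``, ``start``, ``end`` in 0-based
    half-open coordinates.  Genes touching a bin edge without overlap are
    excluded.
    """
    binning = bset.binning
    if annotation.empty:
        return []
    if (annotation["end"] > binning.genome_length).any() or (
        annotation["start"] < 0
    ).any():
        raise ValueError("gene coordinates outside the genome")
    hits: list[tuple[int, str]] = []
    for b in bset.boundaries:
        span_start, span_end = binning.bin_span(int(b))
        sel = (annotation["start"] < span_end) & (annotation["end"] > span_start)
        for _, row in annotation[sel].iterrows():
            hits.append((int(row["start"]), str(row["gene_id"])))
    seen: set[str] = set()
    out: list[str] = []
    for _, gid in sorted(hits):
        if gid not in seen:
            seen.add(gid)
            out.append(gid)
    return out


def boundaries_to_bed(bset: BoundarySet, path, name_prefix: str = "CID_boundary") -> None:
    """Write boundary bin spans as 0-based half-open BED intervals."""
    with open(path, "w") as fh:
        for k, b in enumerate(bset.boundaries):
            start, end = bset.binning.bin_span(int(b))
            fh.write(f"chr\t{start}\t{end}\t{name_prefix}_{k}\n")
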