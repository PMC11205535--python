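"""Binned transcription tracks and structure-expression correlation.

Gene-level FPKM values are spread onto the genome binning (allocation
proportional to overlap length), log2-transformed, and standardized to
Z-scores; the same standardization is applied to per-bin contact summaries
(the matrix diagonal or a near-diagonal band) or to LC profiles, and the
two tracks are compared by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binning import GenomeBinning
from .contact_matrix import ContactMatrix

__all__ = [
    "TranscriptionTrack",
    "CorrelationResult",
    "bin_transcription",
    "diag_band_frequency",
    "zscore_track",
    "correlate_tracks",
    "read_expression_table",
]


@dataclass
class TranscriptionTrack:
    """Per-bin log2 expression level and its Z-score."""

    binning: GenomeBinning
    level: np.ndarray
    zscore: np.ndarray
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.binning.n_bins),
                "level": self.level,
                "zscore": self.zscore,
            }
        )


@dataclass
class CorrelationResult:
    r: float
    p: float
    n_pairs: int


def read_expression_table(path) -> pd.DataFrame:
    """Read a TSV of ``gene_id start end strand fpkm`` (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "start", "end", "fpkm"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    return df


def bin_transcription(
    genes: pd.DataFrame, binning: GenomeBinning, allocation: str = "length"
) -> TranscriptionTrack:
    """Aggregate per-gene FPKM into genome bins.

    Each gene's FPKM is split across the bins it overlaps, proportionally
    to the overlap length (``allocation="length"``), or assigned entirely
    to its start bin (``allocation="start"``).  The bin level is
    ``log2(1 + allocated sum)``; bins with no genes stay at 0.
    """
    if allocation not in ("length", "start"):
        raise ValueError("allocation must be 'length' or 'start'")
    n = binning.n_bins
    raw = np.zeros(n)
    for row in genes.itertuples(index=False):
        start, end, fpkm = int(row.start), int(row.end), float(row.fpkm)
        if end <= start:
            raise ValueError(f"gene with end <= start: {start}..{end}")
        if start < 0 or end > binning.genome_length:
            raise ValueError("gene coordinates outside the genome")
        if fpkm < 0:
            raise ValueError("negative FPKM")
        if allocation == "start":
            raw[binning.bin_of(start)] += fpkm
            continue
        length = end - start
        first = start // binning.bin_size
        last = (end - 1) // binning.bin_size
        for b in range(first, last + 1):
            b_start, b_end = binning.bin_span(b)
            overlap = min(end, b_end) - max(start, b_start)
            raw[b] += fpkm * overlap / length
    level = np.log2(1.0 + raw)
    if np.ptp(level) > 0:
        z = zscore_track(level)
    else:  # uniform (e.g. empty) expression: Z-score undefined
        z = np.full_like(level, np.nan)
    return TranscriptionTrack(binning=binning, level=level, zscore=z, source="fpkm")


def diag_band_frequency(M: ContactMatrix, half_width: int = 10_000) -> np.ndarray:
    """Mean contact frequency of each bin within +/- ``half_width`` bp.

    ``half_width = 0`` reduces to the matrix diagonal.  Masked bins are
    NaN (missing).
    """
    h = half_width // M.binning.bin_size
    n = M.n_bins
    idx = np.arange(n)
    acc = np.array(np.diag(M.values), dtype=float)
    for d in range(1, h + 1):
        acc += M.values[idx, (idx + d) % n] + M.values[idx, (idx - d) % n]
    out = acc / (2 * h + 1)
    out[M.mask] = np.nan
    return out


def zscore_track(x, ddof: int = 1) -> np.ndarray:
    """Standardize a per-bin track to mean 0, SD 1 (sample SD by default).

    NaN entries (masked/missing bins) are ignored for the moments and
    preserved in the output.
    """
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("need at least 2 finite values")
    sd = np.std(x[ok], ddof=ddof)
    if sd == 0:
        raise ValueError("zero standard deviation; Z-score undefined")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def correlate_tracks(a, b) -> CorrelationResult:
    """Pearson correlation between two per-bin tracks.

    Pairs where either track is NaN are dropped; the p-value is two-sided
    from the t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks have different lengths")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    res = stats.pearsonr(a[ok], b[ok])
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n_pairs=int(ok.sum()))
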