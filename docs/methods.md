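# Methods

This note documents the models, conventions and parameter choices behind
`nucleoid3d`, in the order the pipeline runs them.

## Genome model and coordinates

The chromosome is circular (the *E. coli* case: 4,641,652 bp) and is
partitioned into fixed-size bins, 5 kb by default, giving 928 bins for the
full genome. All interval I/O is 0-based half-open internally; 1-based
GFF3 coordinates are converted at the boundary. All genomic distances wrap
around the origin; nothing is truncated at an "end" of the chromosome.
Linear binnings (`circular=False`) exist for test geometries and truncate
windows at the ends instead of wrapping.

## Contact matrices

A `ContactMatrix` is dense, symmetric and non-negative, with an explicit
boolean mask of excluded bins whose rows and columns are kept all-zero.
Asymmetric input files are symmetrized as (M + Mᵀ)/2 with a warning, since
a contact map is symmetric by construction and small asymmetries indicate
upstream rounding.

**SCN balancing.** Rows and then columns of the unmasked submatrix are
divided by their Euclidean (L2) norms, iterating until the largest
relative entry change falls below `tol = 1e-6` (at most 200 iterations,
then a warning but no error — on deep 928-bin matrices the final
approach to the fixed point is slow while row norms already agree to
~1e-6). A final (W + Wᵀ)/2 restores exact symmetry. Before balancing,
bins with raw coverage below the 1st-percentile row sum, and all-zero
bins, are masked: near-empty rows otherwise get inflated by the row
division and dominate every downstream profile.

**Distance decay.** The mean contact at separation *s* is taken over all
pairs (i, i+s) with *both* bins unmasked, for s = 0 … ⌊n/2⌋. Including
pairs with a masked partner would average in structural zeros.

**Ratio maps.** log2((A + pc)/(B + pc)) with the union of masks. The
default pseudocount is the smallest positive entry of the two matrices: it
keeps the map finite without flattening weak contacts, and gives the
symmetric diverging scale the log ratio is meant for.

**Short-range profiles.** The per-bin frequency at separation *d*
averages the upstream and downstream contacts of the bin; the per-bin
proportion is the fraction of a bin's total contacts lying within a
window, with self-contacts excluded from numerator and denominator (a
bin's self-ligation signal says nothing about its neighbourhood). Bins
with zero total contacts get NaN rather than a fabricated proportion.

## Directionality index and CID boundaries

For window w (in bins), A and B are the summed contacts to the w upstream
and downstream bins, E = (A + B)/2, and

    DI = sign(B − A) · ((A − E)²/E + (B − E)²/E),

zero where A = B or E = 0. Boundaries are called from the DI sign pattern
along the circular genome: zero bins are skipped, maximal sign runs
shorter than `min_run = 3` bins are discarded as noise (their neighbours
then merge), and a boundary is placed at the first bin of each surviving
positive run that follows a negative run — the start of a domain of
downstream-biased contacts. On a circular genome every boundary starts a
domain, so the CID count equals the boundary count.

The DI window is an analysis parameter, not a constant of nature. The
default is 100 kb, appropriate for domains of one to two hundred kb.
Sensitivity is best when the window is about half the typical domain
size: then at least one of the two sums crosses a boundary for every bin,
and the DI sign is determined by domain structure everywhere rather than
by noise in domain interiors. The planted-domain validation uses ~465 kb
domains and accordingly a 250 kb window.

Differential boundaries between conditions are matched greedily,
closest-first, under a circular bin-distance tolerance (default ±1 bin);
unmatched boundaries are condition-unique. Genes at boundaries are
reported by strand-agnostic interval overlap with the boundary bin span
(half-open: a gene ending exactly where the bin starts does not overlap).
Enrichment analysis of those genes is out of scope; the gene list is the
interface to external tools.

## 3D models and compactness

A `Structure3D` holds one 3D point per unmasked bin, in arbitrary model
units; all metrics below are invariant under rigid motions and uniform
scaling, so no physical calibration is attempted. Models arrive from
external reconstruction programs (XYZ or PDB-like CA traces); a classical
metric-scaling embedding of (1/M)^α target distances is included as
plumbing so synthetic round-trips can run without any external tool — it
is deliberately not a reconstruction method of its own.

**Global Compactness.** GC = −log2(ΣD(i,j) / Σd(i,j)) over all ordered
pairs, where D is the model distance and d the distance on a reference
circle carrying the bins at angular spacings proportional to the model's
backbone segment lengths. Reference distances are chords, and the circle
radius is chosen so that the reference polygon — the closed chain of
adjacent-bin chords — has the same contour length as the model backbone.
This normalization makes the metric zero-anchored: a model that is itself
a uniform ring reproduces its own reference exactly and scores GC = 0,
and any folding of the ring raises GC. (Fixing the *circumference* to the
contour length instead would leave a small n-dependent offset, since an
inscribed polygon's perimeter is strictly shorter than its circle's
circumference.)

**Local Compactness.** For each bin i and scale `thr`,
LC_i = −log2(Σ_j D(i,j) / Σ_j d(i,j)) with j running over the window
[i − t, i + t], t = thr/bin_size, wrapping on circular genomes. The
reference is a straight line whose consecutive spacings equal the model's
own backbone segment lengths inside the window, so stretching does not
change LC — only folding does. Equally spaced collinear points score
LC = 0 everywhere. Larger LC means higher local compaction. Multiscale
profiles evaluate LC over a list of scales (sorted ascending in the
output); the cross-condition comparison takes log2(LC_a/LC_b) per bin and
scale, reporting NaN where either LC is non-positive (the ratio has no
meaningful logarithm there).

Masked bins are simply absent from the backbone chain; reference curves
are built over present bins only.

## Transcription coupling

Gene-level FPKM is spread over the bins a gene overlaps, proportionally
to overlap length (an assign-to-start-bin mode exists as a flag), and the
bin level is log2(1 + sum) so empty bins are well-defined zeros. Tracks
are standardized to Z-scores using the sample (n−1) standard deviation —
the package-wide convention, pinned by the tests. The structural partner
track is the mean contact frequency in a diagonal band of half-width
10 kb around each bin (half-width 0 reduces to the matrix diagonal; both
are reachable because either convention appears in practice). Association
is measured by Pearson correlation with a two-sided t-distribution
p-value, over pairs where both tracks are finite.

## Nucleoid morphometry

Images are thresholded (Otsu by default; absolute or quantile overrides),
connected components below `min_area = 20` px are discarded, and each
region's length and width are the long and short sides of the
minimum-area rotated rectangle around its sub-pixel outer contour (the
marching-squares isoline at the threshold level, with neighbouring
components blanked first). Using the isoline rather than pixel centres
exploits the graded edge intensity of fluorescence images: on synthetic
rods the dimensions are recovered to well under half a pixel at arbitrary
orientation. Group differences use the two-sided Mann–Whitney U test by
default (no normality assumption; Welch's t is available via a flag) with
star codes ns/*/**/***/**** at p thresholds 0.05/0.01/0.001/0.0001,
boundaries inclusive.

## Synthetic data: what it emulates, and what it does not

The generators plant known structure at the study's real scale (928 bins
of 5 kb) so recovery can be scored exactly:

* **Contact matrices.** E[M_ij] = base · s^(−γ) with circular separation
  s, γ = 1 by default; entries where both bins share a planted domain are
  multiplied by `domain_boost`; contacts crossing a designated Ter-like
  interval at separations beyond `ter_range_bins` (20 bins = 100 kb) are
  divided by `ter_insulation`. `base_level = 1000` puts near-diagonal
  bins in the count range of a deeply sequenced bacterial 3C-seq library
  (~2·10⁷ informative contacts genome-wide). Optional noise draws each
  upper-triangle entry from a Poisson at its expectation, preserving the
  mean.
* **Structures.** A uniform ring with unit bin spacing; each fold region
  adds a radial sinusoidal wiggle (period 8 bins, tapered at the region
  edges) that packs extra backbone into the same span — the signature LC
  detects; optional isotropic jitter models reconstruction noise; the
  contour is rescaled back to its unperturbed length.
* **Transcription.** ρ·z + √(1−ρ²)·noise against the Z-scored diagonal
  band of a given matrix, rescaled to a plausible log2-FPKM range, so the
  planted correlation equals ρ up to sampling error.
* **Images.** Non-overlapping rotated rods with Gaussian-distributed
  dimensions, rendered with per-pixel area coverage (anti-aliased edges,
  as a diffraction-blurred micrograph would show) on a dim background,
  with the true dimensions recorded per rod.

These generators reproduce the *statistical signatures* the pipeline
quantifies, not the physics behind them: there is no polymer model, no
replication or growth-phase dynamics, no optical PSF beyond edge grading,
and real matrices carry coverage biases and long-range artifacts the
Poisson model lacks. Passing the recovery suite therefore shows the
operators measure what they claim on data with known truth — not that
any particular biological conclusion follows from real data.

## Numerical choices and degenerate inputs

* SCN relative-change tolerance 1e-6, 200 iterations, warning (not error)
  on non-convergence; empty-after-masking matrices are errors.
* DI windows must span less than half the genome; LC windows likewise.
* All-zero DI profiles yield an empty boundary set, not an error.
* Zero-variance tracks make Z-scores undefined: an error when requested
  directly, NaN when arising inside track construction (e.g. a genome
  with no genes).
* Embedding requires positive off-diagonal contacts (after an optional
  pseudocount) and refuses all-equal matrices, which admit no meaningful
  3D configuration.
* Coincident-point structures (zero contour) are errors for GC/LC.
* Sub-pixel morphometry falls back to pixel-centre extents (+1 px) if no
  threshold isoline can be traced.

## Validation problem sizes

The validation suite and the reproduction script run the planted-recovery
experiments at the full 928-bin genome scale: 20 Poisson replicates for
boundary recovery (10 planted domains, 3× boost, 250 kb DI window), 20
jittered replicates for fold detection (one 500 kb fold, LC at 50 kb),
100 replicates per planted ρ ∈ {−0.5, 0, 0.5} for correlation recovery,
and one 25-rod field for morphometry; oracle-agreement checks use 20–40
bin inputs where exhaustive double-loop references are cheap.

## Known limitations

* The circle/line reference construction is one defensible convention;
  absolute GC/LC values shift under other conventions (arc instead of
  chord distances, equal instead of length-proportional spacing), so
  comparisons should always use one convention throughout.
* Boundary calling is sign-based by design; it has no confidence score
  and no nested-domain notion.
* The MDS embedding preserves global geometry of exact Euclidean inputs
  but is only a sanity-check stand-in for real reconstruction programs.
* The example macrodomain BED ships rounded, non-wrapping intervals and
  must be verified before any biological use.
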