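# Methods

## Flow-cytometry route

### Model

Propidium iodide intercalates DNA without base-pair preference, so mean
peak fluorescence of a nuclei population is assumed strictly
proportional to nuclear DNA content on the cytometer's linear channel
scale. With a single-point reference standard of known 2C content the
calibration is the exact ratio

    content_pg = (sample peak / standard peak) × standard 2C pg,

with no higher-order standard curve; the estimator is homogeneous in
channel units (rescaling both channels leaves the content unchanged).
The standard may be external (separate tube, a fixed published channel)
or internal (same tube; the lower-channel peak of a two-peak fit).
Content converts to sequence length at 1 pg = 980 Mbp, and to a 1C value
by dividing by the ploidy of the measured nuclei. Ploidy is a user
input per group (haplodiploid males 1, females 2), never inferred from
the data; the `ploidy_consistency` check instead *tests* the expected
2-fold female/male content ratio, passing when |ratio − 2| ≤ 2 × 0.05
by default.

### Peak fitting

Events below a single low-channel debris gate (default 0; a typical
choice is ~10% of the smallest expected peak) are discarded and the rest
binned into 256 uniform bins. Candidate peaks are local maxima of the
lightly smoothed counts with prominence ≥ 5% of the tallest bin; a sum
of independent Gaussians (amplitude, mean, sd each) is then refined
jointly by bounded least squares (`scipy.optimize.curve_fit`), fitting
on the linear channel scale throughout. Initial sds are 4% of the
candidate mean — the CV regime of usable PI histograms — and fit
failures raise a named error rather than returning a partial result.
Each fitted peak carries `cv_percent = 100·sd/mean`; the conventional
validity gate is strict: a peak with CV ≥ 5% is flagged invalid and
excluded from reported sizes unless explicitly overridden. On simulated
runs with n = 20 000 events the fit recovers means within 0.5 channels
and CVs within 0.5 percentage points.

### Replicates and comparison

A group is a set of per-replicate acquisitions (the design emulated
here: 4 replicates of ~50 pooled individuals). Per-replicate peak
channels yield per-replicate contents and sizes; groups are summarized
as mean ± SE (sample sd / √n) and compared by one-way ANOVA computed
from the definitional sums of squares, with pairwise Tukey HSD using
`scipy.stats.studentized_range` quantiles (cached; Tukey–Kramer SE for
unbalanced input, flagged in the output). Compact letters are assigned
by insert-and-absorb in ascending order of group means, so the smallest
mean is "a" and sharing no letter is exactly Tukey significance.

## k-mer route

### Model

For uniform shotgun coverage, genomic k-mer instances total
G × C_k where G is the (haploid) genome length and C_k the mean k-mer
depth, so G = total instances / peak depth of the k-mer spectrum.
Canonical counting (lexicographic minimum of a window and its reverse
complement, k = 17 default) makes the table strand-invariant; windows
containing non-ACGT symbols are skipped whole. Counting is exact and
in-memory: 2-bit integer codes via float64 convolution (max code
4^31 < 2^53, so the arithmetic is exact), `np.unique` for the table.
The memory envelope is ~8 bytes per window, which handles desk-scale
genomes (≤ ~10 Mb at ≤ 50×) in a few GB; it is deliberately not a
disk-backed counter.

### Peak detection and the size estimate

The spectrum f(d) is scanned with a centred moving average (window 3)
for the first local minimum from d = 1 — the error boundary separating
the sequencing-error tail from genomic k-mers; d = 1 itself qualifies
when the spectrum rises immediately (error-free data). Smoothing is
used for landmark detection only; spectrum totals are always computed
on the raw f. The main peak is located on the smoothed curve and then
snapped to the raw argmax within the smoothing half-window. If nothing
above the boundary exceeds the trough height the spectrum is monotone
error-like and a `NoCoveragePeakError` is raised instead of guessing —
raising the error rate at fixed coverage can only keep or create this
condition, never silence it.

Two totals are computed because "total k-mer instances" is ambiguous
when reads contain errors: the all-instances total and the
error-excluded total (depths ≥ boundary). The error-excluded value is
the headline size, since error k-mers only ever inflate the numerator;
both appear in every report. The division is floored to integer bases.

The peak *location* used for the division is a sub-bin refinement: the
mass centroid of raw f over [0.5, 1.5] × mode. At the low end of the
supported design space (k-mer coverage ≈ 14–17) the depth distribution
is visibly overdispersed and right-skewed — reads cover runs of
k − 1 + read-length consecutive k-mers, so depths are strongly
correlated — and the integer mode sits 1–2 bins below the mean depth,
overestimating the size by up to ~12%. The centroid corrects this to
< 4% worst-case across 50–500 kb genomes, 20–50× coverage and 0–1%
error; the integer mode is still reported as `mode_depth`. Depths
beyond `max_depth` (default 1000) are excluded from peak search but
never from totals.

A secondary local maximum in [0.35, 0.65] × the main peak depth with
height ≥ 10% of the main peak (configurable) is reported as the
heterozygous shoulder: haplotype-private k-mers of a diploid occur at
half the depth of shared k-mers. The flag is diagnostic only; no
mixture model is fitted, so the headline size for a strongly
heterozygous diploid approximates the total haplotype span rather than
the 1C length.

## Synthetic data

The generators produce exactly the features the estimators consume, with
ground truth recorded alongside. Genomes are i.i.d. base strings at a
given GC fraction; the second haplotype carries Binomial(L, het_rate)
substitutions at uniform positions. Reads are single-end, sampled
uniformly over positions and haplotypes at a requested fold-coverage
(count exact to ±1 read), with i.i.d. substitution errors and constant
placeholder qualities — no indels, no GC-coverage bias, no insert-size
structure, since k-mer counting consumes none of these. Cytometry
events are Gaussian populations (sd = mean × CV/100) over an
exponential debris background concentrated at low channels (scale
0.15 × the smallest population mean by default; the debris shape is a
free modeling choice, any low-channel-concentrated form exercises the
gate), clipped to the channel range. All randomness is
`numpy.random.default_rng` (PCG64) under one explicit integer seed per
operation, so outputs are byte-reproducible.

Consequently, passing recovery tests show correctness of the estimators
under ideal uniform-coverage, substitution-only, Gaussian-peak
conditions; they do not certify behavior on real libraries with
GC bias, PCR duplicates, repeats beyond chance k-mer collisions, or
non-Gaussian cytometer artifacts.

Simulation sizes in the test and acceptance suites (genomes of 50–500 kb
at 20–50×, 20 000-event cytometry runs, 1000-seed ANOVA calibration)
were chosen as the smallest scales at which the stochastic tolerances
(5% size recovery, 0.5-channel peak recovery, ±1.5 points on the type-I
rate) are statistically meaningful.

## Known limitations

- The k-mer route assumes a mostly unique genome; heavy repeat content
  shifts instance mass to high depths and inflates the estimate (the
  `max_depth` cap bounds the peak search, not the totals).
- No k-mer error correction and no negative-binomial mixture fitting:
  on data where the coverage peak barely clears the error tail the
  module reports the no-peak condition instead of a number.
- FCS binary files are not parsed; per-event CSV export is assumed.
- Cell-cycle (S/G2) populations are not modeled; a 4C shoulder in real
  data would need to be gated out upstream.
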