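# Methods

## Model

The scan tests, window by window, whether the local haplotype frequency
spectrum (HFS) and that of its neighbours look like a sweep centered there.
Windows are SNP-delimited (`winsize` sites, advanced by `winstep`), never
span chromosomes, and drop trailing partial windows. Each sequence — a
haplotype in phased mode, a multilocus genotype (alt-dosage string) in
unphased mode — is reduced to its allele string over the window; ranked
class counts form the window's spectrum. The likelihood uses the spectrum
truncated to the `K` most frequent classes, with the retained counts
rescaled proportionally so they still sum to the number of sequences in the
window.

The neutral expectation `p` is the unweighted mean of the normalized
truncated spectra over all windows genome-wide, re-sorted, renormalized,
floored at `1/(100K)`, and renormalized again. The floor guarantees
`p_K > 0` so every log likelihood is finite and the ε interval below is
well defined. (After the final renormalization `p_K` can sit marginally
below `1/(100K)`; in that degenerate case — a essentially monomorphic
genome — the ε grid collapses to the single point `{p_K}`.)

A sweep with `m` sweeping classes distorts `p` into `q(m)`: tail classes
`k = m+1..K` take `U − (k−m−1)/(K−m−1) · (U−ε)` with `U = p_K`, and the
freed mass `Σ_{j>m}(p_j − q_j)` is added to the top `m` classes with
weights `f_k ∝ e^{-k}`. Edge cases: at `m = K−1` the one-class tail takes
`q_K = ε`; at `m = K` there is no tail and `q = p`, so the null is always a
grid point and Λ (and T) are never negative; they are reported unfloored.

Spatially, window `i` at coordinate `z_i` mixes the distorted and
background spectra with weight `α_i(A) = exp(−A |z_i − z_i*|)`. Composite
log likelihoods sum `x_ik ln p_k` (null) and `x_ik ln g_ik` (alternative)
over the target's chromosome; windows on other chromosomes would contribute
identical terms to both sides and cancel in Λ, so they are omitted from the
sums. Λ, `m̂`, `Â`, `ε̂` come from an exhaustive grid search, re-optimized
independently at every target window.

## Grids and numerical choices

- `m ∈ {1..K}`.
- ε: 100 equally spaced (linear) points on `[1/(100K), U]`.
- A: 100 log-spaced points from `A_min = −ln(0.99999)/d_min` to
  `A_max = −ln(0.00001)/d_min` inclusive, `d_min` the smallest adjacent
  inter-window distance genome-wide (duplicate coordinates are an error).
  At `A_min` the effect barely decays between the closest window pair; at
  `A_max` it is gone (mixture weight ≤ 1e−5) one `d_min` away.
- Ties in the grid maximum break toward smallest `m`, then smallest `A`,
  then smallest ε, giving reproducible argmaxes (exact ties occur: all ε
  are equivalent at `m = K`).
- The `q(m, ε)` table is precomputed once and shared by all targets.
- The scan's inner evaluation groups windows that share an inter-window
  distance and contracts their summed counts against the log-mixture table,
  one decay value at a time. This is an exact regrouping of the naive
  triple-loop sum — same mixture formula, no window skipped — and is
  verified against a literal triple-loop implementation to ~1e−12 in the
  test suite. Memory is bounded by slab-chunking the log-mixture table;
  mixture weights that underflow to exactly zero contribute their counts
  through the (precomputed) null term, which is arithmetically identical.
- Targets are evaluated serially and deterministically; repeated runs are
  byte-identical.

## Distance measures

Physical midpoint (bp) is the default; centiMorgans interpolate the window
midpoint linearly through a whitespace-delimited genetic map (3-column
`chrom pos cM` or 4-column HapMap-style with the rate ignored), clamping
beyond the first/last anchor; window-number uses the window's 1-based
ordinal within its chromosome. VCF positions are 1-based; BED masks are
0-based half-open and drop any SNP whose position they cover. Sites must be
biallelic SNPs polymorphic in the sample; sequences with a missing call
inside a window are dropped from that window only (class strings stay
exact; totals vary by window).

## Summaries

H1, H12, H2/H1 (phased) and G1, G123, G2/G1 (unphased) are computed on the
full, untruncated window spectrum — truncation is a likelihood-model
device, not a property of the data. G123 pools the top three classes
because a heterozygous diploid genotype can arise from two distinct
haplotype pairs.

## Post-processing

Neutral thresholds pool per-window Λ over all replicates and report the
maximum and the top 0.1%/1%/5% quantiles (linear interpolation between
order statistics; the convention matters and is fixed here). Simulated
windows are projected onto real windows by a bp-overlap-weighted mean of Λ
(no overlap → missing). Regions concatenate maximal runs of consecutive
window indices with Λ above the threshold; a region reports the `m̂` and
`log10 Â` of its maximum-Λ member window (ties toward the smaller index) —
one defensible convention where several exist, chosen because per-window
estimates at the peak are the best-supported ones.

## Synthetic data

The count-level generator draws window `i` as Multinomial(n, `g_i(m0, A0,
ε0)`) and ranks each draw (the scan always sees ranked spectra). Default
study conditions, fixed once: harmonic background `p_k ∝ 1/k` with
`K = 10` (a moderately diverse neutral spectrum; top class ≈ 0.34),
`I = 201` windows at unit spacing under the window-number measure, focal
window at the center, `n = 200` sequences per window, `A0` at the middle of
the decay grid, `ε0` at the middle of the ε grid. Per-window RNG streams
are spawned from the root seed, so extending the window set never perturbs
existing windows.

The mosaic generator emits an allele matrix: per window, `K` distinct
random prototype strings (each site's minor allele count among prototypes
is forced above a floor), with each sample copying, per window, the
prototype of a class drawn from `g_i`. Sites that come out monomorphic in
the sampled matrix are repaired by flipping one used class's allele —
class counts, and hence spectra, are untouched — so polymorphism filtering
on read-back preserves the window layout. The mosaic deliberately omits
within-window LD decay, recombination breakpoints, mutation on standing
haplotypes, and realistic allele-frequency spectra: it reproduces the
model's sufficient statistics (window spectra) and their spatial decay,
nothing more. Passing tests on it therefore validate the inference
machinery, not robustness to coalescent noise; realistic inputs should come
from coalescent/forward simulators via the VCF interface.

## Experiment design notes

- Parameter-recovery and null-calibration experiments score the scan
  against the generative model's own `p`. A side effect of ranking:
  `E[sorted multinomial] ≠ n p` at finite `n`, so null data scanned against
  the true `p` carry a uniform positive Λ offset (~250 at `n = 200`,
  `I = 500`), two orders of magnitude below the hard-sweep signal
  (median Λ ≈ 12000). The real-data pipeline instead estimates `p` from
  the ranked window spectra, which absorbs this bias (null 99th percentile
  Λ ≈ 7).
- End-to-end mosaic runs (generate → read → scan with the background
  estimated from the scanned region) place `A0` at the 3/4 point of the
  decay grid. With a mid-grid `A0` the footprint (~87 windows) covers half
  of a 201-window region, contaminating the estimated background and
  biasing `m̂` upward; a genome-scale scan would not have this problem, a
  201-window fixture does.
- Problem sizes used by the suite and the acceptance script (oracle
  instances I=25/K=5, 25–100 recovery seeds, 51–500-window scans) were
  chosen to make the statistical checks decisive on a single CPU in
  minutes; all randomness is derived from fixed or caller-provided seeds.

## Limitations

- Composite likelihood: windows are treated as independent, so Λ has no
  asymptotic null distribution and is inflated in low-recombination
  regions; significance must come from neutral simulation or empirical
  outlier thresholds.
- `m̂` is the number of presently-high-frequency classes, a biased proxy
  for the number of initially selected haplotypes, and `Â` confounds sweep
  age and strength.
- Multi-allelic sites are dropped, not split; missing calls are never
  imputed; no BCF or indexed access; `threads` is accepted for interface
  compatibility but evaluation is serial (already deterministic and fast at
  the scales this package targets).
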