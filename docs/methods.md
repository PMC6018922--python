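# Methods

`dosagescan` estimates gene copy numbers from low-coverage whole-genome
sequencing read depth, and corroborates them with allele-dosage SNP
frequencies, efficiency-corrected qPCR, and phylogenetic regression of
expression on copy number. This note records the model, its assumptions,
the tunable parameters, what the synthetic generators do and do not
emulate, and the numerical choices made.

## 1. Read-depth model

Reads are treated as sampled independently and uniformly from the genome.
The number of read-start events `c_i` landing in gene `i` of length `L_i`
(bp) is then

```
c_i ~ Binomial(N, P_i)
```

where `N` is the total number of reads in the library and `P_i` the
per-read probability of starting inside gene `i`. Without bias,
`P_i = L_i / G` for genome size `G`. Because `G` is typically unknown for
a low-coverage accession, the per-base rate is instead estimated
empirically from presumed single-copy genes via a linear GC model:

```
c_i / L_i = a + b * x_i        (x_i = GC fraction of gene i)
P_i = L_i * (a + b * x_i) / N
```

so the expected single-copy count is `E_i = N * P_i = L_i (a + b x_i)`,
with no reference genome size required. When `b = 0` and `a = N/G` this
reduces exactly to the uniform model (`calling.expected_count` and a test
assert this reduction).

The per-gene copy estimate is the depth ratio `k_i = c_i / E_i`.

### GC coefficient estimation

`gcbias.fit_gc_ensemble`:

1. **Candidate single-copy pool** — keep genes with `length_bp > 700`
   (rate estimates on shorter genes are too noisy), `count > 0`, and
   length-normalised count at most 1.5x the median normalised count over
   non-zero-count genes (removes obvious multi-copy genes). Requires at
   least `min_pool = 200` survivors.
2. **Class-balanced resampling** — GC fractions are binned into 9 equally
   spaced classes on [0.38, 0.78] (the empirical GC range of grass coding
   sequence; half-open bins, last bin closed). Each repeat draws
   `genes_per_class = 60` genes per non-empty class without replacement
   and fits `c/L = a + b x` by ordinary least squares (`numpy.polyfit`).
   Balancing prevents the GC-abundant middle classes from dominating the
   fit.
3. **Ensemble** — `n_repeats = 100` fits form a `GCFitEnsemble`. Every
   downstream call is made once per member; reporting the min / median /
   max across members propagates the coefficient uncertainty.

### Classification

For each ensemble member, each gene gets a two-sided binomial confidence
interval `[lo, hi]` for `Binomial(N, P_i)` at family-wise confidence 0.99,
Bonferroni-corrected over the `M` usable genes (per-gene tail probability
`(1 - 0.99) / (2M)`). Quantiles use the `scipy.stats.binom.ppf`
convention: the smallest integer `q` with `CDF(q) >=` the target (the same
convention as R's `qbinom`). Genes are labelled:

| condition | label |
|---|---|
| `c = 0` and `lo = 0` | `excluded_ci_spans_zero` (no information: zero is consistent with presence) |
| `c = 0` and `lo > 0` | `absent` |
| `0 < c < lo` | `below_ci_removed` (present but depleted; fragmentary or diverged copy) |
| `lo <= c <= hi` | `single` |
| `c > hi` | `duplicated` |

Genes whose fitted rate is non-positive, or whose implied `P_i >= 1`, are
`unusable_rate`. Summary percentages use the denominator
`single + duplicated + absent`.

Integer copy numbers for `duplicated` genes round the depth ratio `k`.
Two modes are provided: `ceiling` (default; conservative — a gene flagged
as duplicated has at least 2 copies, so `k = 1.3` becomes 2) and
`nearest` (`max(2, floor(k + 0.5))`; unbiased when `k-hat` is unbiased,
and the mode used by the recovery checks, since ceiling rounds an
unbiased estimate upward about half the time by construction).

Consensus across ensemble members takes the majority label and the median
`k`.

### Theoretical coverage

`theoretical_coverage(read_pairs, read_length_bp, genome_size_2cx_gb)` =
`read_pairs * 2 * read_length / (2 * genome_size_2cx_gb * 1e9)`, rounded
to two decimals — the sequenced bases over the 2C genome size, taken as
twice the tabulated Gb/2Cx value. When the accession's genome size is
unmeasured, a 2.2 Gb/2Cx maximum is assumed, which deliberately
understates coverage.

## 2. Allele dosage from SNP frequencies

For a gene with `k` copies in a diploid there are `2k` alleles; a variant
carried on `m` of them has expected genomic read frequency `m / (2k)`
(`ase.expected_minor_frequency`). At `k = 4`, variant frequencies
therefore concentrate on eighths: 0.125, 0.25, 0.375, 0.5.

`ase.minor_frequencies` defines the minor variant per site on the
**transcriptome** depths (so `f_transcriptome <= 0.5` always, while
`f_genome` may exceed 0.5); ties break to the lexicographically smaller
base. Sites with zero depth in either dataset are dropped and counted.
`ase_correlation` regresses transcriptome on genomic frequency
(`scipy.stats.linregress`); slope near 1 with high `r^2` indicates all
copies are expressed proportionally to their genomic dosage, and requires
at least 3 sites with non-constant `f_genome`.

## 3. Phylogenetic regression (PGLS)

Per gene family, log-transformed expression `y = log10(rpkm + 1)` is
regressed on copy number across species under a Brownian-motion
covariance: `C[i,j]` is the root-to-MRCA distance of tips `i, j`, and
`C[i,i]` the root-to-tip distance (`phylo.brownian_covariance`, computed
from a rooted tree with branch lengths on every edge; explicitly
unrooted trees are rejected). The GLS estimate is

```
beta = (X' C^-1 X)^-1 X' C^-1 y,   sigma2 = r' C^-1 r / (n - 2)
```

solved via Cholesky factorisation (`scipy.linalg.cho_factor/cho_solve`),
falling back to a pseudo-inverse if `C` is numerically singular. The
slope is tested two-sided against `t(n - 2)`; `run_family_scan` applies
Bonferroni over the number of *testable* families (families with constant
copy number are reported as untestable, not counted). The slope is
invariant to scalar rescaling of `C`, so branch-length units do not
matter. With `C = I` the fit reduces exactly to OLS; the test suite also
cross-checks a 5-tip instance against an explicit matrix-algebra
evaluation and, when `Rscript` is available, against `nlme::gls` with
`ape::corBrownian`.

The `+1` offset in `log10(rpkm + 1)` keeps zero-expression species finite
at the cost of compressing low abundances; it is a fixed design choice,
not a fitted parameter.

## 4. qPCR relative quantification

`qpcr.pfaffl_relative_copy` implements efficiency-corrected relative
quantification: each amplicon's quantity is `Q = E^(-mean Ct)` over its
replicate wells, and the copy number of a target relative to a
single-copy reference is `Q_target / mean(Q_reference)` (averaging over
multiple reference primer pairs when provided). With all efficiencies at
2 this reduces to the familiar `2^(delta Ct)`. Standard errors propagate
replicate Ct variance through the exponential by the delta method.

Measurements with amplification efficiency outside **[1.85, 2.1]**
(bounds inclusive) are discarded before quantification: below 1.85 the
exponential correction amplifies Ct noise unacceptably, above 2.1 the
efficiency estimate itself is implausible. Efficiencies above 2.2 raise
an error suggesting a percent-scale unit mix-up (e.g. 95 instead of
1.95).

## 5. Synthetic data generators

`simulate` provides generators for every pipeline stage, each returning a
`GroundTruth` for assessment. They emulate the *statistical* structure of
the data, not its mechanics:

- **Reference + counts** — gene lengths lognormal (median 1,000 bp,
  sigma 0.45, floor 150 bp), GC uniform on [0.38, 0.78], copy numbers
  drawn from a spectrum (default `{0: 0.01, 1: 0.86, 2: 0.09, 3: 0.03,
  4: 0.01}` — mostly single-copy with a small duplicated tail). Counts
  are exactly `Binomial(N, k_i L_i (a + b x_i) / N)` at default
  `N = 2e6`, `(a, b) = (0.008, 0.005)` — i.e. the generator matches the
  inference model. Not emulated: mappability variation, paralog
  cross-mapping, PCR duplicates, insert-size effects, within-gene GC
  heterogeneity. Recovery results on these data are therefore a
  best-case calibration of the statistics, not a claim about aligner
  behaviour.
- **SNP sites** — per site, multiplicity `m ~ Uniform{1..k}`; genomic
  variant depth `Binomial(depth, m / 2k)`; transcriptome depth binomial
  with the carrier alleles' share of (optionally unequal) per-allele
  expression weights. No sequencing error or mapping bias.
- **Tree + traits** — a pure-birth (Yule) tree built from exponential
  waiting times; traits are Brownian, drawn via the Cholesky factor of
  `C` (with a `1e-10` diagonal jitter for numerical positive
  definiteness); copy numbers discretise a Brownian trait at its 20 / 40
  / 60 / 80% normal quantiles, giving phylogenetically autocorrelated
  copies in 1..5.
- **qPCR** — replicate Ct values are generated from a common
  fluorescence threshold: `Ct = (base_ct * ln 2 - ln q) / ln E`, which
  the Pfaffl computation inverts exactly at zero noise for any
  efficiencies, plus Gaussian Ct noise.

## 6. Parameters (defaults and rationale)

| parameter | default | unit | rationale |
|---|---|---|---|
| `family_confidence` | 0.99 | — | family-wise CI coverage across all usable genes |
| length filter | > 700 | bp | stabilises per-base rate estimates |
| normalised-count filter | <= 1.5x median | — | removes obvious multi-copy genes from the single-copy pool |
| GC classes | 9 on [0.38, 0.78] | fraction | observed GC range of grass coding sequence |
| `genes_per_class` | 60 | genes | enough per-class support without exhausting sparse classes |
| `n_repeats` | 100 | fits | smooth min/median/max envelopes |
| `min_pool` | 200 | genes | below this the balanced resampling is degenerate |
| `rounding` | `ceiling` | — | conservative integer copies; `nearest` for unbiased recovery |
| default 2Cx genome size | 2.2 | Gb | conservative diploid maximum when unmeasured |
| efficiency bounds | [1.85, 2.1] | fold/cycle | plausible qPCR amplification range |
| `log10(rpkm + 1)` | offset 1 | — | finite at zero expression |

## 7. Limitations

- The binomial model ignores overdispersion from library preparation and
  mapping; real data will breach the nominal CI coverage more often than
  the simulation suggests.
- GC bias is modelled as linear in gene-level GC; strongly non-linear
  bias or within-gene GC structure is not captured.
- Copy calls are per-gene and integer; partial duplications, pseudogenes
  and collapsed repeats all violate the model and surface as
  `below_ci_removed` or inflated `k`.
- PGLS assumes a single Brownian rate along the tree and an error-free
  tree; the per-tree robustness report (`extra_trees`) mitigates but does
  not remove tree uncertainty.
- The SNP dosage analysis assumes variants map uniquely and that all
  copies are co-assembled into one reference gene.
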