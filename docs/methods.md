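# Methods

## The exclusion statistic

For every unordered pair of samples the package counts δ, the number of
SNPs at which the two calls are opposing homozygotes (dosages {0, 2}), and
n_eff, the number of SNPs at which both calls are present. The rejection
rate is τ = δ / n_eff. Using the per-pair n_eff rather than one global SNP
count makes τ unbiased under missingness and reduces to the global-count
definition when call rates are complete; n_eff is carried into the mixture
likelihood for the same reason. The computation is formulated as dense
products of 0/1 indicator matrices (hom-ref, hom-alt, called), so all
pairs over 300 samples × 50,000 SNPs take seconds on one CPU and memory
stays O(pairs) for the output.

Dosages count copies of the reference allele; τ is invariant under allele
relabelling, so the convention is inert but fixed. Multiallelic VCF
records are skipped, not split: the statistic is defined for biallelic
SNPs. Positions are 1-based; chromosome names are strings, with pig
autosomes "1".."18" as the default autosome set (overridable).

## Two-component binomial mixture and EM

Within a relationship group each pair's δ_i is modelled as
Bin(n_i, τ_g) with probability γ (true first-degree pairs whose rejections
are pure genotyping error) or Bin(n_i, τ_r) with probability 1 − γ. The
E-step computes the responsibility of the error component through the
log-difference form r_i = 1 / (1 + exp(lnL_i(τ_r) − lnL_i(τ_g))); raw
binomial probabilities at array scale underflow double precision, the
log-odds form never does. By default the responsibility carries no γ
prior weight; `use_gamma_weights=True` switches to the γ-weighted
posterior. With components separated as in real data the two variants give
identical assignments and differ only marginally in the γ estimate.

The M-step updates each rate as the δ-weighted mean of δ_i/n_i
(weight: responsibility × δ_i for the error component, complement for the
rejection component) and γ as the mean responsibility. Two properties of
the δ-weighted estimator are worth knowing:

* pairs with δ_i = 0 carry no weight, so τ̂_g is driven entirely by pairs
  with at least one rejection;
* it is not the self-consistent maximizer of the mixture Q-function, so
  monotone ascent of the observed-data log-likelihood is not guaranteed
  from an arbitrary starting point. In practice responsibilities harden
  after the first iteration and the fitted trace is non-decreasing; the
  estimator carries a small upward relative bias of order 1/E[δ]
  (≈ 3 % at τ_g n ≈ 35, ≈ 0.2 % at τ_r n ≈ 500), visible in the
  parameter-recovery numbers.

Components are re-ordered (τ_g ≤ τ_r) after every M-step to prevent label
switching. Convergence is declared when the maximum relative change in
(τ_g, τ_r, γ) drops below 1e−8 (default cap 1000 iterations; separated
components converge in 2–3). A pair is accepted as a true first-degree
relationship when its responsibility exceeds 0.5; an exact tie is
conservatively not accepted (threshold configurable).

Initialization matters: badly placed starting rates fail to converge to
the two modes. `default_init` takes the 5th and 60th percentiles of the
observed per-pair rates, and `fit_mixture` by default also tries the
25th/75th percentiles and a largest-gap split of the sorted rates,
keeping the fit with the highest final observed-data log-likelihood. The
gap-split start is what rescues groups where true pairs are a small
minority (e.g. 85 maternities among 11,770 dam–offspring pairs, where the
5th percentile already falls inside the rejection component).

Degenerate inputs (every pair at the same rate, e.g. all δ = 0) return a
collapsed single-component fit with γ = 1, every pair assigned, and
`collapsed=True`.

The offspring–offspring group is fitted with the same machinery but its
assignments are labelled full-sib *candidates*: the two components overlap
(full sibs reject at per-locus probability 1/8 only where both parents are
heterozygous) and half sibs of related parents contaminate the error
component, so counts from this group should not be read as verified full
sibs.

## Genotyping-error estimation

τ̂_g is a lower bound on the per-call miscall rate e: a miscall is
observed only when it produces opposing homozygotes. The detection factor
c(p) is the first-order coefficient in τ(p) = e · c(p) at a SNP with
reference-allele frequency p (q = 1 − p), derived by enumerating parent
genotype (HWE), Mendelian transmission and miscall channels, and validated
in the tests by exhaustive enumeration:

| error model | single pool | two pools (p genotyped parent, p_o other) |
|---|---|---|
| `GENOTYPE_UNIFORM` (default): with prob. e the call becomes one of the other two genotypes, equally | p² + q² | (p² + q² + p·p_o + q·q_o) / 2 |
| `ALLELE_FLIP`: each allele miscalled independently at e/2 | p·q | (p·q_o + q·p_o) / 2 |

The adjusted estimate is e = τ̂_g / mean[c(p)] over SNPs with a defined
polymorphic MAF. The two models disagree qualitatively at low MAF:
genotype-uniform detection approaches certainty (c → 1, so the rejection
rate approaches the raw error rate), while allele-flip detection vanishes
(only heterozygotes can flip into an opposing homozygote, so low-MAF SNPs
almost never reject true pairs and are depleted among rejecting SNPs).
Real array errors are usually cluster-shift-like, i.e. closer to
allele-flip in this respect; the default follows the genotype-replacement
convention, and the model is an explicit argument everywhere because the
adjustment is model-dependent. No exact reproduction of any particular
dataset's adjusted error is claimed.

With divergent parental pools the pipeline adjusts with the single-pool
formula on pooled-parent MAFs, which underestimates e by roughly 5 % in
the simulated two-breed cross; the two-pool form is available via
`rejection_detection_prob(p, model, p_other)` when per-pool frequencies
are known.

Per-SNP counts of rejections among verified parent–offspring pairs obey
the conservation identity Σ_SNPs n_rejections = Σ_pairs δ. SNPs with
n_rejections ≥ 5 (configurable) are flagged as failing — recurrent
Mendelian inconsistency points at mismapping, structural variation or
systematic miscalling rather than random error. Failing SNPs are reported,
never silently removed; `drop_failing` produces the filtered SNP list.

## Duplicate samples

Duplicates are detected by a concordance screen separate from τ: the
fraction of jointly called SNPs with identical genotypes. Two copies of
one individual each miscalled at rate e agree at ≈ (1 − e)² of loci
(0.988 at e = 0.6 %), while first-degree pairs sit near 0.6–0.8, so any
threshold between those is safe. The function default is 0.99 (adequate
up to e ≈ 0.5 %); the pipeline default is 0.98 to tolerate per-call error
up to ≈ 1 %. When one offspring is assigned two dams, the pipeline checks
the duplicate list first and collapses copies to the first-seen
identifier; genuinely distinct double assignments are reported as
conflicts.

## Power calculation

`required_snps(p0, p1, alpha, power, n_individuals)` sizes the one-sample
two-proportion z-test separating τ_g = p0 from τ_r = p1, with the global
significance level Bonferroni-divided by the n(n−1)/2 pairwise tests:

n = ⌈( z_{1−α_adj/2} √(p0 q0) + z_{power} √(p1 q1) )² / (p1 − p0)² ⌉

The critical value is two-sided by default (a one-sided flag exists and
yields slightly smaller n); no continuity correction is applied. At rates
this small the normal approximation deviates from the exact binomial tail
by a few parts in a thousand at the power end — the returned n sizes the
z-test exactly and the exact-binomial power at that n can differ; the
tests compare against Monte-Carlo simulation of the z-test with a 0.01
allowance for approximation error.

## Synthetic data: what it emulates, and what it does not

The simulator generates a two-breed terminal cross: parents drawn from
HWE at per-SNP breed frequencies, offspring by strict Mendelian
transmission (one allele per parent, uniformly), then per-call miscalls
under the chosen error model, missing calls, duplicate samples (the same
pre-error individual re-corrupted with fresh error and missingness
draws), systematically failing SNPs (per-sample forced homozygotes,
random calls, or a shuffled column), and offspring whose true parents are
hidden — drawn from ungenotyped pools of the same breeds — so only a
fraction of parentages is resolvable. All output is a deterministic
function of the integer seed.

Defaults are the study conditions the package targets: 9 candidate sires,
55 dams, 214 offspring, 50,000 SNPs, miscall rate 0.006, missing rate
0.01, unresolvable-parent fraction 0.6, two duplicated dams, twenty
failing SNPs, divergent Beta(5,2)/Beta(2,5) breed frequencies. The
50,000-SNP scale is the package's chosen simulation size for routine runs
and tests; the statistics are rate-based and scale-free, and nothing in
the implementation depends on the count. A "common pool" regime
(`dam_breed_freqs={"dist": "shared"}`) reuses the sire pool's per-SNP
frequencies for the dams — note that drawing both pools independently
from the same distribution is *not* a common pool, and the single-pool
c(p) adjustment is exact only under the shared regime.

Deliberately not simulated: linkage and LD (the statistic is single-SNP;
loci are independent), genotype-intensity/cluster-level artifacts,
non-autosomal inheritance, and relatedness among candidate parents.
Passing tests therefore demonstrate correctness of the statistics and the
estimation machinery under the stated generative model — they do not
certify behaviour under LD between nearby SNPs (which correlates
rejections within a pair but leaves rates unbiased) or under related
parent candidates (which, as in the offspring–offspring group, blurs the
component separation).

## Numerical choices and edge cases

* Binomial log-pmfs via `scipy.stats.binom.logpmf`; boundary rates handled
  exactly (τ = 0 ⇒ log-likelihood 0 for δ = 0, −∞ otherwise).
* Equal evidence at boundary rates (−∞ vs −∞) resolves to responsibility
  0.5.
* Pairwise counts accumulate in float64 matrix products and are exact for
  any realistic SNP count (< 2⁵³).
* All-missing SNPs get call_rate 0 and undefined (NaN) MAF, and are
  excluded from detection-factor averaging; monomorphic frequencies raise
  a degenerate-locus error in c(p).
* Ties at the 0.5 assignment threshold are rejected (not assigned), the
  conservative choice for parentage claims.
* `pairwise_rejections` stores each unordered pair once, i < j in sample
  order; symmetry δ(i,j) = δ(j,i) is structural.

## Known limitations

* Second- and third-degree relationships are out of scope; likelihood
  methods over extended pedigrees are the right tool there.
* Full-sib vs half-sib separation in the offspring–offspring group is
  unreliable by construction and flagged as such.
* The adjusted error rate inherits the error model and, across divergent
  pools, the single-frequency approximation (see above).
* The γ update uses the mean responsibility; the δ-scaled expectation
  quantities that drive the rate updates are not a proportion and cannot
  serve as a mixing weight.
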