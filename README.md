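# kinreject

Verify or discover first-degree relationships (parent–offspring, full sibs)
among individuals genotyped on a dense SNP array, estimate the genotyping-error
rate from the verified pairs, and flag SNPs with recurrent Mendelian
inconsistencies.

## Who this is for

Breeding programs, experimental crosses and any study that routinely
genotypes related animals at thousands of SNPs. Sample mix-ups, mislabelled
tubes, duplicated submissions and unrecorded matings are common; with a dense
array no dedicated parentage panel is needed — the genotypes already in hand
settle every pedigree question, and give a per-batch estimate of the
genotyping error for free.

## The statistic and the model

Under Mendelian inheritance a parent and its offspring can never be
homozygous for alternative alleles at a locus (genetic exclusion). For each
unordered pair of individuals *(i, j)* the package counts the
opposing-homozygote SNPs δ and forms the **rejection rate**

> τ<sub>ij</sub> = δ<sub>ij</sub> / n<sub>ij</sub>

where n<sub>ij</sub> is the number of SNPs called in both samples. For a
true parent–offspring pair δ would be 0 without genotyping error; with
per-call miscalls at rate *e* it is small but positive. Full sibs can show
opposing homozygotes where both parents are heterozygous (probability
exactly 1/8 per such locus), and unrelated individuals show them often.

Within a relationship group (dam–offspring, sire–offspring,
offspring–offspring, …) the δ counts are modelled as a two-component
binomial mixture,

> L<sub>i</sub> = γ · Bin(δ<sub>i</sub>; n<sub>i</sub>, τ<sub>g</sub>) + (1 − γ) · Bin(δ<sub>i</sub>; n<sub>i</sub>, τ<sub>r</sub>)

with τ<sub>g</sub> the error-driven rate of true first-degree pairs,
τ<sub>r</sub> the rate of genuine rejections and γ the mixing proportion.
The mixture is fitted by EM with a log-space E-step (raw binomial
likelihoods underflow at array scale); pairs with posterior probability
of the error component above 0.5 are accepted as true relationships.
With realistically separated components convergence takes two to three
iterations.

The fitted τ<sub>g</sub> is only a lower bound on the miscall rate *e*: a
miscall is observable only when it creates opposing homozygotes, which at a
SNP with allele frequency *p* happens with probability *c(p)* per miscall
(the detection factor; *p*² + *q*² under the default genotype-uniform error
model). The adjusted estimate is *e* = τ<sub>g</sub> / mean[*c(p)*].
SNPs that reject five or more verified parent–offspring pairs are flagged
as failing (mismapping, structural variation, bad cluster calling) and
should be removed before GWAS or genomic selection.

A power module answers the design question "how many SNPs do I need":
the number of SNPs separating τ<sub>g</sub> from τ<sub>r</sub> at a given
power, with a Bonferroni-adjusted significance level over all
n(n−1)/2 pairwise tests, via the normal approximation to the binomial.

## Worked example

Simulate a two-breed cross with known truth (5 sires, 20 dams, 60
offspring, 20,000 SNPs, 0.6 % miscalls), compute all pairwise statistics,
fit the dam–offspring group and estimate the error rate:

```python
from kinreject import (SimConfig, simulate, pairwise_rejections, fit_group,
                       adjusted_error_rate, snp_summaries, required_snps)

cfg = SimConfig(n_sires=5, n_dams=20, n_offspring=60, n_snps=20_000,
                error_rate=0.006, seed=1)
g, roles, truth = simulate(cfg)
pairs = pairwise_rejections(g, roles)
annotated, fit = fit_group(pairs, "DAM_OFF")
print(f"dam-offspring pairs: {len(annotated)}")
print(f"tau_g = {fit.tau_g:.6f}   tau_r = {fit.tau_r:.4f}   "
      f"gamma = {fit.gamma:.4f}   iterations = {fit.n_iter}")
print(f"maternities assigned: {int(annotated['assigned'].sum())}")

parents = [s for s in g.samples if roles[s] in ("SIRE", "DAM")]
est = adjusted_error_rate(fit.tau_g, snp_summaries(g.subset_samples(parents)))
print(f"detection factor = {est.detection_factor:.3f}   "
      f"adjusted error = {est.adjusted_error:.4f}")

design = required_snps(p0=0.000735, p1=0.01, alpha_global=0.01,
                       power=0.99, n_individuals=300)
print(f"required SNPs: {design.required_snps}")
```

Output:

```
dam-offspring pairs: 1320
tau_g = 0.003716   tau_r = 0.1048   gamma = 0.0189   iterations = 2
maternities assigned: 25
detection factor = 0.577   adjusted error = 0.0064
required SNPs: 1611
```

The 1,320 dam–offspring pairs split into 25 true maternities rejected at
rate 0.0037 (pure genotyping error) and 1,295 non-maternities rejected at
rate 0.10; adjusting the lower bound 0.0037 by the mean detection factor
0.577 recovers the injected 0.6 % miscall rate. A design of 300 individuals
with these component rates needs 1,611 SNPs for power 0.99 at a global
significance of 0.01.

The same workflow runs from the shell:

```bash
kinreject simulate --config sim.yaml --seed 5 --out sim/
kinreject pairs --vcf sim/genotypes.vcf --roles sim/roles.tsv --out pairs.tsv
kinreject em --pairs pairs.tsv --group DAM_OFF --out fit/
kinreject run --vcf sim/genotypes.vcf --roles sim/roles.tsv --out run/
kinreject power --p0 0.000735 --p1 0.01 --alpha 0.01 --power 0.99 --ni 300
```

`kinreject run` writes `pairs.tsv`, per-group fits, `assignments.tsv`,
`parentage.tsv`, `duplicates.tsv`, `snp_rejections.tsv`,
`error_estimate.json` and `summary.json`.

## Layout

- `kinreject.genotype_io` — VCF / dosage-table input, SNP summaries, filters
- `kinreject.exclusion` — pairwise δ, τ, relationship groups, duplicates
- `kinreject.mixture` — two-component binomial-mixture EM
- `kinreject.error_analysis` — error-rate adjustment, failing-SNP QC
- `kinreject.power` — required-SNP / achieved-power calculations
- `kinreject.synthetic` — crossbred simulator with ground truth
- `kinreject.pipeline`, `kinreject.cli` — orchestration and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
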