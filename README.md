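# isingdmr

Detection of differentially methylated regions (DMRs) from paired
tumor/normal methylation-array data using a modified one-dimensional Ising
model.

## The problem

Cancer changes DNA methylation in two distinct ways: it shifts the *mean*
methylation level of CpG sites (hyper-/hypomethylation) and, because tumors
are heterogeneous, it inflates the *variance* of methylation across
patients. Neighboring CpG sites are also strongly correlated, so
disease-associated changes come in runs — regions — rather than isolated
loci. Most region callers use only the mean shift; this package integrates
mean, variance, and neighbor correlation into a single per-site score and
calls regions of consecutive high-scoring sites. It is aimed at anyone
analyzing paired case/control 450k-style array data (M-values or
beta-values) who wants region calls that are sensitive to heterogeneous,
variance-driven signal.

## The model

For each CpG site *i* and feature *f* ∈ {mean, variance}, a paired test
gives a p-value: a two-sided paired t-test on tumor−normal differences for
the mean, and a one-sided Pitman–Morgan test for inflated tumor variance
(the correlation test of S = tumor+normal against D = tumor−normal). The
p-value becomes a signal

s_i^f = −log p_i^f  if p_i^f < 0.05, else 0,

and the site's energy couples its signal with its manifest neighbors':

e_i^f = −Σ_j J_ij (s_i^f + s_j^f),

where J_ij is the Pearson correlation of sites i and j across the *normal*
samples (by default only the two adjacent neighbors enter). The two feature
energies are blended by a per-site weight λ = e^mean / (e^mean + e^var):

e_i = λ e_i^mean + (1−λ) e_i^var.

Lower (more negative) energy means stronger differential evidence. An
energy threshold τ is taken from within-pair label-swap permutations (mean
over permutations of the 5% lower quantile of pooled site energies), and
candidate regions are grown greedily from the lowest-energy seed below τ,
absorbing the lower-energy flanking neighbor while it stays below τ. Each
candidate's per-site energy E/size is compared against the per-site
energies of regions grown under the same procedure in permuted data,
giving a permutation p-value, Bonferroni-corrected across candidates.

The package also ships the matching simulation generator (AR(1)-correlated
clusters, Beta(1,1) sample-heterogeneity scaling, embedded truth DMRs with
mean-only / variance-only / combined signal) and the sensitivity /
specificity / region-overlap evaluation harness.

## Worked example

```python
import isingdmr as idm

truth = idm.simulate_dataset(idm.preset_config(2, n_pairs=40, n_sites=2000), seed=21)
model = idm.IsingDMRModel(truth.dataset,
                          n_permutations_threshold=100,
                          n_permutations_null=100)
res = model.fit(seed=5)
print(res.summary())
report = res.evaluate(truth.true_dmrs, theta=0.2)
print(f"SE={report.se:.3f} SP={report.sp:.4f} "
      f"TP={report.tp_regions} FP={report.fp_regions}")
```

prints

```
           Ising DMR detection results
==================================================
                No. sites:                    2000
                No. pairs:                      40
     Energy threshold tau:                 -9.2288
Permutations (tau / null):               100 / 100
        Candidate regions:                      11
    Permuted null regions:                    3608
      Significant regions:                       6
               Correction: bonferroni (alpha=0.05)
--------------------------------------------------
                         Significant DMRs
=================================================================
chrom  start    end   n_sites    E      E/size     p      p_adj
-----------------------------------------------------------------
 chr1  266254  267263      13 -441.433 -33.956 0.0002771 0.003048
 chr1  149034  149320       6 -196.573 -32.762 0.0005542 0.006096
 chr1  336760  337202       4 -126.655 -31.664  0.001108  0.01219
 chr1 1848953 1849202       3  -90.993 -30.331  0.001108  0.01219
 chr1 1782297 1782706       7 -194.347 -27.764  0.002771  0.03048
 chr1 1114853 1115680       8 -219.119 -27.390  0.003325  0.03658
-----------------------------------------------------------------
SE=0.631 SP=1.0000 TP=6 FP=0
```

Six regions pass Bonferroni at α = 0.05; τ = −9.23 is the permutation
energy threshold; each region row gives the genomic span, member-site
count, total energy E, per-site energy E/size (the quantity the
permutation p-value ranks), and the raw/adjusted p-values. Against the ten
embedded truth DMRs this scaled-down run recovers 63% of truth sites
(SE) with no false-positive sites outside them (SP = 1.0); all six called
regions overlap a truth DMR at the θ = 0.2 site-overlap rule (TP = 6,
FP = 0). At the full study scale (100 pairs, 10000 sites, 200
permutations) sensitivity rises to ≈ 0.9–1.0 depending on the parameter
setting.

The same pipeline is available from the shell:

```bash
isingdmr simulate --setting 2 --seed 3 --out sim/
isingdmr call --values sim/values.tsv --manifest sim/manifest.tsv \
    --samples sim/samples.tsv --seed 3 --out run/
isingdmr evaluate --called run/significant.bed --truth sim/truth.bed \
    --manifest sim/manifest.tsv --theta 0.2 --theta 0.5 --out eval.tsv
```

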