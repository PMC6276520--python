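# Methods

## Model and procedure

`isingdmr` scores each CpG site of a paired tumor/normal methylation-array
experiment with an Ising-style energy and calls differentially methylated
regions (DMRs) as maximal runs of low-energy sites. The procedure has three
stages.

**Site energies.** Two paired tests are computed per site on M-values
(beta-scale input is logit-transformed first, with boundary values clipped
to [1e-6, 1−1e-6]): a two-sided paired t-test on the differences
D = tumor − normal for the mean feature, and a one-sided Pitman–Morgan test
for Var(tumor) > Var(normal). The Pitman–Morgan statistic is the
correlation r between S = tumor + normal and D: since Cov(S, D) =
Var(tumor) − Var(normal), the upper-tail t-test of r with n − 2 degrees of
freedom tests variance inflation in a paired design. The one-sided
direction is fixed at tumor-variance inflation because heterogeneity
raises, not lowers, methylation variability in cancer.

Each p-value maps to a signal s = −ln p when p < 0.05 and 0 otherwise
(natural log; the boundary p = 0.05 falls in the zero branch; p-values are
floored at 1e-300 so signals stay finite). Per feature,

e_i^f = −[J_left (s_i^f + s_{i−1}^f) + J_right (s_i^f + s_{i+1}^f)],

with J the Pearson correlation between neighboring sites across the
*normal* samples only. J is a property of the methylation landscape, so it
is computed once from the observed normals and held fixed under all label
permutations; recomputing it per permutation would conflate coupling with
signal. Negative correlations are used as-is (a count is logged): sites
whose energy turns positive as a result simply can never seed or join a
region. An absent neighbor (chromosome end) contributes (s = 0, J = 0). A
`window` parameter generalizes the sum to neighbors at offsets 1..w; the
default w = 1 (the two adjacent sites) is the model as studied, and wider
windows are an exploratory option only.

The two feature energies are combined with a per-site convex weight
λ = e^mean / (e^mean + e^var), giving e = λ e^mean + (1−λ) e^var =
((e^mean)² + (e^var)²) / (e^mean + e^var). The weight is data-driven per
site, so a site whose evidence is purely variance-driven is not diluted by
an uninformative mean test. When both energies are zero (or cancel exactly
under negative couplings) the implementation sets λ = 0.5 and e = 0.

**Threshold and region growth.** Permutations respect the paired design:
within each pair, tumor and normal labels swap independently with
probability 1/2 (equivalently, sign-flips of D). For each of
`n_permutations_threshold` permutations the site energies are recomputed
(J fixed) and the 5% lower quantile of the pooled per-site energies is
recorded; τ is the mean of these per-permutation quantiles. The lower tail
is used because informative energies are the most negative; averaging
per-permutation quantiles stabilizes τ against permutation noise.

Candidate regions are grown greedily: seed at the unassigned site with the
globally lowest energy if e < τ (strict); repeatedly absorb whichever
flanking manifest neighbor has lower energy while that energy is < τ; ties
go to the left flank (determinism); growth never crosses a chromosome
boundary (and optionally not a cluster boundary). For this two-flank rule
the closed regions provably coincide with maximal runs of consecutive
sub-τ sites — the test suite checks the equivalence against a brute-force
run finder. Regions with fewer than `min_sites` members (default 2, so a
"region" spans at least two CpGs; set 1 for the literal single-site
variant) are discarded with a logged count.

**Significance.** For each of `n_permutations_null` permutations the whole
calling step is repeated at the same τ and `min_sites`, and the per-site
energies E/size of all permuted regions are pooled. A candidate's p-value
is the fraction of pooled null values strictly below its own E/size; the
reported p uses the standard permutation pseudocount (count+1)/(total+1)
so that p > 0 and Bonferroni semantics stay valid, with the raw count
ratio kept alongside. Bonferroni correction multiplies by the number of
observed candidates (Benjamini–Hochberg is available; Bonferroni is the
default as the conservative choice, and the suite property-tests that its
rejections are a subset of BH's). When the threshold and null permutation
counts match, the identical permutation set is shared between the two
stages; stage seeds are recorded in the run manifest either way.

## Simulation generator

The generator emulates a 100-pair, 10000-site array study on M-values.
Positions lie on one synthetic chromosome with inter-site gaps drawn from a
mixture (80% geometric, mean 120 bp; 20% geometric, mean 5000 bp),
reproducing the clumped island/desert spacing of the first stretch of a
450k chromosome-1 manifest without requiring the platform file. Clusters
are cut wherever a gap exceeds 300 bp (clusterMaker convention).

Within a cluster of h sites, control vectors are X = z·η with
η ~ N(0, Σ), Σ_ij = σ ρ^|i−j| (σ is the marginal variance scale), and
z ~ Beta(1,1) drawn once per sample and scaling the entire methylation
vector — sample-level heterogeneity. η is drawn by the exact AR(1)
recursion restarted at cluster boundaries. Ten clusters with at least 3
sites are chosen uniformly without replacement as truth DMRs: 3 mean-only,
3 variance-only, 4 with both signals. In truth clusters tumor vectors are
X = z·(μ + v∘η): mean-signal sites draw μ_i ~ unif(μ_a, μ_b) and
variance-signal sites draw v_i = α + unif(0, 0.5), so the tumor covariance
is diag(v) Σ diag(v) — the diagonal congruence is the only reading of a
"variance-signal vector" that yields a valid h×h covariance. The five
standard parameter settings (μ_a, μ_b, α, σ, ρ) are available via
`preset_config(1..5)`.

Choices the generator fixes where the design was open: z is drawn
independently for a tumor and its matched control (pairing is positional,
not biological, in the simulation); μ_i ~ unif(−2, 2) straddles zero, so
"mean-signal" sites can carry near-zero shift — implemented literally,
with an optional `mu_mode="split"` that keeps |μ_i| ≥ |μ_a|/2 for
harder-signal experiments (off by default); `z_mode="site"` draws
heterogeneity per site instead of per sample, also off by default.

What the generator does *not* emulate: beta-scale measurement error and
the (0,1) support of raw array intensities, batch/covariate structure,
long-range correlation beyond the AR(1) within clusters, and realistic
cluster-size distributions taken from a platform manifest. Passing tests
therefore demonstrate correct behavior under the stated generative model,
not performance on any particular real cohort.

## Evaluation

Site-level: confusion counts over manifest sites (d true positives inside
called regions, c missed truth sites, b called non-truth sites, a the
rest), SE = d/(c+d), SP = a/(a+b); an empty margin reports NaN with a
warning. Region-level: a call is a true positive when its site overlap
with some truth DMR reaches L = θ × (truth length in sites); fractional L
is handled as overlap ≥ ceil(L), which makes θ = 1 mean full coverage
(the literal strict "> L" is available via `strict=True`). Truth length is
counted in CpG sites, not base pairs. A call overlapping several truth
regions counts once; all matches are reported.

## Numerical and scale choices

- Natural log in the signal transform: any base rescales all energies and
  τ together, leaving calls invariant, but a fixed base is needed for
  reproducible numbers.
- Permutation energies are evaluated by a vectorized engine: sign-flip
  permutations reduce the paired t and Pitman–Morgan statistics for all
  permutations to two matrix products (D @ signs and (S_c∘D) @ signs),
  since S is invariant under within-pair swaps and ΣD² is sign-invariant.
  The engine is tested for exact agreement (1e-10) with the scalar
  per-site composition of the public operations.
- Zero-variance degeneracies (identical pairs, constant differences)
  return p = 1 — "no evidence" — rather than erroring; the relative
  tolerance 1e-12 on the variance of differences catches constant-offset
  pairs that cancel to rounding error.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; fixed seed + fixed inputs gives
  byte-identical BED output.
- Default run sizes in tests and in the acceptance script are 10
  replicates of 100 pairs × 10000 sites with 200 threshold and 200 null
  permutations — enough that the permutation p-value floor
  1/(total regions + 1) sits two orders of magnitude below the Bonferroni
  cutoff at a typical candidate count, while a replicate completes in a
  few seconds.

## Known limitations

- The permutation null pools regions from permuted data at truth loci as
  well; under strong signal with few pairs this fattens the null's lower
  tail, and with very small permutation counts the attainable minimum
  p-value may not clear Bonferroni at α = 0.05 (the p-value resolution is
  1/(total+1)). Use ≥ 100 permutations for the significance stage.
- Couplings use immediate neighbors regardless of genomic distance; two
  adjacent manifest sites separated by a large gap still couple if their
  normal-sample correlation is high.
- The site-level false-positive control is indirect (threshold + region
  significance); no per-site FDR is computed.
- Only complete matrices are analyzed; the loader's within-condition mean
  imputation is a convenience, not a missingness model.
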