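# Methods

This note documents the models, estimators and design choices behind
`mirmaster`, in the spirit of a statistical methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic study

The generator emulates a three-condition liver experiment — a lean
reference and two obesogenic lineages (`HFoleic`, `HFepa`), n = 9/8/7 —
with paired gene (500 × 24 by default) and miRNA (60 × 24) matrices.
Values are drawn directly on the quantile-normalized log2 scale: the
analyses all operate downstream of normalization, so simulating raw
intensities or counts and re-normalizing would add a nuisance stage with no
analytic surface.  A `PAPER_SCALE` preset (60,000 genes × 600 miRNAs)
mirrors array/sequencing dimensions for scaling studies.

For a planted repressive pair, within each condition,

    mirna = mu_m + s·d·c + eps_m,      eps_m ~ N(0, sigma^2)
    gene  = mu_g − b·(mirna − mu_m) + eps_g,   eps_g ~ N(0, sigma^2)

where `c` indicates the two high-fat conditions (the obesogenic response is
shared between lineages), `d = ±1` alternates per regulator so both
signature sides are populated, and the slope is scaled so the regulator
explains `repression_strength` r of the target's within-condition variance:
b = sqrt(r/(1−r))·(sigma_g/sigma_m).  Target genes carry **no direct
condition term**: their differential expression is inherited through the
regulator's shift, which makes planted pairs anti-correlated in direction
(down genes ↔ up miRNAs) by construction.

Key defaults, with the reasoning:

| parameter | default | why |
| --- | --- | --- |
| `repression_strength` | 0.8 | strong but noisy regulation; pooled miRNA–gene r² ≈ 0.9 once the shared condition shift is included |
| `noise_sd` | 0.5 log2 units | typical residual spread of normalized array data |
| `mirna_de_shift` | 1.4 log2 units | chosen by power analysis: the induced target shift b·s ≈ 2.8 gives ≈ 0.9 probability that a target clears BH-adjusted p < 0.05 at n = 7–9, so signatures capture most planted targets |
| `effect_size_de` | 2.0 log2 units | shift of directly condition-responsive features (used by `n_extra_de_genes` and the calibration benchmarks) |
| `targets_per_regulator` | 5 | miRNAs repress target modules, and step 3's network enrichment needs several targets per hub to be detectable |
| `db_overlap` / `db_false_rate` | 0.9 / 5 | each of three mock sources reports a true pair with p = 0.9 (2-of-3 consensus covers 3p²(1−p)+p³ = 97.2%) and adds Poisson(5) spurious targets per miRNA |
| `n_null_de_mirnas` | 6 | differentially expressed miRNAs with no targets, exercising the step-2/3 filters |

**Confounded genes are excluded from the reference benchmark.**  A gene
that responds to condition directly (without a miRNA) is genuinely
correlated with every shifted miRNA through the shared condition driver;
an observational pipeline *should* associate them, so planted-truth
precision would be ill-defined.  The default study therefore generates
differential expression only through planted regulations
(`n_extra_de_genes = 0`); the knob exists for robustness studies.  This is
the main respect in which the simulation is easier than real data, where
diet-responsive but miRNA-independent genes are common: recovery rates
measured here bound what the pipeline can do when its causal assumptions
hold, not its field performance.

Determinism: one `numpy` generator seeded from `seed` drives the study;
derived artifacts (databases, pathways) use `default_rng([seed, k])`
streams so stages can be regenerated independently.

## Differential expression

Genes: two-sided two-sample t-test on log2 values per contrast
(`group1 − group2`, first-named condition is group 1), Welch by default
with a pooled-variance option, BH adjustment per contrast, signature =
up/down split of the adj-p < 0.05 calls.  Welch is the default because
real group variances are not guaranteed equal; under an equal-variance
null at n = 9/8 it is mildly conservative (measured size ≈ 0.045 at
nominal 0.05), while the pooled mode is exact — the calibration tests pin
both behaviors.  Degenerate features (zero variance in both groups, equal
means) yield NaN from the test and are mapped to p = 1, keeping downstream
ranks defined.  miRNAs: the DE call is |log2FC| > 0.25 AND raw p < 0.01,
both strict.  "FC > 0.25" is read on the log2 scale — a *linear* fold
change of 0.25 would denote strong down-regulation and could not describe
up-regulated miRNAs.  At n = 7–9 with sd 0.5 the p < 0.01 condition
already forces |log2FC| > 0.7, so the fold-change filter only bites for
high-variance features.

FDR correction is per contrast (whether the original analyses pooled
contrasts is not derivable; per-contrast is the conservative reading for
signature construction).  Quantile normalization maps each column onto the
row-wise mean of the sorted columns; ties receive the mean of the
reference values at the tied ranks.

## Master-regulator analysis

*Step 2 universe.* Fisher tests use the measured-gene universe (all genes
in the study matrix), the natural choice when targets and signatures are
both subsets of the measured transcriptome.  The one-sided enrichment
p-value is the hypergeometric upper tail; empty target sets give p = 1.

*Step 3 MI estimator.* Equal-frequency binning of rank-transformed data
with `k = max(2, floor(n^0.4))` bins per margin and a Miller–Madow
correction, clipped at zero.  The exponent balances resolution against
sparsity: the expected joint-cell occupancy n/k² = n^0.2 grows with n, so
the first-order bias correction stays valid at every scale (measured
independence bias ≤ 0.03 nats from n = 24 to n = 5000, and agreement with
the analytic Gaussian value −½ln(1−ρ²) within ±0.05 nats at n = 5000 for
ρ ≤ 0.9).  A √n rule was rejected after measurement: with n/k² ≈ 1 the
plug-in estimator is biased by ~0.25 nats even after correction.  A
parametric `estimator="gaussian"` option is available.

*Step 3 threshold.* The target exceedance probability (10⁻⁷ at genome
scale, as recommended for ARACNE-style networks) cannot be reached by
direct permutation at n ≈ 24, so an exponential tail is fitted to the
exceedances over the 95th percentile of a permutation null (≥ 1000
permutations of random gene/miRNA row pairs) and extrapolated:
threshold = u + β·ln(q/p).  At a reachable p = 0.01 the extrapolation
agrees with the empirical 99th percentile within a few percent (tested at
±10%).  For desk-scale studies the preset `desk_scale_config` uses
p = 10⁻³, chosen by the rule *expected false edges per hub =
p·n_genes < 1* (500 × 10⁻³ = 0.5) — the same logic that motivates 10⁻⁷
against a genome-scale universe.  Data-processing-inequality pruning is
deliberately absent: with the miRNA as the only hub the network has no
triangles to prune.  MI is computed on all samples pooled across
conditions (regulation is assumed condition-spanning); networks are
invariant to gene-row order.

*Step 4.* For each signature gene, candidates are the surviving miRNAs
linked to it by a network edge or by the database consensus.  Selection is
bidirectional stepwise OLS from the intercept-only model under
AIC = n·ln(RSS/n) + 2k (k counts the intercept); ties break by candidate
id; zero-variance candidates are dropped; when candidates ≥ n − 2 they are
pre-ranked by |correlation| and truncated to n − 3 for identifiability
(logged loudly).  No sign filter is applied to the selected coefficients —
observed regulator tables contain same-direction pairs, so both signs are
retained.  On ≤ 6 candidates the greedy search matches the exhaustive
2⁶-subset optimum in the large majority of random draws and is always a
one-move local optimum (both are asserted in the suite).

## Enrichment

The unweighted gene-set test is a two-sample KS statistic between the rank
positions of in-set and out-of-set genes on the list of genes with raw
p < 0.05 sorted by signed log2FC (descending; ties by id).  Signed ranking
is intentional: "accumulates at the top or bottom" is a statement about
direction, and reversing the list swaps every direction while preserving
D.  Sets with fewer than three members in the list are skipped (the KS
statistic is degenerate below that).  P-values come from
`scipy.stats.ks_2samp` (exact for small lists via `method`), adjusted with
Benjamini–Yekutieli across sets because set overlaps induce arbitrary
dependence.

Reaction mapping is plain set algebra over a gene → reaction → pathway
table (a schema-compatible TSV stands in for a genome-scale metabolic
model; users may supply a real mapping): reactions hit by DE genes of the
HFoleic contrast get attribute 1, HFepa attribute 2, both 3 — a disjoint
cover of the hit set.  Pathway enrichment is a one-tailed Fisher test of
each attribute class against pathway reaction sets over the
all-reactions universe, BH-adjusted.

## The logical model

The engine implements multi-valued logical models: components with levels
0..max_level, signed threshold interactions, and rules in a small grammar
(`AND`/`OR`/`NOT` over `name>=k` literals; multi-level targets use ordered
level clauses, first match wins, default 0; components without a rule use
the template "max iff some activator active and no inhibitor active").
The update is synchronous; stable states are fixed points, found by
exhaustive enumeration over free internal components (inputs are fixed,
clamped components ignore their rules, and outputs — pure sinks — are
evaluated functionally, shrinking the search space).  Cyclic attractors
are out of scope: the reported biology concerns stable states only, and
fixed points keep the enumeration exact.  States are reported in
lexicographic order; a configurable cap (default 2²⁴ states) guards the
enumeration.

The shipped hepatic model has 24 components — inputs glucose, glucagon,
FA; outputs gluconeogenesis, glycolysis, lipogenesis, lipolysis,
adipogenesis; and 16 internal nodes (insulin, Insr, Irs2, Akt, Foxo1,
ternary Pgc-1α, PPARα, PPARγ, Srebp-1c, ChREBP, PKA, Pck1, G6pc, Gck,
Acc, Hsl) — and 37 interactions.  The published source for this network is
a figure, not a rule table, so the rules here are a reconstruction
constrained by the component/interaction counts, the stated inputs and
outputs, the ternary Pgc-1α, and the narrative behavior of four simulation
environments; each rule in the fixture carries a provenance note.  The
load-bearing choices:

- **Pgc-1α** is driven by glucagon/PKA and damped by Akt: level 2 when PKA
  is active alone, level 1 when PKA and Akt are both active, 0 otherwise.
  This realizes the fasting-priming logic (high Pgc-1α during fasting
  prepares Irs2-mediated insulin responsiveness) and produces the
  intermediate level under ectopic Irs2 in fasting.
- **Akt follows Irs2 alone** (not insulin directly), so clamping Irs2 at
  its maximum suffices for basal Akt signaling during fasting — the
  behavior that lets ectopic Irs2 suppress gluconeogenesis at low glucose.
- **Gluconeogenesis** requires both committed enzymes (Pck1 AND G6pc, each
  needing Foxo1 plus Pgc-1α coactivation and no Akt) or the PPARα/Foxo1
  fasting program; either route collapses under a Pgc-1α knockout or
  active Akt.
- **FA inhibits Insr** (lipid-induced insulin resistance) and activates
  the PPARs; PPARγ is also reachable via Srebp-1c so the fed state
  (FA input low) still mounts lipogenesis and adipogenesis.

Given fixed inputs the internal subgraph is acyclic, so each packaged
environment has exactly one stable state (asserted in the suite).
miR-34a-5p — inferred as a negative regulator of Irs2 — is available as an
optional input (`hepatic_model(with_mir34a=True)`) inhibiting Irs2, off by
default; the 24/37 counts refer to the base model.  An SBML-qual exporter
provides interoperability with logical-modeling tools.

## Verification strategy and problem sizes

Every statistical primitive is checked against an independent oracle:
brute-force hypergeometric tail sums for Fisher p-values (1000 random
tables), hand step-up for BH/BY, exhaustive subset search for stepwise
AIC, full state-space scans for stable states (random ≤ 12-node models),
the analytic Gaussian value for MI, and direct permutation quantiles for
the extrapolated threshold.  Calibration uses 10,000 simulated null
features at n = 9/8 (nominal rates recovered within Monte-Carlo error for
the exact pooled test; Welch bounded above by nominal) and 500 planted
features at 2 log2 units (BH power > 0.99).  End-to-end recovery runs the
default 500 × 60 study; the suite and the acceptance script use these
desk-scale sizes throughout, which a laptop CPU completes in seconds.

## Known limitations

- The generator's planted pairs are linear, homoscedastic and
  condition-shared; it does not emulate probe-level artifacts, count
  overdispersion, or confounded (miRNA-independent) condition response —
  see above for why the latter is excluded from the benchmark.
- Gene DE uses an unmoderated t-test; a moderated-t (limma-style empirical
  Bayes) is a possible extension and would mainly matter at smaller n.
- The miRNA DE stage tests normalized log2 values rather than refitting a
  count model, consistent with quantile-normalized inputs.
- The MI threshold's exponential tail assumes the null's upper tail is
  approximately memoryless; the fit range (tail fraction) is configurable
  and the fit errors out when too few exceedances are available.
- The logical model is a coarse-grained reconstruction for hypothesis
  exploration; it encodes one defensible rule set consistent with the
  published counts and behaviors, not a unique inference from data.
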