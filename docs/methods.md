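# Methods

`hepomix` analyses a two-group (control vs treatment, e.g. chow vs
high-fructose diet) multi-omics study of four layers — transcript counts,
protein intensities with missing values, metabolite intensities and miRNA
counts — and asks which curated pathways and regulator networks the
treatment perturbs, whether combining layers changes that answer, and which
miRNAs plausibly drive the changes. This note documents the models,
parameter choices, numerical decisions and known limitations.

## Per-layer differential abundance

**Count layers (transcripts, miRNAs).** Features with zero counts in every
sample are removed; any feature with a single read anywhere is retained.
Between-sample normalization uses the trimmed mean of M-values (TMM): the
reference sample is the one whose upper-quartile count is closest to the
mean of upper quartiles; for every other sample the log2 scaling factor is
the weighted mean of per-feature log ratios M against the reference
(features positive in both samples only), after discarding the most extreme
30% of M values and 5% of average log intensities A on each side, with
weights equal to inverse asymptotic variances of M. Factors are centred to
geometric mean 1, and testing proceeds on counts-per-million of the
factor-adjusted library sizes. Each feature is tested with a two-sided
pooled-variance (equal-variance) t-test, df = n1 + n2 − 2; significance is
an unadjusted p < 0.05. Benjamini–Hochberg adjustment is available
(`bh_adjust`) but off by default, matching the analysis the package
reproduces.

**Proteins.** Presence filtering retains proteins observed in at least
⌈0.6 n⌉ samples of *each* group (3 of 5 at the default design), plus the
*group-exclusive* branch: proteins observed in every sample of exactly one
group and in no sample of the other. Exclusive proteins are counted as
differential with direction `exclusive_treatment`/`exclusive_control`, a
±inf ratio sentinel and no t statistic — there is nothing to test, the
presence pattern itself is the evidence. Retained testable proteins are
natural-log transformed and missing cells (at most n − 3 per group per
feature, guaranteed by the filter) are imputed *within each group
independently* by sequential regression: features ordered by missingness,
missing cells initialized at the feature's group mean, then each incomplete
feature repeatedly regressed on its most correlated other features and its
missing cells updated until the largest change falls below 1e-6 (cap 100
sweeps). Three numerical decisions matter at n = 5:

* the regression for a feature is fit only on that feature's *observed*
  samples — fitting through initialized cells drags every prediction back
  to the mean;
* the number of predictors is capped at (observed − 2), keeping at least
  one residual degree of freedom;
* predictions are truncated to the feature's observed within-group range.
  Without this the iterative updates can feed back through co-imputed
  predictors and diverge; with it the iteration is a bounded fixed-point
  update. The cost is that imputation never extrapolates, which is the
  conservative choice at three to four observed points.

Observed values are never altered and imputation is the identity on
complete data.

**Metabolites.** The standard chain divides by an internal-standard feature
when one is named, scales samples to a common median, log2 transforms, and
then combines two criteria: a two-sided equal-variance t-test (p < 0.05)
and a variable-importance-in-projection score VIP > 1 from a
one-component projection to latent structures (PLS1) fit of autoscaled
features against the group indicator. With one latent component the VIP
reduces to √P·|w_j|/‖w‖, where w ∝ Xᵀy is the X-weight vector, so
mean(VIP²) = 1 over scorable features; zero-variance features get VIP 0
with a warning. A one-component PLS-DA VIP is used as the surrogate for an
orthogonal-PLS fit: with a single binary response the predictive component
of the two models spans the same direction, and the orthogonal components
do not enter the one-component VIP.

## Analysis sets and pathway enrichment

Per-layer results merge into an *analysis set*: the universe is the union
of quality-passing molecule ids (gene symbols shared by the transcript and
protein layers collapse to one molecule), the differential set the union of
differential ids — a molecule differential in several layers counts once.
Directions resolve with protein precedence over transcript; disagreeing
molecules are recorded as conflicts and excluded from direction-dependent
scores (they still count as differential members).

Each pathway is scored by a right-tailed Fisher test: with N universe
molecules, n differential, K pathway members in the universe and k
differential pathway members, p = P(X ≥ k) for X ~ Hypergeometric(N, K, n),
computed by summing log-gamma log-pmfs from the largest term; the value is
exactly 1 whenever k does not exceed the lower support bound
max(0, n − (N − K)). Before counting k, the *direct-connection requirement*
keeps only differential molecules with at least one knowledge-base edge to
another differential molecule — globally by default, or confined to
within-pathway partners (`connection_scope="pathway"`); the global reading
is the default because it lets a second omics layer connect additional
molecules *into* a pathway, which is the integration behavior the pipeline
is built to expose. Pathways with no members in the universe are skipped
and noted.

**The denominator effect.** Combining layers grows both n and N. A pathway
gaining connected differential molecules from the new layer gains
significance; a pathway to which the new layer contributes nothing loses
it, because every appended differential molecule enlarges the draw. With k
and K fixed, appending d molecules that are all differential and unmapped
moves p from the tail of Hyp(N, K, n) to Hyp(N+d, K, n+d), which is
stochastically larger — p can only rise. Appending *non-differential*
unmapped molecules grows N alone and *lowers* every p (the classic
universe-inflation artifact), so monotonicity holds for the differential
direction only; the test suite checks the monotone direction exhaustively
against an exact-arithmetic oracle and checks general correctness (not
monotonicity) for arbitrary mixes.

## Regulator activation

Regulator analysis first drops knowledge-base edges without tissue (liver)
evidence; regulators left without outgoing edges leave the candidate set.
For each remaining regulator, overlap of its direct targets with the
differential set is scored by the same Fisher test over the analysis-set
universe, and directional coherence by the activation z-score

    z = Σ edge_sign × target_direction_sign / √m

over the m differential, direction-resolved targets (conflicted targets are
excluded from z but kept in the overlap count — membership is defined,
direction is not). |z| ≤ √m always. A regulator is called *activated* when
z ≥ z_min and p < α, *inhibited* when z ≤ −z_min and p < α; z_min defaults
to 2, the conventional threshold, and is exposed as a flag. Calls never
require the regulator itself to be differential: a regulator acting through
post-translational modification is exactly the case the score exists for.

## miRNA pairing

A pair is a differential miRNA and a differential gene/protein connected by
a targeting edge with `validated` or `high_predicted` evidence and strictly
opposite directions; conflicted targets are skipped. Pairs are deduplicated
on (miRNA, target) and annotated with the target's layers. Pairs attach to
every significant pathway containing the target among its counted molecules
and every called network containing it among the regulator's targets;
molecule counts are reported with and without miRNAs and no p-value is
recomputed — the pairing is annotation, not a test.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes, not
the biology. Defaults describe a 5-vs-5 design over 2,672 genes (transcript
layer), 1,000 proteins (a random subset of the genes), 471 metabolites and
576 miRNAs — the metabolite and miRNA universes at the scale of the
motivating study, the gene-level universes at roughly a quarter scale to
keep multi-seed validation runs fast; 20 pathways of 10–40 members (15%
metabolites), 5 regulators with 15 signed targets each (70% of edges
liver-evidenced), and 5 gene targets per miRNA.

Counts are negative-binomial (gamma–Poisson) around lognormal baselines
(median ≈ 150 counts, log-sd 1.2) with dispersion 0.2 and per-sample depth
noise (log-sd 0.1); intensities are lognormal with within-feature log-sd
0.4. These are the minimal standard choices for RNA-seq counts and MS
intensities; no batch effects, no count–intensity coupling, no
mean–dispersion trend.

Planted truth: two pathways receive a log2 effect of ±1.5 on 60% of their
members (applied in every layer measuring the molecule); one regulator is
planted activated and one inhibited, shifting each target by
edge_sign × activation × 1.5; twelve miRNAs targeting planted genes are
shifted (|log2 FC| = 1.5) opposite to their targets' majority direction
with probability 0.8, otherwise parallel; protein values are masked
missing-at-random at rate 0.05, and 24 proteins are made group-exclusive
(12 per side). Planting is deterministic given the seed and recomputable
via `planted_effects`. The planted regulator states are an explicit
configuration field (`planted_regulators`) so recovery can be evaluated;
regulator indices refer to the sorted generated regulator ids.

Because features are generated independently (given their planted shifts),
passing recovery and calibration tests says nothing about correlated
backgrounds, batch structure, or realistic pathway co-regulation — only
that the chain detects effects of the planted size at this design, and
rejects at roughly the nominal rate without them.

## Null calibration: what holds and what cannot

With all effects zero, the transcript, miRNA and metabolite chains reject
at the nominal 5% within a 99% binomial band. Two qualifications:

* the metabolite calibration is evaluated with median normalization off
  (the generator plants no sample-scale effects). Median scaling estimates
  a per-sample shift from the data; under the null that estimated shift is
  shared by every feature, correlating rejections across features and
  voiding the independence the binomial band assumes.
* the protein layer does **not** meet the band, and cannot: any
  deterministic single-value imputation (sequential regression, or even
  plain group-mean filling) deflates the within-group variance of features
  with imputed cells, inflating their empirical type-I rate to ~8–9% at
  n = 5; with 5% missingness ~38% of retained proteins are affected and the
  layer-wide null rate sits near 6.5–7%. This is a property of the
  impute-then-test chain itself, reported as measured rather than patched
  (a stochastic imputation would restore calibration at the cost of
  determinism and a different contract). Downstream enrichment is affected
  only through a mildly enlarged protein differential list.

## Defaults and flags

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | unadjusted per-feature and per-pathway threshold |
| strict α | 0.01 | secondary pathway significance flag |
| VIP threshold | 1.0 | metabolite selection, combined with p < α |
| TMM trims | 0.30 (M), 0.05 (A) | double trim fractions |
| imputation tol / cap | 1e-6 / 100 | convergence of sequential sweeps |
| z_min | 2.0 | activation call threshold |
| connection_scope | global | direct-connection reading (alt: pathway) |
| presence rule | ⌈0.6 n⌉ per group | protein testability |

## Limitations

* Identifiers are bare case-sensitive symbols assumed pre-harmonized across
  layers; no ortholog or synonym mapping. Metabolites are matched by name.
* Enrichment is over-representation only — no ranked (GSEA-style) or
  topology-weighted variant.
* The activation score is the standard sign-consistency statistic; no claim
  of equivalence with any proprietary network tool's calls.
* miRNA target evidence levels are knowledge-base inputs, not predictions.
* The equal-variance t-test is kept deliberately (it is the method under
  study); no moderated/limma-style variance shrinkage.
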