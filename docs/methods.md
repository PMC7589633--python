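# Methods

## Scope and model

`fflnet` quantifies the dysregulation of TF–miRNA feed-forward loops
(FFLs) between two paired conditions. An FFL is a (TF, miRNA, gene)
triple with edges TF→gene and miRNA→gene plus at least one regulation
between the TF and the miRNA; the direction of that third edge fixes
the motif type (TF-FFL, miRNA-FFL, or FB-FFL when mutual). Node classes
are disjoint and derived from the edge classes; an identifier used with
incompatible classes is an error rather than a silent reclassification,
because motif typing depends on the classes. The one deliberate
asymmetry: a `tf_gene` target may itself be a TF (a TF regulating
another TF's gene), whereas a miRNA targeting a TF must be encoded as
`mirna_tf` — so a mutually regulating TF/miRNA pair is two typed edges
and is detected as FB.

## Scoring

Per node, differential expression is summarized as
`Diff = (−log₁₀ p)·|log₂FC|` and folded through
`S = Φ⁻¹(2·Φ(Diff) − 1)`; per edge, the within-condition Spearman
correlations are Fisher-transformed and their standardized difference
`D` (variance `1.06/(n−3)` per condition, the inflation appropriate for
the Fisher z of a Spearman rather than a Pearson correlation) is folded
through the same map with `|D|`. The FFL score is
`γ·mean(S_node) + (1−γ)·mean(S_edge)` with `γ = 0.5`; an FB-FFL scores
its mutual TF↔miRNA pair once (pair coexpression is direction-free), so
every motif has exactly 3 node and 3 edge scores and all types share
one scale.

Numerical choices. The inner probabilities of the inverse-normal maps
are clamped to `[1e−15, 1−1e−15]` and Spearman correlations to
`|r| ≤ 1−1e−9` before the Fisher transform; both maps diverge at their
boundaries and the clamps keep every score finite and order-preserving.
The floor is visible in practice: `Diff = 0` or `D = 0` maps to
`Φ⁻¹(1e−15) ≈ −7.94`, so exactly-null components are strongly
penalized. With 5 samples per condition the Spearman statistic is
discrete and `r_case = r_control` (hence `D = 0` exactly) occurs with
appreciable probability; this affects null and real triples alike, so
calibration is unharmed. Constant expression vectors have undefined
correlation and are scored as `r = 0` with a warning. Spearman ties use
average ranks.

Significance. One shared null of random composition-matched triples
(one TF, one miRNA, one gene, uniform within class; 100,000 draws by
default) is scored exactly like real FFLs — from expression alone,
whether or not the sampled regulations exist, since the edge score
needs no topology. The empirical p-value is the plain proportion of
null scores strictly greater than the FFL's score (a `+1/(N+1)`
pseudocount variant is available by flag); p ≤ 0.05 flags an FFL
dysregulated. A flag allows fully unconstrained triples instead of
composition-matched ones; composition matching is the default because
it keeps the null on the same score scale as the real motifs.

## Differential expression

The paired design (each donor profiled in both conditions) is analyzed
on per-donor differences with an empirical-Bayes moderated t: the prior
df and prior variance are estimated by moment matching on log sample
variances (digamma/trigamma inversion), the posterior variance is the
df-weighted blend, and p-values use the augmented df. The construction
reproduces limma's `eBayes` on the same differences to machine
precision (asserted in the test suite via `Rscript`). Forcing prior
df = 0 recovers the ordinary paired t; prior df = ∞ a pooled-variance
z. BH FDR is computed separately per platform (genes and miRNAs),
mirroring the two-array design. Quantile normalization forces every
sample onto the common distribution of per-rank row means (ties receive
the mean of their ranks' reference values); probe-to-feature collapse
averages probe rows. Default DE thresholds are p ≤ 0.05 and
|log₂FC| ≥ 1, both configurable.

## Downstream analyses

*Body systems.* An FFL belongs to a system iff all three nodes are in
at least one pathway mapped to that system; the system→pathway map is
user input; over-representation is assessed locally with an upper-tail
hypergeometric test over GMT gene sets with BH correction, rather than
through web annotation services. FFLs in exactly one system are
system-specific; in ≥ 3 (configurable), system-general.

*Pan-cancer rank shift.* Genes are ranked by descending perturbation
log₂FC (ties broken by id) and each cancer's up/down DE sets are tested
with one-sided Wilcoxon rank-sum tests for concentration at the top or
bottom of the ranking — exact null when the smaller group has ≤ 25
members (signature ranks are tie-free), normal approximation with
continuity correction otherwise. Significant up-top/down-bottom
(p ≤ 0.1) labels a cancer consistent; up-bottom/down-top, reverse; both
can co-occur. Cancer genes absent from the signature universe are
dropped with a logged count (rank is undefined for unmeasured genes).
No correction is applied across cancers × patterns by default, matching
the raw-p convention; a BH option exists.

*Drug screens.* The miRNA screen ranks drugs by how many target miRNAs
they down-regulate, excluding (drug, miRNA) pairs with contradictory
recorded effects; the signature-reversal screen counts perturbation DE
genes a drug shifts oppositely and keeps drugs reversing ≥ 3 (default).
Both rank by count with lexicographic tie-breaks, so results are
invariant to input row order. No connectivity-map-style KS statistic is
computed — ranking is by reversed-gene count only.

## Synthetic data

The generators emulate a small paired-design regulatory study: 50 TFs, 80 miRNAs,
300 genes with typed edges drawn per class by preferential attachment
on target in-degree (giving right-skewed, roughly power-law degrees) at
density 0.06 — sized so the defaults yield comfortably more than 300
candidate FFLs around 10 planted ones — and paired log2 expression for
5 donors: per-feature baseline N(8, 1.5²), shared donor effect
(sd 0.5), noise sd 0.5. Planted FFLs get (i) case-mean shifts of
±2 log2 units on their nodes and (ii) a per-FFL latent factor with
loadings (+a, +a, +a) in case and (+a, −a, +a) in control, with `a`
set so factor-coupled pairs reach correlation ±0.8. The TF–miRNA and
miRNA–gene pairs therefore flip sign across conditions while the
TF–gene pair stays positive in both: a full sign flip of all three
pairs is impossible (the all-negative 3×3 correlation matrix at 0.8 is
not positive definite). Cancer DE lists sample up/down genes with
exponential rank weights (strength 6) over the realized perturbation
signature, in the concordant, opposed or uniform arrangement; the drug
generator designates one winner that fully counteracts the perturbation
and caps decoys strictly below it, so planted ranks are unambiguous.

What the generator does *not* emulate: probe-level artifacts,
background correction, batch effects, RNA-seq counts, annotation noise,
or realistic hub-gene co-expression structure. Passing tests therefore
demonstrate correctness and calibration of the statistics under the
stated model, not performance on real microarray data.

## Calibration and recovery checks

With no planted effects, empirical FFL p-values are uniform. FFLs that
share a node reuse expression rows and have correlated scores, so the
KS uniformity check pools node-disjoint FFLs from five independent null
datasets (the marginal over all FFLs is also uniform — verified by
pooling across seeds — but a per-run KS over all ~500 dependent FFLs
over-rejects). With the default planted effects, mean AUC of the FFL
score is ≈ 0.95 and recall at p ≤ 0.05 is ≈ 0.9 over five seeds;
occasional misses are planted FFLs whose latent coexpression factor
masks the node mean-shift in the paired differences — a real power
limit at n = 5, not a bug.

## Pipeline determinism

Every stage is a pure function of (inputs, config, master seed). Stage
`k` derives its generator from `SeedSequence([master_seed, ordinal_k])`
with a frozen ordinal table, so single stages reproduce the one-shot
run byte-for-byte regardless of execution order. Outputs carry a
provenance header (version, hash of the parameter part of the config,
seed); floats are written at 6 significant digits. The committed golden
summary (`tests/data/golden_summary.tsv`, seed 7, default demo
configuration: 100,000 permutation draws, 6 synthetic cancers, 8 drugs)
is regenerated and compared byte-for-byte in the test suite.

## Known limitations

- Spearman at n = 5 is extremely coarse; edge scores carry little
  information at that sample size and the node term dominates.
- The permutation null is shared across FFLs, so p-values are granular
  (multiples of 1/n_draws) and not independent across FFLs sharing
  nodes; downstream FDR over FFLs is deliberately not computed.
- System assignment requires the user's system→pathway map; per-system
  counts are therefore not comparable across annotation choices.
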