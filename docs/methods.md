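# Methods

This note documents the statistical models implemented in `qstab`, the
defaults that affect results, what the synthetic generator does and does not
emulate, and the design choices made where conventions in the field
genuinely diverge.

## Data model and units

The atomic observation is one qPCR well: a quantification cycle `Cq` keyed
by `(gene, culture, passage, lysate, tech_rep)`. Cq is proportional to the
negative log2 of template quantity at perfect amplification efficiency, so
all additive modelling happens on the Cq scale and all fold-change
reporting on the linear scale `2^-Cq`. Cq values must satisfy
`0 < Cq <= max_cycles` (default 40, the usual thermocycler programme
length); passages are ordinal labels and are never assumed consecutive.

**Replicate handling.** Technical replicates of one lysate estimate a
single template quantity, so the model front end collapses them to the
arithmetic mean Cq per lysate *before* any `2^-Cq` transform (averaging on
the log scale, i.e. a geometric mean of linear quantities). Every stability
algorithm can also be run at replicate level via `collapse=None`; the
lysate level is the default because technical replicates are
pseudo-replicates for any between-passage question.

**Missing data.** The estimators are defined on complete gene × sample
matrices. Cells are never imputed — imputation would silently move every
score — so incomplete matrices abort with the full list of
`(gene, sample)` holes.

**Amplification efficiency.** A global base (default 2.0, perfect
doubling) is threaded through every linear transform (CV%, normalization
factors, fold changes). Per-gene efficiencies are not implemented: geNorm
M and ΔCt scores are invariant to the base up to a global log factor, and
supporting heterogeneous efficiencies properly would require
dilution-curve inputs that are out of scope. This is a known limitation.

## Stability estimators

All five produce a `StabilityTable` with ascending competition ranks
(tied scores share the minimum rank); lower scores always mean more stable.

**CV%.** Per gene, `100 · SD/mean` of `2^-Cq` over samples (sample SD,
n−1). Adding a constant to a gene's Cq rescales mean and SD equally, so
CV% is offset-invariant.

**geNorm.** Relative quantities are anchored at the per-gene minimum Cq,
`Q_gs = 2^(minCq_g − Cq_gs)`; any anchor gives identical results because
only ratios enter, and the minimum keeps the numeric range tame. The
pairwise measure `SD_s(log2(Q_g/Q_h))` collapses algebraically to
`SD_s(Cq_g − Cq_h)`, which is how it is computed. `M_g` is the mean of a
gene's pairwise SDs over the remaining genes; the highest-M gene is removed
iteratively (ties broken by removing the lexicographically larger name so
runs are deterministic) until two remain, which are reported jointly at
rank 1 with their mutual pairwise SD as score; the next gene gets rank 3.
A gene's reported M is its M at the round of its exclusion. Stepwise M is
not mathematically guaranteed to be monotone along the exclusion order, so
the "sorting by score equals sorting by rank" property is guaranteed for
the other four estimators but only typical for geNorm.

The pairwise variation series uses
`log2 NF_n(s) = mean over the n most stable genes of log2 Q_gs` and
`V_n/n+1 = SD_s(log2 NF_n − log2 NF_{n+1})` for `n = 2..k−1`. The
`optimal_gene_count` rule returns the smallest `n` with `V < 0.15`
(cutoff configurable); when no V clears the cutoff it returns a
no-recommendation flag with the minimising `n`, because the rule is then
a matter of judgement, not arithmetic.

**NormFinder.** The additive model `y_gs = α_g + β_s + ε_gs` with
gene-specific residual variance `σ²_g` is fitted by double centring:
`r_gs = y_gs − ȳ_g· − ȳ_·s + ȳ_··`. The naive per-gene mean square
`u_g = Σ_s r²_gs/(n−1)` has expectation
`(1 − 2/k)σ²_g + Σ_h σ²_h/k²`, so the unmixed estimate is

    σ̂²_g = k/(k−2) · ( u_g − Σ_h u_h / (k(k−1)) ),

truncated at zero before the square root (hence ≥ 3 genes are required).
In single-group mode the stability value is simply `σ̂_g`. With group
labels (e.g. the two sub-clone cultures of a merged dataset) the same
per-group variances `σ̂²_gj` are combined with the gene-by-group
interaction contrasts `d_gj` (unweighted double centring of group means),
an inter-group variance `γ̂²` estimated by moments and truncated at zero,
and the shrunken biases `d̃_gj = d_gj · γ̂²/(γ̂² + σ̂²_gj/n_j)`:

    ρ_g = mean_j ( |d̃_gj| + sqrt(σ̂²_gj / n_j) ).

The best pair minimises the same measure applied to the average of two
genes (`sqrt((σ̂²_g + σ̂²_h)/4)` ungrouped; averaged shrunken biases plus
the pooled sampling SD in grouped mode). The single-group estimator is the
one verified against an independent residual-formula oracle to 1e-10;
the grouped combination follows the published variance-decomposition
approach but exact constants differ between historical implementations,
so grouped scores should be compared within a run, not across tools.

**BestKeeper.** Per gene: geometric and arithmetic mean crossing point,
min, max, and the dispersion "SD ± CP". The original tool computes this as
the **mean absolute deviation** around the arithmetic mean CP, which is
the default here (`dispersion="mad"`); the sample SD is available via
`dispersion="sd"` since published descriptions are ambiguous about which
was used. `x-fold = 2^dispersion` expresses the dispersion as a fold
range; genes with dispersion > 1 cycle are flagged inconsistent. The
BestKeeper index is the per-sample geometric mean CP over all genes;
Pearson r is reported for every gene pair and gene-vs-index. Ranking is
ascending in dispersion (smaller = more stable). Some descriptions ask for
SD "as close as possible to 1 but not greater" — that conflicts with the
tool's own smaller-is-better ordering, and this package ranks
smaller-is-better while flagging > 1.

**Comparative ΔCt.** `score_g = mean_h SD_s(Cq_g − Cq_h)`; with two genes
both share the single pairwise SD.

## Consensus and selection

The consensus is the per-gene **geometric mean of competition ranks**
across whichever algorithm tables are supplied, re-ranked ascending. No
attempt is made to reproduce the web-based RefFinder service's internal
re-computation and weighting, which is not publicly specified; the plain
geomean is transparent and lies provably between a gene's best and worst
single-algorithm rank.

`integrated_selection` codifies the informal "consistently in the top
three" argument: per dataset, each gene counts the algorithms ranking it
in the top k (default k = 3); the reference pair is the two best genes of
the primary dataset, preferring genes with no significant passage trend
(omnibus P > α where supplied, α = 0.05 default) and breaking ties
lexicographically; the "experimental candidate" is the best remaining gene
by total top-k count across all datasets; pair + candidate form the
recommended triplet. Every decision and every violation is written to an
audit log so the selection can be defended line by line.

## Validation engine

The normalization factor is `NF(s) = geomean over refs of 2^-Cq_gs`,
computed as `2^(−mean Cq)` — invariant to reference order. A gene of
interest is normalized as `rel(s) = 2^-Cq_goi(s) / NF(s)`, rescaled so the
calibrator passage's mean is exactly 1, and each other passage is compared
to the calibrator.

**Test gating.** Residuals (values minus group means) are tested with
Shapiro-Wilk at α = 0.05: normal-looking data go to one-way ANOVA with
Welch t comparisons against the calibrator; otherwise Kruskal-Wallis with
Mann-Whitney comparisons. Comparison P values are Holm-adjusted (a
Dunnett-style many-to-one family). A run with zero residual variance is
decided directly on the group means. The passage-trend screen runs on the
linear `2^-Cq` scale by default (matching how fold changes are plotted and
judged); the Cq scale is available via `scale="cq"`.

**Verdict.** "Successful" normalization means every Holm-adjusted
comparison has P > α. This makes the usual figure-level judgement ("no
significant fold changes after normalization") exactly reproducible. With
all-stable synthetic inputs the family-wise false-failure rate is bounded
by α; the test suite checks it stays ≤ 10% over 200 seeds.

**Stress screens.** Per-gene stress-vs-control fold =
`mean(2^-Cq, stress)/mean(2^-Cq, control)`, flagged when it leaves the
(0.5, 2) band — the conventional ≥ 2× rule; a −1 Cq shift is exactly a 2×
up-regulation. Folds are reported as positive linear ratios *and* as
log2 values; a linear ratio cannot be negative, so any signed convention
in external reports is interpreted as log2 down-regulation. Normalized
GOI comparisons between conditions use each condition's own NF (so global
shifts affecting references and target alike cancel) and a two-sided
Mann-Whitney test with ≥ 3 samples per condition; α = 0.05 throughout,
configurable.

## Synthetic data generator

The generator emulates a two-sub-clone passaging study:

    cq(g,p,l,r) = baseline_g + group_shift_{g,culture} + drift_g·(p−1)
                  + P_p + L_{p,l} + ε_{g,p,l,r}

with `P ~ N(0, passage_sd²)` and `L ~ N(0, lysate_sd²)` shared across genes
(they model sample-level effects: input amount, RNA quality) and
`ε ~ N(0, tech_sd_g²)` per well. Noise is Normal on the Cq scale because Cq
is a log-scale quantity and every estimator above assumes log-scale
additivity. Defaults: 12 genes whose baselines and technical SDs follow
the per-gene descriptive statistics of a routinely cultured sub-clone
(means 7.93–26.58 cycles, SDs 0.17–0.35), 5 passages × 3 lysates × 3
technical replicates, `passage_sd = 0.15`, `lysate_sd = 0.10` cycles —
the shared components are generator choices (not measured quantities)
sized so total per-gene SDs land in the observed 0.17–0.61 range. All
randomness comes from named substreams of one integer seed, keyed by
(component, culture, gene), so panels, GOIs and stress conditions are
reproducible and mutually independent: changing a GOI's seed can never
change the panel.

**Genes of interest.** A GOI is generated on the panel's sample grid with
planted per-passage offsets: `stable` draws offsets uniformly within
±amplitude (amplitude ≤ 0.5 cycles), `variable` forces at least one
passage beyond ±0.5, `trend` plants a monotone ramp of total size
amplitude. Offsets are enforced exactly by re-centring the technical noise
within each passage. By default the GOI also inherits the panel's
estimated per-sample effect (the across-gene mean Cq deviation of each
sample): shared sample-level variation is precisely what a normalization
factor exists to remove, and a GOI lacking it would be unfairly penalised
by any verdict at realistic `passage_sd`. For type-I-error studies the
"stable" GOI uses amplitude 0 — a truly null profile — because a planted
0.2–0.5 Cq passage shift is real differential expression that the verdict
engine *should* flag; the ±0.5 band is the stable/variable classification
boundary, not a promise of statistical invisibility.

**Stress conditions** are fresh panel draws with per-gene constant Cq
offsets (−1 Cq ⇒ 2× fold change).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: amplification efficiencies ≠ 2, fluorescence
baselines and melting behaviour, heteroscedastic or heavy-tailed technical
noise, correlated drift across genes, plate/batch effects, and missing
wells. Conclusions about the estimators' algebra and relative ranking
transfer to real data; absolute false-failure rates do so only to the
extent that real residuals are approximately Normal on the Cq scale.

## Numerical choices and problem sizes

Tolerances: implementation-vs-oracle agreement is asserted to 1e-10 on
random 5 × 10 matrices; variance estimates are truncated at zero before
square roots; rank ties use competition ("min") ranking; selection ties
break lexicographically; geNorm exclusion ties remove the
lexicographically larger gene. The routine test and acceptance runs use
the default 12 × (5·3·3) profile, 100-seed recovery experiments, and a
200-seed null for the false-failure rate — sizes chosen so the whole suite
completes in well under a minute per experiment on one CPU while keeping
binomial noise on the reported rates below a few percent.

## Known limitations

* Grouped NormFinder constants differ between historical implementations;
  compare grouped scores within qstab only.
* No efficiency correction from dilution curves; no instrument raw-file
  parsing (RDML/EDS); no amplification-curve QC.
* The consensus is a plain geomean of ranks, not a reproduction of any
  web service's weighting.
* The ≥ 2× stress rule is a convention, not an inference; the Mann-Whitney
  P is reported alongside so users can apply their own threshold.
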