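# qstab

Reference-gene stability analysis and normalization validation for RT-qPCR
quantification-cycle (Cq) data.

Relative quantification by RT-qPCR stands or falls with its reference
("housekeeping") genes: targets are reported as fold changes of
`2^-Cq` relative to a normalization factor built from genes assumed to be
constitutively expressed. That assumption fails surprisingly often —
sub-clones of the same cell line drift apart over passages, and classical
references such as *ACTB* or *GAPDH* can vary more than the genes under
study. `qstab` is for molecular biologists and bioinformaticians who need
to **choose** reference genes defensibly and then **prove** that the chosen
set actually normalizes their genes of interest.

## What it computes

Given a table of Cq values keyed by `(gene, culture, passage, lysate,
tech_rep)`, the package runs the five standard stability estimators (all
scored so that *lower = more stable*):

* **CV%** — coefficient of variation of the linear quantities
  `2^-Cq`: `CV = 100 · SD/mean`.
* **geNorm** — `M_g = mean_h SD_s( log2(Q_gs / Q_hs) )`, the average SD of a
  gene's pairwise log-expression ratios, with iterative exclusion of the
  highest-M gene; plus the pairwise variation
  `V_n/n+1 = SD_s( log2(NF_n / NF_{n+1}) )` that decides how many reference
  genes a normalization factor needs (cutoff 0.15).
* **NormFinder** — model-based variance decomposition on the Cq (log)
  scale: the bias-corrected residual SD of the additive gene + sample
  model, and with group labels the combination of intra-group SD and
  shrunken inter-group bias; also reports the best *pair* of genes.
* **BestKeeper** — descriptive dispersion of crossing points (SD ± CP, with
  `x-fold = 2^SD`), the per-sample geometric-mean index, and Pearson
  correlations between genes and against the index.
* **comparative ΔCt** — the mean SD of pairwise Cq differences.

On top of the estimators sit a geometric-mean-of-ranks consensus, an
auditable integrated selection rule (top-k counts + passage-trend screen →
reference pair + experimental candidate → triplet), and a validation
engine: a gene of interest is divided by the normalization factor
`NF(s) = geomean_g 2^-Cq_gs`, rescaled to a calibrator passage, and every
other passage is compared to the calibrator with a Shapiro-Wilk-gated
ANOVA/Kruskal-Wallis and Holm-adjusted comparisons — "successful"
normalization means no comparison is significant. Nutrient-stress panels
are screened with the ≥2× fold-change rule and Mann-Whitney tests.

Because raw Cq datasets of this design are rarely deposited, the package
ships a first-class synthetic generator (`qstab.simulate`) that emulates
the study design — 12 reference genes with realistic baselines, passages ×
lysates × technical replicates, shared sample-level variance components,
planted drift, and simulated genes of interest — so every claim above is
testable against known ground truth.

## Worked example

```python
from qstab import ReferenceGeneStability, default_profile, generate_reference_panel

panel = generate_reference_panel(default_profile(seed=1), culture="A1")
res = ReferenceGeneStability(panel).fit()
print(res.summary())
```

```
Reference-gene stability analysis
======================================================================
dataset: synthetic:A1   unit: lysate_mean
genes: 12   observations: 180   cultures: A1
algorithms: cv, genorm, normfinder, bestkeeper, delta_ct (all scores: lower = more stable)
----------------------------------------------------------------------
             cv  genorm  normfinder  bestkeeper  delta_ct  geomean_rank  consensus_rank
GAPDH   12.7026  0.1264      0.0890      0.1262    0.1777         1.719               1
PCBP1   10.8690  0.1697      0.1104      0.1326    0.1882         3.245               2
PGK1    15.2211  0.1264      0.1106      0.1597    0.1873         3.277               3
PUM1     9.2097  0.1901      0.1351      0.1150    0.2028         3.347               4
CCSER2   9.7096  0.1876      0.1552      0.1047    0.2140         3.776               5
RNA28S  13.6840  0.1410      0.1218      0.1437    0.1947         4.580               6
RPL13A  12.8877  0.1659      0.1424      0.1599    0.2024         5.650               7
HSPCB   11.6893  0.1901      0.1725      0.1431    0.2223         7.065               8
ACTB    16.0848  0.2002      0.1446      0.1664    0.2082         8.313               9
RNA18S  15.1415  0.2125      0.1625      0.1876    0.2212         9.169              10
SF3A1   17.2704  0.2203      0.1700      0.1920    0.2248        10.792              11
HNRNPL  20.0164  0.2961      0.2629      0.2226    0.2961        12.000              12
----------------------------------------------------------------------
geNorm pairwise variation: V2/3=0.0422  V3/4=0.0366  V4/5=0.0285  V5/6=0.0264  V6/7=0.0224  V7/8=0.0194  V8/9=0.0185  V9/10=0.0173  V10/11=0.0166  V11/12=0.0222
optimal gene count: V_2/3 = 0.0422 < 0.15 -> use 2 reference genes
NormFinder best pair: GAPDH-PCBP1 (score 0.0709)
======================================================================
```

Reading it: every column is one estimator's stability score (e.g. GAPDH's
geNorm M of 0.126 is far below the conventional M < 1 candidacy bound);
`geomean_rank` aggregates the five per-algorithm ranks, so GAPDH is the
consensus winner on this panel. The V series says `V2/3 = 0.042 < 0.15`:
adding a third gene to the two most stable would not change normalization
factors appreciably, so two reference genes suffice for this dataset.

Validation of a gene of interest then looks like:

```python
from qstab import GoiSpec, generate_goi, normalization_factor, normalize_goi
from qstab.data import collapse_replicates

lysates = collapse_replicates(panel)
goi = generate_goi(GoiSpec(mode="stable", amplitude=0.0, seed=2), lysates)
nf = normalization_factor(lysates, ["GAPDH", "CCSER2", "PCBP1"])
print(normalize_goi(goi, nf, calibrator=1).verdict)   # -> successful
```

The same workflow is scriptable from the shell:

```bash
qstab simulate --seed 1 --out panel.csv
qstab stability --in panel.csv --out scores.csv
qstab select --scores scores.csv --out selection.json
qstab report --config run.yaml
```

## Layout

* `src/qstab/data.py` — Cq data model, validation, CSV dialects, matrix
  restructuring.
* `src/qstab/simulate.py` — synthetic panels, genes of interest, stress
  conditions.
* `src/qstab/stability.py` — the five estimators + descriptive screens.
* `src/qstab/consensus.py` — rank aggregation, optimal gene count,
  integrated selection.
* `src/qstab/validation.py` — normalization factors, verdicts, stress
  tests, test gating.
* `src/qstab/model.py` — `ReferenceGeneStability` / `StabilityResults`.
* `src/qstab/report.py`, `src/qstab/cli.py` — orchestration and the
  `qstab` command.

See `docs/methods.md` for the statistical models, defaults, and known
limitations.
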