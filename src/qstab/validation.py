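"""Multi-reference normalization and its statistical validation.

Having ranked candidate reference genes, the remaining question is whether a
chosen set actually normalizes a gene of interest (GOI): after dividing the
GOI's linear quantity by the normalization factor (geometric mean of the
reference quantities) and rescaling to a calibrator group, no group should
differ significantly from the calibrator.  This module codifies that
figure-level judgement into a reproducible verdict, plus the nutrient-stress
screens (>= 2x fold-change rule, Mann-Whitney GOI test) and the
normality-gated test chooser used throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import (
    CqDataset,
    CqValidationError,
    linear_quantity,
    to_matrix,
)

__all__ = [
    "ChooseTestResult",
    "NormalizationFactor",
    "NormalizedExpression",
    "ScreenResult",
    "StressGoiResult",
    "CqExpressionCorrelation",
    "choose_test",
    "normalization_factor",
    "normalize_goi",
    "screen_reference_sets",
    "stress_fold_change",
    "stress_goi_test",
    "correlate_cq_expression",
]


@dataclass(frozen=True)
class ChooseTestResult:
    """Gated omnibus test plus Holm-adjusted comparisons vs the calibrator."""

    test: str  # "anova" | "kruskal" | "degenerate"
    p: float
    shapiro_p: float
    posthoc: pd.Series  # adjusted P per non-calibrator group (empty if no calibrator)


def choose_test(
    groups: Mapping[object, np.ndarray],
    calibrator: object | None = None,
    alpha: float = 0.05,
) -> ChooseTestResult:
    """Shapiro-Wilk-gated group comparison.

    Residuals (values minus their group mean) are tested for normality at
    ``alpha``; a normal-looking sample is analysed by one-way ANOVA with
    Welch t comparisons against the calibrator, otherwise by Kruskal-Wallis
    with Mann-Whitney comparisons.  Comparison P values are Holm-adjusted
    (a Dunnett-style many-to-one contrast set).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    if len(labels) < 2:
        raise CqValidationError("choose_test needs >= 2 groups")
    for lab, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise CqValidationError(f"group {lab!r} has < 2 values")
    if calibrator is not None and calibrator not in groups:
        raise CqValidationError(f"calibrator group {calibrator!r} not present")

    residuals = np.concatenate([a - a.mean() for a in arrays])
    others = [lab for lab in labels if lab != calibrator]

    if np.ptp(residuals) == 0.0:
        # no within-group variation at all: decide on the means alone
        means = [a.mean() for a in arrays]
        same = np.ptp(means) == 0.0
        p = 1.0 if same else 0.0
        posthoc = pd.Series(
            {
                lab: 1.0 if np.asarray(groups[lab]).mean() == np.asarray(groups[calibrator]).mean() else 0.0
                for lab in others
            }
            if calibrator is not None
            else {},
            dtype=float,
        )
        return ChooseTestResult(test="degenerate", p=p, shapiro_p=np.nan, posthoc=posthoc)

    shapiro_p = float(stats.shapiro(residuals).pvalue)
    if shapiro_p >= alpha:
        test = "anova"
        p = float(stats.f_oneway(*arrays).pvalue)
    else:
        test = "kruskal"
        p = float(stats.kruskal(*arrays).pvalue)

    posthoc = pd.Series(dtype=float)
    if calibrator is not None and others:
        cal = np.asarray(groups[calibrator], dtype=float)
        raw = []
        for lab in others:
            arr = np.asarray(groups[lab], dtype=float)
            if test == "anova":
                pv = stats.ttest_ind(arr, cal, equal_var=False).pvalue
            else:
                pv = stats.mannwhitneyu(arr, cal, alternative="two-sided").pvalue
            raw.append(float(pv) if np.isfinite(pv) else 1.0)
        adj = multipletests(raw, method="holm")[1]
        posthoc = pd.Series(adj, index=others, dtype=float)
    return ChooseTestResult(test=test, p=p, shapiro_p=shapiro_p, posthoc=posthoc)


# -- normalization factors ----------------------------------------------------

@dataclass(frozen=True)
class NormalizationFactor:
    """Per-sample geometric mean of the reference genes' linear quantities."""

    values: pd.Series  # indexed by the sample MultiIndex
    refs: tuple[str, ...]

    def __post_init__(self):
        if (self.values <= 0).any():
            raise CqValidationError("normalization factors must be > 0")


def normalization_factor(
    ds: CqDataset, refs: Sequence[str], base: float = 2.0
) -> NormalizationFactor:
    """NF(s) = geometric mean over the reference genes of ``base**-Cq``.

    Invariant to reference order; requires a complete matrix over ``refs``.
    """
    refs = list(refs)
    if not refs:
        raise CqValidationError("empty reference gene set")
    matrix = to_matrix(ds.subset_genes(refs))
    # geometric mean of base**-Cq == base**(-mean Cq)
    nf = np.power(base, -matrix.loc[sorted(refs)].mean(axis=0))
    return NormalizationFactor(values=nf, refs=tuple(sorted(refs)))


@dataclass(frozen=True)
class NormalizedExpression:
    """Calibrator-relative expression of one target after NF division.

    ``verdict`` is "successful" iff every Holm-adjusted comparison of a
    non-calibrator group against the calibrator has P > alpha.
    """

    gene: str
    rel: pd.Series  # per-sample relative expression, calibrator mean == 1
    calibrator: object
    pvalues: pd.Series
    test: str
    verdict: str
    alpha: float

    @property
    def successful(self) -> bool:
        return self.verdict == "successful"


def normalize_goi(
    goi: CqDataset,
    nf: NormalizationFactor,
    calibrator: int,
    group_level: str = "passage",
    alpha: float = 0.05,
    base: float = 2.0,
) -> NormalizedExpression:
    """Normalize a one-gene dataset by ``nf`` and test every group vs the calibrator."""
    genes = goi.genes
    if len(genes) != 1:
        raise CqValidationError("normalize_goi expects a single-gene dataset")
    gene = genes[0]
    matrix = to_matrix(goi)
    if not matrix.columns.equals(nf.values.index):
        raise CqValidationError("GOI and normalization factor sample grids differ")
    rel = pd.Series(
        linear_quantity(matrix.iloc[0].to_numpy(), base=base), index=matrix.columns
    ) / nf.values
    group_labels = rel.index.get_level_values(group_level)
    if calibrator not in set(group_labels):
        raise CqValidationError(f"calibrator {calibrator!r} not in {group_level} labels")
    cal_mean = rel[group_labels == calibrator].mean()
    rel = rel / cal_mean
    groups = {lab: rel[group_labels == lab].to_numpy() for lab in sorted(set(group_labels))}
    res = choose_test(groups, calibrator=calibrator, alpha=alpha)
    verdict = "successful" if (res.posthoc > alpha).all() else "failed"
    return NormalizedExpression(
        gene=gene,
        rel=rel,
        calibrator=calibrator,
        pvalues=res.posthoc,
        test=res.test,
        verdict=verdict,
        alpha=alpha,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Verdict matrix of GOIs x candidate reference sets."""

    verdicts: pd.DataFrame  # "successful" / "failed"
    details: dict  # (goi, set label) -> NormalizedExpression

    def set_label(self, refs: Sequence[str]) -> str:
        return "+".join(sorted(refs))


def screen_reference_sets(
    panel: CqDataset,
    gois: Mapping[str, CqDataset],
    candidate_sets: Sequence[Sequence[str]],
    calibrator: int,
    alpha: float = 0.05,
    base: float = 2.0,
) -> ScreenResult:
    """Screen every (GOI, reference set) combination for successful normalization."""
    labels = ["+".join(sorted(s)) for s in candidate_sets]
    verdicts = pd.DataFrame(index=sorted(gois), columns=labels, dtype=object)
    details: dict = {}
    for refs, label in zip(candidate_sets, labels):
        nf = normalization_factor(panel, refs, base=base)
        for name in sorted(gois):
            norm = normalize_goi(
                gois[name], nf, calibrator=calibrator, alpha=alpha, base=base
            )
            verdicts.loc[name, label] = norm.verdict
            details[(name, label)] = norm
    return ScreenResult(verdicts=verdicts, details=details)


# -- nutrient stress ----------------------------------------------------------

def stress_fold_change(
    control: CqDataset, stress: CqDataset, base: float = 2.0
) -> pd.DataFrame:
    """Per-gene linear fold change of stress vs control with the >= 2x rule.

    fold = mean(base**-Cq, stress) / mean(base**-Cq, control); a gene is
    flagged when the fold leaves the (0.5, 2) band in either direction.
    A Mann-Whitney rank-sum P on the linear values is reported alongside.
    """
    shared = sorted(set(control.genes) & set(stress.genes))
    if not shared:
        raise CqValidationError("control and stress datasets share no genes")
    rows = {}
    for gene in shared:
        c = linear_quantity(
            control.frame.loc[control.frame["gene"] == gene, "cq"], base=base
        )
        s = linear_quantity(
            stress.frame.loc[stress.frame["gene"] == gene, "cq"], base=base
        )
        fold = s.mean() / c.mean()
        p = float(stats.mannwhitneyu(s, c, alternative="two-sided").pvalue)
        rows[gene] = {
            "fold": fold,
            "log2_fold": np.log2(fold),
            "flag_2x": bool(fold >= 2.0 or fold <= 0.5),
            "p_ranksum": p,
        }
    return pd.DataFrame(rows).T.sort_index()


@dataclass(frozen=True)
class StressGoiResult:
    """NF-normalized GOI comparison between a control and a stress condition."""

    gene: str
    refs: tuple[str, ...]
    fold: float
    log2_fold: float
    p: float
    flag_2x: bool
    rel_control: pd.Series
    rel_stress: pd.Series


def stress_goi_test(
    control: CqDataset,
    stress: CqDataset,
    goi: str,
    refs: Sequence[str],
    base: float = 2.0,
) -> StressGoiResult:
    """Fold change of a normalized GOI under stress, with Mann-Whitney P.

    Both datasets must contain the GOI and every reference gene; each
    condition is normalized by its own per-sample factor, so a global shift
    affecting GOI and references equally cancels.
    """
    refs = sorted(refs)
    for label, ds in (("control", control), ("stress", stress)):
        missing = sorted(set(refs + [goi]) - set(ds.genes))
        if missing:
            raise CqValidationError(f"{label} dataset lacks gene(s): {', '.join(missing)}")

    def _rel(ds: CqDataset) -> pd.Series:
        nf = normalization_factor(ds, refs, base=base)
        matrix = to_matrix(ds.subset_genes([goi]))
        lin = pd.Series(
            linear_quantity(matrix.iloc[0].to_numpy(), base=base), index=matrix.columns
        )
        return lin / nf.values

    rel_c = _rel(control)
    rel_s = _rel(stress)
    if len(rel_c) < 3 or len(rel_s) < 3:
        raise CqValidationError("need >= 3 samples per condition for the rank-sum test")
    fold = float(rel_s.mean() / rel_c.mean())
    p = float(
        stats.mannwhitneyu(rel_s.to_numpy(), rel_c.to_numpy(), alternative="two-sided").pvalue
    )
    return StressGoiResult(
        gene=goi,
        refs=tuple(refs),
        fold=fold,
        log2_fold=float(np.log2(fold)),
        p=p,
        flag_2x=bool(fold >= 2.0 or fold <= 0.5),
        rel_control=rel_c,
        rel_stress=rel_s,
    )


# -- Cq vs RNA-seq expression -------------------------------------------------

@dataclass(frozen=True)
class CqExpressionCorrelation:
    r: float
    p: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def correlate_cq_expression(
    cq_means: pd.Series, log2_expression: pd.Series
) -> CqExpressionCorrelation:
    """Pearson r and least-squares fit of per-gene Cq on log2 expression."""
    shared = sorted(set(cq_means.index) & set(log2_expression.index))
    if len(shared) < 3:
        raise CqValidationError("need >= 3 paired genes")
    x = log2_expression[shared].to_numpy(dtype=float)
    y = cq_means[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CqValidationError("zero variance on one axis; correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CqExpressionCorrelation(
        r=float(r),
        p=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(shared),
    )
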