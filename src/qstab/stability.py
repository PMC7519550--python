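"""The five reference-gene stability estimators plus descriptive screens.

Every estimator is defined on a complete gene x sample Cq matrix (see
:func:`qstab.data.to_matrix`) and returns a :class:`StabilityTable` in which
**lower scores always mean more stable**:

* ``cv`` — coefficient of variation of the linear quantities ``2**-Cq``;
* ``genorm`` — the pairwise log-ratio measure M with iterative exclusion of
  the least stable gene, plus the pairwise variation series V_n/n+1 used to
  choose how many reference genes to combine;
* ``normfinder`` — model-based variance decomposition: the gene-specific
  residual SD of the additive gene + sample model, with a small-panel bias
  correction, and (grouped mode) shrunken inter-group biases;
* ``bestkeeper`` — descriptive dispersion of crossing points (SD +/- CP),
  the per-sample geometric-mean index and Pearson correlations;
* ``delta_ct`` — mean SD of pairwise Cq differences between genes.

Amplification efficiency is fixed at perfect doubling (base 2) wherever a
``2**-Cq`` or ``2**dCq`` transform appears; a global base can be supplied
where it changes results (it cancels in geNorm and delta-Ct scores up to a
constant factor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CqDataset,
    CqValidationError,
    ExpressionMatrix,
    linear_quantity,
    to_matrix,
)

__all__ = [
    "StabilityTable",
    "GenormResult",
    "NormFinderResult",
    "BestKeeperResult",
    "FoldChangeResult",
    "describe_genes",
    "cv_linear",
    "genorm",
    "genorm_pairwise_variation",
    "normfinder",
    "bestkeeper",
    "comparative_delta_ct",
    "passage_fold_change",
    "expression_stability_from_counts",
    "competition_rank",
]


def competition_rank(scores: pd.Series) -> pd.Series:
    """Ascending competition ('min') ranks: tied scores share the lowest rank."""
    ranks = stats.rankdata(scores.to_numpy(), method="min")
    return pd.Series(ranks.astype(float), index=scores.index, name="rank")


@dataclass(frozen=True)
class StabilityTable:
    """Per-gene stability scores and ranks for one algorithm.

    ``frame`` is indexed by gene with at least columns ``score`` and
    ``rank``; extra algorithm-specific columns may be present.  Lower score
    means more stable for every algorithm in this package.
    """

    algorithm: str
    frame: pd.DataFrame
    direction: str = "lower_is_stable"

    def __post_init__(self):
        for col in ("score", "rank"):
            if col not in self.frame.columns:
                raise CqValidationError(f"StabilityTable needs a {col!r} column")

    @property
    def scores(self) -> pd.Series:
        return self.frame["score"]

    @property
    def ranks(self) -> pd.Series:
        return self.frame["rank"]

    def top(self, k: int) -> list[str]:
        """Genes ranked within the top ``k`` (ties included)."""
        return sorted(self.frame.index[self.frame["rank"] <= k])


def _score_table(algorithm: str, scores: pd.Series, extra: pd.DataFrame | None = None,
                 ranks: pd.Series | None = None) -> StabilityTable:
    frame = pd.DataFrame({"score": scores})
    if extra is not None:
        frame = extra.join(frame, how="right")[list(extra.columns) + ["score"]]
    frame["rank"] = competition_rank(scores) if ranks is None else ranks
    return StabilityTable(algorithm=algorithm, frame=frame.sort_index())


# -- descriptive statistics ---------------------------------------------------

def describe_genes(ds: CqDataset) -> pd.DataFrame:
    """Per-gene descriptive Cq statistics (n, mean, SD, min, max, geometric mean)."""
    out = {}
    for gene, grp in ds.frame.groupby("gene"):
        cq = grp["cq"].to_numpy()
        if len(cq) < 2:
            raise CqValidationError(f"gene {gene} has a single observation")
        out[gene] = {
            "n": len(cq),
            "mean_cq": cq.mean(),
            "sd_cq": cq.std(ddof=1),
            "min_cq": cq.min(),
            "max_cq": cq.max(),
            "geo_mean_cq": stats.gmean(cq),
        }
    return pd.DataFrame(out).T.sort_index().astype({"n": int})


def cv_linear(ds: CqDataset, base: float = 2.0) -> StabilityTable:
    """CV% of the linear quantities ``base**-Cq``, ranked ascending.

    Adding a constant to every Cq of a gene rescales mean and SD by the same
    factor, so CV% is invariant to per-gene offsets.
    """
    matrix = to_matrix(ds)
    linear = linear_quantity(matrix.to_numpy(), base=base)
    mean = linear.mean(axis=1)
    sd = linear.std(axis=1, ddof=1)
    cv = pd.Series(100.0 * sd / mean, index=matrix.index)
    extra = pd.DataFrame(
        {"mean_linear": mean, "sd_linear": sd}, index=matrix.index
    )
    return _score_table("cv", cv, extra)


# -- geNorm -------------------------------------------------------------------

@dataclass(frozen=True)
class GenormResult:
    """geNorm output: M-value table, exclusion order and stability order.

    ``exclusion_order`` lists genes from least to most stable as removed;
    ``stability_order`` is most-stable-first with the final pair leading.
    ``m_trace`` records, per exclusion round, the M value of every gene
    still in play.
    """

    table: StabilityTable
    exclusion_order: list[str]
    stability_order: list[str]
    m_trace: pd.DataFrame


def _pairwise_dct_sd(matrix: pd.DataFrame) -> pd.DataFrame:
    """SD over samples of Cq_g - Cq_h for every gene pair.

    Equals the SD of log2 of the relative-quantity ratio Q_g/Q_h for
    Q = 2**(anchor - Cq): the anchor cancels, so any per-gene anchor (the
    gene's minimum Cq here) yields identical geNorm M values.
    """
    genes = list(matrix.index)
    vals = matrix.to_numpy()
    k = len(genes)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sd = np.std(vals[i] - vals[j], ddof=1)
            out[i, j] = out[j, i] = sd
    return pd.DataFrame(out, index=genes, columns=genes)


def genorm(ds: CqDataset) -> GenormResult:
    """geNorm M values with iterative exclusion of the least stable gene.

    M_g is the mean, over all other genes h, of the SD across samples of the
    pairwise log2 expression ratio of g and h.  The gene with the highest M
    is removed and M recomputed on the remainder until two genes are left;
    those two are reported jointly with tied rank 1 (their mutual pairwise
    SD is their M).  Ties on M are broken by removing the lexicographically
    larger gene.
    """
    matrix = to_matrix(ds)
    if len(matrix) < 3:
        raise CqValidationError("geNorm needs >= 3 genes")
    D = _pairwise_dct_sd(matrix)
    remaining = list(matrix.index)
    exclusion: list[str] = []
    removal_m: dict[str, float] = {}
    trace_rows = []
    while len(remaining) > 2:
        sub = D.loc[remaining, remaining]
        m = sub.sum(axis=1) / (len(remaining) - 1)
        trace_rows.append(m.rename(f"round_{len(trace_rows) + 1}"))
        worst_m = m.max()
        worst = max(g for g in remaining if m[g] == worst_m)
        removal_m[worst] = float(m[worst])
        exclusion.append(worst)
        remaining.remove(worst)
    pair_m = float(D.loc[remaining[0], remaining[1]])
    for g in remaining:
        removal_m[g] = pair_m
    trace_rows.append(
        pd.Series({g: pair_m for g in remaining}, name=f"round_{len(trace_rows) + 1}")
    )
    stability_order = sorted(remaining) + list(reversed(exclusion))
    ranks = pd.Series(index=matrix.index, dtype=float)
    ranks[remaining] = 1.0
    for pos, g in enumerate(reversed(exclusion)):
        ranks[g] = 3.0 + pos
    scores = pd.Series(removal_m).reindex(matrix.index)
    table = _score_table("genorm", scores, ranks=ranks.reindex(sorted(matrix.index)))
    m_trace = pd.DataFrame(trace_rows).T.sort_index()
    return GenormResult(
        table=table,
        exclusion_order=exclusion,
        stability_order=stability_order,
        m_trace=m_trace,
    )


def genorm_pairwise_variation(
    ds: CqDataset, stability_order: list[str] | None = None
) -> pd.Series:
    """Pairwise variation V_n/n+1 for n = 2..k-1.

    NF_n(s) is the geometric mean of the relative quantities of the n most
    stable genes in sample s; V_n/n+1 is the SD over samples of
    log2(NF_n / NF_n+1).  A small V means the (n+1)-th gene adds nothing to
    the normalization factor; the conventional cutoff is 0.15.
    """
    if stability_order is None:
        stability_order = genorm(ds).stability_order
    matrix = to_matrix(ds)
    k = len(stability_order)
    if k < 3:
        raise CqValidationError("V series needs >= 3 genes")
    if set(stability_order) - set(matrix.index):
        raise CqValidationError("stability_order contains unknown genes")
    # log2 NF_n = mean over the first n genes of (anchor_g - Cq_g); anchors
    # cancel in the NF_n/NF_{n+1} ratio, so -Cq suffices.
    neg = -matrix.loc[stability_order].to_numpy()
    out = {}
    for n in range(2, k):
        nf_n = neg[:n].mean(axis=0)
        nf_n1 = neg[: n + 1].mean(axis=0)
        out[n] = float(np.std(nf_n - nf_n1, ddof=1))
    series = pd.Series(out, name="V")
    series.index.name = "n"
    return series


# -- NormFinder ---------------------------------------------------------------

@dataclass(frozen=True)
class NormFinderResult:
    """NormFinder output: per-gene stability, best pair, and all pair scores."""

    table: StabilityTable
    best_pair: tuple[str, str]
    pair_scores: pd.Series
    grouped: bool


def _normfinder_variances(matrix: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene residual variances of the gene + sample model.

    Residuals are the doubly centred values
    ``r_gs = y_gs - mean_g - mean_s + mean``; the naive per-gene mean square
    u_g mixes every gene's variance, and the correction
    ``sigma2_g = k/(k-2) * (u_g - sum(u)/(k(k-1)))`` unmixes it (undefined
    for k <= 2).  Negative estimates are truncated at zero.
    """
    k, n = matrix.shape
    if k <= 2:
        raise CqValidationError("NormFinder needs >= 3 genes")
    if n < 2:
        raise CqValidationError("NormFinder needs >= 2 samples")
    r = matrix - matrix.mean(axis=1, keepdims=True) - matrix.mean(axis=0, keepdims=True) + matrix.mean()
    u = (r**2).sum(axis=1) / (n - 1)
    sigma2 = (k / (k - 2)) * (u - u.sum() / (k * (k - 1)))
    return np.clip(sigma2, 0.0, None)


def normfinder(ds: CqDataset, groups: str | None = None) -> NormFinderResult:
    """NormFinder stability values on the Cq (log) scale.

    With ``groups=None`` the stability value of gene g is simply the
    bias-corrected residual SD of the additive gene + sample model.  With
    ``groups="culture"`` samples are grouped by culture and the stability
    value combines the intra-group SD with the shrunken inter-group bias:

        rho_g = mean_j ( |d~_gj| + sqrt(sigma2_gj / n_j) )

    where d_gj is the gene-by-group interaction contrast, shrunk towards 0
    by gamma2 / (gamma2 + sigma2_gj/n_j) with gamma2 a moment estimate of
    the inter-group variance (truncated at 0).

    The best pair minimises the same measure applied to the average of two
    genes: sqrt((sigma2_g + sigma2_h)/4) ungrouped, and with the averaged
    shrunken biases in grouped mode.
    """
    matrix = to_matrix(ds)
    genes = list(matrix.index)
    vals = matrix.to_numpy()
    k = len(genes)

    if groups is None:
        sigma2 = _normfinder_variances(vals)
        scores = pd.Series(np.sqrt(sigma2), index=genes)
        pair_scores = {}
        for i, j in itertools.combinations(range(k), 2):
            pair_scores[(genes[i], genes[j])] = float(
                np.sqrt((sigma2[i] + sigma2[j]) / 4.0)
            )
        extra = pd.DataFrame({"intra_sd": np.sqrt(sigma2)}, index=genes)
        grouped = False
    else:
        if groups == "culture":
            labels = matrix.columns.get_level_values("culture")
        else:
            labels = pd.Index(groups)
            if len(labels) != matrix.shape[1]:
                raise CqValidationError("group labels must match sample count")
        uniq = sorted(set(labels))
        if len(uniq) < 2:
            raise CqValidationError("grouped NormFinder needs >= 2 groups")
        sigma2_gj = np.zeros((k, len(uniq)))
        n_j = np.zeros(len(uniq), dtype=int)
        a_gj = np.zeros((k, len(uniq)))
        for j, lab in enumerate(uniq):
            cols = np.asarray(labels) == lab
            n_j[j] = cols.sum()
            if n_j[j] < 2:
                raise CqValidationError(f"group {lab!r} needs >= 2 samples")
            sub = vals[:, cols]
            sigma2_gj[:, j] = _normfinder_variances(sub)
            a_gj[:, j] = sub.mean(axis=1)
        # gene-by-group interaction contrasts (unweighted over groups)
        d_gj = a_gj - a_gj.mean(axis=1, keepdims=True) - a_gj.mean(axis=0, keepdims=True) + a_gj.mean()
        J = len(uniq)
        samp = sigma2_gj / n_j[None, :]
        gamma2 = max(
            0.0,
            (d_gj**2).sum() / ((k - 1) * (J - 1)) - samp.mean(),
        )
        shrink = gamma2 / (gamma2 + samp) if gamma2 > 0 else np.zeros_like(samp)
        d_shrunk = d_gj * shrink
        rho = (np.abs(d_shrunk) + np.sqrt(samp)).mean(axis=1)
        scores = pd.Series(rho, index=genes)
        pair_scores = {}
        for i, j in itertools.combinations(range(k), 2):
            d_pair = (d_shrunk[i] + d_shrunk[j]) / 2.0
            samp_pair = (sigma2_gj[i] + sigma2_gj[j]) / (4.0 * n_j)
            pair_scores[(genes[i], genes[j])] = float(
                (np.abs(d_pair) + np.sqrt(samp_pair)).mean()
            )
        extra = pd.DataFrame(
            {
                "intra_sd": np.sqrt((sigma2_gj / 1.0).mean(axis=1)),
                "inter_bias": np.abs(d_shrunk).mean(axis=1),
            },
            index=genes,
        )
        grouped = True

    pairs = pd.Series(pair_scores).sort_values(kind="stable")
    best_pair = tuple(sorted(pairs.index[0]))
    return NormFinderResult(
        table=_score_table("normfinder", scores, extra),
        best_pair=best_pair,
        pair_scores=pairs,
        grouped=grouped,
    )


# -- BestKeeper ---------------------------------------------------------------

@dataclass(frozen=True)
class BestKeeperResult:
    """BestKeeper output.

    ``descriptives`` per gene: geometric/arithmetic mean CP, min, max, the
    dispersion SD +/- CP (mean absolute deviation around the arithmetic mean
    by default, sample SD with ``dispersion="sd"``) and its fold-range
    expression x-fold = 2**dispersion.  ``index`` is the per-sample
    geometric mean CP over all genes; ``index_corr`` the Pearson r (and P)
    of each gene against the index; ``gene_corr`` the gene x gene Pearson r
    matrix.  Genes with dispersion > 1 cycle are flagged ``inconsistent``.
    """

    descriptives: pd.DataFrame
    table: StabilityTable
    gene_corr: pd.DataFrame
    index: pd.Series
    index_corr: pd.DataFrame
    dispersion: str


def bestkeeper(ds: CqDataset, dispersion: str = "mad", base: float = 2.0) -> BestKeeperResult:
    if dispersion not in ("mad", "sd"):
        raise CqValidationError("dispersion must be 'mad' or 'sd'")
    matrix = to_matrix(ds)
    vals = matrix.to_numpy()
    mean = vals.mean(axis=1)
    if dispersion == "mad":
        disp = np.abs(vals - mean[:, None]).mean(axis=1)
    else:
        disp = vals.std(axis=1, ddof=1)
    desc = pd.DataFrame(
        {
            "geo_mean_cp": stats.gmean(vals, axis=1),
            "mean_cp": mean,
            "min_cp": vals.min(axis=1),
            "max_cp": vals.max(axis=1),
            "sd_cp": disp,
            "x_fold": np.power(base, disp),
            "inconsistent": disp > 1.0,
        },
        index=matrix.index,
    )
    index = pd.Series(stats.gmean(vals, axis=0), index=matrix.columns, name="bestkeeper_index")
    with np.errstate(invalid="ignore"):  # constant genes -> undefined r = NaN
        gene_corr = pd.DataFrame(
            np.corrcoef(vals), index=matrix.index, columns=matrix.index
        )
    rows = {}
    for gene, row in zip(matrix.index, vals):
        if np.ptp(row) == 0.0 or np.ptp(index.to_numpy()) == 0.0:
            rows[gene] = {"r": np.nan, "p": np.nan}
        else:
            r, p = stats.pearsonr(row, index.to_numpy())
            rows[gene] = {"r": r, "p": p}
    index_corr = pd.DataFrame(rows).T
    table = _score_table("bestkeeper", desc["sd_cp"].rename(None))
    return BestKeeperResult(
        descriptives=desc,
        table=table,
        gene_corr=gene_corr,
        index=index,
        index_corr=index_corr,
        dispersion=dispersion,
    )


# -- comparative delta-Ct -----------------------------------------------------

def comparative_delta_ct(ds: CqDataset) -> StabilityTable:
    """Mean SD of pairwise Cq differences: score_g = mean_h SD_s(Cq_g - Cq_h)."""
    matrix = to_matrix(ds)
    if len(matrix) < 2:
        raise CqValidationError("comparative delta-Ct needs >= 2 genes")
    D = _pairwise_dct_sd(matrix)
    k = len(matrix)
    scores = D.sum(axis=1) / (k - 1)
    return _score_table("delta_ct", scores)


# -- calibrator-relative fold changes ----------------------------------------

@dataclass(frozen=True)
class FoldChangeResult:
    """Calibrator-relative linear fold changes plus per-gene passage tests.

    ``folds``: long frame (gene, culture, passage, lysate, tech_rep, fold);
    ``tests``: per gene the gated omnibus test id and P plus Holm-adjusted
    per-passage comparisons against the calibrator.
    """

    folds: pd.DataFrame
    tests: pd.DataFrame
    calibrator: int
    scale: str


def passage_fold_change(
    ds: CqDataset,
    calibrator: int,
    scale: str = "linear",
    alpha: float = 0.05,
    base: float = 2.0,
) -> FoldChangeResult:
    """Per-sample fold change ``base**-Cq`` relative to the calibrator passage.

    The calibrator-passage mean fold is 1 by construction.  Per-gene
    significance of passage effects uses the Shapiro-Wilk-gated test of
    :func:`qstab.validation.choose_test` on linear values by default
    (``scale="cq"`` runs it on Cq values instead).
    """
    from .validation import choose_test  # late import: validation is test plumbing

    calibrator = int(calibrator)
    if calibrator not in ds.passages:
        raise CqValidationError(f"calibrator passage {calibrator} not in dataset")
    frame = ds.frame.copy()
    frame["linear"] = linear_quantity(frame["cq"], base=base)
    cal_mean = (
        frame[frame["passage"] == calibrator].groupby("gene")["linear"].mean()
    )
    frame["fold"] = frame["linear"] / frame["gene"].map(cal_mean)
    tests = {}
    for gene, grp in frame.groupby("gene"):
        col = "linear" if scale == "linear" else "cq"
        groups = {p: sub[col].to_numpy() for p, sub in grp.groupby("passage")}
        res = choose_test(groups, calibrator=calibrator, alpha=alpha)
        tests[gene] = {
            "test": res.test,
            "p_omnibus": res.p,
            "significant": res.p <= alpha,
            **{f"p_vs_calibrator[{p}]": v for p, v in res.posthoc.items()},
        }
    folds = frame[["gene", "culture", "passage", "lysate", "tech_rep", "fold"]]
    return FoldChangeResult(
        folds=folds.reset_index(drop=True),
        tests=pd.DataFrame(tests).T.sort_index(),
        calibrator=calibrator,
        scale=scale,
    )


# -- RNA-seq expression screens ----------------------------------------------

def expression_stability_from_counts(
    m: ExpressionMatrix, mode: str = "counts"
) -> pd.DataFrame:
    """Per-gene mean/SD/CV on the log2 scale of an expression matrix.

    ``mode="counts"`` uses log2(x + 1) (normalized counts); ``mode="tpm"``
    uses log2(x) and rejects zeros.  Genes are labelled by the screens used
    for candidate reference genes: mean log2 TPM > 5 -> medium-to-high
    expression; SD < 1 -> low variance.
    """
    if m.scale != "linear":
        raise CqValidationError("expected a linear-scale matrix")
    vals = m.values.to_numpy(dtype=float)
    if mode == "counts":
        logv = np.log2(vals + 1.0)
    elif mode == "tpm":
        if (vals <= 0).any():
            raise CqValidationError(
                "TPM mode requires strictly positive values; use mode='counts' "
                "for matrices containing zeros"
            )
        logv = np.log2(vals)
    else:
        raise CqValidationError(f"unknown mode {mode!r}")
    mean = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / np.abs(mean), np.nan)
    return pd.DataFrame(
        {
            "mean_log2": mean,
            "sd_log2": sd,
            "cv_pct": cv,
            "medium_to_high_expression": mean > 5.0,
            "low_variance": sd < 1.0,
        },
        index=m.values.index,
    ).sort_index()
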