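"""Rank aggregation, the geNorm optimal-count rule, and integrated selection.

Algorithms disagree; the consensus here is the geometric mean of a gene's
per-algorithm competition ranks (the RefFinder-style aggregate), followed by
an auditable selection procedure: count top-k appearances per algorithm,
prefer genes without a significant passage trend, and emit a reference pair
plus a cross-condition "experimental candidate" as a triplet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CqValidationError
from .stability import StabilityTable, competition_rank

__all__ = [
    "ConsensusResult",
    "OptimalGeneCount",
    "SelectionResult",
    "rank_genes",
    "build_rank_matrix",
    "reffinder_consensus",
    "optimal_gene_count",
    "integrated_selection",
]


def rank_genes(table: StabilityTable) -> pd.Series:
    """Ascending competition ranks recomputed from a table's scores."""
    if table.direction != "lower_is_stable":
        raise CqValidationError(f"unknown score direction {table.direction!r}")
    return competition_rank(table.scores)


def build_rank_matrix(tables: Sequence[StabilityTable]) -> pd.DataFrame:
    """Gene x algorithm matrix of ranks; algorithms must share one gene set."""
    if len(tables) < 2:
        raise CqValidationError("consensus needs >= 2 algorithm rankings")
    gene_sets = [set(t.frame.index) for t in tables]
    if any(gs != gene_sets[0] for gs in gene_sets[1:]):
        raise CqValidationError("algorithm tables cover different gene sets")
    cols = {t.algorithm: t.ranks for t in tables}
    return pd.DataFrame(cols).sort_index()


@dataclass(frozen=True)
class ConsensusResult:
    """Geometric-mean-of-ranks consensus across algorithms."""

    frame: pd.DataFrame  # columns: geomean, rank

    @property
    def geomean(self) -> pd.Series:
        return self.frame["geomean"]

    @property
    def ranks(self) -> pd.Series:
        return self.frame["rank"]

    def as_table(self) -> StabilityTable:
        frame = self.frame.rename(columns={"geomean": "score"})
        return StabilityTable(algorithm="consensus", frame=frame)


def reffinder_consensus(rank_matrix: pd.DataFrame) -> ConsensusResult:
    """Per-gene geometric mean of ranks, re-ranked ascending.

    The geomean of a gene's ranks always lies between its best and worst
    single-algorithm rank, so consensus never promotes a gene above every
    individual ranking.
    """
    if rank_matrix.shape[1] < 2:
        raise CqValidationError("consensus needs >= 2 algorithm columns")
    if rank_matrix.isna().any().any():
        raise CqValidationError("rank matrix has missing entries (gene sets differ)")
    geomean = pd.Series(
        np.exp(np.log(rank_matrix.to_numpy(dtype=float)).mean(axis=1)),
        index=rank_matrix.index,
        name="geomean",
    )
    frame = pd.DataFrame({"geomean": geomean, "rank": competition_rank(geomean)})
    return ConsensusResult(frame=frame.sort_index())


@dataclass(frozen=True)
class OptimalGeneCount:
    """Decision of the V_n/n+1 < cutoff rule.

    ``n`` is the smallest n whose V_n/n+1 falls below the cutoff, or None if
    no V does; ``best_n`` then flags the minimising n for user judgement.
    """

    n: int | None
    below_cutoff: bool
    best_n: int
    cutoff: float
    trace: str


def optimal_gene_count(v_series: pd.Series, cutoff: float = 0.15) -> OptimalGeneCount:
    if len(v_series) == 0:
        raise CqValidationError("empty V series")
    below = v_series[v_series < cutoff]
    best_n = int(v_series.idxmin())
    if below.empty:
        return OptimalGeneCount(
            n=None,
            below_cutoff=False,
            best_n=best_n,
            cutoff=cutoff,
            trace=(
                f"no V_n/n+1 below cutoff {cutoff}; minimum is "
                f"V_{best_n}/{best_n + 1} = {v_series.min():.4g} — judge manually"
            ),
        )
    n = int(below.index[0])
    return OptimalGeneCount(
        n=n,
        below_cutoff=True,
        best_n=best_n,
        cutoff=cutoff,
        trace=f"V_{n}/{n + 1} = {below.iloc[0]:.4g} < {cutoff} -> use {n} reference genes",
    )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the integrated selection rule with a full audit trail."""

    pair: tuple[str, str]
    experimental: str
    triplet: tuple[str, str, str]
    counts: pd.DataFrame
    audit: list[str]


def integrated_selection(
    tables_by_dataset: Mapping[str, Sequence[StabilityTable]],
    passage_pvalues: Mapping[str, pd.Series] | None = None,
    top_k: int = 3,
    alpha: float = 0.05,
) -> SelectionResult:
    """Codified candidate-selection rule.

    For every dataset (e.g. one per culture) each gene scores the number of
    supplied algorithm tables ranking it in the top ``top_k``.  The
    reference pair is the two best genes of the *first* dataset, preferring
    genes with no significant passage trend (P > alpha where a per-gene P is
    supplied) and breaking ties lexicographically.  The "experimental
    candidate" is the gene, outside the pair, with the highest total top-k
    count across all datasets; pair + candidate form the recommended
    triplet.  Every decision is written to the audit log.
    """
    if not tables_by_dataset:
        raise CqValidationError("no stability tables supplied")
    labels = list(tables_by_dataset)
    counts = {}
    genes_ref: set[str] | None = None
    for label in labels:
        tables = list(tables_by_dataset[label])
        if not tables:
            raise CqValidationError(f"dataset {label!r} has no tables")
        genes = set(tables[0].frame.index)
        if genes_ref is None:
            genes_ref = genes
        if genes != genes_ref:
            raise CqValidationError("datasets cover different gene sets")
        c = pd.Series(0, index=sorted(genes), dtype=int)
        for t in tables:
            c[t.top(top_k)] += 1
        counts[label] = c
    assert genes_ref is not None
    if len(genes_ref) < 3:
        raise CqValidationError("integrated selection needs >= 3 genes")
    count_frame = pd.DataFrame(counts)
    count_frame["total"] = count_frame.sum(axis=1)

    audit: list[str] = []
    primary = labels[0]
    audit.append(
        f"primary dataset {primary!r}: top-{top_k} counts over "
        f"{len(tables_by_dataset[primary])} algorithms"
    )

    def trend_violates(gene: str) -> bool:
        if not passage_pvalues or primary not in passage_pvalues:
            return False
        pvals = passage_pvalues[primary]
        return gene in pvals.index and pvals[gene] <= alpha

    order = sorted(
        count_frame.index,
        key=lambda g: (-count_frame.loc[g, primary], trend_violates(g), g),
    )
    pair = tuple(order[:2])
    for g in pair:
        note = f"selected {g}: top-{top_k} in {count_frame.loc[g, primary]} algorithm(s)"
        if trend_violates(g):
            note += f" [violation: significant passage trend at alpha={alpha}]"
        elif passage_pvalues and primary in passage_pvalues:
            note += "; no significant passage trend"
        audit.append(note)

    rest = count_frame.drop(list(pair))
    cand_order = sorted(rest.index, key=lambda g: (-rest.loc[g, "total"], g))
    experimental = cand_order[0]
    audit.append(
        f"experimental candidate {experimental}: highest cross-dataset top-{top_k} "
        f"count ({rest.loc[experimental, 'total']}) outside the pair"
    )
    if len(cand_order) > 1 and rest.loc[cand_order[1], "total"] == rest.loc[experimental, "total"]:
        audit.append(
            f"tie on cross-dataset count with {cand_order[1]}; "
            f"broken lexicographically in favour of {experimental}"
        )
    triplet = (*pair, experimental)
    audit.append(f"recommended triplet: {'-'.join(triplet)}")
    return SelectionResult(
        pair=pair,
        experimental=experimental,
        triplet=triplet,
        counts=count_frame,
        audit=audit,
    )
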