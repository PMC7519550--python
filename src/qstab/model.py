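"""statsmodels-style front end: a model built from Cq data whose ``fit()``
returns a results object carrying every stability table, the V series, the
consensus ranking and a ``summary()``.

    >>> model = ReferenceGeneStability(dataset)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.consensus.ranks.head()

The per-algorithm functions in :mod:`qstab.stability` remain the primitive
interface; this class only orchestrates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import consensus as _consensus
from . import stability as _stab
from .data import CqDataset, CqValidationError, collapse_replicates

__all__ = ["ReferenceGeneStability", "StabilityResults"]

ALL_ALGORITHMS = ("cv", "genorm", "normfinder", "bestkeeper", "delta_ct")


class ReferenceGeneStability:
    """Reference-gene stability model for one Cq dataset.

    Parameters
    ----------
    data
        A :class:`~qstab.data.CqDataset`.  Technical replicates are
        collapsed to lysate means by default before any estimator runs
        (``collapse=None`` keeps the replicate level).
    groups
        ``None`` for a single-condition analysis or ``"culture"`` to let
        NormFinder decompose intra- vs inter-culture variation (use for
        merged sub-clone datasets).
    """

    def __init__(
        self,
        data: CqDataset,
        groups: str | None = None,
        collapse: str | None = "lysate_mean",
    ):
        if collapse is not None and data.sample_unit == "tech_rep":
            data = collapse_replicates(data, level=collapse)
        self.data = data
        self.groups = groups

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, sample_unit: str = "tech_rep", **kwargs
    ) -> "ReferenceGeneStability":
        return cls(CqDataset(frame, sample_unit=sample_unit), **kwargs)

    @classmethod
    def from_csv(cls, path, layout: str = "long", **kwargs) -> "ReferenceGeneStability":
        from .data import read_cq_table

        return cls(read_cq_table(path, layout=layout), **kwargs)

    def fit(
        self,
        algorithms: tuple[str, ...] = ALL_ALGORITHMS,
        bestkeeper_dispersion: str = "mad",
        genorm_cutoff: float = 0.15,
        base: float = 2.0,
    ) -> "StabilityResults":
        unknown = set(algorithms) - set(ALL_ALGORITHMS)
        if unknown:
            raise CqValidationError(f"unknown algorithm(s): {', '.join(sorted(unknown))}")
        if len(algorithms) < 2:
            raise CqValidationError("need >= 2 algorithms for a consensus")
        tables: dict[str, _stab.StabilityTable] = {}
        genorm_res = None
        bestkeeper_res = None
        normfinder_res = None
        v_series = None
        optimal = None
        if "cv" in algorithms:
            tables["cv"] = _stab.cv_linear(self.data, base=base)
        if "genorm" in algorithms:
            genorm_res = _stab.genorm(self.data)
            tables["genorm"] = genorm_res.table
            v_series = _stab.genorm_pairwise_variation(
                self.data, genorm_res.stability_order
            )
            optimal = _consensus.optimal_gene_count(v_series, cutoff=genorm_cutoff)
        if "normfinder" in algorithms:
            normfinder_res = _stab.normfinder(self.data, groups=self.groups)
            tables["normfinder"] = normfinder_res.table
        if "bestkeeper" in algorithms:
            bestkeeper_res = _stab.bestkeeper(
                self.data, dispersion=bestkeeper_dispersion, base=base
            )
            tables["bestkeeper"] = bestkeeper_res.table
        if "delta_ct" in algorithms:
            tables["delta_ct"] = _stab.comparative_delta_ct(self.data)
        rank_matrix = _consensus.build_rank_matrix(list(tables.values()))
        cons = _consensus.reffinder_consensus(rank_matrix)
        return StabilityResults(
            model=self,
            tables=tables,
            rank_matrix=rank_matrix,
            consensus=cons,
            genorm=genorm_res,
            v_series=v_series,
            optimal_count=optimal,
            normfinder=normfinder_res,
            bestkeeper=bestkeeper_res,
        )


@dataclass
class StabilityResults:
    """Fitted stability analysis: estimates, rankings and diagnostics."""

    model: ReferenceGeneStability
    tables: dict
    rank_matrix: pd.DataFrame
    consensus: _consensus.ConsensusResult
    genorm: _stab.GenormResult | None = None
    v_series: pd.Series | None = None
    optimal_count: _consensus.OptimalGeneCount | None = None
    normfinder: _stab.NormFinderResult | None = None
    bestkeeper: _stab.BestKeeperResult | None = None

    @property
    def algorithms(self) -> list[str]:
        return list(self.tables)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (gene, algorithm, score, rank) frame across all algorithms."""
        rows = []
        for name, table in self.tables.items():
            frame = table.frame[["score", "rank"]].copy()
            frame.insert(0, "algorithm", name)
            frame.insert(0, "gene", frame.index)
            rows.append(frame.reset_index(drop=True))
        return pd.concat(rows, ignore_index=True)

    def select(self, passage_pvalues: pd.Series | None = None, top_k: int = 3,
               alpha: float = 0.05) -> _consensus.SelectionResult:
        label = self.model.data.provenance or "dataset"
        tables = list(self.tables.values()) + [self.consensus.as_table()]
        pvals = {label: passage_pvalues} if passage_pvalues is not None else None
        return _consensus.integrated_selection(
            {label: tables}, passage_pvalues=pvals, top_k=top_k, alpha=alpha
        )

    def summary(self) -> str:
        """Human-readable summary table (scores per algorithm + consensus)."""
        data = self.model.data
        wide = pd.DataFrame(
            {name: t.scores.round(4) for name, t in self.tables.items()}
        )
        wide["geomean_rank"] = self.consensus.geomean.round(3)
        wide["consensus_rank"] = self.consensus.ranks.astype(int)
        wide = wide.sort_values("consensus_rank")
        lines = [
            "Reference-gene stability analysis",
            "=" * 70,
            f"dataset: {data.provenance or '(unnamed)'}   unit: {data.sample_unit}",
            f"genes: {len(data.genes)}   observations: {data.n_observations}   "
            f"cultures: {', '.join(data.cultures)}",
            f"algorithms: {', '.join(self.tables)} (all scores: lower = more stable)",
            "-" * 70,
            wide.to_string(),
        ]
        if self.v_series is not None and self.optimal_count is not None:
            v_str = "  ".join(
                f"V{n}/{n + 1}={v:.4f}" for n, v in self.v_series.items()
            )
            lines += ["-" * 70, f"geNorm pairwise variation: {v_str}",
                      f"optimal gene count: {self.optimal_count.trace}"]
        if self.normfinder is not None:
            lines.append(
                "NormFinder best pair: "
                + "-".join(self.normfinder.best_pair)
                + f" (score {self.normfinder.pair_scores.iloc[0]:.4f})"
            )
        lines.append("=" * 70)
        return "\n".join(lines)
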