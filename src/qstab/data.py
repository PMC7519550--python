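"""Data model, validation and I/O for RT-qPCR quantification-cycle (Cq) tables.

The single input currency of every stability algorithm in this package is a
:class:`CqDataset`: a long-format table of Cq observations keyed by
``(gene, culture, passage, lysate, tech_rep)``.  ``culture`` labels a
biological replicate culture (sub-clone), ``passage`` is an ordinal passage
number, ``lysate`` indexes the biological lysate within a passage, and
``tech_rep`` the qPCR technical replicate within a lysate.

Two delimited-text dialects are supported:

* **long** — columns ``gene, culture, passage, lysate, tech_rep, cq``;
* **wide** — first column ``gene``, remaining column headers encode the
  sample as ``culture.passage.lysate.rep`` (or ``culture.passage.lysate``
  once technical replicates have been collapsed), so that sample metadata
  survives a plain CSV round trip.

Missing cells are never imputed: operations that need a complete
gene x sample matrix fail loudly with the list of holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QstabError",
    "SchemaError",
    "CqValidationError",
    "IncompleteMatrixError",
    "CqDataset",
    "ExpressionMatrix",
    "read_cq_table",
    "write_cq_table",
    "collapse_replicates",
    "merge_datasets",
    "to_matrix",
    "from_matrix",
    "missing_cells",
    "linear_quantity",
]

#: canonical long-format column order
OBS_COLUMNS = ["gene", "culture", "passage", "lysate", "tech_rep", "cq"]

#: metadata columns identifying one physical qPCR well
KEY_COLUMNS = OBS_COLUMNS[:-1]

DEFAULT_MAX_CYCLES = 40.0


class QstabError(Exception):
    """Base class for all validation and analysis errors raised by qstab."""


class SchemaError(QstabError):
    """A table is missing required columns or uses an unknown layout."""


class CqValidationError(QstabError):
    """Cq values (or dataset structure) violate the data-model invariants."""


class IncompleteMatrixError(QstabError):
    """A complete gene x sample matrix was required but cells are missing."""

    def __init__(self, holes: Sequence[tuple]):
        self.holes = list(holes)
        preview = ", ".join(repr(h) for h in self.holes[:10])
        more = "" if len(self.holes) <= 10 else f" (+{len(self.holes) - 10} more)"
        super().__init__(
            f"{len(self.holes)} missing (gene, sample) cell(s): {preview}{more}"
        )


def linear_quantity(cq, base: float = 2.0):
    """Relative linear-scale quantity ``base**(-Cq)`` (perfect doubling by default)."""
    return np.power(base, -np.asarray(cq, dtype=float))


def _normalise_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.loc[:, OBS_COLUMNS].copy()
    out["gene"] = out["gene"].astype(str)
    out["culture"] = out["culture"].astype(str)
    for col in ("passage", "lysate", "tech_rep"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
    out["cq"] = pd.to_numeric(out["cq"], errors="raise").astype(float)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class CqDataset:
    """Validated collection of Cq observations.

    Parameters
    ----------
    frame
        Long-format table with columns ``gene, culture, passage, lysate,
        tech_rep, cq``.  Copied and normalised on construction.
    sample_unit
        ``"tech_rep"`` for raw triplicate wells, ``"lysate_mean"`` after
        :func:`collapse_replicates`.
    provenance
        Free-text label carried through analyses and reports.
    max_cycles
        Upper bound of the thermocycler programme; every Cq must satisfy
        ``0 < cq <= max_cycles``.
    """

    frame: pd.DataFrame
    sample_unit: str = "tech_rep"
    provenance: str = ""
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self):
        if self.sample_unit not in ("tech_rep", "lysate_mean"):
            raise SchemaError(f"unknown sample_unit {self.sample_unit!r}")
        missing = [c for c in OBS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        frame = _normalise_frame(self.frame)
        _validate_cq(frame, self.max_cycles)
        dup = frame.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            rows = frame.loc[dup, KEY_COLUMNS].head(5).to_dict("records")
            raise CqValidationError(
                f"duplicate (gene, culture, passage, lysate, tech_rep) keys, e.g. {rows}"
            )
        counts = frame.groupby("gene", sort=False)["cq"].size()
        lonely = counts[counts < 2]
        if not lonely.empty:
            raise CqValidationError(
                "every gene needs >= 2 observations; offending gene(s): "
                + ", ".join(lonely.index)
            )
        object.__setattr__(self, "frame", frame)

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].unique())

    @property
    def cultures(self) -> list[str]:
        return sorted(self.frame["culture"].unique())

    @property
    def passages(self) -> list[int]:
        return sorted(self.frame["passage"].unique())

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    def subset_genes(self, genes: Iterable[str]) -> "CqDataset":
        genes = list(genes)
        unknown = sorted(set(genes) - set(self.genes))
        if unknown:
            raise CqValidationError(f"gene(s) not in dataset: {', '.join(unknown)}")
        return replace(self, frame=self.frame[self.frame["gene"].isin(genes)])

    def subset_cultures(self, cultures: Iterable[str]) -> "CqDataset":
        cultures = list(cultures)
        return replace(self, frame=self.frame[self.frame["culture"].isin(cultures)])

    def to_matrix(self, require_complete: bool = True) -> pd.DataFrame:
        return to_matrix(self, require_complete=require_complete)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CqDataset({len(self.frame)} obs, {len(self.genes)} genes, "
            f"cultures={self.cultures}, unit={self.sample_unit!r})"
        )


def _validate_cq(frame: pd.DataFrame, max_cycles: float) -> None:
    cq = frame["cq"].to_numpy()
    bad = ~np.isfinite(cq) | (cq <= 0) | (cq > max_cycles)
    if bad.any():
        rows = frame.loc[bad].head(10)
        detail = "; ".join(
            f"row {i}: gene={r.gene} cq={r.cq}" for i, r in rows.iterrows()
        )
        raise CqValidationError(
            f"{int(bad.sum())} Cq value(s) outside (0, {max_cycles}]: {detail}"
        )


# -- I/O ----------------------------------------------------------------------

def _sample_id(row, with_rep: bool) -> str:
    parts = [row["culture"], str(row["passage"]), str(row["lysate"])]
    if with_rep:
        parts.append(str(row["tech_rep"]))
    return ".".join(parts)


def read_cq_table(
    path,
    layout: str = "long",
    max_cycles: float = DEFAULT_MAX_CYCLES,
    sample_unit: str = "tech_rep",
    provenance: str | None = None,
) -> CqDataset:
    """Read a delimited Cq table (CSV or TSV, sniffed) into a :class:`CqDataset`.

    ``layout="long"`` expects the canonical six columns; ``layout="wide"``
    expects a first column ``gene`` and sample columns named
    ``culture.passage.lysate[.rep]``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path, sep=None, engine="python")
    if layout == "long":
        missing = [c for c in OBS_COLUMNS if c not in raw.columns]
        if missing:
            raise SchemaError(
                f"long layout requires column(s) {', '.join(missing)} (file {path.name})"
            )
        frame = raw
    elif layout == "wide":
        if raw.columns[0] != "gene":
            raise SchemaError("wide layout requires 'gene' as the first column")
        long = raw.melt(id_vars="gene", var_name="sample", value_name="cq")
        parts = long["sample"].str.split(".", expand=True)
        if parts.shape[1] not in (3, 4):
            raise SchemaError(
                "wide sample headers must be 'culture.passage.lysate[.rep]'"
            )
        long["culture"] = parts[0]
        long["passage"] = parts[1]
        long["lysate"] = parts[2]
        long["tech_rep"] = parts[3] if parts.shape[1] == 4 else 1
        if parts.shape[1] == 3:
            sample_unit = "lysate_mean"
        frame = long.drop(columns="sample")
    else:
        raise SchemaError(f"unknown layout {layout!r}")
    try:
        frame = _normalise_frame(frame)
    except (ValueError, TypeError) as exc:
        raise CqValidationError(f"non-numeric value in {path.name}: {exc}") from exc
    return CqDataset(
        frame,
        sample_unit=sample_unit,
        provenance=provenance if provenance is not None else path.stem,
        max_cycles=max_cycles,
    )


def write_cq_table(ds: CqDataset, path, layout: str = "long") -> None:
    """Write a dataset back to CSV in the long or wide dialect."""
    path = Path(path)
    if layout == "long":
        ds.frame.to_csv(path, index=False)
    elif layout == "wide":
        with_rep = ds.sample_unit == "tech_rep"
        frame = ds.frame.copy()
        frame["sample"] = frame.apply(_sample_id, axis=1, with_rep=with_rep)
        wide = frame.pivot(index="gene", columns="sample", values="cq")
        wide.to_csv(path)
    else:
        raise SchemaError(f"unknown layout {layout!r}")


# -- restructuring ------------------------------------------------------------

def collapse_replicates(ds: CqDataset, level: str = "lysate_mean") -> CqDataset:
    """Average technical replicates to one value per (gene, culture, passage, lysate).

    Cq values are averaged on the cycle (log) scale before any linear
    ``2**-Cq`` transform downstream, matching how triplicate wells of one
    lysate estimate a single template quantity.
    """
    if level != "lysate_mean":
        raise SchemaError(f"unknown collapse level {level!r}")
    if ds.sample_unit != "tech_rep":
        raise SchemaError("dataset is already collapsed past tech_rep level")
    grouped = (
        ds.frame.groupby(["gene", "culture", "passage", "lysate"], sort=False)["cq"]
        .mean()
        .reset_index()
    )
    grouped["tech_rep"] = 1
    return CqDataset(
        grouped[OBS_COLUMNS],
        sample_unit="lysate_mean",
        provenance=ds.provenance,
        max_cycles=ds.max_cycles,
    )


def merge_datasets(a: CqDataset, b: CqDataset) -> CqDataset:
    """Union of two datasets restricted to their shared genes.

    Culture labels are preserved so grouped analyses (e.g. NormFinder with
    sub-clone groups) can still tell the sources apart.
    """
    if a.sample_unit != b.sample_unit:
        raise SchemaError(
            f"sample units differ: {a.sample_unit!r} vs {b.sample_unit!r}"
        )
    shared = sorted(set(a.genes) & set(b.genes))
    if not shared:
        raise CqValidationError("datasets share no genes; nothing to merge")
    frame = pd.concat(
        [
            a.frame[a.frame["gene"].isin(shared)],
            b.frame[b.frame["gene"].isin(shared)],
        ],
        ignore_index=True,
    )
    provenance = "+".join(p for p in (a.provenance, b.provenance) if p)
    return CqDataset(
        frame,
        sample_unit=a.sample_unit,
        provenance=provenance,
        max_cycles=max(a.max_cycles, b.max_cycles),
    )


def _sample_levels(ds: CqDataset) -> list[str]:
    if ds.sample_unit == "tech_rep":
        return ["culture", "passage", "lysate", "tech_rep"]
    return ["culture", "passage", "lysate"]


def to_matrix(ds: CqDataset, require_complete: bool = True) -> pd.DataFrame:
    """Pivot to a gene x sample Cq matrix with deterministic sample order.

    Columns are a MultiIndex over ``(culture, passage, lysate[, tech_rep])``
    sorted lexicographically, so downstream scores never depend on input row
    order.  With ``require_complete`` (default) any hole raises
    :class:`IncompleteMatrixError` listing every missing cell.
    """
    levels = _sample_levels(ds)
    matrix = ds.frame.pivot_table(
        index="gene", columns=levels, values="cq", aggfunc="mean", sort=True
    )
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    if require_complete:
        holes = [
            (gene, col)
            for gene, row in matrix.iterrows()
            for col, val in row.items()
            if pd.isna(val)
        ]
        if holes:
            raise IncompleteMatrixError(holes)
    return matrix


def missing_cells(ds: CqDataset) -> list[tuple]:
    """Report of (gene, sample) holes in the gene x sample matrix (empty if complete)."""
    matrix = to_matrix(ds, require_complete=False)
    return [
        (gene, col)
        for gene, row in matrix.iterrows()
        for col, val in row.items()
        if pd.isna(val)
    ]


def from_matrix(matrix: pd.DataFrame, sample_unit: str = "tech_rep") -> CqDataset:
    """Inverse of :func:`to_matrix` for complete matrices."""
    long = matrix.stack(list(range(matrix.columns.nlevels)), future_stack=True)
    long = long.dropna().reset_index()
    ncols = matrix.columns.nlevels
    names = ["gene", "culture", "passage", "lysate", "tech_rep"][: 1 + ncols]
    long.columns = names + ["cq"]
    if "tech_rep" not in long.columns:
        long["tech_rep"] = 1
    return CqDataset(long[OBS_COLUMNS], sample_unit=sample_unit)


# -- expression matrices (RNA-seq cross-platform comparison) ------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values.

    ``scale`` records whether values are linear (normalized counts, TPM) or
    already log2-transformed.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise SchemaError(f"unknown scale {self.scale!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise CqValidationError("expression values must be finite")
        if self.scale == "linear" and (vals < 0).any():
            raise CqValidationError("linear-scale expression values must be >= 0")

    @classmethod
    def from_csv(cls, path, scale: str = "linear") -> "ExpressionMatrix":
        values = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(values=values, scale=scale)
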