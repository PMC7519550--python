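"""Synthetic Cq panels with the variance structure of a passaging experiment.

The generator emulates a reference-gene study on cultured cell-line
sub-clones: a panel of candidate reference genes measured over successive
passages, with several lysates per passage and technical qPCR replicates per
lysate.  Cq values are built additively on the cycle (log) scale:

    cq(g, p, l, r) = baseline_g + group_shift_{g,culture} + drift_g * (p - 1)
                     + P_p + L_{p,l} + eps_{g,p,l,r}

with P ~ N(0, passage_sd^2) and L ~ N(0, lysate_sd^2) shared across genes
(they model sample-level effects: template amount, RNA quality), and
eps ~ N(0, tech_sd_g^2) per well.  A per-gene linear ``drift`` plants
instability; per-culture ``group_shift`` plants sub-clone divergence.

All randomness is derived from named substreams of a single integer seed, so
the reference panel, each gene of interest, and each stress condition are
reproducible and mutually independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import OBS_COLUMNS, CqDataset, CqValidationError, to_matrix

__all__ = [
    "GeneProfile",
    "SyntheticSpec",
    "GoiSpec",
    "default_profile",
    "generate_reference_panel",
    "generate_goi",
    "generate_stress_panel",
    "sample_effects",
]

#: Baseline mean Cq and per-gene dispersion of the 12 candidate reference
#: genes in the routinely cultured sub-clone used as the default profile
#: (MCF-7 culture A1 descriptives).
DEFAULT_GENE_TABLE: tuple[tuple[str, float, float], ...] = (
    ("ACTB", 15.98, 0.26),
    ("GAPDH", 17.13, 0.17),
    ("RPL13A", 21.03, 0.29),
    ("PGK1", 21.08, 0.22),
    ("HSPCB", 20.40, 0.29),
    ("RNA28S", 8.27, 0.23),
    ("RNA18S", 7.93, 0.27),
    ("PUM1", 23.14, 0.23),
    ("CCSER2", 26.58, 0.21),
    ("HNRNPL", 22.73, 0.35),
    ("PCBP1", 22.13, 0.22),
    ("SF3A1", 23.39, 0.34),
)


def _rng(seed: int, *keys) -> np.random.Generator:
    """Named substream: same (seed, keys) -> same stream, independent otherwise."""
    tokens = [int(seed) & 0x7FFFFFFF]
    tokens += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(tokens))


@dataclass(frozen=True)
class GeneProfile:
    name: str
    baseline_cq: float
    tech_sd: float

    def __post_init__(self):
        if self.tech_sd < 0:
            raise CqValidationError(f"tech_sd < 0 for gene {self.name}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the reference-panel generator (all SDs in cycles)."""

    genes: tuple[GeneProfile, ...]
    n_passages: int = 5
    n_lysates: int = 3
    n_tech: int = 3
    passage_sd: float = 0.15
    lysate_sd: float = 0.10
    drift: Mapping[str, float] = field(default_factory=dict)
    group_shift: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0
    start_passage: int = 1

    def __post_init__(self):
        if self.passage_sd < 0 or self.lysate_sd < 0:
            raise CqValidationError("variance-component SDs must be >= 0")
        if min(self.n_passages, self.n_lysates, self.n_tech) < 1:
            raise CqValidationError("n_passages, n_lysates, n_tech must be >= 1")
        object.__setattr__(
            self,
            "genes",
            tuple(g if isinstance(g, GeneProfile) else GeneProfile(*g) for g in self.genes),
        )

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def with_drift(self, **drift: float) -> "SyntheticSpec":
        merged = {**dict(self.drift), **drift}
        return replace(self, drift=merged)


@dataclass(frozen=True)
class GoiSpec:
    """Planted profile of a simulated gene of interest (GOI).

    ``mode`` controls the passage-level structure: ``stable`` keeps every
    passage mean within +/-0.5 Cq of baseline (amplitude <= 0.5 required),
    ``variable`` forces at least one passage mean more than 0.5 Cq away
    (amplitude > 0.5 required), ``trend`` plants a monotone passage trend
    whose total range equals ``amplitude``.
    """

    name: str = "GOI"
    baseline_cq: float = 24.0
    mode: str = "stable"
    amplitude: float = 0.2
    tech_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise CqValidationError("amplitude must be >= 0")
        if self.mode not in ("stable", "variable", "trend"):
            raise CqValidationError(f"unknown GOI mode {self.mode!r}")
        if self.mode == "stable" and self.amplitude > 0.5:
            raise CqValidationError("stable mode requires amplitude <= 0.5 Cq")
        if self.mode == "variable" and self.amplitude <= 0.5:
            raise CqValidationError("variable mode requires amplitude > 0.5 Cq")


def default_profile(seed: int = 0) -> SyntheticSpec:
    """Default study conditions: 12 genes, 5 passages x 3 lysates x 3 tech reps.

    Baselines and technical dispersions follow the per-gene descriptive
    statistics of a routinely passaged sub-clone; the shared passage
    (0.15 cycles) and lysate (0.10 cycles) components are generator defaults
    chosen so total per-gene SDs land in the observed 0.17-0.61 range.
    """
    return SyntheticSpec(genes=DEFAULT_GENE_TABLE, seed=seed)


def generate_reference_panel(spec: SyntheticSpec, culture: str = "A1") -> CqDataset:
    """Draw one reference-gene panel for a culture under ``spec``.

    Identical (spec, culture) -> bit-for-bit identical dataset.
    """
    passages = np.arange(spec.n_passages)
    p_labels = spec.start_passage + passages
    rng_p = _rng(spec.seed, "passage", culture)
    rng_l = _rng(spec.seed, "lysate", culture)
    P = rng_p.normal(0.0, spec.passage_sd, size=spec.n_passages)
    L = rng_l.normal(0.0, spec.lysate_sd, size=(spec.n_passages, spec.n_lysates))

    rows = []
    for g in spec.genes:
        drift = float(spec.drift.get(g.name, 0.0))
        shift = float(spec.group_shift.get(g.name, {}).get(culture, 0.0))
        rng_e = _rng(spec.seed, "tech", culture, g.name)
        eps = rng_e.normal(
            0.0, g.tech_sd, size=(spec.n_passages, spec.n_lysates, spec.n_tech)
        )
        for ip in passages:
            for il in range(spec.n_lysates):
                for ir in range(spec.n_tech):
                    cq = (
                        g.baseline_cq
                        + shift
                        + drift * ip
                        + P[ip]
                        + L[ip, il]
                        + eps[ip, il, ir]
                    )
                    rows.append(
                        (g.name, culture, int(p_labels[ip]), il + 1, ir + 1, cq)
                    )
    frame = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return CqDataset(frame, sample_unit="tech_rep", provenance=f"synthetic:{culture}")


def sample_effects(panel: CqDataset) -> pd.Series:
    """Per-sample shared Cq effect estimated from a panel.

    For each sample (matrix column) the mean Cq deviation across all panel
    genes, centred to zero mean.  With many genes this recovers the shared
    passage + lysate (+ mean technical) component of the generating model,
    i.e. exactly the sample-level variation that normalization is meant to
    cancel.
    """
    matrix = to_matrix(panel, require_complete=True)
    centred = matrix.sub(matrix.mean(axis=1), axis=0)
    eff = centred.mean(axis=0)
    return eff - eff.mean()


def _passage_offsets(gspec: GoiSpec, n_passages: int) -> np.ndarray:
    rng = _rng(gspec.seed, "goi", gspec.name, gspec.mode)
    a = gspec.amplitude
    if gspec.mode == "stable":
        return rng.uniform(-a, a, size=n_passages)
    if gspec.mode == "variable":
        offsets = rng.uniform(-a, a, size=n_passages)
        hot = int(rng.integers(n_passages))
        offsets[hot] = a * rng.choice([-1.0, 1.0])
        return offsets
    # trend: monotone increase totalling `a` cycles, centred on baseline
    return np.linspace(0.0, a, n_passages) - a / 2.0


def generate_goi(
    gspec: GoiSpec, panel: CqDataset, inherit_sample_effects: bool = True
) -> CqDataset:
    """Simulate one gene of interest on the sample grid of ``panel``.

    The planted per-passage offsets are enforced exactly: within each
    passage the technical noise is re-centred so the intrinsic passage mean
    equals ``baseline + offset``.  With ``inherit_sample_effects`` (default)
    the panel's shared per-sample effect is added on top, so the GOI carries
    the same sample-level variation as the reference genes — the component a
    normalization factor is supposed to remove.  The GOI noise stream
    depends only on ``gspec.seed``, never on the panel's.
    """
    grid = panel.frame[["culture", "passage", "lysate", "tech_rep"]].drop_duplicates()
    grid = grid.sort_values(["culture", "passage", "lysate", "tech_rep"])
    passages = sorted(grid["passage"].unique())
    offsets = dict(zip(passages, _passage_offsets(gspec, len(passages))))

    rng = _rng(gspec.seed, "goi-noise", gspec.name)
    eps = rng.normal(0.0, gspec.tech_sd, size=len(grid))
    out = grid.copy().reset_index(drop=True)
    out["gene"] = gspec.name
    out["cq"] = gspec.baseline_cq + out["passage"].map(offsets).to_numpy() + eps
    # pin the intrinsic passage means to the planted offsets exactly
    out["cq"] -= out.groupby("passage")["cq"].transform("mean") - (
        gspec.baseline_cq + out["passage"].map(offsets)
    )
    if inherit_sample_effects:
        eff = sample_effects(panel)
        levels = list(eff.index.names)
        key = pd.MultiIndex.from_frame(out[levels])
        out["cq"] = out["cq"].to_numpy() + eff.loc[key].to_numpy()
    return CqDataset(
        out[OBS_COLUMNS],
        sample_unit=panel.sample_unit,
        provenance=f"synthetic-goi:{gspec.name}",
    )


def generate_stress_panel(
    spec: SyntheticSpec,
    shifts: Mapping[str, float],
    culture: str = "B5",
) -> CqDataset:
    """Panel for a stress condition: per-gene constant Cq offsets on a fresh draw.

    A shift of -1 Cq doubles the linear-scale quantity (2x fold change up);
    +1 Cq halves it.  Genes absent from ``shifts`` are unshifted.
    """
    unknown = sorted(set(shifts) - set(spec.gene_names))
    if unknown:
        raise CqValidationError(f"shift for unknown gene(s): {', '.join(unknown)}")
    panel = generate_reference_panel(spec, culture=culture)
    frame = panel.frame.copy()
    frame["cq"] = frame["cq"] + frame["gene"].map(lambda g: shifts.get(g, 0.0))
    return CqDataset(
        frame,
        sample_unit="tech_rep",
        provenance=f"synthetic-stress:{culture}",
        max_cycles=panel.max_cycles,
    )
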