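"""End-to-end orchestration: configuration, full pipeline run, report rendering.

A :class:`RunConfig` (usually loaded from YAML) names the per-culture Cq
tables (or asks for synthetic panels), the algorithms to run, the candidate
reference sets to screen, and the statistical defaults.  The bundle returned
by :func:`run_full_analysis` is a plain dict of DataFrames/objects, also
written to disk as CSVs plus a machine-readable JSON summary; identical
config + seed produces byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import simulate as _sim
from .consensus import integrated_selection
from .data import CqDataset, QstabError, merge_datasets, read_cq_table
from .model import ALL_ALGORITHMS, ReferenceGeneStability
from .stability import passage_fold_change
from .validation import screen_reference_sets, stress_fold_change

__all__ = ["RunConfig", "run_full_analysis", "render_report"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``cultures`` maps culture label -> path of a long-format Cq CSV; leave
    empty and set ``simulate=True`` to analyse synthetic panels instead.
    Every stability-affecting default mirrors the package documentation and
    is echoed into the run log.
    """

    cultures: Mapping[str, str] = field(default_factory=dict)
    simulate: bool = False
    simulate_cultures: Sequence[str] = ("A1", "A2")
    algorithms: Sequence[str] = ALL_ALGORITHMS
    alpha: float = 0.05
    cutoff: float = 0.15
    top_k: int = 3
    base: float = 2.0
    bestkeeper_dispersion: str = "mad"
    calibrators: Mapping[str, int] = field(default_factory=dict)
    candidate_sets: Sequence[Sequence[str]] = ()
    goi_tables: Mapping[str, str] = field(default_factory=dict)
    stress_tables: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "qstab_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise QstabError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


def _load_cultures(config: RunConfig) -> dict[str, CqDataset]:
    datasets: dict[str, CqDataset] = {}
    if config.simulate:
        spec = _sim.default_profile(seed=config.seed)
        for culture in config.simulate_cultures:
            datasets[culture] = _sim.generate_reference_panel(spec, culture=culture)
    for culture, path in config.cultures.items():
        datasets[culture] = read_cq_table(path, layout="long", provenance=culture)
    if not datasets:
        raise QstabError("no input datasets: set 'cultures' paths or simulate: true")
    return datasets


def run_full_analysis(config: RunConfig) -> dict:
    """Run stability + consensus per culture and combined, plus optional screens."""
    log: list[str] = [
        f"defaults in effect: alpha={config.alpha} cutoff={config.cutoff} "
        f"top_k={config.top_k} base={config.base} "
        f"bestkeeper_dispersion={config.bestkeeper_dispersion} "
        f"sample_unit=lysate_mean seed={config.seed}",
    ]
    datasets = _load_cultures(config)
    bundle: dict = {"log": log, "per_culture": {}, "config": config}

    results = {}
    tables_by_dataset = {}
    passage_pvalues = {}
    for culture, ds in sorted(datasets.items()):
        res = ReferenceGeneStability(ds).fit(
            algorithms=tuple(config.algorithms),
            bestkeeper_dispersion=config.bestkeeper_dispersion,
            genorm_cutoff=config.cutoff,
            base=config.base,
        )
        results[culture] = res
        tables_by_dataset[culture] = list(res.tables.values()) + [
            res.consensus.as_table()
        ]
        calibrator = config.calibrators.get(culture, min(ds.passages))
        fc = passage_fold_change(
            res.model.data, calibrator=calibrator, alpha=config.alpha, base=config.base
        )
        passage_pvalues[culture] = fc.tests["p_omnibus"].astype(float)
        bundle["per_culture"][culture] = {
            "stability": res.to_frame(),
            "consensus": res.consensus.frame,
            "v_series": res.v_series,
            "optimal_count": res.optimal_count,
            "fold_change_tests": fc.tests,
            "summary": res.summary(),
        }
        log.append(f"{culture}: calibrator passage {calibrator}")

    if len(datasets) > 1:
        labels = sorted(datasets)
        combined = datasets[labels[0]]
        for lab in labels[1:]:
            combined = merge_datasets(combined, datasets[lab])
        res = ReferenceGeneStability(combined, groups="culture").fit(
            algorithms=tuple(config.algorithms),
            bestkeeper_dispersion=config.bestkeeper_dispersion,
            genorm_cutoff=config.cutoff,
            base=config.base,
        )
        results["combined"] = res
        tables_by_dataset["combined"] = list(res.tables.values()) + [
            res.consensus.as_table()
        ]
        bundle["combined"] = {
            "stability": res.to_frame(),
            "consensus": res.consensus.frame,
            "v_series": res.v_series,
            "optimal_count": res.optimal_count,
            "summary": res.summary(),
        }
        log.append("combined dataset analysed with culture groups (NormFinder)")

    selection = integrated_selection(
        tables_by_dataset,
        passage_pvalues=passage_pvalues or None,
        top_k=config.top_k,
        alpha=config.alpha,
    )
    bundle["selection"] = selection

    if config.goi_tables and config.candidate_sets:
        first_culture = sorted(datasets)[0]
        panel = ReferenceGeneStability(datasets[first_culture]).data
        gois = {
            name: ReferenceGeneStability(read_cq_table(path, provenance=name)).data
            for name, path in config.goi_tables.items()
        }
        calibrator = config.calibrators.get(
            first_culture, min(datasets[first_culture].passages)
        )
        screen = screen_reference_sets(
            panel,
            gois,
            config.candidate_sets,
            calibrator=calibrator,
            alpha=config.alpha,
            base=config.base,
        )
        bundle["screen"] = screen
        log.append(
            f"screened {len(gois)} GOI(s) x {len(config.candidate_sets)} set(s)"
        )

    if config.stress_tables:
        control_label = sorted(datasets)[0]
        control = datasets[control_label]
        stress_reports = {}
        for label, path in config.stress_tables.items():
            stress = read_cq_table(path, provenance=label)
            stress_reports[label] = stress_fold_change(control, stress, base=config.base)
        bundle["stress"] = stress_reports
        log.append(f"stress conditions: {', '.join(sorted(config.stress_tables))}")

    _write_bundle(bundle, config)
    return bundle


def _json_default(obj):
    if isinstance(obj, (pd.Series,)):
        return {str(k): v for k, v in obj.items()}
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"log": bundle["log"], "cultures": {}, "seed": config.seed}
    sections = dict(bundle["per_culture"])
    if "combined" in bundle:
        sections["combined"] = bundle["combined"]
    for label, section in sections.items():
        section["stability"].to_csv(out / f"stability_{label}.csv", index=False)
        section["consensus"].to_csv(out / f"consensus_{label}.csv")
        entry = {
            "consensus_rank": section["consensus"]["rank"].to_dict(),
            "geomean": {k: round(v, 6) for k, v in section["consensus"]["geomean"].items()},
        }
        if section.get("v_series") is not None:
            entry["v_series"] = {
                str(n): round(v, 8) for n, v in section["v_series"].items()
            }
            entry["optimal_gene_count"] = section["optimal_count"].n
        summary["cultures"][label] = entry
    sel = bundle["selection"]
    summary["selection"] = {
        "pair": list(sel.pair),
        "experimental": sel.experimental,
        "triplet": list(sel.triplet),
        "audit": sel.audit,
    }
    if "screen" in bundle:
        bundle["screen"].verdicts.to_csv(out / "verdicts.csv")
        summary["verdicts"] = {
            goi: row.to_dict() for goi, row in bundle["screen"].verdicts.iterrows()
        }
    if "stress" in bundle:
        for label, frame in bundle["stress"].items():
            frame.to_csv(out / f"stress_{label}.csv")
        summary["stress"] = {
            label: {g: bool(r["flag_2x"]) for g, r in frame.iterrows()}
            for label, frame in bundle["stress"].items()
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    with open(out / "report.md", "w") as fh:
        fh.write(render_report(bundle))


def render_report(bundle: dict) -> str:
    """Markdown report mirroring the analysis tables and the verdict grid."""
    lines = ["# Reference-gene stability report", ""]
    lines += [f"- {entry}" for entry in bundle["log"]]
    sections = dict(bundle["per_culture"])
    if "combined" in bundle:
        sections["combined"] = bundle["combined"]
    for label, section in sections.items():
        lines += ["", f"## Dataset {label}", "", "```", section["summary"], "```"]
    sel = bundle["selection"]
    lines += [
        "",
        "## Integrated selection",
        "",
        f"recommended pair: **{' + '.join(sel.pair)}**, experimental candidate: "
        f"**{sel.experimental}**, triplet: **{'-'.join(sel.triplet)}**",
        "",
    ]
    lines += [f"- {entry}" for entry in sel.audit]
    lines += ["", "## Normalization screening", ""]
    if "screen" in bundle and not bundle["screen"].verdicts.empty:
        verdicts = bundle["screen"].verdicts
        lines.append("| GOI | " + " | ".join(verdicts.columns) + " |")
        lines.append("|" + "---|" * (len(verdicts.columns) + 1))
        for goi, row in verdicts.iterrows():
            cells = ["OK" if v == "successful" else "FAIL" for v in row]
            lines.append(f"| {goi} | " + " | ".join(cells) + " |")
    else:
        lines.append("no candidate sets screened")
    if "stress" in bundle:
        lines += ["", "## Nutrient-stress fold changes", ""]
        for label, frame in bundle["stress"].items():
            flagged = sorted(frame.index[frame["flag_2x"].astype(bool)])
            lines.append(
                f"- {label}: flagged (>=2x) genes: "
                + (", ".join(flagged) if flagged else "none")
            )
    return "\n".join(lines) + "\n"
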