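"""End-to-end pipeline: filter cascade → stats → screening → selection → fingerprints.

A :class:`PipelineConfig` fully determines a run (inputs, thresholds,
strategy, seed); the :class:`RunReport` it produces embeds the config and
every stage's counts, so the cascade narrative is reproducible from the
report alone.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import fst as compute_fst
from .diversity import matrix_summary, panel_summary
from .fingerprint import build_fingerprints, profiles_table, render_heatmap_matrix, write_heatmap_grid, write_profiles
from .filtering import read_candidate_table, run_filter_cascade
from .genotypes import GenotypeMatrix, read_genotypes, read_group_map
from .selection import CoreSet, ScreeningCriteria, exhaustive_min_set, greedy_min_set, screen_markers
from .simulate import SimulationConfig, simulate_genotypes

logger = logging.getLogger("kaspfp")


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    genotypes: str | None = None       # path to VCF or genotype table
    candidates: str | None = None      # path to candidate table (with flanks)
    reference: str | None = None       # FASTA path (needed with candidates)
    groups: str | None = None          # accession→group map path
    qc: str | None = None              # per-locus stability annotations path
    simulate: dict | None = None       # SimulationConfig kwargs (alternative input)
    filter_params: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)   # ScreeningCriteria kwargs
    strategy: str = "greedy"
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("greedy", "exhaustive"):
            raise ValueError("strategy must be 'greedy' or 'exhaustive'")
        if self.genotypes is None and self.simulate is None:
            raise ValueError("either a genotypes path or a simulate block is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class RunReport:
    """Everything a run computed, plus the exact config that produced it."""

    config: dict
    filter_report: dict | None
    panel: dict | None
    core: dict | None
    differentiation: dict | None
    flags: list[str]
    version: str
    started: str
    finished: str

    def to_dict(self, include_timestamps: bool = True) -> dict:
        out = {
            "config": self.config,
            "filter_report": self.filter_report,
            "panel": self.panel,
            "core": self.core,
            "differentiation": self.differentiation,
            "flags": self.flags,
            "version": self.version,
        }
        if include_timestamps:
            out["started"] = self.started
            out["finished"] = self.finished
        return out

    def to_json(self, path: str | Path | None = None, include_timestamps: bool = True) -> str:
        text = json.dumps(self.to_dict(include_timestamps), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _load_matrix(config: PipelineConfig) -> GenotypeMatrix:
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        # YAML has no tuple literal: a 2-element spectrum list is a range
        # only when flagged as such
        is_range = sim_kwargs.pop("spectrum_is_range", False)
        spec = sim_kwargs.get("allele_freq_spectrum")
        if is_range and isinstance(spec, list) and len(spec) == 2:
            sim_kwargs["allele_freq_spectrum"] = tuple(spec)
        matrix, _ = simulate_genotypes(SimulationConfig(**sim_kwargs))
        return matrix
    return read_genotypes(config.genotypes)


def _read_qc(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
    truthy = {"1", "true", "pass", "stable", "yes"}
    return {row[0]: str(row[1]).strip().lower() in truthy for row in df.itertuples(index=False)}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and return the structured run report.

    Stages: candidate filter cascade (when a candidate table + reference
    are configured) → per-locus statistics → stepwise screening →
    core-set selection → fingerprint construction → group
    differentiation (when a group map is configured).  Deterministic for
    a fixed config + seed.
    """
    started = _dt.datetime.now().isoformat(timespec="seconds")
    flags: list[str] = []
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    matrix = _load_matrix(config)
    logger.info("stage=load accessions=%d loci=%d", matrix.n_accessions, matrix.n_loci)

    filter_report_dict = None
    if config.candidates and config.reference:
        candidates = read_candidate_table(config.candidates)
        retained, filter_report = run_filter_cascade(
            candidates, config.reference, **config.filter_params
        )
        filter_report_dict = filter_report.to_dict()
        for stage in filter_report.stages:
            logger.info("stage=%s input=%d retained=%d", stage.name, stage.n_in, stage.n_retained)
        if outdir:
            filter_report.to_json(outdir / "filter_report.json")
        retained_ids = {c.id for c in retained}
        overlap = [l for l in matrix.loci if l in retained_ids]
        if overlap:
            matrix = matrix.subset_loci(overlap)

    stats = matrix_summary(matrix)
    panel = panel_summary(stats)
    logger.info("stage=stats loci=%d mean_he=%.3f", panel["n_loci"], panel["mean_he"])
    if outdir:
        pd.DataFrame([s.rounded() for s in stats]).to_csv(outdir / "locus_stats.tsv", sep="\t", index=False)

    qc = _read_qc(config.qc) if config.qc else None
    criteria = ScreeningCriteria(**config.screening)
    selectable = screen_markers(stats, qc, criteria)
    logger.info("stage=screening input=%d retained=%d", len(stats), len(selectable))

    core_dict = None
    core: CoreSet | None = None
    profiles = None
    if not selectable:
        flags.append("no_selectable_markers")
    else:
        pic = {s.locus: s.pic for s in stats}
        select = greedy_min_set if config.strategy == "greedy" else exhaustive_min_set
        core = select(matrix, selectable, pic)
        core_dict = core.to_dict()
        logger.info(
            "stage=selection core=%d distinguished=%d/%d unresolved_groups=%d",
            len(core.loci), core.n_distinguished_accessions,
            core.n_accessions, len(core.unresolved_groups),
        )
        assert core.n_distinguished_accessions + sum(
            len(g) for g in core.unresolved_groups
        ) == matrix.n_accessions
        if core.loci:
            profiles = build_fingerprints(matrix, core.loci)
        if outdir:
            core.to_json(outdir / "core_set.json")
            if profiles:
                write_profiles(profiles, outdir / "fingerprints.json")
                profiles_table(profiles).to_csv(outdir / "fingerprints.tsv", sep="\t", index=False)
                write_heatmap_grid(render_heatmap_matrix(profiles), outdir / "heatmap_grid.tsv")

    differentiation = None
    if config.groups:
        groups = read_group_map(config.groups)
        diff = compute_fst(matrix, groups)
        differentiation = {
            "groups": list(diff.groups),
            "fst": diff.fst,
            "nm": diff.nm,
            "nm_label": diff.nm_label,
            "n_loci_used": diff.n_loci_used,
        }
        logger.info("stage=differentiation fst=%.4f nm=%s", diff.fst, diff.nm_label)

    report = RunReport(
        config=asdict(config),
        filter_report=filter_report_dict,
        panel={**panel, "missing_rate_range": list(panel["missing_rate_range"])},
        core=core_dict,
        differentiation=differentiation,
        flags=flags,
        version=__version__,
        started=started,
        finished=_dt.datetime.now().isoformat(timespec="seconds"),
    )
    if outdir:
        report.to_json(outdir / "run_report.json")
    return report


def summarize_sequencing_manifest(
    yields_gb: Sequence[float],
    mapping_rates: Sequence[float] | None = None,
) -> dict:
    """Totals, means and ranges of a per-sample sequencing manifest."""
    if len(yields_gb) == 0:
        raise ValueError("empty manifest")
    y = np.asarray(yields_gb, dtype=float)
    out = {
        "n_samples": int(y.size),
        "total_gb": float(y.sum()),
        "mean_gb": float(y.mean()),
        "yield_range_gb": (float(y.min()), float(y.max())),
    }
    if mapping_rates is not None:
        if len(mapping_rates) != len(yields_gb):
            raise ValueError("mapping_rates length must match yields")
        m = np.asarray(mapping_rates, dtype=float)
        out["mean_mapping_rate"] = float(m.mean())
        out["mapping_rate_range"] = (float(m.min()), float(m.max()))
    return out


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """Share of ``part`` in ``whole`` as a percentage, rounded."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return round(100.0 * part / whole, ndigits)
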