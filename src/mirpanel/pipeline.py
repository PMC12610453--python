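"""End-to-end orchestration: simulate or ingest, DE per contrast, power,
targets and concordance, all under one config with a content-hashed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from mirpanel import panel_io
from mirpanel.concordance import concordance_report, read_external_de
from mirpanel.diffexpr import Contrast, normalize_delta_ct, run_contrast
from mirpanel.panel_io import meta_to_frame, write_table
from mirpanel.power_mdes import mdes_report
from mirpanel.synthetic_data import (
    SimConfig,
    EffectSpec,
    make_external_de_table,
    make_interaction_snapshot,
    make_layout,
    make_term_map,
    simulate_panel,
)
from mirpanel.targets_net import (
    convergence_counts,
    hypergeom_enrich,
    load_interactions,
    target_universe,
)

log = logging.getLogger("mirpanel.pipeline")

CONTRAST_CANCER = "cancer_vs_healthy"
CONTRAST_POLE = "pole_vs_wildtype"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run: inputs (synthetic or files), thresholds, outputs."""

    mode: str = "synthetic"  # or "files"
    sim: SimConfig = field(default_factory=SimConfig)
    ct_path: str | None = None
    layout_path: str | None = None
    meta_path: str | None = None
    interactions_path: str | None = None
    term_map_path: str | None = None
    external_de_path: str | None = None
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    base_alpha: float = 0.05
    power_levels: tuple[float, ...] = (0.80, 0.90)
    pi0_method: str = "fixed"
    functional_only: bool = False
    top_k: int = 20
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lfc_threshold <= 0 or not 0 < self.fdr_threshold < 1:
            raise ValueError("thresholds must be positive (fdr in (0,1))")
        if self.mode == "files":
            for name in ("ct_path", "layout_path", "meta_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"files mode: {name} missing or does not exist: {p}")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run config; nested ``sim`` maps to SimConfig."""
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", None)
    if sim_raw is not None:
        effects = tuple(
            EffectSpec(**e) for e in sim_raw.pop("effects", [])
        )
        if "baseline_dct_range" in sim_raw:
            sim_raw["baseline_dct_range"] = tuple(sim_raw["baseline_dct_range"])
        raw["sim"] = SimConfig(effects=effects, **sim_raw)
    if "power_levels" in raw:
        raw["power_levels"] = tuple(raw["power_levels"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage and return the artifact manifest.

    Both contrasts are run when possible; the POLE contrast uses cancer
    samples only. Optional stages (targets, concordance) are skipped with a
    warning when their snapshot inputs are absent in files mode. A stage
    failure aborts with the stage name; already-written artifacts stay on
    disk beside a ``FAILED`` marker.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.time()

    def _stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        _stage("ingest")
        if config.mode == "synthetic":
            sim = config.sim
            layout = make_layout(n_targets=sim.n_target_assays)
            ct_table, meta = simulate_panel(sim, layout)
            artifacts["ct_table"] = write_table(
                ct_table.to_frame().reset_index(names="sample_id"), out / "ct_table.tsv"
            )
            artifacts["sample_meta"] = write_table(
                meta_to_frame(meta), out / "sample_meta.tsv"
            )
        else:
            layout = panel_io.read_layout(config.layout_path)
            ct_table = panel_io.read_ct_table(config.ct_path, layout)
            meta = panel_io.read_sample_metadata(config.meta_path)
    except Exception as exc:  # noqa: BLE001
        (out / "FAILED").write_text("ingest\n")
        raise PipelineStageError("ingest", exc)

    try:
        _stage("normalize")
        dct = normalize_delta_ct(ct_table)
    except Exception as exc:  # noqa: BLE001
        (out / "FAILED").write_text("normalize\n")
        raise PipelineStageError("normalize", exc)

    try:
        _stage("diffexpr")
        cancer = panel_io.group_ids(meta, "cancer")
        healthy = panel_io.group_ids(meta, "healthy")
        contrasts = [Contrast(CONTRAST_CANCER, cancer, healthy)]
        mutant = panel_io.pole_ids(meta, "mutant")
        wildtype = panel_io.pole_ids(meta, "wildtype")
        if len(mutant) >= 2 and len(wildtype) >= 2:
            contrasts.append(Contrast(CONTRAST_POLE, mutant, wildtype))
        else:
            log.warning("POLE contrast skipped: fewer than 2 samples per arm")
        de_tables = {}
        for contrast in contrasts:
            de = run_contrast(
                dct, contrast, config.lfc_threshold, config.fdr_threshold
            )
            de_tables[contrast.name] = de
            artifacts[f"de_{contrast.name}"] = write_table(
                de, out / f"de_{contrast.name}.tsv"
            )
            log.info(
                "contrast %s: %d tested, %d significant",
                contrast.name, int(de["tested"].sum()), int(de["significant"].sum()),
            )
    except Exception as exc:  # noqa: BLE001
        (out / "FAILED").write_text("diffexpr\n")
        raise PipelineStageError("diffexpr", exc)

    try:
        _stage("power")
        mdes, curves = mdes_report(
            dct,
            de_tables,
            contrasts,
            base_alpha=config.base_alpha,
            power_levels=config.power_levels,
            pi0_method=config.pi0_method,
        )
        artifacts["mdes"] = write_table(mdes, out / "mdes.tsv")
        artifacts["power_curves"] = write_table(curves, out / "power_curves.tsv")
    except Exception as exc:  # noqa: BLE001
        (out / "FAILED").write_text("power\n")
        raise PipelineStageError("power", exc)

    # Targets: per direction of the primary contrast, plus POLE-down when run.
    interactions = None
    if config.mode == "synthetic":
        interactions = load_interactions(
            make_interaction_snapshot(
                list(layout.target_assays), seed=config.seed + 1
            ),
            functional_only=config.functional_only,
        )
    elif config.interactions_path and Path(config.interactions_path).exists():
        interactions = load_interactions(
            config.interactions_path, functional_only=config.functional_only
        )
    else:
        log.warning("targets stage skipped: no interaction snapshot configured")

    if interactions is not None:
        try:
            _stage("targets")
            universe = target_universe(interactions)
            term_map = None
            if config.mode == "synthetic":
                term_map = make_term_map(sorted(universe), seed=config.seed + 2)
            elif config.term_map_path and Path(config.term_map_path).exists():
                term_map = pd.read_csv(config.term_map_path, sep="\t", dtype=str)
            de = de_tables[CONTRAST_CANCER]
            sig = de[de["significant"]]
            for direction, subset in (
                ("up", sig[sig["log2_fold_reg"] > 0]),
                ("down", sig[sig["log2_fold_reg"] < 0]),
            ):
                ranking = convergence_counts(
                    interactions, set(subset["mirna"]), direction
                )
                artifacts[f"convergence_{direction}"] = write_table(
                    ranking.top(config.top_k), out / f"convergence_{direction}.tsv"
                )
                if term_map is not None and universe:
                    genes = set(
                        interactions[interactions["mirna"].isin(set(subset["mirna"]))][
                            "gene_symbol"
                        ]
                    )
                    enrich = hypergeom_enrich(genes, term_map, universe)
                    artifacts[f"enrichment_{direction}"] = write_table(
                        enrich.head(config.top_k), out / f"enrichment_{direction}.tsv"
                    )
        except Exception as exc:  # noqa: BLE001
            (out / "FAILED").write_text("targets\n")
            raise PipelineStageError("targets", exc)

    external = None
    if config.mode == "synthetic":
        external = make_external_de_table(
            de_tables[CONTRAST_CANCER][de_tables[CONTRAST_CANCER]["tested"]],
            seed=config.seed + 3,
        )
    elif config.external_de_path and Path(config.external_de_path).exists():
        external = read_external_de(config.external_de_path)
    else:
        log.warning("concordance stage skipped: no external DE table configured")

    if external is not None and not external.empty:
        try:
            _stage("concordance")
            report = concordance_report(
                de_tables[CONTRAST_CANCER][de_tables[CONTRAST_CANCER]["tested"]],
                external,
                config.lfc_threshold,
                config.fdr_threshold,
            )
            artifacts["concordance_pairs"] = write_table(
                report.pairs, out / "concordance_pairs.tsv"
            )
            artifacts["concordance_summary"] = write_table(
                report.summary_frame(), out / "concordance_summary.tsv"
            )
        except Exception as exc:  # noqa: BLE001
            (out / "FAILED").write_text("concordance\n")
            raise PipelineStageError("concordance", exc)

    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "artifacts": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d artifacts in %.1fs", len(artifacts), time.time() - t0)
    return manifest
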