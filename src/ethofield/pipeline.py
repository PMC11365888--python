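"""End-to-end orchestration: simulate/load -> correct -> metrics -> zones
-> transitions -> discriminate, with a manifest for reproducibility.

All outputs are plain CSV/JSON.  The manifest records the resolved
configuration, the seed and the SHA-256 of every written file; a run with
a fixed seed is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import DEFAULT_RULES, CorrectionRule, apply_corrections
from .io import read_cohort, write_cohort
from .metrics import cohort_metrics
from .ontology import GENOTYPES, SEXES, Cohort
from .simulate import CohortDesign, default_models, simulate_cohort
from .transitions import group_half_similarity, group_transition_graph
from .zoning import (
    find_boundary,
    growth_curve,
    standard_data_driven_division,
    traditional_division,
    zone_metrics,
)
from .discrimination import FEATURE_SETS, build_features, evaluate

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("correct", "metrics", "zones", "transitions", "discriminate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    cohort_dir: str | None = None  # read cohort from here; None -> simulate
    simulate: bool = True
    group_sizes: dict | None = None  # (genotype, sex) -> n; None -> study sizes
    duration_s: float = 3600.0
    frame_rate: float = 30.0
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    correction_rules: tuple[CorrectionRule, ...] = DEFAULT_RULES
    zoning_method: str = "data_driven"  # or "traditional"
    zoning_step_mm: float = 1.0
    prominence_fraction: float = 0.10
    standard_a_mm: float = 135.0
    transition_threshold: float = 0.05
    transition_pool: str = "animals"
    cv: str = "loo"
    write_cohort_files: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not self.simulate:
            if self.cohort_dir is None:
                raise ValueError("cohort_dir required when simulate=False")
            d = Path(self.cohort_dir)
            if not (d / "subjects.csv").exists():
                raise ValueError(f"cohort_dir {d} has no subjects.csv")

    def to_jsonable(self) -> dict:
        cfg = asdict(self)
        cfg["stages"] = list(self.stages)
        cfg["correction_rules"] = [asdict(r) for r in self.correction_rules]
        if self.group_sizes is not None:
            cfg["group_sizes"] = {f"{g}:{s}": n for (g, s), n in self.group_sizes.items()}
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # ---- acquire cohort -------------------------------------------------
    if config.simulate:
        sizes = config.group_sizes
        design = CohortDesign(
            **({"group_sizes": dict(sizes)} if sizes else {}),
            duration_s=config.duration_s,
            frame_rate=config.frame_rate,
            seed=config.seed,
        )
        cohort = simulate_cohort(design, default_models())
        logger.info("simulated cohort of %d animals", len(cohort))
        if config.write_cohort_files:
            write_cohort(cohort, out / "cohort")
    else:
        cohort = read_cohort(config.cohort_dir, config.frame_rate)
        logger.info("loaded cohort of %d animals from %s", len(cohort), config.cohort_dir)

    # ---- label correction ----------------------------------------------
    if "correct" in config.stages and config.correction_rules:
        corrected = {}
        for s in cohort.subjects:
            corrected[s.animal_id] = apply_corrections(
                cohort.ethograms[s.animal_id],
                cohort.trajectories[s.animal_id],
                config.correction_rules,
            )
        cohort = Cohort(cohort.subjects, corrected, cohort.trajectories)

    # ---- zoning ---------------------------------------------------------
    if config.zoning_method == "traditional":
        division = traditional_division()
    else:
        division = standard_data_driven_division(config.standard_a_mm)

    # ---- metrics --------------------------------------------------------
    if "metrics" in config.stages:
        for unit in ("movement", "cluster"):
            df = cohort_metrics(cohort, unit=unit)
            p = out / f"metrics_{unit}.csv"
            df.to_csv(p, index=False, float_format="%.6f")
            written.append(p)
        if config.duration_s >= 600.0:
            seg = cohort_metrics(cohort, unit="cluster", bin_s=600.0)
            p = out / "metrics_cluster_segments.csv"
            seg.to_csv(p, index=False, float_format="%.6f")
            written.append(p)
        else:
            logger.info("session shorter than one 10-min segment; skipping segments table")

    if "zones" in config.stages:
        # per-genotype pooled occupancy boundary (data-driven diagnostics)
        boundaries = {}
        for g in GENOTYPES:
            subs = cohort.select(genotype=g)
            if not subs:
                continue
            pts = np.concatenate(
                [cohort.trajectories[s.animal_id].points for s in subs], axis=0
            )
            from .ontology import Trajectory

            pooled = Trajectory("pooled", config.frame_rate, pts)
            curve = growth_curve(pooled, config.zoning_step_mm)
            try:
                boundaries[g] = find_boundary(curve, config.prominence_fraction)
            except ValueError as exc:
                logger.warning("no boundary for genotype %s: %s", g, exc)
                boundaries[g] = None
        p = out / "boundaries.json"
        _write_json({"a_boundary_mm": boundaries, "method": "growth_curve"}, p)
        written.append(p)

        rows = []
        for s in cohort.subjects:
            zm = zone_metrics(
                cohort.ethograms[s.animal_id],
                cohort.trajectories[s.animal_id],
                division,
            )
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "genotype": s.genotype,
                    "sex": s.sex,
                    "a_boundary_mm": division.a_boundary_mm,
                    "frac_center": zm.fractions["center"],
                    "frac_perimeter": zm.fractions["perimeter"],
                    "per_area_center": zm.per_unit_area["center"],
                    "per_area_perimeter": zm.per_unit_area["perimeter"],
                }
            )
        p = out / "zones.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.8f")
        written.append(p)

    if "transitions" in config.stages:
        half = int(round(config.duration_s / 2 * config.frame_rate))
        n_frames = int(round(config.duration_s * config.frame_rate))
        windows = {"first_half": (0, half), "second_half": (half, n_frames)}
        tdir = out / "transitions"
        tdir.mkdir(exist_ok=True)
        sim_rows = []
        for g in GENOTYPES:
            for sx in SEXES:
                if not cohort.select(genotype=g, sex=sx):
                    continue
                for wname, frange in windows.items():
                    graph = group_transition_graph(
                        cohort,
                        g,
                        sx,
                        threshold=config.transition_threshold,
                        pool=config.transition_pool,
                        frame_range=frange,
                    )
                    edges = pd.DataFrame(
                        graph.pruned_edges, columns=["source", "target", "probability"]
                    )
                    p = tdir / f"{g}_{sx}_{wname}_edges.csv"
                    edges.to_csv(p, index=False, float_format="%.6f")
                    written.append(p)
                    from .transitions import betweenness

                    nodes = pd.DataFrame(
                        {
                            "state": list(graph.states),
                            "state_prob": graph.state_prob.to_numpy(),
                            "self_loop": graph.self_loop.to_numpy(),
                            "betweenness": betweenness(graph).to_numpy(),
                        }
                    )
                    p = tdir / f"{g}_{sx}_{wname}_nodes.csv"
                    nodes.to_csv(p, index=False, float_format="%.6f")
                    written.append(p)
                sim_rows.append(
                    {
                        "genotype": g,
                        "sex": sx,
                        "half_similarity": group_half_similarity(
                            cohort, g, sx, split_s=config.duration_s / 2
                        ),
                    }
                )
        p = out / "half_similarity.csv"
        pd.DataFrame(sim_rows).to_csv(p, index=False, float_format="%.6f")
        written.append(p)

    if "discriminate" in config.stages:
        results = {}
        for sx in SEXES:
            if not cohort.select(sex=sx):
                continue
            results[sx] = {}
            for fset in FEATURE_SETS:
                table = build_features(cohort, fset, traditional_division(), sex=sx)
                res = evaluate(table, cv=config.cv, seed=config.seed)
                results[sx][fset] = {
                    "discrimination": res.discrimination,
                    "accuracy": res.accuracy,
                    "confusion": res.confusion.round(6).to_dict(),
                }
        p = out / "discrimination.json"
        _write_json(results, p)
        written.append(p)

    # ---- manifest -------------------------------------------------------
    cfg = config.to_jsonable()
    # hash the scientific configuration only, not input/output locations
    cfg_hashable = {k: v for k, v in cfg.items() if k not in ("out_dir", "cohort_dir")}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_hashable, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
        "n_subjects": len(cohort),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from YAML with keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    raw.update(overrides)
    if "correction_rules" in raw and raw["correction_rules"] is not None:
        raw["correction_rules"] = tuple(
            CorrectionRule(
                source=r["source"],
                max_speed_mm_s=float(r["max_speed_mm_s"]),
                min_duration_s=float(r["min_duration_s"]),
                target=r["target"],
            )
            for r in raw["correction_rules"]
        )
    if "stages" in raw and raw["stages"] is not None:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)
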