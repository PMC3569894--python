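"""End-to-end orchestration: simulate? → cluster → screen → score → search
→ enrich → report, with a run manifest.

Machine outputs are JSON/TSV only; logs go to stderr. Every machine output
embeds ``manifest_digest``, a SHA-256 over the configuration, seed and
input-table digests, so reruns with identical inputs are byte-identical
(wall-clock timestamps live only in manifest.json).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

from . import __version__
from .datamodel import ScoringWeights, TargetProfile, merge_profiles
from .enrichment import enrich_candidates, pathway_memberships_from_universe
from .errors import CombirankError, SchemaError
from .io import dump_json, read_tables, write_tables
from .report import render_report
from .scoring import score_candidate
from .screen import ScreenConfig, member_profiles, screen_by_ki
from .search import SearchConfig, run_search, tiers_as_dict
from .similarity import SimilarityConfig, form_clusters, merge_clusters
from .synthetic import Dataset, SimulationConfig, gen_dataset

logger = logging.getLogger("combirank")


class PipelineStageError(CombirankError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _filter_kwargs(cls, mapping: Mapping[str, Any]) -> Dict[str, Any]:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise SchemaError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    out = dict(mapping)
    for key in ("groups_per_compound", "targets_per_compound", "pathway_size_range",
                "docking_per_compound", "ki_log10_range", "confidence_probs",
                "fixed_thresholds"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    for key in ("forward_protein_set", "confidence_filter"):
        if key in out and isinstance(out[key], list):
            out[key] = frozenset(out[key])
    return out


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_dataset_from_config(config: Mapping[str, Any], seed: Optional[int]) -> Dataset:
    """Either simulate a dataset or read the four input tables."""
    if "simulate" in config:
        sim_kwargs = _filter_kwargs(SimulationConfig, config.get("simulate") or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        return gen_dataset(SimulationConfig(**sim_kwargs))
    inputs = config.get("inputs")
    if not inputs:
        raise SchemaError("config needs either a 'simulate' or an 'inputs' section")
    for key in ("compounds", "targets", "predictions", "docking"):
        if key not in inputs:
            raise SchemaError(f"inputs section missing {key!r} path")
        if not Path(inputs[key]).exists():
            raise SchemaError(f"input file not found: {inputs[key]}")
    compounds, targets, predictions, docking = read_tables(
        inputs["compounds"], inputs["targets"], inputs["predictions"], inputs["docking"]
    )
    forward: frozenset[str] = frozenset()
    if "forward_proteins" in inputs:
        fpath = Path(inputs["forward_proteins"])
        if not fpath.exists():
            raise SchemaError(f"input file not found: {fpath}")
        forward = frozenset(
            line.strip() for line in fpath.read_text().splitlines() if line.strip()
        )
    else:
        # Fall back to the docked proteins themselves as the forward panel.
        forward = frozenset(r.protein_id for r in docking)
    return Dataset(
        compounds=compounds,
        universe=targets,
        predictions=predictions,
        docking=docking,
        forward_protein_set=forward,
    )


def run_pipeline(
    config: Mapping[str, Any],
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> Path:
    """Execute the full pipeline; returns the output directory.

    A stage failure aborts the run with the failing stage named; outputs
    written before the failure are retained next to a ``FAILED`` marker.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    stage = "configure"
    started = time.time()
    counts: Dict[str, int] = {}
    try:
        weights = ScoringWeights(**_filter_kwargs(ScoringWeights, config.get("weights") or {}))
        search_cfg = SearchConfig(**_filter_kwargs(SearchConfig, config.get("search") or {}))
        sim_cfg = SimilarityConfig(
            **_filter_kwargs(SimilarityConfig, config.get("similarity") or {})
        )

        stage = "simulate" if "simulate" in config else "read_inputs"
        logger.info("stage %s", stage)
        dataset = load_dataset_from_config(config, seed)
        input_dir = out / "inputs"
        paths = write_tables(
            dataset.compounds, dataset.universe, dataset.predictions,
            dataset.docking, input_dir,
        )
        (input_dir / "forward_proteins.txt").write_text(
            "\n".join(sorted(dataset.forward_protein_set)) + "\n"
        )
        counts.update(
            compounds=len(dataset.compounds),
            proteins=len(dataset.universe),
            predictions=len(dataset.predictions),
            docking_records=len(dataset.docking),
        )

        screen_kwargs = _filter_kwargs(ScreenConfig, config.get("screen") or {})
        screen_kwargs.setdefault("forward_protein_set", dataset.forward_protein_set)
        screen_cfg = ScreenConfig(**screen_kwargs)

        digests = {p.name: _sha256_file(p) for p in sorted(paths.values())}
        manifest_digest = hashlib.sha256(
            json.dumps(
                {"config": dict(config), "seed": seed, "inputs": digests},
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest()
        stamp = {"manifest_digest": manifest_digest}

        stage = "cluster"
        logger.info("stage cluster")
        clustering = form_clusters(dataset.compounds, sim_cfg)
        merged = merge_clusters(clustering.clusters)
        dump_json(
            {
                **stamp,
                "st_threshold": sim_cfg.st_threshold,
                "direction": sim_cfg.direction,
                "clusters": [sorted(c.members) for c in merged],
                "excluded": clustering.excluded,
                "st_matrix": {
                    "|".join(k): v for k, v in sorted(clustering.st_matrix.items())
                },
            },
            out / "clusters.json",
        )
        counts["clusters"] = len(merged)

        stage = "screen"
        logger.info("stage screen")
        screened = screen_by_ki(dataset.docking, screen_cfg.ki_cutoff_um)
        strict = screen_by_ki(dataset.docking, screen_cfg.ki_strict_um)
        counts["docking_pass_cutoff"] = len(screened)
        counts["docking_pass_strict"] = len(strict)
        ids = [c.compound_id for c in dataset.compounds]
        kb, dock = member_profiles(
            ids, dataset.predictions, dataset.docking, dataset.universe_map, screen_cfg
        )
        dump_json(
            {
                **stamp,
                "ki_cutoff_um": screen_cfg.ki_cutoff_um,
                "ki_strict_um": screen_cfg.ki_strict_um,
                "n_pass_cutoff": len(screened),
                "n_pass_strict": len(strict),
                "profiles": {
                    cid: {
                        "proteins": sorted(kb[cid].proteins),
                        "ac": kb[cid].ac, "am": kb[cid].am, "ah": kb[cid].ah,
                        "n_total": kb[cid].n_total,
                        "docking_proteins": sorted(dock[cid].proteins),
                    }
                    for cid in ids
                },
            },
            out / "profiles.json",
        )

        stage = "score"
        logger.info("stage score")
        singlet_records = [
            score_candidate((cid,), [kb[cid]], [dock[cid]], weights) for cid in ids
        ]
        dump_json(
            {
                **stamp,
                "scores": [
                    {
                        "owner": r.label, "cscore": r.cscore, "dscore": r.dscore,
                        "combiscore": r.combiscore, "comm": r.comm, "sp": r.sp,
                        "detail": dict(r.detail) if r.detail else None,
                    }
                    for r in singlet_records
                ],
            },
            out / "scores.json",
        )

        stage = "search"
        logger.info("stage search")
        tiers = run_search(dataset, weights, screen_cfg, search_cfg)
        tiers_doc = {**stamp, **tiers_as_dict(tiers)}
        dump_json(tiers_doc, out / "tiers.json")
        counts["selected_total"] = sum(len(t.selected) for t in tiers)

        stage = "enrich"
        logger.info("stage enrich")
        memberships = pathway_memberships_from_universe(dataset.universe)
        background = frozenset(dataset.universe_map)
        selected_profiles: List[TargetProfile] = []
        for tier in tiers:
            for owner in tier.selected:
                selected_profiles.append(merge_profiles([kb[c] for c in owner]))
        if not memberships:
            logger.warning("no pathway annotations supplied; enrichment is empty")
        enrichment = enrich_candidates(selected_profiles, memberships, background)
        enrichment_doc = {
            **stamp,
            "background_size": len(background),
            "candidates": {
                owner: [dataclasses.asdict(r) for r in rows]
                for owner, rows in enrichment.items()
            },
        }
        dump_json(enrichment_doc, out / "enrichment.json")

        stage = "report"
        logger.info("stage report")
        report = render_report(
            tiers_doc, enrichment_doc["candidates"], {**stamp, "seed": seed}
        )
        (out / "report.md").write_text(report)

        manifest = {
            "tool": "combirank",
            "version": __version__,
            "seed": seed,
            "manifest_digest": manifest_digest,
            "config": dict(config),
            "input_digests": digests,
            "stage_counts": counts,
            "outputs": [
                "inputs/compounds.tsv", "inputs/targets.tsv",
                "inputs/predictions.tsv", "inputs/docking.tsv",
                "inputs/forward_proteins.txt", "clusters.json", "profiles.json",
                "scores.json", "tiers.json", "enrichment.json", "report.md",
            ],
            "started_unix": started,
            "finished_unix": time.time(),
        }
        dump_json(manifest, out / "manifest.json")
        failed = out / "FAILED"
        if failed.exists():
            failed.unlink()
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineStageError(stage, exc) from exc


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
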