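"""Pipeline orchestration: load -> group -> score -> MCCV -> aggregate, per rank.

For every requested taxonomic rank the pipeline emits the tool's three
outputs — a per-depth metrics table, the aggregated important-group list with
significance values, and the species-per-group table — plus a per-iteration
long table, a run log and a manifest tying the outputs to the exact inputs,
configuration and seed that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .errors import AggregationError, GSMError, InputError, ModelingError
from .grouping import GROUPING_RANKS, GroupMap, group_features, lineages_for
from .modeling import ModelingConfig, RunResult, run_mccv
from .profile_io import AbundanceMatrix, load_abundance_matrix
from .rank_aggregation import (AggregatedItem, aggregate, aggregated_to_frame,
                               propagate_to_species)
from .scoring import ScoringConfig

logger = logging.getLogger("microbiomegsm")


@dataclass
class RankOutput:
    """In-memory result bundle for one taxonomic rank."""

    rank: str
    group_map: GroupMap
    run_result: RunResult
    aggregated_groups: list[AggregatedItem]
    species_table: "object"


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]
    seed: int
    version: str
    started: str
    finished: str
    outputs: dict[str, dict[str, str]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze_rank(matrix: AbundanceMatrix, rank: str,
                 modeling_cfg: ModelingConfig,
                 scoring_cfg: ScoringConfig | None = None,
                 species_aggregation: str = "propagate") -> RankOutput:
    """Run the full G-S-M analysis for one rank on an in-memory matrix.

    ``species_aggregation`` selects how species significance is obtained:
    ``"propagate"`` (each species inherits its group's p-value, the default)
    or ``"direct"`` (robust rank aggregation run on the per-iteration species
    lists themselves).
    """
    lineages = lineages_for(matrix.species_ids)
    group_map = group_features(lineages, rank)
    logger.info("rank %s: %d groups over %d species",
                rank, group_map.n_groups, matrix.n_species)
    result = run_mccv(matrix, group_map, modeling_cfg, scoring_cfg)
    aggregated = aggregate(result.ranked_group_lists(),
                           universe=group_map.group_names, group_map=group_map)
    if species_aggregation == "direct":
        species_lists = [list(it.ranked_species) for it in result.per_iteration]
        species_agg = aggregate(species_lists, universe=matrix.species_ids)
        species_table = aggregated_to_frame(species_agg).rename(
            columns={"item": "species"}).drop(columns=["member_species"])
    elif species_aggregation == "propagate":
        species_table = propagate_to_species(aggregated, group_map)
    else:
        raise AggregationError(f"unknown species_aggregation {species_aggregation!r}")
    return RankOutput(rank=rank, group_map=group_map, run_result=result,
                      aggregated_groups=aggregated, species_table=species_table)


def write_rank_outputs(out: RankOutput, out_dir: str | Path) -> dict[str, str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out_dir / f"metrics_{out.rank}.csv",
        "groups": out_dir / f"groups_{out.rank}.csv",
        "species": out_dir / f"species_{out.rank}.csv",
        "iterations": out_dir / f"iterations_{out.rank}.csv",
    }
    out.run_result.summary_frame().to_csv(paths["metrics"], index=False)
    aggregated_to_frame(out.aggregated_groups).to_csv(paths["groups"], index=False)
    out.species_table.to_csv(paths["species"], index=False)
    out.run_result.iteration_frame().to_csv(paths["iterations"], index=False)
    return {k: str(v) for k, v in paths.items()}


def run(
    abundance_path: str | Path,
    labels_path: str | Path,
    ranks: Sequence[str],
    out_dir: str | Path,
    read_counts_path: str | Path | None = None,
    positive_label: str | None = None,
    modeling_cfg: ModelingConfig | None = None,
    scoring_cfg: ScoringConfig | None = None,
    species_aggregation: str = "propagate",
) -> RunManifest:
    """Run the tool end to end from input files and write all outputs."""
    modeling_cfg = modeling_cfg or ModelingConfig()
    for rank in ranks:
        if rank not in GROUPING_RANKS:
            raise InputError(f"unsupported rank {rank!r}; choose from {GROUPING_RANKS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    started = datetime.now(timezone.utc).isoformat()
    try:
        matrix = load_abundance_matrix(abundance_path, labels_path,
                                       read_counts_path=read_counts_path,
                                       positive_label=positive_label)
        logger.info("loaded %d samples x %d species (%d disease / %d control)",
                    matrix.n_samples, matrix.n_species,
                    int(matrix.labels.sum()), int((1 - matrix.labels).sum()))
        outputs: dict[str, dict[str, str]] = {}
        for rank in ranks:
            result = analyze_rank(matrix, rank, modeling_cfg, scoring_cfg,
                                  species_aggregation=species_aggregation)
            outputs[rank] = write_rank_outputs(result, out_dir)
        inputs = {str(abundance_path): _sha256(abundance_path),
                  str(labels_path): _sha256(labels_path)}
        if read_counts_path is not None:
            inputs[str(read_counts_path)] = _sha256(read_counts_path)
        manifest = RunManifest(
            config={"modeling": asdict(modeling_cfg),
                    "scoring": asdict(scoring_cfg) if scoring_cfg else None,
                    "ranks": list(ranks), "positive_label": positive_label,
                    "species_aggregation": species_aggregation},
            inputs=inputs,
            seed=modeling_cfg.global_seed,
            version=__version__,
            started=started,
            finished=datetime.now(timezone.utc).isoformat(),
            outputs=outputs,
        )
        (out_dir / "manifest.json").write_text(manifest.to_json())
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
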