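"""Taxonomy-structured synthetic compositional abundance data.

Emulates the structure of species-level metagenomic relative-abundance
cohorts: species nested under genera, families and orders; per-sample species
fractions in [0, 1] summing to 1; and a small number of "informative" taxon
groups whose member species are shifted between the disease and control
classes.

The generative model: each species j gets a fixed baseline weight drawn
log-normally (heavy-tailed abundance spectrum); each sample draws per-species
gamma noise around those baselines (a Dirichlet-like concentration model, one
unit of concentration per species by default); species inside informative
groups have their weights multiplied by exp(effect) in disease samples; the
weights are then closed to sum to 1. Because closure happens after effect
injection, effects are relative, as in real compositional data. Interactions
between taxa and explicit zero inflation are not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .grouping import GROUPING_RANKS, lineages_for
from .profile_io import AbundanceMatrix


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    ``effect`` is a log-scale multiplicative abundance shift: informative
    species' weights are multiplied by exp(effect) in disease samples (so the
    default 2.0 is an e^2 ~ 7.4-fold relative shift before closure).
    """

    n_samples: int = 200
    n_positive: int = 100
    n_genera: int = 30
    species_per_genus: tuple[int, int] = (1, 10)
    n_informative_groups: int = 3
    effect: float = 2.0
    base_concentration: float = 1.0
    baseline_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_positive < self.n_samples:
            raise InputError("need 0 < n_positive < n_samples")
        if self.n_informative_groups > self.n_genera:
            raise InputError("n_informative_groups exceeds n_genera")
        if self.effect < 0:
            raise InputError("effect must be >= 0")
        lo, hi = self.species_per_genus
        if not 1 <= lo <= hi:
            raise InputError("species_per_genus must be a range with 1 <= lo <= hi")


@dataclass(frozen=True)
class GroundTruth:
    """Which groups carry class signal, per rank, plus per-species multipliers."""

    informative_groups: dict[str, tuple[str, ...]]
    species_multipliers: dict[str, float]


def generate_taxonomy(cfg: SynthConfig) -> list[str]:
    """Deterministic clade strings for the configured genera.

    Genera are nested three to a family and families three to an order, with
    a single kingdom on top, producing full seven-level clade strings. Species
    counts per genus are drawn uniformly from ``species_per_genus``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.species_per_genus
    counts = rng.integers(lo, hi + 1, size=cfg.n_genera)
    clades: list[str] = []
    for g in range(cfg.n_genera):
        fam = g // 3
        order = fam // 3
        cls = order // 3
        phylum = cls // 2
        genus = f"Genus{g + 1:03d}"
        prefix = (f"k__Bacteria|p__Phylum{phylum + 1:02d}|c__Class{cls + 1:02d}"
                  f"|o__Order{order + 1:02d}|f__Family{fam + 1:02d}|g__{genus}")
        for s in range(int(counts[g])):
            clades.append(f"{prefix}|s__{genus}_sp{s + 1:02d}")
    return clades


def generate_dataset(cfg: SynthConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Draw a labeled compositional cohort and its ground truth.

    Disease samples (label 1) come first, then controls; informative genera
    are chosen uniformly at random, and their ancestor families and orders are
    the informative groups at the coarser ranks.
    """
    rng = np.random.default_rng(cfg.seed)
    clades = generate_taxonomy(cfg)
    lineages = lineages_for(clades)
    n_species = len(clades)

    genera = sorted({lin.genus for lin in lineages})
    informative_genera = tuple(sorted(
        str(g) for g in rng.choice(genera, size=cfg.n_informative_groups, replace=False)))
    informative: dict[str, tuple[str, ...]] = {"genus": informative_genera}
    for rank in ("family", "order"):
        names = sorted({lin.name_at(rank) for lin in lineages
                        if lin.genus in informative_genera})
        informative[rank] = tuple(names)

    multipliers = np.ones(n_species)
    info_set = set(informative_genera)
    for j, lin in enumerate(lineages):
        if lin.genus in info_set:
            multipliers[j] = float(np.exp(cfg.effect))

    baseline = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=n_species)
    labels = np.array([1] * cfg.n_positive + [0] * (cfg.n_samples - cfg.n_positive))
    weights = rng.gamma(shape=cfg.base_concentration, scale=1.0,
                        size=(cfg.n_samples, n_species)) * baseline
    weights[labels == 1] *= multipliers
    values = weights / weights.sum(axis=1, keepdims=True)

    matrix = AbundanceMatrix(
        sample_ids=[f"S{i + 1:04d}" for i in range(cfg.n_samples)],
        species_ids=clades,
        values=values,
        labels=labels,
    )
    truth = GroundTruth(
        informative_groups=informative,
        species_multipliers={clades[j]: float(multipliers[j]) for j in range(n_species)
                             if multipliers[j] != 1.0},
    )
    return matrix, truth


def write_metaphlan_tsv(matrix: AbundanceMatrix, path: str | Path,
                        percent: bool = True,
                        include_genus_rows: bool = True) -> None:
    """Write the matrix as a merged abundance TSV (clades x samples).

    With ``percent`` the values are written on the 0-100 scale that merged
    profiles conventionally use; ``include_genus_rows`` adds genus-level
    aggregate rows (sums of member species) so the file exercises
    species-level row selection on re-read.
    """
    scale = 100.0 if percent else 1.0
    frame = pd.DataFrame(matrix.values.T * scale,
                         index=matrix.species_ids, columns=matrix.sample_ids)
    if include_genus_rows:
        lineages = lineages_for(matrix.species_ids)
        genus_rows: dict[str, np.ndarray] = {}
        for j, lin in enumerate(lineages):
            genus_clade = matrix.species_ids[j].rsplit("|", 1)[0]
            genus_rows.setdefault(genus_clade, np.zeros(matrix.n_samples))
            genus_rows[genus_clade] += matrix.values[:, j] * scale
        genus_frame = pd.DataFrame(genus_rows).T
        genus_frame.columns = matrix.sample_ids
        frame = pd.concat([genus_frame, frame])
    frame.index.name = "clade_name"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_labels_csv(matrix: AbundanceMatrix, path: str | Path) -> None:
    if matrix.labels is None:
        raise InputError("matrix has no labels")
    pd.DataFrame({"sample_id": matrix.sample_ids,
                  "label": matrix.labels}).to_csv(path, index=False)


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "informative_groups": {k: list(v) for k, v in truth.informative_groups.items()},
        "species_multipliers": truth.species_multipliers,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def simulate_to_dir(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write abundance TSV, labels CSV and truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_dataset(cfg)
    paths = {
        "abundance": out / "abundance.tsv",
        "labels": out / "labels.csv",
        "truth": out / "truth.json",
    }
    write_metaphlan_tsv(matrix, paths["abundance"])
    write_labels_csv(matrix, paths["labels"])
    write_truth_json(truth, paths["truth"])
    return paths
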