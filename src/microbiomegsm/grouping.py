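"""The G component: partition the species feature space by taxonomic rank.

Clade strings are parsed into seven-slot lineages (kingdom..species); species
are then grouped under their genus, family, or order name. Lineages with a
missing intermediate rank get a synthesized ``<ancestor>_unclassified`` name so
that every species belongs to exactly one group at every grouping rank —
such synthetic groups are ordinary groups, mirroring the unclassified clades
that real MetaPhlAn profiles contain.

Grouping is label-free: it depends only on the species identifiers, never on
samples or class labels.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .profile_io import AbundanceMatrix

#: The seven lineage ranks, root first.
RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIX_TO_RANK = dict(zip("kpcofgs", RANKS))
#: Ranks at which the pipeline groups features.
GROUPING_RANKS: tuple[str, ...] = ("genus", "family", "order")

_SEGMENT_RE = re.compile(r"^([a-z])__(.*)$")


@dataclass(frozen=True)
class Lineage:
    """Parsed taxonomy of one species feature; empty slots are gap-filled."""

    kingdom: str | None
    phylum: str | None
    class_: str | None
    order: str | None
    family: str | None
    genus: str | None
    species: str | None
    source_species_id: str

    def name_at(self, rank: str) -> str | None:
        if rank == "class":
            rank = "class_"
        return getattr(self, rank)


@dataclass(frozen=True)
class GroupMap:
    """Partition of the species set into groups at one taxonomic rank.

    ``groups`` maps the taxon name at ``rank`` to the ordered tuple of member
    species ids; iteration order is lexicographic (case-insensitive) by taxon
    name, and species order within a group follows the input feature order.
    """

    rank: str
    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if any(len(v) == 0 for v in self.groups.values()):
            raise InputError("empty group in GroupMap")

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def all_species(self) -> list[str]:
        return [s for members in self.groups.values() for s in members]

    def to_json(self) -> str:
        return json.dumps({"rank": self.rank,
                           "groups": {k: list(v) for k, v in self.groups.items()}},
                          sort_keys=False)


def parse_clade_string(clade: str) -> Lineage:
    """Parse a pipe-joined, rank-prefixed clade string into a :class:`Lineage`.

    Prefixes must appear in strictly descending rank order. Missing intermediate
    ranks are synthesized as ``<deepest_known_ancestor>_unclassified`` so that
    populated slots form a contiguous prefix from kingdom downward.
    """
    clade = clade.strip()
    if not clade:
        raise InputError("empty clade string")
    slots: dict[str, str] = {}
    last_depth = -1
    for token in clade.split("|"):
        m = _SEGMENT_RE.match(token.strip())
        if not m or m.group(1) not in _PREFIX_TO_RANK:
            raise InputError(f"malformed clade segment {token!r} in {clade!r}")
        rank = _PREFIX_TO_RANK[m.group(1)]
        depth = RANKS.index(rank)
        if depth <= last_depth:
            raise InputError(f"clade prefixes out of order at {token!r} in {clade!r}")
        last_depth = depth
        slots[rank] = m.group(2)

    deepest = last_depth
    filled: dict[str, str | None] = {}
    last_real: str | None = None
    for i, rank in enumerate(RANKS):
        if i > deepest:
            filled[rank] = None
        elif rank in slots:
            filled[rank] = slots[rank]
            last_real = slots[rank]
        else:
            filled[rank] = f"{last_real}_unclassified" if last_real else "unclassified"
    return Lineage(
        kingdom=filled["kingdom"], phylum=filled["phylum"], class_=filled["class"],
        order=filled["order"], family=filled["family"], genus=filled["genus"],
        species=filled["species"], source_species_id=clade,
    )


def lineages_for(species_ids: Sequence[str]) -> list[Lineage]:
    """Parse every species id (a full clade string) into a lineage."""
    return [parse_clade_string(s) for s in species_ids]


def read_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Read a lineage sidecar TSV (species_id, kingdom..species columns).

    Used with plain samples x species CSVs whose headers are bare species names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "species_id" not in cols:
        raise InputError("lineage table needs a species_id column")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        sid = str(row["species_id"]).strip()
        segs = []
        for prefix, rank in zip("kpcofgs", RANKS):
            val = row.get(rank)
            if val is not None and not pd.isna(val) and str(val).strip():
                segs.append(f"{prefix}__{str(val).strip()}")
        if not segs:
            raise InputError(f"no lineage information for species {sid!r}")
        lin = parse_clade_string("|".join(segs))
        out[sid] = Lineage(**{**lin.__dict__, "source_species_id": sid})
    return out


def group_features(lineages: Sequence[Lineage], rank: str) -> GroupMap:
    """Partition species into groups by their taxon name at ``rank``.

    Taxon names are matched case-insensitively and reported in the casing of
    their first occurrence; groups iterate in lexicographic (case-folded) name
    order, species within a group in input order. Every species lands in
    exactly one group (gap-filled lineages guarantee totality).
    """
    if rank not in GROUPING_RANKS:
        raise InputError(f"rank must be one of {GROUPING_RANKS}, got {rank!r}")
    display: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for lin in lineages:
        name = lin.name_at(rank)
        if name is None:
            raise InputError(f"species {lin.source_species_id!r} has no name at rank {rank!r}")
        key = name.casefold()
        if key not in members:
            members[key] = []
            display[key] = name
        members[key].append(lin.source_species_id)
    ordered = {display[k]: tuple(members[k]) for k in sorted(members)}
    return GroupMap(rank=rank, groups=ordered)


@dataclass(frozen=True)
class SubDataset:
    """A training matrix restricted to one group's species (the sub_d of G-S-M)."""

    group_name: str
    sample_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.species_ids)


def make_subdataset(matrix: AbundanceMatrix, group_name: str,
                    species: Sequence[str]) -> SubDataset:
    """Column-slice ``matrix`` to one group's species, keeping samples and labels."""
    if matrix.labels is None:
        raise InputError("matrix has no labels attached")
    values = matrix.species_values(species)
    return SubDataset(
        group_name=group_name,
        sample_ids=tuple(matrix.sample_ids),
        species_ids=tuple(species),
        values=values,
        labels=matrix.labels.copy(),
    )
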