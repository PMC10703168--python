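"""Robust rank aggregation of per-iteration group rankings, with propagation
of group significance to member species.

Each MCCV iteration yields an ordered top-k list of taxon groups. For every
group, its positions across lists are turned into normalized ranks r = j/U
(position j over universe size U; groups absent from a list get the worst
normalized rank, 1.0). The beta score b_k is the probability that the k-th
smallest of N independent Uniform(0,1) variables is <= r_(k) — an upper
binomial tail P(Bin(N, r_(k)) >= k). The rho score is the minimum beta score
over k: a small rho means the group sits near the top of the lists far more
consistently than uniform shuffling would allow.

Because rho minimizes over N order statistics, it is Bonferroni-corrected by
N (the robust-rank-aggregation score, exposed per vector as
:func:`rank_vector_p`); :func:`aggregate` additionally corrects across the
universe of U competing items, so an item's reported significance is
p = min(1, min(1, N * min_beta) * U). Species inherit the significance value
of their group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import AggregationError
from .grouping import GroupMap


@dataclass(frozen=True)
class AggregatedItem:
    """One group (or species) with its aggregated significance across lists.

    ``rho`` is the order-statistic score min(1, N * min_beta) — the item-level
    significance bound of robust rank aggregation over N lists; ``p_value``
    Bonferroni-corrects it across the U items of the universe.
    """

    item: str
    rho: float
    p_value: float
    n_lists_present: int
    member_species: tuple[str, ...] = ()


def build_rank_matrix(lists: Sequence[Sequence[str]],
                      universe: Iterable[str] | None = None) -> pd.DataFrame:
    """Normalized-rank matrix (items x lists): position j becomes j/U, absent -> 1.

    ``universe`` defaults to the union of all items seen in any list; passing
    the full item set (e.g. every group at the chosen rank) makes missing items
    explicit and the correction conservative.
    """
    if not lists:
        raise AggregationError("need at least one ranked list")
    seen: dict[str, None] = {}
    for lst in lists:
        if len(set(lst)) != len(lst):
            dup = [x for x in lst if list(lst).count(x) > 1][0]
            raise AggregationError(f"duplicate item {dup!r} within one ranked list")
        for item in lst:
            seen[item] = None
    if universe is None:
        items = list(seen)
    else:
        items = list(dict.fromkeys(universe))
        missing = [i for i in seen if i not in set(items)]
        if missing:
            raise AggregationError(f"items outside the declared universe: {missing[:5]}")
    U = len(items)
    mat = np.ones((U, len(lists)))
    pos = {item: i for i, item in enumerate(items)}
    for col, lst in enumerate(lists):
        for j, item in enumerate(lst, start=1):
            mat[pos[item], col] = j / U
    return pd.DataFrame(mat, index=items, columns=[f"list_{c + 1}" for c in range(len(lists))])


def beta_scores(sorted_ranks: Sequence[float]) -> np.ndarray:
    """Exact order-statistic tail probabilities for a sorted rank vector.

    For r sorted ascending, b_k = P(Bin(N, r_k) >= k), the probability that at
    least k of N uniforms fall at or below r_k.
    """
    r = np.asarray(sorted_ranks, dtype=float)
    if r.ndim != 1 or len(r) == 0:
        raise AggregationError("rank vector must be non-empty and one-dimensional")
    if np.any((r <= 0) | (r > 1)):
        raise AggregationError("normalized ranks must lie in (0, 1]")
    if np.any(np.diff(r) < 0):
        raise AggregationError("rank vector must be sorted ascending")
    n = len(r)
    k = np.arange(1, n + 1)
    return binom.sf(k - 1, n, r)


def rho_score(sorted_ranks: Sequence[float]) -> float:
    """Minimum beta score of a sorted normalized-rank vector."""
    return float(np.min(beta_scores(sorted_ranks)))


def rank_vector_p(sorted_ranks: Sequence[float]) -> float:
    """Bonferroni-corrected p for one rank vector: min(1, N * rho) over its N ranks."""
    return min(1.0, len(sorted_ranks) * rho_score(sorted_ranks))


def aggregate(lists: Sequence[Sequence[str]],
              universe: Iterable[str] | None = None,
              group_map: GroupMap | None = None) -> list[AggregatedItem]:
    """Aggregate ranked lists into items with rho scores and corrected p-values.

    Per item, the minimum beta score over its sorted normalized ranks is
    Bonferroni-corrected for the N order statistics minimized over (giving the
    rho score of the cited aggregation method) and then for the U competing
    items of the universe: p = min(1, min(1, N * min_beta) * U). Output is
    sorted by p ascending, ties broken alphabetically. When ``group_map`` is
    given, each item carries its member species.
    """
    matrix = build_rank_matrix(lists, universe=universe)
    U = matrix.shape[0]
    present = {item: 0 for item in matrix.index}
    for lst in lists:
        for item in lst:
            present[item] += 1
    out: list[AggregatedItem] = []
    for item in matrix.index:
        ranks = np.sort(matrix.loc[item].to_numpy())
        rho = min(1.0, len(lists) * rho_score(ranks))
        members: tuple[str, ...] = ()
        if group_map is not None and item in group_map.groups:
            members = group_map.groups[item]
        out.append(AggregatedItem(item=item, rho=rho,
                                  p_value=min(1.0, rho * U),
                                  n_lists_present=present[item],
                                  member_species=members))
    out.sort(key=lambda a: (a.p_value, a.rho, a.item.casefold()))
    return out


def propagate_to_species(aggregated_groups: Sequence[AggregatedItem],
                         group_map: GroupMap) -> pd.DataFrame:
    """Assign each species the significance value of its taxon group.

    Rows are ordered by group p-value ascending (ties by group name), species
    within a group in their input order.
    """
    ordered = sorted(aggregated_groups, key=lambda a: (a.p_value, a.item.casefold()))
    rows = []
    for agg in ordered:
        if agg.item not in group_map.groups:
            raise AggregationError(f"group {agg.item!r} missing from group map")
        for species in group_map.groups[agg.item]:
            rows.append({"species": species, "group": agg.item,
                         "rho": agg.rho, "p_value": agg.p_value})
    return pd.DataFrame(rows, columns=["species", "group", "rho", "p_value"])


def aggregated_to_frame(items: Sequence[AggregatedItem]) -> pd.DataFrame:
    """Tabular export: item, rho, p_value, n_lists_present, member_species."""
    return pd.DataFrame(
        [{"item": a.item, "rho": a.rho, "p_value": a.p_value,
          "n_lists_present": a.n_lists_present,
          "member_species": ";".join(a.member_species)} for a in items],
        columns=["item", "rho", "p_value", "n_lists_present", "member_species"],
    )
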