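"""Model applications: phenological census and fruiting-branch analysis.

Two analyses built on simulated architectures:

- :func:`phenostage_census` counts, for every day of a date range, the
  growth units and inflorescences standing at given phenological stages
  (stages D and E are the windows of susceptibility to the mango blossom
  gall midge), averaged over the simulated trees.

- :func:`identify_fruiting_branches` delimits carbon-autonomous fruiting
  branches: the set of GUs within a topological distance of N-1 edges of a
  fruiting GU (so N=1 keeps only the fruiting GUs themselves); overlapping
  sets are merged transitively into one branch with several competing
  fruiting GUs.  :func:`leaf_fruit_ratio` is the branch's total leaf count
  over its total fruit count, the key input of the fruit growth model.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .architecture import TreeArchitecture
from .organ_growth import stage_intervals
from .parameters import ParameterSet

__all__ = [
    "FruitingBranch",
    "phenostage_census",
    "identify_fruiting_branches",
    "leaf_fruit_ratio",
]


@dataclass
class FruitingBranch:
    id: int
    member_gu_ids: frozenset[int]
    fruiting_gu_ids: frozenset[int]
    n_leaves: int
    n_fruits: int

    @property
    def leaf_fruit_ratio(self) -> float:
        return leaf_fruit_ratio(self)


def leaf_fruit_ratio(branch: FruitingBranch) -> float:
    """Total member-GU leaves over total fruits on the branch's fruiting GUs."""
    if branch.n_fruits < 1:
        raise ValueError("a fruiting branch must carry at least one fruit")
    return branch.n_leaves / branch.n_fruits


# ---------------------------------------------------------------------------
# Phenological census
# ---------------------------------------------------------------------------

def phenostage_census(
    archs: Sequence[TreeArchitecture],
    weather,
    params: ParameterSet,
    stages: Iterable[str] = ("D", "E"),
    start: Optional[dt.date] = None,
    end: Optional[dt.date] = None,
) -> pd.DataFrame:
    """Daily average per-tree counts of GUs and inflorescences at ``stages``.

    Stage occupancy of every entity is reconstructed from its burst date and
    the weather series through the thermal-time stage schedules.  Days with
    zero counts are kept (they mark the resting periods).  Counts are
    divided by the number of trees.
    """
    stages = set(stages)
    start = start or weather.start
    end = end or weather.end
    n_days = (end - start).days + 1
    gu_counts = [0] * n_days
    inflo_counts = [0] * n_days

    def tally(counts: list[int], kind: str, burst: dt.date) -> None:
        if burst > end:
            return
        for stage, s0, s1 in stage_intervals(kind, max(burst, weather.start), weather,
                                             params.thermal):
            if stage not in stages:
                continue
            lo = max(s0, start)
            hi = min(s1, end)
            for off in range((lo - start).days, (hi - start).days + 1):
                if off >= 0:
                    counts[off] += 1

    for arch in archs:
        for gu in arch.gus.values():
            tally(gu_counts, "gu", gu.burst_date)
        for inf in arch.inflorescences.values():
            tally(inflo_counts, "inflorescence", inf.burst_date)

    n_trees = max(len(archs), 1)
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    return pd.DataFrame(
        {
            "date": dates,
            "gu_count": [c / n_trees for c in gu_counts],
            "inflo_count": [c / n_trees for c in inflo_counts],
        }
    )


# ---------------------------------------------------------------------------
# Fruiting branches
# ---------------------------------------------------------------------------

def identify_fruiting_branches(
    arch: TreeArchitecture,
    size: int,
    cycle: Optional[int] = None,
) -> list[FruitingBranch]:
    """Delimit fruiting branches of size ``size`` (N >= 1).

    Per fruiting GU, the member set is every GU at graph distance <= N-1
    edges; overlapping member sets are merged transitively.  When ``cycle``
    is given only that cycle's fruiting GUs seed branches.
    """
    if size < 1:
        raise ValueError("fruiting-branch size N must be >= 1")
    fruiting = sorted(
        {
            fr.bearer_id
            for fr in arch.fruits.values()
            if cycle is None or fr.cycle == cycle
        }
    )
    if not fruiting:
        return []

    radius = size - 1
    member_sets: list[set[int]] = []
    for fgid in fruiting:
        # BFS on the undirected GU graph out to `radius` edges
        members = {fgid}
        frontier = [fgid]
        for _ in range(radius):
            nxt = []
            for gid in frontier:
                gu = arch.gus[gid]
                neighbours = list(arch.children[gid])
                if gu.parent_id is not None:
                    neighbours.append(gu.parent_id)
                for nb in neighbours:
                    if nb not in members:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
        member_sets.append(members)

    # transitive merge of overlapping member sets (union-find over seeds)
    parent = list(range(len(fruiting)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(fruiting)):
        for j in range(i + 1, len(fruiting)):
            if member_sets[i] & member_sets[j]:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(fruiting)):
        groups.setdefault(find(i), []).append(i)

    branches = []
    for bid, (root, idxs) in enumerate(sorted(groups.items())):
        members: set[int] = set()
        seeds: set[int] = set()
        for i in idxs:
            members |= member_sets[i]
            seeds.add(fruiting[i])
        n_leaves = sum(arch.gus[g].n_leaves or 0 for g in members)
        n_fruits = sum(
            1
            for fr in arch.fruits.values()
            if fr.bearer_id in seeds and (cycle is None or fr.cycle == cycle)
        )
        branches.append(
            FruitingBranch(
                id=bid,
                member_gu_ids=frozenset(members),
                fruiting_gu_ids=frozenset(seeds),
                n_leaves=n_leaves,
                n_fruits=n_fruits,
            )
        )
    return branches


def branches_dataframe(branches: Sequence[FruitingBranch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "branch_id": b.id,
                "n_member_gus": len(b.member_gu_ids),
                "n_fruiting_gus": len(b.fruiting_gu_ids),
                "n_leaves": b.n_leaves,
                "n_fruits": b.n_fruits,
                "leaf_fruit_ratio": b.leaf_fruit_ratio,
            }
            for b in branches
        ]
    )
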