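"""Tree architecture data model.

A mango tree is represented as a forest of growth units (GUs) — the portions
of axis produced during one uninterrupted flush — bearing inflorescences and
fruits.  Each GU knows its parent, its position on the mother (apical or
lateral), its burst date, the growing cycle it appeared in, and its
end-of-cycle fate (quiescent / flowering / fruiting).  The class also keeps
an event log (used for evaluation criteria) and a decision log recording
every stochastic decision taken by the automata (used for calibration).

Topological queries used throughout the model:

- ``terminal_gus``: the leaves of the GU graph at a date (candidate mothers
  and flowering sites);
- ``extract_axes``: the partition of GUs into axes (an axis starts at a
  lateral or founding GU and continues through successive apical daughters);
- ``graph_distance``: number of edges on the unique GU-to-GU path (self = 0),
  the metric defining fruiting branches.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "GrowthUnit",
    "Inflorescence",
    "Fruit",
    "TreeArchitecture",
    "TopologyError",
]


class TopologyError(Exception):
    """A structural invariant of the GU forest would be violated."""


@dataclass
class GrowthUnit:
    id: int
    parent_id: Optional[int]
    position: str                    # "apical" | "lateral"
    burst_date: dt.date
    cycle: int
    ancestor_id: int                 # founding ancestor GU of its cycle lineage
    fate: str = "undetermined"       # quiescent | flowering | fruiting
    fate_history: dict = field(default_factory=dict)  # cycle -> end-of-cycle fate
    n_leaves: Optional[int] = None
    axis_length: Optional[float] = None   # final length L, cm
    leaf_length: Optional[float] = None   # common mature leaf length l, cm
    diameter: Optional[float] = None      # basal diameter, cm
    geometry: dict = field(default_factory=dict)


@dataclass
class Inflorescence:
    id: int
    bearer_id: int
    kind: str                        # "pure" | "mixed"
    position: str                    # "apical" | "lateral"
    burst_date: dt.date
    full_bloom_date: dt.date
    cycle: int
    axis_length: Optional[float] = None
    n_second_order_axes: Optional[int] = None


@dataclass
class Fruit:
    id: int
    bearer_id: int
    inflorescence_id: int
    cycle: int
    bloom_date: dt.date
    dry_mass: Optional[float] = None     # Md, g
    fresh_mass: Optional[float] = None   # Mf, g
    harvest_date: Optional[dt.date] = None


class TreeArchitecture:
    """Forest of growth units with inflorescences, fruits and event logs."""

    def __init__(self) -> None:
        self.gus: dict[int, GrowthUnit] = {}
        self.inflorescences: dict[int, Inflorescence] = {}
        self.fruits: dict[int, Fruit] = {}
        self.children: dict[int, list[int]] = {}
        self.inflos_of: dict[int, list[int]] = {}
        self.events: list[tuple[int, str, dt.date]] = []
        self.decisions: list[dict] = []
        self._next_id = 1

    # -- construction ------------------------------------------------------

    def _new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add_ancestor(
        self,
        position: str,
        fate: str,
        burst_date: dt.date,
        cycle: int = 0,
    ) -> int:
        gid = self._new_id()
        gu = GrowthUnit(
            id=gid,
            parent_id=None,
            position=position,
            burst_date=burst_date,
            cycle=cycle,
            ancestor_id=gid,
            fate=fate,
            fate_history={cycle: fate},
        )
        self.gus[gid] = gu
        self.children[gid] = []
        self.inflos_of[gid] = []
        self.events.append((gid, "gu_burst", burst_date))
        return gid

    def add_daughters(
        self,
        mother_id: int,
        apical: bool,
        n_lateral: int,
        burst_date: dt.date,
        cycle: int,
        ancestor_id: Optional[int] = None,
    ) -> list[int]:
        """Attach daughter GUs at the distal end of ``mother_id``.

        All daughters of one burst share the burst date (daughter GUs appear
        synchronously on a given terminal GU).  A GU can acquire at most one
        apical daughter over its lifetime, and an empty burst (no apical, no
        laterals) is rejected: the automata never emit one.
        """
        if mother_id not in self.gus:
            raise TopologyError(f"mother GU {mother_id} does not exist")
        if not apical and n_lateral == 0:
            raise TopologyError("empty burst: no apical daughter and no laterals")
        if apical and any(
            self.gus[c].position == "apical" for c in self.children[mother_id]
        ):
            raise TopologyError(f"GU {mother_id} already has an apical daughter")
        if ancestor_id is None:
            ancestor_id = self.gus[mother_id].ancestor_id
        new_ids = []
        positions = (["apical"] if apical else []) + ["lateral"] * n_lateral
        for pos in positions:
            gid = self._new_id()
            self.gus[gid] = GrowthUnit(
                id=gid,
                parent_id=mother_id,
                position=pos,
                burst_date=burst_date,
                cycle=cycle,
                ancestor_id=ancestor_id,
            )
            self.children[gid] = []
            self.inflos_of[gid] = []
            self.children[mother_id].append(gid)
            self.events.append((gid, "gu_burst", burst_date))
            new_ids.append(gid)
        return new_ids

    def add_inflorescence(
        self,
        bearer_id: int,
        kind: str,
        position: str,
        burst_date: dt.date,
        full_bloom_date: dt.date,
        cycle: int,
    ) -> int:
        if bearer_id not in self.gus:
            raise TopologyError(f"bearer GU {bearer_id} does not exist")
        if kind == "mixed" and position == "apical":
            # a mixed apical inflorescence is unique on its GU
            for iid in self.inflos_of[bearer_id]:
                if self.inflorescences[iid].position == "apical":
                    raise TopologyError(f"GU {bearer_id} already bears an apical inflorescence")
        iid = self._new_id()
        self.inflorescences[iid] = Inflorescence(
            id=iid,
            bearer_id=bearer_id,
            kind=kind,
            position=position,
            burst_date=burst_date,
            full_bloom_date=full_bloom_date,
            cycle=cycle,
        )
        self.inflos_of[bearer_id].append(iid)
        self.events.append((iid, "inflo_burst", burst_date))
        self.events.append((iid, "full_bloom", full_bloom_date))
        return iid

    def add_fruits(self, bearer_id: int, n_fruits: int, bloom_date: "dt.date", cycle: int) -> list[int]:
        """Distribute ``n_fruits`` round-robin over the bearer's inflorescences."""
        inflos = self.inflos_of.get(bearer_id, [])
        if not inflos:
            raise TopologyError(f"GU {bearer_id} has no inflorescence to bear fruit")
        ids = []
        for k in range(n_fruits):
            fid = self._new_id()
            self.fruits[fid] = Fruit(
                id=fid,
                bearer_id=bearer_id,
                inflorescence_id=inflos[k % len(inflos)],
                cycle=cycle,
                bloom_date=bloom_date,
            )
            self.events.append((fid, "fruit_set", bloom_date))
            ids.append(fid)
        return ids

    # -- queries -----------------------------------------------------------

    def terminal_gus(self, date: Optional[dt.date] = None) -> set[int]:
        """GU ids that have burst by ``date`` and have no daughter GU then.

        A GU bearing an apical inflorescence but no daughter GU is still
        terminal: the between-cycle automaton, keyed on its fate, decides
        whether its apical bud can still produce a daughter.
        """
        out = set()
        for gid, gu in self.gus.items():
            if date is not None and gu.burst_date > date:
                continue
            kids = self.children[gid]
            if date is None:
                has_daughter = bool(kids)
            else:
                has_daughter = any(self.gus[c].burst_date <= date for c in kids)
            if not has_daughter:
                out.add(gid)
        return out

    def extract_axes(self, cycles: Iterable[int]) -> list[int]:
        """Axis lengths (number of in-range GUs) for GUs of the given cycles.

        An axis begins with a lateral (or founding) GU and continues through
        the successive apical daughter GUs; every GU belongs to exactly one
        axis.  Only GUs whose cycle is in ``cycles`` are counted, and axes
        with no in-range GU are dropped.
        """
        cycles = set(cycles)
        axis_of: dict[int, int] = {}

        def axis_root(gid: int) -> int:
            if gid in axis_of:
                return axis_of[gid]
            gu = self.gus[gid]
            if gu.parent_id is None or gu.position == "lateral":
                root = gid
            else:
                root = axis_root(gu.parent_id)
            axis_of[gid] = root
            return root

        counts: dict[int, int] = {}
        for gid, gu in self.gus.items():
            root = axis_root(gid)
            if gu.cycle in cycles:
                counts[root] = counts.get(root, 0) + 1
        return sorted(counts.values())

    def _path_to_root(self, gid: int) -> list[int]:
        path = [gid]
        while self.gus[path[-1]].parent_id is not None:
            path.append(self.gus[path[-1]].parent_id)
        return path

    def graph_distance(self, a: int, b: int) -> int:
        """Number of edges on the unique path between GUs ``a`` and ``b``."""
        if a not in self.gus or b not in self.gus:
            raise TopologyError("both GU ids must exist")
        pa = self._path_to_root(a)
        pb = self._path_to_root(b)
        if pa[-1] != pb[-1]:
            raise TopologyError(f"GUs {a} and {b} belong to different trees")
        depth_a = {g: i for i, g in enumerate(pa)}
        for j, g in enumerate(pb):
            if g in depth_a:
                return depth_a[g] + j
        raise AssertionError("unreachable: common root exists")

    def roots(self) -> list[int]:
        return [gid for gid, gu in self.gus.items() if gu.parent_id is None]

    # -- export ------------------------------------------------------------

    def gus_dataframe(self):
        import pandas as pd

        rows = []
        for gu in self.gus.values():
            rows.append(
                {
                    "gu_id": gu.id,
                    "parent_id": gu.parent_id,
                    "position": gu.position,
                    "burst_date": gu.burst_date.isoformat(),
                    "cycle": gu.cycle,
                    "ancestor_id": gu.ancestor_id,
                    "fate": gu.fate,
                    "n_leaves": gu.n_leaves,
                    "axis_length_cm": gu.axis_length,
                    "diameter_cm": gu.diameter,
                }
            )
        return pd.DataFrame(rows)

    def inflorescences_dataframe(self):
        import pandas as pd

        rows = []
        for inf in self.inflorescences.values():
            rows.append(
                {
                    "inflo_id": inf.id,
                    "bearer_id": inf.bearer_id,
                    "kind": inf.kind,
                    "position": inf.position,
                    "burst_date": inf.burst_date.isoformat(),
                    "full_bloom_date": inf.full_bloom_date.isoformat(),
                    "cycle": inf.cycle,
                    "axis_length_cm": inf.axis_length,
                }
            )
        return pd.DataFrame(rows)

    def fruits_dataframe(self):
        import pandas as pd

        rows = []
        for fr in self.fruits.values():
            rows.append(
                {
                    "fruit_id": fr.id,
                    "bearer_id": fr.bearer_id,
                    "inflo_id": fr.inflorescence_id,
                    "cycle": fr.cycle,
                    "bloom_date": fr.bloom_date.isoformat(),
                    "dry_mass_g": fr.dry_mass,
                    "fresh_mass_g": fr.fresh_mass,
                    "harvest_date": fr.harvest_date.isoformat() if fr.harvest_date else None,
                }
            )
        return pd.DataFrame(rows)

    def write_events_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["entity_id", "event", "date"])
            for eid, event, date in self.events:
                writer.writerow([eid, event, date.isoformat()])

    def to_mtg_text(self) -> str:
        """Indentation-coded plain-text topology export.

        ``/`` introduces the founding GU of a tree, ``<`` an apical daughter
        and ``+`` a lateral one, one entity per line — an MTG-flavoured
        encoding for interoperability with plant-architecture tools.
        """
        lines: list[str] = []

        def walk(gid: int, depth: int, symbol: str) -> None:
            gu = self.gus[gid]
            lines.append(f"{'  ' * depth}{symbol}GU{gid}[{gu.position},{gu.burst_date.isoformat()}]")
            for cid in self.children[gid]:
                child = self.gus[cid]
                walk(cid, depth + 1, "<" if child.position == "apical" else "+")

        for root in sorted(self.roots()):
            walk(root, 0, "/")
        return "\n".join(lines) + "\n"
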