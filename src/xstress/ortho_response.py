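"""Cross-species accounting of differentially expressed orthologs.

Each species' per-stress DEG set is partitioned by what the ortholog(s)
in the other species did under the same stress:

* common_up / common_down - at least one ortholog responds in the same
  direction as the focal gene;
* opposite                - at least one ortholog responds in the
  reverse direction and none in the same direction;
* ortholog_unchanged      - orthologs exist but none is differentially
  expressed;
* no_ortholog             - the focal gene has no cross-species group.

For one-to-many groups the focal gene is classified against all its
orthologs with precedence common > opposite > unchanged (a
same-direction ortholog outweighs an opposite one); the precedence is
configurable.  Core sets collect genes moving in a consistent direction
under every configured stress, and core overlap counts ortholog
*groups* (not gene x gene combinations) shared between the species'
cores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_model import OrthologGroupMap, ValidationError

logger = logging.getLogger("xstress")

RESPONSE_CLASSES = ("common_up", "common_down", "opposite",
                    "ortholog_unchanged", "no_ortholog")


@dataclass
class ResponseClassTable:
    """Per-species response-class assignment of each DEG for one stress."""

    stress: str
    table_a: pd.DataFrame   # columns: gene, direction, response_class, counterparts
    table_b: pd.DataFrame

    def counts(self, species: str) -> dict[str, int]:
        table = self.table_a if species == "A" else self.table_b
        vc = table["response_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in RESPONSE_CLASSES}


def _direction_map(deg: pd.DataFrame) -> dict[str, str]:
    return dict(zip(deg["gene"], deg["direction"]))


def _classify_one(direction: str, partner_dirs: list[str],
                  precedence: str = "common_first") -> str:
    if not partner_dirs:
        return "no_ortholog"
    same = [d for d in partner_dirs if d == direction]
    reverse = {"up": "down", "down": "up"}[direction]
    opp = [d for d in partner_dirs if d == reverse]
    if precedence == "common_first":
        if same:
            return f"common_{direction}"
        if opp:
            return "opposite"
    elif precedence == "opposite_first":
        if opp:
            return "opposite"
        if same:
            return f"common_{direction}"
    else:
        raise ValidationError(f"unknown precedence {precedence!r}")
    return "ortholog_unchanged"


def classify_responses(deg_a: pd.DataFrame, deg_b: pd.DataFrame,
                       orthos: OrthologGroupMap, stress: str = "",
                       universe_a: set[str] | None = None,
                       universe_b: set[str] | None = None,
                       precedence: str = "common_first",
                       ) -> ResponseClassTable:
    """Assign every DEG of both species a cross-species response class.

    ``deg_a`` / ``deg_b`` are DEG tables (gene, direction, ...) for the
    same stress; only rows with direction up/down participate.  A
    partner gene absent from the other species' table counts as
    unchanged.  When gene universes are supplied, DEGs outside them are
    an error.
    """
    tables = {}
    for species, deg, other in (("A", deg_a, deg_b), ("B", deg_b, deg_a)):
        universe = universe_a if species == "A" else universe_b
        if universe is not None:
            offenders = sorted(set(deg["gene"]) - universe)
            if offenders:
                raise ValidationError(
                    f"species {species} DEGs absent from universe: "
                    f"{offenders[:5]}"
                )
        other_dir = _direction_map(other)
        rows = []
        called = deg[deg["direction"].isin(("up", "down"))]
        for gene, direction in zip(called["gene"], called["direction"]):
            partners = orthos.partners(gene)
            partner_dirs = [other_dir.get(p, "unchanged") for p in partners]
            cls = _classify_one(direction, partner_dirs, precedence)
            rows.append((gene, direction, cls, ";".join(partners)))
        tables[species] = pd.DataFrame(
            rows, columns=["gene", "direction", "response_class",
                           "counterparts"]
        )
    return ResponseClassTable(stress=stress, table_a=tables["A"],
                              table_b=tables["B"])


def response_proportions(class_counts: dict[str, int],
                         ) -> pd.DataFrame:
    """Percentages of each response class within one species' DEG set.

    Accepts a class -> count mapping (as from
    :meth:`ResponseClassTable.counts`) and returns a table with raw and
    nearest-integer-rounded percentages (100 x count / total DEGs).
    """
    total = sum(class_counts.values())
    if total == 0:
        logger.warning("empty DEG set: no proportions to report")
        return pd.DataFrame(columns=["response_class", "count",
                                     "percent", "percent_rounded"])
    rows = []
    for cls, k in class_counts.items():
        pct = 100.0 * k / total
        rows.append((cls, k, pct, int(round(pct))))
    return pd.DataFrame(rows, columns=["response_class", "count",
                                       "percent", "percent_rounded"])


@dataclass
class CoreSets:
    """Genes with a consistent direction under every configured stress."""

    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("core up and down sets must be disjoint")


def core_sets(deg_tables: dict[str, pd.DataFrame],
              stresses: list[str]) -> CoreSets:
    """Intersect per-stress up (resp. down) calls across all stresses."""
    missing = [s for s in stresses if s not in deg_tables]
    if missing:
        raise ValidationError(f"missing DEG tables for stresses: {missing}")
    up_sets, down_sets = [], []
    for s in stresses:
        deg = deg_tables[s]
        up = set(deg.loc[deg["direction"] == "up", "gene"])
        down = set(deg.loc[deg["direction"] == "down", "gene"])
        if not up and not down:
            logger.warning("stress %s has zero DEGs; core sets will be "
                           "empty", s)
        up_sets.append(up)
        down_sets.append(down)
    core_up = set.intersection(*up_sets) if up_sets else set()
    core_down = set.intersection(*down_sets) if down_sets else set()
    return CoreSets(up=core_up, down=core_down)


def core_overlap(core_a: CoreSets, core_b: CoreSets,
                 orthos: OrthologGroupMap) -> dict[str, int]:
    """Ortholog-group-level overlap between the two species' core sets.

    Counts groups (so a 1:2 group contributes once) in the categories
    common_up_pairs, common_down_pairs, opposite_pairs,
    orthologous_not_shared (a core gene's group has counterparts, none
    of them core) and no_ortholog (core genes outside any group).  The
    same common > opposite precedence as per-stress classification
    applies at the group level.
    """
    counts = {"common_up_pairs": 0, "common_down_pairs": 0,
              "opposite_pairs": 0, "orthologous_not_shared": 0,
              "no_ortholog": 0}
    seen_groups: set[int] = set()
    core_a_all = core_a.up | core_a.down
    core_b_all = core_b.up | core_b.down
    for gene in sorted(core_a_all):
        gid = orthos.group_of(gene)
        if gid is None:
            counts["no_ortholog"] += 1
            continue
        if gid in seen_groups:
            continue
        seen_groups.add(gid)
        a_members, b_members = orthos.groups[gid]
        a_up = any(g in core_a.up for g in a_members)
        a_down = any(g in core_a.down for g in a_members)
        b_up = any(g in core_b.up for g in b_members)
        b_down = any(g in core_b.down for g in b_members)
        if (a_up and b_up) or (a_down and b_down):
            if a_up and b_up:
                counts["common_up_pairs"] += 1
            else:
                counts["common_down_pairs"] += 1
        elif (a_up and b_down) or (a_down and b_up):
            counts["opposite_pairs"] += 1
        else:
            counts["orthologous_not_shared"] += 1
    # species-B core genes not reachable from any species-A core group
    for gene in sorted(core_b_all):
        gid = orthos.group_of(gene)
        if gid is None:
            counts["no_ortholog"] += 1
        elif gid not in seen_groups:
            seen_groups.add(gid)
            counts["orthologous_not_shared"] += 1
    return counts
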