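"""Mapping of midline gaps onto cell-ring interfaces.

The embryonic intestine is a stack of nine cell rings (int1..int9) whose
ring-ring contacts (int1/2 .. int8/9) cross the apical midline.  The two
anterior and two posterior ring pairs contain "star" cells, which divide
once more after polarization; interfaces touching a star cell (int1/2,
int7/8, int8/9 by default) are potential star-cell gap sites, the rest
are non-star sites.  When star-cell divisions are blocked, only int1/2
and int7/8 remain star sites and embryos carry 14-16 intestinal cells
instead of 20 (the 14-16-cell range is the quality-control criterion for
that background).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gapcall import GapCall

__all__ = [
    "DEFAULT_STAR_SITES",
    "BLOCKED_STAR_SITES",
    "InterfaceMap",
    "GapAssignment",
    "EmbryoAssignments",
    "assign_gap",
    "site_frequencies",
    "gap_class_proportions",
]

logger = logging.getLogger(__name__)

DEFAULT_STAR_SITES = frozenset({"int1/2", "int7/8", "int8/9"})
BLOCKED_STAR_SITES = frozenset({"int1/2", "int7/8"})

#: rings containing star cells (gaps strictly inside these rings count as star)
DEFAULT_STAR_RINGS = frozenset({1, 8, 9})
BLOCKED_STAR_RINGS = frozenset({1, 8})


def _rings_of(name: str) -> tuple[int, int]:
    a, b = name.removeprefix("int").split("/")
    return int(a), int(b)


@dataclass(frozen=True)
class InterfaceMap:
    """Positions of ring-ring interfaces along a midline trace.

    ``interfaces`` is an ordered tuple of ``(name, trace_index)`` with
    strictly increasing indices; ``star_sites`` flags the potential
    star-cell gap sites.  ``n_cells`` is the intestinal cell count used
    for quality control: 20 normally, 14-16 when divisions are blocked.
    """

    interfaces: tuple[tuple[str, int], ...]
    star_sites: frozenset = DEFAULT_STAR_SITES
    division_blocked: bool = False
    n_cells: int = 20

    def __post_init__(self) -> None:
        idx = [i for _, i in self.interfaces]
        if len(idx) == 0:
            raise ValueError("interface map needs >= 1 interface")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("interface indices must be strictly increasing")
        names = set(self.names)
        object.__setattr__(self, "star_sites", frozenset(self.star_sites) & names)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.interfaces)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for _, i in self.interfaces)

    @property
    def star_rings(self) -> frozenset:
        return BLOCKED_STAR_RINGS if self.division_blocked else DEFAULT_STAR_RINGS

    def passes_qc(self) -> bool:
        """Cell-count QC: 14-16 cells for division-blocked maps, 20 otherwise."""
        if self.division_blocked:
            return 14 <= self.n_cells <= 16
        return self.n_cells == 20

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "interfaces": [[n, int(i)] for n, i in self.interfaces],
                    "star_sites": sorted(self.star_sites),
                    "division_blocked": self.division_blocked,
                    "n_cells": self.n_cells,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str) -> "InterfaceMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            interfaces=tuple((n, int(i)) for n, i in d["interfaces"]),
            star_sites=frozenset(d["star_sites"]),
            division_blocked=bool(d.get("division_blocked", False)),
            n_cells=int(d.get("n_cells", 20)),
        )


@dataclass(frozen=True)
class GapAssignment:
    """A gap's interface bookkeeping: touched sites, class, spanning flag."""

    gap: GapCall
    touched: tuple[str, ...]
    context: str  # "star" | "non-star"
    spans_interface: bool
    cell_separation: bool = False  # input annotation, never inferred


def assign_gap(gap: GapCall, imap: InterfaceMap, tol_points: int = 0) -> GapAssignment:
    """Classify a gap as star/non-star and flag interface spanning.

    A gap spans an interface when some interface index lies within its
    half-open index range (widened by ``tol_points``).  It is "star" when
    it touches any star-site interface, or, touching none, when it lies
    strictly inside a star-containing ring segment; a gap touching both
    classes counts as star (it affects a star cell).
    """
    if gap.start_idx < 0:
        raise ValueError("gap start before trace origin")
    lo, hi = gap.start_idx - tol_points, gap.end_idx + tol_points
    touched = tuple(n for n, i in imap.interfaces if lo <= i < hi)
    if touched:
        context = "star" if any(n in imap.star_sites for n in touched) else "non-star"
    else:
        # mid-segment gap: segment k lies between interface k-1 and k,
        # i.e. inside ring k (1-based); after the last interface it is the
        # terminal ring
        n_before = int(np.searchsorted(imap.indices, gap.start_idx, side="right"))
        if n_before == 0:
            ring = _rings_of(imap.names[0])[0]
        elif n_before == len(imap.interfaces):
            ring = _rings_of(imap.names[-1])[1]
        else:
            ring = _rings_of(imap.names[n_before - 1])[1]
        context = "star" if ring in imap.star_rings else "non-star"
    assignment = GapAssignment(
        gap=gap,
        touched=touched,
        context=context,
        spans_interface=bool(touched),
    )
    gap.context = context
    gap.spans_interface = bool(touched)
    return assignment


@dataclass
class EmbryoAssignments:
    """All gap assignments of one embryo plus its interface map."""

    embryo_id: str
    genotype: str
    imap: InterfaceMap
    assignments: list[GapAssignment] = field(default_factory=list)


def site_frequencies(
    embryos: Sequence[EmbryoAssignments],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-genotype star/non-star gap-site frequency table.

    Embryos failing the cell-count QC are excluded (their ids are
    returned and logged).  The primary tally counts one gap per touched
    potential site (a gap spanning two sites contributes to both); the
    ``*_gap_tally`` columns count each gap once, by its class, restricted
    to interface-touching gaps.  Gaps touching no interface do not enter
    site tallies.
    """
    if len(embryos) == 0:
        raise ValueError("empty cohort")
    excluded = [e.embryo_id for e in embryos if not e.imap.passes_qc()]
    for eid in excluded:
        logger.warning("embryo %s excluded by cell-count QC", eid)
    rows: dict[str, dict[str, float]] = {}
    for e in embryos:
        if e.embryo_id in excluded:
            continue
        r = rows.setdefault(
            e.genotype,
            {
                "n_embryos": 0,
                "potential_star_sites": 0,
                "potential_nonstar_sites": 0,
                "gaps_at_star": 0,
                "gaps_at_nonstar": 0,
                "star_gap_tally": 0,
                "nonstar_gap_tally": 0,
            },
        )
        r["n_embryos"] += 1
        n_star = len(e.imap.star_sites)
        r["potential_star_sites"] += n_star
        r["potential_nonstar_sites"] += len(e.imap.interfaces) - n_star
        for a in e.assignments:
            star_hits = sum(1 for n in a.touched if n in e.imap.star_sites)
            r["gaps_at_star"] += star_hits
            r["gaps_at_nonstar"] += len(a.touched) - star_hits
            if a.touched:
                key = "star_gap_tally" if a.context == "star" else "nonstar_gap_tally"
                r[key] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("genotype").reset_index()
    df["freq_star"] = np.where(
        df["potential_star_sites"] > 0, df["gaps_at_star"] / df["potential_star_sites"], 0.0
    )
    df["freq_nonstar"] = np.where(
        df["potential_nonstar_sites"] > 0,
        df["gaps_at_nonstar"] / df["potential_nonstar_sites"],
        0.0,
    )
    return df, excluded


def gap_class_proportions(embryos: Sequence[EmbryoAssignments]) -> pd.DataFrame:
    """Per-genotype proportions over gaps: star, non-star, spanning, cell sep.

    Proportions are over gaps (not embryos); star + non-star = 100%.
    Cell separation is an input annotation on each assignment.  Raises if
    a genotype contributes zero gaps (report "no gaps" instead).
    """
    records = []
    for genotype in dict.fromkeys(e.genotype for e in embryos):
        assigns = [a for e in embryos if e.genotype == genotype for a in e.assignments]
        n = len(assigns)
        if n == 0:
            raise ValueError(
                f"genotype {genotype!r} has zero gaps; report 'no gaps' rather than proportions"
            )
        records.append(
            {
                "genotype": genotype,
                "n_gaps": n,
                "pct_star": 100.0 * sum(a.context == "star" for a in assigns) / n,
                "pct_nonstar": 100.0 * sum(a.context == "non-star" for a in assigns) / n,
                "pct_spanning": 100.0 * sum(a.spans_interface for a in assigns) / n,
                "pct_cell_separation": 100.0 * sum(a.cell_separation for a in assigns) / n,
            }
        )
    return pd.DataFrame.from_records(records)
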