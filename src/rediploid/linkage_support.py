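"""Homeolog support from duplicated markers and map-to-map marker pairing.

In a haploid (gynogenetic) cross, a RAD marker residing in a residually
tetrasomic region can be mapped to both of its paralogous positions.  A
marker whose two placements land on the two arms of the same protokaryotype
(PK) therefore supports that pair's homeologous relationship, and the number
of supporting markers per PK separates tetrasomically inherited pairs (tens
of markers) from rediploidized ones (a handful).  This module counts and
ranks that support, and provides the simplified map-comparison pairing of
markers from two linkage maps through shared contigs of an intermediate
reference genome.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import pandas as pd

from .pk_homology import PKArm

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPlacement",
    "DuplicatedMarkerSet",
    "HomeologSupport",
    "GenomeAnchor",
    "read_duplicated_markers",
    "read_genome_anchors",
    "homeolog_support",
    "classify_support",
    "pair_markers_via_intermediate",
]


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    lg_name: str
    position: float  # cM

    def __post_init__(self) -> None:
        if not self.position >= 0:
            raise ValueError("position must be a finite non-negative cM value")


@dataclass
class DuplicatedMarkerSet:
    """marker_id -> one or two map placements (two = mapped at both paralogs)."""

    records: dict[str, list[MarkerPlacement]]

    def __post_init__(self) -> None:
        for marker, placements in self.records.items():
            if not 1 <= len(placements) <= 2:
                raise ValueError(f"marker {marker} has {len(placements)} placements")

    @property
    def n_both_paralogs(self) -> int:
        return sum(1 for p in self.records.values() if len(p) == 2)

    @property
    def n_single_paralog(self) -> int:
        return sum(1 for p in self.records.values() if len(p) == 1)


@dataclass(frozen=True)
class HomeologSupport:
    pk: int
    arm_pair: tuple[PKArm, PKArm]
    n_supporting_markers: int
    rank: int


@dataclass(frozen=True)
class GenomeAnchor:
    """A marker's alignment position on the intermediate reference genome."""

    marker_id: str
    map_id: str
    contig: str
    position: int  # bp, 0-based

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")


def read_duplicated_markers(source) -> DuplicatedMarkerSet:
    """TSV with columns marker_id, lg, position_cM; one row per placement."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t")
    records: dict[str, list[MarkerPlacement]] = {}
    for r in frame.itertuples():
        records.setdefault(str(r.marker_id), []).append(
            MarkerPlacement(str(r.marker_id), str(r.lg), float(r.position_cM))
        )
    return DuplicatedMarkerSet(records)


def read_genome_anchors(source) -> list[GenomeAnchor]:
    """TSV with columns marker_id, map_id, contig, pos_bp."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t")
    return [
        GenomeAnchor(str(r.marker_id), str(r.map_id), str(r.contig), int(r.pos_bp))
        for r in frame.itertuples()
    ]


def homeolog_support(
    markers: DuplicatedMarkerSet, arm_map: dict[str, PKArm]
) -> list[HomeologSupport]:
    """Count markers whose two placements resolve to a PK's two arms.

    ``arm_map`` maps an LG-arm name (as used in the placements) to a PK arm.
    Markers on LGs absent from the map are skipped and logged; a marker
    placed twice on one LG is excluded with a warning; single-placement
    markers cannot identify an arm pair and do not contribute.  Every PK
    with both arms covered by ``arm_map`` is reported (possibly with zero
    support), ranked by descending count with ties broken by PK number.
    """
    counts: dict[int, int] = {}
    pk_arms: dict[int, set[PKArm]] = {}
    for arm in arm_map.values():
        pk_arms.setdefault(arm.pk_number, set()).add(arm)
    for pk, arms in pk_arms.items():
        if len(arms) == 2:
            counts[pk] = 0
    uncovered = 0
    for marker_id, placements in markers.records.items():
        if len(placements) != 2:
            continue
        a, b = placements
        if a.lg_name == b.lg_name:
            logger.warning("marker %s placed twice on %s; excluded", marker_id, a.lg_name)
            continue
        arm_a = arm_map.get(a.lg_name)
        arm_b = arm_map.get(b.lg_name)
        if arm_a is None or arm_b is None:
            uncovered += 1
            continue
        if arm_a.pk_number == arm_b.pk_number and arm_a.arm != arm_b.arm:
            counts[arm_a.pk_number] = counts.get(arm_a.pk_number, 0) + 1
    if uncovered:
        logger.warning("%d marker(s) on LGs not covered by the arm map; skipped", uncovered)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    supports = []
    for rank, (pk, n) in enumerate(ordered, start=1):
        arms = sorted(pk_arms.get(pk, {PKArm(pk, 1), PKArm(pk, 2)}))
        if len(arms) == 1:
            arms = [PKArm(pk, 1), PKArm(pk, 2)]
        supports.append(
            HomeologSupport(pk=pk, arm_pair=(arms[0], arms[-1]), n_supporting_markers=n, rank=rank)
        )
    return supports


def classify_support(
    supports: list[HomeologSupport], threshold: int = 10
) -> dict[int, str]:
    """Split PKs into high vs low homeolog support at ``threshold`` markers.

    The default of 10 sits with wide margin between the tens-of-markers
    regime of tetrasomic pairs and the 1-6 markers typical of disomic ones.
    The boundary is inclusive: count == threshold is high.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return {
        s.pk: ("high" if s.n_supporting_markers >= threshold else "low")
        for s in supports
    }


def pair_markers_via_intermediate(
    anchors_a: list[GenomeAnchor],
    anchors_b: list[GenomeAnchor],
    max_gap: int = 10_000_000,
) -> list[tuple[str, str]]:
    """Greedily pair markers of two maps that anchor near each other.

    Two markers from different linkage maps that align to nearby positions
    (within ``max_gap``) on the same contig of an intermediate reference
    genome are taken to tag the same locus.  Map-A anchors are processed in
    (contig, position) order and each takes its nearest unpaired map-B
    anchor; no marker is used twice and pairing never crosses contigs.
    """
    maps_a = {a.map_id for a in anchors_a}
    maps_b = {b.map_id for b in anchors_b}
    if maps_a & maps_b:
        raise ValueError(f"inputs share map id(s): {sorted(maps_a & maps_b)}")
    by_contig_b: dict[str, list[GenomeAnchor]] = {}
    for b in anchors_b:
        by_contig_b.setdefault(b.contig, []).append(b)
    for contig in by_contig_b:
        by_contig_b[contig].sort(key=lambda x: (x.position, x.marker_id))
    pairs: list[tuple[str, str]] = []
    used_b: set[str] = set()
    for a in sorted(anchors_a, key=lambda x: (x.contig, x.position, x.marker_id)):
        candidates = [
            b
            for b in by_contig_b.get(a.contig, [])
            if b.marker_id not in used_b and abs(b.position - a.position) <= max_gap
        ]
        if not candidates:
            continue
        best = min(candidates, key=lambda b: (abs(b.position - a.position), b.position))
        used_b.add(best.marker_id)
        pairs.append((a.marker_id, best.marker_id))
    return pairs
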