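"""Homeolog sequence-similarity summaries from pairwise alignment blocks.

After a whole-genome duplication, the two homeologous copies of each
ancestral chromosome diverge unless ongoing homeologous recombination
(residual tetrasomy) keeps homogenizing them.  Divergence is measured here
from tabular pairwise alignments between homeologous arms: blocks are
filtered (minimum identity 75%, minimum length 1,000 bp, both inclusive, to
exclude spurious gene-family alignments), and each homeolog pair is
summarized by the median percent identity of its blocks weighted by
alignment length.  Pairs are then ranked within a species and rank orders
aggregated across species.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk_homology import PKArm

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentBlock",
    "FilterParams",
    "PairSimilarity",
    "SpeciesRanking",
    "read_alignment_blocks",
    "write_pair_similarities",
    "read_pair_similarities",
    "filter_blocks",
    "weighted_median",
    "weighted_median_similarity",
    "assign_blocks_to_pk",
    "rank_pairs",
    "aggregate_cross_species_order",
]


@dataclass(frozen=True)
class AlignmentBlock:
    """One filtered alignment segment between two homeologous arms.

    Coordinates are 0-based half-open on the forward strand of the query;
    ``length`` is the aligned-column count used for weighting (falls back to
    ``query_end - query_start`` when the aligner does not report it).
    """

    query: str
    target: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    length: int
    identity_pct: float

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start:
            raise ValueError("query_end must exceed query_start")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class FilterParams:
    """Alignment retention thresholds (both bounds inclusive)."""

    min_identity: float = 75.0
    min_length: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must lie in [0, 100]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class PairSimilarity:
    """Length-weighted median identity for one homeolog pair in one species."""

    species: str
    pk: int
    weighted_median: float
    n_blocks: int
    total_aligned: int


@dataclass(frozen=True)
class SpeciesRanking:
    """PK pairs of one species ranked 1 (most similar) .. n (least)."""

    species: str
    ranks: tuple[tuple[int, int], ...]  # (pk, rank)


_GENERIC_COLS = [
    "query",
    "qstart",
    "qend",
    "target",
    "tstart",
    "tend",
    "strand",
    "length",
    "identity_pct",
]

# minimal column set of LASTZ --format=general output that we consume
_LASTZ_REQUIRED = ["name1", "zstart1", "end1", "name2", "strand2", "zstart2+", "end2+", "id%"]


def read_alignment_blocks(source, dialect: str = "generic_tsv") -> list[AlignmentBlock]:
    """Read alignment blocks from TSV in LASTZ ``general`` or generic dialect.

    The LASTZ dialect takes aligned length from the denominator of the
    ``identity`` fraction column (``matches/columns``) when present, else
    from the query span.  Generic TSV columns: query, qstart, qend, target,
    tstart, tend, strand, length, identity_pct.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.lstrip("#").strip() for c in frame.columns]
    if dialect not in ("lastz_general", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    required = _LASTZ_REQUIRED if dialect == "lastz_general" else _GENERIC_COLS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{dialect} input missing column(s): {missing}")
    if frame.empty:
        logger.warning("alignment table is empty")
        return []
    if dialect == "lastz_general":
        blocks = []
        for i, row in frame.iterrows():
            try:
                qstart, qend = int(row["zstart1"]), int(row["end1"])
                tstart, tend = int(row["zstart2+"]), int(row["end2+"])
                identity = float(row["id%"].rstrip("%"))
                if "identity" in frame.columns and "/" in row.get("identity", ""):
                    length = int(row["identity"].split("/")[1])
                else:
                    length = qend - qstart
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed lastz_general line {i + 2}: {exc}") from exc
            blocks.append(
                AlignmentBlock(
                    query=row["name1"],
                    target=row["name2"],
                    query_start=qstart,
                    query_end=qend,
                    target_start=tstart,
                    target_end=tend,
                    strand=row["strand2"],
                    length=length,
                    identity_pct=identity,
                )
            )
        return blocks
    blocks = []
    for i, row in frame.iterrows():
        try:
            blocks.append(
                AlignmentBlock(
                    query=row["query"],
                    target=row["target"],
                    query_start=int(row["qstart"]),
                    query_end=int(row["qend"]),
                    target_start=int(row["tstart"]),
                    target_end=int(row["tend"]),
                    strand=row["strand"],
                    length=int(row["length"]),
                    identity_pct=float(row["identity_pct"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed generic_tsv line {i + 2}: {exc}") from exc
    return blocks


def write_alignment_blocks(blocks: list[AlignmentBlock], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "query": b.query,
                "qstart": b.query_start,
                "qend": b.query_end,
                "target": b.target,
                "tstart": b.target_start,
                "tend": b.target_end,
                "strand": b.strand,
                "length": b.length,
                "identity_pct": round(b.identity_pct, 4),
            }
            for b in blocks
        ],
        columns=_GENERIC_COLS,
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


def filter_blocks(
    blocks: list[AlignmentBlock], params: FilterParams = FilterParams()
) -> list[AlignmentBlock]:
    """Keep blocks with identity >= min_identity and length >= min_length."""
    return [
        b
        for b in blocks
        if b.identity_pct >= params.min_identity and b.length >= params.min_length
    ]


def weighted_median(values, weights, convention: str = "lower") -> float:
    """Weighted median: smallest value whose cumulative weight reaches half.

    Equivalent to the plain median of the multiset in which each value is
    repeated ``weight`` times, under the lower-median convention for even
    total weight.  ``convention="midpoint"`` averages the two straddling
    values when the half-weight point falls exactly on a boundary.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median of an empty collection")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cumulative = np.cumsum(weights)
    half = cumulative[-1] / 2.0
    idx = int(np.searchsorted(cumulative, half, side="left"))
    if convention == "lower":
        return float(values[idx])
    if convention == "midpoint":
        if cumulative[idx] == half and idx + 1 < values.size:
            return float((values[idx] + values[idx + 1]) / 2.0)
        return float(values[idx])
    raise ValueError(f"unknown convention {convention!r}")


def weighted_median_similarity(
    blocks: list[AlignmentBlock],
    species: str = "",
    pk: int = 0,
    convention: str = "lower",
) -> PairSimilarity:
    """Summarize one homeolog pair by its length-weighted median identity."""
    if not blocks:
        raise ValueError("cannot summarize an empty block list")
    median = weighted_median(
        [b.identity_pct for b in blocks], [b.length for b in blocks], convention
    )
    return PairSimilarity(
        species=species,
        pk=pk,
        weighted_median=median,
        n_blocks=len(blocks),
        total_aligned=sum(b.length for b in blocks),
    )


def assign_blocks_to_pk(
    blocks: list[AlignmentBlock], name_to_arm: dict[str, PKArm]
) -> dict[int, list[AlignmentBlock]]:
    """Group blocks by protokaryotype via a chromosome-name -> PK-arm map.

    A block is kept only when query and target resolve to the two distinct
    arms of the same PK; anything else (unknown names, self-arm or cross-PK
    alignments, e.g. from multi-arm fusion contamination) is excluded and
    logged rather than silently pooled.
    """
    grouped: dict[int, list[AlignmentBlock]] = {}
    dropped = 0
    for block in blocks:
        qa = name_to_arm.get(block.query)
        ta = name_to_arm.get(block.target)
        if (
            qa is None
            or ta is None
            or qa.pk_number != ta.pk_number
            or qa.arm == ta.arm
        ):
            dropped += 1
            continue
        grouped.setdefault(qa.pk_number, []).append(block)
    if dropped:
        logger.warning("excluded %d non-homeologous alignment block(s)", dropped)
    return grouped


def rank_pairs(summaries: list[PairSimilarity]) -> SpeciesRanking:
    """Rank PK pairs of one species, 1 = highest weighted median.

    Ties are broken by ascending PK number for determinism.
    """
    if not summaries:
        raise ValueError("no summaries to rank")
    species = {s.species for s in summaries}
    if len(species) > 1:
        raise ValueError(f"summaries span multiple species: {sorted(species)}")
    pks = [s.pk for s in summaries]
    if len(set(pks)) != len(pks):
        raise ValueError("duplicate pk in summaries")
    ordered = sorted(summaries, key=lambda s: (-s.weighted_median, s.pk))
    return SpeciesRanking(
        species=summaries[0].species,
        ranks=tuple((s.pk, rank) for rank, s in enumerate(ordered, start=1)),
    )


def aggregate_cross_species_order(rankings: list[SpeciesRanking]) -> list[int]:
    """Order PKs by mean rank across species, most tetrasomy-like first.

    The mean is taken over the species in which a PK is ranked; ties in mean
    rank are broken by ascending PK number.
    """
    if not rankings:
        raise ValueError("no rankings to aggregate")
    totals: dict[int, list[int]] = {}
    for ranking in rankings:
        for pk, rank in ranking.ranks:
            totals.setdefault(pk, []).append(rank)
    return sorted(totals, key=lambda pk: (float(np.mean(totals[pk])), pk))


def write_pair_similarities(summaries: list[PairSimilarity], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "species": s.species,
                "pk": s.pk,
                "weighted_median": s.weighted_median,
                "n_blocks": s.n_blocks,
                "total_aligned": s.total_aligned,
            }
            for s in summaries
        ]
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_pair_similarities(source) -> list[PairSimilarity]:
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t")
    return [
        PairSimilarity(
            species=str(r.species),
            pk=int(r.pk),
            weighted_median=float(r.weighted_median),
            n_blocks=int(r.n_blocks),
            total_aligned=int(r.total_aligned),
        )
        for r in frame.itertuples()
    ]
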