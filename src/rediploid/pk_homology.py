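"""Protokaryotype (PK) arm identifiers, cross-species homology tables,
fusion/fission detection, and linkage-map summary statistics.

Salmonid genomes descend from a whole-genome duplication of a ~25-chromosome
ancestor that resembled the extant northern pike karyotype.  Each ancestral
chromosome ("protokaryotype", PK 01..PK 25) therefore has two descendant
homeologous arms in every salmonid, written ``PK NN.1`` and ``PK NN.2``.
Because every species names its own linkage groups differently, a homology
table maps each PK arm to the linkage-group arm carrying it in each species;
Robertsonian fusions are then visible as one linkage group carrying two or
more PK arms.
"""

from __future__ import annotations

import io
import itertools
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PKArm",
    "Status",
    "ArmAssignment",
    "HomologyTable",
    "Fusion",
    "LinkageMapSummary",
    "parse_homology_table",
    "format_homology_table",
    "detect_fusions",
    "shared_fusions",
    "read_linkage_map_summary",
    "summarize_linkage_map",
    "load_cisco_map_summary",
    "load_coregonine_homology",
]

#: arm-tag letters accepted after a linkage-group stem.  a/b mark the two
#: arms of coregonine and brook-trout metacentrics, p/q the Chinook arms,
#: and c occurs on Atlantic salmon chromosomes assembled in three pieces.
ARM_TAGS = "abcpq"

_LG_TOKEN = re.compile(r"^([A-Za-z_]+\d+)([" + ARM_TAGS + r"])?$")


@dataclass(frozen=True, order=True)
class PKArm:
    """One protokaryotype arm, e.g. ``PK 10.2``."""

    pk_number: int
    arm: int

    def __post_init__(self) -> None:
        if not 1 <= self.pk_number <= 25:
            raise ValueError(f"pk_number must be in 1..25, got {self.pk_number}")
        if self.arm not in (1, 2):
            raise ValueError(f"arm must be 1 or 2, got {self.arm}")

    def __str__(self) -> str:
        return f"PK {self.pk_number:02d}.{self.arm}"

    @property
    def short(self) -> str:
        """Compact row-key form used in tables, e.g. ``10.2``."""
        return f"{self.pk_number:02d}.{self.arm}"

    @classmethod
    def parse(cls, text: str) -> "PKArm":
        """Parse ``"10.2"`` or ``"PK 10.2"`` (case-insensitive)."""
        m = re.fullmatch(r"(?:PK\s*)?(\d{1,2})\.([12])", text.strip(), re.IGNORECASE)
        if m is None:
            raise ValueError(f"not a PK arm identifier: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


class Status(str, Enum):
    IDENTIFIED = "identified"
    WEAK = "weak"
    AMBIGUOUS = "ambiguous"
    NOT_IDENTIFIED = "not_identified"
    MISSING = "missing"


@dataclass(frozen=True)
class ArmAssignment:
    """One homology-table cell: which LG arm carries a PK arm in a species.

    ``weak`` mirrors the table's ``^`` flag and ``ambiguous`` its ``*`` flag;
    cells may carry both.  ``alternatives`` holds every LG-arm token of an
    "or" cell (first token is the provisional assignment and fills
    ``lg_name``/``arm_tag``).
    """

    species: str
    lg_name: str = ""
    arm_tag: str | None = None
    weak: bool = False
    ambiguous: bool = False
    alternatives: tuple[str, ...] = ()
    absent: Status | None = None  # NOT_IDENTIFIED or MISSING, else None

    @property
    def status(self) -> Status:
        if self.absent is not None:
            return self.absent
        if self.ambiguous or len(self.alternatives) > 1:
            return Status.AMBIGUOUS
        if self.weak:
            return Status.WEAK
        return Status.IDENTIFIED

    def format_cell(self) -> str:
        if self.absent is Status.NOT_IDENTIFIED:
            return "not identified"
        if self.absent is Status.MISSING:
            return "missing"
        body = " or ".join(self.alternatives)
        return body + ("^" if self.weak else "") + ("*" if self.ambiguous else "")


def _parse_cell(species: str, cell: str) -> ArmAssignment:
    text = cell.strip()
    if text == "" or text.lower() == "not identified":
        return ArmAssignment(species, absent=Status.NOT_IDENTIFIED)
    if text.lower() == "missing":
        return ArmAssignment(species, absent=Status.MISSING)
    weak = ambiguous = False
    while text and text[-1] in "^*":
        if text[-1] == "^":
            weak = True
        else:
            ambiguous = True
        text = text[:-1]
    tokens = [t.strip() for t in re.split(r"\s+or\s+", text)]
    parsed = []
    for tok in tokens:
        m = _LG_TOKEN.match(tok)
        if m is None:
            raise ValueError(f"unparseable LG token {tok!r}")
        parsed.append((m.group(1), m.group(2)))
    lg, tag = parsed[0]
    return ArmAssignment(
        species,
        lg_name=lg,
        arm_tag=tag,
        weak=weak,
        ambiguous=ambiguous,
        alternatives=tuple(tokens),
    )


@dataclass
class HomologyTable:
    """PK arm x species matrix of :class:`ArmAssignment` cells."""

    rows: dict[PKArm, dict[str, ArmAssignment]]
    species: list[str]

    def __getitem__(self, key: PKArm | str) -> dict[str, ArmAssignment]:
        if isinstance(key, str):
            key = PKArm.parse(key)
        return self.rows[key]

    @property
    def is_complete(self) -> bool:
        return len(self.rows) == 50

    def arms(self) -> list[PKArm]:
        return sorted(self.rows)

    def to_frame(self) -> pd.DataFrame:
        data = {
            arm.short: {sp: self.rows[arm][sp].format_cell() for sp in self.species}
            for arm in self.arms()
        }
        frame = pd.DataFrame.from_dict(data, orient="index", columns=self.species)
        frame.index.name = "PK"
        return frame


def parse_homology_table(
    source, species_columns: list[str] | None = None
) -> HomologyTable:
    """Read a homology table from TSV (path, file object, or literal text).

    The first column holds PK arm keys (``10.1``); the remaining (or the
    explicitly requested) columns are species.  Cell grammar: an LG name with
    optional arm tag, optional ``^``/``*`` flags, ``or``-joined alternatives,
    or the literals ``not identified`` / ``missing``.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    pk_col = frame.columns[0]
    available = [c for c in frame.columns[1:]]
    if species_columns is None:
        species_columns = available
    else:
        unknown = set(species_columns) - set(available)
        if unknown:
            raise ValueError(f"unknown species column(s): {sorted(unknown)}")
    rows: dict[PKArm, dict[str, ArmAssignment]] = {}
    problems: list[str] = []
    for _, record in frame.iterrows():
        try:
            arm = PKArm.parse(record[pk_col])
        except ValueError as exc:
            problems.append(str(exc))
            continue
        if arm in rows:
            raise ValueError(f"duplicate row for {arm}")
        cells = {}
        for sp in species_columns:
            try:
                cells[sp] = _parse_cell(sp, record[sp])
            except ValueError as exc:
                problems.append(f"row {arm.short}, column {sp}: {exc}")
        rows[arm] = cells
    if problems:
        raise ValueError("unparseable homology-table cells:\n  " + "\n  ".join(problems))
    return HomologyTable(rows=rows, species=list(species_columns))


def format_homology_table(table: HomologyTable) -> str:
    """Serialize back to the TSV dialect accepted by :func:`parse_homology_table`."""
    out = ["\t".join(["PK", *table.species])]
    for arm in table.arms():
        cells = [table.rows[arm][sp].format_cell() for sp in table.species]
        out.append("\t".join([arm.short, *cells]))
    return "\n".join(out) + "\n"


@dataclass(frozen=True)
class Fusion:
    """One linkage group carrying two or more PK arms in one species."""

    species: str
    lg_name: str
    arms: frozenset[PKArm]

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValueError("a fusion needs at least two distinct PK arms")

    def arm_pairs(self) -> list[tuple[PKArm, PKArm]]:
        return list(itertools.combinations(sorted(self.arms), 2))


def _usable(assignment: ArmAssignment, policy: str) -> bool:
    if assignment.absent is not None:
        return False
    if policy == "inclusive":
        return True
    if policy == "strict":
        return assignment.status is Status.IDENTIFIED
    raise ValueError(f"unknown policy {policy!r} (expected 'inclusive' or 'strict')")


def detect_fusions(
    table: HomologyTable, species: str, policy: str = "inclusive"
) -> list[Fusion]:
    """Find linkage groups that carry >= 2 PK arms in one species.

    ``inclusive`` keeps weak (``^``) and ambiguous (``*`` / ``or``) cells,
    provisionally taking the first alternative of an ``or`` cell; ``strict``
    drops every flagged cell.  ``not identified`` / ``missing`` never count.
    """
    if species not in table.species:
        raise ValueError(f"species {species!r} not in table (has {table.species})")
    by_lg: dict[str, set[PKArm]] = {}
    for arm in table.arms():
        assignment = table.rows[arm][species]
        if _usable(assignment, policy):
            by_lg.setdefault(assignment.lg_name, set()).add(arm)
    return [
        Fusion(species, lg, frozenset(arms))
        for lg, arms in sorted(by_lg.items())
        if len(arms) >= 2
    ]


def shared_fusions(
    table: HomologyTable, species_set: Iterable[str], policy: str = "inclusive"
) -> dict[tuple[PKArm, PKArm], set[str]]:
    """Map each fused (unordered) PK-arm pair to the species exhibiting it.

    A pair fused in every requested species is a shared fusion; a pair
    mapped to a singleton set is species-specific.
    """
    species_set = list(species_set)
    if not species_set:
        raise ValueError("need at least one species")
    pairs: dict[tuple[PKArm, PKArm], set[str]] = {}
    for sp in species_set:
        for fusion in detect_fusions(table, sp, policy):
            for pair in fusion.arm_pairs():
                pairs.setdefault(pair, set()).add(sp)
    return pairs


# --------------------------------------------------------------------------
# Linkage-map summary statistics


@dataclass
class LinkageMapSummary:
    """Per-linkage-group map summary (loci counts, cM lengths, LG type)."""

    records: pd.DataFrame

    REQUIRED = [
        "lg_name",
        "duplicated_loci",
        "nonduplicated_loci",
        "female_length_cM",
        "male_length_cM",
        "female_loci",
        "male_loci",
        "lg_type",
    ]

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")
        numeric = self.records[self.REQUIRED[1:7]]
        if (numeric < 0).any().any():
            raise ValueError("counts and lengths must be non-negative")


def read_linkage_map_summary(source) -> LinkageMapSummary:
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    return LinkageMapSummary(pd.read_csv(source, sep="\t"))


def summarize_linkage_map(
    summary: LinkageMapSummary,
    subset: str = "all",
    sex: str = "female",
    statistic: str = "total_length",
) -> float:
    """Aggregate a map summary over a subset of linkage groups.

    Linkage groups with zero loci for the requested sex are absent from that
    sex's map and are excluded before aggregating (the female cisco map has
    38 LGs, the male map 40).
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    frame = summary.records
    if subset != "all":
        if subset not in ("metacentric", "acrocentric"):
            raise ValueError(f"unknown subset {subset!r}")
        frame = frame[frame["lg_type"] == subset]
    frame = frame[frame[f"{sex}_loci"] > 0]
    if frame.empty:
        raise ValueError(f"no linkage groups left for subset={subset!r}, sex={sex!r}")
    length = frame[f"{sex}_length_cM"]
    loci = frame[f"{sex}_loci"]
    if statistic == "total_length":
        return float(length.sum())
    if statistic == "total_loci":
        return float(loci.sum())
    if statistic == "mean_length":
        return float(length.mean())
    if statistic == "mean_loci":
        return float(loci.mean())
    if statistic == "total_duplicated":
        return float(frame["duplicated_loci"].sum())
    raise ValueError(f"unknown statistic {statistic!r}")


def load_cisco_map_summary() -> LinkageMapSummary:
    """Published female/male cisco linkage-map summary (40 linkage groups)."""
    ref = resources.files("rediploid.data") / "cisco_linkage_map_summary.tsv"
    with ref.open("r") as fh:
        return read_linkage_map_summary(fh)


def load_coregonine_homology() -> HomologyTable:
    """Published six-species homology table keyed by PK arm (50 rows)."""
    ref = resources.files("rediploid.data") / "coregonine_homology_table.tsv"
    with ref.open("r") as fh:
        return parse_homology_table(fh)
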