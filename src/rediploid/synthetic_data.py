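"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate, at desk scale, the data a rediploidization study
consumes: homeologous chromosome-arm pairs diverging since a whole-genome
duplication, windowed alignment blocks between them, species panels of 25
protokaryotype (PK) pairs, homology tables with planted fusion histories,
and duplicated-marker sets concentrated on tetrasomic pairs.

The sequence model is deliberately minimal: an equal-rates (Jukes-Cantor
type) substitution process with no indels, so the two copies stay
positionally aligned and the expected identity after a per-lineage
divergence of d substitutions per site has the closed form

    E[identity] = 1/4 + 3/4 * exp(-8 d / 3),

which serves as an independent oracle for the simulator.  Residual
tetrasomy is modeled as homeologous-exchange tracts applied after
divergence: tract count ~ Poisson(exchange_rate), tract length ~
geometric(1/tract_mean), start positions uniform, each tract copying one
copy's segment over the other (direction by fair coin), which raises
identity toward 100% over the covered fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .homeolog_similarity import (
    AlignmentBlock,
    FilterParams,
    PairSimilarity,
    filter_blocks,
    weighted_median_similarity,
)
from .pk_homology import ArmAssignment, HomologyTable, PKArm, Status
from .linkage_support import DuplicatedMarkerSet, MarkerPlacement

__all__ = [
    "SimConfig",
    "SimulatedPair",
    "SimulatedPanel",
    "DEFAULT_TETRASOMIC_PKS",
    "expected_identity",
    "simulate_homeolog_pair",
    "apply_exchange_tracts",
    "windowed_identity",
    "simulate_panel",
    "panel_pair_similarities",
    "panel_arm_map",
    "simulate_homology_table",
    "simulate_duplicated_markers",
    "write_panel_fasta",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")

#: the eight PK pairs repeatedly classified tetrasomic from genome analyses
DEFAULT_TETRASOMIC_PKS = (1, 2, 9, 11, 20, 22, 23, 25)


@dataclass(frozen=True)
class SimConfig:
    """Panel-simulation parameters.

    ``subst_rate_per_site`` is the expected number of substitutions per site
    per lineage since the duplication (sets the disomic divergence;
    the default puts disomic identity at ~88%).  ``exchange_rate`` and
    ``tract_mean`` control tetrasomic homogenization (defaults cover ~78%
    of the arm, putting tetrasomic identity at ~97%); many short tracts
    keep the identity variance between tetrasomic pairs small.
    """

    chrom_length: int = 100_000
    subst_rate_per_site: float = 0.0654
    exchange_rate: float = 150.0
    tract_mean: float = 1_000.0
    n_pairs: int = 25
    n_tetrasomic: int = 8
    window: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subst_rate_per_site < 0 or self.exchange_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1")
        if not 0 <= self.n_tetrasomic <= self.n_pairs:
            raise ValueError("need 0 <= n_tetrasomic <= n_pairs")
        if self.window < 1 or self.chrom_length < 1:
            raise ValueError("window and chrom_length must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls(**yaml.safe_load(text))


@dataclass(frozen=True)
class SimulatedPair:
    pk: int
    seq_a: str
    seq_b: str
    true_label: str  # tetrasomic | disomic
    realized_identity: float  # percent


@dataclass(frozen=True)
class SimulatedPanel:
    species: str
    pairs: tuple[SimulatedPair, ...]
    config: SimConfig

    def true_labels(self) -> dict[int, str]:
        return {p.pk: p.true_label for p in self.pairs}


def expected_identity(subst_rate_per_site: float) -> float:
    """Closed-form expected percent identity of two copies diverged by
    ``subst_rate_per_site`` substitutions per site per lineage (equal-rates
    model): 100 * (1/4 + 3/4 * exp(-8 d / 3))."""
    return 100.0 * (0.25 + 0.75 * math.exp(-8.0 * subst_rate_per_site / 3.0))


def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One lineage of equal-rates substitution over branch length d.

    Drawing each site from the transition distribution (change with
    probability 3/4(1 - e^{-4d/3}), uniformly to another base) is exactly
    equivalent to accumulating Poissonian substitutions at rate d.
    """
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    mask = rng.random(seq.size) < p_change
    shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.int8)
    out[mask] = (out[mask] + shifts) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode("ascii")


def _to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    codes = np.searchsorted(_ALPHABET, arr)
    return codes.astype(np.int8)


def apply_exchange_tracts(
    pair: SimulatedPair, tracts: list[tuple[int, int, str]]
) -> SimulatedPair:
    """Copy homeologous-exchange tracts between the two copies.

    Each tract is ``(start, end, direction)`` with 0-based half-open
    coordinates; direction ``"a_to_b"`` overwrites B's segment with A's,
    ``"b_to_a"`` the reverse.  Applied in order; later tracts win overlaps.
    """
    a, b = _to_codes(pair.seq_a), _to_codes(pair.seq_b)
    for start, end, direction in tracts:
        start, end = max(0, start), min(a.size, end)
        if end <= start:
            continue
        if direction == "a_to_b":
            b[start:end] = a[start:end]
        elif direction == "b_to_a":
            a[start:end] = b[start:end]
        else:
            raise ValueError(f"unknown tract direction {direction!r}")
    return SimulatedPair(
        pk=pair.pk,
        seq_a=_to_str(a),
        seq_b=_to_str(b),
        true_label=pair.true_label,
        realized_identity=float(100.0 * np.mean(a == b)),
    )


def simulate_homeolog_pair(
    cfg: SimConfig, pk: int, label: str, seed: int
) -> SimulatedPair:
    """Simulate one homeolog pair under disomic or tetrasomic evolution.

    A uniform ancestral sequence diverges along two lineages at
    ``subst_rate_per_site``; tetrasomic pairs then receive exchange tracts
    that re-homogenize part of the sequence.
    """
    if label not in ("tetrasomic", "disomic"):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=cfg.chrom_length, dtype=np.int8)
    a = _mutate(ancestor, cfg.subst_rate_per_site, rng)
    b = _mutate(ancestor, cfg.subst_rate_per_site, rng)
    pair = SimulatedPair(
        pk=pk,
        seq_a=_to_str(a),
        seq_b=_to_str(b),
        true_label=label,
        realized_identity=float(100.0 * np.mean(a == b)),
    )
    if label == "tetrasomic" and cfg.exchange_rate > 0:
        n_tracts = int(rng.poisson(cfg.exchange_rate))
        tracts = []
        for _ in range(n_tracts):
            length = int(rng.geometric(1.0 / cfg.tract_mean))
            start = int(rng.integers(0, cfg.chrom_length))
            direction = "a_to_b" if rng.random() < 0.5 else "b_to_a"
            tracts.append((start, start + length, direction))
        pair = apply_exchange_tracts(pair, tracts)
    return pair


def windowed_identity(pair: SimulatedPair, window: int) -> list[AlignmentBlock]:
    """Tile the pair into non-overlapping windows of per-window identity.

    Stands in for whole-arm aligner output: each full window becomes one
    alignment block (identity = matches/window * 100); the final partial
    window is dropped.
    """
    a, b = _to_codes(pair.seq_a), _to_codes(pair.seq_b)
    if window > a.size:
        raise ValueError(f"window {window} exceeds sequence length {a.size}")
    n_win = a.size // window
    matches = (a[: n_win * window] == b[: n_win * window]).reshape(n_win, window)
    identities = matches.sum(axis=1) / window * 100.0
    query = f"PK{pair.pk:02d}.1"
    target = f"PK{pair.pk:02d}.2"
    return [
        AlignmentBlock(
            query=query,
            target=target,
            query_start=i * window,
            query_end=(i + 1) * window,
            target_start=i * window,
            target_end=(i + 1) * window,
            strand="+",
            length=window,
            identity_pct=float(identities[i]),
        )
        for i in range(n_win)
    ]


def simulate_panel(
    cfg: SimConfig,
    species: str = "Sim",
    tetrasomic_pks: tuple[int, ...] | str | None = None,
) -> SimulatedPanel:
    """Simulate a species panel of ``n_pairs`` homeolog pairs.

    Tetrasomic labels default to the eight PK pairs recurrently found
    tetrasomic in salmonid genome analyses (truncated or padded to
    ``n_tetrasomic``); pass ``"random"`` to draw them instead.  Per-pair
    seeds are derived from the master seed, so the panel is byte-identical
    for equal (config, seed).
    """
    ss = np.random.SeedSequence(cfg.seed)
    pk_ids = list(range(1, cfg.n_pairs + 1))
    if tetrasomic_pks == "random":
        rng = np.random.default_rng(ss.spawn(1)[0])
        chosen = set(rng.choice(pk_ids, size=cfg.n_tetrasomic, replace=False).tolist())
    elif tetrasomic_pks is None:
        chosen = set(pk for pk in DEFAULT_TETRASOMIC_PKS if pk <= cfg.n_pairs)
        for pk in pk_ids:  # pad deterministically if n_tetrasomic > default set
            if len(chosen) >= cfg.n_tetrasomic:
                break
            chosen.add(pk)
        chosen = set(sorted(chosen)[: cfg.n_tetrasomic])
    else:
        chosen = set(tetrasomic_pks)
        if len(chosen) != cfg.n_tetrasomic:
            raise ValueError("tetrasomic_pks must contain n_tetrasomic distinct PKs")
    pair_seeds = ss.generate_state(cfg.n_pairs + 1)[1:]
    pairs = tuple(
        simulate_homeolog_pair(
            cfg,
            pk,
            "tetrasomic" if pk in chosen else "disomic",
            int(pair_seeds[i]),
        )
        for i, pk in enumerate(pk_ids)
    )
    return SimulatedPanel(species=species, pairs=pairs, config=cfg)


def panel_pair_similarities(
    panel: SimulatedPanel,
    params: FilterParams | None = None,
    window: int | None = None,
) -> list[PairSimilarity]:
    """Windowed blocks -> filter -> weighted median, for every pair."""
    window = window or panel.config.window
    if params is None:
        params = FilterParams(min_identity=75.0, min_length=min(1000, window))
    out = []
    for pair in panel.pairs:
        blocks = filter_blocks(windowed_identity(pair, window), params)
        if not blocks:
            raise ValueError(f"no alignment blocks survive filtering for PK {pair.pk}")
        out.append(
            weighted_median_similarity(blocks, species=panel.species, pk=pair.pk)
        )
    return out


# --------------------------------------------------------------------------
# Homology tables with planted fusion histories


def _root_to_tip_paths(species_tree: list[tuple[str, str | None]]):
    parent = {child: par for child, par in species_tree}
    children = {par for _, par in species_tree if par is not None}
    tips = [node for node, _ in species_tree if node not in children]
    paths = {}
    for tip in tips:
        path, node = [], tip
        while node is not None:
            path.append(node)
            node = parent.get(node)
        paths[tip] = path  # tip .. root
    return paths


def simulate_homology_table(
    species_tree: list[tuple[str, str | None]],
    fusion_events: list[tuple[str, tuple]],
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> HomologyTable:
    """Plant a fusion history on a species tree and emit the homology table.

    ``species_tree`` lists (node, parent) edges with ``None`` for the root;
    leaves become species columns.  Each fusion event ``(branch, (arm_x,
    arm_y))`` is inherited by every species whose root-to-tip path crosses
    that branch; fused arms share an LG name with a/b tags.  ``dropout_rate``
    converts assignments to ``not identified`` independently at that rate.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    paths = _root_to_tip_paths(species_tree)
    events = [
        (branch, (PKArm.parse(str(x)) if not isinstance(x, PKArm) else x,
                  PKArm.parse(str(y)) if not isinstance(y, PKArm) else y))
        for branch, (x, y) in fusion_events
    ]
    all_arms = [PKArm(pk, arm) for pk in range(1, 26) for arm in (1, 2)]
    rows: dict[PKArm, dict[str, ArmAssignment]] = {arm: {} for arm in all_arms}
    tips = list(paths)
    for tip in tips:
        on_path = [pair for branch, pair in events if branch in paths[tip]]
        seen: set[PKArm] = set()
        for x, y in on_path:
            if x in seen or y in seen or x == y:
                raise ValueError(
                    f"conflicting fusions on the path to {tip}: arm reused"
                )
            seen.update((x, y))
        fused: dict[PKArm, tuple[str, str]] = {}
        lg_index = 0
        for x, y in sorted(on_path, key=lambda p: min(p)):
            lg_index += 1
            lg = f"{tip}{lg_index:02d}"
            first, second = sorted((x, y))
            fused[first] = (lg, "a")
            fused[second] = (lg, "b")
        for arm in all_arms:
            if dropout_rate and rng.random() < dropout_rate:
                rows[arm][tip] = ArmAssignment(tip, absent=Status.NOT_IDENTIFIED)
                continue
            if arm in fused:
                lg, tag = fused[arm]
            else:
                lg_index += 1
                lg, tag = f"{tip}{lg_index:02d}", None
            rows[arm][tip] = ArmAssignment(
                tip, lg_name=lg, arm_tag=tag, alternatives=(lg + (tag or ""),)
            )
    return HomologyTable(rows=rows, species=tips)


# --------------------------------------------------------------------------
# Duplicated markers


def panel_arm_map(panel: SimulatedPanel) -> dict[str, PKArm]:
    """LG-arm name -> PK arm for the synthetic map underlying a panel."""
    out = {}
    for pair in panel.pairs:
        out[f"{panel.species}{pair.pk:02d}a"] = PKArm(pair.pk, 1)
        out[f"{panel.species}{pair.pk:02d}b"] = PKArm(pair.pk, 2)
    return out


def simulate_duplicated_markers(
    panel: SimulatedPanel,
    markers_per_tetrasomic: float = 60.0,
    markers_per_disomic: float = 3.0,
    seed: int = 0,
) -> DuplicatedMarkerSet:
    """Draw both-paralog duplicated markers concentrated on tetrasomic pairs.

    Per-PK marker counts are Poisson with the label's mean; each marker is
    placed at uniform cM positions on the PK's two arms (LG names as in
    :func:`panel_arm_map`).
    """
    if markers_per_tetrasomic < 0 or markers_per_disomic < 0:
        raise ValueError("marker means must be >= 0")
    rng = np.random.default_rng(seed)
    records: dict[str, list[MarkerPlacement]] = {}
    for pair in sorted(panel.pairs, key=lambda p: p.pk):
        mean = (
            markers_per_tetrasomic
            if pair.true_label == "tetrasomic"
            else markers_per_disomic
        )
        n = int(rng.poisson(mean))
        for j in range(n):
            marker = f"{panel.species}_pk{pair.pk:02d}_m{j:04d}"
            records[marker] = [
                MarkerPlacement(marker, f"{panel.species}{pair.pk:02d}a",
                                float(rng.uniform(0.0, 100.0))),
                MarkerPlacement(marker, f"{panel.species}{pair.pk:02d}b",
                                float(rng.uniform(0.0, 100.0))),
            ]
    return DuplicatedMarkerSet(records)


def write_panel_fasta(panel: SimulatedPanel, path) -> None:
    """Write both copies of every pair as FASTA (ids ``<species>_PKNN.{1,2}``)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for pair in panel.pairs:
        records.append(
            SeqRecord(Seq(pair.seq_a), id=f"{panel.species}_PK{pair.pk:02d}.1",
                      description=pair.true_label)
        )
        records.append(
            SeqRecord(Seq(pair.seq_b), id=f"{panel.species}_PK{pair.pk:02d}.2",
                      description=pair.true_label)
        )
    seqio_write(records, path, "fasta")
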