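"""Tetrasomic vs disomic classification of homeolog pairs.

Homeolog pairs still undergoing tetrasomic (multivalent) meiosis keep high
sequence identity through ongoing homeologous exchange, while rediploidized
(disomic) pairs diverge.  Rather than a hand-picked identity cutoff, each
species' pairs are classified with an extreme-anchored k-nearest-neighbor
rule: the four highest-similarity pairs anchor the tetrasomic class, the
four lowest anchor the disomic class, and every remaining pair is labeled by
majority vote of its k nearest anchors in weighted-median-identity space.
k is chosen by repeated stratified cross-validation; with 4 anchors per
class and k = 5 the attainable winning vote proportions are exactly 3/5 and
4/5, so a 0.6 vote marks an intermediate pair.  A Wilcoxon rank-sum test on
alignment-level identities checks that the two predicted classes differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .homeolog_similarity import PairSimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorSet",
    "CVConfig",
    "ClassificationResult",
    "WilcoxonResult",
    "build_anchor_set",
    "knn_classify",
    "cross_validate_k",
    "select_k",
    "wilcoxon_rank_sum",
    "TetrasomyKNN",
    "TetrasomyResults",
]

TETRASOMIC = "tetrasomic"
DISOMIC = "disomic"
N_ANCHORS_PER_CLASS = 4


@dataclass(frozen=True)
class AnchorSet:
    """Training exemplars: the 4 most and 4 least similar homeolog pairs."""

    tetrasomic_anchors: tuple[tuple[int, float], ...]  # (pk, weighted_median)
    disomic_anchors: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        tet = {pk for pk, _ in self.tetrasomic_anchors}
        dis = {pk for pk, _ in self.disomic_anchors}
        if tet & dis:
            raise ValueError(f"anchor classes overlap on pk(s) {sorted(tet & dis)}")
        if self.tetrasomic_anchors and self.disomic_anchors:
            if min(m for _, m in self.tetrasomic_anchors) < max(
                m for _, m in self.disomic_anchors
            ):
                raise ValueError("tetrasomic anchors must dominate disomic anchors")

    @property
    def pks(self) -> set[int]:
        return {pk for pk, _ in self.tetrasomic_anchors + self.disomic_anchors}

    def labeled(self) -> list[tuple[float, str, int]]:
        """(median, class, pk) for every anchor."""
        return [(m, TETRASOMIC, pk) for pk, m in self.tetrasomic_anchors] + [
            (m, DISOMIC, pk) for pk, m in self.disomic_anchors
        ]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for choosing k."""

    k_grid: tuple[int, ...] = tuple(range(1, 11))
    n_folds: int = 10
    n_repeats: int = 100
    seed: int = 0
    alpha: float = 0.01
    mode: str = "provisional"  # or "anchors_only"

    def __post_init__(self) -> None:
        if not all(1 <= k <= 10 for k in self.k_grid):
            raise ValueError("k_grid must lie within 1..10")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.mode not in ("provisional", "anchors_only"):
            raise ValueError(f"unknown CV mode {self.mode!r}")


@dataclass(frozen=True)
class ClassificationResult:
    pk: int
    label: str  # tetrasomic | disomic | anchor_tetrasomic | anchor_disomic
    votes_for_label: int
    vote_proportion: float
    tie_flagged: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of group A
    p_value: float
    n_a: int
    n_b: int
    method: str  # exact | normal_approx
    alpha: float
    significant: bool


def build_anchor_set(summaries: list[PairSimilarity]) -> AnchorSet:
    """Anchor the classes on the 4 highest and 4 lowest weighted medians.

    Ties at either cut are broken by ascending PK number.
    """
    if len(summaries) < 2 * N_ANCHORS_PER_CLASS + 1:
        raise ValueError(
            f"need at least {2 * N_ANCHORS_PER_CLASS + 1} pairs, got {len(summaries)}"
        )
    top = sorted(summaries, key=lambda s: (-s.weighted_median, s.pk))
    bottom = sorted(summaries, key=lambda s: (s.weighted_median, s.pk))
    tet = tuple((s.pk, s.weighted_median) for s in top[:N_ANCHORS_PER_CLASS])
    dis = tuple((s.pk, s.weighted_median) for s in bottom[:N_ANCHORS_PER_CLASS])
    return AnchorSet(tetrasomic_anchors=tet, disomic_anchors=dis)


def _vote(value: float, exemplars: list[tuple[float, str, int]], k: int):
    """Majority vote among the k nearest exemplars of ``value``.

    Distance ties are resolved by a stable sort on (distance, pk); a 50/50
    vote falls to the disomic class (the conservative call, tetrasomy being
    the positive claim) and is flagged.
    """
    ranked = sorted(exemplars, key=lambda e: (abs(e[0] - value), e[2]))[:k]
    tet_votes = sum(1 for _, lab, _ in ranked if lab == TETRASOMIC)
    dis_votes = k - tet_votes
    if tet_votes > dis_votes:
        return TETRASOMIC, tet_votes, False
    if dis_votes > tet_votes:
        return DISOMIC, dis_votes, False
    return DISOMIC, dis_votes, True


def knn_classify(
    summaries: list[PairSimilarity], anchors: AnchorSet, k: int
) -> list[ClassificationResult]:
    """Label every pair by majority vote of its k nearest anchors.

    Anchors are reported with ``anchor_*`` labels; their vote fields are
    computed against the other anchors only (an anchor never votes on
    itself).  Results are ordered by PK number.
    """
    exemplars = anchors.labeled()
    if not 1 <= k <= len(exemplars):
        raise ValueError(f"k must lie in 1..{len(exemplars)}, got {k}")
    anchor_class = {pk: lab for _, lab, pk in exemplars}
    results = []
    for s in sorted(summaries, key=lambda s: s.pk):
        if s.pk in anchor_class:
            own = anchor_class[s.pk]
            others = [e for e in exemplars if e[2] != s.pk]
            kk = min(k, len(others))
            ranked = sorted(others, key=lambda e: (abs(e[0] - s.weighted_median), e[2]))[:kk]
            own_votes = sum(1 for _, lab, _ in ranked if lab == own)
            results.append(
                ClassificationResult(
                    pk=s.pk,
                    label=f"anchor_{own}",
                    votes_for_label=own_votes,
                    vote_proportion=own_votes / kk,
                )
            )
        else:
            label, votes, tie = _vote(s.weighted_median, exemplars, k)
            results.append(
                ClassificationResult(
                    pk=s.pk,
                    label=label,
                    votes_for_label=votes,
                    vote_proportion=votes / k,
                    tie_flagged=tie,
                )
            )
    return results


def _provisional_labels(
    summaries: list[PairSimilarity], anchors: AnchorSet
) -> list[tuple[float, str, int]]:
    """Label every pair by the nearer anchor-class median (anchors keep theirs)."""
    tet_center = float(np.median([m for _, m in anchors.tetrasomic_anchors]))
    dis_center = float(np.median([m for _, m in anchors.disomic_anchors]))
    anchor_class = {pk: lab for _, lab, pk in anchors.labeled()}
    out = []
    for s in sorted(summaries, key=lambda s: s.pk):
        if s.pk in anchor_class:
            lab = anchor_class[s.pk]
        elif abs(s.weighted_median - tet_center) < abs(s.weighted_median - dis_center):
            lab = TETRASOMIC
        else:
            lab = DISOMIC
        out.append((s.weighted_median, lab, s.pk))
    return out


def _stratified_folds(labels: list[str], n_folds: int, rng: np.random.Generator):
    """Deal shuffled within-class indices round-robin into n_folds folds."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        idx = list(rng.permutation(idx))
        for j, i in enumerate(idx):
            folds[j % n_folds].append(i)
    return [f for f in folds if f]


def cross_validate_k(
    summaries: list[PairSimilarity], anchors: AnchorSet, cfg: CVConfig = CVConfig()
) -> pd.DataFrame:
    """Mean kNN accuracy for each k by repeated stratified k-fold CV.

    In the default ``provisional`` mode every pair first receives a
    provisional label from the nearer anchor-class median, and CV runs over
    all pairs: each test fold is classified by its k nearest neighbors among
    the training-fold pairs.  ``anchors_only`` restricts the CV to the eight
    anchors (folds capped accordingly).  Fold shuffles are drawn from
    per-repeat substreams of the master seed, so changing ``n_repeats`` does
    not perturb earlier repeats.
    """
    if cfg.mode == "provisional":
        items = _provisional_labels(summaries, anchors)
    else:
        items = anchors.labeled()
    labels = [lab for _, lab, _ in items]
    minority = min(labels.count(TETRASOMIC), labels.count(DISOMIC))
    n_folds = cfg.n_folds
    if minority < n_folds:
        logger.warning(
            "minority class has %d members < %d folds; reducing folds to %d",
            minority,
            n_folds,
            minority,
        )
        n_folds = max(2, minority)
    correct = {k: 0 for k in cfg.k_grid}
    total = {k: 0 for k in cfg.k_grid}
    for repeat in range(cfg.n_repeats):
        rng = np.random.default_rng([cfg.seed, repeat])
        folds = _stratified_folds(labels, n_folds, rng)
        for fold in folds:
            train = [items[i] for i in range(len(items)) if i not in fold]
            for i in fold:
                value, truth, _ = items[i]
                for k in cfg.k_grid:
                    kk = min(k, len(train))
                    pred, _, _ = _vote(value, train, kk)
                    correct[k] += pred == truth
                    total[k] += 1
    return pd.DataFrame(
        {
            "k": list(cfg.k_grid),
            "accuracy": [correct[k] / total[k] for k in cfg.k_grid],
        }
    )


def select_k(
    summaries: list[PairSimilarity], anchors: AnchorSet, cfg: CVConfig = CVConfig()
) -> int:
    """The largest k among those attaining the maximal mean CV accuracy."""
    table = cross_validate_k(summaries, anchors, cfg)
    best = table["accuracy"].max()
    tied = table.loc[table["accuracy"] >= best - 1e-12, "k"]
    return int(tied.max())


def wilcoxon_rank_sum(
    group_a, group_b, alpha: float = 0.01
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact null enumeration when n_a + n_b <= 20 and the pooled sample
    is tie-free, and the tie-corrected normal approximation with continuity
    correction otherwise.  The reported statistic is the rank sum of group A.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 20 and no_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    ranks = stats.rankdata(pooled)
    statistic = float(ranks[: a.size].sum())
    p = float(min(res.pvalue, 1.0))
    return WilcoxonResult(
        statistic=statistic,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
        alpha=alpha,
        significant=p < alpha,
    )


# --------------------------------------------------------------------------
# Model / Results front-end


class TetrasomyKNN:
    """Extreme-anchored kNN inheritance-mode model for one species' panel.

    Parameters
    ----------
    summaries
        One :class:`PairSimilarity` per homeolog pair (single species).
    alignment_identities
        Optional mapping ``pk -> array of block identities`` used for the
        class-contrast Wilcoxon test.
    """

    def __init__(
        self,
        summaries: list[PairSimilarity],
        alignment_identities: dict[int, np.ndarray] | None = None,
    ):
        self.summaries = sorted(summaries, key=lambda s: s.pk)
        self.alignment_identities = alignment_identities
        self.anchors = build_anchor_set(self.summaries)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, species: str = "", **kwargs):
        """Build from a DataFrame with columns pk, weighted_median[, n_blocks, total_aligned]."""
        summaries = [
            PairSimilarity(
                species=species,
                pk=int(r.pk),
                weighted_median=float(r.weighted_median),
                n_blocks=int(getattr(r, "n_blocks", 1)),
                total_aligned=int(getattr(r, "total_aligned", 0)),
            )
            for r in frame.itertuples()
        ]
        return cls(summaries, **kwargs)

    def fit(self, k: int | str = "auto", cv: CVConfig = CVConfig()) -> "TetrasomyResults":
        """Classify every pair; ``k="auto"`` first selects k by CV.

        The CV grid extends to 10, but classification voting draws on the 8
        anchors only, so a selected k above 8 is capped at the anchor count.
        """
        cv_table = None
        if k == "auto":
            cv_table = cross_validate_k(self.summaries, self.anchors, cv)
            best = cv_table["accuracy"].max()
            k = int(cv_table.loc[cv_table["accuracy"] >= best - 1e-12, "k"].max())
        k = min(int(k), len(self.anchors.labeled()))
        classifications = knn_classify(self.summaries, self.anchors, int(k))
        wilcoxon = None
        if self.alignment_identities is not None:
            label_of = {c.pk: c.label.removeprefix("anchor_") for c in classifications}
            tet = np.concatenate(
                [
                    np.asarray(v, dtype=float)
                    for pk, v in self.alignment_identities.items()
                    if label_of.get(pk) == TETRASOMIC
                ]
                or [np.array([])]
            )
            dis = np.concatenate(
                [
                    np.asarray(v, dtype=float)
                    for pk, v in self.alignment_identities.items()
                    if label_of.get(pk) == DISOMIC
                ]
                or [np.array([])]
            )
            if tet.size and dis.size:
                wilcoxon = wilcoxon_rank_sum(tet, dis, alpha=cv.alpha)
        return TetrasomyResults(
            model=self, k=int(k), classifications=classifications,
            cv_table=cv_table, wilcoxon=wilcoxon,
        )


@dataclass
class TetrasomyResults:
    """Fitted classification: labels, vote proportions, k table, contrast test."""

    model: TetrasomyKNN
    k: int
    classifications: list[ClassificationResult]
    cv_table: pd.DataFrame | None = None
    wilcoxon: WilcoxonResult | None = None

    def frame(self) -> pd.DataFrame:
        medians = {s.pk: s.weighted_median for s in self.model.summaries}
        return pd.DataFrame(
            [
                {
                    "pk": c.pk,
                    "weighted_median": medians[c.pk],
                    "label": c.label,
                    "votes_for_label": c.votes_for_label,
                    "vote_proportion": c.vote_proportion,
                    "tie_flagged": c.tie_flagged,
                }
                for c in self.classifications
            ]
        )

    def tetrasomic_pks(self) -> list[int]:
        return [
            c.pk
            for c in self.classifications
            if c.label in (TETRASOMIC, f"anchor_{TETRASOMIC}")
        ]

    def summary(self) -> str:
        lines = [
            "Tetrasomy kNN classification",
            f"  pairs: {len(self.classifications)}   k: {self.k}",
            f"  tetrasomic: {sorted(self.tetrasomic_pks())}",
        ]
        if self.cv_table is not None:
            acc = ", ".join(
                f"k={int(r.k)}:{r.accuracy:.3f}" for r in self.cv_table.itertuples()
            )
            lines.append(f"  CV accuracy: {acc}")
        if self.wilcoxon is not None:
            w = self.wilcoxon
            lines.append(
                f"  Wilcoxon rank-sum: W={w.statistic:.1f}, p={w.p_value:.3g} "
                f"({w.method}, n={w.n_a}/{w.n_b}, "
                f"{'significant' if w.significant else 'not significant'} "
                f"at alpha={w.alpha})"
            )
        return "\n".join(lines)

    def plot_similarity(self, ax=None):
        """Scatter of weighted medians ordered by rank, colored by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.frame().sort_values("weighted_median", ascending=False)
        colors = [
            "tab:purple" if lab.endswith(TETRASOMIC) else "tab:olive"
            for lab in frame["label"]
        ]
        ax.scatter(range(1, len(frame) + 1), frame["weighted_median"], c=colors)
        for x, (_, row) in enumerate(frame.iterrows(), start=1):
            ax.annotate(str(int(row["pk"])), (x, row["weighted_median"]),
                        fontsize=7, xytext=(0, 4), textcoords="offset points")
        ax.set_xlabel("similarity rank")
        ax.set_ylabel("weighted median identity (%)")
        return ax
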