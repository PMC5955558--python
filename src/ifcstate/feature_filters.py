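"""Filter-based feature scoring and ranking.

Filters score each feature by intrinsic statistics of the labeled data,
independently of any classifier, and are cheap enough to rerun inside
every cross-validation fold.  Three schemes are provided:

* **MIM** (mutual information maximization) — univariate; scores each
  feature by the mutual information between its discretized values and
  the class labels,

  .. math:: I(\\chi_i, c) = \\sum_j \\sum_k P(\\chi_{i,j}, c_k)
            \\log_2 \\frac{P(\\chi_{i,j}, c_k)}{P(\\chi_{i,j}) P(c_k)}.

* **mRMR** (maximum relevance, minimum redundancy) — multivariate greedy
  selection; after seeding with the MIM winner, each step adds the
  feature maximizing relevance minus mean redundancy to the already
  selected set ``S``:

  .. math:: \\Theta(\\chi_i, c) = I(\\chi_i, c)
            - \\frac{1}{|S|} \\sum_{s \\in S} I(\\chi_s, \\chi_i).

* **Fisher score** — univariate ratio of between-class mean scatter to
  within-class variance,

  .. math:: \\Psi_i = \\frac{\\sum_k m_k (\\mu_{i,k} - \\mu_i)^2}
            {\\sum_k m_k \\sigma_{i,k}^2}.

Mutual information is estimated by the plug-in formula on equal-frequency
(quantile) bins, which makes MIM rankings invariant under any strictly
increasing per-feature transform — a useful property for heavy-tailed
fluorescence intensities.  Scores are reported in bits (log base 2; the
base rescales scores but never reorders them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .feature_table import FeatureTable

logger = logging.getLogger("ifcstate")

__all__ = [
    "FilterRanking",
    "ClassStatistics",
    "discretize",
    "mutual_information",
    "mim_rank",
    "mrmr_rank",
    "fisher_rank",
    "rank_features",
    "select_top",
]

#: sentinel score for a feature that is constant within every class yet
#: differs between classes — perfectly discriminative, ranked first
FISHER_INF_SENTINEL = 1e12


@dataclass
class FilterRanking:
    """Per-feature scores and the resulting rank order (best first).

    For mRMR, ``scores`` holds the selection-step score of each selected
    feature (the MIM score for the first) and the plain MIM score for
    features beyond ``n_select``; ``order`` lists selected features in
    selection sequence with the remainder appended by MIM score, so that
    ``select_top`` works for any requested subset size.
    """

    method: str
    feature_names: list[str]
    scores: np.ndarray
    order: np.ndarray
    params: dict = field(default_factory=dict)

    def top_names(self, n_fs: int) -> list[str]:
        return [self.feature_names[i] for i in select_top(self, n_fs)]


@dataclass
class ClassStatistics:
    """Per-class counts, means and standard deviations of every feature."""

    class_names: list[str]
    counts: np.ndarray  # (n_c,)
    class_means: np.ndarray  # (n_c, n)
    class_stds: np.ndarray  # (n_c, n), population form (ddof=0)
    overall_means: np.ndarray  # (n,)

    @classmethod
    def from_table(cls, table: FeatureTable) -> "ClassStatistics":
        if table.labels is None:
            raise ValueError("class statistics require labels")
        X = table.values
        means, stds, counts = [], [], []
        for c in table.class_names:
            mask = table.labels == c
            counts.append(int(mask.sum()))
            means.append(X[mask].mean(axis=0))
            stds.append(X[mask].std(axis=0, ddof=0))
        return cls(
            class_names=list(table.class_names),
            counts=np.asarray(counts),
            class_means=np.vstack(means),
            class_stds=np.vstack(stds),
            overall_means=X.mean(axis=0),
        )


def discretize(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency (quantile) binning into indices ``0 .. n_bins-1``.

    Bin edges are the ``j/n_bins`` quantiles; equal values always land in
    the same bin, so a constant vector maps entirely to bin 0 and any
    strictly increasing transform of the values yields identical indices.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    values = np.asarray(values, dtype=float)
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, values, side="left").astype(np.intp)


def _codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(np.asarray(x), return_inverse=True)
    return codes, int(codes.max()) + 1 if codes.size else 0


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Empty joint cells contribute zero (the ``0 log 0 := 0`` convention);
    the estimate is non-negative and symmetric in its arguments.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("length mismatch between the two variables")
    m = a.size
    if m == 0:
        raise ValueError("empty input")
    ca, na = _codes(a)
    cb, nb = _codes(b)
    joint = np.zeros((na, nb))
    np.add.at(joint, (ca, cb), 1.0)
    joint /= m
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))
    return max(mi, 0.0)  # clip tiny negative rounding


def _require_labels(table: FeatureTable) -> None:
    if table.labels is None:
        raise ValueError("filter ranking requires class labels")


def _ordered(scores: np.ndarray) -> np.ndarray:
    # descending score, ties by ascending feature index (stable sort on -score)
    return np.argsort(-scores, kind="stable")


def mim_rank(table: FeatureTable, n_bins: int = 10) -> FilterRanking:
    """Rank every feature by its mutual information with the class labels."""
    _require_labels(table)
    scores = np.array(
        [
            mutual_information(discretize(table.values[:, i], n_bins), table.labels)
            for i in range(table.n)
        ]
    )
    return FilterRanking(
        method="MIM",
        feature_names=list(table.feature_names),
        scores=scores,
        order=_ordered(scores),
        params={"n_bins": n_bins, "binning": "quantile"},
    )


def mrmr_rank(
    table: FeatureTable, n_bins: int = 10, n_select: int | None = None
) -> FilterRanking:
    """Greedy maximum-relevance minimum-redundancy selection.

    The first feature is the MIM winner; each subsequent step adds the
    candidate maximizing relevance minus the mean mutual information to
    the features already selected (both features discretized on their own
    quantile grids).  Features beyond ``n_select`` are appended in MIM
    order so any ``select_top`` size is well defined.
    """
    _require_labels(table)
    n = table.n
    if n_select is None:
        n_select = n
    if not 1 <= n_select <= n:
        raise ValueError("n_select out of range")

    disc = np.column_stack(
        [discretize(table.values[:, i], n_bins) for i in range(n)]
    )
    relevance = np.array(
        [mutual_information(disc[:, i], table.labels) for i in range(n)]
    )
    mim_order = _ordered(relevance)

    selected: list[int] = [int(mim_order[0])]
    step_scores = np.full(n, np.nan)
    step_scores[selected[0]] = relevance[selected[0]]
    redundancy_sum = np.zeros(n)  # sum over selected of I(feature_s, feature_i)

    ff_mi = {}  # cache of feature-feature MI, keyed by (min, max)

    def pair_mi(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in ff_mi:
            ff_mi[key] = mutual_information(disc[:, key[0]], disc[:, key[1]])
        return ff_mi[key]

    while len(selected) < n_select:
        last = selected[-1]
        remaining = [i for i in range(n) if i not in selected]
        for i in remaining:
            redundancy_sum[i] += pair_mi(last, i)
        theta = relevance[remaining] - redundancy_sum[remaining] / len(selected)
        # argmax with ties to the lowest original feature index
        best = remaining[int(np.argmax(theta))]
        step_scores[best] = relevance[best] - redundancy_sum[best] / len(selected)
        selected.append(best)

    rest = [int(i) for i in mim_order if i not in selected]
    for i in rest:
        step_scores[i] = relevance[i]
    order = np.array(selected + rest, dtype=np.intp)
    return FilterRanking(
        method="MRMR",
        feature_names=list(table.feature_names),
        scores=step_scores,
        order=order,
        params={"n_bins": n_bins, "binning": "quantile", "n_select": n_select},
    )


def fisher_rank(table: FeatureTable) -> FilterRanking:
    """Rank features by the Fisher score.

    Class variances use the population form (ddof=0).  A feature constant
    within every class scores 0 when the class means also coincide, and a
    large sentinel (ranked first) when they differ — such a feature is
    perfectly discriminative.
    """
    _require_labels(table)
    stats = ClassStatistics.from_table(table)
    for c, mk in zip(stats.class_names, stats.counts):
        if mk < 2:
            raise ValueError(f"class '{c}' has fewer than 2 members")
    mk = stats.counts[:, None].astype(float)
    numerator = np.sum(mk * (stats.class_means - stats.overall_means) ** 2, axis=0)
    denominator = np.sum(mk * stats.class_stds**2, axis=0)
    zero_den = denominator <= 0
    scores = np.zeros(table.n)
    ok = ~zero_den
    scores[ok] = numerator[ok] / denominator[ok]
    degenerate = zero_den & (numerator > 0)
    if degenerate.any():
        logger.warning(
            "%d feature(s) constant within classes but differing between "
            "them; assigned sentinel Fisher score",
            degenerate.sum(),
        )
        scores[degenerate] = FISHER_INF_SENTINEL
    return FilterRanking(
        method="Fisher",
        feature_names=list(table.feature_names),
        scores=scores,
        order=_ordered(scores),
        params={},
    )


def rank_features(
    table: FeatureTable, method: str, n_bins: int = 10
) -> FilterRanking:
    """Dispatch to one of the ranking schemes by name (MIM/MRMR/Fisher)."""
    method_u = method.upper()
    if method_u == "MIM":
        return mim_rank(table, n_bins)
    if method_u == "MRMR":
        return mrmr_rank(table, n_bins)
    if method_u == "FISHER":
        return fisher_rank(table)
    raise ValueError(f"unknown filter method: {method}")


def select_top(ranking: FilterRanking, n_fs: int) -> list[int]:
    """The ``n_fs`` best-ranked feature indices, best first."""
    if not 1 <= n_fs <= len(ranking.order):
        raise ValueError(
            f"n_fs must be in 1..{len(ranking.order)}, got {n_fs}"
        )
    return [int(i) for i in ranking.order[:n_fs]]
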