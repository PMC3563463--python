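"""AdaBoost-based feature ranking with single-feature decision stumps.

Each boosting iteration evaluates every feature as a threshold stump
(both polarities), selects the one with the lowest weighted error
``eps_t``, assigns it the weight ``alpha_t = 0.5 * ln((1 - eps_t) /
eps_t)`` and re-weights the samples multiplicatively so later iterations
focus on the samples the selected stumps misclassify.  Summing ``alpha``
per feature over iterations (and, across repeated trials, over trials)
yields a ranking of features by discriminative power for a binary task.

A feature may be selected at several iterations; its alphas accumulate.
The reported ranking is sorted by cumulative weight (ties broken
lexicographically by feature name), so weights are non-increasing in
rank by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, TrainingError

__all__ = [
    "RankedFeature",
    "BoostingTrace",
    "adaboost_rank",
    "rank_across_trials",
    "rank_binary_task",
]

_EPS_CLAMP = 1e-10


@dataclass(frozen=True)
class RankedFeature:
    name: str
    weight: float  # cumulative alpha over selections (and trials)
    rank: int  # 1 = highest cumulative weight


@dataclass
class BoostingTrace:
    """Per-iteration details kept for inspection and invariant checks."""

    features: list[int] = field(default_factory=list)
    thresholds: list[float] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)
    weight_sums: list[float] = field(default_factory=list)  # after each update


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Lowest weighted-error threshold stump over all features.

    Returns ``(feature, threshold, polarity, error, predictions)`` where
    ``polarity=+1`` predicts positive for values strictly above the
    threshold and ``polarity=-1`` for values at or below it.
    """
    n, d = X.shape
    best = (0, -np.inf, 1, np.inf, None)
    total_pos = float(np.sum(w[y == 1]))
    for f in range(d):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs, ys, ws = x[order], y[order], w[order]
        # error of "positive above t" with t below all samples: all predicted 1
        # err = sum of weights of negatives
        werr_pos_above = float(np.sum(ws[ys == 0]))
        # moving the threshold past sample i flips its prediction to 0
        flip = np.where(ys == 1, ws, -ws)
        errs_above = werr_pos_above + np.cumsum(flip)
        # candidate thresholds: midpoints between distinct consecutive values
        distinct = np.empty(n, dtype=bool)
        distinct[:-1] = xs[:-1] < xs[1:]
        distinct[-1] = False  # threshold above all values = predict all 0
        cand = np.flatnonzero(distinct)
        if werr_pos_above < best[3]:  # threshold below every value, predict all 1
            best = (f, -np.inf, 1, werr_pos_above, None)
        if 1.0 - werr_pos_above < best[3]:  # predict all 0
            best = (f, -np.inf, -1, 1.0 - werr_pos_above, None)
        if len(cand):
            thr = 0.5 * (xs[cand] + xs[cand + 1])
            e_above = errs_above[cand]
            i = int(np.argmin(e_above))
            if e_above[i] < best[3]:
                best = (f, float(thr[i]), 1, float(e_above[i]), None)
            e_below = 1.0 - e_above  # total weight is 1
            i = int(np.argmin(e_below))
            if e_below[i] < best[3]:
                best = (f, float(thr[i]), -1, float(e_below[i]), None)
    f, thr, pol, err, _ = best
    if pol == 1:
        pred = (X[:, f] > thr).astype(int)
    else:
        pred = (X[:, f] <= thr).astype(int)
    return f, thr, pol, err, pred


def adaboost_rank(
    X,
    y,
    feature_names=None,
    T: int = 10,
    seed: int | None = None,
    return_trace: bool = False,
):
    """Rank features by cumulative AdaBoost stump weight on a binary task.

    ``y`` holds two classes (any labels); ``T`` is the number of boosting
    iterations.  The procedure is deterministic; ``seed`` is accepted for
    interface uniformity and reserved for future stochastic variants.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ConfigurationError("X must be 2-dimensional")
    classes = np.unique(y)
    if len(classes) != 2:
        raise TrainingError(f"need exactly two classes, got {len(classes)}")
    if T < 1:
        raise ConfigurationError("T must be >= 1")
    y01 = (y == classes[1]).astype(int)
    n, d = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(d)]
    feature_names = list(feature_names)
    if len(feature_names) != d:
        raise ConfigurationError("feature_names length must match X columns")

    w = np.full(n, 1.0 / n)
    cumulative = np.zeros(d)
    trace = BoostingTrace()
    for t in range(T):
        f, thr, pol, err, pred = _best_stump(X, y01, w)
        eps = min(max(err, _EPS_CLAMP), 0.5 - _EPS_CLAMP)
        alpha = 0.5 * math.log((1.0 - eps) / eps)
        cumulative[f] += alpha
        correct = pred == y01
        w = w * np.exp(np.where(correct, -alpha, alpha))
        w = w / w.sum()
        trace.features.append(f)
        trace.thresholds.append(thr)
        trace.alphas.append(alpha)
        trace.errors.append(err)
        trace.weight_sums.append(float(w.sum()))

    selected = np.flatnonzero(cumulative > 0)
    order = sorted(selected, key=lambda i: (-cumulative[i], feature_names[i]))
    ranked = [
        RankedFeature(name=feature_names[i], weight=float(cumulative[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]
    if return_trace:
        return ranked, trace
    return ranked


def rank_binary_task(
    X,
    y,
    positive_group,
    negative_group,
    feature_names=None,
    T: int = 10,
    n_trials: int = 20,
    subsample: float = 2.0 / 3.0,
    seed: int = 0,
) -> list[RankedFeature]:
    """Rank features for one group-vs-group task over repeated trials.

    Each trial boosts on a stratified random ``subsample`` fraction of the
    task's samples; per-feature weights are summed across trials.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = np.isin(y, list(positive_group))
    neg = np.isin(y, list(negative_group))
    if not pos.any() or not neg.any():
        raise TrainingError("both task groups must be present in the data")
    sel = pos | neg
    Xt, yt = X[sel], pos[sel].astype(int)
    rng = np.random.default_rng(seed)
    rankings = []
    for _ in range(n_trials):
        idx = []
        for cls in (0, 1):
            members = np.flatnonzero(yt == cls)
            k = max(2, int(round(subsample * len(members))))
            idx.append(rng.choice(members, size=min(k, len(members)), replace=False))
        idx = np.concatenate(idx)
        rankings.append(adaboost_rank(Xt[idx], yt[idx], feature_names, T=T))
    return rank_across_trials(rankings)


def rank_across_trials(per_trial_rankings) -> list[RankedFeature]:
    """Sum cumulative weights over trials and re-rank.

    Ties break lexicographically by feature name.
    """
    rankings = list(per_trial_rankings)
    if not rankings:
        raise ConfigurationError("need at least one trial ranking")
    totals: dict[str, float] = {}
    for ranking in rankings:
        for rf in ranking:
            totals[rf.name] = totals.get(rf.name, 0.0) + rf.weight
    order = sorted(totals, key=lambda name: (-totals[name], name))
    return [
        RankedFeature(name=name, weight=totals[name], rank=r + 1)
        for r, name in enumerate(order)
    ]
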