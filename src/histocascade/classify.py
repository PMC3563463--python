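"""Multi-class strategies over decision-tree base learners.

Three ways to assign one of seven tissue labels to a feature vector:

* CAS (cascaded): a binary tree of class groups.  The default cascade
  first separates cancer {G3, G4, G5} from non-cancer {BE, BS, AT, PIN},
  then splits cancer into {G3, G4} vs {G5} and non-cancer into the
  confounders {AT, PIN} vs the normals {BE, BS}, and finally resolves the
  remaining pairs — six independently trained binary classifiers, seven
  leaves.  A sample is routed root-to-leaf (at most three classifier
  calls).
* OSC (one-shot): a single multi-leaf decision tree over all seven labels.
* OVA (one-versus-all): seven independent binary target-vs-rest
  classifiers, each scored on its own task (no fusion into a single label
  by default, so errors in one task do not affect another; a fused argmax
  mode is available).

Per-class performance is summarized by accuracy, positive predictive
value and negative predictive value:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    PPV = TP / (TP + FP),   NPV = TN / (TN + FN)

A metric whose denominator is zero is reported as missing and excluded
from trial averaging.  The base learner is a CART-style entropy decision
tree (the closest open analogue of C5.0), with hyperparameters exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, TrainingError

__all__ = [
    "STRATEGIES",
    "CascadeNode",
    "ContingencyCounts",
    "Metrics",
    "StrategyReport",
    "default_cascade",
    "cascade_from_dict",
    "cascade_to_dict",
    "load_cascade_yaml",
    "save_cascade_yaml",
    "train_binary",
    "train_cascade",
    "cascade_predict",
    "train_osc",
    "osc_predict",
    "train_ova",
    "ova_predict",
    "ova_fused_predict",
    "contingency_from_labels",
    "evaluate",
    "run_experiment",
]

STRATEGIES = ("CAS", "OSC", "OVA")

DEFAULT_TREE_PARAMS = dict(criterion="entropy", min_samples_leaf=2)


@dataclass
class CascadeNode:
    """One bifurcation: left group vs right group, with optional children."""

    name: str
    left_labels: tuple[str, ...]
    right_labels: tuple[str, ...]
    left: "CascadeNode | None" = None
    right: "CascadeNode | None" = None
    model: DecisionTreeClassifier | None = None

    def __post_init__(self) -> None:
        left, right = set(self.left_labels), set(self.right_labels)
        if left & right:
            raise ConfigurationError(
                f"node {self.name!r}: left and right groups overlap"
            )
        if not left or not right:
            raise ConfigurationError(f"node {self.name!r}: empty group")
        for side, child in (("left", self.left), ("right", self.right)):
            labels = left if side == "left" else right
            if child is not None:
                child_labels = set(child.left_labels) | set(child.right_labels)
                if child_labels != labels:
                    raise ConfigurationError(
                        f"node {self.name!r}: {side} child labels {child_labels} "
                        f"do not match group {labels}"
                    )
            elif len(labels) != 1:
                raise ConfigurationError(
                    f"node {self.name!r}: {side} group {labels} has no child "
                    "but is not a singleton leaf"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.left_labels) + tuple(self.right_labels)

    def nodes(self) -> list["CascadeNode"]:
        out = [self]
        for child in (self.left, self.right):
            if child is not None:
                out += child.nodes()
        return out

    def leaf_labels(self) -> list[str]:
        out = []
        for side_labels, child in (
            (self.left_labels, self.left),
            (self.right_labels, self.right),
        ):
            if child is None:
                out += list(side_labels)
            else:
                out += child.leaf_labels()
        return out


def default_cascade() -> CascadeNode:
    """The domain-knowledge cascade over the seven prostate tissue classes."""
    g3g4 = CascadeNode("g3_vs_g4", ("G3",), ("G4",))
    cancer = CascadeNode("g34_vs_g5", ("G3", "G4"), ("G5",), left=g3g4)
    atpin = CascadeNode("at_vs_pin", ("AT",), ("PIN",))
    bebs = CascadeNode("be_vs_bs", ("BE",), ("BS",))
    noncancer = CascadeNode(
        "confounder_vs_normal", ("AT", "PIN"), ("BE", "BS"), left=atpin, right=bebs
    )
    return CascadeNode(
        "cancer_vs_noncancer",
        ("G3", "G4", "G5"),
        ("BE", "BS", "AT", "PIN"),
        left=cancer,
        right=noncancer,
    )


def cascade_to_dict(node: CascadeNode) -> dict:
    d = {
        "name": node.name,
        "left": list(node.left_labels),
        "right": list(node.right_labels),
    }
    if node.left is not None:
        d["left_child"] = cascade_to_dict(node.left)
    if node.right is not None:
        d["right_child"] = cascade_to_dict(node.right)
    return d


def cascade_from_dict(d: dict) -> CascadeNode:
    return CascadeNode(
        name=d["name"],
        left_labels=tuple(d["left"]),
        right_labels=tuple(d["right"]),
        left=cascade_from_dict(d["left_child"]) if "left_child" in d else None,
        right=cascade_from_dict(d["right_child"]) if "right_child" in d else None,
    )


def save_cascade_yaml(node: CascadeNode, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cascade_to_dict(node), fh, sort_keys=False)


def load_cascade_yaml(path) -> CascadeNode:
    with open(path) as fh:
        return cascade_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# training and prediction


def _make_tree(seed: int | None, tree_params: dict | None) -> DecisionTreeClassifier:
    params = dict(DEFAULT_TREE_PARAMS)
    if tree_params:
        params.update(tree_params)
    return DecisionTreeClassifier(random_state=seed, **params)


def train_binary(
    X: np.ndarray,
    y: np.ndarray,
    positive_group,
    negative_group,
    seed: int | None = 0,
    tree_params: dict | None = None,
) -> DecisionTreeClassifier:
    """Entropy decision tree on the binary relabeling positive vs negative.

    Only samples whose label belongs to one of the groups are used; the
    tree selects its own features per task.
    """
    positive_group = set(positive_group)
    negative_group = set(negative_group)
    y = np.asarray(y)
    in_pos = np.isin(y, list(positive_group))
    in_neg = np.isin(y, list(negative_group))
    if not in_pos.any() or not in_neg.any():
        raise TrainingError(
            f"both groups must appear in the training data "
            f"(positives: {int(in_pos.sum())}, negatives: {int(in_neg.sum())})"
        )
    sel = in_pos | in_neg
    target = in_pos[sel].astype(int)
    model = _make_tree(seed, tree_params)
    model.fit(np.asarray(X)[sel], target)
    return model


def train_cascade(
    cascade: CascadeNode,
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = 0,
    tree_params: dict | None = None,
) -> CascadeNode:
    """Train every bifurcation of the cascade independently (in place)."""
    for k, node in enumerate(cascade.nodes()):
        node_seed = None if seed is None else seed + 1009 * k
        node.model = train_binary(
            X, y, node.left_labels, node.right_labels, node_seed, tree_params
        )
    return cascade


def cascade_predict(cascade: CascadeNode, X: np.ndarray) -> np.ndarray:
    """Route samples root-to-leaf; returns the singleton leaf labels."""
    X = np.atleast_2d(np.asarray(X))
    out = np.empty(len(X), dtype=object)

    def _route(node: CascadeNode, idx: np.ndarray) -> None:
        if len(idx) == 0:
            return
        if node.model is None:
            raise TrainingError(f"cascade node {node.name!r} is untrained")
        goes_left = node.model.predict(X[idx]).astype(bool)
        for side, mask in (("left", goes_left), ("right", ~goes_left)):
            child = node.left if side == "left" else node.right
            labels = node.left_labels if side == "left" else node.right_labels
            sub = idx[mask]
            if child is None:
                out[sub] = labels[0]
            else:
                _route(child, sub)

    _route(cascade, np.arange(len(X)))
    return out.astype(str)


def train_osc(
    X, y, seed: int | None = 0, tree_params: dict | None = None
) -> DecisionTreeClassifier:
    """One-shot: a single multi-leaf tree over all labels."""
    model = _make_tree(seed, tree_params)
    model.fit(np.asarray(X), np.asarray(y))
    return model


def osc_predict(model: DecisionTreeClassifier, X) -> np.ndarray:
    return model.predict(np.atleast_2d(np.asarray(X)))


def train_ova(
    X, y, classes, seed: int | None = 0, tree_params: dict | None = None
) -> dict[str, DecisionTreeClassifier]:
    """One binary target-vs-rest tree per class."""
    y = np.asarray(y)
    models = {}
    for k, cls in enumerate(classes):
        rest = [c for c in classes if c != cls]
        node_seed = None if seed is None else seed + 2003 * k
        models[cls] = train_binary(X, y, [cls], rest, node_seed, tree_params)
    return models


def ova_predict(models: dict, X) -> dict[str, np.ndarray]:
    """Per-class boolean decisions, one independent task per class."""
    X = np.atleast_2d(np.asarray(X))
    return {cls: m.predict(X).astype(bool) for cls, m in models.items()}


def ova_fused_predict(models: dict, X) -> np.ndarray:
    """Optional fusion: argmax of the per-class positive probabilities."""
    X = np.atleast_2d(np.asarray(X))
    classes = list(models)
    scores = np.column_stack(
        [m.predict_proba(X)[:, list(m.classes_).index(1)] for m in models.values()]
    )
    return np.array(classes, dtype=object)[np.argmax(scores, axis=1)].astype(str)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    acc: float
    ppv: float | None
    npv: float | None


def contingency_from_labels(true, pred, cls) -> ContingencyCounts:
    """One-vs-rest contingency for class ``cls`` from label arrays."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    is_t = true == cls
    is_p = pred == cls
    return ContingencyCounts(
        tp=int(np.sum(is_p & is_t)),
        tn=int(np.sum(~is_p & ~is_t)),
        fp=int(np.sum(is_p & ~is_t)),
        fn=int(np.sum(~is_p & is_t)),
    )


def contingency_from_binary(is_target, decided) -> ContingencyCounts:
    is_target = np.asarray(is_target, dtype=bool)
    decided = np.asarray(decided, dtype=bool)
    return ContingencyCounts(
        tp=int(np.sum(decided & is_target)),
        tn=int(np.sum(~decided & ~is_target)),
        fp=int(np.sum(decided & ~is_target)),
        fn=int(np.sum(~decided & is_target)),
    )


def evaluate(counts: ContingencyCounts) -> Metrics:
    """ACC / PPV / NPV; a zero-denominator metric is reported as None."""
    if counts.total == 0:
        raise ConfigurationError("cannot evaluate all-zero counts")
    acc = (counts.tp + counts.tn) / counts.total
    ppv = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    npv = counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn > 0 else None
    return Metrics(acc=acc, ppv=ppv, npv=npv)


@dataclass
class StrategyReport:
    """Per-class contingency counts for every (trial, fold) evaluation."""

    strategy: str
    classes: tuple[str, ...]
    records: list[dict] = field(default_factory=list)  # {class: ContingencyCounts}

    def summarize(self) -> pd.DataFrame:
        """Mean and standard error per class and metric, missing values
        (undefined PPV/NPV) excluded from averaging."""
        rows = []
        for cls in self.classes:
            pools: dict[str, list[float]] = {"ACC": [], "PPV": [], "NPV": []}
            for rec in self.records:
                m = evaluate(rec[cls])
                pools["ACC"].append(m.acc)
                if m.ppv is not None:
                    pools["PPV"].append(m.ppv)
                if m.npv is not None:
                    pools["NPV"].append(m.npv)
            for metric, vals in pools.items():
                n = len(vals)
                mean = float(np.mean(vals)) if n else float("nan")
                se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
                rows.append(
                    dict(
                        strategy=self.strategy,
                        **{"class": cls},
                        metric=metric,
                        mean=mean,
                        stderr=se,
                        n=n,
                    )
                )
        return pd.DataFrame(rows)

    def mean_metric(self, metric: str = "PPV") -> float:
        df = self.summarize()
        return float(df[df.metric == metric]["mean"].mean())


def run_experiment(
    X,
    y,
    n_trials: int = 20,
    n_folds: int = 3,
    seed: int = 0,
    strategies=STRATEGIES,
    cascade: CascadeNode | None = None,
    tree_params: dict | None = None,
) -> dict[str, StrategyReport]:
    """Repeated stratified k-fold comparison of the strategies.

    Each trial reshuffles the folds with seed ``seed + trial``; every
    strategy is evaluated per class on every test fold, so each per-class
    mean aggregates ``n_trials * n_folds`` contingency tables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    classes = tuple(sorted(set(y)))
    counts = pd.Series(y).value_counts()
    if counts.min() < max(n_folds, 8):
        raise ConfigurationError(
            f"every class needs at least {max(n_folds, 8)} samples; "
            f"smallest has {counts.min()}"
        )
    reports = {s: StrategyReport(strategy=s, classes=classes) for s in strategies}
    for trial in range(n_trials):
        trial_seed = seed + trial
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=trial_seed)
        for train_idx, test_idx in skf.split(X, y):
            Xtr, ytr = X[train_idx], y[train_idx]
            Xte, yte = X[test_idx], y[test_idx]
            if "CAS" in strategies:
                tree = cascade if cascade is not None else default_cascade()
                tree = cascade_from_dict(cascade_to_dict(tree))  # fresh copy
                train_cascade(tree, Xtr, ytr, seed=trial_seed, tree_params=tree_params)
                pred = cascade_predict(tree, Xte)
                reports["CAS"].records.append(
                    {c: contingency_from_labels(yte, pred, c) for c in classes}
                )
            if "OSC" in strategies:
                model = train_osc(Xtr, ytr, seed=trial_seed, tree_params=tree_params)
                pred = osc_predict(model, Xte)
                reports["OSC"].records.append(
                    {c: contingency_from_labels(yte, pred, c) for c in classes}
                )
            if "OVA" in strategies:
                models = train_ova(Xtr, ytr, classes, seed=trial_seed, tree_params=tree_params)
                decisions = ova_predict(models, Xte)
                reports["OVA"].records.append(
                    {
                        c: contingency_from_binary(yte == c, decisions[c])
                        for c in classes
                    }
                )
    return reports
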