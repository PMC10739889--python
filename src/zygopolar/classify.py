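"""Supervised apical/basal classification with a random forest.

The apical/basal position labels obtained from hierarchical clustering are
used to train a random forest (500 trees, 10 features tried per split,
trees grown to purity) on the positions × features matrix.  Accuracy is
reported as the out-of-bag (OOB) error from majority voting among trees
whose bootstrap excluded the position, and feature relevance as the mean
decrease in Gini impurity, aggregated per intracellular structure (one
value per biological replicate, averaged over time points) and compared
across structures with the Tukey–Kramer test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .compartment import FeatureMatrix

__all__ = [
    "ClassificationResult",
    "train_random_forest",
    "oob_error_from_confusion",
    "aggregate_importance",
    "tukey_kramer",
]

DEFAULT_N_TREES = 500
DEFAULT_M_TRY = 10
DEFAULT_SEED = 20231218


@dataclass
class ClassificationResult:
    """Random-forest OOB evaluation and Gini importances."""

    confusion: np.ndarray  # rows true (apical, basal), cols predicted
    oob_error_pct: float
    classes: tuple[str, str]
    importance: pd.Series  # raw mean decrease in Gini per feature column
    importance_pct: pd.Series  # rescaled to percent of total
    importance_by_structure: pd.DataFrame  # rows (probe, replicate), col value (%)
    rf_params: dict


def oob_error_from_confusion(confusion) -> float:
    """Percent of off-diagonal (misclassified) counts, to full precision.

    Report with one decimal, e.g. ``round(x, 1)``.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("confusion must be a 2x2 matrix of non-negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix has zero total count")
    return float(100.0 * (c[0, 1] + c[1, 0]) / total)


def train_random_forest(
    matrix: FeatureMatrix,
    labels,
    n_trees: int = DEFAULT_N_TREES,
    m_try: int = DEFAULT_M_TRY,
    seed: int = DEFAULT_SEED,
) -> ClassificationResult:
    """Fit a classification forest on positions and evaluate it out-of-bag.

    Bootstrap samples of size L with replacement per tree, Gini splits over
    ``m_try`` randomly chosen features per node, trees grown to purity.
    Fully reproducible for a fixed ``seed``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if np.min([np.sum(labels == c) for c in classes]) < 2:
        raise ValueError("each class needs at least 2 members")
    if m_try > matrix.F:
        raise ValueError(f"m_try ({m_try}) exceeds feature count ({matrix.F})")

    # deterministic class order: apical first when present
    if "apical" in classes:
        classes = np.array(["apical", "basal"])

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m_try,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        min_samples_leaf=1,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(matrix.values, labels)

    oob_proba = rf.oob_decision_function_
    pred = rf.classes_[np.argmax(oob_proba, axis=1)]
    confusion = np.zeros((2, 2), dtype=int)
    for i, true_c in enumerate(classes):
        for j, pred_c in enumerate(classes):
            confusion[i, j] = int(np.sum((labels == true_c) & (pred == pred_c)))
    oob_pct = oob_error_from_confusion(confusion)

    # raw mean decrease in Gini: per-tree unnormalized impurity decrease,
    # averaged over the forest
    raw = np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in rf.estimators_],
        axis=0,
    )
    names = [
        f"{row.probe}|T{row.timepoint}|{row.replicate_id}"
        for row in matrix.columns.itertuples()
    ]
    importance = pd.Series(raw, index=names, name="mean_decrease_gini")
    importance_pct = 100.0 * importance / importance.sum()
    by_structure = aggregate_importance(importance, matrix.columns)
    return ClassificationResult(
        confusion=confusion,
        oob_error_pct=oob_pct,
        classes=tuple(classes),
        importance=importance,
        importance_pct=importance_pct,
        importance_by_structure=by_structure,
        rf_params={"n_trees": n_trees, "m_try": m_try, "seed": int(seed)},
    )


def aggregate_importance(importance: pd.Series, columns: pd.DataFrame) -> pd.DataFrame:
    """Per-structure importance: one percent-scale value per replicate.

    Importances are first rescaled to percent of total, then averaged over
    the time points of each (probe, replicate); for the full design this
    yields three values per structure.
    """
    required = {"probe", "timepoint", "replicate_id"}
    if not required.issubset(columns.columns) or len(columns) != len(importance):
        raise ValueError("column metadata missing or misaligned")
    pct = 100.0 * np.asarray(importance, dtype=float) / float(np.sum(importance))
    df = columns.copy()
    df["importance_pct"] = pct
    out = (
        df.groupby(["probe", "replicate_id"], sort=True)["importance_pct"]
        .mean()
        .reset_index()
    )
    return out


def _compact_letter_display(names, significant: set[frozenset]) -> dict[str, str]:
    """Insert–absorb compact letter display.

    Groups sharing a letter are not significantly different.
    """
    letters: list[set] = [set(names)]
    for pair in significant:
        a, b = tuple(pair)
        for col in list(letters):
            if a in col and b in col:
                letters.remove(col)
                ca, cb = col - {b}, col - {a}
                for c in (ca, cb):
                    if not any(c <= other for other in letters):
                        letters.append(c)
    # stable ordering: by first member appearance
    order = {n: i for i, n in enumerate(names)}
    letters.sort(key=lambda col: min(order[n] for n in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for letter, col in zip(alphabet, letters):
        for n in names:
            if n in col:
                out[n] += letter
    return out


def tukey_kramer(groups: dict[str, np.ndarray], alpha: float = 0.01) -> pd.DataFrame:
    """All-pairs Tukey–Kramer comparison with a compact letter display.

    ``groups`` maps group name → 1-D array of observations (each with at
    least 2 values).  Returns a tidy frame of pairwise p-values plus a
    ``letters`` attribute (dict) on ``DataFrame.attrs``: groups sharing a
    letter do not differ at ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    names = list(arrays)
    res = stats.tukey_hsd(*arrays.values())
    rows = []
    significant = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "meandiff": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                    "pvalue": p,
                    "reject": p < alpha,
                }
            )
            if p < alpha:
                significant.add(frozenset((names[i], names[j])))
    table = pd.DataFrame(rows)
    table.attrs["letters"] = _compact_letter_display(names, significant)
    table.attrs["alpha"] = alpha
    return table
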