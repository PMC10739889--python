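"""Unsupervised compartmentalization of axial positions.

The standardized profiles from all probes, time points, and replicates are
assembled into a positions × features matrix (110 × 120 for the full
design of 4 probes × 10 time points × 3 replicates).  Hierarchical
clustering of the position rows (Euclidean distance, Ward's minimum-
variance linkage in the variant that squares dissimilarities internally,
i.e. ward.D2) cut at two clusters yields an apical and a basal cluster;
the boundary is the two-segment split that best agrees with the labels,
reported as a percentage of cell length from the tip.  Feature columns are
clustered the same way into a basal-high group (Group 1) and an
apical-high group (Group 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .profile import NormalizedProfile

__all__ = [
    "FeatureMatrix",
    "CompartmentResult",
    "assemble_matrix",
    "cluster_positions",
    "cluster_features",
    "locate_boundary",
    "group_composition",
    "compartmentalize",
]


@dataclass
class FeatureMatrix:
    """Positions × features matrix with per-column (probe, T, replicate) metadata."""

    values: np.ndarray  # (L positions, F features); row 0 = tip
    columns: pd.DataFrame  # columns: probe, timepoint, replicate_id

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def F(self) -> int:
        return self.values.shape[1]


def _column_zscore(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd; idempotent on z-scored columns
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0].tolist()
        raise ValueError(f"zero-variance feature column(s) {bad}")
    return (values - mean) / sd


def assemble_matrix(
    profiles: list[NormalizedProfile],
    probe_order: list[str] | None = None,
) -> FeatureMatrix:
    """Stack standardized profiles into a positions × features matrix.

    Column order is probe (declared order, else first-appearance order),
    then replicate, then time point.  The (probe, timepoint, replicate)
    triple must be unique per profile, and the probe × replicate ×
    timepoint grid must be complete.  Columns are re-z-scored (divisor n),
    a no-op on already standardized profiles.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    lengths = {p.values.size for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have inconsistent lengths {sorted(lengths)}")

    seen: dict[tuple, NormalizedProfile] = {}
    for p in profiles:
        key = (p.probe, p.timepoint, p.replicate_id)
        if key in seen:
            raise ValueError(f"duplicate (probe, timepoint, replicate) {key}")
        seen[key] = p

    if probe_order is None:
        probe_order = list(dict.fromkeys(p.probe for p in profiles))
    replicates = sorted({p.replicate_id for p in profiles})
    timepoints = sorted({p.timepoint for p in profiles})

    missing = [
        (pr, t, rep)
        for pr in probe_order
        for rep in replicates
        for t in timepoints
        if (pr, t, rep) not in seen
    ]
    if missing:
        raise ValueError(
            f"incomplete probe × replicate × timepoint grid; missing {missing}"
        )

    ordered = [
        seen[(pr, t, rep)]
        for pr in probe_order
        for rep in replicates
        for t in timepoints
    ]
    values = np.column_stack([p.values for p in ordered])
    columns = pd.DataFrame(
        {
            "probe": [p.probe for p in ordered],
            "timepoint": [p.timepoint for p in ordered],
            "replicate_id": [p.replicate_id for p in ordered],
        }
    )
    return FeatureMatrix(values=_column_zscore(values), columns=columns)


def _ward_labels(vectors: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    if not np.all(np.isfinite(vectors)):
        raise ValueError("matrix contains non-finite entries")
    n = vectors.shape[0]
    if n < k:
        raise ValueError(f"fewer items ({n}) than clusters ({k})")
    if n == k:
        # degenerate: every item its own cluster
        Z = linkage(vectors, method="ward") if n > 1 else np.empty((0, 4))
        return np.arange(1, n + 1), Z
    Z = linkage(vectors, method="ward")  # Euclidean; ward.D2-equivalent
    return fcluster(Z, t=k, criterion="maxclust"), Z


def cluster_positions(matrix: FeatureMatrix, k_clusters: int = 2):
    """Ward-cluster the position rows; the cluster holding the tip is 'apical'.

    Returns ``(labels, linkage)`` where labels are 'apical'/'basal' strings
    for k=2 (raw integer cluster ids otherwise).
    """
    raw, Z = _ward_labels(matrix.values, k_clusters)
    if k_clusters != 2:
        return raw, Z
    apical_id = raw[0]
    labels = np.where(raw == apical_id, "apical", "basal")
    return labels, Z


def cluster_features(
    matrix: FeatureMatrix,
    k_groups: int = 2,
    position_labels: np.ndarray | None = None,
):
    """Ward-cluster the feature columns into groups.

    For ``k_groups == 2`` the groups are numbered by the convention that
    Group 1 has the larger mean value over basal-cluster positions
    (basal-high features) and Group 2 the smaller (apical-high features).
    ``position_labels`` supplies the basal positions; without it the basal
    half defaults to the lower half of the rows.
    """
    raw, Z = _ward_labels(matrix.values.T, k_groups)
    if k_groups != 2:
        return raw, Z
    if position_labels is not None:
        basal_rows = np.asarray(position_labels) == "basal"
        if not basal_rows.any():
            basal_rows = np.arange(matrix.L) >= matrix.L // 2
    else:
        basal_rows = np.arange(matrix.L) >= matrix.L // 2
    basal_means = matrix.values[basal_rows].mean(axis=0)
    ids = np.unique(raw)
    group_basal = {i: basal_means[raw == i].mean() for i in ids}
    one = max(ids, key=lambda i: group_basal[i])
    groups = np.where(raw == one, 1, 2)
    return groups, Z


def locate_boundary(position_labels) -> tuple[int, float, int]:
    """Best two-segment split of tip→base labels.

    The tip segment is expected to carry the label of position 0 (the
    apical cluster).  Over all splits with ``s`` tip-side positions,
    ``s ∈ {1..L-1}``, the split minimizing the number of disagreeing
    positions is chosen (ties toward smaller ``s``).  Returns
    ``(boundary_index, boundary_pct, contiguity_violations)`` with
    ``boundary_pct = 100*s/L``.
    """
    labels = np.asarray(position_labels)
    L = labels.size
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 label values, got {uniq.size}")
    apical = labels[0]
    is_apical = (labels == apical).astype(int)
    # violations(s) = (#non-apical in first s) + (#apical in last L-s)
    cum = np.concatenate([[0], np.cumsum(is_apical)])
    total_apical = cum[-1]
    s_vals = np.arange(1, L)
    viol = (s_vals - cum[1:L]) + (total_apical - cum[1:L])
    best = int(np.argmin(viol))  # argmin returns first minimum -> smallest s
    s = int(s_vals[best])
    return s, 100.0 * s / L, int(viol[best])


def group_composition(
    feature_groups: np.ndarray, columns: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Counts and within-group fractions of probes and time points per group."""
    if len(feature_groups) != len(columns):
        raise ValueError("feature_groups and column metadata are misaligned")
    df = columns.copy()
    df["group"] = np.asarray(feature_groups)
    out = {}
    for key in ("probe", "timepoint"):
        counts = df.groupby(["group", key], sort=True).size().unstack(fill_value=0)
        fractions = counts.div(counts.sum(axis=1), axis=0)
        out[f"{key}_counts"] = counts
        out[f"{key}_fractions"] = fractions
    return out


@dataclass
class CompartmentResult:
    """Two-cluster compartmentalization of a feature matrix."""

    position_labels: np.ndarray
    boundary_index: int
    boundary_pct: float
    contiguity_violations: int
    feature_groups: np.ndarray
    linkage_positions: np.ndarray
    linkage_features: np.ndarray
    composition: dict[str, pd.DataFrame] = field(default_factory=dict)


def compartmentalize(matrix: FeatureMatrix) -> CompartmentResult:
    """Full unsupervised analysis: cluster rows, locate boundary, group columns."""
    labels, Zp = cluster_positions(matrix, 2)
    s, pct, viol = locate_boundary(labels)
    groups, Zf = cluster_features(matrix, 2, position_labels=labels)
    comp = group_composition(groups, matrix.columns)
    return CompartmentResult(
        position_labels=labels,
        boundary_index=s,
        boundary_pct=pct,
        contiguity_violations=viol,
        feature_groups=groups,
        linkage_positions=Zp,
        linkage_features=Zf,
        composition=comp,
    )
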