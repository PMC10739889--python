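"""Shared fixtures and independent reference (oracle) implementations."""

from __future__ import annotations

import numpy as np
import pytest

from zygopolar.geometry import OrientedCell
from zygopolar.synthetic_data import ProbeTemplate, SyntheticConfig


# ---------------------------------------------------------------- oracles


def ward_d2_reference(X: np.ndarray):
    """Exhaustive O(n^3) Lance–Williams agglomeration for Ward's method on
    squared Euclidean dissimilarities (the ward.D2 variant), with
    lexicographic tie-breaking.

    Returns a list of merges in agglomeration order:
    ``(leafset_a, leafset_b, height)`` with height = sqrt of the Ward cost.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    leaves = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    next_id = n
    merges = []
    while len(active) > 1:
        best = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                i, j = active[a_idx], active[b_idx]
                key = (min(i, j), max(i, j))
                if best is None or d2[key] < best[0] - 1e-15:
                    best = (d2[key], key)
        cost, (i, j) = best
        merges.append((leaves[i], leaves[j], float(np.sqrt(cost))))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            dij = d2[(i, j)]
            d2[(k, new)] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (
                ni + nj + nk
            )
        leaves[new] = leaves[i] | leaves[j]
        sizes[new] = ni + nj
        active = [k for k in active if k not in (i, j)] + [new]
    return merges


def linkage_to_merges(Z: np.ndarray, n: int):
    """Convert a scipy linkage matrix to (leafset_a, leafset_b, height)."""
    leaves = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, h, _) in enumerate(Z):
        fa, fb = leaves[int(a)], leaves[int(b)]
        merges.append((fa, fb, float(h)))
        leaves[n + k] = fa | fb
    return merges


def brute_force_boundary(labels):
    """Exhaustive split search: min disagreement with [tip-seg | base-seg]."""
    labels = np.asarray(labels)
    L = labels.size
    apical = labels[0]
    best = None
    for s in range(1, L):
        v = int(np.sum(labels[:s] != apical)) + int(np.sum(labels[s:] == apical))
        if best is None or v < best[1]:
            best = (s, v)
    return best


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def straight_cell():
    """Hand-built vertical oriented cell, 20 rows × 7 cols, mask rows 5..16."""

    def build(values_fn, mask_width=None):
        image = np.zeros((20, 7))
        mask = np.zeros((20, 7), dtype=bool)
        for r in range(5, 17):
            w = mask_width(r) if mask_width else 7
            lo = (7 - w) // 2
            mask[r, lo : lo + w] = True
            image[r, lo : lo + w] = values_fn(r)
        return OrientedCell(
            image=image,
            mask=mask,
            tip_row=5,
            base_row=16,
            rotation_deg=0.0,
            _matrix=np.eye(2),
            _center_in=np.array([9.5, 3.0]),
            _center_out=np.array([9.5, 3.0]),
        )

    return build


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size generator config for fast I/O and pipeline tests."""
    return SyntheticConfig(
        length_initial=60.0,
        length_final=100.0,
        cell_width=24.0,
        z_slices=3,
        margin=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_config):
    from zygopolar.synthetic_data import generate_dataset

    out = tmp_path_factory.mktemp("smallds")
    manifest = generate_dataset(small_config, out)
    return manifest


@pytest.fixture(scope="session")
def clean_gradient_cell():
    """Noise-free vertical basal-gradient cell rendered analytically."""
    from zygopolar.synthetic_data import render_frame

    t = ProbeTemplate("basal_gradient", amplitude=1.0, width=0.05)
    canvas = (220, 220)
    img, mask, tip, base = render_frame(
        canvas, (109.5, 109.5), 160.0, 36.0, 90.0, t, 0.436
    )
    return {"template": t, "image": img, "mask": mask, "tip": tip, "base": base}
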