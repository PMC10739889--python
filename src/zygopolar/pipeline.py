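"""End-to-end orchestration: movies → profiles → compartments → forest.

Two front doors exist: :func:`run_pipeline` consumes an on-disk dataset
through its manifest, and :func:`analyze_movies` consumes in-memory
movies (e.g. straight from the synthetic generator).  Both produce the
same analysis report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classify as _classify
from .compartment import CompartmentResult, assemble_matrix, compartmentalize
from .division import boundary_vs_plane, division_plane_position
from .geometry import OrientedCell, fit_ellipse_axis, max_intensity_projection, rotate_and_mask
from .profile import STANDARD_LENGTH, NormalizedProfile, axial_profile, normalize_profile
from .stack_io import DatasetManifest, load_manifest, read_mask, read_stack
from .temporal import select_normalized_frames

__all__ = [
    "MovieInput",
    "PipelineResult",
    "orient_frame",
    "movie_profiles",
    "analyze_movies",
    "run_pipeline",
]


@dataclass
class MovieInput:
    """In-memory movie: selected-frame volumes, masks and annotations."""

    probe: str
    replicate_id: str
    frames: list[np.ndarray]  # k volumes (z, row, col), one per time point
    masks: list[np.ndarray]  # k binary masks
    apex_hints: list[tuple[float, float]]  # per frame (or a single hint)
    division_plane: tuple[int, tuple[float, float]] | None = None  # (T index, point)


def orient_frame(volume: np.ndarray, mask: np.ndarray, apex_hint) -> OrientedCell:
    """MIP → ellipse fit → rotation with apex up, for one time point."""
    mip = max_intensity_projection(volume)
    axis = fit_ellipse_axis(mask)
    return rotate_and_mask(mip, mask, axis, apex_hint)


def movie_profiles(movie: MovieInput, L: int = STANDARD_LENGTH):
    """Standardized profiles for every selected time point of one movie.

    Returns ``(profiles, division_pct)``; ``division_pct`` is the plane
    position (% from tip) when the movie carries a plane annotation.
    """
    profiles: list[NormalizedProfile] = []
    division_pct = None
    for ti, (vol, msk) in enumerate(zip(movie.frames, movie.masks)):
        hint = (
            movie.apex_hints[ti]
            if len(movie.apex_hints) > 1
            else movie.apex_hints[0]
        )
        cell = orient_frame(vol, msk, hint)
        raw = axial_profile(
            cell, probe=movie.probe, replicate_id=movie.replicate_id, timepoint=ti
        )
        profiles.append(normalize_profile(raw, L))
        if movie.division_plane is not None and movie.division_plane[0] == ti:
            prow, _ = cell.map_point(movie.division_plane[1])
            prow = float(np.clip(prow, cell.tip_row, cell.base_row))
            division_pct = division_plane_position(prow, cell.tip_row, cell.base_row)
    return profiles, division_pct


@dataclass
class PipelineResult:
    profiles: list[NormalizedProfile]
    matrix: "object"
    compartment: CompartmentResult
    classification: "object"
    tukey: "object"
    division: dict | None
    division_pcts: list[float]

    def report(self) -> dict:
        rep = {
            "n_profiles": len(self.profiles),
            "L": self.matrix.L,
            "F": self.matrix.F,
            "boundary": {
                "index": self.compartment.boundary_index,
                "pct_from_tip": self.compartment.boundary_pct,
                "contiguity_violations": self.compartment.contiguity_violations,
            },
            "position_labels": self.compartment.position_labels.tolist(),
            "feature_groups": self.compartment.feature_groups.tolist(),
            "composition": {
                k: v.to_dict() for k, v in self.compartment.composition.items()
            },
        }
        if self.classification is not None:
            rep["classification"] = {
                "confusion": self.classification.confusion.tolist(),
                "classes": list(self.classification.classes),
                "oob_error_pct": self.classification.oob_error_pct,
                "rf_params": self.classification.rf_params,
                "importance_by_structure": self.classification.importance_by_structure.to_dict(
                    orient="records"
                ),
            }
        if self.tukey is not None:
            rep["tukey_kramer"] = {
                "alpha": self.tukey.attrs["alpha"],
                "letters": self.tukey.attrs["letters"],
                "pairs": self.tukey.to_dict(orient="records"),
            }
        if self.division is not None:
            rep["division_plane"] = dict(
                self.division, positions_pct=self.division_pcts
            )
        return rep


def analyze_movies(
    movies: list[MovieInput],
    L: int = STANDARD_LENGTH,
    probe_order: list[str] | None = None,
    n_trees: int = _classify.DEFAULT_N_TREES,
    m_try: int = _classify.DEFAULT_M_TRY,
    seed: int = _classify.DEFAULT_SEED,
    with_forest: bool = True,
) -> PipelineResult:
    """Full analysis of a set of movies."""
    profiles: list[NormalizedProfile] = []
    division_pcts: list[float] = []
    for movie in movies:
        p, dpct = movie_profiles(movie, L)
        profiles.extend(p)
        if dpct is not None:
            division_pcts.append(dpct)

    matrix = assemble_matrix(profiles, probe_order=probe_order)
    comp = compartmentalize(matrix)

    classification = tukey = None
    if with_forest:
        classification = _classify.train_random_forest(
            matrix, comp.position_labels, n_trees=n_trees, m_try=m_try, seed=seed
        )
        by_probe = classification.importance_by_structure.groupby("probe")[
            "importance_pct"
        ]
        groups = {probe: vals.to_numpy() for probe, vals in by_probe}
        if len(groups) >= 2 and min(len(v) for v in groups.values()) >= 2:
            tukey = _classify.tukey_kramer(groups, alpha=0.01)

    division = (
        boundary_vs_plane(comp.boundary_pct, division_pcts) if division_pcts else None
    )
    return PipelineResult(
        profiles=profiles,
        matrix=matrix,
        compartment=comp,
        classification=classification,
        tukey=tukey,
        division=division,
        division_pcts=division_pcts,
    )


def _movies_from_manifest(manifest: DatasetManifest) -> list[MovieInput]:
    movies = []
    k = manifest.k_timepoints
    for e in manifest.entries:
        stack = read_stack(e.stack_path, probe=e.probe, replicate_id=e.replicate_id)
        selected = select_normalized_frames(e.onset_frame, e.predivision_frame, k)
        if e.masks_per == "selected":
            if len(e.mask_paths) != k:
                raise ValueError(
                    f"{e.stack_path}: expected {k} selected-frame masks, got "
                    f"{len(e.mask_paths)}"
                )
            mask_for = lambda i, f: e.mask_paths[i]  # noqa: E731
        else:
            mask_for = lambda i, f: e.mask_paths[f]  # noqa: E731
        frames = [stack.intensity[f] for f in selected]
        masks = [read_mask(mask_for(i, f)) for i, f in enumerate(selected)]
        hints = e.apex_hints if len(e.apex_hints) > 1 else [e.apex_hints[0]]
        division = None
        if e.division_plane:
            dframe = int(e.division_plane["frame"])
            # the annotation frame is a raw index; map to its selected slot
            if dframe in selected:
                ti = selected.index(dframe)
                point = tuple(e.division_plane["point"])
                division = (ti, point)
        movies.append(
            MovieInput(
                probe=e.probe,
                replicate_id=e.replicate_id,
                frames=frames,
                masks=masks,
                apex_hints=hints,
                division_plane=division,
            )
        )
    return movies


def run_pipeline(manifest_path, L: int = STANDARD_LENGTH, **kwargs) -> PipelineResult:
    """Run the complete analysis on an on-disk dataset."""
    manifest = load_manifest(manifest_path)
    movies = _movies_from_manifest(manifest)
    return analyze_movies(movies, L=L, probe_order=manifest.probes, **kwargs)


def movies_from_synthetic(dataset) -> list[MovieInput]:
    """Adapt an in-memory synthetic dataset to pipeline inputs."""
    movies = []
    k = dataset.config.k_timepoints
    for m in dataset.movies:
        movies.append(
            MovieInput(
                probe=m.probe,
                replicate_id=m.replicate_id,
                frames=[m.stack[t] for t in range(k)],
                masks=list(m.masks),
                apex_hints=list(m.apex_hints),
                division_plane=(k - 1, m.plane_point),
            )
        )
    return movies
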