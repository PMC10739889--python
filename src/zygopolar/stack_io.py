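"""I/O for image stacks, masks, manifests and tabular outputs.

On-disk contract: stacks are multi-page TIFFs in (frame, z, row, col)
order (row index increases downward); masks are single-plane TIFF/PNG
images, any nonzero pixel = cell; the dataset manifest is a YAML file
declaring the probe set and one entry per movie with the manual
annotations (onset / pre-division frames, apex hint, optional division
plane).  Tabular outputs are CSV with a header row; the analysis report
is a single JSON document.

8/16-bit integer and floating-point pixel data are accepted as-is; no
rescaling is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import AxisInferenceError, EmptyMaskError, ManifestError
from .profile import NormalizedProfile

__all__ = [
    "ZygoteStack",
    "ManifestEntry",
    "DatasetManifest",
    "read_stack",
    "write_stack",
    "read_mask",
    "load_manifest",
    "profiles_to_csv",
    "profiles_from_csv",
    "matrix_to_csv",
    "write_report_json",
]

KNOWN_PROBES = (
    "actin_filaments",
    "mitochondria",
    "microtubules",
    "vacuolar_membranes",
)


@dataclass
class ZygoteStack:
    """One zygote movie: intensity over (frame, z, row, col) plus metadata."""

    intensity: np.ndarray
    probe: str = ""
    replicate_id: str = ""
    frame_interval_min: float = 20.0  # provenance only
    z_step_um: float = 1.0  # provenance only

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 4:
            raise ValueError(
                f"stack must have 4 axes (frame, z, row, col); got "
                f"{self.intensity.ndim}"
            )
        if min(self.intensity.shape) < 1:
            raise ValueError("every stack axis must have extent >= 1")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("stack contains non-finite values")
        if self.intensity.min() < 0:
            raise ValueError("stack contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]


def read_stack(path, axes: str | None = None, **meta) -> ZygoteStack:
    """Read a multi-page TIFF as a (frame, z, row, col) stack.

    A 4-D file is taken as TZYX.  A 3-D file is ambiguous and requires an
    ``axes`` hint of ``"ZYX"`` (single frame) or ``"TYX"`` (single slice);
    without one an :class:`AxisInferenceError` is raised — never a silent
    guess.
    """
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read stack {path}: {exc}") from exc
    if arr.ndim == 4:
        pass
    elif arr.ndim == 3:
        if axes == "ZYX":
            arr = arr[None, ...]
        elif axes == "TYX":
            arr = arr[:, None, ...]
        else:
            raise AxisInferenceError(
                f"axis inference failed for {path}: 3-axis stack needs an "
                "axes hint ('ZYX' or 'TYX')"
            )
    else:
        raise AxisInferenceError(
            f"axis inference failed for {path}: expected 3 or 4 axes, got "
            f"{arr.ndim}"
        )
    return ZygoteStack(intensity=arr, **meta)


def write_stack(stack: ZygoteStack, path) -> None:
    tifffile.imwrite(path, stack.intensity, metadata={"axes": "TZYX"})


def read_mask(path) -> np.ndarray:
    """Read a 2-D mask; any nonzero pixel is foreground.

    Raises :class:`EmptyMaskError` for an all-zero mask.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse RGB(A)
            arr = arr.max(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"mask {path} must have exactly 2 axes, got {arr.ndim}")
    mask = arr > 0
    if not mask.any():
        raise EmptyMaskError(f"empty mask: {path}")
    return mask


@dataclass
class ManifestEntry:
    stack_path: Path
    probe: str
    replicate_id: str
    onset_frame: int
    predivision_frame: int
    mask_paths: list[Path]
    masks_per: str  # "selected" or "raw"
    apex_hints: list[tuple[float, float]]  # one per selected frame, or one
    division_plane: dict | None = None  # {"frame": int, "point": (row, col)}

    def apex_hint(self, i: int) -> tuple[float, float]:
        hints = self.apex_hints
        return hints[i] if len(hints) > 1 else hints[0]


@dataclass
class DatasetManifest:
    base_dir: Path
    probes: list[str]
    k_timepoints: int
    entries: list[ManifestEntry] = field(default_factory=list)


def load_manifest(path) -> DatasetManifest:
    """Load and validate a dataset manifest, reporting ALL violations."""
    path = Path(path)
    base = path.parent
    raw = yaml.safe_load(path.read_text())
    violations: list[str] = []
    probes = raw.get("probes") or list(KNOWN_PROBES)
    k = int(raw.get("k_timepoints", 10))
    if raw.get("axis_convention", "frame-z-row-col") != "frame-z-row-col":
        violations.append(
            f"unsupported axis_convention {raw.get('axis_convention')!r}"
        )
    entries: list[ManifestEntry] = []
    for idx, e in enumerate(raw.get("entries", [])):
        tag = f"entry {idx} ({e.get('probe')}/{e.get('replicate_id')})"
        stack_path = base / e.get("stack", "")
        if not stack_path.is_file():
            violations.append(f"{tag}: stack file not found: {stack_path}")
        if e.get("probe") not in probes:
            violations.append(
                f"{tag}: probe {e.get('probe')!r} not in declared set {probes}"
            )
        onset = int(e.get("onset_frame", 0))
        prediv = int(e.get("predivision_frame", -1))
        if onset >= prediv:
            violations.append(
                f"{tag}: onset_frame ({onset}) must precede "
                f"predivision_frame ({prediv})"
            )
        masks = e.get("masks", {})
        masks_per = "selected" if "selected" in masks else "raw"
        mask_paths = [base / p for p in masks.get(masks_per, [])]
        if not mask_paths:
            violations.append(f"{tag}: no masks listed")
        for p in mask_paths:
            if not p.is_file():
                violations.append(f"{tag}: mask file not found: {p}")
        hints = e.get("apex_hints") or (
            [e["apex_hint"]] if "apex_hint" in e else []
        )
        if not hints:
            violations.append(f"{tag}: apex hint missing")
        division = e.get("division_plane")
        entries.append(
            ManifestEntry(
                stack_path=stack_path,
                probe=str(e.get("probe")),
                replicate_id=str(e.get("replicate_id")),
                onset_frame=onset,
                predivision_frame=prediv,
                mask_paths=mask_paths,
                masks_per=masks_per,
                apex_hints=[(float(h[0]), float(h[1])) for h in hints],
                division_plane=division,
            )
        )
    if violations:
        raise ManifestError(violations)
    return DatasetManifest(base_dir=base, probes=probes, k_timepoints=k, entries=entries)


def profiles_to_csv(profiles: list[NormalizedProfile], path) -> None:
    """One row per profile: metadata columns then v000..v{L-1}."""
    if not profiles:
        raise ValueError("no profiles to write")
    L = profiles[0].L
    rows = []
    for p in profiles:
        row = {"probe": p.probe, "replicate_id": p.replicate_id, "timepoint": p.timepoint}
        row.update({f"v{i:03d}": p.values[i] for i in range(L)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def profiles_from_csv(path) -> list[NormalizedProfile]:
    df = pd.read_csv(path)
    vcols = [c for c in df.columns if c.startswith("v")]
    return [
        NormalizedProfile(
            values=row[vcols].to_numpy(dtype=float),
            L=len(vcols),
            probe=str(row["probe"]),
            replicate_id=str(row["replicate_id"]),
            timepoint=int(row["timepoint"]),
        )
        for _, row in df.iterrows()
    ]


def matrix_to_csv(matrix, path) -> None:
    """Feature matrix as CSV: header rows carry probe/timepoint/replicate."""
    cols = [
        f"{r.probe}|T{r.timepoint}|{r.replicate_id}"
        for r in matrix.columns.itertuples()
    ]
    pd.DataFrame(matrix.values, columns=cols).to_csv(path, index_label="position")


def write_report_json(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json())
        if isinstance(o, pd.Series):
            return json.loads(o.to_json())
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
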