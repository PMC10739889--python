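"""Synthetic zygote time-lapse generator with planted ground truth.

Real zygote movies are not publicly deposited, so every pipeline stage is
exercised on synthetic datasets that emulate the essential features of
the imaging data: a capsule-shaped cell elongating linearly over the
normalized time window, rendered at an arbitrary in-plane rotation angle,
carrying a per-probe axial fluorescence density fixed in relative
coordinate u ∈ [0, 1] (tip → base) across frames, plus additive noise.
The planted compartment boundary fraction ``b`` controls all densities:

* ``apical_band``   — Gaussian bump peaking at u = b/2, the midpoint of
  the apical compartment (cortical microtubule band analogue);
* ``basal_gradient`` — logistic step centred at u = b (vacuolar membrane /
  actin basal enrichment analogue); at u = b the density is exactly the
  baseline plus half the amplitude;
* ``uniform``       — constant (mitochondria analogue).

The default configuration mirrors the full study design: 4 probes ×
3 replicates × 10 time points, b = 0.436, noise SD = 10% of the signal
range.  Masks are the noiseless support; the division plane is planted on
the axis of the last frame at a fraction drawn around b/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ProbeTemplate",
    "SyntheticConfig",
    "SyntheticMovie",
    "SyntheticDataset",
    "planted_density",
    "default_probes",
    "generate_arrays",
    "generate_dataset",
]


@dataclass(frozen=True)
class ProbeTemplate:
    """Closed-form axial density f(u; b), u ∈ [0,1] from tip to base.

    ``center_sd`` models replicate-to-replicate biological variability: at
    render time the template's anchor (logistic centre or band peak) is
    shifted by a per-movie offset drawn from N(0, center_sd).
    ``center_tsd`` adds an independent per-time-point shift on top,
    modelling structures that rearrange on the imaging timescale (actin
    is highly dynamic; vacuolar architecture is comparatively stable).
    The canonical density (offset 0) keeps the logistic centred exactly
    at u = b and the band peak exactly at u = b/2.
    """

    kind: str  # apical_band | basal_gradient | uniform
    amplitude: float = 1.0
    baseline: float = 0.2
    width: float = 0.1  # Gaussian sigma (band) or logistic scale (gradient)
    center_sd: float = 0.0
    center_tsd: float = 0.0


def planted_density(template: ProbeTemplate, u, b: float, center_offset: float = 0.0):
    """Evaluate a template density at relative position(s) ``u``."""
    u = np.asarray(u, dtype=float)
    if template.kind == "uniform":
        return np.ones_like(u)
    if template.kind == "basal_gradient":
        return template.baseline + template.amplitude / (
            1.0 + np.exp(-(u - b - center_offset) / template.width)
        )
    if template.kind == "apical_band":
        peak = b / 2.0 + center_offset
        return template.baseline + template.amplitude * np.exp(
            -((u - peak) ** 2) / (2.0 * template.width**2)
        )
    raise ValueError(f"unknown template kind {template.kind!r}")


def default_probes() -> dict[str, ProbeTemplate]:
    """The four-structure design used throughout.

    The vacuolar template carries the sharpest, highest-contrast
    boundary-locked transition (the planted compartmentalization signal);
    actin is a weaker, more gradual basal gradient; microtubules form a
    subapical band; mitochondria are uniform.  Because the imaging noise
    is probe-independent (detector noise), the per-probe amplitudes set
    the signal-to-noise ranking between structures.
    """
    return {
        "actin_filaments": ProbeTemplate(
            "basal_gradient", amplitude=0.35, width=0.08, center_sd=0.03,
            center_tsd=0.04,
        ),
        "mitochondria": ProbeTemplate("uniform"),
        "microtubules": ProbeTemplate(
            "apical_band", amplitude=0.8, width=0.05, center_sd=0.02
        ),
        "vacuolar_membranes": ProbeTemplate(
            "basal_gradient", amplitude=1.0, width=0.02, center_sd=0.005
        ),
    }


@dataclass
class SyntheticConfig:
    probes: dict[str, ProbeTemplate] = field(default_factory=default_probes)
    n_replicates: int = 3
    k_timepoints: int = 10
    boundary_fraction: float = 0.436
    length_initial: float = 120.0  # axial mask extent at T=0, px
    length_final: float = 220.0  # at T=k-1, px
    cell_width: float = 40.0  # px
    z_slices: int = 5
    noise_sd_frac: float = 0.10  # Gaussian SD as fraction of signal range
    speckle_sd: float = 0.05  # multiplicative axial clumpiness, per frame
    speckle_corr: float = 0.03  # speckle correlation length in u units
    poisson_gain: float = 0.0  # photons per intensity unit; 0 disables
    margin: float = 12.0  # canvas padding, px
    angles: dict | None = None  # (probe, replicate_id) -> degrees; None = random
    plane_mean_frac: float | None = None  # default: boundary_fraction / 2
    plane_sd_frac: float = 0.0215
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.boundary_fraction < 1.0):
            raise ValueError("boundary_fraction must lie in (0, 1)")
        if min(self.length_initial, self.length_final) < 20:
            raise ValueError("cell lengths must be at least 20 px")
        if self.noise_sd_frac < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.k_timepoints < 2 or self.n_replicates < 1 or self.z_slices < 1:
            raise ValueError("k_timepoints >= 2, n_replicates >= 1, z_slices >= 1")


@dataclass
class SyntheticMovie:
    probe: str
    replicate_id: str
    stack: np.ndarray  # (T, Z, Y, X) float32
    masks: list[np.ndarray]  # T binary frames (noiseless support)
    angle_deg: float
    apex_hints: list[tuple[float, float]]  # mask tip point per frame (row, col)
    tip_points: list[tuple[float, float]]
    base_points: list[tuple[float, float]]
    plane_fraction: float
    plane_point: tuple[float, float]  # on the last frame


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    movies: list[SyntheticMovie]

    def ground_truth(self) -> dict:
        cfg = self.config
        return {
            "boundary_fraction": cfg.boundary_fraction,
            "boundary_pct": 100.0 * cfg.boundary_fraction,
            "templates": {k: asdict(v) for k, v in cfg.probes.items()},
            "movies": [
                {
                    "probe": m.probe,
                    "replicate_id": m.replicate_id,
                    "angle_deg": m.angle_deg,
                    "plane_fraction": m.plane_fraction,
                }
                for m in self.movies
            ],
        }


def _signal_range(templates, b: float) -> float:
    """Detector-noise reference: the largest dynamic range over all probes.

    Noise is probe-independent, so weaker-contrast probes have lower SNR,
    as in real single-detector imaging.
    """
    u = np.linspace(0.0, 1.0, 512)
    best = 0.0
    for t in templates:
        d = planted_density(t, u, b)
        best = max(best, float(d.max() - d.min()), 0.0)
    if best == 0.0:  # all-uniform design: fall back to the intensity scale
        best = max(float(planted_density(t, u, b).max()) for t in templates)
    return best


def _axial_speckle(rng, sd: float, corr: float, n: int = 256) -> np.ndarray:
    """Smooth zero-mean axial modulation (organelle clumpiness), unit grid.

    Gaussian noise on a fine u grid, smoothed to correlation length
    ``corr`` (in u units) and rescaled to standard deviation ``sd``.
    Unlike per-voxel detector noise this survives averaging across the
    cell width, so it sets the per-profile noise floor.
    """
    from scipy.ndimage import gaussian_filter1d

    g = rng.standard_normal(n)
    g = gaussian_filter1d(g, corr * n, mode="wrap")
    s = g.std()
    return g * (sd / s) if s > 0 else g


def _z_weights(n: int) -> np.ndarray:
    """Hemispheric chord falloff over z, normalized so the MIP of the
    noiseless stack equals the 2D render exactly."""
    zc = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0 + 0.5)
    w = np.sqrt(np.clip(1.0 - zc**2, 0.0, None))
    return w / w.max()


def render_frame(
    canvas_shape: tuple[int, int],
    center: tuple[float, float],
    length: float,
    width: float,
    angle_deg: float,
    template: ProbeTemplate,
    b: float,
    center_offset: float = 0.0,
    axial_mod: np.ndarray | None = None,
):
    """Render one capsule cell analytically at an arbitrary angle.

    ``length`` is the full axial mask extent (caps included).  Returns
    (image, mask, tip_point, base_point); tip/base are the extreme points
    of the mask on the axis, tip on the apical side.
    """
    theta = math.radians(angle_deg)
    e = np.array([-math.sin(theta), math.cos(theta)])  # toward the tip
    center = np.asarray(center, dtype=float)
    half_seg = max(length - width, 0.0) / 2.0  # capsule segment half-length
    tip_seg = center + half_seg * e
    base_seg = center - half_seg * e
    tip_point = center + (length / 2.0) * e
    base_point = center - (length / 2.0) * e

    rr, cc = np.meshgrid(
        np.arange(canvas_shape[0], dtype=float),
        np.arange(canvas_shape[1], dtype=float),
        indexing="ij",
    )
    drow = rr - tip_seg[0]
    dcol = cc - tip_seg[1]
    seg = base_seg - tip_seg
    seg_len2 = float(seg @ seg) if half_seg > 0 else 1.0
    t = (drow * seg[0] + dcol * seg[1]) / seg_len2
    tc = np.clip(t, 0.0, 1.0)
    dist = np.hypot(drow - tc * seg[0], dcol - tc * seg[1])
    mask = dist <= width / 2.0
    # axial coordinate over the full mask extent, caps included
    s = t * (2.0 * half_seg) + width / 2.0
    u = np.clip(s / length, 0.0, 1.0)
    density = planted_density(template, u, b, center_offset)
    if axial_mod is not None:
        grid = np.linspace(0.0, 1.0, axial_mod.size)
        density = density * (1.0 + np.interp(u, grid, axial_mod))
    image = np.where(mask, np.clip(density, 0.0, None), 0.0)
    return image, mask, tuple(tip_point), tuple(base_point)


def generate_arrays(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the dataset in memory; byte-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    side = int(math.ceil(config.length_final + 2 * config.margin))
    canvas = (side, side)
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    zw = _z_weights(config.z_slices)
    k = config.k_timepoints
    lengths = np.linspace(config.length_initial, config.length_final, k)
    plane_mean = (
        config.plane_mean_frac
        if config.plane_mean_frac is not None
        else config.boundary_fraction / 2.0
    )

    movies = []
    sig_range = _signal_range(config.probes.values(), config.boundary_fraction)
    for probe, template in config.probes.items():
        for rep in range(1, config.n_replicates + 1):
            rep_id = f"rep{rep}"
            if config.angles and (probe, rep_id) in config.angles:
                angle = float(config.angles[(probe, rep_id)])
            else:
                angle = float(rng.uniform(0.0, 180.0))
            offset = (
                float(rng.normal(0.0, template.center_sd))
                if template.center_sd > 0
                else 0.0
            )
            frames, masks, apexes, tips, bases = [], [], [], [], []
            for ti in range(k):
                off_t = offset + (
                    float(rng.normal(0.0, template.center_tsd))
                    if template.center_tsd > 0
                    else 0.0
                )
                mod = None
                if config.speckle_sd > 0:
                    mod = _axial_speckle(
                        rng, config.speckle_sd, config.speckle_corr
                    )
                img, msk, tip, base = render_frame(
                    canvas, center, float(lengths[ti]), config.cell_width,
                    angle, template, config.boundary_fraction, off_t, mod,
                )
                vol = img[None, :, :] * zw[:, None, None]
                frames.append(vol.astype(np.float32))
                masks.append(msk)
                apexes.append(tip)
                tips.append(tip)
                bases.append(base)
            stack = np.stack(frames)  # (T, Z, Y, X)
            if config.noise_sd_frac > 0:
                noise = rng.standard_normal(stack.shape, dtype=np.float32)
                stack = stack + np.float32(config.noise_sd_frac * sig_range) * noise
            if config.poisson_gain > 0:
                lam = np.clip(stack, 0, None) * config.poisson_gain
                stack = rng.poisson(lam).astype(np.float32) / config.poisson_gain
            stack = np.clip(stack, 0.0, None)

            frac = float(
                np.clip(
                    rng.normal(plane_mean, config.plane_sd_frac), 0.02, 0.98
                )
            )
            tip_l, base_l = np.asarray(tips[-1]), np.asarray(bases[-1])
            plane_pt = tuple(tip_l + frac * (base_l - tip_l))
            movies.append(
                SyntheticMovie(
                    probe=probe,
                    replicate_id=rep_id,
                    stack=stack,
                    masks=masks,
                    angle_deg=angle,
                    apex_hints=apexes,
                    tip_points=tips,
                    base_points=bases,
                    plane_fraction=frac,
                    plane_point=plane_pt,
                )
            )
    return SyntheticDataset(config=config, movies=movies)


def generate_dataset(config: SyntheticConfig, out_dir) -> Path:
    """Write a dataset to disk: stacks, masks, manifest, ground truth.

    Returns the manifest path.  Layout::

        out_dir/
          <probe>_<rep>.tif          multi-page TIFF, axes (T, Z, Y, X)
          masks/<probe>_<rep>_T<i>.tif
          manifest.yaml
          ground_truth.json
    """
    import tifffile

    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    ds = generate_arrays(config)
    entries = []
    for m in ds.movies:
        stem = f"{m.probe}_{m.replicate_id}"
        stack_path = out / f"{stem}.tif"
        tifffile.imwrite(stack_path, m.stack, metadata={"axes": "TZYX"})
        mask_paths = []
        for ti, msk in enumerate(m.masks):
            p = out / "masks" / f"{stem}_T{ti}.tif"
            tifffile.imwrite(p, msk.astype(np.uint8) * 255)
            mask_paths.append(str(p.relative_to(out)))
        entries.append(
            {
                "stack": str(stack_path.relative_to(out)),
                "probe": m.probe,
                "replicate_id": m.replicate_id,
                "onset_frame": 0,
                "predivision_frame": config.k_timepoints - 1,
                "masks": {"selected": mask_paths},
                "apex_hints": [[float(r), float(c)] for r, c in m.apex_hints],
                "division_plane": {
                    "frame": config.k_timepoints - 1,
                    "point": [float(m.plane_point[0]), float(m.plane_point[1])],
                },
            }
        )
    manifest = {
        "axis_convention": "frame-z-row-col",
        "probes": list(config.probes),
        "k_timepoints": config.k_timepoints,
        "entries": entries,
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "ground_truth.json").write_text(json.dumps(ds.ground_truth(), indent=2))
    return manifest_path
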