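"""Synthetic 4D TR-MRA phantom: parent artery, aneurysm remnant, coil mass.

The phantom emulates a time-resolved contrast-enhanced acquisition of a
coiled aneurysm: a cylindrical parent artery with an ellipsoidal remnant
attached through a narrow neck channel, partially capped by a
signal-void sphere standing in for the coil mass. A gamma-variate bolus
drives the lumen intensity over the dynamic phases; each phase is blurred
with a Gaussian point-spread function and degraded with Rician
(magnitude-MRI) noise. Ground truth is computed from the unblurred
voxelized geometry, so every downstream measurement can be checked
against exact values.

Defaults follow the acquisition the pipeline is designed for: ten
dynamic phases at 1.23 s temporal resolution and 1.0 mm isotropic voxels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from fwhmvasc._errors import ConfigurationError
from fwhmvasc.volio import AnnotationSet, VolumeSeries

__all__ = [
    "BolusParams",
    "PhantomConfig",
    "PhantomTruth",
    "gamma_variate",
    "generate_phantom",
    "default_annotations",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass(frozen=True)
class BolusParams:
    """Normalized gamma-variate bolus: peak intensity ``amplitude`` at
    ``t0 + alpha * beta`` seconds.

    ``alpha`` sets the shape (rise steepness), ``beta`` the time scale in
    seconds, ``t0`` the arrival onset.
    """

    amplitude: float = 200.0
    t0: float = 2.0
    alpha: float = 3.0
    beta: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ConfigurationError("bolus amplitude must be > 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError("bolus alpha and beta must be > 0")
        if self.t0 < 0:
            raise ConfigurationError("bolus onset t0 must be >= 0")

    @property
    def peak_time_s(self) -> float:
        return self.t0 + self.alpha * self.beta


def gamma_variate(t, p: BolusParams):
    """Normalized gamma-variate intensity multiplier at time ``t`` seconds.

    Zero for ``t <= t0``; for ``t > t0`` equals
    ``A * ((t - t0) / (alpha*beta))**alpha * exp(alpha - (t - t0)/beta)``,
    which attains its maximum ``A`` at ``t = t0 + alpha*beta``.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=np.float64)
    tau = t - p.t0
    with np.errstate(invalid="ignore"):
        val = np.where(
            tau > 0,
            p.amplitude
            * np.power(np.clip(tau, 0, None) / (p.alpha * p.beta), p.alpha)
            * np.exp(p.alpha - np.clip(tau, 0, None) / p.beta),
            0.0,
        )
    return float(val) if val.ndim == 0 else val


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic acquisition.

    All geometry is in world millimetres; the world position of voxel
    ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size_mm`` with the
    origin at zero, so a grid of shape ``n`` spans ``[0, (n-1)*voxel]``.
    ``seed`` is required: two runs with the same config and seed are
    bit-identical.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    n_phases: int = 10
    phase_interval_s: float = 1.23
    parent_radius_mm: float = 1.5
    parent_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    parent_center_mm: tuple[float, float, float] | None = None
    remnant_center_mm: tuple[float, float, float] | None = None
    remnant_semiaxes_mm: tuple[float, float, float] = (4.0, 3.0, 2.5)
    coil_center_mm: tuple[float, float, float] | None = None
    coil_radius_mm: float = 2.0
    neck_width_mm: float = 2.5
    bolus: BolusParams = field(default_factory=BolusParams)
    psf_sigma_mm: float = 0.5
    noise_sigma: float = 4.0
    background_level: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        object.__setattr__(self, "grid_shape", shape)
        for name in ("voxel_size_mm", "phase_interval_s", "parent_radius_mm",
                     "coil_radius_mm", "neck_width_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.n_phases < 1:
            raise ConfigurationError("n_phases must be >= 1")
        if self.psf_sigma_mm < 0 or self.noise_sigma < 0:
            raise ConfigurationError("psf_sigma_mm and noise_sigma must be >= 0")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")
        semi = tuple(float(s) for s in self.remnant_semiaxes_mm)
        if any(s <= 0 for s in semi):
            raise ConfigurationError("remnant_semiaxes_mm must be strictly positive")
        object.__setattr__(self, "remnant_semiaxes_mm", semi)
        axis = np.asarray(self.parent_axis, dtype=np.float64)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ConfigurationError("parent_axis must be a nonzero direction")
        object.__setattr__(self, "parent_axis", tuple(axis / norm))
        if self.seed is None:
            raise ConfigurationError("seed is required")

        centre = self._grid_centre()
        if self.parent_center_mm is None:
            object.__setattr__(self, "parent_center_mm", tuple(centre))
        if self.remnant_center_mm is None:
            # remnant sits above the parent in +z, joined by the neck channel
            zc = centre[2] + self.parent_radius_mm + 1.0 + semi[2]
            object.__setattr__(
                self, "remnant_center_mm", (centre[0], centre[1], zc)
            )
        if self.coil_center_mm is None:
            # coil mass caps the remnant dome from above, biting a small cap
            rc = np.asarray(self.remnant_center_mm)
            zc = rc[2] + semi[2] + 0.6 * self.coil_radius_mm
            object.__setattr__(self, "coil_center_mm", (rc[0], rc[1], zc))
        self._check_inside("remnant", np.asarray(self.remnant_center_mm),
                           max(semi))
        self._check_inside("coil", np.asarray(self.coil_center_mm),
                           self.coil_radius_mm)

    def _grid_centre(self) -> np.ndarray:
        # the central voxel's centre (not the half-voxel geometric centre):
        # anchoring structures on voxel centres avoids voxelization ties
        # where an analytic boundary passes exactly between voxel centres
        return (np.array(self.grid_shape) // 2) * self.voxel_size_mm

    def _check_inside(self, name: str, centre: np.ndarray, radius: float) -> None:
        hi = (np.array(self.grid_shape) - 1) * self.voxel_size_mm
        if np.any(centre - radius < 0) or np.any(centre + radius > hi):
            raise ConfigurationError(
                f"{name} geometry (centre {centre.tolist()}, extent {radius} mm) "
                f"does not fit inside the grid bounding box "
                f"{self.grid_shape} at {self.voxel_size_mm} mm"
            )

    @property
    def phase_times_s(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.phase_interval_s


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth of one generated phantom."""

    true_parent_diameter_mm: float
    true_remnant_largest_diameter_mm: float
    true_remnant_smallest_diameter_mm: float
    true_neck_length_mm: float
    true_remnant_volume_mm3: float
    lumen_mask: np.ndarray
    peak_phase_index: int

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("lumen_mask")
        return d


def _world_grid(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = cfg.grid_shape
    v = cfg.voxel_size_mm
    return np.meshgrid(
        np.arange(nx) * v, np.arange(ny) * v, np.arange(nz) * v, indexing="ij"
    )


def _lumen_masks(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize the analytic lumen by a centre-in-region test.

    Returns ``(lumen, remnant_component)`` where the remnant component is
    the ellipsoid (minus coil) used for the truth volume.
    """
    X, Y, Z = _world_grid(cfg)
    pts = np.stack([X, Y, Z], axis=-1)

    axis = np.asarray(cfg.parent_axis)
    c0 = np.asarray(cfg.parent_center_mm)
    rel = pts - c0
    along = rel @ axis
    radial2 = np.sum(rel * rel, axis=-1) - along**2
    cylinder = radial2 <= cfg.parent_radius_mm**2

    rc = np.asarray(cfg.remnant_center_mm)
    semi = np.asarray(cfg.remnant_semiaxes_mm)
    ellipsoid = np.sum(((pts - rc) / semi) ** 2, axis=-1) <= 1.0

    # neck channel: cylinder of radius neck_width/2 joining the parent axis
    # point nearest the remnant centre to the remnant centre
    foot = c0 + ((rc - c0) @ axis) * axis
    seg = rc - foot
    seg_len = np.linalg.norm(seg)
    if seg_len > 0:
        seg_dir = seg / seg_len
        rel_n = pts - foot
        t = rel_n @ seg_dir
        rad2 = np.sum(rel_n * rel_n, axis=-1) - t**2
        neck = (t >= 0) & (t <= seg_len) & (rad2 <= (cfg.neck_width_mm / 2) ** 2)
    else:
        neck = np.zeros_like(cylinder)

    cc = np.asarray(cfg.coil_center_mm)
    coil = np.sum((pts - cc) ** 2, axis=-1) <= cfg.coil_radius_mm**2

    lumen = (cylinder | ellipsoid | neck) & ~coil
    remnant = ellipsoid & ~coil
    return lumen, remnant


def generate_phantom(cfg: PhantomConfig) -> tuple[VolumeSeries, PhantomTruth]:
    """Generate the 4D volume and its exact ground truth.

    Per phase ``k`` at time ``k * phase_interval_s`` the lumen intensity is
    ``background_level + gamma_variate(t)``; the phase is then blurred with
    an isotropic Gaussian PSF and degraded with Rician noise
    ``sqrt((S + n1)^2 + n2^2)``. Deterministic given ``cfg.seed``.
    """
    lumen, remnant = _lumen_masks(cfg)
    rng = np.random.default_rng(cfg.seed)
    v = cfg.voxel_size_mm
    enh = gamma_variate(cfg.phase_times_s, cfg.bolus)
    enh = np.atleast_1d(enh)

    phases = []
    sigma_vox = cfg.psf_sigma_mm / v
    for k in range(cfg.n_phases):
        img = np.full(cfg.grid_shape, cfg.background_level, dtype=np.float64)
        img[lumen] += enh[k]
        if sigma_vox > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
        if cfg.noise_sigma > 0:
            n1 = rng.normal(0.0, cfg.noise_sigma, size=img.shape)
            n2 = rng.normal(0.0, cfg.noise_sigma, size=img.shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
        phases.append(img)
    data = np.stack(phases, axis=3)
    series = VolumeSeries(data, np.full(3, v), np.zeros(3), cfg.phase_interval_s)

    semi = np.asarray(cfg.remnant_semiaxes_mm)
    truth = PhantomTruth(
        true_parent_diameter_mm=2.0 * cfg.parent_radius_mm,
        true_remnant_largest_diameter_mm=2.0 * float(np.max(semi)),
        true_remnant_smallest_diameter_mm=2.0 * float(np.min(semi)),
        true_neck_length_mm=cfg.neck_width_mm,
        true_remnant_volume_mm3=float(np.count_nonzero(remnant)) * v**3,
        lumen_mask=lumen,
        peak_phase_index=int(np.argmax(enh)),
    )
    return series, truth


def default_annotations(cfg: PhantomConfig) -> AnnotationSet:
    """Operator annotations matched to the phantom geometry.

    The profile line crosses the remnant centre along the parent axis
    (its largest in-plane direction under the default y-projection),
    extended 6 mm beyond each end into background; neck points sit at the
    remnant/neck junction plane; the seed is the remnant centre; the
    projection normal is perpendicular to both the parent axis and the
    parent-to-remnant direction.
    """
    rc = np.asarray(cfg.remnant_center_mm)
    semi = np.asarray(cfg.remnant_semiaxes_mm)
    axis = np.asarray(cfg.parent_axis)
    line_half = semi[0] + 6.0
    a = rc - line_half * axis
    b = rc + line_half * axis

    c0 = np.asarray(cfg.parent_center_mm)
    up = rc - (c0 + ((rc - c0) @ axis) * axis)
    up = up / np.linalg.norm(up)
    normal = np.cross(axis, up)
    normal /= np.linalg.norm(normal)

    # neck junction plane: bottom of the ellipsoid along the neck direction
    z_neck = rc - semi[2] * up * 0.9
    half_neck = cfg.neck_width_mm / 2.0
    p_prox = z_neck - half_neck * axis
    p_dist = z_neck + half_neck * axis
    return AnnotationSet(
        profile_line=(a, b),
        neck_points=(p_prox, p_dist),
        seed_point=rc,
        projection_normal=normal,
    )


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def config_to_yaml(cfg: PhantomConfig, path: str | Path) -> None:
    import yaml

    d = _to_builtin(dataclasses.asdict(cfg))
    d["bolus"] = _to_builtin(dataclasses.asdict(cfg.bolus))
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> PhantomConfig:
    import yaml

    d = yaml.safe_load(Path(path).read_text())
    if "bolus" in d and d["bolus"] is not None:
        d["bolus"] = BolusParams(**d["bolus"])
    for key in ("grid_shape", "parent_axis", "parent_center_mm",
                "remnant_center_mm", "remnant_semiaxes_mm", "coil_center_mm"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)
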