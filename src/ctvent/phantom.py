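"""Synthetic inhale/exhale phantoms with analytically known Jacobian fields.

The phantom plays the role of a 4DCT extreme-phase pair: the reference
(exhale) image, a target (inhale) image deformed by a known diffeomorphism
``phi``, binary lung masks in both frames, the sampled inverse transformation
``phi_inv`` on the target grid, and the true ``det J`` field on the reference
grid.  A blurred, downsampled, noise-perturbed copy of the true field stands
in for a low-resolution nuclear-medicine ventilation reference.

Lungs are two half-ellipsoids (flat mediastinal face) inside a water-density
body cylinder; the exterior is air.  Densities inside the lungs carry a
smooth, seeded cosine-series texture so that intensity-based estimation has
structure to work with.  With ``mass_conserving=True`` the target density
satisfies ``rho_T(phi(x)) * detJ(x) = rho_R(x)`` exactly before noise, the
assumption underlying intensity-based (HU) ventilation estimation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grid import DisplacementField, Grid, ImageVolume

__all__ = [
    "Deformation",
    "Identity",
    "UniformScale",
    "Sinusoid",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "analytic_jacobian",
    "degrade_to_reference",
    "make_deformation",
]

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# deformation families
# ---------------------------------------------------------------------------

class Deformation:
    """A diffeomorphism phi: reference world coords -> target world coords."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def inverse(self, y: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def jacobian_det(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Identity(Deformation):
    def forward(self, x):
        return np.asarray(x, dtype=float).copy()

    def inverse(self, y):
        return np.asarray(y, dtype=float).copy()

    def jacobian_det(self, x):
        x = np.asarray(x, dtype=float)
        return np.ones(x.shape[:-1])


@dataclass(frozen=True)
class UniformScale(Deformation):
    """Anisotropic scaling about a fixed center: phi(x) = c + s * (x - c)."""

    scale: tuple[float, float, float]
    center: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale factors must be positive")

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        c = np.asarray(self.center)
        return c + np.asarray(self.scale) * (x - c)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        c = np.asarray(self.center)
        return c + (y - c) / np.asarray(self.scale)

    def jacobian_det(self, x):
        x = np.asarray(x, dtype=float)
        return np.full(x.shape[:-1], float(np.prod(self.scale)))


@dataclass(frozen=True)
class Sinusoid(Deformation):
    """Separable sinusoidal warp phi_i(x) = x_i + A_i sin(2 pi (x_i - o_i)/lambda_i).

    Diffeomorphic iff 2 pi A_i / lambda_i < 1 on every axis (the axial
    derivative 1 + (2 pi A/lambda) cos(.) then stays positive).  Because the
    warp is separable the Jacobian is diagonal and det J is the product of
    the axial derivatives; the inverse is computed per axis by Newton
    iteration on a strictly increasing scalar map.
    """

    amplitude_mm: tuple[float, float, float]
    wavelength_mm: tuple[float, float, float]
    phase_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for a, lam in zip(self.amplitude_mm, self.wavelength_mm):
            if lam <= 0:
                raise ValueError("wavelength must be positive")
            if _TWO_PI * abs(a) / lam >= 1.0:
                raise ValueError(
                    f"sinusoid with amplitude {a} mm and wavelength {lam} mm is "
                    "not diffeomorphic (requires 2*pi*A/lambda < 1)"
                )

    def _k(self):
        return _TWO_PI / np.asarray(self.wavelength_mm)

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        o = np.asarray(self.phase_origin)
        return x + np.asarray(self.amplitude_mm) * np.sin(self._k() * (x - o))

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        o = np.asarray(self.phase_origin)
        amp = np.asarray(self.amplitude_mm)
        k = self._k()
        x = y.copy()
        # Newton on g(x) = x + A sin(k (x - o)) - y; g' >= 1 - 2piA/lambda > 0
        for _ in range(60):
            g = x + amp * np.sin(k * (x - o)) - y
            gp = 1.0 + amp * k * np.cos(k * (x - o))
            step = g / gp
            x -= step
            if np.max(np.abs(step)) < 1e-12:
                break
        return x

    def jacobian_det(self, x):
        x = np.asarray(x, dtype=float)
        o = np.asarray(self.phase_origin)
        amp = np.asarray(self.amplitude_mm)
        k = self._k()
        d = 1.0 + amp * k * np.cos(k * (x - o))
        return np.prod(d, axis=-1)


def finite_difference_jacobian(deformation: Deformation, x: np.ndarray, step: float) -> np.ndarray:
    """Central-difference determinant of ``d phi / dx`` at points ``x`` (n,3).

    Independent numerical check of the closed-form ``jacobian_det``; accuracy
    is O(step^2), so use a step well below the deformation's length scale.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    J = np.empty((n, 3, 3))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = step
        J[:, :, ax] = (deformation.forward(x + e) - deformation.forward(x - e)) / (2 * step)
    return np.linalg.det(J)


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """All knobs of one synthetic case; seeded and fully reproducible.

    Deformation families: ``identity``, ``uniform_scale`` (per-axis factors,
    about the reference lung-mask centroid), ``sinusoid`` (per-axis amplitude
    and wavelength in mm).  ``base_density`` is the exhale lung density in
    g/cm^3; the texture is a smooth relative modulation of it.
    """

    grid_dims: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    deformation: str = "identity"
    scale: tuple[float, float, float] = (1.1, 1.1, 1.1)
    amplitude_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    wavelength_mm: tuple[float, float, float] = (40.0, 40.0, 40.0)
    base_density: float = 0.25
    density_texture_amplitude: float = 0.1
    texture_correlation_mm: float = 12.0
    hu_noise_sd: float = 0.0
    mass_conserving: bool = True
    seed: int = 0
    # slab-shaped acquisition-artifact injection (off by default; no
    # literature-fixed parameters exist for it)
    artifact_slab_z_mm: tuple[float, float] | None = None
    artifact_hu_offset: float = 0.0
    # degraded low-resolution reference
    coarse_spacing_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    blur_fwhm_mm: float = 10.0
    reference_noise_cv: float = 0.1

    def __post_init__(self):
        self.grid_dims = tuple(int(n) for n in self.grid_dims)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(n < 16 for n in self.grid_dims):
            raise ValueError("grid_dims must be >= 16 per axis")
        if not 0.0 < self.base_density <= 1.0:
            raise ValueError("base_density must lie in (0, 1]")
        if self.density_texture_amplitude < 0 or self.hu_noise_sd < 0:
            raise ValueError("texture amplitude and noise SD must be >= 0")
        if self.deformation not in ("identity", "uniform_scale", "sinusoid"):
            raise ValueError(f"unknown deformation family {self.deformation!r}")
        if self.deformation == "sinusoid":
            for a, lam, h in zip(self.amplitude_mm, self.wavelength_mm, self.spacing_mm):
                if _TWO_PI * abs(a) / lam >= 1.0:
                    raise ValueError("sinusoid parameters are not diffeomorphic")
                if lam < 4 * h:
                    raise ValueError(
                        f"wavelength {lam} mm below 4 voxels ({4 * h} mm): aliased"
                    )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("grid_dims", "spacing_mm", "scale", "amplitude_mm",
                    "wavelength_mm", "coarse_spacing_mm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("artifact_slab_z_mm") is not None:
            d["artifact_slab_z_mm"] = tuple(d["artifact_slab_z_mm"])
        return cls(**d)


@dataclass
class PhantomCase:
    """One generated case; everything mutually consistent by construction."""

    spec: PhantomSpec
    reference_image: ImageVolume      # HU, exhale role
    target_image: ImageVolume         # HU, inhale role
    mask_R: ImageVolume               # bool, reference lungs
    mask_T: ImageVolume               # bool, target lungs
    inverse_displacement: DisplacementField
    true_jacobian: ImageVolume        # det J at reference voxel centers
    spect_like_reference: ImageVolume # coarse, blurred, noisy true field
    deformation: Deformation


# ---------------------------------------------------------------------------
# anatomy and texture
# ---------------------------------------------------------------------------

class _LungShape:
    """Two half-ellipsoid lungs (flat medial faces) in a body cylinder.

    The medial cut plane is slightly tilted off the lattice axes so that
    voxel-center counting of the flat face dithers across voxel rows instead
    of systematically including a half-voxel slab (which would bias mask
    volumes by several percent and differently in the two frames).
    """

    _CUT_NORMAL = np.array([1.0, 0.21, 0.13])

    def __init__(self, grid: Grid):
        extent = grid.extent_mm
        self.center = grid.center_mm
        # semi-axes and medial offset scale with the field of view
        self.semi = np.array([0.1875, 0.26, 0.40]) * extent
        self.offset_x = 0.115 * extent[0]
        self.body_radius = 0.45 * min(extent[0], extent[1])
        self._n_hat = self._CUT_NORMAL / np.linalg.norm(self._CUT_NORMAL)

    def inside_lungs(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.zeros(pts.shape[:-1], dtype=bool)
        for side in (-1.0, +1.0):
            c = self.center + np.array([side * (self.offset_x + self.semi[0] / 2), 0, 0])
            r = ((pts - c) / self.semi) ** 2
            ell = r.sum(axis=-1) <= 1.0
            # flat mediastinal face through the ellipsoid center
            lateral = side * ((pts - c) @ self._n_hat) >= 0.0
            out |= ell & lateral
        return out

    def inside_body(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        d2 = (pts[..., 0] - self.center[0]) ** 2 + (pts[..., 1] - self.center[1]) ** 2
        return d2 <= self.body_radius ** 2


class _CosineTexture:
    """Smooth seeded random field: normalized sum of oblique cosine modes.

    Evaluable at arbitrary world points (needed to sample the deformed
    density consistently), zero mean, unit RMS before scaling.
    """

    def __init__(self, correlation_mm: float, rng: np.random.Generator, n_modes: int = 8):
        lam = rng.uniform(0.7 * correlation_mm, 1.4 * correlation_mm, size=n_modes)
        dirs = rng.normal(size=(n_modes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        self.k = dirs * (_TWO_PI / lam)[:, None]
        self.phase = rng.uniform(0, _TWO_PI, size=n_modes)
        self.norm = np.sqrt(2.0 / n_modes)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        acc = np.zeros(pts.shape[:-1])
        for km, ph in zip(self.k, self.phase):
            acc += np.cos(pts @ km + ph)
        return self.norm * acc


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def make_deformation(spec: PhantomSpec, center: np.ndarray | None = None) -> Deformation:
    """Instantiate the deformation family of a spec.

    ``center`` (world mm) anchors ``uniform_scale``; defaults to the grid
    center when no mask centroid is supplied.
    """
    if spec.deformation == "identity":
        return Identity()
    grid = Grid(spec.grid_dims, spec.spacing_mm)
    if center is None:
        center = grid.center_mm
    if spec.deformation == "uniform_scale":
        return UniformScale(tuple(spec.scale), tuple(np.asarray(center, dtype=float)))
    if spec.deformation == "sinusoid":
        return Sinusoid(tuple(spec.amplitude_mm), tuple(spec.wavelength_mm),
                        tuple(np.asarray(center, dtype=float)))
    raise ValueError(f"unknown deformation family {spec.deformation!r}")


def analytic_jacobian(spec: PhantomSpec, x: np.ndarray,
                      center: np.ndarray | None = None) -> np.ndarray:
    """Closed-form det J of the spec's deformation at world points ``x``."""
    return make_deformation(spec, center).jacobian_det(x)


def _density_to_hu(rho: np.ndarray) -> np.ndarray:
    return 1000.0 * rho - 1000.0


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build a fully consistent synthetic inhale/exhale case.

    The reference and target grids coincide (as for same-session 4DCT
    phases).  The target lung mask is the image of the continuous lung shape
    under phi, evaluated via the analytic inverse at target voxel centers,
    so that mask volumes are consistent with the deformation.
    """
    grid = Grid(spec.grid_dims, spec.spacing_mm)
    ss = np.random.SeedSequence(spec.seed)
    rng_texture, rng_noise_r, rng_noise_t, rng_ref = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    shape = _LungShape(grid)
    centers = grid.voxel_centers().reshape(*grid.shape, 3)
    mask_R = shape.inside_lungs(centers)
    if not mask_R.any():
        raise ValueError("degenerate phantom: empty lung mask")

    centroid = centers[mask_R].mean(axis=0)
    deformation = make_deformation(spec, centroid)

    # inverse transformation sampled at every target voxel center
    xr = deformation.inverse(centers.reshape(-1, 3)).reshape(*grid.shape, 3)
    u = xr - centers

    # target mask = discrete forward image of the reference mask: a target
    # voxel belongs to the inhale lung iff its inverse-mapped position falls
    # in the cell of a reference lung voxel (the same nearest-center
    # convention the hit-counting membership oracle uses).  This mirrors
    # mask-aligned registration and makes the two masks exactly consistent
    # with the displacement field at the lattice level.
    idx_r = np.rint(grid.world_to_index(xr.reshape(-1, 3))).astype(np.int64)
    inside = grid.contains_index(idx_r)
    mask_T_flat = np.zeros(idx_r.shape[0], dtype=bool)
    mask_T_flat[inside] = mask_R.ravel()[
        np.ravel_multi_index(idx_r[inside].T, grid.shape)]
    mask_T = mask_T_flat.reshape(grid.shape)

    detj_R = deformation.jacobian_det(centers.reshape(-1, 3)).reshape(grid.shape)
    if np.any(detj_R[mask_R] <= 0):
        raise ValueError("non-positive Jacobian inside the lung mask")

    texture = _CosineTexture(spec.texture_correlation_mm, rng_texture)

    def density_R_at(pts):
        rho = spec.base_density * (1.0 + spec.density_texture_amplitude * texture(pts))
        return np.clip(rho, 0.01, None)

    rho_R = density_R_at(centers)
    hu_R = np.where(mask_R, _density_to_hu(rho_R),
                    np.where(shape.inside_body(centers), 0.0, -1000.0))

    # target density at y: rho_T(y) = rho_R(phi_inv(y)) / detJ(phi_inv(y))
    detj_at_xr = deformation.jacobian_det(xr.reshape(-1, 3)).reshape(grid.shape)
    rho_T = density_R_at(xr)
    if spec.mass_conserving:
        rho_T = rho_T / detj_at_xr
    hu_T = np.where(mask_T, _density_to_hu(rho_T),
                    np.where(shape.inside_body(centers), 0.0, -1000.0))

    if spec.hu_noise_sd > 0:
        hu_R = hu_R + rng_noise_r.normal(0.0, spec.hu_noise_sd, hu_R.shape)
        hu_T = hu_T + rng_noise_t.normal(0.0, spec.hu_noise_sd, hu_T.shape)

    if spec.artifact_slab_z_mm is not None:
        z = centers[..., 2]
        z0, z1 = spec.artifact_slab_z_mm
        hu_T = np.where((z >= z0) & (z <= z1), hu_T + spec.artifact_hu_offset, hu_T)

    true_j = np.where(mask_R, detj_R, 0.0)
    spect_like = degrade_to_reference(
        ImageVolume(true_j, grid),
        spec.coarse_spacing_mm,
        spec.blur_fwhm_mm,
        rng_ref,
        noise_cv=spec.reference_noise_cv,
    )

    return PhantomCase(
        spec=spec,
        reference_image=ImageVolume(hu_R, grid),
        target_image=ImageVolume(hu_T, grid),
        mask_R=ImageVolume(mask_R, grid),
        mask_T=ImageVolume(mask_T, grid),
        inverse_displacement=DisplacementField(u, grid),
        true_jacobian=ImageVolume(true_j, grid),
        spect_like_reference=spect_like,
        deformation=deformation,
    )


def perturb_displacement(field: DisplacementField, sd_voxels: float,
                         correlation_voxels: float, seed: int) -> DisplacementField:
    """Add smooth, zero-mean vector noise to a displacement field.

    Emulates registration (DIR) variability: white Gaussian noise per
    component is smoothed with a Gaussian of ``correlation_voxels`` and
    rescaled so each component has standard deviation ``sd_voxels`` (in
    voxel units, converted to mm with the grid spacing).
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    noise = np.empty_like(field.data)
    for comp in range(3):
        w = rng.standard_normal(field.grid.shape)
        s = gaussian_filter(w, sigma=correlation_voxels)
        s /= s.std()
        noise[..., comp] = s * sd_voxels * field.grid.spacing[comp]
    return DisplacementField(field.data + noise, field.grid)


def degrade_to_reference(volume: ImageVolume, coarse_spacing_mm,
                         blur_fwhm_mm: float, noise_seed,
                         noise_cv: float = 0.1) -> ImageVolume:
    """Blur, downsample and perturb a field into a low-resolution reference.

    Gaussian blur (FWHM in mm), trilinear resampling onto a coarser grid
    centered on the same field of view, then additive Gaussian noise with SD
    proportional to the local mean, truncated below at zero — rank-preserving
    in expectation without modeling emission physics.

    ``noise_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    from scipy.ndimage import gaussian_filter, map_coordinates

    grid = volume.grid
    coarse_spacing = tuple(float(s) for s in coarse_spacing_mm)
    if any(s <= 0 for s in coarse_spacing):
        raise ValueError("coarse spacing must be positive")
    if any(c < f - 1e-9 for c, f in zip(coarse_spacing, grid.spacing)):
        raise ValueError("coarse spacing must be >= input spacing on every axis")

    data = np.asarray(volume.data, dtype=float)
    if blur_fwhm_mm > 0:
        sigma_vox = (blur_fwhm_mm / 2.3548) / np.asarray(grid.spacing)
        data = gaussian_filter(data, sigma=sigma_vox)

    cdims = tuple(max(1, int(np.floor(e / s))) for e, s in zip(grid.extent_mm, coarse_spacing))
    center = grid.center_mm
    corigin = tuple(center - (np.asarray(cdims) - 1) / 2.0 * np.asarray(coarse_spacing))
    cgrid = Grid(cdims, coarse_spacing, corigin)

    idx = grid.world_to_index(cgrid.voxel_centers()).T
    coarse = map_coordinates(data, idx, order=1, mode="nearest").reshape(cdims)

    if noise_cv > 0:
        rng = (noise_seed if isinstance(noise_seed, np.random.Generator)
               else np.random.default_rng(noise_seed))
        sd = noise_cv * np.abs(coarse)
        coarse = np.clip(coarse + rng.normal(0.0, 1.0, coarse.shape) * sd, 0.0, None)

    return ImageVolume(coarse, cgrid)
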