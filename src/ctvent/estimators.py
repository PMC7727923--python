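"""Subregional volume-change estimators and their uncertainty criteria.

Two estimator classes for the deformed volume of a reference subregion
``Omega``, i.e. the integral of det J over it:

* IJF (Integrated Jacobian Formulation, transformation-based): hit-or-miss
  counting.  Every target lung voxel whose inverse-mapped position lands
  inside ``Omega`` is a "hit"; the hit count H estimates the deformed volume
  in unit-voxel units.

* MCVC (Mass Conserving Volume Change, intensity-based): under air-mass
  conservation, mean reference density over ``Omega`` divided by mean target
  density over the deformed region, times |Omega|.

Both carry Gaussian uncertainty models that translate a relative tolerance
``tau`` (the 95%-probability cap on relative estimation error) into a
minimum region / hit-count size: larger regions, lower uncertainty, lower
spatial resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DisplacementField, Grid, ImageVolume
from .sampling import Subregion

__all__ = [
    "BETA_95",
    "DensityVolume",
    "SubregionEstimate",
    "hu_to_density",
    "HitMap",
    "count_hits",
    "ijf_tolerance",
    "ijf_estimate",
    "mcvc_tolerance",
    "mcvc_estimate",
    "ijf_predicate",
    "mcvc_predicate",
]

#: two-sided 95% Gaussian quantile used throughout the uncertainty criteria
BETA_95 = 1.96

#: mean target densities at or below this floor (g/cm^3) invalidate a region
MIN_MEAN_DENSITY = 1e-3


@dataclass
class DensityVolume:
    """Physical density (g/cm^3) derived from HU; role is reference or target."""

    values: ImageVolume
    source_role: str  # "reference" or "target"


def hu_to_density(hu: ImageVolume, source_role: str = "reference") -> DensityVolume:
    """Linear air/water calibration: rho = (HU + 1000)/1000, clamped at 0.

    Air (-1000 HU) maps to 0 g/cm^3 and water (0 HU) to 1 g/cm^3; values
    below -1000 HU clamp to zero density.
    """
    rho = np.clip((np.asarray(hu.data, dtype=float) + 1000.0) / 1000.0, 0.0, None)
    return DensityVolume(values=hu.like(rho), source_role=source_role)


@dataclass
class SubregionEstimate:
    """One subregional volume-change measurement b_k with its tolerance status."""

    region: Subregion
    method: str                 # "IJF" or "MCVC"
    hit_count: int
    value: float                # b_k, estimated integral of det J (voxel units)
    tolerance_met: bool
    tau: float
    valid: bool = True


# ---------------------------------------------------------------------------
# hit-or-miss machinery
# ---------------------------------------------------------------------------

class HitMap:
    """Precomputed landing statistics of target voxels on the reference grid.

    For every target-mask voxel center y, ``phi_inv(y)`` is binned to the
    nearest reference voxel (the membership test is a binary oracle, not a
    splat).  Per reference voxel we accumulate the hit count and, if a target
    density is supplied, the sum and sum of squares of the landing voxels'
    densities — everything region predicates and estimates need as box sums.
    """

    def __init__(self, displacement: DisplacementField, target_mask: ImageVolume,
                 reference_grid: Grid, density_T: DensityVolume | None = None):
        m = np.asarray(target_mask.data, dtype=bool)
        self.M = int(m.sum())
        self.reference_grid = reference_grid
        pos = displacement.phi_inv(m)
        idx = np.rint(reference_grid.world_to_index(pos)).astype(np.int64)
        inside = reference_grid.contains_index(idx)
        self.n_outside = int((~inside).sum())

        self._target_flat = np.flatnonzero(m.ravel())[inside]
        self._landing_flat = np.ravel_multi_index(idx[inside].T, reference_grid.shape)

        self.hit_count = np.zeros(reference_grid.shape, dtype=np.float64)
        np.add.at(self.hit_count.ravel(), self._landing_flat, 1.0)

        self.sum_T = None
        self.sum_T2 = None
        if density_T is not None:
            tvals = np.asarray(density_T.values.data, dtype=float).ravel()[self._target_flat]
            self.sum_T = np.zeros(reference_grid.shape, dtype=np.float64)
            self.sum_T2 = np.zeros(reference_grid.shape, dtype=np.float64)
            np.add.at(self.sum_T.ravel(), self._landing_flat, tvals)
            np.add.at(self.sum_T2.ravel(), self._landing_flat, tvals ** 2)

        order = np.argsort(self._landing_flat, kind="stable")
        self._landing_sorted = self._landing_flat[order]
        self._target_sorted = self._target_flat[order]

    def hits_in(self, region_flat: np.ndarray) -> tuple[int, np.ndarray]:
        """Hit count and the flat target-voxel indices landing in the region."""
        lo = np.searchsorted(self._landing_sorted, region_flat, side="left")
        hi = np.searchsorted(self._landing_sorted, region_flat, side="right")
        picks = [self._target_sorted[a:b] for a, b in zip(lo, hi) if b > a]
        hit_idx = np.concatenate(picks) if picks else np.empty(0, dtype=np.int64)
        return int(hit_idx.size), hit_idx


def count_hits(region: Subregion, inverse_displacement: DisplacementField,
               target_mask: ImageVolume, reference_grid: Grid | None = None,
               hit_map: HitMap | None = None) -> tuple[int, np.ndarray]:
    """Number of target voxels whose inverse-mapped position lands in ``region``.

    Landing positions outside the reference image domain count as misses
    (their number is available as ``HitMap.n_outside``).  Pass a prebuilt
    ``hit_map`` to amortize the landing computation over many regions.
    """
    if hit_map is None:
        if reference_grid is None:
            reference_grid = inverse_displacement.grid
        hit_map = HitMap(inverse_displacement, target_mask, reference_grid)
    return hit_map.hits_in(region.voxel_indices)


# ---------------------------------------------------------------------------
# IJF
# ---------------------------------------------------------------------------

def ijf_tolerance(H: float, M: float, tau: float, beta: float = BETA_95) -> bool:
    """Hit-count uncertainty criterion.

    The hit proportion H/M carries binomial sampling uncertainty; requiring
    the beta-sigma relative standard error of the estimated volume,
    ``beta * sqrt(H (1 - H/M)) / H``, to stay within ``tau`` yields the
    minimum hit count H* for a 95% relative-error guarantee.
    """
    if H <= 0:
        return False
    return beta * np.sqrt(H * max(0.0, 1.0 - H / M)) / H <= tau


def ijf_estimate(region: Subregion, hit_map: HitMap, tau: float,
                 beta: float = BETA_95) -> SubregionEstimate:
    """Hit-or-miss deformed-volume estimate b_k = H (unit-voxel volumes)."""
    H = int(hit_map.hit_count.ravel()[region.voxel_indices].sum())
    met = region.valid and ijf_tolerance(H, hit_map.M, tau, beta)
    return SubregionEstimate(
        region=region, method="IJF", hit_count=H,
        value=float(H), tolerance_met=bool(met), tau=float(tau),
        valid=region.valid and H > 0,
    )


def ijf_predicate(hit_count_field_index: int, M: int, tau: float,
                  beta: float = BETA_95):
    """Growth predicate for :class:`~ctvent.sampling.RegionGrower`.

    ``hit_count_field_index`` selects the hit-count array among the grower's
    fields.
    """
    def predicate(nvox: int, sums: np.ndarray) -> bool:
        return ijf_tolerance(sums[hit_count_field_index], M, tau, beta)
    return predicate


# ---------------------------------------------------------------------------
# MCVC
# ---------------------------------------------------------------------------

def _sd(total: float, total_sq: float, n: float) -> float:
    if n <= 0:
        return 0.0
    mean = total / n
    var = max(0.0, total_sq / n - mean ** 2)
    return float(np.sqrt(var))


def mcvc_tolerance(nvox: float, H: float, tau: float,
                   sums: np.ndarray | None = None,
                   mode: str = "fixed", beta: float = BETA_95) -> bool:
    """Region-size criteria controlling both sample-mean uncertainties.

    ``mode="fixed"`` (default): |Omega| >= beta^2/tau^2 and H >= beta^2/tau^2,
    the printed form of the Gaussian standard-error bounds with densities
    normalized to unit scale.

    ``mode="adaptive"``: plug-in coefficient-of-variation form using the
    in-region sample statistics, |Omega| >= (beta * sd_R / (mean_R tau))^2
    and H >= (beta * sd_T / (mean_T tau))^2.  Requires ``sums`` =
    (sum_R, sum_R2, sum_T, sum_T2) over the region / hit set.  Constant
    densities therefore pass for any region with at least one voxel and one
    hit.
    """
    if nvox < 1 or H < 1:
        return False
    if mode == "fixed":
        need = (beta / tau) ** 2
        return nvox >= need and H >= need
    if mode == "adaptive":
        if sums is None:
            raise ValueError("adaptive mode requires in-region density sums")
        sum_r, sum_r2, sum_t, sum_t2 = sums
        mean_r = sum_r / nvox
        mean_t = sum_t / H
        if mean_r <= MIN_MEAN_DENSITY or mean_t <= MIN_MEAN_DENSITY:
            return False
        need_r = (beta * _sd(sum_r, sum_r2, nvox) / (mean_r * tau)) ** 2
        need_t = (beta * _sd(sum_t, sum_t2, H) / (mean_t * tau)) ** 2
        return nvox >= need_r and H >= need_t
    raise ValueError(f"unknown MCVC tolerance mode {mode!r}")


def mcvc_estimate(region: Subregion, density_R: DensityVolume, hit_map: HitMap,
                  tau: float, mode: str = "fixed",
                  beta: float = BETA_95) -> SubregionEstimate:
    """Density-ratio deformed-volume estimate.

    b_k = mean(rho_R over region) / mean(rho_T over landing target voxels)
    * |region|.  The target-side mean is taken over exactly the hit set, so
    its sample size is the hit count H.  Regions whose mean target density
    falls at or below a small floor are invalidated (ratio blow-up).
    """
    if hit_map.sum_T is None:
        raise ValueError("hit map was built without a target density")
    flat = region.voxel_indices
    rvals = np.asarray(density_R.values.data, dtype=float).ravel()[flat]
    nvox = flat.size
    H = float(hit_map.hit_count.ravel()[flat].sum())
    sum_t = float(hit_map.sum_T.ravel()[flat].sum())
    sum_t2 = float(hit_map.sum_T2.ravel()[flat].sum())
    sum_r = float(rvals.sum())
    sum_r2 = float((rvals ** 2).sum())

    valid = region.valid and nvox > 0 and H > 0
    value = np.nan
    if valid:
        mean_r = sum_r / nvox
        mean_t = sum_t / H
        if mean_t <= MIN_MEAN_DENSITY:
            valid = False
        else:
            value = mean_r / mean_t * nvox
    met = valid and mcvc_tolerance(
        nvox, H, tau, sums=(sum_r, sum_r2, sum_t, sum_t2), mode=mode, beta=beta
    )
    return SubregionEstimate(
        region=region, method="MCVC", hit_count=int(H),
        value=float(value) if valid else np.nan,
        tolerance_met=bool(met), tau=float(tau), valid=bool(valid),
    )


def mcvc_predicate(tau: float, mode: str = "fixed", beta: float = BETA_95):
    """Growth predicate; grower fields must be (hits, sum_T, sum_T2, rho_R, rho_R^2)."""
    def predicate(nvox: int, sums: np.ndarray) -> bool:
        H = sums[0]
        return mcvc_tolerance(
            nvox, H, tau,
            sums=(sums[3], sums[4], sums[1], sums[2]),
            mode=mode, beta=beta,
        )
    return predicate
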