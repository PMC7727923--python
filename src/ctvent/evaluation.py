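"""Comparison of ventilation images against a low-resolution reference.

The protocol mirrors how CT-ventilation maps are validated against nuclear-
medicine ventilation: resample the fine-grid ventilation signal into the
reference frame with a (given) affine transform, median-filter the reference
slice by slice, and compute the voxelwise Spearman rank correlation inside
the lung mask at the reference resolution.  A tolerance sweep repeats the
whole reconstruction at each uncertainty value and records one correlation
per tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, stats

from .grid import Grid, ImageVolume, same_grid

__all__ = [
    "CorrelationRecord",
    "SweepSummary",
    "resample_with_affine",
    "median_filter_slicewise",
    "spearman_masked",
    "correlate_to_reference",
    "sweep_tau",
    "default_tau_grid",
    "summarize",
    "sweep_summary",
    "wilcoxon_signed_rank",
]


@dataclass
class CorrelationRecord:
    case_id: str
    method: str
    tau: float
    rho: float                 # NaN when undefined (constant field) or failed
    n_voxels: int
    error: str | None = None


@dataclass
class SweepSummary:
    taus: np.ndarray
    minimum: np.ndarray
    q25: np.ndarray
    median: np.ndarray
    q75: np.ndarray
    maximum: np.ndarray
    optimal_tau: float


def resample_with_affine(image: ImageVolume, affine: np.ndarray,
                         target_grid: Grid) -> ImageVolume:
    """Trilinear resampling of an affinely transformed image onto a grid.

    ``affine`` is a 4x4 world-space transform mapping input-image coordinates
    to output coordinates; each output voxel center y is sampled at
    ``affine^-1 y``.  Voxels sampled outside the input field of view are
    marked missing (NaN).
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    det = np.linalg.det(affine[:3, :3])
    if abs(det) < 1e-12:
        raise ValueError("affine transform is singular")
    inv = np.linalg.inv(affine)

    y = target_grid.voxel_centers()
    x = y @ inv[:3, :3].T + inv[:3, 3]
    idx = image.grid.world_to_index(x).T
    vals = ndimage.map_coordinates(
        np.asarray(image.data, dtype=float), idx, order=1,
        mode="constant", cval=np.nan,
    )
    return ImageVolume(vals.reshape(target_grid.shape), target_grid)


def median_filter_slicewise(image: ImageVolume) -> ImageVolume:
    """Per-axial-slice 3x3 median; edges use the reduced in-bounds window."""
    data = np.asarray(image.data, dtype=float)
    nx, ny, nz = data.shape
    padded = np.full((nx + 2, ny + 2, nz), np.nan)
    padded[1:-1, 1:-1, :] = data
    stack = np.empty((9, nx, ny, nz))
    n = 0
    for dx in (0, 1, 2):
        for dy in (0, 1, 2):
            stack[n] = padded[dx:dx + nx, dy:dy + ny, :]
            n += 1
    with np.errstate(all="ignore"):
        out = np.nanmedian(stack, axis=0)
    return image.like(out)


def spearman_masked(a: ImageVolume, b: ImageVolume, mask: ImageVolume) -> float:
    """Spearman rank correlation (midranks for ties) over masked voxels.

    Voxels with a missing value in either image are excluded pairwise.
    Returns NaN (missing, not zero) when either input is constant on the
    usable voxels; raises if fewer than 3 usable voxels remain.
    """
    m = np.asarray(mask.data, dtype=bool)
    av = np.asarray(a.data, dtype=float)[m]
    bv = np.asarray(b.data, dtype=float)[m]
    ok = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[ok], bv[ok]
    if av.size < 3:
        raise ValueError("Spearman correlation needs at least 3 usable voxels")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(av, bv)
    return float(rho)


def correlate_to_reference(signal: ImageVolume, reference: ImageVolume,
                           mask: ImageVolume, affine: np.ndarray | None = None,
                           median_filter: bool = True,
                           mask_threshold: float = 0.5) -> tuple[float, int]:
    """Full comparison protocol; returns (rho, n usable voxels).

    The signal and mask are brought onto the reference grid (identity affine
    when none is given); the mask survives where its partial-volume fraction
    is at least ``mask_threshold``.  The reference is median-filtered slice
    by slice unless disabled (disable when the reference is already clean,
    e.g. a known ground-truth field).
    """
    if affine is None:
        affine = np.eye(4)
    if median_filter:
        reference = median_filter_slicewise(reference)
    if not same_grid(signal.grid, reference.grid) or not np.allclose(affine, np.eye(4)):
        signal = resample_with_affine(signal, affine, reference.grid)
        mask_f = resample_with_affine(
            ImageVolume(np.asarray(mask.data, dtype=float), mask.grid),
            affine, reference.grid)
        mask = ImageVolume(np.nan_to_num(mask_f.data) >= mask_threshold,
                           reference.grid)
    n = int(np.asarray(mask.data, dtype=bool).sum())
    rho = spearman_masked(signal, reference, mask)
    return rho, n


def default_tau_grid(n: int = 30, lo: float = 0.01, hi: float = 0.25) -> np.ndarray:
    """The uncertainty-tolerance sweep grid: n uniform values on [lo, hi]."""
    return np.linspace(lo, hi, n)


def sweep_tau(ventilate: Callable[[float], ImageVolume],
              reference: ImageVolume, mask: ImageVolume,
              tau_values: Sequence[float] | None = None,
              case_id: str = "case", method: str = "IJF",
              affine: np.ndarray | None = None,
              median_filter: bool = True) -> list[CorrelationRecord]:
    """Run the full pipeline at each tolerance and correlate each result.

    ``ventilate`` maps a tolerance tau to the ventilation signal image.
    Per-tolerance failures (e.g. no subregion passes at a very small tau)
    are recorded on the record and the sweep continues.
    """
    if tau_values is None:
        tau_values = default_tau_grid()
    records = []
    for tau in tau_values:
        tau = float(tau)
        if not 0.0 < tau < 1.0:
            raise ValueError(f"tau must lie in (0, 1); got {tau}")
        try:
            signal = ventilate(tau)
            rho, n = correlate_to_reference(
                signal, reference, mask, affine=affine, median_filter=median_filter)
            records.append(CorrelationRecord(case_id, method, tau, rho, n))
        except Exception as exc:  # per-tau failure: record and continue
            records.append(CorrelationRecord(case_id, method, tau, float("nan"), 0,
                                             error=str(exc)))
    return records


def summarize(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, 25th, median, 75th, max) with midpoint interpolation."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty list")
    return (
        float(vals.min()),
        float(np.percentile(vals, 25, method="midpoint")),
        float(np.median(vals)),
        float(np.percentile(vals, 75, method="midpoint")),
        float(vals.max()),
    )


def sweep_summary(records: list[CorrelationRecord]) -> SweepSummary:
    """Percentile curves over cases at each swept tolerance."""
    taus = sorted({r.tau for r in records})
    curves = {k: [] for k in ("minimum", "q25", "median", "q75", "maximum")}
    for tau in taus:
        vals = [r.rho for r in records if r.tau == tau and np.isfinite(r.rho)]
        if not vals:
            for k in curves:
                curves[k].append(float("nan"))
            continue
        mn, q25, med, q75, mx = summarize(vals)
        for k, v in zip(curves, (mn, q25, med, q75, mx)):
            curves[k].append(v)
    med = np.asarray(curves["median"])
    optimal = float(taus[int(np.nanargmax(med))]) if np.isfinite(med).any() else float("nan")
    return SweepSummary(
        taus=np.asarray(taus), minimum=np.asarray(curves["minimum"]),
        q25=np.asarray(curves["q25"]), median=med,
        q75=np.asarray(curves["q75"]), maximum=np.asarray(curves["maximum"]),
        optimal_tau=optimal,
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test: returns (W_minus, two-sided p).

    Zero differences are dropped; tied absolute differences receive
    midranks.  For n <= 25 the p-value comes from the exact permutation
    distribution of the rank sum under sign flips (computed by dynamic
    programming over doubled midranks, so tied ranks are handled exactly);
    above that, a normal approximation with tie-corrected variance is used.
    The two-sided p is twice the smaller tail, capped at 1.
    """
    x = np.asarray(list(x), dtype=float)
    if y is not None:
        d = x - np.asarray(list(y), dtype=float)
    else:
        d = x
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_minus = float(ranks[d < 0].sum())
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        # DP over the distribution of the doubled rank sum under sign flips
        dranks = np.rint(2 * ranks).astype(int)
        total = int(dranks.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in dranks:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:total + 1 - r]
            counts = counts + shifted
        counts /= 2.0 ** n
        w_obs = int(round(2 * min(w_minus, w_plus)))
        p = 2.0 * counts[: w_obs + 1].sum()
    else:
        mean = n * (n + 1) / 4.0
        var = float((ranks ** 2).sum()) / 4.0
        w = min(w_minus, w_plus)
        z = (w - mean) / np.sqrt(var)
        p = 2.0 * stats.norm.cdf(z)
    return w_minus, float(min(1.0, p))
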