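"""End-to-end orchestration: case preparation, single runs, tolerance sweeps.

A :class:`PreparedCase` holds everything that is tolerance-independent —
densities, the hit map (landing statistics of every target voxel), dart-thrown
knots and subdomain seed points, the MLS weight matrix, summed-area tables for
region growth, and the per-method global constants h.  ``ventilate`` then
reconstructs one image for a given method and tolerance; ``sweep`` repeats it
over a tolerance grid; ``run_case`` drives everything from a file-based
configuration and writes volumes, diagnostics tables and a machine-readable
report.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import estimators, evaluation, io, mls, sampling, solver
from .grid import DisplacementField, Grid, ImageVolume, same_grid

__all__ = ["CaseConfig", "PreparedCase", "run_case"]

CLINICAL_KNOT_SPACING_MM = 30.0
CLINICAL_SUBDOMAIN_SPACING_MM = 7.0

# Protocol for the synthetic phantoms, whose lungs are ~10x smaller than
# clinical lungs: the knot spacing must resolve the deformation length scale
# (the MLS representation ceiling collapses above ~1/3 of the deformation
# wavelength) and the subdomain cloud is densified proportionally.
PHANTOM_KNOT_SPACING_MM = 12.0
PHANTOM_SUBDOMAIN_SPACING_MM = 5.0


@dataclass
class CaseConfig:
    """File-based description of one ventilation computation."""

    reference_image: str = ""
    target_image: str = ""
    mask_R: str = ""
    mask_T: str = ""
    displacement: str = ""
    reference_ventilation: str | None = None   # optional comparison image
    affine: str | None = None                  # optional 4x4 text file
    method: str = "IJF"
    tau: float = 0.07
    tau_sweep: bool = False
    tau_min: float = 0.01
    tau_max: float = 0.25
    tau_count: int = 30
    knot_spacing_mm: float = CLINICAL_KNOT_SPACING_MM
    subdomain_spacing_mm: float = CLINICAL_SUBDOMAIN_SPACING_MM
    structure: tuple[int, int, int] = (3, 3, 3)
    max_dilations: int = 20
    mcvc_mode: str = "fixed"
    epsilon: float = 0.05
    lambda_reg: float = 1.0
    signal_direction: str = "reference_is_exhale"
    seed: int = 0
    output_dir: str = "."
    case_id: str = "case"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "structure" in d:
            d["structure"] = tuple(d["structure"])
        return cls(**d)


class PreparedCase:
    """Tolerance-independent precomputation shared by all reconstructions."""

    def __init__(self, reference_image: ImageVolume, target_image: ImageVolume,
                 mask_R: ImageVolume, mask_T: ImageVolume,
                 displacement: DisplacementField,
                 knot_spacing_mm: float = CLINICAL_KNOT_SPACING_MM,
                 subdomain_spacing_mm: float = CLINICAL_SUBDOMAIN_SPACING_MM,
                 structure: tuple[int, int, int] = (3, 3, 3),
                 max_dilations: int = 20,
                 mcvc_mode: str = "fixed",
                 seed: int = 0,
                 need_densities: bool = True):
        for vol, name in ((target_image, "target image"), (mask_R, "reference mask"),
                          (mask_T, "target mask")):
            if vol is not None:
                io.check_same_grid(reference_image, vol, f"reference image and {name}")
        io.check_same_grid(mask_T, ImageVolume(displacement.data[..., 0], displacement.grid),
                           "target mask and displacement field")

        self.grid = reference_image.grid
        self.mask_R = ImageVolume(np.asarray(mask_R.data, dtype=bool), mask_R.grid)
        self.mask_T = ImageVolume(np.asarray(mask_T.data, dtype=bool), mask_T.grid)
        self.displacement = displacement
        self.structure = tuple(structure)
        self.max_dilations = int(max_dilations)
        self.mcvc_mode = mcvc_mode

        self.density_R = self.density_T = None
        if need_densities:
            self.density_R = estimators.hu_to_density(reference_image, "reference")
            self.density_T = estimators.hu_to_density(target_image, "target")

        self.hit_map = estimators.HitMap(
            displacement, self.mask_T, self.grid, density_T=self.density_T)

        ss = np.random.SeedSequence(seed)
        knot_seed, seed_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
        self.knots = sampling.dart_throw(self.mask_R, knot_spacing_mm, knot_seed)
        self.seeds = sampling.dart_throw(self.mask_R, subdomain_spacing_mm, seed_seed)
        self.seed_indices = np.rint(
            self.grid.world_to_index(self.seeds.points)).astype(int)

        self.model = mls.build_weight_matrix(self.mask_R, self.knots)
        self.N = self.model.n_voxels

        rho_R = self.density_R.values.data if self.density_R else None
        fields = [self.hit_map.hit_count]
        if self.density_T is not None:
            fields += [self.hit_map.sum_T, self.hit_map.sum_T2,
                       rho_R, np.asarray(rho_R) ** 2]
        self.grower = sampling.RegionGrower(self.mask_R, fields, self.structure)

        self.h = {"IJF": solver.global_constraint_constant(
            "IJF", self.mask_R, self.mask_T)}
        if need_densities:
            self.h["MCVC"] = solver.global_constraint_constant(
                "MCVC", self.mask_R, self.mask_T, self.density_R, self.density_T)

    # -- per-tolerance reconstruction ------------------------------------

    def estimates(self, method: str, tau: float) -> list[estimators.SubregionEstimate]:
        """Grow all subregions and measure them for one method/tolerance."""
        method = method.upper()
        if method == "IJF":
            predicate = estimators.ijf_predicate(0, self.hit_map.M, tau)
        elif method == "MCVC":
            if self.density_T is None:
                raise ValueError("case was prepared without densities; MCVC unavailable")
            predicate = estimators.mcvc_predicate(tau, mode=self.mcvc_mode)
        else:
            raise ValueError(f"unknown method {method!r}")

        out = []
        for seed_idx in self.seed_indices:
            region = self.grower.grow(seed_idx, predicate, self.max_dilations)
            if not region.valid:
                continue
            if method == "IJF":
                est = estimators.ijf_estimate(region, self.hit_map, tau)
            else:
                est = estimators.mcvc_estimate(
                    region, self.density_R, self.hit_map, tau, mode=self.mcvc_mode)
            out.append(est)
        return out

    def ventilate(self, method: str, tau: float,
                  cfg: solver.SolveConfig | None = None,
                  signal_direction: str = "reference_is_exhale"
                  ) -> solver.VentilationResult:
        """Subregions -> estimates -> linear system -> constrained solve."""
        method = method.upper()
        ests = self.estimates(method, tau)
        system = mls.assemble_system(ests, self.model, self.h[method])
        return solver.solve_ventilation(
            system, self.model, cfg, tau=tau, method=method,
            signal_direction=signal_direction)

    def sweep(self, method: str, reference: ImageVolume, mask: ImageVolume,
              tau_values=None, affine=None, median_filter: bool = True,
              cfg: solver.SolveConfig | None = None, case_id: str = "case",
              signal_direction: str = "reference_is_exhale"):
        """Tolerance sweep with the standard correlation protocol."""
        return evaluation.sweep_tau(
            lambda tau: self.ventilate(method, tau, cfg, signal_direction).signal,
            reference, mask, tau_values=tau_values, case_id=case_id,
            method=method.upper(), affine=affine, median_filter=median_filter)


def _load_affine(path: str | None) -> np.ndarray | None:
    if path is None:
        return None
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: affine file must contain a 4x4 matrix")
    return mat


def run_case(cfg: CaseConfig) -> dict:
    """Run one configured case end to end and write all artifacts.

    Writes the ventilation and signal volumes (NIfTI), a subregion
    diagnostics table (CSV), a sweep table when sweeping, and a JSON report.
    Deterministic given the config seed.  Returns the report dictionary.
    """
    method = cfg.method.upper()
    if method not in ("IJF", "MCVC"):
        raise ValueError(f"unknown method {cfg.method!r}")
    for path, name in ((cfg.reference_image, "reference image"),
                       (cfg.mask_R, "reference mask"),
                       (cfg.mask_T, "target mask"),
                       (cfg.displacement, "displacement field")):
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"{name} not found: {path!r}")
    if method == "MCVC" and (not cfg.target_image or not os.path.exists(cfg.target_image)):
        raise FileNotFoundError(
            f"MCVC requires a target image; not found: {cfg.target_image!r}")

    ref = io.read_volume(cfg.reference_image)
    tgt = io.read_volume(cfg.target_image) if cfg.target_image else ref
    mask_R = io.read_volume(cfg.mask_R)
    mask_T = io.read_volume(cfg.mask_T)
    disp = io.read_displacement(cfg.displacement)
    affine = _load_affine(cfg.affine)
    reference_vent = (io.read_volume(cfg.reference_ventilation)
                      if cfg.reference_ventilation else None)

    prepared = PreparedCase(
        ref, tgt,
        ImageVolume(mask_R.data > 0.5, mask_R.grid),
        ImageVolume(mask_T.data > 0.5, mask_T.grid),
        disp,
        knot_spacing_mm=cfg.knot_spacing_mm,
        subdomain_spacing_mm=cfg.subdomain_spacing_mm,
        structure=cfg.structure, max_dilations=cfg.max_dilations,
        mcvc_mode=cfg.mcvc_mode, seed=cfg.seed,
        need_densities=(method == "MCVC" or bool(cfg.target_image)),
    )
    solve_cfg = solver.SolveConfig(epsilon=cfg.epsilon, lambda_reg=cfg.lambda_reg)

    os.makedirs(cfg.output_dir, exist_ok=True)
    report: dict = {
        "case_id": cfg.case_id, "method": method, "seed": cfg.seed,
        "n_knots": prepared.model.n_knots, "n_seeds": len(prepared.seeds),
        "N": prepared.N, "M": prepared.hit_map.M,
        "h": prepared.h[method],
    }

    if cfg.tau_sweep:
        taus = evaluation.default_tau_grid(cfg.tau_count, cfg.tau_min, cfg.tau_max)
        rows = []
        for tau in taus:
            row = {"tau": float(tau)}
            try:
                result = prepared.ventilate(method, float(tau), solve_cfg,
                                            cfg.signal_direction)
                row.update(residual_norm=result.residual_norm,
                           constraint_gap=result.constraint_gap)
                if reference_vent is not None:
                    rho, n = evaluation.correlate_to_reference(
                        result.signal, reference_vent, prepared.mask_R, affine=affine)
                    row.update(rho=rho, n_voxels=n)
            except Exception as exc:
                row.update(error=str(exc))
            rows.append(row)
        sweep_df = pd.DataFrame(rows)
        sweep_path = os.path.join(cfg.output_dir, f"{cfg.case_id}_{method}_sweep.csv")
        sweep_df.to_csv(sweep_path, index=False)
        report["sweep_table"] = sweep_path
        report["n_tau"] = len(taus)
    else:
        result = prepared.ventilate(method, cfg.tau, solve_cfg, cfg.signal_direction)
        ests = prepared.estimates(method, cfg.tau)
        vent_path = os.path.join(cfg.output_dir, f"{cfg.case_id}_{method}_vent.nii.gz")
        sig_path = os.path.join(cfg.output_dir, f"{cfg.case_id}_{method}_signal.nii.gz")
        io.write_volume(result.V, vent_path)
        io.write_volume(result.signal, sig_path)
        diag = pd.DataFrame({
            "seed_i": [e.region.seed_index[0] for e in ests],
            "seed_j": [e.region.seed_index[1] for e in ests],
            "seed_k": [e.region.seed_index[2] for e in ests],
            "size": [e.region.size for e in ests],
            "dilations": [e.region.dilation_count for e in ests],
            "hits": [e.hit_count for e in ests],
            "b": [e.value for e in ests],
            "tolerance_met": [e.tolerance_met for e in ests],
        })
        diag_path = os.path.join(cfg.output_dir, f"{cfg.case_id}_{method}_subregions.csv")
        diag.to_csv(diag_path, index=False)
        report.update(
            tau=cfg.tau, K=int(diag.tolerance_met.sum()),
            residual_norm=result.residual_norm,
            constraint_gap=result.constraint_gap,
            hit_stats={"median": float(diag.hits.median()),
                       "min": int(diag.hits.min()), "max": int(diag.hits.max())},
            ventilation_volume=vent_path, signal_volume=sig_path,
            subregion_table=diag_path,
        )
        if reference_vent is not None:
            rho, n = evaluation.correlate_to_reference(
                result.signal, reference_vent, prepared.mask_R, affine=affine)
            report.update(rho=rho, n_voxels_correlated=n)

    report_path = os.path.join(cfg.output_dir, f"{cfg.case_id}_{method}_report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    report["report_path"] = report_path
    return report
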