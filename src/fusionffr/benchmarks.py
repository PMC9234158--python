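"""Canonical validation benchmarks for the solver and the fusion pipeline.

Each function builds its inputs from the synthetic generators (or closed-form
geometry), runs the package end to end, and returns a dict of measured
quantities.  They are exercised by the acceptance test suite and by
``scripts/acceptance.py``; problem sizes are chosen so the full set runs on
one CPU in well under an hour.
"""
from __future__ import annotations

import numpy as np

from .contours import SurfaceMesh
from .fuse import fuse, register
from .hemodynamics import (MMHG_TO_PA, BoundaryConditions, FluidParams,
                           SolverConfig, carreau_yasuda_viscosity,
                           compute_vorticity_helicity, compute_wss,
                           resistance_for_target_flow, solve_steady, voxelize)
from .metrics import (area_stenosis, confusion_from_rates,
                      diagnostic_performance, roc_auc, steiger_z)
from .reconstruct import ray_cast_surface, reconstruct_stack
from .synthetic import ImagingSpec, VesselSpec, generate_vessel, image_vessel

INLET_PRESSURE_MMHG = 90.0


def cylinder_mesh(radius_mm: float, length_mm: float, n_points: int = 128,
                  dz_mm: float = 0.2) -> SurfaceMesh:
    th = np.arange(n_points) * 2 * np.pi / n_points
    zs = np.arange(0.0, length_mm + 1e-9, dz_mm)
    rings = np.stack([
        np.stack([radius_mm * np.cos(th), radius_mm * np.sin(th),
                  np.full(n_points, z)], axis=1) for z in zs])
    return ray_cast_surface(rings)


# ---------------------------------------------------------------------------
# solver physics
# ---------------------------------------------------------------------------

def poiseuille_benchmark(radius_mm: float = 1.5, length_mm: float = 12.0,
                         dx_mm: float = 0.1, dp_pa: float = 0.6,
                         tol: float = 1e-5) -> dict:
    """Newtonian pressure-driven tube flow against Hagen-Poiseuille.

    The driving pressure keeps Re of order 1 so the mid-tube region is fully
    developed; the axial pressure gradient is fitted there and compared with
    8*mu*Q/(pi*r^4) at the measured flow.  Wall shear stress is compared with
    4*mu*Q/(pi*r^3) over the same region.
    """
    mesh = cylinder_mesh(radius_mm, length_mm)
    lattice = voxelize(mesh, dx_mm, min_diameter_mm=2 * radius_mm)
    fluid = FluidParams.newtonian()
    bc = BoundaryConditions(
        inlet_pressure=INLET_PRESSURE_MMHG,
        outlet_reference_pressure=INLET_PRESSURE_MMHG - dp_pa / MMHG_TO_PA)
    sol = solve_steady(lattice, fluid, bc, SolverConfig(tol=tol))

    prof = sol.centerline_pressure_profile
    lo, hi = length_mm / 3.0, length_mm * 0.72
    sel = (prof[:, 0] > lo) & (prof[:, 0] < hi)
    grad_pa_m = -np.polyfit(prof[sel, 0], prof[sel, 1], 1)[0] * MMHG_TO_PA * 1e3
    q_m3 = sol.q_out_ml_s * 1e-6
    r_m = radius_mm * 1e-3
    grad_hp = 8.0 * fluid.mu_inf * q_m3 / (np.pi * r_m ** 4)
    _, s_mm, wss = compute_wss(sol)
    core = (s_mm > lo) & (s_mm < hi)
    wss_hp = 4.0 * fluid.mu_inf * q_m3 / (np.pi * r_m ** 3)
    dp_hp_20mm_pa = grad_hp * 0.02  # the drop an r=1.5 tube shows over 20 mm
    return {
        "q_ml_s": sol.q_out_ml_s,
        "gradient_error_pct": 100.0 * abs(grad_pa_m / grad_hp - 1.0),
        "dp_pa_per_20mm": grad_pa_m * 0.02,
        "dp_hp_pa_per_20mm": dp_hp_20mm_pa,
        "mass_imbalance_pct": 100.0 * abs(sol.q_in_ml_s - sol.q_out_ml_s)
        / abs(sol.q_in_ml_s),
        "wss_error_pct": 100.0 * abs(float(wss[core].mean()) / wss_hp - 1.0),
        "steps": sol.steps,
    }


def carreau_yasuda_limits() -> dict:
    p = FluidParams()
    return {
        "mu_zero_shear": carreau_yasuda_viscosity(0.0, p),
        "mu_infinite_shear": carreau_yasuda_viscosity(1e9, p),
        "mu_unit_shear": carreau_yasuda_viscosity(1.0, p),
    }


def zero_flow_ffr(dx_mm: float = 0.15) -> dict:
    """Equal inlet and outlet pressures with no outlet resistance: the fluid
    stays at rest and FFR is exactly 1."""
    mesh = cylinder_mesh(1.5, 6.0)
    lattice = voxelize(mesh, dx_mm, min_diameter_mm=3.0)
    bc = BoundaryConditions(inlet_pressure=INLET_PRESSURE_MMHG,
                            outlet_resistance=0.0,
                            outlet_reference_pressure=INLET_PRESSURE_MMHG)
    sol = solve_steady(lattice, FluidParams(), bc, SolverConfig())
    return {"ffr": sol.ffr, "q_ml_s": sol.q_out_ml_s}


def stenosis_ffr_family(severities=(0, 40, 60, 75, 90),
                        radius_mm: float = 1.5, length_mm: float = 10.0,
                        dx_mm: float = 0.11, q_hyp_ml_s: float = 0.5,
                        tol: float = 1e-4) -> dict:
    """Computational FFR across area-stenosis severities, all else fixed.

    Uses the synthetic vessel family imaged noiselessly at CTA spacing, a
    resistance outlet sized for the target flow, and Carreau-Yasuda blood.
    """
    resistance = resistance_for_target_flow(INLET_PRESSURE_MMHG, q_hyp_ml_s)
    out = {}
    for sev in severities:
        sten = (length_mm / 2.0, float(sev), 4.0) if sev else None
        geom = generate_vessel(VesselSpec(
            length_mm=length_mm, base_radius_mm=radius_mm, stenosis=sten))
        cta, _ = image_vessel(geom, ImagingSpec())
        _, mesh = reconstruct_stack(cta)
        lattice = voxelize(mesh, dx_mm,
                           min_diameter_mm=2 * np.sqrt(geom.mla_mm2 / np.pi))
        bc = BoundaryConditions(inlet_pressure=INLET_PRESSURE_MMHG,
                                outlet_resistance=resistance)
        cfg = SolverConfig(tol=tol, min_area_mm2=geom.mla_mm2)
        sol = solve_steady(lattice, FluidParams(), bc, cfg)
        out[int(sev)] = {"ffr": sol.ffr, "q_ml_s": sol.q_out_ml_s,
                         "steps": sol.steps}
    return out


def curvature_benchmark(radius_mm: float = 1.2, length_mm: float = 10.0,
                        dx_mm: float = 0.12, q_hyp_ml_s: float = 0.5,
                        tol: float = 1e-4) -> dict:
    """Identical lumen profile on a straight vs a helical centerline.

    Vessel curvature induces secondary (Dean) flow, so the helical model
    must show larger volume-averaged |vorticity| and |helicity|.
    """
    resistance = resistance_for_target_flow(INLET_PRESSURE_MMHG, q_hyp_ml_s)
    out = {}
    for kind in ("straight", "helix"):
        geom = generate_vessel(VesselSpec(
            centerline_kind=kind, length_mm=length_mm,
            base_radius_mm=radius_mm, helix_radius_mm=2.0,
            helix_pitch_mm=10.0))
        cta, _ = image_vessel(geom, ImagingSpec())
        _, mesh = reconstruct_stack(cta)
        lattice = voxelize(mesh, dx_mm, min_diameter_mm=2 * radius_mm)
        bc = BoundaryConditions(inlet_pressure=INLET_PRESSURE_MMHG,
                                outlet_resistance=resistance)
        cfg = SolverConfig(tol=tol, min_area_mm2=np.pi * radius_mm ** 2)
        sol = solve_steady(lattice, FluidParams(), bc, cfg,
                           centerline_points_mm=cta.centerline.points)
        _, _, summary = compute_vorticity_helicity(sol)
        out[kind] = summary
    out["helicity_ratio"] = (out["helix"]["mean_abs_helicity_m_s2"]
                             / out["straight"]["mean_abs_helicity_m_s2"])
    out["vorticity_ratio"] = (out["helix"]["mean_abs_vorticity_s"]
                              / out["straight"]["mean_abs_vorticity_s"])
    return out


# ---------------------------------------------------------------------------
# fusion geometry
# ---------------------------------------------------------------------------

def registration_recovery(n_cases: int = 20, seed: int = 42) -> dict:
    """Random circumferential rotation and longitudinal offset with 2%
    radial contour noise; landmark-based registration must recover them."""
    geom = generate_vessel(VesselSpec(
        length_mm=20.0, base_radius_mm=1.5, stenosis=(10.0, 60.0, 6.0),
        bifurcations=[(4.0, 90.0, 1.0), (16.0, 200.0, 1.0)]))
    rng = np.random.default_rng(seed)
    hits = 0
    rot_errs, off_errs = [], []
    for _ in range(n_cases):
        rot = rng.uniform(-180.0, 180.0)
        off = max(rng.uniform(-5.0, 5.0), 0.0)
        cta, oct_stack = image_vessel(geom, ImagingSpec(
            oct_rotation_deg=rot, oct_offset_mm=off,
            cta_radial_noise_sd=0.02, oct_radial_noise_sd=0.02,
            seed=int(rng.integers(1 << 31))))
        reg = register(cta, oct_stack)
        rerr = float(np.abs((np.asarray(reg.rotation_knots_deg) - rot + 180)
                            % 360 - 180).max())
        oerr = abs(reg.longitudinal_offset_mm - off)
        rot_errs.append(rerr)
        off_errs.append(oerr)
        hits += (rerr < 5.0) and (oerr < 0.125)
    return {"n_cases": n_cases, "hits": hits,
            "recovery_rate": hits / n_cases,
            "max_rotation_error_deg": max(rot_errs),
            "max_offset_error_mm": max(off_errs)}


def fusion_mla_recovery(cta_bias: float = 1.2, seed: int = 0) -> dict:
    """CTA inflated 20% in radius, OCT exact: the fused model must recover
    the true minimal lumen area while CTA alone errs by ~44% in area."""
    geom = generate_vessel(VesselSpec(
        length_mm=20.0, base_radius_mm=1.5, stenosis=(10.0, 60.0, 6.0),
        bifurcations=[(4.0, 90.0, 1.0), (16.0, 200.0, 1.0)]))
    cta, oct_stack = image_vessel(geom, ImagingSpec(
        oct_rotation_deg=30.0, oct_offset_mm=2.0, cta_radial_bias=cta_bias,
        seed=seed))
    model = fuse(cta, oct_stack)
    truth = geom.mla_mm2
    return {
        "true_mla_mm2": truth,
        "fused_mla_mm2": model.stack.minimal_lumen_area(),
        "cta_mla_mm2": cta.minimal_lumen_area(),
        "fused_mla_error_pct":
            100.0 * abs(model.stack.minimal_lumen_area() - truth) / truth,
        "cta_mla_error_pct":
            100.0 * abs(cta.minimal_lumen_area() - truth) / truth,
    }


# ---------------------------------------------------------------------------
# statistics layer
# ---------------------------------------------------------------------------

CLINICAL_N, CLINICAL_N_POS = 148, 65
CLINICAL_RATES = {  # reported sensitivity/specificity per computational FFR
    "fusion": (0.846, 0.843),
    "ct": (0.877, 0.614),
    "oct": (0.785, 0.735),
}


def clinical_performance_tables() -> dict:
    """Diagnostic performance recomputed from the cohort size, prevalence
    and per-modality sensitivity/specificity via reconstructed confusion
    matrices."""
    out = {}
    for name, (sens, spec) in CLINICAL_RATES.items():
        cm = confusion_from_rates(CLINICAL_N, CLINICAL_N_POS, sens, spec)
        summary = diagnostic_performance(cm)
        out[name] = {
            "confusion": (cm.tp, cm.fp, cm.fn, cm.tn),
            "predicted_positive": cm.tp + cm.fp,
            "accuracy_pct": summary.accuracy.rounded(),
            "sensitivity_pct": summary.sensitivity.rounded(),
            "specificity_pct": summary.specificity.rounded(),
            "ppv_pct": summary.ppv.rounded(),
            "npv_pct": summary.npv.rounded(),
        }
    out["area_stenosis_example_pct"] = area_stenosis((7.2 + 6.5) / 2, 2.3)
    return out


def roc_oracle_agreement(n_cohorts: int = 300, seed: int = 5) -> dict:
    """Fraction of random small cohorts (n <= 12, heavy ties) on which the
    rank-based AUC equals the exhaustive pairwise comparison."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    while total < n_cohorts:
        n = int(rng.integers(2, 13))
        labels = rng.integers(0, 2, n)
        if labels.all() or not labels.any():
            continue
        scores = rng.integers(0, 4, n).astype(float)
        pos, neg = scores[labels == 1], scores[labels == 0]
        oracle = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                          for p in pos for q in neg])
        agree += abs(roc_auc(scores, labels) - oracle) < 1e-12
        total += 1
    return {"n_cohorts": total, "agreement_rate": agree / total}


def steiger_null_uniformity(n: int = 60, reps: int = 2000,
                            seed: int = 3) -> dict:
    """KS test of Steiger-Z p-values under the null of equal dependent
    correlations (trivariate normal with symmetric structure)."""
    from scipy import stats
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.3], [0.5, 0.3, 1.0]])
    chol = np.linalg.cholesky(cov)
    pvals = np.empty(reps)
    for i in range(reps):
        x = rng.standard_normal((n, 3)) @ chol.T
        r = np.corrcoef(x, rowvar=False)
        pvals[i] = steiger_z(r[0, 1], r[0, 2], r[1, 2], n)[1]
    return {"ks_pvalue": float(stats.kstest(pvals, "uniform").pvalue),
            "reps": reps}
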