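"""Fluence-map optimization: standard and functional-liver-sparing plans.

The objective is a weighted sum of one-sided quadratic penalties (PTV
underdose below the prescription, PTV overdose above a ceiling, OAR dose
above structure-specific levels, liver mean dose above its limit) plus, for
sparing plans, a "parallel organ" term on the functional liver volume: the
mean over FLV voxels of a logistic-in-log-dose damage response
x/(1+x) with x = (d/d_ref)^k.  Because that response has gradient spread
across the whole dose range, the optimiser can trade low dose to a large
volume against high dose to a small volume — the behaviour wanted when
protecting a parallel-architecture organ — instead of only pushing one
DVH level set.

The solver is projected gradient descent with a monotone backtracking line
search and a fixed deterministic initial fluence, so plan pairs differing
only in the sparing term are exactly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dose import DoseInfluence, compute_dose
from .grids import VoxelImage
from .metrics import dose_at_volume_percent, mean_dose


@dataclass
class OarConstraint:
    structure: str
    kind: str  # 'max' (one-sided quadratic above level) or 'mean'
    level_gy: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("max", "mean"):
            raise ValueError("kind must be 'max' or 'mean'")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class ParallelObjective:
    """Parallel-organ damage objective on the functional liver volume."""

    d_ref_gy: float = 15.0
    k_power: float = 3.0
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.d_ref_gy <= 0 or self.k_power <= 0:
            raise ValueError("d_ref and k must be positive")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class PlanObjectives:
    ptv_prescription_gy: float = 50.0
    ptv_underdose_weight: float = 100.0
    ptv_overdose_weight: float = 20.0
    ptv_max_fraction: float = 1.25
    oar_constraints: list[OarConstraint] = field(default_factory=list)
    liver_structure: str = "liver_minus_gtv"
    liver_mean_limit_gy: float = 13.0
    liver_mean_weight: float = 2000.0
    flv_parallel: ParallelObjective | None = None

    def __post_init__(self) -> None:
        if self.ptv_prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        for w in (self.ptv_underdose_weight, self.ptv_overdose_weight, self.liver_mean_weight):
            if w < 0:
                raise ValueError("weights must be >= 0")


@dataclass
class PrescriptionTiers:
    """Ordered prescription tiers, each capped by a liver-mean-dose limit."""

    tiers: list[dict] = field(
        default_factory=lambda: [
            {"rx_gy": 50.0, "lmd_limit_gy": 13.0},
            {"rx_gy": 40.0, "lmd_limit_gy": 15.0},
        ]
    )

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValueError("tier list must be non-empty")
        rx = [t["rx_gy"] for t in self.tiers]
        if any(b >= a for a, b in zip(rx, rx[1:])):
            raise ValueError("rx must be strictly decreasing down the tier list")


@dataclass
class PlanResult:
    fluence: np.ndarray
    dose: VoxelImage
    rx_gy: float
    objective_trace: list[float]
    converged: bool
    constraint_report: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def parallel_damage(dose_values: np.ndarray, d_ref_gy: float, k_power: float) -> float:
    """Mean parallel-organ damage fraction in [0, 1].

    Per-voxel damage 1/(1 + (d_ref/d)^k), with the d = 0 term defined as 0
    (computed stably as x/(1+x), x = (d/d_ref)^k); all voxels at d_ref give
    0.5, the logistic midpoint.
    """
    if d_ref_gy <= 0 or k_power <= 0:
        raise ValueError("d_ref and k must be positive")
    d = np.asarray(dose_values, dtype=float)
    if d.size == 0:
        raise ValueError("empty dose set")
    x = (np.maximum(d, 0.0) / d_ref_gy) ** k_power
    return float((x / (1.0 + x)).mean())


def _parallel_damage_grad(d: np.ndarray, d_ref: float, k: float) -> np.ndarray:
    """d(damage_i)/d(d_i); 0 at d = 0 (k > 1 limit, and flat for the mask)."""
    g = np.zeros_like(d)
    pos = d > 0
    x = (d[pos] / d_ref) ** k
    g[pos] = k * x / (d[pos] * (1.0 + x) ** 2)
    return g


class _Objective:
    """Objective value and gradient w.r.t. the voxel-dose vector."""

    def __init__(self, objectives: PlanObjectives, structures: dict[str, np.ndarray]):
        self.obj = objectives
        self.idx = {
            name: np.nonzero(np.asarray(m).ravel())[0] for name, m in structures.items()
        }
        if "ptv" not in self.idx or self.idx["ptv"].size == 0:
            raise ValueError("PTV mask is empty")

    def __call__(self, dose: np.ndarray) -> tuple[float, np.ndarray]:
        o = self.obj
        grad = np.zeros_like(dose)
        val = 0.0

        ptv = self.idx["ptv"]
        d = dose[ptv]
        rx = o.ptv_prescription_gy
        under = np.maximum(rx - d, 0.0)
        val += o.ptv_underdose_weight * float((under**2).mean())
        grad[ptv] += o.ptv_underdose_weight * (-2.0 * under) / ptv.size
        ceiling = o.ptv_max_fraction * rx
        over = np.maximum(d - ceiling, 0.0)
        val += o.ptv_overdose_weight * float((over**2).mean())
        grad[ptv] += o.ptv_overdose_weight * (2.0 * over) / ptv.size

        for c in o.oar_constraints:
            vox = self.idx.get(c.structure)
            if vox is None or vox.size == 0 or c.weight == 0:
                continue
            dv = dose[vox]
            if c.kind == "max":
                ex = np.maximum(dv - c.level_gy, 0.0)
                val += c.weight * float((ex**2).mean())
                grad[vox] += c.weight * (2.0 * ex) / vox.size
            else:
                ex = max(float(dv.mean()) - c.level_gy, 0.0)
                val += c.weight * ex**2
                grad[vox] += c.weight * 2.0 * ex / vox.size

        liver = self.idx.get(o.liver_structure)
        if liver is not None and liver.size and o.liver_mean_weight > 0:
            ex = max(float(dose[liver].mean()) - o.liver_mean_limit_gy, 0.0)
            val += o.liver_mean_weight * ex**2
            grad[liver] += o.liver_mean_weight * 2.0 * ex / liver.size

        par = o.flv_parallel
        if par is not None and par.weight > 0:
            flv = self.idx.get("flv")
            if flv is not None and flv.size:
                dv = dose[flv]
                val += par.weight * parallel_damage(dv, par.d_ref_gy, par.k_power)
                grad[flv] += (
                    par.weight
                    * _parallel_damage_grad(dv, par.d_ref_gy, par.k_power)
                    / flv.size
                )
        return val, grad


def optimize_plan(
    influence: DoseInfluence,
    structures: dict[str, np.ndarray],
    objectives: PlanObjectives,
    max_iter: int = 120,
    tol: float = 1e-7,
    initial_fluence: np.ndarray | None = None,
) -> PlanResult:
    """Projected-gradient fluence optimization.

    Non-negative fluence is enforced by projection; the backtracking line
    search only accepts decreases, so the objective trace is non-increasing.
    Deterministic for fixed inputs and fixed initial fluence (default:
    uniform 1.0, then scaled so the PTV mean equals the prescription).
    """
    D = influence.matrix
    n = influence.n_beamlets
    objective = _Objective(objectives, structures)

    if initial_fluence is not None:
        f = np.asarray(initial_fluence, dtype=float).copy()
        if f.size != n:
            raise ValueError("initial fluence length mismatch")
        if (f < 0).any():
            raise ValueError("initial fluence must be non-negative")
    else:
        f = np.ones(n)
        ptv_mean = float((D @ f)[objective.idx["ptv"]].mean())
        if ptv_mean <= 0:
            raise ValueError("PTV receives no dose from any beamlet: infeasible geometry")
        f *= objectives.ptv_prescription_gy / ptv_mean

    dose = D @ f
    val, gd = objective(dose)
    trace = [val]
    step = 1.0
    converged = False
    for _ in range(max_iter):
        g = D.T @ gd
        gnorm = float(np.abs(g).max())
        if gnorm < 1e-15:
            converged = True
            break
        improved = False
        alpha = step * 2.0
        for _bt in range(40):
            f_new = np.maximum(f - alpha * g, 0.0)
            dose_new = D @ f_new
            val_new, gd_new = objective(dose_new)
            if val_new < val:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            converged = True
            break
        step = alpha
        rel = (val - val_new) / max(abs(val), 1e-12)
        f, dose, val, gd = f_new, dose_new, val_new, gd_new
        trace.append(val)
        if rel < tol:
            converged = True
            break

    dose_img = VoxelImage(
        dose.reshape(influence.grid_shape), influence.spacing, influence.origin
    )
    report = _constraint_report(dose_img, structures, objectives)
    return PlanResult(
        fluence=f,
        dose=dose_img,
        rx_gy=objectives.ptv_prescription_gy,
        objective_trace=trace,
        converged=converged,
        constraint_report=report,
    )


def _constraint_report(dose: VoxelImage, structures, objectives: PlanObjectives) -> dict:
    rep: dict = {}
    ptv = structures["ptv"]
    rep["ptv_d95_gy"] = dose_at_volume_percent(dose, ptv, 95.0)
    rep["ptv_mean_gy"] = mean_dose(dose, ptv)
    liver = structures.get(objectives.liver_structure)
    if liver is not None and np.asarray(liver).any():
        rep["liver_mean_gy"] = mean_dose(dose, liver)
        rep["liver_mean_limit_gy"] = objectives.liver_mean_limit_gy
    flv = structures.get("flv")
    if flv is not None and np.asarray(flv).any():
        rep["flv_mean_gy"] = mean_dose(dose, flv)
    for c in objectives.oar_constraints:
        m = structures.get(c.structure)
        if m is not None and np.asarray(m).any():
            rep[f"{c.structure}_{c.kind}_gy"] = (
                float(np.max(dose.data[np.asarray(m, bool)]))
                if c.kind == "max"
                else mean_dose(dose, m)
            )
    return rep


def auto_sparing_weight(
    influence: DoseInfluence,
    structures: dict[str, np.ndarray],
    objectives: PlanObjectives,
    d95_floor_gy: float,
    standard_plan: PlanResult | None = None,
    start_weight: float = 25.0,
    max_steps: int = 8,
    ladder_factor: float = 2.0,
    **opt_kwargs,
) -> PlanResult:
    """Push the sparing weight up a geometric ladder while coverage holds.

    Doubles the parallel-objective weight per step and returns the plan with
    the largest weight whose PTV D95% stays at or above ``d95_floor_gy``.
    If even the first rung breaks the floor (or the FLV is empty) the
    standard plan is returned with a flag.  Ladder plans warm-start from the
    standard plan's fluence; the ladder is recorded in the result meta.
    """
    flv = structures.get("flv")
    if standard_plan is None:
        standard_plan = optimize_plan(
            influence, structures, replace(objectives, flv_parallel=None), **opt_kwargs
        )
    if flv is None or not np.asarray(flv).any():
        out = replace(standard_plan)
        out.meta = dict(standard_plan.meta, sparing_applied=False, reason="empty FLV")
        return out

    base_par = objectives.flv_parallel or ParallelObjective()
    best: PlanResult | None = None
    ladder: list[dict] = []
    w = start_weight
    for _ in range(max_steps):
        obj_w = replace(objectives, flv_parallel=replace(base_par, weight=w))
        plan = optimize_plan(
            influence,
            structures,
            obj_w,
            initial_fluence=standard_plan.fluence,
            **opt_kwargs,
        )
        d95 = plan.constraint_report["ptv_d95_gy"]
        ladder.append({"weight": w, "ptv_d95_gy": d95})
        if d95 >= d95_floor_gy:
            best = plan
            best.meta = {"sparing_weight": w}
        else:
            break
        w *= ladder_factor
    if best is None:
        out = replace(standard_plan)
        out.meta = dict(
            standard_plan.meta,
            sparing_applied=False,
            reason="smallest weight violated the D95 floor",
            ladder=ladder,
        )
        return out
    best.meta["sparing_applied"] = True
    best.meta["ladder"] = ladder
    return best


def select_prescription(
    influence: DoseInfluence,
    structures: dict[str, np.ndarray],
    tiers: PrescriptionTiers,
    objectives: PlanObjectives,
    **opt_kwargs,
) -> tuple[float, PlanResult]:
    """Highest prescription tier whose optimized plan meets its LMD limit.

    Plans each tier from the top down and returns the first whose
    liver-minus-GTV mean dose is at or below the tier's limit; if none
    passes, the lowest tier is returned with a warning flag in meta.
    """
    last = None
    for tier in tiers.tiers:
        obj = replace(
            objectives,
            ptv_prescription_gy=tier["rx_gy"],
            liver_mean_limit_gy=tier["lmd_limit_gy"],
            flv_parallel=None,
        )
        plan = optimize_plan(influence, structures, obj, **opt_kwargs)
        lmd = plan.constraint_report.get("liver_mean_gy", 0.0)
        plan.meta["tier"] = dict(tier)
        last = plan
        if lmd <= tier["lmd_limit_gy"]:
            return tier["rx_gy"], plan
    last.meta["lmd_warning"] = True
    return tiers.tiers[-1]["rx_gy"], last


def rescale_to_d95(plan: PlanResult, ptv_mask: np.ndarray, target_d95_gy: float) -> PlanResult:
    """Multiply fluence and dose so PTV D95% equals the target exactly.

    Used to compare plan pairs at matched coverage: a pure linear scaling,
    so every DVH D-metric scales by the same factor.
    """
    current = dose_at_volume_percent(plan.dose, ptv_mask, 95.0)
    if current <= 0:
        raise ValueError("plan has zero PTV D95; cannot rescale")
    factor = target_d95_gy / current
    dose = plan.dose.copy(data=plan.dose.data * factor)
    out = replace(plan, fluence=plan.fluence * factor, dose=dose)
    out.meta = dict(plan.meta, rescale_factor=factor)
    return out
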