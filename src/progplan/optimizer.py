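"""Inner fluence solve, prescription normalization, and leaf sequencing.

The inner solve minimizes the weighted composite objective over
nonnegative beamlet weights with a projected-gradient method
(Barzilai-Borwein step lengths safeguarded by Armijo backtracking): the
composite objective is nonincreasing across accepted iterations, weight
nonnegativity holds at every iterate, and iteration stops at ``max_iters``
or when the relative improvement falls below a tolerance.

Direct machine parameter optimization is deliberately **not**
re-implemented: apertures and monitor units are produced post hoc by a
unidirectional sliding-window decomposition of each control point's
fluence, which reconstructs the (quantized) fluence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_engine import InfluenceMatrix, MachineModel, dose_from_weights
from .objectives import TemplateState, composite_objective
from .phantom import Phantom

__all__ = [
    "PlanState",
    "Aperture",
    "ControlPointApertures",
    "ApertureSequence",
    "inner_optimize",
    "normalize_to_prescription",
    "sequence_leaves",
]


@dataclass
class PlanState:
    """Beamlet weights + the dose grid they imply, plus run bookkeeping."""

    weights: np.ndarray
    dose: np.ndarray  # flat, cGy
    normalization_factor: float = 1.0
    cycle_index: int = 0
    iterations_used: int = 0
    objective_trace: list[float] = field(default_factory=list)
    stop_reason: str = ""

    def copy(self) -> "PlanState":
        return PlanState(
            weights=self.weights.copy(),
            dose=self.dose.copy(),
            normalization_factor=self.normalization_factor,
            cycle_index=self.cycle_index,
            iterations_used=self.iterations_used,
            objective_trace=list(self.objective_trace),
            stop_reason=self.stop_reason,
        )


def inner_optimize(
    influence: InfluenceMatrix,
    template: TemplateState,
    phantom: Phantom,
    start_weights: np.ndarray,
    *,
    rx: float = 6000.0,
    max_iters: int = 80,
    rel_tol: float = 1e-6,
    grad_tol: float = 1e-14,
) -> PlanState:
    """One optimization cycle: bound-constrained descent on the composite.

    ``max_iters`` defaults to 80 (the midpoint of the usual 60-100 steps
    per cycle); any positive override is accepted.  Raises if the
    objective turns non-finite, naming the offending template row.
    """
    w = np.asarray(start_weights, dtype=np.float64).copy()
    if np.any(w < 0):
        raise ValueError("start weights must be nonnegative")
    A = influence.matrix

    def f_and_g(weights: np.ndarray):
        dose = A @ weights
        total, per_spec, gdose = composite_objective(
            template, dose, phantom, rx, want_gradient=True
        )
        if not np.isfinite(total):
            bad = [
                template.specs[i].label()
                for i, v in enumerate(per_spec)
                if not np.isfinite(v)
            ]
            raise FloatingPointError(f"non-finite objective value in spec(s): {bad}")
        return total, A.T @ gdose, dose

    f0, g0, dose0 = f_and_g(w)
    trace = [f0]
    w_prev, g_prev = None, None
    step = 1.0 / max(np.linalg.norm(g0), 1e-30)
    iters = 0
    reason = "max_iters"
    for it in range(1, max_iters + 1):
        iters = it
        # projected-gradient stationarity check
        pg = np.where((w <= 0) & (g0 > 0), 0.0, g0)
        if np.linalg.norm(pg) <= grad_tol * max(1.0, np.linalg.norm(w)):
            reason = "stationary"
            break
        if w_prev is not None:
            sw = w - w_prev
            sg = g0 - g_prev
            denom = sw @ sg
            if denom > 0:
                step = (sw @ sw) / denom
            step = float(np.clip(step, 1e-12, 1e12))
        accepted = False
        for _ in range(30):
            w_new = np.maximum(0.0, w - step * g0)
            delta = w_new - w
            f_new, g_new, dose_new = f_and_g(w_new)
            if f_new <= f0 + 1e-4 * (g0 @ delta) or f_new < f0:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            reason = "no_descent"
            break
        w_prev, g_prev = w, g0
        rel_impr = (f0 - f_new) / max(abs(f0), 1e-30)
        w, f0, g0, dose0 = w_new, f_new, g_new, dose_new
        trace.append(f0)
        if rel_impr < rel_tol:
            reason = "converged"
            break
    return PlanState(
        weights=w, dose=dose0, iterations_used=iters, objective_trace=trace, stop_reason=reason
    )


def normalize_to_prescription(
    plan: PlanState,
    influence: InfluenceMatrix,
    phantom: Phantom,
    rx: float = 6000.0,
    coverage_pct: float = 95.0,
    target: str = "ptv",
) -> PlanState:
    """Scale weights so that ``coverage_pct`` of the target receives ``rx``.

    Uses the sort-based (non-interpolated) D95 so that, after scaling,
    V(rx) >= coverage exactly; idempotent within floating-point tolerance.
    """
    d = np.sort(plan.dose[phantom.mask(target).ravel()])[::-1]
    # k voxels must receive >= rx for k/n to reach the coverage fraction
    k = int(np.ceil(d.size * coverage_pct / 100.0 - 1e-12))
    d_cov = float(d[max(k, 1) - 1])
    if d_cov <= 0:
        raise ValueError(f"target D{coverage_pct:g}% is zero; cannot normalize")
    s = rx / d_cov
    while d_cov * s < rx:  # guard the pinned voxel against one-ulp rounding
        s = np.nextafter(s, np.inf)
    out = plan.copy()
    out.weights = plan.weights * s
    out.dose = plan.dose * s
    out.normalization_factor = plan.normalization_factor * s
    return out


# ---------------------------------------------------------------------------
# Leaf sequencing


@dataclass
class Aperture:
    """Per-row (left, right) leaf edges in cm (None = closed row) + MU."""

    rows: list[tuple[float, float] | None]
    mu: float


@dataclass
class ControlPointApertures:
    gantry_deg: float
    apertures: list[Aperture]


@dataclass
class ApertureSequence:
    """Per-control-point MLC openings with per-aperture monitor units."""

    control_points: list[ControlPointApertures]
    leaf_width_cm: float
    row_centers_cm: list[np.ndarray]  # per control point
    column_edges_cm: list[np.ndarray]  # per control point (len = n_cols + 1)

    @property
    def total_mu(self) -> float:
        return sum(ap.mu for cp in self.control_points for ap in cp.apertures)

    def iter_apertures(self):
        """Yield (rows_in_mm, mu) pairs over the whole plan (for metrics)."""
        for cp in self.control_points:
            for ap in cp.apertures:
                rows_mm = [
                    None if r is None else (r[0] * 10.0, r[1] * 10.0) for r in ap.rows
                ]
                yield rows_mm, ap.mu

    def to_json_dict(self) -> dict:
        return {
            "leaf_width_cm": self.leaf_width_cm,
            "total_mu": self.total_mu,
            "control_points": [
                {
                    "gantry_deg": cp.gantry_deg,
                    "apertures": [
                        {"mu": ap.mu, "rows": [list(r) if r else None for r in ap.rows]}
                        for ap in cp.apertures
                    ],
                }
                for cp in self.control_points
            ],
        }


def _sweep_decompose(fluence: np.ndarray, quantum: float) -> list[tuple[np.ndarray, float]]:
    """Unidirectional sliding-window decomposition of one fluence map.

    Rows are leaf pairs, columns run along leaf travel.  Column j of row r
    is open during the MU interval [a(r,j), a(r,j) + f(r,j)), with
    a(r,j) = cumulative sum of the negative increments of row r — the
    classic sweep construction, under which the open set of every row is a
    contiguous interval at every instant and the reconstruction is exact.
    Returns (open_mask, mu) pairs.
    """
    # integer arithmetic in units of the MU quantum: exact event times
    f = np.round(np.asarray(fluence, dtype=np.float64) / quantum).astype(np.int64)
    f[f < 0] = 0
    n_rows, n_cols = f.shape
    prev = np.hstack([np.zeros((n_rows, 1), np.int64), f[:, :-1]])
    a = np.cumsum(np.maximum(0, prev - f), axis=1)
    b = a + f
    events = np.unique(np.concatenate([a[f > 0].ravel(), b[f > 0].ravel(), [0]]))
    out = []
    for t0, t1 in zip(events[:-1], events[1:]):
        open_mask = (a <= t0) & (t0 < b) & (f > 0)
        if open_mask.any():
            out.append((open_mask, float((t1 - t0) * quantum)))
    return out


def sequence_leaves(
    weights: np.ndarray,
    influence: InfluenceMatrix,
    machine: MachineModel | None = None,
    *,
    mu_per_weight: float = 1.0,
    mu_quantum: float = 0.1,
) -> ApertureSequence:
    """Decompose per-control-point fluence into leaf openings with MU.

    Calibration: 1 weight unit = ``mu_per_weight`` MU (a configuration
    choice; the absolute MU scale of this sandbox is internally consistent
    but not comparable to a clinical optimizer's).  MU is quantized at
    ``mu_quantum``.  Ties in window openings resolve leftward by the
    deterministic sweep construction.
    """
    machine = machine or MachineModel()
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights < 0):
        raise ValueError("beamlet weights must be nonnegative")
    half_span = machine.max_field_cm[0] / 2.0

    cps_out = []
    row_centers_all, col_edges_all = [], []
    for cp_i, bg in enumerate(influence.grids):
        sel = influence.beamlet_cp == cp_i
        uv = influence.beamlet_uv[sel]
        w_cp = weights[sel] * mu_per_weight
        # fluence map: rows = v (leaf rows), cols = u (travel direction)
        fl = np.zeros((len(bg.v_centers_mm), len(bg.u_centers_mm)))
        fl[uv[:, 1], uv[:, 0]] = w_cp
        pitch_u_cm = (
            (bg.u_centers_mm[1] - bg.u_centers_mm[0]) / 10.0
            if len(bg.u_centers_mm) > 1
            else machine.leaf_width_cm
        )
        col_edges = bg.u_centers_mm / 10.0 - pitch_u_cm / 2.0
        col_edges = np.append(col_edges, col_edges[-1] + pitch_u_cm)
        row_centers = bg.v_centers_mm / 10.0
        apertures = []
        for open_mask, mu in _sweep_decompose(fl, mu_quantum):
            rows: list[tuple[float, float] | None] = []
            for r in range(open_mask.shape[0]):
                cols = np.nonzero(open_mask[r])[0]
                if cols.size == 0:
                    rows.append(None)
                    continue
                left = col_edges[cols[0]]
                right = col_edges[cols[-1] + 1]
                if left < -half_span or right > half_span:
                    raise ValueError(
                        f"aperture at control point {cp_i} violates the leaf span"
                    )
                rows.append((left, right))
            apertures.append(Aperture(rows, mu))
        cps_out.append(ControlPointApertures(bg.control_point.gantry_deg, apertures))
        row_centers_all.append(row_centers)
        col_edges_all.append(col_edges)
    return ApertureSequence(cps_out, machine.leaf_width_cm, row_centers_all, col_edges_all)


def reconstruct_fluence(seq: ApertureSequence, cp_index: int) -> np.ndarray:
    """Sum of MU_i * aperture_i for one control point, on the beamlet lattice."""
    col_edges = seq.column_edges_cm[cp_index]
    n_rows = len(seq.row_centers_cm[cp_index])
    n_cols = len(col_edges) - 1
    fl = np.zeros((n_rows, n_cols))
    centers = 0.5 * (col_edges[:-1] + col_edges[1:])
    for ap in seq.control_points[cp_index].apertures:
        for r, edges in enumerate(ap.rows):
            if edges is None:
                continue
            sel = (centers > edges[0]) & (centers < edges[1])
            fl[r, sel] += ap.mu
    return fl
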