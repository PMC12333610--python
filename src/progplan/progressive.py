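"""The three-phase automatic progressive plan optimization loop.

Phase 1 — *initialization*: assign the objective template
(:func:`build_initial_template`) with deliberately loose dose levels.

Phase 2 — *iterative optimization and feedback evaluation*: each cycle
runs the inner fluence solve, normalizes the plan so 95% of the PTV
receives the prescription, and evaluates the per-objective feedback
values.  Any adaptive objective whose feedback lies below the threshold
(default 4e-4) has slack: its target is retargeted to the currently
achieved dose scaled by the tightening factor (default 0.98) and
re-evaluated, repeatedly, until the feedback rises above the threshold
(or a per-spec update cap is hit).

Phase 3 — *convergence and complexity control*: the loop stops once the
feedback values of the key conformity objectives (ring, normal tissue,
body dose-falloff) all exceed the threshold after normalization — those
constraints are then binding, i.e. maximally tightened.  If more than the
allowed number of cycles runs without convergence, the weights and
template are reset and the whole optimization restarts (once); after
that, the better of the two runs by composite objective is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dose_engine import InfluenceMatrix
from .objectives import (
    ObjectiveSpec,
    TemplateState,
    achieved_quantity,
    composite_objective,
    objective_value,
)
from .optimizer import PlanState, inner_optimize, normalize_to_prescription
from .phantom import Phantom

__all__ = [
    "ProgressiveConfig",
    "RunLog",
    "build_initial_template",
    "tighten_targets",
    "run_progressive",
]


@dataclass
class ProgressiveConfig:
    """Hyperparameters of the progressive loop (all institution-tunable)."""

    feedback_threshold: float = 4e-4
    tighten_factor: float = 0.98
    max_cycles_before_reset: int = 3
    inner_iters: int = 80
    per_spec_update_cap: int = 50
    rx: float = 6000.0
    coverage_pct: float = 95.0

    def __post_init__(self) -> None:
        if not 0 < self.tighten_factor < 1:
            raise ValueError("tighten factor must lie in (0, 1)")
        if self.feedback_threshold <= 0:
            raise ValueError("feedback threshold must be > 0")
        if self.max_cycles_before_reset < 1:
            raise ValueError("need at least one cycle before a reset")


@dataclass
class RunLog:
    """Append-only audit record of the progressive loop."""

    cycles: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    status: str = "running"

    def log_cycle(self, **kwargs) -> None:
        self.cycles.append(kwargs)

    def log_event(self, kind: str, **kwargs) -> None:
        self.events.append({"kind": kind, **kwargs})

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.cycles:
                fh.write(json.dumps({"record": "cycle", **c}) + "\n")
            for e in self.events:
                fh.write(json.dumps({"record": "event", **e}) + "\n")
            fh.write(json.dumps({"record": "status", "status": self.status}) + "\n")


def build_initial_template(rx: float = 6000.0) -> TemplateState:
    """The 19-row initial objective template for a prescription of ``rx`` cGy.

    Dose levels are fixed multiples of the prescription (so a different
    prescription scales every level proportionally); weights are absolute.
    The adaptive flag marks the conformity-driving rows — ring, normal
    tissue and the body dose-falloffs — whose targets the progressive loop
    tightens; target-coverage and organ-at-risk rows stay fixed at their
    clinical levels.
    """
    if rx <= 0:
        raise ValueError("prescription must be > 0")
    S = ObjectiveSpec
    specs = [
        S("ptv", "MinDose", rx, weight=50),
        S("ctv", "MinEud", rx, a_param=-150, weight=50),
        S("ptv", "MinDvh", rx, volume_pct=98, weight=200),
        S("ptv", "MaxEud", rx * 1.05, a_param=150, weight=50),
        S("ring", "MaxEud", rx * 0.95, a_param=150, weight=8, adaptive=True),
        S("nt", "MaxEud", rx * 0.80, a_param=150, weight=8, adaptive=True),
        S("nt", "MaxEud", rx * 0.1, a_param=1, weight=8, adaptive=True),
        S("sp0.3", "MaxDose", rx * 2 / 3, weight=20),
        S("sp0.3", "MaxEud", rx * 0.65, a_param=150, weight=10),
        S("heart", "MaxEud", rx * 11 / 30, a_param=1, weight=10),
        S("lungs", "MaxDvh", rx / 12, volume_pct=48, weight=20),
        S("lungs", "MaxDvh", rx / 3, volume_pct=28, weight=20),
        S("lungs", "MaxDvh", rx / 2, volume_pct=18, weight=20),
        S("lung-ptv", "MaxEud", rx * 0.2, a_param=1, weight=20),
        S("body", "DoseFallOff", rx, low_level=rx * 0.95, distance_cm=0.5, weight=20, adaptive=True),
        S("body", "DoseFallOff", rx, low_level=rx * 0.85, distance_cm=1.0, weight=20, adaptive=True),
        S("body", "DoseFallOff", rx, low_level=rx * 0.75, distance_cm=1.5, weight=20, adaptive=True),
        S("body", "DoseFallOff", rx, low_level=rx * 0.7, distance_cm=2.0, weight=20, adaptive=True),
        S("body", "MaxDose", rx * 1.1, weight=200),
    ]
    return TemplateState(specs=specs)


def tighten_targets(
    template: TemplateState,
    dose: np.ndarray,
    phantom: Phantom,
    config: ProgressiveConfig,
) -> tuple[TemplateState, int]:
    """Phase-2 target update on a normalized dose distribution.

    For each adaptive spec whose feedback value is below the threshold,
    the target is replaced by the tightening factor times the currently
    achieved dose (never above the current target), the feedback is
    re-evaluated, and the update repeats until the feedback reaches the
    threshold or the per-spec cap is hit.  Non-adaptive specs and specs
    already binding are untouched.  Returns the updated template (a copy)
    and the number of applied updates.
    """
    out = template.copy()
    n_updates = 0
    for i, spec in enumerate(out.specs):
        if not spec.adaptive:
            continue
        for _ in range(config.per_spec_update_cap):
            value = objective_value(
                spec, dose, phantom, config.rx, target=out.current_targets[i]
            )
            if value >= config.feedback_threshold:
                break
            achieved = achieved_quantity(spec, dose, phantom, target=out.current_targets[i])
            new_target = config.tighten_factor * min(out.current_targets[i], achieved)
            out.set_target(i, new_target)
            n_updates += 1
    return out, n_updates


def _feedback_values(template: TemplateState, dose, phantom, rx) -> list[float]:
    return [
        objective_value(spec, dose, phantom, rx, target=target)
        for spec, target in zip(template.specs, template.current_targets)
    ]


def run_progressive(
    phantom: Phantom,
    influence: InfluenceMatrix,
    initial_template: TemplateState | None = None,
    config: ProgressiveConfig | None = None,
    seed: int = 0,
    start_weights: np.ndarray | None = None,
) -> tuple[PlanState, TemplateState, RunLog]:
    """Run the full progressive loop; returns (plan, final template, log).

    The run is deterministic for fixed inputs (the loop itself draws no
    random numbers; ``seed`` is recorded in the log for provenance of the
    caller's inputs).  The returned plan is normalized to the
    prescription.
    """
    config = config or ProgressiveConfig()
    initial_template = initial_template or build_initial_template(config.rx)
    log = RunLog()
    log.log_event("start", seed=seed, config=asdict(config))

    if start_weights is None:
        # uniform start scaled so the mean PTV dose equals the prescription
        n_b = influence.n_beamlets
        ones = np.ones(n_b)
        ptv_mean = float(
            (influence.matrix @ ones)[phantom.mask("ptv").ravel()].mean()
        )
        if ptv_mean <= 0:
            raise ValueError("influence matrix deposits no dose in the PTV")
        start_weights = ones * (config.rx / ptv_mean)
    w0 = np.asarray(start_weights, dtype=np.float64)

    adaptive_idx = [i for i, s in enumerate(initial_template.specs) if s.adaptive]
    best: tuple[float, PlanState, TemplateState] | None = None

    for attempt in range(2):  # initial run + at most one restart
        template = initial_template.copy()
        w = w0.copy()
        converged = False
        for cycle in range(1, config.max_cycles_before_reset + 1):
            plan = inner_optimize(
                influence,
                template,
                phantom,
                w,
                rx=config.rx,
                max_iters=config.inner_iters,
            )
            if not np.all(np.isfinite(plan.dose)):
                log.status = "aborted_nonfinite"
                log.log_event("abort", cycle=cycle)
                raise FloatingPointError("non-finite dose encountered; see run log")
            plan = normalize_to_prescription(
                plan, influence, phantom, rx=config.rx, coverage_pct=config.coverage_pct
            )
            plan.cycle_index = cycle
            feedbacks = _feedback_values(template, plan.dose, phantom, config.rx)
            total_initial, _, _ = composite_objective(
                initial_template, plan.dose, phantom, config.rx
            )
            if best is None or total_initial < best[0]:
                best = (total_initial, plan.copy(), template.copy())
            converged = all(
                feedbacks[i] > config.feedback_threshold for i in adaptive_idx
            )
            new_template, n_updates = (
                (template, 0)
                if converged
                else tighten_targets(template, plan.dose, phantom, config)
            )
            log.log_cycle(
                attempt=attempt,
                cycle=cycle,
                iterations=plan.iterations_used,
                normalization=plan.normalization_factor,
                objective=plan.objective_trace[-1],
                feedback_before=feedbacks,
                targets_after=list(new_template.current_targets),
                n_tighten_updates=n_updates,
                converged=converged,
            )
            if converged:
                log.status = "converged"
                log.log_event("converged", attempt=attempt, cycle=cycle)
                return plan, template, log
            template = new_template
            w = plan.weights
        if attempt == 0:
            log.log_event("reset", after_cycle=config.max_cycles_before_reset)
    log.status = "best_effort_after_reset"
    _, plan, template = best
    return plan, template, log
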