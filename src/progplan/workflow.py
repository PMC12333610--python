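"""End-to-end planning workflow: phantom -> influence -> progressive plan.

This is the glue the command line and the acceptance script share.  The
*standard case* is the package's documented desk-scale study condition: the
default synthetic thorax on a 4 mm grid, the six partial thoracic arcs at
6-degree control-point spacing, the 19-row initial template, and the
default progressive-loop hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dose_engine, evaluate, phantom as phantom_mod, progressive
from .optimizer import sequence_leaves

__all__ = ["CaseResult", "run_standard_case", "standard_case_inputs"]

#: control-point spacing (deg) of the standard desk-scale case; the engine
#: default is 4 but the standard case trades angular resolution for runtime
STANDARD_CP_SPACING_DEG = 6.0


@dataclass
class CaseResult:
    phantom: "phantom_mod.Phantom"
    influence: "dose_engine.InfluenceMatrix"
    plan: object
    template: object
    log: "progressive.RunLog"
    apertures: object
    metrics: dict = field(default_factory=dict)
    goals: object = None


def standard_case_inputs(
    seed: int = 7,
    *,
    phantom_config: "phantom_mod.PhantomConfig | None" = None,
    cp_spacing_deg: float = STANDARD_CP_SPACING_DEG,
):
    """Build phantom, machine, control points and influence for the standard case."""
    cfg = phantom_config or phantom_mod.PhantomConfig()
    ph = phantom_mod.build_phantom(cfg, seed=seed)
    machine = dose_engine.default_machine()
    arcs = dose_engine.standard_arcs(control_point_spacing_deg=cp_spacing_deg)
    cps = dose_engine.discretize_arcs(arcs)
    influence = dose_engine.compute_influence(ph, cps, machine=machine)
    return ph, machine, influence


def run_standard_case(
    seed: int = 7,
    *,
    phantom_config=None,
    prog_config: "progressive.ProgressiveConfig | None" = None,
    cp_spacing_deg: float = STANDARD_CP_SPACING_DEG,
    with_apertures: bool = True,
) -> CaseResult:
    """Run the full automatic progressive optimization on the standard case."""
    prog_config = prog_config or progressive.ProgressiveConfig()
    ph, machine, influence = standard_case_inputs(
        seed, phantom_config=phantom_config, cp_spacing_deg=cp_spacing_deg
    )
    template = progressive.build_initial_template(prog_config.rx)
    plan, final_template, log = progressive.run_progressive(
        ph, influence, template, prog_config, seed=seed
    )
    apertures = (
        sequence_leaves(plan.weights, influence, machine) if with_apertures else None
    )
    metrics = evaluate.compute_metrics(plan.dose, ph, rx_cgy=prog_config.rx)
    if apertures is not None:
        metrics["plan_MU"] = apertures.total_mu
        metrics["edge_metric_mm^-1"] = evaluate.edge_metric(apertures)
    goals = evaluate.check_goals(
        plan.dose, ph, evaluate.default_clinical_goals(prog_config.rx), rx_cgy=prog_config.rx
    )
    return CaseResult(ph, influence, plan, final_template, log, apertures, metrics, goals)
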