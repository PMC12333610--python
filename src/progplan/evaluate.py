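"""DVH engine, dose metrics, conformity/homogeneity indices, clinical-goal
checks and aperture edge-metric complexity.

Conventions
-----------
* VxGy / V(d): percent of the structure receiving a dose **greater than or
  equal to** d (cumulative >= convention).
* Dx%: dose to the hottest x% of the structure.  Queries through
  :func:`dose_at_volume_pct` interpolate linearly on the empirical
  quantile function by default; ``interpolate=False`` returns the largest
  actual voxel dose received by at least x% of the volume.
* Dxcc: dose to the hottest x cm^3, interpolated between sorted voxel
  doses (each voxel treated as a point mass at the midpoint of its
  cumulative volume); a no-interpolation switch is provided.
* Paddick conformity index: CI = |TV ∩ PIV|^2 / (|TV| * |PIV|) where PIV
  is the prescription isodose volume.
* Homogeneity index: HI = (D2% - D98%) / D50%.
* Edge metric: M = (1/MU) * sum_i MU_i * y_i / A_i over all apertures,
  where y_i is the aperture perimeter excluding the MLC leaf ends (the
  leaf-side edges only, including inter-leaf steps) and A_i the open area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import Phantom

__all__ = [
    "DVHCurve",
    "ClinicalGoal",
    "dvh",
    "dose_at_volume_pct",
    "volume_at_dose",
    "dose_at_volume_cc",
    "mean_dose",
    "paddick_ci",
    "homogeneity_index",
    "edge_metric",
    "aperture_open_area_mm2",
    "aperture_side_edge_mm",
    "compute_metrics",
    "check_goals",
    "default_clinical_goals",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: V(d) in % of structure volume."""

    dose_bins_cgy: np.ndarray
    volume_pct: np.ndarray

    def v_at(self, dose_cgy: float) -> float:
        """Percent volume receiving >= dose, linearly interpolated."""
        return float(np.interp(dose_cgy, self.dose_bins_cgy, self.volume_pct))

    def d_at(self, volume_pct: float) -> float:
        """Dose received by at least ``volume_pct`` of the volume."""
        # volume_pct is nonincreasing along dose; invert by reversing
        v = self.volume_pct[::-1]
        d = self.dose_bins_cgy[::-1]
        return float(np.interp(volume_pct, v, d))


def _roi_doses(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    d = dose.ravel()[mask.ravel()]
    if d.size == 0:
        raise ValueError("structure mask is empty")
    return d


def dvh(dose: np.ndarray, mask: np.ndarray, bin_width_cgy: float = 10.0) -> DVHCurve:
    """Cumulative (>= dose) DVH; starts at 100% at 0 cGy and ends at 0%."""
    d = _roi_doses(dose, mask)
    top = float(d.max()) + bin_width_cgy
    bins = np.arange(0.0, top + bin_width_cgy, bin_width_cgy)
    # V(b) = fraction of voxels with dose >= b
    counts = np.array([np.count_nonzero(d >= b) for b in bins], dtype=float)
    return DVHCurve(bins, 100.0 * counts / d.size)


def dose_at_volume_pct(
    dose: np.ndarray, mask: np.ndarray, volume_pct: float, *, interpolate: bool = True
) -> float:
    """D_x%: dose received by (at least) the hottest x% of the structure."""
    d = _roi_doses(dose, mask)
    if not 0 < volume_pct <= 100:
        raise ValueError("volume_pct must be in (0, 100]")
    method = "linear" if interpolate else "inverted_cdf"
    return float(np.quantile(d, 1.0 - volume_pct / 100.0, method=method))


def volume_at_dose(dose: np.ndarray, mask: np.ndarray, dose_cgy: float) -> float:
    """V(d): percent of the structure receiving >= ``dose_cgy``."""
    d = _roi_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(d >= dose_cgy)) / d.size


def dose_at_volume_cc(
    dose: np.ndarray,
    mask: np.ndarray,
    cc: float,
    voxel_volume_cc: float,
    *,
    interpolate: bool = True,
) -> float:
    """Dxcc: maximum dose received by ``cc`` cm^3 of the structure."""
    d = np.sort(_roi_doses(dose, mask))[::-1]
    total_cc = d.size * voxel_volume_cc
    if cc <= 0 or cc >= total_cc:
        raise ValueError(f"cc must be in (0, ROI volume = {total_cc:.3f} cc)")
    if not interpolate:
        k = min(d.size - 1, int(np.ceil(cc / voxel_volume_cc)) - 1)
        return float(d[max(k, 0)])
    # voxel i covers cumulative volume ((i + 0.5) * voxel_volume) at its center
    centers = (np.arange(d.size) + 0.5) * voxel_volume_cc
    return float(np.interp(cc, centers, d))


def mean_dose(dose: np.ndarray, mask: np.ndarray) -> float:
    return float(np.mean(_roi_doses(dose, mask)))


def paddick_ci(dose: np.ndarray, tv_mask: np.ndarray, rx_cgy: float) -> float:
    """Paddick conformity index (TV ∩ PIV)^2 / (TV * PIV), in [0, 1]."""
    dose = np.asarray(dose, dtype=np.float64).ravel()
    tv = np.asarray(tv_mask, dtype=bool).ravel()
    n_tv = int(np.count_nonzero(tv))
    if n_tv == 0:
        raise ValueError("target volume is empty")
    piv = dose >= rx_cgy
    n_piv = int(np.count_nonzero(piv))
    if n_piv == 0:
        warnings.warn("prescription isodose volume is empty; CI = 0")
        return 0.0
    n_both = int(np.count_nonzero(tv & piv))
    return n_both**2 / (n_tv * n_piv)


def homogeneity_index(dose: np.ndarray, ptv_mask: np.ndarray) -> float:
    """HI = (D2% - D98%) / D50%; 0 for a perfectly uniform target dose."""
    d2 = dose_at_volume_pct(dose, ptv_mask, 2.0)
    d98 = dose_at_volume_pct(dose, ptv_mask, 98.0)
    d50 = dose_at_volume_pct(dose, ptv_mask, 50.0)
    if d50 == 0:
        raise ValueError("median target dose is zero; HI undefined")
    return (d2 - d98) / d50


# ---------------------------------------------------------------------------
# Aperture complexity


def aperture_open_area_mm2(rows: list[tuple[float, float] | None], leaf_width_mm: float) -> float:
    """Open area of one aperture given per-row (left, right) edges in mm."""
    return leaf_width_mm * sum(r[1] - r[0] for r in rows if r is not None)


def aperture_side_edge_mm(rows: list[tuple[float, float] | None]) -> float:
    """Leaf-side edge length y_i of one aperture (leaf ends excluded).

    Edges parallel to leaf travel that separate open from closed regions:
    the free top/bottom of the first/last open row plus, between adjacent
    rows, the length of the symmetric difference of their open intervals
    (aligned leaves contribute no inter-row edge).
    """

    def _len(iv):
        return 0.0 if iv is None else iv[1] - iv[0]

    def _overlap(a, b):
        if a is None or b is None:
            return 0.0
        return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))

    y = 0.0
    padded = [None, *rows, None]
    for above, below in zip(padded[:-1], padded[1:]):
        y += _len(above) + _len(below) - 2.0 * _overlap(above, below)
    return y


def edge_metric(apertures, leaf_width_cm: float | None = None) -> float:
    """MU-weighted mean of y_i / A_i over all apertures, in mm^-1.

    ``apertures`` is either an :class:`~progplan.optimizer.ApertureSequence`
    or an iterable of ``(rows, mu)`` pairs, where ``rows`` lists per-row
    (left, right) leaf edges in mm (``None`` for a closed row).
    """
    if hasattr(apertures, "iter_apertures"):
        leaf_width_mm = apertures.leaf_width_cm * 10.0
        items = list(apertures.iter_apertures())
    else:
        if leaf_width_cm is None:
            raise ValueError("leaf_width_cm required for raw aperture lists")
        leaf_width_mm = leaf_width_cm * 10.0
        items = list(apertures)

    total_mu = sum(mu for _, mu in items)
    if total_mu <= 0:
        raise ValueError("total MU must be positive")
    m = 0.0
    for rows, mu in items:
        if mu < 0:
            raise ValueError("aperture MU must be nonnegative")
        if mu == 0:
            continue
        area = aperture_open_area_mm2(rows, leaf_width_mm)
        if area <= 0:
            raise ValueError("aperture with positive MU has zero open area")
        m += mu * aperture_side_edge_mm(rows) / area
    return m / total_mu


# ---------------------------------------------------------------------------
# Metrics report and clinical goals


@dataclass(frozen=True)
class ClinicalGoal:
    """One clinical requirement, e.g. lungs V20Gy < 28%."""

    roi: str
    metric: str  # 'VxGy' | 'Dx%' | 'Dxcc' | 'Dmean' | 'CI'
    arg: float | None  # x for VxGy (cGy), Dx% (%), Dxcc (cc); None otherwise
    threshold: float
    direction: str  # '<', '<=', '>', '>='

    def describe(self) -> str:
        if self.metric == "VxGy":
            metric = f"V{self.arg / 100:g}Gy (%)"
        elif self.metric in ("Dx%", "Dxcc"):
            metric = f"D{self.arg:g}{self.metric[2:]} (cGy)"
        elif self.metric == "Dmean":
            metric = "Dmean (cGy)"
        else:
            metric = self.metric
        return f"{self.roi} {metric} {self.direction} {self.threshold:g}"


def default_clinical_goals(rx_cgy: float = 6000.0) -> list[ClinicalGoal]:
    """Protocol-style goal set for conventionally fractionated lung plans."""
    return [
        ClinicalGoal("ptv", "VxGy", rx_cgy, 95.0, ">="),
        ClinicalGoal("ptv", "Dxcc", 0.03, 1.15 * rx_cgy, "<"),
        ClinicalGoal("ptv", "CI", None, 0.8, ">"),
        ClinicalGoal("lungs", "VxGy", 3000.0, 18.0, "<"),
        ClinicalGoal("lungs", "VxGy", 2000.0, 28.0, "<"),
        ClinicalGoal("lungs", "VxGy", 500.0, 50.0, "<"),
        ClinicalGoal("lungs", "Dmean", None, 1250.0, "<"),
        ClinicalGoal("heart", "VxGy", 3000.0, 40.0, "<"),
        ClinicalGoal("heart", "Dmean", None, 2500.0, "<"),
        ClinicalGoal("spinal_cord", "Dxcc", 0.03, 4500.0, "<"),
    ]


def _evaluate_goal_metric(goal: ClinicalGoal, dose, phantom: Phantom, rx_cgy: float) -> float:
    mask = phantom.mask(goal.roi)
    if goal.metric == "VxGy":
        return volume_at_dose(dose, mask, goal.arg)
    if goal.metric == "Dx%":
        return dose_at_volume_pct(dose, mask, goal.arg)
    if goal.metric == "Dxcc":
        return dose_at_volume_cc(dose, mask, goal.arg, phantom.grid.voxel_volume_cc)
    if goal.metric == "Dmean":
        return mean_dose(dose, mask)
    if goal.metric == "CI":
        return paddick_ci(dose, mask, rx_cgy)
    raise ValueError(f"unknown goal metric {goal.metric!r}")


_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def check_goals(
    dose: np.ndarray, phantom: Phantom, goals: list[ClinicalGoal], rx_cgy: float = 6000.0
) -> pd.DataFrame:
    """Evaluate each goal; one row per goal with achieved value and verdict.

    Strict inequalities are honored strictly.  A goal whose ROI is missing
    is flagged not-evaluable and fails the plan verdict.  The plan verdict
    is attached as ``df.attrs['plan_pass']`` (vacuously True for an empty
    goal list).
    """
    rows = []
    plan_pass = True
    for goal in goals:
        try:
            achieved = _evaluate_goal_metric(goal, dose, phantom, rx_cgy)
            verdict = bool(_OPS[goal.direction](achieved, goal.threshold))
            evaluable = True
        except KeyError:
            achieved, verdict, evaluable = np.nan, False, False
        plan_pass &= verdict
        rows.append(
            {
                "goal": goal.describe(),
                "roi": goal.roi,
                "achieved": achieved,
                "threshold": goal.threshold,
                "direction": goal.direction,
                "evaluable": evaluable,
                "pass": verdict,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["plan_pass"] = bool(plan_pass)
    return df


def compute_metrics(
    dose: np.ndarray,
    phantom: Phantom,
    rx_cgy: float = 6000.0,
    rois: list[str] | None = None,
) -> dict[str, float]:
    """Flat metric table for one plan (keys like ``'ptv_D98%'``)."""
    dose = np.asarray(dose, dtype=np.float64)
    vox_cc = phantom.grid.voxel_volume_cc
    rois = rois or ["ctv", "ptv", "lungs", "heart", "spinal_cord"]
    out: dict[str, float] = {}
    for roi in rois:
        if roi not in phantom.structures:
            continue
        mask = phantom.mask(roi)
        out[f"{roi}_Dmean"] = mean_dose(dose, mask)
        for q in (98.0, 50.0, 2.0):
            out[f"{roi}_D{q:g}%"] = dose_at_volume_pct(dose, mask, q)
        if phantom.volume_cc(roi) > 0.03:
            out[f"{roi}_D0.03cc"] = dose_at_volume_cc(dose, mask, 0.03, vox_cc)
        if roi in ("lungs", "heart"):
            for gy in (5, 10, 20, 30):
                out[f"{roi}_V{gy}Gy"] = volume_at_dose(dose, mask, gy * 100.0)
    if "ptv" in phantom.structures:
        out["ptv_V_rx"] = volume_at_dose(dose, phantom.mask("ptv"), rx_cgy)
        out["ptv_CI"] = paddick_ci(dose, phantom.mask("ptv"), rx_cgy)
        out["ptv_HI"] = homogeneity_index(dose, phantom.mask("ptv"))
    return out
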