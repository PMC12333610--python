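"""Optimization objective functions: value, gradient, and achieved dose.

Every template row is an :class:`ObjectiveSpec` with a function type, an
ROI, a dose level (its *target*), optional shape parameters and a weight.
Each type provides

* a **feedback value** — a dimensionless penalty, zero iff the constraint
  is satisfied, normalized by the prescription dose squared so that a
  single threshold (e.g. 4e-4) is meaningful across rows;
* a **gradient** with respect to per-voxel dose (zero outside the ROI);
* an **achieved quantity** — the dose scalar that the progressive
  tightening rule rescales (gEUD for EUD types, ROI extremum for
  min/max-dose, the dose at the spec's volume percentile for DVH types,
  and the achieved low-level-equivalent falloff dose for DoseFallOff).

Penalty forms (d = voxel dose, T = current target, Rx = prescription):

* MinDose:  mean over ROI of (max(0, T - d) / Rx)^2
* MaxDose:  mean over ROI of (max(0, d - T) / Rx)^2
* MaxDvh(T, V%): quadratic penalty on the violating subvolume between the
  current V%-dose and T (one-sided DVH objective); MinDvh is the mirror
  image on the deficit side.
* MaxEud:   (max(0, gEUD - T) / Rx)^2;  MinEud: (max(0, T - gEUD) / Rx)^2
* DoseFallOff(H, L, r): for voxels outside the PTV, allowed dose
  A(v) = H - (H - L) * min(1, dist(v, PTV surface) / r); penalty is the
  mean over those voxels of (max(0, d - A) / Rx)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .phantom import Phantom

__all__ = [
    "FUNCTION_TYPES",
    "ObjectiveSpec",
    "TemplateState",
    "geud",
    "geud_gradient",
    "objective_value_and_gradient",
    "objective_value",
    "composite_objective",
    "achieved_quantity",
    "dose_floor_cgy",
]

FUNCTION_TYPES = (
    "MinDose",
    "MaxDose",
    "MinDvh",
    "MaxDvh",
    "MinEud",
    "MaxEud",
    "DoseFallOff",
)

#: doses are clamped here before negative-exponent gEUD (avoids 0**-150)
dose_floor_cgy = 0.1


@dataclass
class ObjectiveSpec:
    """One optimization-template row."""

    roi: str
    ftype: str
    dose_level: float | None = None  # cGy; for DoseFallOff this is high_level
    low_level: float | None = None  # cGy, DoseFallOff only
    distance_cm: float | None = None  # DoseFallOff only
    volume_pct: float | None = None  # DVH types only
    a_param: float | None = None  # EUD types only
    weight: float = 1.0
    adaptive: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in FUNCTION_TYPES:
            raise ValueError(f"unknown function type {self.ftype!r}")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.ftype in ("MinDvh", "MaxDvh"):
            if not (self.volume_pct is not None and 0 < self.volume_pct <= 100):
                raise ValueError("DVH objectives need 0 < volume_pct <= 100")
        if self.ftype in ("MinEud", "MaxEud"):
            if not self.a_param:
                raise ValueError("EUD objectives need a nonzero exponent a")
        if self.ftype == "DoseFallOff":
            if self.distance_cm is None or self.distance_cm <= 0:
                raise ValueError("DoseFallOff needs distance > 0")
            if self.low_level is None or self.dose_level is None:
                raise ValueError("DoseFallOff needs high and low dose levels")
            if self.dose_level < self.low_level:
                raise ValueError("DoseFallOff requires high_level >= low_level")
        elif self.dose_level is None:
            raise ValueError(f"{self.ftype} needs a dose level")

    @property
    def initial_target(self) -> float:
        """The tightenable scalar: low_level for DoseFallOff, else dose_level."""
        return self.low_level if self.ftype == "DoseFallOff" else self.dose_level

    def label(self) -> str:
        bits = [self.roi, self.ftype]
        if self.ftype == "DoseFallOff":
            bits.append(f"{self.dose_level:.0f}->{self.low_level:.0f}cGy/{self.distance_cm}cm")
        else:
            bits.append(f"{self.dose_level:.0f}cGy")
        if self.volume_pct is not None:
            bits.append(f"to {self.volume_pct:g}%")
        if self.a_param is not None:
            bits.append(f"a={self.a_param:g}")
        return " ".join(bits)


@dataclass
class TemplateState:
    """An ordered objective template plus its current tightened targets."""

    specs: list[ObjectiveSpec]
    current_targets: list[float] = field(default_factory=list)
    tighten_history: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.current_targets:
            self.current_targets = [s.initial_target for s in self.specs]
        if not self.tighten_history:
            self.tighten_history = [[] for _ in self.specs]

    def set_target(self, i: int, new_target: float) -> None:
        spec = self.specs[i]
        old = self.current_targets[i]
        if spec.adaptive and spec.ftype.startswith("Max") and new_target > spec.initial_target:
            raise ValueError("tightening may only decrease Max-type targets")
        self.current_targets[i] = float(new_target)
        self.tighten_history[i].append((old, float(new_target)))

    def copy(self) -> "TemplateState":
        return TemplateState(
            specs=list(self.specs),
            current_targets=list(self.current_targets),
            tighten_history=[list(h) for h in self.tighten_history],
        )

    def reset(self) -> None:
        self.current_targets = [s.initial_target for s in self.specs]
        self.tighten_history = [[] for _ in self.specs]

    # -- YAML round trip, one mapping per template row ----------------------
    def to_yaml(self, path) -> None:
        rows = []
        for spec, tgt in zip(self.specs, self.current_targets):
            row = {k: v for k, v in spec.__dict__.items() if v is not None}
            row["current_target"] = tgt
            rows.append(row)
        with open(path, "w") as fh:
            yaml.safe_dump(rows, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TemplateState":
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        specs, targets = [], []
        for row in rows:
            tgt = row.pop("current_target", None)
            spec = ObjectiveSpec(**row)
            specs.append(spec)
            targets.append(tgt if tgt is not None else spec.initial_target)
        return cls(specs=specs, current_targets=targets)


# ---------------------------------------------------------------------------
# gEUD


def geud(dose_values: np.ndarray, a: float) -> float:
    """Generalized equivalent uniform dose, (mean of d^a)^(1/a).

    a = 1 is the mean, a -> +inf the maximum, a -> -inf the minimum.
    Numerically stabilized by scaling with the dose extremum so that
    |a| = 150 does not overflow; doses are clamped to a small positive
    floor when a < 0.
    """
    d = np.asarray(dose_values, dtype=np.float64)
    if d.size == 0:
        raise ValueError("gEUD of an empty ROI is undefined")
    if a == 0:
        raise ValueError("gEUD exponent a must be nonzero")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    if a < 0:
        d = np.maximum(d, dose_floor_cgy)
    scale = d.max() if a > 0 else d.min()
    if scale == 0:
        return 0.0
    return float(scale * np.mean((d / scale) ** a) ** (1.0 / a))


def geud_gradient(dose_values: np.ndarray, a: float) -> np.ndarray:
    """d gEUD / d dose_v = (1/N) * (d_v / gEUD)^(a-1), with the same clamping."""
    d = np.asarray(dose_values, dtype=np.float64)
    if a < 0:
        d = np.maximum(d, dose_floor_cgy)
    g = geud(d, a)
    if g == 0:
        return np.zeros_like(d)
    return (d / g) ** (a - 1.0) / d.size


# ---------------------------------------------------------------------------
# per-spec value / gradient / achieved quantity


def _percentile_dose(doses: np.ndarray, volume_pct: float, interpolate: bool = False) -> float:
    """D_x%: largest dose received by at least x% of the voxels.

    The non-interpolated form (default) returns an actual voxel dose — the
    convention used by the tightening readout; ``interpolate=True`` uses
    linear interpolation on the empirical quantile function.
    """
    q = 1.0 - volume_pct / 100.0
    method = "linear" if interpolate else "inverted_cdf"
    return float(np.quantile(doses, q, method=method))


def _falloff_allowed(spec: ObjectiveSpec, low_level: float, dist_mm: np.ndarray) -> np.ndarray:
    high = spec.dose_level
    r_mm = spec.distance_cm * 10.0
    frac = np.minimum(1.0, dist_mm / r_mm)
    return high - (high - low_level) * frac


def objective_value_and_gradient(
    spec: ObjectiveSpec,
    dose: np.ndarray,
    phantom: Phantom,
    rx: float,
    *,
    target: float | None = None,
    want_gradient: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Feedback value (dimensionless, >= 0) and per-voxel dose gradient.

    ``target`` overrides the spec's nominal dose level (the progressive
    loop passes the current tightened target).  The gradient array is
    full-volume-flat and zero outside the ROI; ``want_gradient=False``
    skips its allocation.
    """
    dose = np.asarray(dose, dtype=np.float64).ravel()
    mask = phantom.mask(spec.roi).ravel()
    n_roi = int(np.count_nonzero(mask))
    if n_roi == 0:
        raise ValueError(f"ROI {spec.roi!r} is empty")
    T = spec.initial_target if target is None else float(target)
    d = dose[mask]
    rx2 = rx * rx
    grad = np.zeros(dose.size) if want_gradient else None
    g_roi = None

    if spec.ftype == "MinDose":
        deficit = np.maximum(0.0, T - d)
        value = float(np.mean(deficit**2)) / rx2
        if want_gradient:
            g_roi = -2.0 * deficit / (rx2 * n_roi)
    elif spec.ftype == "MaxDose":
        excess = np.maximum(0.0, d - T)
        value = float(np.mean(excess**2)) / rx2
        if want_gradient:
            g_roi = 2.0 * excess / (rx2 * n_roi)
    elif spec.ftype in ("MaxDvh", "MinDvh"):
        dv = _percentile_dose(d, spec.volume_pct)
        if spec.ftype == "MaxDvh":
            sel = (d > T) & (d <= dv)
            diff = d - T
        else:
            sel = (d < T) & (d >= dv)
            diff = d - T  # negative on the deficit side
        viol = np.where(sel, diff, 0.0)
        value = float(np.sum(viol**2)) / (rx2 * n_roi)
        if want_gradient:
            g_roi = 2.0 * viol / (rx2 * n_roi)
    elif spec.ftype in ("MaxEud", "MinEud"):
        a = spec.a_param
        g = geud(d, a)
        diff = g - T if spec.ftype == "MaxEud" else T - g
        viol = max(0.0, diff)
        value = (viol / rx) ** 2
        if want_gradient:
            sign = 1.0 if spec.ftype == "MaxEud" else -1.0
            g_roi = sign * 2.0 * viol / rx2 * geud_gradient(d, a)
    elif spec.ftype == "DoseFallOff":
        dist = phantom.distance_outside_mm("ptv").ravel()[mask]
        outside = dist > 0
        allowed = _falloff_allowed(spec, T, dist)
        excess = np.where(outside, np.maximum(0.0, d - allowed), 0.0)
        n_out = int(np.count_nonzero(outside))
        if n_out == 0:
            raise ValueError("DoseFallOff ROI contains no voxels outside the PTV")
        value = float(np.sum(excess**2)) / (rx2 * n_out)
        if want_gradient:
            g_roi = 2.0 * excess / (rx2 * n_out)
    else:  # pragma: no cover - guarded by ObjectiveSpec
        raise ValueError(f"unknown function type {spec.ftype!r}")

    if want_gradient:
        grad[np.nonzero(mask)[0]] = g_roi
    return value, grad


def objective_value(
    spec: ObjectiveSpec, dose: np.ndarray, phantom: Phantom, rx: float, target: float | None = None
) -> float:
    return objective_value_and_gradient(
        spec, dose, phantom, rx, target=target, want_gradient=False
    )[0]


def composite_objective(
    template: TemplateState,
    dose: np.ndarray,
    phantom: Phantom,
    rx: float,
    *,
    want_gradient: bool = False,
) -> tuple[float, list[float], np.ndarray | None]:
    """Weighted sum of feedback values plus the per-spec values themselves."""
    total = 0.0
    per_spec: list[float] = []
    grad = np.zeros(np.asarray(dose).size) if want_gradient else None
    for spec, target in zip(template.specs, template.current_targets):
        value, g = objective_value_and_gradient(
            spec, dose, phantom, rx, target=target, want_gradient=want_gradient
        )
        per_spec.append(value)
        total += spec.weight * value
        if want_gradient:
            grad += spec.weight * g
    return total, per_spec, grad


def achieved_quantity(
    spec: ObjectiveSpec,
    dose: np.ndarray,
    phantom: Phantom,
    *,
    target: float | None = None,
) -> float:
    """The dose scalar (cGy) that the tightening rule rescales."""
    dose = np.asarray(dose, dtype=np.float64).ravel()
    mask = phantom.mask(spec.roi).ravel()
    d = dose[mask]
    if d.size == 0:
        raise ValueError(f"ROI {spec.roi!r} is empty")
    if spec.ftype in ("MaxEud", "MinEud"):
        return geud(d, spec.a_param)
    if spec.ftype == "MaxDose":
        return float(d.max())
    if spec.ftype == "MinDose":
        return float(d.min())
    if spec.ftype in ("MaxDvh", "MinDvh"):
        return _percentile_dose(d, spec.volume_pct)
    if spec.ftype == "DoseFallOff":
        # smallest low level L' whose allowed-dose curve no voxel exceeds,
        # i.e. the achieved falloff dose equivalent to the low level
        dist = phantom.distance_outside_mm("ptv").ravel()[mask]
        r_mm = spec.distance_cm * 10.0
        frac = np.minimum(1.0, dist / r_mm)
        sel = frac > 0
        if not sel.any():
            return spec.low_level if target is None else float(target)
        high = spec.dose_level
        lp = (d[sel] - high * (1.0 - frac[sel])) / frac[sel]
        return float(np.clip(lp.max(), 0.0, high))
    raise ValueError(f"unknown function type {spec.ftype!r}")  # pragma: no cover
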