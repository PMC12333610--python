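"""Sparse beamlet dose-influence matrix for partial-arc VMAT geometry.

The engine replaces a clinical dose algorithm with a documented simplified
pencil-beam model: each beamlet deposits

    dose(b, v) = exp(-mu * radiological_depth(v))
                 * (SAD / (SAD + z(v)))**2
                 * exp(-rho(b, v)**2 / (2 * sigma**2)),   rho <= trunc * sigma

where ``radiological_depth`` is the line integral of relative electron
density from the body surface to the voxel along the beam direction,
``z`` the depth coordinate relative to the isocenter plane, and ``rho``
the lateral distance from the beamlet axis (parallel-beam lateral
geometry, Gaussian penumbra).  Dose is linear in beamlet weights; the
absolute scale is arbitrary ("cGy per unit weight") because plans are
normalized to the prescription downstream.

This is qualitative realism sufficient for exercising the optimization
algorithm, not clinical accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .phantom import GridSpec, Phantom

__all__ = [
    "MachineModel",
    "BeamArc",
    "ControlPoint",
    "BeamletGrid",
    "InfluenceMatrix",
    "default_machine",
    "standard_arcs",
    "discretize_arcs",
    "build_beamlet_grids",
    "compute_influence",
    "dose_from_weights",
    "save_influence_h5",
    "load_influence_h5",
]


@dataclass(frozen=True)
class MachineModel:
    """Delivery-machine description (defaults: O-ring linac, 6 MV FFF)."""

    max_field_cm: tuple[float, float] = (28.0, 28.0)
    leaf_width_cm: float = 0.5  # single effective layer of 0.5 cm leaves
    energy_label: str = "6MV-FFF"
    dose_rate_mu_per_min: float = 800.0
    max_gantry_speed_deg_s: float = 24.0
    max_leaf_speed_cm_s: float = 5.0
    source_axis_distance_cm: float = 100.0

    def __post_init__(self) -> None:
        if self.leaf_width_cm <= 0:
            raise ValueError("leaf width must be > 0")
        if self.dose_rate_mu_per_min <= 0:
            raise ValueError("dose rate must be > 0")


@dataclass(frozen=True)
class BeamArc:
    """One partial arc.  ``cw`` sweeps increasing gantry angle (mod 360)."""

    start_deg: float
    stop_deg: float
    direction: str = "cw"
    collimator_deg: float = 10.0
    control_point_spacing_deg: float = 4.0

    def span_deg(self) -> float:
        if self.direction == "cw":
            span = (self.stop_deg - self.start_deg) % 360.0
        elif self.direction == "ccw":
            span = (self.start_deg - self.stop_deg) % 360.0
        else:
            raise ValueError(f"direction must be 'cw' or 'ccw', got {self.direction!r}")
        if span == 0:
            raise ValueError(f"zero-length arc {self.start_deg}->{self.stop_deg}")
        return span


@dataclass(frozen=True)
class ControlPoint:
    gantry_deg: float
    collimator_deg: float


def standard_arcs(control_point_spacing_deg: float = 4.0) -> list[BeamArc]:
    """The six partial arcs of the conventional thoracic beam arrangement.

    Three arcs (182-230, 300-60, 130-178 degrees) and the same three
    traversed in the opposite direction; collimator 10 degrees for one
    direction and 350 for the other.
    """
    spans = [(182.0, 230.0), (300.0, 60.0), (130.0, 178.0)]
    arcs = []
    for start, stop in spans:
        arcs.append(BeamArc(start, stop, "cw", 10.0, control_point_spacing_deg))
    for start, stop in spans:
        arcs.append(BeamArc(stop, start, "ccw", 350.0, control_point_spacing_deg))
    return arcs


def default_machine() -> MachineModel:
    """O-ring-style linac defaults: 0.5 cm effective leaves, 6 MV FFF, 800 MU/min."""
    return MachineModel()


def discretize_arcs(arcs: list[BeamArc]) -> list[ControlPoint]:
    """Control points covering each arc inclusive of both endpoints.

    Angle arithmetic is modulo 360, so e.g. an arc from 300 to 60 degrees
    wraps through 0.  Spacing must be > 0; a zero-length arc is an error.
    """
    cps: list[ControlPoint] = []
    for arc in arcs:
        spacing = arc.control_point_spacing_deg
        if spacing <= 0:
            raise ValueError("control-point spacing must be > 0")
        span = arc.span_deg()
        n_steps = int(np.ceil(span / spacing - 1e-9))
        offsets = np.minimum(np.arange(n_steps + 1) * spacing, span)
        sign = 1.0 if arc.direction == "cw" else -1.0
        for off in offsets:
            cps.append(ControlPoint((arc.start_deg + sign * off) % 360.0, arc.collimator_deg))
    return cps


# ---------------------------------------------------------------------------
# Beamlet lattice per control point


@dataclass
class BeamletGrid:
    """2D beamlet lattice at the isocenter plane for one control point.

    ``u`` runs along leaf travel, ``v`` across leaf rows (pitch =
    ``leaf_width``); the lattice is rotated with the collimator.  ``active``
    flags beamlets inside the target's beam's-eye-view plus margin.
    """

    control_point: ControlPoint
    u_centers_mm: np.ndarray
    v_centers_mm: np.ndarray
    active: np.ndarray  # bool, shape (len(u), len(v))
    e_u: np.ndarray = field(default=None)
    e_v: np.ndarray = field(default=None)
    e_d: np.ndarray = field(default=None)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.active))


def _beam_frame(cp: ControlPoint) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors (e_u, e_v, e_d): lateral, leaf-row (collimator-rotated), beam travel."""
    g = np.deg2rad(cp.gantry_deg)
    e_d = np.array([-np.sin(g), np.cos(g), 0.0])  # direction of travel
    e_u0 = np.array([np.cos(g), np.sin(g), 0.0])
    e_v0 = np.array([0.0, 0.0, 1.0])
    c = np.deg2rad(cp.collimator_deg)
    e_u = np.cos(c) * e_u0 + np.sin(c) * e_v0
    e_v = -np.sin(c) * e_u0 + np.cos(c) * e_v0
    return e_u, e_v, e_d


def build_beamlet_grids(
    phantom: Phantom,
    control_points: list[ControlPoint],
    machine: MachineModel | None = None,
    *,
    target: str = "ptv",
    bev_margin_mm: float = 10.0,
    along_leaf_step_cm: float = 0.5,
    isocenter_mm: np.ndarray | None = None,
) -> list[BeamletGrid]:
    """Per control point, lay out beamlets covering the target's BEV + margin.

    The isocenter defaults to the PTV centroid.  Beamlet pitch is the leaf
    width across rows and ``along_leaf_step_cm`` along leaf travel.
    """
    machine = machine or MachineModel()
    iso = phantom.centroid_mm(target) if isocenter_mm is None else np.asarray(isocenter_mm)
    tgt_idx = np.argwhere(phantom.mask(target))
    tgt_xyz = np.asarray(phantom.grid.origin) + tgt_idx * np.asarray(phantom.grid.spacing)
    rel = tgt_xyz - iso

    pitch_u = along_leaf_step_cm * 10.0
    pitch_v = machine.leaf_width_cm * 10.0
    half_u = machine.max_field_cm[0] * 10.0 / 2.0
    half_v = machine.max_field_cm[1] * 10.0 / 2.0

    grids = []
    dil = int(np.ceil(bev_margin_mm / min(pitch_u, pitch_v)))
    for cp in control_points:
        e_u, e_v, e_d = _beam_frame(cp)
        u = rel @ e_u
        v = rel @ e_v
        u_lo = max(-half_u, u.min() - bev_margin_mm - pitch_u)
        u_hi = min(half_u, u.max() + bev_margin_mm + pitch_u)
        v_lo = max(-half_v, v.min() - bev_margin_mm - pitch_v)
        v_hi = min(half_v, v.max() + bev_margin_mm + pitch_v)
        u_centers = np.arange(np.floor(u_lo / pitch_u), np.ceil(u_hi / pitch_u) + 1) * pitch_u
        v_centers = np.arange(np.floor(v_lo / pitch_v), np.ceil(v_hi / pitch_v) + 1) * pitch_v

        iu = np.clip(np.round((u - u_centers[0]) / pitch_u).astype(int), 0, len(u_centers) - 1)
        iv = np.clip(np.round((v - v_centers[0]) / pitch_v).astype(int), 0, len(v_centers) - 1)
        active = np.zeros((len(u_centers), len(v_centers)), dtype=bool)
        active[iu, iv] = True
        active = ndimage.binary_dilation(active, iterations=dil)
        grids.append(BeamletGrid(cp, u_centers, v_centers, active, e_u, e_v, e_d))
    return grids


# ---------------------------------------------------------------------------
# Influence matrix


@dataclass
class InfluenceMatrix:
    """Sparse beamlet -> voxel dose map, plus the beamlet bookkeeping.

    ``matrix`` has shape (n_voxels, n_beamlets); columns are grouped per
    control point in the order of ``grids``; ``beamlet_cp`` maps each
    column to its control-point index, ``beamlet_uv`` to its lattice
    indices within that control point's grid.
    """

    matrix: sparse.csr_matrix
    grids: list[BeamletGrid]
    beamlet_cp: np.ndarray
    beamlet_uv: np.ndarray  # (n_beamlets, 2) lattice indices
    isocenter_mm: np.ndarray
    grid_shape: tuple[int, int, int]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


def _radiological_depth_grid(
    phantom: Phantom, e_u_ax: np.ndarray, e_d: np.ndarray, iso: np.ndarray, step_mm: float
):
    """Cumulative density line integral resampled on a beam-aligned grid.

    Returns (depth_grid[u, t, z], u0, t0, z0, du, dt, dz) where ``t`` runs
    along the beam from an entry plane well outside the body.
    """
    grid = phantom.grid
    extent = 0.5 * float(np.hypot(grid.shape[0] * grid.spacing[0], grid.shape[1] * grid.spacing[1]))
    t0 = -extent - step_mm
    u_vals = np.arange(-extent, extent + step_mm, step_mm)
    t_vals = np.arange(t0, extent + step_mm, step_mm)
    z_vals = grid.axis_coords(2)

    uu = u_vals[:, None]
    tt = t_vals[None, :]
    px = iso[0] + uu * e_u_ax[0] + tt * e_d[0]
    py = iso[1] + uu * e_u_ax[1] + tt * e_d[1]
    ix = (px - grid.origin[0]) / grid.spacing[0]
    iy = (py - grid.origin[1]) / grid.spacing[1]
    shape2 = ix.shape
    dens = np.empty(shape2 + (len(z_vals),), dtype=np.float32)
    coords = np.stack([ix.ravel(), iy.ravel()], axis=0)
    for k in range(len(z_vals)):
        plane = phantom.density[:, :, k]
        dens[..., k] = ndimage.map_coordinates(
            plane, coords, order=1, mode="constant", cval=0.0
        ).reshape(shape2)
    depth = np.cumsum(dens, axis=1) * step_mm - dens * (step_mm / 2.0)
    return depth, u_vals[0], t_vals[0], z_vals[0], step_mm, step_mm, grid.spacing[2]


def compute_influence(
    phantom: Phantom,
    control_points: list[ControlPoint],
    beamlet_grids: list[BeamletGrid] | None = None,
    *,
    machine: MachineModel | None = None,
    mu_per_mm: float = 0.005,
    sigma_mm: float = 4.0,
    truncation_sigmas: float = 3.0,
    depth_step_mm: float = 4.0,
    restrict_to: str = "body",
    isocenter_mm: np.ndarray | None = None,
    **grid_kwargs,
) -> InfluenceMatrix:
    """Build the sparse influence matrix for the given control points.

    Entries are kept only for voxels inside ``restrict_to`` (the body by
    default: air receives no primary attenuation and is irrelevant to
    every objective and metric).  Bitwise reproducible for identical
    inputs (pure deterministic numpy).
    """
    if mu_per_mm <= 0 or sigma_mm <= 0:
        raise ValueError("mu and sigma must be > 0")
    machine = machine or MachineModel()
    iso = (
        phantom.centroid_mm("ptv") if isocenter_mm is None else np.asarray(isocenter_mm, float)
    )
    if beamlet_grids is None:
        beamlet_grids = build_beamlet_grids(
            phantom, control_points, machine, isocenter_mm=iso, **grid_kwargs
        )
    if len(beamlet_grids) != len(control_points):
        raise ValueError("one beamlet grid per control point required")
    if sum(g.n_active for g in beamlet_grids) == 0:
        raise ValueError("no active beamlets; increase the BEV margin")

    grid = phantom.grid
    sad = machine.source_axis_distance_cm * 10.0
    trunc = truncation_sigmas * sigma_mm
    inv_two_sigma2 = 1.0 / (2.0 * sigma_mm**2)

    body_idx = np.argwhere(phantom.mask(restrict_to))
    body_flat = np.ravel_multi_index(body_idx.T, grid.shape).astype(np.int64)
    body_xyz = (np.asarray(grid.origin) + body_idx * np.asarray(grid.spacing)).astype(np.float64)
    rel_all = body_xyz - iso

    rows_parts, cols_parts, data_parts = [], [], []
    beamlet_cp_parts, beamlet_uv_parts = [], []
    col_offset = 0

    for cp_i, (cp, bg) in enumerate(zip(control_points, beamlet_grids)):
        e_u, e_v, e_d = _beam_frame(cp)
        e_u_ax, _, _ = _beam_frame(ControlPoint(cp.gantry_deg, 0.0))

        # active beamlets of this control point get global column indices
        act_iu, act_iv = np.nonzero(bg.active)
        n_act = len(act_iu)
        col_of = -np.ones(bg.active.shape, dtype=np.int64)
        col_of[act_iu, act_iv] = col_offset + np.arange(n_act)
        beamlet_cp_parts.append(np.full(n_act, cp_i, dtype=np.int32))
        beamlet_uv_parts.append(np.stack([act_iu, act_iv], axis=1).astype(np.int32))

        pitch_u = bg.u_centers_mm[1] - bg.u_centers_mm[0] if len(bg.u_centers_mm) > 1 else 5.0
        pitch_v = bg.v_centers_mm[1] - bg.v_centers_mm[0] if len(bg.v_centers_mm) > 1 else 5.0

        u = rel_all @ e_u
        v = rel_all @ e_v
        zb = rel_all @ e_d

        # candidate voxels: lateral bin within truncation reach of an active beamlet
        reach_u = int(np.ceil(trunc / pitch_u))
        reach_v = int(np.ceil(trunc / pitch_v))
        near = ndimage.binary_dilation(
            bg.active, structure=np.ones((2 * reach_u + 1, 2 * reach_v + 1), bool)
        )
        biu = np.round((u - bg.u_centers_mm[0]) / pitch_u).astype(int)
        biv = np.round((v - bg.v_centers_mm[0]) / pitch_v).astype(int)
        inlat = (
            (biu >= 0)
            & (biu < len(bg.u_centers_mm))
            & (biv >= 0)
            & (biv < len(bg.v_centers_mm))
        )
        cand = inlat.copy()
        cand[inlat] = near[biu[inlat], biv[inlat]]
        if not cand.any():
            continue

        vu = u[cand]
        vv = v[cand]
        vz = zb[cand]
        vflat = body_flat[cand]
        vbiu = biu[cand]
        vbiv = biv[cand]

        # radiological depth via beam-aligned cumulative integral
        depth_grid, u0, t0, z0, du, dt, dz = _radiological_depth_grid(
            phantom, e_u_ax, e_d, iso, depth_step_mm
        )
        u_ax = rel_all[cand] @ e_u_ax
        ci = np.stack(
            [
                (u_ax - u0) / du,
                (vz - t0) / dt,
                (body_xyz[cand][:, 2] - z0) / dz,
            ]
        )
        raddepth = ndimage.map_coordinates(depth_grid, ci, order=1, mode="nearest")
        central = np.exp(-mu_per_mm * raddepth) * (sad / (sad + vz)) ** 2

        for off_u in range(-reach_u, reach_u + 1):
            ku = vbiu + off_u
            ok_u = (ku >= 0) & (ku < len(bg.u_centers_mm))
            if not ok_u.any():
                continue
            dup = vu - (bg.u_centers_mm[0] + np.where(ok_u, ku, 0) * pitch_u)
            for off_v in range(-reach_v, reach_v + 1):
                kv = vbiv + off_v
                ok = ok_u & (kv >= 0) & (kv < len(bg.v_centers_mm))
                if not ok.any():
                    continue
                cols_cand = np.where(ok, col_of[np.where(ok, ku, 0), np.where(ok, kv, 0)], -1)
                ok &= cols_cand >= 0
                if not ok.any():
                    continue
                dvp = vv - (bg.v_centers_mm[0] + kv * pitch_v)
                rho2 = dup**2 + dvp**2
                ok &= rho2 <= trunc**2
                if not ok.any():
                    continue
                val = central[ok] * np.exp(-rho2[ok] * inv_two_sigma2)
                keep = val > 1e-8
                rows_parts.append(vflat[ok][keep])
                cols_parts.append(cols_cand[ok][keep])
                data_parts.append(val[keep].astype(np.float32))
        col_offset += n_act

    rows = np.concatenate(rows_parts) if rows_parts else np.empty(0, np.int64)
    cols = np.concatenate(cols_parts) if cols_parts else np.empty(0, np.int64)
    data = np.concatenate(data_parts) if data_parts else np.empty(0, np.float32)
    mat = sparse.coo_matrix(
        (data, (rows, cols)), shape=(grid.n_voxels, col_offset)
    ).tocsr()
    mat.sum_duplicates()
    return InfluenceMatrix(
        matrix=mat,
        grids=beamlet_grids,
        beamlet_cp=np.concatenate(beamlet_cp_parts),
        beamlet_uv=np.concatenate(beamlet_uv_parts),
        isocenter_mm=iso,
        grid_shape=grid.shape,
    )


def dose_from_weights(influence: InfluenceMatrix, weights: np.ndarray) -> np.ndarray:
    """Dose volume (flat, cGy per weight unit) for nonnegative beamlet weights."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (influence.n_beamlets,):
        raise ValueError(
            f"expected {influence.n_beamlets} weights, got shape {weights.shape}"
        )
    if np.any(weights < 0):
        raise ValueError("beamlet weights must be nonnegative")
    return influence.matrix @ weights


# ---------------------------------------------------------------------------
# HDF5 caching


def save_influence_h5(influence: InfluenceMatrix, path, config_key: str = "") -> None:
    import h5py

    m = influence.matrix
    with h5py.File(path, "w") as fh:
        fh.attrs["config_key"] = config_key
        fh.attrs["shape"] = m.shape
        fh.attrs["grid_shape"] = influence.grid_shape
        fh.attrs["isocenter_mm"] = influence.isocenter_mm
        fh.create_dataset("data", data=m.data, compression="gzip")
        fh.create_dataset("indices", data=m.indices, compression="gzip")
        fh.create_dataset("indptr", data=m.indptr, compression="gzip")
        fh.create_dataset("beamlet_cp", data=influence.beamlet_cp)
        fh.create_dataset("beamlet_uv", data=influence.beamlet_uv)


def load_influence_h5(path, grids: list[BeamletGrid] | None = None, expected_key: str | None = None):
    import h5py

    with h5py.File(path, "r") as fh:
        if expected_key is not None and fh.attrs["config_key"] != expected_key:
            raise ValueError("influence cache was built from a different configuration")
        mat = sparse.csr_matrix(
            (fh["data"][:], fh["indices"][:], fh["indptr"][:]),
            shape=tuple(fh.attrs["shape"]),
        )
        return InfluenceMatrix(
            matrix=mat,
            grids=grids or [],
            beamlet_cp=fh["beamlet_cp"][:],
            beamlet_uv=fh["beamlet_uv"][:],
            isocenter_mm=np.asarray(fh.attrs["isocenter_mm"]),
            grid_shape=tuple(int(s) for s in fh.attrs["grid_shape"]),
        )
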