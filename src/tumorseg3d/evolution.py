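"""Level-set evolution under the hybrid speed.

The PDE is the advection-free normal-speed form

    phi_t + F |grad phi| = 0,      F = alpha*S_e + beta*S_r + gamma*S_s

with F > 0 moving the front outward (interior {phi < 0} grows). The edge
term is discretized with Godunov upwinding on the sign of the local speed;
the region term is applied as the variational two-phase force (equivalent
at a reinitialized front, where |grad phi| = 1, and able to seize detached
interior-like regions); the curvature part uses central differences. The
time step obeys a CFL bound (hyperbolic, scaled by the speed maxima) and a
parabolic bound for the curvature term; region statistics are refreshed
every iteration from the current interior; phi is periodically restored to
a signed distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contour_init import InitialContour, init_phi
from .errors import GeometryError, GridError, ParameterError
from .grid_core import (
    BinaryMask,
    ImageVolume,
    LevelSetField,
    extract_mask,
    mean_curvature,
    reinitialize,
)
from .speed_terms import (
    SpeedWeights,
    check_weight_recommendations,
    default_contrast_scale,
    edge_term,
    load_presets,
    region_stats,
    region_term,
)

logger = logging.getLogger("tumorseg3d")

#: Voxel dilation of the interior bounding box defining the analysis region
#: for the region statistics (keeps distant anatomy out of c_out).
ANALYSIS_DILATION = 16


@dataclass
class EvolutionConfig:
    """Iteration, stability and convergence settings for the evolution loop."""

    max_iterations: int = 300
    dt_safety: float = 0.5  # CFL fraction in (0, 1]
    reinit_interval: int = 20
    convergence_tol: float = 1.0e-3  # relative interior-volume change
    convergence_window: int = 30
    use_3d: bool = True  # False confines growth to the seed slice

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if not (0 < self.dt_safety <= 1):
            raise ParameterError("dt_safety must be in (0, 1]")
        if self.reinit_interval < 1:
            raise ParameterError("reinit_interval must be >= 1")


@dataclass
class SegmentationResult:
    """Final mask + phi + per-iteration diagnostics of one evolution run."""

    mask: BinaryMask
    phi: LevelSetField
    iterations_run: int
    converged: bool
    collapsed: bool
    volume_history: list[float] = field(default_factory=list)  # mm^3 per iteration
    dt_history: list[float] = field(default_factory=list)  # time step per iteration

    def volume_mm3(self) -> float:
        return self.mask.volume_mm3()


def _upwind_gradients(phi: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Godunov upwind |grad phi| approximations (nabla+, nabla-).

    nabla+ is used where F > 0 (outward motion), nabla- where F < 0.
    One-sided differences use edge replication at the domain boundary.
    """
    plus_sq = np.zeros_like(phi)
    minus_sq = np.zeros_like(phi)
    for axis in range(3):
        h = spacing[axis]
        fwd = (np.roll(phi, -1, axis=axis) - phi) / h  # D+
        bwd = (phi - np.roll(phi, 1, axis=axis)) / h  # D-
        # replicate edges: zero the wrapped differences
        head = tuple(slice(-1, None) if a == axis else slice(None) for a in range(3))
        tail = tuple(slice(0, 1) if a == axis else slice(None) for a in range(3))
        fwd[head] = 0.0
        bwd[tail] = 0.0
        plus_sq += np.maximum(bwd, 0.0) ** 2 + np.minimum(fwd, 0.0) ** 2
        minus_sq += np.minimum(bwd, 0.0) ** 2 + np.maximum(fwd, 0.0) ** 2
    return np.sqrt(plus_sq), np.sqrt(minus_sq)


def _central_gradient_norm(phi: np.ndarray, spacing) -> np.ndarray:
    gx, gy, gz = np.gradient(phi, *spacing)
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def _dilated_bbox_mask(interior: np.ndarray, dilation: int) -> np.ndarray:
    """Boolean mask of the interior's bounding box dilated by ``dilation`` voxels."""
    sl = ndimage.find_objects(interior.astype(np.int8))[0]
    out = np.zeros(interior.shape, dtype=bool)
    grown = tuple(
        slice(max(s.start - dilation, 0), min(s.stop + dilation, n))
        for s, n in zip(sl, interior.shape)
    )
    out[grown] = True
    return out


def _clamp_domain_boundary(phi: np.ndarray, hmin: float) -> int:
    """Force the one-voxel shell at the domain boundary to stay exterior.

    Returns the number of clamped (previously interior) voxels.
    """
    shell = np.zeros(phi.shape, dtype=bool)
    for axis in range(3):
        shell[tuple(slice(0, 1) if a == axis else slice(None) for a in range(3))] = True
        shell[tuple(slice(-1, None) if a == axis else slice(None) for a in range(3))] = True
    clamped = int(np.count_nonzero(shell & (phi < 0)))
    phi[shell] = np.maximum(phi[shell], 0.5 * hmin)
    return clamped


def evolve(
    vol: ImageVolume,
    phi0: LevelSetField,
    w: SpeedWeights,
    cfg: EvolutionConfig | None = None,
    *,
    edge_scale: float = 1.0,
    contrast_scale: float | None = None,
    seed_slice: int | None = None,
) -> SegmentationResult:
    """Iterate phi under the hybrid speed until convergence or the budget.

    ``contrast_scale`` defaults to the volume-median smoothed gradient (the
    flat-tissue noise floor). If ``cfg.use_3d`` is False the front is
    confined to ``seed_slice`` (required in that case).
    """
    cfg = cfg or EvolutionConfig()
    if vol.shape != phi0.shape:
        raise GridError(f"volume shape {vol.shape} != phi shape {phi0.shape}")
    interior0 = phi0.phi < 0
    if not interior0.any():
        raise GeometryError("initial interior is empty")
    if not cfg.use_3d and seed_slice is None:
        raise ParameterError("2D mode needs the seed slice index")

    spacing = vol.spacing
    hmin = min(spacing)
    voxvol = vol.voxel_volume
    curvature_cap = 1.0 / hmin

    if contrast_scale is None:
        contrast_scale = default_contrast_scale(vol, interior0, edge_scale)
    se = edge_term(vol, edge_scale, contrast_scale) if w.alpha > 0 else None

    fld = phi0.copy()
    volume_history: list[float] = []
    dt_history: list[float] = []
    converged = False
    collapsed = False
    warned_boundary = False
    iterations = 0

    for it in range(cfg.max_iterations):
        interior = fld.phi < 0
        n_in = int(np.count_nonzero(interior))
        if n_in == 0:
            collapsed = True
            logger.warning("front collapsed at iteration %d", it)
            break

        analysis = _dilated_bbox_mask(interior, ANALYSIS_DILATION)

        # --- assemble the speed -------------------------------------------
        # edge term: geometric propagation, Godunov-upwinded below
        f_edge = w.alpha * se if w.alpha > 0 else None
        # region term: variational (gradient-flow) force, applied directly.
        # At a reinitialized front |grad phi| ~ 1, so the front's normal
        # speed is beta*S_r exactly as in the hybrid speed; away from the
        # front the direct force lets detached interior-like regions be
        # seized (a strictly upwinded F|grad phi| is zero at any local
        # minimum of phi and could never create an isolated component).
        if w.beta > 0:
            stats = region_stats(vol, fld, analysis)
            f_region = w.beta * region_term(vol, fld, stats, analysis)
        else:
            f_region = None
        if w.gamma > 0:
            kappa = np.clip(mean_curvature(fld), -curvature_cap, curvature_cap)
        else:
            kappa = None

        # --- time step: hyperbolic CFL + parabolic (curvature) bound ------
        amax = 0.0
        if f_edge is not None:
            amax += float(np.abs(f_edge).max())
        if f_region is not None:
            amax += float(np.abs(f_region).max())
        if kappa is not None:
            amax += w.gamma * float(np.abs(kappa).max())
        dt = cfg.dt_safety * hmin / max(amax, 1e-12)
        if w.gamma > 0:
            dt = min(dt, cfg.dt_safety * hmin**2 / (6.0 * w.gamma))
        dt_history.append(dt)

        # --- update --------------------------------------------------------
        phi = fld.phi
        if f_edge is not None:
            gplus, gminus = _upwind_gradients(phi, spacing)
            phi = phi - dt * (
                np.maximum(f_edge, 0.0) * gplus + np.minimum(f_edge, 0.0) * gminus
            )
        if f_region is not None:
            phi = phi - dt * f_region
        if kappa is not None:
            # phi_t = -gamma*S_s*|grad phi| = +gamma*kappa*|grad phi|
            phi = phi + dt * w.gamma * kappa * _central_gradient_norm(fld.phi, spacing)

        clamped = _clamp_domain_boundary(phi, hmin)
        if clamped and not warned_boundary:
            logger.warning("interior touched the volume boundary; clamped %d voxels", clamped)
            warned_boundary = True

        if not cfg.use_3d:
            # confine the front to the seed slice
            off = np.ones(vol.shape[2], dtype=bool)
            off[seed_slice] = False
            phi[:, :, off] = np.maximum(phi[:, :, off], 0.5 * hmin)

        fld = LevelSetField(phi, spacing, fld.band_width)
        iterations = it + 1

        if (it + 1) % cfg.reinit_interval == 0 and (fld.phi < 0).any():
            fld = reinitialize(fld)

        volume_history.append(float(np.count_nonzero(fld.phi < 0)) * voxvol)

        # --- convergence: relative volume span over the trailing window ----
        if len(volume_history) > cfg.convergence_window:
            recent = volume_history[-(cfg.convergence_window + 1):]
            span = max(recent) - min(recent)
            if max(recent) > 0 and span / max(recent) < cfg.convergence_tol:
                converged = True
                logger.info("converged after %d iterations", iterations)
                break

    if (fld.phi < 0).any():
        fld = reinitialize(fld)
    else:
        collapsed = True
    mask = extract_mask(fld, vol)
    return SegmentationResult(
        mask=mask,
        phi=fld,
        iterations_run=iterations,
        converged=converged,
        collapsed=collapsed,
        volume_history=volume_history,
        dt_history=dt_history,
    )


def segment_from_contour(
    vol: ImageVolume,
    contour: InitialContour,
    component: str = "contrast_enhancing",
    w: SpeedWeights | None = None,
    cfg: EvolutionConfig | None = None,
    *,
    edge_scale: float | None = None,
    contrast_scale: float | None = None,
) -> SegmentationResult:
    """Steps 2-4 of the workflow: contour -> phi0 -> preset/weights -> evolve.

    The component preset supplies weights (unless ``w`` overrides them),
    edge scale and iteration budget; recommendation violations are logged as
    warnings, never fatal.
    """
    preset = load_presets()[component]
    weights = w if w is not None else preset.weights
    check_weight_recommendations(weights, component)
    if edge_scale is None:
        edge_scale = preset.edge_scale
    if cfg is None:
        cfg = EvolutionConfig(max_iterations=preset.iterations)
    phi0 = init_phi(contour, vol)
    return evolve(
        vol,
        phi0,
        weights,
        cfg,
        edge_scale=edge_scale,
        contrast_scale=contrast_scale,
        seed_slice=contour.slice_index,
    )
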