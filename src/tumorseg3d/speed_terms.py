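"""The three energy terms of the hybrid speed and their combination.

The front's outward normal speed is

    F = alpha * S_e + beta * S_r + gamma * S_s

with F > 0 expanding the interior.  The three terms:

* ``S_e`` (edge): geodesic-active-contour stopping function
  ``1 / (1 + (|grad(G_sigma * I)| / c)^2)`` in (0, 1] — close to 1 in flat
  tissue (free outward propagation), near 0 at strong edges, so a dominant
  alpha halts expansion at boundaries.
* ``S_r`` (region): two-phase interior/exterior contrast force
  ``(I - c_out)^2 - (I - c_in)^2`` normalized to [-1, 1] — positive where a
  voxel's intensity resembles the current interior mean (expand), negative
  where it resembles the exterior (contract).
* ``S_s`` (smoothing): ``-kappa`` (negative mean curvature) — shrinks convex
  bulges and fills concavities; a dominant gamma over-smooths and
  under-segments.

Each term is normalized to a comparable O(1) range so the weights printed on
a control panel are meaningful across images.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage

from .errors import GridError, ParameterError, StatsError
from .grid_core import ImageVolume, LevelSetField, gradient_magnitude, mean_curvature

logger = logging.getLogger("tumorseg3d")

COMPONENTS = ("contrast_enhancing", "necrotic", "edema")

#: Edema is large with ambiguous contrast and fuzzy edges: the region term
#: must dominate (beta >= 0.5) for it to be captured.
MIN_EDEMA_BETA = 0.5
#: Above gamma = 0.3 the smoothing term erodes genuine boundary irregularity.
MAX_RECOMMENDED_GAMMA = 0.3


@dataclass(frozen=True)
class SpeedWeights:
    """The (alpha, beta, gamma) weight triple, stored normalized to sum 1."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        a, b, g = float(self.alpha), float(self.beta), float(self.gamma)
        if min(a, b, g) < 0:
            raise ParameterError(f"weights must be >= 0, got ({a}, {b}, {g})")
        total = a + b + g
        if total <= 0:
            raise ParameterError("alpha + beta + gamma must be > 0")
        object.__setattr__(self, "alpha", a / total)
        object.__setattr__(self, "beta", b / total)
        object.__setattr__(self, "gamma", g / total)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def __str__(self) -> str:
        return f"(alpha={self.alpha:.3g}, beta={self.beta:.3g}, gamma={self.gamma:.3g})"


@dataclass(frozen=True)
class RegionStats:
    """Interior / exterior mean intensities driving the region term."""

    mean_inside: float
    mean_outside: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean_inside) and np.isfinite(self.mean_outside)):
            raise StatsError("region statistics must be finite")


@dataclass(frozen=True)
class ComponentPreset:
    """Recommended weights, edge scale and iteration budget for one tumor component."""

    component: str
    weights: SpeedWeights
    edge_scale: float
    iterations: int

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ParameterError(f"unknown component {self.component!r}")
        if self.component == "edema" and self.weights.beta < MIN_EDEMA_BETA:
            raise ParameterError("edema preset must have beta >= 0.5")
        if self.weights.gamma > MAX_RECOMMENDED_GAMMA + 1e-12:
            raise ParameterError("presets must have gamma <= 0.3")


def load_presets(path=None) -> dict[str, ComponentPreset]:
    """Load the per-component presets from the shipped (or a user) YAML table."""
    if path is None:
        text = importlib.resources.files("tumorseg3d").joinpath("presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    presets = {}
    for name, entry in raw.items():
        presets[name] = ComponentPreset(
            component=name,
            weights=SpeedWeights(*entry["weights"]),
            edge_scale=float(entry["edge_scale"]),
            iterations=int(entry["iterations"]),
        )
    return presets


def region_stats(
    vol: ImageVolume, fld: LevelSetField, analysis: np.ndarray | None = None
) -> RegionStats:
    """Mean intensity inside (phi < 0) and outside (phi >= 0, within ``analysis``)."""
    if vol.shape != fld.shape:
        raise GridError("volume and phi shapes differ")
    inside = fld.phi < 0
    outside = ~inside if analysis is None else (~inside) & analysis
    if not inside.any():
        raise StatsError("interior is empty")
    if not outside.any():
        raise StatsError("exterior (analysis region) is empty")
    return RegionStats(float(vol.data[inside].mean()), float(vol.data[outside].mean()))


def edge_term(
    vol: ImageVolume, smoothing_scale: float = 1.0, contrast_scale: float = 1.0
) -> np.ndarray:
    """Edge-stopping speed S_e = 1 / (1 + (|grad(G_sigma*I)| / c)^2), in (0, 1].

    ``contrast_scale`` c is the gradient magnitude at which propagation speed
    drops to one half; see :func:`default_contrast_scale`.
    """
    if contrast_scale <= 0:
        raise ParameterError("contrast_scale must be > 0")
    g = gradient_magnitude(vol, smoothing_scale)
    return 1.0 / (1.0 + (g / contrast_scale) ** 2)


def default_contrast_scale(
    vol: ImageVolume,
    seed_mask: np.ndarray | None = None,
    smoothing_scale: float = 1.0,
) -> float:
    """Median smoothed gradient magnitude over the whole volume.

    The volume-wide median sits at the flat-parenchyma noise level (most of
    a head volume is not boundary), so genuine tissue boundaries and strong
    intratumoral texture — gradients several times this scale — register as
    S_e ~ 0 while noise-level gradients barely slow propagation. A
    seed-local scale would self-calibrate to whatever texture the seed sits
    in and blind the edge term to exactly the edges it must stop at.
    ``seed_mask`` is accepted for signature stability and unused.
    """
    g = gradient_magnitude(vol, smoothing_scale)
    scale = float(np.median(g))
    if scale <= 0:  # synthetic perfectly-flat volume: behaves as "no edges"
        scale = 1.0
    return scale


def region_term(
    vol: ImageVolume,
    fld: LevelSetField,
    stats: RegionStats | None = None,
    analysis: np.ndarray | None = None,
) -> np.ndarray:
    """Region speed S_r in [-1, 1].

    ``raw = (I - c_out)^2 - (I - c_in)^2`` scaled by ``(c_in - c_out)^2``
    and clipped into [-1, 1]; positive for interior-like intensities. With
    this scale S_r is exactly +1 at I = c_in and -1 at I = c_out regardless
    of extreme voxels elsewhere (a max-based normalization would let a few
    outlier voxels — noise spikes, a small dark necrotic core — deflate the
    force everywhere and stall the front). Outside ``analysis`` (if given)
    S_r is 0, so distant anatomy neither biases the statistics nor feels
    the force.
    """
    if vol.shape != fld.shape:
        raise GridError("volume and phi shapes differ")
    if stats is None:
        stats = region_stats(vol, fld, analysis)
    data = vol.data
    raw = (data - stats.mean_outside) ** 2 - (data - stats.mean_inside) ** 2
    if analysis is not None:
        raw = np.where(analysis | (fld.phi < 0), raw, 0.0)
    scale = (stats.mean_inside - stats.mean_outside) ** 2
    if scale == 0.0:
        peak = float(np.abs(raw).max())
        if peak == 0.0:
            return np.zeros_like(raw)
        return raw / peak
    return np.clip(raw / scale, -1.0, 1.0)


def smoothing_term(fld: LevelSetField, curvature_cap: float | None = None) -> np.ndarray:
    """Smoothing speed S_s = -kappa (clamped), so convex interiors contract."""
    kappa = mean_curvature(fld)
    if curvature_cap is None:
        curvature_cap = 1.0 / min(fld.spacing)
    return -np.clip(kappa, -curvature_cap, curvature_cap)


def hybrid_speed(
    se: np.ndarray, sr: np.ndarray, ss: np.ndarray, w: SpeedWeights
) -> np.ndarray:
    """Pointwise F = alpha*S_e + beta*S_r + gamma*S_s (no clipping)."""
    if not (se.shape == sr.shape == ss.shape):
        raise GridError("speed term fields must share one grid")
    return w.alpha * se + w.beta * sr + w.gamma * ss


def check_weight_recommendations(w: SpeedWeights, component: str | None = None) -> list[str]:
    """Warnings (never errors) for weights outside the recommended regimes.

    The user may override — parameter tuning is part of the workflow — but
    edema with beta < 0.5 or any run with gamma > 0.3 is flagged.
    """
    warnings: list[str] = []
    if component == "edema" and w.beta < MIN_EDEMA_BETA:
        warnings.append(
            f"edema segmentation works best with beta >= {MIN_EDEMA_BETA} "
            f"(got beta = {w.beta:.3g}): the fuzzy halo is region-driven"
        )
    if w.gamma > MAX_RECOMMENDED_GAMMA + 1e-12:
        warnings.append(
            f"gamma = {w.gamma:.3g} > {MAX_RECOMMENDED_GAMMA}: strong smoothing "
            "cannot maintain irregular tumor boundaries (under-segmentation likely)"
        )
    for msg in warnings:
        logger.warning(msg)
    return warnings
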