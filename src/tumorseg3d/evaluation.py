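"""Evaluation protocol: Dice overlap, Bland-Altman agreement, tumor features.

The three scalar tumor features mirror what raters compare between tools:

* ``area`` — total in-plane masked area summed over slices (mm^2);
* ``edge_sharpness`` — mean image gradient magnitude on the mask surface
  (intensity/mm): how crisp the boundary the mask sits on is;
* ``slope`` — mean signed intensity change per mm along outward surface
  normals over a +-2 mm probe (intensity/mm): boundary contrast polarity
  and steepness (negative when the interior is brighter than the exterior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FeatureError, GridError, SampleSizeError
from .grid_core import BinaryMask, ImageVolume, gradient_magnitude

#: probe half-length (mm) for the boundary slope feature
SLOPE_PROBE_MM = 2.0


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman bias and 95% limits of agreement for paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class TumorFeatures:
    area: float  # mm^2
    edge_sharpness: float  # intensity / mm
    slope: float  # intensity / mm


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) in [0, 1].

    Two empty masks agree perfectly (defined as 1).
    """
    if a.shape != b.shape:
        raise GridError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def bland_altman(pairs) -> AgreementReport:
    """Bias (mean of a-b), sample SD of differences and 1.96-SD limits."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise SampleSizeError("pairs must be an (n, 2) sequence")
    if len(arr) < 2:
        raise SampleSizeError(f"need >= 2 pairs, got {len(arr)}")
    if not np.all(np.isfinite(arr)):
        raise SampleSizeError("pairs must be finite")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, len(arr))


def bland_altman_plot(pairs, path) -> None:
    """Render the classic mean-vs-difference plot with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    rep = bland_altman(arr)
    mean = arr.mean(axis=1)
    diff = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=12, alpha=0.7)
    for y, style, label in (
        (rep.bias, "-", f"bias = {rep.bias:.3g}"),
        (rep.loa_low, "--", f"LoA low = {rep.loa_low:.3g}"),
        (rep.loa_high, "--", f"LoA high = {rep.loa_high:.3g}"),
    ):
        ax.axhline(y, linestyle=style, color="k", lw=1)
        ax.annotate(label, (0.01, y), xycoords=("axes fraction", "data"), fontsize=7)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (a - b)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one background 6-neighbor."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def _outward_normals(mask: np.ndarray, spacing, where: np.ndarray) -> np.ndarray:
    """Unit outward normals at ``where`` voxels, from the smoothed signed EDT."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    sdf = np.where(mask, -inside, outside)
    sdf = ndimage.gaussian_filter(sdf, sigma=[1.0 / s for s in spacing], mode="nearest")
    grads = np.gradient(sdf, *spacing)
    n = np.stack([g[where] for g in grads], axis=1)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.maximum(norms, 1e-12)


def tumor_features(mask: BinaryMask, vol: ImageVolume) -> TumorFeatures:
    """Area, edge sharpness and boundary slope of a component mask."""
    if mask.shape != vol.shape:
        raise GridError("mask and volume shapes differ")
    if not mask.data.any():
        raise FeatureError("cannot compute features of an empty mask")
    dx, dy, _ = mask.spacing
    area = float(mask.data.sum()) * dx * dy

    surf = surface_voxels(mask.data)
    grad = gradient_magnitude(vol, 0.0)
    edge_sharpness = float(grad[surf].mean())

    idx = np.argwhere(surf).astype(float)
    normals = _outward_normals(mask.data, mask.spacing, surf)
    sp = np.asarray(mask.spacing)
    probe_vox = (SLOPE_PROBE_MM * normals) / sp  # mm offset in voxel units
    fwd = (idx + probe_vox).T
    bwd = (idx - probe_vox).T
    i_fwd = ndimage.map_coordinates(vol.data, fwd, order=1, mode="nearest")
    i_bwd = ndimage.map_coordinates(vol.data, bwd, order=1, mode="nearest")
    slope = float(np.mean(i_fwd - i_bwd) / (2.0 * SLOPE_PROBE_MM))
    return TumorFeatures(area=area, edge_sharpness=edge_sharpness, slope=slope)


def volume_ratio(result: BinaryMask, truth: BinaryMask) -> float:
    """Segmented / true interior volume (0 when the result is empty)."""
    tv = truth.data.sum()
    if tv == 0:
        raise FeatureError("truth mask is empty")
    return float(result.data.sum()) / float(tv)


def connected_components(mask: BinaryMask) -> int:
    """Number of 6-connected foreground components."""
    _, n = ndimage.label(mask.data, structure=ndimage.generate_binary_structure(3, 1))
    return int(n)
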