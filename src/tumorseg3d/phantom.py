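"""Synthetic 3D MR tumor phantoms with exact ground truth.

The phantom emulates the contrast structure of post-contrast T1 / FLAIR
glioblastoma imaging: a dark necrotic core nested inside a bright
contrast-enhancing lesion, surrounded by a large intermediate-intensity
edema halo with a fuzzy (Gaussian-blurred) outer boundary, on uniform
parenchyma. Shapes are star-convex — a sphere whose radius is modulated by
a seeded band-limited angular perturbation (spherical harmonics up to order
4) — so ground-truth masks are computed exactly by radius comparison and
nesting is guaranteed. Optional extras: strong band-limited intensity
texture inside the lesion core (heterogeneous enhancement) and a detached
bright distractor lesion with enhancing-like intensity (the look-alike
region a region-dominant speed seizes).

Intensities are rounded to integers (as MR magnitude images are), which also
makes DICOM round-trips exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .contour_init import InitialContour
from .errors import SpecError
from .grid_core import BinaryMask, ImageVolume

COMPONENTS = ("contrast_enhancing", "necrotic", "edema")


@dataclass(frozen=True)
class DistractorSpec:
    """A detached spherical lesion with enhancing-like intensity."""

    center: tuple[float, float, float]  # mm
    radius: float  # mm
    intensity: float


@dataclass
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic tumor volume.

    Defaults give a desk-scale anisotropic grid (96 x 96 x 48 voxels at
    1 x 1 x 2 mm) with the intensity ordering necrotic < parenchyma < edema
    < enhancing typical of post-contrast T1.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    center: tuple[float, float, float] | None = None  # mm; grid center if None
    background_intensity: float = 400.0
    necrotic_intensity: float = 150.0
    enhancing_intensity: float = 800.0
    edema_intensity: float = 550.0
    r_necrotic: float = 4.0  # mm
    r_enhancing: float = 15.0
    r_edema: float = 22.0
    noise_sd: float = 15.0
    edema_boundary_blur: float = 1.0  # mm
    irregularity_amplitude: float = 0.08  # radial perturbation fraction
    texture_amplitude: float = 0.0  # relative intensity modulation in the core
    distractor: DistractorSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_necrotic < self.r_enhancing < self.r_edema):
            raise SpecError(
                "radii must nest: 0 < r_necrotic < r_enhancing < r_edema, got "
                f"({self.r_necrotic}, {self.r_enhancing}, {self.r_edema})"
            )
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.center is None:
            self.center = tuple(
                0.5 * (n - 1) * s for n, s in zip(self.shape, self.spacing)
            )
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        rmax = self.r_edema * (1.0 + abs(self.irregularity_amplitude))
        if any(c - rmax < 0 or c + rmax > e for c, e in zip(self.center, extent)):
            raise SpecError("lesion radii do not fit inside the grid")


@dataclass
class PhantomTruth:
    """Ground-truth component masks; edema is a superset of the whole tumor."""

    masks: dict[str, BinaryMask] = field(default_factory=dict)

    def core(self) -> BinaryMask:
        """Tumor core = necrotic | contrast_enhancing (the bright T1 target)."""
        nec = self.masks["necrotic"]
        ce = self.masks["contrast_enhancing"]
        return BinaryMask(
            nec.data | ce.data, nec.spacing, nec.origin, nec.orientation
        )


def _angular_perturbation(theta: np.ndarray, phi: np.ndarray, amplitude: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Band-limited radial modulation in [-amplitude, amplitude].

    A seeded random combination of real spherical harmonics of degree 1..4;
    low order keeps the shape star-convex and smooth.
    """
    if amplitude == 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    for ell in range(1, 5):
        for m in range(-ell, ell + 1):
            c = rng.normal(0.0, 1.0 / ell)
            y = sph_harm_y(ell, abs(m), theta, phi)
            out += c * (y.real if m >= 0 else y.imag)
    peak = np.abs(out).max()
    if peak > 0:
        out *= amplitude / peak
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Deterministic phantom volume + exact truth masks for the given spec."""
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.shape, sp)], indexing="ij"
    )
    offs = [g - c for g, c in zip(grids, spec.center)]
    rho = np.sqrt(offs[0] ** 2 + offs[1] ** 2 + offs[2] ** 2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, offs[2] / np.where(rho > 0, rho, 1.0), 1.0), -1, 1))
    phi_ang = np.arctan2(offs[1], offs[0])

    pert = 1.0 + _angular_perturbation(theta, phi_ang, spec.irregularity_amplitude, rng)

    nec_mask = rho <= spec.r_necrotic * pert
    core_mask = rho <= spec.r_enhancing * pert
    edema_mask = rho <= spec.r_edema * pert
    ce_mask = core_mask & ~nec_mask

    img = np.full(spec.shape, spec.background_intensity, dtype=np.float64)

    # fuzzy edema: blur only the edema/background transition
    edema_ind = edema_mask.astype(np.float64)
    if spec.edema_boundary_blur > 0:
        sigma_vox = [spec.edema_boundary_blur / s for s in sp]
        edema_ind = ndimage.gaussian_filter(edema_ind, sigma=sigma_vox, mode="nearest")
    img += (spec.edema_intensity - spec.background_intensity) * edema_ind

    # sharp, high-contrast core overwrites the blurred halo interior
    img[core_mask] = spec.enhancing_intensity
    if spec.texture_amplitude > 0:
        # heterogeneous enhancement: strong band-limited intensity texture
        # (correlation length ~2 mm) filling the core with gradients several
        # times the noise floor; clipped so the darkest texture stays near
        # the interior/exterior midpoint rather than background level
        tex = rng.normal(0.0, 1.0, spec.shape)
        tex = ndimage.gaussian_filter(tex, sigma=[2.0 / s for s in sp], mode="nearest")
        tex /= max(tex.std(), 1e-12)
        amp = spec.texture_amplitude * spec.enhancing_intensity
        img[core_mask] += np.clip(amp * tex, -1.3 * amp, 1.3 * amp)[core_mask]
    img[nec_mask] = spec.necrotic_intensity

    if spec.distractor is not None:
        d = spec.distractor
        rho_d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, d.center)))
        img[rho_d <= d.radius] = d.intensity

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, spec.shape)

    img = np.clip(np.round(img), 0, None)

    vol = ImageVolume(
        img,
        sp,
        metadata={
            "Modality": "MR",
            "PatientSex": "O",
            "PatientAge": "060Y",
            "Manufacturer": "tumorseg3d synthetic phantom",
            "Width": str(spec.shape[0]),
            "Height": str(spec.shape[1]),
            "PixelSpacing": f"{sp[0]}\\{sp[1]}",
        },
    )
    truth = PhantomTruth(
        masks={
            "necrotic": BinaryMask(nec_mask, sp),
            "contrast_enhancing": BinaryMask(ce_mask, sp),
            "edema": BinaryMask(edema_mask, sp),
        }
    )
    return vol, truth


def standard_fixtures() -> dict[str, PhantomSpec]:
    """The three named study phantoms.

    * ``clear`` — high-contrast, low-noise lesion (the easy, clean case).
    * ``heterogeneous`` — strong intensity texture inside the lesion plus a
      detached bright distractor 3 mm from the lesion surface (the case
      where a region-dominant speed seizes isolated look-alike regions).
    * ``fuzzy_edema`` — large halo with ambiguous contrast (edema/background
      contrast-to-noise ratio below 2) and a heavily blurred boundary.
    """
    clear = PhantomSpec(seed=1)
    # lesion center is the grid center (47.5, 47.5, 47) mm; the distractor
    # sits along +x with a ~2.5 mm surface-to-surface gap to the (perturbed)
    # lesion surface
    het = PhantomSpec(
        seed=2,
        r_necrotic=5.0,
        r_enhancing=15.0,
        r_edema=21.0,
        noise_sd=20.0,
        irregularity_amplitude=0.06,
        texture_amplitude=0.11,
        distractor=DistractorSpec(center=(74.0, 47.5, 47.0), radius=6.0, intensity=800.0),
    )
    fuzzy = PhantomSpec(
        seed=3,
        r_necrotic=4.0,
        r_enhancing=10.0,
        r_edema=26.0,
        noise_sd=80.0,
        edema_boundary_blur=3.0,
        irregularity_amplitude=0.08,
    )
    return {"clear": clear, "heterogeneous": het, "fuzzy_edema": fuzzy}

def standard_contours() -> dict[str, InitialContour]:
    """Reference initial contours for the standard fixtures.

    Each mimics what a rater draws: a small closed polygon on the central
    slice, placed well inside the target component — in the bright enhancing
    shell for ``clear`` and ``heterogeneous`` (clear of the dark necrotic
    core), inside the halo for ``fuzzy_edema`` (the edema target).
    """
    return {
        "clear": InitialContour(
            24, [[52.5, 44.5], [58.5, 45.5], [58.0, 51.0], [52.0, 50.5]]
        ),
        "heterogeneous": InitialContour(
            24, [[55.5, 42.5], [61.0, 42.5], [61.0, 48.0], [55.5, 48.0]]
        ),
        "fuzzy_edema": InitialContour(
            24, [[61.0, 43.5], [68.0, 44.0], [67.5, 51.5], [61.5, 51.0]]
        ),
    }


def robustness_contours() -> list[InitialContour]:
    """Three deliberately different initializations inside the ``clear``
    lesion (varied shape, size and position), for seeding-robustness
    experiments."""
    return [
        standard_contours()["clear"],
        InitialContour(24, [[44.0, 53.5], [51.0, 54.0], [47.5, 59.0]]),
        InitialContour(
            24,
            [[39.5, 41.0], [43.0, 39.0], [45.5, 41.5], [44.0, 45.0], [40.5, 45.5]],
        ),
    ]
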