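"""Thalamus-scale phantoms and synthetic two-group cohorts.

The phantom family is the superellipsoid

    |x/a|^e + |y/b|^e + |z/c|^e <= 1

whose volume has the closed form ``8abc * Gamma(1+1/e)^3 / Gamma(1+3/e)``
(the ellipsoid ``(4/3)pi*abc`` at e = 2).  A closed-form volume is what makes
the phantoms usable as unbiasedness oracles for the Cavalieri estimator: the
voxelised mask converges to the analytic volume as the voxel size shrinks.

Cohorts emulate a two-group volumetry study: per-hemisphere true volumes are
drawn from truncated normal distributions (group mean/SD configurable, with
defaults matching a healthy-control group of 62 and a patient group of 10
showing bilateral atrophy), and each "measurement method" is an observation
process applied to the true structure — either a spatially smooth boundary
perturbation of the mask (human rater) or additive noise on the volume itself
(automated segmentation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma
from scipy.spatial.transform import Rotation

from .masks import SegmentationMask

# Printed group distributions (mm^3) used as generative truth: stereology
# volumes for 62 controls and 10 patients, left and right thalamus.
CONTROL_LEFT = (7507.8, 805.6)
CONTROL_RIGHT = (7482.6, 767.2)
PATIENT_LEFT = (6843.2, 746.6)
PATIENT_RIGHT = (6763.3, 824.0)


class BoundsError(ValueError):
    """Phantom does not fit in the requested array."""


class ConnectivityError(RuntimeError):
    """Boundary perturbation repeatedly destroyed mask connectivity."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a superellipsoid phantom.

    Parameters
    ----------
    semi_axes
        Three semi-axis lengths in mm.
    exponent
        Superellipsoid exponent; 2 gives an ellipsoid, larger values are
        progressively boxier.  Must be >= 1 (convex family).
    target_volume
        If given, semi-axes are rescaled isotropically so that the analytic
        volume equals this value exactly (mm^3).
    voxel_size
        Voxel edge lengths in mm (isotropic scalar or per-axis triple).
    orientation
        Euler angles in degrees (extrinsic x-y-z) rotating the phantom in the
        array frame.  Rotation does not change the analytic volume.
    """

    semi_axes: tuple[float, float, float] = (15.0, 10.0, 9.0)
    exponent: float = 2.0
    target_volume: float | None = None
    voxel_size: float | tuple[float, float, float] = 1.0
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        axes = np.asarray(self.semi_axes, dtype=float)
        if axes.shape != (3,) or np.any(axes <= 0):
            raise ValueError(f"semi_axes must be 3 positive lengths, got {self.semi_axes}")
        if self.exponent < 1:
            raise ValueError(f"exponent must be >= 1, got {self.exponent}")
        if np.any(np.asarray(self.voxel_size, dtype=float) <= 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.target_volume is not None and self.target_volume <= 0:
            raise ValueError("target_volume must be positive")

    @property
    def spacing(self) -> np.ndarray:
        v = np.asarray(self.voxel_size, dtype=float)
        return np.broadcast_to(v, (3,)).astype(float)

    def analytic_volume(self) -> float:
        """Closed-form volume of the (unrescaled) superellipsoid in mm^3."""
        a, b, c = self.semi_axes
        e = self.exponent
        return float(8.0 * a * b * c * _gamma(1 + 1 / e) ** 3 / _gamma(1 + 3 / e))

    def resolved(self) -> "PhantomSpec":
        """Spec with semi-axes rescaled to hit ``target_volume`` exactly."""
        if self.target_volume is None:
            return self
        s = (self.target_volume / self.analytic_volume()) ** (1.0 / 3.0)
        axes = tuple(float(s * a) for a in self.semi_axes)
        return replace(self, semi_axes=axes, target_volume=None)


def superellipsoid_indicator(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Evaluate the inside/outside indicator at (n, 3) body-frame-offset points.

    Points are world coordinates relative to the phantom centre; the spec's
    orientation is applied here.
    """
    spec = spec.resolved()
    rot = Rotation.from_euler("xyz", spec.orientation, degrees=True)
    body = points @ rot.as_matrix()  # world -> body frame
    axes = np.asarray(spec.semi_axes)
    return np.sum(np.abs(body / axes) ** spec.exponent, axis=-1) <= 1.0


def make_phantom(
    spec: PhantomSpec,
    seed: int | None = None,
    margin: int = 2,
    shape: tuple[int, int, int] | None = None,
) -> SegmentationMask:
    """Rasterise a superellipsoid phantom onto a voxel grid.

    The mask array is auto-sized to contain the rotated shape plus ``margin``
    voxels on every side unless ``shape`` is given explicitly.  A voxel is
    foreground iff its centre lies inside the superellipsoid, so the
    voxel-count volume converges to the analytic volume as voxels shrink.

    ``seed`` randomises the orientation (uniform rotation) when the spec's
    orientation is left at the default and a seed is provided.
    """
    spec = spec.resolved()
    if seed is not None and tuple(spec.orientation) == (0.0, 0.0, 0.0):
        rng = np.random.default_rng(seed)
        angles = tuple(rng.uniform(-45.0, 45.0, size=3))
        spec = replace(spec, orientation=angles)

    spacing = spec.spacing
    # conservative bound on the rotated half-extent: the semi-axis vector norm
    radius = float(np.linalg.norm(spec.semi_axes))
    if shape is None:
        half = np.ceil(radius / spacing).astype(int) + margin
        shape = tuple(2 * half + 1)
    else:
        half = (np.asarray(shape) - 1) // 2
        if np.any(half * spacing < radius):
            raise BoundsError(
                f"array shape {shape} at spacing {spacing} cannot contain a "
                f"phantom of bounding radius {radius:.1f} mm"
            )
    centre = (np.asarray(shape) * spacing) / 2.0
    coords = [
        (np.arange(n) + 0.5) * s - c for n, s, c in zip(shape, spacing, centre)
    ]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    data = superellipsoid_indicator(pts.reshape(-1, 3), spec).reshape(shape)
    if not data.any():
        raise BoundsError("phantom rasterised to an empty mask (voxels too coarse)")
    n_components = ndimage.label(data)[1]
    if n_components != 1:
        raise ConnectivityError(f"rasterised phantom has {n_components} components")
    return SegmentationMask(data, spacing=spacing)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with per-hemisphere true-volume distributions.

    Per-hemisphere volumes are drawn from normals truncated at 0 (the
    truncation is negligible at these means/SDs but guards degenerate
    configurations).  ``lr_correlation`` couples the left and right latent
    normals within a subject; 0.7 by default to give realistic asymmetry
    scatter — a modelling choice, not an observed quantity.
    """

    n_controls: int = 62
    n_patients: int = 10
    control_left: tuple[float, float] = CONTROL_LEFT
    control_right: tuple[float, float] = CONTROL_RIGHT
    patient_left: tuple[float, float] = PATIENT_LEFT
    patient_right: tuple[float, float] = PATIENT_RIGHT
    lr_correlation: float = 0.7
    seed: int | None = None  # None: derive from the study master seed (or 0 standalone)

    def __post_init__(self):
        if self.n_controls <= 0 or self.n_patients <= 0:
            raise ValueError("group sizes must be positive")
        for pair in (self.control_left, self.control_right, self.patient_left, self.patient_right):
            if pair[1] < 0:
                raise ValueError(f"SD must be >= 0, got {pair}")
        if not -1.0 <= self.lr_correlation <= 1.0:
            raise ValueError("lr_correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class TrueSubject:
    """Ground-truth subject: true volumes plus per-hemisphere phantom specs."""

    subject_id: str
    group: Literal["control", "patient"]
    true_volume_left: float
    true_volume_right: float
    phantom_left: PhantomSpec
    phantom_right: PhantomSpec


def _draw_truncated_pair(rng, mean_l, sd_l, mean_r, sd_r, rho, max_tries=1000):
    """One (left, right) volume pair: correlated normals, rejection at <= 0."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov) if abs(rho) < 1 else None
    for _ in range(max_tries):
        z = rng.standard_normal(2)
        if chol is not None:
            z = chol @ z
        else:
            z = np.array([z[0], np.sign(rho) * z[0]])
        left = mean_l + sd_l * z[0]
        right = mean_r + sd_r * z[1]
        if left > 0 and right > 0:
            return float(left), float(right)
    raise RuntimeError("truncated-normal rejection sampling failed")


def sample_cohort(spec: CohortSpec, phantom_template: PhantomSpec | None = None) -> list[TrueSubject]:
    """Draw the full two-group cohort, deterministic given ``spec.seed``.

    Each subject's per-hemisphere phantoms reuse the template's shape with the
    target volume set to the drawn true volume and a small random orientation.
    """
    if phantom_template is None:
        phantom_template = PhantomSpec(exponent=2.2)
    seed = 0 if spec.seed is None else spec.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    subjects: list[TrueSubject] = []
    groups = [("control", spec.n_controls, spec.control_left, spec.control_right),
              ("patient", spec.n_patients, spec.patient_left, spec.patient_right)]
    idx = 0
    for group, n, (ml, sl), (mr, sr) in groups:
        for _ in range(n):
            left, right = _draw_truncated_pair(rng, ml, sl, mr, sr, spec.lr_correlation)
            angles = rng.uniform(-30.0, 30.0, size=(2, 3))
            subjects.append(
                TrueSubject(
                    subject_id=f"{group[0].upper()}{idx:03d}",
                    group=group,
                    true_volume_left=left,
                    true_volume_right=right,
                    phantom_left=replace(phantom_template, target_volume=left,
                                         orientation=tuple(angles[0])),
                    phantom_right=replace(phantom_template, target_volume=right,
                                          orientation=tuple(angles[1])),
                )
            )
            idx += 1
    return subjects


def cohort_table(subjects: list[TrueSubject]):
    """Long-format truth table (subject_id, group, hemisphere, true_volume)."""
    import pandas as pd

    rows = []
    for s in subjects:
        rows.append((s.subject_id, s.group, "left", s.true_volume_left))
        rows.append((s.subject_id, s.group, "right", s.true_volume_right))
    return pd.DataFrame(rows, columns=["subject_id", "group", "hemisphere", "true_volume"])


# ---------------------------------------------------------------------------
# Observation models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverModel:
    """A measurement process applied to the true structure.

    ``mask`` mode perturbs the phantom surface with a spatially smooth radial
    noise field (SD ``boundary_noise_sd`` mm, correlation length
    ``correlation_length`` mm) and then applies a multiplicative volume bias
    — a model of coherent human boundary disagreement.  ``volume`` mode
    returns ``true_volume * (1 + bias) + N(0, volume_noise_sd)`` directly —
    a model of an automated segmentation whose spatial errors are not of
    interest.
    """

    label: str
    mode: Literal["mask", "volume"] = "mask"
    boundary_noise_sd: float = 0.0
    bias: float = 0.0
    volume_noise_sd: float = 0.0
    correlation_length: float = 5.0

    def __post_init__(self):
        if self.boundary_noise_sd < 0 or self.volume_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.mode not in ("mask", "volume"):
            raise ValueError(f"unknown observer mode {self.mode!r}")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


def _smooth_unit_field(shape, spacing, corr_length, rng) -> np.ndarray:
    """Smooth Gaussian random field with ~unit SD and given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = corr_length / np.asarray(spacing)
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    if sd == 0:  # degenerate tiny array
        return np.zeros(shape)
    return f / sd


def perturb_mask(
    mask: SegmentationMask,
    boundary_noise_sd: float,
    rng: np.random.Generator,
    bias: float = 0.0,
    correlation_length: float = 5.0,
    max_retries: int = 5,
) -> SegmentationMask:
    """Displace the mask boundary by a smooth random field, then apply bias.

    The surface is moved along its normal by the local field value (mm): with
    the signed Euclidean distance d(x) (negative inside), the perturbed mask
    is {x : d(x) <= field(x)}.  The field has zero mean, so the perturbation
    is unbiased to first order.  A nonzero ``bias`` then shifts the threshold
    so the voxel volume equals (1 + bias) x the perturbed volume.

    Retries with a fresh stream (up to ``max_retries``) if the perturbation
    splits the mask into several components.
    """
    pad = int(np.ceil(4.0 * boundary_noise_sd / mask.spacing.min())) + 2
    data = np.pad(mask.data, pad)
    d_out = ndimage.distance_transform_edt(~data, sampling=mask.spacing)
    d_in = ndimage.distance_transform_edt(data, sampling=mask.spacing)
    # signed distance to the interface: voxel centres adjacent to the surface
    # sit half a voxel away, hence the half-step correction on each side
    half = mask.spacing.min() / 2.0
    signed = np.where(data, -(d_in - half), d_out - half)

    for _ in range(max_retries):
        field = boundary_noise_sd * _smooth_unit_field(
            data.shape, mask.spacing, correlation_length, rng
        )
        g = signed - field
        new = g <= 0.0
        if bias != 0.0:
            target = int(round((1.0 + bias) * new.sum()))
            target = max(1, min(target, g.size))
            # threshold at the target-th smallest value of g
            thresh = np.partition(g.ravel(), target - 1)[target - 1]
            new = g <= thresh
        if new.any() and ndimage.label(new)[1] == 1:
            origin = mask.origin - pad * mask.spacing
            return SegmentationMask(new, spacing=mask.spacing, origin=origin)
    raise ConnectivityError(
        f"perturbation (sd={boundary_noise_sd} mm) destroyed connectivity "
        f"in {max_retries} attempts"
    )


def observe_subject(
    subject: TrueSubject,
    model: ObserverModel,
    seed,
    hemisphere: Literal["left", "right"] = "left",
):
    """Observe one hemisphere of a subject through a measurement process.

    Returns a perturbed :class:`SegmentationMask` in ``mask`` mode or a float
    volume (mm^3) in ``volume`` mode.  Deterministic given ``seed`` (an int or
    a ``numpy.random.SeedSequence``).
    """
    rng = np.random.default_rng(seed)
    true_volume = subject.true_volume_left if hemisphere == "left" else subject.true_volume_right
    if model.mode == "volume":
        return float(true_volume * (1.0 + model.bias) + rng.normal(0.0, model.volume_noise_sd))
    spec = subject.phantom_left if hemisphere == "left" else subject.phantom_right
    mask = make_phantom(spec)
    if model.boundary_noise_sd == 0.0 and model.bias == 0.0:
        return mask
    return perturb_mask(
        mask,
        model.boundary_noise_sd,
        rng,
        bias=model.bias,
        correlation_length=model.correlation_length,
    )
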