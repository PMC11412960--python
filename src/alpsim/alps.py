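"""DTI-ALPS index from a fitted tensor field.

The index summarizes water diffusion along the perivascular space at the
level of the lateral ventricles: in projection-fiber ROIs (fibers run
inferior-superior, z) and association-fiber ROIs (fibers run
anterior-posterior, y) the x-axis is perpendicular to the dominant fiber
direction, so x-diffusivity there is attributed to perivascular flow.

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

Subcortical-fiber diffusivities are extracted and reported alongside but
never enter the index.  The manual radiological review of ROI placement
is replaced by an automated orientation check: the ROI-mean principal
eigenvector must lie within a configurable angle of the expected fiber
axis (projection -> z, association -> y, subcortical -> x; image axes in
the radiological convention x = left-right, y = anterior-posterior,
z = inferior-superior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import DIFFUSIVITY_KEYS, ROI_LABELS
from .tensor import TensorField, tensor_eigen

__all__ = [
    "DiffusivityProfile",
    "ALPSResult",
    "OrientationCheck",
    "extract_roi_diffusivities",
    "alps_index",
    "validate_roi_orientation",
]

_EXPECTED_AXIS = {"proj": 2, "assoc": 1, "sub": 0}
_AXIS_NAMES = ("x", "y", "z")


@dataclass(frozen=True)
class DiffusivityProfile:
    """The nine ROI-mean diagonal diffusivities for one subject (mm^2/s)."""

    subject_id: str
    dxx_proj: float
    dyy_proj: float
    dzz_proj: float
    dxx_assoc: float
    dyy_assoc: float
    dzz_assoc: float
    dxx_sub: float
    dyy_sub: float
    dzz_sub: float

    def __post_init__(self) -> None:
        for key in DIFFUSIVITY_KEYS:
            v = getattr(self, key)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"diffusivity {key!r} must be finite and > 0")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DIFFUSIVITY_KEYS}


@dataclass(frozen=True)
class OrientationCheck:
    """Directionality report for one ROI block."""

    label: int
    fiber: str
    side: str
    expected_axis: str
    angle_deg: float
    passed: bool
    valid_fraction: float


@dataclass(frozen=True)
class ALPSResult:
    subject_id: str
    alps_index: float
    numerator: float  # mean(Dxx_proj, Dxx_assoc), mm^2/s
    denominator: float  # mean(Dyy_proj, Dzz_assoc), mm^2/s
    orientation: tuple[OrientationCheck, ...] = ()

    def __post_init__(self) -> None:
        if self.alps_index <= 0:
            raise ValueError("ALPS index must be > 0")
        ratio = self.numerator / self.denominator
        if abs(self.alps_index - ratio) > 1e-12 * abs(ratio):
            raise ValueError("alps_index inconsistent with its components")


def _roi_voxel_index(roi: np.ndarray, field: TensorField) -> None:
    roi = np.asarray(roi)
    if roi.shape != field.shape:
        raise ValueError(
            f"ROI mask shape {roi.shape} does not match field {field.shape}"
        )


def extract_roi_diffusivities(
    field: TensorField,
    roi: np.ndarray,
    subject_id: str = "sub-000",
    min_valid_fraction: float = 0.5,
) -> DiffusivityProfile:
    """ROI-mean diagonal diffusivities per fiber type.

    For each fiber type the left and right blocks are pooled with equal
    weight per voxel, using only voxels the fitter flagged valid.  An ROI
    whose valid fraction drops below ``min_valid_fraction`` triggers a
    warning; an ROI with no valid voxel (or a missing label) is an error.
    """
    _roi_voxel_index(roi, field)
    values: dict[str, float] = {}
    for fiber in ("proj", "assoc", "sub"):
        labels = [l for l, (f, _s) in ROI_LABELS.items() if f == fiber]
        in_roi = np.isin(roi, labels)
        n_total = int(in_roi.sum())
        if n_total == 0:
            raise ValueError(f"ROI labels {labels} ({fiber}) missing from mask")
        usable = in_roi & field.valid
        n_valid = int(usable.sum())
        if n_valid == 0:
            raise ValueError(f"all voxels invalid in {fiber!r} ROI")
        if n_valid < min_valid_fraction * n_total:
            warnings.warn(
                f"{fiber} ROI: only {n_valid}/{n_total} voxels valid",
                stacklevel=2,
            )
        diag = field.elements[usable][:, :3].mean(axis=0)
        values[f"dxx_{fiber}"] = float(diag[0])
        values[f"dyy_{fiber}"] = float(diag[1])
        values[f"dzz_{fiber}"] = float(diag[2])
    return DiffusivityProfile(subject_id=subject_id, **values)


def alps_index(
    profile: DiffusivityProfile,
    orientation: tuple[OrientationCheck, ...] = (),
) -> ALPSResult:
    """ALPS index from a diffusivity profile.

    ``mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)``; the
    subcortical diffusivities ride along in the profile but are excluded
    from the formula.
    """
    num = 0.5 * (profile.dxx_proj + profile.dxx_assoc)
    den = 0.5 * (profile.dyy_proj + profile.dzz_assoc)
    if den <= 0:
        raise ValueError("ALPS denominator must be > 0")
    return ALPSResult(
        subject_id=profile.subject_id,
        alps_index=num / den,
        numerator=num,
        denominator=den,
        orientation=orientation,
    )


def validate_roi_orientation(
    field: TensorField,
    roi: np.ndarray,
    max_angle_deg: float = 20.0,
) -> tuple[OrientationCheck, ...]:
    """Automated stand-in for manual ROI placement review.

    For each of the six ROI blocks, the mean fiber direction is the
    principal eigenvector of the ROI-averaged dyadic tensor (mean of
    outer products of per-voxel principal eigenvectors — the standard
    sign-ambiguity-free way to average axes).  A block passes when that
    direction lies within ``max_angle_deg`` of the expected fiber axis.
    Report-only: no exception on failure.
    """
    _roi_voxel_index(roi, field)
    evals, evecs, _fa, valid = tensor_eigen(field)
    principal = evecs[..., :, 0]  # (nx, ny, nz, 3)
    checks = []
    for label in sorted(ROI_LABELS):
        fiber, side = ROI_LABELS[label]
        in_roi = roi == label
        usable = in_roi & valid
        n_total = int(in_roi.sum())
        frac = float(usable.sum()) / n_total if n_total else 0.0
        if usable.sum() == 0:
            checks.append(
                OrientationCheck(label, fiber, side,
                                 _AXIS_NAMES[_EXPECTED_AXIS[fiber]],
                                 float("nan"), False, frac)
            )
            continue
        v = principal[usable]  # (V, 3)
        dyad = np.einsum("vi,vj->ij", v, v) / v.shape[0]
        w, u = np.linalg.eigh(dyad)
        mean_dir = u[:, -1]
        axis = np.zeros(3)
        axis[_EXPECTED_AXIS[fiber]] = 1.0
        cosang = abs(float(mean_dir @ axis))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        checks.append(
            OrientationCheck(
                label, fiber, side, _AXIS_NAMES[_EXPECTED_AXIS[fiber]],
                angle, angle <= max_angle_deg, frac,
            )
        )
    return tuple(checks)
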