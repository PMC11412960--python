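"""Synthetic DTI-ALPS cohort generator.

Builds cohorts with a known ground truth: per-subject regional
diffusivities drawn around published group summary statistics, voxel
phantoms realizing those diffusivities as diagonal tensors in fiber-type
ROI blocks, single-shell DWI signals with Rician noise, and a subject
table (demographics plus neuropsychological scores) in which two
imaging–cognition couplings are injected at configurable strength:
ALPS index <-> Trail-Making Test B (executive function) and the
projection-fiber y-diffusivity <-> Auditory Verbal Learning Test
(memory).  Everything is reproducible from one master seed.

Default parameters correspond to a two-group study of 50 chronic-tinnitus
patients and 50 matched healthy controls.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tensor import GradientTable, TensorField, default_gradient_table

__all__ = [
    "DIFFUSIVITY_KEYS",
    "SCORE_KEYS",
    "GroupParams",
    "CouplingSpec",
    "SubjectTruth",
    "PhantomGeometry",
    "SimulationConfig",
    "CohortBundle",
    "tinnitus_group_params",
    "control_group_params",
    "alps_from_diffusivities",
    "alps_population_moments",
    "draw_subject_truth",
    "build_tensor_field",
    "simulate_dwi",
    "generate_cognitive_scores",
    "simulate_cohort",
    "derive_subject_seed",
]

#: the nine ROI diffusivities, grouped by fiber type (mm^2/s)
DIFFUSIVITY_KEYS = (
    "dxx_proj", "dyy_proj", "dzz_proj",
    "dxx_assoc", "dyy_assoc", "dzz_assoc",
    "dxx_sub", "dyy_sub", "dzz_sub",
)

#: continuous demographic / clinical / cognitive columns of the cohort table
SCORE_KEYS = (
    "age", "education_years", "thq",
    "hearing_left", "hearing_right",
    "gm_pct_tiv", "wm_pct_tiv",
    "mmse", "moca", "avlt", "cft", "cft_delay", "dst",
    "tmt_a", "tmt_b", "cdt", "vft", "dsst", "sas", "sds",
)

#: diffusivity draws are truncated below here (mm^2/s); >=6 SD from every
#: default mean, so the truncation bias is negligible
DIFFUSIVITY_FLOOR = 1e-5

_PHYS_RANGE = (1e-5, 5e-3)


@dataclass(frozen=True)
class GroupParams:
    """Marginal summary statistics defining one study group.

    ``diffusivity_mean``/``sd`` cover the nine ROI diffusivities in
    mm^2/s; ``score_mean``/``sd`` cover demographics and cognitive
    scores (test units); ``male_fraction`` drives a Bernoulli draw for
    the gender column.
    """

    group_label: str
    n_subjects: int
    diffusivity_mean: dict[str, float]
    diffusivity_sd: dict[str, float]
    score_mean: dict[str, float]
    score_sd: dict[str, float]
    male_fraction: float = 23.0 / 50.0

    def __post_init__(self) -> None:
        if self.group_label not in ("tinnitus", "HC"):
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for key in DIFFUSIVITY_KEYS:
            for name, table in (("mean", self.diffusivity_mean),
                                ("sd", self.diffusivity_sd)):
                if key not in table:
                    raise ValueError(f"missing diffusivity {name} for {key!r}")
                v = table[key]
                if not np.isfinite(v):
                    raise ValueError(f"non-finite diffusivity {name}: {key!r}")
            # sd == 0 is allowed as a degenerate (deterministic) draw
            if self.diffusivity_mean[key] <= 0 or self.diffusivity_sd[key] < 0:
                raise ValueError(
                    f"diffusivity mean must be > 0 and sd >= 0: {key!r}"
                )
            if not _PHYS_RANGE[0] <= self.diffusivity_mean[key] <= _PHYS_RANGE[1]:
                raise ValueError(
                    f"diffusivity mean for {key!r} outside physiological "
                    f"range {_PHYS_RANGE}"
                )
        # NaN marks a score not administered in that group (e.g. THQ in
        # controls); infinities are configuration errors
        for key, v in list(self.score_mean.items()) + list(self.score_sd.items()):
            if np.isinf(v):
                raise ValueError(f"non-finite score parameter: {key!r}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


def tinnitus_group_params(n_subjects: int = 50) -> GroupParams:
    """Default chronic-tinnitus group (published mean +/- SD summaries)."""
    return GroupParams(
        group_label="tinnitus",
        n_subjects=n_subjects,
        diffusivity_mean={
            "dxx_proj": 0.00060, "dyy_proj": 0.00042, "dzz_proj": 0.00111,
            "dxx_assoc": 0.00063, "dyy_assoc": 0.00111, "dzz_assoc": 0.00038,
            "dxx_sub": 0.00110, "dyy_sub": 0.00051, "dzz_sub": 0.00089,
        },
        diffusivity_sd={
            "dxx_proj": 0.00005, "dyy_proj": 0.00006, "dzz_proj": 0.00006,
            "dxx_assoc": 0.00007, "dyy_assoc": 0.00007, "dzz_assoc": 0.00007,
            "dxx_sub": 0.00010, "dyy_sub": 0.00011, "dzz_sub": 0.00033,
        },
        score_mean={
            "age": 50.38, "education_years": 10.78, "thq": 51.51,
            "hearing_left": 16.60, "hearing_right": 16.85,
            "gm_pct_tiv": 32.16, "wm_pct_tiv": 29.58,
            "mmse": 28.88, "moca": 25.74, "avlt": 32.68,
            "cft": 34.40, "cft_delay": 16.83, "dst": 11.16,
            "tmt_a": 69.34, "tmt_b": 183.10, "cdt": 3.48,
            "vft": 14.39, "dsst": 69.78, "sas": 36.52, "sds": 38.58,
        },
        score_sd={
            "age": 13.56, "education_years": 1.81, "thq": 15.64,
            "hearing_left": 2.68, "hearing_right": 3.03,
            "gm_pct_tiv": 2.05, "wm_pct_tiv": 1.45,
            "mmse": 1.27, "moca": 1.72, "avlt": 7.13,
            "cft": 1.76, "cft_delay": 3.40, "dst": 1.60,
            "tmt_a": 20.44, "tmt_b": 51.57, "cdt": 0.54,
            "vft": 3.90, "dsst": 7.72, "sas": 5.96, "sds": 9.08,
        },
    )


def control_group_params(n_subjects: int = 50) -> GroupParams:
    """Default healthy-control group (published mean +/- SD summaries)."""
    return GroupParams(
        group_label="HC",
        n_subjects=n_subjects,
        diffusivity_mean={
            "dxx_proj": 0.00059, "dyy_proj": 0.00039, "dzz_proj": 0.00110,
            "dxx_assoc": 0.00062, "dyy_assoc": 0.00110, "dzz_assoc": 0.00036,
            "dxx_sub": 0.00108, "dyy_sub": 0.00058, "dzz_sub": 0.00098,
        },
        diffusivity_sd={
            "dxx_proj": 0.00004, "dyy_proj": 0.00005, "dzz_proj": 0.00006,
            "dxx_assoc": 0.00008, "dyy_assoc": 0.00005, "dzz_assoc": 0.00006,
            "dxx_sub": 0.00013, "dyy_sub": 0.00027, "dzz_sub": 0.00030,
        },
        score_mean={
            "age": 48.76, "education_years": 10.94, "thq": float("nan"),
            "hearing_left": 17.68, "hearing_right": 17.10,
            "gm_pct_tiv": 32.75, "wm_pct_tiv": 29.50,
            "mmse": 28.82, "moca": 26.20, "avlt": 35.78,
            "cft": 34.71, "cft_delay": 17.32, "dst": 11.80,
            "tmt_a": 69.44, "tmt_b": 152.36, "cdt": 3.54,
            "vft": 14.96, "dsst": 69.04, "sas": 36.02, "sds": 38.00,
        },
        score_sd={
            "age": 15.21, "education_years": 1.87, "thq": float("nan"),
            "hearing_left": 3.81, "hearing_right": 3.48,
            "gm_pct_tiv": 1.92, "wm_pct_tiv": 1.67,
            "mmse": 1.24, "moca": 1.76, "avlt": 7.19,
            "cft": 1.53, "cft_delay": 3.69, "dst": 2.14,
            "tmt_a": 21.13, "tmt_b": 48.65, "cdt": 0.54,
            "vft": 3.68, "dsst": 10.16, "sas": 6.45, "sds": 9.14,
        },
    )


@dataclass(frozen=True)
class CouplingSpec:
    """Population correlations injected between imaging truth and scores.

    ``target_r_alps_tmtb`` couples the true ALPS index to TMT-B within the
    patient group; ``target_r_dyyproj_avlt`` couples the true projection
    y-diffusivity to AVLT.  Both must satisfy |r| < 1.
    """

    target_r_alps_tmtb: float = -0.309
    target_r_dyyproj_avlt: float = -0.413

    def __post_init__(self) -> None:
        for name in ("target_r_alps_tmtb", "target_r_dyyproj_avlt"):
            r = getattr(self, name)
            if not np.isfinite(r) or abs(r) >= 1.0:
                raise ValueError(f"{name} must satisfy |r| < 1, got {r}")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth regional diffusivities and ALPS index for one subject."""

    subject_id: str
    group_label: str
    diffusivities: dict[str, float]
    alps_true: float

    def __post_init__(self) -> None:
        for key in DIFFUSIVITY_KEYS:
            if self.diffusivities.get(key, 0.0) <= 0:
                raise ValueError(f"diffusivity {key!r} must be > 0")
        expected = alps_from_diffusivities(self.diffusivities)
        if abs(self.alps_true - expected) > 1e-12 * abs(expected):
            raise ValueError("alps_true inconsistent with diffusivities")


def alps_from_diffusivities(d: dict[str, float]) -> float:
    """ALPS index: mean(Dxxproj, Dxxassoc) / mean(Dyyproj, Dzzassoc)."""
    num = 0.5 * (d["dxx_proj"] + d["dxx_assoc"])
    den = 0.5 * (d["dyy_proj"] + d["dzz_assoc"])
    if den <= 0:
        raise ValueError("ALPS denominator must be > 0")
    return num / den


def alps_population_moments(params: GroupParams) -> tuple[float, float]:
    """Population mean and SD of the true ALPS index under the generator.

    With the four constituent diffusivities drawn independently, the
    index is a ratio R = N/D of two independent normals (N the mean of
    the two x-diffusivities, D the mean of Dyy_proj and Dzz_assoc).
    Then E[R] = E[N] E[1/D] and E[R^2] = E[N^2] E[1/D^2]; the reciprocal
    moments of D are evaluated by Gauss-Hermite quadrature restricted to
    D above the positivity floor (the generator truncates there; the
    excluded mass is ~1e-18 at the default parameters).  This is exact
    up to quadrature error, unlike a first-order delta expansion, whose
    ~4% SD underestimate would visibly bias the injected imaging to
    cognition correlations.
    """
    m, s = params.diffusivity_mean, params.diffusivity_sd
    mu_n = 0.5 * (m["dxx_proj"] + m["dxx_assoc"])
    mu_d = 0.5 * (m["dyy_proj"] + m["dzz_assoc"])
    var_n = 0.25 * (s["dxx_proj"] ** 2 + s["dxx_assoc"] ** 2)
    var_d = 0.25 * (s["dyy_proj"] ** 2 + s["dzz_assoc"] ** 2)
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    d = mu_d + np.sqrt(2.0 * var_d) * nodes
    keep = d > DIFFUSIVITY_FLOOR
    w = weights[keep] / weights[keep].sum()
    inv1 = float((w / d[keep]).sum())
    inv2 = float((w / d[keep] ** 2).sum())
    mean_r = mu_n * inv1
    var_r = (mu_n**2 + var_n) * inv2 - mean_r**2
    return mean_r, float(np.sqrt(var_r))


def derive_subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed (< 2^31) from the master seed."""
    token = f"{master_seed}:{subject_index}".encode()
    return zlib.crc32(token) & 0x7FFFFFFF


def draw_subject_truth(
    params: GroupParams,
    coupling: CouplingSpec,
    rng_seed: int,
    subject_id: str = "sub-000",
) -> SubjectTruth:
    """Draw one subject's nine true diffusivities and ALPS index.

    Each diffusivity is an independent normal with the group's mean/SD,
    truncated below at ``DIFFUSIVITY_FLOOR`` (positivity; the floor sits
    >= 6 SD below every default mean, so moments are preserved to <0.1%).
    ``coupling`` is validated here but only consumed when scores are
    generated.
    """
    if rng_seed < 0:
        raise ValueError("rng_seed must be a non-negative integer")
    rng = np.random.default_rng(rng_seed)
    d = {}
    for key in DIFFUSIVITY_KEYS:
        v = rng.normal(params.diffusivity_mean[key], params.diffusivity_sd[key])
        d[key] = max(v, DIFFUSIVITY_FLOOR)
    return SubjectTruth(
        subject_id=subject_id,
        group_label=params.group_label,
        diffusivities=d,
        alps_true=alps_from_diffusivities(d),
    )


# ---------------------------------------------------------------------------
# voxel phantom
# ---------------------------------------------------------------------------

_FIBER_TYPES = ("proj", "assoc", "sub")
#: ROI label mask convention: 0 background, then these labels
ROI_LABELS = {
    1: ("proj", "L"), 2: ("proj", "R"),
    3: ("assoc", "L"), 4: ("assoc", "R"),
    5: ("sub", "L"), 6: ("sub", "R"),
}


@dataclass(frozen=True)
class PhantomGeometry:
    """Grid layout of the rectangular fiber-type ROI blocks.

    ``blocks`` maps label -> ((x0, x1), (y0, y1), (z0, z1)) half-open
    voxel index ranges; the six blocks are {projection, association,
    subcortical} x {left, right}.  Defaults: 40x40x20 grid of 2 mm
    isotropic voxels with 2x2x2 blocks, small enough for desk-scale runs.
    """

    shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    blocks: dict[int, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: {
            1: ((12, 14), (18, 20), (8, 10)),   # projection, left
            2: ((26, 28), (18, 20), (8, 10)),   # projection, right
            3: ((12, 14), (24, 26), (8, 10)),   # association, left
            4: ((26, 28), (24, 26), (8, 10)),   # association, right
            5: ((12, 14), (12, 14), (8, 10)),   # subcortical, left
            6: ((26, 28), (12, 14), (8, 10)),   # subcortical, right
        }
    )
    background_diffusivity: float = 0.0008

    def __post_init__(self) -> None:
        if self.background_diffusivity <= 0:
            raise ValueError("background diffusivity must be > 0")
        if set(self.blocks) != set(ROI_LABELS):
            raise ValueError(f"blocks must carry labels {sorted(ROI_LABELS)}")
        seen: set[tuple[int, int, int]] = set()
        for label, ranges in self.blocks.items():
            vox = []
            for axis, (lo, hi) in enumerate(ranges):
                if not (0 <= lo < hi <= self.shape[axis]):
                    raise ValueError(
                        f"ROI block {label} outside grid on axis {axis}"
                    )
                vox.append(range(lo, hi))
            cells = {(x, y, z) for x in vox[0] for y in vox[1] for z in vox[2]}
            if len(cells) < 4:
                raise ValueError(f"ROI block {label} smaller than 4 voxels")
            if cells & seen:
                raise ValueError(f"ROI block {label} overlaps another block")
            seen |= cells

    def label_mask(self) -> np.ndarray:
        """Integer label volume (0 background, 1..6 ROI blocks)."""
        mask = np.zeros(self.shape, dtype=np.int16)
        for label, ((x0, x1), (y0, y1), (z0, z1)) in self.blocks.items():
            mask[x0:x1, y0:y1, z0:z1] = label
        return mask


def build_tensor_field(
    truth: SubjectTruth, geom: PhantomGeometry
) -> TensorField:
    """Realize a subject's true diffusivities as a voxel tensor phantom.

    Each fiber-type block (both sides) gets a diagonal tensor with that
    fiber's (Dxx, Dyy, Dzz); background voxels are isotropic at the
    configured background diffusivity.  All tensors are symmetric
    positive-definite by construction.
    """
    d = truth.diffusivities
    elements = np.zeros(geom.shape + (6,))
    elements[..., :3] = geom.background_diffusivity
    for label, (fiber, _side) in ROI_LABELS.items():
        diag = (d[f"dxx_{fiber}"], d[f"dyy_{fiber}"], d[f"dzz_{fiber}"])
        if min(diag) <= 0:
            raise ValueError(f"non-positive diagonal requested for {fiber!r}")
        (x0, x1), (y0, y1), (z0, z1) = geom.blocks[label]
        elements[x0:x1, y0:y1, z0:z1, 0] = diag[0]
        elements[x0:x1, y0:y1, z0:z1, 1] = diag[1]
        elements[x0:x1, y0:y1, z0:z1, 2] = diag[2]
    valid = np.ones(geom.shape, dtype=bool)
    return TensorField(elements, valid, voxel_size=geom.voxel_size)


def simulate_dwi(
    field: TensorField,
    gtab: GradientTable,
    s0: float = 1000.0,
    sigma: float = 0.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Single-shell DWI signals from a tensor field, with Rician noise.

    The noiseless signal per voxel and direction is
    ``s0 * exp(-b g^T D g)``; for ``sigma > 0`` the magnitude-MR noise
    model applies: ``sqrt((S + e1)^2 + e2^2)`` with e1, e2 independent
    zero-mean normals of SD sigma (so E[S_noisy^2] = S^2 + 2 sigma^2).
    """
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    mats = field.as_matrices()  # (..., 3, 3)
    g = gtab.bvecs  # (N, 3)
    # quadratic form g^T D g for every voxel/direction
    q = np.einsum("ni,...ij,nj->...n", g, mats, g)
    signal = s0 * np.exp(-gtab.bvals * q)
    if sigma > 0:
        rng = np.random.default_rng(rng_seed)
        e1 = rng.normal(0.0, sigma, signal.shape)
        e2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    return signal


# ---------------------------------------------------------------------------
# subject table
# ---------------------------------------------------------------------------

def generate_cognitive_scores(
    truth: SubjectTruth,
    params: GroupParams,
    coupling: CouplingSpec,
    rng_seed: int,
) -> dict[str, object]:
    """Draw one subject's demographic and cognitive record.

    Every score is marginally normal with the group's mean/SD.  Within
    the patient group, TMT-B is a linear function of the subject's true
    ALPS index plus independent noise — slope ``r * sd_tmtb / sd_alps``
    and noise SD ``sd_tmtb * sqrt(1 - r^2)`` chosen so the population
    correlation equals the coupling target while the marginal moments are
    preserved (ALPS ratio moments via ``alps_population_moments``).  AVLT
    is coupled to the true projection y-diffusivity the same way
    (exactly, since that truth is normal).  Covariates are drawn independently of the imaging
    truths, so marginal and covariate-adjusted correlations coincide in
    expectation.  Gender is Bernoulli on ``params.male_fraction``,
    encoded 1 = male, 0 = female; the average hearing threshold is the
    mean of the two per-ear draws.
    """
    if rng_seed < 0:
        raise ValueError("rng_seed must be a non-negative integer")
    rng = np.random.default_rng(rng_seed)
    rec: dict[str, object] = {
        "subject_id": truth.subject_id,
        "group": truth.group_label,
        "gender": int(rng.random() < params.male_fraction),
    }
    for key in SCORE_KEYS:
        m, s = params.score_mean[key], params.score_sd[key]
        if np.isnan(m) or np.isnan(s):
            rec[key] = np.nan
        else:
            rec[key] = rng.normal(m, s)

    if truth.group_label == "tinnitus":
        # re-draw the two coupled scores conditionally on the imaging truth
        r1 = coupling.target_r_alps_tmtb
        mu_a, sd_a = alps_population_moments(params)
        z_alps = (truth.alps_true - mu_a) / sd_a if sd_a > 0 else 0.0
        m, s = params.score_mean["tmt_b"], params.score_sd["tmt_b"]
        rec["tmt_b"] = m + r1 * s * z_alps + s * np.sqrt(1 - r1**2) * rng.normal()

        r2 = coupling.target_r_dyyproj_avlt
        mu_d = params.diffusivity_mean["dyy_proj"]
        sd_d = params.diffusivity_sd["dyy_proj"]
        z_dyy = ((truth.diffusivities["dyy_proj"] - mu_d) / sd_d
                 if sd_d > 0 else 0.0)
        m, s = params.score_mean["avlt"], params.score_sd["avlt"]
        rec["avlt"] = m + r2 * s * z_dyy + s * np.sqrt(1 - r2**2) * rng.normal()

    rec["hearing_avg"] = 0.5 * (rec["hearing_left"] + rec["hearing_right"])
    return rec


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one synthetic cohort."""

    seed: int = 0
    tinnitus: GroupParams = field(default_factory=tinnitus_group_params)
    controls: GroupParams = field(default_factory=control_group_params)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    n_directions: int = 32
    b_value: float = 1000.0
    s0: float = 1000.0
    snr: float = 30.0  # s0 / sigma; 0 or inf disables noise
    write_dwi: bool = True

    @property
    def sigma(self) -> float:
        if not self.snr or not np.isfinite(self.snr):
            return 0.0
        return self.s0 / self.snr


@dataclass
class CohortBundle:
    """In-memory view of a simulated cohort plus where it was written."""

    cohort: pd.DataFrame  # subject table
    truth: pd.DataFrame  # ground-truth diffusivities and ALPS per subject
    gradient_table: GradientTable
    roi_labels: np.ndarray
    out_dir: object | None = None  # pathlib.Path when written


def simulate_cohort(
    config: SimulationConfig, out_dir=None
) -> CohortBundle:
    """Simulate a full two-group cohort; optionally write it to disk.

    Per subject (deterministic seed derived from the master seed): draw
    the ground truth, generate the score record and — when ``out_dir`` is
    given and ``config.write_dwi`` — build the voxel phantom, simulate
    DWI and write NIfTI + bval/bvec files.  A single ROI label mask, the
    cohort table and the ground-truth table are written alongside.
    """
    from . import io as _io  # local import to keep module load light

    gtab = default_gradient_table(config.n_directions, config.b_value)
    records, truths = [], []
    subject_index = 0
    if out_dir is not None:
        out_dir = _io.ensure_dir(out_dir)

    for params in (config.tinnitus, config.controls):
        for _ in range(params.n_subjects):
            sid = f"sub-{subject_index:03d}"
            seed = derive_subject_seed(config.seed, subject_index)
            truth = draw_subject_truth(params, config.coupling, seed, sid)
            rec = generate_cognitive_scores(
                truth, params, config.coupling, derive_subject_seed(seed, 1)
            )
            records.append(rec)
            truths.append(
                {"subject_id": sid, "group": truth.group_label,
                 **truth.diffusivities, "alps_true": truth.alps_true}
            )
            if out_dir is not None and config.write_dwi:
                fieldv = build_tensor_field(truth, config.geometry)
                dwi = simulate_dwi(
                    fieldv, gtab, s0=config.s0, sigma=config.sigma,
                    rng_seed=derive_subject_seed(seed, 2),
                )
                _io.write_dwi(
                    out_dir / f"{sid}_dwi.nii.gz", dwi,
                    voxel_size=config.geometry.voxel_size,
                )
                _io.write_bval_bvec(
                    out_dir / f"{sid}.bval", out_dir / f"{sid}.bvec", gtab
                )
            subject_index += 1

    columns = ["subject_id", "group", "age", "gender", "education_years",
               "thq", "hearing_left", "hearing_right", "hearing_avg",
               "gm_pct_tiv", "wm_pct_tiv", "mmse", "moca", "avlt", "cft",
               "cft_delay", "dst", "tmt_a", "tmt_b", "cdt", "vft", "dsst",
               "sas", "sds"]
    cohort = pd.DataFrame(records)[columns]
    truth_df = pd.DataFrame(truths)
    roi = config.geometry.label_mask()

    if out_dir is not None:
        _io.write_roi_mask(
            out_dir / "roi_labels.nii.gz", roi,
            voxel_size=config.geometry.voxel_size,
        )
        _io.write_cohort_csv(out_dir / "cohort.csv", cohort)
        truth_df.to_csv(out_dir / "truth.csv", index=False, float_format="%.10g")

    return CohortBundle(cohort, truth_df, gtab, roi, out_dir)
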