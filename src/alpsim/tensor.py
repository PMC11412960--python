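"""Diffusion-tensor estimation by log-linear least squares.

The single-shell diffusion signal is modelled as monoexponential,
``S = s0 * exp(-b g^T D g)``, with D a symmetric positive-definite 3x3
tensor per voxel.  Taking logarithms turns estimation into ordinary least
squares on a fixed 7-column design (six unique tensor elements plus
``ln s0``), which is deterministic and recovers noiseless phantom signals
exactly — the property the downstream ALPS round-trip checks rely on.

Diagonal elements are reported in the image coordinate frame (x, y, z),
not as eigenvalues: the ALPS index reads frame diagonals directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientTable",
    "TensorField",
    "default_gradient_table",
    "design_matrix",
    "fit_tensor_loglinear",
    "tensor_eigen",
    "fractional_anisotropy",
]

#: storage order of the six unique tensor elements
TENSOR_ELEMENT_ORDER = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions of a DWI acquisition.

    Requires at least one b=0 entry and at least six diffusion-weighted
    entries, otherwise the 7-parameter tensor model is underdetermined.
    Directions of weighted volumes must be unit-norm to within 1e-6.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # shape (N, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"shape mismatch: {bvals.size} b-values vs bvecs {bvecs.shape}"
            )
        if not np.all(np.isfinite(bvals)) or not np.all(np.isfinite(bvecs)):
            raise ValueError("gradient table contains non-finite entries")
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        weighted = bvals > 0
        if np.count_nonzero(~weighted) < 1 or np.count_nonzero(weighted) < 6:
            raise ValueError(
                "gradient table needs >=1 b=0 and >=6 diffusion-weighted "
                f"entries, got {np.count_nonzero(~weighted)} and "
                f"{np.count_nonzero(weighted)}"
            )
        norms = np.linalg.norm(bvecs[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            worst = float(np.max(np.abs(norms - 1.0)))
            raise ValueError(
                f"non-unit gradient direction (max |norm-1| = {worst:.2e})"
            )

    def __len__(self) -> int:
        return int(self.bvals.size)


def default_gradient_table(
    n_directions: int = 32, b_value: float = 1000.0
) -> GradientTable:
    """One b=0 volume plus ``n_directions`` weighted directions.

    Directions are placed deterministically on a hemisphere by a
    golden-angle spiral (an electrostatic-repulsion-style even coverage;
    diffusion sensitization is antipodally symmetric, so a hemisphere
    suffices).
    """
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions")
    i = np.arange(n_directions)
    z = (i + 0.5) / n_directions  # upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientTable(bvals, bvecs)


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """N x 7 design for the log-linearized tensor model.

    Row i is ``[-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz,
    -2b gy gz, 1]`` so that ``row @ [Dxx..Dyz, ln s0] = ln S_i``.
    """
    b = gtab.bvals
    if b.size < 7:
        raise ValueError(f"underdetermined design: {b.size} rows < 7")
    gx, gy, gz = gtab.bvecs[:, 0], gtab.bvecs[:, 1], gtab.bvecs[:, 2]
    return np.column_stack(
        [
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
            np.ones_like(b),
        ]
    )


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors on a regular grid.

    ``elements`` stores the six unique entries in ``TENSOR_ELEMENT_ORDER``
    (image coordinate frame, mm^2/s); symmetry holds by construction.
    ``valid`` flags voxels whose fit is trustworthy (no signal clamping,
    finite result, positive-definite tensor).
    """

    elements: np.ndarray  # (nx, ny, nz, 6)
    valid: np.ndarray  # (nx, ny, nz) bool
    s0: np.ndarray | None = None  # (nx, ny, nz)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.elements.ndim != 4 or self.elements.shape[-1] != 6:
            raise ValueError("elements must have shape (nx, ny, nz, 6)")
        if self.valid.shape != self.elements.shape[:3]:
            raise ValueError("valid mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.elements.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full 3x3 symmetric matrices, shape (nx, ny, nz, 3, 3)."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.elements, -1, 0)
        m = np.empty(self.shape + (3, 3), dtype=float)
        m[..., 0, 0] = dxx
        m[..., 1, 1] = dyy
        m[..., 2, 2] = dzz
        m[..., 0, 1] = m[..., 1, 0] = dxy
        m[..., 0, 2] = m[..., 2, 0] = dxz
        m[..., 1, 2] = m[..., 2, 1] = dyz
        return m

    @classmethod
    def from_matrices(
        cls,
        mats: np.ndarray,
        valid: np.ndarray | None = None,
        **kw,
    ) -> "TensorField":
        mats = np.asarray(mats, dtype=float)
        el = np.stack(
            [
                mats[..., 0, 0],
                mats[..., 1, 1],
                mats[..., 2, 2],
                mats[..., 0, 1],
                mats[..., 0, 2],
                mats[..., 1, 2],
            ],
            axis=-1,
        )
        if valid is None:
            valid = np.ones(mats.shape[:3], dtype=bool)
        return cls(el, valid, **kw)


def fit_tensor_loglinear(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    *,
    weighted: bool = False,
    clamp_rel: float = 1e-6,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> TensorField:
    """Fit a tensor per masked voxel by (weighted) log-linear least squares.

    Parameters
    ----------
    dwi
        4D signal array, last axis ordered like the gradient table.
    gtab
        Acquisition description; must match ``dwi.shape[-1]``.
    mask
        Boolean voxel mask; all voxels if None.
    weighted
        If True, one-pass weighted LS with the observed signals as
        weights (variance-stabilizing for log-transformed Rician data);
        default is ordinary LS, which is exact on noiseless data.
    clamp_rel
        Signals below ``clamp_rel * mean(b0 signal)`` are clamped up to
        that floor before the log; such voxels are fitted anyway but
        flagged invalid.

    Returns
    -------
    TensorField with per-voxel elements, s0 estimates and validity flags.
    A voxel is valid iff no clamping was needed, the solution is finite,
    and all three eigenvalues are strictly positive.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, volumes)")
    if dwi.shape[-1] != len(gtab):
        raise ValueError(
            f"{dwi.shape[-1]} volumes vs {len(gtab)} gradient-table entries"
        )
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask: no voxels to fit")

    X = design_matrix(gtab)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design: gradient directions are degenerate")

    signals = dwi[mask]  # (V, N)
    b0_mean = signals[:, gtab.bvals == 0].mean(axis=1)
    floor = clamp_rel * np.maximum(b0_mean, np.finfo(float).tiny)
    clamped = signals < floor[:, None]
    needs_clamp = clamped.any(axis=1)
    logS = np.log(np.maximum(signals, floor[:, None]))

    if weighted:
        # per-voxel weights => per-voxel normal equations
        w = np.maximum(signals, floor[:, None])  # predicted-signal proxy
        coefs = np.empty((signals.shape[0], 7))
        for i in range(signals.shape[0]):
            Xw = X * w[i][:, None]
            coefs[i], *_ = np.linalg.lstsq(Xw, w[i] * logS[i], rcond=None)
    else:
        coefs = np.linalg.lstsq(X, logS.T, rcond=None)[0].T  # (V, 7)

    nx, ny, nz = dwi.shape[:3]
    elements = np.zeros((nx, ny, nz, 6))
    s0 = np.zeros((nx, ny, nz))
    elements[mask] = coefs[:, :6]
    s0[mask] = np.exp(coefs[:, 6])

    finite = np.isfinite(coefs).all(axis=1)
    evals = np.linalg.eigvalsh(_mats_from_rows(coefs[:, :6]))
    posdef = (evals > 0).all(axis=1) & finite
    valid = np.zeros((nx, ny, nz), dtype=bool)
    valid[mask] = finite & posdef & ~needs_clamp
    return TensorField(elements, valid, s0=s0, voxel_size=voxel_size)


def _mats_from_rows(rows: np.ndarray) -> np.ndarray:
    """(V, 6) element rows -> (V, 3, 3) symmetric matrices."""
    rows = np.nan_to_num(rows, nan=0.0, posinf=0.0, neginf=0.0)
    m = np.empty((rows.shape[0], 3, 3))
    m[:, 0, 0] = rows[:, 0]
    m[:, 1, 1] = rows[:, 1]
    m[:, 2, 2] = rows[:, 2]
    m[:, 0, 1] = m[:, 1, 0] = rows[:, 3]
    m[:, 0, 2] = m[:, 2, 0] = rows[:, 4]
    m[:, 1, 2] = m[:, 2, 1] = rows[:, 5]
    return m


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from eigenvalues along the last axis; 0 for isotropic tensors."""
    lam = np.asarray(eigenvalues, dtype=float)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - md) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def tensor_eigen(
    field: TensorField,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decompose every voxel tensor.

    Returns ``(eigenvalues, eigenvectors, fa, valid)``: eigenvalues sorted
    descending along the last axis; ``eigenvectors[..., :, k]`` is the unit
    eigenvector of eigenvalue k, its sign fixed so the largest-magnitude
    component is positive; FA in [0, 1].  Voxels with non-finite tensors
    are flagged invalid and returned as zeros.
    """
    mats = field.as_matrices()
    finite = np.isfinite(mats).all(axis=(-2, -1))
    safe = np.where(finite[..., None, None], mats, np.eye(3))
    evals, evecs = np.linalg.eigh(safe)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., :, ::-1]
    # deterministic sign: largest-|component| positive
    idx = np.argmax(np.abs(evecs), axis=-2, keepdims=True)
    signs = np.sign(np.take_along_axis(evecs, idx, axis=-2))
    signs = np.where(signs == 0, 1.0, signs)
    evecs = evecs * signs
    fa = fractional_anisotropy(evals)
    valid = field.valid & finite
    zero = ~finite
    evals = np.where(zero[..., None], 0.0, evals)
    fa = np.where(zero, 0.0, fa)
    return evals, evecs, fa, valid
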