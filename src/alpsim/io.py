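"""File I/O: NIfTI volumes, FSL-dialect bval/bvec, cohort CSV, YAML config.

All images are NIfTI-1 with a diagonal affine built from the voxel size;
4D DWI volumes are ordered like the bval file.  bval/bvec follow the FSL
text dialect: whitespace-separated rows, bvec as 3 rows x N columns.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .tensor import GradientTable, TensorField

__all__ = [
    "ensure_dir",
    "write_nifti",
    "read_nifti",
    "write_dwi",
    "read_dwi",
    "write_roi_mask",
    "read_roi_mask",
    "write_bval_bvec",
    "read_bval_bvec",
    "write_tensor_field",
    "read_tensor_field",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
    "load_config",
    "dump_config",
]

COHORT_COLUMNS = (
    "subject_id", "group", "age", "gender", "education_years", "thq",
    "hearing_left", "hearing_right", "hearing_avg", "gm_pct_tiv",
    "wm_pct_tiv", "mmse", "moca", "avlt", "cft", "cft_delay", "dst",
    "tmt_a", "tmt_b", "cdt", "vft", "dsst", "sas", "sds",
)

#: volume order of the tensor NIfTI written by write_tensor_field
TENSOR_NIFTI_ORDER = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


def ensure_dir(path) -> Path:
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {path}: {exc}") from exc
    return path


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_nifti(path, data: np.ndarray, voxel_size=(2.0, 2.0, 2.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    nib.save(img, path)
    return path


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel


def write_dwi(path, dwi: np.ndarray, voxel_size=(2.0, 2.0, 2.0)) -> Path:
    dwi = np.asarray(dwi)
    if dwi.ndim != 4:
        raise ValueError("DWI must be 4D")
    return write_nifti(path, dwi.astype(np.float32), voxel_size)


def read_dwi(path, gtab: GradientTable | None = None) -> np.ndarray:
    data, _ = read_nifti(path)
    if data.ndim != 4:
        raise ValueError(f"expected 4D DWI, got {data.ndim}D: {path}")
    if gtab is not None and data.shape[-1] != len(gtab):
        raise ValueError(
            f"{data.shape[-1]} DWI volumes but {len(gtab)} bval entries: {path}"
        )
    return data


def write_roi_mask(path, labels: np.ndarray, voxel_size=(2.0, 2.0, 2.0)) -> Path:
    return write_nifti(path, np.asarray(labels, dtype=np.int16), voxel_size)


def read_roi_mask(path) -> np.ndarray:
    data, _ = read_nifti(path)
    labels = np.rint(data).astype(np.int16)
    return labels


def write_bval_bvec(bval_path, bvec_path, gtab: GradientTable) -> None:
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    bval_path.write_text(
        " ".join(f"{b:g}" for b in gtab.bvals) + "\n", encoding="utf-8"
    )
    rows = [" ".join(f"{v:.10g}" for v in gtab.bvecs[:, axis])
            for axis in range(3)]
    bvec_path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_bval_bvec(bval_path, bvec_path) -> GradientTable:
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    for p in (bval_path, bvec_path):
        if not p.exists():
            raise FileNotFoundError(f"no such file: {p}")
    bvals = np.loadtxt(bval_path, ndmin=1)
    if bvals.ndim != 1:
        raise ValueError(f"bval file must be a single row: {bval_path}")
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(
            f"bvec file must have 3 rows (FSL dialect), got "
            f"{bvecs.shape[0]}: {bvec_path}"
        )
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bvec columns ({bvecs.shape[1]}) do not match bval entries "
            f"({bvals.size}): {bvec_path}"
        )
    return GradientTable(bvals, bvecs.T)


def write_tensor_field(path, field: TensorField, prefix_maps: bool = False):
    """Tensor elements as a 4D NIfTI (6 volumes, Dxx..Dyz order).

    With ``prefix_maps`` also writes ``<stem>_s0`` and ``<stem>_valid``
    maps next to it.
    """
    path = Path(path)
    out = write_nifti(
        path, field.elements.astype(np.float32), field.voxel_size
    )
    if prefix_maps:
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        if field.s0 is not None:
            write_nifti(path.parent / f"{stem}_s0.nii.gz",
                        field.s0.astype(np.float32), field.voxel_size)
        write_nifti(path.parent / f"{stem}_valid.nii.gz",
                    field.valid.astype(np.int16), field.voxel_size)
    return out


def read_tensor_field(path, valid_path=None) -> TensorField:
    data, voxel = read_nifti(path)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(f"tensor NIfTI must have 6 volumes: {path}")
    if valid_path is not None:
        valid, _ = read_nifti(valid_path)
        valid = valid.astype(bool)
    else:
        valid = np.isfinite(data).all(axis=-1)
    return TensorField(data, valid, voxel_size=voxel)


def write_cohort_csv(path, cohort: pd.DataFrame) -> Path:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort CSV: {path}")
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

CONFIG_SCHEMA_VERSION = 1


def dump_config(config, path) -> Path:
    """Serialize a SimulationConfig to YAML (lossless round trip)."""
    from .cohort import SimulationConfig  # avoid import cycle at load

    if not isinstance(config, SimulationConfig):
        raise TypeError("expected a SimulationConfig")
    doc = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "seed": config.seed,
        "n_directions": config.n_directions,
        "b_value": config.b_value,
        "s0": config.s0,
        "snr": config.snr,
        "write_dwi": config.write_dwi,
        "coupling": {
            "target_r_alps_tmtb": config.coupling.target_r_alps_tmtb,
            "target_r_dyyproj_avlt": config.coupling.target_r_dyyproj_avlt,
        },
        "geometry": {
            "shape": list(config.geometry.shape),
            "voxel_size": list(config.geometry.voxel_size),
            "background_diffusivity": config.geometry.background_diffusivity,
            "blocks": {
                int(k): [list(r) for r in v]
                for k, v in config.geometry.blocks.items()
            },
        },
        "groups": {
            params.group_label: {
                "n_subjects": params.n_subjects,
                "male_fraction": params.male_fraction,
                "diffusivity_mean": dict(params.diffusivity_mean),
                "diffusivity_sd": dict(params.diffusivity_sd),
                "score_mean": {k: _none_if_nan(v)
                               for k, v in params.score_mean.items()},
                "score_sd": {k: _none_if_nan(v)
                             for k, v in params.score_sd.items()},
            }
            for params in (config.tinnitus, config.controls)
        },
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")
    return path


def load_config(path):
    from .cohort import (CouplingSpec, GroupParams, PhantomGeometry,
                         SimulationConfig)

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if doc.get("schema_version") != CONFIG_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported config schema_version {doc.get('schema_version')!r}"
        )

    def group(label):
        g = doc["groups"][label]
        return GroupParams(
            group_label=label,
            n_subjects=int(g["n_subjects"]),
            male_fraction=float(g["male_fraction"]),
            diffusivity_mean={k: float(v) for k, v in g["diffusivity_mean"].items()},
            diffusivity_sd={k: float(v) for k, v in g["diffusivity_sd"].items()},
            score_mean={k: _nan_if_none(v) for k, v in g["score_mean"].items()},
            score_sd={k: _nan_if_none(v) for k, v in g["score_sd"].items()},
        )

    geom = doc["geometry"]
    return SimulationConfig(
        seed=int(doc["seed"]),
        tinnitus=group("tinnitus"),
        controls=group("HC"),
        coupling=CouplingSpec(**{k: float(v)
                                 for k, v in doc["coupling"].items()}),
        geometry=PhantomGeometry(
            shape=tuple(geom["shape"]),
            voxel_size=tuple(geom["voxel_size"]),
            background_diffusivity=float(geom["background_diffusivity"]),
            blocks={int(k): tuple(tuple(r) for r in v)
                    for k, v in geom["blocks"].items()},
        ),
        n_directions=int(doc["n_directions"]),
        b_value=float(doc["b_value"]),
        s0=float(doc["s0"]),
        snr=float(doc["snr"]),
        write_dwi=bool(doc["write_dwi"]),
    )


def _none_if_nan(v):
    return None if (isinstance(v, float) and np.isnan(v)) else float(v)


def _nan_if_none(v):
    return float("nan") if v is None else float(v)
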