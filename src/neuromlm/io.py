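"""File formats and cohort-table utilities.

Voxelwise data travel through the pipeline as a 2-D ``scans x voxels``
matrix (:class:`BoldMatrix`) tied to a boolean 3-D mask and an affine, so
that every spatial vector can be written back into the original grid
losslessly.  Volumes are flattened with the mask in NumPy C order; the
same order is used everywhere, which makes matrix <-> volume round trips
exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUPS = ("schizophrenia", "depression")
SEXES = ("M", "F")
AGE_RANGE = (18.0, 65.0)

MANIFEST_COLUMNS = ["subject_id", "group", "age", "sex"]
MANIFEST_PATH_COLUMNS = ["bold_path", "mask_path", "motion_path"]


@dataclass
class BoldMatrix:
    """Masked 4-D BOLD data as a ``scans x voxels`` matrix.

    ``mask`` is the boolean 3-D array whose True entries, taken in C
    order, index the columns of ``values``; ``affine`` is the 4x4
    voxel-to-world transform of the source image.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (scans x voxels)")
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D boolean array")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        n_mask = int(self.mask.sum())
        if n_mask == 0:
            raise ValueError("mask selects zero voxels")
        if self.values.shape[1] != n_mask:
            raise ValueError(
                f"values has {self.values.shape[1]} columns but mask selects "
                f"{n_mask} voxels"
            )
        if not np.all(np.isfinite(self.values)):
            n_bad = int((~np.isfinite(self.values)).sum())
            raise ValueError(f"values contains {n_bad} non-finite entries")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_4d(self) -> np.ndarray:
        """Unflatten back to an ``(x, y, z, t)`` volume (zeros off-mask)."""
        vol = np.zeros(self.mask.shape + (self.n_scans,))
        vol[self.mask, :] = self.values.T
        return vol


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI mask; returns (boolean array, affine)."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0.5
    if mask.ndim != 3:
        raise ValueError(f"mask {path} is not 3-D")
    if mask.sum() == 0:
        raise ValueError(f"mask {path} selects zero voxels")
    return mask, np.asarray(img.affine, dtype=float)


def read_bold(bold_path: str | Path, mask_path: str | Path) -> BoldMatrix:
    """Load a 4-D NIfTI plus mask into a :class:`BoldMatrix`.

    Raises if the grids or affines disagree or the data contain
    non-finite voxels.
    """
    img = nib.load(str(bold_path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{bold_path} is not a 4-D image")
    mask, mask_affine = read_mask(mask_path)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"grid mismatch: data {data.shape[:3]} vs mask {mask.shape}"
        )
    if not np.allclose(img.affine, mask_affine):
        raise ValueError("affine mismatch between BOLD image and mask")
    values = data[mask, :].T  # scans x voxels, C-order flattening
    if not np.all(np.isfinite(values)):
        n_bad = int((~np.isfinite(values)).sum())
        raise ValueError(f"{bold_path}: {n_bad} non-finite in-mask voxels")
    return BoldMatrix(values=values, mask=mask, affine=np.asarray(img.affine))


def write_volume(
    values: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
) -> Path:
    """Write a masked vector (3-D image) or scans x voxels matrix (4-D).

    Off-mask voxels are written as zero.  The affine is passed through
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects zero voxels")
    if values.ndim == 1:
        if values.shape[0] != mask.sum():
            raise ValueError("vector length does not match mask")
        vol = np.zeros(mask.shape)
        vol[mask] = values
    elif values.ndim == 2:
        if values.shape[1] != mask.sum():
            raise ValueError("matrix width does not match mask")
        vol = np.zeros(mask.shape + (values.shape[0],))
        vol[mask, :] = values.T
    else:
        raise ValueError("values must be 1-D or 2-D")
    img = nib.Nifti1Image(vol, np.asarray(affine, dtype=float))
    path = Path(path)
    img.to_filename(str(path))
    return path


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    path = Path(path)
    img.to_filename(str(path))
    return path


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def validate_manifest(
    manifest: pd.DataFrame,
    base_dir: str | Path | None = None,
    check_paths: bool = True,
) -> pd.DataFrame:
    """Validate a participants table; returns it with resolved paths."""
    manifest = manifest.copy()
    for col in MANIFEST_COLUMNS:
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    if manifest["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in manifest")
    bad_group = set(manifest["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    bad_sex = set(manifest["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    ages = manifest["age"].astype(float)
    if (ages < AGE_RANGE[0]).any() or (ages > AGE_RANGE[1]).any():
        raise ValueError(f"ages outside inclusion range {AGE_RANGE}")
    path_cols = [c for c in MANIFEST_PATH_COLUMNS if c in manifest.columns]
    if base_dir is not None:
        base = Path(base_dir)
        for col in path_cols:
            manifest[col] = [str(base / p) for p in manifest[col]]
    if check_paths:
        for col in path_cols:
            for p in manifest[col]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return manifest


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    path = Path(path)
    manifest = pd.read_csv(path, sep="\t")
    return validate_manifest(manifest, base_dir=path.parent, check_paths=check_paths)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# demographics statistics
# ---------------------------------------------------------------------------

def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction.

    Uses the closed form N(ad-bc)^2 / (r1 r2 c1 c2) with a 1-df
    chi-square reference distribution.  All four margins must be
    positive.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.all(np.equal(np.mod(table, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    table = table.astype(float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("all margins must be positive")
    n = table.sum()
    a, b = table[0]
    c, d = table[1]
    statistic = n * (a * d - b * c) ** 2 / (rows.prod() * cols.prod())
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value


def sex_table(manifest: pd.DataFrame) -> np.ndarray:
    """2x2 group-by-sex count table in (GROUPS x SEXES) order."""
    return np.array(
        [
            [int(((manifest["group"] == g) & (manifest["sex"] == s)).sum()) for s in SEXES]
            for g in GROUPS
        ]
    )
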