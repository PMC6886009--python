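"""Individual-level multivariate linear model (MLM).

For each subject the whitened cross-covariance between the condition
part of the design and the data,

    Z = (Xc' S Xc)^(-1/2) Xc' Y,

is decomposed by SVD, Z = U L V'.  The columns of U live in condition
space and are the subject's *clinical loadings*; the rows of V are
unit-norm voxel patterns, the *eigenimages*; L holds the singular
values.  S is the temporal covariance of the noise, either the identity
or a stationary AR(1) matrix S[t, u] = rho^|t-u|.

Nuisance regressors (motion, drift, intercept) are partialled out of
both the data and the condition columns beforehand (Frisch-Waugh), so
the decomposition has exactly three condition-space directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .design import CONDITIONS, ContrastSpec, DesignMatrix
from .io import BoldMatrix

#: relative eigenvalue cutoff for the pseudo-inverse square root
PSD_TOL = 1e-12
#: relative singular-value gap below which components count as degenerate
DEGENERACY_TOL = 1e-8


@dataclass
class TemporalCovariance:
    """Noise temporal covariance: identity or AR(1) with coefficient rho."""

    form: str = "identity"
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("identity", "ar1"):
            raise ValueError("form must be 'identity' or 'ar1'")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    def matrix(self, n: int) -> np.ndarray:
        if self.form == "identity":
            return np.eye(n)
        return toeplitz(self.rho ** np.arange(n))

    def quad_form(self, x: np.ndarray) -> np.ndarray:
        """x' S x without forming S when it is the identity."""
        if self.form == "identity" or self.rho == 0.0:
            return x.T @ x
        return x.T @ (self.matrix(x.shape[0]) @ x)


def inverse_sqrt_psd(matrix: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Pseudo-inverse square root of a symmetric PSD matrix.

    Eigenvalues below ``tol`` times the largest are treated as zero;
    a negative eigenvalue beyond that slack is an error, as is an
    asymmetric input.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > 1e-10 * scale:
        raise ValueError("input is not symmetric")
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    top = max(w.max(), 0.0)
    if w.min() < -tol * max(top, 1.0):
        raise ValueError(f"matrix has negative eigenvalue {w.min():g}")
    cutoff = tol * top
    inv_root = np.zeros_like(w)
    keep = w > cutoff
    inv_root[keep] = 1.0 / np.sqrt(w[keep])
    return (v * inv_root) @ v.T


@dataclass
class MLMDecomposition:
    """SVD of the whitened cross-covariance Z = U L V'.

    clinical_loadings: condition-space directions x components (U)
    eigenvalues: descending non-negative singular values (L)
    eigenimages: components x voxels, rows unit norm (V')
    """

    clinical_loadings: np.ndarray
    eigenvalues: np.ndarray
    eigenimages: np.ndarray
    condition_labels: tuple[str, ...] = CONDITIONS
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.clinical_loadings = np.asarray(self.clinical_loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenimages = np.asarray(self.eigenimages, dtype=float)
        k = self.eigenvalues.shape[0]
        if self.clinical_loadings.shape[1] != k or self.eigenimages.shape[0] != k:
            raise ValueError("component counts disagree")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.shape[0])

    def reconstruct(self) -> np.ndarray:
        return (self.clinical_loadings * self.eigenvalues) @ self.eigenimages


def _canonical_svd(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD with deterministic signs and a documented degenerate-pair order.

    Signs: the first element of each U column with magnitude above
    1e-12 is made positive (V row flipped jointly).  Near-degenerate
    singular values (relative gap < DEGENERACY_TOL) are ordered by the
    lexicographic order of their sign-fixed U columns.
    """
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    for j in range(s.shape[0]):
        col = u[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            u[:, j] = -u[:, j]
            vt[j, :] = -vt[j, :]
    # stable order inside near-degenerate groups
    top = s[0] if s.size else 0.0
    order = list(range(s.size))
    i = 0
    while i < s.size - 1:
        j = i
        while j + 1 < s.size and (s[j] - s[j + 1]) <= DEGENERACY_TOL * max(top, 1.0):
            j += 1
        if j > i:
            group = sorted(order[i : j + 1], key=lambda k: tuple(-u[:, k]))
            order[i : j + 1] = group
        i = j + 1
    order = np.asarray(order)
    return u[:, order], s[order], vt[order, :]


def individual_mlm(
    bold: BoldMatrix | np.ndarray,
    design: DesignMatrix,
    sigma: TemporalCovariance | None = None,
    contrast: ContrastSpec | None = None,
    n_components: int = 3,
    center: bool = True,
) -> MLMDecomposition:
    """Individual-level MLM decomposition of one subject's data.

    The contrast rows define the condition-space directions (by default
    the three condition columns); they must not touch nuisance columns.
    Nuisance columns are partialled out of both the data and the
    condition regressors, the cross-covariance is whitened by the
    pseudo-inverse square root of Xc' S Xc, and the result is decomposed
    by SVD.
    """
    from .design import condition_contrast  # local to avoid cycle at import

    y = bold.values if isinstance(bold, BoldMatrix) else np.asarray(bold, dtype=float)
    x = design.values
    if y.shape[0] != x.shape[0]:
        raise ValueError("data and design must have the same number of scans")
    if contrast is None:
        contrast = condition_contrast(design)
    c = contrast.matrix
    if c.shape[1] != x.shape[1]:
        raise ValueError("contrast width does not match design")
    touched = np.nonzero(np.any(c != 0.0, axis=0))[0]
    for col in touched:
        if design.labels[col] not in CONDITIONS:
            raise ValueError(
                f"contrast selects nuisance column {design.labels[col]!r}"
            )
    if n_components > contrast.rank:
        raise ValueError(
            f"n_components={n_components} exceeds contrast rank {contrast.rank}"
        )
    if sigma is None:
        sigma = TemporalCovariance("identity")

    if center:
        y = y - y.mean(axis=0, keepdims=True)
    xc = x @ c.T
    nuis = [i for i in range(x.shape[1]) if i not in set(touched.tolist())]
    if nuis:
        n_mat = x[:, nuis]
        pinv_n = np.linalg.pinv(n_mat)
        y = y - n_mat @ (pinv_n @ y)
        xc = xc - n_mat @ (pinv_n @ xc)

    w = inverse_sqrt_psd(sigma.quad_form(xc))
    z = w @ (xc.T @ y)
    u, s, vt = _canonical_svd(z)
    k = n_components
    return MLMDecomposition(
        clinical_loadings=u[:, :k],
        eigenvalues=s[:k],
        eigenimages=vt[:k, :],
        condition_labels=tuple(design.labels[i] for i in design.condition_indices),
        mask=bold.mask if isinstance(bold, BoldMatrix) else None,
        affine=bold.affine if isinstance(bold, BoldMatrix) else None,
    )


def align_decompositions(
    decomps: list[MLMDecomposition], reference_index: int = 0
) -> list[MLMDecomposition]:
    """Fix component signs cohort-wide against a reference subject.

    For each subject and rank, the sign of the dot product between the
    subject's and the reference's clinical-loading columns is made
    positive by jointly flipping that subject's U column and V row,
    which preserves U L V'.  Component order (descending eigenvalue) is
    untouched.  A zero loading column has no defined sign and is an
    error.
    """
    if not decomps:
        return []
    k = decomps[0].n_components
    d_dim = decomps[0].clinical_loadings.shape[0]
    for d in decomps:
        if d.n_components != k or d.clinical_loadings.shape[0] != d_dim:
            raise ValueError("decompositions have mismatched shapes")
    ref = decomps[reference_index]
    out: list[MLMDecomposition] = []
    for i, d in enumerate(decomps):
        u = d.clinical_loadings.copy()
        v = d.eigenimages.copy()
        for j in range(k):
            if np.linalg.norm(u[:, j]) == 0.0 or np.linalg.norm(
                ref.clinical_loadings[:, j]
            ) == 0.0:
                raise ValueError(
                    f"zero clinical-loading column (subject {i}, component {j})"
                )
            if i != reference_index and float(u[:, j] @ ref.clinical_loadings[:, j]) < 0:
                u[:, j] = -u[:, j]
                v[j, :] = -v[j, :]
        out.append(
            MLMDecomposition(
                clinical_loadings=u,
                eigenvalues=d.eigenvalues.copy(),
                eigenimages=v,
                condition_labels=d.condition_labels,
                mask=d.mask,
                affine=d.affine,
            )
        )
    return out
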