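"""Group-level MLM: brain signatures, subject loadings and T-maps.

The aligned rank-k eigenimages of all subjects are stacked into a
subjects x voxels matrix Y_G.  Age and sex are regressed out of both
Y_G and the diagnosis contrast (so the signature cannot be driven by
confounds), then

    Z_G = (X_G' X_G)^(-1/2) X_G' Y_G

is decomposed by SVD.  The first right singular vector is the *brain
signature* for that rank; projecting each subject's adjusted eigenimage
onto it gives the per-subject *subject loadings* that feed the
classifier.  One group MLM is run per component rank, yielding three
signatures and three loading vectors.

Subjects are treated as exchangeable (identity temporal/spatial weight
on the group level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GROUPS
from .mlm import MLMDecomposition, _canonical_svd, inverse_sqrt_psd

log = logging.getLogger(__name__)

#: documented cap for T values at |r| -> 1
T_CAP = 1e4


@dataclass
class GroupDesign:
    """Subjects x covariates design: diagnosis contrast, age, sex."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = tuple(self.labels)
        if self.values.ndim != 2 or len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per design column required")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("group design is rank deficient")

    @classmethod
    def from_manifest(cls, manifest) -> "GroupDesign":
        """Diagnosis coded +1 (schizophrenia) / -1 (depression), age
        centered, sex coded M=+1 / F=-1."""
        group = np.where(manifest["group"].to_numpy() == GROUPS[0], 1.0, -1.0)
        age = manifest["age"].to_numpy(dtype=float)
        age = age - age.mean()
        sex = np.where(manifest["sex"].to_numpy() == "M", 1.0, -1.0)
        return cls(
            values=np.column_stack([group, age, sex]),
            labels=("group", "age", "sex"),
        )

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


@dataclass
class EigenimageStack:
    """Subjects x voxels matrix of rank-k aligned eigenimages."""

    rank: int
    values: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("stack must be 2-D (subjects x voxels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stack contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class GroupDecomposition:
    """Group MLM result for one component rank.

    Two coupled decompositions are kept.  The subject-space SVD of the
    adjusted eigenimage stack Y_G = U L V' supplies the brain signature
    (first right singular vector, the most consistent pattern across
    individuals in variance-explained terms) and the subject loadings
    (projections of each subject's adjusted eigenimage onto it).  The
    design-space cross-covariance Z_G = (X'X)^(-1/2) X' Y_G and its SVD
    are kept alongside: its left factors are the design-space group
    loadings, and the hat-matrix fit of the subject loadings on the
    reduced design is the design projection.
    """

    rank: int
    z: np.ndarray
    group_loadings: np.ndarray      # U_G of SVD(Z_G), design-space
    z_eigenvalues: np.ndarray
    z_patterns: np.ndarray          # V' of SVD(Z_G)
    eigenvalues: np.ndarray         # singular values of the adjusted stack
    signature: np.ndarray           # first spatial eigenvector, unit norm
    subject_loadings: np.ndarray    # one scalar per subject (data-side)
    design_projection: np.ndarray   # hat-matrix projection of the loadings
    sigma_form: str = "identity"
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.signature) - 1.0) > 1e-8:
            raise ValueError("signature must be unit norm")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be descending")


def stack_eigenimages(
    aligned: list[MLMDecomposition], rank: int
) -> EigenimageStack:
    """Row i = subject i's rank-k eigenimage (k is 1-based)."""
    if not aligned:
        raise ValueError("no decompositions to stack")
    k = aligned[0].n_components
    if not 1 <= rank <= k:
        raise ValueError(f"rank must lie in [1, {k}]")
    ref_mask = aligned[0].mask
    for i, d in enumerate(aligned[1:], start=1):
        same = (
            (ref_mask is None and d.mask is None)
            or (ref_mask is not None and d.mask is not None and np.array_equal(ref_mask, d.mask))
        )
        if not same:
            raise ValueError(f"subject {i} mask differs from subject 0")
    rows = np.vstack([d.eigenimages[rank - 1] for d in aligned])
    return EigenimageStack(
        rank=rank, values=rows, mask=ref_mask, affine=aligned[0].affine
    )


def residualize_confounds(
    stack: EigenimageStack,
    design: GroupDesign,
    confound_labels: tuple[str, ...] = ("age", "sex"),
) -> tuple[EigenimageStack, GroupDesign]:
    """Partial confounds (plus an intercept) out of the stack and the
    retained design columns.

    Both the eigenimage stack and the remaining covariates (the
    diagnosis contrast) are replaced by their residuals from a
    regression on [intercept, confounds]; afterwards the adjusted stack
    is orthogonal to the confounds.
    """
    for lab in confound_labels:
        if lab not in design.labels:
            raise ValueError(f"confound {lab!r} not in group design")
    conf = np.column_stack(
        [np.ones(design.values.shape[0])]
        + [design.column(lab) for lab in confound_labels]
    )
    if np.linalg.matrix_rank(conf) < conf.shape[1]:
        raise ValueError("confound matrix (with intercept) is rank deficient")
    pinv_c = np.linalg.pinv(conf)
    adjusted = stack.values - conf @ (pinv_c @ stack.values)
    retained = [lab for lab in design.labels if lab not in confound_labels]
    if not retained:
        raise ValueError("no design columns left after removing confounds")
    x = np.column_stack([design.column(lab) for lab in retained])
    x = x - conf @ (pinv_c @ x)
    return (
        EigenimageStack(rank=stack.rank, values=adjusted, mask=stack.mask, affine=stack.affine),
        GroupDesign(values=x, labels=tuple(retained)),
    )


def group_mlm(
    adjusted_stack: EigenimageStack, reduced_design: GroupDesign
) -> GroupDecomposition:
    """Group MLM for one rank.

    The signature is the first right singular vector of the adjusted
    stack; subject loadings are the projections of the adjusted
    eigenimages onto it (equal to the scaled first left singular
    vector), and the design projection is their hat-matrix fit from the
    reduced design.  The whitened design-space cross-covariance
    Z_G = (X'X)^(-1/2) X' Y_G and its SVD are computed alongside.
    """
    y = adjusted_stack.values
    x = reduced_design.values
    if x.shape[0] != y.shape[0]:
        raise ValueError("design and stack subject counts disagree")
    if not np.any(y):
        raise ValueError("adjusted stack is identically zero")
    w = inverse_sqrt_psd(x.T @ x)
    z = w @ (x.T @ y)
    zu, zs, zvt = _canonical_svd(z)
    u, s, vt = _canonical_svd(y)
    signature = vt[0]
    subject_loadings = y @ signature
    hat = x @ np.linalg.pinv(x)
    return GroupDecomposition(
        rank=adjusted_stack.rank,
        z=z,
        group_loadings=zu,
        z_eigenvalues=zs,
        z_patterns=zvt,
        eigenvalues=s,
        signature=signature,
        subject_loadings=subject_loadings,
        design_projection=hat @ subject_loadings,
        mask=adjusted_stack.mask,
        affine=adjusted_stack.affine,
    )


def weighted_clinical_loadings(
    individual: list[MLMDecomposition],
    group: dict[int, GroupDecomposition],
) -> dict[int, np.ndarray]:
    """Cohort-average clinical loadings, weighted by subject loadings.

    For each rank k the result is sum_i w_i U_i[:, k] / sum_i |w_i|
    with w_i the rank-k subject loadings — the condition-space profile
    of each group signature.
    """
    out: dict[int, np.ndarray] = {}
    for rank, gd in group.items():
        w = gd.subject_loadings
        if len(w) != len(individual):
            raise ValueError("subject counts disagree")
        denom = float(np.sum(np.abs(w)))
        if denom == 0.0:
            raise ValueError("all subject loadings are zero")
        cols = np.column_stack(
            [d.clinical_loadings[:, rank - 1] for d in individual]
        )
        out[rank] = cols @ w / denom
    return out


def critical_t(p: float = 0.05, df: int = 28, sided: str = "one") -> float:
    """Critical t value at uncorrected level ``p``."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if sided == "one":
        return float(stats.t.ppf(1.0 - p, df))
    if sided == "two":
        return float(stats.t.ppf(1.0 - p / 2.0, df))
    raise ValueError("sided must be 'one' or 'two'")


@dataclass
class SignatureTMap:
    """Voxelwise loading-correlation T map with threshold masks."""

    t: np.ndarray
    r: np.ndarray
    df: int
    threshold: float
    positive_mask: np.ndarray
    negative_mask: np.ndarray
    n_constant: int


def signature_tmap(
    adjusted_stack: EigenimageStack,
    subject_loadings: np.ndarray,
    p: float = 0.05,
    sided: str = "one",
) -> SignatureTMap:
    """T map of the voxelwise correlation between subject loadings and
    eigenimage values.

    Per voxel, Pearson r between the loadings and the stack column is
    converted to T = r sqrt((s-2)/(1-r^2)) with s-2 degrees of freedom.
    Constant voxel columns get T = 0 (counted and logged); |T| is capped
    at T_CAP when r -> +-1.  Masks threshold at the critical t for the
    requested uncorrected level.
    """
    y = adjusted_stack.values
    w = np.asarray(subject_loadings, dtype=float)
    s = y.shape[0]
    if s < 3:
        raise ValueError("need at least 3 subjects")
    if w.shape != (s,):
        raise ValueError("one loading per subject required")
    if np.std(w) == 0.0:
        raise ValueError("subject loadings are constant")
    wc = w - w.mean()
    yc = y - y.mean(axis=0, keepdims=True)
    col_norm = np.linalg.norm(yc, axis=0)
    constant = col_norm == 0.0
    n_constant = int(constant.sum())
    if n_constant:
        log.warning("%d constant voxel columns; their T set to 0", n_constant)
    denom = np.where(constant, 1.0, col_norm) * np.linalg.norm(wc)
    r = np.where(constant, 0.0, yc.T @ wc / denom)
    r = np.clip(r, -1.0, 1.0)
    df = s - 2
    one_minus = 1.0 - r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / one_minus)
    t = np.where(one_minus < 1.0 / (1.0 + T_CAP**2 / df), np.sign(r) * T_CAP, t)
    t = np.clip(t, -T_CAP, T_CAP)
    thr = critical_t(p=p, df=df, sided=sided)
    return SignatureTMap(
        t=t,
        r=r,
        df=df,
        threshold=thr,
        positive_mask=t > thr,
        negative_mask=t < -thr,
        n_constant=n_constant,
    )
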