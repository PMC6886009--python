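"""Paradigm, design matrix and voxelwise GLM.

The experiment is a classic block design with three active conditions —
depression-specific (DS), paranoia-specific (PS) and diagnostically
neutral (DN) statements — separated by fixation-cross rest blocks.
Condition regressors are boxcars convolved with a canonical double-gamma
hemodynamic response function; nuisance regressors are the six
rigid-body motion parameters, an optional discrete-cosine drift basis
and an intercept.  The GLM is an ordinary least-squares fit per voxel;
temporal autocorrelation is summarized afterwards by a single pooled
AR(1) coefficient estimated from the residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import BoldMatrix

CONDITIONS = ("DS", "PS", "DN")
REST = "rest"

# canonical double-gamma HRF parameters (seconds)
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISPERSION = 1.0
HRF_UNDERSHOOT_DISPERSION = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_DURATION = 32.0


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float
    duration: float


@dataclass
class Paradigm:
    """Ordered, non-overlapping blocks plus the total run duration."""

    blocks: tuple[Block, ...]
    total_duration: float

    def __post_init__(self) -> None:
        blocks = tuple(sorted(self.blocks, key=lambda b: b.onset))
        for blk in blocks:
            if blk.condition not in CONDITIONS + (REST,):
                raise ValueError(f"unknown condition {blk.condition!r}")
            if blk.duration <= 0:
                raise ValueError("block durations must be positive")
        for prev, nxt in zip(blocks, blocks[1:]):
            if prev.onset + prev.duration > nxt.onset + 1e-9:
                raise ValueError("blocks overlap")
        if blocks and self.total_duration < blocks[-1].onset + blocks[-1].duration - 1e-9:
            raise ValueError("total_duration shorter than the last block")
        self.blocks = blocks

    def active_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.condition != REST)


def canonical_hrf(tr: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds.

    Difference of two gamma densities (response peaking near 5-6 s and a
    late undershoot weighted 1/6), rescaled to unit peak.  The kernel
    spans ``duration`` seconds (32 s by default).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    n = int(math.ceil(duration / tr))
    t = np.arange(n) * tr
    peak = stats.gamma.pdf(
        t, HRF_PEAK_DELAY / HRF_PEAK_DISPERSION, scale=HRF_PEAK_DISPERSION
    )
    under = stats.gamma.pdf(
        t,
        HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISPERSION,
        scale=HRF_UNDERSHOOT_DISPERSION,
    )
    h = peak - HRF_UNDERSHOOT_RATIO * under
    return h / h.max()


def build_paradigm(
    blocks_per_condition: int = 4,
    statement_duration: float = 8.0,
    statements_per_block: int = 4,
    rest_duration: float = 20.0,
    order: tuple[str, ...] = ("DS", "DN", "PS"),
    lead_in_rest: float = 40.0,
    lead_out_rest: float = 40.0,
) -> Paradigm:
    """Build the block paradigm.

    Each active block holds ``statements_per_block`` statements of
    ``statement_duration`` seconds (4 x 8 s = 32 s by default) and is
    followed by a rest block; active blocks cycle through ``order``.
    The defaults reproduce the study timing: 4 blocks per condition,
    20 s rest blocks, and 40 s of lead-in and lead-out rest, for a
    704 s run.
    """
    if blocks_per_condition < 1 or statements_per_block < 1:
        raise ValueError("counts must be positive")
    if statement_duration <= 0:
        raise ValueError("statement_duration must be positive")
    if rest_duration < 0 or lead_in_rest < 0 or lead_out_rest < 0:
        raise ValueError("rest durations must be non-negative")
    if not order or any(c not in CONDITIONS for c in order):
        raise ValueError(f"order must draw from {CONDITIONS}")
    active_duration = statements_per_block * statement_duration
    blocks: list[Block] = []
    t = 0.0
    if lead_in_rest > 0:
        blocks.append(Block(REST, t, lead_in_rest))
        t += lead_in_rest
    n_active = blocks_per_condition * len(order)
    for i in range(n_active):
        blocks.append(Block(order[i % len(order)], t, active_duration))
        t += active_duration
        if rest_duration > 0:
            blocks.append(Block(REST, t, rest_duration))
            t += rest_duration
    if lead_out_rest > 0:
        blocks.append(Block(REST, t, lead_out_rest))
        t += lead_out_rest
    return Paradigm(blocks=tuple(blocks), total_duration=t)


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with one label per column."""

    values: np.ndarray
    labels: tuple[str, ...]
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = tuple(self.labels)
        if self.values.ndim != 2:
            raise ValueError("design values must be 2-D")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate column labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design contains non-finite entries")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column_indices(self, labels) -> list[int]:
        return [self.labels.index(lab) for lab in labels]

    @property
    def condition_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab in CONDITIONS]

    @property
    def nuisance_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab not in CONDITIONS]


def drift_regressors(n_scans: int, tr: float, period: float) -> np.ndarray:
    """Cosine/sine pair modeling a low-frequency scanner drift.

    A single slow cosine of the given period with arbitrary phase is
    spanned exactly by this pair, so it models the drift confound
    without absorbing task variance at other frequencies (the
    three-condition block cycle sits at a longer period than typical
    drift).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.arange(n_scans) * tr
    omega = 2.0 * np.pi / period
    return np.column_stack([np.cos(omega * t), np.sin(omega * t)])


def build_design_matrix(
    paradigm: Paradigm,
    tr: float,
    n_scans: int,
    motion: np.ndarray | None = None,
    hrf: np.ndarray | None = None,
    drift_period: float | None = None,
) -> DesignMatrix:
    """Assemble the scans x regressors design matrix.

    Condition boxcars (1 while a block of that condition covers the scan
    onset) are convolved with ``hrf`` (canonical by default) and
    truncated to ``n_scans``.  Columns: DS, PS, DN, then the six motion
    parameters if given, then the optional cosine drift pair, then an
    intercept.  A paradigm longer than the acquisition is an error.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_scans < 1:
        raise ValueError("n_scans must be positive")
    if paradigm.total_duration > n_scans * tr + 1e-9:
        raise ValueError(
            f"paradigm lasts {paradigm.total_duration} s but the acquisition "
            f"covers only {n_scans * tr} s"
        )
    if hrf is None:
        hrf = canonical_hrf(tr)
    hrf = np.asarray(hrf, dtype=float)
    times = np.arange(n_scans) * tr
    columns: list[np.ndarray] = []
    labels: list[str] = []
    for cond in CONDITIONS:
        box = np.zeros(n_scans)
        for blk in paradigm.blocks:
            if blk.condition == cond:
                box[(times >= blk.onset - 1e-9) & (times < blk.onset + blk.duration - 1e-9)] = 1.0
        columns.append(np.convolve(box, hrf)[:n_scans])
        labels.append(cond)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_scans, 6):
            raise ValueError(f"motion must be {n_scans} x 6, got {motion.shape}")
        for j in range(6):
            columns.append(motion[:, j])
            labels.append(f"motion{j + 1}")
    if drift_period is not None:
        basis = drift_regressors(n_scans, tr, drift_period)
        for j, suffix in enumerate(("cos", "sin")):
            columns.append(basis[:, j])
            labels.append(f"drift_{suffix}")
    columns.append(np.ones(n_scans))
    labels.append("intercept")
    return DesignMatrix(values=np.column_stack(columns), labels=tuple(labels), tr=tr)


@dataclass
class GlmFit:
    """Ordinary least-squares GLM fit: betas, residuals and residual dof."""

    betas: np.ndarray      # regressors x voxels
    residuals: np.ndarray  # scans x voxels
    dof: int


def fit_glm(bold: BoldMatrix | np.ndarray, design: DesignMatrix) -> GlmFit:
    """Voxelwise OLS fit of the design to the data.

    Requires a full-column-rank design; residuals are exactly orthogonal
    to the design columns (normal equations).
    """
    y = bold.values if isinstance(bold, BoldMatrix) else np.asarray(bold, dtype=float)
    x = design.values
    if y.shape[0] != x.shape[0]:
        raise ValueError("design rows must match number of scans")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {x.shape[1]} columns)"
        )
    betas, *_ = np.linalg.lstsq(x, y, rcond=None)
    residuals = y - x @ betas
    return GlmFit(betas=betas, residuals=residuals, dof=y.shape[0] - x.shape[1])


def estimate_ar1(residuals: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of residual time series.

    rho = sum over voxels of sum_t e_t e_{t-1}, divided by the pooled
    sum of squares.  A single coefficient pooled over all in-mask voxels
    is the stable choice at small problem sizes.
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim == 1:
        e = e[:, None]
    if e.shape[0] < 3:
        raise ValueError("need at least 3 scans to estimate AR(1)")
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise ValueError("residuals are identically zero")
    num = float(np.sum(e[1:] * e[:-1]))
    return num / denom


@dataclass
class ContrastSpec:
    """Rows x regressors matrix selecting/combining design columns."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if np.linalg.matrix_rank(self.matrix) < 1:
            raise ValueError("contrast must have rank >= 1")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def condition_contrast(design: DesignMatrix) -> ContrastSpec:
    """F-contrast spanning exactly the three condition columns."""
    idx = design.condition_indices
    if len(idx) != len(CONDITIONS):
        raise ValueError("design lacks the three condition columns")
    mat = np.zeros((len(idx), design.values.shape[1]))
    for row, col in enumerate(idx):
        mat[row, col] = 1.0
    return ContrastSpec(matrix=mat)


def f_statistic_map(
    fit: GlmFit, design: DesignMatrix, contrast: ContrastSpec
) -> np.ndarray:
    """Extra-sum-of-squares F statistic per voxel for ``contrast``.

    F = (Cb)' [C (X'X)^-1 C']^-1 (Cb) / (rank(C) * MSE) with
    (rank(C), dof) degrees of freedom.
    """
    c = contrast.matrix
    x = design.values
    if c.shape[1] != x.shape[1]:
        raise ValueError("contrast width does not match design")
    if not np.any(c):
        raise ValueError("zero contrast")
    r = contrast.rank
    xtx_inv = np.linalg.inv(x.T @ x)
    cb = c @ fit.betas  # rows x voxels
    m = c @ xtx_inv @ c.T
    quad = np.sum(cb * np.linalg.solve(m, cb), axis=0)
    mse = np.sum(fit.residuals**2, axis=0) / fit.dof
    with np.errstate(divide="ignore", invalid="ignore"):
        f = quad / (r * mse)
    return np.where(mse > 0, f, 0.0)
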