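"""Synthetic block-design fMRI cohorts with known ground truth.

The generator realizes exactly the generative model the two-level MLM
analysis assumes: per subject,

    Y = Xc B' + drift + AR(1) noise,

where the condition-space/voxel-space structure of B is planted through
the whitened geometry of the decomposition.  Concretely, three
orthonormal condition-space directions (the clinical-loading profile),
three orthonormal smooth spatial maps (the eigenimages) and descending
component amplitudes are chosen, and B is pre-colored with the inverse
of the analysis whitener so that the planted components are fixed
points of the individual MLM: on noise-free data the decomposition
returns them exactly.

A group difference of amplitude ``delta`` planted at component rank k
tilts that component's spatial direction by +-(delta/2) times a
dedicated unit-norm difference map (orthogonal to all base maps), with
opposite signs in the two diagnostic groups.  This is the kind of
effect the group-level MLM is built to detect: it survives the
unit-normalization of eigenimages, unlike a pure gain difference.

Defaults reproduce the study conditions: 16 schizophrenia + 14
depression subjects, four 32 s blocks per condition (four 8 s
statements each) alternating DS -> DN -> PS with 20 s rest blocks and
40 s lead-in/lead-out rest (704 s, 352 scans at TR 2 s), AR(1) noise
with rho = 0.3, a 128 s cosine drift, and Table-1 age/sex demographics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import lfilter
from scipy.stats import truncnorm

from . import io as nio
from .design import Paradigm, build_design_matrix, build_paradigm
from .io import BoldMatrix, GROUPS
from .mlm import TemporalCovariance

#: default clinical-loading profile over (DS, PS, DN), one row per
#: component, matching the consistent cohort-wide pattern the analysis
#: is designed to expose: (+DS, -PS, +DN), (+DS, +PS, -DN), (-DS, +PS, +DN)
LOADING_PROFILE = np.array(
    [
        [1.0, -1.0, 1.0],
        [1.0, 1.0, -1.0],
        [-1.0, 1.0, 1.0],
    ]
)


@dataclass
class ParadigmConfig:
    blocks_per_condition: int = 4
    statement_duration: float = 8.0
    statements_per_block: int = 4
    rest_duration: float = 20.0
    order: tuple[str, ...] = ("DS", "DN", "PS")
    lead_in_rest: float = 40.0
    lead_out_rest: float = 40.0

    def build(self) -> Paradigm:
        return build_paradigm(**asdict(self))


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort, plus the seed."""

    n_per_group: tuple[int, int] = (16, 14)
    groups: tuple[str, str] = GROUPS
    grid: tuple[int, int, int] = (16, 16, 8)
    tr: float = 2.0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    rho: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    drift_period: float = 128.0
    motion_step_sd: float = 0.01
    component_amplitudes: tuple[float, float, float] = (100.0, 75.0, 50.0)
    amplitude_jitter_sd: float = 0.1
    group_effect: dict[int, float] = field(default_factory=lambda: {3: 1.0})
    spatial_smoothing: float = 1.5
    age_means: tuple[float, float] = (36.4, 45.3)
    age_sd: float = 12.5
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_counts: tuple[tuple[int, int], tuple[int, int]] = ((10, 6), (5, 9))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("need at least 2 subjects per group")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(g < 4 for g in self.grid):
            raise ValueError("grid dimensions must be >= 4")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")
        for rank in self.group_effect:
            if rank not in (1, 2, 3):
                raise ValueError("group_effect ranks must be 1, 2 or 3")
        for g, (m, f) in zip(self.n_per_group, self.sex_counts):
            if m + f != g:
                raise ValueError("sex_counts must sum to n_per_group")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))

    def n_scans(self) -> int:
        total = self.paradigm.build().total_duration
        return int(np.ceil(total / self.tr))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    condition_maps: np.ndarray           # 3 x voxels, unit norm per row
    component_maps: np.ndarray           # 3 x voxels, orthonormal rows
    loading_directions: np.ndarray       # 3 x 3, columns per component
    difference_maps: dict[int, np.ndarray]  # rank -> unit-norm voxel map
    amplitudes: np.ndarray               # subjects x 3 per-condition amplitudes
    component_amplitudes: np.ndarray     # subjects x 3 per-component scales
    group_labels: list[str]
    rho: float
    seed: int
    mask: np.ndarray
    affine: np.ndarray

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "condition_maps": self.condition_maps.tolist(),
            "component_maps": self.component_maps.tolist(),
            "loading_directions": self.loading_directions.tolist(),
            "difference_maps": {str(k): v.tolist() for k, v in self.difference_maps.items()},
            "amplitudes": self.amplitudes.tolist(),
            "component_amplitudes": self.component_amplitudes.tolist(),
            "group_labels": self.group_labels,
            "rho": self.rho,
            "seed": self.seed,
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path


def ellipsoid_mask(grid: tuple[int, int, int]) -> np.ndarray:
    """Brain-like ellipsoid mask inscribed in the grid."""
    axes = [np.arange(g) - (g - 1) / 2.0 for g in grid]
    radii = [max(g / 2.0 - 0.5, 1.0) for g in grid]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (xx / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (zz / radii[2]) ** 2 <= 1.0


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


@dataclass
class _CohortStructure:
    """Seed-determined quantities shared by every subject of a cohort."""

    mask: np.ndarray
    affine: np.ndarray
    paradigm: Paradigm
    n_scans: int
    times: np.ndarray
    xc: np.ndarray                 # raw condition regressors, scans x 3
    coloring: np.ndarray           # 3x3 inverse-whitener pre-coloring of B
    loading_directions: np.ndarray  # 3x3, columns orthonormal
    component_maps: np.ndarray     # 3 x voxels
    difference_maps: dict[int, np.ndarray]


def _smooth_orthonormal_maps(
    rng: np.random.Generator, grid, mask: np.ndarray, n_maps: int, smoothing: float
) -> np.ndarray:
    fields = []
    for _ in range(n_maps):
        white = rng.standard_normal(grid)
        fields.append(gaussian_filter(white, sigma=smoothing)[mask])
    m = np.column_stack(fields)  # voxels x n_maps
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))  # keep orientation of the raw fields
    return q.T  # n_maps x voxels, orthonormal rows


def cohort_structure(config: CohortConfig, seed: int | None = None) -> _CohortStructure:
    """Deterministic cohort-level structure (maps, directions, coloring)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    mask = ellipsoid_mask(config.grid)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic voxels

    paradigm = config.paradigm.build()
    n_scans = int(np.ceil(paradigm.total_duration / config.tr))
    times = np.arange(n_scans) * config.tr
    design = build_design_matrix(paradigm, config.tr, n_scans, motion=None)
    xc = design.values[:, design.condition_indices]

    # pre-coloring: with B = G U L M', the analysis whitener maps the
    # planted components onto themselves (G = (Xc'Xc)^-1 (Xc' S Xc)^1/2
    # for intercept-adjusted Xc)
    xc_adj = xc - xc.mean(axis=0, keepdims=True)
    sigma = TemporalCovariance("ar1" if config.rho > 0 else "identity", config.rho)
    s_mat = sigma.quad_form(xc_adj)
    coloring = np.linalg.solve(xc_adj.T @ xc_adj, _psd_sqrt(s_mat))

    ranks = sorted(config.group_effect)
    maps = _smooth_orthonormal_maps(
        rng, config.grid, mask, 3 + len(ranks), config.spatial_smoothing
    )
    component_maps = maps[:3]
    difference_maps = {rank: maps[3 + i] for i, rank in enumerate(ranks)}

    q, r = np.linalg.qr(LOADING_PROFILE.T)  # columns = per-component profiles
    directions = q * np.sign(np.diag(r))

    return _CohortStructure(
        mask=mask,
        affine=affine,
        paradigm=paradigm,
        n_scans=n_scans,
        times=times,
        xc=xc,
        coloring=coloring,
        loading_directions=directions,
        component_maps=component_maps,
        difference_maps=difference_maps,
    )


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1000 + subject_index]))


def _group_sign(config: CohortConfig, group_label: str) -> float:
    if group_label not in config.groups:
        raise ValueError(
            f"unknown group label {group_label!r}; expected one of {config.groups}"
        )
    return 1.0 if group_label == config.groups[0] else -1.0


def _subject_effect_matrix(
    config: CohortConfig,
    structure: _CohortStructure,
    rng: np.random.Generator,
    group_label: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted B (conditions x voxels) and per-component amplitudes."""
    sign = _group_sign(config, group_label)
    lam = np.asarray(config.component_amplitudes, dtype=float)
    lam = lam * np.exp(rng.normal(0.0, config.amplitude_jitter_sd, size=3))
    m_rows = structure.component_maps.copy()
    for rank, delta in config.group_effect.items():
        tilted = m_rows[rank - 1] + sign * (delta / 2.0) * structure.difference_maps[rank]
        m_rows[rank - 1] = tilted / np.linalg.norm(tilted)
    b = structure.coloring @ (structure.loading_directions * lam) @ m_rows
    return b, lam


def simulate_subject(
    config: CohortConfig,
    subject_index: int,
    group_label: str,
    seed: int | None = None,
    structure: _CohortStructure | None = None,
) -> tuple[BoldMatrix, np.ndarray, dict]:
    """Simulate one subject: BOLD matrix, motion series, truth slice.

    Identical (config, subject_index, seed) reproduce identical output.
    """
    seed = config.seed if seed is None else seed
    if structure is None:
        structure = cohort_structure(config, seed)
    rng = _subject_rng(seed, subject_index)
    n, v = structure.n_scans, int(structure.mask.sum())

    b, lam = _subject_effect_matrix(config, structure, rng, group_label)
    signal = structure.xc @ b

    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = config.drift_amplitude * np.cos(
        2.0 * np.pi * structure.times / config.drift_period + phase
    )
    y = signal + drift[:, None]

    if config.noise_sd > 0:
        innov = rng.standard_normal((n, v))
        rho = config.rho
        innov[0] /= np.sqrt(1.0 - rho**2) if rho > 0 else 1.0
        noise = lfilter([1.0], [1.0, -rho], innov, axis=0)
        y = y + noise * (config.noise_sd * np.sqrt(1.0 - rho**2) if rho > 0 else config.noise_sd)

    steps = rng.normal(0.0, config.motion_step_sd, size=(n, 6))
    motion = gaussian_filter1d(np.cumsum(steps, axis=0), sigma=3.0, axis=0)

    bold = BoldMatrix(values=y, mask=structure.mask, affine=structure.affine)
    truth_slice = {
        "subject_index": subject_index,
        "group": group_label,
        "component_amplitudes": lam,
        "condition_amplitudes": np.linalg.norm(b, axis=1),
        "effect_matrix": b,
    }
    return bold, motion, truth_slice


def _demographics(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    lo, hi = config.age_range
    for group, n, mean, (n_m, n_f) in zip(
        config.groups, config.n_per_group, config.age_means, config.sex_counts
    ):
        a, bnd = (lo - mean) / config.age_sd, (hi - mean) / config.age_sd
        ages = truncnorm.rvs(a, bnd, loc=mean, scale=config.age_sd, size=n, random_state=rng)
        sexes = np.array(["M"] * n_m + ["F"] * n_f)
        rng.shuffle(sexes)
        for j in range(n):
            rows.append(
                {
                    "subject_id": f"sub-{idx + 1:02d}",
                    "group": group,
                    "age": round(float(ages[j]), 1),
                    "sex": str(sexes[j]),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


@dataclass
class CohortData:
    """In-memory synthetic cohort: per-subject data plus ground truth."""

    config: CohortConfig
    manifest: pd.DataFrame
    bolds: list[BoldMatrix]
    motions: list[np.ndarray]
    truth: GroundTruth


def simulate_cohort_data(config: CohortConfig, seed: int | None = None) -> CohortData:
    """Generate a whole cohort in memory (no files written)."""
    seed = config.seed if seed is None else seed
    structure = cohort_structure(config, seed)
    demo_rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    manifest = _demographics(config, demo_rng)

    bolds, motions, lam_rows, amp_rows = [], [], [], []
    for i, row in manifest.iterrows():
        bold, motion, truth_slice = simulate_subject(
            config, i, row["group"], seed=seed, structure=structure
        )
        bolds.append(bold)
        motions.append(motion)
        lam_rows.append(truth_slice["component_amplitudes"])
        amp_rows.append(truth_slice["condition_amplitudes"])

    base_b = (
        structure.coloring
        @ (structure.loading_directions * np.asarray(config.component_amplitudes))
        @ structure.component_maps
    )
    norms = np.linalg.norm(base_b, axis=1, keepdims=True)
    truth = GroundTruth(
        condition_maps=base_b / norms,
        component_maps=structure.component_maps,
        loading_directions=structure.loading_directions,
        difference_maps=structure.difference_maps,
        amplitudes=np.vstack(amp_rows),
        component_amplitudes=np.vstack(lam_rows),
        group_labels=list(manifest["group"]),
        rho=config.rho,
        seed=seed,
        mask=structure.mask,
        affine=structure.affine,
    )
    return CohortData(
        config=config, manifest=manifest, bolds=bolds, motions=motions, truth=truth
    )


def simulate_cohort(
    config: CohortConfig,
    out_dir: str | Path,
    seed: int | None = None,
    overwrite: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Write a synthetic cohort to disk (NIfTI + motion + manifest).

    Produces sub-XX_bold.nii.gz, sub-XX_motion.txt, a shared mask.nii.gz,
    participants.tsv with path columns, and ground_truth.json.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "participants.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)

    data = simulate_cohort_data(config, seed)
    nio.write_mask(data.truth.mask, data.truth.affine, out_dir / "mask.nii.gz")
    bold_paths, motion_paths = [], []
    for i, row in data.manifest.iterrows():
        sid = row["subject_id"]
        bold_file = f"{sid}_bold.nii.gz"
        motion_file = f"{sid}_motion.txt"
        nio.write_volume(
            data.bolds[i].values,
            data.truth.mask,
            data.truth.affine,
            out_dir / bold_file,
        )
        np.savetxt(out_dir / motion_file, data.motions[i], fmt="%.8f")
        bold_paths.append(bold_file)
        motion_paths.append(motion_file)
    manifest = data.manifest.copy()
    manifest["bold_path"] = bold_paths
    manifest["mask_path"] = "mask.nii.gz"
    manifest["motion_path"] = motion_paths
    nio.write_manifest(manifest, manifest_path)
    data.truth.to_json(out_dir / "ground_truth.json")
    return manifest, data.truth
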