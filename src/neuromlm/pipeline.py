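"""End-to-end pipeline: design -> GLM -> individual MLM -> alignment ->
per-rank group MLM -> classification.

:func:`analyze_cohort` runs the whole analysis in memory on loaded
data; :func:`run_pipeline` is the file-based driver that reads a cohort
from a participants manifest, writes every artifact (signatures,
T-maps, F-maps, loading tables, classification JSONs) and a provenance
record tying the outputs to the seed, configuration hash and library
versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .classify import ClassificationResult, repeated_kfold_accuracy
from .design import (
    build_design_matrix,
    build_paradigm,
    condition_contrast,
    estimate_ar1,
    f_statistic_map,
    fit_glm,
)
from .group import (
    GroupDecomposition,
    GroupDesign,
    SignatureTMap,
    group_mlm,
    residualize_confounds,
    signature_tmap,
    stack_eigenimages,
    weighted_clinical_loadings,
)
from .io import (
    BoldMatrix,
    read_bold,
    read_manifest,
    validate_manifest,
    write_volume,
)
from .mlm import MLMDecomposition, TemporalCovariance, align_decompositions, individual_mlm

log = logging.getLogger(__name__)


class ParadigmParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    blocks_per_condition: int = 4
    statement_duration: float = 8.0
    statements_per_block: int = 4
    rest_duration: float = 20.0
    order: tuple[str, ...] = ("DS", "DN", "PS")
    lead_in_rest: float = 40.0
    lead_out_rest: float = 40.0


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    tr: float = 2.0
    paradigm: ParadigmParams = ParadigmParams()
    drift_period: float | None = 128.0
    sigma_form: str = "ar1"          # 'ar1' or 'identity'
    n_components: int = 3
    center: bool = True
    confounds: tuple[str, ...] = ("age", "sex")
    reference_subject: int = 0
    cv_k: int = 2
    cv_repeats: int = 100
    seed: int = 0
    p_uncorrected: float = 0.05
    sidedness: str = "one"
    positive_label: str = "schizophrenia"
    write_fmaps: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**(data or {}))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RankResult:
    """Group-level outputs for one component rank."""

    group: GroupDecomposition
    tmap: SignatureTMap
    classification: ClassificationResult


@dataclass
class CohortResult:
    """Full two-level analysis of one cohort."""

    decompositions: list[MLMDecomposition]
    per_rank: dict[int, RankResult]
    weighted_clinical: dict[int, np.ndarray]
    rho_estimates: np.ndarray
    f_maps: list[np.ndarray]
    group_design: GroupDesign
    labels: np.ndarray


def _cv_seed(config: PipelineConfig, rank: int) -> int:
    ss = np.random.SeedSequence([config.seed, 7, rank])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))


def analyze_cohort(
    bolds: list[BoldMatrix],
    motions: list[np.ndarray],
    manifest: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> CohortResult:
    """Run the two-level MLM analysis on an in-memory cohort."""
    config = config or PipelineConfig()
    if not len(bolds) == len(motions) == len(manifest):
        raise ValueError("bolds, motions and manifest rows must align")
    paradigm = build_paradigm(**config.paradigm.model_dump())

    decomps: list[MLMDecomposition] = []
    rhos = np.empty(len(bolds))
    f_maps: list[np.ndarray] = []
    t0 = time.time()
    for i, (bold, motion) in enumerate(zip(bolds, motions)):
        design = build_design_matrix(
            paradigm,
            config.tr,
            bold.n_scans,
            motion=motion,
            drift_period=config.drift_period,
        )
        fit = fit_glm(bold, design)
        rhos[i] = estimate_ar1(fit.residuals)
        contrast = condition_contrast(design)
        f_maps.append(f_statistic_map(fit, design, contrast))
        sigma = (
            TemporalCovariance("ar1", rhos[i])
            if config.sigma_form == "ar1"
            else TemporalCovariance("identity")
        )
        decomps.append(
            individual_mlm(
                bold,
                design,
                sigma=sigma,
                contrast=contrast,
                n_components=config.n_components,
                center=config.center,
            )
        )
    log.info("individual MLM stage: %.1f s", time.time() - t0)

    aligned = align_decompositions(decomps, config.reference_subject)
    gdesign = GroupDesign.from_manifest(manifest)
    labels = manifest["group"].to_numpy()

    per_rank: dict[int, RankResult] = {}
    for rank in range(1, config.n_components + 1):
        stack = stack_eigenimages(aligned, rank)
        adjusted, reduced = residualize_confounds(stack, gdesign, config.confounds)
        gd = group_mlm(adjusted, reduced)
        tmap = signature_tmap(
            adjusted, gd.subject_loadings, p=config.p_uncorrected, sided=config.sidedness
        )
        clf = repeated_kfold_accuracy(
            gd.subject_loadings[:, None],
            labels,
            k=config.cv_k,
            repeats=config.cv_repeats,
            seed=_cv_seed(config, rank),
            positive_label=config.positive_label,
        )
        per_rank[rank] = RankResult(group=gd, tmap=tmap, classification=clf)

    wcl = weighted_clinical_loadings(aligned, {r: rr.group for r, rr in per_rank.items()})
    return CohortResult(
        decompositions=aligned,
        per_rank=per_rank,
        weighted_clinical=wcl,
        rho_estimates=rhos,
        f_maps=f_maps,
        group_design=gdesign,
        labels=labels,
    )


def _write_outputs(
    result: CohortResult,
    manifest: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Path,
) -> list[str]:
    files: list[str] = []

    def record(path: Path) -> Path:
        files.append(str(path.relative_to(out_dir)))
        return path

    mask = result.decompositions[0].mask
    affine = result.decompositions[0].affine
    subj_ids = list(manifest["subject_id"])

    for i, (sid, d) in enumerate(zip(subj_ids, result.decompositions)):
        write_volume(d.eigenimages, mask, affine, record(out_dir / f"{sid}_eigenimages.nii.gz"))
        if config.write_fmaps:
            write_volume(result.f_maps[i], mask, affine, record(out_dir / f"{sid}_fmap.nii.gz"))
        tbl = pd.DataFrame(
            d.clinical_loadings,
            index=list(d.condition_labels),
            columns=[f"component{k + 1}" for k in range(d.n_components)],
        )
        tbl.loc["eigenvalue"] = d.eigenvalues
        tbl.to_csv(record(out_dir / f"{sid}_clinical_loadings.tsv"), sep="\t", float_format="%.10g")

    loadings = pd.DataFrame({"subject_id": subj_ids, "group": manifest["group"]})
    for rank, rr in result.per_rank.items():
        gd, tmap, clf = rr.group, rr.tmap, rr.classification
        write_volume(gd.signature, mask, affine, record(out_dir / f"signature_rank{rank}.nii.gz"))
        write_volume(tmap.t, mask, affine, record(out_dir / f"tmap_rank{rank}.nii.gz"))
        loadings[f"loading_rank{rank}"] = gd.subject_loadings
        loadings[f"design_projection_rank{rank}"] = gd.design_projection
        payload = clf.summary() | {
            "accuracies": clf.accuracies.tolist(),
            "roc_points": clf.roc_points.tolist(),
            "roc_points_insample": clf.roc_points_insample.tolist(),
            "tmap_threshold": tmap.threshold,
            "tmap_df": tmap.df,
            "eigenvalues": gd.eigenvalues.tolist(),
        }
        record(out_dir / f"classification_rank{rank}.json").write_text(
            json.dumps(payload, indent=2)
        )
    loadings.to_csv(record(out_dir / "subject_loadings.tsv"), sep="\t", index=False, float_format="%.10g")

    wcl = pd.DataFrame(
        {f"rank{r}": v for r, v in result.weighted_clinical.items()},
        index=list(result.decompositions[0].condition_labels),
    )
    wcl.to_csv(record(out_dir / "weighted_clinical_loadings.tsv"), sep="\t", float_format="%.10g")
    return files


def run_pipeline(
    config: PipelineConfig,
    manifest: pd.DataFrame | str | Path,
    out_dir: str | Path,
) -> CohortResult:
    """File-based pipeline driver.

    ``manifest`` is a participants.tsv path or an already-validated
    DataFrame with resolved path columns.  Writes all artifacts plus
    ``provenance.json`` into ``out_dir``.
    """
    if isinstance(manifest, (str, Path)):
        manifest = read_manifest(manifest)
    else:
        manifest = validate_manifest(manifest)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage_t = time.time()
    bolds, motions = [], []
    for _, row in manifest.iterrows():
        bolds.append(read_bold(row["bold_path"], row["mask_path"]))
        motions.append(np.loadtxt(row["motion_path"]))
    log.info("loading stage: %.1f s", time.time() - stage_t)

    result = analyze_cohort(bolds, motions, manifest, config)
    files = _write_outputs(result, manifest, config, out_dir)

    import scipy
    import sklearn

    provenance = {
        "package": "neuromlm",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "rho_estimates": result.rho_estimates.tolist(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pd.__version__,
        },
        "files": files,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=list))
    return result
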