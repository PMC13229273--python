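"""End-to-end orchestration: simulate -> (glm) -> rdm -> searchlight -> group.

A :class:`PipelineConfig` fully determines a run (all seeds explicit); the
pipeline is deterministic given the config.  Outputs are written as NIfTI
volumes (maps, cluster labels), tab-separated tables (events, model fits,
correlations, MDS coordinates, cluster tables, cohort manifest), PNG figures,
and a JSON provenance record (config hash, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import stimulus_design as sd
from .crossnobis import BetaSet
from .first_level_glm import run_glm
from .group_inference import TwoStepPlan, brain_behavior_corr, classical_mds, run_two_step
from .model_rdms import (
    PairMask,
    lexical_model,
    partition_mask,
    shared_phonemes_model,
    sublexical_model,
)
from .searchlight import (
    Searchlight,
    SearchlightSpec,
    cluster_average_rdms,
    conjunction_group_map,
    within_type_distance_maps,
)
from .synthetic_fmri import (
    CohortSpec,
    EffectSpec,
    NoiseSpec,
    ReadingModel,
    VolumeGeometry,
    cohort_manifest,
    generate_cohort,
)

log = logging.getLogger("phonorsa")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    group: str = "hearing"
    n_subjects: int = 12
    grid: tuple[int, int, int] = (20, 20, 20)
    mode: str = "betas"  # betas | timeseries
    seed: int = 0
    peak_p: float = 0.001
    cluster_q: float = 0.05
    n_permutations: int = 2000
    effect: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    reading: ReadingModel = field(default_factory=ReadingModel)
    searchlight: SearchlightSpec = field(default_factory=SearchlightSpec)
    effect_base: float = 1.0
    effect_sd: float = 0.6
    output_dir: str = "phonorsa_out"

    def __post_init__(self):
        if not (0 < self.peak_p < 1 and 0 < self.cluster_q < 1):
            raise ValueError("thresholds must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("effect", EffectSpec),
        ("noise", NoiseSpec),
        ("reading", ReadingModel),
        ("searchlight", SearchlightSpec),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = kwargs[key]
            if "roi_center" in sub:
                sub["roi_center"] = tuple(sub["roi_center"])
            kwargs[key] = cls(**sub)
    if "grid" in kwargs:
        kwargs["grid"] = tuple(kwargs["grid"])
    return PipelineConfig(**kwargs)


def _write_nifti(volume: np.ndarray, geometry: VolumeGeometry, path: Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), geometry.affine)
    nib.save(img, str(path))


def _subject_betas(cfg: PipelineConfig, subjects, paradigm) -> tuple[list, list]:
    """Beta sets and residuals per subject (estimating a GLM in timeseries mode)."""
    betas, residuals = [], []
    conditions = sd.enumerate_conditions(paradigm)
    labels = tuple(c.label for c in conditions)
    for rec in subjects:
        if cfg.mode == "betas":
            betas.append(rec.betas)
            residuals.append(rec.residuals)
            continue
        run_betas, run_resid = [], []
        for data, events, motion in zip(rec.timeseries, rec.events, rec.motion):
            design, fit = run_glm(events, data, motion=motion)
            run_betas.append(fit.condition_betas(design))
            run_resid.append(fit.residuals)
        betas.append(BetaSet(np.stack(run_betas), labels))
        residuals.append(run_resid)
    return betas, residuals


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> dict:
    """Run the full analysis for one group; returns the in-memory result bundle."""
    out = Path(cfg.output_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    paradigm = sd.ParadigmSpec(group=cfg.group)
    geometry = VolumeGeometry(shape=cfg.grid)
    conditions = sd.enumerate_conditions(paradigm)

    log.info("simulating cohort: group=%s n=%d mode=%s", cfg.group, cfg.n_subjects, cfg.mode)
    subjects = generate_cohort(
        paradigm, geometry, cfg.effect, cfg.noise,
        CohortSpec(cfg.n_subjects, cfg.effect_base, cfg.effect_sd),
        seed=int(rng.integers(2**31 - 1)), reading=cfg.reading, mode=cfg.mode,
    )
    betas, residuals = _subject_betas(cfg, subjects, paradigm)

    log.info("searchlight: within-type distance maps")
    sl = Searchlight(geometry, cfg.searchlight)
    types = paradigm.stimulus_types
    maps_by_type = {t: [] for t in types}
    for b, r in zip(betas, residuals):
        maps = within_type_distance_maps(sl, b, r, conditions)
        for t in types:
            maps_by_type[t].append(maps[t].values)
    stacks = {t: np.stack(v) for t, v in maps_by_type.items()}

    log.info("group conjunction and cluster inference")
    conj_map, clusters = conjunction_group_map(
        sl, stacks, cfg.peak_p, cfg.cluster_q, cfg.n_permutations,
        rng=int(rng.integers(2**31 - 1)),
    )

    full_mask = PairMask(tuple(conditions), ~np.eye(len(conditions), dtype=bool))
    models = {
        "shared_phonemes": shared_phonemes_model(conditions),
        "sublexical": sublexical_model(conditions),
        "lexical": lexical_model(conditions),
    }

    fits = pd.DataFrame()
    corr: dict | None = None
    mds_coords = None
    cluster_rdms = {}
    if len(clusters.table) and clusters.table["significant"].any():
        log.info("two-step model testing in %d cluster(s)",
                 int(clusters.table["significant"].sum()))
        cluster_rdms = cluster_average_rdms(sl, clusters, betas, residuals, full_mask)
        fits = run_two_step(cluster_rdms, models, conditions, TwoStepPlan(cfg.cluster_q))

        # brain-behavior: across-stimulus Shared Phonemes fit vs reading score
        across_rows = fits[(fits["step"] == "2_across_shared") & fits["significant"]]
        if len(across_rows):
            from .group_inference import model_fit_z

            cid = across_rows.iloc[0]["cluster"]
            across = partition_mask(conditions, "across_type")
            per_subject = np.array(
                [model_fit_z(r, models["shared_phonemes"], across)
                 for r in cluster_rdms[cid]]
            )
            scores = np.array([s.reading_score for s in subjects])
            corr = brain_behavior_corr(per_subject, scores)
            corr["cluster"] = int(cid)
            # MDS of the group-average RDM in that cluster
            from .crossnobis import average_rdms

            group_rdm = average_rdms(cluster_rdms[cid]).to_matrix()
            np.fill_diagonal(group_rdm, 0.0)
            mds_coords = classical_mds(np.nan_to_num(group_rdm), dims=2)

    bundle = {
        "config": cfg,
        "paradigm": paradigm,
        "geometry": geometry,
        "subjects": subjects,
        "conjunction_map": conj_map,
        "clusters": clusters,
        "model_fits": fits,
        "behavior_correlation": corr,
        "mds": mds_coords,
        "searchlight": sl,
    }
    if write_outputs:
        _write_bundle(bundle, out, conditions)
    return bundle


def _write_bundle(bundle: dict, out: Path, conditions) -> None:
    cfg: PipelineConfig = bundle["config"]
    geometry: VolumeGeometry = bundle["geometry"]
    sl: Searchlight = bundle["searchlight"]

    cohort_manifest(bundle["subjects"]).to_csv(out / "cohort.tsv", sep="\t", index=False)
    _write_nifti(bundle["conjunction_map"].to_volume(), geometry,
                 out / "conjunction_min_t.nii.gz")
    _write_nifti(bundle["clusters"].labels.astype(float), geometry,
                 out / "cluster_labels.nii.gz")
    bundle["clusters"].table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    if len(bundle["model_fits"]):
        bundle["model_fits"].to_csv(out / "model_fits.tsv", sep="\t", index=False)
    if bundle["behavior_correlation"] is not None:
        pd.DataFrame([bundle["behavior_correlation"]]).to_csv(
            out / "behavior_correlation.tsv", sep="\t", index=False
        )
    if bundle["mds"] is not None:
        labels = [c.label for c in conditions]
        pd.DataFrame(bundle["mds"], index=labels, columns=["dim1", "dim2"]).to_csv(
            out / "mds_coordinates.tsv", sep="\t"
        )
        _plot_mds(bundle["mds"], conditions, out / "mds.png")

    cfg_dict = cfg.to_dict()
    provenance = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))


def _plot_mds(coords: np.ndarray, conditions, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    types = sorted({c.stimulus_type for c in conditions})
    colors = {t: c for t, c in zip(types, ("tab:blue", "tab:orange"))}
    for (x, y), cond in zip(coords, conditions):
        ax.scatter(x, y, color=colors[cond.stimulus_type], s=12)
        ax.annotate(cond.word.orthography, (x, y), fontsize=6)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_title("MDS of group-average neural RDM")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
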