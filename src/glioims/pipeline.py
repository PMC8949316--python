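"""End-to-end orchestration: simulate -> process -> segment -> compare ->
modules -> survival as one reproducible, config-driven run.

The section-level helpers (:func:`run_arm`, :func:`run_lipidomics_comparison`)
are also the entry points the acceptance checks use; :func:`run_all` wires
every stage together under a single YAML config and writes a machine-readable
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition_stats import (
    CompositionTable,
    GroupComparison,
    build_composition_table,
    compare_groups,
    composition,
    pca_separation,
)
from .coexpression import detect_modules, module_subtype_nes
from .ims_proc import process_section
from .lipid_chem import Panel, default_panel, load_panel
from .segmentation import segment_section
from .survival_epigenetics import logrank_two_groups, subtype_anova_tukey
from .synth_data import (
    CompositionProfile,
    NoiseModel,
    default_section_spec,
    default_study_spec,
    make_study_config,
    simulate_expression_study,
    simulate_section,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_arm", "run_lipidomics_comparison", "run_all"]

DEFAULT_ARMS = ("healthy_vehicle", "gbm_vehicle", "healthy_tmz", "gbm_tmz")


@dataclass
class ArmResult:
    """Composition of one study arm's sections (one polarity)."""

    arm: str
    table: CompositionTable
    segmentations: list = field(default_factory=list)


def _arm_condition_treatment(arm: str) -> tuple[str, str]:
    condition, treatment = arm.rsplit("_", 1)
    return condition, treatment


def run_arm(
    arm: str,
    profiles: Mapping[str, CompositionProfile],
    panel: Panel,
    noise: NoiseModel,
    n_sections: int = 5,
    grid: tuple[int, int] = (60, 60),
    polarity: str = "negative",
    seeds: Sequence[int] | None = None,
    tol_ppm: float = 9.0,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
) -> ArmResult:
    """Simulate and fully process ``n_sections`` sections of one study arm:
    simulate -> align/annotate -> background filter -> segment -> ROI match ->
    per-section composition of the selected cluster."""
    condition, treatment = _arm_condition_treatment(arm)
    seeds = list(seeds) if seeds is not None else list(range(1, n_sections + 1))
    if len(seeds) != n_sections:
        raise ValueError("need one seed per section")

    tables, segmentations = [], []
    for i, seed in enumerate(seeds):
        spec = default_section_spec(
            condition, treatment, polarity=polarity, grid=grid, seed=seed
        )
        dataset, roi = simulate_section(spec, profiles, panel, noise)
        features = process_section(dataset, panel, tol_ppm=tol_ppm)
        seg = segment_section(features, roi, k=k, k_range=k_range, seed=seed)
        sample_id = f"{arm}_s{i + 1}"
        tables.append(composition(features, seg, sample_id))
        segmentations.append(seg)
    return ArmResult(
        arm=arm,
        table=build_composition_table(tables, group=arm),
        segmentations=segmentations,
    )


def run_lipidomics_comparison(
    arm_a: str,
    arm_b: str,
    n_sections: int = 5,
    grid: tuple[int, int] = (60, 60),
    polarity: str = "negative",
    seed: int = 1,
    sigma: float | None = None,
    jitter_ppm: float | None = None,
    panel: Panel | None = None,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    arm_results: dict[str, ArmResult] | None = None,
) -> tuple[GroupComparison, dict[str, ArmResult]]:
    """Full two-arm study at the packaged composition config.

    Per-arm section seeds are ``seed .. seed + n_sections - 1`` offset by a
    fixed per-arm stride so arms are independent replicates. ``arm_results``
    lets callers reuse already-computed arms across comparisons.
    """
    panel = panel or default_panel()
    profiles, noise, _ = make_study_config(panel)
    if sigma is not None or jitter_ppm is not None:
        noise = NoiseModel(
            sigma=noise.sigma if sigma is None else sigma,
            mz_jitter_ppm=(noise.mz_jitter_ppm if jitter_ppm is None
                           else jitter_ppm),
            background_tic_fraction=noise.background_tic_fraction,
            background_peaks=noise.background_peaks,
        )
    results = arm_results if arm_results is not None else {}
    for arm in (arm_a, arm_b):
        if arm in results:
            continue
        stride = 100 * DEFAULT_ARMS.index(arm)
        results[arm] = run_arm(
            arm, profiles, panel, noise,
            n_sections=n_sections, grid=grid, polarity=polarity,
            seeds=[seed + stride + i for i in range(n_sections)],
            k=k, k_range=k_range,
        )
    comparison = compare_groups(results[arm_a].table, results[arm_b].table)
    return comparison, results


def panel_presence_survey(
    grid: tuple[int, int] = (40, 40),
    seed: int = 0,
    sigma: float = 0.0,
    jitter_ppm: float = 0.0,
    threshold: float = 0.8,
    panel: Panel | None = None,
) -> dict:
    """Species surviving the cross-sample presence filter on fresh sections.

    One section per study arm and polarity is simulated, processed, background
    filtered, and the presence filter applied per polarity (a species can only
    be detected in sections of its own ion mode). Returns the union of kept
    species with per-class counts.
    """
    from .ims_proc import presence_filter
    from .segmentation import filter_background

    panel = panel or default_panel()
    profiles, noise, _ = make_study_config(panel)
    noise = NoiseModel(
        sigma=sigma, mz_jitter_ppm=jitter_ppm,
        background_tic_fraction=noise.background_tic_fraction,
        background_peaks=noise.background_peaks,
    )
    kept_species = set()
    for polarity in ("negative", "positive"):
        tables = []
        for i, arm in enumerate(DEFAULT_ARMS):
            condition, treatment = _arm_condition_treatment(arm)
            spec = default_section_spec(
                condition, treatment, polarity=polarity, grid=grid,
                seed=seed + i,
            )
            dataset, _roi = simulate_section(spec, profiles, panel, noise)
            features = process_section(dataset, panel)
            tissue = filter_background(features.raw_tic)
            features.matrix = features.matrix[tissue]
            features.coords = features.coords[tissue]
            features.raw_tic = features.raw_tic[tissue]
            features.kept_pixel_index = features.kept_pixel_index[tissue]
            tables.append(features)
        kept_keys, _log = presence_filter(tables, threshold=threshold)
        kept_species |= {sp for sp, _adduct in kept_keys}
    classes = sorted({sp.lipid_class.value for sp in kept_species})
    return {
        "n_species": len(kept_species),
        "n_classes": len(classes),
        "classes": classes,
        "species": kept_species,
    }


@dataclass
class RunConfig:
    """Validated configuration of a full run. Every tunable appears exactly
    once; the config hash is recorded in the report for provenance."""

    out_dir: Path
    seed: int = 1
    panel_path: Path | None = None
    n_sections: int = 5
    grid: tuple[int, int] = (60, 60)
    tol_ppm: float = 9.0
    presence_threshold: float = 0.8
    display_min_pct: float = 5.0
    k_range: tuple[int, int] = (2, 8)
    beta: float = 9.0
    diss_cutoff: float = 0.8
    n_perm: int = 1000
    survival_genes: tuple[str, ...] = (
        "PLA2G5", "FABP7", "ELOVL2", "PLA2G2A", "ALOX5AP"
    )
    comparisons: tuple[tuple[str, str], ...] = (
        ("healthy_vehicle", "gbm_vehicle"),
        ("healthy_vehicle", "healthy_tmz"),
        ("gbm_vehicle", "gbm_tmz"),
    )

    REQUIRED = ("out_dir",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in cls.REQUIRED:
            if key not in raw:
                raise ValueError(f"run config is missing required field {key!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(raw)
        kwargs["out_dir"] = Path(raw["out_dir"])
        if raw.get("panel_path"):
            kwargs["panel_path"] = Path(raw["panel_path"])
        if "grid" in raw:
            kwargs["grid"] = tuple(raw["grid"])
        if "k_range" in raw:
            kwargs["k_range"] = tuple(raw["k_range"])
        if "comparisons" in raw:
            kwargs["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        if "survival_genes" in raw:
            kwargs["survival_genes"] = tuple(raw["survival_genes"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        # hash of the scientific tunables only (paths excluded)
        payload = {k: str(v) for k, v in self.__dict__.items()
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _comparison_block(comp: GroupComparison) -> dict:
    return {
        "group_a": comp.group_a,
        "group_b": comp.group_b,
        "class_fold_changes": comp.classes["fold_change"].round(4).to_dict(),
        "class_p": comp.classes["p"].round(6).to_dict(),
    }


def run_all(config: RunConfig | str | Path) -> dict:
    """Run every stage under one config and write a JSON report.

    Stage outputs land under ``config.out_dir``; any stage failure aborts
    with the stage name while preserving partial outputs. Reruns with the
    same config and seed are reproducible.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }
    stage = "simulate"
    try:
        profiles, noise, study_spec = make_study_config(panel)
        study_spec.seed = config.seed
        study = simulate_expression_study(study_spec)
        study.expr.to_csv(out / "expression.tsv", sep="\t")
        study.methylation.to_csv(out / "methylation.tsv", sep="\t")
        study.survival.to_csv(out / "survival.tsv", sep="\t")
        report["stages"]["simulate"] = {
            "n_genes": int(study.expr.shape[0]),
            "n_samples": int(study.expr.shape[1]),
            "panel_species": len(panel),
            "panel_classes": len(panel.classes),
        }

        stage = "lipidomics"
        arm_results: dict[str, ArmResult] = {}
        comparisons = {}
        for arm_a, arm_b in config.comparisons:
            comp, arm_results = run_lipidomics_comparison(
                arm_a, arm_b,
                n_sections=config.n_sections, grid=config.grid,
                seed=config.seed, panel=panel, k_range=config.k_range,
                arm_results=arm_results,
            )
            name = f"{arm_b}_vs_{arm_a}"
            comparisons[name] = _comparison_block(comp)
            comp.classes.to_csv(out / f"classes_{name}.tsv", sep="\t")
            for cls, frame in comp.species.items():
                safe = cls.replace(" ", "_").replace("-", "")
                frame.to_csv(out / f"species_{name}_{safe}.tsv", sep="\t")
        report["stages"]["lipidomics"] = comparisons

        stage = "pca"
        shares = pd.concat(
            [r.table.class_shares for r in arm_results.values()]
        ).fillna(0.0)
        labels = [s.rsplit("_s", 1)[0] for s in shares.index]
        pca = pca_separation(shares, labels)
        pca["scores"].to_csv(out / "pca_scores.tsv", sep="\t")
        report["stages"]["pca"] = {
            "explained_variance_ratio":
                [round(float(v), 4) for v in pca["explained_variance_ratio"]],
            "group_silhouette": (None if np.isnan(pca["group_silhouette"])
                                 else round(pca["group_silhouette"], 4)),
        }

        stage = "modules"
        module_set = detect_modules(
            study, beta=config.beta, diss_cutoff=config.diss_cutoff,
            seed=config.seed,
        )
        nes = module_subtype_nes(
            module_set, study, n_perm=config.n_perm, seed=config.seed
        )
        module_set.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
        nes.nes.to_csv(out / "nes.tsv", sep="\t")
        report["stages"]["modules"] = {
            "n_modules": len(module_set.modules),
            "top_subtype_per_module": {
                m: str(nes.nes.loc[m].idxmax()) for m in nes.nes.index
            },
        }

        stage = "survival"
        surv_rows = {}
        for gene in config.survival_genes:
            res = logrank_two_groups(study.survival, study.expr.loc[gene])
            surv_rows[gene] = {"chi2": round(res.chi2, 4), "p": res.p}
        pd.DataFrame(surv_rows).T.to_csv(out / "logrank.tsv", sep="\t")
        report["stages"]["survival"] = surv_rows

        stage = "epigenetics"
        epi = {}
        for gene in ("PLA2G5", "FABP7", "ALOX5AP"):
            expr_cmp = subtype_anova_tukey(study.expr.loc[gene], study.subtypes)
            meth_cmp = subtype_anova_tukey(
                study.methylation.loc[gene], study.subtypes
            )
            epi[gene] = {
                "expression_F": round(expr_cmp.f_stat, 3),
                "expression_p": expr_cmp.p,
                "methylation_F": round(meth_cmp.f_stat, 3),
                "methylation_p": meth_cmp.p,
            }
        report["stages"]["epigenetics"] = epi
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
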