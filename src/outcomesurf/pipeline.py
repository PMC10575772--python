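"""End-to-end orchestration: simulate → stratify → GLM → RFT → decode → enrich.

A RunConfig (JSON-serializable) drives the whole analysis.  The default grid
fits one model per outcome subgroup × cortical feature × analysis timepoint
(3 × 2 × 3 = 18 contrasts); each contrast is cluster-corrected separately
(no pooling across features or subgroups), decoded against the expression
atlas, and a single joint enrichment table is BH-FDR-corrected across every
contrast × gene-set pair.  Outputs are plain text (CSV/TSV/JSON) with fixed
names under the run directory, and are byte-identical across reruns with the
same config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imtranscriptomics import build_parcellation, enrich_all, parcel_mean_map, spatial_decode
from .rftcorr import rft_cluster_correct
from .stratify import SUBGROUPS, add_outcome_labels, apply_filters, build_cohort_table
from .surfstats import (
    DesignSpec,
    VertexMetricStack,
    build_icosphere,
    compute_change_stack,
    fit_vertex_glm,
    make_design,
)
from .synthcohort import AtlasSpec, CohortSpec, EffectSpec, generate_cohort, generate_expression_atlas, write_gmt

logger = logging.getLogger("outcomesurf")

__all__ = ["RunConfig", "run_full_pipeline"]

_CONFIG_KEYS = {
    "cohort",
    "effects",
    "atlas",
    "mesh_subdivisions",
    "mesh_radius",
    "features",
    "timepoints",
    "comparisons",
    "dimensional",
    "stratification_basis",
    "mcid",
    "alpha_form",
    "alpha_cluster",
    "n_spins",
    "decode_alpha",
    "n_parcels",
    "medication_covariate",
    "total_brain_covariates",
    "exclude_id",
    "exclude_medicated",
    "age_band",
    "seed",
}


@dataclass
class RunConfig:
    """Serializable configuration of one full analysis run.

    Simulation-driven by default: ``cohort``/``effects``/``atlas`` hold the
    generator specs.  Statistical knobs mirror the analysis defaults
    (cluster-forming and cluster p thresholds both 0.01 two-tailed, MCID 4,
    decoding at 500 spins, q < 0.05).
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: list = field(default_factory=list)
    atlas: AtlasSpec = field(default_factory=lambda: AtlasSpec(
        n_genes=1000,
        n_parcels=200,
        signal_sets=[("planted_signal", 50, 0.8, None)],
        background_sets=[("random_background", 50)],
    ))
    mesh_subdivisions: int = 4
    mesh_radius: float = 100.0
    features: tuple = ("SA", "CT")
    timepoints: tuple = ("T1", "delta", "T2")
    comparisons: tuple = SUBGROUPS
    dimensional: bool = False
    stratification_basis: str = "vabs_standard"
    mcid: float = 4.0
    alpha_form: float = 0.01
    alpha_cluster: float = 0.01
    n_spins: int = 500
    decode_alpha: float = 0.05
    n_parcels: int = 200
    medication_covariate: bool = False
    total_brain_covariates: bool = True
    exclude_id: bool = False
    exclude_medicated: bool = False
    age_band: tuple | None = None
    seed: int = 0

    def to_json(self) -> str:
        doc = asdict(self)
        doc["cohort"] = asdict(self.cohort)
        doc["atlas"] = asdict(self.atlas)
        doc["effects"] = [asdict(e) for e in self.effects]
        return json.dumps(doc, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in doc:
            c = doc["cohort"]
            for k in ("subgroup_sizes", "age_range"):
                if k in c:
                    c[k] = tuple(c[k])
            doc["cohort"] = CohortSpec(**c)
        if "atlas" in doc:
            a = doc["atlas"]
            a["signal_sets"] = [tuple(s) for s in a.get("signal_sets", [])]
            a["background_sets"] = [tuple(s) for s in a.get("background_sets", [])]
            doc["atlas"] = AtlasSpec(**a)
        if "effects" in doc:
            doc["effects"] = [
                EffectSpec(**{**e, "cluster_seed_vertices": tuple(e["cluster_seed_vertices"])})
                for e in doc["effects"]
            ]
        for k in ("features", "timepoints", "comparisons"):
            if k in doc:
                doc[k] = tuple(doc[k])
        if doc.get("age_band") is not None:
            doc["age_band"] = tuple(doc["age_band"])
        return cls(**doc)


def _float_fmt(x) -> str:
    return f"{x:.10g}"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_full_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full analysis under ``out_dir`` and return the path.

    Writes per-contrast t-maps and cluster tables, per-contrast decoding
    tables, one joint enrichment table, the labelled phenotype table, cohort
    summary tables, and a manifest JSON with config, versions, and per-stage
    counts.  Any stage error is re-raised tagged with stage and contrast.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    manifest: dict = {
        "config": json.loads(config.to_json()),
        "versions": {"outcomesurf": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # -- simulate -----------------------------------------------------------
    t0 = stage("simulate")
    mesh = build_icosphere(config.mesh_subdivisions, config.mesh_radius)
    cohort_spec = config.cohort
    if cohort_spec.seed != config.seed:
        from dataclasses import replace

        cohort_spec = replace(cohort_spec, seed=config.seed)
    phenotypes, stacks = generate_cohort(cohort_spec, mesh, config.effects)
    manifest["stages"]["simulate"] = {
        "n_subjects": int(len(phenotypes)),
        "n_vertices": mesh.n_vertices,
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # -- stratify -----------------------------------------------------------
    t0 = stage("stratify")
    basis = config.stratification_basis
    phenotypes = add_outcome_labels(phenotypes, basis=basis, mcid=config.mcid)
    if basis != "vabs_standard":
        phenotypes = add_outcome_labels(phenotypes, basis="vabs_standard", mcid=config.mcid)
    phenotypes = apply_filters(
        phenotypes,
        exclude_id=config.exclude_id,
        exclude_medicated=config.exclude_medicated,
        age_band=config.age_band,
        outcome_column=f"outcome_{basis}",
    )
    filter_log = phenotypes.attrs.get("filter_log", {})
    phenotypes.to_csv(out / "phenotypes.csv", index=False, float_format="%.10g",
                      lineterminator="\n")
    counts = phenotypes[f"outcome_{basis}"].value_counts().to_dict()
    groupings = ["diagnosis"]
    if basis == "vabs_standard" and sum(1 for g in SUBGROUPS if counts.get(g)) >= 2:
        groupings.append("subgroups")
    for grouping in groupings:
        tbl = build_cohort_table(phenotypes, grouping=grouping)
        _write_csv(tbl, out / f"cohort_table_{grouping}.csv")
    manifest["stages"]["stratify"] = {
        "n_autistic": int((phenotypes["diagnosis"] == "autistic").sum()),
        "n_neurotypical": int((phenotypes["diagnosis"] == "neurotypical").sum()),
        "subgroup_counts": {str(k): int(v) for k, v in counts.items()},
        "filter_log": filter_log,
    }

    # align stacks with the (possibly filtered) phenotype rows
    keep_ids = list(phenotypes["subject_id"])
    for key, st in list(stacks.items()):
        pos = [st.subject_ids.index(s) for s in keep_ids]
        stacks[key] = st.subset(np.asarray(pos))
    for feat in config.features:
        stacks[(feat, "delta")] = compute_change_stack(
            stacks[(feat, "T1")], stacks[(feat, "T2")]
        )

    # -- GLM + RFT per contrast --------------------------------------------
    comparisons = list(config.comparisons) + (["dimensional"] if config.dimensional else [])
    contrast_maps: dict[str, np.ndarray] = {}
    cluster_counts: dict[str, int] = {}
    for comp in comparisons:
        for feat in config.features:
            for tp in config.timepoints:
                label = f"{comp}_{feat}_{tp}"
                t0 = stage(f"glm:{label}")
                try:
                    dspec = DesignSpec(
                        feature=feat,
                        analysis=tp,
                        comparison=comp,
                        total_brain=config.total_brain_covariates,
                        medication=config.medication_covariate,
                        outcome_column=f"outcome_{basis}",
                    )
                    X, cvec, rows = make_design(phenotypes, dspec)
                    st = stacks[(feat, tp)].subset(rows)
                    res = fit_vertex_glm(st, X, cvec, label=label)
                    table = rft_cluster_correct(
                        res, mesh,
                        alpha_form=config.alpha_form,
                        alpha_cluster=config.alpha_cluster,
                    )
                except Exception as exc:  # tag failures with stage + contrast
                    raise RuntimeError(f"stage glm/rft failed for contrast {label}") from exc
                np.savetxt(out / f"tmap_{label}.tsv", res.t_map[None], delimiter="\t", fmt="%.10g")
                _write_csv(table.drop(columns=["vertex_ids"]), out / f"clusters_{label}.csv")
                contrast_maps[label] = res.t_map
                cluster_counts[label] = int(table["significant"].sum()) if len(table) else 0
    manifest["stages"]["glm_rft"] = {
        "n_contrasts": len(contrast_maps),
        "significant_clusters": cluster_counts,
        "corrected_across_contrasts": False,
        "corrected_across_features": False,
    }

    # -- decode + enrich ----------------------------------------------------
    t0 = stage("decode")
    parc = build_parcellation(mesh, config.n_parcels, seed=config.seed)
    effect_parcel_maps = {
        label: parcel_mean_map(tmap, parc) for label, tmap in contrast_maps.items()
    }
    atlas_spec = config.atlas
    if atlas_spec.seed != config.seed:
        from dataclasses import replace

        atlas_spec = replace(atlas_spec, seed=config.seed)
    atlas, gene_sets = generate_expression_atlas(
        atlas_spec, parc.centroids, effect_parcel_maps
    )
    atlas.write_tsv(out / "expression_atlas.tsv")
    write_gmt(gene_sets, out / "gene_sets.gmt")
    decoded_by_contrast = {}
    for label, pm in effect_parcel_maps.items():
        dr = spatial_decode(
            pm, atlas, n_spins=config.n_spins, seed=config.seed,
            alpha=config.decode_alpha, contrast=label,
        )
        _write_csv(dr.table, out / f"decoding_{label}.csv")
        decoded_by_contrast[label] = dr.decoded
    enrichment = enrich_all(decoded_by_contrast, gene_sets, atlas.universe)
    _write_csv(enrichment, out / "enrichment.csv")
    manifest["stages"]["decode_enrich"] = {
        "n_genes": atlas_spec.n_genes,
        "n_parcels": atlas_spec.n_parcels,
        "n_decoded": {k: len(v) for k, v in decoded_by_contrast.items()},
        "n_enrichment_tests": int(len(enrichment)),
        "fdr_joint_across_contrasts_and_sets": True,
    }

    manifest["total_seconds"] = round(time.perf_counter() - t_start, 2)
    # wall-clock timings stay out of the determinism-checked outputs
    det = {k: v for k, v in manifest.items() if k != "total_seconds"}
    for st in det["stages"].values():
        st.pop("seconds", None)
    with open(out / "manifest.json", "w") as fh:
        json.dump(det, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete in %.1fs", manifest["total_seconds"])
    return out
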