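"""Seeded synthetic cohorts with the statistical structure of the study design.

Generates, on a shared spherical surface: two-visit phenotypes (demographics,
VABS-II scores with MCID-consistent change, ADOS severity scores), vertex-wise
surface-area and cortical-thickness maps at both visits with planted
subgroup × timepoint effects, and a genes × parcels expression atlas with
planted gene-set/map correlations.  Everything is driven by one integer seed
and reproduces byte-identically.

Outcome labels are generated first; each autistic subject's composite change
score is then drawn from a normal distribution truncated to the label's MCID
interval, so re-classification by the MCID rule recovers the generated label
by construction (as it does, trivially, in the real data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort_reference as ref
from .stratify import SUBGROUPS
from .surfstats import SurfaceMesh, VertexMetricStack, smoothed_noise

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "AtlasSpec",
    "FEATURE_PARAMS",
    "MCID_INTERVALS",
    "generate_phenotypes",
    "generate_cohort",
    "generate_expression_atlas",
    "write_gmt",
    "read_gmt",
]


class SpecError(ValueError):
    """A generator specification is internally inconsistent."""


# MCID intervals per label (closed at the changer boundaries)
MCID_INTERVALS = {
    "Decreaser": (-np.inf, -4.0),
    "No-changer": (-4.0, 4.0),
    "Increaser": (4.0, np.inf),
}

# Per-feature map-generation parameters.  Units: SA mm² per vertex, CT mm.
# baseline/subject/noise magnitudes are set so that subject totals match the
# reference cohort's total-SA and mean-CT distributions; change terms emulate
# slow developmental drift over a ~1.6-year interval.
FEATURE_PARAMS = {
    "SA": dict(
        baseline_total_cm2=2293.4,
        subject_sd=7.8,
        noise_sd=8.0,
        age_slope=-0.10,
        sex_effect=-2.0,
        site_sd=1.5,
        noise_fwhm=20.0,
        change_mean=-1.0,
        change_subject_sd=1.5,
        change_noise_sd=2.5,
    ),
    "CT": dict(
        baseline_mean=2.69,
        subject_sd=0.10,
        noise_sd=0.20,
        age_slope=-0.005,
        sex_effect=0.01,
        site_sd=0.02,
        noise_fwhm=20.0,
        change_mean=-0.03,
        change_subject_sd=0.03,
        change_noise_sd=0.05,
    ),
}


@dataclass
class CohortSpec:
    """Cohort marginals; defaults emulate the reference study sample."""

    n_nt: int = ref.N_NEUROTYPICAL
    subgroup_sizes: tuple[int, int, int] = (
        ref.SUBGROUP_NS["Decreaser"],
        ref.SUBGROUP_NS["No-changer"],
        ref.SUBGROUP_NS["Increaser"],
    )
    age_range: tuple[float, float] = (6.0, 30.0)
    delta_t_mean: float = 1.6
    delta_t_sd: float = 0.3
    vabs_t1_mean: float = ref.VABS_STANDARD_T1[0]
    vabs_t1_sd: float = ref.VABS_STANDARD_T1[1]
    delta_v_params: dict = field(
        default_factory=lambda: dict(ref.DELTA_V_STANDARD)
    )
    fsiq_params: dict = field(default_factory=lambda: dict(ref.FSIQ))
    sex_proportions: dict = field(
        default_factory=lambda: {
            "Decreaser": 25 / 53,
            "No-changer": 6 / 42,
            "Increaser": 19 / 66,
            "neurotypical": 64 / 172,
        }
    )
    n_sites: int = 4
    seed: int = 0
    medication_rate: dict = field(
        default_factory=lambda: {"autistic": 0.30, "neurotypical": 0.02}
    )

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.subgroup_sizes) or self.n_nt < 0:
            raise SpecError("group sizes must be non-negative")
        if not self.delta_t_mean > 0:
            raise SpecError("delta_t_mean must be positive")
        if self.n_sites < 1:
            raise SpecError("need at least one site")
        for label, (mu, sd) in self.delta_v_params.items():
            lo, hi = MCID_INTERVALS[label]
            if not (lo <= mu <= hi):
                raise SpecError(
                    f"delta-V mean {mu} for {label} outside its MCID interval"
                )
            if sd <= 0:
                raise SpecError("delta-V sd must be positive")

    @property
    def n_autistic(self) -> int:
        return int(sum(self.subgroup_sizes))


@dataclass
class EffectSpec:
    """One planted group difference: a geodesic patch on the mesh where the
    named subgroup differs from neurotypicals in one feature at one analysis
    timepoint, with magnitude ``effect_size`` (Cohen's d in within-group SD
    units of that feature's subject + spatial-noise variability).

    T1 effects are added at both visits (a persistent baseline offset, so the
    change maps stay clean); delta and T2 effects are added at the second
    visit only.
    """

    subgroup: str
    feature: str  # "SA" | "CT"
    analysis: str  # "T1" | "delta" | "T2"
    cluster_seed_vertices: tuple[int, ...] = (0,)
    cluster_radius: int = 3  # geodesic hops
    effect_size: float = 1.0
    noise_fwhm: float | None = None  # override of the feature default
    subject_sd: float | None = None
    vertex_noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise SpecError(f"unknown subgroup {self.subgroup!r}")
        if self.feature not in FEATURE_PARAMS:
            raise SpecError(f"unknown feature {self.feature!r}")
        if self.analysis not in ("T1", "delta", "T2"):
            raise SpecError(f"unknown analysis {self.analysis!r}")
        if self.noise_fwhm is not None and not self.noise_fwhm > 0:
            raise SpecError("noise_fwhm must be positive")


@dataclass
class AtlasSpec:
    """Synthetic genes × parcels expression atlas with planted signal sets."""

    n_genes: int = 1000
    n_parcels: int = 200
    # (set name, size, target correlation r, key of the effect map to track)
    signal_sets: list = field(default_factory=list)
    background_sets: list = field(default_factory=list)  # (name, size)
    length_scale_factor: float = 1.5  # GP length scale / mean parcel spacing
    seed: int = 0

    def __post_init__(self) -> None:
        for name, size, r, *_ in self.signal_sets:
            if size > self.n_genes:
                raise SpecError(f"signal set {name} larger than the gene universe")
            if not abs(r) < 1:
                raise SpecError("target correlation must satisfy |r| < 1")
        for name, size in self.background_sets:
            if size > self.n_genes:
                raise SpecError(f"background set {name} larger than the gene universe")
        if self.n_parcels < 3:
            raise SpecError("need at least 3 parcels")


# ---------------------------------------------------------------------------
# phenotypes


def _truncnorm(rng, mu, sd, lo, hi, size):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _exact_count_flags(rng, n: int, fraction: float) -> np.ndarray:
    """Boolean vector with round(fraction·n) True entries, randomly placed."""
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def generate_phenotypes(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per subject with demographics, clinical scores at both visits,
    and the generated outcome label (column ``generated_outcome``)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = []
    labels = [g for g, n in zip(SUBGROUPS, spec.subgroup_sizes) for _ in range(n)]
    groups = [("autistic", labels), ("neurotypical", [None] * spec.n_nt)]
    counter = 0
    for diagnosis, lab in groups:
        n = len(lab)
        lo, hi = spec.age_range
        age_t1 = rng.uniform(lo, hi - spec.delta_t_mean - 3 * spec.delta_t_sd, n)
        delta_t = _truncnorm(rng, spec.delta_t_mean, spec.delta_t_sd, 0.5, np.inf, n)
        mu_iq, sd_iq = spec.fsiq_params[diagnosis]
        fsiq = np.clip(rng.normal(mu_iq, sd_iq, n), 40, 160)
        med = rng.random(n) < spec.medication_rate[diagnosis]
        for i in range(n):
            counter += 1
            rows.append(
                dict(
                    subject_id=f"{'A' if diagnosis == 'autistic' else 'N'}{counter:04d}",
                    diagnosis=diagnosis,
                    generated_outcome=lab[i],
                    age_t1=age_t1[i],
                    delta_t=delta_t[i],
                    age_t2=age_t1[i] + delta_t[i],
                    fsiq=fsiq[i],
                    id_flag=bool(fsiq[i] < 70.0),
                    medication_flag=bool(med[i]),
                )
            )
    df = pd.DataFrame(rows)

    # sex with exact per-group counts
    df["sex"] = "M"
    for key, frac in spec.sex_proportions.items():
        if key == "neurotypical":
            mask = df["diagnosis"] == "neurotypical"
        else:
            mask = df["generated_outcome"] == key
        flags = _exact_count_flags(rng, int(mask.sum()), frac)
        df.loc[mask, "sex"] = np.where(flags, "F", "M")

    # equal site allocation, round-robin within diagnosis
    df["site"] = ""
    for diagnosis in ("autistic", "neurotypical"):
        mask = df["diagnosis"] == diagnosis
        idx = np.flatnonzero(mask)
        df.loc[df.index[idx], "site"] = [f"site{1 + i % spec.n_sites}" for i in range(len(idx))]

    # VABS-II: composite T1, label-consistent truncated change, domain scores
    for col in (
        "vabs_standard_t1", "vabs_standard_t2",
        "vabs_comm_t1", "vabs_comm_t2",
        "vabs_daily_t1", "vabs_daily_t2",
        "vabs_social_t1", "vabs_social_t2",
        "ados_total_css_t1", "ados_total_css_t2",
        "ados_sa_css_t1", "ados_sa_css_t2",
        "ados_rrb_css_t1", "ados_rrb_css_t2",
        "total_sa_t1", "total_sa_t2", "mean_ct_t1", "mean_ct_t2",
    ):
        df[col] = np.nan

    aut = df["diagnosis"] == "autistic"
    n_aut = int(aut.sum())
    t1 = np.clip(rng.normal(spec.vabs_t1_mean, spec.vabs_t1_sd, n_aut), 20, 160)
    df.loc[aut, "vabs_standard_t1"] = t1
    delta_v = np.empty(n_aut)
    lab_arr = df.loc[aut, "generated_outcome"].to_numpy()
    for g in SUBGROUPS:
        m = lab_arr == g
        if not m.any():
            continue
        mu, sd = spec.delta_v_params[g]
        lo_g, hi_g = MCID_INTERVALS[g]
        delta_v[m] = _truncnorm(rng, mu, sd, lo_g, hi_g, int(m.sum()))
    df.loc[aut, "vabs_standard_t2"] = t1 + delta_v

    for dom in ("comm", "daily", "social"):
        d_t1 = np.clip(t1 + rng.normal(0.0, 6.0, n_aut), 20, 160)
        d_delta = np.empty(n_aut)
        for g in SUBGROUPS:
            m = lab_arr == g
            if not m.any():
                continue
            mu, sd = ref.DELTA_V_DOMAINS[dom][g]
            d_delta[m] = rng.normal(mu, sd, int(m.sum()))
        df.loc[aut, f"vabs_{dom}_t1"] = d_t1
        df.loc[aut, f"vabs_{dom}_t2"] = d_t1 + d_delta

    for dom, (mu, sd) in ref.ADOS_CSS_T1.items():
        a_t1 = np.clip(rng.normal(mu, sd, n_aut), 1, 10)
        df.loc[aut, f"ados_{dom}_css_t1"] = a_t1
        df.loc[aut, f"ados_{dom}_css_t2"] = np.clip(
            a_t1 + rng.normal(0.0, 1.5, n_aut), 1, 10
        )
    return df


# ---------------------------------------------------------------------------
# vertex maps


def _feature_params(feature: str, effects: list[EffectSpec]) -> dict:
    p = dict(FEATURE_PARAMS[feature])
    for e in effects:
        if e.feature != feature:
            continue
        for src, dst in (
            ("noise_fwhm", "noise_fwhm"),
            ("subject_sd", "subject_sd"),
            ("vertex_noise_sd", "noise_sd"),
        ):
            v = getattr(e, src)
            if v is not None:
                if p.get(f"_{dst}_overridden") and p[dst] != v:
                    raise SpecError(f"conflicting {dst} overrides for {feature}")
                p[dst] = v
                p[f"_{dst}_overridden"] = True
    return p


def generate_cohort(
    spec: CohortSpec,
    mesh: SurfaceMesh,
    effects: list[EffectSpec] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], VertexMetricStack]]:
    """Full synthetic cohort: phenotypes plus vertex maps.

    Returns (phenotypes, stacks) with stacks keyed by (feature, timepoint) for
    feature in {SA, CT} and timepoint in {T1, T2}.  Per-subject total surface
    area (cm²) and mean cortical thickness (mm) are computed from the maps and
    written into the phenotype table, so downstream covariates are consistent
    with the maps by construction.
    """
    mesh.require_sphere()
    effects = list(effects or [])
    rng = np.random.default_rng(spec.seed)
    ph = generate_phenotypes(spec, rng)
    n = len(ph)
    V = mesh.n_vertices
    stacks: dict[tuple[str, str], VertexMetricStack] = {}

    age_c = ph["age_t1"].to_numpy() - ph["age_t1"].mean()
    is_f = (ph["sex"] == "F").to_numpy(float)
    sites = sorted(ph["site"].unique())
    site_idx = ph["site"].map({s: k for k, s in enumerate(sites)}).to_numpy()
    subject_ids = list(ph["subject_id"])

    for feature in ("SA", "CT"):
        p = _feature_params(feature, effects)
        if feature == "SA":
            base_mean = p["baseline_total_cm2"] * 100.0 / V  # cm² → mm², per vertex
        else:
            base_mean = p["baseline_mean"]
        site_offsets = rng.normal(0.0, p["site_sd"], len(sites))
        subj_int = rng.normal(0.0, p["subject_sd"], n)
        noise_t1 = p["noise_sd"] * smoothed_noise(mesh, n, p["noise_fwhm"], rng)
        t1 = (
            base_mean
            + (p["age_slope"] * age_c + p["sex_effect"] * is_f
               + site_offsets[site_idx] + subj_int)[:, None]
            + noise_t1
        )
        change = (
            p["change_mean"]
            + rng.normal(0.0, p["change_subject_sd"], n)[:, None]
            + p["change_noise_sd"] * smoothed_noise(mesh, n, p["noise_fwhm"], rng)
        )
        t2 = t1 + change

        within_sd_cross = float(np.hypot(p["subject_sd"], p["noise_sd"]))
        within_sd_change = float(np.hypot(p["change_subject_sd"], p["change_noise_sd"]))
        for e in effects:
            if e.feature != feature:
                continue
            patch = mesh.vertex_neighborhood(e.cluster_seed_vertices, e.cluster_radius)
            rows = (ph["generated_outcome"] == e.subgroup).to_numpy()
            sd = within_sd_change if e.analysis == "delta" else within_sd_cross
            amp = e.effect_size * sd
            if e.analysis == "T1":
                t1[np.ix_(rows, patch)] += amp
                t2[np.ix_(rows, patch)] += amp
            else:  # delta or T2: second-visit offset
                t2[np.ix_(rows, patch)] += amp

        stacks[(feature, "T1")] = VertexMetricStack(feature, "T1", t1, subject_ids)
        stacks[(feature, "T2")] = VertexMetricStack(feature, "T2", t2, subject_ids)
        if feature == "SA":
            ph["total_sa_t1"] = t1.sum(axis=1) / 100.0  # mm² → cm²
            ph["total_sa_t2"] = t2.sum(axis=1) / 100.0
        else:
            ph["mean_ct_t1"] = t1.mean(axis=1)
            ph["mean_ct_t2"] = t2.mean(axis=1)
    return ph, stacks


# ---------------------------------------------------------------------------
# expression atlas


def generate_expression_atlas(
    spec: AtlasSpec,
    parcel_centroids: np.ndarray,
    effect_maps: dict[str, np.ndarray] | None = None,
):
    """Synthetic genes × parcels atlas plus gene sets.

    Each signal-set gene's expression map is a mixture
    r·(standardized effect map) + sqrt(1−r²)·(independent smooth map), so its
    correlation with the designated effect map has expectation ≈ r.
    Background genes (and background sets) are smooth Gaussian-process maps on
    the parcel centroids.  Returns (ExpressionAtlas, gene_sets dict).
    """
    from .imtranscriptomics import ExpressionAtlas

    effect_maps = dict(effect_maps or {})
    rng = np.random.default_rng(spec.seed)
    P = spec.n_parcels
    cent = np.asarray(parcel_centroids, dtype=float)
    if cent.shape != (P, 3):
        raise SpecError("parcel centroids must be (n_parcels, 3)")

    # GP covariance over parcel centroids: smooth null maps
    d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=2)
    mean_nn = np.mean(np.sort(d, axis=1)[:, 1])
    ell = spec.length_scale_factor * mean_nn
    K = np.exp(-(d**2) / (2.0 * ell**2)) + 1e-8 * np.eye(P)
    L = np.linalg.cholesky(K)

    def smooth_maps(k: int) -> np.ndarray:
        z = rng.standard_normal((k, P))
        m = z @ L.T
        m -= m.mean(axis=1, keepdims=True)
        m /= m.std(axis=1, keepdims=True)
        return m

    genes = [f"G{k:05d}" for k in range(spec.n_genes)]
    expr = smooth_maps(spec.n_genes)

    gene_sets: dict[str, list[str]] = {}
    used = 0
    for entry in spec.signal_sets:
        name, size, r = entry[0], entry[1], entry[2]
        key = entry[3] if len(entry) > 3 and entry[3] is not None else next(iter(effect_maps), None)
        if key is None or key not in effect_maps:
            raise SpecError(f"signal set {name!r} needs an effect map")
        e = np.asarray(effect_maps[key], dtype=float)
        if e.shape != (P,):
            raise SpecError("effect map length must equal n_parcels")
        if e.std() == 0:
            raise SpecError("effect map is constant")
        e_std = (e - e.mean()) / e.std()
        members = list(range(used, used + size))
        used += size
        if used > spec.n_genes:
            raise SpecError("signal sets exceed the gene universe")
        mix = r * e_std + np.sqrt(1.0 - r**2) * smooth_maps(size)
        mix -= mix.mean(axis=1, keepdims=True)
        mix /= mix.std(axis=1, keepdims=True)
        expr[members] = mix
        gene_sets[name] = [genes[k] for k in members]
    for name, size in spec.background_sets:
        members = rng.choice(spec.n_genes, size=size, replace=False)
        gene_sets[name] = [genes[k] for k in sorted(members)]

    atlas = ExpressionAtlas(
        gene_ids=genes, expression=expr, parcel_centroids=cent
    )
    return atlas, gene_sets


# ---------------------------------------------------------------------------
# plain-text I/O with provenance sidecars


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    """GMT: one set per line — name, description, then member ids."""
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = parts[2:]
    return out


def write_sidecar(path, spec) -> None:
    """JSON sidecar recording the generating spec (including its seed)."""
    doc = asdict(spec)
    doc["spec_type"] = type(spec).__name__
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
        fh.write("\n")
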