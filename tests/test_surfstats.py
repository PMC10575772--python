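"""Mesh construction, smoothing, design matrices, and the vertex-wise GLM."""

import numpy as np
import pandas as pd
import pytest

from outcomesurf import surfstats as ss
from outcomesurf.synthcohort import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# icosphere


@pytest.mark.parametrize("subdiv,n_vertices", [(0, 12), (1, 42), (2, 162), (4, 2562)])
def test_icosphere_vertex_count(subdiv, n_vertices):
    mesh = ss.build_icosphere(subdiv, 100.0)
    assert mesh.n_vertices == n_vertices
    assert mesh.euler_characteristic == 2


def test_icosphere_area_approaches_sphere(mesh_ico3):
    assert mesh_ico3.total_area == pytest.approx(4 * np.pi * 100.0**2, rel=0.01)


def test_icosahedron_face_count():
    mesh = ss.build_icosphere(0, 1.0)
    assert mesh.n_faces == 20
    assert len(mesh.edges) == 30


def test_non_spherical_mesh_rejected():
    # a flat sheet: two triangles, open boundary
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    faces = np.array([[0, 1, 2], [1, 3, 2]])
    mesh = ss.SurfaceMesh(verts, faces)
    with pytest.raises(ss.TopologyError):
        mesh.require_sphere()


# ---------------------------------------------------------------------------
# smoothing


def test_smoothing_zero_fwhm_is_identity(mesh_ico3, rng):
    v = rng.standard_normal(mesh_ico3.n_vertices)
    assert np.array_equal(ss.smooth_vertex_map(mesh_ico3, v, 0.0), v)


def test_smoothing_constant_map_fixed_point(mesh_ico3):
    v = np.full(mesh_ico3.n_vertices, 3.7)
    out = ss.smooth_vertex_map(mesh_ico3, v, 25.0)
    np.testing.assert_allclose(out, v, atol=1e-12)


def test_smoothing_preserves_mean_reduces_variance(mesh_ico3, rng):
    v = rng.standard_normal(mesh_ico3.n_vertices) + 5.0
    out = ss.smooth_vertex_map(mesh_ico3, v, 30.0)
    assert out.mean() == pytest.approx(v.mean(), rel=1e-3)
    assert out.var() < v.var()


def test_smoothing_negative_fwhm_rejected(mesh_ico3):
    with pytest.raises(ValueError):
        ss.smooth_vertex_map(mesh_ico3, np.zeros(mesh_ico3.n_vertices), -1.0)


def test_smoothed_noise_attains_requested_fwhm(mesh_ico4_fine, rng):
    """White noise smoothed to 10 mm measures ~10 mm under the edge-derivative
    smoothness estimator (the calibration target)."""
    from outcomesurf.rftcorr import estimate_smoothness

    noise = ss.smoothed_noise(mesh_ico4_fine, 150, 10.0, rng)
    u = noise / noise.std(axis=0)
    sm = estimate_smoothness(u, mesh_ico4_fine)
    assert 8.5 <= sm.global_fwhm <= 11.5


def test_smoothed_noise_unit_variance(mesh_ico3, rng):
    noise = ss.smoothed_noise(mesh_ico3, 400, 25.0, rng)
    per_vertex_var = noise.var(axis=0)
    assert per_vertex_var.mean() == pytest.approx(1.0, abs=0.02)


# ---------------------------------------------------------------------------
# I/O


def test_mesh_and_stack_writers_round_trip(tmp_path, rng):
    mesh = ss.build_icosphere(1, 50.0)
    mesh.write_ply(tmp_path / "mesh.ply")
    import trimesh

    loaded = trimesh.load(tmp_path / "mesh.ply", process=False)
    np.testing.assert_allclose(np.asarray(loaded.vertices), mesh.vertices, atol=1e-4)

    mesh.write_gifti(tmp_path / "mesh.surf.gii")
    stack = ss.VertexMetricStack(
        "CT", "T1", rng.standard_normal((3, mesh.n_vertices)), ["a", "b", "c"]
    )
    stack.write_tsv(tmp_path / "stack.tsv")
    back = ss.VertexMetricStack.read_tsv(tmp_path / "stack.tsv", "CT", "T1")
    assert back.subject_ids == stack.subject_ids
    np.testing.assert_allclose(back.values, stack.values, atol=1e-12)
    stack.write_gifti(tmp_path / "map.shape.gii", subject=1)
    import nibabel as nib

    img = nib.load(tmp_path / "map.shape.gii")
    np.testing.assert_allclose(img.darrays[0].data, stack.values[1], atol=1e-5)


# ---------------------------------------------------------------------------
# designs


def _toy_phenotypes(n_per=30, seed=0):
    spec = CohortSpec(
        n_nt=n_per,
        subgroup_sizes=(n_per, n_per, n_per),
        seed=seed,
    )
    mesh = ss.build_icosphere(2, 100.0)
    ph, stacks = generate_cohort(spec, mesh)
    from outcomesurf.stratify import add_outcome_labels

    return add_outcome_labels(ph), stacks, mesh


def test_design_sa_t1_has_linear_age_only():
    ph, _, _ = _toy_phenotypes()
    spec = ss.DesignSpec(feature="SA", analysis="T1", comparison="Decreaser")
    X, c, rows = ss.make_design(ph, spec)
    assert "age_t1" in X.columns and "age_t1_sq" not in X.columns
    assert {"intercept", "group", "sex", "fsiq", "total_sa_t1"} <= set(X.columns)
    assert any(col.startswith("site_") for col in X.columns)
    assert c[X.columns.get_loc("group")] == 1 and c.sum() == 1


def test_design_ct_delta_has_quadratic_age_and_interval_terms():
    ph, _, _ = _toy_phenotypes()
    spec = ss.DesignSpec(feature="CT", analysis="delta", comparison="No-changer")
    X, _, _ = ss.make_design(ph, spec)
    assert {"age_t1", "age_t1_sq", "delta_t", "age_t1_x_delta_t"} <= set(X.columns)
    assert "mean_ct_t1" in X.columns  # total-brain covariate matched to CT


def test_design_t2_uses_age_t2():
    ph, _, _ = _toy_phenotypes()
    spec = ss.DesignSpec(feature="SA", analysis="T2", comparison="Increaser")
    X, _, _ = ss.make_design(ph, spec)
    assert "age_t2" in X.columns and "age_t1" not in X.columns


def test_design_total_brain_toggle_removes_one_column():
    ph, _, _ = _toy_phenotypes()
    on = ss.make_design(ph, ss.DesignSpec("SA", "T1", "Decreaser"))[0]
    off = ss.make_design(ph, ss.DesignSpec("SA", "T1", "Decreaser", total_brain=False))[0]
    assert set(on.columns) - set(off.columns) == {"total_sa_t1"}


def test_design_dimensional_uses_continuous_change():
    ph, _, _ = _toy_phenotypes()
    X, c, rows = ss.make_design(ph, ss.DesignSpec("CT", "T1", "dimensional"))
    assert "delta_v" in X.columns and "group" not in X.columns
    assert len(rows) == int((ph["diagnosis"] == "autistic").sum())


def test_rank_deficient_design_reports_columns():
    ph, _, _ = _toy_phenotypes()
    ph = ph.copy()
    ph["fsiq"] = 100.0  # constant, collinear with the intercept
    with pytest.raises(ValueError, match="collinear"):
        ss.make_design(ph, ss.DesignSpec("SA", "T1", "Decreaser"))


# ---------------------------------------------------------------------------
# GLM


def _ols_oracle(X, y, c):
    """Independent normal-equations solution for one response."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * (c @ np.linalg.solve(XtX, c)))
    return c @ beta, (c @ beta) / se


def test_glm_matches_normal_equations_oracle(rng):
    n, p = 23, 4
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    Xdf = pd.DataFrame(X, columns=[f"c{k}" for k in range(p)])
    c = np.array([0.0, 1.0, 0.0, 0.0])
    Y = rng.standard_normal((n, 5))
    stack = ss.VertexMetricStack("CT", "T1", Y, [f"s{i}" for i in range(n)])
    res = ss.fit_vertex_glm(stack, Xdf, c)
    for j in range(Y.shape[1]):
        beta_o, t_o = _ols_oracle(X, Y[:, j], c)
        assert res.beta_map[j] == pytest.approx(beta_o, abs=1e-10)
        assert res.t_map[j] == pytest.approx(t_o, abs=1e-10)


def test_glm_constant_response_gives_zero_group_t(rng):
    n = 40
    X = pd.DataFrame({"intercept": np.ones(n), "group": np.r_[np.zeros(20), np.ones(20)],
                      "cov": rng.standard_normal(n)})
    Y = np.full((n, 7), 2.5) + rng.standard_normal((n, 7)) * 0  # constant across subjects
    Y += np.arange(7)  # vertex-specific constants
    stack = ss.VertexMetricStack("CT", "T1", Y, [])
    res = ss.fit_vertex_glm(stack, X, np.array([0.0, 1.0, 0.0]))
    # zero residual variance: flagged sentinel, effect exactly zero
    assert res.flagged.all()
    assert np.allclose(res.beta_map, 0.0, atol=1e-10)


def test_glm_null_t_variance_matches_student(rng):
    """t-maps under pure noise behave as Student t(df): Var ≈ df/(df−2)."""
    n, V, nsim = 60, 400, 60
    X = pd.DataFrame({"intercept": np.ones(n), "group": np.r_[np.zeros(30), np.ones(30)]})
    c = np.array([0.0, 1.0])
    variances = []
    for _ in range(nsim):
        Y = rng.standard_normal((n, V))
        res = ss.fit_vertex_glm(ss.VertexMetricStack("CT", "T1", Y, []), X, c)
        variances.append(res.t_map.var())
    variances = np.asarray(variances)
    expected = (n - 2) / (n - 4)
    se = variances.std(ddof=1) / np.sqrt(nsim)
    assert abs(variances.mean() - expected) < 3 * se


def test_glm_t_invariant_to_covariate_rescaling(rng):
    n = 50
    cov = rng.standard_normal(n)
    base = dict(intercept=np.ones(n), group=np.r_[np.zeros(25), np.ones(25)])
    X1 = pd.DataFrame({**base, "cov": cov})
    X2 = pd.DataFrame({**base, "cov": cov * 1e4 + 7.0})
    Y = rng.standard_normal((n, 30))
    c = np.array([0.0, 1.0, 0.0])
    t1 = ss.fit_vertex_glm(ss.VertexMetricStack("SA", "T1", Y, []), X1, c).t_map
    t2 = ss.fit_vertex_glm(ss.VertexMetricStack("SA", "T1", Y, []), X2, c).t_map
    np.testing.assert_allclose(t1, t2, atol=1e-8)


def test_glm_two_group_equals_pooled_t(rng):
    from scipy import stats

    n = 44
    X = pd.DataFrame({"intercept": np.ones(n), "group": np.r_[np.zeros(22), np.ones(22)]})
    Y = rng.standard_normal((n, 25))
    res = ss.fit_vertex_glm(ss.VertexMetricStack("CT", "T1", Y, []), X, np.array([0.0, 1.0]))
    t_ref = stats.ttest_ind(Y[22:], Y[:22], equal_var=True).statistic
    np.testing.assert_allclose(res.t_map, t_ref, atol=1e-10)


def test_glm_residuals_orthogonal_to_design(rng):
    n = 30
    X = pd.DataFrame({"intercept": np.ones(n), "x": rng.standard_normal(n)})
    Y = rng.standard_normal((n, 10))
    res = ss.fit_vertex_glm(ss.VertexMetricStack("CT", "T1", Y, []), X, np.array([0.0, 1.0]))
    # standardized residuals stay in the orthogonal complement of the design
    proj = X.to_numpy().T @ res.residuals
    np.testing.assert_allclose(proj, 0.0, atol=1e-8)


# ---------------------------------------------------------------------------
# change stacks


def test_change_stack_trivials():
    ids = ["a", "b"]
    t1 = ss.VertexMetricStack("CT", "T1", np.ones((2, 5)), ids)
    t2 = ss.VertexMetricStack("CT", "T2", np.ones((2, 5)), ids)
    assert np.all(ss.compute_change_stack(t1, t2).values == 0)
    t2b = ss.VertexMetricStack("CT", "T2", np.ones((2, 5)) + 1, ids)
    assert np.all(ss.compute_change_stack(t1, t2b).values == 1)


def test_change_stack_misaligned_ids_rejected():
    t1 = ss.VertexMetricStack("CT", "T1", np.ones((2, 5)), ["a", "b"])
    t2 = ss.VertexMetricStack("CT", "T2", np.ones((2, 5)), ["b", "a"])
    with pytest.raises(ValueError, match="misaligned"):
        ss.compute_change_stack(t1, t2)


def test_planted_change_effect_recovered(mesh_ico3):
    """A planted within-interval change effect appears in the delta maps at
    the planted magnitude (3-SE Monte-Carlo tolerance)."""
    from outcomesurf.synthcohort import EffectSpec, FEATURE_PARAMS

    spec = CohortSpec(n_nt=40, subgroup_sizes=(40, 0, 0), seed=5)
    eff = EffectSpec(
        subgroup="Decreaser", feature="CT", analysis="delta",
        cluster_seed_vertices=(7,), cluster_radius=3, effect_size=1.0,
        noise_fwhm=40.0,
    )
    ph, stacks = generate_cohort(spec, mesh_ico3, [eff])
    delta = ss.compute_change_stack(stacks[("CT", "T1")], stacks[("CT", "T2")])
    patch = mesh_ico3.vertex_neighborhood((7,), 3)
    rows = (ph["generated_outcome"] == "Decreaser").to_numpy()
    inside = delta.values[np.ix_(rows, patch)].mean(axis=1)
    outside_mask = np.ones(mesh_ico3.n_vertices, bool)
    outside_mask[patch] = False
    outside = delta.values[rows][:, outside_mask].mean(axis=1)
    diff = inside - outside
    p = FEATURE_PARAMS["CT"]
    planted = 1.0 * np.hypot(p["change_subject_sd"], p["change_noise_sd"])
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean() - planted) < 3 * se
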