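"""Parcel reduction, spin-test decoding, Fisher enrichment and BH-FDR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import gammaln

from outcomesurf import imtranscriptomics as it
from outcomesurf.synthcohort import AtlasSpec, generate_expression_atlas


@pytest.fixture(scope="module")
def parcels(mesh_ico3):
    return it.build_parcellation(mesh_ico3, 100, seed=0)


@pytest.fixture(scope="module")
def atlas_with_signal(parcels):
    rng = np.random.default_rng(99)
    effect = rng.standard_normal(100)
    spec = AtlasSpec(n_genes=300, n_parcels=100,
                     signal_sets=[("sig", 40, 0.8, "e")], seed=7)
    atlas, sets = generate_expression_atlas(spec, parcels.centroids, {"e": effect})
    return atlas, sets, effect


# ---------------------------------------------------------------------------
# parcellation and parcel means


def test_parcellation_covers_mesh(parcels, mesh_ico3):
    assert len(parcels.labels) == mesh_ico3.n_vertices
    assert set(np.unique(parcels.labels)) == set(range(100))


def test_parcel_mean_constant_map(parcels):
    out = it.parcel_mean_map(np.full(len(parcels.labels), 3.25), parcels)
    np.testing.assert_allclose(out, 3.25)


def test_parcel_mean_one_hot(parcels):
    v = np.zeros(len(parcels.labels))
    v[17] = 1.0
    out = it.parcel_mean_map(v, parcels)
    k = parcels.labels[17]
    size = int((parcels.labels == k).sum())
    assert out[k] == pytest.approx(1.0 / size)
    others = np.delete(out, k)
    np.testing.assert_allclose(others, 0.0)


def test_parcel_mean_linearity(parcels, rng):
    a = rng.standard_normal(len(parcels.labels))
    b = rng.standard_normal(len(parcels.labels))
    np.testing.assert_allclose(
        it.parcel_mean_map(a + b, parcels),
        it.parcel_mean_map(a, parcels) + it.parcel_mean_map(b, parcels),
        atol=1e-12,
    )


# ---------------------------------------------------------------------------
# spin decoding


def test_decode_self_gene_has_r_one_smallest_p(atlas_with_signal):
    atlas, _, _ = atlas_with_signal
    target = atlas.expression[5].copy()
    res = it.spatial_decode(target, atlas, n_spins=120, seed=0)
    row = res.table.iloc[5]
    assert row["r"] == pytest.approx(1.0, abs=1e-9)
    assert row["p_spin"] == min(res.table["p_spin"])


def test_decode_constant_map_rejected(atlas_with_signal):
    atlas, _, _ = atlas_with_signal
    with pytest.raises(ValueError, match="constant"):
        it.spatial_decode(np.ones(atlas.n_parcels), atlas, n_spins=120, seed=0)


def test_decode_equivariant_under_parcel_relabelling(atlas_with_signal):
    """Permuting parcel order consistently in map, atlas, and centroids
    leaves every similarity and p-value unchanged."""
    atlas, _, effect = atlas_with_signal
    res1 = it.spatial_decode(effect, atlas, n_spins=150, seed=3)
    perm = np.random.default_rng(1).permutation(atlas.n_parcels)
    atlas_p = it.ExpressionAtlas(
        gene_ids=list(atlas.gene_ids),
        expression=atlas.expression[:, perm],
        parcel_centroids=atlas.parcel_centroids[perm],
    )
    res2 = it.spatial_decode(effect[perm], atlas_p, n_spins=150, seed=3)
    np.testing.assert_allclose(res1.table["r"], res2.table["r"], atol=1e-12)
    np.testing.assert_allclose(res1.table["p_spin"], res2.table["p_spin"], atol=1e-12)


def test_decode_minimum_spins_enforced(atlas_with_signal):
    atlas, _, effect = atlas_with_signal
    with pytest.raises(ValueError, match="spins"):
        it.spatial_decode(effect, atlas, n_spins=50, seed=0)


def test_decode_recovers_planted_signal_set(atlas_with_signal):
    atlas, sets, effect = atlas_with_signal
    res = it.spatial_decode(effect, atlas, n_spins=300, seed=5)
    hits = set(res.decoded) & set(sets["sig"])
    assert len(hits) >= 0.8 * len(sets["sig"])


# ---------------------------------------------------------------------------
# Fisher enrichment


def _fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration: sum probabilities of all tables
    with the observed margins that are no more probable than the observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_p(x):
        return (
            gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= obs + 1e-10:
            total += np.exp(lp)
    return min(total, 1.0)


def test_fisher_worked_example():
    bg = [f"g{k}" for k in range(1000)]
    decoded = bg[:50]
    gene_set = bg[:10] + bg[50:140]  # a=10, b=40, c=90, d=860
    res = it.fisher_enrichment(decoded, gene_set, bg)
    assert (res["a"], res["b"], res["c"], res["d"]) == (10, 40, 90, 860)
    assert res["odds_ratio"] == pytest.approx((10 * 860) / (40 * 90), rel=1e-12)
    assert res["p"] == pytest.approx(_fisher_two_sided_oracle(10, 40, 90, 860), abs=1e-12)


def test_fisher_matches_enumeration_oracle_small_margins():
    """Implementation equals the exhaustive-table oracle for all 2×2 tables
    with margins ≤ 30."""
    universe = [f"g{k}" for k in range(60)]
    cases = [(a, b, c, d)
             for a, b, c, d in itertools.product((0, 1, 3, 7), (0, 2, 5), (0, 4, 9), (5, 12, 20))
             if (a + b) and (a + c)]
    for a, b, c, d in cases:
        decoded = universe[: a + b]
        gene_set = universe[:a] + universe[a + b: a + b + c]
        bg = universe[: a + b + c + d]
        res = it.fisher_enrichment(decoded, gene_set, bg)
        oracle = _fisher_two_sided_oracle(a, b, c, d)
        assert res["p"] == pytest.approx(oracle, abs=1e-12), (a, b, c, d)


def test_fisher_zero_overlap_gives_zero_or():
    bg = [f"g{k}" for k in range(100)]
    res = it.fisher_enrichment(bg[:10], bg[50:60], bg)
    assert res["odds_ratio"] == 0.0


def test_fisher_decoded_equals_background_uninformative():
    bg = [f"g{k}" for k in range(100)]
    res = it.fisher_enrichment(bg, bg[:20], bg)
    assert res["p"] == pytest.approx(1.0)


def test_fisher_empty_inputs_flagged():
    bg = [f"g{k}" for k in range(50)]
    res = it.fisher_enrichment([], bg[:10], bg)
    assert not res["defined"] and res["p"] == 1.0 and np.isnan(res["odds_ratio"])


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_single_p():
    assert it.bh_fdr([0.037])[0] == pytest.approx(0.037)


def test_bh_worked_step_up():
    """Hand step-up on (0.01, 0.02, 0.03, 0.04): q_(i) = min_{j≥i} p_(j)·4/j
    gives (0.04, 0.04, 0.04, 0.04)."""
    q = it.bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_dominates_p_and_is_monotone(ps):
    q = it.bh_fdr(ps)
    assert np.all(q >= np.asarray(ps) - 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        it.bh_fdr([0.5, 1.2])


# ---------------------------------------------------------------------------
# background restriction and joint enrichment


def test_restrict_background_identity(atlas_with_signal):
    atlas, _, effect = atlas_with_signal
    same = it.restrict_background(atlas, atlas.gene_ids)
    res1 = it.spatial_decode(effect, atlas, n_spins=120, seed=2)
    res2 = it.spatial_decode(effect, same, n_spins=120, seed=2)
    assert res1.decoded == res2.decoded


def test_restrict_background_margins_sum_to_universe(atlas_with_signal):
    atlas, sets, _ = atlas_with_signal
    half = atlas.gene_ids[::2]
    sub = it.restrict_background(atlas, half)
    decoded = atlas.gene_ids[:30]  # includes genes outside the new background
    res = it.fisher_enrichment(decoded, sets["sig"], sub.universe)
    assert res["a"] + res["b"] + res["c"] + res["d"] == len(sub.universe)


def test_restrict_background_empty_rejected(atlas_with_signal):
    atlas, _, _ = atlas_with_signal
    with pytest.raises(ValueError):
        it.restrict_background(atlas, ["not_a_gene"])


def test_enrich_all_joint_fdr(atlas_with_signal):
    atlas, sets, effect = atlas_with_signal
    decoded = {"c1": sets["sig"][:30], "c2": atlas.gene_ids[250:270]}
    table = it.enrich_all(decoded, sets, atlas.universe)
    assert len(table) == len(decoded) * len(sets)
    # joint BH over all pairs: q computed on the pooled p column
    np.testing.assert_allclose(table["q"], it.bh_fdr(table["p"].to_numpy()))
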