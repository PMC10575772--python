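"""Imaging-transcriptomics decoding and gene-set enrichment.

A difference map (vertex-wise contrast t-map) is reduced to parcel means and
correlated with each gene's spatial expression profile from a genes × parcels
atlas.  Significance of each gene's map similarity is assessed with a spin
test — spherical rotations of the parcel centroids build a null that
preserves spatial autocorrelation — and genes passing BH-FDR on the spin
p-values form the decoded list.  Decoded lists are then tested for enrichment
in a-priori gene sets with 2×2 Fisher exact tests (odds ratios), and BH-FDR
is applied jointly across every (contrast, gene set) pair in the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import special_ortho_group
from statsmodels.stats.multitest import multipletests

from .surfstats import SurfaceMesh

__all__ = [
    "Parcellation",
    "ExpressionAtlas",
    "DecodingResult",
    "build_parcellation",
    "parcel_mean_map",
    "spatial_decode",
    "fisher_enrichment",
    "bh_fdr",
    "restrict_background",
    "enrich_all",
]


@dataclass
class Parcellation:
    """Assignment of mesh vertices to parcels, with spherical centroids."""

    labels: np.ndarray  # per-vertex parcel id, 0..P-1
    centroids: np.ndarray  # (P, 3), on the sphere

    @property
    def n_parcels(self) -> int:
        return len(self.centroids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"vertex": np.arange(len(self.labels)), "parcel": self.labels})


def build_parcellation(mesh: SurfaceMesh, n_parcels: int, seed: int = 0) -> Parcellation:
    """Roughly equal-size parcels: farthest-point sampled seeds, then nearest-
    seed (chord distance) assignment, with centroids re-projected to the
    sphere.  Deterministic given the seed."""
    if n_parcels < 1 or n_parcels > mesh.n_vertices:
        raise ValueError("n_parcels out of range")
    rng = np.random.default_rng(seed)
    pts = mesh.vertices
    seeds = [int(rng.integers(mesh.n_vertices))]
    d = np.linalg.norm(pts - pts[seeds[0]], axis=1)
    for _ in range(n_parcels - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    seed_pts = pts[seeds]
    dists = np.linalg.norm(pts[:, None, :] - seed_pts[None, :, :], axis=2)
    labels = np.argmin(dists, axis=1)
    center = pts.mean(axis=0)
    radius = np.linalg.norm(pts - center, axis=1).mean()
    cent = np.vstack([pts[labels == k].mean(axis=0) for k in range(n_parcels)])
    cent = cent - center
    cent = cent / np.linalg.norm(cent, axis=1, keepdims=True) * radius + center
    return Parcellation(labels=labels, centroids=cent)


def parcel_mean_map(values: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Unweighted mean of vertex values per parcel."""
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != len(parcellation.labels):
        raise ValueError("map length does not match parcellation")
    P = parcellation.n_parcels
    counts = np.bincount(parcellation.labels, minlength=P)
    if np.any(counts == 0):
        raise ValueError("parcellation contains empty parcels")
    sums = np.bincount(parcellation.labels, weights=v, minlength=P)
    return sums / counts


@dataclass
class ExpressionAtlas:
    """Genes × parcels expression matrix, rows standardized (mean 0, SD 1)."""

    gene_ids: list
    expression: np.ndarray
    parcel_centroids: np.ndarray
    universe: list = field(default_factory=list)  # background; defaults to all genes

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape[0] != len(self.gene_ids):
            raise ValueError("expression rows must match gene ids")
        mu = self.expression.mean(axis=1, keepdims=True)
        sd = self.expression.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant expression row")
        self.expression = (self.expression - mu) / sd
        if not self.universe:
            self.universe = list(self.gene_ids)

    @property
    def n_parcels(self) -> int:
        return self.expression.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"p{j}" for j in range(self.n_parcels)]
        return pd.DataFrame(self.expression, index=self.gene_ids, columns=cols)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, parcel_centroids) -> "ExpressionAtlas":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), np.asarray(parcel_centroids))


@dataclass
class DecodingResult:
    """Per-gene map similarity with spin-test significance for one contrast."""

    contrast: str
    table: pd.DataFrame  # gene, r, p_spin, q
    decoded: list  # genes with q < alpha
    n_spins: int
    alpha: float


def _spin_permutations(
    centroids: np.ndarray, n_spins: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_spins, P) index arrays: parcel i takes the value of parcel perm[i].

    Each spin applies one uniform random 3-D rotation to the centroids; each
    rotated centroid is matched to the nearest original centroid.  The same
    rotation sequence is shared by every gene, preserving gene–gene
    dependence under the null.
    """
    center = centroids.mean(axis=0)
    c = centroids - center
    perms = np.empty((n_spins, len(c)), dtype=np.int64)
    rots = special_ortho_group.rvs(3, size=n_spins, random_state=rng)
    if n_spins == 1:
        rots = rots[None]
    for s in range(n_spins):
        rotated = c @ rots[s].T
        d = np.linalg.norm(rotated[:, None, :] - c[None, :, :], axis=2)
        perms[s] = np.argmin(d, axis=1)
    return perms


def _corr_rows(map_std: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """Pearson r of a standardized map (or maps) against standardized rows."""
    return map_std @ expr.T / expr.shape[1]


def spatial_decode(
    parcel_map: np.ndarray,
    atlas: ExpressionAtlas,
    n_spins: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    contrast: str = "",
) -> DecodingResult:
    """Correlate a parcel-level map with every gene's expression profile and
    keep genes whose |r| beats the spin-rotation null (BH q < alpha).

    p = (1 + #{|r_null| ≥ |r|}) / (1 + n_spins), two-sided on |r|.
    """
    if n_spins < 100:
        raise ValueError("need at least 100 spins")
    m = np.asarray(parcel_map, dtype=float)
    if m.std() == 0:
        raise ValueError("constant map: correlation undefined")
    if m.shape != (atlas.n_parcels,):
        raise ValueError("map length does not match atlas parcels")
    m_std = (m - m.mean()) / m.std()
    # restrict to the atlas background universe
    pos = {g: k for k, g in enumerate(atlas.gene_ids)}
    uidx = [pos[g] for g in atlas.universe]
    expr = atlas.expression[uidx]
    r_obs = _corr_rows(m_std, expr)

    rng = np.random.default_rng(seed)
    perms = _spin_permutations(atlas.parcel_centroids, n_spins, rng)
    spun = m[perms]
    spun = (spun - spun.mean(axis=1, keepdims=True)) / spun.std(axis=1, keepdims=True)
    r_null = _corr_rows(spun, expr)  # n_spins × genes
    exceed = (np.abs(r_null) >= np.abs(r_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_spins)
    q = bh_fdr(p)
    genes = [atlas.universe[k] for k in range(len(uidx))]
    table = pd.DataFrame({"gene": genes, "r": r_obs, "p_spin": p, "q": q})
    decoded = table.loc[table["q"] < alpha, "gene"].tolist()
    return DecodingResult(
        contrast=contrast, table=table, decoded=decoded, n_spins=n_spins, alpha=alpha
    )


def fisher_enrichment(decoded, gene_set, background) -> dict:
    """2×2 enrichment of a decoded gene list in a gene set over a background.

    a = |decoded ∩ set|, b = |decoded \\ set|, c = |set \\ decoded|,
    d = |background \\ (decoded ∪ set)|.  OR = ad/bc with 0 and +inf
    sentinels; p is the two-sided Fisher exact probability (sum of
    hypergeometric tables no more probable than the observed one).
    """
    bg = set(background)
    dec = set(decoded) & bg  # genes outside the background are ignored
    gs = set(gene_set) & bg
    a = len(dec & gs)
    b = len(dec - gs)
    c = len(gs - dec)
    d = len(bg) - a - b - c
    if len(dec) == 0 or len(gs) == 0:
        return dict(a=a, b=b, c=c, d=d, odds_ratio=float("nan"), p=1.0, defined=False)
    if a == 0:
        oddsr = 0.0
    elif b * c == 0:
        oddsr = float("inf")
    else:
        oddsr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return dict(a=a, b=b, c=c, d=d, odds_ratio=oddsr, p=float(p), defined=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: q_(i) = min_{j≥i} p_(j)·m/j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def restrict_background(atlas: ExpressionAtlas, cortical_expressed) -> ExpressionAtlas:
    """Atlas with the background universe reduced to a gene list (e.g. genes
    expressed in cortical tissue).  Decoding and enrichment margins are then
    computed against the reduced universe."""
    keep = [g for g in atlas.gene_ids if g in set(cortical_expressed)]
    if not keep:
        raise ValueError("restricted background has no genes in the atlas")
    return ExpressionAtlas(
        gene_ids=atlas.gene_ids,
        expression=atlas.expression,
        parcel_centroids=atlas.parcel_centroids,
        universe=keep,
    )


def enrich_all(
    decoded_by_contrast: dict[str, list],
    gene_sets: dict[str, list],
    background,
) -> pd.DataFrame:
    """Fisher enrichment for every (contrast, gene set) pair with BH-FDR
    applied jointly across all pairs (never within a single contrast)."""
    rows = []
    for contrast, decoded in decoded_by_contrast.items():
        for set_name, members in gene_sets.items():
            res = fisher_enrichment(decoded, members, background)
            rows.append(dict(contrast=contrast, gene_set=set_name, **res))
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < 0.05
    return table
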