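"""Surface meshes, mesh-native smoothing, GLM designs and vertex-wise fits.

The analysis operates on scalar fields (surface area per vertex in mm²,
cortical thickness in mm) sampled on a shared closed triangulated surface.
Three cross-sectional/longitudinal designs are supported per cortical
feature: baseline (T1), intra-individual change (delta = T2 − T1), and
follow-up (T2), each comparing one clinical outcome subgroup against the
neurotypical group (or regressing on continuous adaptive change within the
autistic group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

__all__ = [
    "SurfaceMesh",
    "VertexMetricStack",
    "DesignSpec",
    "ContrastResult",
    "build_icosphere",
    "smoothing_iterations",
    "smooth_vertex_map",
    "smoothed_noise",
    "make_design",
    "fit_vertex_glm",
    "compute_change_stack",
]

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM / sigma for a Gaussian


class TopologyError(ValueError):
    """Mesh fails a required topological property."""


@dataclass
class SurfaceMesh:
    """Closed triangulated 2-manifold with cached differential structure.

    vertices : (V, 3) float array, coordinates in mm.
    faces    : (F, 3) int array, counter-clockwise vertex triples.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        # unique undirected edges
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        self.edges = np.unique(e, axis=0)
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        self.edge_lengths = np.linalg.norm(d, axis=1)
        if np.any(self.edge_lengths <= 0):
            raise TopologyError("zero-length edge")
        # per-face area via cross product
        v0, v1, v2 = (self.vertices[self.faces[:, k]] for k in range(3))
        self.face_areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
        if np.any(self.face_areas <= 0):
            raise TopologyError("degenerate face with zero area")
        self.total_area = float(self.face_areas.sum())

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_faces

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric vertex adjacency (binary, no diagonal)."""
        if not hasattr(self, "_adjacency"):
            i, j = self.edges.T
            n = self.n_vertices
            a = sp.coo_matrix(
                (np.ones(2 * len(i)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
            )
            self._adjacency = a.tocsr()
        return self._adjacency

    @property
    def averaging_operator(self) -> sp.csr_matrix:
        """Row-stochastic smoothing step: mean over {vertex} ∪ neighbours."""
        if not hasattr(self, "_avg"):
            a = (self.adjacency + sp.eye(self.n_vertices, format="csr")).tocsr()
            inv_deg = 1.0 / np.asarray(a.sum(axis=1)).ravel()
            self._avg = sp.diags(inv_deg) @ a
        return self._avg

    def require_sphere(self, rel_tol: float = 0.05) -> None:
        """Raise TopologyError unless the mesh is a closed sphere-like surface."""
        if self.euler_characteristic != 2:
            raise TopologyError(
                f"Euler characteristic {self.euler_characteristic} != 2; "
                "mesh is not a closed topological sphere"
            )
        r = np.linalg.norm(self.vertices - self.vertices.mean(axis=0), axis=1)
        if r.std() / r.mean() > rel_tol:
            raise TopologyError("vertices are not approximately equidistant from centroid")

    def vertex_neighborhood(self, seeds, hops: int) -> np.ndarray:
        """Vertex ids within `hops` edge steps of any seed (BFS ball)."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[np.atleast_1d(seeds)] = True
        for _ in range(hops):
            mask = mask | (self.adjacency @ mask.astype(float) > 0)
        return np.flatnonzero(mask)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def write_ply(self, path) -> None:
        """ASCII PLY export."""
        data = trimesh.exchange.ply.export_ply(self.to_trimesh(), encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)

    def write_gifti(self, path) -> None:
        """GIFTI surface export (pointset + triangle arrays)."""
        import nibabel as nib

        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(self.vertices.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(self.faces.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(path))


def build_icosphere(subdivisions: int, radius: float = 100.0) -> SurfaceMesh:
    """Icosahedron subdivided `subdivisions` times, vertices projected onto the
    sphere of the given radius.  V = 10·4ⁿ + 2."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# smoothing


def _edge_variance_fwhm(mesh: SurfaceMesh, fields: np.ndarray) -> float:
    """Global FWHM of unit-standardized fields via the edge-derivative
    estimator (the same measure the cluster-correction stage uses)."""
    u = fields / np.sqrt(np.mean(fields**2, axis=0))
    i, j = mesh.edges.T
    d = (u[:, i] - u[:, j]) / mesh.edge_lengths
    v_edge = np.mean(d * d, axis=0)
    v_face = v_edge[_face_edge_index(mesh)].mean(axis=1)
    resels = float((mesh.face_areas * v_face).sum()) / (4.0 * np.log(2.0))
    return float(np.sqrt(mesh.total_area / resels))


_CALIBRATION_MAPS = 512  # white maps used to measure an operator's FWHM


def operator_fwhm(mesh: SurfaceMesh, k: int, lam: float) -> float:
    """FWHM of the smoothing schedule (k−1 full averaging steps plus one
    fractional step λ), measured on a fixed block of white-noise maps with
    the edge-derivative estimator.  The probe block is seeded, so the
    calibration is deterministic; its sampling error (< 1%) is far below the
    schedule's quantisation."""
    white = np.random.default_rng(1234567).standard_normal(
        (_CALIBRATION_MAPS, mesh.n_vertices)
    )
    out = white.T
    if k >= 1:
        A = mesh.averaging_operator
        for _ in range(k - 1):
            out = A @ out
        out = (1.0 - lam) * out + lam * (A @ out)
    return _edge_variance_fwhm(mesh, out.T)


def _face_edge_index(mesh: SurfaceMesh) -> np.ndarray:
    """(F, 3) indices into mesh.edges for each face's three edges."""
    if not hasattr(mesh, "_face_edge_idx"):
        order = np.lexsort((mesh.edges[:, 1], mesh.edges[:, 0]))  # already sorted rows
        keys = mesh.edges[:, 0].astype(np.int64) * mesh.n_vertices + mesh.edges[:, 1]
        fe = np.empty((mesh.n_faces, 3), dtype=np.int64)
        for k, (a, b) in enumerate(((0, 1), (1, 2), (2, 0))):
            lo = np.minimum(mesh.faces[:, a], mesh.faces[:, b])
            hi = np.maximum(mesh.faces[:, a], mesh.faces[:, b])
            fk = lo.astype(np.int64) * mesh.n_vertices + hi
            fe[:, k] = order[np.searchsorted(keys[order], fk)]
        mesh._face_edge_idx = fe
    return mesh._face_edge_idx


def _smoother_for(mesh: SurfaceMesh, k: int, lam: float) -> sp.csr_matrix:
    """((1−λ)I + λA) · A^(k−1): k−1 full averaging steps plus one fractional."""
    A = mesh.averaging_operator
    M = sp.eye(mesh.n_vertices, format="csr")
    for _ in range(k - 1):
        M = A @ M
    if k >= 1:
        M = ((1.0 - lam) * sp.eye(mesh.n_vertices, format="csr") + lam * A) @ M
    return M.tocsr()


def smoothing_schedule(mesh: SurfaceMesh, fwhm_mm: float) -> tuple[int, float]:
    """Calibrate iterated neighbour-averaging to a requested FWHM.

    Returns (k, λ): k−1 full averaging passes plus one partial pass
    (1−λ)I + λA, chosen so that white noise smoothed with this schedule has
    the requested FWHM under the edge-derivative smoothness estimator (the
    same measure the cluster-correction stage uses).  FWHM below the
    mesh-resolution floor (unsmoothed white noise) returns (0, 0): identity.
    Cached per mesh geometry and FWHM.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return (0, 0.0)
    cache = getattr(mesh, "_fwhm_cache", None)
    if cache is None:
        cache = mesh._fwhm_cache = {}
    key = round(float(fwhm_mm), 6)
    if key in cache:
        return cache[key]
    white = np.random.default_rng(1234567).standard_normal(
        (_CALIBRATION_MAPS, mesh.n_vertices)
    )
    if fwhm_mm <= _edge_variance_fwhm(mesh, white):  # below the lattice floor
        cache[key] = (0, 0.0)
        return cache[key]
    A = mesh.averaging_operator
    base = white.T  # A^(k-1) applied to the probe block, updated in place
    k = 1
    while True:
        stepped = A @ base
        if _edge_variance_fwhm(mesh, stepped.T) >= fwhm_mm:
            break
        base = stepped
        k += 1
        if k > 5000:
            raise ValueError("requested FWHM unreachable")
    lo, hi = 0.0, 1.0
    for _ in range(20):  # bisection on the fractional final step
        mid = 0.5 * (lo + hi)
        blend = (1.0 - mid) * base + mid * stepped
        if _edge_variance_fwhm(mesh, blend.T) < fwhm_mm:
            lo = mid
        else:
            hi = mid
    cache[key] = (k, 0.5 * (lo + hi))
    return cache[key]


def smooth_vertex_map(mesh: SurfaceMesh, values: np.ndarray, fwhm_mm: float) -> np.ndarray:
    """Iterative neighbour-averaging smoothing of one or more vertex maps.

    `values` is (V,) or (n_maps, V).  The map mean is preserved exactly
    (re-centred after averaging) and variance never increases.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    values = np.asarray(values, dtype=float)
    k, lam = smoothing_schedule(mesh, fwhm_mm)
    if k == 0:
        return values.copy()
    M = _smoother_for(mesh, k, lam)
    out = (M @ values.T).T if values.ndim == 2 else M @ values
    # averaging on irregular vertex degrees drifts the mean slightly; restore it
    if out.ndim == 2:
        out = out + (values.mean(axis=1) - out.mean(axis=1))[:, None]
    else:
        out = out + (values.mean() - out.mean())
    return out


def _smoother_row_norms(mesh: SurfaceMesh, k: int, lam: float) -> np.ndarray:
    """Row L2 norms of the smoothing operator (per-vertex SD of smoothed
    white noise); cached per mesh and schedule."""
    cache = getattr(mesh, "_smoother_cache", None)
    if cache is None:
        cache = mesh._smoother_cache = {}
    ck = (k, round(lam, 9))
    if ck not in cache:
        M = _smoother_for(mesh, k, lam)
        cache[ck] = np.sqrt(np.asarray(M.multiply(M).sum(axis=1)).ravel())
    return cache[ck]


def smoothed_noise(
    mesh: SurfaceMesh, n_maps: int, fwhm_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_maps, V) spatially smooth Gaussian fields, unit variance per vertex.

    White noise is averaged iteratively (k−1 full steps plus one fractional
    step, per the calibrated schedule) and rescaled by the operator's row
    norms so every vertex has exactly unit variance.
    """
    white = rng.standard_normal((n_maps, mesh.n_vertices))
    k, lam = smoothing_schedule(mesh, fwhm_mm)
    if k == 0:
        return white
    A = mesh.averaging_operator
    out = white.T  # V × n_maps: sparse matmul on the left
    for _ in range(k - 1):
        out = A @ out
    out = (1.0 - lam) * out + lam * (A @ out)
    norms = _smoother_row_norms(mesh, k, lam)
    return (out / norms[:, None]).T


# ---------------------------------------------------------------------------
# metric stacks


@dataclass
class VertexMetricStack:
    """Subjects × vertices matrix of one cortical feature at one timepoint.

    feature   : "SA" (mm² per vertex) or "CT" (mm).
    timepoint : "T1", "T2" or "delta" (T2 − T1).
    """

    feature: str
    timepoint: str
    values: np.ndarray
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = list(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects × vertices")
        if self.subject_ids and len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def subset(self, row_index: np.ndarray) -> "VertexMetricStack":
        ids = [self.subject_ids[i] for i in row_index] if self.subject_ids else []
        return VertexMetricStack(self.feature, self.timepoint, self.values[row_index], ids)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"v{j}" for j in range(self.n_vertices)]
        return pd.DataFrame(self.values, index=self.subject_ids or None, columns=cols)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "subject_id"
        df.to_csv(path, sep="\t")

    def write_gifti(self, path, subject: int = 0) -> None:
        """One subject's map as a GIFTI functional (shape) file."""
        import nibabel as nib

        arr = nib.gifti.GiftiDataArray(
            self.values[subject].astype(np.float32), intent="NIFTI_INTENT_SHAPE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))

    @classmethod
    def read_tsv(cls, path, feature: str, timepoint: str) -> "VertexMetricStack":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(feature, timepoint, df.to_numpy(), list(df.index))


def compute_change_stack(
    stack_t1: VertexMetricStack, stack_t2: VertexMetricStack
) -> VertexMetricStack:
    """Elementwise T2 − T1 change maps (raw change; interval variation is a
    design covariate, not a divisor)."""
    if stack_t1.subject_ids != stack_t2.subject_ids:
        raise ValueError("subject ids misaligned between timepoints")
    if stack_t1.values.shape != stack_t2.values.shape:
        raise ValueError("stack shapes differ")
    if stack_t1.feature != stack_t2.feature:
        raise ValueError("features differ")
    return VertexMetricStack(
        stack_t1.feature,
        "delta",
        stack_t2.values - stack_t1.values,
        stack_t1.subject_ids,
    )


# ---------------------------------------------------------------------------
# designs


@dataclass
class DesignSpec:
    """One vertex-wise model: a cortical feature, an analysis timepoint, and a
    comparison (one outcome subgroup vs neurotypicals, or continuous adaptive
    change within the autistic group).

    Cortical-thickness designs include quadratic age; surface-area designs do
    not.  The change design additionally covaries follow-up duration and its
    interaction with baseline age.  Total-brain covariates (total SA for SA,
    mean CT for CT) can be toggled off for sensitivity analyses, and a
    medication covariate toggled on.
    """

    feature: str  # "SA" | "CT"
    analysis: str  # "T1" | "delta" | "T2"
    comparison: str  # subgroup name, or "dimensional"
    total_brain: bool = True
    medication: bool = False
    site: bool = True
    outcome_column: str = "outcome_vabs_standard"

    def __post_init__(self) -> None:
        if self.feature not in ("SA", "CT"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.analysis not in ("T1", "delta", "T2"):
            raise ValueError(f"unknown analysis {self.analysis!r}")

    @property
    def label(self) -> str:
        return f"{self.comparison}_{self.feature}_{self.analysis}"


def make_design(
    phenotypes: pd.DataFrame, spec: DesignSpec
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the design matrix and contrast vector for one comparison.

    Returns (design, contrast, row_index) where row_index selects the
    phenotype rows entering the model (subgroup ∪ neurotypicals, or the
    autistic group for the dimensional analysis).  Continuous covariates are
    mean-centred within the model; quadratic age is the square of the centred
    age.  The contrast picks out the group (or continuous change) column.
    """
    ph = phenotypes.reset_index(drop=True)
    if spec.comparison == "dimensional":
        keep = ph["diagnosis"] == "autistic"
    else:
        keep = (ph[spec.outcome_column] == spec.comparison) | (
            ph["diagnosis"] == "neurotypical"
        )
        if not (ph[spec.outcome_column] == spec.comparison).any():
            raise ValueError(f"comparison group {spec.comparison!r} is empty")
    row_index = np.flatnonzero(keep.to_numpy())
    sub = ph.loc[row_index]

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    if spec.comparison == "dimensional":
        cols["delta_v"] = _centered(sub["delta_vabs_standard"])
    else:
        cols["group"] = (sub[spec.outcome_column] == spec.comparison).to_numpy(float)
    cols["sex"] = (sub["sex"] == "F").to_numpy(float)

    age_col = "age_t2" if spec.analysis == "T2" else "age_t1"
    age = _centered(sub[age_col])
    cols[age_col] = age
    if spec.feature == "CT":
        cols[age_col + "_sq"] = age**2
    if spec.analysis == "delta":
        dt = _centered(sub["delta_t"])
        cols["delta_t"] = dt
        cols["age_t1_x_delta_t"] = age * dt
    cols["fsiq"] = _centered(sub["fsiq"])
    if spec.total_brain:
        tb = "total_sa_t1" if spec.feature == "SA" else "mean_ct_t1"
        cols[tb] = _centered(sub[tb])
    if spec.medication:
        if sub["medication_flag"].isna().any():
            raise ValueError("medication covariate requested but values are missing")
        cols["medication"] = sub["medication_flag"].to_numpy(float)
    if spec.site:
        sites = sorted(sub["site"].unique())
        for s in sites[1:]:  # first site is the reference level
            cols[f"site_{s}"] = (sub["site"] == s).to_numpy(float)

    X = pd.DataFrame(cols, index=sub.index)
    _check_rank(X)
    contrast = np.zeros(X.shape[1])
    target = "delta_v" if spec.comparison == "dimensional" else "group"
    contrast[X.columns.get_loc(target)] = 1.0
    return X, contrast, row_index


def _centered(s: pd.Series) -> np.ndarray:
    v = s.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError(f"missing values in design column {s.name!r}")
    return v - v.mean()


def _check_rank(X: pd.DataFrame) -> None:
    m = X.to_numpy()
    rank = np.linalg.matrix_rank(m)
    if rank < m.shape[1]:
        # identify a minimal set of offending columns for the error message
        bad = []
        cols = list(X.columns)
        base: list[int] = []
        for j in range(m.shape[1]):
            trial = base + [j]
            if np.linalg.matrix_rank(m[:, trial]) == len(trial):
                base = trial
            else:
                bad.append(cols[j])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# vertex-wise GLM


@dataclass
class ContrastResult:
    """Per-vertex OLS contrast: t-map, effect map, standardized residuals."""

    t_map: np.ndarray
    beta_map: np.ndarray
    df: int
    residuals: np.ndarray  # subjects × vertices, unit empirical variance per vertex
    design_columns: list
    contrast: np.ndarray
    flagged: np.ndarray  # vertices with zero residual variance
    label: str = ""


def fit_vertex_glm(
    stack: VertexMetricStack, design: pd.DataFrame, contrast: np.ndarray, label: str = ""
) -> ContrastResult:
    """Ordinary least squares at every vertex with a common design.

    t = cᵀβ̂ / sqrt(σ̂² cᵀ(XᵀX)⁻¹c) with σ̂² from the residual sum of squares
    at that vertex.  Residuals are returned standardized to unit empirical
    variance per vertex (for downstream smoothness estimation).  Vertices with
    zero residual variance get t = ±inf and are flagged.
    """
    Y = stack.values
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("stack rows do not align with design rows")
    df = n - p
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    c = np.asarray(contrast, dtype=float)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # p × V
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    cvar = float(c @ xtx_inv @ c)
    effect = c @ beta
    # zero residual variance up to floating-point roundoff on the data scale
    yscale2 = np.max(Y * Y, axis=0) + 1.0
    flagged = sigma2 <= np.finfo(float).eps**2 * yscale2 * 1e6
    se = np.sqrt(np.where(flagged, np.nan, sigma2) * cvar)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = effect / se
    t[flagged] = np.where(effect[flagged] >= 0, np.inf, -np.inf)

    rms = np.sqrt(np.mean(resid**2, axis=0))
    std_resid = np.divide(resid, rms, out=np.zeros_like(resid), where=rms > 0)
    return ContrastResult(
        t_map=t,
        beta_map=effect,
        df=df,
        residuals=std_resid,
        design_columns=list(design.columns),
        contrast=c,
        flagged=flagged,
        label=label,
    )
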