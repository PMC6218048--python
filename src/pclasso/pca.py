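"""Voxel-wise PCA of subject-by-voxel binding-ratio matrices.

Every template voxel in the ROI is a variable and every subject an
observation.  The decomposition of the centered data is

    f_n = mean + sum_k s_nk * w_k

with orthonormal voxel-weight loadings w_k (rows of ``loadings``), subject
scores s_nk, and components ranked by variance accounted for (VAF, percent of
total centered variance).  Covariance PCA (mean removal, no variance scaling)
is used deliberately: voxels are commensurate BR values and the first
component of striatal BR data is a weighted mean, which per-voxel variance
scaling would destroy.

Sign convention: PCA leaves the loading signs free, so loadings are
canonicalized to a nonnegative weight sum (ties broken by making the
largest-magnitude weight positive), with score columns flipped accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .clinical import ClinicalTable
from .errors import DegenerateInputError, ValidationError
from .imaging import VoxelMatrix


@dataclass
class PCDecomposition:
    """PCA result over one ROI / side: mean, loadings, scores, VAF."""

    mean_vector: np.ndarray  # (V,)
    loadings: np.ndarray  # (K, V), row-orthonormal
    scores: np.ndarray  # (N, K)
    vaf: np.ndarray  # (K,) percentages, nonincreasing
    voxel_index: np.ndarray  # (V, 3)
    roi_label: int | None = None
    side: str | None = None
    subject_ids: tuple[str, ...] | None = None
    provenance: dict | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.loadings.shape[1]


def fit_pca(voxel_matrix: VoxelMatrix, n_components: int | None = None) -> PCDecomposition:
    """Covariance PCA of a subject-by-voxel matrix via SVD of the centered data.

    ``K = min(N-1, V)`` components are kept by default (full rank of the
    centered matrix), so the reconstruction ``mean + scores @ loadings``
    reproduces the input exactly.  ``VAF_k = 100 * sigma_k^2 / sum sigma^2``.
    """
    X = voxel_matrix.data
    n, v = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise ValidationError("voxel matrix contains non-finite values")

    mean_vector = X.mean(axis=0)
    centered = X - mean_vector
    total_var = float(np.sum(centered**2))
    if total_var <= 1e-12 * max(1.0, float(np.sum(X**2))):
        raise DegenerateInputError("voxel matrix has (numerically) zero variance")

    k_full = min(n - 1, v)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = k_full if n_components is None else min(int(n_components), k_full)
    loadings = vt[:k]
    scores = u[:, :k] * s[:k]
    vaf = 100.0 * s[:k] ** 2 / np.sum(s**2)

    decomp = PCDecomposition(
        mean_vector=mean_vector,
        loadings=loadings,
        scores=scores,
        vaf=vaf,
        voxel_index=voxel_matrix.voxel_index,
        roi_label=voxel_matrix.roi_label,
        side=voxel_matrix.side,
        subject_ids=voxel_matrix.subject_ids,
    )
    return canonical_sign(decomp)


def canonical_sign(decomposition: PCDecomposition) -> PCDecomposition:
    """Flip loadings (with their score columns) to the canonical sign.

    Each loading is flipped so its weight sum is >= 0; when the sum is zero
    (a balanced gradient), the largest-magnitude weight is made positive.
    The reconstruction is unchanged.
    """
    loadings = decomposition.loadings.copy()
    scores = decomposition.scores.copy()
    for k in range(loadings.shape[0]):
        wsum = float(loadings[k].sum())
        if abs(wsum) < 1e-12 * loadings.shape[1]:
            pivot = int(np.argmax(np.abs(loadings[k])))
            flip = loadings[k, pivot] < 0
        else:
            flip = wsum < 0
        if flip:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return replace(decomposition, loadings=loadings, scores=scores)


def project(decomposition: PCDecomposition, voxel_matrix: VoxelMatrix) -> np.ndarray:
    """Scores of (possibly new) subjects: ``(data - mean) @ loadings.T``."""
    if not np.array_equal(decomposition.voxel_index, voxel_matrix.voxel_index):
        raise ValidationError("voxel_index mismatch between decomposition and matrix")
    return (voxel_matrix.data - decomposition.mean_vector) @ decomposition.loadings.T


def compare_loadings(
    decomp_a: PCDecomposition, decomp_b: PCDecomposition, top_k: int = 5
) -> np.ndarray:
    """Absolute-cosine similarity matrix between the top-k loadings of two PCAs.

    Entry (a, b) = |cos(w_a^A, w_b^B)|; sign-invariant by construction, so
    equivalent loadings with inverted signs compare as identical.
    """
    if not np.array_equal(decomp_a.voxel_index, decomp_b.voxel_index):
        raise ValidationError("voxel_index mismatch between decompositions")
    ka = min(top_k, decomp_a.n_components)
    kb = min(top_k, decomp_b.n_components)
    a = decomp_a.loadings[:ka]
    b = decomp_b.loadings[:kb]
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    return np.abs((a / na) @ (b / nb).T)


@dataclass(frozen=True)
class SubgroupSpec:
    """Filter defining a subject subgroup for a stratified PCA.

    DD bounds apply to PD subjects; ``include_hc`` adds the healthy controls;
    ``exclude_agonist_on`` drops subjects on agonist therapy (relevant for the
    postsynaptic tracer, whose binding agonists alter).
    """

    name: str
    dd_min: float | None = None
    dd_max: float | None = None
    include_hc: bool = False
    exclude_agonist_on: bool = False

    def select(self, table: ClinicalTable) -> np.ndarray:
        df = table.df
        is_pd = (df["group"] == "PD").to_numpy()
        keep = is_pd.copy()
        if self.dd_min is not None:
            keep &= df["DD"].to_numpy() >= self.dd_min
        if self.dd_max is not None:
            keep &= df["DD"].to_numpy() <= self.dd_max
        if self.include_hc:
            keep |= ~is_pd
        if self.exclude_agonist_on and "agonist_status" in df.columns:
            keep &= (df["agonist_status"] != "ON").to_numpy()
        return keep


#: Disease-stage presets: mixed HC plus PD with DD <= 2 years, early PD
#: (DD <= 3), moderate PD (DD >= 4).
PRESET_SUBGROUPS: tuple[SubgroupSpec, ...] = (
    SubgroupSpec(name="mixed_hc_pd", dd_max=2.0, include_hc=True),
    SubgroupSpec(name="early_pd", dd_max=3.0),
    SubgroupSpec(name="moderate_pd", dd_min=4.0),
)


def run_subgroup_pca(
    voxel_matrix: VoxelMatrix,
    clinical_table: ClinicalTable,
    subgroups: Sequence[SubgroupSpec] = PRESET_SUBGROUPS,
) -> Mapping[str, PCDecomposition]:
    """One PCA per subgroup, with the filter and subject count in provenance.

    Rows of the voxel matrix are matched to clinical rows by subject id.
    """
    table_ids = [str(s) for s in clinical_table.subject_ids]
    matrix_ids = [str(s) for s in voxel_matrix.subject_ids]
    missing = set(matrix_ids) - set(table_ids)
    if missing:
        raise ValidationError(f"no clinical rows for subjects: {sorted(missing)[:5]}")
    row_of = {sid: i for i, sid in enumerate(table_ids)}

    results: dict[str, PCDecomposition] = {}
    for sg in subgroups:
        keep_table = sg.select(clinical_table)
        keep_rows = [i for i, sid in enumerate(matrix_ids) if keep_table[row_of[sid]]]
        if len(keep_rows) < 2:
            raise ValidationError(
                f"subgroup {sg.name!r} selects {len(keep_rows)} subjects (< 2)"
            )
        sub = voxel_matrix.subset(keep_rows)
        decomp = fit_pca(sub)
        decomp.provenance = {
            "subgroup": sg.name,
            "n": len(keep_rows),
            "filter": {
                "dd_min": sg.dd_min,
                "dd_max": sg.dd_max,
                "include_hc": sg.include_hc,
                "exclude_agonist_on": sg.exclude_agonist_on,
            },
        }
        results[sg.name] = decomp
    return results
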