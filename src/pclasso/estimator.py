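"""Voxel-space estimators: back-transform fitted score models into weight maps.

Because PCA and the LASSO fit are both linear, a fitted score-space model

    y = b0 + sum_j s_j * b_j          (s_j the subject's j-th PC score)

can be rewritten over voxels.  With s_j = (f - mean) . w_j this becomes

    y = b0' + (f - mean) . v,     v = sum_j b_j * w_j

so ``v`` is a single voxel-weight map — the PC-LASSO estimator — whose inner
product with a subject's (centered) image predicts the clinical metric.
Unlike PC loadings, whose sign PCA leaves free, the sign of ``v`` is fixed by
the fit.  Coefficients fitted on z-scored scores are mapped back to the raw
score scale (b_j / sd_j, with the means folded into the intercept), so the
score-space and voxel-space predictions agree exactly.  Covariate
coefficients have no voxel support and are carried beside the map, never
folded into it.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, ValidationError
from .lasso import LassoModel
from .pca import PCDecomposition

AXIS_OF = {"LM": 0, "AP": 1, "IS": 2}


def pc_name(k: int) -> str:
    """Canonical design-column name of the k-th component score (1-based)."""
    return f"PC{k}"


_PC_RE = re.compile(r"^PC(\d+)$")


@dataclass
class EstimatorMap:
    """A voxel-weight estimator ``v`` plus the non-imaging parts of the model."""

    v: np.ndarray  # (V,) voxel weights over the ROI
    beta0: float  # intercept of the centered voxel-space form
    mean_vector: np.ndarray  # (V,) per-voxel mean of the source decomposition
    covariate_betas: dict[str, float]  # raw-scale coefficients of non-imaging inputs
    voxel_index: np.ndarray  # (V, 3)
    provenance: dict | None = None


def compute_estimator(
    decomposition: PCDecomposition, lasso_model: LassoModel
) -> EstimatorMap:
    """Assemble ``v = sum_j b_j w_j`` from a fit over PC scores (+ covariates).

    Imaging inputs are recognized by the ``PC<k>`` naming convention and must
    have a loading in the decomposition.  Coefficients are mapped from the
    standardized-score scale back to the raw-score scale using the model's
    standardization record before the loadings are combined.
    """
    names = lasso_model.names
    rec = lasso_model.record
    mus = rec.means if rec is not None else np.zeros(len(names))
    sds = rec.sds if rec is not None else np.ones(len(names))
    if rec is not None and tuple(rec.names) != tuple(names):
        raise ValidationError("standardization record does not match model inputs")

    v = np.zeros(decomposition.n_voxels)
    covariate_betas: dict[str, float] = {}
    beta0 = lasso_model.beta0
    for name, b, mu, sd in zip(names, lasso_model.betas, mus, sds):
        b_raw = b / sd
        beta0 -= b * mu / sd
        m = _PC_RE.match(name)
        if m:
            k = int(m.group(1))
            if b != 0.0 and k > decomposition.n_components:
                raise ValidationError(
                    f"model retains {name} but the decomposition has only "
                    f"{decomposition.n_components} components"
                )
            if k <= decomposition.n_components:
                v += b_raw * decomposition.loadings[k - 1]
        else:
            covariate_betas[name] = float(b_raw)

    return EstimatorMap(
        v=v,
        beta0=float(beta0),
        mean_vector=decomposition.mean_vector,
        covariate_betas=covariate_betas,
        voxel_index=decomposition.voxel_index,
        provenance={
            "lambda": lasso_model.lambda_,
            "retained_terms": list(lasso_model.active_set),
            "roi_label": decomposition.roi_label,
            "side": decomposition.side,
        },
    )


def predict_from_voxels(
    estimator_map: EstimatorMap,
    voxel_vector: np.ndarray,
    covariates: dict[str, float] | None = None,
) -> float:
    """Predict the clinical metric from a raw ROI voxel vector.

    ``prediction = b0 + (f - mean) . v + sum_c beta_c * covariate_c``; equals
    the score-space prediction of the source model for every subject.
    """
    f = np.asarray(voxel_vector, dtype=float).ravel()
    if f.shape[0] != estimator_map.v.shape[0]:
        raise ValidationError(
            f"voxel vector length {f.shape[0]} does not match the estimator "
            f"({estimator_map.v.shape[0]} voxels)"
        )
    pred = estimator_map.beta0 + float((f - estimator_map.mean_vector) @ estimator_map.v)
    for name, beta in estimator_map.covariate_betas.items():
        if beta == 0.0:
            continue
        if covariates is None or name not in covariates:
            raise ValidationError(f"prediction requires covariate {name!r}")
        pred += beta * float(covariates[name])
    return pred


def embed_map(
    weights: np.ndarray, voxel_index: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Scatter an ROI weight vector back into the full template grid."""
    w = np.asarray(weights, dtype=float).ravel()
    idx = np.asarray(voxel_index, dtype=int)
    if idx.shape != (w.shape[0], 3):
        raise ShapeError("voxel_index must be (V, 3) matching the weights")
    vol = np.zeros(grid_shape)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = w
    return vol


@dataclass
class MIPPair:
    """Maximum-intensity projections of a signed weight map.

    Positive weights and magnitudes of negative weights are projected
    separately along the chosen axis; both are normalized by the global
    maximum absolute weight (``scale``), so intensities are comparable
    between the two panels.
    """

    positive: np.ndarray
    negative: np.ndarray
    axis: int
    scale: float


def mip_render(weight_map: np.ndarray, projection_axis: int | str) -> MIPPair:
    """Project a 3-D signed weight map to a (positive, negative) MIP pair."""
    vol = np.asarray(weight_map, dtype=float)
    if vol.ndim != 3:
        raise ShapeError("weight map must be a 3-D volume (see embed_map)")
    axis = AXIS_OF[projection_axis] if isinstance(projection_axis, str) else int(projection_axis)
    if axis not in (0, 1, 2):
        raise ValidationError(f"projection axis must be 0, 1 or 2 (LM/AP/IS), got {axis}")

    pos = np.clip(vol, 0.0, None).max(axis=axis)
    neg = np.clip(-vol, 0.0, None).max(axis=axis)
    scale = float(np.max(np.abs(vol)))
    if scale == 0.0:
        warnings.warn("all-zero weight map; projections are zero", stacklevel=2)
        return MIPPair(positive=pos, negative=neg, axis=axis, scale=0.0)
    return MIPPair(positive=pos / scale, negative=neg / scale, axis=axis, scale=scale)
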