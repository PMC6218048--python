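"""Synthetic striatal phantom: template, planted covariance patterns, cohorts.

The phantom emulates cohorts of striatal binding-ratio (BR) images in a common
labeled template space with a *known* low-rank spatial covariance structure,
so every downstream stage (voxel matrix extraction, PCA, LASSO, estimator
back-projection) can be tested against planted ground truth:

* a labeled template with two disjoint ellipsoidal ROIs — a "putamen"
  elongated along the anteroposterior (AP) axis and a "caudate + ventral
  striatum" elongated along the inferosuperior (IS) axis;
* an orthonormal basis of planted voxel-weight patterns over one ROI: a
  global all-positive pattern (the empirical first principal component of
  striatal BR data is a weighted mean) plus directional gradient patterns;
* per-subject pattern scores coupled linearly to adjusted disease duration
  (aDD), a lateralized motor score coupled to selected pattern scores, and a
  hemispheric asymmetry offset making worse-side images look like more
  progressed better-side images;
* iid Gaussian voxel noise, clipped at zero because BR is a nonnegative ratio.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clinical
from .clinical import ADDParams, ClinicalTable, compute_add, item_column
from .errors import ConfigurationError, ShapeError, ValidationError
from .imaging import ParametricImage

PUTAMEN, CAUDATE = 1, 2
ROI_NAMES = {PUTAMEN: "putamen", CAUDATE: "caudate"}
AXIS_NAMES = ("LM", "AP", "IS")  # lateromedial, anteroposterior, inferosuperior

PATTERN_KINDS = (
    "global_positive",
    "ap_gradient",
    "is_gradient",
    "vd_gradient",
    "noise_pattern",
)


@dataclass(frozen=True)
class LabeledTemplate:
    """Labeled common-space grid: 0 = background, 1 = putamen, 2 = caudate+VS.

    Axis convention: axis 0 = LM, axis 1 = AP (increasing index = anterior),
    axis 2 = IS (increasing index = superior).  Left and right hemispheres are
    mirror copies, so a single template serves both sides.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ShapeError("template labels must be a 3-D array")
        extra = set(np.unique(labels)) - {0, PUTAMEN, CAUDATE}
        if extra:
            raise ValidationError(f"unexpected label values: {sorted(extra)}")
        for roi in (PUTAMEN, CAUDATE):
            if not (labels == roi).any():
                raise ValidationError(f"ROI label {roi} ({ROI_NAMES[roi]}) is empty")
        object.__setattr__(self, "labels", labels.astype(np.int16))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    def roi_mask(self, roi_label: int) -> np.ndarray:
        if roi_label not in ROI_NAMES:
            raise ValidationError(f"unknown ROI label {roi_label}")
        return self.labels == roi_label

    def roi_indices(self, roi_label: int) -> np.ndarray:
        """(V, 3) voxel coordinates of one ROI in lexicographic (i,j,k) order."""
        return np.argwhere(self.roi_mask(roi_label))

    def roi_size(self, roi_label: int) -> int:
        return int(self.roi_mask(roi_label).sum())


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid: voxel center and semi-axes, in voxel units."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


#: Default ROI geometry on a 32x48x32 grid: putamen elongated along AP,
#: caudate along IS, separated along the LM axis.
DEFAULT_ROI_GEOMETRY: Mapping[int, EllipsoidSpec] = {
    PUTAMEN: EllipsoidSpec(center=(9.0, 24.0, 14.0), semi_axes=(5.0, 14.0, 7.0)),
    CAUDATE: EllipsoidSpec(center=(22.0, 26.0, 17.0), semi_axes=(5.0, 7.0, 10.0)),
}

DEFAULT_GRID_SHAPE = (32, 48, 32)


def make_template(
    grid_shape: Sequence[int] = DEFAULT_GRID_SHAPE,
    roi_geometry: Mapping[int, EllipsoidSpec] = DEFAULT_ROI_GEOMETRY,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabeledTemplate:
    """Build a labeled template with two disjoint ellipsoidal ROIs.

    Deterministic for fixed inputs.  Raises :class:`ConfigurationError` if the
    ellipsoids overlap, leave the grid, or share a center.
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ConfigurationError(f"grid_shape must be 3 integers >= 8, got {shape}")
    if set(roi_geometry) != {PUTAMEN, CAUDATE}:
        raise ConfigurationError("roi_geometry must define labels 1 (putamen) and 2 (caudate)")
    if tuple(roi_geometry[PUTAMEN].center) == tuple(roi_geometry[CAUDATE].center):
        raise ConfigurationError("ROI ellipsoid centers coincide")

    grids = np.indices(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int16)
    for roi, spec in sorted(roi_geometry.items()):
        c = np.asarray(spec.center, dtype=float)
        a = np.asarray(spec.semi_axes, dtype=float)
        if np.any(a <= 0):
            raise ConfigurationError(f"semi-axes must be positive for ROI {roi}")
        if np.any(c - a < 0) or np.any(c + a > np.asarray(shape) - 1):
            raise ConfigurationError(
                f"ROI {roi} ellipsoid extends outside the grid {shape}"
            )
        dist2 = sum(((grids[d] - c[d]) / a[d]) ** 2 for d in range(3))
        mask = dist2 <= 1.0
        if not mask.any():
            raise ConfigurationError(f"ROI {roi} ellipsoid contains no voxels")
        if (labels[mask] != 0).any():
            raise ConfigurationError("ROI ellipsoids overlap")
        labels[mask] = roi
    return LabeledTemplate(labels=labels, voxel_size=voxel_size)


@dataclass(frozen=True)
class PlantedBasis:
    """Orthonormal planted voxel-weight patterns over one ROI.

    ``patterns`` is (K, V) over the ROI's lexicographically ordered voxels;
    ``mean_level`` is the baseline BR added to every ROI voxel.
    """

    patterns: np.ndarray
    kinds: tuple[str, ...]
    roi_label: int
    voxel_index: np.ndarray
    mean_level: float = 2.0

    def __post_init__(self) -> None:
        p = np.asarray(self.patterns, dtype=float)
        if p.ndim != 2 or p.shape[0] != len(self.kinds):
            raise ShapeError("patterns must be (K, V) with one kind per pattern")
        gram = p @ p.T
        if not np.allclose(gram, np.eye(p.shape[0]), atol=1e-10):
            raise ValidationError("planted patterns are not orthonormal")
        object.__setattr__(self, "patterns", p)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]


def _raw_pattern(kind: str, coords: np.ndarray, position: int) -> np.ndarray:
    """Un-normalized pattern of one kind over ROI voxel coordinates."""
    if kind == "global_positive":
        return np.ones(len(coords))
    if kind == "ap_gradient":
        ramp = coords[:, 1].astype(float)
    elif kind == "is_gradient":
        ramp = coords[:, 2].astype(float)
    elif kind == "vd_gradient":
        # ventral->dorsal runs along the posterior-inferior to anterior-superior
        # diagonal in this template; distinct from the pure AP and IS ramps
        ramp = (coords[:, 1] + coords[:, 2]).astype(float)
    elif kind == "noise_pattern":
        # deterministic pseudo-random texture; seeded by position for stability
        rng = np.random.default_rng(777_000 + position)
        return rng.standard_normal(len(coords))
    else:
        raise ConfigurationError(f"unknown pattern kind {kind!r}")
    return ramp - ramp.mean()


def make_planted_basis(
    template: LabeledTemplate,
    roi_label: int,
    kinds: Sequence[str],
    mean_level: float = 2.0,
) -> PlantedBasis:
    """Construct orthonormal planted patterns over one ROI.

    Raw patterns (a positive constant; mean-centered linear ramps along the
    named axes; deterministic noise textures) are Gram-Schmidt
    orthonormalized in the order given, with the global pattern first so it
    stays all-positive.
    """
    kinds = tuple(kinds)
    if not kinds:
        raise ConfigurationError("at least one pattern kind is required")
    for k in kinds:
        if k not in PATTERN_KINDS:
            raise ConfigurationError(f"unknown pattern kind {k!r}")
    if "global_positive" in kinds and kinds[0] != "global_positive":
        raise ConfigurationError("global_positive must be the first pattern kind")

    coords = template.roi_indices(roi_label)
    patterns = []
    for pos, kind in enumerate(kinds):
        raw = _raw_pattern(kind, coords, pos)
        for prev in patterns:
            raw = raw - (raw @ prev) * prev
        norm = np.linalg.norm(raw)
        if norm < 1e-8:
            raise ConfigurationError(
                f"pattern kind {kind!r} is linearly dependent on earlier patterns"
            )
        patterns.append(raw / norm)
    return PlantedBasis(
        patterns=np.vstack(patterns),
        kinds=kinds,
        roi_label=int(roi_label),
        voxel_index=coords,
        mean_level=float(mean_level),
    )


@dataclass(frozen=True)
class ScoreCoupling:
    """Linear coupling of one pattern score to aDD: score = intercept + slope*aDD + noise."""

    intercept: float = 0.0
    slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("score noise SD must be nonnegative")


@dataclass(frozen=True)
class LmsModel:
    """Coupling of the lateral motor score to pattern scores."""

    intercept: float = 4.0
    coefs: tuple[float, ...] = ()
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("LMS noise SD must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a phantom cohort.

    ``score_model`` has one :class:`ScoreCoupling` per planted pattern;
    ``asymmetry_offset`` is added to every worse-side pattern score, so
    worse-side images are "more progressed" copies of the better side;
    ``noise_sigma`` is the iid voxel noise SD in BR units.
    """

    n_subjects: int = 40
    dd_range: tuple[float, float] = (0.0, 16.0)
    score_model: tuple[ScoreCoupling, ...] = ()
    lms_model: LmsModel = field(default_factory=LmsModel)
    asymmetry_offset: float = 0.0
    noise_sigma: float = 0.1
    seed: int = 0
    add_params: ADDParams = field(default_factory=ADDParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        lo, hi = self.dd_range
        if lo < 0 or hi < lo:
            raise ValidationError("dd_range must be nonnegative and ordered")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be nonnegative")


def default_cohort_spec(n_patterns: int = 4, seed: int = 0, **overrides) -> CohortSpec:
    """Study-condition defaults for a phantom cohort.

    40 subjects (the size of the cross-validated fits), DD uniform on 0–16
    years, voxel noise 0.1 BR units (5% of the 2.0 baseline).  Disease
    progression expresses through the global pattern: its score decreases
    with aDD (binding loss, slope −1.5 from a positive baseline).  The other
    pattern scores are independent with well-separated variances (SD 4.0,
    2.4, then 1.2) — PCA expressions are uncorrelated by construction, and
    uncorrelated scores with distinct variances are what makes the planted
    basis identifiable at this sample size.  The lateral motor score is
    generated from patterns 1 and 3 (coefficients −0.25 and +0.4, noise SD
    0.2), and the worse side leads the better side by 1.5 score units.
    """
    couplings = []
    for k in range(n_patterns):
        if k == 0:
            couplings.append(ScoreCoupling(intercept=30.0, slope=-1.5, noise_sd=1.0))
        elif k == 1:
            couplings.append(ScoreCoupling(intercept=0.0, slope=0.0, noise_sd=4.0))
        elif k == 2:
            couplings.append(ScoreCoupling(intercept=0.0, slope=0.0, noise_sd=2.4))
        else:
            couplings.append(ScoreCoupling(intercept=0.0, slope=0.0, noise_sd=1.2))
    coefs = tuple(
        -0.25 if k == 0 else (0.4 if k == 2 else 0.0) for k in range(n_patterns)
    )
    base = dict(
        n_subjects=40,
        dd_range=(0.0, 16.0),
        score_model=tuple(couplings),
        lms_model=LmsModel(intercept=11.0, coefs=coefs, noise_sd=0.2),
        asymmetry_offset=1.5,
        noise_sigma=0.1,
        seed=seed,
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass(frozen=True)
class TrueScores:
    """Ground-truth generative quantities for a phantom cohort."""

    better: np.ndarray  # (N, K) pattern scores, better hemisphere
    worse: np.ndarray  # (N, K) pattern scores, worse hemisphere
    lms_better: np.ndarray  # continuous latent LMS, better body side
    lms_worse: np.ndarray
    add: np.ndarray  # aDD per subject


def _items_from_lms(lms_int: int) -> list[int]:
    """Decompose an integer LMS in [0, 28] into seven items in 0..4."""
    base, rem = divmod(int(lms_int), len(clinical.LATERAL_ITEMS))
    return [base + 1 if i < rem else base for i in range(len(clinical.LATERAL_ITEMS))]


def sample_cohort(spec: CohortSpec, basis: PlantedBasis) -> tuple[ClinicalTable, TrueScores]:
    """Draw a cohort: disease durations, pattern scores, lateralized motor scores.

    DD is uniform on ``spec.dd_range``; aDD follows the clinical adjustment;
    pattern scores are linear in aDD plus Gaussian noise; the worse side's
    scores receive ``asymmetry_offset``; lateralized motor scores are linear
    in each side's pattern scores.  Fully reproducible from ``spec.seed``.
    """
    if basis.n_patterns == 0:
        raise ValidationError("basis has no patterns")
    if spec.score_model and len(spec.score_model) != basis.n_patterns:
        raise ValidationError(
            f"score_model has {len(spec.score_model)} couplings for "
            f"{basis.n_patterns} patterns"
        )
    couplings = spec.score_model or tuple(ScoreCoupling() for _ in range(basis.n_patterns))
    lms_coefs = np.zeros(basis.n_patterns)
    if spec.lms_model.coefs:
        if len(spec.lms_model.coefs) != basis.n_patterns:
            raise ValidationError("lms_model.coefs length must match the basis")
        lms_coefs = np.asarray(spec.lms_model.coefs, dtype=float)

    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    dd = rng.uniform(spec.dd_range[0], spec.dd_range[1], size=n)
    add = np.asarray(compute_add(dd, spec.add_params))

    scores_better = np.empty((n, basis.n_patterns))
    for k, c in enumerate(couplings):
        scores_better[:, k] = c.intercept + c.slope * add + rng.normal(0.0, c.noise_sd, n)
    scores_worse = scores_better + spec.asymmetry_offset

    lm = spec.lms_model
    lms_better = lm.intercept + scores_better @ lms_coefs + rng.normal(0, lm.noise_sd, n)
    lms_worse = lm.intercept + scores_worse @ lms_coefs + rng.normal(0, lm.noise_sd, n)
    # worse side must not score below the better side; enforce the ordering
    lms_worse = np.maximum(lms_worse, lms_better)

    worse_body = rng.choice(["left", "right"], size=n)
    age = np.clip(rng.normal(60.0, 10.0, n), 35.0, 85.0).round(1)
    agonist_on = rng.random(n) < 0.4
    agled = np.where(agonist_on, np.abs(rng.normal(160.0, 90.0, n)).round(1), 0.0)

    rows = []
    for i in range(n):
        lms_b = int(np.clip(round(lms_better[i]), 0, 28))
        lms_w = int(np.clip(round(lms_worse[i]), lms_b, 28))
        items = {"left": None, "right": None}
        items[worse_body[i]] = _items_from_lms(lms_w)
        items["left" if worse_body[i] == "right" else "right"] = _items_from_lms(lms_b)
        row = {
            "subject_id": f"sub-{i + 1:03d}",
            "group": "PD",
            "DD": round(float(dd[i]), 3),
            "age": float(age[i]),
            "AgLED": float(agled[i]),
            "agonist_status": "ON" if agonist_on[i] else "OFF",
            "sex": "M" if rng.random() < 0.55 else "F",
            "worse_body_side": str(worse_body[i]),
        }
        for side in ("left", "right"):
            for item, value in zip(clinical.LATERAL_ITEMS, items[side]):
                row[item_column(item, side)] = value
        rows.append(row)

    table = ClinicalTable(pd.DataFrame(rows), add_params=spec.add_params)
    truth = TrueScores(
        better=scores_better,
        worse=scores_worse,
        lms_better=lms_better,
        lms_worse=lms_worse,
        add=add,
    )
    return table, truth


def render_images(
    template: LabeledTemplate,
    basis: PlantedBasis,
    true_scores: np.ndarray,
    noise_sigma: float,
    seed: int,
    side: str = "better",
    subject_ids: Sequence[str] | None = None,
) -> list[ParametricImage]:
    """Render one image per subject from planted patterns and scores.

    ROI voxel values are ``mean_level + sum_k s_nk * pattern_k + noise``,
    clipped at zero; voxels outside the ROI are zero.
    """
    scores = np.atleast_2d(np.asarray(true_scores, dtype=float))
    if scores.shape[1] != basis.n_patterns:
        raise ShapeError(
            f"scores have {scores.shape[1]} columns for {basis.n_patterns} patterns"
        )
    if subject_ids is not None and len(subject_ids) != scores.shape[0]:
        raise ShapeError("subject_ids length must match the score rows")
    idx = basis.voxel_index
    rng = np.random.default_rng(seed)
    images = []
    for n in range(scores.shape[0]):
        roi_values = basis.mean_level + scores[n] @ basis.patterns
        if noise_sigma > 0:
            roi_values = roi_values + rng.normal(0.0, noise_sigma, idx.shape[0])
        vol = np.zeros(template.grid_shape)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = np.clip(roi_values, 0.0, None)
        images.append(
            ParametricImage(
                values=vol,
                affine=template.affine,
                subject_id=subject_ids[n] if subject_ids is not None else f"sub-{n + 1:03d}",
                side=side,
            )
        )
    return images


def render_cohort(
    template: LabeledTemplate,
    basis: PlantedBasis,
    truth: TrueScores,
    spec: CohortSpec,
    subject_ids: Sequence[str] | None = None,
) -> dict[str, list[ParametricImage]]:
    """Render both hemispheres of a sampled cohort, seeds derived from the spec."""
    return {
        "better": render_images(
            template, basis, truth.better, spec.noise_sigma, spec.seed + 1,
            side="better", subject_ids=subject_ids,
        ),
        "worse": render_images(
            template, basis, truth.worse, spec.noise_sigma, spec.seed + 2,
            side="worse", subject_ids=subject_ids,
        ),
    }


def write_fixture(
    cohort: ClinicalTable,
    images: Mapping[str, Sequence[ParametricImage]] | Sequence[ParametricImage],
    directory,
    template: LabeledTemplate | None = None,
    seed: int | None = None,
    spec: CohortSpec | None = None,
) -> dict:
    """Write a phantom fixture to disk and return its manifest.

    Layout: one NIfTI file per subject/side (``sub-<id>_<side>.nii.gz``), the
    clinical table as ``clinical.csv``, optional ``template.nii.gz``, and a
    JSON manifest recording the seed, spec and file list.  The written files
    round-trip losslessly through :func:`pclasso.imaging.read_image` and
    :func:`pclasso.clinical.read_clinical_table`.
    """
    from .imaging import write_image  # local import to avoid cycle at module load

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc

    if not isinstance(images, Mapping):
        images = {"all": list(images)}
    files = []
    for group in images.values():
        for img in group:
            name = f"{img.subject_id}_{img.side or 'na'}.nii.gz"
            write_image(img, directory / name)
            files.append(name)
    cohort.to_csv(directory / "clinical.csv")
    if template is not None:
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(template.labels.astype(np.int16), template.affine),
            str(directory / "template.nii.gz"),
        )
    manifest = {
        "seed": seed if seed is not None else (spec.seed if spec is not None else None),
        "n_subjects": len(cohort),
        "images": sorted(files),
        "clinical": "clinical.csv",
        "template": "template.nii.gz" if template is not None else None,
        "spec": _spec_to_dict(spec) if spec is not None else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_subjects": spec.n_subjects,
        "dd_range": list(spec.dd_range),
        "score_model": [
            {"intercept": c.intercept, "slope": c.slope, "noise_sd": c.noise_sd}
            for c in spec.score_model
        ],
        "lms_model": {
            "intercept": spec.lms_model.intercept,
            "coefs": list(spec.lms_model.coefs),
            "noise_sd": spec.lms_model.noise_sd,
        },
        "asymmetry_offset": spec.asymmetry_offset,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
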