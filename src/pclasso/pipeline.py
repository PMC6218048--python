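"""Configuration-driven orchestration of the full analysis flow.

A run is defined by a serializable :class:`RunConfig` (JSON on disk) naming
either a phantom specification or a directory of common-space images plus a
clinical table.  Two analyses mirror the method's two halves:

* :func:`run_pattern_analysis` — per ROI and hemisphere (and optionally per
  disease-stage subgroup): PCA, VAF tables, loading maps and their maximum
  intensity projections, cross-side and cross-subgroup loading similarities.
* :func:`run_prediction` — per model (outcome, input side, ROI): constant,
  mean-BR and PC-LASSO cross-validation on a shared split sequence, the
  comparison table, penalty trace data, predicted-vs-actual data, coefficient
  statistics, and voxel-space estimator maps with projections.

Identical config + seed reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clinical as clin
from . import estimator as est
from . import lasso as ls
from . import pca as pc
from . import phantom as ph
from .errors import ConfigurationError, ValidationError
from .imaging import ParametricImage, extract_voxel_matrix, read_image, write_image


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom data source: pattern kinds and cohort parameters."""

    n_subjects: int = 40
    kinds: tuple[str, ...] = ("global_positive", "ap_gradient", "is_gradient", "noise_pattern")
    roi_label: int = ph.PUTAMEN
    noise_sigma: float = 0.1
    seed: int = 0


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol settings.

    The default profile is the reduced desk-scale one (100 splits); the full
    protocol (500 splits, 0.3 holdout, 100 penalty steps) is a config choice.
    """

    n_splits: int = 100
    holdout_fraction: float = 0.3
    grid_steps: int = 100
    seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    """One prediction model: outcome, imaging input side/ROI, covariates."""

    outcome: str  # "aDD" | "LMS_better" | "LMS_worse"
    input_side: str  # "better" | "worse"
    roi_label: int = ph.PUTAMEN
    n_components: int = 5
    covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a full run."""

    output_dir: str
    phantom: PhantomConfig | None = None
    data_dir: str | None = None
    sides: tuple[str, ...] = ("better", "worse")
    rois: tuple[int, ...] = (ph.PUTAMEN,)
    top_k: int = 5
    run_subgroups: bool = False
    models: tuple[ModelSpec, ...] = (
        ModelSpec(outcome="aDD", input_side="better"),
        ModelSpec(outcome="aDD", input_side="worse"),
        ModelSpec(outcome="LMS_better", input_side="better"),
        ModelSpec(outcome="LMS_worse", input_side="worse"),
    )
    cv: CVConfig = field(default_factory=CVConfig)
    write_png: bool = False

    @staticmethod
    def from_json(path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if kwargs.get("phantom") is not None:
            p = dict(kwargs["phantom"])
            if "kinds" in p:
                p["kinds"] = tuple(p["kinds"])
            kwargs["phantom"] = PhantomConfig(**p)
        if kwargs.get("cv") is not None:
            kwargs["cv"] = CVConfig(**kwargs["cv"])
        if kwargs.get("models") is not None:
            kwargs["models"] = tuple(
                ModelSpec(**{**m, "covariates": tuple(m.get("covariates", ()))})
                for m in kwargs["models"]
            )
        for key in ("sides", "rois"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return RunConfig(**kwargs)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


@dataclass
class Dataset:
    """In-memory common-space dataset: template, clinical table, images per side."""

    template: ph.LabeledTemplate
    clinical: clin.ClinicalTable
    images: dict[str, list[ParametricImage]]
    basis: ph.PlantedBasis | None = None
    truth: ph.TrueScores | None = None


def load_dataset(config: RunConfig) -> Dataset:
    """Materialize the dataset a config describes (phantom or on-disk)."""
    if (config.phantom is None) == (config.data_dir is None):
        raise ConfigurationError("config must set exactly one of 'phantom' or 'data_dir'")
    if config.phantom is not None:
        return generate_phantom_dataset(config.phantom)

    data_dir = Path(config.data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    import nibabel as nib

    tpl_img = nib.load(str(data_dir / manifest["template"]))
    template = ph.LabeledTemplate(labels=np.asarray(tpl_img.get_fdata()).astype(int))
    table = clin.read_clinical_table(data_dir / manifest["clinical"])
    images: dict[str, list[ParametricImage]] = {}
    for name in manifest["images"]:
        stem = name.removesuffix(".nii.gz").removesuffix(".nii")
        subject_id, side = stem.rsplit("_", 1)
        img = read_image(data_dir / name, template=template)
        img.subject_id, img.side = subject_id, side
        images.setdefault(side, []).append(img)
    order = {sid: i for i, sid in enumerate(table.subject_ids)}
    for side in images:
        images[side].sort(key=lambda im: order[im.subject_id])
    return Dataset(template=template, clinical=table, images=images)


def generate_phantom_dataset(pconf: PhantomConfig) -> Dataset:
    """Build a phantom cohort in memory under the study-condition defaults."""
    template = ph.make_template()
    basis = ph.make_planted_basis(template, pconf.roi_label, pconf.kinds)
    spec = ph.default_cohort_spec(
        n_patterns=basis.n_patterns,
        seed=pconf.seed,
        n_subjects=pconf.n_subjects,
        noise_sigma=pconf.noise_sigma,
    )
    table, truth = ph.sample_cohort(spec, basis)
    images = ph.render_cohort(template, basis, truth, spec, subject_ids=table.subject_ids)
    return Dataset(template=template, clinical=table, images=images, basis=basis, truth=truth)


def _save_mips(vol: np.ndarray, stem: Path, write_png: bool) -> None:
    for axis_name in ("LM", "AP", "IS"):
        mip = est.mip_render(vol, axis_name)
        np.savetxt(f"{stem}_mip{axis_name}_pos.csv", mip.positive, delimiter=",")
        np.savetxt(f"{stem}_mip{axis_name}_neg.csv", mip.negative, delimiter=",")
        if write_png:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            plt.imsave(f"{stem}_mip{axis_name}_pos.png", mip.positive.T, cmap="hot", origin="lower")
            plt.imsave(f"{stem}_mip{axis_name}_neg.png", mip.negative.T, cmap="cool", origin="lower")


def _write_decomposition(decomp, template, out: Path, tag: str, top_k: int, write_png: bool):
    pd.DataFrame(
        {"component": [est.pc_name(k + 1) for k in range(decomp.n_components)],
         "vaf_percent": decomp.vaf}
    ).to_csv(out / f"{tag}_vaf.csv", index=False)
    scores = pd.DataFrame(
        decomp.scores,
        columns=[est.pc_name(k + 1) for k in range(decomp.n_components)],
    )
    scores.insert(0, "subject_id", list(decomp.subject_ids))
    scores.to_csv(out / f"{tag}_scores.csv", index=False)
    import nibabel as nib

    for k in range(min(top_k, decomp.n_components)):
        vol = est.embed_map(decomp.loadings[k], decomp.voxel_index, template.grid_shape)
        nib.save(
            nib.Nifti1Image(vol, template.affine),
            str(out / f"{tag}_{est.pc_name(k + 1)}.nii.gz"),
        )
        _save_mips(vol, out / f"{tag}_{est.pc_name(k + 1)}", write_png)


def run_pattern_analysis(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """PCA pattern discovery per ROI x side (x subgroup), with similarity tables."""
    dataset = dataset or load_dataset(config)
    out = Path(config.output_dir) / "patterns"
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    report: dict = {"panels": [], "similarities": {}}
    decomps: dict[tuple[int, str], pc.PCDecomposition] = {}
    for roi in config.rois:
        for side in config.sides:
            if side not in dataset.images:
                raise ValidationError(f"dataset has no images for side {side!r}")
            vm = extract_voxel_matrix(dataset.images[side], dataset.template, roi)
            decomp = pc.fit_pca(vm)
            decomps[(roi, side)] = decomp
            tag = f"roi{roi}_{side}"
            _write_decomposition(decomp, dataset.template, out, tag, config.top_k, config.write_png)
            report["panels"].append(
                {"roi": roi, "side": side, "n": vm.n_subjects,
                 "vaf_top": [float(v) for v in decomp.vaf[: config.top_k]]}
            )
        if all((roi, s) in decomps for s in ("better", "worse")):
            sim = pc.compare_loadings(
                decomps[(roi, "better")], decomps[(roi, "worse")], top_k=config.top_k
            )
            np.savetxt(out / f"roi{roi}_better_vs_worse_similarity.csv", sim, delimiter=",")
            report["similarities"][f"roi{roi}_better_vs_worse"] = sim.tolist()

        if config.run_subgroups:
            side0 = config.sides[0]
            vm = extract_voxel_matrix(dataset.images[side0], dataset.template, roi)
            sub = pc.run_subgroup_pca(vm, dataset.clinical)
            names = list(sub)
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    sim = pc.compare_loadings(sub[names[a]], sub[names[b]], top_k=config.top_k)
                    key = f"roi{roi}_{names[a]}_vs_{names[b]}"
                    np.savetxt(out / f"{key}_similarity.csv", sim, delimiter=",")
                    report["similarities"][key] = sim.tolist()
    return report


def _design_for_model(dataset: Dataset, model: ModelSpec):
    vm = extract_voxel_matrix(
        dataset.images[model.input_side], dataset.template, model.roi_label
    )
    decomp = pc.fit_pca(vm, n_components=model.n_components)
    names = [est.pc_name(k + 1) for k in range(decomp.n_components)]
    cols = [decomp.scores]
    for cov in model.covariates:
        cols.append(dataset.clinical.column(cov).reshape(-1, 1).astype(float))
        names.append(cov)
    design = np.hstack(cols)
    outcome = dataset.clinical.column(model.outcome).astype(float)
    mean_br = vm.data.mean(axis=1)
    return vm, decomp, design, tuple(names), outcome, mean_br


def run_prediction(config: RunConfig, dataset: Dataset | None = None) -> pd.DataFrame:
    """Constant / mean-BR / PC-LASSO model comparison on shared splits."""
    dataset = dataset or load_dataset(config)
    out = Path(config.output_dir) / "prediction"
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    import nibabel as nib

    rows = []
    for model in config.models:
        vm, decomp, design, names, outcome, mean_br = _design_for_model(dataset, model)
        n = len(outcome)
        splits = ls.make_splits(
            n, config.cv.n_splits, config.cv.holdout_fraction, config.cv.seed
        )
        cv = ls.repeated_holdout_cv(
            design, outcome, names=names, splits=splits,
            grid_steps=config.cv.grid_steps, seed=config.cv.seed,
            holdout_fraction=config.cv.holdout_fraction,
        )
        const_ref, br_ref = ls.fit_reference_models(mean_br, outcome, splits)

        tag = f"{model.outcome}_{model.input_side}_roi{model.roi_label}"
        rows.append(
            {
                "predicted_metric": model.outcome,
                "input_side": model.input_side,
                "roi_label": model.roi_label,
                "constant_mse_test": const_ref.mse_test_mean,
                "constant_mse_test_se": const_ref.mse_test_se,
                "constant_mse_all": const_ref.mse_all,
                "mean_br_mse_test": br_ref.mse_test_mean,
                "mean_br_mse_test_se": br_ref.mse_test_se,
                "mean_br_mse_all": br_ref.mse_all,
                "pclasso_mse_test": float(cv.mse_test_mean[cv.lambda_min_index]),
                "pclasso_mse_test_se": float(cv.mse_test_se[cv.lambda_min_index]),
                "pclasso_mse_all": cv.mse_all,
                "lambda_min": cv.lambda_min,
                "retained_terms": ";".join(cv.retained_terms) or "none",
            }
        )

        trace = pd.DataFrame(cv.full_path, columns=list(names))
        trace.insert(0, "lambda", cv.lambda_grid)
        trace["mse_test_mean"] = cv.mse_test_mean
        trace["mse_test_se"] = cv.mse_test_se
        trace.to_csv(out / f"{tag}_trace.csv", index=False)

        z_full = cv.full_model.record.apply(design)
        pva = pd.DataFrame(
            {
                "subject_id": dataset.clinical.subject_ids,
                "actual": outcome,
                "pclasso_predicted": cv.full_model.predict(z_full),
                "mean_br_predicted": br_ref.full_coef[0] + br_ref.full_coef[1] * mean_br,
            }
        )
        pva.to_csv(out / f"{tag}_pva.csv", index=False)

        coef = ls.coefficient_significance(cv, design, outcome)
        coef.to_csv(out / f"{tag}_coefficients.csv")

        emap = est.compute_estimator(decomp, cv.full_model)
        vol = est.embed_map(emap.v, emap.voxel_index, dataset.template.grid_shape)
        nib.save(
            nib.Nifti1Image(vol, dataset.template.affine),
            str(out / f"{tag}_estimator.nii.gz"),
        )
        (out / f"{tag}_estimator.json").write_text(
            json.dumps(
                {
                    "beta0": emap.beta0,
                    "covariate_betas": emap.covariate_betas,
                    "provenance": emap.provenance,
                    "pvalue_method": coef.attrs.get("pvalue_method"),
                },
                indent=2,
            )
        )
        _save_mips(vol, out / f"{tag}_estimator", config.write_png)

    table = pd.DataFrame(rows)
    table.to_csv(out / "model_comparison.csv", index=False)
    return table


def run_phantom_demo(config: RunConfig) -> dict:
    """Generate a phantom fixture, run both analyses, summarize recovery."""
    if config.phantom is None:
        raise ConfigurationError("run_phantom_demo requires a phantom config")
    dataset = generate_phantom_dataset(config.phantom)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = ph.default_cohort_spec(
        n_patterns=dataset.basis.n_patterns,
        seed=config.phantom.seed,
        n_subjects=config.phantom.n_subjects,
        noise_sigma=config.phantom.noise_sigma,
    )
    ph.write_fixture(
        dataset.clinical, dataset.images, out / "fixture",
        template=dataset.template, spec=spec,
    )

    run_pattern_analysis(config, dataset=dataset)
    comparison = run_prediction(config, dataset=dataset)

    # planted-vs-recovered similarity on the better side
    roi = config.phantom.roi_label
    vm = extract_voxel_matrix(dataset.images["better"], dataset.template, roi)
    decomp = pc.fit_pca(vm)
    k = dataset.basis.n_patterns
    cosines = np.abs(decomp.loadings[:k] @ dataset.basis.patterns.T)
    recovery = {
        kind: float(cosines[:, i].max()) for i, kind in enumerate(dataset.basis.kinds)
    }
    summary = {
        "seed": config.phantom.seed,
        "n_subjects": config.phantom.n_subjects,
        "planted_pattern_recovery_abs_cosine": recovery,
        "model_comparison": comparison.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
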