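"""Back-transform a fitted score model into a voxel-weight estimator map.

The fitted model over PC scores is rewritten over voxels as a single weight
map v; the inner product of a subject's (centered) image with v reproduces
the score-space prediction exactly.  Positive and negative weights are then
projected separately as maximum-intensity projections, the standard way to
display signed voxel-weight maps.
"""

import numpy as np

import pclasso as p

template = p.make_template()
basis = p.make_planted_basis(
    template, 1, ["global_positive", "ap_gradient", "is_gradient", "noise_pattern"]
)
spec = p.default_cohort_spec(4, seed=0)
table, truth = p.sample_cohort(spec, basis)
images = p.render_cohort(template, basis, truth, spec, subject_ids=table.subject_ids)

vm = p.extract_voxel_matrix(images["better"], template, 1)
decomp = p.fit_pca(vm, n_components=5)
names = tuple(p.pc_name(k + 1) for k in range(5))
y = table.column("LMS_better").astype(float)
cv = p.repeated_holdout_cv(decomp.scores, y, names=names, n_splits=100, seed=0)

emap = p.compute_estimator(decomp, cv.full_model)
z = cv.full_model.record.apply(decomp.scores)
score_preds = cv.full_model.predict(z)
voxel_preds = np.array([p.predict_from_voxels(emap, f) for f in vm.data])
print(f"score-space vs voxel-space predictions: max |difference| "
      f"{np.max(np.abs(score_preds - voxel_preds)):.2e}")

# how close is the estimator to the generative truth (outcome was built
# from patterns 1 and 3 with weights -0.25 and +0.4)?
v_true = -0.25 * basis.patterns[0] + 0.4 * basis.patterns[2]
cosine = abs(emap.v @ v_true) / (np.linalg.norm(emap.v) * np.linalg.norm(v_true))
print(f"|cosine| between estimator map and true weighted pattern sum: {cosine:.3f}")

vol = p.embed_map(emap.v, emap.voxel_index, template.grid_shape)
mip = p.mip_render(vol, "IS")
print(f"MIP along IS: positive panel max {mip.positive.max():.2f}, "
      f"negative panel max {mip.negative.max():.2f} "
      f"(both normalized by the global max |weight| = {mip.scale:.4f})")
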