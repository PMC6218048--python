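"""PCA core: decomposition identities, sign canonicalization, comparisons."""

import numpy as np
import pytest

import pclasso as p
from pclasso.imaging import VoxelMatrix
from pclasso.pca import PRESET_SUBGROUPS, SubgroupSpec


def _matrix(data, side="better"):
    data = np.asarray(data, dtype=float)
    idx = np.column_stack(
        [np.zeros(data.shape[1], dtype=int), np.zeros(data.shape[1], dtype=int),
         np.arange(data.shape[1])]
    )
    return VoxelMatrix(
        data=data, voxel_index=idx, roi_label=1, side=side,
        subject_ids=tuple(f"s{i}" for i in range(data.shape[0])),
    )


def brute_force_pca(data):
    """Independent oracle: eigendecomposition of the sample covariance."""
    data = np.asarray(data, dtype=float)
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    vaf = 100.0 * evals / evals.sum()
    return evecs.T, vaf  # loadings as rows


class TestFitPca:
    def test_hand_worked_two_voxel_example(self):
        # rows (2,0),(0,2),(1,1): mean (1,1); centered (1,-1),(-1,1),(0,0)
        # only variance direction is (1,-1)/sqrt(2); scores sqrt(2),-sqrt(2),0
        vm = _matrix([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        d = p.fit_pca(vm)
        w = np.array([1.0, -1.0]) / np.sqrt(2)
        assert abs(abs(d.loadings[0] @ w) - 1.0) < 1e-10
        sign = np.sign(d.loadings[0] @ w)
        np.testing.assert_allclose(d.scores[:, 0] * sign, [np.sqrt(2), -np.sqrt(2), 0.0], atol=1e-10)
        assert d.vaf[0] == pytest.approx(100.0, abs=1e-8)

    def test_rank_identity_zero_noise_two_patterns(self, template, basis2, noiseless_cohort):
        vm = p.extract_voxel_matrix(noiseless_cohort["images"], template, 1)
        d = p.fit_pca(vm)
        assert np.sum(d.vaf > 1e-8) == 2

    def test_reconstruction_orthonormality_vaf(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        gram = d.loadings @ d.loadings.T
        assert np.max(np.abs(gram - np.eye(d.n_components))) < 1e-8
        recon = d.mean_vector + d.scores @ d.loadings
        assert np.max(np.abs(recon - putamen_matrix.data)) < 1e-8
        assert np.sum(d.vaf) == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(d.vaf) <= 1e-12)

    @pytest.mark.parametrize("n,v", [(3, 3), (5, 4), (6, 6), (4, 6)])
    def test_agreement_with_brute_force(self, n, v, rng):
        data = rng.normal(size=(n, v))
        d = p.fit_pca(_matrix(data))
        loadings_bf, vaf_bf = brute_force_pca(data)
        k = d.n_components
        np.testing.assert_allclose(d.vaf, vaf_bf[:k], atol=1e-8)
        for a in range(k):
            if vaf_bf[a] < 1e-10:
                continue
            assert abs(abs(d.loadings[a] @ loadings_bf[a]) - 1.0) < 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(p.DegenerateInputError):
            p.fit_pca(_matrix(np.ones((4, 3))))

    def test_single_subject_rejected(self):
        with pytest.raises(p.ValidationError):
            p.fit_pca(_matrix(np.ones((1, 3))))


class TestCanonicalSign:
    def test_negative_sum_flipped_reconstruction_unchanged(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        flipped = p.canonical_sign(
            type(d)(
                mean_vector=d.mean_vector, loadings=-d.loadings, scores=-d.scores,
                vaf=d.vaf, voxel_index=d.voxel_index,
            )
        )
        recon_a = d.mean_vector + d.scores @ d.loadings
        recon_b = flipped.mean_vector + flipped.scores @ flipped.loadings
        np.testing.assert_allclose(recon_a, recon_b, atol=1e-12)
        assert np.all(flipped.loadings.sum(axis=1) >= -1e-9)

    def test_all_positive_loading_is_fixed_point(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        again = p.canonical_sign(d)
        np.testing.assert_array_equal(d.loadings, again.loadings)

    def test_zero_sum_tie_rule(self):
        # balanced gradient: weight sum 0, pivot on the largest-|weight| voxel
        vm = _matrix([[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        d = p.fit_pca(vm)
        pivot = int(np.argmax(np.abs(d.loadings[0])))
        assert d.loadings[0, pivot] > 0


class TestProject:
    def test_training_projection_reproduces_scores(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        np.testing.assert_allclose(p.project(d, putamen_matrix), d.scores, atol=1e-10)

    def test_mean_vector_projects_to_zero(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        vm_mean = _matrix(d.mean_vector[None, :])
        vm_mean.voxel_index = d.voxel_index
        np.testing.assert_allclose(p.project(d, vm_mean), 0.0, atol=1e-8)

    def test_held_out_zero_noise_scores_recovered(self, template, basis2, noiseless_cohort):
        vm = p.extract_voxel_matrix(noiseless_cohort["images"], template, 1)
        truth = noiseless_cohort["truth"]
        d = p.fit_pca(vm.subset(np.arange(30)))
        held = vm.subset(np.arange(30, 40))
        scores = p.project(d, held)
        # recovered expression must reproduce the held-out images exactly
        recon = d.mean_vector + scores @ d.loadings
        np.testing.assert_allclose(recon, held.data, atol=1e-8)
        # and the planted-score subspace is the same
        planted = (held.data - basis2.mean_level) @ basis2.patterns.T
        np.testing.assert_allclose(planted, truth.better[30:], atol=1e-8)

    def test_voxel_index_mismatch_rejected(self, putamen_matrix, template, cohort4):
        d = p.fit_pca(putamen_matrix)
        other = p.extract_voxel_matrix(cohort4["images"]["better"], template, 2)
        with pytest.raises(p.ValidationError):
            p.project(d, other)


class TestCompareLoadings:
    def test_self_similarity_diagonal_one(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        sim = p.compare_loadings(d, d, top_k=4)
        np.testing.assert_allclose(np.diag(sim), 1.0, atol=1e-10)
        assert np.all(sim <= 1.0 + 1e-10)

    def test_sign_invariance(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        flipped = type(d)(
            mean_vector=d.mean_vector, loadings=-d.loadings, scores=-d.scores,
            vaf=d.vaf, voxel_index=d.voxel_index,
        )
        np.testing.assert_allclose(
            p.compare_loadings(d, d, 4), p.compare_loadings(d, flipped, 4), atol=1e-12
        )

    def test_orthogonal_loadings_give_zero(self, putamen_matrix):
        d = p.fit_pca(putamen_matrix)
        sim = p.compare_loadings(d, d, top_k=3)
        off = sim - np.diag(np.diag(sim))
        assert np.max(off) < 1e-8


class TestSubgroupPca:
    def test_preset_filter_semantics(self, cohort4, putamen_matrix):
        table = cohort4["table"]
        early = SubgroupSpec(name="early", dd_max=3.0)
        keep = early.select(table)
        dd = table.column("DD")
        assert np.array_equal(keep, (dd <= 3.0) & (table.column("group") == "PD"))

    def test_agonist_exclusion(self, cohort4):
        table = cohort4["table"]
        sg = SubgroupSpec(name="x", exclude_agonist_on=True)
        keep = sg.select(table)
        assert not np.any(table.column("agonist_status")[keep] == "ON")

    def test_small_subgroup_rejected(self, cohort4, putamen_matrix):
        with pytest.raises(p.ValidationError, match="tiny"):
            p.run_subgroup_pca(
                putamen_matrix, cohort4["table"],
                [SubgroupSpec(name="tiny", dd_max=-1.0)],
            )

    def test_shared_planted_basis_across_stages(self, template, basis4):
        # stage-independent patterns: scores do not depend on disease stage
        # (zero aDD slopes), so early- and moderate-PD PCAs see the same basis
        couplings = (
            p.ScoreCoupling(30.0, 0.0, 7.0),
            p.ScoreCoupling(0.0, 0.0, 4.0),
            p.ScoreCoupling(0.0, 0.0, 2.4),
            p.ScoreCoupling(0.0, 0.0, 1.2),
        )
        spec = p.default_cohort_spec(4, seed=21, n_subjects=120, score_model=couplings)
        table, truth = p.sample_cohort(spec, basis4)
        imgs = p.render_images(
            template, basis4, truth.better, spec.noise_sigma, seed=22,
            subject_ids=table.subject_ids,
        )
        vm = p.extract_voxel_matrix(imgs, template, 1)
        groups = p.run_subgroup_pca(vm, table, PRESET_SUBGROUPS[1:])
        sim = p.compare_loadings(groups["early_pd"], groups["moderate_pd"], top_k=2)
        assert np.all(np.diag(sim) >= 0.9)
        assert groups["early_pd"].provenance["n"] >= 2
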