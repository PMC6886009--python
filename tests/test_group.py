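"""Group-level MLM: stacking, confound removal, signatures, T-maps."""

import numpy as np
import pytest

from neuromlm.group import (
    EigenimageStack,
    GroupDesign,
    critical_t,
    group_mlm,
    residualize_confounds,
    signature_tmap,
    stack_eigenimages,
    weighted_clinical_loadings,
)
from neuromlm.mlm import MLMDecomposition


def _decomp(rng, voxels=20, mask=None):
    u, _ = np.linalg.qr(rng.standard_normal((3, 3)) + 2 * np.eye(3))
    v, _ = np.linalg.qr(rng.standard_normal((voxels, 3)))
    return MLMDecomposition(
        clinical_loadings=u,
        eigenvalues=np.array([3.0, 2.0, 1.0]),
        eigenimages=v.T,
        mask=mask,
    )


def _group_design(rng, n):
    return GroupDesign(
        values=np.column_stack(
            [
                np.repeat([1.0, -1.0], [n - n // 2, n // 2]),
                rng.standard_normal(n),
                rng.choice([-1.0, 1.0], size=n),
            ]
        ),
        labels=("group", "age", "sex"),
    )


class TestStackEigenimages:
    def test_shape_and_rows(self, rng):
        decs = [_decomp(np.random.default_rng(s)) for s in range(30)]
        stack = stack_eigenimages(decs, 2)
        assert stack.values.shape == (30, 20)
        for i, d in enumerate(decs):
            assert np.array_equal(stack.values[i], d.eigenimages[1])

    def test_rank_out_of_range(self, rng):
        decs = [_decomp(np.random.default_rng(s)) for s in range(3)]
        with pytest.raises(ValueError):
            stack_eigenimages(decs, 4)

    def test_mask_mismatch_rejected(self):
        m1 = np.ones((4, 4, 4), dtype=bool)
        m2 = m1.copy()
        m2[0, 0, 0] = False
        d1 = _decomp(np.random.default_rng(0), voxels=64, mask=m1)
        d2 = _decomp(np.random.default_rng(1), voxels=63, mask=m2)
        with pytest.raises(ValueError, match="mask"):
            stack_eigenimages([d1, d2], 1)


class TestResidualizeConfounds:
    def test_matches_hat_matrix_oracle(self, rng):
        n = 12
        design = _group_design(rng, n)
        stack = EigenimageStack(rank=1, values=rng.standard_normal((n, 25)))
        adjusted, reduced = residualize_confounds(stack, design)
        c = np.column_stack([np.ones(n), design.column("age"), design.column("sex")])
        p = np.eye(n) - c @ np.linalg.inv(c.T @ c) @ c.T
        assert np.allclose(adjusted.values, p @ stack.values, atol=1e-10)
        assert np.allclose(reduced.values[:, 0], p @ design.column("group"), atol=1e-10)

    def test_adjusted_stack_orthogonal_to_confounds(self, rng):
        design = _group_design(rng, 16)
        stack = EigenimageStack(rank=1, values=rng.standard_normal((16, 30)))
        adjusted, _ = residualize_confounds(stack, design)
        for lab in ("age", "sex"):
            proj = design.column(lab) @ adjusted.values
            assert np.abs(proj).max() < 1e-8 * np.abs(stack.values).max() * 16

    def test_pure_confound_stack_vanishes(self, rng):
        design = _group_design(rng, 14)
        pattern = rng.standard_normal(40)
        stack = EigenimageStack(rank=1, values=np.outer(design.column("age"), pattern))
        adjusted, _ = residualize_confounds(stack, design)
        assert np.linalg.norm(adjusted.values) < 1e-8 * np.linalg.norm(stack.values)

    def test_rank_deficient_confounds_rejected(self, rng):
        n = 10
        design = GroupDesign(
            values=np.column_stack(
                [np.repeat([1.0, -1.0], 5), np.full(n, 2.0), rng.standard_normal(n)]
            ),
            labels=("group", "age", "sex"),
        )  # constant age column collides with the implicit intercept
        stack = EigenimageStack(rank=1, values=rng.standard_normal((n, 8)))
        with pytest.raises(ValueError, match="rank deficient"):
            residualize_confounds(stack, design, confound_labels=("age",))


class TestGroupMlm:
    def test_noise_free_two_group_geometry(self, rng):
        pattern = rng.standard_normal(50)
        signs = np.repeat([1.0, -1.0], 4)
        stack = EigenimageStack(rank=1, values=np.outer(signs, pattern))
        design = GroupDesign(values=signs[:, None], labels=("group",))
        gd = group_mlm(stack, design)
        cos = gd.signature @ (pattern / np.linalg.norm(pattern))
        assert abs(cos) > 1 - 1e-8
        assert np.all(np.sign(gd.subject_loadings) == np.sign(signs * cos))

    def test_z_svd_reconstruction(self, rng):
        y = rng.standard_normal((6, 20))
        design = GroupDesign(
            values=np.repeat([1.0, -1.0], 3)[:, None], labels=("group",)
        )
        gd = group_mlm(EigenimageStack(rank=1, values=y), design)
        z_rec = (gd.group_loadings * gd.z_eigenvalues) @ gd.z_patterns
        assert np.allclose(z_rec, gd.z, atol=1e-10)
        # subject loadings are the projection onto the unit signature
        assert np.allclose(gd.subject_loadings, y @ gd.signature, atol=1e-12)

    def test_zero_stack_rejected(self):
        design = GroupDesign(values=np.repeat([1.0, -1.0], 3)[:, None], labels=("group",))
        with pytest.raises(ValueError, match="zero"):
            group_mlm(EigenimageStack(rank=1, values=np.zeros((6, 10))), design)

    def test_null_loadings_uncorrelated_with_labels(self):
        """Noise-only cohorts: point-biserial correlation between subject
        loadings and group labels stays below 0.5 in >= 95% of replicates."""
        labels = np.repeat([1.0, -1.0], [16, 14])
        labels_c = labels - labels.mean()
        hits = 0
        reps = 200
        for s in range(reps):
            r = np.random.default_rng(s)
            y = r.standard_normal((30, 200))
            design = GroupDesign(values=labels[:, None], labels=("group",))
            gd = group_mlm(EigenimageStack(rank=1, values=y - y.mean(0)), design)
            w = gd.subject_loadings
            r_pb = (w - w.mean()) @ labels_c / (
                np.linalg.norm(w - w.mean()) * np.linalg.norm(labels_c)
            )
            hits += abs(r_pb) <= 0.5
        assert hits / reps >= 0.95

    def test_confound_invariance(self, rng):
        """Adding any linear-in-confounds component to the stack leaves
        the signature and subject loadings unchanged."""
        n = 20
        design = _group_design(rng, n)
        base = rng.standard_normal((n, 30))
        stack = EigenimageStack(rank=1, values=base)
        spiked = EigenimageStack(
            rank=1,
            values=base
            + np.outer(design.column("age"), rng.standard_normal(30))
            + np.outer(design.column("sex"), rng.standard_normal(30)),
        )
        g1 = group_mlm(*residualize_confounds(stack, design))
        g2 = group_mlm(*residualize_confounds(spiked, design))
        assert np.allclose(g1.signature, g2.signature, atol=1e-8)
        assert np.allclose(g1.subject_loadings, g2.subject_loadings, atol=1e-8)

    def test_signature_sign_flip_flips_loadings(self, rng):
        # the loading projection is linear in the signature, so a sign
        # flip of the signature flips every subject loading and leaves
        # any sign-invariant downstream use (LDA separation) unchanged
        y = rng.standard_normal((10, 15))
        sig = rng.standard_normal(15)
        assert np.allclose(y @ (-sig), -(y @ sig))


class TestWeightedClinicalLoadings:
    @staticmethod
    def _group_stub(weights):
        class G:
            subject_loadings = np.asarray(weights, dtype=float)
        return G()

    def test_equal_weights_give_mean(self, rng):
        decs = [_decomp(np.random.default_rng(s)) for s in range(5)]
        out = weighted_clinical_loadings(decs, {1: self._group_stub(np.ones(5))})
        mean = np.mean([d.clinical_loadings[:, 0] for d in decs], axis=0)
        assert np.allclose(out[1], mean)

    def test_single_nonzero_weight_selects_subject(self, rng):
        decs = [_decomp(np.random.default_rng(s)) for s in range(4)]
        w = np.array([0.0, -2.0, 0.0, 0.0])
        out = weighted_clinical_loadings(decs, {2: self._group_stub(w)})
        assert np.allclose(out[2], -decs[1].clinical_loadings[:, 1])

    def test_all_zero_weights_rejected(self, rng):
        decs = [_decomp(np.random.default_rng(s)) for s in range(3)]
        with pytest.raises(ValueError):
            weighted_clinical_loadings(decs, {1: self._group_stub(np.zeros(3))})

    def test_planted_dominant_condition_survives_weighting(self):
        """If every subject's first component loads mostly on DS, so does
        the weighted cohort average."""
        rng = np.random.default_rng(7)
        decs = []
        for _ in range(6):
            u = np.array([[0.9, 0.1, 0.3], [0.3, 0.9, -0.1], [0.3, -0.4, 0.9]])
            u += 0.05 * rng.standard_normal((3, 3))
            q, r = np.linalg.qr(u)
            v, _ = np.linalg.qr(rng.standard_normal((20, 3)))
            decs.append(
                MLMDecomposition(
                    clinical_loadings=q * np.sign(np.diag(r)),
                    eigenvalues=np.array([3.0, 2.0, 1.0]),
                    eigenimages=v.T,
                )
            )
        w = rng.uniform(0.5, 1.5, size=6)
        out = weighted_clinical_loadings(decs, {1: self._group_stub(w)})
        assert np.argmax(np.abs(out[1])) == 0  # DS entry dominates


class TestSignatureTmap:
    def test_critical_t_matches_printed_threshold(self):
        assert critical_t(0.05, 28, "one") == pytest.approx(1.70, abs=0.005)

    def test_perfect_correlation_is_capped(self, rng):
        w = rng.standard_normal(10)
        stack = EigenimageStack(rank=1, values=np.column_stack([w, rng.standard_normal(10)]))
        res = signature_tmap(stack, w)
        assert res.t[0] == pytest.approx(1e4)

    def test_constant_column_gets_zero(self, rng):
        vals = rng.standard_normal((8, 3))
        vals[:, 1] = 5.0
        res = signature_tmap(EigenimageStack(rank=1, values=vals), rng.standard_normal(8))
        assert res.t[1] == 0.0
        assert res.n_constant == 1

    def test_permutation_null_tail_fraction(self):
        """With loadings independent of the stack, ~5% of voxels per tail
        exceed the p = 0.05 one-sided critical value."""
        r = np.random.default_rng(42)
        stack = EigenimageStack(rank=1, values=r.standard_normal((30, 4000)))
        res = signature_tmap(stack, r.standard_normal(30), p=0.05)
        frac = (np.abs(res.t) > res.threshold).mean()
        assert frac == pytest.approx(0.10, abs=0.03)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            signature_tmap(
                EigenimageStack(rank=1, values=rng.standard_normal((2, 5))),
                np.array([1.0, 2.0]),
            )

    def test_constant_loadings_rejected(self, rng):
        with pytest.raises(ValueError):
            signature_tmap(
                EigenimageStack(rank=1, values=rng.standard_normal((5, 5))),
                np.ones(5),
            )
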