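"""Essential-dynamics diagnostics: superposition, PCA, cosine content,
RMSIP and the replica-concatenability discriminant test."""

import numpy as np
import pytest

from conftest import horn_superpose
from psnkit.convergence import (cosine_content, essential_fraction,
                                lda_consistency, pca, project,
                                replica_diagnostics, rmsip, superpose)
from psnkit.synth import (ModeSpec, make_mode_ensemble, make_replica_set,
                          orthonormal_shape_modes)


def mode_spec(n=10, variances=(4.0,)):
    mean = np.zeros((n, 3))
    mean[:, 0] = np.arange(n) * 3.8
    modes = orthonormal_shape_modes(mean, len(variances))
    return ModeSpec(mean, modes, np.array(variances))


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestSuperpose:
    def test_rotated_copy_recovered_exactly(self):
        rng = np.random.default_rng(0)
        ens = make_mode_ensemble(mode_spec(), 5, seed=1)
        rot = random_rotation(rng)
        moved = ens.coords.copy()
        moved[1:] = moved[1:] @ rot.T + np.array([3.0, -2.0, 7.0])
        from psnkit.io import Ensemble
        fitted = superpose(Ensemble(ens.topology, moved), ens.coords[0])
        rmsd = np.sqrt(((fitted.coords - ens.coords) ** 2).mean())
        assert rmsd < 1e-8

    def test_identity_on_reference(self):
        ens = make_mode_ensemble(mode_spec(), 3, seed=2)
        fitted = superpose(ens, ens.coords[0])
        np.testing.assert_allclose(fitted.coords[0], ens.coords[0],
                                   atol=1e-10)

    def test_matches_quaternion_oracle(self):
        # a genuinely 3-D cloud: collinear chains leave the rotation about
        # the chain axis undetermined and the comparison meaningless
        rng = np.random.default_rng(3)
        ens = make_mode_ensemble(mode_spec(), 8, seed=3)
        ref = rng.uniform(-10, 10, size=ens.coords[0].shape)
        noisy = ref[None] + rng.normal(scale=0.5, size=ens.coords.shape)
        from psnkit.io import Ensemble
        fitted = superpose(Ensemble(ens.topology, noisy), ref)
        for f in range(1, 8):
            want = horn_superpose(noisy[f], ref)
            np.testing.assert_allclose(fitted.coords[f], want, atol=1e-8)

    def test_rmsd_not_increased(self):
        rng = np.random.default_rng(4)
        ens = make_mode_ensemble(mode_spec(), 5, seed=4)
        noisy = ens.coords + rng.normal(scale=1.0, size=ens.coords.shape)
        from psnkit.io import Ensemble
        fitted = superpose(Ensemble(ens.topology, noisy), ens.coords[0])
        for f in range(5):
            pre = np.sqrt(((noisy[f] - ens.coords[0]) ** 2).mean())
            post = np.sqrt(((fitted.coords[f] - ens.coords[0]) ** 2).mean())
            assert post <= pre + 1e-12

    def test_idempotent(self):
        ens = make_mode_ensemble(mode_spec(), 6, seed=5)
        once = superpose(ens)
        twice = superpose(once)
        assert np.abs(twice.coords - once.coords).max() < 1e-10

    def test_too_few_calpha(self):
        spec = mode_spec(n=10)
        ens = make_mode_ensemble(spec, 3, seed=0)
        from psnkit.io import Atom, Ensemble, Residue, Topology
        tiny = Topology([Residue(1, "A", "GLY", (Atom("CA", "C", 12.0),)),
                         Residue(2, "A", "GLY", (Atom("CA", "C", 12.0),),
                                 atom_offset=1)])
        with pytest.raises(ValueError):
            superpose(Ensemble(tiny, ens.coords[:, :2, :]))


class TestPCA:
    def test_planted_variance_and_direction(self):
        spec = mode_spec(variances=(4.0,))
        ens = make_mode_ensemble(spec, 10_000, seed=6)
        model = pca(ens)
        assert model.eigenvalues[0] == pytest.approx(4.0, rel=0.05)
        assert abs(model.eigenvectors[0] @ spec.modes[0]) > 0.99

    def test_zero_variance(self):
        spec = mode_spec(variances=(0.0,))
        ens = make_mode_ensemble(spec, 10, seed=0)
        model = pca(ens)
        assert np.abs(model.eigenvalues).max() < 1e-12

    def test_trace_identity(self):
        spec = mode_spec(variances=(3.0, 1.0))
        ens = make_mode_ensemble(spec, 500, seed=7)
        model = pca(ens)
        ca = ens.topology.ca_indices()
        x = ens.coords[:, ca, :].reshape(500, -1)
        total = np.var(x, axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_single_frame_rejected(self):
        spec = mode_spec()
        ens = make_mode_ensemble(spec, 1, seed=0)
        with pytest.raises(ValueError):
            pca(ens)


class TestEssentialFraction:
    def test_full_rank_is_one(self):
        ens = make_mode_ensemble(mode_spec(variances=(2.0, 1.0)), 200, seed=8)
        model = pca(ens)
        assert essential_fraction(model, model.eigenvalues.size) == 1.0

    def test_single_mode_d1(self):
        ens = make_mode_ensemble(mode_spec(variances=(4.0,)), 2000, seed=9)
        assert essential_fraction(pca(ens), 1) == pytest.approx(1.0, abs=1e-9)

    def test_two_equal_modes(self):
        ens = make_mode_ensemble(mode_spec(variances=(2.0, 2.0)), 20_000,
                                 seed=10)
        assert essential_fraction(pca(ens), 1) == pytest.approx(0.5, abs=0.02)

    def test_non_decreasing_in_dimension(self):
        ens = make_mode_ensemble(mode_spec(variances=(3.0, 2.0, 1.0)), 500,
                                 seed=11)
        model = pca(ens)
        fr = [essential_fraction(model, d) for d in range(1, 10)]
        assert all(b >= a for a, b in zip(fr, fr[1:]))

    def test_invalid_dimension(self):
        ens = make_mode_ensemble(mode_spec(), 50, seed=0)
        with pytest.raises(ValueError):
            essential_fraction(pca(ens), 0)


class TestProjection:
    def test_variance_matches_eigenvalue(self):
        ens = make_mode_ensemble(mode_spec(variances=(4.0, 1.0)), 5000,
                                 seed=12)
        model = pca(ens)
        p = project(ens, model, 0)
        assert np.var(p, ddof=1) == pytest.approx(model.eigenvalues[0],
                                                  rel=1e-6)

    def test_zero_mean_on_fitting_ensemble(self):
        ens = make_mode_ensemble(mode_spec(variances=(4.0,)), 500, seed=13)
        model = pca(ens)
        assert abs(project(ens, model, 0).mean()) < 1e-10

    def test_component_out_of_range(self):
        ens = make_mode_ensemble(mode_spec(), 50, seed=0)
        model = pca(ens)
        with pytest.raises(IndexError):
            project(ens, model, 10_000)


class TestCosineContent:
    def test_half_period_cosine_is_one(self):
        t = np.arange(1000)
        c = cosine_content(np.cos(np.pi * t / 1000), index=1)
        assert c == pytest.approx(1.0, abs=1e-3)

    def test_orthogonal_sine_is_zero(self):
        t = np.arange(1000)
        c = cosine_content(np.sin(np.pi * t / 1000), index=1)
        assert c == pytest.approx(0.0, abs=1e-3)

    def test_constant_series_is_zero(self):
        c = cosine_content(np.ones(1000), index=1)
        assert c == pytest.approx(0.0, abs=1e-3)

    def test_second_component(self):
        t = np.arange(2000)
        c = cosine_content(np.cos(2 * np.pi * t / 2000), index=2)
        assert c == pytest.approx(1.0, abs=1e-3)

    def test_all_zero_series_undefined(self):
        with pytest.raises(ValueError):
            cosine_content(np.zeros(100))


class TestRMSIP:
    def basis(self, rng, dim=30, k=6):
        q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
        return q.T[:k]

    def test_self_is_exactly_one(self):
        rng = np.random.default_rng(0)
        a = self.basis(rng)
        assert rmsip(a, a, 6) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_subspaces_zero(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((30, 30)))
        assert rmsip(q.T[:5], q.T[5:10], 5) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_within_span_invariant(self):
        rng = np.random.default_rng(2)
        a = self.basis(rng, k=6)
        rot, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        b = rot @ a
        assert rmsip(a, b, 6) == pytest.approx(1.0, abs=1e-10)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = self.basis(rng), self.basis(rng)
        assert rmsip(a, b, 6) == pytest.approx(rmsip(b, a, 6), abs=1e-12)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            rmsip(self.basis(rng, dim=30), self.basis(rng, dim=27), 5)


class TestLDAConsistency:
    def test_identical_replicas_consistent(self):
        rng = np.random.default_rng(0)
        proj = {f"r{i}": rng.standard_normal((100, 2)) for i in range(3)}
        report = lda_consistency(proj)
        assert report.all_consistent

    def test_separated_replicas_inconsistent(self):
        rng = np.random.default_rng(1)
        proj = {f"r{i}": rng.standard_normal((100, 2)) + i * 100.0
                for i in range(3)}
        report = lda_consistency(proj)
        assert not any(p.consistent for p in report.pairs)

    def test_single_frame_replica_rejected(self):
        with pytest.raises(ValueError):
            lda_consistency({"a": np.zeros((1, 2)), "b": np.zeros((5, 2))})

    def test_matches_sklearn_fisher_direction(self):
        """Hand-rolled Fisher LD1 agrees with sklearn's eigen-solver LDA."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(5)
        x1 = rng.standard_normal((200, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]])
        x2 = rng.standard_normal((200, 2)) + np.array([1.5, -1.0])
        report = lda_consistency({"a": x1, "b": x2})
        w = report.pairs[0].direction
        skl = LinearDiscriminantAnalysis(solver="eigen")
        skl.fit(np.vstack([x1, x2]), [0] * 200 + [1] * 200)
        w_skl = skl.scalings_[:, 0]
        w_skl = w_skl / np.linalg.norm(w_skl)
        assert abs(abs(w @ w_skl) - 1.0) < 1e-6


class TestReplicaDiagnostics:
    def test_exchangeable_replicas(self):
        spec = mode_spec(variances=(4.0, 1.0))
        reps = make_replica_set(spec, 3, 200, 0.0, seed=1)
        sub, lda = replica_diagnostics(reps, dimension=4)
        assert lda.all_consistent
        assert all(0.0 <= v <= 1.0 for v in sub.rmsip.values())
        assert 0.0 <= sub.es_fraction <= 1.0

    def test_offset_replicas_flagged(self):
        spec = mode_spec(variances=(4.0, 1.0))
        reps = make_replica_set(spec, 3, 200, 200.0, seed=2)
        _sub, lda = replica_diagnostics(reps, dimension=4)
        assert not any(p.consistent for p in lda.pairs)
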