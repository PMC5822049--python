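"""Shape projection: losses, planted recovery, penalization behavior."""

import numpy as np
import pytest

from shapereadout.fixtures import BindingSpec, TableSpec, make_planted_model, make_table
from shapereadout.models import MechanismAgnosticModel, to_sequence_representation
from shapereadout.projection import (
    ProjectionConfig,
    loss_affinity,
    loss_kl,
    project,
    unpenalized_project,
)
from shapereadout.seq2shape import MONO_DI, fit as fit_seq2shape

from conftest import random_agn


@pytest.fixture(scope="module")
def planted_setup():
    tbl = make_table(TableSpec(), seed=21)
    srm, agn = make_planted_model(
        BindingSpec(footprint=8, base_scale=0.5, planted=((tbl.feature_name, 4, -1.0),)),
        {tbl.feature_name: tbl},
        seed=21,
    )
    s2s = {tbl.feature_name: fit_seq2shape(tbl, MONO_DI)}
    return tbl.feature_name, srm, agn, s2s


class TestLosses:
    def test_identical_models_have_zero_loss(self, rng):
        m = random_agn(4, rng)
        assert loss_kl(m, m) == pytest.approx(0.0, abs=1e-12)
        assert loss_affinity(m, m) == pytest.approx(0.0, abs=1e-6)

    def test_kl_ignores_intercept_differences(self, rng):
        m = random_agn(4, rng)
        shifted = MechanismAgnosticModel(4, m.beta0 + 3.0, m.beta1, m.beta2)
        assert loss_kl(m, shifted) == pytest.approx(0.0, abs=1e-10)

    def test_affinity_loss_matches_enumeration(self, rng):
        a, b = random_agn(4, rng), random_agn(4, rng)
        brute = float(np.sum((np.exp(a.score_all()) - np.exp(b.score_all())) ** 2))
        assert loss_affinity(a, b) == pytest.approx(brute, rel=1e-10)

    def test_affinity_loss_symmetric_in_arguments(self, rng):
        a, b = random_agn(4, rng), random_agn(4, rng)
        assert loss_affinity(a, b) == pytest.approx(loss_affinity(b, a), rel=1e-10)

    def test_kl_matches_enumeration_and_is_nonnegative(self, rng):
        for _ in range(20):
            a, b = random_agn(4, rng), random_agn(4, rng)
            pa = np.exp(a.score_all())
            pa /= pa.sum()
            pb = np.exp(b.score_all())
            pb /= pb.sum()
            brute = float(np.sum(pa * np.log(pa / pb)))
            v = loss_kl(a, b)
            assert v == pytest.approx(brute, rel=1e-9, abs=1e-12)
            assert v >= -1e-12


class TestUnpenalized:
    def test_planted_model_reaches_zero_loss(self, planted_setup):
        _, _, agn, s2s = planted_setup
        res = unpenalized_project(agn, s2s, ProjectionConfig(loss="kl"))
        assert res.loss < 1e-8

    def test_unpenalized_loss_not_above_penalized(self, planted_setup):
        name, _, agn, s2s = planted_setup
        cfg = ProjectionConfig(loss="kl")
        unpen = unpenalized_project(agn, s2s, cfg)
        pen = project(agn, s2s, cfg)
        assert unpen.loss <= pen.loss + 1e-9

    def test_near_null_instability_leaves_scores_stable(self, planted_setup):
        """Perturbed starting points may wander along near-null parameter
        directions, but the implied sequence-only scores agree."""
        name, _, agn, s2s = planted_setup
        cfg = ProjectionConfig(loss="kl")
        r1 = unpenalized_project(agn, s2s, cfg)
        # second run: start from a perturbation by refitting with the
        # stage-1 route of project (different path, same optimum class)
        r2 = project(agn, s2s, ProjectionConfig(loss="kl", lambda_mono=1e-9, lambda_shape=1e-9))
        s1 = to_sequence_representation(r1.model).score_all()
        s2 = to_sequence_representation(r2.model).score_all()
        np.testing.assert_allclose(s1 - s1.mean(), s2 - s2.mean(), atol=1e-5)


class TestPenalized:
    def test_minimal_norm_recovery_of_planted_profile(self, planted_setup):
        name, srm, agn, s2s = planted_setup
        res = project(
            agn, s2s, ProjectionConfig(loss="kl", lambda_mono=1e-6, lambda_shape=1e-6)
        )
        assert res.loss < 1e-8
        got, want = res.model.profiles[name], srm.profiles[name]
        inner = slice(2, 6)
        assert np.corrcoef(got[inner], want[inner])[0, 1] > 0.99

    def test_strong_shape_penalty_drives_profiles_to_zero(self, planted_setup, rng):
        name, _, _, s2s = planted_setup
        k = 8
        agn = MechanismAgnosticModel(k, 0.0, rng.normal(size=(k, 4)), None)
        res = project(
            agn, s2s, ProjectionConfig(loss="kl", lambda_shape=1e6, lambda_mono=1e-9)
        )
        assert np.max(np.abs(res.model.profiles[name])) < 1e-3
        np.testing.assert_allclose(
            res.model.beta1 - res.model.beta1.mean(axis=1, keepdims=True),
            agn.beta1 - agn.beta1.mean(axis=1, keepdims=True),
            atol=1e-3,
        )

    def test_profile_norm_shrinks_monotonically_in_lambda_shape(self, planted_setup):
        # a model with generic dinucleotide structure (not exactly
        # representable), so the reference loss is nonzero and the
        # normalized objective well-conditioned
        name, _, _, s2s = planted_setup
        rng = np.random.default_rng(5)
        agn = MechanismAgnosticModel(
            8, 0.0, rng.normal(0, 0.5, (8, 4)), rng.normal(0, 0.15, (7, 16))
        )
        norms = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            res = project(agn, s2s, ProjectionConfig(loss="kl", lambda_shape=lam))
            norms.append(np.sum(res.model.profiles[name] ** 2))
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_result_sequence_representation_reproduces_scores(self, planted_setup):
        name, _, agn, s2s = planted_setup
        res = project(agn, s2s, ProjectionConfig(loss="kl"))
        seq = to_sequence_representation(res.model)
        np.testing.assert_allclose(
            res.model.score_all(), seq.score_all(), atol=1e-9
        )

    def test_l1_penalty_path_runs_and_sparsifies(self, planted_setup):
        name, _, agn, s2s = planted_setup
        res = project(agn, s2s, ProjectionConfig(loss="kl", p=1))
        prof = res.model.profiles[name]
        assert res.converged
        # planted single position dominates; L1 suppresses the others
        assert np.argmax(np.abs(prof)) == 4

    def test_affinity_loss_agrees_with_kl_on_small_perturbations(self, rng):
        """Both losses rank small gauge-fixed perturbations of a base model
        alike.  Perturbations are centered per position/step because a
        per-position mean shift is pure gauge (it rescales every affinity
        identically): the KL loss is exactly invariant to it while the
        affinity loss is not, so uncentered perturbations would compare
        models that induce identical sequence distributions."""
        cors = []
        for _ in range(6):
            base = MechanismAgnosticModel(
                5, 0.0, rng.normal(0, 0.2, (5, 4)), rng.normal(0, 0.07, (4, 16))
            )
            kl, aff = [], []
            for _ in range(100):
                d1 = rng.normal(0, 0.02, (5, 4))
                d1 -= d1.mean(axis=1, keepdims=True)
                d2 = rng.normal(0, 0.02, (4, 16))
                d2 -= d2.mean(axis=1, keepdims=True)
                pert = MechanismAgnosticModel(5, 0.0, base.beta1 + d1, base.beta2 + d2)
                kl.append(loss_kl(base, pert))
                aff.append(loss_affinity(base, pert))
            cors.append(np.corrcoef(kl, aff)[0, 1])
        assert np.median(cors) > 0.9

    def test_rc_symmetric_inputs_give_rc_symmetric_profile(self):
        tbl = make_table(TableSpec(), seed=33)
        k = 8
        prof = np.zeros(k)
        prof[3] = prof[4] = -0.7
        rng = np.random.default_rng(33)
        b1 = rng.normal(0, 0.4, size=(k, 4))
        b1 = 0.5 * (b1 + b1[::-1, ::-1])
        from shapereadout.models import ShapeReadoutModel

        s2s = {tbl.feature_name: fit_seq2shape(tbl, MONO_DI)}
        srm = ShapeReadoutModel(k, 0.0, b1, {tbl.feature_name: prof}, s2s)
        agn = to_sequence_representation(srm)
        res = project(agn, s2s, ProjectionConfig(loss="kl"))
        got = res.model.profiles[tbl.feature_name]
        np.testing.assert_allclose(got, got[::-1], atol=1e-4)
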