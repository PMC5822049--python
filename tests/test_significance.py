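"""Conditional-variance matching, null ensembles, empirical FDR."""

import numpy as np
import pytest

from shapereadout._seq import all_kmer_codes
from shapereadout.fixtures import BindingSpec, TableSpec, make_planted_model, make_table
from shapereadout.models import MechanismAgnosticModel
from shapereadout.projection import ProjectionConfig, project
from shapereadout.seq2shape import MONO_DI, fit as fit_seq2shape
from shapereadout.significance import (
    NullEnsemble,
    conditional_variance,
    null_bands,
    position_fdr,
    random_matched_table,
)
from shapereadout.tables import (
    BASE_CENTERED,
    KmerShapeTable,
    permute_table,
    reverse_complement_symmetrize,
)


def _brute_C(values, k, i, j):
    codes = all_kmer_codes(k)
    tot, n = 0.0, 0
    for c in range(4):
        for d in range(4):
            if i == j and c != d:
                continue
            mask = (codes[:, i] == c) & (codes[:, j] == d)
            tot += values[mask].var()
            n += 1
    return tot / n


class TestConditionalVariance:
    def test_constant_table_has_zero_C(self):
        t = KmerShapeTable("x", 4, BASE_CENTERED, np.full(256, 2.0))
        assert np.all(conditional_variance(t).C == 0)

    def test_single_position_indicator_pattern(self):
        """A table indicating base A at position 3 (k=5) has zero C when
        either conditioned position is 3, and the table variance else."""
        codes = all_kmer_codes(5)
        vals = (codes[:, 2] == 0).astype(float)
        t = KmerShapeTable("x", 5, BASE_CENTERED, vals)
        C = conditional_variance(t).C
        v = vals.var()
        for i in range(5):
            for j in range(5):
                want = 0.0 if (i == 2 or j == 2) else v
                assert C[i, j] == pytest.approx(want, abs=1e-12)

    def test_matches_brute_force_double_loop(self, mgw_like_table):
        C = conditional_variance(mgw_like_table).C
        for i, j in [(0, 0), (1, 3), (2, 4), (4, 4)]:
            assert C[i, j] == pytest.approx(
                _brute_C(mgw_like_table.values, 5, i, j), rel=1e-10
            )

    def test_symmetries(self, mgw_like_table):
        cv = conditional_variance(mgw_like_table)
        C = cv.C
        np.testing.assert_allclose(C, C.T)
        # RC symmetry: C_ij = C_{k-1-j, k-1-i} for an RC-symmetric table
        k = 5
        for i in range(k):
            for j in range(k):
                assert C[i, j] == pytest.approx(C[k - 1 - j, k - 1 - i], rel=1e-9)
        assert np.all(C <= cv.total_variance + 1e-12)


class TestMatchedTables:
    def test_requires_symmetric_reference(self, rng):
        t = KmerShapeTable("x", 5, BASE_CENTERED, rng.normal(size=1024))
        with pytest.raises(ValueError, match="symmetric"):
            random_matched_table(t, 0)

    def test_constant_reference_gives_near_constant_result(self):
        t = KmerShapeTable("x", 4, BASE_CENTERED, np.full(256, 3.0))
        mt, _ = random_matched_table(t, 5)
        assert mt.values.std() < 1e-3

    def test_output_rc_symmetric_and_matching_error_small(self, mgw_like_table):
        rels = []
        for seed in range(30):
            mt, rel = random_matched_table(mgw_like_table, seed)
            assert mt.is_rc_symmetric(tol=1e-9)
            rels.append(rel)
        assert np.median(rels) < 0.15

    def test_conditional_variance_structure_correlates_with_reference(self, mgw_like_table):
        C_ref = conditional_variance(mgw_like_table).C
        iu = np.triu_indices(5)
        cors = []
        for seed in range(15):
            mt, _ = random_matched_table(mgw_like_table, 100 + seed)
            C = conditional_variance(mt).C
            cors.append(np.corrcoef(C[iu], C_ref[iu])[0, 1])
        assert np.median(cors) > 0.9


@pytest.fixture(scope="module")
def small_ensemble():
    tbl = make_table(TableSpec(), seed=77)
    srm, agn = make_planted_model(
        BindingSpec(footprint=7, base_scale=0.5, planted=((tbl.feature_name, 3, -1.0),)),
        {tbl.feature_name: tbl},
        seed=77,
    )
    cfg = ProjectionConfig(loss="kl", features=(tbl.feature_name,))
    s2s = {tbl.feature_name: fit_seq2shape(tbl, MONO_DI)}
    obs = project(agn, s2s, cfg)
    ens = null_bands(agn, {tbl.feature_name: tbl}, cfg, N=60, seed=5)
    return tbl, agn, cfg, obs, ens


class TestNullBands:
    def test_empty_ensemble_rejected(self, mgw_like_table, rng):
        agn = MechanismAgnosticModel(6, 0.0, rng.normal(size=(6, 4)), None)
        with pytest.raises(ValueError, match="positive"):
            null_bands(agn, {"synthetic-MGW": mgw_like_table}, ProjectionConfig(), 0, 1)

    def test_band_pairs_are_nested(self, small_ensemble):
        tbl, _, _, _, ens = small_ensemble
        b = ens.bands[tbl.feature_name]  # rows: 2.5, 25, 75, 97.5 percentiles
        assert np.all(b[0] <= b[1] + 1e-12)
        assert np.all(b[1] <= b[2] + 1e-12)
        assert np.all(b[2] <= b[3] + 1e-12)

    def test_planted_position_escapes_the_null_band(self, small_ensemble):
        tbl, _, _, obs, ens = small_ensemble
        prof = obs.model.profiles[tbl.feature_name]
        b = ens.bands[tbl.feature_name]
        assert prof[3] < b[0][3]  # planted narrowing below the 2.5 percentile


class TestPositionFDR:
    def test_zero_observed_profile_gives_all_ones(self, small_ensemble):
        tbl, _, _, _, ens = small_ensemble
        obs = {tbl.feature_name: np.zeros(7)}
        res = position_fdr(obs, ens, 7)[tbl.feature_name]
        assert np.all(res["q"] == 1.0)

    def test_extreme_outlier_bh_arithmetic(self, small_ensemble):
        tbl, _, _, _, ens = small_ensemble
        N = ens.N
        obs_prof = np.zeros(7)
        obs_prof[3] = 1e6  # beyond every null everywhere
        res = position_fdr({tbl.feature_name: obs_prof}, ens, 7)[tbl.feature_name]
        i = list(res["positions"]).index(3)
        assert res["p"][i] == pytest.approx(1.0 / (N + 1))
        n_pos = res["positions"].size
        assert res["q"][i] == pytest.approx(n_pos / (N + 1))

    def test_planted_readout_attains_minimum_q(self, small_ensemble):
        tbl, _, _, obs, ens = small_ensemble
        res = position_fdr(obs.model.profiles, ens, 7)[tbl.feature_name]
        i = list(res["positions"]).index(3)
        assert res["q"][i] == res["q"].min()
        assert res["q"][i] <= 0.1


class TestNullComparison:
    def test_matched_nulls_wider_than_permutation_nulls(self):
        """Complexity-matched nulls absorb more of the model's structure as
        apparent shape readout than naive permutation nulls do, giving
        wider null bands (scaled-down check).

        The comparison is made in free-energy units (coefficient times the
        standard deviation of the table's fitted shape predictions):
        sensitivity coefficients are per unit shape, and a permuted table
        fits an almost-flat mono+di model, which would mechanically inflate
        its per-unit-shape coefficients and make the raw comparison a
        statement about units rather than structure."""
        tbl = make_table(TableSpec(), seed=99)
        rng = np.random.default_rng(2)
        k = 6
        beta1 = rng.normal(0, 0.5, (k, 4))
        agn = MechanismAgnosticModel(k, 0.0, beta1, rng.normal(0, 0.15, (k - 1, 16)))
        cfg = ProjectionConfig(loss="kl", features=(tbl.feature_name,))
        widths = {"matched": [], "permuted": []}
        for n in range(25):
            mt, _ = random_matched_table(tbl, 200 + n)
            pt = permute_table(tbl, 300 + n)
            for tag, t in (("matched", mt), ("permuted", pt)):
                m = fit_seq2shape(t, MONO_DI)
                res = project(agn, {tbl.feature_name: m}, cfg)
                widths[tag].append(
                    np.max(np.abs(res.model.profiles[tbl.feature_name]))
                    * m.predict_all().std()
                )
        assert np.median(widths["matched"]) > np.median(widths["permuted"])
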