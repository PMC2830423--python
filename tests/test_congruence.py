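"""Per-amino-acid congruence and convergence statistics."""

import numpy as np
import pytest
from scipy import stats

import ribochron as rc
from ribochron.usage import AMINO_ACIDS, DeltaProfile


def make_profile(delta, se):
    return DeltaProfile(np.asarray(delta, float), np.asarray(se, float), "rate_difference")


class TestPositionZ:
    def test_equal_deltas_zero(self):
        assert rc.position_z((0.1, 0.02), (0.1, 0.05)) == 0.0

    def test_closed_form(self):
        z = rc.position_z((0.1, 0.05 / np.sqrt(2)), (0.0, 0.05 / np.sqrt(2)))
        assert z == pytest.approx(2.0)

    def test_hand_vector(self):
        pairs = [((0.1, 0.1), (0.0, 0.1)), ((0.0, 0.2), (0.2, 0.2)),
                 ((-0.1, 0.05), (-0.1, 0.05)), ((0.3, 0.3), (0.0, 0.4))]
        expect = [0.1 / np.sqrt(0.02), -0.2 / np.sqrt(0.08), 0.0, 0.3 / 0.5]
        got = [rc.position_z(a, b) for a, b in pairs]
        assert got == pytest.approx(expect)

    def test_both_se_zero_unequal(self):
        with pytest.raises(ValueError, match="infinite"):
            rc.position_z((0.1, 0.0), (0.2, 0.0))

    def test_antisymmetry(self):
        a, b = (0.12, 0.03), (-0.05, 0.07)
        assert rc.position_z(a, b) == pytest.approx(-rc.position_z(b, a))


class TestWeightedZ:
    def test_equal_weights_reduce_to_stouffer(self):
        z = [1.0, -0.5, 2.0]
        se = [(0.1, 0.1)] * 3
        zw, _ = rc.weighted_z(z, se)
        assert zw == pytest.approx(sum(z) / np.sqrt(3))

    def test_single_position(self):
        zw, p = rc.weighted_z([1.5], [(0.1, 0.2)])
        assert zw == pytest.approx(1.5)
        assert p == pytest.approx(2 * stats.norm.sf(1.5))

    def test_all_zero(self):
        zw, p = rc.weighted_z([0.0, 0.0], [(0.1, 0.1), (0.2, 0.2)])
        assert zw == 0.0 and p == 1.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            rc.weighted_z([1.0], [(0.0, 0.0)])


class TestConvergenceZ:
    def test_no_change(self):
        assert rc.convergence_z((0.1, 0.02), (0.1, 0.02)) == 0.0

    def test_five_to_one_se(self):
        z = rc.convergence_z((0.10, 0.02), (0.02, 0.02))
        assert z == pytest.approx(-4.0)
        assert z < -rc.CONVERGENCE_Z

    def test_toy_arithmetic(self):
        assert rc.convergence_z((-0.1, 0.02), (-0.01, 0.02)) == pytest.approx(-4.5)

    def test_sign_invariance_of_trajectory(self):
        a = rc.convergence_z((0.1, 0.02), (0.02, 0.01))
        b = rc.convergence_z((-0.1, 0.02), (-0.02, 0.01))
        assert a == pytest.approx(b)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rc.convergence_z((0.1, 0.0), (0.1, 0.1))


class TestCongruenceTable:
    def test_identical_profiles_fully_congruent(self):
        rng = np.random.default_rng(1)
        d = make_profile(rng.normal(0, 0.01, (5, 20)), np.full((5, 20), 0.02))
        aln = rc.ChronologyAlignment(tuple((i, i) for i in range(1, 6)))
        rep = rc.congruence_table(d, d, aln)
        assert (rep.table["congruent_positions"] == 5).all()
        assert np.allclose(rep.table["p"], 1.0)
        assert np.allclose(rep.table["z_w"], 0.0)

    def test_two_se_everywhere_never_congruent(self):
        n = 4
        dL = make_profile(np.zeros((n, 20)), np.full((n, 20), 0.05 / np.sqrt(2)))
        dS = make_profile(np.full((n, 20), 0.1), np.full((n, 20), 0.05 / np.sqrt(2)))
        aln = rc.ChronologyAlignment(tuple((i, i) for i in range(1, n + 1)))
        rep = rc.congruence_table(dL, dS, aln)
        assert (rep.table["congruent_positions"] == 0).all()

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        dL = make_profile(rng.normal(0, 0.02, (4, 20)), np.full((4, 20), 0.02))
        dS = make_profile(rng.normal(0, 0.02, (4, 20)), np.full((4, 20), 0.02))
        aln = rc.ChronologyAlignment(tuple((i, i) for i in range(1, 5)))
        r1 = rc.congruence_table(dL, dS, aln)
        r2 = rc.congruence_table(dS, dL, aln)
        for aa in AMINO_ACIDS:
            assert r1.position_scores[aa] == pytest.approx(
                [-z for z in r2.position_scores[aa]]
            )
        assert np.allclose(np.abs(r1.table["z_w"]), np.abs(r2.table["z_w"]))
        assert (r1.table["congruent_positions"] == r2.table["congruent_positions"]).all()

    def test_alignment_outside_profiles_rejected(self):
        d = make_profile(np.zeros((3, 20)), np.full((3, 20), 0.01))
        aln = rc.ChronologyAlignment(((1, 1), (4, 2)))
        with pytest.raises(ValueError, match="outside"):
            rc.congruence_table(d, d, aln)

    def test_late_added_amino_acids_converge_as_group(self):
        """Late code additions converge toward expectation; early ones start high.

        Endpoint-level Z_V for any single amino acid is noisy, so the
        assertion is at the group level: the six latest additions of the
        default schedule show mean Z_V(ave) < -1 in most worlds, while the
        four earliest amino acids are over-represented (positive delta) at
        the first chronology position — their excess, forced by the
        absence of later amino acids, is what subsequently decays.
        """
        late, early = list("FCMHYW"), list("GADV")
        late_conv, early_over, n = 0, 0, 20
        early_idx = [AMINO_ACIDS.index(a) for a in early]
        for seed in range(60, 60 + n):
            w = rc.simulate_world(seed=seed)
            L, S = w.subunits["LSU"], w.subunits["SSU"]
            dL = rc.delta_profile(rc.reo_matrix(L.ruleset), L.usage)
            dS = rc.delta_profile(rc.reo_matrix(S.ruleset), S.usage)
            k = min(dL.n_positions, dS.n_positions)
            aln = rc.ChronologyAlignment(tuple((i, i) for i in range(1, k + 1)))
            rep = rc.congruence_table(dL, dS, aln)
            late_conv += rep.table.loc[late, "z_v_ave"].mean() < -rc.CONVERGENCE_Z
            early_over += dL.delta[0, early_idx].sum() > 0
        assert late_conv / n >= 0.75
        assert early_over / n >= 0.9

    def test_consistently_convergent_rule(self):
        rng = np.random.default_rng(3)
        # profiles where every AA moves from 5 SE to 0.5 SE from zero
        n = 3
        dL = make_profile(
            np.vstack([np.full(20, 0.10), np.full(20, 0.05), np.full(20, 0.01)]),
            np.full((n, 20), 0.02),
        )
        aln = rc.ChronologyAlignment(tuple((i, i) for i in range(1, n + 1)))
        rep = rc.congruence_table(dL, dL, aln)
        assert rep.table["consistently_convergent"].all()
        assert rep.z_v_lsu_ave == pytest.approx(rep.z_v_ssu_ave)
        assert rep.z_v_lsu_ave < -1

    def test_report_serialization(self, tmp_path):
        d = make_profile(np.zeros((3, 20)), np.full((3, 20), 0.01))
        aln = rc.ChronologyAlignment(tuple((i, i) for i in range(1, 4)))
        rep = rc.congruence_table(d, d, aln)
        rep.to_tsv(tmp_path / "r.tsv")
        text = (tmp_path / "r.tsv").read_text()
        assert "3/3" in text
        import json
        j = json.loads(rep.to_json())
        assert set(j["per_aa"]) == set(AMINO_ACIDS)


def test_weighted_z_type_one_error_under_null():
    """Rejection rate of the weighted Z-transform is ~5% on null worlds."""
    rng = np.random.default_rng(7)
    rejections = []
    for _ in range(400):
        k = 6
        se = 0.02
        zL = rng.normal(0, se, (k, 20))
        zS = rng.normal(0, se, (k, 20))
        dL = make_profile(zL, np.full((k, 20), se))
        dS = make_profile(zS, np.full((k, 20), se))
        aln = rc.ChronologyAlignment(tuple((i, i) for i in range(1, k + 1)))
        rep = rc.congruence_table(dL, dS, aln)
        rejections.append((rep.table["p"] < 0.05).mean())
    assert abs(np.mean(rejections) - 0.05) < 0.02
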