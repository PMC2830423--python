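"""RMSD matrices, the permutation background, and structure tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

import ribochron as rc
from ribochron.chronology import randomized_residuals, RmsdMatrix
from ribochron.usage import AMINO_ACIDS, DeltaProfile, UsageTable


def toy_profile(deltas):
    d = np.asarray(deltas, dtype=float)
    return DeltaProfile(d, np.full_like(d, 0.01), "rate_difference")


class TestRmsd:
    def test_equal_profiles_zero_diagonal(self):
        d = toy_profile(np.random.default_rng(0).normal(size=(3, 20)) * 0.01)
        m = rc.rmsd_matrix(d, d)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_single_amino_acid_offset_closed_form(self):
        a = np.zeros((1, 20))
        b = np.zeros((1, 20))
        b[0, 0] = 0.1
        m = rc.rmsd_matrix(toy_profile(a), toy_profile(b))
        assert m.values[0, 0] == pytest.approx(0.1 / np.sqrt(20))

    def test_two_by_two_hand_computed(self):
        dL = np.zeros((2, 20))
        dS = np.zeros((2, 20))
        dL[0, :2] = [0.1, -0.1]
        dS[1, :2] = [0.3, 0.1]
        m = rc.rmsd_matrix(toy_profile(dL), toy_profile(dS))
        assert m.values[0, 0] == pytest.approx(np.sqrt(0.02 / 20))
        assert m.values[0, 1] == pytest.approx(np.sqrt((0.04 + 0.04) / 20))
        assert m.values[1, 1] == pytest.approx(np.sqrt((0.09 + 0.01) / 20))

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(1)
        dL = toy_profile(rng.normal(size=(3, 20)) * 0.01)
        dS = toy_profile(rng.normal(size=(4, 20)) * 0.01)
        assert np.allclose(
            rc.rmsd_matrix(dL, dS).values, rc.rmsd_matrix(dS, dL).values.T
        )


def random_doubly_stochastic(rng, n, k=4):
    """Average of k random permutation matrices: doubly stochastic, non-uniform."""
    P = np.zeros((n, n))
    for _ in range(k):
        P[np.arange(n), rng.permutation(n)] += 1 / k
    return P


def tiny_tables(rng, nL=3, nS=3):
    tL = UsageTable("LSU", tuple(f"L{k}" for k in range(nL)),
                    rng.integers(1, 20, (nL, 20)), rng.integers(1, 20, (nL, 20)))
    tS = UsageTable("SSU", tuple(f"S{k}" for k in range(nS)),
                    rng.integers(1, 20, (nS, 20)), rng.integers(1, 20, (nS, 20)))
    reoL = rc.ReoMatrix(tL.proteins, random_doubly_stochastic(rng, nL), {"method": "exact"})
    reoS = rc.ReoMatrix(tS.proteins, random_doubly_stochastic(rng, nS), {"method": "exact"})
    return tL, tS, reoL, reoS


class TestBackground:
    def test_single_protein_background_equals_raw(self):
        rng = np.random.default_rng(2)
        tL, tS, reoL, reoS = tiny_tables(rng, nL=1, nS=1)
        dL = rc.delta_profile(reoL, tL)
        dS = rc.delta_profile(reoS, tS)
        raw = rc.rmsd_matrix(dL, dS)
        with pytest.warns(UserWarning, match="vacuous"):
            bg = rc.background_matrix(tL, tS, reoL, reoS, reps=3, seed=0)
        assert np.allclose(bg.values, raw.values)

    def test_identical_usage_vectors_invariant(self):
        U = np.full((3, 20), 4, dtype=int)
        D = np.full((3, 20), 2, dtype=int)
        tL = UsageTable("LSU", ("L0", "L1", "L2"), U, D)
        tS = UsageTable("SSU", ("S0", "S1", "S2"), U + 1, D + 1)
        reoL = rc.ReoMatrix(tL.proteins, np.eye(3))
        reoS = rc.ReoMatrix(tS.proteins, np.eye(3))
        raw = rc.rmsd_matrix(rc.delta_profile(reoL, tL), rc.delta_profile(reoS, tS))
        bg = rc.background_matrix(tL, tS, reoL, reoS, reps=5, seed=1)
        assert np.allclose(bg.values, raw.values)

    def test_monte_carlo_matches_exhaustive_permutations(self):
        """Background converges to the exact average over all 3!x3! pairs."""
        rng = np.random.default_rng(3)
        tL, tS, reoL, reoS = tiny_tables(rng)
        # exact average over all permutation pairs
        rUL, rDL = rc.usage_rates(tL)
        rUS, rDS = rc.usage_rates(tS)
        vL = rUL.to_numpy() - rDL.to_numpy()
        vS = rUS.to_numpy() - rDS.to_numpy()
        acc = np.zeros((3, 3))
        count = 0
        for pl in itertools.permutations(range(3)):
            dL = reoL.P.T @ vL[list(pl)]
            for ps in itertools.permutations(range(3)):
                dS = reoS.P.T @ vS[list(ps)]
                diff = dL[:, None, :] - dS[None, :, :]
                acc += np.sqrt(np.mean(diff**2, axis=2))
                count += 1
        exact = acc / count
        bg = rc.background_matrix(tL, tS, reoL, reoS, reps=4000, seed=4)
        assert np.allclose(bg.values, exact, atol=4 * exact.std() / np.sqrt(4000) + 1e-4)

    def test_relabelling_invariance(self):
        """Permuting protein labels of the inputs leaves the background unchanged."""
        rng = np.random.default_rng(5)
        tL, tS, reoL, reoS = tiny_tables(rng)
        bg1 = rc.background_matrix(tL, tS, reoL, reoS, reps=4000, seed=6)
        perm = [2, 0, 1]
        tL2 = UsageTable("LSU", tuple(tL.proteins[k] for k in perm), tL.U[perm], tL.D[perm])
        reoL2 = rc.ReoMatrix(tL2.proteins, reoL.P[perm], {"method": "exact"})
        bg2 = rc.background_matrix(tL2, tS, reoL2, reoS, reps=4000, seed=7)
        # tolerance = a few Monte-Carlo standard errors of the averaged entries
        mc_se = bg1.values.std() / np.sqrt(4000)
        assert np.allclose(bg1.values, bg2.values, atol=max(6 * mc_se, 1e-3))


class TestResidual:
    def test_background_equals_raw_gives_zero(self):
        m = RmsdMatrix(np.ones((2, 2)), "raw")
        assert np.allclose(rc.residual_matrix(m, RmsdMatrix(m.values, "background")).values, 0)

    def test_zero_background_gives_raw(self):
        m = RmsdMatrix(np.ones((2, 2)), "raw")
        z = RmsdMatrix(np.zeros((2, 2)), "background")
        assert np.allclose(rc.residual_matrix(m, z).values, m.values)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rc.residual_matrix(
                RmsdMatrix(np.ones((2, 2)), "raw"), RmsdMatrix(np.ones((2, 3)), "background")
            )

    def test_randomized_residual_mean_near_zero(self):
        """Residuals of permuted data center on zero by construction."""
        rng = np.random.default_rng(8)
        tL, tS, reoL, reoS = tiny_tables(rng, nL=4, nS=4)
        bg = rc.background_matrix(tL, tS, reoL, reoS, reps=3000, seed=9)
        rand = randomized_residuals(tL, tS, reoL, reoS, bg, 200, seed=10)
        means = np.array([r.values.mean() for r in rand])
        assert abs(means.mean()) < 3 * means.std(ddof=1) / np.sqrt(len(means))


class TestStructureTest:
    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        mats = [RmsdMatrix(rng.normal(size=(4, 4)), "residual") for _ in range(400)]
        actual = mats[0]
        rep = rc.structure_test(actual, mats[1:])
        assert abs(rep["z_var"]) < 3 and abs(rep["z_mean"]) < 3

    def test_three_sigma_closed_form(self):
        rng = np.random.default_rng(12)
        rand = [RmsdMatrix(rng.normal(size=(3, 3)), "residual") for _ in range(300)]
        vals = np.array([r.values.mean() for r in rand])
        target = vals.mean() + 3 * vals.std(ddof=1)
        base = rand[0].values
        actual = RmsdMatrix(base - base.mean() + target, "residual")
        rep = rc.structure_test(actual, rand)
        assert rep["z_mean"] == pytest.approx(3.0)
        assert rep["p_mean"] == pytest.approx(stats.norm.sf(3), rel=1e-6)

    def test_degenerate_null_rejected(self):
        rand = [RmsdMatrix(np.ones((2, 2)), "residual") for _ in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            rc.structure_test(RmsdMatrix(np.ones((2, 2)), "residual"), rand)

    def test_structured_worlds_detected(self):
        """Code drift produces detectable variance excess in most runs."""
        hits = 0
        n = 10
        for seed in range(30, 30 + n):
            w = rc.simulate_world(seed=seed)
            L, S = w.subunits["LSU"], w.subunits["SSU"]
            reoL, reoS = rc.reo_matrix(L.ruleset), rc.reo_matrix(S.ruleset)
            dL, dS = rc.delta_profile(reoL, L.usage), rc.delta_profile(reoS, S.usage)
            bg = rc.background_matrix(L.usage, S.usage, reoL, reoS, reps=150, seed=seed + 1)
            res = rc.residual_matrix(rc.rmsd_matrix(dL, dS), bg)
            st = rc.structure_test(
                res, randomized_residuals(L.usage, S.usage, reoL, reoS, bg, 40, seed=seed + 2)
            )
            hits += st["p_var"] < 0.05
        assert hits / n >= 0.8
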