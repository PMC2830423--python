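"""Conserved-site calling, U/D classification, rates and delta profiles."""

import numpy as np
import pytest

import ribochron as rc
from ribochron.usage import AMINO_ACIDS, AncestralProfile, UsageTable


def profile(rows, protein="P1", node="n1"):
    """Build a profile from {aa: prob} dicts; remainder spread uniformly."""
    sites = []
    for row in rows:
        v = np.zeros(20)
        for aa, p in row.items():
            v[AMINO_ACIDS.index(aa)] = p
        rest = 1 - v.sum()
        free = v == 0
        v[free] += rest / free.sum()
        sites.append(v)
    return AncestralProfile(protein, node, np.array(sites))


class TestCallConserved:
    def test_certain_site_called(self):
        p1 = profile([{"G": 1.0}])
        p2 = profile([{"G": 1.0}], node="n2")
        assert rc.call_conserved(p1, p2) == {(1, "G")}

    def test_identity_disagreement_excluded(self):
        p1 = profile([{"G": 0.95}])
        p2 = profile([{"A": 0.95}], node="n2")
        assert rc.call_conserved(p1, p2) == set()

    def test_threshold_boundary_inclusive(self):
        hi = profile([{"K": 0.91}])
        lo = profile([{"K": 0.89}], node="n2")
        assert rc.call_conserved(hi, lo) == set()
        both = profile([{"K": 0.90}])
        both2 = profile([{"K": 0.90}], node="n2")
        assert rc.call_conserved(both, both2) == {(1, "K")}

    def test_threshold_monotone(self):
        p1 = profile([{"G": 0.92}, {"A": 1.0}, {"W": 0.5}])
        p2 = profile([{"G": 0.91}, {"A": 1.0}, {"W": 0.5}], node="n2")
        strict = rc.call_conserved(p1, p2, threshold=1.0)
        loose = rc.call_conserved(p1, p2, threshold=0.9)
        assert strict <= loose

    def test_length_mismatch(self):
        p1 = profile([{"G": 1.0}])
        p2 = profile([{"G": 1.0}, {"A": 1.0}], node="n2")
        with pytest.raises(ValueError, match="mismatch"):
            rc.call_conserved(p1, p2)

    def test_bad_threshold(self):
        p = profile([{"G": 1.0}])
        with pytest.raises(ValueError, match="threshold"):
            rc.call_conserved(p, p, threshold=0.0)


class TestClassify:
    def test_shared_identity_universal(self):
        u, db, da = rc.classify_positions({(1, "G")}, {(1, "G")})
        assert u == {(1, "G")} and not db and not da

    def test_one_domain_only(self):
        u, db, da = rc.classify_positions({(1, "G")}, set())
        assert not u and db == {(1, "G")} and not da

    def test_conflicting_identity_feeds_both_domains(self):
        u, db, da = rc.classify_positions({(1, "G")}, {(1, "A")})
        assert not u and db == {(1, "G")} and da == {(1, "A")}


class TestRates:
    def test_simple_rates(self):
        t = UsageTable.from_sets(
            "x",
            {"P1": [(1, "G"), (2, "G"), (3, "A"), (4, "A")]},
            {"P1": [(9, "G")]},
        )
        rU, rD = rc.usage_rates(t)
        assert rU.loc["P1", "G"] == 0.5 and rU.loc["P1", "A"] == 0.5
        assert rU.loc["P1"].sum() == pytest.approx(1)

    def test_uniform_counts(self):
        U = np.ones((1, 20), dtype=int)
        t = UsageTable("x", ("P1",), U, U.copy())
        rU, rD = rc.usage_rates(t)
        assert np.allclose(rU.to_numpy(), 0.05)

    def test_zero_total_names_protein(self):
        t = UsageTable("x", ("P1",), np.ones((1, 20), dtype=int), np.zeros((1, 20), dtype=int))
        with pytest.raises(ValueError, match="P1"):
            rc.usage_rates(t)

    def test_tsv_round_trip_and_percentages(self, tmp_path):
        """Recomputed rates agree with rates from the reloaded count table."""
        rng = np.random.default_rng(5)
        t = UsageTable(
            "x", ("P1", "P2"),
            rng.integers(0, 9, (2, 20)), rng.integers(1, 9, (2, 20)),
        )
        t.to_tsv(tmp_path / "t.tsv")
        again = UsageTable.from_tsv(tmp_path / "t.tsv", "x")
        assert np.array_equal(again.U, t.U) and np.array_equal(again.D, t.D)
        rU1, _ = rc.usage_rates(t)
        rU2, _ = rc.usage_rates(again)
        assert np.allclose(rU1.to_numpy(), rU2.to_numpy())


class TestDeltaProfile:
    def one_protein_world(self):
        rng = np.random.default_rng(0)
        U = rng.integers(1, 10, (1, 20))
        D = rng.integers(1, 10, (1, 20))
        t = UsageTable("x", ("P1",), U, D)
        reo = rc.ReoMatrix(("P1",), np.ones((1, 1)), {"method": "exact"})
        return t, reo

    def test_single_protein_constant_profile(self):
        t, reo = self.one_protein_world()
        d = rc.delta_profile(reo, t)
        rU, rD = rc.usage_rates(t)
        assert np.allclose(d.delta[0], (rU.to_numpy() - rD.to_numpy())[0])

    def test_identical_rates_zero_delta(self):
        U = np.full((2, 20), 3, dtype=int)
        t = UsageTable("x", ("P1", "P2"), U, U.copy())
        reo = rc.ReoMatrix(("P1", "P2"), np.full((2, 2), 0.5))
        d = rc.delta_profile(reo, t)
        assert np.allclose(d.delta, 0.0)

    def test_hand_weighted_mean(self):
        """2 proteins x 2 positions against explicit arithmetic."""
        U = np.zeros((2, 20), dtype=int)
        D = np.zeros((2, 20), dtype=int)
        # P1: U all G (4), D all A (4); P2: U all A (4), D all G (4)
        U[0, AMINO_ACIDS.index("G")] = 4
        D[0, AMINO_ACIDS.index("A")] = 4
        U[1, AMINO_ACIDS.index("A")] = 4
        D[1, AMINO_ACIDS.index("G")] = 4
        t = UsageTable("x", ("P1", "P2"), U, D)
        P = np.array([[0.75, 0.25], [0.25, 0.75]])
        reo = rc.ReoMatrix(("P1", "P2"), P)
        d = rc.delta_profile(reo, t)
        g = AMINO_ACIDS.index("G")
        # v_G = +1 for P1, -1 for P2 -> position 1: .75*1+.25*(-1) = .5
        assert d.delta[0, g] == pytest.approx(0.5)
        assert d.delta[1, g] == pytest.approx(-0.5)

    def test_rate_difference_sums_to_zero(self, default_world):
        sub = default_world.subunits["LSU"]
        d = rc.delta_profile(rc.reo_matrix(sub.ruleset), sub.usage)
        assert np.allclose(d.delta.sum(axis=1), 0.0, atol=1e-12)

    def test_linearity_in_usage_values(self):
        t, reo = self.one_protein_world()
        d1 = rc.delta_profile(reo, t)
        t2 = UsageTable("x", ("P1",), t.U * 2, t.D * 2)  # same rates
        d2 = rc.delta_profile(reo, t2)
        assert np.allclose(d1.delta, d2.delta)

    def test_count_quotient_variant(self):
        U = np.zeros((1, 20), dtype=int)
        D = np.zeros((1, 20), dtype=int)
        U[0, 0], D[0, 0] = 6, 2  # A: (6-2)/(6-2) = 1
        t = UsageTable("x", ("P1",), U, D)
        reo = rc.ReoMatrix(("P1",), np.ones((1, 1)))
        d = rc.delta_profile(reo, t, variant="count_quotient")
        assert d.delta[0, 0] == pytest.approx(1.0)

    def test_count_quotient_equal_totals_error(self):
        U = np.zeros((1, 20), dtype=int)
        U[0, 0] = 4
        D = np.zeros((1, 20), dtype=int)
        D[0, 1] = 4
        t = UsageTable("x", ("P1",), U, D)
        reo = rc.ReoMatrix(("P1",), np.ones((1, 1)))
        with pytest.raises(ValueError, match="equal"):
            rc.delta_profile(reo, t, variant="count_quotient")

    def test_null_world_deltas_within_three_se(self):
        """With zero code drift |delta| stays within 3 SE almost everywhere."""
        w = rc.simulate_world(seed=21, drift=0.0)
        hits, cells = 0, 0
        for sub in w.subunits.values():
            d = rc.delta_profile(rc.reo_matrix(sub.ruleset), sub.usage)
            ok = np.abs(d.delta) <= 3 * d.se
            hits += ok.sum()
            cells += ok.size
        assert hits / cells >= 0.95
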