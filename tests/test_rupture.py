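"""Bell-bond rupture competition: analytic quadrature vs Monte Carlo."""

import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from mfaquant import (
    BellBond,
    DuplexSpec,
    RampProtocol,
    bond_from_duplex,
    reference_rupture_probability,
    simulate_rupture,
    solve_sample_bond,
)
from mfaquant.errors import UnsupportedGeometryError


def trapezoid_oracle(sample, reference, ramp, n_grid=400_001):
    """Independent brute-force of the competing-hazards integral on a fine grid."""
    f_hi = 1.0
    while True:
        grid = np.linspace(0.0, f_hi, n_grid)
        h_s = sample.k0 * np.exp(grid / sample.f_beta) / ramp.loading_rate
        h_r = reference.k0 * np.exp(grid / reference.f_beta) / ramp.loading_rate
        cum = cumulative_trapezoid(h_s + h_r, grid, initial=0.0)
        if cum[-1] > 35.0:  # survival < 1e-15 at the end of the grid
            break
        f_hi *= 2.0
    density = h_r * np.exp(-cum)
    return float(np.trapezoid(density, grid))


class TestBondFromDuplex:
    def test_default_rule_matches_hand_computation(self):
        bond = bond_from_duplex(DuplexSpec(20, "shear"))
        assert bond.k0 == pytest.approx(30.0 * math.exp(-0.6 * 20), rel=1e-12)
        assert bond.f_beta == 8.0

    def test_longer_shear_duplex_has_lower_off_rate(self):
        assert bond_from_duplex(DuplexSpec(40)).k0 < bond_from_duplex(DuplexSpec(20)).k0

    def test_single_bp_is_valid(self):
        bond = bond_from_duplex(DuplexSpec(1, "shear"))
        assert bond.k0 == pytest.approx(30.0 * math.exp(-0.6), rel=1e-12)

    @pytest.mark.parametrize("n_bp", [0, -3])
    def test_non_positive_length_rejected(self, n_bp):
        with pytest.raises(ValueError):
            DuplexSpec(n_bp)

    def test_unknown_geometry_rejected(self):
        with pytest.raises(UnsupportedGeometryError):
            DuplexSpec(20, "hairpin")

    def test_longer_reference_lowers_rupture_probability(self, ramp):
        sample = BellBond("sample", 1e-4, 10.0)
        probs = [
            reference_rupture_probability(sample, bond_from_duplex(DuplexSpec(n)), ramp)
            for n in (10, 15, 20, 25, 30)
        ]
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestAnalyticProbability:
    def test_identical_bonds_split_evenly(self, ramp):
        bond = BellBond("b", 1e-4, 10.0)
        assert reference_rupture_probability(bond, bond, ramp) == pytest.approx(0.5, abs=1e-6)

    def test_dominant_reference_hazard(self, ramp):
        sample = BellBond("s", 1e-4, 10.0)
        reference = BellBond("r", 1e-1, 10.0)
        assert reference_rupture_probability(sample, reference, ramp) > 0.99

    def test_agrees_with_trapezoid_oracle(self, ramp):
        sample = BellBond("s", 1e-4, 10.0)
        reference = BellBond("r", 1e-3, 10.0)
        p = reference_rupture_probability(sample, reference, ramp)
        assert p == pytest.approx(trapezoid_oracle(sample, reference, ramp), abs=1e-4)

    @pytest.mark.parametrize("k0s,fbs,k0r,fbr", [
        (1e-4, 10.0, 1e-3, 10.0),
        (1e-2, 5.0, 1e-5, 12.0),
        (3e-6, 7.0, 3e-6, 9.0),
    ])
    def test_swap_symmetry_probabilities_sum_to_one(self, ramp, k0s, fbs, k0r, fbr):
        s = BellBond("s", k0s, fbs)
        r = BellBond("r", k0r, fbr)
        p = reference_rupture_probability(s, r, ramp)
        q = reference_rupture_probability(r, s, ramp)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-6)

    def test_sample_weakening_raises_reference_survival(self, ramp):
        reference = BellBond("r", 1e-4, 10.0)
        probs = [
            reference_rupture_probability(BellBond("s", k0, 10.0), reference, ramp)
            for k0 in (1e-6, 1e-5, 1e-4, 1e-3)
        ]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_force_cap_censors_probability_mass(self):
        bond = BellBond("b", 1e-4, 10.0)
        capped = RampProtocol(loading_rate=100.0, f_max=60.0)
        p = reference_rupture_probability(bond, bond, capped)
        # by symmetry both bonds get probability p; the rest survives the ramp
        assert 2 * p < 1.0


class TestKineticMonteCarlo:
    def test_zero_replicates_gives_empty_frame(self, ramp):
        bond = BellBond("b", 1e-4, 10.0)
        df = simulate_rupture(bond, bond, ramp, 0, seed=1)
        assert len(df) == 0
        assert list(df.columns) == ["replicate", "winner", "rupture_force_pN"]

    def test_negative_n_rejected(self, ramp):
        bond = BellBond("b", 1e-4, 10.0)
        with pytest.raises(ValueError):
            simulate_rupture(bond, bond, ramp, -1, seed=1)

    def test_seed_reproducibility(self, ramp):
        s = BellBond("s", 1e-4, 10.0)
        r = BellBond("r", 1e-3, 10.0)
        a = simulate_rupture(s, r, ramp, 500, seed=42)
        b = simulate_rupture(s, r, ramp, 500, seed=42)
        assert a.equals(b)
        assert not a.equals(simulate_rupture(s, r, ramp, 500, seed=43))

    def test_identical_bonds_fraction_near_half(self, ramp):
        bond = BellBond("b", 1e-4, 10.0)
        n = 20000
        frac = (simulate_rupture(bond, bond, ramp, n, seed=1).winner == "reference").mean()
        assert abs(frac - 0.5) < 4 * math.sqrt(0.25 / n)

    def test_fraction_matches_analytic_probability(self, ramp):
        s = BellBond("s", 1e-4, 10.0)
        r = BellBond("r", 1e-3, 10.0)
        p = reference_rupture_probability(s, r, ramp)
        n = 50000
        frac = (simulate_rupture(s, r, ramp, n, seed=7).winner == "reference").mean()
        assert abs(frac - p) < 4 * math.sqrt(p * (1 - p) / n)

    @pytest.mark.parametrize("case", range(5))
    def test_oracle_agreement_random_parameters(self, ramp, case):
        rng = np.random.default_rng(100 + case)
        s = BellBond("s", 10.0 ** rng.uniform(-6, -1), rng.uniform(4, 15))
        r = BellBond("r", 10.0 ** rng.uniform(-6, -1), rng.uniform(4, 15))
        p = reference_rupture_probability(s, r, ramp)
        n = 20000
        frac = (simulate_rupture(s, r, ramp, n, seed=case).winner == "reference").mean()
        se = math.sqrt(max(p * (1 - p), 1e-6) / n)
        assert abs(frac - p) <= 4 * se

    def test_force_cap_yields_censored_outcomes(self):
        bond = BellBond("b", 1e-4, 10.0)
        capped = RampProtocol(loading_rate=100.0, f_max=60.0)
        df = simulate_rupture(bond, bond, capped, 5000, seed=2)
        censored = df.winner == "none"
        assert censored.any()
        assert df.loc[censored, "rupture_force_pN"].isna().all()
        assert (df.loc[~censored, "rupture_force_pN"] <= 60.0).all()

    def test_rupture_forces_concentrate_near_predicted_scale(self, ramp):
        # most probable rupture force of a single Bell bond: f_beta*ln(r/(k0*f_beta))
        bond = BellBond("b", 1e-4, 10.0)
        df = simulate_rupture(bond, bond, ramp, 20000, seed=3)
        # two identical bonds double the hazard, shifting the peak down by ln(2)*f_beta
        predicted = 10.0 * math.log(100.0 / (2 * 1e-4 * 10.0))
        assert abs(df.rupture_force_pN.median() - predicted) < 5.0


def test_solve_sample_bond_hits_target_probability(ramp):
    reference = bond_from_duplex(DuplexSpec(20))
    for target in (0.65, 0.32, 0.2):
        sample = solve_sample_bond(target, reference, ramp)
        assert reference_rupture_probability(sample, reference, ramp) == pytest.approx(
            target, abs=1e-6
        )
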