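"""Unit and property tests for the closed-form RH models."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rhcalc import (
    DomainError,
    GeneralizedMixture,
    PolymerParams,
    RangeError,
    RHValue,
    SaltParams,
    SolventSpec,
    WATER,
    generalized_rh,
    mass_fraction_to_mole_ratio,
    polymer_rh,
    raoult_rh,
    salt_rh,
    solve_concentration,
    volume_fraction_factor,
    work_function_factor,
)


def flory_huggins_activity(phi2: float, r: float) -> float:
    """Independent oracle: solvent activity from the lattice entropy of
    mixing, ln a1 = ln phi1 + (1 - 1/r) phi2."""
    phi1 = 1.0 - phi2
    return math.exp(math.log(phi1) + (1.0 - 1.0 / r) * phi2)


class TestRaoult:
    @pytest.mark.parametrize(
        "x, expected", [(0.0, 1.0), (0.1, 0.9), (0.5, 0.5)]
    )
    def test_ideal_law(self, x, expected):
        assert float(raoult_rh(x)) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5, float("nan")])
    def test_rejects_out_of_range_mole_fraction(self, bad):
        with pytest.raises(DomainError):
            raoult_rh(bad)

    @given(st.floats(min_value=0.0, max_value=0.998))
    def test_strictly_decreasing(self, x):
        assert float(raoult_rh(x)) > float(raoult_rh(x + 1e-3))


class TestRHValue:
    def test_percent_view(self):
        assert RHValue(0.964).percent == pytest.approx(96.4)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.0001])
    def test_rejects_nonphysical_fraction(self, bad):
        with pytest.raises(DomainError):
            RHValue(bad)


class TestGeneralizedMixture:
    @pytest.mark.parametrize(
        "kwargs, factor, expected",
        [
            (dict(n1=1, v1=1, n2=0, v2=5), volume_fraction_factor, 1.0),
            (dict(n1=9, v1=1, n2=1, v2=1), volume_fraction_factor, 0.9),
            (dict(n1=1, v1=1, n2=1, v2=3), volume_fraction_factor, 0.25),
            (dict(n1=4, v1=2, n2=3, v2=2), work_function_factor, 1.0),
            (dict(n1=1, v1=1, n2=0, v2=7), work_function_factor, 1.0),
            (dict(n1=1, v1=1, n2=1, v2=3), work_function_factor,
             math.exp(0.5)),
        ],
    )
    def test_factor_examples(self, kwargs, factor, expected):
        assert factor(GeneralizedMixture(**kwargs)) == pytest.approx(
            expected, rel=1e-14
        )

    def test_product_of_factors(self):
        mix = GeneralizedMixture(n1=1, v1=1, n2=1, v2=3)
        assert float(generalized_rh(mix)) == pytest.approx(
            0.25 * math.exp(0.5), rel=1e-14
        )

    @given(
        n1=st.floats(min_value=0.5, max_value=1e6),
        n2=st.floats(min_value=0.0, max_value=1e6),
        v=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_equal_volumes_reduce_to_raoult(self, n1, n2, v):
        mix = GeneralizedMixture(n1=n1, v1=v, n2=n2, v2=v)
        expected = float(raoult_rh(n2 / (n1 + n2)))
        assert float(generalized_rh(mix)) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("r", [0.1, 1.0, 10.0, 100.0, 1000.0])
    def test_extreme_dilution_reduces_to_raoult(self, r):
        # The depression must match Raoult's to < 1% of the depression
        # itself for any volume ratio, once dilution is deep enough for
        # that ratio (the deviation scales as (n2/n1) r^2 / 2).
        ratio = 1e-6 if r <= 100.0 else 1e-8
        mix = GeneralizedMixture(n1=1.0, v1=1.0, n2=ratio, v2=r)
        mole_fraction = ratio / (1.0 + ratio)
        rh_gen = float(generalized_rh(mix))
        rh_raoult = float(raoult_rh(mole_fraction))
        assert abs(rh_gen - rh_raoult) / (1.0 - rh_raoult) < 1e-2

    @given(
        n2=st.floats(min_value=0.01, max_value=100.0),
        r=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_matches_flory_huggins_activity(self, n2, r):
        mix = GeneralizedMixture(n1=10.0, v1=1.0, n2=n2, v2=r)
        phi2 = n2 * r / (10.0 + n2 * r)
        assert float(generalized_rh(mix)) == pytest.approx(
            flory_huggins_activity(phi2, r), abs=1e-12
        )

    def test_invariant_violations_rejected(self):
        with pytest.raises(DomainError):
            GeneralizedMixture(n1=0, v1=1, n2=1, v2=1)
        with pytest.raises(DomainError):
            GeneralizedMixture(n1=1, v1=-1, n2=1, v2=1)


class TestSaltRH:
    def test_pure_water(self, nacl):
        assert float(salt_rh(0.0, nacl)) == 1.0

    def test_one_molar_nacl_brute_force(self, nacl):
        # Mole counting: 1 L of 1 M NaCl holds (1000/18)(1 - 0.027) mol
        # water and 2 mol free ions; RH is the water mole fraction.
        moles_water = (1000.0 / 18.0) * (1.0 - 0.027)
        expected = moles_water / (moles_water + 2.0)
        assert float(salt_rh(1.0, nacl)) == pytest.approx(expected,
                                                          abs=1e-12)
        assert float(salt_rh(1.0, nacl)) == pytest.approx(0.9643, abs=5e-4)

    def test_salt_volume_cannot_exceed_solution(self, nacl):
        with pytest.raises(DomainError, match="salt volume"):
            salt_rh(1.0 / 0.027 + 1.0, nacl)

    def test_negative_molarity_rejected(self, nacl):
        with pytest.raises(DomainError):
            salt_rh(-0.5, nacl)

    def test_initial_slope_set_by_dissociation(self):
        # d(RH)/dM at M=0 is -x/55.56 (y enters only at second order), so
        # doubling x doubles the initial RH depression.
        h = 1e-7
        water_molar = 1000.0 / 18.0
        for x in (1, 2, 3):
            salt = SaltParams(name="s", x_ions=x, y_volume=0.03)
            slope = (float(salt_rh(h, salt)) - 1.0) / h
            assert slope == pytest.approx(-x / water_molar, rel=1e-5)

    @given(m=st.floats(min_value=0.0, max_value=6.0))
    def test_strictly_decreasing_in_molarity(self, m, nacl):
        assert float(salt_rh(m, nacl)) > float(salt_rh(m + 0.01, nacl))

    def test_nonstandard_solvent_enters_through_molar_mass(self, nacl):
        heavy = SolventSpec(name="heavy water", molar_mass=20.0,
                            molar_volume=0.020)
        w = (1000.0 / 20.0) * (1.0 - 0.027)
        assert float(salt_rh(1.0, nacl, heavy)) == pytest.approx(
            w / (w + 2.0), abs=1e-12
        )


class TestPolymerRH:
    def test_pure_water(self, peg6000):
        assert float(polymer_rh(0.0, peg6000)) == 1.0

    @pytest.mark.parametrize(
        "w, n, expected",
        [(0.5, 6000.0, 0.003), (0.25, 400.0, 0.015)],
    )
    def test_mole_ratio_from_mass_fraction(self, w, n, expected):
        poly = PolymerParams(name="p", n_mw=n)
        assert mass_fraction_to_mole_ratio(w, poly) == pytest.approx(
            expected, rel=1e-12
        )

    def test_mass_fraction_one_rejected(self, peg6000):
        with pytest.raises(DomainError):
            polymer_rh(1.0, peg6000)
        with pytest.raises(DomainError):
            mass_fraction_to_mole_ratio(1.2, peg6000)

    def test_half_mass_fraction_peg6000(self, peg6000):
        # Independent evaluation through the lattice activity:
        # f = (18/38) w/(1-w), r = 6000/38, RH = phi1 exp[(1-1/r) phi2].
        f = (18.0 / 38.0) * 1.0
        r = 6000.0 / 38.0
        expected = flory_huggins_activity(f / (1 + f), r)
        assert float(polymer_rh(0.5, peg6000)) == pytest.approx(
            expected, abs=1e-14
        )
        assert float(polymer_rh(0.5, peg6000)) == pytest.approx(
            0.9339, abs=5e-4
        )

    @pytest.mark.parametrize("n", [200.0, 1000.0, 6000.0, 20000.0])
    @pytest.mark.parametrize("w", np.linspace(0.0, 0.6, 7).tolist())
    def test_agrees_with_flory_huggins_on_grid(self, w, n):
        poly = PolymerParams(name="p", n_mw=n, m_monomer=38.0)
        r = n / 38.0
        f = r * mass_fraction_to_mole_ratio(w, poly)
        expected = flory_huggins_activity(f / (1.0 + f), r)
        assert float(polymer_rh(w, poly)) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_long_chain_limit_independent_of_n(self):
        # RH depends on n only through 1/r = m/n, so the drift between
        # successive chain lengths falls off as 1/n.
        rh = lambda n: float(
            polymer_rh(0.5, PolymerParams(name="p", n_mw=n,
                                          m_monomer=38.0))
        )
        assert abs(rh(1e8) - rh(1e9)) < 1e-6
        assert abs(rh(1e7) - rh(1e9)) < 1.2e-5

    @given(w=st.floats(min_value=0.0, max_value=0.85))
    def test_strictly_decreasing_in_mass_fraction(self, w, peg6000):
        assert float(polymer_rh(w, peg6000)) > float(
            polymer_rh(w + 0.005, peg6000)
        )

    def test_polymer_smaller_than_monomer_rejected(self):
        with pytest.raises(DomainError):
            PolymerParams(name="p", n_mw=20.0, m_monomer=38.0)


class TestSolveConcentration:
    @pytest.mark.parametrize("conc", [0.1, 0.5, 1.0, 2.5, 5.0])
    def test_salt_round_trip(self, conc, nacl):
        rh = float(salt_rh(conc, nacl))
        assert solve_concentration(rh, nacl) == pytest.approx(conc,
                                                              abs=1e-8)

    @pytest.mark.parametrize("conc", [0.02, 0.1, 0.3, 0.5, 0.7])
    def test_polymer_round_trip(self, conc, peg6000):
        rh = float(polymer_rh(conc, peg6000))
        assert solve_concentration(rh, peg6000) == pytest.approx(conc,
                                                                 abs=1e-8)

    def test_continuity_at_pure_solvent(self, nacl):
        assert solve_concentration(1.0 - 1e-9, nacl) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_unattainable_target_reports_range(self, nacl):
        # The salt domain ends where y*M -> 1; just above that boundary
        # the RH is ~1e-9, so 1e-12 is below the attainable interval.
        with pytest.raises(RangeError, match="attainable"):
            solve_concentration(1e-12, nacl)

    def test_nonphysical_target_rejected(self, nacl):
        with pytest.raises(RangeError):
            solve_concentration(1.5, nacl)
        with pytest.raises(RangeError):
            solve_concentration(0.0, nacl)

    def test_zero_volume_salt_still_invertible(self):
        ideal = SaltParams(name="ideal", x_ions=2, y_volume=0.0)
        rh = float(salt_rh(3.0, ideal))
        assert solve_concentration(rh, ideal) == pytest.approx(3.0,
                                                               abs=1e-8)
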