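"""Free-energy mathematics: printed worked examples, limits and symmetries."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ssipsolv import (
    DEFAULT_CONSTANTS,
    assign,
    complexation_dg,
    complexation_dg_reference,
    constants_from_ss,
    dg_alpha_polar,
    dg_alpha_simple,
    dg_beta_polar,
    dg_beta_simple,
    get_solvent,
    rt_ln_ss,
    solvation_free_energy,
    transfer_free_energy,
)
from ssipsolv.assignment import SSIP, SSIPProfile
from ssipsolv.errors import UnsupportedFeatureError
from ssipsolv.parameters import SimpleSolvent, SiteFractions, TwoDomainSolvent

RT = DEFAULT_CONSTANTS.rt

#: back-calculated RT ln[S.S] column, kJ/mol, for the simple organic solvents
RT_LN_SS_TABLE = {
    "hexadecane": 6.0, "benzene": 6.4, "toluene": 6.4, "hexane": 6.0,
    "cyclohexane": 5.9, "carbon tetrachloride": 6.0, "dichloromethane": 6.4,
    "chloroform": 6.6, "1,2-dichloroethane": 6.4, "chlorobenzene": 6.2,
    "perfluoroalkane": 5.5,
}

#: experimental hexadecane->water transfer free energies for the 16-H alkanes
ALKANE_16H_EXPERIMENTAL = {
    "CCCCCCC": 29.3,  # n-heptane
    "CCC(C)CCC": 28.7,  # 3-methylhexane
    "CCCC(C)(C)C": 28.0,  # 2,2-dimethylpentane
    "CCC1CCCCC1": 31.1,  # ethylcyclohexane
    "CCCC1CCCC1": 30.6,  # propylcyclopentane
    "CC1CCCCC1C": 28.6,  # cis-1,2-dimethylcyclohexane
    "CC1CCC(C)CC1": 28.7,  # trans-1,4-dimethylcyclohexane
    "C1CCCCCCC1": 28.3,  # cyclooctane
    "C1C2CC3CC1CC(C2)C3": 27.5,  # adamantane
}


def _simple(alpha_s, c_alpha, beta_s, c_beta, c0=0.0, name="synthetic"):
    return SimpleSolvent(name=name, alpha_s=alpha_s, c_alpha=c_alpha,
                         beta_s=beta_s, c_beta=c_beta, c0=c0)


def _two_domain(a1, ca1, b1, cb1, a2, ca2, b2, cb2, n_a=(3, 7), n_b=(2, 5), c0=0.0):
    frac = SiteFractions(member="x", smiles="", n_alpha1=n_a[0], n_alpha2=n_a[1],
                         n_beta1=n_b[0], n_beta2=n_b[1])
    return TwoDomainSolvent(
        class_name="synthetic", alpha_s1=a1, c_alpha1=ca1, beta_s1=b1, c_beta1=cb1,
        alpha_s2=a2, c_alpha2=ca2, beta_s2=b2, c_beta2=cb2, c0=c0,
        members={"x": frac},
    )


class TestPerSSIPWorkedExamples:
    def test_alkane_donor_in_water(self):
        assert round(dg_alpha_simple(1.20, get_solvent("water")), 2) == -3.40

    def test_alkane_acceptor_in_water(self):
        assert round(dg_beta_simple(0.60, get_solvent("water")), 2) == -1.52

    def test_alkane_pair_in_hexadecane(self):
        hexadecane = get_solvent("hexadecane")
        assert round(dg_alpha_simple(1.20, hexadecane), 2) == -3.36
        assert round(dg_beta_simple(0.60, hexadecane), 2) == -3.36

    def test_zero_polarity_zero_constant_gives_zero(self):
        s = _simple(alpha_s=1.0, c_alpha=0.0, beta_s=1.0, c_beta=0.0)
        assert dg_alpha_simple(0.0, s) == 0.0
        assert dg_beta_simple(0.0, s) == 0.0


class TestTwoDomainSolvation:
    @given(
        b=st.floats(0.2, 6.0), c=st.floats(-5.0, 5.0),
        alpha=st.floats(0.0, 6.0),
        n1=st.integers(1, 20), n2=st.integers(1, 20),
    )
    @settings(derandomize=True, max_examples=200)
    def test_degenerate_sites_reduce_to_simple_formula(self, b, c, alpha, n1, n2):
        polar = _two_domain(1.2, 2.0, b, c, 1.2, 2.0, b, c, n_b=(n1, n2))
        simple = _simple(alpha_s=1.2, c_alpha=2.0, beta_s=b, c_beta=c)
        assert dg_alpha_polar(alpha, polar, "x") == pytest.approx(
            dg_alpha_simple(alpha, simple), abs=1e-9
        )

    @given(a=st.floats(0.2, 6.0), c=st.floats(-5.0, 5.0), beta=st.floats(0.0, 6.0))
    @settings(derandomize=True, max_examples=100)
    def test_degenerate_donor_sites_reduce_to_simple_formula(self, a, c, beta):
        polar = _two_domain(a, c, 0.6, 2.0, a, c, 5.0, -3.0)
        simple = _simple(alpha_s=a, c_alpha=c, beta_s=0.6, c_beta=2.0)
        assert dg_beta_polar(beta, polar, "x") == pytest.approx(
            dg_beta_simple(beta, simple), abs=1e-9
        )

    def test_all_polar_limit_is_single_site(self):
        polar = _two_domain(1.2, 2.0, 0.6, 3.0, 1.2, 2.0, 5.3, -3.65, n_b=(0, 1))
        # f_beta2 == 1: only the polar acceptor site is seen
        assert dg_alpha_polar(2.0, polar, "x") == pytest.approx(
            -2.0 * 5.3 - (-3.65), abs=1e-12
        )

    def test_ether_donor_side_is_single_site(self):
        ethers = get_solvent("ethers")
        for member in ethers.member_names:
            for beta in (0.6, 2.0, 5.3):
                assert dg_beta_polar(beta, ethers, member) == pytest.approx(
                    -ethers.alpha_s1 * beta - ethers.c_alpha1, abs=1e-12
                )

    def test_thf_donor_solvation_oracle(self):
        """Hand transcription of the two-acceptor-site equilibrium for THF."""
        ethers = get_solvent("tetrahydrofuran")
        alpha = 2.7
        k1 = math.exp((alpha * 0.60 + 2.98) / RT)
        k2 = math.exp((alpha * 5.30 - 3.65) / RT)
        expected = -RT * math.log(0.8 * k1 + 0.2 * k2)
        assert dg_alpha_polar(alpha, ethers, "tetrahydrofuran") == pytest.approx(
            expected, abs=1e-12
        )

    def test_methanol_acceptor_solvation_oracle(self):
        """Hand transcription of the two-donor-site equilibrium for methanol."""
        alcohols = get_solvent("methanol")
        beta = 5.3
        k1 = math.exp((1.20 * beta + 2.75) / RT)
        k2 = math.exp((3.50 * beta - 6.02) / RT)
        expected = -RT * math.log(0.75 * k1 + 0.25 * k2)
        assert dg_beta_polar(beta, alcohols, "methanol") == pytest.approx(
            expected, abs=1e-12
        )


class TestMolecularSolvation:
    def _ch_pair(self):
        return SSIPProfile(smiles="[CH]", ssips=[
            SSIP("donor", 1.20, "[CX4H]"), SSIP("acceptor", 0.60, "[CX4H]")
        ])

    def test_single_ch_pair_in_water(self):
        breakdown = solvation_free_energy(self._ch_pair(), "water")
        assert round(breakdown.total, 2) == -4.92

    def test_single_ch_pair_in_hexadecane(self):
        breakdown = solvation_free_energy(self._ch_pair(), "hexadecane")
        assert round(breakdown.total, 2) == -6.72

    def test_empty_profile_is_offset_only(self):
        empty = SSIPProfile(smiles="", ssips=[])
        assert solvation_free_energy(empty, "hexane").total == pytest.approx(-1.38)

    def test_breakdown_sums_to_total(self):
        breakdown = solvation_free_energy(assign("CCO"), "chloroform")
        assert breakdown.total == pytest.approx(
            sum(c[3] for c in breakdown.contributions) + breakdown.c0_term
        )
        assert len(breakdown.contributions) == 13

    def test_positive_c0_favours_that_solvent(self):
        # hexane vs hexadecane: site terms differ by 0.02 per SSIP (8 for
        # methane), the remaining -1.38 is the offset acting in hexane's favour
        dg = transfer_free_energy(assign("C"), "hexadecane", "hexane").dg
        assert dg == pytest.approx(8 * 0.02 - 1.38, abs=1e-9)
        assert dg < 0


class TestTransfer:
    def test_per_ch_group_transfer(self):
        res = transfer_free_energy(self_ch := SSIPProfile(
            smiles="[CH]",
            ssips=[SSIP("donor", 1.20, "x"), SSIP("acceptor", 0.60, "x")],
        ), "hexadecane", "water")
        assert round(res.dg, 2) == 1.80

    def test_sixteen_h_alkane_transfer(self):
        per_ch = transfer_free_energy(
            SSIPProfile(smiles="[CH]", ssips=[SSIP("donor", 1.20, "x"),
                                              SSIP("acceptor", 0.60, "x")]),
            "hexadecane", "water",
        ).dg
        assert 16 * round(per_ch, 2) == pytest.approx(28.8)
        heptane = transfer_free_energy(assign("CCCCCCC"), "hexadecane", "water")
        assert heptane.dg == pytest.approx(28.8, abs=0.1)

    @pytest.mark.parametrize("smiles,experimental", sorted(ALKANE_16H_EXPERIMENTAL.items()))
    def test_16h_alkanes_match_experiment(self, smiles, experimental):
        # the experimental values cluster at 29 +/- 2; the model predicts a
        # single constant value for all 16-H alkanes, which must land in
        # that band
        profile = assign(smiles)
        assert profile.n_alpha == 16  # every C-H contributes one donor
        res = transfer_free_energy(profile, "hexadecane", "water")
        assert 29.0 - 2.0 <= res.dg <= 29.0 + 2.0
        assert 27.0 <= experimental <= 31.5  # the printed band itself

    @pytest.mark.parametrize(
        "solvent", ["hexadecane", "water", "chloroform", "tetrahydrofuran", "ethanol"]
    )
    def test_zero_diagonal(self, solvent):
        res = transfer_free_energy(assign("CCO"), solvent, solvent)
        assert res.dg == 0.0 and res.logp == 0.0

    def test_antisymmetry_over_fixture_set(self):
        from conftest import FIXTURE_COUNTS

        solvents = ["hexadecane", "water", "chloroform", "benzene",
                    "tetrahydrofuran", "acetone", "methanol"]
        for smiles in FIXTURE_COUNTS:
            profile = assign(smiles)
            for a in solvents:
                for b in solvents:
                    fwd = transfer_free_energy(profile, a, b).dg
                    rev = transfer_free_energy(profile, b, a).dg
                    assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_logp_convention(self):
        res = transfer_free_energy(assign("CCCCCCC"), "hexadecane", "water")
        assert res.logp == pytest.approx(-res.dg / (RT * math.log(10)))
        assert res.logp < 0  # heptane prefers hexadecane over water


class TestComplexation:
    def test_water_pair_in_carbon_tetrachloride(self):
        # oracle: the solvent-competition form -(a - a_S)(b - b_S) + 6
        expected = -(2.80 - 1.40) * (4.50 - 0.60) + 6
        res = complexation_dg(2.80, 4.50, "carbon tetrachloride")
        assert res.dg == pytest.approx(expected, abs=1e-9)
        assert round(res.dg, 2) == 0.54
        assert res.k == pytest.approx(math.exp(-res.dg / RT))

    def test_zero_polarities_leave_solvent_constants(self):
        res = complexation_dg(0.0, 0.0, "carbon tetrachloride")
        assert res.dg == pytest.approx(2.58 + 2.58)

    def test_polar_solvent_refused(self):
        with pytest.raises(UnsupportedFeatureError, match="non-polar"):
            complexation_dg(2.0, 5.0, "acetone")

    @given(
        alpha_s=st.floats(0.1, 5.0), beta_s=st.floats(0.1, 5.0),
        split=st.floats(0.0, 1.0),
        alpha=st.floats(0.0, 6.0), beta=st.floats(0.0, 6.0),
    )
    @settings(derandomize=True, max_examples=300)
    def test_equivalence_of_the_two_forms(self, alpha_s, beta_s, split, alpha, beta):
        """When C_a + C_b = 6 - a_S*b_S the two expressions agree everywhere."""
        total_c = 6.0 - alpha_s * beta_s
        s = _simple(alpha_s, total_c * split, beta_s, total_c * (1 - split))
        assert complexation_dg(alpha, beta, s).dg == pytest.approx(
            complexation_dg_reference(alpha, beta, s), abs=1e-9
        )


class TestSolventSelfConsistency:
    @pytest.mark.parametrize("name,expected", sorted(RT_LN_SS_TABLE.items()))
    def test_back_calculated_ss_term(self, name, expected):
        assert rt_ln_ss(get_solvent(name)) == pytest.approx(expected, abs=0.05)

    def test_alcohol_domains(self):
        alcohols = get_solvent("alcohols")
        assert rt_ln_ss(alcohols, domain=1) == pytest.approx(6.4, abs=0.05)
        assert rt_ln_ss(alcohols, domain=2) == pytest.approx(11.7, abs=0.05)

    def test_water_domain_matches_alcohol_polar_domain(self):
        assert rt_ln_ss(get_solvent("water")) == pytest.approx(11.7, abs=0.05)

    def test_alkane_closure(self):
        c_alpha, c_beta = constants_from_ss(1.20, 0.60, rt_ln_ss_value=6.0)
        assert (round(c_alpha, 2), round(c_beta, 2)) == (2.64, 2.64)

    def test_carbon_tetrachloride_closure(self):
        c_alpha, c_beta = constants_from_ss(1.40, 0.60, rt_ln_ss_value=6.0)
        assert round(c_alpha, 2) == 2.58

    def test_water_closure_from_solute_parameters(self):
        c_alpha, c_beta = constants_from_ss(2.80, 4.50, 110.0)
        assert round(c_alpha, 2) == -0.47

    def test_closure_needs_exactly_one_ss_argument(self):
        with pytest.raises(ValueError):
            constants_from_ss(1.2, 0.6)
        with pytest.raises(ValueError):
            constants_from_ss(1.2, 0.6, 10.0, rt_ln_ss_value=6.0)


class TestMonotonicity:
    @given(
        alpha=st.floats(0.1, 6.0),
        beta_s1=st.floats(0.1, 5.0), delta=st.floats(0.01, 3.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_donor_solvation_strictly_decreasing_in_solvent_acceptor(
        self, alpha, beta_s1, delta
    ):
        weak = _simple(1.0, 1.0, beta_s1, 1.0)
        strong = _simple(1.0, 1.0, beta_s1 + delta, 1.0)
        assert dg_alpha_simple(alpha, strong) < dg_alpha_simple(alpha, weak)
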