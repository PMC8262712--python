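"""Henderson-Hasselbalch net charge, bisection pI and the pKa-set registry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopoint.charge import (
    ACIDIC_GROUPS,
    BASIC_GROUPS,
    GROUP_ORDER,
    PKaSet,
    UnknownPKaSetError,
    charge_profile,
    get_pka_set,
    isoelectric_point,
    net_charge,
    registry,
)
from isopoint.seqio import PolypeptideSequence, ionizable_composition


def hh_charge_oracle(groups, ph):
    """Loop-free independent summation: groups = [(pka, sign, count)]."""
    total = 0.0
    for pka, sign, count in groups:
        if sign > 0:
            total += count / (1.0 + 10.0 ** (ph - pka))
        else:
            total -= count / (1.0 + 10.0 ** (pka - ph))
    return total


class TestNetCharge:
    def test_half_protonation_at_pka(self, toy_acid_base_set):
        seq = PolypeptideSequence("g", "G")
        # At pH = n_term pKa the amine is half protonated (+0.5); the
        # carboxyl (pKa 2) is essentially fully deprotonated (-1).
        q = net_charge(seq, 9.0, toy_acid_base_set)
        assert q == pytest.approx(-0.5, abs=1e-4)

    def test_midpoint_symmetry_gives_zero(self, toy_acid_base_set):
        q = net_charge(PolypeptideSequence("g", "G"), 5.5, toy_acid_base_set)
        assert q == pytest.approx(0.0, abs=1e-6)

    def test_kde_emboss_term_by_term(self):
        emboss = get_pka_set("EMBOSS")
        expected = hh_charge_oracle(
            [
                (8.6, +1, 1),   # alpha-amino
                (3.6, -1, 1),   # alpha-carboxyl
                (10.8, +1, 1),  # Lys
                (3.9, -1, 1),   # Asp
                (4.1, -1, 1),   # Glu
            ],
            7.0,
        )
        q = net_charge(PolypeptideSequence("p", "KDE"), 7.0, emboss)
        assert q == pytest.approx(expected, abs=1e-12)

    def test_ph_domain_enforced(self, toy_acid_base_set):
        with pytest.raises(ValueError, match="pH"):
            net_charge(PolypeptideSequence("g", "G"), 14.5, toy_acid_base_set)

    def test_composition_and_sequence_agree_for_order_free_set(self):
        emboss = get_pka_set("EMBOSS")
        seq = PolypeptideSequence("p", "KCDERHY")
        q_seq = net_charge(seq, 6.0, emboss)
        q_comp = net_charge(ionizable_composition(seq), 6.0, emboss)
        assert q_seq == pytest.approx(q_comp, abs=1e-12)

    def test_position_aware_set_requires_sequence(self):
        promost = get_pka_set("ProMoST")
        comp = ionizable_composition(PolypeptideSequence("p", "KDE"))
        with pytest.raises(TypeError, match="position-aware"):
            net_charge(comp, 7.0, promost)


class TestIsoelectricPoint:
    def test_closed_form_acid_base_midpoint(self, toy_acid_base_set):
        # With one acid (pKa 2) and one base (pKa 9), Q(pH)=0 exactly at the
        # midpoint (2+9)/2 = 5.5.
        pi = isoelectric_point(PolypeptideSequence("g", "GG"), toy_acid_base_set)
        assert pi == pytest.approx(5.5, abs=1e-3)

    def test_matches_fine_grid_argmin(self):
        emboss = get_pka_set("EMBOSS")
        seq = PolypeptideSequence("p", "KDE")
        grid = np.arange(0.0, 14.0001, 1e-4)
        q = net_charge(seq, grid, emboss)
        grid_pi = grid[np.argmin(np.abs(q))]
        assert isoelectric_point(seq, emboss) == pytest.approx(grid_pi, abs=2e-3)

    def test_adding_a_base_raises_pi(self, all_sets):
        for pka in all_sets.values():
            lo = isoelectric_point(PolypeptideSequence("a", "GGG"), pka)
            hi = isoelectric_point(PolypeptideSequence("b", "GKG"), pka)
            assert hi > lo, pka.name

    def test_tolerance_validated(self, toy_acid_base_set):
        with pytest.raises(ValueError, match="tol"):
            isoelectric_point(PolypeptideSequence("g", "G"), toy_acid_base_set, tol=0)

    def test_order_independence_for_order_free_sets(self, all_sets):
        a = PolypeptideSequence("a", "KDEHACG")
        b = PolypeptideSequence("b", "GCAHEDK")
        for pka in all_sets.values():
            if pka.position_aware:
                continue
            assert isoelectric_point(a, pka) == pytest.approx(
                isoelectric_point(b, pka), abs=1e-9
            ), pka.name


class TestChargeProfile:
    def test_strictly_decreasing(self, all_sets):
        seq = PolypeptideSequence("p", "ACDKRH")
        for pka in all_sets.values():
            prof = charge_profile(seq, pka, step=0.05)
            assert np.all(np.diff(prof.charge) < 0), pka.name

    def test_full_protonation_limit_kkk(self):
        prof = charge_profile(
            PolypeptideSequence("p", "KKK"), get_pka_set("EMBOSS"), step=0.5
        )
        assert prof.charge[0] == pytest.approx(4.0, abs=1e-2)  # 3 Lys + N-term

    def test_limits_match_group_counts(self, all_sets):
        seq = PolypeptideSequence("p", "KDYRC")
        for pka in all_sets.values():
            prof = charge_profile(seq, pka, step=0.5)
            comp = ionizable_composition(seq)
            n_basic = 1 + sum(
                comp.side_chain_count(g)
                for g in ("H", "K", "R") if g in pka.side_chain
            )
            n_acidic = 1 + sum(
                comp.side_chain_count(g)
                for g in ("C", "D", "E", "Y") if g in pka.side_chain
            )
            # Residual (de)protonation at the pH extremes is largest for Arg
            # (pKa ~12.5 leaves ~3% at pH 14), hence the 0.05 slack.
            assert prof.charge[0] == pytest.approx(n_basic, abs=0.05), pka.name
            assert prof.charge[-1] == pytest.approx(-n_acidic, abs=0.05), pka.name

    def test_root_bracket_matches_bisection(self):
        emboss = get_pka_set("EMBOSS")
        seq = PolypeptideSequence("p", "ADEKRHC")
        step = 0.01
        prof = charge_profile(seq, emboss, step=step)
        pi = isoelectric_point(seq, emboss, tol=1e-5)
        idx = np.searchsorted(-prof.charge, 0.0)  # first grid point with Q <= 0
        assert prof.ph[idx - 1] <= pi <= prof.ph[idx] + step


class TestRegistry:
    REQUIRED = {
        "EMBOSS", "Dawson", "Rodwell", "Grimsley", "Solomon", "Lehninger",
        "Sillero", "Thurlkill", "Toseland", "Nozaki", "Patrickios",
        "DTASelect", "Wikipedia", "IPC_protein", "IPC_peptide",
        "IPC2_protein", "IPC2_peptide", "Bjellqvist", "ProMoST",
    }

    def test_contains_published_sets(self, all_sets):
        assert self.REQUIRED <= set(all_sets)
        assert len(all_sets) >= 17

    def test_all_sets_satisfy_invariants(self, all_sets):
        for pka in all_sets.values():
            vec = pka.as_vector()
            finite = vec[np.isfinite(vec)]
            assert np.all((finite > 0) & (finite < 14)), pka.name

    def test_groups_partition_into_acidic_and_basic(self):
        assert BASIC_GROUPS | ACIDIC_GROUPS == set(GROUP_ORDER)
        assert not (BASIC_GROUPS & ACIDIC_GROUPS)

    def test_position_aware_flags(self, all_sets):
        assert all_sets["Bjellqvist"].position_aware
        assert all_sets["ProMoST"].position_aware
        assert not all_sets["EMBOSS"].position_aware

    def test_unknown_name_lists_available(self):
        with pytest.raises(UnknownPKaSetError, match="EMBOSS"):
            get_pka_set("nope")

    def test_registry_returns_copy(self):
        reg = registry()
        reg.pop("EMBOSS")
        assert "EMBOSS" in registry()


class TestMonotonicityProperties:
    def test_q_strictly_decreasing_random_peptides(self, random_peptides, all_sets):
        grid = np.linspace(0.0, 14.0, 57)
        for seq in random_peptides(10, seed=3):
            for pka in all_sets.values():
                q = net_charge(seq, grid, pka)
                assert np.all(np.diff(q) < 0), (seq.residues, pka.name)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        residues=st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=40),
        ph=st.floats(min_value=0.05, max_value=13.95),
    )
    def test_charge_bounded_by_group_counts(self, residues, ph):
        """|Q| never exceeds the number of groups of the matching sign."""
        seq = PolypeptideSequence("h", residues)
        emboss = get_pka_set("EMBOSS")
        q = net_charge(seq, ph, emboss)
        n_basic = 1 + sum(residues.count(c) for c in "HKR")
        n_acidic = 1 + sum(residues.count(c) for c in "CDEY")
        assert -n_acidic - 1e-9 <= q <= n_basic + 1e-9

    def test_raising_any_pka_raises_pi(self):
        base = get_pka_set("EMBOSS")
        seq = PolypeptideSequence("p", "KDECHRY")
        pi0 = isoelectric_point(seq, base, tol=1e-5)
        for group in GROUP_ORDER:
            vec = base.as_vector()
            idx = GROUP_ORDER.index(group)
            vec[idx] = min(vec[idx] + 0.3, 13.9)
            bumped = PKaSet.from_vector("bumped", vec)
            pi1 = isoelectric_point(seq, bumped, tol=1e-5)
            assert pi1 >= pi0 - 1e-6, group
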