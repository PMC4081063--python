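"""Lattice equilibrium: register counting, enumeration, transfer recursion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tbplattice as tl
from tbplattice.errors import InputError, LatticeSizeError


def brute_force_motif_scan(seq: str, motif: str = "TATAWAWR"):
    """Independent oracle: positional IUPAC comparison without regex."""
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "R": "AG"}
    for off in range(len(seq) - len(motif) + 1):
        if all(seq[off + i] in iupac[m] for i, m in enumerate(motif)):
            return off + (len(motif) - 1) // 2
    return None


def dp_placement_count(n_registers: int, footprint: int) -> int:
    """Independent oracle: count of valid configurations by recursion.

    f(i) = number of subsets of registers {i..} with pairwise gap >= footprint,
    f(i) = f(i+1) + f(i+footprint).
    """
    f = [1] * (n_registers + footprint)
    for i in range(n_registers - 1, -1, -1):
        f[i] = f[i + 1] + f[i + footprint]
    return f[0]


class TestRegisters:
    def test_14bp_construct_has_14_registers(self, tata14E):
        assert tl.count_binding_registers(tata14E) == 14

    def test_single_position_lattice(self):
        assert tl.count_binding_registers(tl.LatticeSpec(length_bp=1)) == 1

    def test_inactive_registers_are_excluded(self):
        lat = tl.LatticeSpec(length_bp=25, inactive_registers=frozenset(range(11)))
        assert tl.count_binding_registers(lat) == 14


class TestMotifScan:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GGTATAAAAGGG", 5),
            ("GGGGGGGG", None),
            ("TATATATA", 3),
            ("GCGCTATAAAAGGC", 7),
        ],
    )
    def test_known_sequences(self, seq, expected):
        assert tl.locate_specific_site(seq) == expected
        assert brute_force_motif_scan(seq) == expected

    def test_matches_brute_force_scan_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(8, 40)))
            assert tl.locate_specific_site(seq) == brute_force_motif_scan(seq)

    def test_invalid_characters_rejected(self):
        with pytest.raises(InputError):
            tl.locate_specific_site("ACGTX")


class TestEnumeration:
    def test_two_registers_single_occupancy(self):
        lat = tl.LatticeSpec(length_bp=2)
        configs = tl.enumerate_configurations(lat)
        assert sorted(c.bound_registers for c in configs) == [(), (0,), (1,)]

    def test_footprint_equal_length_gives_one_per_register(self):
        lat = tl.LatticeSpec(length_bp=14, footprint_bp=14, contact_span_bp=14)
        assert len(tl.enumerate_configurations(lat)) == 15

    @pytest.mark.parametrize("length, footprint", [(25, 8), (20, 5), (12, 3)])
    def test_count_matches_dp_oracle(self, length, footprint):
        lat = tl.LatticeSpec(
            length_bp=length, footprint_bp=footprint, contact_span_bp=footprint
        )
        configs = tl.enumerate_configurations(lat)
        assert len(configs) == dp_placement_count(length, footprint)
        assert len({c.bound_registers for c in configs}) == len(configs)
        for c in configs:
            gaps = np.diff(c.bound_registers)
            assert (gaps >= footprint).all() if gaps.size else True

    def test_oversized_lattice_directs_to_transfer_path(self):
        with pytest.raises(LatticeSizeError, match="transfer"):
            tl.enumerate_configurations(tl.LatticeSpec(length_bp=40))


class TestConfigurationWeight:
    def test_empty_configuration_is_reference_state(self, tata14E):
        w = tl.configuration_weight(
            tl.LatticeConfiguration(()), tata14E, tl.BindingEnergetics(), 50.0
        )
        assert w == 1.0

    def test_specific_site_at_its_kd(self, tata14E):
        en = tl.BindingEnergetics(kd_specific_nM=5.0)
        w = tl.configuration_weight(
            tl.LatticeConfiguration((7,)), tata14E, en, en.kd_specific_eff_nM
        )
        assert w == pytest.approx(1.0)

    def test_contact_pair_cooperativity_product(self):
        # two non-specific proteins at separation exactly n, c/Kd = 2, omega = 3
        lat = tl.LatticeSpec(length_bp=16)
        en = tl.BindingEnergetics(kd_nonspecific_nM=10.0, cooperativity_omega=3.0)
        w = tl.configuration_weight(tl.LatticeConfiguration((0, 8)), lat, en, 20.0)
        assert w == pytest.approx(2.0 * 2.0 * 3.0)

    def test_negative_concentration_rejected(self, tata14E):
        with pytest.raises(InputError):
            tl.configuration_weight(
                tl.LatticeConfiguration(()), tata14E, tl.BindingEnergetics(), -1.0
            )


class TestEquilibrium:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        length=st.integers(4, 25),
        footprint=st.integers(2, 10),
        omega=st.floats(0.0, 8.0),
        conc=st.floats(0.0, 400.0),
        kd_ns=st.floats(1.0, 500.0),
        specific=st.booleans(),
    )
    def test_transfer_matches_enumeration(
        self, length, footprint, omega, conc, kd_ns, specific
    ):
        lat = tl.LatticeSpec(
            length_bp=length,
            footprint_bp=footprint,
            contact_span_bp=footprint,
            specific_register=length // 2 if specific else None,
        )
        en = tl.BindingEnergetics(
            kd_nonspecific_nM=kd_ns, cooperativity_omega=omega
        )
        by_enum = tl.equilibrium_occupancy(lat, en, conc, method="enumeration")
        by_tm = tl.equilibrium_occupancy(lat, en, conc, method="transfer")
        assert by_tm.partition_function == pytest.approx(
            by_enum.partition_function, rel=1e-9
        )
        np.testing.assert_allclose(
            by_tm.register_occupancy, by_enum.register_occupancy, atol=1e-9
        )
        k = min(
            len(by_enum.multi_occupancy_fractions),
            len(by_tm.multi_occupancy_fractions),
        )
        np.testing.assert_allclose(
            by_tm.multi_occupancy_fractions[:k],
            by_enum.multi_occupancy_fractions[:k],
            atol=1e-9,
        )
        assert by_enum.multi_occupancy_fractions[k:].sum() < 1e-9
        assert by_tm.multi_occupancy_fractions[k:].sum() < 1e-9

    def test_occupancy_result_invariants(self, tata14I, energetics_50mM):
        res = tl.equilibrium_occupancy(tata14I, energetics_50mM, 50.0)
        assert res.partition_function >= 1.0
        assert ((res.register_occupancy >= 0) & (res.register_occupancy <= 1)).all()
        assert res.multi_occupancy_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_langmuir_limit_single_register(self):
        lat = tl.LatticeSpec(
            length_bp=14,
            specific_register=7,
            inactive_registers=frozenset(i for i in range(14) if i != 7),
        )
        en = tl.BindingEnergetics(kd_specific_nM=5.0, cooperativity_omega=1.0)
        res = tl.equilibrium_occupancy(lat, en, en.kd_specific_eff_nM)
        assert res.p_specific_bound == pytest.approx(0.5)

    @pytest.mark.parametrize("c_over_kd", [0.1, 1.0, 10.0])
    def test_mcghee_von_hippel_closed_form(self, c_over_kd):
        lat = tl.LatticeSpec(length_bp=2000)
        en = tl.BindingEnergetics(kd_nonspecific_nM=100.0, cooperativity_omega=1.0)
        occ = tl.equilibrium_occupancy(lat, en, c_over_kd * 100.0, method="transfer")
        density = occ.mean_bound / lat.length_bp
        nu = tl.mcghee_von_hippel_density(c_over_kd, lat.footprint_bp)
        assert density == pytest.approx(nu, rel=0.01)

    def test_partition_function_nondecreasing_in_concentration(self, tata14I):
        en = tl.BindingEnergetics()
        zs = [
            tl.equilibrium_occupancy(tata14I, en, c).partition_function
            for c in (0.0, 1.0, 10.0, 100.0)
        ]
        assert zs[0] == pytest.approx(1.0)
        assert all(a <= b for a, b in zip(zs, zs[1:]))

    def test_specific_occupancy_vanishes_at_zero_concentration(self, tata14E):
        res = tl.equilibrium_occupancy(tata14E, tl.BindingEnergetics(), 0.0)
        assert res.p_specific_bound == 0.0

    def test_exclusion_only_suppresses_for_noncooperative_lattice(self, tata14E):
        # omega <= 1: competing registers can only reduce specific occupancy
        en = tl.BindingEnergetics(cooperativity_omega=0.7)
        full = tl.equilibrium_occupancy(tata14E, en, 30.0).p_specific_bound
        alone = tl.LatticeSpec(
            length_bp=14,
            sequence=tata14E.sequence,
            specific_register=7,
            inactive_registers=frozenset(i for i in range(14) if i != 7),
        )
        isolated = tl.equilibrium_occupancy(alone, en, 30.0).p_specific_bound
        assert full <= isolated + 1e-12


class TestIsothermPrediction:
    def test_zero_concentration_gives_flat_unbound_curve(
        self, tata14I, energetics_50mM, bend, fret_params
    ):
        table = tl.predicted_isotherm(
            tata14I, energetics_50mM, bend, fret_params, [0.0, 0.0, 0.0]
        )
        unbound = tl.configuration_proximity(
            tata14I, tl.LatticeConfiguration(()), bend, fret_params
        )
        np.testing.assert_allclose(table["proximity_ratio"], unbound)

    def test_specific_only_lattice_reduces_to_single_site_curve(
        self, tata14E_minimal, bend, fret_params, conc_grid
    ):
        en = tl.BindingEnergetics(kd_specific_nM=5.0, salt_mM=50.0)
        table = tl.predicted_isotherm(
            tata14E_minimal, en, bend, fret_params, conc_grid
        )
        p_u = tl.configuration_proximity(
            tata14E_minimal, tl.LatticeConfiguration(()), bend, fret_params
        )
        p_b = tl.configuration_proximity(
            tata14E_minimal, tl.LatticeConfiguration((7,)), bend, fret_params
        )
        expected = p_u + (p_b - p_u) * conc_grid / (conc_grid + en.kd_specific_eff_nM)
        np.testing.assert_allclose(table["proximity_ratio"], expected, atol=1e-12)

    def test_biphasic_at_low_salt_monotone_at_high_salt(
        self, tata14I, bend, fret_params, conc_grid
    ):
        low = tl.predicted_isotherm(
            tata14I, tl.BindingEnergetics(salt_mM=50.0), bend, fret_params, conc_grid
        )["proximity_ratio"].to_numpy()
        high = tl.predicted_isotherm(
            tata14I, tl.BindingEnergetics(salt_mM=150.0), bend, fret_params, conc_grid
        )["proximity_ratio"].to_numpy()
        # low salt: rises, then falls at least 10% below its peak
        assert low.argmax() not in (0, low.size - 1)
        assert low[-1] <= 0.9 * low.max()
        # high salt: essentially monotone (no comparable decline)
        assert high[-1] >= 0.98 * high.max()

    def test_equimolar_competitor_reduces_binding(self, tata14I, energetics_50mM):
        # cooperative exclusion makes individual register occupancies
        # non-monotone in free ligand, so the per-register statement is
        # checked on a non-cooperative lattice and the ensemble statements
        # (free ligand and mean occupancy drop) on the full model
        from tbplattice import datasets

        comp = tl.CompetitorSpec(datasets.get_construct("competitor25"))
        total = 100.0
        free = tl.solve_free_tbp(
            total,
            [(comp.lattice, energetics_50mM, comp.concentration(total))],
        )
        assert free < total
        with_comp = tl.equilibrium_occupancy(tata14I, energetics_50mM, free)
        without = tl.equilibrium_occupancy(tata14I, energetics_50mM, total)
        assert with_comp.mean_bound < without.mean_bound
        # the competitor soaks up the TBP excess that would otherwise coat
        # the flank and displace the TATA complex, *rescuing* specific binding
        assert with_comp.p_specific_bound > without.p_specific_bound

        # mean occupancy is monotone in free ligand for any lattice
        # (d<n>/d ln c = Var(n) >= 0), so it must drop for the simple
        # non-cooperative energetics as well
        simple = tl.BindingEnergetics(cooperativity_omega=1.0)
        free_s = tl.solve_free_tbp(
            total, [(comp.lattice, simple, comp.concentration(total))]
        )
        assert free_s < total
        assert (
            tl.equilibrium_occupancy(tata14I, simple, free_s).mean_bound
            < tl.equilibrium_occupancy(tata14I, simple, total).mean_bound
        )

    def test_descending_concentration_grid_rejected(
        self, tata14I, energetics_50mM, bend, fret_params
    ):
        with pytest.raises(InputError):
            tl.predicted_isotherm(
                tata14I, energetics_50mM, bend, fret_params, [10.0, 1.0]
            )


class TestSpecValidation:
    def test_sequence_length_mismatch(self):
        with pytest.raises(InputError):
            tl.LatticeSpec(length_bp=5, sequence="ACGT")

    def test_specific_register_outside_lattice(self):
        with pytest.raises(InputError):
            tl.LatticeSpec(length_bp=5, specific_register=5)

    def test_dye_outside_lattice(self):
        with pytest.raises(InputError):
            tl.LatticeSpec(length_bp=5, dye_donor=tl.DyeSite(9))
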