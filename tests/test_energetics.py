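"""Pairwise Coulomb/LJ energies and the mutant-box energy decomposition."""

import numpy as np
import pytest

from xhpi import (AtomParams, EnsembleSpec, PairEnergy, dddE, dde,
                  generate_xhpi_ensemble, pair_energy, percent_cooperativity,
                  triple_energy)
from xhpi.constants import COULOMB_K
from xhpi.cycles import TMB_KEYS, TMB_SIGNS
from xhpi.structures import Ensemble


def _two_atoms(r_angstrom, res_a="AAA", res_b="BBB"):
    return Ensemble(chain_id=["A", "A"], res_id=[1, 2], res_name=[res_a, res_b],
                    atom_name=["X1", "X2"], element=["C", "C"],
                    coord=np.array([[[0, 0, 0], [0, 0, r_angstrom]]], dtype=float))


def _params(q1=0.0, q2=0.0, sigma=0.34, eps=0.1):
    return AtomParams({("AAA", "X1"): (q1, sigma, eps),
                       ("BBB", "X2"): (q2, sigma, eps)})


class TestClosedForms:
    def test_lj_zero_at_sigma(self):
        p = _params()
        pe = pair_energy(_two_atoms(3.4), [0], [1], p, epsilon_eff=1.0)
        assert pe.e_lj == pytest.approx(0.0, abs=1e-12)
        assert pe.e_coul == 0.0

    def test_lj_minimum_at_rmin(self):
        p = _params(eps=0.25)
        r_min = 2 ** (1 / 6) * 3.4
        pe = pair_energy(_two_atoms(r_min), [0], [1], p, epsilon_eff=1.0)
        assert pe.e_lj == pytest.approx(-0.25, rel=1e-10)

    def test_coulomb_hand_value(self):
        p = _params(q1=1.0, q2=-1.0, eps=0.0)
        pe = pair_energy(_two_atoms(3.320636), [0], [1], p, epsilon_eff=4.0)
        assert pe.e_coul == pytest.approx(-COULOMB_K / (4.0 * 3.320636), rel=1e-12)
        assert pe.e_coul == pytest.approx(-25.000, abs=1e-3)

    def test_epsilon_scaling_affects_only_coulomb(self):
        p = _params(q1=0.5, q2=-0.3, eps=0.2)
        pe1 = pair_energy(_two_atoms(4.0), [0], [1], p, epsilon_eff=1.0)
        pe4 = pair_energy(_two_atoms(4.0), [0], [1], p, epsilon_eff=4.0)
        assert pe4.e_coul == pytest.approx(pe1.e_coul / 4.0, rel=1e-12)
        assert pe4.e_lj == pytest.approx(pe1.e_lj, rel=1e-12)

    def test_lorentz_berthelot_combination(self):
        p = AtomParams({("AAA", "X1"): (0.0, 0.30, 0.04),
                        ("BBB", "X2"): (0.0, 0.40, 0.09)})
        # sigma_ij = 0.35 nm, eps_ij = 0.06 -> LJ zero at 3.5 A
        pe = pair_energy(_two_atoms(3.5), [0], [1], p, epsilon_eff=1.0)
        assert pe.e_lj == pytest.approx(0.0, abs=1e-12)
        r_min = 2 ** (1 / 6) * 3.5
        pe2 = pair_energy(_two_atoms(r_min), [0], [1], p, epsilon_eff=1.0)
        assert pe2.e_lj == pytest.approx(-0.06, rel=1e-10)

    def test_pair_override_beats_combination(self):
        p = AtomParams({("AAA", "X1"): (0.0, 0.30, 0.04),
                        ("BBB", "X2"): (0.0, 0.40, 0.09)},
                       pair_overrides={(("AAA", "X1"), ("BBB", "X2")): (0.32, 0.10)})
        pe = pair_energy(_two_atoms(3.2), [0], [1], p, epsilon_eff=1.0)
        assert pe.e_lj == pytest.approx(0.0, abs=1e-12)


class TestSelectionContracts:
    def test_overlapping_selections_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pair_energy(_two_atoms(3.4), [0, 1], [1], _params())

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pair_energy(_two_atoms(3.4), [], [1], _params())

    def test_missing_parameter_names_atom(self):
        p = AtomParams({("AAA", "X1"): (0.0, 0.34, 0.1)})
        with pytest.raises(KeyError, match="BBB:X2"):
            pair_energy(_two_atoms(3.4), [0], [1], p)

    def test_decomposability_over_selection_partition(self, rng, toy_params):
        spec = EnsembleSpec(n_models=2, d_target=0.45, omega_target=150.0,
                            jitter_sd=0.003, seed=8)
        ens = generate_xhpi_ensemble(spec)
        model = ens[0]
        donor_idx = np.nonzero(model.res_id == 1)[0]
        ring_idx = np.nonzero(model.res_id == 2)[0]
        whole = pair_energy(ens, donor_idx, ring_idx, toy_params)
        part1 = pair_energy(ens, donor_idx[:2], ring_idx, toy_params)
        part2 = pair_energy(ens, donor_idx[2:], ring_idx, toy_params)
        assert whole.e_total == pytest.approx(part1.e_total + part2.e_total, rel=1e-10)

    def test_rigid_motion_invariance(self, rng, toy_params):
        from scipy.spatial.transform import Rotation
        spec = EnsembleSpec(n_models=1, d_target=0.45, omega_target=150.0, jitter_sd=0.0)
        ens = generate_xhpi_ensemble(spec)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = Ensemble(ens.chain_id, ens.res_id, ens.res_name, ens.atom_name,
                         ens.element, ens.coord @ rot.T + [3.0, -7.0, 2.0])
        e0 = pair_energy(ens, ens[0].res_id == 1, ens[0].res_id == 2, toy_params)
        e1 = pair_energy(moved, ens[0].res_id == 1, ens[0].res_id == 2, toy_params)
        assert e1.e_total == pytest.approx(e0.e_total, rel=1e-9)

    def test_weakening_with_distance_over_contact_range(self, toy_params):
        totals = []
        for d in (0.40, 0.45, 0.50, 0.55, 0.60):
            spec = EnsembleSpec(d_target=d, omega_target=160.0, jitter_sd=0.0)
            ens = generate_xhpi_ensemble(spec)
            pe = pair_energy(ens, ens[0].res_id == 1, ens[0].res_id == 2, toy_params)
            totals.append(pe.e_total)
        assert all(a < b < 0 for a, b in zip(totals, totals[1:]))


class TestDecomposition:
    def test_dde_cancellation_and_arithmetic(self):
        z = PairEnergy.zero()
        assert dde(z, z, z, z).dde == 0.0
        assert dde(-1.2, -0.5, -0.4, -0.1).dde == pytest.approx(-0.4, abs=1e-12)

    def test_alanine_truncation_none_counts_zero(self):
        assert dde(-1.2, None, None, None).dde == pytest.approx(-1.2)

    def test_dde_se_quadrature(self):
        def pe(se):
            return PairEnergy("p", 0.0, 0.0, 0.0, 4.0, 10, se)
        res = dde(pe(0.03), pe(0.04), pe(0.0), pe(0.0))
        assert res.se == pytest.approx(0.05, rel=1e-12)

    def test_triple_energy_sum_and_symmetry(self):
        assert triple_energy(-1.0, -2.0, -3.0) == -6.0
        assert triple_energy(-3.0, -1.0, -2.0) == -6.0

    def test_triple_energy_matches_brute_force_cross_terms(self, toy_params):
        # three-residue toy scene: donor vs two rings; per-pair energies must
        # add up to the brute-force sum restricted to the three pairs
        from xhpi import add_decoy_ring
        spec = EnsembleSpec(n_models=1, d_target=0.45, omega_target=150.0, jitter_sd=0.0)
        ens = add_decoy_ring(generate_xhpi_ensemble(spec), 0.8, res_id=3)
        m = ens[0]
        pe_ab = pair_energy(ens, m.res_id == 1, m.res_id == 2, toy_params)
        pe_ac = pair_energy(ens, m.res_id == 1, m.res_id == 3, toy_params)
        pe_bc = pair_energy(ens, m.res_id == 2, m.res_id == 3, toy_params)
        total = triple_energy(pe_ab, pe_ac, pe_bc)
        brute = 0.0
        for ra, rb in ((1, 2), (1, 3), (2, 3)):
            brute += pair_energy(ens, m.res_id == ra, m.res_id == rb, toy_params).e_total
        assert total == pytest.approx(brute, rel=1e-12)

    def test_planted_box_term_recovered(self, rng):
        base = {k: float(rng.normal(-5, 1)) for k in TMB_KEYS}
        # make the combination vanish, then plant +0.3 on the full box
        planted = dict(base)
        resid = sum(TMB_SIGNS[k] * base[k] for k in TMB_KEYS)
        planted["xyz"] -= resid        # now combination = 0
        planted["xyz"] += 0.3
        assert dddE(planted).ddde == pytest.approx(0.3, abs=1e-12)

    def test_dddE_identity_with_dde_difference(self, rng):
        vals = {k: float(rng.normal(0, 2)) for k in TMB_KEYS}
        box = dddE(vals)
        in_z = dde(vals["xyz"], vals["x'yz"], vals["xy'z"], vals["x'y'z"]).dde
        in_zp = dde(vals["xyz'"], vals["x'yz'"], vals["xy'z'"], vals["x'y'z'"]).dde
        assert box.ddde == pytest.approx(in_z - in_zp, abs=1e-12)

    def test_missing_variant_key(self):
        vals = {k: 0.0 for k in TMB_KEYS if k != "x'y'z'"}
        with pytest.raises(KeyError) as exc:
            dddE(vals)
        assert "x'y'z'" in exc.value.args[0]


class TestPercentagewise:
    def test_reference_fraction(self):
        assert percent_cooperativity(-0.2, -0.4, -0.6) == pytest.approx(-0.40)

    def test_zero_numerator(self):
        assert percent_cooperativity(0.0, -0.4, -0.6) == 0.0

    def test_linearity(self):
        one = percent_cooperativity(-0.1, -0.4, -0.6)
        two = percent_cooperativity(-0.2, -0.4, -0.6)
        assert two == pytest.approx(2 * one)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_cooperativity(-0.2, 0.3, -0.3)

    def test_sign_preserved_for_attractive_interactions(self):
        assert percent_cooperativity(0.15, -0.4, -0.6) > 0
        assert percent_cooperativity(-0.15, -0.4, -0.6) < 0
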