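"""XH...pi geometric measurement, detection, and distance changes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xhpi import (EnsembleSpec, MissingAtomError, add_decoy_ring,
                  candidate_residue_pairs, delta_d, detect_candidates,
                  donor_definition, find_donors, find_rings,
                  generate_xhpi_ensemble, measure_ensemble, ring_centroid,
                  ring_definition, xh_pi_geometry)
from xhpi.structures import Ensemble


def _hexagon(radius=0.139, center=(0, 0, 0)):
    ang = np.arange(6) * np.pi / 3
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)
    return pts + np.asarray(center, dtype=float)


def _transformed(ensemble, rot, shift):
    coords = ensemble.coord @ rot.T + np.asarray(shift)
    return Ensemble(ensemble.chain_id, ensemble.res_id, ensemble.res_name,
                    ensemble.atom_name, ensemble.element, coords)


def _angle_oracle(a, b, c):
    """Independent angle routine (atan2 form, unlike the arccos used inside)."""
    u, v = np.asarray(a) - b, np.asarray(c) - b
    return np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))


class TestCentroid:
    def test_regular_hexagon_centroid_is_origin(self):
        assert np.linalg.norm(ring_centroid(_hexagon())) < 1e-12

    def test_translation_equivariance(self):
        c = ring_centroid(_hexagon(center=(1, 2, 3)))
        assert np.allclose(c, (1, 2, 3), atol=1e-12)

    def test_matches_direct_average_on_random_points(self, rng):
        pts = rng.normal(size=(6, 3))
        assert np.allclose(ring_centroid(pts), pts.mean(axis=0), atol=1e-12)

    def test_mass_weighting_identical_for_all_carbon(self, rng):
        pts = rng.normal(size=(6, 3))
        unw = ring_centroid(pts)
        mw = ring_centroid(pts, masses=np.full(6, 12.011), rule="mass-weighted")
        assert np.allclose(unw, mw, atol=1e-12)

    def test_wrong_atom_count_rejected(self):
        with pytest.raises(ValueError):
            ring_centroid(np.zeros((5, 3)))


class TestMeasurement:
    def test_collinear_hydrogen_gives_180(self):
        spec = EnsembleSpec(d_target=0.40, omega_target=180.0, jitter_sd=0.0)
        ens = generate_xhpi_ensemble(spec)
        g = xh_pi_geometry(ens[0], donor_definition(spec), ring_definition(spec))
        assert g.omega == pytest.approx(180.0, abs=1e-9)
        assert g.d == pytest.approx(0.40, abs=1e-9)

    def test_omega_max_rule_equals_brute_force_over_hydrogens(self):
        rng = np.random.default_rng(2024)
        for trial in range(300):
            kind = "methyl" if trial % 2 == 0 else "amide"
            spec = EnsembleSpec(
                d_target=float(rng.uniform(0.30, 0.80)),
                omega_target=float(rng.uniform(95.0, 179.0)),
                donor_kind=kind, jitter_sd=0.0, seed=trial)
            ens = _transformed(generate_xhpi_ensemble(spec),
                               Rotation.random(rng=rng).as_matrix(),
                               rng.normal(scale=30.0, size=3))
            donor, ring = donor_definition(spec), ring_definition(spec)
            g = xh_pi_geometry(ens[0], donor, ring)
            model = ens[0]
            res = (model.res_id == donor.res_id)
            heavy = model.coord[res & (model.atom_name == donor.heavy_atom)][0] / 10
            ring_xyz = np.array([
                model.coord[(model.res_id == ring.res_id)
                            & (model.atom_name == n)][0] / 10
                for n in ring.atom_names])
            x = ring_xyz.mean(axis=0)
            brute = {h: _angle_oracle(heavy, model.coord[res & (model.atom_name == h)][0] / 10, x)
                     for h in donor.hydrogens}
            assert g.omega == pytest.approx(max(brute.values()), abs=1e-9)
            assert brute[g.which_h] == max(brute.values())

    def test_rigid_motion_invariance(self, rng):
        spec = EnsembleSpec(d_target=0.45, omega_target=150.0, jitter_sd=0.0)
        ens = generate_xhpi_ensemble(spec)
        donor, ring = donor_definition(spec), ring_definition(spec)
        g0 = xh_pi_geometry(ens[0], donor, ring)
        moved = _transformed(ens, Rotation.random(rng=rng).as_matrix(), [5.0, -3.0, 12.0])
        g1 = xh_pi_geometry(moved[0], donor, ring)
        assert g1.d == pytest.approx(g0.d, abs=1e-9)
        assert g1.omega == pytest.approx(g0.omega, abs=1e-7)

    def test_group_com_distance_mode_differs_from_heavy(self):
        spec = EnsembleSpec(d_target=0.45, omega_target=150.0, jitter_sd=0.0)
        ens = generate_xhpi_ensemble(spec)
        donor, ring = donor_definition(spec), ring_definition(spec)
        g_heavy = xh_pi_geometry(ens[0], donor, ring, d_from="heavy")
        g_com = xh_pi_geometry(ens[0], donor, ring, d_from="group_com")
        assert g_heavy.d == pytest.approx(0.45, abs=1e-9)
        assert abs(g_com.d - g_heavy.d) > 1e-4  # hydrogens shift the group COM

    def test_missing_ring_atom_is_named(self):
        spec = EnsembleSpec(d_target=0.45, omega_target=150.0, jitter_sd=0.0)
        ens = generate_xhpi_ensemble(spec)
        keep = ens.atom_name != "CZ"
        pruned = Ensemble(ens.chain_id[keep], ens.res_id[keep], ens.res_name[keep],
                          ens.atom_name[keep], ens.element[keep],
                          ens.coord[:, keep, :])
        with pytest.raises(MissingAtomError, match="CZ"):
            xh_pi_geometry(pruned[0], donor_definition(spec), ring_definition(spec))

    def test_hydrogen_construction_when_absent(self):
        spec = EnsembleSpec(d_target=0.45, omega_target=160.0, jitter_sd=0.0)
        ens = generate_xhpi_ensemble(spec)
        keep = ~np.char.startswith(ens.atom_name.astype(str), "H")
        noh = Ensemble(ens.chain_id[keep], ens.res_id[keep], ens.res_name[keep],
                       ens.atom_name[keep], ens.element[keep], ens.coord[:, keep, :])
        donor = donor_definition(spec)
        bare = type(donor)(kind=donor.kind, chain_id=donor.chain_id,
                           res_id=donor.res_id, res_name=donor.res_name,
                           heavy_atom=donor.heavy_atom, parent_atom=donor.parent_atom)
        g = xh_pi_geometry(noh[0], bare, ring_definition(spec))
        assert g.hydrogens_built
        assert g.d == pytest.approx(0.45, abs=1e-9)  # d is H-placement independent
        with pytest.raises(MissingAtomError, match="construction"):
            xh_pi_geometry(noh[0], bare, ring_definition(spec), build_hydrogens=False)


class TestDetection:
    def _scene(self, omega=150.0, n_models=3, jitter=0.002, seed=5):
        spec = EnsembleSpec(n_models=n_models, d_target=0.45, omega_target=omega,
                            jitter_sd=jitter, seed=seed)
        return add_decoy_ring(generate_xhpi_ensemble(spec), 1.2), spec

    def test_planted_pair_found_decoy_rejected(self):
        ens, _ = self._scene()
        cands = detect_candidates(ens)
        assert [c.pair_label for c in cands] == ["ALA1-PHE2"]
        assert candidate_residue_pairs(cands) == [("ALA1", "PHE2", "methyl")]

    def test_low_omega_pair_rejected(self):
        ens, _ = self._scene(omega=100.0)
        assert detect_candidates(ens, omega_min_deg=120.0) == []

    def test_thresholds_are_monotone(self):
        ens, _ = self._scene()
        loose = len(detect_candidates(ens, d_max_nm=1.5, omega_min_deg=60.0))
        tight_d = len(detect_candidates(ens, d_max_nm=0.3, omega_min_deg=60.0))
        tight_w = len(detect_candidates(ens, d_max_nm=1.5, omega_min_deg=170.0))
        assert tight_d <= loose and tight_w <= loose

    def test_atom_order_independence(self, rng):
        ens, _ = self._scene()
        perm = rng.permutation(ens.array_length())
        shuffled = Ensemble(ens.chain_id[perm], ens.res_id[perm], ens.res_name[perm],
                            ens.atom_name[perm], ens.element[perm],
                            ens.coord[:, perm, :])
        a = [(c.pair_label, round(c.geometry.d, 9)) for c in detect_candidates(ens)]
        b = [(c.pair_label, round(c.geometry.d, 9)) for c in detect_candidates(shuffled)]
        assert a == b

    def test_finds_rings_and_donors(self):
        ens, spec = self._scene()
        model = ens[0]
        rings = find_rings(model)
        assert {r.res_id for r in rings} == {2, 9}
        donors = find_donors(model)
        assert [(d.kind, d.res_id) for d in donors] == [("methyl", 1)]


class TestDeltaD:
    def _series(self, d, n=4):
        spec = EnsembleSpec(n_models=n, d_target=d, omega_target=150.0,
                            jitter_sd=0.0, seed=0)
        return measure_ensemble(generate_xhpi_ensemble(spec),
                                donor_definition(spec), ring_definition(spec))

    def test_identical_series_give_zero_under_both_conventions(self):
        s = self._series(0.45)
        assert delta_d(s, s).delta_d == 0.0
        assert delta_d(s, s, convention="weakening-positive").delta_d == 0.0

    def test_sign_semantics(self):
        wt, mut = self._series(0.45), self._series(0.47)
        lit = delta_d(wt, mut, convention="eq-literal")
        wp = delta_d(wt, mut, convention="weakening-positive")
        assert lit.delta_d == pytest.approx(-0.02, abs=1e-9)
        assert wp.delta_d == pytest.approx(+0.02, abs=1e-9)

    def test_single_snapshot_series(self):
        assert delta_d(self._series(0.45, n=1), self._series(0.45, n=1)).delta_d \
            == pytest.approx(0.0, abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            delta_d([], self._series(0.45))
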