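"""Seeded generators for every input the analysis pipeline consumes.

Three families of synthetic data:

* noisy two-state denaturation curves (linear baselines, i.i.d. Gaussian
  signal noise, exact denaturant concentrations);
* mutant families whose per-variant folding free energies are strictly
  additive plus planted pairwise-interaction and three-body cooperativity
  terms, so the mutant-cycle algebra recovers the planted values exactly on
  noiseless data;
* multi-model coordinate ensembles containing one donor group (methyl or
  side-chain amide) and one aromatic six-ring placed to reproduce a target
  (d, omega) exactly before isotropic per-atom thermal jitter is applied.

All randomness flows through explicit integer seeds; identical specs and
seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .constants import (ANGSTROM_PER_NM, BOND_CC_AROMATIC_NM, BOND_CH_NM,
                        BOND_NH_NM, DEFAULT_TEMPERATURE)
from .curves import DenaturationCurve, two_state_signal
from .cycles import Mutations, format_variant_label
from .geometry import DonorGroup, RingDefinition
from .structures import Ensemble

__all__ = [
    "CurveSpec",
    "FamilySpec",
    "EnsembleSpec",
    "FamilyData",
    "generate_denaturation_curve",
    "generate_mutant_family",
    "generate_xhpi_ensemble",
    "donor_definition",
    "ring_definition",
    "add_decoy_ring",
    "full_box_variants",
]


@dataclass(frozen=True)
class CurveSpec:
    """Ground-truth parameters for one synthetic melt.

    Defaults describe a stable small protein denatured in GdnHCl: m = 2.0
    kcal/mol/M, midpoint 2.5 M, a 25-point 0-6 M titration, gently sloping
    fluorescence baselines spanning ~0.8 signal units, and Gaussian noise of
    1% of that span.
    """

    alpha_N: float = 1.0
    beta_N: float = -0.01
    alpha_U: float = 0.2
    beta_U: float = 0.005
    m_value: float = 2.0          # kcal/mol/M
    d50: float = 2.5              # M
    temperature: float = DEFAULT_TEMPERATURE
    d_grid: tuple = tuple(np.linspace(0.0, 6.0, 25))
    noise_sd: float = 0.008       # signal units

    def __post_init__(self):
        grid = tuple(float(x) for x in self.d_grid)
        object.__setattr__(self, "d_grid", grid)
        if self.m_value <= 0:
            raise ValueError("invalid CurveSpec: m_value must be positive")
        if self.d50 <= 0:
            raise ValueError("invalid CurveSpec: d50 must be positive")
        if self.temperature <= 0:
            raise ValueError("invalid CurveSpec: temperature must be positive")
        if self.noise_sd < 0:
            raise ValueError("invalid CurveSpec: noise_sd must be non-negative")
        arr = np.asarray(grid)
        if arr.size < 2 or np.any(np.diff(arr) <= 0):
            raise ValueError("invalid CurveSpec: d_grid must be strictly increasing")
        if np.any(arr < 0):
            raise ValueError("invalid CurveSpec: d_grid entries must be non-negative")

    def signal(self, D):
        return two_state_signal(D, self.alpha_N, self.beta_N, self.alpha_U,
                                self.beta_U, self.m_value, self.d50,
                                temperature=self.temperature)


def generate_denaturation_curve(spec: CurveSpec, seed: int,
                                variant_label: str = "synthetic") -> DenaturationCurve:
    """One noisy melt: ideal two-state signal plus N(0, noise_sd) per point."""
    rng = np.random.default_rng(seed)
    d = np.asarray(spec.d_grid, dtype=float)
    signal = spec.signal(d) + rng.normal(0.0, spec.noise_sd, size=d.size)
    return DenaturationCurve(variant_label=variant_label, denaturant=d,
                             signal=signal, temperature=spec.temperature)


# ---------------------------------------------------------------------------
# mutant families

def _as_mut_set(label) -> Mutations:
    if isinstance(label, str):
        from .cycles import parse_variant_label
        return parse_variant_label(label)
    return frozenset(label)


@dataclass(frozen=True)
class FamilySpec:
    """Additive truth model for a mutant family.

    ``pair_terms`` maps unordered residue pairs to planted interaction
    energies (kcal/mol) that survive only while both residues are unmutated;
    ``coop_terms`` does the same for residue triples.  ``variant_labels``
    lists the mutation sets to realize (the empty set is the wild type).
    """

    base_dg: float = 5.0
    pair_terms: Mapping = field(default_factory=dict)
    coop_terms: Mapping = field(default_factory=dict)
    variant_labels: Sequence = (frozenset(),)
    extra_residues: tuple = ()

    def __post_init__(self):
        pairs = {frozenset(k): float(v) for k, v in dict(self.pair_terms).items()}
        trips = {frozenset(k): float(v) for k, v in dict(self.coop_terms).items()}
        for p in pairs:
            if len(p) != 2:
                raise ValueError(f"pair term key {sorted(p)} must name two residues")
        for t in trips:
            if len(t) != 3:
                raise ValueError(f"cooperativity term key {sorted(t)} must name three residues")
        variants = tuple(_as_mut_set(v) for v in self.variant_labels)
        if len(set(variants)) != len(variants):
            raise ValueError("variant_labels must be unique")
        known = set().union(*pairs, *trips) if (pairs or trips) else set()
        known |= set(self.extra_residues)
        mutated_anywhere = set().union(*variants) if variants else set()
        for res in set().union(*pairs, *trips) if (pairs or trips) else set():
            if res not in mutated_anywhere:
                raise ValueError(
                    f"residue {res!r} carries a planted term but is never mutated "
                    "in any variant")
        for v in variants:
            unknown = v - known
            if unknown:
                raise ValueError(
                    f"variant {format_variant_label(v)!r} references unknown "
                    f"residue(s) {sorted(unknown)}")
        object.__setattr__(self, "pair_terms", pairs)
        object.__setattr__(self, "coop_terms", trips)
        object.__setattr__(self, "variant_labels", variants)

    def true_dg(self, mutations) -> float:
        """Truth folding free energy: base plus all surviving planted terms."""
        muts = _as_mut_set(mutations)
        dg = self.base_dg
        for members, term in {**self.pair_terms, **self.coop_terms}.items():
            if not (members & muts):
                dg += term
        return float(dg)


@dataclass(frozen=True)
class FamilyData:
    """Generated curves and the ground-truth free-energy table."""

    curves: Mapping  # variant label -> DenaturationCurve
    truth: pd.DataFrame  # columns: variant, dg_true, d50_true


def generate_mutant_family(fspec: FamilySpec, cspec: CurveSpec, seed: int) -> FamilyData:
    """One melt per variant, midpoint set by the truth model (d50 = dG/m).

    Per-variant noise streams are spawned from ``seed`` so adding a variant
    does not perturb the others.
    """
    children = np.random.SeedSequence(seed).spawn(len(fspec.variant_labels))
    curves, rows = {}, []
    for muts, ss in zip(fspec.variant_labels, children):
        label = format_variant_label(muts)
        dg = fspec.true_dg(muts)
        if dg <= 0:
            raise ValueError(
                f"variant {label!r} has non-positive truth dG ({dg:.3g}); "
                "choose a larger base_dg")
        d50 = dg / cspec.m_value
        vspec = dataclasses.replace(cspec, d50=d50)
        rng_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        curves[label] = generate_denaturation_curve(vspec, rng_seed, variant_label=label)
        rows.append({"variant": label, "dg_true": dg, "d50_true": d50})
    return FamilyData(curves=curves, truth=pd.DataFrame(rows))


def full_box_variants(x: str, y: str, z: str):
    """The eight mutation sets of a triple mutant box for residues x, y, z."""
    out = []
    for mx in (frozenset(), frozenset({x})):
        for my in (frozenset(), frozenset({y})):
            for mz in (frozenset(), frozenset({z})):
                out.append(mx | my | mz)
    return out


# ---------------------------------------------------------------------------
# coordinate ensembles

@dataclass(frozen=True)
class EnsembleSpec:
    """A donor group facing an aromatic ring at a prescribed geometry."""

    n_models: int = 1
    d_target: float = 0.40        # nm, heavy atom to ring centroid
    omega_target: float = 160.0   # degrees
    donor_kind: str = "methyl"    # "methyl" | "amide"
    jitter_sd: float = 0.0        # nm, isotropic per-atom Gaussian noise
    ring_kind: str = "PHE-like"   # "PHE-like" | "TYR-like"
    seed: int = 0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("invalid EnsembleSpec: n_models must be >= 1")
        if self.d_target <= 0:
            raise ValueError("invalid EnsembleSpec: d_target must be positive")
        if not (0 < self.omega_target <= 180):
            raise ValueError("invalid EnsembleSpec: omega_target must be in (0, 180]")
        if self.jitter_sd < 0:
            raise ValueError("invalid EnsembleSpec: jitter_sd must be non-negative")
        if self.donor_kind not in ("methyl", "amide"):
            raise ValueError("invalid EnsembleSpec: donor_kind must be methyl or amide")
        if self.ring_kind not in ("PHE-like", "TYR-like"):
            raise ValueError("invalid EnsembleSpec: ring_kind must be PHE-like or TYR-like")

    @property
    def xh_bond(self) -> float:
        return BOND_CH_NM if self.donor_kind == "methyl" else BOND_NH_NM


def _omega_of_tilt(theta: float, d: float, r: float) -> float:
    """Angle heavy-H-centroid when the X-H bond is tilted by theta from the
    heavy-to-centroid direction (all in one plane)."""
    c = np.array([0.0, 0.0, d])
    h = c + r * np.array([np.sin(theta), 0.0, -np.cos(theta)])
    u = c - h
    v = -h  # centroid at origin
    cosw = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosw, -1.0, 1.0))))


def _solve_tilt(d: float, r: float, omega_deg: float) -> float:
    """Tilt angle reproducing omega for a donor at distance d with bond r."""
    if d <= r:
        raise ValueError(
            f"infeasible geometry: d_target {d:.3f} nm does not exceed the "
            f"X-H bond length {r:.3f} nm (hydrogen would overshoot the centroid)")
    if omega_deg >= 180.0:
        return 0.0
    lo, hi = 1e-9, np.pi - 1e-9
    f = lambda th: _omega_of_tilt(th, d, r) - omega_deg
    return float(brentq(f, lo, hi, xtol=1e-14))


def _hexagon(centroid, radius_nm=BOND_CC_AROMATIC_NM, normal_axis=2):
    pts = []
    for k in range(6):
        ang = np.pi / 3.0 * k
        p = np.zeros(3)
        p[(normal_axis + 1) % 3] = radius_nm * np.cos(ang)
        p[(normal_axis + 2) % 3] = radius_nm * np.sin(ang)
        pts.append(np.asarray(centroid, dtype=float) + p)
    return np.array(pts)


_RING_NAME_ORDER = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")  # adjacency order


def _build_reference_atoms(spec: EnsembleSpec):
    """Ideal (jitter-free) atom names/coords in nm, plus residue metadata."""
    d, r = spec.d_target, spec.xh_bond
    theta = _solve_tilt(d, r, spec.omega_target)
    heavy = np.array([0.0, 0.0, d])
    dir1 = np.array([np.sin(theta), 0.0, -np.cos(theta)])
    atoms = []  # (res_id, res_name, atom_name, element, coord)

    if spec.donor_kind == "methyl":
        # rotor axis tilted *past* the designed C-H bond so the designed
        # hydrogen sits closest to the centroid direction and therefore
        # carries the maximal heavy-H-centroid angle
        tau = np.deg2rad(180.0 - 109.471)
        axis = np.array([np.sin(theta + tau), 0.0, -np.cos(theta + tau)])
        h1 = heavy + r * dir1
        rot = Rotation.from_rotvec(axis * np.deg2rad(120.0))
        d2 = rot.apply(dir1)
        d3 = rot.apply(d2)
        ca = heavy - 0.152 * axis
        res = "ALA"
        atoms += [(1, res, "CA", "C", ca), (1, res, "CB", "C", heavy),
                  (1, res, "HB1", "H", h1),
                  (1, res, "HB2", "H", heavy + r * d2),
                  (1, res, "HB3", "H", heavy + r * d3)]
        others = (d2, d3)
    else:
        # planar sp2 amide: second hydrogen 120 deg from the first, in-plane
        cand_a = np.array([np.sin(theta + 2 * np.pi / 3), 0.0,
                           -np.cos(theta + 2 * np.pi / 3)])
        cand_b = np.array([np.sin(theta - 2 * np.pi / 3), 0.0,
                           -np.cos(theta - 2 * np.pi / 3)])
        dir2 = cand_a if cand_a[2] > cand_b[2] else cand_b
        cg_dir = -(dir1 + dir2)
        cg_dir /= np.linalg.norm(cg_dir)
        cg = heavy + 0.134 * cg_dir
        u = (heavy - cg) / np.linalg.norm(heavy - cg)
        rot = Rotation.from_rotvec(np.array([0.0, 1.0, 0.0]) * np.deg2rad(120.0))
        od1 = cg + 0.123 * rot.apply(u)
        res = "ASN"
        atoms += [(1, res, "CG", "C", cg), (1, res, "OD1", "O", od1),
                  (1, res, "ND2", "N", heavy),
                  (1, res, "HD21", "H", heavy + r * dir1),
                  (1, res, "HD22", "H", heavy + r * dir2)]
        others = (dir2,)

    # the designed hydrogen must tilt least from the centroid direction,
    # otherwise a sibling would take over the max-angle rule
    toward_x = -heavy / np.linalg.norm(heavy)
    designed_tilt = np.arccos(np.clip(dir1 @ toward_x, -1, 1))
    for other in others:
        if np.arccos(np.clip(other @ toward_x, -1, 1)) <= designed_tilt + 1e-9:
            raise ValueError(
                f"infeasible geometry: omega_target {spec.omega_target:.1f} deg "
                f"cannot be made the maximal angle of a {spec.donor_kind} donor "
                f"at d_target {d:.3f} nm")

    ring_res = "PHE" if spec.ring_kind == "PHE-like" else "TYR"
    hex_pts = _hexagon(np.zeros(3))
    for name, p in zip(_RING_NAME_ORDER, hex_pts):
        atoms.append((2, ring_res, name, "C", p))
    if ring_res == "TYR":
        cz = hex_pts[_RING_NAME_ORDER.index("CZ")]
        out = cz / np.linalg.norm(cz)
        atoms.append((2, ring_res, "OH", "O", cz + 0.136 * out))
    return atoms


def _rows_to_ensemble(atom_rows, coords_nm) -> Ensemble:
    coords_nm = np.asarray(coords_nm, dtype=np.float64)
    if coords_nm.ndim == 2:
        coords_nm = coords_nm[None, :, :]
    return Ensemble(
        chain_id=["A"] * len(atom_rows),
        res_id=[a[0] for a in atom_rows],
        res_name=[a[1] for a in atom_rows],
        atom_name=[a[2] for a in atom_rows],
        element=[a[3] for a in atom_rows],
        coord=coords_nm * ANGSTROM_PER_NM)


def generate_xhpi_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Multi-model coordinate set realizing (d_target, omega_target).

    The jitter-free geometry reproduces the targets exactly under the
    measurement conventions (heavy-atom distance, max-angle hydrogen);
    isotropic Gaussian jitter of sd ``jitter_sd`` nm is then added per atom
    per model from ``spec.seed``.  Coordinates are float64 so the zero-
    jitter round trip holds to 1e-6.
    """
    atom_rows = _build_reference_atoms(spec)
    ref = np.array([a[4] for a in atom_rows])
    rng = np.random.default_rng(spec.seed)
    coords = np.stack([ref + rng.normal(0.0, spec.jitter_sd, size=ref.shape)
                       for _ in range(spec.n_models)])
    return _rows_to_ensemble(atom_rows, coords)


def donor_definition(spec: EnsembleSpec) -> DonorGroup:
    """DonorGroup matching :func:`generate_xhpi_ensemble` output."""
    if spec.donor_kind == "methyl":
        return DonorGroup(kind="methyl", chain_id="A", res_id=1, res_name="ALA",
                          heavy_atom="CB", hydrogens=("HB1", "HB2", "HB3"),
                          parent_atom="CA")
    return DonorGroup(kind="amide", chain_id="A", res_id=1, res_name="ASN",
                      heavy_atom="ND2", hydrogens=("HD21", "HD22"),
                      parent_atom="CG", carbonyl_oxygen="OD1")


def ring_definition(spec: EnsembleSpec) -> RingDefinition:
    """RingDefinition matching :func:`generate_xhpi_ensemble` output."""
    return RingDefinition(chain_id="A", res_id=2,
                          res_name="PHE" if spec.ring_kind == "PHE-like" else "TYR")


def add_decoy_ring(ensemble: Ensemble, distance_nm: float,
                   ring_kind: str = "PHE-like", res_id: int = 9,
                   direction=(1.0, 0.0, 0.0)) -> Ensemble:
    """Append a far-away aromatic ring (centered ``distance_nm`` from the
    original ring centroid along ``direction``) to every model — a negative
    control for detection thresholds."""
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    centroid = distance_nm * direction
    ring_res = "PHE" if ring_kind == "PHE-like" else "TYR"
    rows = [(res_id, ring_res, name, "C", p)
            for name, p in zip(_RING_NAME_ORDER, _hexagon(centroid))]
    coords = np.repeat(np.array([r[4] for r in rows])[None, :, :],
                       len(ensemble), axis=0)
    return ensemble.merged_with(_rows_to_ensemble(rows, coords))
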