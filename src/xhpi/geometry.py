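"""Detect and measure C-H...pi and N-H...pi geometries in coordinate models.

An XH...pi contact is characterized by two parameters:

* ``d`` — distance from the donor heavy atom (methyl carbon or amide
  nitrogen) to the centroid X of the aromatic six-ring, in nm;
* ``omega`` — the angle (heavy atom)-H-X at the hydrogen, in degrees; for
  donors with several hydrogens the largest such angle is taken.

By default ``d`` is measured from the heavy atom because that choice does
not depend on hydrogen placement; a donor-group center-of-mass mode is
available (``d_from="group_com"``).  Crystal structures usually lack
hydrogens, so ideal ones are constructed on demand (tetrahedral methyl,
planar amide) and flagged in the result.

Coordinate containers are biotite :class:`AtomArray` /
:class:`AtomArrayStack` objects (angstrom, as in PDB files); every distance
this module reports is converted to nm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import (ANGSTROM_PER_NM, BOND_CH_NM, BOND_NH_NM,
                        DEFAULT_D_MAX_NM, DEFAULT_OMEGA_MIN_DEG)

__all__ = [
    "RING_ATOMS",
    "METHYL_GROUPS",
    "AMIDE_GROUPS",
    "RingDefinition",
    "DonorGroup",
    "XHPiGeometry",
    "Candidate",
    "DeltaDResult",
    "MissingAtomError",
    "ring_centroid",
    "find_rings",
    "find_donors",
    "xh_pi_geometry",
    "measure_ensemble",
    "detect_candidates",
    "candidate_residue_pairs",
    "delta_d",
]

#: Six ring-carbon names per aromatic residue kind (exocyclic atoms such as
#: the TYR hydroxyl oxygen are deliberately excluded from the centroid).
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

#: Methyl donors: residue -> {methyl carbon: parent heavy atom}.
METHYL_GROUPS = {
    "ALA": {"CB": "CA"},
    "VAL": {"CG1": "CB", "CG2": "CB"},
    "LEU": {"CD1": "CG", "CD2": "CG"},
    "ILE": {"CG2": "CB", "CD1": "CG1"},
    "THR": {"CG2": "CB"},
    "MET": {"CE": "SD"},
}

#: Side-chain amide donors: residue -> (N, attached C, carbonyl O).
AMIDE_GROUPS = {
    "ASN": ("ND2", "CG", "OD1"),
    "GLN": ("NE2", "CD", "OE1"),
}

_ATOM_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}


class MissingAtomError(KeyError):
    """A required atom is absent from the coordinate model."""


@dataclass(frozen=True)
class RingDefinition:
    """One aromatic six-ring in a specific residue."""

    chain_id: str
    res_id: int
    res_name: str
    atom_names: tuple = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    centroid_rule: str = "unweighted"

    def __post_init__(self):
        if len(self.atom_names) != 6:
            raise ValueError("a ring definition needs exactly six atoms")
        if self.centroid_rule not in ("unweighted", "mass-weighted"):
            raise ValueError(f"unknown centroid rule {self.centroid_rule!r}")

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.res_id}"


@dataclass(frozen=True)
class DonorGroup:
    """A methyl or side-chain amide XH donor."""

    kind: str  # "methyl" | "amide"
    chain_id: str
    res_id: int
    res_name: str
    heavy_atom: str
    hydrogens: tuple = ()
    parent_atom: str | None = None
    carbonyl_oxygen: str | None = None  # amide only, for H rebuilding

    def __post_init__(self):
        if self.kind not in ("methyl", "amide"):
            raise ValueError(f"unknown donor kind {self.kind!r}")
        if self.hydrogens:
            n = len(self.hydrogens)
            if self.kind == "methyl" and n != 3:
                raise ValueError("a methyl donor carries exactly 3 hydrogens")
            if self.kind == "amide" and n not in (1, 2):
                raise ValueError("an amide donor carries 1 or 2 hydrogens")

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.res_id}"


@dataclass(frozen=True)
class XHPiGeometry:
    """Measured (d, omega) for one donor/ring pair in one snapshot."""

    d: float  # nm
    omega: float  # degrees
    which_h: str
    snapshot_index: int = 0
    donor_kind: str = "methyl"
    hydrogens_built: bool = False

    def __post_init__(self):
        if not (0.0 < self.omega <= 180.0):
            raise ValueError("omega must lie in (0, 180] degrees")
        if self.d <= 0:
            raise ValueError("d must be positive")


@dataclass(frozen=True)
class Candidate:
    """A donor/ring pair passing the detection thresholds (ensemble means)."""

    donor: DonorGroup
    ring: RingDefinition
    geometry: XHPiGeometry            # means over snapshots (snapshot_index=-1)
    geometries: tuple = ()            # per-snapshot measurements

    @property
    def pair_label(self) -> str:
        return f"{self.donor.label}-{self.ring.label}"


@dataclass(frozen=True)
class DeltaDResult:
    """Change in mean donor-centroid distance between two ensembles."""

    pair_label: str
    d_wt_mean: float
    d_mut_mean: float
    delta_d: float
    convention: str

    def __post_init__(self):
        if self.convention not in ("eq-literal", "weakening-positive"):
            raise ValueError(f"unknown convention {self.convention!r}")


# ---------------------------------------------------------------------------
# selection helpers

def _models(structure):
    """Models of a multi-model container (biotite stack or Ensemble) or a
    single model; dispatch on coordinate dimensionality."""
    if np.asarray(structure.coord).ndim == 3:
        return list(structure)
    return [structure]


def _residue_mask(atoms, chain_id, res_id):
    return (atoms.chain_id == chain_id) & (atoms.res_id == res_id)


def _atom_coord_nm(atoms, chain_id, res_id, atom_name, res_label=""):
    mask = _residue_mask(atoms, chain_id, res_id) & (atoms.atom_name == atom_name)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise MissingAtomError(
            f"atom {atom_name!r} missing from residue {res_label or res_id} "
            f"(chain {chain_id!r})")
    return atoms.coord[idx[0]] / ANGSTROM_PER_NM


def _unit(v, context="vector"):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate {context}: zero-length vector")
    return v / n


def _perpendicular_pair(u):
    e = np.zeros(3)
    e[np.argmin(np.abs(u))] = 1.0
    v = _unit(np.cross(u, e))
    w = np.cross(u, v)
    return v, w


# ---------------------------------------------------------------------------
# ideal hydrogen construction

_TETRA_HALF = np.deg2rad(180.0 - 109.471)  # angle of C-H from the methyl axis


def methyl_hydrogen_positions(c, parent, bond=BOND_CH_NM, phase=0.0):
    """Three ideal tetrahedral hydrogens on a methyl carbon.

    ``c`` and ``parent`` are nm coordinates of the methyl carbon and the
    heavy atom it is bonded to; ``phase`` rotates the rotor (radians).
    """
    u = _unit(np.asarray(c) - np.asarray(parent), "methyl axis")
    v, w = _perpendicular_pair(u)
    cos_t, sin_t = np.cos(_TETRA_HALF), np.sin(_TETRA_HALF)
    out = []
    for k in range(3):
        phi = phase + 2.0 * np.pi * k / 3.0
        direction = cos_t * u + sin_t * (np.cos(phi) * v + np.sin(phi) * w)
        out.append(np.asarray(c) + bond * direction)
    return np.array(out)


def amide_hydrogen_positions(n, attached_c, carbonyl_o, bond=BOND_NH_NM):
    """Two ideal planar hydrogens on an sp2 amide nitrogen (C-N-H = 120 deg)."""
    n = np.asarray(n, dtype=float)
    a = _unit(n - np.asarray(attached_c), "amide C-N bond")
    normal = _unit(np.cross(a, np.asarray(carbonyl_o) - np.asarray(attached_c)),
                   "amide plane normal")
    p = _unit(np.cross(normal, a))
    cos60, sin60 = 0.5, np.sqrt(3.0) / 2.0
    return np.array([n + bond * (cos60 * a + sin60 * p),
                     n + bond * (cos60 * a - sin60 * p)])


def _donor_hydrogen_coords(atoms, donor: DonorGroup, build: bool = True):
    """Hydrogen coordinates (nm) for a donor in one model.

    Uses hydrogens present in the model (named in the donor or found within
    bonding distance of the heavy atom); otherwise constructs ideal ones.
    Returns ``(names, coords, built_flag)``.
    """
    heavy = _atom_coord_nm(atoms, donor.chain_id, donor.res_id, donor.heavy_atom,
                           donor.label)
    if donor.hydrogens:
        coords = np.array([
            _atom_coord_nm(atoms, donor.chain_id, donor.res_id, h, donor.label)
            for h in donor.hydrogens])
        return list(donor.hydrogens), coords, False
    # search for hydrogens bonded to the heavy atom
    res = _residue_mask(atoms, donor.chain_id, donor.res_id)
    is_h = np.char.startswith(atoms.atom_name.astype(str), "H")
    if hasattr(atoms, "element"):
        elem = atoms.element.astype(str)
        is_h = is_h | (np.char.strip(elem) == "H")
    cand = np.nonzero(res & is_h)[0]
    if cand.size:
        coords = atoms.coord[cand] / ANGSTROM_PER_NM
        dist = np.linalg.norm(coords - heavy, axis=1)
        bonded = cand[dist < 0.125]
        want = 3 if donor.kind == "methyl" else 2
        if bonded.size:
            names = list(atoms.atom_name[bonded])
            return names, atoms.coord[bonded] / ANGSTROM_PER_NM, False
    if not build:
        raise MissingAtomError(
            f"no hydrogens on {donor.label} {donor.heavy_atom} and hydrogen "
            "construction is disabled; enable build_hydrogens to place ideal ones")
    if donor.kind == "methyl":
        parent = donor.parent_atom or METHYL_GROUPS.get(donor.res_name, {}).get(donor.heavy_atom)
        if parent is None:
            raise MissingAtomError(
                f"cannot build methyl hydrogens on {donor.label}: unknown parent atom")
        ppos = _atom_coord_nm(atoms, donor.chain_id, donor.res_id, parent, donor.label)
        coords = methyl_hydrogen_positions(heavy, ppos)
        return [f"H{k+1}*" for k in range(3)], coords, True
    c_name = donor.parent_atom or AMIDE_GROUPS.get(donor.res_name, ("", "", ""))[1]
    o_name = donor.carbonyl_oxygen or AMIDE_GROUPS.get(donor.res_name, ("", "", ""))[2]
    if not c_name or not o_name:
        raise MissingAtomError(
            f"cannot build amide hydrogens on {donor.label}: unknown frame atoms")
    cpos = _atom_coord_nm(atoms, donor.chain_id, donor.res_id, c_name, donor.label)
    opos = _atom_coord_nm(atoms, donor.chain_id, donor.res_id, o_name, donor.label)
    coords = amide_hydrogen_positions(heavy, cpos, opos)
    return ["H1*", "H2*"], coords, True


# ---------------------------------------------------------------------------
# measurement

def ring_centroid(coords, masses=None, rule="unweighted"):
    """Centroid of six ring-atom coordinates (same units as input).

    ``rule="mass-weighted"`` weights by ``masses`` (identical to the
    unweighted mean for an all-carbon ring).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (6, 3):
        raise ValueError("ring centroid needs exactly six 3-D coordinates")
    if rule == "mass-weighted" and masses is not None:
        m = np.asarray(masses, dtype=float)
        return (coords * m[:, None]).sum(axis=0) / m.sum()
    return coords.mean(axis=0)


def _ring_centroid_nm(atoms, ring: RingDefinition):
    coords = np.array([
        _atom_coord_nm(atoms, ring.chain_id, ring.res_id, name, ring.label)
        for name in ring.atom_names])
    masses = None
    if ring.centroid_rule == "mass-weighted":
        masses = np.array([_ATOM_MASS.get(n[0], 12.011) for n in ring.atom_names])
    return ring_centroid(coords, masses, ring.centroid_rule)


def _angle_deg(a, b, c):
    """Angle a-b-c at vertex b, degrees."""
    u = _unit(np.asarray(a) - np.asarray(b), "angle arm")
    v = _unit(np.asarray(c) - np.asarray(b), "angle arm")
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def xh_pi_geometry(atoms, donor: DonorGroup, ring: RingDefinition,
                   snapshot_index: int = 0, d_from: str = "heavy",
                   build_hydrogens: bool = True) -> XHPiGeometry:
    """Measure (d, omega) for one donor/ring pair in one model.

    ``d`` is heavy-atom-to-centroid by default; ``d_from="group_com"`` uses
    the donor group's center of mass (heavy atom plus hydrogens).  ``omega``
    is the largest (heavy)-H-centroid angle over the donor's hydrogens.
    """
    if d_from not in ("heavy", "group_com"):
        raise ValueError(f"unknown d_from mode {d_from!r}")
    centroid = _ring_centroid_nm(atoms, ring)
    heavy = _atom_coord_nm(atoms, donor.chain_id, donor.res_id, donor.heavy_atom,
                           donor.label)
    h_names, h_coords, built = _donor_hydrogen_coords(atoms, donor, build_hydrogens)
    if d_from == "heavy":
        ref = heavy
    else:
        m_heavy = _ATOM_MASS["C" if donor.kind == "methyl" else "N"]
        m_h = _ATOM_MASS["H"]
        ref = (m_heavy * heavy + m_h * h_coords.sum(axis=0)) / (m_heavy + m_h * len(h_coords))
    d = float(np.linalg.norm(ref - centroid))
    if d < 1e-9:
        raise ValueError("donor coincides with ring centroid")
    angles = [_angle_deg(heavy, h, centroid) for h in h_coords]
    best = int(np.argmax(angles))
    return XHPiGeometry(d=d, omega=float(angles[best]), which_h=str(h_names[best]),
                        snapshot_index=snapshot_index, donor_kind=donor.kind,
                        hydrogens_built=built)


def measure_ensemble(structure, donor: DonorGroup, ring: RingDefinition,
                     d_from: str = "heavy", build_hydrogens: bool = True):
    """Per-snapshot (d, omega) series over all models of a structure."""
    return [xh_pi_geometry(model, donor, ring, snapshot_index=i, d_from=d_from,
                           build_hydrogens=build_hydrogens)
            for i, model in enumerate(_models(structure))]


# ---------------------------------------------------------------------------
# enumeration / detection

def find_rings(atoms, ring_atoms: dict | None = None):
    """All complete PHE/TYR-type six-rings present in a model."""
    table = ring_atoms or RING_ATOMS
    rings = []
    for chain_id, res_id, res_name in _iter_residues(atoms):
        names = table.get(res_name)
        if names is None:
            continue
        mask = _residue_mask(atoms, chain_id, res_id)
        present = set(atoms.atom_name[mask])
        if all(n in present for n in names):
            rings.append(RingDefinition(chain_id=chain_id, res_id=int(res_id),
                                        res_name=res_name, atom_names=tuple(names)))
    return rings


def find_donors(atoms, kinds=("methyl", "amide")):
    """All methyl and side-chain amide donor groups present in a model."""
    donors = []
    for chain_id, res_id, res_name in _iter_residues(atoms):
        mask = _residue_mask(atoms, chain_id, res_id)
        present = set(atoms.atom_name[mask])
        if "methyl" in kinds:
            for carbon, parent in METHYL_GROUPS.get(res_name, {}).items():
                if carbon in present and parent in present:
                    donors.append(DonorGroup(
                        kind="methyl", chain_id=chain_id, res_id=int(res_id),
                        res_name=res_name, heavy_atom=carbon, parent_atom=parent))
        if "amide" in kinds and res_name in AMIDE_GROUPS:
            n, c, o = AMIDE_GROUPS[res_name]
            if {n, c, o} <= present:
                donors.append(DonorGroup(
                    kind="amide", chain_id=chain_id, res_id=int(res_id),
                    res_name=res_name, heavy_atom=n, parent_atom=c,
                    carbonyl_oxygen=o))
    return donors


def _iter_residues(atoms):
    seen, out = set(), []
    for chain_id, res_id, res_name in zip(atoms.chain_id, atoms.res_id, atoms.res_name):
        key = (str(chain_id), int(res_id))
        if key not in seen:
            seen.add(key)
            out.append((str(chain_id), int(res_id), str(res_name)))
    return out


def detect_candidates(structure, d_max_nm: float = DEFAULT_D_MAX_NM,
                      omega_min_deg: float = DEFAULT_OMEGA_MIN_DEG,
                      d_from: str = "heavy", build_hydrogens: bool = True,
                      kinds=("methyl", "amide")):
    """Enumerate donor-group/aromatic-ring pairs with mean d <= ``d_max_nm``
    and mean omega >= ``omega_min_deg`` over the models of ``structure``.

    Defaults (0.6 nm, 120 deg) reflect where XH...pi contacts cluster in
    folded proteins.  Same-residue pairs are excluded.  Results are sorted by
    (donor residue, ring residue, d) and independent of input atom order.
    """
    first = _models(structure)[0]
    rings = find_rings(first)
    donors = find_donors(first, kinds=kinds)
    candidates = []
    for donor, ring in itertools.product(donors, rings):
        if (donor.chain_id, donor.res_id) == (ring.chain_id, ring.res_id):
            continue
        # cheap prefilter on the first model before measuring the whole stack
        try:
            g0 = xh_pi_geometry(first, donor, ring, d_from=d_from,
                                build_hydrogens=build_hydrogens)
        except MissingAtomError:
            continue
        if g0.d > 2.0 * max(d_max_nm, 0.1):
            continue
        series = measure_ensemble(structure, donor, ring, d_from=d_from,
                                  build_hydrogens=build_hydrogens)
        d_mean = float(np.mean([g.d for g in series]))
        omega_mean = float(np.mean([g.omega for g in series]))
        if d_mean <= d_max_nm and omega_mean >= omega_min_deg:
            mean_geom = XHPiGeometry(
                d=d_mean, omega=omega_mean, which_h=series[0].which_h,
                snapshot_index=-1, donor_kind=donor.kind,
                hydrogens_built=any(g.hydrogens_built for g in series))
            candidates.append(Candidate(donor=donor, ring=ring,
                                        geometry=mean_geom, geometries=tuple(series)))
    candidates.sort(key=lambda c: (c.donor.chain_id, c.donor.res_id,
                                   c.ring.chain_id, c.ring.res_id, c.geometry.d))
    return candidates


def candidate_residue_pairs(candidates):
    """Collapse donor-group candidates to unique residue pairs.

    Returns a sorted list of ``(donor_label, ring_label, donor_kind)``;
    residues with several qualifying methyls contribute one pair.
    """
    pairs = {(c.donor.label, c.ring.label, c.donor.kind) for c in candidates}
    return sorted(pairs)


def delta_d(wt_series: Sequence[XHPiGeometry], mut_series: Sequence[XHPiGeometry],
            pair_label: str = "", convention: str = "eq-literal") -> DeltaDResult:
    """Change of the mean donor-centroid distance upon a neighboring mutation.

    ``convention="eq-literal"`` returns d_WT - d_MUT; ``"weakening-positive"``
    returns the negation, so a positive value means the contact lengthened
    (weakened) in the mutant.
    """
    if not wt_series or not mut_series:
        raise ValueError("both geometry series must be non-empty")
    d_wt = float(np.mean([g.d for g in wt_series]))
    d_mut = float(np.mean([g.d for g in mut_series]))
    literal = d_wt - d_mut
    value = literal if convention == "eq-literal" else -literal
    return DeltaDResult(pair_label=pair_label, d_wt_mean=d_wt, d_mut_mean=d_mut,
                        delta_d=float(value), convention=convention)
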