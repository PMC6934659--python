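"""Residue-pair nonbonded energies and the mutant-box energy decomposition.

The pair interaction energy between two disjoint atom selections x and y is

    E_xy = E_coul / eps + E_LJ
    E_coul = sum_ij k_e q_i q_j / r_ij          (k_e = 332.0636 kcal A / e^2)
    E_LJ   = sum_ij 4 eps_ij [(sigma_ij/r_ij)^12 - (sigma_ij/r_ij)^6]

with Lorentz-Berthelot combination (arithmetic sigma, geometric epsilon),
an effective dielectric constant eps (default 4.0) screening the
electrostatics, and no distance cutoff within the pair.  Energies are
averaged over the snapshots of a coordinate ensemble.

The mutant-cycle algebra then mirrors the thermodynamic one on energies:

    ddE  = E_xy - E_x'y - E_xy' + E_x'y'
    E_xyz = E_xy + E_yz + E_xz
    dddE = ddE(z background) - ddE(z' background)

and the percentagewise cooperativity is dddE divided by the magnitude of
the mean of the two pair interactions it couples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ANGSTROM_PER_NM, COULOMB_K, DEFAULT_EPSILON_EFF
from .cycles import TMB_KEYS, TMB_SIGNS

__all__ = [
    "AtomParams",
    "PairEnergy",
    "DecompositionResult",
    "TripleDecomposition",
    "pair_energy",
    "dde",
    "triple_energy",
    "dddE",
    "percent_cooperativity",
]

DDE_SIGNS = {"xy": +1.0, "x'y": -1.0, "xy'": -1.0, "x'y'": +1.0}


class AtomParams:
    """Nonbonded parameters keyed by (residue name, atom name).

    Each entry carries a partial charge (e), an LJ sigma (nm) and an LJ
    epsilon (kcal/mol).  Per-pair overrides of (sigma_ij, eps_ij) take
    precedence over Lorentz-Berthelot combination when present.
    """

    def __init__(self, table: Mapping[tuple, tuple], pair_overrides=None):
        self._table = {}
        for (res, atom), (q, sig, eps) in table.items():
            if sig <= 0:
                raise ValueError(f"lj_sigma must be positive for {res}:{atom}")
            if eps < 0:
                raise ValueError(f"lj_epsilon must be non-negative for {res}:{atom}")
            self._table[(str(res), str(atom))] = (float(q), float(sig), float(eps))
        self._overrides = {}
        for key, (sig, eps) in (pair_overrides or {}).items():
            self._overrides[frozenset(key) if len(set(key)) == 2 else (key[0],)] = \
                (float(sig), float(eps))

    @classmethod
    def from_tsv(cls, path) -> "AtomParams":
        """Read a parameter table with columns
        residue, atom, charge_e, sigma_nm, epsilon_kcal ('#' comments allowed)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"residue", "atom", "charge_e", "sigma_nm", "epsilon_kcal"}
        if not required <= set(df.columns):
            raise ValueError(f"parameter table must have columns {sorted(required)}")
        table = {(r.residue, r.atom): (r.charge_e, r.sigma_nm, r.epsilon_kcal)
                 for r in df.itertuples()}
        return cls(table)

    def lookup(self, res_name: str, atom_name: str):
        key = (str(res_name), str(atom_name))
        if key not in self._table:
            raise KeyError(f"no nonbonded parameters for atom {res_name}:{atom_name}")
        return self._table[key]

    def combined(self, key_i: tuple, key_j: tuple):
        """(q_i*q_j, sigma_ij [nm], eps_ij) for an atom-type pair."""
        qi, si, ei = self.lookup(*key_i)
        qj, sj, ej = self.lookup(*key_j)
        okey = frozenset((key_i, key_j)) if key_i != key_j else (key_i,)
        if okey in self._overrides:
            sij, eij = self._overrides[okey]
        else:
            sij = 0.5 * (si + sj)
            eij = math.sqrt(ei * ej)
        return qi * qj, sij, eij


@dataclass(frozen=True)
class PairEnergy:
    """Ensemble-averaged pair interaction energy (kcal/mol)."""

    pair_label: str
    e_coul: float
    e_lj: float
    e_total: float
    epsilon_eff: float
    n_snapshots: int
    se: float
    snapshot_totals: tuple = ()

    def __post_init__(self):
        if self.epsilon_eff <= 0:
            raise ValueError("epsilon_eff must be positive")
        if abs(self.e_total - (self.e_coul + self.e_lj)) > 1e-10 * max(
                1.0, abs(self.e_total)):
            raise ValueError("e_total must equal e_coul + e_lj")

    @classmethod
    def zero(cls, pair_label: str = "absent", epsilon_eff: float = DEFAULT_EPSILON_EFF,
             n_snapshots: int = 1) -> "PairEnergy":
        """The alanine-truncation convention: a selection emptied by mutation
        contributes zero interaction energy."""
        return cls(pair_label=pair_label, e_coul=0.0, e_lj=0.0, e_total=0.0,
                   epsilon_eff=epsilon_eff, n_snapshots=n_snapshots, se=0.0)


@dataclass(frozen=True)
class DecompositionResult:
    """ddE for one pair in one background (kcal/mol)."""

    pair_label: str
    background_label: str
    dde: float
    se: float


@dataclass(frozen=True)
class TripleDecomposition:
    """dddE for one residue triple, with optional percentagewise value."""

    triple_label: str
    ddde: float
    se: float
    percentagewise: float | None = None


def _models(structure):
    if np.asarray(structure.coord).ndim == 3:
        return list(structure)
    return [structure]


def pair_energy(structure, sel_x, sel_y, params: AtomParams,
                epsilon_eff: float = DEFAULT_EPSILON_EFF,
                pair_label: str = "") -> PairEnergy:
    """Coulomb/eps + LJ interaction between atom selections over an ensemble.

    ``sel_x`` and ``sel_y`` are boolean masks or index arrays into the
    structure's atoms; they must be disjoint and non-empty.  No distance
    cutoff is applied within the pair.
    """
    if epsilon_eff <= 0:
        raise ValueError("epsilon_eff must be positive")
    models = _models(structure)
    atoms0 = models[0]
    ix = np.arange(atoms0.array_length())[np.asarray(sel_x)] \
        if np.asarray(sel_x).dtype == bool else np.asarray(sel_x, dtype=int)
    iy = np.arange(atoms0.array_length())[np.asarray(sel_y)] \
        if np.asarray(sel_y).dtype == bool else np.asarray(sel_y, dtype=int)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("both selections must be non-empty")
    if np.intersect1d(ix, iy).size:
        raise ValueError("selections overlap; pair energy requires disjoint atom sets")

    qq = np.empty((ix.size, iy.size))
    sig = np.empty_like(qq)
    eps = np.empty_like(qq)
    for a, i in enumerate(ix):
        key_i = (str(atoms0.res_name[i]), str(atoms0.atom_name[i]))
        for b, j in enumerate(iy):
            key_j = (str(atoms0.res_name[j]), str(atoms0.atom_name[j]))
            qq[a, b], sig[a, b], eps[a, b] = params.combined(key_i, key_j)
    sig_a = sig * ANGSTROM_PER_NM  # work in angstrom alongside coordinates

    coul_snap, lj_snap = [], []
    for atoms in models:
        rx = atoms.coord[ix]
        ry = atoms.coord[iy]
        r = np.linalg.norm(rx[:, None, :] - ry[None, :, :], axis=-1)
        if np.any(r < 1e-6):
            raise ValueError("coincident atoms between the two selections")
        coul_snap.append(np.sum(COULOMB_K * qq / (epsilon_eff * r)))
        sr6 = (sig_a / r) ** 6
        lj_snap.append(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    coul = np.asarray(coul_snap)
    lj = np.asarray(lj_snap)
    totals = coul + lj
    n = totals.size
    se = float(np.std(totals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return PairEnergy(
        pair_label=pair_label,
        e_coul=float(coul.mean()), e_lj=float(lj.mean()),
        e_total=float(totals.mean()), epsilon_eff=epsilon_eff,
        n_snapshots=n, se=se, snapshot_totals=tuple(float(t) for t in totals))


def _as_energy_se(obj):
    if obj is None:
        return 0.0, 0.0
    if isinstance(obj, PairEnergy):
        return obj.e_total, obj.se
    return float(obj), 0.0


def dde(pe_xy, pe_xpy, pe_xyp, pe_xpyp, pair_label: str = "",
        background_label: str = "") -> DecompositionResult:
    """ddE = E_xy - E_x'y - E_xy' + E_x'y' with quadrature SE.

    Arguments may be :class:`PairEnergy`, bare numbers, or ``None`` (treated
    as zero energy, the alanine-truncation convention).
    """
    vals = [_as_energy_se(p) for p in (pe_xy, pe_xpy, pe_xyp, pe_xpyp)]
    value = vals[0][0] - vals[1][0] - vals[2][0] + vals[3][0]
    se = math.sqrt(sum(v[1] ** 2 for v in vals))
    return DecompositionResult(pair_label=pair_label,
                               background_label=background_label,
                               dde=float(value), se=float(se))


def triple_energy(pe_xy, pe_yz, pe_xz) -> float:
    """E_xyz = E_xy + E_yz + E_xz within one variant ensemble."""
    return sum(_as_energy_se(p)[0] for p in (pe_xy, pe_yz, pe_xz))


def dddE(energies: Mapping[str, float], ses: Mapping[str, float] | None = None,
         triple_label: str = "", interactions: tuple | None = None) -> TripleDecomposition:
    """dddE from eight per-variant triple energies keyed ``"xyz"`` ... ``"x'y'z'"``.

    Expands ddE(z background) - ddE(z' background) over the eight variants.
    ``interactions=(int_1, int_2)`` additionally reports the percentagewise
    cooperativity against those two pair energies.
    """
    missing = [k for k in TMB_KEYS if k not in energies]
    if missing:
        raise KeyError(f"missing variant energy key(s): {missing}")
    value = sum(TMB_SIGNS[k] * float(energies[k]) for k in TMB_KEYS)
    var = sum(float(ses.get(k, 0.0)) ** 2 for k in TMB_KEYS) if ses else 0.0
    pct = None
    if interactions is not None:
        pct = percent_cooperativity(value, *interactions)
    return TripleDecomposition(triple_label=triple_label, ddde=float(value),
                               se=math.sqrt(var), percentagewise=pct)


def percent_cooperativity(ddde: float, int_1: float, int_2: float) -> float:
    """dddE divided by |mean(int_1, int_2)|, as a signed fraction.

    The absolute value in the denominator keeps the sign of the
    cooperativity: negative fractions are cooperative, positive
    anticooperative, regardless of the sign of the pair interactions.
    """
    mean = 0.5 * (int_1 + int_2)
    if abs(mean) < 1e-12:
        raise ZeroDivisionError(
            "percentagewise cooperativity undefined: mean pair interaction is zero")
    return float(ddde / abs(mean))
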