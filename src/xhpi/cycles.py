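"""Double-mutant-cycle (DMC) and triple-mutant-box (TMB) free-energy algebra.

A DMC isolates the pairwise interaction of side chains x and y from the
folding free energies of four variants:

    ddG_xy = dG_xy - dG_x'y - dG_xy' + dG_x'y'

(negative = favorable interaction).  Two DMCs measured in backgrounds that
differ only in a third residue z form a TMB whose difference is the
three-body cooperativity energy:

    dddG_coop = ddG_xy(z background) - ddG_xy(z' background)

(negative = cooperative: removing z weakens the x-y interaction).

Uncertainties propagate in quadrature by default (independent variant
measurements); a full covariance matrix over the input free energies can be
supplied when variants share measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Mutations",
    "parse_variant_label",
    "format_variant_label",
    "FreeEnergyRecord",
    "CycleResult",
    "BoxResult",
    "InteractionSummary",
    "BenchmarkResult",
    "dmc_energy",
    "cycle_from_family",
    "tmb_cooperativity",
    "tmb_from_records",
    "summarize_interactions",
    "rmsd_benchmark",
]

Mutations = frozenset

DMC_KEYS = ("xy", "x'y", "xy'", "x'y'")
DMC_SIGNS = {"xy": +1.0, "x'y": -1.0, "xy'": -1.0, "x'y'": +1.0}
TMB_KEYS = ("xyz", "x'yz", "xy'z", "x'y'z", "xyz'", "x'yz'", "xy'z'", "x'y'z'")
TMB_SIGNS = {"xyz": +1.0, "x'yz": -1.0, "xy'z": -1.0, "x'y'z": +1.0,
             "xyz'": -1.0, "x'yz'": +1.0, "xy'z'": +1.0, "x'y'z'": -1.0}


def parse_variant_label(label: str) -> Mutations:
    """Order-free mutation set from a label like ``"L5V-T18A"``; ``"WT"``/"" = none."""
    label = label.strip()
    if label in ("", "WT", "wt"):
        return frozenset()
    return frozenset(tok.strip() for tok in label.replace("+", "-").split("-") if tok.strip())


def format_variant_label(mutations: Iterable[str]) -> str:
    muts = sorted(mutations)
    return "-".join(muts) if muts else "WT"


@dataclass(frozen=True)
class FreeEnergyRecord:
    """Folding free energy of one variant (kcal/mol)."""

    mutations: Mutations
    dg: float
    sigma: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "mutations", frozenset(self.mutations))
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def variant_label(self) -> str:
        return format_variant_label(self.mutations)


@dataclass(frozen=True)
class CycleResult:
    """Pairwise interaction energy ddG from one DMC (kcal/mol)."""

    pair_label: str
    background_label: str
    ddg: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class BoxResult:
    """Three-body cooperativity energy dddG from one TMB (kcal/mol)."""

    triple_label: str
    dddg: float
    sigma: float
    classification: str

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.classification not in ("cooperative", "anticooperative", "indeterminate"):
            raise ValueError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class InteractionSummary:
    kind_label: str
    count: int
    n_favorable: int
    min: float
    max: float
    mean: float


@dataclass(frozen=True)
class BenchmarkResult:
    """RMSD between experimental ddG and computed ddE over paired entries."""

    rmsd: float
    n_used: int
    excluded_labels: tuple

    def __post_init__(self):
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def _combine(records: Mapping[str, FreeEnergyRecord], keys, signs,
             covariance=None):
    missing = [k for k in keys if k not in records]
    if missing:
        raise KeyError(f"missing variant role(s): {missing}")
    extra = [k for k in records if k not in keys]
    if extra:
        raise KeyError(f"unexpected variant role(s): {extra}")
    value = sum(signs[k] * records[k].dg for k in keys)
    c = np.array([signs[k] for k in keys])
    if covariance is not None:
        cov = np.asarray(covariance, dtype=float)
        if cov.shape != (len(keys), len(keys)):
            raise ValueError(f"covariance must be {len(keys)}x{len(keys)}")
        var = float(c @ cov @ c)
    else:
        var = sum(records[k].sigma ** 2 for k in keys)
    return float(value), math.sqrt(max(0.0, var))


def dmc_energy(records: Mapping[str, FreeEnergyRecord], pair_label: str = "",
               background_label: str = "WT", covariance=None) -> CycleResult:
    """ddG_xy from four variants keyed by role ``"xy"``, ``"x'y"``, ``"xy'"``, ``"x'y'"``.

    ``covariance`` (4x4, role order as above) replaces the default quadrature
    when the four measurements are correlated.
    """
    ddg, sigma = _combine(records, DMC_KEYS, DMC_SIGNS, covariance)
    return CycleResult(pair_label=pair_label, background_label=background_label,
                       ddg=ddg, sigma=sigma)


def cycle_from_family(family: Mapping[Mutations, FreeEnergyRecord] | Sequence[FreeEnergyRecord],
                      x: str, y: str, background: Iterable[str] = (),
                      pair_label: str | None = None) -> CycleResult:
    """Assemble a DMC for mutations ``x`` and ``y`` from a family table.

    ``family`` maps mutation sets to records (or is a sequence of records);
    ``background`` names extra mutations carried by all four variants.
    """
    if not isinstance(family, Mapping):
        family = {rec.mutations: rec for rec in family}
    bg = frozenset(background)
    roles = {
        "xy": bg,
        "x'y": bg | {x},
        "xy'": bg | {y},
        "x'y'": bg | {x, y},
    }
    records = {}
    for role, muts in roles.items():
        if muts not in family:
            raise KeyError(
                f"family table lacks variant {format_variant_label(muts)!r} (role {role})")
        records[role] = family[muts]
    return dmc_energy(records,
                      pair_label=pair_label or f"{x}-{y}",
                      background_label=format_variant_label(bg))


def _classify(dddg: float, sigma: float, mode: str) -> str:
    if mode == "sign":
        if dddg < 0:
            return "cooperative"
        if dddg > 0:
            return "anticooperative"
        return "indeterminate"
    if mode == "1sigma":
        if dddg < 0 and abs(dddg) > sigma:
            return "cooperative"
        if dddg > 0 and dddg > sigma:
            return "anticooperative"
        return "indeterminate"
    raise ValueError(f"unknown classification mode {mode!r}")


def tmb_cooperativity(cycle_in_z: CycleResult, cycle_in_zprime: CycleResult,
                      triple_label: str | None = None,
                      classification_mode: str = "sign") -> BoxResult:
    """dddG_coop = ddG(z background) - ddG(z' background).

    The two cycles must probe the same pair; negative values are classified
    cooperative.  ``classification_mode`` ``"sign"`` (default) classifies by
    sign alone; ``"1sigma"`` requires |dddG| to exceed its propagated sigma.
    """
    if cycle_in_z.pair_label != cycle_in_zprime.pair_label:
        raise ValueError(
            f"cycles probe different pairs: {cycle_in_z.pair_label!r} vs "
            f"{cycle_in_zprime.pair_label!r}")
    dddg = cycle_in_z.ddg - cycle_in_zprime.ddg
    sigma = math.hypot(cycle_in_z.sigma, cycle_in_zprime.sigma)
    label = triple_label or (
        f"{cycle_in_z.pair_label}|{cycle_in_z.background_label}"
        f"vs{cycle_in_zprime.background_label}")
    return BoxResult(triple_label=label, dddg=float(dddg), sigma=float(sigma),
                     classification=_classify(dddg, sigma, classification_mode))


def tmb_from_records(records: Mapping[str, FreeEnergyRecord],
                     triple_label: str = "",
                     classification_mode: str = "sign",
                     covariance=None) -> BoxResult:
    """dddG_coop from the full eight-variant box keyed ``"xyz"`` ... ``"x'y'z'"``.

    Expands (dG_xyz - dG_x'yz - dG_xy'z + dG_x'y'z) - (dG_xyz' - dG_x'yz' -
    dG_xy'z' + dG_x'y'z').  ``covariance`` is 8x8 in the key order above.
    """
    dddg, sigma = _combine(records, TMB_KEYS, TMB_SIGNS, covariance)
    return BoxResult(triple_label=triple_label, dddg=dddg, sigma=sigma,
                     classification=_classify(dddg, sigma, classification_mode))


def summarize_interactions(cycles: Sequence[CycleResult], kind_label: str) -> InteractionSummary:
    """Count / range / mean over a set of DMC interaction energies.

    ``n_favorable`` counts strictly negative (attractive) ddG values.
    """
    if not cycles:
        raise ValueError("cannot summarize an empty list of cycles")
    vals = np.array([c.ddg for c in cycles], dtype=float)
    return InteractionSummary(
        kind_label=kind_label,
        count=int(vals.size),
        n_favorable=int(np.sum(vals < 0)),
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
    )


def rmsd_benchmark(paired: Sequence[tuple], exclude: Sequence[str] = ()) -> BenchmarkResult:
    """Root-mean-square deviation between paired experimental and computed
    interaction energies, RMSD = sqrt(sum_i (ddG_exp,i - ddE_calc,i)^2 / N),
    after removing entries whose labels are listed in ``exclude``.
    """
    labels = [p[0] for p in paired]
    unknown = [e for e in exclude if e not in labels]
    if unknown:
        raise KeyError(f"exclusion label(s) not found: {unknown}")
    kept = [p for p in paired if p[0] not in set(exclude)]
    if not kept:
        raise ValueError("no entries left after exclusion")
    diff = np.array([p[1] - p[2] for p in kept], dtype=float)
    return BenchmarkResult(
        rmsd=float(np.sqrt(np.mean(diff ** 2))),
        n_used=len(kept),
        excluded_labels=tuple(exclude),
    )
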