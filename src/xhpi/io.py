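"""File I/O: schema-versioned CSV tables, multi-model PDB ensembles,
packaged reference data.

CSV dialect: comma-separated, '.' decimal, UTF-8, '#'-prefixed header
comments.  Every table this package writes starts with a schema line
(``# xhpi-schema: MAJOR.MINOR``); readers reject unknown major versions.
PDB is the only coordinate format (MODEL/ENDMDL records delimit snapshots,
coordinates in angstrom as the format requires).
"""

from __future__ import annotations

import io as _io
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure.io.pdb as pdb

from .constants import DEFAULT_TEMPERATURE
from .curves import DenaturationCurve, FoldingEnergy, TwoStateFit
from .cycles import (BoxResult, CycleResult, FreeEnergyRecord,
                     parse_variant_label)
from .energetics import AtomParams
from .structures import Ensemble

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_table",
    "read_table",
    "write_curves_csv",
    "read_curves_csv",
    "write_free_energies_csv",
    "read_free_energies_csv",
    "write_fits_csv",
    "write_cycles_csv",
    "write_boxes_csv",
    "read_ensemble",
    "write_ensemble",
    "load_reference_interactions",
    "reference_cycles",
    "load_toy_params",
]

SCHEMA_VERSION = "1.0"
_SCHEMA_RE = re.compile(r"#\s*xhpi-schema:\s*(\d+)\.(\d+)")


class SchemaError(ValueError):
    """A table carries an incompatible schema version."""


def _header_lines(extra: Sequence[str] = (), seed=None, config_hash=None):
    lines = [f"# xhpi-schema: {SCHEMA_VERSION}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config-hash: {config_hash}")
    lines.extend(f"# {e}" for e in extra)
    return lines


def write_table(df: pd.DataFrame, path, extra_comments: Sequence[str] = (),
                seed=None, config_hash=None) -> None:
    """Write a DataFrame as CSV under a schema-versioned comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    text = "\n".join(_header_lines(extra_comments, seed, config_hash)) + "\n" + buf.getvalue()
    path.write_text(text, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, enforcing schema major."""
    path = Path(path)
    major_here = int(SCHEMA_VERSION.split(".")[0])
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _SCHEMA_RE.match(line)
            if m and int(m.group(1)) != major_here:
                raise SchemaError(
                    f"{path.name}: schema major {m.group(1)} is not supported "
                    f"(this reader understands {major_here}.x)")
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# denaturation curves and free energies

def write_curves_csv(curves: Mapping[str, DenaturationCurve] | Iterable[DenaturationCurve],
                     path, **meta) -> None:
    """Columns: variant, denaturant_M, signal."""
    if isinstance(curves, Mapping):
        curves = list(curves.values())
    rows = []
    for c in curves:
        for d, s in zip(c.denaturant, c.signal):
            rows.append({"variant": c.variant_label, "denaturant_M": d, "signal": s})
    write_table(pd.DataFrame(rows), path, **meta)


def read_curves_csv(path, temperature: float = DEFAULT_TEMPERATURE):
    """Inverse of :func:`write_curves_csv`: dict variant -> curve."""
    df = read_table(path)
    out = {}
    for variant, grp in df.groupby("variant", sort=False):
        out[str(variant)] = DenaturationCurve(
            variant_label=str(variant),
            denaturant=grp["denaturant_M"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            temperature=temperature)
    return out


def write_free_energies_csv(records: Iterable[FreeEnergyRecord], path, **meta) -> None:
    rows = [{"variant": r.variant_label, "dg": r.dg, "sigma": r.sigma} for r in records]
    write_table(pd.DataFrame(rows), path, **meta)


def read_free_energies_csv(path):
    """Columns variant, dg, sigma -> list of FreeEnergyRecord."""
    df = read_table(path)
    return [FreeEnergyRecord(mutations=parse_variant_label(str(r.variant)),
                             dg=float(r.dg), sigma=float(getattr(r, "sigma", 0.0)))
            for r in df.itertuples()]


def write_fits_csv(fits: Iterable[TwoStateFit], energies: Iterable[FoldingEnergy],
                   path, **meta) -> None:
    """Per-variant fit table mirroring a stability-summary layout:
    baselines, m, D50, dG and its sigma."""
    emap = {e.variant_label: e for e in energies}
    rows = []
    for f in fits:
        e = emap.get(f.variant_label)
        rows.append({
            "variant": f.variant_label,
            "alpha_N": f.alpha_N, "beta_N": f.beta_N,
            "alpha_U": f.alpha_U, "beta_U": f.beta_U,
            "m_value": f.m_value, "d50_M": f.d50,
            "residual_sd": f.residual_sd,
            "dg": None if e is None else e.dg,
            "dg_sigma": None if e is None else e.sigma,
        })
    write_table(pd.DataFrame(rows), path, **meta)


def write_cycles_csv(cycles: Iterable[CycleResult], path, protein: str = "", **meta) -> None:
    rows = [{"protein": protein, "background": c.background_label, "pair": c.pair_label,
             "ddg": c.ddg, "sigma": c.sigma} for c in cycles]
    write_table(pd.DataFrame(rows), path, **meta)


def write_boxes_csv(boxes: Iterable[BoxResult], path, **meta) -> None:
    rows = [{"triple": b.triple_label, "dddg": b.dddg, "sigma": b.sigma,
             "classification": b.classification} for b in boxes]
    write_table(pd.DataFrame(rows), path, **meta)


# ---------------------------------------------------------------------------
# coordinate ensembles

def read_ensemble(path) -> Ensemble:
    """Read a single- or multi-model PDB as a float64 :class:`Ensemble`.

    Models must contain the same atoms; otherwise the error names the
    offending models.  Parsing is delegated to biotite.
    """
    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        structure = pdb_file.get_structure(model=None)
    except Exception as exc:
        counts = _model_atom_counts(path)
        if counts and len(set(counts)) > 1:
            bad = [i + 1 for i, c in enumerate(counts) if c != counts[0]]
            raise ValueError(
                f"{path.name}: inconsistent atom counts across models "
                f"(model(s) {bad} differ from model 1: {counts})") from exc
        raise ValueError(f"{path.name}: could not parse PDB: {exc}") from exc
    return Ensemble.from_biotite(structure)


def _model_atom_counts(path: Path):
    counts, current, in_model = [], 0, False
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, current = True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM") and in_model:
            current += 1
    return counts


def write_ensemble(stack, path, remarks: Sequence[str] = ()) -> None:
    """Write an AtomArray/AtomArrayStack as (multi-model) PDB with REMARK
    lines recording the schema version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(stack, Ensemble):
        stack = stack.to_biotite()
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    header = [f"REMARK 300 XHPI-SCHEMA {SCHEMA_VERSION}"]
    header += [f"REMARK 300 {r}" for r in remarks]
    pdb_file.lines = header + pdb_file.lines
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# packaged reference data

def _data_path(name: str):
    return resources.files("xhpi") / "data" / name


def load_reference_interactions(kind: str | None = None) -> pd.DataFrame:
    """The packaged experimental DMC interaction-energy table (kcal/mol).

    ``kind`` filters to ``"CH_pi"`` or ``"NH_pi"`` rows.
    """
    with resources.as_file(_data_path("experimental_ddg.csv")) as p:
        df = read_table(p)
    if kind is not None:
        df = df[df["kind"] == kind].reset_index(drop=True)
    return df


def reference_cycles(kind: str | None = None):
    """The packaged experimental table as CycleResult objects."""
    df = load_reference_interactions(kind)
    return [CycleResult(pair_label=str(r.pair), background_label=str(r.background),
                        ddg=float(r.ddg_kcal_mol), sigma=float(r.sigma_kcal_mol))
            for r in df.itertuples()]


def load_toy_params() -> AtomParams:
    """The packaged toy nonbonded parameter set (tests/examples only)."""
    with resources.as_file(_data_path("toy_params.tsv")) as p:
        return AtomParams.from_tsv(p)
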