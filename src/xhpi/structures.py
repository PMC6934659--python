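"""Double-precision coordinate ensembles.

Measured XH...pi parameters are contracted to round-trip generated
geometries at 1e-6 precision, which requires float64 coordinates; PDB-array
libraries typically store float32.  :class:`Ensemble` is therefore a thin
float64 container whose per-model views expose the same annotation
attributes as a biotite ``AtomArray`` (``chain_id``, ``res_id``,
``res_name``, ``atom_name``, ``element``, ``coord``), so every measurement
routine in this package accepts either interchangeably.  File I/O always
goes through biotite (:mod:`xhpi.io`).

Coordinates are in angstrom, matching the PDB convention; measurements
convert to nm at their boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

__all__ = ["ModelView", "Ensemble"]


@dataclass(frozen=True)
class ModelView:
    """One snapshot of an :class:`Ensemble` (annotation arrays are shared)."""

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray  # (n_atoms, 3) float64, angstrom

    def array_length(self) -> int:
        return self.coord.shape[0]


class Ensemble:
    """Multi-model coordinate set with float64 coordinates (angstrom)."""

    def __init__(self, chain_id, res_id, res_name, atom_name, element, coord):
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_id = np.asarray(res_id, dtype=int)
        self.res_name = np.asarray(res_name, dtype="U5")
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        coord = np.asarray(coord, dtype=np.float64)
        if coord.ndim != 3 or coord.shape[2] != 3:
            raise ValueError("coord must have shape (n_models, n_atoms, 3)")
        n = self.chain_id.shape[0]
        for name, arr in (("res_id", self.res_id), ("res_name", self.res_name),
                          ("atom_name", self.atom_name), ("element", self.element)):
            if arr.shape[0] != n:
                raise ValueError(f"annotation {name} length mismatch")
        if coord.shape[1] != n:
            raise ValueError("coord atom dimension does not match annotations")
        self.coord = coord

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.coord.shape[0]

    def array_length(self) -> int:
        return self.coord.shape[1]

    def __getitem__(self, i) -> ModelView:
        if isinstance(i, (int, np.integer)):
            return ModelView(self.chain_id, self.res_id, self.res_name,
                             self.atom_name, self.element, self.coord[i])
        raise TypeError("Ensemble indexing takes a model index")

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    # -- interop ------------------------------------------------------------
    @classmethod
    def from_biotite(cls, stack) -> "Ensemble":
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        return cls(stack.chain_id, stack.res_id, stack.res_name,
                   stack.atom_name, stack.element,
                   np.asarray(stack.coord, dtype=np.float64))

    def to_biotite(self) -> struc.AtomArrayStack:
        models = []
        for i in range(len(self)):
            arr = struc.AtomArray(self.array_length())
            arr.coord = self.coord[i]
            arr.chain_id = self.chain_id.copy()
            arr.res_id = self.res_id.copy()
            arr.res_name = self.res_name.copy()
            arr.atom_name = self.atom_name.copy()
            arr.element = self.element.copy()
            arr.hetero = np.zeros(self.array_length(), dtype=bool)
            models.append(arr)
        return struc.stack(models)

    def merged_with(self, other: "Ensemble") -> "Ensemble":
        """Concatenate atoms model-wise (both must have equal model counts)."""
        if len(self) != len(other):
            raise ValueError("model counts differ")
        return Ensemble(
            np.concatenate([self.chain_id, other.chain_id]),
            np.concatenate([self.res_id, other.res_id]),
            np.concatenate([self.res_name, other.res_name]),
            np.concatenate([self.atom_name, other.atom_name]),
            np.concatenate([self.element, other.element]),
            np.concatenate([self.coord, other.coord], axis=1))
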