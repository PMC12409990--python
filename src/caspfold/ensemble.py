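"""Multi-frame structural ensembles.

A :class:`ConformationalEnsemble` is the common substrate of the network and
essential-dynamics stages: a ``(n_frames, n_atoms, 3)`` coordinate array in
Angstrom plus a per-atom metadata table shared by all frames.  Multi-model PDB
is the on-disk interchange format (``MODEL``/``ENDMDL`` records, 1-based
residue numbering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

ATOM_COLUMNS = ["residue_index", "residue_name", "chain_id", "atom_name", "element"]


@dataclass
class ConformationalEnsemble:
    """Frames x atoms x 3 coordinates with a shared atom table.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    atoms
        DataFrame with one row per atom and columns ``residue_index``
        (1-based), ``residue_name``, ``chain_id``, ``atom_name``, ``element``.
    region
        Optional mapping of residue index to structural-region class
        (helix, beta, top_loop, bottom_loop, short_beta).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    region: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table is missing columns: {missing}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table length does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_indices(self) -> np.ndarray:
        """Sorted unique 1-based residue indices."""
        return np.unique(self.atoms["residue_index"].to_numpy())

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def sequence(self) -> str:
        """One-letter residue sequence in residue-index order."""
        per_res = (
            self.atoms.drop_duplicates("residue_index")
            .sort_values("residue_index")["residue_name"]
            .tolist()
        )
        return "".join(_THREE_TO_ONE.get(name, "X") for name in per_res)

    def frame(self, index: int) -> np.ndarray:
        return self.coords[index]

    def with_coords(self, coords: np.ndarray) -> "ConformationalEnsemble":
        """Copy of this ensemble with replaced coordinates (same atom table)."""
        return ConformationalEnsemble(coords, self.atoms, self.region)

    # ------------------------------------------------------------------ I/O

    def to_atom_array_stack(self) -> struc.AtomArrayStack:
        stack = struc.AtomArrayStack(self.n_frames, self.n_atoms)
        stack.coord = self.coords.copy()
        stack.chain_id = self.atoms["chain_id"].to_numpy(dtype="U4")
        stack.res_id = self.atoms["residue_index"].to_numpy(dtype=int)
        stack.res_name = self.atoms["residue_name"].to_numpy(dtype="U5")
        stack.atom_name = self.atoms["atom_name"].to_numpy(dtype="U6")
        stack.element = self.atoms["element"].to_numpy(dtype="U2")
        stack.hetero = np.zeros(self.n_atoms, dtype=bool)
        return stack

    def write_pdb(self, path: str | Path) -> None:
        """Write as a multi-model PDB (one MODEL per frame)."""
        pdb = PDBFile()
        pdb.set_structure(self.to_atom_array_stack())
        pdb.write(str(path))

    @classmethod
    def from_atom_array_stack(
        cls, stack: struc.AtomArrayStack, region: dict[int, str] | None = None
    ) -> "ConformationalEnsemble":
        atoms = pd.DataFrame(
            {
                "residue_index": stack.res_id.astype(int),
                "residue_name": stack.res_name.astype(str),
                "chain_id": stack.chain_id.astype(str),
                "atom_name": stack.atom_name.astype(str),
                "element": stack.element.astype(str),
            }
        )
        return cls(np.asarray(stack.coord, dtype=float), atoms, region)

    @classmethod
    def read_pdb(cls, path: str | Path) -> "ConformationalEnsemble":
        """Read a (multi-model) PDB file."""
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        return cls.from_atom_array_stack(stack)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
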