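"""Core containers for molecular systems and trajectories.

A :class:`Topology` stores the static description of a system — atom names,
elements, residues, chains, bonds — and a :class:`Trajectory` couples it with
a ``frames x atoms x 3`` coordinate array in Angstrom.  Everything downstream
(hydrogen-bond occupancy, interface contacts, RMSD, PCA) consumes these two
objects, so both validate their invariants at construction time and are
immutable afterwards.

Conventions
-----------
* Atom indices are 0-based, unique and contiguous from 0.
* Coordinates are in Angstrom everywhere; file readers convert on ingest.
* Residue numbers follow the source file (PDB convention, usually 1-based).
* Atoms of one residue are contiguous in the atom list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import MDCompareError

__all__ = [
    "Topology",
    "Trajectory",
    "AtomSelection",
    "HBondCriteria",
    "element_from_name",
    "mass_of_element",
]

#: Standard atomic masses (amu) for the elements that occur in protein systems.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "MG": 24.305, "K": 39.098, "CA": 40.078,
    "CL": 35.45, "FE": 55.845, "ZN": 65.38, "MN": 54.938,
}


def element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB-style atom name.

    Leading digits are ignored (``1HB`` -> ``H``); the first alphabetic
    character is taken as the element.  This is the standard fallback when
    the element column of a PDB file is blank and is reliable for protein
    and nucleotide atoms (H, C, N, O, S, P).
    """
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise MDCompareError(f"cannot infer element from atom name {name!r}")


def mass_of_element(element: str) -> float:
    return _MASSES.get(element.upper(), 0.0)


class Topology:
    """Immutable description of a molecular system.

    Parameters
    ----------
    names, elements, resnames, chain_ids : sequences of str, length n_atoms
    resnums : sequence of int, length n_atoms
    masses : optional sequence of float (amu); inferred from elements if absent
    bonds : iterable of (i, j) atom-index pairs
    """

    __slots__ = ("names", "elements", "resnames", "resnums", "chain_ids",
                 "masses", "bonds", "_adjacency")

    def __init__(self, names, elements, resnames, resnums, chain_ids,
                 masses=None, bonds=()):
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resnums = np.asarray(resnums, dtype=np.int64)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        n = len(self.names)
        for arr, label in ((self.elements, "elements"), (self.resnames, "resnames"),
                           (self.resnums, "resnums"), (self.chain_ids, "chain_ids")):
            if len(arr) != n:
                raise MDCompareError(f"{label} length {len(arr)} != n_atoms {n}")
        if masses is None:
            masses = [mass_of_element(e) for e in self.elements]
        self.masses = np.asarray(masses, dtype=np.float64)
        if len(self.masses) != n:
            raise MDCompareError("masses length mismatch")

        bond_list = sorted({(min(i, j), max(i, j)) for i, j in bonds})
        self.bonds = np.asarray(bond_list, dtype=np.int64).reshape(-1, 2)
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise MDCompareError(f"invalid bond ({i}, {j}) for {n} atoms")
        self._check_residue_contiguity()

        adjacency: dict[int, list[int]] = {}
        for i, j in self.bonds:
            adjacency.setdefault(int(i), []).append(int(j))
            adjacency.setdefault(int(j), []).append(int(i))
        self._adjacency = adjacency
        for arr in (self.names, self.elements, self.resnames, self.resnums,
                    self.chain_ids, self.masses, self.bonds):
            arr.flags.writeable = False

    def _check_residue_contiguity(self) -> None:
        seen: set[tuple] = set()
        prev = None
        for key in zip(self.chain_ids, self.resnums):
            if key != prev:
                if key in seen:
                    raise MDCompareError(
                        f"atoms of residue {key} are not contiguous")
                seen.add(key)
                prev = key

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chains(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        out: list[str] = []
        for c in self.chain_ids:
            if c not in out:
                out.append(c)
        return out

    def residues(self) -> Iterator[tuple[str, int, str, np.ndarray]]:
        """Yield ``(chain_id, resnum, resname, atom_indices)`` per residue."""
        n = self.n_atoms
        start = 0
        for i in range(1, n + 1):
            if i == n or (self.chain_ids[i], self.resnums[i]) != \
                    (self.chain_ids[start], self.resnums[start]):
                yield (self.chain_ids[start], int(self.resnums[start]),
                       self.resnames[start], np.arange(start, i))
                start = i

    def bonded_to(self, index: int) -> list[int]:
        return list(self._adjacency.get(index, ()))

    def hydrogens_of(self, index: int) -> list[int]:
        """Indices of hydrogen atoms bonded to ``index``."""
        return [j for j in self.bonded_to(index) if self.elements[j] == "H"]

    def has_hydrogens(self) -> bool:
        return bool(np.any(self.elements == "H"))

    def atom_label(self, index: int) -> str:
        """``RES<num>:<atom>`` label in the conventional report style."""
        return f"{self.resnames[index]}{self.resnums[index]}:{self.names[index]}"

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return (f"<Topology {self.n_atoms} atoms, "
                f"{len(list(self.residues()))} residues, "
                f"chains {self.chains}>")


class Trajectory:
    """A topology plus one or more coordinate frames (Angstrom).

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; all values must be
    finite and the atom count must match the topology.
    """

    __slots__ = ("topology", "coords", "frame_times")

    def __init__(self, topology: Topology, coords, frame_times=None):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise MDCompareError(f"coords must be (frames, atoms, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise MDCompareError("trajectory must contain at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise MDCompareError(
                f"coords have {coords.shape[1]} atoms, topology has {topology.n_atoms}")
        if not np.all(np.isfinite(coords)):
            raise MDCompareError("trajectory contains non-finite coordinates")
        self.topology = topology
        self.coords = coords
        self.coords.flags.writeable = False
        if frame_times is not None:
            frame_times = np.asarray(frame_times, dtype=np.float64)
            if frame_times.shape != (coords.shape[0],):
                raise MDCompareError("frame_times length mismatch")
        self.frame_times = frame_times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __repr__(self) -> str:
        return f"<Trajectory {self.n_frames} frames x {self.n_atoms} atoms>"


@dataclass(frozen=True)
class AtomSelection:
    """A resolved atom selection: sorted unique indices plus its source text.

    Produced by :func:`mdcompare.selection.select`; re-evaluating
    ``expression`` on the same topology yields the same indices.
    """

    indices: tuple[int, ...]
    expression: str
    n_atoms_topology: int

    def __post_init__(self):
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        object.__setattr__(self, "indices", idx)
        if idx and (idx[0] < 0 or idx[-1] >= self.n_atoms_topology):
            raise MDCompareError(
                f"selection {self.expression!r} references atoms outside topology")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``max_da_distance`` is the donor-heavy-atom to acceptor-heavy-atom
    distance cutoff (Angstrom) and ``min_dha_angle`` the donor-hydrogen-
    acceptor angle cutoff (degrees).  The defaults (3.0 A, 135 deg) are the
    convention of standard AMBER/CPPTRAJ trajectory analysis.  Boundaries
    are closed: distance == cutoff and angle == cutoff both count as bonded.
    """

    max_da_distance: float = 3.0
    min_dha_angle: float = 135.0

    def __post_init__(self):
        if not self.max_da_distance > 0:
            raise MDCompareError("max_da_distance must be positive")
        if not (0 < self.min_dha_angle <= 180.0):
            raise MDCompareError("min_dha_angle must be in (0, 180]")
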