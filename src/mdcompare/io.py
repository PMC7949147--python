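"""Structure and trajectory file I/O.

PDB reading/writing is implemented directly against the fixed-width column
layout so that parse errors can name the offending line, TER-separated
segments with colliding chain ids can be relabelled deterministically, and
per-residue B-factor maps can be written with explanatory REMARK records.
Binary trajectory formats (DCD, XTC) go through MDAnalysis; coordinates are
Angstrom in memory (MDAnalysis converts XTC's nm on read).

Bonds are not stored in PDB ATOM records, so :func:`read_structure` infers
them with a distance heuristic on the first frame: heavy-heavy pairs below
1.9 A and X-H pairs below 1.2 A are bonded.  This is only needed for
hydrogen-bond donor detection, not for energetics.
"""

from __future__ import annotations

import logging
import string
from os import PathLike
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .core import Topology, Trajectory, element_from_name
from .errors import (EmptyStructureError, MDCompareError, ParseError,
                     TopologyMismatchError)

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_bfactor_pdb",
    "write_dcd",
    "MASKED",
]

logger = logging.getLogger(__name__)

#: Sentinel for residues excluded from a B-factor map (written as 0.00 and
#: listed in a REMARK record).
MASKED = object()

_HEAVY_BOND_CUTOFF = 1.9  # A
_HYDROGEN_BOND_CUTOFF = 1.2  # A


def _infer_bonds(elements: np.ndarray, coords: np.ndarray) -> list[tuple[int, int]]:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(_HEAVY_BOND_CUTOFF)
    bonds = []
    for i, j in pairs:
        hi = elements[i] == "H"
        hj = elements[j] == "H"
        if hi and hj:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if (hi or hj) and d >= _HYDROGEN_BOND_CUTOFF:
            continue
        bonds.append((i, j))
    return bonds


def read_structure(path: str | PathLike) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-model) PDB file.

    MODEL blocks become trajectory frames sharing one topology; elements are
    taken from columns 77-78 when present, else inferred from the atom name.
    TER records delimit segments; if segments share a chain id (or have
    none), all segments are relabelled A, B, C, ... in file order and a
    warning is logged.
    """
    path = Path(path)
    names: list[str] = []
    elements: list[str] = []
    resnames: list[str] = []
    resnums: list[int] = []
    segments: list[int] = []
    raw_chains: list[str] = []
    frames: list[list[tuple[float, float, float]]] = [[]]
    in_first_model = True
    segment = 0

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record in ("ATOM", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: malformed coordinate field "
                        f"in ATOM record: {exc}") from None
                frames[-1].append((x, y, z))
                if in_first_model:
                    name = line[12:16].strip()
                    if not name:
                        raise ParseError(
                            f"{path.name}:{lineno}: ATOM record has no atom name")
                    element = line[76:78].strip() if len(line) >= 78 else ""
                    try:
                        resnum = int(line[22:26])
                    except ValueError:
                        raise ParseError(
                            f"{path.name}:{lineno}: malformed residue number "
                            f"{line[22:26]!r}") from None
                    names.append(name)
                    elements.append(element.upper() if element
                                    else element_from_name(name))
                    resnames.append(line[17:20].strip() or "UNK")
                    resnums.append(resnum)
                    raw_chains.append(line[21].strip())
                    segments.append(segment)
            elif record == "TER":
                segment += 1
            elif record == "ENDMDL":
                in_first_model = False
                segment = 0
                frames.append([])
            # MODEL, REMARK, END, etc. need no action

    frames = [f for f in frames if f]
    if not names:
        raise EmptyStructureError(f"{path.name}: no ATOM records found")
    n_atoms = len(names)
    for k, f in enumerate(frames):
        if len(f) != n_atoms:
            raise ParseError(
                f"{path.name}: model {k + 1} has {len(f)} atoms, expected {n_atoms}")

    chain_ids = _resolve_chain_ids(raw_chains, segments, path.name)
    coords = np.asarray(frames, dtype=np.float64)
    bonds = _infer_bonds(np.asarray(elements, dtype=object), coords[0])
    topology = Topology(names, elements, resnames, resnums, chain_ids,
                        bonds=bonds)
    return topology, Trajectory(topology, coords)


def _resolve_chain_ids(raw_chains: list[str], segments: list[int],
                       filename: str) -> list[str]:
    """Relabel TER-separated segments A, B, ... on chain-id collision."""
    seg_chains: dict[int, set[str]] = {}
    for c, s in zip(raw_chains, segments):
        seg_chains.setdefault(s, set()).add(c)
    seen: set[str] = set()
    collision = False
    for s in sorted(seg_chains):
        ids = seg_chains[s]
        if "" in ids or len(ids & seen) > 0:
            collision = True
        seen |= ids
    if not collision:
        return list(raw_chains)
    letters = string.ascii_uppercase
    logger.warning("%s: blank or colliding chain ids across TER segments; "
                   "relabelling segments %s", filename,
                   ", ".join(letters[s % 26] for s in sorted(seg_chains)))
    return [letters[s % 26] for s in segments]


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names shorter than 4 characters start at column 14.
    return name.ljust(4) if len(name) >= 4 else f" {name}".ljust(4)


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resnum: int, xyz, bfactor: float, element: str) -> str:
    # columns (0-based): [12:16] name, [16] altLoc, [17:20] resname,
    # [21] chain, [22:26] resnum, [30:54] xyz, [60:66] B, [76:78] element
    return (f"ATOM  {serial:>5d} {_format_atom_name(name)} {resname:>3s} "
            f"{(chain or ' ')[:1]}{resnum:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}"
            f"{bfactor:6.2f}          {element:>2s}\n")


def write_pdb(topology: Topology, coords, path: str | PathLike,
              bfactors=None, remarks: tuple[str, ...] = ()) -> Path:
    """Write a (multi-model) PDB file.

    ``coords`` is ``(n_atoms, 3)`` or ``(n_frames, n_atoms, 3)``; each frame
    becomes a MODEL block when more than one is given.  ``bfactors`` is an
    optional per-atom array written to the B-factor column.
    """
    path = Path(path)
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != topology.n_atoms:
        raise TopologyMismatchError(
            f"coords have {coords.shape[1]} atoms, topology has {topology.n_atoms}")
    if bfactors is None:
        bfactors = np.zeros(topology.n_atoms)
    bfactors = np.asarray(bfactors, dtype=np.float64)
    multi = coords.shape[0] > 1
    with open(path, "w") as out:
        for remark in remarks:
            out.write(f"REMARK   3 {remark}\n")
        for imodel, frame in enumerate(coords, start=1):
            if multi:
                out.write(f"MODEL     {imodel:>4d}\n")
            last_chain = None
            serial = 0
            for i in range(topology.n_atoms):
                chain = topology.chain_ids[i]
                if last_chain is not None and chain != last_chain:
                    out.write("TER\n")
                last_chain = chain
                serial += 1
                out.write(_pdb_atom_line(
                    serial, topology.names[i], topology.resnames[i], chain,
                    int(topology.resnums[i]), frame[i], float(bfactors[i]),
                    topology.elements[i]))
            out.write("TER\n")
            if multi:
                out.write("ENDMDL\n")
        out.write("END\n")
    return path


def write_bfactor_pdb(topology: Topology, frame, per_residue_values: Mapping,
                      path: str | PathLike) -> Path:
    """Write one frame with per-residue values in the B-factor column.

    ``per_residue_values`` maps residue keys — either ``resnum`` (int) or
    ``(chain_id, resnum)`` — to numbers in [-999.99, 999.99] or to
    :data:`MASKED`.  Every atom of a residue carries its residue's value;
    masked or unlisted residues get 0.00, masked ones are listed in a
    REMARK record.  This is the standard mechanism for colorimetric
    per-residue maps in molecular-graphics programs.
    """
    values: dict[tuple[str, int], object] = {}
    for key, value in per_residue_values.items():
        if isinstance(key, tuple):
            values[(key[0], int(key[1]))] = value
        else:
            for chain in topology.chains:
                values[(chain, int(key))] = value
    bfactors = np.zeros(topology.n_atoms)
    masked: list[str] = []
    for chain, resnum, _resname, idx in topology.residues():
        value = values.get((chain, resnum))
        if value is None:
            continue
        if value is MASKED or (isinstance(value, float) and np.isnan(value)):
            masked.append(f"{chain}:{resnum}")
            continue
        value = float(value)
        if not -999.99 <= value <= 999.99:
            raise MDCompareError(
                f"B-factor value {value} for residue {chain}:{resnum} outside "
                f"[-999.99, 999.99]")
        bfactors[idx] = value
    remarks = ()
    if masked:
        remarks = ("MASKED RESIDUES (B-FACTOR SET TO 0.00): " + " ".join(masked),)
    return write_pdb(topology, frame, path, bfactors=bfactors, remarks=remarks)


def read_bfactors(path: str | PathLike) -> dict[tuple[str, int], float]:
    """Read per-residue B-factor values back from a PDB file (first model)."""
    out: dict[tuple[str, int], float] = {}
    with open(path) as handle:
        for line in handle:
            if line.startswith("ENDMDL"):
                break
            if line[:6].strip() in ("ATOM", "HETATM"):
                key = (line[21].strip(), int(line[22:26]))
                out[key] = float(line[60:66])
    return out


def read_trajectory(path: str | PathLike, topology: Topology) -> Trajectory:
    """Read a DCD or XTC trajectory against an existing topology.

    Frames are returned in file order, in Angstrom (XTC nm values are
    converted by the reader).  An atom-count mismatch raises
    :class:`TopologyMismatchError`; unreadable/empty files raise
    :class:`ParseError`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    elif suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    else:
        raise MDCompareError(f"unsupported trajectory format {suffix!r}")
    try:
        reader = Reader(str(path))
    except Exception as exc:
        raise ParseError(f"cannot read trajectory {path.name}: {exc}") from exc
    with reader:
        if reader.n_atoms != topology.n_atoms:
            raise TopologyMismatchError(
                f"{path.name} has {reader.n_atoms} atoms, topology has "
                f"{topology.n_atoms}")
        coords = np.array([ts.positions.copy() for ts in reader],
                          dtype=np.float64)
    if coords.shape[0] < 1:
        raise ParseError(f"{path.name}: trajectory contains no frames")
    return Trajectory(topology, coords)


def write_dcd(coords, path: str | PathLike) -> Path:
    """Write a coordinate array (frames x atoms x 3, Angstrom) as DCD."""
    import MDAnalysis as mda

    path = Path(path)
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with mda.coordinates.DCD.DCDWriter(str(path), n_atoms) as writer:
        for frame in coords:
            u.atoms.positions = frame
            writer.write(u.atoms)
    return path
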