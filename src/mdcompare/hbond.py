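"""Geometric hydrogen-bond detection and occupancy time-averaging.

A donor-hydrogen-acceptor triple is *bonded* in a frame when the
donor-heavy-atom to acceptor-heavy-atom distance is at or below the cutoff
and the donor-hydrogen-acceptor angle is at or above the angle cutoff
(closed boundaries on both).  Occupancy is the percentage of frames bonded,
computed as an exact frame count.  Occupancies below 5% are reported but
flagged as low.

Report naming follows the ``RES<num>:<atom>-RES<num>:<atom>`` convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

import numpy as np

from .core import (AtomSelection, HBondCriteria, Topology, Trajectory)
from .errors import GeometryError, MDCompareError

__all__ = [
    "HBondTriple",
    "OccupancyRecord",
    "find_donors_acceptors",
    "spanning_triples",
    "hbond_present",
    "bonded_matrix",
    "occupancy",
    "composite_occupancy",
    "write_occupancy_tsv",
    "LOW_OCCUPANCY_THRESHOLD",
]

logger = logging.getLogger(__name__)

LOW_OCCUPANCY_THRESHOLD = 5.0  # percent; below this a record is flagged


@dataclass(frozen=True)
class HBondTriple:
    """Donor heavy atom, its hydrogen, and an acceptor heavy atom."""

    donor: int
    hydrogen: int
    acceptor: int

    def validate(self, topology: Topology) -> None:
        if self.donor == self.acceptor:
            raise MDCompareError("donor and acceptor must differ")
        if self.hydrogen not in topology.bonded_to(self.donor):
            raise MDCompareError(
                f"hydrogen {self.hydrogen} is not bonded to donor {self.donor}")
        if self.acceptor in topology.bonded_to(self.hydrogen):
            raise MDCompareError(
                f"acceptor {self.acceptor} is bonded to hydrogen {self.hydrogen}")

    def label(self, topology: Topology) -> str:
        """``RES<num>:<donoratom>-RES<num>:<acceptoratom>`` report label."""
        return (f"{topology.atom_label(self.donor)}-"
                f"{topology.atom_label(self.acceptor)}")


@dataclass(frozen=True)
class OccupancyRecord:
    """Occupancy of one triple: ``occupancy = 100 * n_bonded / n_frames``."""

    triple: HBondTriple
    occupancy: float
    n_frames: int
    n_bonded_frames: int

    @property
    def low(self) -> bool:
        return self.occupancy < LOW_OCCUPANCY_THRESHOLD


def _require_hydrogens(topology: Topology) -> None:
    if not topology.has_hydrogens():
        raise MDCompareError(
            "topology has no explicit hydrogens; hydrogen-bond analysis "
            "requires a protonated structure")


def find_donors_acceptors(
        topology: Topology, selection: AtomSelection,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Enumerate donors ``(heavy, hydrogen)`` and acceptor heavy atoms.

    Donors are N/O atoms with at least one bonded hydrogen — one entry per
    hydrogen, so a lysine NZ with three protons yields three donor entries.
    Acceptors are all N/O atoms in the selection.  An N/O-free selection
    returns empty lists with a logged warning.
    """
    _require_hydrogens(topology)
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i in selection.indices:
        if topology.elements[i] not in ("N", "O"):
            continue
        acceptors.append(i)
        for h in topology.hydrogens_of(i):
            donors.append((i, h))
    if not acceptors:
        logger.warning("selection %r contains no N/O atoms; no donors or "
                       "acceptors found", selection.expression)
    return donors, acceptors


def spanning_triples(topology: Topology, side_a: AtomSelection,
                     side_b: AtomSelection) -> list[HBondTriple]:
    """All donor/acceptor triples spanning two selections, both directions."""
    donors_a, acceptors_a = find_donors_acceptors(topology, side_a)
    donors_b, acceptors_b = find_donors_acceptors(topology, side_b)
    triples = [HBondTriple(d, h, a)
               for (d, h) in donors_a for a in acceptors_b]
    triples += [HBondTriple(d, h, a)
                for (d, h) in donors_b for a in acceptors_a]
    return triples


def _geometry(coords: np.ndarray, donors: np.ndarray, hydrogens: np.ndarray,
              acceptors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances and D-H-A angles for triples over frames.

    ``coords`` is ``(frames, atoms, 3)``; returns ``(dist, angle)`` each of
    shape ``(frames, n_triples)`` with angles in degrees.
    """
    d = coords[:, donors]
    h = coords[:, hydrogens]
    a = coords[:, acceptors]
    da = d - a
    dist = np.linalg.norm(da, axis=-1)
    if np.any(dist == 0.0):
        raise GeometryError("coincident donor and acceptor coordinates")
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 == 0.0) or np.any(n2 == 0.0):
        raise GeometryError("hydrogen coincides with donor or acceptor")
    cosang = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return dist, angle


def bonded_matrix(traj: Trajectory, triples: Sequence[HBondTriple],
                  criteria: HBondCriteria = HBondCriteria(),
                  chunk: int = 2000) -> np.ndarray:
    """Boolean ``(frames, n_triples)`` matrix of the per-frame bonded test."""
    if not triples:
        return np.zeros((traj.n_frames, 0), dtype=bool)
    donors = np.array([t.donor for t in triples])
    hydrogens = np.array([t.hydrogen for t in triples])
    acceptors = np.array([t.acceptor for t in triples])
    out = np.empty((traj.n_frames, len(triples)), dtype=bool)
    for start in range(0, traj.n_frames, chunk):
        sl = slice(start, start + chunk)
        dist, angle = _geometry(traj.coords[sl], donors, hydrogens, acceptors)
        out[sl] = (dist <= criteria.max_da_distance) & \
                  (angle >= criteria.min_dha_angle)
    return out


def hbond_present(frame: np.ndarray, triple: HBondTriple,
                  criteria: HBondCriteria = HBondCriteria()) -> bool:
    """Per-frame bonded test for a single triple on one coordinate frame."""
    frame = np.asarray(frame, dtype=np.float64)
    dist, angle = _geometry(frame[None],
                            np.array([triple.donor]),
                            np.array([triple.hydrogen]),
                            np.array([triple.acceptor]))
    return bool((dist[0, 0] <= criteria.max_da_distance) and
                (angle[0, 0] >= criteria.min_dha_angle))


def occupancy(traj: Trajectory, triples: Sequence[HBondTriple],
              criteria: HBondCriteria = HBondCriteria()) -> list[OccupancyRecord]:
    """Occupancy of each triple over all frames (exact frame counts)."""
    for t in triples:
        t.validate(traj.topology)
    bonded = bonded_matrix(traj, triples, criteria)
    n = traj.n_frames
    records = []
    for k, t in enumerate(triples):
        n_bonded = int(bonded[:, k].sum())
        records.append(OccupancyRecord(
            triple=t, occupancy=100.0 * n_bonded / n,
            n_frames=n, n_bonded_frames=n_bonded))
    return records


def composite_occupancy(traj: Trajectory, group: Sequence[HBondTriple],
                        criteria: HBondCriteria = HBondCriteria(),
                        mode: str = "sum") -> float:
    """Aggregate occupancy of a group of triples.

    ``mode="sum"`` adds the individual occupancies (may exceed 100, the
    convention for summed occupancies over equivalent acceptors such as the
    oxygens of one phosphate group); ``mode="union"`` is the percentage of
    frames in which at least one triple in the group is bonded (<= 100).
    """
    if not group:
        raise MDCompareError("composite_occupancy requires a non-empty group")
    if mode not in ("sum", "union"):
        raise MDCompareError(f"unknown composite mode {mode!r}")
    bonded = bonded_matrix(traj, group, criteria)
    if mode == "sum":
        return float(100.0 * bonded.mean(axis=0).sum())
    return float(100.0 * bonded.any(axis=1).mean())


def write_occupancy_tsv(records: Iterable[OccupancyRecord],
                        topology: Topology, path: str | PathLike,
                        criteria: HBondCriteria = HBondCriteria()) -> None:
    """TSV report with the criteria echoed in header comment lines."""
    with open(path, "w") as out:
        out.write(f"# max_da_distance_A\t{criteria.max_da_distance}\n")
        out.write(f"# min_dha_angle_deg\t{criteria.min_dha_angle}\n")
        out.write("label\tdonor\thydrogen\tacceptor\toccupancy_pct\t"
                  "n_bonded\tn_frames\tlow_occupancy\n")
        for r in records:
            t = r.triple
            out.write(f"{t.label(topology)}\t{topology.atom_label(t.donor)}\t"
                      f"{topology.atom_label(t.hydrogen)}\t"
                      f"{topology.atom_label(t.acceptor)}\t"
                      f"{r.occupancy:.4f}\t{r.n_bonded_frames}\t{r.n_frames}\t"
                      f"{'yes' if r.low else 'no'}\n")
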