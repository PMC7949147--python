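"""Intermolecular interface contacts and the mutant-vs-WT reduction statistic.

A :class:`ContactMap` records, for two disjoint atom selections (e.g. one
protein chain each), which residue pairs are in contact in which fraction of
frames and how many atom-level contacts exist per frame.  Contacts are
hydrogen bonds ("hbond", the default), heavy-atom van der Waals proximity
("vdw"), or both.

The destabilization statistic compares a mutant map against a wild-type
map: per residue, ``100 * (1 - occ_mut / occ_wt)``; overall,
``100 * (1 - mean_mut_contacts_per_frame / mean_wt_contacts_per_frame)``.
Residues with zero wild-type occupancy are masked rather than reported as
infinities; negative reductions (mutant above wild type) are reported as
negative percentages, not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np

from .core import AtomSelection, HBondCriteria, Topology, Trajectory
from .errors import ComparabilityError, MDCompareError
from .hbond import bonded_matrix, spanning_triples
from . import io as _io

__all__ = [
    "ContactMap",
    "ReductionProfile",
    "contact_map",
    "reduction_profile",
    "groove_report",
    "write_pair_tsv",
    "write_reduction_tsv",
    "write_reduction_pdb",
]

ResidueKey = tuple[str, int]  # (chain_id, residue_number)

DEFAULT_VDW_CUTOFF = 4.5  # A, heavy-atom pair distance


@dataclass
class ContactMap:
    """Interface contact occupancies between two selections.

    ``pair_occupancy`` maps ``(residue_a, residue_b)`` keys (each a
    ``(chain_id, resnum)`` tuple) to the percentage of frames in which at
    least one atom-level contact joins the two residues.
    ``per_frame_contact_count`` counts contacting atom pairs per frame.
    Per-residue occupancies on side A are provided in both union semantics
    (percent of frames with any interface contact; used for the reduction
    statistic and colorimetric maps) and sum semantics (sum of the
    residue's pair occupancies).
    """

    side_a: AtomSelection
    side_b: AtomSelection
    pair_occupancy: dict[tuple[ResidueKey, ResidueKey], float]
    per_frame_contact_count: np.ndarray
    contact_kind: str
    criteria: HBondCriteria
    vdw_cutoff: float
    n_frames: int
    residue_union_occupancy: dict[ResidueKey, float]
    residue_sum_occupancy: dict[ResidueKey, float]

    @property
    def mean_contacts_per_frame(self) -> float:
        return float(self.per_frame_contact_count.mean())


@dataclass
class ReductionProfile:
    """Per-residue and overall contact reduction of a mutant vs wild type.

    ``per_residue_reduction`` holds percentages for residues with non-zero
    wild-type occupancy; ``masked`` lists side-A residues excluded because
    their wild-type occupancy is zero.
    """

    per_residue_reduction: dict[ResidueKey, float]
    masked: tuple[ResidueKey, ...]
    overall_reduction: float


def _residue_keys(topology: Topology, atom_indices: np.ndarray) -> np.ndarray:
    return np.array([(topology.chain_ids[i], int(topology.resnums[i]))
                     for i in atom_indices], dtype=object)


def _vdw_contact_counts(traj: Trajectory, heavy_a: np.ndarray,
                        heavy_b: np.ndarray, cutoff: float,
                        chunk: int = 200) -> np.ndarray:
    """Per-frame boolean contact matrix flattened over (a, b) atom pairs.

    Shape ``(frames, na*nb)``; computed in frame chunks to bound memory.
    """
    n_frames = traj.n_frames
    na, nb = len(heavy_a), len(heavy_b)
    contact = np.empty((n_frames, na * nb), dtype=bool)
    for start in range(0, n_frames, chunk):
        sl = slice(start, min(start + chunk, n_frames))
        ca = traj.coords[sl, heavy_a]          # (f, na, 3)
        cb = traj.coords[sl, heavy_b]          # (f, nb, 3)
        diff = ca[:, :, None, :] - cb[:, None, :, :]
        dist2 = np.einsum("fabx,fabx->fab", diff, diff)
        contact[sl] = (dist2 <= cutoff * cutoff).reshape(sl.stop - sl.start, -1)
    return contact


def contact_map(traj: Trajectory, side_a: AtomSelection, side_b: AtomSelection,
                criteria: HBondCriteria = HBondCriteria(),
                kind: str = "hbond",
                vdw_cutoff: float = DEFAULT_VDW_CUTOFF) -> ContactMap:
    """Compute interface contact occupancies between two selections.

    ``kind="hbond"`` counts donor/acceptor triples spanning the two sides in
    either direction; ``kind="vdw"`` counts heavy-atom pairs within
    ``vdw_cutoff``; ``kind="both"`` combines the two contact sets (a residue
    pair is in contact when either criterion holds; the per-frame count is
    the sum of bonded triples and vdW pairs).
    """
    if kind not in ("hbond", "vdw", "both"):
        raise MDCompareError(f"unknown contact kind {kind!r}")
    if not side_a.indices or not side_b.indices:
        raise MDCompareError("contact_map requires non-empty selections")
    if set(side_a.indices) & set(side_b.indices):
        raise MDCompareError("side_a and side_b selections overlap")
    topology = traj.topology

    # contact columns: each column is one atom-pair-level contact test,
    # annotated with its (residue_a, residue_b) key
    columns: list[np.ndarray] = []
    keys: list[tuple[ResidueKey, ResidueKey]] = []

    if kind in ("hbond", "both"):
        triples = spanning_triples(topology, side_a, side_b)
        if triples:
            bonded = bonded_matrix(traj, triples, criteria)
            in_a = set(side_a.indices)
            for k, t in enumerate(triples):
                a_atom = t.donor if t.donor in in_a else t.acceptor
                b_atom = t.acceptor if a_atom == t.donor else t.donor
                keys.append((
                    (topology.chain_ids[a_atom], int(topology.resnums[a_atom])),
                    (topology.chain_ids[b_atom], int(topology.resnums[b_atom]))))
                columns.append(bonded[:, k])
    if kind in ("vdw", "both"):
        heavy_a = np.array([i for i in side_a.indices
                            if topology.elements[i] != "H"], dtype=np.int64)
        heavy_b = np.array([i for i in side_b.indices
                            if topology.elements[i] != "H"], dtype=np.int64)
        if len(heavy_a) and len(heavy_b):
            contact = _vdw_contact_counts(traj, heavy_a, heavy_b, vdw_cutoff)
            keys_a = _residue_keys(topology, heavy_a)
            keys_b = _residue_keys(topology, heavy_b)
            for p in range(contact.shape[1]):
                ia, ib = divmod(p, len(heavy_b))
                keys.append((tuple(keys_a[ia]), tuple(keys_b[ib])))
                columns.append(contact[:, p])

    n_frames = traj.n_frames
    if columns:
        matrix = np.stack(columns, axis=1)       # (frames, n_atom_pairs)
        per_frame = matrix.sum(axis=1).astype(np.int64)
    else:
        matrix = np.zeros((n_frames, 0), dtype=bool)
        per_frame = np.zeros(n_frames, dtype=np.int64)

    pair_occ: dict[tuple[ResidueKey, ResidueKey], float] = {}
    union_cols: dict[tuple[ResidueKey, ResidueKey], np.ndarray] = {}
    for k, key in enumerate(keys):
        col = matrix[:, k]
        union_cols[key] = union_cols[key] | col if key in union_cols else col
    for key, col in union_cols.items():
        pair_occ[key] = float(100.0 * col.mean())

    residue_union: dict[ResidueKey, float] = {}
    residue_sum: dict[ResidueKey, float] = {}
    res_cols: dict[ResidueKey, np.ndarray] = {}
    for (res_a, _res_b), col in union_cols.items():
        res_cols[res_a] = res_cols[res_a] | col if res_a in res_cols else col
    for (res_a, _res_b), occ in pair_occ.items():
        residue_sum[res_a] = residue_sum.get(res_a, 0.0) + occ
    for res_a, col in res_cols.items():
        residue_union[res_a] = float(100.0 * col.mean())
    # side-A residues with no interface partner at all get explicit zeros
    for res_a in {tuple(k) for k in
                  _residue_keys(topology, side_a.as_array())}:
        residue_union.setdefault(res_a, 0.0)
        residue_sum.setdefault(res_a, 0.0)

    return ContactMap(side_a=side_a, side_b=side_b, pair_occupancy=pair_occ,
                      per_frame_contact_count=per_frame, contact_kind=kind,
                      criteria=criteria, vdw_cutoff=vdw_cutoff,
                      n_frames=n_frames,
                      residue_union_occupancy=residue_union,
                      residue_sum_occupancy=residue_sum)


def reduction_profile(wt: ContactMap, mutant: ContactMap,
                      semantics: str = "union") -> ReductionProfile:
    """Mutant-vs-WT contact reduction, per side-A residue and overall.

    Both maps must have been computed with identical criteria and contact
    kind.  ``semantics`` selects the per-residue occupancy entering the
    ratio: ``"union"`` (default; percent of frames with any interface
    contact) or ``"sum"`` (summed pair occupancies).
    """
    if wt.contact_kind != mutant.contact_kind or wt.criteria != mutant.criteria \
            or wt.vdw_cutoff != mutant.vdw_cutoff:
        raise ComparabilityError(
            "contact maps were computed with different criteria or kind")
    if semantics not in ("union", "sum"):
        raise MDCompareError(f"unknown reduction semantics {semantics!r}")
    wt_occ = (wt.residue_union_occupancy if semantics == "union"
              else wt.residue_sum_occupancy)
    mut_occ = (mutant.residue_union_occupancy if semantics == "union"
               else mutant.residue_sum_occupancy)
    residues = sorted(set(wt_occ) | set(mut_occ))
    per_residue: dict[ResidueKey, float] = {}
    masked: list[ResidueKey] = []
    for res in residues:
        w = wt_occ.get(res, 0.0)
        m = mut_occ.get(res, 0.0)
        if w == 0.0:
            masked.append(res)
        else:
            per_residue[res] = 100.0 * (1.0 - m / w)
    wt_mean = wt.mean_contacts_per_frame
    if wt_mean == 0.0:
        raise MDCompareError(
            "wild-type map has no contacts; overall reduction is undefined")
    overall = 100.0 * (1.0 - mutant.mean_contacts_per_frame / wt_mean)
    return ReductionProfile(per_residue_reduction=per_residue,
                            masked=tuple(masked), overall_reduction=overall)


def groove_report(cmap: ContactMap, top_n: int) -> list[tuple[ResidueKey, float]]:
    """Side-A residues ranked by summed interface occupancy, descending.

    Ties are broken by ascending residue number (then chain id).  This
    identifies the highest-occupancy contact patch — e.g. the groove along
    a binding interface — without any electrostatics.
    """
    if top_n < 1:
        raise MDCompareError("top_n must be >= 1")
    if not cmap.residue_sum_occupancy:
        raise MDCompareError("contact map is empty")
    ranked = sorted(cmap.residue_sum_occupancy.items(),
                    key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    return [(res, occ) for res, occ in ranked[:top_n]]


def write_pair_tsv(cmap: ContactMap, path: str | PathLike) -> None:
    with open(path, "w") as out:
        out.write(f"# contact_kind\t{cmap.contact_kind}\n")
        out.write(f"# max_da_distance_A\t{cmap.criteria.max_da_distance}\n")
        out.write(f"# min_dha_angle_deg\t{cmap.criteria.min_dha_angle}\n")
        out.write(f"# vdw_cutoff_A\t{cmap.vdw_cutoff}\n")
        out.write("chain_a\tresidue_a\tchain_b\tresidue_b\toccupancy_pct\n")
        for (ra, rb), occ in sorted(cmap.pair_occupancy.items()):
            out.write(f"{ra[0]}\t{ra[1]}\t{rb[0]}\t{rb[1]}\t{occ:.4f}\n")


def write_reduction_tsv(profile: ReductionProfile, path: str | PathLike) -> None:
    with open(path, "w") as out:
        out.write(f"# overall_reduction_pct\t{profile.overall_reduction:.4f}\n")
        out.write("chain\tresidue\treduction_pct\tmasked\n")
        rows = [(res, f"{v:.4f}", "no")
                for res, v in profile.per_residue_reduction.items()]
        rows += [(res, "", "yes") for res in profile.masked]
        for res, value, masked in sorted(rows, key=lambda r: r[0]):
            out.write(f"{res[0]}\t{res[1]}\t{value}\t{masked}\n")


def write_reduction_pdb(profile: ReductionProfile, topology, frame,
                        path: str | PathLike) -> None:
    """B-factor PDB of the per-residue reduction (masked residues 0.00)."""
    values: dict[ResidueKey, object] = dict(profile.per_residue_reduction)
    for res in profile.masked:
        values[res] = _io.MASKED
    _io.write_bfactor_pdb(topology, frame, values, path)
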