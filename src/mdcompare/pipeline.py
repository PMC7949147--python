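"""Orchestration of the full comparative wild-type vs mutant analysis.

``run_compare`` consumes a declarative TOML config naming the systems (one
flagged as the reference), the interface selections, the hydrogen-bond
criteria and histogram settings, and writes per-system occupancy / contact /
RMSD / PCA reports plus per-mutant reduction profiles, B-factor maps and
PC1 divergence scores.  A manifest JSON records the config echo, package
version, seed, warnings, and a checksum for every output file, so a report
directory is self-describing and two runs with the same config are
byte-identical.

``simulate`` writes a complete synthetic fixture set (topology PDB, DCD
trajectories, chase TSV, planted-truth tables and a ready-to-run config)
for a wild-type/mutant pair with a planted contact reduction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import contacts as _contacts
from . import hbond as _hbond
from . import io as _io
from .pca import compare_pc1 as _compare_pc1
from .pca import pc_histogram as _pc_histogram
from .pca import pca as _pca_fn
from . import rmsd as _rmsd
from . import synthetic as _synthetic
from . import turnover as _turnover
from .core import HBondCriteria
from .errors import ComparabilityError, DataError, MDCompareError
from .selection import select

__all__ = ["RunConfig", "SystemEntry", "load_config", "run_compare",
           "run_turnover", "simulate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SystemEntry:
    label: str
    topology: Path
    trajectory: Path
    reference: bool = False


@dataclass
class RunConfig:
    """Validated comparison-run configuration (see ``load_config``)."""

    systems: list[SystemEntry]
    side_a: str = "chain A"
    side_b: str = "chain B"
    pca_selection: str = "name CA"
    subdomains: dict[str, str] = field(default_factory=dict)
    criteria: HBondCriteria = HBondCriteria()
    contact_kind: str = "hbond"
    vdw_cutoff: float = _contacts.DEFAULT_VDW_CUTOFF
    bins: int = 100
    pca_k: int = 3
    seed: int = 0

    def __post_init__(self):
        labels = [s.label for s in self.systems]
        if len(labels) != len(set(labels)):
            raise MDCompareError("system labels must be unique")
        refs = [s for s in self.systems if s.reference]
        if len(refs) != 1:
            raise MDCompareError(
                f"exactly one system must be flagged as reference, got {len(refs)}")
        if len(self.systems) < 2:
            raise MDCompareError("a comparison needs at least two systems")
        for s in self.systems:
            for p in (s.topology, s.trajectory):
                if not Path(p).exists():
                    raise MDCompareError(f"{s.label}: path {p} does not exist")

    @property
    def reference(self) -> SystemEntry:
        return next(s for s in self.systems if s.reference)


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration; relative paths resolve to its folder."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = path.parent
    systems = [SystemEntry(label=s["label"],
                           topology=base / s["topology"],
                           trajectory=base / s["trajectory"],
                           reference=bool(s.get("reference", False)))
               for s in raw.get("systems", [])]
    sel = raw.get("selections", {})
    crit = raw.get("criteria", {})
    ana = raw.get("analysis", {})
    return RunConfig(
        systems=systems,
        side_a=sel.get("side_a", "chain A"),
        side_b=sel.get("side_b", "chain B"),
        pca_selection=sel.get("pca", "name CA"),
        subdomains=dict(sel.get("subdomains", {})),
        criteria=HBondCriteria(
            max_da_distance=float(crit.get("max_da_distance", 3.0)),
            min_dha_angle=float(crit.get("min_dha_angle", 135.0))),
        contact_kind=ana.get("contact_kind", "hbond"),
        vdw_cutoff=float(ana.get("vdw_cutoff", _contacts.DEFAULT_VDW_CUTOFF)),
        bins=int(ana.get("bins", 100)),
        pca_k=int(ana.get("pca_k", 3)),
        seed=int(raw.get("seed", 0)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    return {
        "systems": [{"label": s.label, "topology": str(s.topology),
                     "trajectory": str(s.trajectory), "reference": s.reference}
                    for s in config.systems],
        "side_a": config.side_a, "side_b": config.side_b,
        "pca_selection": config.pca_selection,
        "subdomains": config.subdomains,
        "max_da_distance": config.criteria.max_da_distance,
        "min_dha_angle": config.criteria.min_dha_angle,
        "contact_kind": config.contact_kind,
        "vdw_cutoff": config.vdw_cutoff,
        "bins": config.bins, "pca_k": config.pca_k, "seed": config.seed,
    }


def run_compare(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full comparative analysis; returns the manifest dict.

    Per system: interface hydrogen-bond occupancy table, contact-pair
    table, subdomain time-averaged RMSD table, PCA eigenvalue report and
    PC1 histogram.  Per mutant vs reference: per-residue reduction TSV,
    B-factor PDB and PC1 histogram-divergence score.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    outputs: dict[str, Path] = {}
    summary: dict = {"systems": {}, "comparisons": {}}

    loaded: dict[str, dict] = {}
    atom_counts: dict[str, tuple] = {}
    for entry in config.systems:
        topology, first = _io.read_structure(entry.topology)
        traj = _io.read_trajectory(entry.trajectory, topology)
        side_a = select(topology, config.side_a)
        side_b = select(topology, config.side_b)
        pca_sel = select(topology, config.pca_selection)
        counts = (len(side_a), len(side_b), len(pca_sel))
        for other, other_counts in atom_counts.items():
            if other_counts != counts:
                raise ComparabilityError(
                    f"selections resolve to different atom counts in systems "
                    f"{other!r} {other_counts} vs {entry.label!r} {counts}")
        atom_counts[entry.label] = counts
        loaded[entry.label] = {"entry": entry, "topology": topology,
                               "reference_frame": first.coords[0],
                               "traj": traj, "side_a": side_a,
                               "side_b": side_b, "pca_sel": pca_sel}

    for label, sysdata in loaded.items():
        topology, traj = sysdata["topology"], sysdata["traj"]
        side_a, side_b = sysdata["side_a"], sysdata["side_b"]

        triples = _hbond.spanning_triples(topology, side_a, side_b)
        records = _hbond.occupancy(traj, triples, config.criteria)
        path = out / f"{label}_hbond.tsv"
        _hbond.write_occupancy_tsv(records, topology, path, config.criteria)
        outputs[path.name] = path
        for r in records:
            if 0.0 < r.occupancy < _hbond.LOW_OCCUPANCY_THRESHOLD:
                warnings.append(
                    f"{label}: occupancy of {r.triple.label(topology)} below "
                    f"{_hbond.LOW_OCCUPANCY_THRESHOLD:.0f}% "
                    f"({r.occupancy:.2f}%)")

        cmap = _contacts.contact_map(traj, side_a, side_b, config.criteria,
                                     kind=config.contact_kind,
                                     vdw_cutoff=config.vdw_cutoff)
        sysdata["cmap"] = cmap
        path = out / f"{label}_contact_pairs.tsv"
        _contacts.write_pair_tsv(cmap, path)
        outputs[path.name] = path

        rmsd_rows = []
        for name, expression in config.subdomains.items():
            sub = select(topology, expression)
            value = _rmsd.time_averaged_rmsd(
                traj, sysdata["reference_frame"], sub, sub)
            rmsd_rows.append((name, expression, value))
        path = out / f"{label}_rmsd.tsv"
        with open(path, "w") as fh:
            fh.write("subdomain\tselection\ttime_averaged_rmsd_A\n")
            for name, expression, value in rmsd_rows:
                fh.write(f"{name}\t{expression}\t{value:.6f}\n")
        outputs[path.name] = path

        result = _pca_fn(traj, sysdata["pca_sel"], k=config.pca_k)
        sysdata["pca"] = result
        hist = _pc_histogram(result, 0, config.bins)
        path = out / f"{label}_pc1_hist.tsv"
        with open(path, "w") as fh:
            fh.write(f"# eigenvalue_A2\t{hist.eigenvalue!r}\n")
            fh.write("bin_left\tbin_right\tdensity\n")
            for left, right, dens in zip(hist.bin_edges[:-1],
                                         hist.bin_edges[1:], hist.density):
                fh.write(f"{left:.6f}\t{right:.6f}\t{dens:.8f}\n")
        outputs[path.name] = path
        path = out / f"{label}_pca.json"
        with open(path, "w") as fh:
            json.dump({"eigenvalues": list(result.eigenvalues[:config.pca_k]),
                       "total_variance_A2": result.total_variance,
                       "selection": config.pca_selection,
                       "n_frames": traj.n_frames}, fh, sort_keys=True, indent=1)
        outputs[path.name] = path

        summary["systems"][label] = {
            "mean_contacts_per_frame": cmap.mean_contacts_per_frame,
            "subdomain_rmsd_A": {name: value for name, _e, value in rmsd_rows},
            "pc1_eigenvalue_A2": float(result.eigenvalues[0]),
        }

    ref_label = config.reference.label
    ref = loaded[ref_label]
    for label, sysdata in loaded.items():
        if label == ref_label:
            continue
        profile = _contacts.reduction_profile(ref["cmap"], sysdata["cmap"])
        path = out / f"{label}_reduction.tsv"
        _contacts.write_reduction_tsv(profile, path)
        outputs[path.name] = path
        path = out / f"{label}_reduction.pdb"
        _contacts.write_reduction_pdb(profile, ref["topology"],
                                      ref["reference_frame"], path)
        outputs[path.name] = path
        for res in profile.masked:
            warnings.append(f"{label}: residue {res[0]}:{res[1]} masked "
                            f"(zero occupancy in {ref_label})")
        divergence = _compare_pc1(ref["pca"], sysdata["pca"], config.bins)
        summary["comparisons"][label] = {
            "overall_reduction_pct": profile.overall_reduction,
            "n_masked_residues": len(profile.masked),
            "pc1_divergence": divergence,
        }

    manifest = {
        "package": "mdcompare",
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "summary": summary,
        "warnings": sorted(warnings),
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest


def run_turnover(input_tsv: str | Path, out_dir: str | Path,
                 method: str = "log-linear") -> dict:
    """Fit chase decay per condition from a TSV of band intensities.

    Input columns: ``time_h``, ``raw``, ``loading``, ``condition``; every
    condition needs a ``time_h == 0`` row.  Writes ``turnover.json`` (one
    fit report per condition) and ``turnover_summary.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(input_tsv, sep="\t", comment="#")
    required = {"time_h", "raw", "loading", "condition"}
    if not required.issubset(table.columns):
        raise DataError(f"input must have columns {sorted(required)}")
    reports: dict[str, dict] = {}
    for condition, group in table.groupby("condition", sort=True):
        group = group.sort_values("time_h")
        if not (group["time_h"] == 0).any():
            raise DataError(f"condition {condition!r} has no t=0 row")
        series = _turnover.normalize_series(
            group["raw"].to_numpy(), group["loading"].to_numpy(),
            group["time_h"].to_numpy(), genotype=str(condition))
        fit = _turnover.fit_decay(series, method=method)
        reports[str(condition)] = {
            "rate_per_h": fit.rate_k,
            "half_life_h": fit.half_life if np.isfinite(fit.half_life) else None,
            "stable": fit.stable, "rss": fit.rss, "n_points": fit.n_points,
            "method": fit.method,
            "fractions": list(series.fractions),
            "times_h": list(series.times),
        }
    with open(out / "turnover.json", "w") as fh:
        json.dump(reports, fh, sort_keys=True, indent=1)
    with open(out / "turnover_summary.tsv", "w") as fh:
        fh.write("condition\trate_per_h\thalf_life_h\tn_points\n")
        for condition, rep in sorted(reports.items()):
            hl = "inf" if rep["half_life_h"] is None else f"{rep['half_life_h']:.4f}"
            fh.write(f"{condition}\t{rep['rate_per_h']:.6f}\t{hl}\t"
                     f"{rep['n_points']}\n")
    return reports


def simulate(out_dir: str | Path, seed: int = 0, n_frames: int = 2000) -> dict:
    """Write a synthetic wild-type/mutant fixture set plus a run config.

    Produces ``complex.pdb`` (shared topology, base frame), ``WT.dcd`` and
    ``MUT.dcd`` realizing the planted contact probabilities, a chase-series
    TSV, planted-truth tables, and ``config.toml`` ready for
    :func:`run_compare`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = _synthetic.GeneratorSpec(seed=seed, n_frames=n_frames)
    scenario = _synthetic.gen_interface_trajectory(spec)
    _io.write_pdb(scenario.topology, scenario.wt.coords[0],
                  out / "complex.pdb")
    _io.write_dcd(scenario.wt.coords, out / "WT.dcd")
    _io.write_dcd(scenario.mutant.coords, out / "MUT.dcd")
    with open(out / "planted_truth.tsv", "w") as fh:
        fh.write("pair\tchain_a\tresidue_a\tchain_b\tresidue_b\t"
                 "wt_prob\tmutant_prob\n")
        for i, (ra, rb) in enumerate(scenario.pair_residues):
            fh.write(f"{i}\t{ra[0]}\t{ra[1]}\t{rb[0]}\t{rb[1]}\t"
                     f"{scenario.wt_probs[i]:.6f}\t"
                     f"{scenario.mutant_probs[i]:.6f}\n")

    series, truth = _synthetic.gen_decay_series(spec)
    with open(out / "chase.tsv", "w") as fh:
        fh.write("time_h\traw\tloading\tcondition\n")
        for label, s in series.items():
            for t, f in zip(s.times, s.fractions):
                fh.write(f"{t}\t{float(f)!r}\t1.0\t{label}\n")
    with open(out / "chase_truth.tsv", "w") as fh:
        fh.write("condition\thalf_life_h\n")
        for label, t_half in truth.items():
            fh.write(f"{label}\t{t_half}\n")

    n_res = len(scenario.wt_probs)
    config_text = (
        f'seed = {seed}\n\n'
        f'[selections]\nside_a = "chain A"\nside_b = "chain B"\n'
        f'pca = "name CA"\n\n'
        f'[selections.subdomains]\nreceptor = "chain A"\n'
        f'ligand = "chain B"\n\n'
        f'[criteria]\nmax_da_distance = 3.0\nmin_dha_angle = 135.0\n\n'
        f'[analysis]\ncontact_kind = "hbond"\nvdw_cutoff = 4.5\n'
        f'bins = 100\npca_k = 3\n\n'
        f'[[systems]]\nlabel = "WT"\nreference = true\n'
        f'topology = "complex.pdb"\ntrajectory = "WT.dcd"\n\n'
        f'[[systems]]\nlabel = "MUT"\n'
        f'topology = "complex.pdb"\ntrajectory = "MUT.dcd"\n')
    (out / "config.toml").write_text(config_text)
    return {"out_dir": str(out), "n_frames": n_frames, "n_pairs": n_res,
            "config": str(out / "config.toml")}
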