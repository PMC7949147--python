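"""Synthetic trajectories and chase series with planted ground truth.

Real production MD of a solvated two-chain complex is far outside desk
scale, and the analyses in this package only assume *statistical* structure
in the coordinates: hydrogen bonds toggling between bonded and broken
geometries, interface contacts firing with condition-dependent
probabilities, one dominant collective mode over isotropic noise,
rigid-body motion, and exponential band decay.  The generators here emulate
exactly those features on a toy two-chain backbone complex and return the
hidden truth alongside the data, so every analysis module can be tested
against what was actually planted rather than against itself.

Determinism: each generator draws from ``default_rng(SeedSequence([seed,
stream_id]))`` with a fixed per-generator stream id, so equal specs give
bit-identical output and adding a generator never perturbs existing ones.

Geometry: the "bonded" realization places the acceptor 2.9 A from the
donor with a D-H-A angle of ~166 deg — comfortably inside the default
criteria (3.0 A, 135 deg) — and the "broken" realization is 5 A further
away, so criteria boundary effects can never flip a planted state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Topology, Trajectory
from .errors import GeneratorSpecError
from .hbond import HBondTriple
from .turnover import DecaySeries

__all__ = [
    "GeneratorSpec",
    "HBondScenario",
    "InterfaceScenario",
    "ModeScenario",
    "gen_toy_complex",
    "gen_hbond_trajectory",
    "gen_interface_trajectory",
    "gen_mode_trajectory",
    "gen_rigid_trajectory",
    "gen_decay_series",
    "iid_rates",
]

logger = logging.getLogger(__name__)

# fixed sub-seed stream ids (see module docstring)
_STREAMS = {"hbond": 11, "interface": 12, "mode": 13, "rigid": 14, "decay": 15}

_RESIDUE_SPACING = 8.0      # A between residues along x
_BROKEN_OFFSET = 5.0        # A added to the donor-acceptor distance when broken
_ATOMS_PER_RESIDUE = 5      # N, H, CA, C, O


@dataclass(frozen=True)
class GeneratorSpec:
    """All planted truths and sizes for the synthetic generators.

    Defaults encode the reference scenario sizes used throughout the test
    contract: a 0.70-duty-cycle hydrogen bond, five interface contacts whose
    mutant condition retains 66% of the wild-type contact rate (i.e. a 34%
    overall reduction), a 1 A collective mode over 0.05 A isotropic noise,
    and chase series for four genotypes with half-lives 63.7 / 15.5 /
    24.1 / 24.7 h sampled at 0, 8, 18, 24 h.
    """

    seed: int = 0
    n_frames: int = 10_000
    residues_per_chain: int = 5
    # two-state Markov hydrogen bonds: one (p_on, p_off) per planted pair
    hbond_rates: tuple[tuple[float, float], ...] = ((0.35, 0.15),)
    # interface contact probabilities (per residue pair, wild type)
    wt_contact_probs: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5)
    mutant_ratio: float = 0.66
    mutant_contact_probs: Optional[tuple[float, ...]] = None
    # planted collective mode
    mode_amplitude: float = 1.0          # A, std of Gaussian amplitudes
    noise_sigma: float = 0.05            # A, isotropic positional noise
    mode_vector: Optional[tuple[float, ...]] = None   # optional explicit mode
    mode_mixture: Optional[tuple[tuple[float, float], ...]] = None  # (loc, weight)
    mixture_sigma: float = 1.0           # A, width of each mixture component
    # rigid-body trajectory
    rigid_noise_sigma: float = 0.0       # A
    rigid_max_translation: float = 5.0   # A
    # cycloheximide-chase series
    half_lives_h: tuple[tuple[str, float], ...] = (
        ("WT", 63.7), ("E359K", 15.5), ("PBS", 24.1), ("K220M", 24.7))
    decay_sigma: float = 0.02            # multiplicative log-normal noise
    times_h: tuple[float, ...] = (0.0, 8.0, 18.0, 24.0)

    def __post_init__(self):
        if self.n_frames < 1 or self.residues_per_chain < 1:
            raise GeneratorSpecError("n_frames and residues_per_chain must be >= 1")
        for p_on, p_off in self.hbond_rates:
            if not (0 <= p_on <= 1 and 0 <= p_off <= 1):
                raise GeneratorSpecError("Markov rates must lie in [0, 1]")
            if p_on == 0 and p_off == 0:
                raise GeneratorSpecError("degenerate Markov rates (both zero)")
        for p in self.wt_contact_probs + (self.mutant_contact_probs or ()):
            if not 0 <= p <= 1:
                raise GeneratorSpecError("contact probabilities must lie in [0, 1]")
        if not 0 <= self.mutant_ratio:
            raise GeneratorSpecError("mutant_ratio must be non-negative")
        if self.mode_amplitude <= 0 or self.mixture_sigma <= 0:
            raise GeneratorSpecError("amplitudes must be positive")
        if self.noise_sigma < 0 or self.rigid_noise_sigma < 0:
            raise GeneratorSpecError("noise sigmas must be non-negative")
        for _label, t_half in self.half_lives_h:
            if t_half <= 0:
                raise GeneratorSpecError("half-lives must be positive")
        if self.decay_sigma < 0:
            raise GeneratorSpecError("decay_sigma must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))


def iid_rates(duty_cycle: float) -> tuple[float, float]:
    """Markov rates that make the bonded state i.i.d. Bernoulli(duty_cycle)."""
    return (duty_cycle, 1.0 - duty_cycle)


@dataclass
class HBondScenario:
    trajectory: Trajectory
    states: np.ndarray            # (n_frames, n_pairs) bool, hidden truth
    triples: list[HBondTriple]


@dataclass
class InterfaceScenario:
    topology: Topology
    wt: Trajectory
    mutant: Trajectory
    wt_probs: np.ndarray
    mutant_probs: np.ndarray
    wt_states: np.ndarray         # (n_frames, n_pairs) bool
    mutant_states: np.ndarray
    pair_residues: list[tuple[tuple[str, int], tuple[str, int]]]


@dataclass
class ModeScenario:
    trajectory: Trajectory
    mode: np.ndarray              # unit vector, length 3 * n_atoms
    amplitudes: np.ndarray        # (n_frames,) A


def _residue_template_a(x: float) -> np.ndarray:
    return np.array([
        [x, 0.0, 0.0],        # N  (interface donor heavy atom)
        [x, 1.0, 0.0],        # H  (points toward chain B)
        [x + 1.4, -0.6, 0.0],  # CA
        [x + 2.9, -0.2, 0.0],  # C
        [x + 2.9, -1.43, 0.0],  # O (points away from the interface)
    ])


def _residue_template_b(x: float) -> np.ndarray:
    # the O sits _BROKEN_OFFSET above its bonded position relative to A's N-H
    o = np.array([x + 0.46, 2.86 + _BROKEN_OFFSET, 0.0])
    c = o + [0.0, 1.23, 0.0]
    ca = c + [1.4, 0.6, 0.0]
    n = ca + [1.2, 0.9, 0.0]
    h = n + [0.0, 1.0, 0.0]   # points away from chain A
    return np.array([n, h, ca, c, o])


def gen_toy_complex(spec: GeneratorSpec) -> tuple[Topology, np.ndarray]:
    """Two-chain backbone-fragment complex with explicit N, H, CA, C, O.

    Chain A (the receptor stand-in) presents one backbone N-H donor per
    residue toward chain B (the ligand stand-in), whose carbonyl O per
    residue is the matching acceptor, 7.9 A away in the broken base state.
    Bonds are explicit (N-H, N-CA, CA-C, C-O) so donor detection works.
    Deterministic: no randomness enters the base geometry.
    """
    n_res = spec.residues_per_chain
    names, elements, resnames, resnums, chain_ids = [], [], [], [], []
    coords_list = []
    bonds: list[tuple[int, int]] = []
    for chain, template in (("A", _residue_template_a),
                            ("B", _residue_template_b)):
        for i in range(n_res):
            base = len(names)
            coords_list.append(template(i * _RESIDUE_SPACING))
            names += ["N", "H", "CA", "C", "O"]
            elements += ["N", "H", "C", "C", "O"]
            resnames += ["ALA"] * 5
            resnums += [i + 1] * 5
            chain_ids += [chain] * 5
            bonds += [(base, base + 1), (base, base + 2),
                      (base + 2, base + 3), (base + 3, base + 4)]
    topology = Topology(names, elements, resnames, resnums, chain_ids,
                        bonds=bonds)
    return topology, np.concatenate(coords_list, axis=0)


def _chain_b_residue_atoms(spec: GeneratorSpec, pair: int) -> np.ndarray:
    n_res = spec.residues_per_chain
    start = (n_res + pair) * _ATOMS_PER_RESIDUE
    return np.arange(start, start + _ATOMS_PER_RESIDUE)


def _interface_triples(spec: GeneratorSpec, n_pairs: int) -> list[HBondTriple]:
    triples = []
    for i in range(n_pairs):
        donor = i * _ATOMS_PER_RESIDUE          # chain A residue i, atom N
        hydrogen = donor + 1
        acceptor = _chain_b_residue_atoms(spec, i)[4]  # chain B, atom O
        triples.append(HBondTriple(donor, hydrogen, int(acceptor)))
    return triples


def _realize(spec: GeneratorSpec, base: np.ndarray,
             states: np.ndarray) -> np.ndarray:
    """Turn per-frame per-pair contact indicators into coordinates.

    When pair ``i`` is bonded in a frame, chain B residue ``i`` translates
    rigidly toward chain A so its O reaches the canonical bonded geometry.
    """
    n_frames, n_pairs = states.shape
    coords = np.repeat(base[None], n_frames, axis=0)
    shift = np.array([0.0, -_BROKEN_OFFSET, 0.0])
    for i in range(n_pairs):
        atoms = _chain_b_residue_atoms(spec, i)
        frames = np.flatnonzero(states[:, i])
        coords[np.ix_(frames, atoms)] += shift
    return coords


def gen_hbond_trajectory(spec: GeneratorSpec) -> HBondScenario:
    """Hydrogen bonds toggling via two-state Markov chains.

    One planted donor/H/acceptor triple per entry of ``spec.hbond_rates``;
    states start from the stationary distribution, so the empirical bonded
    fraction converges to ``p_on / (p_on + p_off)``.  The hidden state
    sequence is returned for oracle tests.
    """
    n_pairs = len(spec.hbond_rates)
    if n_pairs > spec.residues_per_chain:
        raise GeneratorSpecError("more planted bonds than residue pairs")
    rng = spec.rng("hbond")
    states = np.zeros((spec.n_frames, n_pairs), dtype=bool)
    for i, (p_on, p_off) in enumerate(spec.hbond_rates):
        stationary = p_on / (p_on + p_off)
        u = rng.random(spec.n_frames)
        s = u[0] < stationary
        states[0, i] = s
        for t in range(1, spec.n_frames):
            s = (u[t] < p_on) if not s else (u[t] >= p_off)
            states[t, i] = s
    topology, base = gen_toy_complex(spec)
    coords = _realize(spec, base, states)
    return HBondScenario(trajectory=Trajectory(topology, coords),
                         states=states,
                         triples=_interface_triples(spec, n_pairs))


def gen_interface_trajectory(spec: GeneratorSpec) -> InterfaceScenario:
    """Wild-type vs mutant interface with planted contact probabilities.

    Contact indicators are independent Bernoulli draws per frame and pair;
    the mutant probabilities default to ``mutant_ratio * wt`` (the overall
    per-frame contact rate then scales by exactly that ratio), or may be
    given explicitly.  Both conditions share one topology and residue
    numbering.
    """
    wt_probs = np.asarray(spec.wt_contact_probs, dtype=float)
    if spec.mutant_contact_probs is not None:
        mut_probs = np.asarray(spec.mutant_contact_probs, dtype=float)
        if mut_probs.shape != wt_probs.shape:
            raise GeneratorSpecError(
                "wild-type and mutant contact probability lists differ in length")
    else:
        mut_probs = np.clip(spec.mutant_ratio * wt_probs, 0.0, 1.0)
    n_pairs = len(wt_probs)
    if n_pairs > spec.residues_per_chain:
        raise GeneratorSpecError("more contact pairs than residues per chain")
    rng = spec.rng("interface")
    wt_states = rng.random((spec.n_frames, n_pairs)) < wt_probs
    mut_states = rng.random((spec.n_frames, n_pairs)) < mut_probs
    topology, base = gen_toy_complex(spec)
    pair_residues = [(("A", i + 1), ("B", i + 1)) for i in range(n_pairs)]
    return InterfaceScenario(
        topology=topology,
        wt=Trajectory(topology, _realize(spec, base, wt_states)),
        mutant=Trajectory(topology, _realize(spec, base, mut_states)),
        wt_probs=wt_probs, mutant_probs=mut_probs,
        wt_states=wt_states, mutant_states=mut_states,
        pair_residues=pair_residues)


def gen_mode_trajectory(spec: GeneratorSpec) -> ModeScenario:
    """One planted collective mode plus isotropic Gaussian noise.

    ``frame_t = base + amplitude_t * mode + noise``; amplitudes are either
    Gaussian with std ``mode_amplitude`` or drawn from the two-component
    mixture ``mode_mixture`` (per-component std ``mixture_sigma``).  The
    mode is a random unit vector in 3N-space unless ``mode_vector`` is
    given (non-unit inputs are normalized with a warning).
    """
    topology, base = gen_toy_complex(spec)
    n_atoms = topology.n_atoms
    rng = spec.rng("mode")
    if spec.mode_vector is not None:
        mode = np.asarray(spec.mode_vector, dtype=float)
        if mode.shape != (3 * n_atoms,):
            raise GeneratorSpecError(
                f"mode_vector must have length {3 * n_atoms}")
        norm = np.linalg.norm(mode)
        if abs(norm - 1.0) > 1e-9:
            logger.warning("mode vector norm %.4f != 1; normalizing", norm)
        mode = mode / norm
    else:
        mode = rng.normal(size=3 * n_atoms)
        mode /= np.linalg.norm(mode)
    if spec.mode_mixture is None:
        amplitudes = rng.normal(0.0, spec.mode_amplitude, spec.n_frames)
    else:
        locs = np.array([loc for loc, _w in spec.mode_mixture])
        weights = np.array([w for _loc, w in spec.mode_mixture], dtype=float)
        weights /= weights.sum()
        comp = rng.choice(len(locs), size=spec.n_frames, p=weights)
        amplitudes = rng.normal(locs[comp], spec.mixture_sigma)
    noise = rng.normal(0.0, spec.noise_sigma, (spec.n_frames, n_atoms, 3))
    coords = base[None] + amplitudes[:, None, None] * \
        mode.reshape(1, n_atoms, 3) + noise
    return ModeScenario(trajectory=Trajectory(topology, coords),
                        mode=mode, amplitudes=amplitudes)


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
    ], axis=-2)


def gen_rigid_trajectory(spec: GeneratorSpec) -> Trajectory:
    """Frames that are random rigid transforms of the base, plus noise.

    Each frame applies a uniform random rotation about the centroid and a
    uniform translation in ``[-rigid_max_translation, +...]^3``, then adds
    isotropic Gaussian noise of std ``rigid_noise_sigma`` (0 by default:
    pure rigid motion, the RMSD/PCA invariance fixture).
    """
    topology, base = gen_toy_complex(spec)
    rng = spec.rng("rigid")
    rots = _random_rotations(rng, spec.n_frames)
    trans = rng.uniform(-spec.rigid_max_translation,
                       spec.rigid_max_translation, (spec.n_frames, 3))
    centroid = base.mean(axis=0)
    coords = (base - centroid) @ np.swapaxes(rots, -2, -1) \
        + centroid + trans[:, None, :]
    if spec.rigid_noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.rigid_noise_sigma, coords.shape)
    return Trajectory(topology, coords)


def gen_decay_series(spec: GeneratorSpec) -> tuple[dict[str, DecaySeries],
                                                   dict[str, float]]:
    """Chase series per condition with planted half-lives.

    ``fraction(t) = exp(-t ln2 / t_half) * exp(eps)`` with
    ``eps ~ N(0, decay_sigma^2)`` for t > 0; the t = 0 point is exactly 1,
    matching the normalization convention of a chase series.
    """
    rng = spec.rng("decay")
    times = np.asarray(spec.times_h, dtype=float)
    series: dict[str, DecaySeries] = {}
    truth: dict[str, float] = {}
    for label, t_half in spec.half_lives_h:
        fractions = np.exp(-times * np.log(2.0) / t_half)
        eps = rng.normal(0.0, spec.decay_sigma, times.size)
        fractions = fractions * np.exp(eps)
        fractions[times == 0.0] = 1.0
        series[label] = DecaySeries(times=tuple(times),
                                    fractions=tuple(fractions),
                                    protein="ILK", genotype=label)
        truth[label] = t_half
    return series, truth
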