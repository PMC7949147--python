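# Methods

This note documents the models and procedures implemented in mdcompare,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions that make results
reproducible.

## Hydrogen-bond occupancy

A donor–hydrogen–acceptor triple (donor and acceptor are N or O heavy
atoms; the hydrogen must be covalently bonded to the donor) is *bonded*
in a frame when

- d(donor, acceptor) ≤ `max_da_distance` (default 3.0 Å), and
- ∠(donor–hydrogen–acceptor) ≥ `min_dha_angle` (default 135°).

Both boundaries are closed (equality counts as bonded).  The defaults are
the convention of mainstream MD trajectory-analysis toolchains for
heavy-atom distance cutoffs; both are configurable per run and echoed in
every report header.  Occupancy is an exact frame count,
100·n_bonded/n_frames, never a smoothed estimate.  Occupancies below 5%
are reported but flagged as low — at that level a 100 ns-scale trajectory
provides few independent bonded episodes and the number is mostly noise.

Composite occupancy over a group of triples comes in two semantics,
because both appear in practice: **sum** (arithmetic sum of the
individual occupancies; may exceed 100% and is the convention for
"summed occupancies" over equivalent acceptors such as the oxygens of one
phosphate group) and **union** (percent of frames in which at least one
member is bonded; bounded by 100%).  For any group,
union ≤ min(100, sum).

Structures without explicit hydrogens are accepted by the I/O layer but
rejected by all hydrogen-bond operations; protonate first.  Donor
detection needs covalent bonds, which PDB files do not carry, so bonds
are inferred once per structure by a distance heuristic (heavy–heavy
< 1.9 Å, X–H < 1.2 Å) — adequate for donor/acceptor topology, not meant
as a chemistry model.

## Interface contacts and the reduction statistic

A contact map between two disjoint selections counts, per frame,
atom-level contacts of one of three kinds: hydrogen bonds spanning the
sides in either direction (`hbond`, the default — the headline quantity
of interface-occupancy analyses), heavy-atom pairs within a cutoff
(`vdw`, default 4.5 Å), or both.  Aggregations:

- **pair occupancy** (residue_a, residue_b): percent of frames with ≥ 1
  atom-level contact joining the two residues;
- **per-residue occupancy** on side A, in union semantics (percent of
  frames with any interface contact — one number per residue, which is
  what a colorimetric map needs) or sum semantics (sum of the residue's
  pair occupancies);
- **per-frame contact count**: number of contacting atom pairs, the basis
  of the overall statistic.

The mutant-vs-wild-type comparison reports, per side-A residue,
100·(1 − occ_mut/occ_wt), and overall
100·(1 − mean_mut/mean_wt) on per-frame contact counts.  Residues whose
wild-type occupancy is zero are *masked* (the ratio is undefined), listed
separately, and written as 0.00 plus a REMARK in B-factor maps — never as
±∞.  Mutant occupancy above wild type yields a negative reduction and is
reported as such, not clamped.  Maps entering a comparison must share
criteria and contact kind; mismatches raise a comparability error rather
than silently comparing different definitions.

The groove report ranks side-A residues by summed interface occupancy
(ties broken by ascending residue number) — a geometry-only way to locate
the highest-occupancy contact patch; surface electrostatics are out of
scope.

## Rigid superposition and RMSD

The optimal rotation between two conformations is the classic SVD
solution of the 3×3 cross-covariance, with the determinant sign corrected
so the rotation is always proper (no reflections).  The implementation is
batched over frames via numpy's batched SVD, so superposing a whole
trajectory is one vectorized call; fewer than three fit atoms or a
collinear arrangement raises an error (the rotation is not unique).

Time-averaged RMSD of a region: each frame is superposed on the *fit*
selection against the reference, the RMSD is evaluated on the *measure*
selection, and the per-frame values are averaged.  Conventions, all
configurable: reference = frame 0 of the topology file (typically the
crystal structure), heavy-atom/all-atom selections as supplied by the
user, no mass weighting by default.  Subdomain boundaries are user
config, never hard-coded.  A consequence of fit optimality worth knowing:
fitting directly on a subdomain always gives an RMSD for that subdomain
less than or equal to measuring it after a global fit.

## Trajectory PCA

Rigid-body motion is removed by iteratively superposing all frames on
their mean: starting from frame 0, fit every frame to the current mean,
re-average, and stop when the mean moves < 1 μÅ (RMSD), capped at 100
iterations (non-convergence is an error that reports the last delta).
The covariance of the centered, superposed Cartesian coordinates
(1/(F−1) normalization, no mass weighting) is diagonalized directly for
3N ≤ 3000 and through the F×F dual Gram matrix above that — identical
spectra, purely a cost decision.  Eigenvector signs follow a fixed
convention (largest-magnitude element positive) so repeated runs are
bit-identical.  The eigenvalue sum equals the covariance trace; the suite
checks this to 1e-8 relative.

PC1 projection histograms are density-normalized on a range symmetric
about zero spanning the observed extremes (default 100 bins).  Two
systems' PC1 distributions are compared by histogram intersection on a
shared binning: score = 1 − Σ min(p_a, p_b)·Δx, 0 for identical
distributions, 1 for disjoint support.  This operationalizes the usual
visual "the mutant PC1 is of divergent shape" comparison as a single
number; it deliberately compares *distributions of motion along each
system's own PC1*, not the subspace angle between the PCs.

## Turnover kinetics

Chase band intensities are normalized as
f(t) = (raw(t)/loading(t)) / (raw(0)/loading(0)), which forces f(0) = 1
and makes the whole chain invariant to rescaling either channel.
First-order decay f(t) = e^(−kt) is fitted through the origin by linear
regression of −ln f on t (k = Σtᵢyᵢ/Σtᵢ², the standard chase-assay
estimator, exact on noiseless data); nonlinear least squares on the
linear scale is available as `method="nls"`.  t½ = ln 2/k; a
non-positive fitted rate is reported as stable (t½ = ∞), never as a
negative half-life.  With only three post-zero time points inside 24 h,
half-lives much longer than the window (tens of hours) are intrinsically
poorly constrained — expect ±15% scatter there even at 2% band noise,
versus ±3% for fast decays.

The cross-probability helper multiplies independent per-locus
transmission probabilities (e.g. ½ each for a heterozygous mutant allele,
a floxed allele, and a Cre transgene → 12.5% of offspring).

## Synthetic generators

The generators produce the *statistical* structure the analyses assume,
on a deliberately minimal system: two chains of backbone fragments
(N, H, CA, C, O per residue, explicit bonds), chain A presenting one
N–H donor per residue toward chain B's carbonyl O acceptor.  The bonded
realization places the acceptor at 2.9 Å / ~166°, comfortably inside the
default criteria; broken is 5 Å further out — boundary effects can never
flip a planted state, so tests compare against hidden truth exactly.

Planted truths and their defaults:

- **Bond duty cycles**: two-state Markov chains per bond; default
  (p_on, p_off) = (0.35, 0.15), i.e. stationary 0.70 with fast mixing —
  chosen so the 10,000-frame occupancy estimator's sampling s.d. (~0.8
  points) is well inside the ±2-point recovery tolerance.  i.i.d.
  Bernoulli is the special case p_off = 1 − p_on.
- **Interface contacts**: independent Bernoulli indicators per frame and
  residue pair; wild-type probabilities (0.9, 0.8, 0.7, 0.6, 0.5), mutant
  = 0.66 × wild type, so the planted overall reduction is 34%.  The
  wild-type values are kept ≥ 0.5 because the per-residue ratio statistic
  is ill-conditioned at low wild-type occupancy: its sampling s.d. at
  10,000 frames grows from ~1 point at occupancy 0.5 to ~3 points at 0.1,
  which is the same reason real analyses color-map but do not over-read
  reductions at marginal contacts.  Low-occupancy recovery (down to 0.1)
  is still tested at the pair-occupancy level, where it is
  well-conditioned.
- **Collective mode**: frame = base + aₜ·v + ε, with v a random (or
  supplied) unit 3N-vector, aₜ Gaussian (default s.d. 1 Å) or a
  two-component mixture (for bimodal PC1 scenarios), ε isotropic Gaussian
  (default 0.05 Å).  The analytic covariance A²vvᵀ + σ²I makes PC1
  alignment and eigenvalue ratios predictable.
- **Rigid trajectories**: uniform random rotations (quaternion method)
  plus uniform translations, optional noise — the invariance fixture.
- **Chase series**: f(t) = e^(−t ln2/t½)·e^ε, ε ~ N(0, σ²) for t > 0,
  exactly 1 at t = 0; default half-lives 63.7/15.5/24.1/24.7 h over the
  0/8/18/24 h grid, band noise σ = 0.02.

Each generator draws from its own seeded substream
(`SeedSequence([seed, stream_id])`), so equal specs are bit-identical and
adding a generator never perturbs existing fixtures.

What the toy data do **not** emulate: force-field physics, solvent,
correlated side-chain motions, drift, periodic-box artifacts, gel
densitometry nonlinearity.  Passing the recovery suite therefore
demonstrates the *estimators* are correct at realistic sampling sizes; it
says nothing about force-field accuracy or whether 100 ns suffices for a
given real system.

## Pipeline determinism and scenario sizes

`run_compare` writes TSV/JSON/PDB only, with sorted keys, fixed float
formatting, no timestamps, and a manifest listing every output with its
SHA-256 — identical config and seed give byte-identical directories
(DCD headers are deterministic too).  The recovery suite uses 10,000
frames for occupancy/contact statistics (matching the scenario sizes the
tolerances were derived for), 2,000 frames for PCA mode recovery, and
1,000 frames for RMSD expectations; on one CPU the whole suite runs in
well under a minute.

## Known limitations

- The hydrogen-bond model excludes C–H donors, π acceptors and
  water-mediated bridges.
- `both` contact kind counts hydrogen-bond triples and vdW pairs
  additively in the per-frame count; an atom pair that is both is counted
  in each category.
- PDB chain relabeling (on blank/colliding TER segments) supports up to
  26 segments (A–Z).
- Trajectories are assumed whole/re-imaged; no periodic-boundary handling.
- The PC1 divergence depends on bin count at small sample sizes; compare
  systems with equal frame counts and the same `bins`.
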