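# Methods

## The model

`cgchannel` simulates the diffusion of a reaction intermediate (indole)
through the internal channel of a two-site enzyme, at coarse-grained
resolution.  The protein is rigid: one bead per residue, centered on the
Cα.  Each bead carries an effective radius standing in for its side chain
— a per-residue default table (`data/radii.tsv`, 2.0–4.0 Å scaled by
side-chain size) plus per-residue overrides measured from a crystal
structure as the Cα → side-chain distance (centroid of the heavy
side-chain atoms by default; a farthest-atom convention is available,
since "the side-chain point" is genuinely a convention, not a fact).
Residue beads optionally carry formal charges (Asp/Glu −1 e, Lys/Arg +1 e,
His neutral).

Indole is two mobile beads — pyrrole ring 1.6 Å, benzene ring 1.9 Å —
joined by a rigid virtual bond of 2.17 Å (the ring-centroid separation of
an MMFF-minimized planar indole, computed once and frozen in
`model.INDOLE_BOND_LENGTH`).  Indole is electrically neutral.

### Interactions

Van der Waals, a soft 8–6 Lennard-Jones form with σ = r_i + r_j:

    U_vdw(r) = s · 0.5 [ (σ/r)^8 − 1.5 (σ/r)^6 ]

with contact value U(σ) = −0.25 s and minimum −0.266968 s at r = σ√(8/9).
The scale s defaults to 1 kcal/mol per unit bracket, i.e. a well depth of
≈ 0.267 kcal/mol ≈ 0.46 kT at 293 K: a weak, mostly steric interaction, so
nothing "steers" the intermediate — transport is diffusive search.

Electrostatics, a screened Coulomb term with distance-dependent dielectric
ε(r) = 4r (avoiding vacuum-strength interactions in a model with no
explicit solvent):

    U_elec(r) = 332.06 · q_i q_j / (4 r²)   [kcal/mol, Å, e]

Pair terms are switched smoothly to zero with a cubic switch between
`switch_start` (default 18 Å) and `nonbond_cutoff` (default 20 Å), where
both potentials are negligible.

### Propagation

Each indole bead follows the overdamped Ermak–McCammon update

    Δx = (D Δt / kT) F + R,   R ~ N(0, 2 D Δt) per coordinate,

with D from Stokes–Einstein, D = k_B T/(6π η r): 134.1 Å²/ns (pyrrole
bead) and 113.0 Å²/ns (benzene bead) at 293 K in water (η = 1 cp).  The
time step is 50 fs.  After each step the rigid bond is re-imposed by
projecting both beads about their (preserved) midpoint; because the
projection preserves the midpoint, the free pair's midpoint diffuses with
exactly D_pair = (D₁+D₂)/4 ≈ 61.8 Å²/ns, which the tests assert.

A trajectory starts with the indole midpoint at the α-site center and
terminates as

* **reached** — any indole bead within 5 Å of the β-site center (tested
  first, every step);
* **escaped** — *both* beads farther than 40 Å from the α-site center (the
  conservative reading; the one-bead alternative differs negligibly);
* **blocked** — neither within the time cap (4 µs by default).

The inner loop is a numba kernel consuming Gaussian noise generated in
chunks by a seeded `numpy.random.Generator`; a trajectory is
bit-reproducible given its seed.  Ensemble seed k derives from
`SeedSequence([base, k])`, so results are independent of execution order.
A Verlet neighbor list about the bead midpoint (4 Å skin, rebuilt after
> 2 Å midpoint displacement) keeps the per-step cost low.  If the initial
placement overlaps a protein bead, up to 100 rigid-body steepest-descent
relaxation steps are applied; an unresolved overlap aborts the trajectory
as `invalid_start`, excluded from statistics and counted separately.

### Ensembles and occupancy

`run_ensemble` aggregates outcome fractions (which partition exactly) and
travel-time statistics over the reached subset.  `occupancy_histogram`
projects sampled indole midpoints onto the channel axis (a polyline,
default the straight α→β segment) and bins arc length into 72 equal
sections; projections falling off either end are clamped into the end
bins and counted separately.  `compare_states` ranks conformations by
success fraction with percentile bootstrap intervals (1000 resamples) —
an uncertainty label the original analysis did not carry, added here
because the fractions are stochastic.

## Synthetic channels

`make_toy_channel` builds a ground-truth geometry: two spherical wall-bead
pockets (radii 8 Å at the α end, 6 Å at the β end) joined by a 25 Å
cylindrical tunnel of inner radius 4 Å, all walls made of 2 Å beads at
3 Å spacing (spacing ≤ 2 × bead radius guarantees steric closure: the
largest lattice gap keeps any 1.6 Å probe within 0.6 σ of a wall bead,
≈ 27 kcal/mol of repulsion).  The tunnel rings join the pocket shells
flush, so the interior wall surface is continuous from pocket to tunnel —
important because the summed 8–6 attraction makes the walls mildly sticky
(≈ 4 kT), and an intermediate exploring the pocket largely crawls along
the wall.  An early construction that protruded the tube into the pocket
made the mouth reachable only through a 3 Å axial disk and essentially
blocked passage; the flush junction fixed this.  The α- and β-sites are
12-bead rings laid exactly on the pocket equators, so the site centers
coincide with the pocket centers by symmetry and the site separation is
the tunnel length by construction.

Three variants mimic the enzyme's conformational states:

* **closed** (fully closed, active): watertight — no trajectory can escape;
* **leaky** (open, ligand-free-like): an aperture cut through the wall.
  The default aperture, 12 Å at axial position 3 Å, breaks open the α
  pocket the way the open loop conformation uncovers the α site; smaller
  holes let the intermediate slip out but re-adsorb and re-enter, which is
  not what the open state does.  With this default roughly half the
  trajectories escape, the open-state behavior the variant exists to
  emulate;
* **plugged** (blocked): a plug bead of the tunnel's inner radius on the
  axis; nothing passes, everything times out.

`sample_dihedral_series` draws i.i.d. angles from a mixture of von Mises
components (κ = 0 handled as an exact circular uniform), giving dihedral
series whose binned entropy is known in closed form or by quadrature.

## Configurational entropy and RMSF

For each rotatable dihedral x, the Gibbs (plug-in) entropy of the binned
distribution, S = −R Σ p ln p over k = 360°/width periodic bins, is
reported as T·S (kcal/mol) at T = 298 K.  Defaults: 10° bins (36 per
dihedral), no bias correction — the plug-in form is the printed estimator;
empty bins contribute zero; 0 ≤ S ≤ R ln k always.  Binding entropy
changes are differences, TΔS = TS_bound − TS_free, over matched dihedral
identities.  Backbone φ/ψ and side-chain χ1–χ4 are extracted with mdtraj;
ω is excluded by default (stiff, near-constant); χ5 is not extracted
(mdtraj defines χ1–χ4; externally computed χ5 series are accepted).
The BD temperature (293 K) and the entropy temperature (298 K) are
deliberately independent settings.

Cα RMSF is computed after superposing all frames onto their mean structure
(two refinement passes), √⟨|x − ⟨x⟩|²⟩ per residue, in Å.

## Problem sizes and numerical choices

Test and acceptance ensembles use 50 seeds per state with a 400 ns cap
(20 ns for the plugged state, whose trajectories always run to the cap)
instead of 500 seeds × 4 µs — the toy channel's passage times (tens of
ns) make longer caps uninformative, and the plugged state's classification
is cap-invariant.  Toy runs use a 12 Å cutoff (10 Å switch): the toy
beads are uncharged and the 8–6 tail is < 0.02 kT beyond 8 Å.  The
Einstein-relation diagnostic estimates MSD/t by time-origin averaging
(displacements over ten disjoint windows pooled across replicates), the
standard way a diffusion coefficient is read off an MSD curve; the
single-final-point estimator carries ~2.6% sampling noise at 1000
replicates and says the same thing more noisily.

With the default geometry the closed channel passes essentially every
trajectory with mean travel times of a few tens of ns — the same transport
regime as the real fully closed enzyme (99.6% / 39 ns at full scale) —
but the toy walls are smooth lattices, carry no charges and have no
conformational dynamics, so quantitative agreement of travel times with
the real channel is not claimed, and passing tests demonstrate
correctness of the machinery, not fidelity to the crystal geometry.

## Known limitations

* The protein is rigid; coupling between protein motions and intermediate
  diffusion is out of scope by design.
* No hydrodynamic interactions between the two indole beads.
* The charge model is formal charges at Cα positions with strong
  screening; it is a caricature adequate for a mostly nonpolar channel.
* The entropy estimator is the plug-in form; it is biased low at small
  n (an optional Miller–Madow-style correction was deliberately not made
  the default, to keep the printed estimator).
* Real-structure workflows (radii overrides, indole placement by
  superposition) are exercised against synthetic structures in the test
  suite; applying them to crystal structures requires the user to supply
  the PDB files.
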