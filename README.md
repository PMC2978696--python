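# cgchannel

Coarse-grained Brownian dynamics of **substrate channeling** — the direct
transfer of a reaction intermediate between two active sites through an
internal protein tunnel — plus dihedral **configurational entropy** and
**Cα RMSF** analysis of protein flexibility.

The motivating system is tryptophan synthase (TRPS), whose α/β dimeric
unit passes the unstable intermediate indole from the α-site to the
β-site through a ~25 Å channel without releasing it to solvent; whether
the channel passes, leaks or blocks the intermediate depends on the
enzyme's conformational state.  `cgchannel` is for computational
biophysicists who want to quantify that dependence with a cheap,
reproducible model: protein as a rigid set of one-bead-per-residue
particles, intermediate as two bonded mobile beads, transport as
overdamped stochastic dynamics.

## Model in brief

* **Protein**: one bead per residue at the Cα, effective radius per
  residue (table + per-residue crystal-structure overrides), optional
  formal charges.  Rigid.
* **Indole**: pyrrole bead (1.6 Å) + benzene bead (1.9 Å), rigid virtual
  bond (2.17 Å), neutral.
* **Potentials**: soft 8–6 van der Waals
  `U = 0.5[(σ/r)⁸ − 1.5(σ/r)⁶]` (σ = rᵢ + rⱼ, well ≈ 0.267 kcal/mol) and
  screened Coulomb `U = 332.06 qᵢqⱼ/(4r²)` (distance-dependent dielectric
  ε = 4r).
* **Dynamics**: Ermak–McCammon steps, Δx = (DΔt/kT)F + 𝒩(0, 2DΔt), with
  Stokes–Einstein D at 293 K / 1 cp and a 50 fs time step.
* **Outcomes**: *reached* (a bead within 5 Å of the β-site center),
  *escaped* (both beads beyond 40 Å of the α-site), *blocked* (time cap).
* **Entropy**: per-dihedral Gibbs entropy S = −R Σ p ln p over binned
  angle distributions, reported as T·S (kcal/mol, 298 K);
  TΔS = TS_bound − TS_free for binding changes.

A synthetic module builds toy channels (two wall-bead pockets joined by a
25 Å tunnel; watertight / leaky / plugged variants standing in for the
closed, open and obstructed conformational states) and circular-mixture
dihedral series with known entropy, so the whole pipeline runs and is
tested without any external structure files.

## Worked example

```python
import numpy as np
from cgchannel import (BDParams, IndoleLigand, make_toy_channel,
                       run_ensemble, three_state_specs)

params = BDParams(max_time_us=0.4, nonbond_cutoff=12.0, switch_start=10.0)
for name, spec in three_state_specs().items():
    protein = make_toy_channel(spec)
    indole = IndoleLigand().placed_at(
        protein.alpha_center, protein.beta_center - protein.alpha_center)
    cap = BDParams(max_time_us=0.02, nonbond_cutoff=12.0, switch_start=10.0)
    stats, table, _ = run_ensemble(
        protein, indole, cap if name == "plugged" else params, 50, base_seed=1)
    print(f"{name:8s} reached={stats.fraction_reached:.2f} "
          f"escaped={stats.fraction_escaped:.2f} "
          f"blocked={stats.fraction_blocked:.2f} "
          f"t={stats.mean_travel_time_ns}")
```

Output from this exact script:

```
closed   reached=1.00 escaped=0.00 blocked=0.00 t=75.746156
leaky    reached=0.46 escaped=0.54 blocked=0.00 t=65.47367608695652
plugged  reached=0.00 escaped=0.00 blocked=1.00 t=None
```

Reading it: in the watertight ("fully closed") channel every trajectory
delivers the intermediate to the β-site, with a mean first-passage time of
a few tens of ns over the 25 Å tunnel; breaking an aperture into the α
pocket (the "open" state) lets roughly half of the intermediate escape to
solvent; a plug in the tunnel blocks everything.  That ordering —
closed ≥ leaky ≥ plugged — is the conformational-gating effect the model
exists to expose, and `compare_states` attaches bootstrap confidence
intervals to it.

There is also a CLI for shell use:

```bash
cgchannel make-toy --out toy.pdb
cgchannel ensemble --structure toy.pdb --n-seeds 50 --out results/closed
cgchannel histogram --structure toy.pdb --n-seeds 50 --sections 72 --out occ.tsv
cgchannel entropy --traj traj.pdb --out entropy.tsv
```

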