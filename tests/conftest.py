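"""Shared fixtures: toy-channel systems and seed ensembles.

The three-state ensembles (watertight / leaky / plugged) are expensive, so
they are computed once per session and shared by the channeling statistics,
state-comparison and acceptance tests.  Study conditions: 50 seeds per
state, 400 ns cap (20 ns for the plugged state, whose trajectories always
run to the cap), 12 Å cutoff with 10 Å switch (toy beads are uncharged and
the 8–6 tail is negligible beyond ~8 Å).
"""

from __future__ import annotations

import numpy as np
import pytest

from cgchannel import (
    BDParams, IndoleLigand, make_toy_channel, run_ensemble, three_state_specs,
)

N_SEEDS = 50
ENSEMBLE_BASE_SEED = 2026

TOY_PARAMS = BDParams(max_time_us=0.4, nonbond_cutoff=12.0, switch_start=10.0)
PLUG_PARAMS = BDParams(max_time_us=0.02, nonbond_cutoff=12.0, switch_start=10.0)


def place_indole(protein) -> IndoleLigand:
    """Indole midpoint at the α-site center, bond along the channel axis."""
    return IndoleLigand().placed_at(protein.alpha_center,
                                    protein.beta_center - protein.alpha_center)


@pytest.fixture(scope="session")
def three_state_ensembles():
    out = {}
    for name, spec in three_state_specs().items():
        protein = make_toy_channel(spec)
        params = PLUG_PARAMS if name == "plugged" else TOY_PARAMS
        stats, table, samples = run_ensemble(
            protein, place_indole(protein), params, N_SEEDS,
            base_seed=ENSEMBLE_BASE_SEED, keep_samples=(name == "closed"))
        out[name] = {"protein": protein, "params": params, "stats": stats,
                     "table": table, "samples": samples}
    return out
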