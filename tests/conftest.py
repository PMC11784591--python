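"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive allele states and genetic values
by the dumbest possible route — per-node root-path walks and explicit
genotype-dosage sums — so they share no code with the traversal-based
implementation they check.
"""

import numpy as np
import pandas as pd
import pytest

import argtrait as at


@pytest.fixture
def fig1():
    return at.make_fig1()


def path_walk_states(arg, site):
    """Brute-force allele resolution: walk each node's root path.

    Mutations on one node are ordered purely by time here (newest =
    smallest time), independently of the parent_mutation-link logic used
    by the implementation.
    """
    position = float(arg.sites["position"].iloc[site])
    ancestral = str(arg.sites["ancestral_state"].iloc[site])
    parent = {}
    for e in arg.edges.itertuples(index=False):
        if e.left <= position < e.right:
            parent[int(e.child)] = int(e.parent)
    muts = arg.mutations[arg.mutations["site"] == site]
    by_node = {}
    for r in muts.itertuples(index=False):
        by_node.setdefault(int(r.node), []).append((float(r.time), str(r.derived_state)))
    states = {}
    for u in range(arg.num_nodes):
        node, state = u, ancestral
        while True:
            if node in by_node:
                state = min(by_node[node])[1]
                break
            if node not in parent:
                break
            node = parent[node]
        states[u] = state
    return states


def dosage_oracle(arg, traits):
    """G_ind = sum over causal sites of scaled_beta * genotype dosage,
    accumulated in ascending site order, from brute-force states."""
    trait_ids = sorted(set(int(t) for t in traits["trait_id"])) or [0]
    rows = []
    for trait_id in trait_ids:
        sub = traits[traits["trait_id"] == trait_id].sort_values("site_id")
        g = np.zeros(arg.num_individuals)
        for r in sub.itertuples(index=False):
            states = path_walk_states(arg, int(r.site_id))
            dose = np.array([
                sum(1 for u in nodes if states[int(u)] == str(r.causal_allele))
                for nodes in arg.individuals["nodes"]
            ])
            g = g + float(r.scaled_beta) * dose
        for i in range(arg.num_individuals):
            rows.append((i, trait_id, g[i]))
    return pd.DataFrame(
        rows, columns=["individual_id", "trait_id", "genetic_value"]
    ).astype({"individual_id": np.int64, "trait_id": np.int64})
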