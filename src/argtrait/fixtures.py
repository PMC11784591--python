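"""Synthetic ARG generators.

Everything in the test suite and the examples runs on ARGs built here, so
no external download or binary file is ever needed.  Two generators are
provided:

* :func:`make_fig1` — the canonical six-leaf worked example: three
  diploid individuals, one site with ancestral state A, a mutation to T
  on an internal branch and a back-mutation to A above one leaf.  The
  caption-level facts (which nodes exist, who carries T, the causal
  allele frequency of 0.5) pin the fixture down only partially; the
  concrete branching order used here is one consistent choice, frozen so
  every test agrees on it.
* :func:`make_random_arg` — random coalescent-style ARGs with a chosen
  number of samples, local trees (recombination breakpoints) and sites,
  optionally with stacked mutations (back-mutations and multiallelic
  sites), for property and oracle-equivalence testing.

These ARGs capture the structural features the trait simulator must
handle — recombination, stacked/back mutations, diploid individuals —
but not population-genetic realism (no demography, no realistic allele
frequency spectrum, independent topologies across local trees).
"""

from __future__ import annotations

import numpy as np

from ._seed import SeedLike, as_generator
from .arg import ArgTables, build_tables

__all__ = ["make_fig1", "make_random_arg", "make_coalescent_arg"]

_ALPHABET = ("A", "C", "G", "T")

# Node letters for the worked example: leaves a-f are ids 0-5, internal
# nodes g,h,i,j,k are ids 6,7,8,9,10.
FIG1_NODE_LABELS = {0: "a", 1: "b", 2: "c", 3: "d", 4: "e", 5: "f",
                    6: "g", 7: "h", 8: "i", 9: "j", 10: "k"}
FIG1_CAUSAL_NODE = 8       # "i": the mutation to T sits on the branch above it
FIG1_BACK_MUTATED_LEAF = 4  # "e": back-mutation to A above it


def make_fig1() -> ArgTables:
    """The canonical worked-example ARG.

    Six diploid sample leaves a–f (ids 0–5) in three individuals
    (individual 0 = {a, b}), one local tree rooted at k:

    ``k → (g → (a, b), i → (h → (c, d), j → (e, f)))``

    One site at position 50 with ancestral state A, a mutation to T above
    node i, and a back-mutation to A above leaf e.  Samples c, d and f
    therefore carry T (frequency 0.5) and e carries A.
    """
    L = 100.0
    nodes = [
        # id, time, is_sample, individual
        (0, 0.0, 1, 0), (1, 0.0, 1, 0),
        (2, 0.0, 1, 1), (3, 0.0, 1, 1),
        (4, 0.0, 1, 2), (5, 0.0, 1, 2),
        (6, 1.0, 0, -1), (7, 1.0, 0, -1), (8, 2.0, 0, -1),
        (9, 1.0, 0, -1), (10, 3.0, 0, -1),
    ]
    edges = [
        (0.0, L, 6, 0), (0.0, L, 6, 1),
        (0.0, L, 7, 2), (0.0, L, 7, 3),
        (0.0, L, 9, 4), (0.0, L, 9, 5),
        (0.0, L, 8, 7), (0.0, L, 8, 9),
        (0.0, L, 10, 6), (0.0, L, 10, 8),
    ]
    sites = [(0, 50.0, "A")]
    mutations = [
        (0, 0, FIG1_CAUSAL_NODE, "T", -1, 2.5),
        (1, 0, FIG1_BACK_MUTATED_LEAF, "A", 0, 0.5),
    ]
    individuals = [(0, (0, 1)), (1, (2, 3)), (2, (4, 5))]
    return build_tables(
        sequence_length=L, nodes=nodes, edges=edges, sites=sites,
        mutations=mutations, individuals=individuals,
    )


def _random_binary_tree(rng, sample_ids, next_node_id, node_times):
    """Random merge order over ``sample_ids``; returns (edge pairs, root,
    new next id).  Appends internal-node times to ``node_times``."""
    active = list(sample_ids)
    pairs = []
    t = 0.0
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        right = active.pop(int(j))
        left = active.pop(int(i))
        t += float(rng.exponential(1.0)) + 1e-6
        node_times.append(t)
        pairs.append((next_node_id, left))
        pairs.append((next_node_id, right))
        active.append(next_node_id)
        next_node_id += 1
    return pairs, active[0], next_node_id


def make_random_arg(
    n_samples: int,
    n_sites: int,
    n_trees: int = 1,
    stacked_mutation_rate: float = 0.0,
    seed: SeedLike = None,
    ploidy: int = 2,
) -> ArgTables:
    """Generate a random valid ARG with the requested shape.

    ``n_trees`` local trees with independent random binary topologies are
    laid side by side on a genome of length ``100 * n_trees`` (so there
    are exactly ``n_trees - 1`` recombination breakpoints).  Each of the
    ``n_sites`` sites receives one mutation on a random non-root branch of
    its local tree, so every site segregates in the samples; with
    probability ``stacked_mutation_rate`` a second, more recent mutation
    is stacked on a proper-descendant branch — a back-mutation to the
    ancestral allele or a third allele, chosen at random.  Samples are
    grouped into individuals of ``ploidy`` consecutive nodes.

    Deterministic for a given ``seed``.
    """
    rng = as_generator(seed)
    if n_samples < 2:
        raise ValueError(f"need at least 2 samples, got {n_samples}")
    if n_sites < 0 or n_trees < 1 or ploidy < 1:
        raise ValueError(
            f"infeasible shape: n_sites={n_sites}, n_trees={n_trees}, "
            f"ploidy={ploidy}")
    if not 0.0 <= stacked_mutation_rate <= 1.0:
        raise ValueError("stacked_mutation_rate must lie in [0, 1]")

    tree_span = 100.0
    L = tree_span * n_trees
    node_times = [0.0] * n_samples
    next_id = n_samples
    edges = []
    tree_info = []  # (left, right, parent_of dict, children dict, root)
    for t in range(n_trees):
        pairs, root, next_id = _random_binary_tree(
            rng, range(n_samples), next_id, node_times)
        left, right = t * tree_span, (t + 1) * tree_span
        parent_of, children = {}, {}
        for parent, child in pairs:
            edges.append((left, right, parent, child))
            parent_of[child] = parent
            children.setdefault(parent, []).append(child)
        tree_info.append((left, right, parent_of, children, root))

    # Distinct, strictly increasing site positions.
    positions = np.sort(rng.uniform(0.0, L, size=n_sites))
    while n_sites and len(np.unique(positions)) < n_sites:  # pragma: no cover
        positions = np.sort(rng.uniform(0.0, L, size=n_sites))

    sites, mutations = [], []
    mut_id = 0
    for site_id, pos in enumerate(positions):
        tree_idx = min(int(pos // tree_span), n_trees - 1)
        left, right, parent_of, children, root = tree_info[tree_idx]
        ancestral = _ALPHABET[rng.integers(4)]
        sites.append((site_id, float(pos), ancestral))

        non_root = [u for u in parent_of]  # every node with a parent
        node = int(non_root[rng.integers(len(non_root))])
        derived = rng.choice([a for a in _ALPHABET if a != ancestral])
        t_lo, t_hi = node_times[node], node_times[parent_of[node]]
        mutations.append((mut_id, site_id, node, str(derived), -1,
                          0.5 * (t_lo + t_hi)))
        first_id, first_node, first_derived = mut_id, node, str(derived)
        mut_id += 1

        if rng.random() < stacked_mutation_rate:
            # proper descendants of the first mutation's node
            desc, stack = [], list(children.get(first_node, ()))
            while stack:
                u = stack.pop()
                desc.append(u)
                stack.extend(children.get(u, ()))
            if desc:
                node2 = int(desc[rng.integers(len(desc))])
                derived2 = rng.choice(
                    [a for a in _ALPHABET if a != first_derived])
                t_lo, t_hi = node_times[node2], node_times[parent_of[node2]]
                mutations.append((mut_id, site_id, node2, str(derived2),
                                  first_id, 0.5 * (t_lo + t_hi)))
                mut_id += 1

    individuals = []
    node_individual = [-1] * next_id
    for ind_id, start in enumerate(range(0, n_samples, ploidy)):
        node_ids = tuple(range(start, min(start + ploidy, n_samples)))
        individuals.append((ind_id, node_ids))
        for u in node_ids:
            node_individual[u] = ind_id

    nodes = [
        (u, node_times[u], 1 if u < n_samples else 0, node_individual[u])
        for u in range(next_id)
    ]
    return build_tables(
        sequence_length=L, nodes=nodes, edges=edges, sites=sites,
        mutations=mutations, individuals=individuals,
    )


def make_coalescent_arg(
    n_individuals: int,
    sequence_length: float = 1e6,
    recombination_rate: float = 1e-8,
    mutation_rate: float = 1e-8,
    population_size: float = 1e4,
    seed: int = 1,
) -> ArgTables:
    """Optional wrapper around the msprime coalescent simulator for larger
    integration checks.  Nothing in the package requires it; callers
    without msprime should use :func:`make_random_arg` instead."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_individuals, sequence_length=sequence_length,
        recombination_rate=recombination_rate,
        population_size=population_size, random_seed=max(1, int(seed)),
    )
    ts = msprime.sim_mutations(
        ts, rate=mutation_rate, random_seed=max(1, int(seed)) + 1)
    from .arg import from_tree_sequence

    return from_tree_sequence(ts)
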