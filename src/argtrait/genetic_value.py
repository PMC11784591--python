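"""Propagate effect sizes through local trees to per-node and
per-individual genetic values.

At a causal site, every node of the local tree that inherits the causal
allele carries a genetic value equal to the (scaled) effect size; a node
under a back-mutation to a different allele carries zero.  Under the
additive model, an individual's genetic value is the sum of its nodes'
values, accumulated over causal sites.

Carrier nodes are found by traversing downward from each mutation to the
causal allele (or from the tree tops, when the causal allele is the
ancestral state), pruning wherever a descendant mutation switches the
lineage to a different allele.  The cost per site is proportional to the
causal subtree, not to the number of samples times sites — full
genotypes are never decoded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import arg as _arg
from .arg import NULL, ArgTables

__all__ = [
    "NodeValueMap",
    "INDIVIDUAL_VALUE_COLUMNS",
    "carrier_nodes",
    "node_values_for_site",
    "genetic_values",
]

INDIVIDUAL_VALUE_COLUMNS = ["individual_id", "trait_id", "genetic_value"]


@dataclass
class NodeValueMap:
    """Per-node genetic values for one trait at one or more causal sites."""

    trait_id: int
    value: np.ndarray  # indexed by node id

    def as_dict(self) -> dict[int, float]:
        return {u: float(v) for u, v in enumerate(self.value)}


def carrier_nodes(arg: ArgTables, site: int, causal_allele: str) -> np.ndarray:
    """Boolean mask over nodes: does the node inherit ``causal_allele``?

    Subtree traversal: start from every state-change point whose final
    state is the causal allele (a mutation to it, or a parentless node
    when the causal allele is ancestral), descend, and prune at any child
    that carries its own mutation — that child's subtree is covered by
    its own traversal if and only if its final state is causal.
    """
    if not 0 <= site < arg.num_sites:
        raise ValueError(f"site {site} does not exist")
    position = float(arg.sites["position"].iloc[site])
    ancestral = str(arg.sites["ancestral_state"].iloc[site])
    tree = _arg.tree_at(arg, position)
    own = _arg._newest_mutation_per_node(arg, site)

    carrier = np.zeros(arg.num_nodes, dtype=bool)
    origins = [node for node, state in own.items() if state == causal_allele]
    if causal_allele == ancestral:
        origins.extend(
            u for u in range(arg.num_nodes)
            if tree.parent[u] == NULL and u not in own)
    stack = list(origins)
    while stack:
        node = stack.pop()
        carrier[node] = True
        for child in tree.children.get(node, ()):
            if child not in own:  # a mutation on the child ends this sweep
                stack.append(child)
    return carrier


def node_values_for_site(
    arg: ArgTables,
    site: int,
    causal_allele: str,
    scaled_beta: float,
    trait_id: int = 0,
) -> NodeValueMap:
    """Genetic value of every node for one causal site: ``scaled_beta`` on
    carriers of the causal allele, zero elsewhere."""
    carrier = carrier_nodes(arg, site, causal_allele)
    return NodeValueMap(trait_id=trait_id,
                        value=np.where(carrier, float(scaled_beta), 0.0))


def _validate_trait_table(arg: ArgTables, traits: pd.DataFrame) -> None:
    required = {"site_id", "causal_allele", "scaled_beta", "trait_id"}
    missing = required - set(traits.columns)
    if missing:
        raise ValueError(f"trait table is missing columns {sorted(missing)}")
    for r in traits.itertuples(index=False):
        site = int(r.site_id)
        if not 0 <= site < arg.num_sites:
            raise ValueError(f"trait table references unknown site {site}")
        ancestral = str(arg.sites["ancestral_state"].iloc[site])
        known = set(
            arg.mutations.loc[arg.mutations["site"] == site, "derived_state"]
        ) | {ancestral}
        if str(r.causal_allele) not in known:
            raise ValueError(
                f"trait table references unknown allele "
                f"'{r.causal_allele}' at site {site}")


def genetic_values(arg: ArgTables, traits: pd.DataFrame) -> pd.DataFrame:
    """Accumulate genetic values per individual from a trait table.

    For each trait, causal sites are processed in ascending site order and
    each individual receives ``scaled_beta``  times the number of its nodes
    carrying the causal allele — the additive dosage model.  The fixed
    accumulation order makes results bit-reproducible.  Individuals appear
    in the output even when their genetic value is zero.

    Returns a DataFrame ``individual_id, trait_id, genetic_value``.
    """
    _validate_trait_table(arg, traits)
    trait_ids = sorted(set(int(t) for t in traits["trait_id"])) or [0]
    n_ind = arg.num_individuals

    # node -> owning individual (-1 for unassigned); covers pedigree-embedded
    # internal nodes too, which contribute like any other owned node.
    owner = np.full(arg.num_nodes, -1, dtype=np.int64)
    for ind_id, node_ids in zip(arg.individuals["id"], arg.individuals["nodes"]):
        owner[np.asarray(node_ids, dtype=int)] = int(ind_id)

    frames = []
    for trait_id in trait_ids:
        sub = traits[traits["trait_id"] == trait_id]
        sub = sub.sort_values("site_id", kind="stable")
        g = np.zeros(n_ind)
        for r in sub.itertuples(index=False):
            carrier = carrier_nodes(arg, int(r.site_id), str(r.causal_allele))
            owners = owner[carrier]
            counts = np.bincount(owners[owners >= 0], minlength=n_ind)
            g += float(r.scaled_beta) * counts
        frames.append(pd.DataFrame({
            "individual_id": np.arange(n_ind, dtype=np.int64),
            "trait_id": np.int64(trait_id),
            "genetic_value": g,
        }))
    if not frames:
        frames = [pd.DataFrame(columns=INDIVIDUAL_VALUE_COLUMNS)]
    out = pd.concat(frames, ignore_index=True)
    return out[INDIVIDUAL_VALUE_COLUMNS].astype(
        {"individual_id": np.int64, "trait_id": np.int64,
         "genetic_value": np.float64})
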