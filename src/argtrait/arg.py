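"""In-memory ARG data model, local-tree extraction, and allele-state resolution.

An ancestral recombination graph (ARG) is held as a set of plain tables
mirroring the succinct tree-sequence encoding: nodes, edges, sites,
mutations and individuals.  Two on-disk dialects are supported:

* the standard binary ``.trees`` format, read and written through tskit;
* a plain-text TSV dialect (five blocks headed ``#nodes``, ``#edges``,
  ``#sites``, ``#mutations``, ``#individuals``, preceded by a
  ``#sequence_length`` line) so that every test fixture is human-readable
  and diffable.

Coordinates are 0-based with half-open edge intervals ``[left, right)``.
Node/site/mutation/individual ids are required to be dense (``id`` equals
the row index), matching the tree-sequence convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NULL = -1

__all__ = [
    "ArgTables",
    "LocalTree",
    "AlleleStateMap",
    "ArgParseError",
    "ArgValidationError",
    "load_arg",
    "write_arg",
    "tree_at",
    "resolve_states",
    "allele_frequency",
    "from_tree_sequence",
    "to_tree_sequence",
]


class ArgParseError(ValueError):
    """A table file could not be parsed."""


class ArgValidationError(ValueError):
    """Parsed tables violate an ARG invariant."""


NODE_COLUMNS = ["id", "time", "is_sample", "individual"]
EDGE_COLUMNS = ["left", "right", "parent", "child"]
SITE_COLUMNS = ["id", "position", "ancestral_state"]
MUTATION_COLUMNS = ["id", "site", "node", "derived_state", "parent_mutation", "time"]
INDIVIDUAL_COLUMNS = ["id", "nodes"]


@dataclass(eq=False)
class ArgTables:
    """Tabular encoding of an ARG.

    Attributes
    ----------
    sequence_length
        Length of the genome in base pairs; all positions lie in
        ``[0, sequence_length)``.
    nodes
        One row per haploid genome or ancestor: ``id``, ``time``
        (generations before present), ``is_sample`` (0/1), ``individual``
        (individual id or -1).
    edges
        Parent-child relationships over genomic intervals:
        ``left``, ``right``, ``parent``, ``child``.
    sites
        Variant positions with ancestral alleles.
    mutations
        State changes on edges: ``site``, ``node`` (the node below the
        edge the mutation occurred on), ``derived_state``,
        ``parent_mutation`` (previous mutation at the same site on the
        path to the root, or -1) and ``time`` (NaN when unknown).
    individuals
        Diploid (or arbitrary-ploidy) individuals; ``nodes`` is a tuple
        of the node ids belonging to each individual.
    """

    sequence_length: float
    nodes: pd.DataFrame
    edges: pd.DataFrame
    sites: pd.DataFrame
    mutations: pd.DataFrame
    individuals: pd.DataFrame
    # Tables are treated as immutable once built; local trees and resolved
    # allele states are memoised here so repeated per-site queries are cheap.
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_sites(self) -> int:
        return len(self.sites)

    @property
    def num_individuals(self) -> int:
        return len(self.individuals)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.nodes["id"].to_numpy()[self.nodes["is_sample"].to_numpy() == 1]

    def individual_nodes(self, individual_id: int) -> tuple[int, ...]:
        return tuple(self.individuals["nodes"].iloc[individual_id])

    def equals(self, other: "ArgTables") -> bool:
        return (
            self.sequence_length == other.sequence_length
            and self.nodes.equals(other.nodes)
            and self.edges.equals(other.edges)
            and self.sites.equals(other.sites)
            and self.mutations.equals(other.mutations)
            and self.individuals.equals(other.individuals)
        )


@dataclass
class LocalTree:
    """The genealogical tree at one genomic interval.

    ``parent[u]`` is the parent node of ``u``, or -1 when ``u`` is a root
    of this tree or does not appear in any edge covering the interval.
    """

    interval: tuple[float, float]
    parent: np.ndarray
    children: dict[int, list[int]] = field(repr=False)

    def is_in_tree(self, node: int) -> bool:
        return self.parent[node] != NULL or node in self.children

    def root_path(self, node: int) -> list[int]:
        """Nodes from ``node`` (inclusive) up to its root."""
        path = [node]
        while self.parent[path[-1]] != NULL:
            path.append(int(self.parent[path[-1]]))
        return path


@dataclass
class AlleleStateMap:
    """Resolved allele state of every node at one site."""

    site: int
    state: dict[int, str]


# ---------------------------------------------------------------------------
# Construction and I/O


def _as_frame(rows, columns: list[str], dtypes: Mapping[str, type]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=columns)
    for col, dt in dtypes.items():
        df[col] = df[col].astype(dt)
    return df.reset_index(drop=True)


def build_tables(
    *,
    sequence_length: float,
    nodes: Sequence,
    edges: Sequence = (),
    sites: Sequence = (),
    mutations: Sequence = (),
    individuals: Sequence = (),
    validate: bool = True,
) -> ArgTables:
    """Assemble and (by default) validate an :class:`ArgTables` from row lists."""
    arg = ArgTables(
        sequence_length=float(sequence_length),
        nodes=_as_frame(
            nodes, NODE_COLUMNS,
            {"id": np.int64, "time": np.float64, "is_sample": np.int64,
             "individual": np.int64},
        ),
        edges=_as_frame(
            edges, EDGE_COLUMNS,
            {"left": np.float64, "right": np.float64, "parent": np.int64,
             "child": np.int64},
        ),
        sites=_as_frame(
            sites, SITE_COLUMNS,
            {"id": np.int64, "position": np.float64, "ancestral_state": str},
        ),
        mutations=_as_frame(
            mutations, MUTATION_COLUMNS,
            {"id": np.int64, "site": np.int64, "node": np.int64,
             "derived_state": str, "parent_mutation": np.int64,
             "time": np.float64},
        ),
        individuals=_as_frame(
            [(i, tuple(int(n) for n in ns)) for i, ns in individuals],
            INDIVIDUAL_COLUMNS, {"id": np.int64},
        ),
    )
    if validate:
        validate_tables(arg)
    return arg


def validate_tables(arg: ArgTables) -> ArgTables:
    """Check every ARG invariant, raising :class:`ArgValidationError` on failure."""
    if not arg.sequence_length > 0:
        raise ArgValidationError("sequence_length must be positive")

    n = arg.num_nodes
    for name, df in (("nodes", arg.nodes), ("sites", arg.sites),
                     ("mutations", arg.mutations), ("individuals", arg.individuals)):
        ids = df["id"].to_numpy()
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise ArgValidationError(
                f"{name}: ids must be dense 0..{len(ids) - 1} in row order")

    times = arg.nodes["time"].to_numpy()
    if np.any(times < 0):
        raise ArgValidationError("nodes: time must be non-negative")

    # Edge invariants: node ids in range, parent strictly older than child,
    # non-overlapping intervals for a fixed child.
    e = arg.edges
    if len(e):
        for col in ("parent", "child"):
            bad = (e[col] < 0) | (e[col] >= n)
            if bad.any():
                raise ArgValidationError(
                    f"edges: {col} id out of range at row {int(np.argmax(bad.to_numpy()))}")
        if np.any(e["left"].to_numpy() >= e["right"].to_numpy()):
            raise ArgValidationError("edges: require left < right")
        if np.any(e["left"].to_numpy() < 0) or np.any(
                e["right"].to_numpy() > arg.sequence_length):
            raise ArgValidationError("edges: interval outside [0, sequence_length]")
        parents = e["parent"].to_numpy().astype(np.int64)
        children = e["child"].to_numpy().astype(np.int64)
        if np.any(times[parents] <= times[children]):
            row = int(np.argmax(times[parents] <= times[children]))
            raise ArgValidationError(
                f"edges: parent time must exceed child time (row {row})")
        for child, grp in e.groupby("child"):
            ivals = sorted(zip(grp["left"], grp["right"]))
            for (l0, r0), (l1, _r1) in zip(ivals, ivals[1:]):
                if l1 < r0:
                    raise ArgValidationError(
                        f"edges: overlapping intervals for child {child}")

    s = arg.sites
    if len(s):
        pos = s["position"].to_numpy()
        if np.any(pos < 0) or np.any(pos >= arg.sequence_length):
            raise ArgValidationError("sites: position outside [0, sequence_length)")
        if np.any(np.diff(pos) <= 0):
            raise ArgValidationError("sites: positions must be strictly increasing")

    m = arg.mutations
    if len(m):
        if np.any((m["site"] < 0) | (m["site"] >= arg.num_sites)):
            raise ArgValidationError("mutations: site id out of range")
        if np.any((m["node"] < 0) | (m["node"] >= n)):
            raise ArgValidationError("mutations: node id out of range")
        pm = m["parent_mutation"].to_numpy()
        if np.any((pm != NULL) & ((pm < 0) | (pm >= len(m)))):
            raise ArgValidationError("mutations: parent_mutation id out of range")
        for mid, parent_mid in enumerate(pm):
            if parent_mid == NULL:
                continue
            if m["site"].iloc[parent_mid] != m["site"].iloc[mid]:
                raise ArgValidationError(
                    f"mutations: parent of mutation {mid} is at a different site")
            # Parent mutation must lie on the ancestor-or-self lineage in the
            # local tree at the site's position.
            site = int(m["site"].iloc[mid])
            tree = tree_at(arg, float(arg.sites["position"].iloc[site]))
            if int(m["node"].iloc[parent_mid]) not in tree.root_path(
                    int(m["node"].iloc[mid])):
                raise ArgValidationError(
                    f"mutations: parent of mutation {mid} is not on an "
                    f"ancestor-or-self lineage")

    seen: dict[int, int] = {}
    for ind_id, node_ids in zip(arg.individuals["id"], arg.individuals["nodes"]):
        for node in node_ids:
            if not 0 <= node < n:
                raise ArgValidationError(
                    f"individuals: node {node} of individual {ind_id} out of range")
            if node in seen:
                raise ArgValidationError(
                    f"individuals: node {node} belongs to individuals "
                    f"{seen[node]} and {ind_id}")
            seen[node] = int(ind_id)
    # Cross-check the per-node individual column.
    for node_id, ind in zip(arg.nodes["id"], arg.nodes["individual"]):
        if ind != NULL and seen.get(int(node_id)) != int(ind):
            raise ArgValidationError(
                f"nodes: node {node_id} individual column ({ind}) disagrees "
                f"with the individuals table")
    return arg


def _parse_tsv_dialect(text: str) -> ArgTables:
    sequence_length = None
    blocks: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            key = parts[0].strip()
            if key == "sequence_length":
                if len(parts) != 2:
                    raise ArgParseError(
                        f"line {lineno}: #sequence_length needs one value")
                sequence_length = float(parts[1])
                current = None
            elif key in ("nodes", "edges", "sites", "mutations", "individuals"):
                current = blocks.setdefault(key, [])
            else:
                raise ArgParseError(f"line {lineno}: unknown block '#{key}'")
            continue
        if current is None:
            raise ArgParseError(f"line {lineno}: data outside any block")
        current.append(line.split("\t"))
    if sequence_length is None:
        raise ArgParseError("missing #sequence_length header")

    def rows(key: str, columns: list[str]):
        data = blocks.get(key, [])
        if not data:
            return []
        header = data[0]
        if header != columns:
            raise ArgParseError(
                f"block #{key}: expected columns {columns}, got {header}")
        return data[1:]

    def intify(key, row, i, col):
        try:
            return int(row[i])
        except (ValueError, IndexError) as err:
            raise ArgParseError(f"block #{key}, row {row}: bad {col}") from err

    def floatify(key, row, i, col):
        try:
            return float(row[i])
        except (ValueError, IndexError) as err:
            raise ArgParseError(f"block #{key}, row {row}: bad {col}") from err

    nodes = [
        (intify("nodes", r, 0, "id"), floatify("nodes", r, 1, "time"),
         intify("nodes", r, 2, "is_sample"), intify("nodes", r, 3, "individual"))
        for r in rows("nodes", NODE_COLUMNS)
    ]
    edges = [
        (floatify("edges", r, 0, "left"), floatify("edges", r, 1, "right"),
         intify("edges", r, 2, "parent"), intify("edges", r, 3, "child"))
        for r in rows("edges", EDGE_COLUMNS)
    ]
    sites = [
        (intify("sites", r, 0, "id"), floatify("sites", r, 1, "position"), r[2])
        for r in rows("sites", SITE_COLUMNS)
    ]
    mutations = [
        (intify("mutations", r, 0, "id"), intify("mutations", r, 1, "site"),
         intify("mutations", r, 2, "node"), r[3],
         intify("mutations", r, 4, "parent_mutation"),
         floatify("mutations", r, 5, "time"))
        for r in rows("mutations", MUTATION_COLUMNS)
    ]
    individuals = []
    for r in rows("individuals", INDIVIDUAL_COLUMNS):
        ind_id = intify("individuals", r, 0, "id")
        node_field = r[1].strip()
        node_ids = tuple(
            int(tok) for tok in node_field.split(",") if tok != "") if node_field else ()
        individuals.append((ind_id, node_ids))

    return build_tables(
        sequence_length=sequence_length, nodes=nodes, edges=edges, sites=sites,
        mutations=mutations, individuals=individuals,
    )


def load_arg(source) -> ArgTables:
    """Load an ARG from a ``.trees`` file, a TSV-dialect file/text, or tables.

    ``source`` may be a path (``.trees`` files are routed through tskit,
    anything else is parsed as the TSV dialect), a string containing TSV
    dialect text, a file-like object, a tskit ``TreeSequence`` or an
    :class:`ArgTables` (re-validated and returned).
    """
    if isinstance(source, ArgTables):
        return validate_tables(source)
    try:  # a tskit TreeSequence, duck-typed so tskit stays an optional import
        import tskit
        if isinstance(source, tskit.TreeSequence):
            return from_tree_sequence(source)
    except ImportError:  # pragma: no cover
        pass
    if hasattr(source, "read"):
        return _parse_tsv_dialect(source.read())
    if isinstance(source, (str, Path)):
        path = Path(source)
        if isinstance(source, str) and "\n" in source:
            return _parse_tsv_dialect(source)
        if not path.exists():
            raise FileNotFoundError(f"ARG input file not found: {path}")
        if path.suffix == ".trees":
            import tskit
            return from_tree_sequence(tskit.load(str(path)))
        return _parse_tsv_dialect(path.read_text())
    raise TypeError(f"cannot load an ARG from {type(source).__name__}")


def write_arg(arg: ArgTables, path) -> None:
    """Write ``arg`` in the TSV fixture dialect."""
    out = io.StringIO()
    out.write(f"#sequence_length\t{arg.sequence_length!r}\n")
    out.write("#nodes\n" + "\t".join(NODE_COLUMNS) + "\n")
    for r in arg.nodes.itertuples(index=False):
        out.write(f"{r.id}\t{r.time!r}\t{r.is_sample}\t{r.individual}\n")
    out.write("#edges\n" + "\t".join(EDGE_COLUMNS) + "\n")
    for r in arg.edges.itertuples(index=False):
        out.write(f"{r.left!r}\t{r.right!r}\t{r.parent}\t{r.child}\n")
    out.write("#sites\n" + "\t".join(SITE_COLUMNS) + "\n")
    for r in arg.sites.itertuples(index=False):
        out.write(f"{r.id}\t{r.position!r}\t{r.ancestral_state}\n")
    out.write("#mutations\n" + "\t".join(MUTATION_COLUMNS) + "\n")
    for r in arg.mutations.itertuples(index=False):
        out.write(f"{r.id}\t{r.site}\t{r.node}\t{r.derived_state}\t"
                  f"{r.parent_mutation}\t{r.time!r}\n")
    out.write("#individuals\n" + "\t".join(INDIVIDUAL_COLUMNS) + "\n")
    for r in arg.individuals.itertuples(index=False):
        out.write(f"{r.id}\t{','.join(str(n) for n in r.nodes)}\n")
    Path(path).write_text(out.getvalue())


def from_tree_sequence(ts) -> ArgTables:
    """Convert a tskit ``TreeSequence`` to :class:`ArgTables`."""
    nodes = [
        (u, ts.node(u).time, 1 if ts.node(u).is_sample() else 0,
         ts.node(u).individual)
        for u in range(ts.num_nodes)
    ]
    edges = [(e.left, e.right, e.parent, e.child) for e in ts.edges()]
    sites = [(s.id, s.position, s.ancestral_state) for s in ts.sites()]
    mutations = [
        (m.id, m.site, m.node, m.derived_state,
         m.parent if m.parent is not None else NULL,
         m.time if m.time is not None else float("nan"))
        for m in ts.mutations()
    ]
    individuals = [(ind.id, tuple(int(n) for n in ind.nodes))
                   for ind in ts.individuals()]
    return build_tables(
        sequence_length=ts.sequence_length, nodes=nodes, edges=edges,
        sites=sites, mutations=mutations, individuals=individuals,
    )


def to_tree_sequence(arg: ArgTables):
    """Convert :class:`ArgTables` to a tskit ``TreeSequence``."""
    import tskit

    tables = tskit.TableCollection(sequence_length=arg.sequence_length)
    for r in arg.individuals.itertuples(index=False):
        tables.individuals.add_row()
    for r in arg.nodes.itertuples(index=False):
        tables.nodes.add_row(
            flags=tskit.NODE_IS_SAMPLE if r.is_sample else 0,
            time=r.time,
            individual=r.individual if r.individual != NULL else tskit.NULL,
        )
    for r in arg.edges.itertuples(index=False):
        tables.edges.add_row(left=r.left, right=r.right,
                             parent=r.parent, child=r.child)
    for r in arg.sites.itertuples(index=False):
        tables.sites.add_row(position=r.position, ancestral_state=r.ancestral_state)
    for r in arg.mutations.itertuples(index=False):
        tables.mutations.add_row(
            site=r.site, node=r.node, derived_state=r.derived_state,
            parent=r.parent_mutation if r.parent_mutation != NULL else tskit.NULL,
            time=r.time if not np.isnan(r.time) else tskit.UNKNOWN_TIME,
        )
    tables.sort()
    return tables.tree_sequence()


# ---------------------------------------------------------------------------
# Local trees and allele states


def tree_at(arg: ArgTables, position: float) -> LocalTree:
    """Extract the local tree covering ``position``.

    The parent array is built from the edges whose interval contains
    ``position``.  The reported interval spans the consecutive edge
    breakpoints around ``position``, on which the tree is constant; trees
    are memoised per interval, treating the tables as immutable.
    """
    if not 0 <= position < arg.sequence_length:
        raise ValueError(
            f"position {position} outside [0, {arg.sequence_length})")
    if "breakpoints" not in arg._cache:
        arg._cache["breakpoints"] = np.unique(np.concatenate([
            [0.0, arg.sequence_length],
            arg.edges["left"].to_numpy(), arg.edges["right"].to_numpy(),
        ]))
        arg._cache["trees"] = {}
    bp = arg._cache["breakpoints"]
    idx = int(np.searchsorted(bp, position, side="right") - 1)
    if idx in arg._cache["trees"]:
        return arg._cache["trees"][idx]

    left = arg.edges["left"].to_numpy()
    right = arg.edges["right"].to_numpy()
    active = (left <= position) & (position < right)
    parent = np.full(arg.num_nodes, NULL, dtype=np.int64)
    parent[arg.edges["child"].to_numpy()[active]] = \
        arg.edges["parent"].to_numpy()[active]
    children: dict[int, list[int]] = {}
    for c, p in zip(arg.edges["child"].to_numpy()[active],
                    arg.edges["parent"].to_numpy()[active]):
        children.setdefault(int(p), []).append(int(c))
    for c in children.values():
        c.sort()
    tree = LocalTree(interval=(float(bp[idx]), float(bp[idx + 1])),
                     parent=parent, children=children)
    arg._cache["trees"][idx] = tree
    return tree


def _newest_mutation_per_node(arg: ArgTables, site: int) -> dict[int, str]:
    """Final allele carried by each node bearing mutations at ``site``.

    Among several mutations stacked on one node, the newest (furthest from
    the root) wins; ordering uses parent_mutation links when present, then
    mutation times (newest = smallest time), otherwise the input is
    rejected as ambiguous.
    """
    muts = arg.mutations[arg.mutations["site"] == site]
    by_node: dict[int, list] = {}
    for r in muts.itertuples(index=False):
        by_node.setdefault(int(r.node), []).append(r)
    out: dict[int, str] = {}
    for node, group in by_node.items():
        if len(group) == 1:
            out[node] = group[0].derived_state
            continue
        ids = {int(r.id) for r in group}
        parents = {int(r.parent_mutation) for r in group}
        leaves = ids - parents  # mutations no other in the group descends from
        internal_links = sum(1 for r in group if int(r.parent_mutation) in ids)
        if len(leaves) == 1 and internal_links == len(group) - 1:
            # parent links chain the whole stack; the unique leaf is newest
            chosen = next(r for r in group if int(r.id) in leaves)
            out[node] = chosen.derived_state
            continue
        times = [r.time for r in group]
        if all(not np.isnan(t) for t in times) and len(set(times)) == len(times):
            chosen = min(group, key=lambda r: r.time)
            out[node] = chosen.derived_state
            continue
        raise ArgValidationError(
            f"mutations at site {site} on node {node} cannot be ordered: "
            f"no complete parent_mutation chain and no distinct times")
    return out


def resolve_states(arg: ArgTables, site: int) -> AlleleStateMap:
    """Resolve the allele carried by every node at ``site``.

    A node's state is the derived state of the most recent mutation on its
    root path, or the ancestral state if there is none.  Nodes absent from
    the local tree at the site take the ancestral state (unless they carry
    a mutation themselves).
    """
    if not 0 <= site < arg.num_sites:
        raise ValueError(f"site {site} does not exist")
    cached = arg._cache.get("states", {}).get(site)
    if cached is not None:
        return cached
    position = float(arg.sites["position"].iloc[site])
    ancestral = str(arg.sites["ancestral_state"].iloc[site])
    tree = tree_at(arg, position)
    own = _newest_mutation_per_node(arg, site)

    state = {u: ancestral for u in range(arg.num_nodes)}
    # Preorder propagation from every parentless node.
    for top in range(arg.num_nodes):
        if tree.parent[top] != NULL:
            continue
        stack = [(top, ancestral)]
        while stack:
            node, inherited = stack.pop()
            s = own.get(node, inherited)
            state[node] = s
            for child in tree.children.get(node, ()):
                stack.append((child, s))
    result = AlleleStateMap(site=site, state=state)
    arg._cache.setdefault("states", {})[site] = result
    return result


def allele_frequency(arg: ArgTables, site: int, allele: str) -> float:
    """Frequency of ``allele`` among sample nodes at ``site``."""
    samples = arg.sample_ids
    if len(samples) == 0:
        raise ValueError("ARG has no sample nodes")
    states = resolve_states(arg, site).state
    count = sum(1 for u in samples if states[int(u)] == allele)
    return count / len(samples)
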