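"""Phylogenetic tree handling for comparative analysis.

Trees enter the pipeline as Newick text (typically a taxonomy-derived
topology without branch lengths), get usable branch lengths assigned when
needed (Grafen's method), and are turned into the among-species
variance-covariance matrix that a phylogenetic generalized least squares
(PGLS) fit consumes.  Pagel's lambda acts on that matrix by scaling its
off-diagonal entries.

dendropy provides the Newick parser/writer and node surgery; the
covariance construction, branch-length assignment, lambda transform and
the Yule tree simulator used for synthetic studies are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "assign_grafen_lengths",
    "vcv_from_tree",
    "lambda_transform",
    "simulate_yule",
    "prune_to_taxa",
]


class NewickParseError(ValueError):
    """Raised when Newick text cannot be parsed; message carries position."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


class Phylogeny:
    """A rooted phylogeny with uniquely-labelled tips.

    Thin wrapper around a :class:`dendropy.Tree` enforcing the invariants
    the downstream covariance construction relies on:

    * exactly one root, every node reachable from it;
    * tip labels unique and non-empty;
    * branch lengths, when present, finite and >= 0, and present on
      *every* non-root edge or on none (a mixed state is rejected);
    * polytomies are permitted.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        labels = []
        n_with_length = 0
        n_edges = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else None
                if not label:
                    raise TreeValidationError("tip with empty or missing label")
                labels.append(label)
            if node.parent_node is not None:
                n_edges += 1
                bl = node.edge.length
                if bl is not None:
                    if not math.isfinite(bl) or bl < 0:
                        raise TreeValidationError(
                            f"branch length {bl!r} above node "
                            f"{label if node.is_leaf() else '<internal>'} "
                            "is not finite and non-negative"
                        )
                    n_with_length += 1
        seen: set[str] = set()
        for label in labels:
            if label in seen:
                raise TreeValidationError(f"duplicate tip label: {label!r}")
            seen.add(label)
        if len(labels) == 0:
            raise TreeValidationError("tree has no tips")
        if 0 < n_with_length < n_edges:
            raise TreeValidationError(
                f"mixed branch-length state: {n_with_length} of {n_edges} "
                "edges carry lengths (must be all or none)"
            )
        self._has_lengths = n_with_length == n_edges and n_edges > 0
        self._tip_labels = labels

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in left-to-right (preorder) traversal order."""
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def has_branch_lengths(self) -> bool:
        return self._has_lengths

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (mutate at your own risk)."""
        return self._tree

    def clone(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def root_to_tip_distances(self) -> dict[str, float]:
        """Root-to-tip path length per tip (requires branch lengths)."""
        if not self._has_lengths:
            raise TreeValidationError("tree has no branch lengths")
        out: dict[str, float] = {}
        depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
            if node.is_leaf():
                out[node.taxon.label] = depth[id(node)]
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Phylogeny(n_tips={self.n_tips}, "
            f"branch_lengths={self._has_lengths})"
        )


@dataclass
class PhyloCovariance:
    """Among-species covariance implied by a tree.

    ``matrix[i, j]`` is the root-to-MRCA path length of taxa i and j (the
    shared evolutionary history under Brownian motion); the diagonal holds
    root-to-tip distances.  ``lambda_applied`` is ``None`` for the raw
    matrix, or the Pagel's-lambda value by which the off-diagonal has been
    scaled.
    """

    taxa: list[str]
    matrix: np.ndarray
    lambda_applied: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} taxa")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("covariance diagonal must be strictly positive")
        self.matrix = m

    def subset(self, taxa: list[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(
            list(taxa), self.matrix[np.ix_(idx, idx)], self.lambda_applied
        )


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Quoted labels and underscore-escaped labels are both accepted;
    underscores are kept verbatim (no silent conversion to spaces).
    Internal node labels are ignored.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip label: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    # drop internal labels so they never round-trip
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = None
            node.taxon = None
    return Phylogeny(tree)


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick with full-precision branch lengths.

    Lengths are written with 17 significant digits so that a
    read -> write -> read round trip is exact at float64 resolution.
    """
    out = tree.dendropy_tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        suppress_internal_node_labels=True,
        real_value_format_specifier=".17g",
    )
    return out.strip()


# ---------------------------------------------------------------------------
# Branch lengths


def assign_grafen_lengths(
    tree: Phylogeny, rho: float = 1.0, overwrite: bool = False
) -> Phylogeny:
    """Assign branch lengths by Grafen's method.

    Each internal node gets height ``((d - 1) / (n - 1)) ** rho`` where
    ``d`` is its number of descendant tips and ``n`` the total tip count;
    tips sit at height 0.  The result is ultrametric with unit root-to-tip
    depth — the conventional repair for taxonomy-derived topologies that
    carry no branch lengths.
    """
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips to assign branch lengths")
    if tree.has_branch_lengths and not overwrite:
        raise TreeValidationError(
            "tree already has branch lengths; pass overwrite=True to replace"
        )
    new = tree.clone()
    d = new.dendropy_tree
    n = tree.n_tips
    height: dict[int, float] = {}
    for node in d.postorder_node_iter():
        if node.is_leaf():
            height[id(node)] = 0.0
        else:
            ntips = sum(1 for _ in node.leaf_iter())
            height[id(node)] = ((ntips - 1) / (n - 1)) ** rho
    for node in d.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = height[id(node.parent_node)] - height[id(node)]
    return Phylogeny(d)


def assign_unit_lengths(tree: Phylogeny, overwrite: bool = False) -> Phylogeny:
    """Set every branch length to 1 (alternative repair policy)."""
    if tree.has_branch_lengths and not overwrite:
        raise TreeValidationError(
            "tree already has branch lengths; pass overwrite=True to replace"
        )
    new = tree.clone()
    for node in new.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = 1.0
    return Phylogeny(new.dendropy_tree)


# ---------------------------------------------------------------------------
# Covariance


def vcv_from_tree(tree: Phylogeny) -> PhyloCovariance:
    """Phylogenetic variance-covariance matrix of the tips.

    Entry (i, j) is the depth (root-to-node distance) of the most recent
    common ancestor of tips i and j; the diagonal is each tip's own depth.
    Computed in one postorder sweep: at each internal node, pairs of tips
    drawn from two different child subtrees share exactly that node's
    depth.
    """
    if not tree.has_branch_lengths:
        raise TreeValidationError(
            "tree has no branch lengths; run assign_grafen_lengths "
            "(or assign_unit_lengths) first"
        )
    d = tree.dendropy_tree
    taxa = tree.tip_labels
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))

    depth: dict[int, float] = {id(d.seed_node): 0.0}
    for node in d.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    tipsets: dict[int, list[int]] = {}
    for node in d.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depth[id(node)]
            tipsets[id(node)] = [i]
        else:
            children = [tipsets.pop(id(c)) for c in node.child_nodes()]
            h = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = h
                            V[j, i] = h
            merged: list[int] = []
            for c in children:
                merged.extend(c)
            tipsets[id(node)] = merged
    return PhyloCovariance(taxa, V, lambda_applied=None)


def lambda_transform(vcv: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Apply Pagel's lambda: scale off-diagonal covariances by ``lam``.

    lambda = 0 erases the phylogeny (independent species); lambda = 1
    leaves the Brownian-motion covariance untouched.  The domain is
    restricted to [0, 1], which guarantees the result stays positive
    semi-definite.
    """
    if vcv.lambda_applied is not None:
        raise ValueError(
            f"lambda={vcv.lambda_applied} already applied; "
            "transform the raw matrix instead"
        )
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    diag = np.diag(np.diag(vcv.matrix))
    out = lam * (vcv.matrix - diag) + diag
    return PhyloCovariance(list(vcv.taxa), out, lambda_applied=float(lam))


# ---------------------------------------------------------------------------
# Simulation


def simulate_yule(n_tips: int, birth_rate: float, seed: int) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` tips.

    Starting from two lineages at the root, at k extant lineages the next
    split occurs after an Exp(k * birth_rate) waiting time and a uniformly
    chosen lineage bifurcates.  A final Exp(n * birth_rate) waiting time
    is appended so terminal branches have positive length.  Tips are
    labelled ``sp1..spN`` in traversal order.  Deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)

    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += wait
        idx = rng.integers(0, k)
        parent = active.pop(int(idx))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    wait = rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.edge.length += wait

    taxon_namespace = tree.taxon_namespace
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            i += 1
            node.taxon = taxon_namespace.new_taxon(label=f"sp{i}")
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Pruning


def prune_to_taxa(tree: Phylogeny, names) -> Phylogeny:
    """Induced subtree on ``names``; root-to-tip distances are preserved.

    Degree-2 internal nodes left behind by the pruning are suppressed with
    their branch lengths summed.  The root is kept even if it ends up with
    a single child, so every retained tip keeps its exact original depth
    (and hence the pruned tree's covariance equals the corresponding
    submatrix of the full tree's covariance).
    """
    names = set(names)
    missing = sorted(names - set(tree.tip_labels))
    if missing:
        raise ValueError(f"taxa not in tree: {', '.join(missing)}")
    if len(names) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    new = tree.clone()
    d = new.dendropy_tree
    has_lengths = tree.has_branch_lengths

    # drop unwanted leaves, then cascade removal of childless internals
    changed = True
    while changed:
        changed = False
        for node in list(d.postorder_node_iter()):
            if node.parent_node is None:
                continue
            if node.is_leaf():
                keep = node.taxon is not None and node.taxon.label in names
                if not keep:
                    node.parent_node.remove_child(node)
                    changed = True

    # suppress non-root unifurcations, summing lengths
    for node in list(d.postorder_node_iter()):
        if node.parent_node is None:
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            if has_lengths:
                child.edge.length += node.edge.length
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    return Phylogeny(d)


def match_tip_labels(
    table_species: list[str], tree_labels: list[str]
) -> tuple[dict[str, str], list[str]]:
    """Match trait-table species to tree tips.

    Comparison is case-insensitive with spaces and underscores treated as
    equivalent — the usual state of affairs when a trait compilation meets
    a taxonomy-derived tree.  Returns (mapping table-name -> tip-label,
    list of unmatched table names); unmatched species are for the caller
    to drop with a warning, not an error.
    """

    def norm(s: str) -> str:
        return s.strip().casefold().replace(" ", "_")

    lookup = {norm(label): label for label in tree_labels}
    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for sp in table_species:
        hit = lookup.get(norm(sp))
        if hit is None:
            unmatched.append(sp)
        else:
            mapping[sp] = hit
    return mapping, unmatched
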