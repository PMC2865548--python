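"""Distance-based phylogenetics for gene families.

Provides protein distances (p-distance with optional Kimura correction),
neighbor joining with a deterministic tie rule, nonparametric bootstrap
supports mapped onto the full-alignment reference tree, outgroup rooting,
species-overlap duplication annotation, and relative dating of duplications
against a speciation split — the machinery used to ask whether gene
duplicates arose before or after a given divergence (e.g. whether a
duplication predates the tetrapod/teleost or cyclostome/gnathostome split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import Alignment
from .trees import DistanceMatrix, PhyloTree, TreeNode


class SaturationError(ValueError):
    """The observed proportion of differences is at or beyond the point where
    the distance correction diverges."""


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _encode(alignment: Alignment) -> np.ndarray:
    """Rows as int8 codes; gap and X encode as -1 (excluded from comparisons)."""
    from .align import _AA_INDEX

    mat = np.full((alignment.n_rows, alignment.length), -1, dtype=np.int8)
    for r, (_, row) in enumerate(alignment.rows):
        for c, res in enumerate(row):
            mat[r, c] = _AA_INDEX.get(res, -1)
    return mat


def kimura_correction(p: float) -> float:
    """Kimura's protein-distance correction d = -ln(1 - p - 0.2 p^2).

    Diverges as p approaches the positive root of 1 - p - 0.2 p^2
    (~0.854102); beyond it the distance is undefined.
    """
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        raise SaturationError(f"p = {p:.6f} is at or beyond the correction singularity")
    return -float(np.log(arg))


def protein_distance_matrix(
    alignment: Alignment,
    correction: str = "none",
    *,
    gap_handling: str = "pairwise",
    saturation: str = "error",
    saturation_cap: float = 10.0,
) -> DistanceMatrix:
    """Pairwise distances over mutually ungapped columns.

    p = mismatches / compared columns; ``correction='kimura'`` applies
    d = -ln(1 - p - 0.2 p^2). ``gap_handling`` is 'pairwise' (default:
    per-pair deletion of columns where either row has a gap or X) or
    'complete' (drop any column with a gap in any row). ``saturation``
    controls behaviour at the correction singularity: 'error' raises
    :class:`SaturationError`, 'cap' substitutes ``saturation_cap`` (used by
    the bootstrap, where a rare saturated replicate pair should not abort
    the whole run).
    """
    if alignment.n_rows < 2:
        raise ValueError("need at least two rows")
    if correction not in ("none", "kimura"):
        raise ValueError("correction must be 'none' or 'kimura'")
    codes = _encode(alignment)
    if gap_handling == "complete":
        keep = np.all(codes >= 0, axis=0)
        codes = codes[:, keep]
    elif gap_handling != "pairwise":
        raise ValueError("gap_handling must be 'pairwise' or 'complete'")
    return _distances_from_codes(codes, alignment.ids, correction, saturation, saturation_cap)


def _distances_from_codes(
    codes: np.ndarray,
    labels: list[str],
    correction: str,
    saturation: str = "error",
    saturation_cap: float = 10.0,
) -> DistanceMatrix:
    n = codes.shape[0]
    d = np.zeros((n, n))
    valid = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"rows {labels[i]!r} and {labels[j]!r} share no comparable columns"
                )
            p = float((codes[i][both] != codes[j][both]).sum()) / compared
            if correction == "kimura":
                try:
                    dist = kimura_correction(p)
                except SaturationError:
                    if saturation == "cap":
                        dist = saturation_cap
                    else:
                        raise
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=list(labels), values=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(distances: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration on the Q criterion.

    Ties in Q are broken by the lowest (i, j) node-index pair (original
    taxa first, then join nodes in creation order), so the output is
    deterministic. Negative branch-length estimates are clamped to zero.
    For an additive input matrix, leaf-to-leaf path lengths reproduce the
    input distances.
    """
    n = len(distances)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = distances.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in distances.labels]
    active = list(range(n))
    full_D = D  # grows as joins are appended

    while len(active) > 3:
        m = len(active)
        sub = full_D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = lexicographically lowest (i, j) among ties
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes.append(new)
        # distances from the join to every other active node
        new_row = np.zeros(full_D.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        grown = np.zeros((full_D.shape[0] + 1, full_D.shape[0] + 1))
        grown[:-1, :-1] = full_D
        grown[-1, :-1] = new_row[:-1]
        grown[:-1, -1] = new_row[:-1]
        full_D = grown
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    dab = full_D[a, b]
    dac = full_D[a, c]
    dbc = full_D[b, c]
    nodes[a].length = max(0.5 * (dab + dac - dbc), 0.0)
    nodes[b].length = max(0.5 * (dab + dbc - dac), 0.0)
    nodes[c].length = max(0.5 * (dac + dbc - dab), 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    correction: str = "kimura",
) -> PhyloTree:
    """Column-resampling bootstrap mapped onto the reference NJ tree.

    Each internal edge of the full-alignment tree is annotated with the
    percentage of replicate trees containing its bipartition. With
    ``n_replicates=0`` the reference tree is returned without supports.
    Saturated replicate distances are capped rather than aborting the run.
    """
    if n_replicates < 0:
        raise ValueError("replicate count must be non-negative")
    ref_D = protein_distance_matrix(alignment, correction=correction, saturation="cap")
    ref = neighbor_joining(ref_D)
    if n_replicates == 0:
        return ref
    codes = _encode(alignment)
    L = alignment.length
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in ref.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_codes = codes[:, cols]
        try:
            rep_D = _distances_from_codes(rep_codes, alignment.ids, correction, saturation="cap")
        except ValueError:
            continue  # replicate with an incomparable pair contributes nothing
        rep_tree = neighbor_joining(rep_D)
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = frozenset(ref.leaf_names())
    anchor = min(all_leaves)
    for node in ref.internal_edges():
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_replicates
    return ref


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root on the edge separating the outgroup leaves from everything else.

    The outgroup must form one side of an edge of the unrooted tree; the
    root is placed at the midpoint of that edge. Anything else is an error
    — there is no silent fallback.
    """
    out = frozenset(outgroup)
    all_leaves = frozenset(tree.leaf_names())
    if not out or out == all_leaves:
        raise ValueError("outgroup must be a proper non-empty subset of the leaves")
    if not out <= all_leaves:
        raise ValueError(f"unknown outgroup leaves: {sorted(out - all_leaves)}")

    work = tree.root.copy()
    parents: dict[int, TreeNode | None] = {id(work): None}
    for node in work.postorder():
        for child in node.children:
            parents[id(child)] = node

    target: TreeNode | None = None
    for node in work.postorder():
        if node is work:
            continue
        side = frozenset(node.leaf_names())
        if side == out or (all_leaves - side) == out:
            # normalize so the clade below `target` is the outgroup
            target = node
            break
    if target is None:
        raise ValueError("outgroup does not form one side of any edge")

    below = frozenset(target.leaf_names())
    half = target.length / 2.0

    # detach target; invert the path from its parent back to the old root
    def invert(node: TreeNode, new_child_length: float) -> TreeNode:
        """Return `node` re-hung so its former parent becomes its child."""
        parent = parents[id(node)]
        node_children = list(node.children)
        if parent is not None:
            parent.children = [c for c in parent.children if c is not node]
            inverted_parent = invert(parent, node.length)
            node_children.append(inverted_parent)
        node.children = node_children
        node.length = new_child_length
        return node

    parent = parents[id(target)]
    assert parent is not None  # target is not the root
    parent.children = [c for c in parent.children if c is not target]
    other_side = invert(parent, half)
    target.length = half
    if below == out:
        new_root = TreeNode(children=[target, other_side])
    else:
        new_root = TreeNode(children=[other_side, target])
    _suppress_unary(new_root)
    return PhyloTree(root=new_root, rooted=True)


def _suppress_unary(node: TreeNode) -> None:
    """Collapse single-child internal nodes created by rerooting (the old
    trifurcating top), summing branch lengths."""
    for child in list(node.children):
        _suppress_unary(child)
    new_children = []
    for child in node.children:
        if not child.is_leaf() and len(child.children) == 1:
            grand = child.children[0]
            grand.length += child.length
            new_children.append(grand)
        else:
            new_children.append(child)
    node.children = new_children


# ---------------------------------------------------------------------------
# Duplication annotation and relative dating
# ---------------------------------------------------------------------------

def annotate_duplications(tree: PhyloTree) -> PhyloTree:
    """Species-overlap rule: an internal node is a duplication iff the
    species sets of its child clades intersect, else a speciation."""
    if not tree.rooted:
        raise ValueError("duplication annotation requires a rooted tree")
    annotated = PhyloTree(root=tree.root.copy(), rooted=True)
    for node in annotated.root.postorder():
        if node.is_leaf():
            continue
        child_sets = [frozenset(l.species() for l in c.leaves()) for c in node.children]
        overlap = any(
            child_sets[i] & child_sets[j]
            for i in range(len(child_sets))
            for j in range(i + 1, len(child_sets))
        )
        node.annotation = "duplication" if overlap else "speciation"
    return annotated


@dataclass(frozen=True)
class DuplicationDating:
    clade: frozenset[str]  # leaf names under the duplication node
    label: str  # before_split | after_split | unresolved


def relative_dating(
    tree: PhyloTree,
    split: tuple[Iterable[str], Iterable[str]],
) -> list[DuplicationDating]:
    """Date each annotated duplication against a speciation split.

    *before_split*: each child clade of the duplication contains species
    from both sides of the split (the duplicate pair was present in the
    common ancestor). *after_split*: the whole duplication clade is
    confined to one side. Anything else (e.g. losses have emptied one side
    from a child clade) is *unresolved*.

    Species outside the split (e.g. outgroups) are ignored when classifying.
    """
    side_a, side_b = frozenset(split[0]), frozenset(split[1])
    if side_a & side_b:
        raise ValueError("split sides must be disjoint")
    if not side_a or not side_b:
        raise ValueError("both split sides must be non-empty")
    tree_species = {l.species() for l in tree.leaves()}
    unknown = (side_a | side_b) - tree_species
    if unknown:
        raise ValueError(f"split references species absent from the tree: {sorted(unknown)}")
    if not tree.rooted:
        raise ValueError("relative dating requires a rooted, annotated tree")

    out: list[DuplicationDating] = []
    for node in tree.root.postorder():
        if node.is_leaf() or node.annotation != "duplication":
            continue
        child_sets = [frozenset(l.species() for l in c.leaves()) for c in node.children]
        whole = frozenset().union(*child_sets) & (side_a | side_b)
        if all(s & side_a and s & side_b for s in child_sets):
            label = "before_split"
        elif whole and (whole <= side_a or whole <= side_b):
            label = "after_split"
        else:
            label = "unresolved"
        out.append(DuplicationDating(clade=frozenset(node.leaf_names()), label=label))
    return out
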