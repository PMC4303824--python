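"""Distance trees, midpoint rooting, topology classes and branch ratios.

Trees are DendroPy objects throughout. Point estimates are built by
neighbor joining on Kimura-corrected protein distances — a fast,
deterministic builder adequate for recovering which of the three clade
arrangements a family supports; externally computed trees (e.g. from a
full ML search) can be supplied as Newick and classified identically.

The three-clade topology classes, for leaf sets M (metazoa), F (fungi)
and P (plant) on a rooted tree:

* ``tol_like``             — M u F monophyletic (Opisthokonta intact);
* ``autotrophic_paraphyly`` — F u P monophyletic (fungi group with
  plants, the non-ToL arrangement);
* ``fungi_outgroup``       — M u P monophyletic;
* ``unresolved``           — none of the unions is monophyletic.

The mf/fp branch-length ratio is the mean patristic distance over all
metazoa x fungi leaf pairs divided by the mean over fungi x plant
pairs: > 1 means the metazoan side of the tree carries the extra
length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from regen_evo.seqio import GAP, CladeMap, ProteinAlignment

__all__ = [
    "TopologyCall",
    "protein_distance_matrix",
    "neighbor_joining",
    "midpoint_root",
    "classify_topology",
    "mf_fp_ratio",
    "bootstrap_support",
    "patristic_matrix",
]

_UNSCORABLE = {GAP, "X", "*"}

#: p beyond the Kimura correction's domain is capped at this distance.
DEFAULT_MAX_DISTANCE = 10.0


def protein_distance_matrix(
    aln: ProteinAlignment,
    correction: str = "kimura",
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pairwise protein distances with Kimura's correction.

    For each pair, p is the mismatch proportion over pairwise gap-free
    columns and d = -ln(1 - p - 0.2 p^2). p outside the formula's domain
    is capped at ``max_distance`` and flagged in the returned boolean
    saturation matrix. With ``correction="p"`` the raw proportion is
    returned. A pair with zero gap-free overlap is an error.
    """
    if correction not in ("kimura", "p"):
        raise ValueError(f"unknown correction {correction!r}")
    ids = aln.ids
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    n, length = len(ids), aln.length
    enc = np.zeros((n, length), dtype=np.uint8)
    valid = np.zeros((n, length), dtype=bool)
    for r, sid in enumerate(ids):
        row = aln.rows[sid]
        for c, aa in enumerate(row):
            if aa not in _UNSCORABLE:
                enc[r, c] = ord(aa)
                valid[r, c] = True
    D = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            overlap = int(both.sum())
            if overlap == 0:
                raise ValueError(f"no gap-free overlap between {ids[i]!r} and {ids[j]!r}")
            p = float((enc[i, both] != enc[j, both]).sum()) / overlap
            if correction == "p":
                d = p
            else:
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0.0:
                    d = max_distance
                    saturated[i, j] = saturated[j, i] = True
                else:
                    d = min(-math.log(arg), max_distance)
            D[i, j] = D[j, i] = d
    return ids, D, saturated


def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted DendroPy tree.

    Negative estimated branch lengths are clamped to zero with the
    deficit shifted to the sibling edge (their sum is preserved). For an
    additive input matrix the generating topology and branch lengths are
    recovered exactly.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in labels:
        taxon = dendropy.Taxon(label=lab)
        tns.add_taxon(taxon)
        nodes.append(dendropy.Node(taxon=taxon))

    D = D.copy()
    active = list(range(n))

    def _clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
        if li < 0.0:
            return 0.0, total
        if lj < 0.0:
            return total, 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj, dij)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # reuse slot i for the new node
        for ak in active:
            if ak not in (i, j):
                D[i, ak] = D[ak, i] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(0.0, lk)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length (patristic) distance matrix."""
    dist_maps: dict[int, dict[str, float]] = {}
    labels: list[str] = []
    pair_dist: dict[tuple[str, str], float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            labels.append(node.taxon.label)
            dist_maps[id(node)] = {node.taxon.label: 0.0}
            continue
        merged: dict[str, float] = {}
        child_maps = []
        for child in node.child_nodes():
            elen = child.edge.length or 0.0
            cmap = {lab: d + elen for lab, d in dist_maps.pop(id(child)).items()}
            child_maps.append(cmap)
        for k in range(len(child_maps)):
            for l in range(k + 1, len(child_maps)):
                for la, da in child_maps[k].items():
                    for lb, db in child_maps[l].items():
                        key = (la, lb) if la < lb else (lb, la)
                        pair_dist[key] = da + db
        for cmap in child_maps:
            merged.update(cmap)
        dist_maps[id(node)] = merged
    labels = sorted(labels)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    D = np.zeros((n, n))
    for (la, lb), d in pair_dist.items():
        D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = d
    return labels, D


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest (sorted) leaf-label pair, making the rooting deterministic.
    Operates on a clone; the input tree is untouched. All-zero branch
    lengths are an error.
    """
    tree = tree.clone(depth=1)
    labels, D = patristic_matrix(tree)
    if D.max() <= 0.0:
        raise ValueError("cannot midpoint-root a tree with all-zero branch lengths")
    best = None
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            key = (-D[i, j], labels[i], labels[j])
            if best is None or key < best:
                best = key
    total, leaf_a, leaf_b = -best[0], best[1], best[2]

    node_a = next(l for l in tree.leaf_node_iter() if l.taxon.label == leaf_a)
    node_b = next(l for l in tree.leaf_node_iter() if l.taxon.label == leaf_b)
    anc_a = []
    node = node_a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_b = []
    node = node_b
    while node is not None and node not in anc_a:
        anc_b.append(node)
        node = node.parent_node
    mrca = node
    path = anc_a[: anc_a.index(mrca)] + [mrca] + list(reversed(anc_b))
    # edges along the path, oriented from leaf_a towards leaf_b
    mid = total / 2.0
    cum = 0.0
    k = path.index(mrca)
    steps = []  # (child_node_of_edge, length, child_is_towards_a)
    for node in path[:k]:
        steps.append((node, node.edge.length or 0.0, True))
    for node in path[k + 1 :]:
        steps.append((node, node.edge.length or 0.0, False))
    for child, elen, towards_a in steps:
        if cum + elen >= mid - 1e-12:
            within = mid - cum  # distance from the a-side end of this edge
            child_side = within if towards_a else elen - within
            tail_side = elen - child_side
            tree.reroot_at_edge(
                child.edge,
                length1=tail_side,
                length2=child_side,
                suppress_unifurcations=True,
            )
            tree.is_rooted = True
            _canonical_child_order(tree)
            return tree
        cum += elen
    raise AssertionError("midpoint not located on path")  # pragma: no cover


def _canonical_child_order(tree: dendropy.Tree) -> None:
    """Sort children by smallest descendant leaf label, in place, so
    equal rootings serialize identically."""
    min_leaf: dict[int, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            min_leaf[id(node)] = node.taxon.label
        else:
            node._child_nodes.sort(key=lambda c: min_leaf[id(c)])
            min_leaf[id(node)] = min_leaf[id(node._child_nodes[0])]


@dataclass(frozen=True)
class TopologyCall:
    """Topology class, per-clade monophyly and the mf/fp ratio."""

    category: str
    mf_fp_ratio: float
    monophyly: dict[str, bool]


def _clade_leaf_sets(tree: dendropy.Tree, clade_map: CladeMap) -> dict[str, frozenset[str]]:
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    unmapped = [l for l in leaves if l not in clade_map.entries]
    if unmapped:
        raise ValueError(f"tree leaves not in clade map: {unmapped[:5]}")
    out = {}
    for clade in clade_map.clade_order:
        members = frozenset(l for l in leaves if clade_map.entries[l] == clade)
        if not members:
            raise ValueError(f"clade {clade!r} has no leaves on the tree")
        out[clade] = members
    return out


def classify_topology(tree: dendropy.Tree, clade_map: CladeMap) -> TopologyCall:
    """Classify a three-clade tree into its topology category.

    Unrooted input (root of degree >= 3) is midpoint-rooted first. The
    category is decided purely by which clade-pair union is
    monophyletic on the rooted tree.
    """
    if len(tree.seed_node.child_nodes()) != 2:
        tree = midpoint_root(tree)
    sets = _clade_leaf_sets(tree, clade_map)
    P, F, M = (sets[c] for c in clade_map.clade_order)
    node_sets = set()
    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ls = frozenset([node.taxon.label])
        else:
            ls = frozenset().union(*(leafsets[id(c)] for c in node.child_nodes()))
        leafsets[id(node)] = ls
        node_sets.add(ls)
    if M | F in node_sets:
        category = "tol_like"
    elif F | P in node_sets:
        category = "autotrophic_paraphyly"
    elif M | P in node_sets:
        category = "fungi_outgroup"
    else:
        category = "unresolved"
    monophyly = {
        clade: sets[clade] in node_sets for clade in clade_map.clade_order
    }
    return TopologyCall(
        category=category,
        mf_fp_ratio=mf_fp_ratio(tree, clade_map),
        monophyly=monophyly,
    )


def mf_fp_ratio(tree: dendropy.Tree, clade_map: CladeMap) -> float:
    """Mean metazoa-fungi patristic distance over mean fungi-plant one."""
    sets = _clade_leaf_sets(tree, clade_map)
    P, F, M = (sets[c] for c in clade_map.clade_order)
    labels, D = patristic_matrix(tree)
    idx = {lab: i for i, lab in enumerate(labels)}

    def mean_between(A: frozenset[str], B: frozenset[str]) -> float:
        return float(np.mean([D[idx[a], idx[b]] for a in A for b in B]))

    mf = mean_between(M, F)
    fp = mean_between(F, P)
    if fp == 0.0:
        raise ValueError("fungi-plant mean patristic distance is zero")
    return mf / fp


def _splits(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions keyed by the side not holding the
    lexicographically smallest leaf; values are the defining nodes."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_leaves)
    leafsets: dict[int, frozenset[str]] = {}
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
            continue
        ls = frozenset().union(*(leafsets[id(c)] for c in node.child_nodes()))
        leafsets[id(node)] = ls
        if node.parent_node is None:
            continue
        side = ls if ref not in ls else all_leaves - ls
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int = 100,
    seed: int = 0,
    builder=None,
) -> dendropy.Tree:
    """Column-resampling bootstrap supports on the point-estimate tree.

    ``builder`` maps a ProteinAlignment to an (unrooted) tree; the
    default is neighbor joining on Kimura distances. Supports (fraction
    of replicates containing each bipartition of the point tree) are
    attached as internal-node labels. Reproducible given ``seed``.
    """
    if aln.length < 2:
        raise ValueError("alignment must have at least 2 columns")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if builder is None:
        def builder(a: ProteinAlignment) -> dendropy.Tree:
            ids, D, _ = protein_distance_matrix(a)
            return neighbor_joining(D, ids)

    point = builder(aln)
    targets = _splits(point)
    counts = {s: 0 for s in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_aln = ProteinAlignment(
            {sid: "".join(row[c] for c in cols) for sid, row in aln.rows.items()}
        )
        try:
            rep_splits = _splits(builder(rep_aln))
        except ValueError:
            continue  # e.g. zero-overlap pair after resampling
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    for s, node in targets.items():
        node.label = f"{counts[s] / n_reps:.3f}"
    return point
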