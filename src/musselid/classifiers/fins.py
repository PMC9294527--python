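"""FINS: species identification by placement in a neighbour-joining tree.

Forensically informative nucleotide sequencing places a query sequence in a
distance-based phylogenetic tree (here Saitou–Nei neighbour joining on TN93
distances) together with conspecific reference barcodes, and assigns the
species of the smallest clade containing the query and at least one
reference — provided all references in that clade are conspecific and the
clade's bootstrap support clears a minimum (70 % by default).
"""

from __future__ import annotations

import dendropy
import numpy as np

from musselid.classifiers.result import AMBIGUOUS, IdentificationResult
from musselid.distances import (
    DistanceMatrix,
    SitePolicy,
    distance_matrix,
    distance_matrix_from_encoded,
    encode_alignment,
)
from musselid.seqio import AlignedSet


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - sum_k d(i,k)
    - sum_k d(j,k); exact ties are broken by the lexicographically smallest
    pair of representative leaf labels, so the result is invariant to record
    order.  Negative branch lengths are clamped to zero with the deficit
    moved onto the sibling branch.  The returned tree is unrooted (trifurcate
    at the seed node).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distance matrix contains non-finite values")

    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.values
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for rid in dm.ids:
        taxon = dendropy.Taxon(label=rid)
        tns.add_taxon(taxon)
        nodes.append(dendropy.Node(taxon=taxon))
        reps.append(rid)
    active = list(range(n))
    nxt = n

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q is symmetric up to floating rounding, so the exact minimum may
        # appear on one side of the diagonal only: normalize pairs to i<j
        ties = {(min(ai, aj), max(ai, aj)) for ai, aj in np.argwhere(Q == qmin)}
        ai, aj = min(
            ties,
            key=lambda t: tuple(sorted((reps[active[t[0]]], reps[active[t[1]]]))),
        )
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        for k in active:
            if k in (i, j):
                continue
            D[nxt, k] = D[k, nxt] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    # three remaining nodes: close the unrooted tree with a trifurcation
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].edge.length = max(lk, 0.0)
        root.add_child(nodes[k])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest label is the canonical representative.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(labels)
    n = len(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (2 <= len(side) <= n - 2):
            continue
        if anchor in side:
            side = frozenset(labels - side)
        out.add(side)
    return out


def bootstrap_support(
    aln: AlignedSet,
    model: str = "TN93",
    replicates: int = 100,
    seed: int = 0,
    policy: SitePolicy = SitePolicy(),
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap support for the full-data NJ tree.

    Returns the full-data tree and, for each of its non-trivial
    bipartitions, the percentage of replicate NJ trees containing it.  The
    seed fixes the column-resampling stream, so identical inputs and seed
    give identical supports.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    encoded = encode_alignment(aln)
    full = nj_tree(distance_matrix_from_encoded(encoded, aln.ids, model, policy))
    target = tree_bipartitions(full)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    length = encoded.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        rep_dm = distance_matrix_from_encoded(encoded[:, cols], aln.ids, model, policy)
        if not np.all(np.isfinite(rep_dm.values)):
            continue  # saturated replicate: contributes to no bipartition
        rep_bps = tree_bipartitions(nj_tree(rep_dm))
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    return full, supports


def annotate_support(tree: dendropy.Tree, supports: dict[frozenset[str], float]) -> None:
    """Write bootstrap supports onto internal node labels (newick dialect)."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(labels)
    n = len(labels)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (2 <= len(side) <= n - 2):
            continue
        if anchor in side:
            side = frozenset(labels - side)
        if side in supports:
            node.label = f"{supports[side]:.0f}"


def fins_classify(
    tree: dendropy.Tree,
    supports: dict[frozenset[str], float],
    query_id: str,
    labels: dict[str, str],
    min_support: float = 70.0,
    outgroup_id: str | None = None,
) -> IdentificationResult:
    """Assign the query to the species of its smallest supported pure clade.

    The tree is rooted on ``outgroup_id`` when given (midpoint otherwise);
    the query's ancestors are walked until a clade containing at least one
    labelled reference is found.  That species is assigned iff all references
    in the clade share it and the clade's bootstrap support reaches
    ``min_support``; otherwise the outcome is ambiguous.
    """
    work = tree.clone(depth=1)
    if outgroup_id is not None:
        og = work.find_node_with_taxon_label(outgroup_id)
        if og is None:
            raise ValueError(f"outgroup {outgroup_id!r} not in tree")
        work.to_outgroup_position(og, update_bipartitions=False)
    else:
        work.reroot_at_midpoint(update_bipartitions=False)
    query = work.find_node_with_taxon_label(query_id)
    if query is None:
        raise ValueError(f"query {query_id!r} not in tree")

    all_labels = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    anchor = min(all_labels)
    node = query.parent_node
    while node is not None:
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        ref_species = {
            labels[lid]
            for lid in clade
            if lid != query_id and lid != outgroup_id and lid in labels and labels[lid]
        }
        if ref_species:
            side = frozenset(clade)
            if anchor in side:
                side = frozenset(all_labels - side)
            support = supports.get(side, 0.0)
            evidence = {
                "clade_size": len(clade),
                "clade_species": sorted(ref_species),
                "support": support,
            }
            if len(ref_species) == 1 and support >= min_support:
                return IdentificationResult(query_id, "FINS", next(iter(ref_species)), evidence)
            return IdentificationResult(query_id, "FINS", AMBIGUOUS, evidence)
        node = node.parent_node
    return IdentificationResult(query_id, "FINS", AMBIGUOUS, {"clade_species": []})
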