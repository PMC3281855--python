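"""Neighbor-joining tree construction and species-cluster assessment.

NJ agglomerates the pair minimizing the rate-corrected Q-criterion

    Q(i,j) = (n-2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)

and is exact on additive distance matrices. Ties are broken on the
lexicographically smallest label pair (labels of internal nodes are the
smallest leaf label beneath them) so output is deterministic. Negative
branch-length estimates are clamped to zero and the deficit logged.

A species "forms a cluster" when some edge of the unrooted tree separates
exactly that species' specimens from everything else (a leafset
bipartition test); singletons are trivially clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .errors import ComputationError, ParseError, ValidationError

__all__ = ["neighbor_joining", "species_clusters", "ClusterReport",
           "write_newick", "read_newick", "clusters_to_tsv"]

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a complete distance matrix.

    Requires >=3 labels and no undefined (saturated) cells; exclude or
    impute saturated pairs upstream before calling.
    """
    n0 = len(matrix.labels)
    if n0 < 3:
        raise ValidationError(f"neighbor joining requires >=3 taxa, got {n0}")
    if matrix.n_undefined:
        raise ComputationError(
            f"{matrix.n_undefined} undefined (saturated) cells; exclude those "
            "specimens or impute distances before tree building"
        )
    tns = dendropy.TaxonNamespace(matrix.labels)
    nodes: list[dendropy.Node] = []
    for lab in matrix.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    labels = list(matrix.labels)  # smallest leaf label under each active node
    D = matrix.values.astype(float).copy()
    clamp_deficit = 0.0

    def _clamp(length: float, child_label: str) -> float:
        nonlocal clamp_deficit
        if length < 0:
            clamp_deficit += -length
            logger.info(
                "clamped negative branch length %.6g to 0 above %s",
                length, child_label,
            )
            return 0.0
        return length + 0.0  # normalize -0.0

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + _TIE_EPS)
        pairs = {tuple(sorted((int(i), int(j)))) for i, j in ties}
        i, j = min(pairs, key=lambda p: tuple(sorted((labels[p[0]], labels[p[1]]))))
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = _clamp(li, labels[i]), _clamp(lj, labels[j])
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        Dn = np.zeros((n - 1, n - 1))
        Dn[:-1, :-1] = D[np.ix_(keep, keep)]
        Dn[-1, :-1] = Dn[:-1, -1] = dnew[keep]
        D = Dn
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final three-point join: la = (dab + dac - dbc) / 2, cyclically
    a, b, c = 0, 1, 2
    root = dendropy.Node()
    lens = (
        0.5 * (D[a, b] + D[a, c] - D[b, c]),
        0.5 * (D[a, b] + D[b, c] - D[a, c]),
        0.5 * (D[a, c] + D[b, c] - D[a, b]),
    )
    for k, ln in zip((a, b, c), lens):
        root.add_child(nodes[k])
        nodes[k].edge.length = _clamp(ln, labels[k])

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    if clamp_deficit:
        logger.info("total clamped branch-length deficit: %.6g", clamp_deficit)
    return tree


@dataclass(frozen=True)
class ClusterReport:
    """Whether one species' specimens are separable by a single edge cut."""

    species: str
    n_specimens: int
    is_cluster: bool


def species_clusters(
    tree: dendropy.Tree, taxonomy: pd.DataFrame
) -> list[ClusterReport]:
    """Bipartition test for every species with leaves on the tree."""
    tns = tree.taxon_namespace
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = leaf_labels - set(taxonomy.index)
    if missing:
        raise ValidationError(f"tree leaves absent from taxonomy: {sorted(missing)}")
    tree.encode_bipartitions()
    all_mask = tns.all_taxa_bitmask()
    splits: set[int] = set()
    for bp in tree.bipartition_encoding:
        splits.add(bp.leafset_bitmask)
        splits.add(bp.leafset_bitmask ^ all_mask)
    tax = taxonomy.loc[sorted(leaf_labels)]
    reports = []
    for sp, ids in tax.groupby("species").groups.items():
        mask = 0
        for sid in ids:
            mask |= tns.taxon_bitmask(tns.get_taxon(sid))
        is_cluster = len(ids) == 1 or mask == all_mask or mask in splits
        reports.append(ClusterReport(str(sp), len(ids), bool(is_cluster)))
    return sorted(reports, key=lambda r: r.species)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize as newick with 6-decimal branch lengths."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as e:  # dendropy raises several DataError subclasses
        raise ParseError(f"{path}: malformed newick ({e})") from e


def clusters_to_tsv(reports: list[ClusterReport], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in reports]).to_csv(path, sep="\t", index=False)
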