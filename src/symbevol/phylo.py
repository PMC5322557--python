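"""Concatenation + distance phylogeny with bootstrap and monophyly checks.

A deliberately lightweight substitute for a full maximum-likelihood
pipeline, adequate for validating clade structure on synthetic data:
per-locus alignments are concatenated, pairwise p-distances computed with
pairwise deletion of gapped/ambiguous columns, a neighbor-joining tree built
with the canonical Q-matrix algorithm and deterministic (lexicographic)
tie-breaking, and clade support assessed by bootstrap resampling of
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .records import SpeciesTree


@dataclass
class LocusSet:
    """Named per-locus alignments over an identical taxon set."""

    loci: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        taxa_sets = {name: set(aln) for name, aln in self.loci.items()}
        ref = None
        for name, taxa in taxa_sets.items():
            aln = self.loci[name]
            lengths = {len(s) for s in aln.values()}
            if len(lengths) > 1:
                raise ValueError(f"locus {name!r}: unequal sequence lengths")
            if ref is None:
                ref = taxa
            elif taxa != ref:
                raise ValueError(f"locus {name!r}: taxon set differs")

    @property
    def taxa(self) -> list[str]:
        first = next(iter(self.loci.values()))
        return sorted(first)


def concatenate(loci: LocusSet) -> dict[str, str]:
    """Per-taxon concatenation in fixed (sorted) locus order."""
    out = {t: [] for t in loci.taxa}
    for name in sorted(loci.loci):
        aln = loci.loci[name]
        for t in loci.taxa:
            if t not in aln:
                raise ValueError(f"locus {name!r}: taxon {t!r} missing")
            out[t].append(aln[t])
    return {t: "".join(parts) for t, parts in out.items()}


class DistanceMatrix:
    """Symmetric taxon x taxon p-distance matrix with zero diagonal."""

    def __init__(self, taxa: list[str], matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(taxa), len(taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(matrix, matrix.T) or not np.allclose(np.diag(matrix), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.taxa = list(taxa)
        self.matrix = matrix

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])


def p_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """Proportion of differing sites per pair, ignoring columns where either
    sequence has a gap or an N (pairwise deletion)."""
    taxa = sorted(alignment)
    arrs = {t: np.frombuffer(alignment[t].encode(), dtype="S1") for t in taxa}
    n = len(taxa)
    mat = np.zeros((n, n))
    bad = (b"-", b"N", b"n", b"?")
    valid = {t: ~np.isin(arrs[t], bad) for t in taxa}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[taxa[i]], arrs[taxa[j]]
            ok = valid[taxa[i]] & valid[taxa[j]]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}"
                )
            d = float((a[ok] != b[ok]).sum()) / m
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(taxa, mat)


def nj_tree(dm: DistanceMatrix) -> SpeciesTree:
    """Canonical neighbor-joining on a distance matrix.

    At each step the pair minimising the Q criterion is joined; exact ties
    are broken by the lexicographically smallest (name_i, name_j) pair, so
    the output is deterministic. Negative branch lengths are clamped to
    zero. The returned tree carries an (arbitrary) root at the final join,
    as is conventional for NJ output.
    """
    names = list(dm.taxa)
    if len(names) < 3:
        raise ValueError("NJ requires at least 3 taxa")
    d = dm.matrix.copy()
    nodes: dict[str, str] = {t: t for t in names}  # name -> newick fragment

    active = list(names)
    while len(active) > 2:
        n = len(active)
        idx = {t: i for i, t in enumerate(active)}
        totals = d.sum(axis=1)
        best: Optional[tuple[float, str, str]] = None
        for a_i in range(n):
            for b_i in range(a_i + 1, n):
                q = (n - 2) * d[a_i, b_i] - totals[a_i] - totals[b_i]
                ta, tb = sorted((active[a_i], active[b_i]))
                key = (round(q, 12), ta, tb)
                if best is None or key < best:
                    best = key
        _, ta, tb = best
        a_i, b_i = idx[ta], idx[tb]
        dist_ab = d[a_i, b_i]
        la = 0.5 * dist_ab + (totals[a_i] - totals[b_i]) / (2 * (n - 2))
        lb = dist_ab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_name = f"({ta},{tb})"
        nodes[new_name] = f"({nodes[ta]}:{la:.10g},{nodes[tb]}:{lb:.10g})"
        # distances from the new node to every remaining taxon
        keep = [i for i in range(n) if i not in (a_i, b_i)]
        new_row = 0.5 * (d[a_i, keep] + d[b_i, keep] - dist_ab)
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        active = [active[i] for i in keep] + [new_name]

    ta, tb = sorted(active)
    final_dist = max(d[0, 1], 0.0)
    newick = f"({nodes[ta]}:{final_dist / 2:.10g},{nodes[tb]}:{final_dist / 2:.10g});"
    return SpeciesTree.from_newick(newick)


def _bipartitions(tree: SpeciesTree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each encoded as the side not
    containing the lexicographically smallest taxon."""
    labels = sorted(tree.leaf_labels)
    anchor = labels[0]
    all_taxa = frozenset(labels)
    out: set[frozenset[str]] = set()
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_taxa - clade if anchor in clade else clade
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def bootstrap(
    alignment: dict[str, str], n_replicates: int = 100, seed: int = 0
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for the NJ tree's bipartitions.

    Returns support (fraction of replicate trees containing the bipartition)
    for every non-trivial bipartition of the original tree.
    """
    rng = np.random.default_rng(seed)
    taxa = sorted(alignment)
    length = len(alignment[taxa[0]])
    original = _bipartitions(nj_tree(p_distance(alignment)))
    counts = {bp: 0 for bp in original}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {
            t: "".join(alignment[t][c] for c in cols) for t in taxa
        }
        reps = _bipartitions(nj_tree(p_distance(resampled)))
        for bp in original:
            if bp in reps:
                counts[bp] += 1
    return {bp: counts[bp] / n_replicates for bp in original}


def support_for_clade(
    supports: dict[frozenset[str], float], taxa: set[str], all_taxa: set[str]
) -> Optional[float]:
    """Bootstrap support of the bipartition separating ``taxa`` from the
    rest, under the anchor encoding used by :func:`bootstrap`."""
    anchor = min(all_taxa)
    side = frozenset(all_taxa - taxa) if anchor in taxa else frozenset(taxa)
    return supports.get(side)


def is_monophyletic(tree: SpeciesTree, taxa: set[str], outgroup: str) -> bool:
    """True iff ``taxa`` is exactly the leaf set of a clade of the tree
    rooted on ``outgroup``."""
    labels = tree.leaf_labels
    unknown = (set(taxa) | {outgroup}) - labels
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    rooted = tree.tree.clone(depth=1)
    og = rooted.find_node_with_taxon_label(outgroup)
    rooted.to_outgroup_position(og, update_bipartitions=False)
    taxa = set(taxa)
    for node in rooted.preorder_node_iter():
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        if clade == taxa:
            return True
    return False
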