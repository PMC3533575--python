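"""Population structure: simple-matching distances, neighbor joining, PCA.

The genotype-call matrix (states AA/AB/BB) is an unordered categorical
character set, so between-genotype dissimilarity is the simple matching
distance: one minus the fraction of co-classified sites with identical
states. The distance matrix feeds a classical Saitou-Nei neighbor-joining
agglomeration (unweighted, as in PHYLIP's ``neighbor``); the same call
matrix, numerically coded 0/1/2 and site-centered, feeds a PCA via
singular value decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, DataError
from .genotyping import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PCAResult",
    "simple_matching_distance",
    "neighbor_joining",
    "pca",
    "write_newick",
    "newick_string",
    "write_phylip_distances",
    "write_pca",
    "tree_splits",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    n_compared: np.ndarray  # per-pair count of co-classified sites

    def validate(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise DataError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise DataError("distance matrix diagonal is not zero")


@dataclass
class TreeNode:
    """Unrooted tree stored rooted at the last agglomeration node.

    ``children`` holds (child, branch_length) pairs; leaves carry the
    genotype id in ``name``. Classical NJ branch lengths may be negative;
    ``neighbor_joining(clamp_negative=True)`` clamps them to zero.
    """

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def n_edges(self) -> int:
        total = 0
        for child, _ in self.children:
            total += 1 + child.n_edges()
        return total

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Pairwise path lengths between all leaves (oracle/validation aid)."""
        pair_dist: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = [
                {k: v + bl for k, v in walk(child).items()}
                for child, bl in node.children
            ]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i].items():
                        for lb, db in sub[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            pair_dist[key] = da + db
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self)
        return pair_dist


@dataclass
class PCAResult:
    ids: list[str]
    scores: np.ndarray  # genotypes x components
    variance_fraction: np.ndarray


# ---------------------------------------------------------------------------
# simple matching distance

def simple_matching_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - (matching states)/(co-classified sites) for every genotype pair.

    Missing entries are excluded pairwise; a pair with zero co-classified
    sites has no defined distance and is an error.
    """
    ids = list(matrix.genotypes)
    if len(ids) < 2:
        raise DataError("need at least 2 genotypes for distances")
    codes = matrix.codes
    present = codes != MISSING
    n = len(ids)
    d = np.zeros((n, n))
    ncomp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[:, i] & present[:, j]
            m = int(both.sum())
            if m == 0:
                raise DataError(f"no comparable sites for pair ({ids[i]!r}, {ids[j]!r})")
            same = int((codes[both, i] == codes[both, j]).sum())
            d[i, j] = d[j, i] = 1.0 - same / m
            ncomp[i, j] = ncomp[j, i] = m
    np.fill_diagonal(ncomp, matrix.n_sites)
    return DistanceMatrix(ids, d, ncomp)


# ---------------------------------------------------------------------------
# neighbor joining (classical Saitou-Nei)

def neighbor_joining(dist: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Classical NJ agglomeration with deterministic tie-breaking.

    At each step the pair (i, j) minimising
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` (r = row sums) is joined; exact
    Q ties are broken by the lexicographically smallest sorted pair of
    subtree labels, so column order never changes the result. Limb
    lengths follow the standard formulas; negative lengths are kept
    unless ``clamp_negative``.
    """
    dist.validate()
    n = len(dist.ids)
    if n < 2:
        raise DataError("neighbor joining needs >= 2 taxa")
    if n == 2:
        root = TreeNode()
        root.children = [
            (TreeNode(dist.ids[0]), dist.values[0, 1] / 2.0),
            (TreeNode(dist.ids[1]), dist.values[0, 1] / 2.0),
        ]
        return root

    nodes = [TreeNode(name) for name in dist.ids]
    labels = [min(node.leaves()) for node in nodes]  # tie-break keys
    d = dist.values.astype(float).copy()

    def clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        parent.children = [(nodes[i], clamp(li)), (nodes[j], clamp(lj))]

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(parent.leaves())]
        d = d2

    # terminal 3-star: unique unrooted resolution
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    root = TreeNode()
    root.children = [
        (nodes[0], clamp((d01 + d02 - d12) / 2.0)),
        (nodes[1], clamp((d01 + d12 - d02) / 2.0)),
        (nodes[2], clamp((d02 + d12 - d01) / 2.0)),
    ]
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartition halves induced by internal edges.

    Each internal edge splits the leaves in two; the side not containing
    the root-adjacent subtree is returned. A group is monophyletic in the
    unrooted tree iff its leaf set (or its complement) appears here.
    """
    all_leaves = frozenset(tree.leaves())
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            splits.add(below)
        return below

    for child, _ in tree.children:
        walk(child)
    return splits


# ---------------------------------------------------------------------------
# newick

def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name)
        inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
        return f"({inner})"

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    """Write the tree as Newick with 6-decimal fixed branch lengths."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def write_phylip_distances(dist: DistanceMatrix, path) -> None:
    """Square PHYLIP-format distance matrix (names padded to 10 chars)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist.ids)}\n")
        for i, name in enumerate(dist.ids):
            row = " ".join(f"{x:.6f}" for x in dist.values[i])
            fh.write(f"{name[:10]:<10} {row}\n")


# ---------------------------------------------------------------------------
# PCA

def pca(matrix: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the numerically coded genotype matrix.

    States are coded AA=0, AB=1, BB=2; missing entries are imputed with
    the site mean (the core set has none, but the API tolerates them);
    each site (column) is mean-centered and the genotype x site matrix is
    decomposed by SVD. ``variance_fraction[k]`` is the share of total
    variance on component k.
    """
    if len(matrix.genotypes) < 2 or matrix.n_sites < 1:
        raise DataError("pca needs >= 2 genotypes and >= 1 site")
    g = matrix.codes.T.astype(float)  # genotypes x sites
    miss = matrix.codes.T == MISSING
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.nanmean(np.where(miss, np.nan, g), axis=0),
            0.0,
        )
        g = np.where(miss, col_mean[None, :], g)
    g = g - g.mean(axis=0, keepdims=True)

    u, s, _ = np.linalg.svd(g, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        k = n_components or len(s)
        return PCAResult(list(matrix.genotypes), np.zeros((g.shape[0], k)), np.zeros(k))
    scores = u * s
    varfrac = s**2 / total
    if n_components is not None:
        scores = scores[:, :n_components]
        varfrac = varfrac[:n_components]
    return PCAResult(list(matrix.genotypes), scores, varfrac)


def write_pca(result: PCAResult, scores_path, variance_path) -> None:
    k = result.scores.shape[1]
    df = pd.DataFrame(result.scores, columns=[f"PC{i+1}" for i in range(k)])
    df.insert(0, "genotype", result.ids)
    df.to_csv(scores_path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")
    vf = pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(len(result.variance_fraction))],
            "variance_fraction": result.variance_fraction,
        }
    )
    vf.to_csv(variance_path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")
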