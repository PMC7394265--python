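"""Per-cluster evolutionary analysis: JTT distances, neighbor joining, bootstrap.

Distances are maximum-likelihood under the JTT empirical amino-acid
substitution model (rate matrix assembled from the published exchangeability
counts and equilibrium frequencies, normalised to one expected substitution
per site per unit time); trees are Saitou-Nei neighbor joining with
deterministic tie-breaking; branch support comes from column bootstrap of
the cluster alignment.  The cluster alignment is representative-anchored:
each member is globally aligned to the representative and projected onto
its coordinates, so no external multiple-alignment step is required (an
externally computed alignment in FASTA can be supplied instead).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy.optimize import minimize_scalar

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

D_MAX_DEFAULT = 5.0
MIN_COMPARABLE_COLUMNS = 10

# Published JTT model constants: lower-triangle exchangeabilities (row i,
# column j < i, in AA_ORDER) and equilibrium frequencies.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]
JTT_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()


def _build_jtt() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rate matrix eigensystem: Q = S*diag(pi), mean rate 1.

    Returns (eigenvalues, left, right) with P(t) = (left * exp(lam*t)) @ right,
    computed through the pi-symmetrised form for numerical stability."""
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = _JTT_LOWER[k]
            k += 1
    Q = S * JTT_FREQS[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -np.sum(JTT_FREQS * np.diag(Q))  # expected substitutions/site/time = 1
    sqrt_pi = np.sqrt(JTT_FREQS)
    # B = D^{1/2} Q D^{-1/2} is symmetric for a reversible Q
    B = (Q * sqrt_pi[:, np.newaxis]) / sqrt_pi[np.newaxis, :]
    assert np.allclose(B, B.T, atol=1e-10)
    lam, V = np.linalg.eigh((B + B.T) / 2.0)
    left = V / sqrt_pi[:, np.newaxis]
    right = V.T * sqrt_pi[np.newaxis, :]
    return Q, lam, left, right


JTT_Q, _JTT_LAM, _JTT_LEFT, _JTT_RIGHT = _build_jtt()


def jtt_transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to 1, entries clipped at 0."""
    P = (_JTT_LEFT * np.exp(_JTT_LAM * t)) @ _JTT_RIGHT
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# pairwise ML distance


def global_align_pair(a_aa: str, b_aa: str) -> tuple[str, str]:
    """Optimal unit-cost global alignment of two peptides as gapped rows."""
    result = edlib.align(a_aa, b_aa, mode="NW", task="path")
    nice = edlib.getNiceAlignment(result, a_aa, b_aa)
    return nice["query_aligned"], nice["target_aligned"]


def pair_count_matrix(row_a: str, row_b: str) -> np.ndarray:
    """20x20 residue-pair counts over comparable columns (gap/X columns excluded)."""
    C = np.zeros((20, 20))
    for x, y in zip(row_a, row_b):
        i = _AA_INDEX.get(x)
        j = _AA_INDEX.get(y)
        if i is not None and j is not None:
            C[i, j] += 1
    return C


def _ml_distance_from_counts(C: np.ndarray, d_max: float) -> float:
    n = C.sum()
    if n == 0:
        return 0.0
    if C.sum() == np.trace(C):  # identical over all comparable columns
        return 0.0

    def neg_loglik(t: float) -> float:
        P = jtt_transition_matrix(t)
        with np.errstate(divide="ignore"):
            L = np.log(JTT_FREQS[:, np.newaxis] * P + 1e-300)
        return -float(np.sum(C * L))

    res = minimize_scalar(neg_loglik, bounds=(1e-8, d_max), method="bounded",
                          options={"xatol": 1e-7})
    t_hat = float(res.x)
    # a boundary optimum at d_max means saturation: report the cap itself
    if neg_loglik(d_max) <= res.fun + 1e-9:
        return d_max
    return t_hat


def jtt_distance(a_aa: str, b_aa: str,
                 aligned: tuple[str, str] | None = None,
                 d_max: float = D_MAX_DEFAULT) -> float:
    """ML distance (expected substitutions/site) between two peptides.

    ``aligned`` may supply pre-aligned gapped rows; otherwise a global
    alignment is computed.  Columns with a gap or a non-standard residue are
    excluded; fewer than 10 comparable columns triggers an 'unreliable'
    warning but the estimate is still returned.  Saturated pairs cap at d_max.
    """
    row_a, row_b = aligned if aligned is not None else global_align_pair(a_aa, b_aa)
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    C = pair_count_matrix(row_a, row_b)
    if C.sum() < MIN_COMPARABLE_COLUMNS:
        warnings.warn(f"only {int(C.sum())} comparable columns; "
                      "distance estimate unreliable", stacklevel=2)
    return _ml_distance_from_counts(C, d_max)


def simulate_jtt_pair(t: float, n_sites: int,
                      rng: np.random.Generator) -> tuple[str, str]:
    """Simulate a peptide pair at divergence t: ancestor from the equilibrium
    frequencies, descendant per-site from P(t)."""
    P = jtt_transition_matrix(t)
    cum = np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)
    anc = rng.choice(20, size=n_sites, p=JTT_FREQS)
    des = (rng.random(n_sites)[:, np.newaxis] > cum[anc]).sum(axis=1)
    return ("".join(AA_ORDER[i] for i in anc),
            "".join(AA_ORDER[i] for i in des))


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch to parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode
    taxa: list[str]

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.root.leaves()}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0) or np.any(np.diag(self.d) != 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")


def distance_matrix_from_alignment(taxa: Sequence[str], rows: Sequence[str],
                                   d_max: float = D_MAX_DEFAULT) -> DistanceMatrix:
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_distance("", "", aligned=(rows[i], rows[j]),
                                             d_max=d_max)
    return DistanceMatrix(list(taxa), d)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative branch clamped to 0, deficit moved to the sibling edge
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root for n >= 3).

    Ties in the Q criterion break on the smallest (i, j) index pair in the
    current working order, so the result is deterministic.
    """
    n = len(dm.taxa)
    nodes = [TreeNode(name=t) for t in dm.taxa]
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return PhyloTree(root=nodes[0], taxa=list(dm.taxa))
    D = dm.d.copy()
    if n == 2:
        half = D[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        return PhyloTree(root=TreeNode(children=nodes), taxa=list(dm.taxa))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        new_node = TreeNode(children=[nodes[i], nodes[j]])
        new_index = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_index, k] = D[k, new_index] = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        nodes.append(new_node)
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    li = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    lj = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    lk = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    nodes[i].length = max(0.0, li)
    nodes[j].length = max(0.0, lj)
    nodes[k].length = max(0.0, lk)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, taxa=list(dm.taxa))


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-name sets.

    Each internal edge splits the taxa; the side not containing the
    lexicographically smallest taxon represents the split."""
    all_taxa = frozenset(tree.leaf_names())
    anchor = min(all_taxa)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 2 <= len(below) <= len(all_taxa) - 2:
            side = all_taxa - below if anchor in below else below
            splits.add(side)
        return below

    walk(tree.root)
    return splits


def _annotate_supports(tree: PhyloTree, counts: dict[frozenset[str], int],
                       n_reps: int) -> None:
    all_taxa = frozenset(tree.leaf_names())
    anchor = min(all_taxa)

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 2 <= len(below) <= len(all_taxa) - 2:
            side = all_taxa - below if anchor in below else below
            node.support = counts.get(side, 0) / n_reps
        return below

    walk(tree.root)


def bootstrap_support(taxa: Sequence[str], rows: Sequence[str],
                      n_reps: int = 1000, seed: int | None = None,
                      d_max: float = D_MAX_DEFAULT) -> PhyloTree:
    """NJ tree from the alignment with column-bootstrap bipartition supports.

    Columns are resampled with replacement once per replicate (shared across
    all pairs), distances re-estimated, the tree rebuilt, and each internal
    bipartition's support is the fraction of replicates containing it.
    ``n_reps=0`` returns the tree without supports.
    """
    if not rows or len(set(len(r) for r in rows)) != 1:
        raise ValueError("alignment rows must be non-empty and equal length")
    if n_reps > 0 and seed is None:
        raise ValueError("seed required when n_reps > 0")
    n_taxa, n_cols = len(taxa), len(rows[0])
    tree = neighbor_joining(distance_matrix_from_alignment(taxa, rows, d_max=d_max))
    if n_reps == 0 or n_taxa < 4:
        return tree

    # per-pair column pair-codes for fast resampled counting (-1 = excluded)
    codes = np.full((n_taxa, n_cols), -1, dtype=np.int64)
    for t in range(n_taxa):
        for c, ch in enumerate(rows[t]):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                codes[t, c] = idx

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        d = np.zeros((n_taxa, n_taxa))
        for i in range(n_taxa):
            ci = codes[i, cols]
            for j in range(i + 1, n_taxa):
                cj = codes[j, cols]
                mask = (ci >= 0) & (cj >= 0)
                pair_codes = ci[mask] * 20 + cj[mask]
                C = np.bincount(pair_codes, minlength=400).reshape(20, 20).astype(float)
                d[i, j] = d[j, i] = _ml_distance_from_counts(C, d_max)
        rep_tree = neighbor_joining(DistanceMatrix(list(taxa), d))
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    _annotate_supports(tree, counts, n_reps)
    return tree


# ---------------------------------------------------------------------------
# cluster alignments and Newick output


def stack_alignment(labels: Sequence[str], seqs: Sequence[str],
                    ) -> tuple[list[str], list[str]]:
    """Representative-anchored stacked pairwise alignment.

    The first sequence anchors the coordinate system: every other sequence is
    globally aligned to it and projected onto its columns (insertions relative
    to the anchor are dropped, deletions become gaps)."""
    anchor = seqs[0]
    rows = [anchor]
    for seq in seqs[1:]:
        a_row, s_row = global_align_pair(anchor, seq)
        projected = [s for a, s in zip(a_row, s_row) if a != "-"]
        rows.append("".join(projected))
    return list(labels), rows


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Adapter for an externally computed multiple alignment (gapped FASTA)."""
    labels, rows, current = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if current:
                    rows.append("".join(current))
                    current = []
                labels.append(line[1:].split()[0])
            elif line:
                current.append(line.upper())
    if current:
        rows.append("".join(current))
    if len(set(map(len, rows))) > 1:
        raise ValueError("alignment rows differ in length")
    return labels, rows


_NEWICK_UNSAFE = set(" \t()[]':;,")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode, top: bool = False) -> str:
    if node.is_leaf:
        body = _quote(node.name or "")
    else:
        inner = ",".join(_newick_node(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:.3f}"
        body = f"({inner}){label}"
    if top:
        return body
    return f"{body}:{node.length:.6f}"


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize to Newick (6-decimal branch lengths, supports as internal
    node labels, labels quoted when needed)."""
    text = _newick_node(tree.root, top=True) + ";"
    if path is not None:
        with open(path, "w") as out:
            out.write(text + "\n")
    return text
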