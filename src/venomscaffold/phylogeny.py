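"""Distance-based phylogenetics: p-distance with pairwise deletion,
Saitou-Nei neighbor-joining, bootstrap supports and a center-star guide
alignment.

Pairwise deletion discards alignment columns with a gap or 'X' in either
member of a pair; a pair whose usable-column fraction falls below 50% is
marked undefined.  NJ is exact on additive matrices; branch lengths from the
standard rate equations with negatives clamped to zero and deterministic
tie-breaking by index order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import global_align
from .io_formats import PhyloTree, TreeNode, ValidationError

PAIRWISE_DELETION_MIN = 0.50
BOOTSTRAP_DEFAULT = 1000


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray                    # symmetric, zero diagonal, NaN=undefined
    usable_fraction: np.ndarray      # per-pair fraction of columns used

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.d[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


def p_distance(aligned_a: str, aligned_b: str,
               min_fraction: float = PAIRWISE_DELETION_MIN,
               model: str = "p") -> tuple[float, float]:
    """Pairwise-deletion distance between two equal-length gapped strings.

    Returns ``(distance, usable_fraction)``; distance is NaN when fewer than
    ``min_fraction`` of the columns are usable (gap or 'X' in either
    sequence deletes the column for this pair).  model='poisson' applies the
    Poisson correction -ln(1 - p).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned sequences differ in length")
    total = len(aligned_a)
    if total == 0:
        raise ValidationError("empty alignment")
    usable = mismatch = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in "-X" or y in "-X":
            continue
        usable += 1
        if x != y:
            mismatch += 1
    frac = usable / total
    if usable == 0 or frac < min_fraction:
        return float("nan"), frac
    p = mismatch / usable
    if model == "poisson":
        if p >= 1.0:
            return float("nan"), frac
        return -math.log(1.0 - p), frac
    if model != "p":
        raise ValidationError(f"unknown distance model {model!r}")
    return p, frac


def distance_matrix(msa: Mapping[str, str],
                    min_fraction: float = PAIRWISE_DELETION_MIN,
                    model: str = "p") -> DistanceMatrix:
    labels = list(msa)
    n = len(labels)
    d = np.zeros((n, n))
    frac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist, f = p_distance(msa[labels[i]], msa[labels[j]],
                                 min_fraction, model)
            d[i, j] = d[j, i] = dist
            frac[i, j] = frac[j, i] = f
    return DistanceMatrix(labels=labels, d=d, usable_fraction=frac)


def site_coverage_filter(msa: Mapping[str, str],
                         min_coverage: float = 0.50) -> dict[str, str]:
    """Drop alignment columns whose residue coverage is below the cutoff.

    Coverage of a column = fraction of sequences with a residue (not gap,
    not 'X').  Applying this before pairwise-deletion distances removes the
    gap-dominated columns a star-shaped guide alignment accumulates, which
    would otherwise push every pair below the usable-fraction cutoff.
    """
    labels = list(msa)
    rows = [msa[l] for l in labels]
    n = len(rows)
    keep = [j for j in range(len(rows[0]))
            if sum(r[j] not in "-X" for r in rows) / n >= min_coverage]
    return {l: "".join(r[j] for j in keep) for l, r in zip(labels, rows)}


def prune_undefined(dm: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Greedily drop the taxa responsible for undefined pairs.

    Repeatedly removes the label involved in the most undefined (NaN)
    distances until every remaining pair is defined; ties broken by label
    order.  Returns the reduced matrix and the excluded labels.
    """
    labels = list(dm.labels)
    d = dm.d.copy()
    frac = dm.usable_fraction.copy()
    excluded: list[str] = []
    while True:
        bad = np.isnan(d).sum(axis=1)
        if not bad.any():
            break
        worst = int(max(range(len(labels)),
                        key=lambda i: (bad[i], labels[i])))
        excluded.append(labels.pop(worst))
        keep = [i for i in range(d.shape[0]) if i != worst]
        d = d[np.ix_(keep, keep)]
        frac = frac[np.ix_(keep, keep)]
    return DistanceMatrix(labels=labels, d=d, usable_fraction=frac), excluded


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing Q = (n-2)d_ij - r_i - r_j, with
    ties broken by (smaller i, smaller j); branch lengths from the rate
    equations, negatives clamped to 0.  The returned tree is unrooted,
    stored with a degree-3 root (degree-2 for 2 leaves).
    """
    labels = list(dm.labels)
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate labels in distance matrix")
    if len(labels) < 2:
        raise ValidationError("need at least 2 taxa")
    undef = dm.undefined_pairs()
    if undef:
        raise ValidationError(f"undefined distances for pairs {undef[:5]}")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    d = dm.d.astype(float).copy()

    if len(nodes) == 2:
        nodes[0].length = nodes[1].length = d[0, 1] / 2.0
        return PhyloTree(root=TreeNode(children=nodes))

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        nd = np.zeros((n - 1, n - 1))
        nd[:-1, :-1] = d[np.ix_(keep, keep)]
        nd[-1, :-1] = nd[:-1, -1] = dk[keep]
        d = nd
        nodes = [nodes[k] for k in keep] + [new]

    # final three branches around the root
    a, b, c = nodes
    a.length = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    b.length = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    c.length = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    return PhyloTree(root=TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    tree: PhyloTree
    replicates: int
    counted: int
    skipped: int
    supports: dict[frozenset, int] = field(default_factory=dict)


def bootstrap_support(msa: Mapping[str, str], B: int = BOOTSTRAP_DEFAULT,
                      seed: int | None = None,
                      min_fraction: float = PAIRWISE_DELETION_MIN,
                      model: str = "p") -> BootstrapResult:
    """Column-resampling bootstrap supports on the NJ tree of ``msa``.

    Each replicate resamples alignment columns with replacement, recomputes
    pairwise-deletion distances and an NJ tree; the support of each internal
    edge of the original tree is the percentage of successful replicates
    containing the same bipartition.  Replicates with an undefined pair are
    skipped and counted in ``skipped``.  B=0 leaves the tree unannotated.
    """
    if len(msa) < 4 and B > 0:
        raise ValidationError("bootstrap needs >= 4 sequences")
    dm = distance_matrix(msa, min_fraction, model)
    tree = nj_tree(dm)
    if B == 0:
        return BootstrapResult(tree=tree, replicates=0, counted=0, skipped=0)

    labels = list(msa)
    mat = np.array([list(msa[l]) for l in labels])
    ncol = mat.shape[1]
    rng = np.random.default_rng(seed)
    target = tree.bipartitions()
    tally = {bp: 0 for bp in target}
    counted = skipped = 0
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        rep = {l: "".join(mat[k, cols]) for k, l in enumerate(labels)}
        rdm = distance_matrix(rep, min_fraction, model)
        if rdm.undefined_pairs():
            skipped += 1
            continue
        counted += 1
        rbp = nj_tree(rdm).bipartitions()
        for bp in target & rbp:
            tally[bp] += 1

    supports = {bp: (round(100.0 * c / counted) if counted else 0)
                for bp, c in tally.items()}
    _annotate_supports(tree, supports)
    return BootstrapResult(tree=tree, replicates=B, counted=counted,
                           skipped=skipped, supports=supports)


def _annotate_supports(tree: PhyloTree, supports: Mapping[frozenset, int]):
    full = frozenset(tree.leaf_names())

    def walk(node: TreeNode):
        if not node.is_leaf:
            below = frozenset(n.name for n in node.leaves())
            if 1 < len(below) < len(full) - 1:
                side = min(below, full - below,
                           key=lambda s: (len(s), sorted(s)))
                if side in supports:
                    node.support = supports[side]
            for c in node.children:
                walk(c)

    for c in tree.root.children:
        walk(c)


# ---------------------------------------------------------------------------
# center-star guide alignment


def guide_msa(sequences: Mapping[str, str]) -> dict[str, str]:
    """Center-star progressive multiple alignment.

    The center is the sequence maximizing summed pairwise identity; all
    others are merged via their pairwise global alignment to the center
    ("once a gap, always a gap").  Intended as a dependency-free guide
    alignment, not a substitute for a proper MSA program.
    """
    labels = list(sequences)
    if len(labels) < 2:
        raise ValidationError("alignment needs >= 2 sequences")
    if len(labels) == 2:
        a, b = labels
        aln = global_align(sequences[a], sequences[b], query_id=a, ref_id=b)
        return {a: aln.aligned_query, b: aln.aligned_ref}

    # choose center
    total = {l: 0.0 for l in labels}
    pair_cache: dict[tuple[str, str], object] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            aln = global_align(sequences[a], sequences[b], query_id=a,
                               ref_id=b)
            pair_cache[(a, b)] = aln
            total[a] += aln.identity_pct
            total[b] += aln.identity_pct
    center = max(labels, key=lambda l: (total[l], -labels.index(l)))

    master = sequences[center]          # center row with accumulated gaps
    rows: dict[str, str] = {center: master}
    for other in labels:
        if other == center:
            continue
        key = (center, other) if (center, other) in pair_cache else (other, center)
        aln = pair_cache[key]
        if key[0] == center:
            c_aln, o_aln = aln.aligned_query, aln.aligned_ref
        else:
            c_aln, o_aln = aln.aligned_ref, aln.aligned_query
        master, rows = _merge(master, rows, c_aln, o_aln, other)
    return {l: rows[l] for l in labels}


def _merge(master: str, rows: dict[str, str], c_aln: str, o_aln: str,
           other: str) -> tuple[str, dict[str, str]]:
    """Merge one center-vs-other pairwise alignment into the growing MSA."""
    new_master = []
    new_other = []
    inserts_at: list[int] = []      # master positions needing a new gap column
    i = j = 0                       # i -> master, j -> c_aln
    while i < len(master) or j < len(c_aln):
        mc = master[i] if i < len(master) else None
        cc = c_aln[j] if j < len(c_aln) else None
        if mc == "-" and (cc != "-" or cc is None):
            # gap already present in master but not in this pairwise aln
            new_master.append("-")
            new_other.append("-")
            i += 1
        elif cc == "-" and (mc != "-" or mc is None):
            # new gap introduced by this pairwise alignment
            new_master.append("-")
            new_other.append(o_aln[j])
            inserts_at.append(len(new_master) - 1)
            j += 1
        else:
            new_master.append(mc)
            new_other.append(o_aln[j])
            i += 1
            j += 1
    # propagate new gap columns into previously merged rows
    out_rows: dict[str, str] = {}
    for label, row in rows.items():
        chars = list(row)
        for pos in inserts_at:
            chars.insert(pos, "-")
        out_rows[label] = "".join(chars)
    out_rows[other] = "".join(new_other)
    return "".join(new_master), out_rows
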