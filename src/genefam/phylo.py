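"""Alignment, distance, neighbor-joining and paralog-pair extraction.

The pairwise engine is an affine-gap global aligner (Gotoh three-state DP,
row-vectorized).  The multiple aligner is a self-contained progressive
method: k-mer guide distances, UPGMA guide tree, profile-profile merges
scored by sum-of-pairs.  Distances use pairwise gap deletion so divergent,
gappy regions still contribute wherever both rows are ungapped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord
from .tree import TreeNode

_SUBMAT_CACHE: dict[str, tuple[str, np.ndarray]] = {}
NEG = -1e30


def _load_submat(name: str) -> tuple[str, np.ndarray]:
    """(alphabet string, square score array) for a named matrix."""
    if name not in _SUBMAT_CACHE:
        mat = substitution_matrices.load(name)
        alphabet = str(mat.alphabet)
        arr = np.array([[float(mat[a, b]) for b in alphabet]
                        for a in alphabet])
        _SUBMAT_CACHE[name] = (alphabet, arr)
    return _SUBMAT_CACHE[name]


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float


@dataclass
class MultipleAlignment:
    records: list[SequenceRecord]

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v


@dataclass(frozen=True)
class ParalogPair:
    gene_a: str
    gene_b: str
    identity_pct: float
    is_cherry: bool = True

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("pair ids must be distinct and ordered")


@dataclass
class SubfamilyPartition:
    subfamily_of: dict[str, str]
    support_of: dict[str, int | None] = field(default_factory=dict)

    def members(self, label: str) -> list[str]:
        return sorted(g for g, s in self.subfamily_of.items() if s == label)


# ---------------------------------------------------------------------------
# Affine-gap dynamic programming core


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap DP over a precomputed position-score matrix.

    Returns (score, moves) where moves is the traceback as a list of
    (consume_row, consume_col) steps from the start of both sequences.
    A gap of length L costs gap_open + (L - 1) * gap_extend.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)   # gap in columns (consumes rows)
    Iy = np.full((n + 1, m + 1), NEG)   # gap in rows (consumes columns)
    M[0, 0] = 0.0
    Ix[1:, 0] = -gap_open - gap_extend * np.arange(n)
    Iy[0, 1:] = -gap_open - gap_extend * np.arange(m)
    ext = gap_extend * np.arange(m)

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) - gap_open,
            Ix[i - 1, 1:] - gap_extend)
        # horizontal pass via the prefix-max trick
        q = np.maximum(M[i, :-1], Ix[i, :-1])
        r = q - gap_open
        r[0] = max(r[0], Iy[i, 0] - gap_extend)
        Iy[i, 1:] = np.maximum.accumulate(r + ext) - ext

    moves: list[tuple[int, int]] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    score = float([M[n, m], Ix[n, m], Iy[n, m]][state])
    while i > 0 or j > 0:
        if state == 0:
            moves.append((1, 1))
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            moves.append((1, 0))
            cand = [M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend,
                    Iy[i - 1, j] - gap_open]
            i -= 1
            state = int(np.argmax(cand))
        else:
            moves.append((0, 1))
            cand = [M[i, j - 1] - gap_open, Ix[i, j - 1] - gap_open,
                    Iy[i, j - 1] - gap_extend]
            j -= 1
            state = int(np.argmax(cand))
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    moves.reverse()
    return score, moves


def pairwise_align(a: str, b: str, substitution: str = "BLOSUM62",
                   gap_open: float = 10.0,
                   gap_extend: float = 0.5) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps.

    Identity is the percentage of identical residues among gap-free
    aligned columns.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    alphabet, sub = _load_submat(substitution)
    index = {c: i for i, c in enumerate(alphabet)}
    try:
        ai = np.array([index[c] for c in a])
        bi = np.array([index[c] for c in b])
    except KeyError as exc:
        raise ValueError(f"residue {exc} not in {substitution}") from exc
    score, moves = _affine_dp(sub[ai][:, bi], gap_open, gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for di, dj in moves:
        out_a.append(a[i] if di else "-")
        out_b.append(b[j] if dj else "-")
        i, j = i + di, j + dj
    aligned_a, aligned_b = "".join(out_a), "".join(out_b)
    return PairwiseAlignment(aligned_a, aligned_b, score,
                             alignment_identity(aligned_a, aligned_b))


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identical among gap-free aligned columns."""
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b)
             if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    same = sum(1 for x, y in pairs if x == y)
    return 100.0 * same / len(pairs)


def percent_identity(a: str, b: str, **kwargs) -> float:
    return pairwise_align(a, b, **kwargs).identity_pct


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - len(ka & kb) / denom


def _profile_counts(rows: list[str], index: dict[str, int]) -> np.ndarray:
    """(columns, alphabet+1) residue counts; last slot counts gaps."""
    n_sym = len(index) + 1
    arr = np.zeros((len(rows[0]), n_sym))
    for row in rows:
        for col, ch in enumerate(row):
            arr[col, index.get(ch, n_sym - 1)] += 1
    return arr


def _profile_align(rows_a: list[str], rows_b: list[str], sub, index,
                   gap_open: float, gap_extend: float) -> list[str]:
    """Merge two aligned blocks; sum-of-pairs column scores via matmul."""
    ca = _profile_counts(rows_a, index)
    cb = _profile_counts(rows_b, index)
    res_a, res_b = ca[:, :-1], cb[:, :-1]
    weight = np.outer(res_a.sum(axis=1), res_b.sum(axis=1))
    weight[weight == 0] = 1.0
    S = (res_a @ sub @ res_b.T) / weight
    _, moves = _affine_dp(S, gap_open, gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for di, dj in moves:
        for r, row in enumerate(rows_a):
            out_a[r].append(row[i] if di else "-")
        for r, row in enumerate(rows_b):
            out_b[r].append(row[j] if dj else "-")
        i, j = i + di, j + dj
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def build_msa(records: list[SequenceRecord], substitution: str = "BLOSUM62",
              gap_open: float = 10.0, gap_extend: float = 0.5,
              k: int = 3) -> MultipleAlignment:
    """Progressive multiple alignment with a k-mer UPGMA guide tree."""
    if len(records) == 1:
        return MultipleAlignment(list(records))
    alphabet, sub = _load_submat(substitution)
    index = {c: i for i, c in enumerate(alphabet)}

    n = len(records)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = _kmer_distance(records[i].residues, records[j].residues, k)
        dist[i, j] = dist[j, i] = d

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(n)}
    cdist = {(i, j): dist[i, j] for i, j in
             itertools.combinations(range(n), 2)}
    next_id = n
    while len(clusters) > 1:
        (ci, cj), _ = min(cdist.items(), key=lambda kv: (kv[1], kv[0]))
        members_i, rows_i = clusters.pop(ci)
        members_j, rows_j = clusters.pop(cj)
        merged = _profile_align(rows_i, rows_j, sub, index,
                                gap_open, gap_extend)
        members = members_i + members_j
        cdist = {key: v for key, v in cdist.items()
                 if ci not in key and cj not in key}
        for other, (members_o, _) in clusters.items():
            d = np.mean([dist[a, b] for a in members for b in members_o])
            cdist[(min(other, next_id), max(other, next_id))] = float(d)
        clusters[next_id] = (members, merged)
        next_id += 1

    members, rows = next(iter(clusters.values()))
    ordered = sorted(zip(members, rows))
    out = [SequenceRecord(records[i].id, records[i].description, row)
           for i, row in ordered]
    for rec, orig in zip(out, records):
        assert rec.residues.replace("-", "") == orig.residues, \
            "progressive merge corrupted a sequence"
    return MultipleAlignment(out)


# ---------------------------------------------------------------------------
# Distances


def msa_pdistance(msa: MultipleAlignment,
                  on_empty: str = "error") -> DistanceMatrix:
    """p-distance with pairwise gap deletion.

    d(i, j) = mismatches / number of columns where both rows are ungapped.
    ``on_empty`` controls pairs sharing no ungapped column: "error" raises,
    "max" assigns distance 1.0 (used by the bootstrap resampler).
    """
    rows = [r.residues for r in msa.records]
    labels = [r.id for r in msa.records]
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    arr = np.array([list(r) for r in rows])
    ungapped = arr != "-"
    n = len(rows)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ungapped[i] & ungapped[j]
        shared = int(both.sum())
        if shared == 0:
            if on_empty == "max":
                values[i, j] = values[j, i] = 1.0
                continue
            raise ValueError(
                f"rows {labels[i]!r} and {labels[j]!r} share no ungapped "
                "columns")
        mism = int((arr[i][both] != arr[j][both]).sum())
        values[i, j] = values[j, i] = mism / shared
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic label tie-breaks.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge.
    """
    if len(dm.labels) < 3:
        raise ValueError("need at least three labels")
    D = dm.values.copy()
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    reps = list(dm.labels)          # smallest leaf label under each node

    while len(nodes) > 3:
        r = len(nodes)
        net = D.sum(axis=0)
        Q = (r - 2) * D - net[:, None] - net[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min(
            (tuple(sorted((a, b))) for a, b in ties),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        dij = D[i, j]
        li = 0.5 * dij + (net[i] - net[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        na, nb = nodes[i], nodes[j]
        na.length, nb.length = max(li, 0.0), max(lj, 0.0)
        new_row = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        parent = TreeNode(children=[na, nb])
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    order = sorted(range(3), key=lambda k: reps[k])
    x, y, z = order
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    root = TreeNode()
    for k, length in ((x, lx), (y, ly), (z, lz)):
        node = nodes[k]
        node.length = max(length, 0.0)
        root.children.append(node)
    return root


def additive_tree_distances(root: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (oracle support)."""
    leaves = sorted(root.leaf_labels())
    idx = {lab: i for i, lab in enumerate(leaves)}
    n = len(leaves)
    values = np.zeros((n, n))

    def walk(node) -> dict[str, float]:
        if node.is_leaf:
            below = {node.label: 0.0}
        else:
            below = {}
            child_maps = [walk(c) for c in node.children]
            for ma, mb in itertools.combinations(child_maps, 2):
                for la, da in ma.items():
                    for lb, db in mb.items():
                        values[idx[la], idx[lb]] = values[idx[lb], idx[la]] \
                            = da + db
            for cm in child_maps:
                below.update(cm)
        return {lab: dv + (node.length or 0.0) for lab, dv in below.items()}

    walk(root)
    return DistanceMatrix(leaves, values)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(msa: MultipleAlignment, reps: int = 100,
                      seed: int = 0) -> TreeNode:
    """NJ tree from the full alignment; internal nodes annotated with the
    percentage of column-resampled replicate trees containing each
    bipartition."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    full = nj_tree(msa_pdistance(msa, on_empty="max"))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    arr = np.array([list(r.residues) for r in msa.records])
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = MultipleAlignment([
            SequenceRecord(r.id, r.description, "".join(row))
            for r, row in zip(msa.records, arr[:, cols])])
        rep_tree = nj_tree(msa_pdistance(resampled, on_empty="max"))
        for part in rep_tree.bipartitions():
            counts[part] = counts.get(part, 0) + 1
    all_leaves = frozenset(full.leaf_labels())
    for node in full.preorder():
        if node.is_leaf or node is full:
            continue
        side = frozenset(node.leaf_labels())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            node.support = None
            continue
        part = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = round(100 * counts.get(part, 0) / reps)
    return full


# ---------------------------------------------------------------------------
# Subfamilies and paralog pairs


def cut_subfamilies(tree: TreeNode, min_support: int = 50,
                    min_size: int = 2, min_stem: float = 0.05,
                    reroot: bool = True) -> SubfamilyPartition:
    """Maximal supported distal clades become subfamilies; the rest
    singletons.

    A clade qualifies when its support is at least ``min_support``, it has
    at least ``min_size`` leaves, and its stem branch is at least
    ``min_stem`` long.  The stem requirement skips near-zero edges that
    merely resolve the arbitrary arrangement of anciently diverged
    groups (such splits can reach high bootstrap support even though the
    grouping is not a cohesive family).  By default the tree is first
    rerooted on its most balanced weakly supported edge so each deep
    group forms a proper clade.
    """
    if reroot:
        from .tree import reroot_balanced_weak
        tree = reroot_balanced_weak(tree, max_support=min_support)
    assigned: dict[str, str] = {}
    support_of: dict[str, int | None] = {}
    serial = itertools.count(1)

    def visit(node: TreeNode) -> None:
        if node.is_leaf:
            return
        qualifies = (node is not tree and node.support is not None
                     and node.support >= min_support
                     and (node.length or 0.0) >= min_stem
                     and len(node.leaves()) >= min_size)
        if qualifies:
            label = f"SF{next(serial):03d}"
            support_of[label] = node.support
            for leaf in node.leaves():
                assigned[leaf.label] = label
            return
        for child in node.children:
            visit(child)

    visit(tree)
    for leaf in tree.leaves():
        if leaf.label not in assigned:
            label = f"SF{next(serial):03d}"
            assigned[leaf.label] = label
            support_of[label] = None
    return SubfamilyPartition(assigned, support_of)


def find_paralog_pairs(tree: TreeNode, identity_fn,
                       min_identity: float = 70.0,
                       mode: str = "cherry") -> list[ParalogPair]:
    """Sister leaf pairs (cherries) above an identity threshold.

    ``identity_fn(gene_a, gene_b)`` must return percent identity.  Mode
    "nearest" relaxes strict cherries to mutual nearest leaves by
    topological path length.
    """
    pairs: list[ParalogPair] = []
    if mode == "cherry":
        for node in tree.preorder():
            if len(node.children) == 2 and all(
                    c.is_leaf for c in node.children):
                a, b = sorted(c.label for c in node.children)
                ident = identity_fn(a, b)
                if ident >= min_identity:
                    pairs.append(ParalogPair(a, b, ident, True))
    elif mode == "nearest":
        leaves = tree.leaves()
        parent: dict[int, TreeNode] = {}
        for node in tree.preorder():
            for child in node.children:
                parent[id(child)] = node
        ancestor_depth: dict[str, dict[int, int]] = {}
        for leaf in leaves:
            node, d, path = leaf, 0, {}
            while id(node) in parent:
                node = parent[id(node)]
                d += 1
                path[id(node)] = d
            ancestor_depth[leaf.label] = path
        nearest: dict[str, str] = {}
        for la in leaves:
            best = None
            for lb in leaves:
                if lb.label == la.label:
                    continue
                da, db = ancestor_depth[la.label], ancestor_depth[lb.label]
                dd = min(da[k] + db[k] for k in da if k in db)
                key = (dd, lb.label)
                if best is None or key < best:
                    best = key
                    nearest[la.label] = lb.label
        for a in sorted(nearest):
            b = nearest[a]
            if a < b and nearest.get(b) == a:
                ident = identity_fn(a, b)
                if ident >= min_identity:
                    pairs.append(ParalogPair(a, b, ident, False))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))
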