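"""COI barcode comparison from first principles.

Pairwise Kimura two-parameter (K2P) distances on pre-aligned sequences,
percent identity, neighbor-joining (NJ) tree construction, and
nonparametric bootstrap supports.

The K2P model distinguishes transitions (A<->G, C<->T; proportion P over
compared sites) from transversions (proportion Q) and estimates the
substitutions-per-site distance

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)].

Sites with a gap or N in either sequence of a pair are excluded from that
pair only (pairwise deletion; a complete-deletion switch is provided).
Saturated pairs (either log argument non-positive) raise
:class:`SaturationError` rather than returning a silently large number.

NJ follows the Saitou-Nei agglomeration on the Q-criterion with a
deterministic tie-break (smallest index pair); it exactly recovers additive
distance matrices.  Negative branch lengths are clamped to zero with the
deficit moved to the sister branch.  Bootstrap supports are per-branch
bipartition percentages over column-resampled replicates, mapped onto the
full-data tree; supports below a display threshold (50% by default) are
suppressed in rendered output but retained in the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

VALID_RESIDUES = set("ACGTN-")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


class PhyloError(ValueError):
    """Invalid alignment or matrix input."""


class SaturationError(PhyloError):
    """K2P distance undefined: too many observed differences."""


@dataclass(frozen=True)
class AlignedSeq:
    """One sequence of a fixed-length alignment, residues over {A,C,G,T,N,-}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise PhyloError(f"{self.id}: illegal residues {sorted(bad)}")
        if not self.residues:
            raise PhyloError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion proportions over the compared sites of one pair."""

    P: float
    Q: float
    L: int

    def __post_init__(self) -> None:
        if self.L < 1:
            raise PhyloError("no compared sites")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise PhyloError("invalid proportions")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise PhyloError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise PhyloError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise PhyloError("nonzero diagonal")
        if (m < -1e-12).any():
            raise PhyloError("negative distances")
        self.matrix = m

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


# ---------------------------------------------------------------------------
# Alignment I/O and pairwise statistics


def read_fasta(source: Union[str, IO]) -> list[AlignedSeq]:
    """Read an aligned FASTA file; residues are uppercased and validated."""
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise PhyloError("empty FASTA input")
    seqs = [AlignedSeq(id=r.id, residues=str(r.seq).upper()) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise PhyloError(f"aligned sequences must share one length, got {sorted(lengths)}")
    return seqs


def write_fasta(seqs: Sequence[AlignedSeq], handle: IO) -> None:
    for s in seqs:
        handle.write(f">{s.id}\n{s.residues}\n")


def encode_alignment(seqs: Sequence[AlignedSeq]) -> np.ndarray:
    """Alignment as an (n_seqs, L) uint8 matrix; A,C,G,T -> 0..3, N -> 4, '-' -> 5."""
    return np.array([[_CODE[ch] for ch in s.residues] for s in seqs], dtype=np.uint8)


def _pair_counts_rows(a: np.ndarray, b: np.ndarray) -> PairCounts:
    valid = (a < 4) & (b < 4)
    L = int(valid.sum())
    if L == 0:
        raise PhyloError("no compared sites after excluding gaps and N")
    x, y = a[valid], b[valid]
    diff = x != y
    # A(0)/G(2) are even codes, C(1)/T(3) odd: a difference within one parity
    # class is a transition, across classes a transversion.
    ts = int((diff & ((x % 2) == (y % 2))).sum())
    tv = int(diff.sum()) - ts
    return PairCounts(P=ts / L, Q=tv / L, L=L)


def pair_counts(a: AlignedSeq, b: AlignedSeq) -> PairCounts:
    """Transition/transversion proportions for one pair, pairwise deletion."""
    if len(a) != len(b):
        raise PhyloError("sequences differ in length")
    enc = encode_alignment([a, b])
    return _pair_counts_rows(enc[0], enc[1])


def k2p_distance(c: PairCounts) -> float:
    """Kimura two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined for P={c.P:.4f}, Q={c.Q:.4f} (saturated pair)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(c: PairCounts) -> float:
    """Uncorrected proportion of differing compared sites."""
    return c.P + c.Q


def percent_identity(a: AlignedSeq, b: AlignedSeq) -> float:
    """Percent identical compared sites, with the same exclusion rule as pair_counts."""
    c = pair_counts(a, b)
    return 100.0 * (1.0 - c.P - c.Q)


def k2p_matrix(seqs: Sequence[AlignedSeq], deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P distance matrix.

    ``deletion`` is "pairwise" (sites dropped per pair) or "complete"
    (columns with any gap/N dropped for all pairs).
    """
    if len(seqs) < 2:
        raise PhyloError("need at least two sequences")
    enc = encode_alignment(seqs)
    if deletion == "complete":
        keep = (enc < 4).all(axis=0)
        if not keep.any():
            raise PhyloError("no columns left under complete deletion")
        enc = enc[:, keep]
    elif deletion != "pairwise":
        raise PhyloError(f"unknown deletion mode {deletion!r}")
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = k2p_distance(_pair_counts_rows(enc[i], enc[j]))
    return DistanceMatrix(ids=[s.id for s in seqs], matrix=m)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list = field(default_factory=list)  # list[(TreeNode, branch_length)]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root (basal multifurcation).

    ``support`` maps canonical bipartitions (see :func:`bipartitions`) to
    bootstrap percentages once :func:`bootstrap_support` has run.
    """

    root: TreeNode
    ids: list[str]
    support: dict = field(default_factory=dict)

    def bipartitions(self) -> dict[frozenset, float]:
        """Canonical nontrivial bipartitions mapped to their branch lengths.

        A bipartition is represented by the side not containing the
        lexicographically smallest taxon, so both orientations of an edge
        canonicalize identically.
        """
        anchor = min(self.ids)
        full = frozenset(self.ids)
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode):
            for child, length in node.children:
                side = frozenset(child.leaves())
                if 2 <= len(side) <= len(full) - 2:
                    canon = side if anchor not in side else full - side
                    out[canon] = length
                walk(child)

        walk(self.root)
        return out

    def newick(self, min_support: Optional[float] = None, decimals: int = 6) -> str:
        """Newick string; bootstrap supports rendered as internal node labels.

        Supports below ``min_support`` are suppressed in the rendering (the
        values remain available in ``self.support``).
        """
        anchor = min(self.ids)
        full = frozenset(self.ids)

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            parts = []
            for child, length in node.children:
                label = ""
                if not child.is_leaf and self.support:
                    side = frozenset(child.leaves())
                    if 2 <= len(side) <= len(full) - 2:
                        canon = side if anchor not in side else full - side
                        sup = self.support.get(canon)
                        if sup is not None and (min_support is None or sup >= min_support):
                            label = f"{sup:.0f}"
                parts.append(f"{fmt(child)}{label}:{length:.{decimals}f}")
            return "(" + ",".join(parts) + ")"

        return fmt(self.root) + ";"


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # negative NJ branch lengths: clamp to 0, move the deficit to the sister
    if la < 0:
        lb = max(lb + la, 0.0)
        la = 0.0
    if lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Agglomerates the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j,
    breaking exact ties by the smallest (i, j) index pair in the current
    node order (original taxon order, new internal nodes appended).  The
    result is an unrooted tree rooted for storage at the final three-way
    join; additive matrices are recovered exactly up to rounding.
    """
    n = len(D.ids)
    if n < 3:
        raise PhyloError("neighbor joining requires at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.ids]
    m = D.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = m[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: smallest (i, j) among exact minima
        ii, jj = min(zip(*np.where(q == qmin)))
        i, j = active[ii], active[jj]
        dij = m[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        u = m.shape[0]
        m = np.pad(m, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            m[u, a] = m[a, u] = 0.5 * (m[i, a] + m[j, a] - dij)
        active = [a for a in active if a not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (m[a, b] + m[a, c] - m[b, c])
    lb = 0.5 * (m[a, b] + m[b, c] - m[a, c])
    lc = 0.5 * (m[a, c] + m[b, c] - m[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return Tree(root=root, ids=list(D.ids))


@dataclass
class BootstrapResult:
    tree: Tree
    n_replicates: int
    n_skipped: int  # replicates dropped because a pair saturated


def bootstrap_support(
    seqs: Sequence[AlignedSeq],
    n_reps: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> BootstrapResult:
    """Nonparametric bootstrap supports mapped onto the full-data NJ tree.

    Alignment columns are resampled with replacement; each replicate is run
    through K2P + NJ and its bipartitions tallied.  Replicates in which any
    pair saturates are skipped and counted; supports are percentages over
    the successful replicates.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    full = nj_tree(k2p_matrix(seqs, deletion=deletion))
    target = set(full.bipartitions())
    counts = {bp: 0 for bp in target}
    enc = encode_alignment(seqs)
    L = enc.shape[1]
    ids = [s.id for s in seqs]
    rng = np.random.default_rng(seed)
    n_ok = 0
    n_skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        sub = enc[:, cols]
        try:
            if deletion == "complete":
                keep = (sub < 4).all(axis=0)
                if not keep.any():
                    raise SaturationError("no columns in replicate")
                sub2 = sub[:, keep]
            else:
                sub2 = sub
            k = len(seqs)
            mat = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    mat[i, j] = mat[j, i] = k2p_distance(_pair_counts_rows(sub2[i], sub2[j]))
            rep_tree = nj_tree(DistanceMatrix(ids=ids, matrix=mat))
        except (SaturationError, PhyloError):
            n_skipped += 1
            continue
        n_ok += 1
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if n_ok == 0:
        raise PhyloError("all bootstrap replicates saturated")
    full.support = {bp: 100.0 * c / n_ok for bp, c in counts.items()}
    return BootstrapResult(tree=full, n_replicates=n_ok, n_skipped=n_skipped)
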