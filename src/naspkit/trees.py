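"""Minimal distance-based tree utility: neighbor joining with newick output.

Used for cluster-pattern checks on p-distance matrices -- e.g. whether
duplicated paralogs group by subtype rather than by species.  The
agglomeration is the standard Saitou-Nei algorithm with a deterministic
tie-break (lowest taxon-index pair), negative branch lengths clamped to zero
with the deficit moved to the sibling branch, and trees represented as
:class:`skbio.TreeNode` so newick round-trips use a standard parser/writer.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from skbio import TreeNode

from naspkit.seqio import CodonAlignment, SequenceSet


class DistanceMatrix:
    """A symmetric non-negative distance matrix with taxon labels."""

    def __init__(self, taxa: TypingSequence[str], matrix):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa labels must be unique")
        m = np.asarray(matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa count")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.matrix[i, j])

    @classmethod
    def from_alignment(
        cls, aln: SequenceSet | CodonAlignment, level: str = "aa"
    ) -> "DistanceMatrix":
        """Pairwise p-distance matrix of an alignment (no bootstrap)."""
        seqs = aln.translate_rows() if (
            isinstance(aln, CodonAlignment) and level == "aa"
        ) else (aln.rows if isinstance(aln, CodonAlignment) else aln)
        rows = [s.residues for s in seqs]
        n = len(rows)
        m = np.zeros((n, n))
        length = len(rows[0])
        for i in range(n):
            for j in range(i + 1, n):
                d = sum(a != b for a, b in zip(rows[i], rows[j])) / length
                m[i, j] = m[j, i] = d
        return cls([s.id for s in seqs], m)

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            taxa = header[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(taxa) + 1:
                    raise ValueError(f"{path}: ragged distance-matrix row")
                rows.append([float(x) for x in parts[1:]])
        return cls(taxa, rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for label, row in zip(self.taxa, self.matrix):
                fh.write(label + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou-Nei) on a distance matrix.

    Returns an unrooted tree (trifurcating root for >= 3 taxa).  When several
    pairs minimize the Q criterion the pair with the lowest taxon indices is
    joined, making the output deterministic.  Negative branch lengths are
    clamped to zero and the deficit moved to the sibling branch.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # grow matrix with the new node's distances
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for m_ in active:
            if m_ in (i, j):
                continue
            d[k, m_] = d[m_, k] = 0.5 * (d[i, m_] + d[j, m_] - d[i, j])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.append(nodes[idx])
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a newick string with branch lengths."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick",
                         convert_underscores=False)


def splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the tree, each as its smaller-side-free tip set."""
    all_tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out.add(min(side, all_tips - side, key=lambda s: tuple(sorted(s))))
    return out


def same_split(tree: TreeNode, bipartition: Iterable[str]) -> bool:
    """True iff the taxon set (or its complement) is a branch of the tree."""
    tips = frozenset(t.name for t in tree.tips())
    part = frozenset(bipartition)
    unknown = part - tips
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(part) <= 1 or len(tips - part) <= 1:
        return True  # trivial splits are present in every unrooted tree
    canon = min(part, tips - part, key=lambda s: tuple(sorted(s)))
    return canon in splits(tree)
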