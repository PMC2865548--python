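"""Progressive multiple protein alignment.

The aligner follows the classic Clustal recipe: quick k-mer distances give a
guide tree (UPGMA), and profiles are merged up the tree with an affine-gap
global profile-profile dynamic program (Gotoh). Column scores between
profiles are average-of-pairs substitution scores; a gap of length k costs
``gap_open + k * gap_extend`` (the opening column is charged both).

Defaults follow the gap penalties in common use for protein work
(open 10.0, extend 0.20 per column) with BLOSUM62 scores; the Gonnet matrix
is available by name. Terminal gaps are charged by default; a flag makes
them free.

Tie-breaking in the dynamic program is deterministic: a residue/residue
column is preferred over a gap in the first input, which is preferred over
a gap in the second input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .trees import DistanceMatrix, PhyloTree, TreeNode

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_MATRIX_NAMES = {"blosum62": "BLOSUM62", "gonnet": "GONNET1992"}
_MATRIX_CACHE: dict[str, np.ndarray] = {}


def _substitution_array(name: str) -> np.ndarray:
    """20x20 substitution scores in AA_ORDER order."""
    key = name.lower()
    if key not in _MATRIX_CACHE:
        if key not in _MATRIX_NAMES:
            raise ValueError(f"unknown substitution table {name!r}; use one of {sorted(_MATRIX_NAMES)}")
        m = substitution_matrices.load(_MATRIX_NAMES[key])
        arr = np.zeros((20, 20))
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                arr[i, j] = m[a, b]
        _MATRIX_CACHE[key] = arr
    return _MATRIX_CACHE[key]


@dataclass(frozen=True)
class ScoringScheme:
    matrix: str = "blosum62"
    gap_open: float = 10.0
    gap_extend: float = 0.20
    penalize_terminal_gaps: bool = True

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        _substitution_array(self.matrix)  # validate the name eagerly

    def table(self) -> np.ndarray:
        return _substitution_array(self.matrix)

    def score(self, a: str, b: str) -> float:
        """Residue pair score; X (or any unknown) scores 0 against everything."""
        i, j = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if i is None or j is None:
            return 0.0
        return float(self.table()[i, j])


@dataclass
class Alignment:
    """Ordered gapped rows of equal length with no all-gap column."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        if self.rows and self.length:
            for col in range(self.length):
                if all(s[col] == "-" for _, s in self.rows):
                    raise ValueError(f"all-gap column at {col}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, sequence_id: str) -> str:
        for i, s in self.rows:
            if i == sequence_id:
                return s
        raise KeyError(f"unknown sequence id {sequence_id!r}")

    def ungapped(self, sequence_id: str) -> str:
        return self.row(sequence_id).replace("-", "")

    def column(self, col: int) -> list[str]:
        return [s[col] for _, s in self.rows]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for i, s in self.rows:
                fh.write(f">{i}\n{s}\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(rows=rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain (ungapped) FASTA as an id -> residues mapping, order preserved."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, s in sequences.items():
            fh.write(f">{i}\n{s}\n")


# ---------------------------------------------------------------------------
# Profile-profile dynamic program
# ---------------------------------------------------------------------------

def _column_counts(aln: Alignment) -> np.ndarray:
    """(n_columns, 20) residue counts per column; gaps and X contribute nothing."""
    counts = np.zeros((aln.length, 20))
    for _, row in aln.rows:
        for c, res in enumerate(row):
            idx = _AA_INDEX.get(res)
            if idx is not None:
                counts[c, idx] += 1
    return counts


_M, _X, _Y = 0, 1, 2  # states: both-columns, gap-in-B, gap-in-A


def _profile_dp(a: Alignment, b: Alignment, scoring: ScoringScheme) -> tuple[list[str], float]:
    """Align the column sequences of two profiles.

    Returns the merge operations ('M' pair of columns, 'X' column of ``a``
    against a gap, 'Y' column of ``b`` against a gap) and the score.
    Deterministic tie-breaking prefers M, then Y (gap in ``a``), then X.
    """
    m, n = a.length, b.length
    subs = scoring.table()
    ca, cb = _column_counts(a), _column_counts(b)
    # average-of-pairs column scores over residue pairs only
    S = (ca @ subs @ cb.T) / (a.n_rows * b.n_rows)
    go, ge = scoring.gap_open, scoring.gap_extend
    open_cost = go + ge  # opening column charges both
    lead_open, lead_ext = (open_cost, ge) if scoring.penalize_terminal_gaps else (0.0, 0.0)

    NEG = -np.inf
    V = np.full((3, m + 1, n + 1), NEG)
    V[_M, 0, 0] = 0.0
    for i in range(1, m + 1):
        V[_X, i, 0] = -(lead_open + (i - 1) * lead_ext)
    for j in range(1, n + 1):
        V[_Y, 0, j] = -(lead_open + (j - 1) * lead_ext)

    # traceback: predecessor state per (state, i, j)
    P = np.full((3, m + 1, n + 1), -1, dtype=np.int8)
    P[_X, 1:, 0] = _X
    P[_X, 1, 0] = _M
    P[_Y, 0, 1:] = _Y
    P[_Y, 0, 1] = _M

    for i in range(1, m + 1):
        Vm_prev, Vx_prev, Vy_prev = V[_M, i - 1], V[_X, i - 1], V[_Y, i - 1]
        for j in range(1, n + 1):
            # M: consume a column from each profile
            cand = (Vm_prev[j - 1], Vy_prev[j - 1], Vx_prev[j - 1])
            val = max(cand)
            for t in range(3):  # first of the preference order achieving the max
                if cand[t] == val:
                    P[_M, i, j] = (_M, _Y, _X)[t]
                    break
            V[_M, i, j] = S[i - 1, j - 1] + val
            # X: column of a against gap in b
            cand_x = (
                Vm_prev[j] - open_cost,
                V[_Y, i - 1, j] - open_cost,
                Vx_prev[j] - ge,
            )
            vx = max(cand_x)
            for t in range(3):
                if cand_x[t] == vx:
                    P[_X, i, j] = (_M, _Y, _X)[t]
                    break
            V[_X, i, j] = vx
            # Y: gap in a against column of b
            cand_y = (
                V[_M, i, j - 1] - open_cost,
                V[_Y, i, j - 1] - ge,
                V[_X, i, j - 1] - open_cost,
            )
            vy = max(cand_y)
            for t in range(3):
                if cand_y[t] == vy:
                    P[_Y, i, j] = (_M, _Y, _X)[t]
                    break
            V[_Y, i, j] = vy

    if scoring.penalize_terminal_gaps:
        end_i, end_j = m, n
        finals = (V[_M, m, n], V[_Y, m, n], V[_X, m, n])
        score = max(finals)
        state = (_M, _Y, _X)[[finals[t] == score for t in range(3)].index(True)]
        tail_ops: list[str] = []
    else:
        # free end gaps: best cell on the last row or column, pad the rest
        best = (NEG, m, n, _M)
        for j in range(n + 1):
            for t in (_M, _Y, _X):
                if V[t, m, j] > best[0]:
                    best = (V[t, m, j], m, j, t)
        for i in range(m + 1):
            for t in (_M, _Y, _X):
                if V[t, i, n] > best[0]:
                    best = (V[t, i, n], i, n, t)
        score, end_i, end_j, state = best
        tail_ops = ["X"] * (m - end_i) + ["Y"] * (n - end_j)

    ops: list[str] = []
    i, j, t = end_i, end_j, state
    while i > 0 or j > 0:
        prev = P[t, i, j]
        if t == _M:
            ops.append("M")
            i, j = i - 1, j - 1
        elif t == _X:
            ops.append("X")
            i -= 1
        else:
            ops.append("Y")
            j -= 1
        t = prev
    ops.reverse()
    ops.extend(tail_ops)
    return ops, float(score)


def profile_merge(a: Alignment, b: Alignment, scoring: ScoringScheme | None = None) -> Alignment:
    """Merge two alignments, preserving each input's columns as units; only
    full gap columns are ever inserted into a profile."""
    scoring = scoring or ScoringScheme()
    if set(a.ids) & set(b.ids):
        raise ValueError("profiles share sequence ids")
    if a.n_rows == 0 or b.n_rows == 0:
        raise ValueError("profiles must be non-empty")
    ops, _ = _profile_dp(a, b, scoring)
    rows: list[tuple[str, str]] = []
    for sid, row in a.rows:
        out, pos = [], 0
        for op in ops:
            if op in ("M", "X"):
                out.append(row[pos])
                pos += 1
            else:
                out.append("-")
        rows.append((sid, "".join(out)))
    for sid, row in b.rows:
        out, pos = [], 0
        for op in ops:
            if op in ("M", "Y"):
                out.append(row[pos])
                pos += 1
            else:
                out.append("-")
        rows.append((sid, "".join(out)))
    return Alignment(rows=rows)


def pairwise_align(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    *,
    ids: tuple[str, str] = ("a", "b"),
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under affine gap costs.

    Returns the two gapped strings and the alignment score.
    """
    scoring = scoring or ScoringScheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    pa = Alignment(rows=[(ids[0], a)])
    pb = Alignment(rows=[(ids[1], b)])
    ops, score = _profile_dp(pa, pb, scoring)
    ga, gb, ia, ib = [], [], 0, 0
    for op in ops:
        if op == "M":
            ga.append(a[ia]); gb.append(b[ib]); ia += 1; ib += 1
        elif op == "X":
            ga.append(a[ia]); gb.append("-"); ia += 1
        else:
            ga.append("-"); gb.append(b[ib]); ib += 1
    return "".join(ga), "".join(gb), score


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------

def guide_tree_distances(sequences: dict[str, str], k: int = 3) -> DistanceMatrix:
    """k-mer distance: 1 - shared / min(k-mer totals), shared counted over the
    multiset intersection. 0 for identical sequences, 1 for disjoint k-mer sets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(sequences)
    kmers: dict[str, dict[str, int]] = {}
    for sid in ids:
        seq = sequences[sid]
        if len(seq) < k:
            raise ValueError(f"sequence {sid!r} shorter than k={k}")
        counts: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            counts[w] = counts.get(w, 0) + 1
        kmers[sid] = counts
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ka, kb = kmers[ids[i]], kmers[ids[j]]
            shared = sum(min(c, kb.get(w, 0)) for w, c in ka.items())
            denom = min(sum(ka.values()), sum(kb.values()))
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return DistanceMatrix(labels=ids, values=d)


def upgma_guide_tree(distances: DistanceMatrix) -> PhyloTree:
    """Rooted guide tree by average-linkage clustering."""
    n = len(distances)
    if n == 1:
        return PhyloTree(root=TreeNode(name=distances.labels[0]), rooted=True)
    condensed = squareform(distances.values, checks=False)
    Z = linkage(condensed, method="average")
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=lab), 0.0) for i, lab in enumerate(distances.labels)
    }
    for idx, (ia, ib, height, _) in enumerate(Z):
        left, hl = nodes[int(ia)]
        right, hr = nodes[int(ib)]
        h = float(height) / 2.0
        left.length = max(h - hl, 0.0)
        right.length = max(h - hr, 0.0)
        nodes[n + idx] = (TreeNode(children=[left, right]), h)
    root, _ = nodes[n + len(Z) - 1]
    return PhyloTree(root=root, rooted=True)


def progressive_align(
    sequences: dict[str, str],
    guide_tree: PhyloTree,
    scoring: ScoringScheme | None = None,
) -> Alignment:
    """Align by post-order profile merging along the guide tree."""
    scoring = scoring or ScoringScheme()
    leaf_names = set(guide_tree.leaf_names())
    if leaf_names != set(sequences):
        raise ValueError("guide tree leaves must match sequence ids exactly")

    def build(node: TreeNode) -> Alignment:
        if node.is_leaf():
            return Alignment(rows=[(node.name, sequences[node.name])])
        result = build(node.children[0])
        for child in node.children[1:]:
            result = profile_merge(result, build(child), scoring)
        return result

    return build(guide_tree.root)


def align_sequences(
    sequences: dict[str, str],
    scoring: ScoringScheme | None = None,
    k: int = 3,
) -> Alignment:
    """Convenience: k-mer guide tree then progressive alignment."""
    scoring = scoring or ScoringScheme()
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        ((sid, seq),) = sequences.items()
        return Alignment(rows=[(sid, seq)])
    tree = upgma_guide_tree(guide_tree_distances(sequences, k=k))
    return progressive_align(sequences, tree, scoring)
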