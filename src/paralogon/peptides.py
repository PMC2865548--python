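"""Prepropeptide annotation: motif scanning and mature-peptide prediction.

Opioid prepropeptides (proenkephalin PENK, prodynorphin PDYN, proorphanin
PNOC, proopiomelanocortin POMC) share a recognisable architecture: conserved
N-terminal cysteines, one or more opioid "core" tetrapeptides (Y/FGGF, the
start of enkephalins, dynorphins, nociceptin and beta-endorphin) and, in
POMC, melanocortin HFRW motifs. Mature peptides are excised from the
precursor at dibasic prohormone-convertase sites (KK, KR, RK, RR).

This module scans precursors for such motifs, classifies core positions in
alignment context as intact / degenerate / absent (a "relic" core is one
that homologs show to be a core position but that no longer matches the
pattern), locates conserved cysteine columns, and predicts mature-peptide
intervals by the dibasic-cleavage rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .align import Alignment

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
DIBASIC = {"KK", "KR", "RK", "RR"}


@dataclass(frozen=True)
class MotifPattern:
    """Anchor pattern: one residue class (set of allowed residues) per position."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError("pattern must have length >= 2")
        if any(not p for p in self.positions):
            raise ValueError("every pattern position needs a non-empty residue class")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_string(cls, name: str, spec: str) -> "MotifPattern":
        """Build from a compact spec like ``[YF]GGF``."""
        positions: list[frozenset[str]] = []
        i = 0
        while i < len(spec):
            if spec[i] == "[":
                j = spec.index("]", i)
                positions.append(frozenset(spec[i + 1 : j]))
                i = j + 1
            else:
                positions.append(frozenset(spec[i]))
                i += 1
        return cls(name=name, positions=tuple(positions))

    def mismatches(self, window: str) -> int:
        """Mismatch count of a window against the anchor. X never matches."""
        return sum(
            1
            for residue, allowed in zip(window, self.positions)
            if residue == "X" or residue not in allowed
        )


# The opioid core anchor is the tetrapeptide Y/FGGF; the fifth residue
# (M/L/I...) distinguishes individual peptides but is variable across the
# family, so it is reported as context, not scored.
OPIOID_CORE = MotifPattern.from_string("opioid_core", "[YF]GGF")
MELANOCORTIN = MotifPattern.from_string("melanocortin", "HFRW")


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    position: int  # 0-based start
    matched_text: str
    motif_class: str  # opioid_core | melanocortin | custom
    status: str  # intact | degenerate | absent
    mismatches: int = 0
    context: str = ""  # matched window plus one trailing residue, if any

    def __post_init__(self) -> None:
        if self.mismatches == 0 and self.status not in ("intact",):
            raise ValueError("a zero-mismatch hit must be intact")
        if self.mismatches > 0 and self.status == "intact":
            raise ValueError("an intact hit must have zero mismatches")


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} (20-letter alphabet plus X)")


def scan_motifs(
    sequence: str,
    pattern: MotifPattern = OPIOID_CORE,
    max_mismatch: int = 0,
    *,
    sequence_id: str = "",
    motif_class: str | None = None,
) -> list[MotifHit]:
    """Report every window matching the anchor with at most ``max_mismatch``
    mismatches, in ascending position; overlapping hits are allowed."""
    _check_alphabet(sequence)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    k = len(pattern)
    cls = motif_class if motif_class is not None else (
        pattern.name if pattern.name in ("opioid_core", "melanocortin") else "custom"
    )
    hits: list[MotifHit] = []
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        mm = pattern.mismatches(window)
        if mm <= max_mismatch:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    position=i,
                    matched_text=window,
                    motif_class=cls,
                    status="intact" if mm == 0 else "degenerate",
                    mismatches=mm,
                    context=sequence[i : i + k + 1],
                )
            )
    return hits


def classify_core_status(
    alignment: Alignment,
    core_columns: Sequence[int],
    sequence_id: str,
    pattern: MotifPattern = OPIOID_CORE,
    max_degenerate: int = 2,
) -> str:
    """Classify one row at a set of core columns as intact/degenerate/absent.

    A site counts as a core position because homologous rows are intact
    there; this row is *intact* if it matches the pattern at every core
    column, *absent* if all core columns are gaps or the mismatch count
    exceeds ``max_degenerate``, and *degenerate* otherwise (gaps count as
    mismatches).
    """
    if len(core_columns) != len(pattern):
        raise ValueError("core_columns length must equal the pattern length")
    ncol = alignment.length
    for c in core_columns:
        if not 0 <= c < ncol:
            raise ValueError(f"core column {c} outside alignment of width {ncol}")
    row = alignment.row(sequence_id)  # raises KeyError if unknown
    residues = [row[c] for c in core_columns]
    if all(r == "-" for r in residues):
        return "absent"
    mm = sum(
        1
        for r, allowed in zip(residues, pattern.positions)
        if r == "-" or r == "X" or r not in allowed
    )
    if mm == 0:
        return "intact"
    if mm <= max_degenerate:
        return "degenerate"
    return "absent"


def find_conserved_cysteines(
    alignment: Alignment,
    min_presence: float = 1.0,
    n_terminal_limit: int | None = None,
) -> list[int]:
    """Columns where the fraction of non-gap rows that are C is >= the
    threshold (and at least one row is non-gap), optionally restricted to
    columns before ``n_terminal_limit``."""
    if alignment.n_rows == 0:
        raise ValueError("alignment has no rows")
    limit = alignment.length if n_terminal_limit is None else min(n_terminal_limit, alignment.length)
    out: list[int] = []
    for col in range(limit):
        column = [row[col] for _, row in alignment.rows]
        residues = [r for r in column if r != "-"]
        if not residues:
            continue
        if sum(1 for r in residues if r == "C") / len(residues) >= min_presence:
            out.append(col)
    return out


def predict_mature_peptides(sequence: str, hits: Iterable[MotifHit]) -> list[tuple[int, int]]:
    """Extend each intact hit to the nearest flanking dibasic cleavage sites.

    The peptide runs from just after the nearest upstream dibasic pair (or
    the N-terminus) to just before the nearest downstream dibasic pair (or
    the C-terminus); the basic residues themselves are excluded. Duplicate
    intervals (several hits in one peptide) are merged. 0-based half-open.
    """
    _check_alphabet(sequence)
    n = len(sequence)
    dibasic_starts = [i for i in range(n - 1) if sequence[i : i + 2] in DIBASIC]
    intervals: set[tuple[int, int]] = set()
    for hit in hits:
        end = hit.position + len(hit.matched_text)
        if hit.position < 0 or end > n:
            raise ValueError(f"hit at {hit.position} outside sequence of length {n}")
        if hit.status != "intact":
            continue
        left = 0
        for d in dibasic_starts:
            if d + 2 <= hit.position:
                left = max(left, d + 2)
        right = n
        for d in dibasic_starts:
            if d >= end:
                right = min(right, d)
        intervals.add((left, right))
    return sorted(intervals)


def conservation_count(
    alignment: Alignment,
    positions: Sequence[int],
    consensus: Sequence[str],
    sequence_id: str,
) -> int:
    """Number of the given columns at which the row carries the consensus
    residue (a gap never matches)."""
    if len(positions) != len(consensus):
        raise ValueError("positions and consensus must have equal length")
    for c in positions:
        if not 0 <= c < alignment.length:
            raise ValueError(f"column {c} outside alignment")
    row = alignment.row(sequence_id)
    return sum(1 for c, res in zip(positions, consensus) if row[c] == res and row[c] != "-")


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def write_motif_report(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sequence_id\tmotif_class\tposition\tmatched_text\tstatus\tmismatches\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.motif_class}\t{h.position}\t"
                f"{h.matched_text}\t{h.status}\t{h.mismatches}\n"
            )


def write_peptide_intervals(
    intervals_by_sequence: dict[str, list[tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sequence_id\tstart\tend\n")
        for seq_id in sorted(intervals_by_sequence):
            for start, end in intervals_by_sequence[seq_id]:
                fh.write(f"{seq_id}\t{start}\t{end}\n")
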