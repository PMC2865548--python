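"""Parsimony over duplication-event orderings.

A four-member gene family sitting on three chromosomes of a four-fold
paralogon — with two members adjacent on one chromosome — can be explained
by two whole-genome duplications plus one local (tandem) duplication. The
local duplication may have happened before, between, or after the two
genome doublings; each ordering predicts a different pre-loss gene layout
and therefore requires a different number of gene losses to match the
observed repertoire. The ordering requiring fewest losses is the most
parsimonious; relative-dating constraints (e.g. a duplicate pair already
present in a lineage that branched before the second doubling) can rule
orderings out regardless of loss count.

The search spaces are tiny, so every quantity here is computed by
exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

LOCAL, WGD1, WGD2 = "LOCAL", "WGD1", "WGD2"
_EVENTS = (LOCAL, WGD1, WGD2)

INFEASIBLE = None  # min_losses result for a structurally unreachable layout


@dataclass(frozen=True)
class EventOrder:
    """An ordering of {LOCAL, WGD1, WGD2} with WGD1 before WGD2."""

    events: tuple[str, str, str]

    def __post_init__(self) -> None:
        if sorted(self.events) != sorted(_EVENTS):
            raise ValueError(f"events must be a permutation of {_EVENTS}")
        if self.events.index(WGD1) > self.events.index(WGD2):
            raise ValueError("WGD1 must precede WGD2")

    def __str__(self) -> str:
        return "(" + ", ".join(self.events) + ")"

    def precedes(self, first: str, second: str) -> bool:
        return self.events.index(first) < self.events.index(second)


ALL_ORDERS = (
    EventOrder((LOCAL, WGD1, WGD2)),
    EventOrder((WGD1, LOCAL, WGD2)),
    EventOrder((WGD1, WGD2, LOCAL)),
)


@dataclass(frozen=True)
class ChromosomeClass:
    """One paralogous chromosome in an observed repertoire."""

    count: int
    adjacent_pair: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("gene count must be non-negative")
        if self.adjacent_pair and self.count < 2:
            raise ValueError("an adjacent pair needs at least two genes")


@dataclass(frozen=True)
class ObservedRepertoire:
    """Per-chromosome-class gene counts and same-family adjacency flags.

    Chromosome classes are unlabeled: the parsimony search minimizes over
    all assignments of predicted chromosomes to observed classes.
    """

    classes: tuple[ChromosomeClass, ...]

    @classmethod
    def from_counts(cls, counts: Sequence[int], adjacent: Sequence[bool] | None = None) -> "ObservedRepertoire":
        adjacent = adjacent or [False] * len(counts)
        return cls(tuple(ChromosomeClass(c, a) for c, a in zip(counts, adjacent)))

    @property
    def total(self) -> int:
        return sum(c.count for c in self.classes)


# The observed layout of the four opioid prepropeptide genes on the ancestral
# (chicken-like) chromosome arrangement: one gene alone, an adjacent
# same-family pair on one chromosome, one more gene alone, and one
# paralogous chromosome with no surviving family member.
OPIOID_OBSERVED = ObservedRepertoire.from_counts([1, 2, 1, 0], [False, True, False, False])


@dataclass(frozen=True)
class Constraint:
    """Relative-dating feasibility statement: ``before`` must precede ``after``."""

    before: str
    after: str
    note: str = ""

    def __post_init__(self) -> None:
        for ev in (self.before, self.after):
            if ev not in _EVENTS:
                raise ValueError(f"constraint references unknown event {ev!r}")

    def satisfied_by(self, order: EventOrder) -> bool:
        return order.precedes(self.before, self.after)


# ---------------------------------------------------------------------------
# Pre-loss layout prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictedChromosome:
    """Genes on one predicted chromosome; ``pair`` marks a tandem-adjacent
    pair (the first two genes) produced by the local duplication."""

    genes: int
    pair: bool

    @property
    def max_retainable_adjacent(self) -> bool:
        return self.pair


def expected_repertoire(order: EventOrder, dup_choice: int = 0) -> tuple[PredictedChromosome, ...]:
    """Pre-loss layout predicted by an event ordering.

    Starts from one gene on one chromosome. A genome doubling duplicates
    every chromosome with its contents; the local duplication adds one
    adjacent copy of the gene indexed by ``dup_choice`` (counted over genes
    present at that moment; the choice matters only for bookkeeping since
    all copies are equivalent by symmetry).
    """
    chroms: list[list[bool]] = [[False]]  # per chromosome: per gene, paired flag
    for ev in order.events:
        if ev in (WGD1, WGD2):
            chroms = [list(c) for c in chroms] + [list(c) for c in chroms]
        else:
            flat = [(ci, gi) for ci, genes in enumerate(chroms) for gi in range(len(genes))]
            ci, gi = flat[dup_choice % len(flat)]
            chroms[ci][gi] = True
            chroms[ci].insert(gi + 1, True)
    return tuple(
        PredictedChromosome(genes=len(c), pair=any(c)) for c in chroms
    )


def _chromosome_feasible_losses(pred: PredictedChromosome, obs: ChromosomeClass) -> int | None:
    """Minimum losses to turn one predicted chromosome into one observed
    class, or None if impossible."""
    if obs.count > pred.genes:
        return None
    if obs.adjacent_pair:
        # must retain the tandem pair: needs one, and both its genes kept
        if not pred.pair or obs.count < 2:
            return None
        return pred.genes - obs.count
    # no adjacency observed: if keeping >= 2 genes would force keeping the
    # pair adjacent, the assignment is impossible
    if obs.count >= 2 and pred.pair and pred.genes - obs.count < 1 and pred.genes == 2:
        return None
    if obs.count >= 2 and pred.pair:
        # keeping obs.count of pred.genes genes without both pair members:
        # possible iff there are enough non-pair genes plus at most one pair member
        non_pair = pred.genes - 2
        if obs.count > non_pair + 1:
            return None
    return pred.genes - obs.count


def min_losses(order: EventOrder, observed: ObservedRepertoire) -> int | None:
    """Minimum gene deletions mapping the predicted pre-loss layout onto the
    observed repertoire, minimized exhaustively over chromosome assignments
    and over which gene was locally duplicated. ``None`` if unreachable."""
    best: int | None = None
    # enumerate the (symmetric) choices of locally duplicated gene
    n_choices = {0: 1, 1: 2, 2: 4}[order.events.index(LOCAL)]
    for dup_choice in range(n_choices):
        predicted = expected_repertoire(order, dup_choice)
        n = len(predicted)
        obs_classes = list(observed.classes)
        # pad with empty classes so every predicted chromosome maps somewhere
        while len(obs_classes) < n:
            obs_classes.append(ChromosomeClass(0))
        if len(obs_classes) > n:
            return None  # more observed chromosome classes than predicted
        for perm in itertools.permutations(range(n)):
            total = 0
            ok = True
            for pi, oi in enumerate(perm):
                losses = _chromosome_feasible_losses(predicted[pi], obs_classes[oi])
                if losses is None:
                    ok = False
                    break
                total += losses
            if ok and (best is None or total < best):
                best = total
    return best


@dataclass(frozen=True)
class RankedScenario:
    order: EventOrder
    losses: int | None
    feasible: bool
    violated: tuple[str, ...] = ()


def rank_scenarios(
    orders: Sequence[EventOrder],
    observed: ObservedRepertoire,
    constraints: Sequence[Constraint] = (),
) -> list[RankedScenario]:
    """Rank orderings by required losses; constraint violations are flagged
    infeasible but still reported with their loss counts. Feasible orders
    come first, ascending by losses, ties in input order; infeasible orders
    follow in input order."""
    results: list[RankedScenario] = []
    for order in orders:
        losses = min_losses(order, observed)
        violated = tuple(
            c.note or f"{c.before} precedes {c.after}"
            for c in constraints
            if not c.satisfied_by(order)
        )
        feasible = not violated and losses is not None
        results.append(RankedScenario(order=order, losses=losses, feasible=feasible, violated=violated))
    feasible_part = [r for r in results if r.feasible]
    infeasible_part = [r for r in results if not r.feasible]
    feasible_part.sort(key=lambda r: r.losses)  # stable: ties keep input order
    return feasible_part + infeasible_part


def write_ranking(ranking: Iterable[RankedScenario], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\torder\tlosses\tfeasible\tconstraint_notes\n")
        for i, r in enumerate(ranking, start=1):
            losses = "infeasible" if r.losses is None else str(r.losses)
            fh.write(
                f"{i}\t{'>'.join(r.order.events)}\t{losses}\t"
                f"{'yes' if r.feasible else 'no'}\t{'; '.join(r.violated)}\n"
            )
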