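"""Synthetic genome evolution with a complete, replayable truth log.

The simulator produces the data structures the downstream analyses assume a
real vertebrate history would leave behind: an ancestral chromosome set
carrying gene families, one or more rounds of whole-genome duplication (the
two early-vertebrate rounds, "2R", plus an optional teleost-branch third
round, "3R"), an optional local (tandem) duplication, per-gene stochastic
loss, lineage-specific translocations, and residue substitution along a
species tree. Selected families can carry a planted peptide-motif cassette
(e.g. the opioid core YGGFM) whose sites may be protected from substitution.

Every event is appended to a :class:`TruthLog`; replaying the log from the
ancestral state reproduces each extant genome and sequence set exactly,
which is the basis of the recovery tests downstream.

Coordinates follow :mod:`paralogon.genome` (0-based half-open). Substitution
uses a single fixed symmetric exchangeability table (uniform over the 19
alternative residues); there is no rate heterogeneity and no indel process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np

from .genome import GeneRecord, Genome, write_gene_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_TANDEM_OFFSET = 50_000  # bp between a tandem duplicate and its template
DEFAULT_GENE_LENGTH = 1_000  # bp footprint of a simulated gene
DEFAULT_GENE_SPACING = 1_000_000  # bp between gene starts on an ancestral chromosome
DEFAULT_SEQ_LENGTH = 120  # residues of a simulated precursor

EVENT_KINDS = (
    "ANCESTOR",
    "WGD",
    "LOSS",
    "LOCAL_DUP",
    "TRANSLOCATION",
    "SPECIATION",
    "SUBSTITUTION_EPOCH",
)


# ---------------------------------------------------------------------------
# Truth log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    kind: str
    branch: str
    params: dict[str, Any] = field(default_factory=dict)
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class TruthLog:
    """Ordered event history; replaying it reproduces the extant genomes."""

    master_seed: int
    events: list[Event] = field(default_factory=list)

    def append(self, event: Event) -> None:
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# master_seed={self.master_seed}\n")
            fh.write("kind\tbranch\tgene_ids\tparams\n")
            for e in self.events:
                fh.write(
                    f"{e.kind}\t{e.branch}\t{','.join(e.gene_ids)}\t"
                    f"{json.dumps(e.params, sort_keys=True)}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "TruthLog":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if not header.startswith("# master_seed="):
                raise ValueError(f"{path}: missing master_seed header")
            seed = int(header.split("=", 1)[1])
            fh.readline()  # column header
            events = []
            for line in fh:
                kind, branch, ids, params = line.rstrip("\n").split("\t")
                events.append(
                    Event(
                        kind=kind,
                        branch=branch,
                        params=json.loads(params),
                        gene_ids=tuple(i for i in ids.split(",") if i),
                    )
                )
        return cls(master_seed=seed, events=events)


def _stream(master_seed: int, counter: int) -> np.random.Generator:
    """Deterministic child RNG stream for one event."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(counter,)))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CassetteSpec:
    """A peptide-motif cassette planted in the root sequences of some families.

    ``pattern`` is the exact residue string inserted ``copies`` times,
    separated by random linker residues. When ``protected`` is set the
    cassette positions are shielded from substitution so motif-recovery
    tests have an exact ground truth.
    """

    pattern: str = "YGGFM"
    copies: int = 7
    families: tuple[str, ...] = ()
    protected: bool = True
    linker: int = 6  # residues between consecutive cassette copies

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("cassette pattern must be non-empty")
        if self.copies < 1:
            raise ValueError("cassette copies must be >= 1")


@dataclass
class BranchSpec:
    """One branch of the species tree: a name, a substitution epoch length
    (substitutions/site), an ordered event list, and child branches."""

    name: str
    length: float = 0.0
    events: list[dict[str, Any]] = field(default_factory=list)
    children: list["BranchSpec"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"branch {self.name}: negative length")

    @classmethod
    def from_dict(cls, spec: dict[str, Any]) -> "BranchSpec":
        if "name" not in spec:
            raise ValueError("branch spec missing 'name'")
        return cls(
            name=str(spec["name"]),
            length=float(spec.get("length", 0.0)),
            events=list(spec.get("events", [])),
            children=[cls.from_dict(c) for c in spec.get("children", [])],
        )

    def leaf_names(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class SimulationConfig:
    seed: int
    tree: BranchSpec
    n_chromosomes: int = 4
    families_per_chromosome: int = 10
    sequence_length: int = DEFAULT_SEQ_LENGTH
    cassette: CassetteSpec | None = None
    retention_prob: float = 0.7
    tandem_offset: int = DEFAULT_TANDEM_OFFSET

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0, 1]")

    @classmethod
    def from_dict(cls, spec: dict[str, Any]) -> "SimulationConfig":
        cassette = None
        if spec.get("cassette"):
            c = dict(spec["cassette"])
            if "families" in c:
                c["families"] = tuple(c["families"])
            cassette = CassetteSpec(**c)
        return cls(
            seed=int(spec["seed"]),
            tree=BranchSpec.from_dict(spec["tree"]),
            n_chromosomes=int(spec.get("n_chromosomes", 4)),
            families_per_chromosome=int(spec.get("families_per_chromosome", 10)),
            sequence_length=int(spec.get("sequence_length", DEFAULT_SEQ_LENGTH)),
            cassette=cassette,
            retention_prob=float(spec.get("retention_prob", 0.7)),
            tandem_offset=int(spec.get("tandem_offset", DEFAULT_TANDEM_OFFSET)),
        )


# ---------------------------------------------------------------------------
# Lineage state
# ---------------------------------------------------------------------------

@dataclass
class LineageState:
    """Genome plus sequences (and protected sites) of one lineage."""

    genome: Genome
    sequences: dict[str, str]
    protected: dict[str, frozenset[int]] = field(default_factory=dict)

    def clone(self, species: str) -> "LineageState":
        genome = Genome(
            species=species,
            genes=[replace(g, species=species) for g in self.genome.genes],
            chromosome_lengths=dict(self.genome.chromosome_lengths),
        )
        return LineageState(genome=genome, sequences=dict(self.sequences), protected=dict(self.protected))


# ---------------------------------------------------------------------------
# Ancestral genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _plant_cassette(rng: np.random.Generator, length: int, cassette: CassetteSpec) -> tuple[str, frozenset[int]]:
    """Build a root sequence containing exactly ``copies`` cassette occurrences.

    Rejection-samples the random flanks/linkers until no chance occurrence
    inflates the count, so the planted count is exact by construction.
    """
    m, k = cassette.pattern, cassette.copies
    body_len = k * len(m) + (k - 1) * cassette.linker
    if body_len > length:
        raise ValueError("cassette does not fit in the sequence length")
    lead = (length - body_len) // 2
    tail = length - body_len - lead
    for _ in range(1000):
        parts = [_random_sequence(rng, lead)]
        positions = []
        pos = lead
        for i in range(k):
            positions.append(pos)
            parts.append(m)
            pos += len(m)
            if i < k - 1:
                parts.append(_random_sequence(rng, cassette.linker))
                pos += cassette.linker
        parts.append(_random_sequence(rng, tail))
        seq = "".join(parts)
        if seq.count(m) == k:
            protected = frozenset(p + j for p in positions for j in range(len(m)))
            return seq, protected
    raise RuntimeError("could not plant cassette without chance duplicates")


def make_ancestral_genome(
    n_chromosomes: int,
    families_per_chromosome: int,
    cassette: CassetteSpec | None = None,
    seed: int = 0,
    *,
    sequence_length: int = DEFAULT_SEQ_LENGTH,
    species: str = "ancestor",
    log: TruthLog | None = None,
) -> LineageState:
    """Create the pre-duplication ancestor: one gene per family, laid out in
    order on each chromosome with disjoint intervals; deterministic given seed."""
    if n_chromosomes < 1 or families_per_chromosome < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    genes: list[GeneRecord] = []
    sequences: dict[str, str] = {}
    protected: dict[str, frozenset[int]] = {}
    lengths: dict[str, int] = {}
    fam_index = 0
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        lengths[chrom] = (families_per_chromosome + 1) * DEFAULT_GENE_SPACING
        for i in range(families_per_chromosome):
            family = f"fam{fam_index:03d}"
            gene_id = f"{family}.0"
            start = (i + 1) * DEFAULT_GENE_SPACING
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    species=species,
                    chromosome=chrom,
                    start=start,
                    end=start + DEFAULT_GENE_LENGTH,
                    strand="+",
                    family_id=family,
                )
            )
            if cassette is not None and family in cassette.families:
                seq, prot = _plant_cassette(rng, sequence_length, cassette)
                sequences[gene_id] = seq
                if cassette.protected:
                    protected[gene_id] = prot
            else:
                sequences[gene_id] = _random_sequence(rng, sequence_length)
            fam_index += 1
    genome = Genome(species=species, genes=genes, chromosome_lengths=lengths)
    genome.validate()
    if log is not None:
        log.append(
            Event(
                kind="ANCESTOR",
                branch=species,
                params={
                    "n_chromosomes": n_chromosomes,
                    "families_per_chromosome": families_per_chromosome,
                    "sequence_length": sequence_length,
                    "seed": seed,
                    "cassette": None
                    if cassette is None
                    else {
                        "pattern": cassette.pattern,
                        "copies": cassette.copies,
                        "families": list(cassette.families),
                        "protected": cassette.protected,
                        "linker": cassette.linker,
                    },
                },
            )
        )
    return LineageState(genome=genome, sequences=sequences, protected=protected)


# ---------------------------------------------------------------------------
# Evolutionary operators
# ---------------------------------------------------------------------------

def apply_wgd(state: LineageState, label: str, *, log: TruthLog | None = None, branch: str = "") -> LineageState:
    """Whole-genome duplication: every chromosome (and its gene content) is
    copied wholesale; the copy carries a ``-<label>`` suffix. Gene and
    chromosome counts exactly double."""
    genome = state.genome
    if len(genome) == 0:
        raise ValueError("cannot duplicate an empty genome")
    new_genes = list(genome.genes)
    new_lengths = dict(genome.chromosome_lengths)
    new_seqs = dict(state.sequences)
    new_protected = dict(state.protected)
    copied: list[str] = []
    for chrom in genome.chromosomes():
        dup_chrom = f"{chrom}-{label}"
        new_lengths[dup_chrom] = genome.chromosome_lengths[chrom]
        for g in genome.genes_on(chrom):
            dup_id = f"{g.gene_id}-{label}"
            new_genes.append(replace(g, gene_id=dup_id, chromosome=dup_chrom))
            new_seqs[dup_id] = state.sequences[g.gene_id]
            if g.gene_id in state.protected:
                new_protected[dup_id] = state.protected[g.gene_id]
            copied.append(dup_id)
    out = Genome(species=genome.species, genes=new_genes, chromosome_lengths=new_lengths)
    out.validate()
    if log is not None:
        log.append(Event(kind="WGD", branch=branch or genome.species, params={"label": label}, gene_ids=tuple(copied)))
    return LineageState(genome=out, sequences=new_seqs, protected=new_protected)


def apply_losses(
    state: LineageState,
    retention_prob: float,
    seed: int,
    *,
    log: TruthLog | None = None,
    branch: str = "",
    _stream_counter: int | None = None,
    _master_seed: int | None = None,
    _forced_deletions: Sequence[str] | None = None,
) -> LineageState:
    """Delete each gene independently with probability ``1 - retention_prob``."""
    if not 0.0 <= retention_prob <= 1.0:
        raise ValueError("retention probability must be in [0, 1]")
    genome = state.genome
    if _forced_deletions is not None:
        deleted = set(_forced_deletions)
    else:
        if _stream_counter is not None and _master_seed is not None:
            rng = _stream(_master_seed, _stream_counter)
        else:
            rng = np.random.default_rng(seed)
        keep = rng.random(len(genome.genes)) < retention_prob
        deleted = {g.gene_id for g, k in zip(genome.genes, keep) if not k}
    new_genes = [g for g in genome.genes if g.gene_id not in deleted]
    new_seqs = {k: v for k, v in state.sequences.items() if k not in deleted}
    new_protected = {k: v for k, v in state.protected.items() if k not in deleted}
    out = Genome(species=genome.species, genes=new_genes, chromosome_lengths=dict(genome.chromosome_lengths))
    if log is not None:
        log.append(
            Event(
                kind="LOSS",
                branch=branch or genome.species,
                params={"retention_prob": retention_prob, "seed": seed},
                gene_ids=tuple(sorted(deleted)),
            )
        )
    return LineageState(genome=out, sequences=new_seqs, protected=new_protected)


def apply_local_duplication(
    state: LineageState,
    gene_id: str,
    *,
    tandem_offset: int = DEFAULT_TANDEM_OFFSET,
    log: TruthLog | None = None,
    branch: str = "",
) -> LineageState:
    """Tandem duplication: insert a same-family copy immediately downstream of
    the template, within ``tandem_offset`` bp; downstream genes shift right to
    preserve non-overlap."""
    genome = state.genome
    template = genome.gene(gene_id)  # raises KeyError for unknown ids
    dup_id = f"{gene_id}-tdup"
    n = 1
    while dup_id in genome:
        n += 1
        dup_id = f"{gene_id}-tdup{n}"
    gap = max(1, min(tandem_offset - template.length, tandem_offset // 2))
    new_start = template.end + gap
    duplicate = replace(template, gene_id=dup_id, start=new_start, end=new_start + template.length)
    # every downstream gene shifts by a constant, preserving spacing
    shift = duplicate.end - template.end
    shifted_genes: list[GeneRecord] = []
    for g in genome.genes:
        if g.chromosome == template.chromosome and g.start >= template.end:
            shifted_genes.append(g.moved(start=g.start + shift))
        else:
            shifted_genes.append(g)
    shifted_genes.append(duplicate)
    lengths = dict(genome.chromosome_lengths)
    lengths[template.chromosome] += shift
    out = Genome(species=genome.species, genes=shifted_genes, chromosome_lengths=lengths)
    out.validate()
    new_seqs = dict(state.sequences)
    new_seqs[dup_id] = state.sequences[gene_id]
    new_protected = dict(state.protected)
    if gene_id in state.protected:
        new_protected[dup_id] = state.protected[gene_id]
    if log is not None:
        log.append(
            Event(
                kind="LOCAL_DUP",
                branch=branch or genome.species,
                params={"template": gene_id, "tandem_offset": tandem_offset},
                gene_ids=(dup_id,),
            )
        )
    return LineageState(genome=out, sequences=new_seqs, protected=new_protected)


def apply_translocation(
    state: LineageState,
    source_chromosome: str,
    interval: tuple[int, int],
    target_chromosome: str,
    *,
    log: TruthLog | None = None,
    branch: str = "",
) -> LineageState:
    """Move genes whose start lies in ``interval`` (half-open) from the source
    chromosome to the end of the target chromosome, preserving relative order.
    An interval containing no genes is a logged no-op."""
    genome = state.genome
    for chrom in (source_chromosome, target_chromosome):
        if chrom not in genome.chromosome_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
    lo, hi = interval
    if lo > hi or lo < 0 or hi > genome.chromosome_lengths[source_chromosome]:
        raise ValueError("interval outside source chromosome")
    moving = [
        g
        for g in sorted(genome.genes_on(source_chromosome), key=lambda g: g.start)
        if lo <= g.start < hi
    ]
    moving_ids = [g.gene_id for g in moving]
    target_genes = genome.genes_on(target_chromosome)
    cursor = max((g.end for g in target_genes), default=0) + DEFAULT_GENE_SPACING
    relocated: dict[str, GeneRecord] = {}
    for g in moving:
        relocated[g.gene_id] = g.moved(chromosome=target_chromosome, start=cursor)
        cursor += g.length + DEFAULT_GENE_SPACING
    new_genes = [relocated.get(g.gene_id, g) for g in genome.genes]
    lengths = dict(genome.chromosome_lengths)
    lengths[target_chromosome] = max(lengths[target_chromosome], cursor)
    out = Genome(species=genome.species, genes=new_genes, chromosome_lengths=lengths)
    out.validate()
    if log is not None:
        log.append(
            Event(
                kind="TRANSLOCATION",
                branch=branch or genome.species,
                params={
                    "source": source_chromosome,
                    "interval": [int(lo), int(hi)],
                    "target": target_chromosome,
                },
                gene_ids=tuple(moving_ids),
            )
        )
    return LineageState(genome=out, sequences=dict(state.sequences), protected=dict(state.protected))


def evolve_sequences(
    sequences: dict[str, str],
    branch_length: float,
    seed: int,
    protected_sites: dict[str, frozenset[int]] | None = None,
    *,
    _stream_counter: int | None = None,
    _master_seed: int | None = None,
) -> dict[str, str]:
    """Substitute residues along a branch.

    The number of substitution events per sequence is Poisson with mean
    ``branch_length * len(sequence)``; event positions are uniform over the
    unprotected sites (a site may be hit more than once); the replacement is
    drawn uniformly from the 19 residues differing from the current one.
    """
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    if branch_length == 0:
        return dict(sequences)
    if _stream_counter is not None and _master_seed is not None:
        rng = _stream(_master_seed, _stream_counter)
    else:
        rng = np.random.default_rng(seed)
    protected_sites = protected_sites or {}
    out: dict[str, str] = {}
    for gene_id in sorted(sequences):
        seq = list(sequences[gene_id])
        prot = protected_sites.get(gene_id, frozenset())
        free = [i for i in range(len(seq)) if i not in prot]
        n_events = rng.poisson(branch_length * len(seq))
        if free:
            for _ in range(n_events):
                pos = free[rng.integers(len(free))]
                current = seq[pos]
                alternatives = [a for a in AMINO_ACIDS if a != current]
                seq[pos] = alternatives[rng.integers(len(alternatives))]
        out[gene_id] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# History simulation and replay
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    genomes: dict[str, Genome]
    sequences: dict[str, dict[str, str]]  # species -> gene_id -> residues
    protected: dict[str, dict[str, frozenset[int]]]
    log: TruthLog


def _apply_branch_event(
    state: LineageState,
    ev: dict[str, Any],
    branch: str,
    config: SimulationConfig,
    log: TruthLog | None,
    counter: int,
) -> LineageState:
    kind = str(ev["kind"]).lower()
    if kind == "wgd":
        return apply_wgd(state, label=str(ev.get("label", "dup")), log=log, branch=branch)
    if kind == "loss":
        p = float(ev.get("retention", config.retention_prob))
        return apply_losses(
            state, p, seed=counter, log=log, branch=branch,
            _stream_counter=counter, _master_seed=config.seed,
        )
    if kind == "local_dup":
        return apply_local_duplication(
            state, str(ev["gene_id"]),
            tandem_offset=int(ev.get("tandem_offset", config.tandem_offset)),
            log=log, branch=branch,
        )
    if kind == "translocation":
        return apply_translocation(
            state, str(ev["source"]), (int(ev["interval"][0]), int(ev["interval"][1])),
            str(ev["target"]), log=log, branch=branch,
        )
    raise ValueError(f"unknown branch event kind {ev.get('kind')!r}")


def simulate_history(config: SimulationConfig) -> SimulationResult:
    """Run the configured history down the species tree.

    Each branch applies its event list in order, then undergoes a
    substitution epoch of its branch length. Fully deterministic given
    ``config.seed``; the returned truth log replays exactly (see
    :func:`replay_log`).
    """
    log = TruthLog(master_seed=config.seed)
    root_state = make_ancestral_genome(
        config.n_chromosomes,
        config.families_per_chromosome,
        config.cassette,
        seed=config.seed,
        sequence_length=config.sequence_length,
        species=config.tree.name,
        log=log,
    )
    results: dict[str, LineageState] = {}
    counter = [1]  # stream 0 used by the ancestor

    def walk(node: BranchSpec, state: LineageState) -> None:
        for ev in node.events:
            c = counter[0]
            counter[0] += 1
            state = _apply_branch_event(state, ev, node.name, config, log, c)
        if node.length > 0:
            c = counter[0]
            counter[0] += 1
            new_seqs = evolve_sequences(
                state.sequences, node.length, seed=c,
                protected_sites=state.protected,
                _stream_counter=c, _master_seed=config.seed,
            )
            log.append(
                Event(
                    kind="SUBSTITUTION_EPOCH",
                    branch=node.name,
                    params={"branch_length": node.length, "stream": c},
                )
            )
            state = LineageState(genome=state.genome, sequences=new_seqs, protected=state.protected)
        if node.children:
            log.append(
                Event(
                    kind="SPECIATION",
                    branch=node.name,
                    params={"children": [c.name for c in node.children]},
                )
            )
            for child in node.children:
                walk(child, state.clone(child.name))
        else:
            results[node.name] = state

    walk(config.tree, root_state.clone(config.tree.name))
    return SimulationResult(
        genomes={s: st.genome for s, st in results.items()},
        sequences={s: st.sequences for s, st in results.items()},
        protected={s: st.protected for s, st in results.items()},
        log=log,
    )


def replay_log(log: TruthLog) -> SimulationResult:
    """Rebuild every extant genome and sequence set from the truth log alone.

    Loss events replay from their recorded gene ids (exact); substitution
    epochs replay from their recorded stream numbers and the master seed.
    """
    if not log.events or log.events[0].kind != "ANCESTOR":
        raise ValueError("log must start with an ANCESTOR event")
    anc = log.events[0]
    p = anc.params
    cassette = None
    if p.get("cassette"):
        c = dict(p["cassette"])
        c["families"] = tuple(c["families"])
        cassette = CassetteSpec(**c)
    root = make_ancestral_genome(
        p["n_chromosomes"],
        p["families_per_chromosome"],
        cassette,
        seed=p["seed"],
        sequence_length=p["sequence_length"],
        species=anc.branch,
    )
    states: dict[str, LineageState] = {anc.branch: root.clone(anc.branch)}
    speciated: set[str] = set()
    for ev in log.events[1:]:
        state = states[ev.branch]
        if ev.kind == "WGD":
            states[ev.branch] = apply_wgd(state, ev.params["label"], branch=ev.branch)
        elif ev.kind == "LOSS":
            states[ev.branch] = apply_losses(
                state, ev.params["retention_prob"], seed=0,
                branch=ev.branch, _forced_deletions=ev.gene_ids,
            )
        elif ev.kind == "LOCAL_DUP":
            states[ev.branch] = apply_local_duplication(
                state, ev.params["template"],
                tandem_offset=ev.params["tandem_offset"], branch=ev.branch,
            )
        elif ev.kind == "TRANSLOCATION":
            states[ev.branch] = apply_translocation(
                state, ev.params["source"],
                (ev.params["interval"][0], ev.params["interval"][1]),
                ev.params["target"], branch=ev.branch,
            )
        elif ev.kind == "SUBSTITUTION_EPOCH":
            new_seqs = evolve_sequences(
                state.sequences, ev.params["branch_length"], seed=0,
                protected_sites=state.protected,
                _stream_counter=ev.params["stream"], _master_seed=log.master_seed,
            )
            states[ev.branch] = LineageState(state.genome, new_seqs, state.protected)
        elif ev.kind == "SPECIATION":
            speciated.add(ev.branch)
            for child in ev.params["children"]:
                states[child] = states[ev.branch].clone(child)
        else:  # pragma: no cover - EVENT_KINDS guards this
            raise ValueError(f"cannot replay event kind {ev.kind!r}")
    extant = {s: st for s, st in states.items() if s not in speciated}
    return SimulationResult(
        genomes={s: st.genome for s, st in extant.items()},
        sequences={s: st.sequences for s, st in extant.items()},
        protected={s: st.protected for s, st in extant.items()},
        log=log,
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def sequence_label(species: str, gene_id: str, chromosome: str) -> str:
    """Leaf-name convention used in FASTA and newick output."""
    return f"{species}|{gene_id}|{chromosome}"


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write gene tables (TSV), per-species protein FASTA and the truth log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gene_table = outdir / "genes.tsv"
    write_gene_table([result.genomes[s] for s in sorted(result.genomes)], gene_table)
    paths["gene_table"] = gene_table
    for species in sorted(result.genomes):
        fasta = outdir / f"{species}.fasta"
        with open(fasta, "w", encoding="utf-8", newline="\n") as fh:
            for g in result.genomes[species].genes:
                label = sequence_label(species, g.gene_id, g.chromosome)
                fh.write(f">{label}\n{result.sequences[species][g.gene_id]}\n")
        paths[f"fasta:{species}"] = fasta
    log_path = outdir / "truth_log.tsv"
    result.log.write(log_path)
    paths["truth_log"] = log_path
    return paths
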