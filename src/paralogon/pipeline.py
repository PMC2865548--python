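"""Configured, logged, deterministic orchestration of the full analysis.

Stages: simulate -> annotate -> align -> tree -> synteny -> scenarios.
Every stage reads only declared inputs or files written by earlier stages,
and all randomness derives from the single configured seed, so two runs of
the same configuration produce bit-identical data artifacts. A manifest
records a SHA-256 checksum for every emitted data file (the free-running
log and the manifest itself are excluded, since timings are not
reproducible).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import peptides as pep
from .align import Alignment, ScoringScheme, align_sequences, read_fasta
from .genome import genomes_from_frame, read_gene_table
from .phylo import bootstrap_support
from .scenarios import (
    ALL_ORDERS,
    Constraint,
    ObservedRepertoire,
    rank_scenarios,
    write_ranking,
)
from .simulate import SimulationConfig, sequence_label, simulate_history, write_outputs
from .synteny import Region, build_synteny_table, family_presence, quartet_completeness, select_families

STAGES = ("simulate", "annotate", "align", "tree", "synteny", "scenarios")

log = logging.getLogger("paralogon")


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "paralogon_out"
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    bootstrap_replicates: int = 1000
    flank: int = 10_000_000  # bp around anchor genes for interval regions
    min_chromosomes: int = 3
    motif_pattern: str = "[YF]GGF"
    motif_max_mismatch: int = 0
    max_align_families: int = 8
    reference_species: str | None = None
    candidate_chromosomes: list[str] | None = None
    simulation: dict[str, Any] | None = None
    gene_table: str | None = None
    fasta: list[str] = field(default_factory=list)
    scenario_observed: dict[str, Any] | None = None
    scenario_constraints: list[dict[str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        scoring = ScoringScheme(**raw.get("scoring", {}))
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "paralogon_out")),
            scoring=scoring,
            bootstrap_replicates=int(raw.get("bootstrap_replicates", 1000)),
            flank=int(raw.get("flank", 10_000_000)),
            min_chromosomes=int(raw.get("min_chromosomes", 3)),
            motif_pattern=str(raw.get("motif", {}).get("pattern", "[YF]GGF")),
            motif_max_mismatch=int(raw.get("motif", {}).get("max_mismatch", 0)),
            max_align_families=int(raw.get("max_align_families", 8)),
            reference_species=raw.get("reference_species"),
            candidate_chromosomes=list(raw["candidate_chromosomes"]) if raw.get("candidate_chromosomes") else None,
            simulation=raw.get("simulation"),
            gene_table=raw.get("gene_table"),
            fasta=list(raw.get("fasta", [])),
            scenario_observed=raw.get("scenario", {}).get("observed"),
            scenario_constraints=list(raw.get("scenario", {}).get("constraints", [])),
        )


def validate_inputs(config: RunConfig) -> list[str]:
    """Collect every configuration problem rather than failing at the first."""
    errors: list[str] = []
    if config.simulation is None and config.gene_table is None:
        errors.append("either a simulation block or a gene_table input is required")
    if config.simulation is not None:
        try:
            SimulationConfig.from_dict({**config.simulation, "seed": config.seed})
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(f"simulation config invalid: {exc}")
    if config.gene_table is not None:
        if not Path(config.gene_table).exists():
            errors.append(f"gene table not found: {config.gene_table}")
        else:
            try:
                read_gene_table(config.gene_table)
            except ValueError as exc:
                errors.append(str(exc))
    for fasta in config.fasta:
        if not Path(fasta).exists():
            errors.append(f"FASTA not found: {fasta}")
        else:
            try:
                for sid, seq in read_fasta(fasta).items():
                    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX-")
                    if bad:
                        errors.append(f"{fasta}:{sid}: illegal residues {sorted(bad)}")
            except ValueError as exc:
                errors.append(f"{fasta}: {exc}")
    if config.bootstrap_replicates < 0:
        errors.append("bootstrap_replicates must be non-negative")
    if config.min_chromosomes < 1:
        errors.append("min_chromosomes must be >= 1")
    try:
        pep.MotifPattern.from_string("configured", config.motif_pattern)
    except (ValueError, IndexError) as exc:
        errors.append(f"motif pattern invalid: {exc}")
    return errors


@dataclass
class ReportBundle:
    output_dir: Path
    files: dict[str, Path]
    manifest_path: Path
    quartet_summary: dict[str, Any] = field(default_factory=dict)

    def checksum(self, key: str) -> str:
        return _sha256(self.files[key])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, files: dict[str, Path], config_digest: str) -> Path:
    manifest = {
        "config_sha256": config_digest,
        "files": {
            key: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p), "bytes": p.stat().st_size}
            for key, p in sorted(files.items())
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages in order; abort on a stage error with upstream
    outputs preserved and a stage marker for resumption."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    files: dict[str, Path] = {}
    marker = outdir / "STAGE"

    problems = validate_inputs(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))

    config_digest = hashlib.sha256(
        json.dumps(
            {k: v for k, v in vars(config).items() if k not in ("scoring", "output_dir")}
            | {"scoring": vars(config.scoring)},
            sort_keys=True, default=str,
        ).encode()
    ).hexdigest()

    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            _run_stage(stage, config, outdir, files)
            marker.write_text(stage + "\n", encoding="utf-8")
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    except Exception:
        log.exception("pipeline aborted at stage %r; upstream outputs preserved", marker.read_text().strip() if marker.exists() else "(none)")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest_path = _write_manifest(outdir, files, config_digest)
    bundle = ReportBundle(output_dir=outdir, files=files, manifest_path=manifest_path)
    summary_path = outdir / "synteny" / "quartet_summary.json"
    if summary_path.exists():
        bundle.quartet_summary = json.loads(summary_path.read_text(encoding="utf-8"))
    return bundle


def _run_stage(stage: str, config: RunConfig, outdir: Path, files: dict[str, Path]) -> None:
    if stage == "simulate":
        _stage_simulate(config, outdir, files)
    elif stage == "annotate":
        _stage_annotate(config, outdir, files)
    elif stage == "align":
        _stage_align(config, outdir, files)
    elif stage == "tree":
        _stage_tree(config, outdir, files)
    elif stage == "synteny":
        _stage_synteny(config, outdir, files)
    elif stage == "scenarios":
        _stage_scenarios(config, outdir, files)


def _stage_simulate(config: RunConfig, outdir: Path, files: dict[str, Path]) -> None:
    if config.simulation is None:
        log.info("no simulation block; using declared inputs")
        return
    sim_config = SimulationConfig.from_dict({**config.simulation, "seed": config.seed})
    result = simulate_history(sim_config)
    paths = write_outputs(result, outdir / "simulate")
    for key, p in paths.items():
        files[f"simulate/{key}"] = p
    log.info(
        "simulated %d species, %d genes total",
        len(result.genomes),
        sum(len(g) for g in result.genomes.values()),
    )


def _gather_sequences(config: RunConfig, outdir: Path) -> dict[str, str]:
    """All input sequences labeled species|gene_id|chromosome (simulated) or
    by FASTA id (declared inputs)."""
    seqs: dict[str, str] = {}
    if config.simulation is not None:
        sim_dir = outdir / "simulate"
        for fasta in sorted(sim_dir.glob("*.fasta")):
            seqs.update(read_fasta(fasta))
    for fasta in config.fasta:
        seqs.update(read_fasta(fasta))
    return seqs


def _gene_table(config: RunConfig, outdir: Path) -> pd.DataFrame:
    if config.simulation is not None:
        return read_gene_table(outdir / "simulate" / "genes.tsv")
    assert config.gene_table is not None
    return read_gene_table(config.gene_table)


def _stage_annotate(config: RunConfig, outdir: Path, files: dict[str, Path]) -> None:
    seqs = _gather_sequences(config, outdir)
    pattern = pep.MotifPattern.from_string("opioid_core", config.motif_pattern)
    stage_dir = outdir / "annotate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    hits = []
    intervals: dict[str, list[tuple[int, int]]] = {}
    for sid in sorted(seqs):
        seq_hits = pep.scan_motifs(
            seqs[sid], pattern, config.motif_max_mismatch, sequence_id=sid
        )
        hits.extend(seq_hits)
        if seq_hits:
            intervals[sid] = pep.predict_mature_peptides(seqs[sid], seq_hits)
    report = stage_dir / "motif_report.tsv"
    pep.write_motif_report(hits, report)
    files["annotate/motif_report"] = report
    peptide_report = stage_dir / "peptides.tsv"
    pep.write_peptide_intervals(intervals, peptide_report)
    files["annotate/peptides"] = peptide_report
    log.info("annotated %d motif hits in %d sequences", len(hits), len(seqs))


def _families_to_align(config: RunConfig, table: pd.DataFrame) -> list[str]:
    fams = sorted(set(table["family_id"].astype(str)))
    cassette_fams: list[str] = []
    if config.simulation and config.simulation.get("cassette"):
        cassette_fams = [f for f in config.simulation["cassette"].get("families", []) if f in fams]
    rest = [f for f in fams if f not in cassette_fams]
    return (cassette_fams + rest)[: config.max_align_families]


def _family_sequences(table: pd.DataFrame, family: str, seqs: dict[str, str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for row in table.itertuples():
        if str(row.family_id) != family:
            continue
        label = sequence_label(str(row.species), str(row.gene_id), str(row.chromosome))
        if label in seqs:
            out[label] = seqs[label]
    return out


def _stage_align(config: RunConfig, outdir: Path, files: dict[str, Path]) -> None:
    table = _gene_table(config, outdir)
    seqs = _gather_sequences(config, outdir)
    stage_dir = outdir / "align"
    stage_dir.mkdir(parents=True, exist_ok=True)
    for family in _families_to_align(config, table):
        fam_seqs = _family_sequences(table, family, seqs)
        if len(fam_seqs) < 2:
            continue
        aln = align_sequences(fam_seqs, config.scoring)
        path = stage_dir / f"{family}.aln.fasta"
        aln.write_fasta(path)
        files[f"align/{family}"] = path
    log.info("aligned %d families", len([k for k in files if k.startswith('align/')]))


def _stage_tree(config: RunConfig, outdir: Path, files: dict[str, Path]) -> None:
    stage_dir = outdir / "tree"
    stage_dir.mkdir(parents=True, exist_ok=True)
    aln_dir = outdir / "align"
    for i, path in enumerate(sorted(aln_dir.glob("*.aln.fasta"))):
        aln = Alignment.read_fasta(path)
        if aln.n_rows < 3:
            continue
        tree = bootstrap_support(
            aln, config.bootstrap_replicates, seed=config.seed + 7919 * (i + 1)
        )
        family = path.name.replace(".aln.fasta", "")
        out = stage_dir / f"{family}.nwk"
        tree.write(out)
        files[f"tree/{family}"] = out
    log.info("built %d trees", len([k for k in files if k.startswith('tree/')]))


def _stage_synteny(config: RunConfig, outdir: Path, files: dict[str, Path]) -> None:
    table = _gene_table(config, outdir)
    stage_dir = outdir / "synteny"
    stage_dir.mkdir(parents=True, exist_ok=True)
    species_list = sorted(set(table["species"].astype(str)))
    reference = config.reference_species or species_list[0]
    ref_table = table[table["species"].astype(str) == reference]
    if config.candidate_chromosomes:
        candidates = list(config.candidate_chromosomes)
    else:
        candidates = sorted(set(ref_table["chromosome"].astype(str)))
    regions = {c: Region(chromosome=c, whole_chromosome=True) for c in candidates}
    presence = family_presence(ref_table, regions)
    selected = select_families(presence, config.min_chromosomes)
    per_family, n_full = quartet_completeness(selected, presence)
    selected_path = stage_dir / "selected_families.tsv"
    with open(selected_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("family_id\tn_chromosomes\tfull_quartet\n")
        for fam in selected:
            n, flag = per_family[fam]
            fh.write(f"{fam}\t{n}\t{'yes' if flag else 'no'}\n")
    files["synteny/selected_families"] = selected_path
    summary = {
        "reference_species": reference,
        "candidate_chromosomes": candidates,
        "n_selected": len(selected),
        "n_full_quartets": n_full,
    }
    summary_path = stage_dir / "quartet_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    files["synteny/quartet_summary"] = summary_path

    # ortholog groups: genes sharing an identifier across species (the
    # shared-name convention; for real data supply curated groups instead)
    groups: dict[str, list[str]] = {}
    for row in table.itertuples():
        groups.setdefault(str(row.gene_id), []).append(f"{row.gene_id}@{row.species}")
    tables = build_synteny_table(table, groups, reference, candidates)
    for sp in sorted(tables):
        path = stage_dir / f"paralogon_{sp}.tsv"
        tables[sp].write(path)
        files[f"synteny/paralogon_{sp}"] = path
    log.info("synteny: %d families selected, %d full quartets", len(selected), n_full)


def _stage_scenarios(config: RunConfig, outdir: Path, files: dict[str, Path]) -> None:
    stage_dir = outdir / "scenarios"
    stage_dir.mkdir(parents=True, exist_ok=True)
    if config.scenario_observed is None:
        observed = ObservedRepertoire.from_counts([1, 2, 1, 0], [False, True, False, False])
    else:
        observed = ObservedRepertoire.from_counts(
            config.scenario_observed["counts"],
            config.scenario_observed.get("adjacent"),
        )
    constraints = [Constraint(**c) for c in config.scenario_constraints]
    ranking = rank_scenarios(ALL_ORDERS, observed, constraints)
    path = stage_dir / "scenario_ranking.tsv"
    write_ranking(ranking, path)
    files["scenarios/ranking"] = path
    log.info("ranked %d scenarios", len(ranking))
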