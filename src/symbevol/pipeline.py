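"""End-to-end orchestration: simulate or load genomes, align, cluster,
triage statuses, reconstruct the ancestor, compare lineage losses, and
optionally test selection on shared pseudogenes — as one reproducible run
with a machine-readable summary and a content-hash MANIFEST.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as gio
from .align import ScoringConfig
from .ancestor import (
    AncestralReconstruction,
    assign_lineage_events,
    call_ancestral,
    compare_loss_counts,
    mobile_excluded_families,
)
from .families import (
    FamilyPartition,
    StateMatrix,
    all_vs_all_align,
    best_hit_edges,
    build_state_matrix,
    cluster,
)
from .kaks import kaks_pair, purifying_verdict
from .records import GenomeSet, SpeciesTree
from .simulate import EvolutionConfig, TruthTable, emit, simulate
from .status import apply_status_rules, write_status_calls

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_dir`` points at an emitted/curated genome directory, or
    ``simulation`` holds an :class:`EvolutionConfig` to generate one.
    """

    input_dir: Optional[str] = None
    simulation: Optional[EvolutionConfig] = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    clade_presence: str = "any"
    loss_test: str = "2x2"
    compare_lineages: Optional[tuple[str, str]] = None
    run_kaks: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        scoring = raw.pop("scoring", None)
        cfg = cls(**raw)
        if sim is not None:
            if "clades" in sim:
                sim["clades"] = {k: set(v) for k, v in sim["clades"].items()}
            if "ingroup" in sim:
                sim["ingroup"] = tuple(sim["ingroup"])
            cfg.simulation = EvolutionConfig(**sim)
        if scoring is not None:
            cfg.scoring = ScoringConfig(**scoring)
        return cfg


@dataclass
class PipelineResult:
    genomeset: GenomeSet
    tree: Optional[SpeciesTree]
    hits: list
    partition: FamilyPartition
    status_calls: list
    state_matrix: StateMatrix
    reconstruction: AncestralReconstruction
    kaks_table: list[dict]
    truth: Optional[TruthTable] = None
    summary: dict = field(default_factory=dict)


def run(config: RunConfig, outdir: Optional[str | Path] = None) -> PipelineResult:
    """Execute the full pipeline; identical config and seed give an
    identical bundle. Stage failures abort with the failing stage named."""
    stage = "input"
    try:
        truth = None
        tree = None
        if config.simulation is not None:
            stage = "simulate"
            sim = config.simulation
            if config.seed and not sim.seed:
                sim.seed = config.seed
            genomeset, truth = simulate(sim)
            tree = SpeciesTree.from_newick(sim.tree_newick)
        elif config.input_dir is not None:
            genomeset = gio.load_genome_set(config.input_dir)
            tree_path = Path(config.input_dir) / "tree.nwk"
            if tree_path.exists():
                tree = gio.read_tree(tree_path, genomeset)
        else:
            raise ValueError("RunConfig needs input_dir or simulation")

        stage = "align"
        hits = all_vs_all_align(genomeset, config.scoring)
        has_hit: dict[str, bool] = {}
        for h in hits:
            has_hit[h.query_id] = True
            has_hit[h.subject_id] = True

        stage = "cluster"
        all_ids = [r.gene_id for r in genomeset.all_records()]
        # provisional partition for the family-relative rules
        edges = best_hit_edges(hits, genomeset)
        partition = cluster(edges, all_ids)

        stage = "classify"
        status_calls = apply_status_rules(
            genomeset, partition, has_hit, scoring=config.scoring
        )
        # artifacts leave the partition
        non_artifacts = [
            r.gene_id for r in genomeset.all_records() if r.status != "artifact"
        ]
        keep = set(non_artifacts)
        partition = cluster(
            [e for e in edges if e[0] in keep and e[1] in keep], non_artifacts
        )

        stage = "state_matrix"
        state_matrix = build_state_matrix(partition, genomeset)

        stage = "ancestor"
        lineages = genomeset.lineages()
        excluded = mobile_excluded_families(partition, genomeset)
        calls = call_ancestral(
            state_matrix,
            lineages,
            genomeset.outgroup_ids,
            excluded,
            config.clade_presence,
        )
        events = assign_lineage_events(
            calls, state_matrix, lineages, genomeset.outgroup_ids
        )
        pair = config.compare_lineages or tuple(sorted(lineages))[:2]
        comparison = compare_loss_counts(events, pair[0], pair[1], config.loss_test)
        reconstruction = AncestralReconstruction(calls, events, comparison)

        stage = "kaks"
        kaks_table = (
            shared_pseudogene_kaks(genomeset, partition, state_matrix)
            if config.run_kaks
            else []
        )

        stage = "summary"
        summary = {
            "seed": config.seed,
            "genomes": genomeset.genome_ids,
            "genes": len(all_ids),
            "hits": len(hits),
            "families": len(partition),
            "artifacts": len(all_ids) - len(non_artifacts),
            "ancestral_families": len(reconstruction.ancestral_families),
            "ancestrally_inactivated": len(reconstruction.ancestrally_inactivated),
            "mobile_excluded": len(reconstruction.excluded_families),
            "lineage_counts": {
                lin: events.counts(lin) for lin in sorted(lineages)
            },
            "loss_comparison": json.loads(comparison.to_json()),
            "kaks_pairs": len(kaks_table),
        }
        result = PipelineResult(
            genomeset,
            tree,
            hits,
            partition,
            status_calls,
            state_matrix,
            reconstruction,
            kaks_table,
            truth,
            summary,
        )
        if outdir is not None:
            stage = "report"
            write_bundle(result, outdir, config)
        return result
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


def shared_pseudogene_kaks(
    genomeset: GenomeSet,
    partition: FamilyPartition,
    state_matrix: StateMatrix,
) -> list[dict]:
    """Ka/Ks for families pseudogenized in every ingroup genome.

    For each such family the longest pseudogene member of each ingroup
    lineage is paired across the first two lineages; a ratio below one
    indicates the shared pseudogene still evolves under purifying
    selection (i.e. it was inactivated recently or the pair predates the
    inactivation)."""
    lineages = genomeset.lineages()
    if len(lineages) < 2:
        return []
    lin_a, lin_b = sorted(lineages)[:2]
    idx = genomeset.gene_index()
    rows: list[dict] = []
    for fid in state_matrix.family_ids:
        ingroup_states = [
            state_matrix.state(fid, g) for g in genomeset.ingroup_ids
        ]
        if not all(s == "pseudogene" for s in ingroup_states):
            continue

        def pick(lineage_genomes: set[str]):
            members = [
                idx[g]
                for g in partition.members(fid)
                if idx[g].genome_id in lineage_genomes
                and idx[g].nt_seq is not None
            ]
            return max(members, key=lambda r: (len(r.nt_seq), r.gene_id), default=None)

        a = pick(lineages[lin_a])
        b = pick(lineages[lin_b])
        if a is None or b is None:
            continue
        try:
            res = kaks_pair(a.nt_seq, b.nt_seq)
        except ValueError:
            continue
        rows.append(
            {
                "family_id": fid,
                "gene_a": a.gene_id,
                "gene_b": b.gene_id,
                "verdict": purifying_verdict(res),
                **res.row(),
            }
        )
    return rows


def write_bundle(result: PipelineResult, outdir: str | Path, config: RunConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_hits(result.hits, outdir / "hits.tsv")
    result.partition.write_tsv(outdir / "families.tsv")
    write_status_calls(result.status_calls, outdir / "status_calls.tsv")
    result.state_matrix.write_tsv(outdir / "state_matrix.tsv")
    result.reconstruction.write_calls_tsv(outdir / "ancestral_calls.tsv")
    result.reconstruction.events.write_tsv(outdir / "lineage_events.tsv")
    with open(outdir / "ancestrally_inactivated.txt", "w", newline="\n") as fh:
        for fid in result.reconstruction.ancestrally_inactivated:
            fh.write(fid + "\n")
    if result.reconstruction.comparison is not None:
        with open(outdir / "loss_comparison.json", "w", newline="\n") as fh:
            fh.write(result.reconstruction.comparison.to_json() + "\n")
    if result.kaks_table:
        keys = list(result.kaks_table[0])
        with open(outdir / "kaks.tsv", "w", newline="\n") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in result.kaks_table:
                fh.write("\t".join(str(row[k]) for k in keys) + "\n")
    if result.truth is not None and config.simulation is not None:
        emit(result.genomeset, result.truth, result.tree, outdir / "input")
    with open(outdir / "summary.json", "w", newline="\n") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.txt", "w", newline="\n") as fh:
        fh.write(result.reconstruction.summary() + "\n")
    manifest = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "MANIFEST.json":
            manifest[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    with open(outdir / "MANIFEST.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
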