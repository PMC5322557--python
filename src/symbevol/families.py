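"""Ortholog family construction by best-hit transitive closure.

Each protein is searched against all proteins of the other genomes; every
gene is attached to its single best hit in each other genome (ties broken
deterministically), and families are the connected components of the
resulting undirected best-hit graph. Two genes of one genome may share a
family — this is what reunites fragments of one gene and recent duplicates.
The per-genome family states (intact / pseudogene / absent) summarise the
partition into the presence table the downstream reconstruction consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .align import (
    UNGAPPED_SCREEN_BITS,
    ScoringConfig,
    _substring_fast_path,
    best_ungapped_segment,
    bitscore,
    encode_protein,
    evalue,
    local_align,
    make_aligner,
    seed_candidates,
    segment_alignment,
)
from .records import GenomeSet, SimilarityHit

log = logging.getLogger(__name__)


class FamilyPartition:
    """Disjoint grouping of gene ids into families.

    Families are named ``FAM#####`` in a deterministic order (by the
    lexicographically smallest member). Singleton families are genes with no
    qualifying best-hit edge.
    """

    def __init__(self, families: dict[str, set[str]]) -> None:
        self.families = families
        self.gene_to_family: dict[str, str] = {}
        for fid, members in families.items():
            for g in members:
                if g in self.gene_to_family:
                    raise ValueError(f"gene {g} assigned to two families")
                self.gene_to_family[g] = fid

    @classmethod
    def from_components(cls, components: Iterable[set[str]]) -> "FamilyPartition":
        ordered = sorted((sorted(c) for c in components), key=lambda c: c[0])
        return cls({f"FAM{i:05d}": set(c) for i, c in enumerate(ordered)})

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.families)

    def members(self, family_id: str) -> set[str]:
        return self.families[family_id]

    def family_of(self, gene_id: str) -> str:
        return self.gene_to_family[gene_id]

    def as_labeling(self) -> dict[str, str]:
        return dict(self.gene_to_family)

    def __len__(self) -> int:
        return len(self.families)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("family_id\tgene_id\n")
            for fid in self.family_ids:
                for g in sorted(self.families[fid]):
                    fh.write(f"{fid}\t{g}\n")


def all_vs_all_align(
    genomeset: GenomeSet,
    config: Optional[ScoringConfig] = None,
    exclude_artifacts: bool = True,
) -> list[SimilarityHit]:
    """Cross-genome all-vs-all local protein search.

    Ordered gene pairs of different genomes that share at least
    ``config.min_shared_seeds`` distinct ``seed_k``-mers are aligned
    (BLOSUM62, affine gaps); hits passing both the bit-score floor and the
    e-value ceiling are reported, ordered by query id, then descending
    bitscore, then subject id. Both hit directions are emitted, mirroring a
    reciprocal database search.
    """
    config = config or ScoringConfig()
    records = [
        r
        for r in genomeset.all_records()
        if not (exclude_artifacts and r.status == "artifact")
    ]
    for r in records:
        if r.aa_seq is None:
            raise ValueError(f"{r.gene_id}: amino-acid sequence required for alignment")
    seqs = {r.gene_id: r.aa_seq for r in records}
    genome_of = {r.gene_id: r.genome_id for r in records}
    # letters per genome, to build per-query effective database sizes
    letters: dict[str, int] = {}
    for r in records:
        letters[r.genome_id] = letters.get(r.genome_id, 0) + len(r.aa_seq)
    total_letters = sum(letters.values())

    aligner = make_aligner(config, mode="local")
    pairs = seed_candidates(seqs, config.seed_k, config.min_shared_seeds)
    log.info("all-vs-all: %d genes, %d seeded pairs", len(seqs), len(pairs))
    encoded = {gid: encode_protein(s) for gid, s in seqs.items()}

    hits: list[SimilarityHit] = []
    n_screened = 0
    for a, b in sorted(pairs):
        if genome_of[a] == genome_of[b]:
            continue
        fast = _substring_fast_path(seqs[a], seqs[b])
        segment = None
        if fast is None:
            # cheap ungapped extension along the seeded diagonals decides
            # whether the pair deserves full dynamic programming
            segment = best_ungapped_segment(encoded[a], encoded[b], pairs[(a, b)])
            if bitscore(segment[0]) < UNGAPPED_SCREEN_BITS:
                n_screened += 1
                continue
            score = aligner.score(seqs[a], seqs[b])
        else:
            score = fast.score
        bits = bitscore(score)
        if bits < config.min_bitscore:
            continue
        detail = None
        for q, s in ((a, b), (b, a)):
            db = total_letters - letters[genome_of[q]]
            ev = evalue(score, len(seqs[q]), db)
            if ev > config.max_evalue:
                continue
            if detail is None:
                if fast is not None:
                    detail = fast
                elif segment is not None and segment[0] == score:
                    # the gapped optimum is the ungapped segment itself
                    detail = segment_alignment(encoded[a], encoded[b], segment)
                else:
                    detail = local_align(seqs[a], seqs[b], aligner)
            if q == a:
                qs, qe, ss, se = detail.qstart, detail.qend, detail.sstart, detail.send
            else:
                qs, qe, ss, se = detail.sstart, detail.send, detail.qstart, detail.qend
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    identity_pct=round(detail.identity_pct, 2),
                    aln_length=detail.aln_length,
                    mismatches=detail.mismatches,
                    gap_opens=detail.gap_opens,
                    qstart=qs,
                    qend=qe,
                    sstart=ss,
                    send=se,
                    evalue=ev,
                    bitscore=round(bits, 2),
                )
            )
    hits.sort(key=lambda h: (h.query_id, -h.bitscore, h.subject_id))
    return hits


def best_hit_edges(
    hits: Iterable[SimilarityHit], genomeset: GenomeSet
) -> list[tuple[str, str]]:
    """One undirected edge per (query gene, other genome): the best hit.

    Best = maximal bitscore; ties broken by lower e-value, then higher
    identity, then lexicographically smallest subject id.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, genomeset.genome_of(h.subject_id))
        cur = best.get(key)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[key] = h
    edges = {tuple(sorted((h.query_id, h.subject_id))) for h in best.values()}
    return sorted(edges)


def _hit_rank(h: SimilarityHit) -> tuple:
    return (-h.bitscore, h.evalue, -h.identity_pct, h.subject_id)


def cluster(
    edges: Iterable[tuple[str, str]], genes: Iterable[str]
) -> FamilyPartition:
    """Families = connected components of the best-hit graph (transitive
    closure of co-membership); genes with no edge form singletons. The result
    is independent of edge order."""
    parent: dict[str, str] = {g: g for g in genes}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in edges:
        if a not in parent or b not in parent:
            raise ValueError(f"edge ({a}, {b}) references unknown gene")
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic union: smaller label becomes the root
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra
    comps: dict[str, set[str]] = {}
    for g in parent:
        comps.setdefault(find(g), set()).add(g)
    return FamilyPartition.from_components(comps.values())


STATE_TOKENS = {"intact": "Intact", "pseudogene": "Pseudogene", "absent": "Absent"}


@dataclass
class StateMatrix:
    """family x genome table of {intact, pseudogene, absent} states.

    A cell is ``intact`` when the family has at least one intact member in
    that genome (intact dominates pseudogene), ``pseudogene`` when it has
    only pseudogene members there, ``absent`` otherwise. Members still
    ``unclassified`` after triage count as putatively intact (the annotation
    default for a full-length CDS); artifacts are never counted.
    """

    genome_ids: list[str]
    states: dict[tuple[str, str], str] = field(default_factory=dict)
    member_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def family_ids(self) -> list[str]:
        return sorted({f for f, _ in self.states})

    def state(self, family_id: str, genome_id: str) -> str:
        return self.states.get((family_id, genome_id), "absent")

    def count(self, family_id: str, genome_id: str) -> int:
        return self.member_counts.get((family_id, genome_id), 0)

    def present(self, family_id: str, genome_id: str) -> bool:
        return self.state(family_id, genome_id) != "absent"

    def fragmented(self, family_id: str, genome_id: str) -> bool:
        return self.count(family_id, genome_id) > 1

    def write_tsv(self, path) -> None:
        """Table-style report: one genome per column, tokens
        Intact/Pseudogene/Absent, with a Fragmented marker where a family has
        several members in one genome."""
        with open(path, "w", newline="\n") as fh:
            fh.write("family_id\t" + "\t".join(self.genome_ids) + "\n")
            for fid in self.family_ids:
                row = [fid]
                for g in self.genome_ids:
                    tok = STATE_TOKENS[self.state(fid, g)]
                    if self.fragmented(fid, g):
                        tok += " (Fg)"
                    row.append(tok)
                fh.write("\t".join(row) + "\n")


def build_state_matrix(
    partition: FamilyPartition, genomeset: GenomeSet
) -> StateMatrix:
    """Summarise finalized gene statuses into per-genome family states."""
    sm = StateMatrix(genome_ids=genomeset.genome_ids)
    idx = genomeset.gene_index()
    for fid in partition.family_ids:
        per_genome: dict[str, list[str]] = {}
        for gid in partition.members(fid):
            rec = idx[gid]
            if rec.status == "artifact":
                continue
            per_genome.setdefault(rec.genome_id, []).append(rec.status)
        for genome, statuses in per_genome.items():
            if any(s in ("intact", "unclassified") for s in statuses):
                state = "intact"
            elif any(s == "pseudogene" for s in statuses):
                state = "pseudogene"
            else:  # pragma: no cover - statuses exhaust the options
                continue
            sm.states[(fid, genome)] = state
            sm.member_counts[(fid, genome)] = len(statuses)
    return sm
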