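"""Annotation triage: artifact filtering, the relative-length pseudogene
rule with its domain exception, the 5'-start rescue, and the contig-edge
rule.

The rules run in a fixed order — artifacts first (they must not pollute the
family-relative comparisons), then the 80% length rule within each family,
then the 5' start-codon rescue for 5'-truncated pseudogenes, then the
contig-edge override (missing sequence, not mutation, explains a short gene
broken by a contig edge). Re-application is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .align import ScoringConfig, local_align, make_aligner
from .families import FamilyPartition
from .records import GeneRecord, GenomeSet, STOP_CODONS

log = logging.getLogger(__name__)

RULES = (
    "artifact_short_no_evidence",
    "length_lt_80",
    "domain_exception",
    "five_prime_rescue",
    "contig_edge_active",
    "no_change",
)

ALT_STARTS = ("ATG", "GTG", "TTG")  # standard bacterial start codons

#: strict threshold of the relative-length pseudogene rule
LENGTH_RATIO_THRESHOLD = 0.8
#: strict amino-acid length below which an unsupported gene is an artifact
ARTIFACT_LENGTH = 100


@dataclass
class StatusCall:
    gene_id: str
    old_status: str
    new_status: str
    rule_fired: str
    reference_length: Optional[float] = None
    length_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rule_fired not in RULES:
            raise ValueError(f"unknown rule {self.rule_fired!r}")
        if self.rule_fired == "length_lt_80":
            assert self.length_ratio is not None and self.length_ratio < 0.8


def flag_artifacts(
    genes: Iterable[GeneRecord], has_hit: dict[str, bool]
) -> list[StatusCall]:
    """Mark short unsupported genes as artifacts.

    A gene becomes an artifact iff its protein is strictly shorter than 100
    amino acids AND it has no significant similarity hit AND it carries no
    annotated domain. All other genes are untouched.
    """
    calls: list[StatusCall] = []
    for g in genes:
        if g.aa_seq is None:
            raise ValueError(f"{g.gene_id}: amino-acid sequence required")
        if (
            g.aa_length < ARTIFACT_LENGTH
            and not has_hit.get(g.gene_id, False)
            and not g.domains
        ):
            calls.append(
                StatusCall(g.gene_id, g.status, "artifact", "artifact_short_no_evidence")
            )
            g.status = "artifact"
        else:
            calls.append(StatusCall(g.gene_id, g.status, g.status, "no_change"))
    return calls


def classify_pseudogenes(
    members: list[GeneRecord],
) -> list[StatusCall]:
    """Apply the relative-length rule within one family.

    The reference length is the median protein length of the family's
    intact members; for each member only members of *other* genomes count
    as references. A member shorter than 80% (strictly) of its reference
    becomes a pseudogene — unless it preserves every ancestral domain
    (domain ids shared by all of its intact references), in which case it
    stays intact. Members with no cross-genome intact reference are left
    unchanged (logged, not an error).
    """
    calls: list[StatusCall] = []
    candidates = [m for m in members if m.status != "artifact"]
    for m in candidates:
        refs = [
            r
            for r in candidates
            if r.genome_id != m.genome_id and r.status == "intact"
        ]
        if not refs:
            log.debug("%s: no cross-genome intact reference, left unchanged", m.gene_id)
            calls.append(StatusCall(m.gene_id, m.status, m.status, "no_change"))
            continue
        ref_len = _median([float(r.aa_length) for r in refs])
        ratio = m.aa_length / ref_len
        if ratio < LENGTH_RATIO_THRESHOLD:
            ancestral_domains = frozenset.intersection(
                *[r.domain_ids for r in refs]
            )
            if ancestral_domains and ancestral_domains <= m.domain_ids:
                # a truncated copy that kept every ancestral domain is not
                # demoted; an unclassified member is confirmed intact
                calls.append(
                    StatusCall(m.gene_id, m.status, "intact", "domain_exception", ref_len, ratio)
                )
                m.status = "intact"
            else:
                calls.append(
                    StatusCall(m.gene_id, m.status, "pseudogene", "length_lt_80", ref_len, ratio)
                )
                m.status = "pseudogene"
        else:
            calls.append(
                StatusCall(m.gene_id, m.status, m.status, "no_change", ref_len, ratio)
            )
    return calls


def _median(values: list[float]) -> float:
    values = sorted(values)
    n = len(values)
    mid = n // 2
    return values[mid] if n % 2 else 0.5 * (values[mid - 1] + values[mid])


def truncation_side(
    gene: GeneRecord, reference: GeneRecord, config: Optional[ScoringConfig] = None
) -> Optional[str]:
    """Which end of the reference is missing from a truncated member.

    Returns ``"5prime"`` when the local alignment covers the reference's
    3' end but not its 5' end, ``"3prime"`` for the converse, and ``None``
    when coverage is ambiguous (both ends missing or neither).
    """
    aligner = make_aligner(config or ScoringConfig(), mode="local")
    aln = local_align(gene.aa_seq, reference.aa_seq, aligner)
    ref_len = reference.aa_length
    missing5 = aln.sstart - 1
    missing3 = ref_len - aln.send
    tol = max(5, int(0.05 * ref_len))
    if missing5 > tol and missing3 <= tol:
        return "5prime"
    if missing3 > tol and missing5 <= tol:
        return "3prime"
    return None


def rescue_five_prime(
    gene: GeneRecord,
    contig_seq: Optional[str],
    reference_length: float,
    side: Optional[str],
) -> StatusCall:
    """Start-codon check for 5'-truncated pseudogenes.

    When the annotated start is too far downstream, scan upstream in frame
    on the coding strand until the nearest in-frame stop; if an alternative
    start codon (ATG/GTG/TTG) gives an ORF reaching at least 80% of the
    reference length with no internal stop, the gene is reclassified intact
    and its start coordinate corrected. Applies only to 5'-side truncations.
    """
    if gene.status != "pseudogene" or side != "5prime":
        return StatusCall(gene.gene_id, gene.status, gene.status, "no_change")
    if contig_seq is None:
        log.warning("%s: contig sequence missing, 5' rescue skipped", gene.gene_id)
        return StatusCall(gene.gene_id, gene.status, gene.status, "no_change")

    if gene.strand == "+":
        codon_starts = range(gene.start - 1 - 3, -1, -3)  # 0-based upstream codons

        def codon_at(p: int) -> str:
            return contig_seq[p : p + 3]

        def new_coords(p: int) -> tuple[int, int]:
            return (p + 1, gene.end)

    else:
        # coding strand runs rightward from `end` on the reverse complement
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        codon_starts = range(gene.end, len(contig_seq) - 2, 3)

        def codon_at(p: int) -> str:
            return "".join(comp[b] for b in reversed(contig_seq[p : p + 3]))

        def new_coords(p: int) -> tuple[int, int]:
            return (gene.start, p + 3)

    extension = 0
    for p in codon_starts:
        codon = codon_at(p)
        if len(codon) < 3 or codon in STOP_CODONS:
            break
        extension += 1
        if codon in ALT_STARTS:
            new_aa_len = gene.aa_length + extension
            if new_aa_len >= LENGTH_RATIO_THRESHOLD * reference_length:
                start, end = new_coords(p)
                gene.start, gene.end = start, end
                gene.status = "intact"
                return StatusCall(
                    gene.gene_id,
                    "pseudogene",
                    "intact",
                    "five_prime_rescue",
                    reference_length,
                    new_aa_len / reference_length,
                )
    return StatusCall(gene.gene_id, gene.status, gene.status, "no_change")


def apply_contig_edge_rule(gene: GeneRecord) -> StatusCall:
    """A gene broken by a contig edge with no apparent stop mutation is
    considered active regardless of its length ratio. A trailing partial
    codon (the broken end) is ignored for the internal-stop check."""
    if not gene.contig_edge:
        return StatusCall(gene.gene_id, gene.status, gene.status, "no_change")
    if gene.nt_seq is None:
        raise ValueError(f"{gene.gene_id}: nucleotide sequence required for edge rule")
    n = len(gene.nt_seq) - (len(gene.nt_seq) % 3)
    codons = [gene.nt_seq[i : i + 3] for i in range(0, n, 3)]
    internal = codons[:-1] if codons and codons[-1] in STOP_CODONS else codons
    if any(c in STOP_CODONS for c in internal):
        return StatusCall(gene.gene_id, gene.status, gene.status, "no_change")
    old = gene.status
    gene.status = "intact"
    rule = "contig_edge_active" if old != "intact" else "no_change"
    return StatusCall(gene.gene_id, old, "intact", rule)


def apply_status_rules(
    genomeset: GenomeSet,
    partition: FamilyPartition,
    has_hit: dict[str, bool],
    contigs: Optional[dict[str, str]] = None,
    scoring: Optional[ScoringConfig] = None,
) -> list[StatusCall]:
    """Run the four triage rules in their fixed order over a genome set.

    Returns one call per rule application that changed or confirmed a
    status; the order is artifact filter, per-family length rule, 5'
    rescue, contig-edge rule.
    """
    idx = genomeset.gene_index()
    calls = flag_artifacts(genomeset.all_records(), has_hit)

    ref_lengths: dict[str, float] = {}
    for fid in partition.family_ids:
        members = [idx[g] for g in sorted(partition.members(fid))]
        family_calls = classify_pseudogenes(members)
        calls.extend(family_calls)
        for c in family_calls:
            if c.reference_length is not None:
                ref_lengths[c.gene_id] = c.reference_length

    if contigs is not None:
        for fid in partition.family_ids:
            members = [idx[g] for g in sorted(partition.members(fid))]
            intact_refs = [m for m in members if m.status == "intact"]
            for m in members:
                if m.status != "pseudogene" or m.gene_id not in ref_lengths:
                    continue
                refs = [r for r in intact_refs if r.genome_id != m.genome_id]
                if not refs:
                    continue
                ref = max(refs, key=lambda r: (r.aa_length, r.gene_id))
                side = truncation_side(m, ref, scoring)
                calls.append(
                    rescue_five_prime(
                        m,
                        contigs.get(m.contig_id),
                        ref_lengths[m.gene_id],
                        side,
                    )
                )

    for rec in genomeset.all_records():
        if rec.contig_edge and rec.nt_seq is not None and rec.status != "artifact":
            calls.append(apply_contig_edge_rule(rec))
    return calls


def write_status_calls(calls: Iterable[StatusCall], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\told_status\tnew_status\trule_fired\treference_length\tlength_ratio\n")
        for c in calls:
            rl = "" if c.reference_length is None else f"{c.reference_length:g}"
            lr = "" if c.length_ratio is None else f"{c.length_ratio:.4f}"
            fh.write(
                f"{c.gene_id}\t{c.old_status}\t{c.new_status}\t{c.rule_fired}\t{rl}\t{lr}\n"
            )
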