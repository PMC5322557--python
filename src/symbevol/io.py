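"""Readers and writers for the external representations.

FASTA (protein and CDS), the bespoke gene-table TSV, BLAST outfmt-6 tabular
hits, Newick trees, a GFF3 exporter, and directory-level load/emit of a whole
:class:`~symbevol.records.GenomeSet`. All outputs are UTF-8 with LF line
endings.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO

from .records import (
    Domain,
    GeneRecord,
    GenomeSet,
    SimilarityHit,
    SpeciesTree,
    STATUSES,
)

log = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

GENE_TABLE_COLUMNS = [
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "status",
    "contig_edge",
    "mobile_category",
    "domains",
]


def read_fasta(path: str | Path, kind: str) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}``.

    The record id is the first whitespace-delimited token of the header.
    Sequences are uppercased; ``kind`` is ``"protein"`` (20 amino acids + X)
    or ``"nucleotide"`` (ACGTN). Duplicate ids and illegal characters are
    hard errors.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"kind must be protein/nucleotide, got {kind!r}")
    alphabet = PROTEIN_ALPHABET if kind == "protein" else NUCLEOTIDE_ALPHABET
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in alphabet:
                raise ValueError(
                    f"{path}: illegal {kind} character {ch!r} at position "
                    f"{i + 1} of record {rec.id!r}"
                )
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for sid in seqs:
            fh.write(f">{sid}\n")
            s = seqs[sid]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _parse_domains(text: str) -> list[Domain]:
    domains: list[Domain] = []
    if not text or text == ".":
        return domains
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            did, span = item.split(":")
            a, b = span.split("-")
            domains.append(Domain(did, int(a), int(b)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed domain triple {item!r}") from exc
    return domains


def _format_domains(domains: Iterable[Domain]) -> str:
    return ";".join(f"{d.domain_id}:{d.aa_start}-{d.aa_end}" for d in domains)


def read_gene_table(path: str | Path, genome_id: str) -> list[GeneRecord]:
    """Read the bespoke tab-separated gene table for one genome.

    Columns: gene_id, contig_id, start, end, strand, status, contig_edge,
    mobile_category, domains (semicolon-separated ``id:aa_start-aa_end``,
    empty allowed). Unknown status values map to ``unclassified`` with a
    logged warning; start > end and malformed domains are hard errors.
    """
    records: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TABLE_COLUMNS:
            raise ValueError(
                f"{path}: unexpected gene-table header {header}; "
                f"expected {GENE_TABLE_COLUMNS}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(GENE_TABLE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            (gid, contig, start, end, strand, status, edge, mobile, domains) = parts
            if status not in STATUSES:
                log.warning(
                    "%s:%d: unknown status %r for %s mapped to 'unclassified'",
                    path,
                    lineno,
                    status,
                    gid,
                )
                status = "unclassified"
            records.append(
                GeneRecord(
                    gene_id=gid,
                    genome_id=genome_id,
                    contig_id=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    status=status,
                    contig_edge=edge.lower() == "true",
                    mobile_category=mobile,
                    domains=_parse_domains(domains),
                )
            )
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        r.contig_id,
                        str(r.start),
                        str(r.end),
                        r.strand,
                        r.status,
                        "true" if r.contig_edge else "false",
                        r.mobile_category,
                        _format_domains(r.domains),
                    ]
                )
                + "\n"
            )


def write_gff3(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Export gene records as GFF3; status, mobile category and domains are
    carried as column-9 attributes."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = [f"ID={r.gene_id}", f"status={r.status}"]
            if r.mobile_category != "none":
                attrs.append(f"mobile_category={r.mobile_category}")
            if r.domains:
                attrs.append(f"domains={_format_domains(r.domains)}")
            if r.contig_edge:
                attrs.append("contig_edge=true")
            fh.write(
                "\t".join(
                    [
                        r.contig_id,
                        "symbevol",
                        "CDS",
                        str(r.start),
                        str(r.end),
                        ".",
                        r.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_hits(
    path: str | Path, genomeset: Optional[GenomeSet] = None
) -> list[SimilarityHit]:
    """Read 12-column tabular hits (BLAST outfmt-6 dialect).

    Self-hits are discarded. When a ``genomeset`` is supplied, ids must
    resolve to loaded gene records (unresolvable ids are a hard error listing
    the first 10 offenders) and hits between genes of the same genome are
    discarded with a logged count — the search is cross-genome only.
    """
    idx = genomeset.gene_index() if genomeset is not None else None
    hits: list[SimilarityHit] = []
    missing: list[str] = []
    n_self = 0
    n_within = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            q, s = parts[0], parts[1]
            if q == s:
                n_self += 1
                continue
            if idx is not None:
                for gid in (q, s):
                    if gid not in idx and gid not in missing:
                        missing.append(gid)
                if missing:
                    continue
                if idx[q].genome_id == idx[s].genome_id:
                    n_within += 1
                    continue
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    identity_pct=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            )
    if missing:
        raise ValueError(
            f"{path}: hit ids not found among loaded gene records: "
            f"{missing[:10]}"
        )
    if n_self or n_within:
        log.info(
            "%s: discarded %d self-hits and %d within-genome hits",
            path,
            n_self,
            n_within,
        )
    return hits


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for h in hits:
            fh.write(h.to_outfmt6() + "\n")


def read_tree(
    path: str | Path, genomeset: Optional[GenomeSet] = None
) -> SpeciesTree:
    with open(path) as fh:
        tree = SpeciesTree.from_newick(fh.read())
    if genomeset is not None:
        tree.validate_against(genomeset)
    return tree


def write_tree(tree: SpeciesTree, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(tree.as_newick())


# ---------------------------------------------------------------------------
# Directory-level GenomeSet I/O.
#
# Layout written by the simulator's emit() and read back by the pipeline:
#   manifest.yaml              roles and clades
#   tree.nwk                   species tree
#   <genome>.faa / <genome>.fna / <genome>.genes.tsv   per genome
# ---------------------------------------------------------------------------


def load_genome_set(directory: str | Path, with_sequences: bool = True) -> GenomeSet:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    roles = dict(manifest["genomes"])
    clades = {k: set(v) for k, v in (manifest.get("clades") or {}).items()}
    genomes: dict[str, list[GeneRecord]] = {}
    for gid in roles:
        recs = read_gene_table(directory / f"{gid}.genes.tsv", gid)
        if with_sequences:
            aa = read_fasta(directory / f"{gid}.faa", "protein")
            nt = read_fasta(directory / f"{gid}.fna", "nucleotide")
            for r in recs:
                r.aa_seq = aa.get(r.gene_id)
                r.nt_seq = nt.get(r.gene_id)
        genomes[gid] = recs
    return GenomeSet(genomes, roles, clades)


def save_genome_set(
    genomeset: GenomeSet, tree: Optional[SpeciesTree], directory: str | Path
) -> None:
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "genomes": {g: genomeset.roles[g] for g in genomeset.genome_ids},
        "clades": {k: sorted(v) for k, v in sorted(genomeset.clades.items())},
    }
    with open(directory / "manifest.yaml", "w", newline="\n") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    for gid in genomeset.genome_ids:
        recs = genomeset.genomes[gid]
        write_gene_table(recs, directory / f"{gid}.genes.tsv")
        write_fasta(
            {r.gene_id: r.aa_seq for r in recs if r.aa_seq is not None},
            directory / f"{gid}.faa",
        )
        write_fasta(
            {r.gene_id: r.nt_seq for r in recs if r.nt_seq is not None},
            directory / f"{gid}.fna",
        )
    if tree is not None:
        write_tree(tree, directory / "tree.nwk")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned nucleotide FASTA (gaps allowed) for phylo input."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out
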