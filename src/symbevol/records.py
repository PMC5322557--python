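"""Shared domain types for annotated genomes and similarity searches.

A :class:`GeneRecord` is one annotated coding sequence; a :class:`GenomeSet`
collects the records of several genomes together with their ingroup/outgroup
roles and named ingroup clades; a :class:`SpeciesTree` wraps a rooted dendropy
tree whose leaves are genome identifiers.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Optional

import dendropy

STATUSES = ("intact", "pseudogene", "artifact", "unclassified")
MOBILE_CATEGORIES = (
    "none",
    "phage",
    "plasmid",
    "transposase",
    "toxin_antitoxin",
    "APSE",
    "pHD5AT",
)
#: categories removed when reconstructing the ancestor (APSE and the
#: non-integrated plasmid are exempt)
EXCLUDED_MOBILE = frozenset({"phage", "plasmid", "transposase", "toxin_antitoxin"})

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class Domain:
    """A protein domain annotation, 1-based inclusive amino-acid coordinates."""

    domain_id: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start < 1 or self.aa_end < self.aa_start:
            raise ValueError(
                f"bad domain interval {self.domain_id}:{self.aa_start}-{self.aa_end}"
            )


@dataclass
class GeneRecord:
    """One annotated coding sequence.

    Coordinates are 1-based inclusive on the forward strand of the contig
    (GFF3 convention). ``nt_seq`` carries the CDS on the coding strand,
    including the terminal stop codon for intact genes; ``aa_seq`` carries
    the translation without a stop character. Both sequences are optional so
    presence/absence-only analyses can run without FASTA input.
    """

    gene_id: str
    genome_id: str
    contig_id: str = "contig1"
    start: int = 1
    end: int = 3
    strand: str = "+"
    nt_seq: Optional[str] = None
    aa_seq: Optional[str] = None
    status: str = "unclassified"
    contig_edge: bool = False
    mobile_category: str = "none"
    domains: list[Domain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.status not in STATUSES:
            raise ValueError(f"{self.gene_id}: bad status {self.status!r}")
        if self.mobile_category not in MOBILE_CATEGORIES:
            raise ValueError(
                f"{self.gene_id}: bad mobile_category {self.mobile_category!r}"
            )
        if self.aa_seq is not None:
            for d in self.domains:
                if d.aa_end > len(self.aa_seq):
                    raise ValueError(
                        f"{self.gene_id}: domain {d.domain_id} exceeds protein length"
                    )
        if (
            self.nt_seq is not None
            and self.aa_seq is not None
            and self.status == "intact"
            and len(self.nt_seq) != 3 * (len(self.aa_seq) + 1)
        ):
            raise ValueError(
                f"{self.gene_id}: intact CDS length {len(self.nt_seq)} does not "
                f"match 3*(aa+stop) = {3 * (len(self.aa_seq) + 1)}"
            )

    @property
    def aa_length(self) -> int:
        if self.aa_seq is None:
            raise ValueError(f"{self.gene_id}: amino-acid sequence missing")
        return len(self.aa_seq)

    @property
    def is_mobile(self) -> bool:
        return self.mobile_category != "none"

    @property
    def domain_ids(self) -> frozenset[str]:
        return frozenset(d.domain_id for d in self.domains)


class GenomeSet:
    """Gene records of several genomes plus their phylogenetic roles.

    Parameters
    ----------
    genomes
        Mapping genome_id -> list of :class:`GeneRecord`.
    roles
        Mapping genome_id -> ``"ingroup"`` or ``"outgroup"``; keys must
        coincide with ``genomes``.
    clades
        Named subsets of ingroup genome ids (e.g. a two-genome sister clade).
        Ingroup genomes not covered by any clade form singleton lineages.
    """

    def __init__(
        self,
        genomes: dict[str, list[GeneRecord]],
        roles: dict[str, str],
        clades: Optional[dict[str, set[str]]] = None,
    ) -> None:
        if set(genomes) != set(roles):
            raise ValueError("genome ids in `genomes` and `roles` must coincide")
        for gid, role in roles.items():
            if role not in ("ingroup", "outgroup"):
                raise ValueError(f"{gid}: role must be ingroup/outgroup, got {role!r}")
        clades = dict(clades or {})
        ingroup = {g for g, r in roles.items() if r == "ingroup"}
        for name, members in clades.items():
            if not set(members) <= ingroup:
                raise ValueError(f"clade {name!r} is not a subset of the ingroup")
        self.genomes = genomes
        self.roles = dict(roles)
        self.clades = {k: set(v) for k, v in clades.items()}
        seen: dict[str, str] = {}
        for gid, recs in genomes.items():
            for r in recs:
                if r.gene_id in seen:
                    raise ValueError(
                        f"duplicate gene_id {r.gene_id!r} in genomes "
                        f"{seen[r.gene_id]} and {gid}"
                    )
                if r.genome_id != gid:
                    raise ValueError(
                        f"{r.gene_id}: genome_id {r.genome_id!r} filed under {gid!r}"
                    )
                seen[r.gene_id] = gid

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.genomes)

    @property
    def ingroup_ids(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == "ingroup")

    @property
    def outgroup_ids(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == "outgroup")

    def lineages(self) -> dict[str, set[str]]:
        """Ingroup lineages: named clades plus singleton lineages for every
        ingroup genome not claimed by a clade (keyed by the genome id)."""
        out = {name: set(m) for name, m in self.clades.items()}
        claimed = set().union(*out.values()) if out else set()
        for g in self.ingroup_ids:
            if g not in claimed:
                out[g] = {g}
        return out

    def all_records(self) -> list[GeneRecord]:
        return [r for gid in self.genome_ids for r in self.genomes[gid]]

    def record(self, gene_id: str) -> GeneRecord:
        rec = self.gene_index().get(gene_id)
        if rec is None:
            raise KeyError(gene_id)
        return rec

    def gene_index(self) -> dict[str, GeneRecord]:
        idx = getattr(self, "_gene_index", None)
        if idx is None or len(idx) != sum(len(v) for v in self.genomes.values()):
            idx = {r.gene_id: r for r in self.all_records()}
            self._gene_index = idx
        return idx

    def genome_of(self, gene_id: str) -> str:
        return self.record(gene_id).genome_id


class SpeciesTree:
    """A rooted species tree whose leaf labels are genome ids."""

    def __init__(self, tree: dendropy.Tree) -> None:
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        return cls(tree)

    @property
    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def validate_against(self, genomeset: GenomeSet) -> None:
        want = set(genomeset.genome_ids)
        have = self.leaf_labels
        if want != have:
            raise ValueError(
                f"tree leaves {sorted(have)} do not match genomes {sorted(want)}"
            )

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + "\n"

    def __str__(self) -> str:  # pragma: no cover - convenience
        buf = _io.StringIO()
        self.tree.print_plot(plot_metric="level", show_internal_node_labels=True)
        return buf.getvalue()


@dataclass(frozen=True)
class SimilarityHit:
    """One tabular similarity hit (BLAST outfmt-6 dialect) between genes of
    different genomes."""

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def to_outfmt6(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.identity_pct:.2f}",
                str(self.aln_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                f"{self.evalue:.3g}",
                f"{self.bitscore:.1f}",
            ]
        )


def translate_cds(nt_seq: str, trim_stop: bool = True) -> str:
    """Translate a CDS under the bacterial code, internal stops as ``*``.

    The codon->amino-acid map of translation table 11 is identical to the
    standard code; a trailing stop codon is dropped when ``trim_stop``.
    """
    from Bio.Seq import Seq

    n = len(nt_seq) - (len(nt_seq) % 3)
    aa = str(Seq(nt_seq[:n]).translate(table=11))
    if trim_stop and aa.endswith("*"):
        aa = aa[:-1]
    return aa
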