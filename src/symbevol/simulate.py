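"""Gene-content evolution simulator with a known truth history.

An ancestral repertoire of random CDSs evolves along a rooted species tree.
On each branch every intact family can be lost, pseudogenized (truncated to
a uniform 20-79% of its sense codons, half the time destroying an annotated
domain), or retained; retained copies accumulate codon substitutions at
separate synonymous and nonsynonymous per-site rates, can be duplicated,
and new mobile-element families arrive by horizontal transfer. Pseudogenes
persist unchanged downstream and are never re-lost; mobile acquisitions are
never ancestral. The full history is recorded in a :class:`TruthTable` so
every downstream inference stage can be scored against truth.

Modelling notes: the start codon is held fixed and substitutions that would
create an internal stop are rejected (treated as lethal in a retained
gene), so an intact CDS always has the start..stop structure a gene caller
recognises. Truncated CDSs retain only sense codons and therefore lack a
terminal stop, which is what lets the emitted annotation mark them
``unclassified`` from sequence structure alone — the emitted tables never
consult the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .io import save_genome_set
from .kaks import codon_sites, translate_codon
from .records import (
    Domain,
    GeneRecord,
    GenomeSet,
    SpeciesTree,
    STOP_CODONS,
    translate_cds,
)

SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    )
)
HGT_CATEGORIES = ("phage", "plasmid", "transposase", "toxin_antitoxin")

DEFAULT_TREE = "(((sym1:1,sym2:1)cladeA:1,sym3:1)ingroup:1,(out1:1,out2:1)outs:1)root;"

BranchParam = Union[float, dict[str, float]]


def _branch_value(param: BranchParam, label: str) -> float:
    if isinstance(param, dict):
        return float(param.get(label, param.get("default", 0.0)))
    return float(param)


@dataclass
class EvolutionConfig:
    """Study conditions for one simulated history.

    Per-branch parameters accept either a single value applied to every
    branch or a ``{branch_label: value}`` mapping with an optional
    ``default`` key; branches are labelled by their child node (leaf label
    or internal node label).
    """

    ancestral_size: int = 200
    tree_newick: str = DEFAULT_TREE
    ingroup: tuple[str, ...] = ("sym1", "sym2", "sym3")
    clades: dict[str, set[str]] = field(
        default_factory=lambda: {"cladeA": {"sym1", "sym2"}}
    )
    loss_prob: BranchParam = 0.15
    pseudo_prob: BranchParam = 0.05
    hgt_rate: BranchParam = 0.5
    dup_prob: BranchParam = 0.01
    syn_rate: BranchParam = 0.0
    nonsyn_rate: BranchParam = 0.0
    codon_len_mean: int = 320
    codon_len_min: int = 150
    domain_frac: float = 0.3
    sequences: bool = True
    seed: int = 0

    def validate(self, branch_labels: list[str]) -> None:
        if self.ancestral_size < 1:
            raise ValueError("ancestral_size must be >= 1")
        if not (0.0 <= self.domain_frac <= 1.0):
            raise ValueError("domain_frac must lie in [0, 1]")
        if self.codon_len_min < 10 or self.codon_len_mean < self.codon_len_min:
            raise ValueError("codon length parameters out of range")
        for label in branch_labels:
            lp = _branch_value(self.loss_prob, label)
            pp = _branch_value(self.pseudo_prob, label)
            dp = _branch_value(self.dup_prob, label)
            hr = _branch_value(self.hgt_rate, label)
            sr = _branch_value(self.syn_rate, label)
            nr = _branch_value(self.nonsyn_rate, label)
            for name, v in (("loss_prob", lp), ("pseudo_prob", pp), ("dup_prob", dp)):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name} on branch {label!r} out of [0,1]: {v}")
            if lp + pp > 1.0:
                raise ValueError(
                    f"loss_prob + pseudo_prob > 1 on branch {label!r}"
                )
            for name, v in (("hgt_rate", hr), ("syn_rate", sr), ("nonsyn_rate", nr)):
                if v < 0:
                    raise ValueError(f"{name} on branch {label!r} negative: {v}")


@dataclass
class Substitution:
    position: int  # 0-based within the sense-codon CDS
    old: str
    new: str
    kind: str  # syn | nonsyn


@dataclass
class SimGene:
    """One gene copy tracked through the simulation."""

    family: str
    copy_id: int
    seq: Optional[str]  # sense codons only, no terminal stop
    pseudo: bool = False
    domains: list[Domain] = field(default_factory=list)
    subs: list[Substitution] = field(default_factory=list)
    mobile_category: str = "none"

    def clone(self) -> "SimGene":
        return SimGene(
            family=self.family,
            copy_id=self.copy_id,
            seq=self.seq,
            pseudo=self.pseudo,
            domains=list(self.domains),
            subs=list(self.subs),
            mobile_category=self.mobile_category,
        )


@dataclass
class TruthTable:
    """Recorded history of one simulation.

    ``states`` holds the true per-(family, genome) state; ``events`` the
    per-branch loss / inactivation / acquisition / duplication family lists;
    ``substitutions`` the applied codon changes per extant gene;
    ``family_members`` the true gene partition. ``ancestral`` flags families
    truly present in the ingroup's most recent common ancestor.
    """

    ancestral: dict[str, bool] = field(default_factory=dict)
    states: dict[tuple[str, str], str] = field(default_factory=dict)
    events: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    substitutions: dict[str, list[Substitution]] = field(default_factory=dict)
    family_members: dict[str, set[str]] = field(default_factory=dict)
    mobile_category: dict[str, str] = field(default_factory=dict)
    ancestor_seqs: dict[str, str] = field(default_factory=dict)
    genome_ids: list[str] = field(default_factory=list)
    ingroup_ids: list[str] = field(default_factory=list)

    def state(self, family: str, genome: str) -> str:
        return self.states.get((family, genome), "absent")

    def true_partition(self) -> dict[str, str]:
        return {
            g: fam for fam, members in self.family_members.items() for g in members
        }

    def losses_on_branch(self, label: str) -> list[str]:
        return self.events.get(label, {}).get("losses", [])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in codons)


def _draw_length(rng: np.random.Generator, cfg: EvolutionConfig) -> int:
    extra_mean = max(cfg.codon_len_mean - cfg.codon_len_min, 1)
    return cfg.codon_len_min + int(rng.geometric(1.0 / extra_mean)) - 1


def mutate_cds(
    seq: str,
    syn_rate: float,
    nonsyn_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[Substitution]]:
    """Apply codon substitutions at the given per-site rates.

    The number of synonymous (nonsynonymous) changes is Poisson with mean
    rate x synonymous (nonsynonymous) site count of the input sequence;
    changes are placed by rejection sampling over single-nucleotide
    mutations of the evolving sequence. The start codon is held fixed and
    mutations creating a stop codon are rejected.
    """
    n_codons = len(seq) // 3
    if n_codons < 2 or (syn_rate == 0 and nonsyn_rate == 0):
        return seq, []
    S = sum(codon_sites(seq[3 * i : 3 * i + 3])[0] for i in range(n_codons))
    N = 3 * n_codons - S
    n_syn = int(rng.poisson(syn_rate * S)) if syn_rate > 0 else 0
    n_nonsyn = int(rng.poisson(nonsyn_rate * N)) if nonsyn_rate > 0 else 0
    chars = list(seq)
    subs: list[Substitution] = []
    for kind, quota in (("syn", n_syn), ("nonsyn", n_nonsyn)):
        applied = 0
        guard = 0
        while applied < quota:
            guard += 1
            if guard > 10000 * (quota + 1):  # pragma: no cover - degenerate seq
                break
            ci = int(rng.integers(1, n_codons))  # start codon conserved
            pos = int(rng.integers(0, 3))
            old_codon = "".join(chars[3 * ci : 3 * ci + 3])
            old_base = chars[3 * ci + pos]
            new_base = "ACGT".replace(old_base, "")[int(rng.integers(0, 3))]
            new_codon = old_codon[:pos] + new_base + old_codon[pos + 1 :]
            if new_codon in STOP_CODONS:
                continue
            change = (
                "syn"
                if translate_codon(new_codon) == translate_codon(old_codon)
                else "nonsyn"
            )
            if change != kind:
                continue
            chars[3 * ci + pos] = new_base
            subs.append(Substitution(3 * ci + pos, old_base, new_base, kind))
            applied += 1
    return "".join(chars), subs


def _truncate(
    gene: SimGene, rng: np.random.Generator
) -> None:
    """Truncate to a uniform 20-79% of sense codons; with an annotated
    domain, the cut destroys it with probability 1/2."""
    m = len(gene.seq) // 3
    lo = math.ceil(0.20 * m)
    hi = math.floor(0.79 * m)
    dom = gene.domains[0] if gene.domains else None
    if dom is not None and lo < dom.aa_end <= hi:
        if rng.random() < 0.5:
            k = int(rng.integers(lo, dom.aa_end))  # cuts into/before the domain
        else:
            k = int(rng.integers(dom.aa_end, hi + 1))  # domain fully retained
    else:
        k = int(rng.integers(lo, hi + 1))
    gene.seq = gene.seq[: 3 * k]
    gene.pseudo = True
    gene.domains = [d for d in gene.domains if d.aa_end <= k]


def _node_label(node, counter: list[int]) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    return f"node{counter[0]}"


def simulate(config: EvolutionConfig) -> tuple[GenomeSet, TruthTable]:
    """Run the gene-content evolution model; returns the extant genomes and
    the full truth history. The same config (and seed) always yields the
    same output."""
    tree = SpeciesTree.from_newick(config.tree_newick)
    leaves = sorted(tree.leaf_labels)
    ingroup = set(config.ingroup)
    if not ingroup <= set(leaves):
        raise ValueError("ingroup labels must be tree leaves")
    counter = [0]
    labels: dict[int, str] = {}
    for node in tree.tree.preorder_node_iter():
        labels[id(node)] = _node_label(node, counter)
    branch_labels = [
        labels[id(n)] for n in tree.tree.preorder_node_iter() if n.parent_node
    ]
    config.validate(branch_labels)
    rng = np.random.default_rng(config.seed)

    truth = TruthTable(
        genome_ids=leaves, ingroup_ids=sorted(ingroup)
    )

    # ancestral repertoire at the root
    root_genes: dict[str, list[SimGene]] = {}
    for i in range(config.ancestral_size):
        fam = f"AF{i:05d}"
        if config.sequences:
            n_codons = _draw_length(rng, config)
            seq = _random_cds(rng, n_codons)
            domains = []
            if rng.random() < config.domain_frac:
                aa_start = max(1, round(0.30 * n_codons))
                aa_end = max(aa_start, round(0.60 * n_codons))
                domains = [Domain(f"dom_{fam}", aa_start, aa_end)]
            truth.ancestor_seqs[fam] = seq
        else:
            seq, domains = None, []
            if rng.random() < config.domain_frac:
                domains = [Domain(f"dom_{fam}", 1, 10)]
        root_genes[fam] = [SimGene(fam, 0, seq, domains=domains)]

    mrca = tree.tree.mrca(taxa=[t for t in tree.tree.taxon_namespace if t.label in ingroup])
    hgt_counter = [0]

    def evolve(node, genes: dict[str, list[SimGene]]) -> None:
        label = labels[id(node)]
        if node.parent_node is not None:
            lp = _branch_value(config.loss_prob, label)
            pp = _branch_value(config.pseudo_prob, label)
            dp = _branch_value(config.dup_prob, label)
            hr = _branch_value(config.hgt_rate, label)
            sr = _branch_value(config.syn_rate, label)
            nr = _branch_value(config.nonsyn_rate, label)
            ev = {"losses": [], "inactivations": [], "acquisitions": [], "duplications": []}
            for fam in sorted(genes):
                copies = genes[fam]
                if all(g.pseudo for g in copies):
                    continue  # pseudogenes persist unchanged downstream
                u = rng.random()
                if u < lp:
                    del genes[fam]
                    ev["losses"].append(fam)
                    continue
                if u < lp + pp:
                    for g in copies:
                        if not g.pseudo and g.seq is not None:
                            _truncate(g, rng)
                        g.pseudo = True
                    ev["inactivations"].append(fam)
                    continue
                for g in copies:
                    if g.seq is not None and not g.pseudo and (sr > 0 or nr > 0):
                        g.seq, new_subs = mutate_cds(g.seq, sr, nr, rng)
                        g.subs.extend(new_subs)
                if dp > 0 and rng.random() < dp:
                    twin = copies[0].clone()
                    twin.copy_id = max(c.copy_id for c in copies) + 1
                    copies.append(twin)
                    ev["duplications"].append(fam)
            n_hgt = int(rng.poisson(hr)) if hr > 0 else 0
            for _ in range(n_hgt):
                hgt_counter[0] += 1
                fam = f"HF{hgt_counter[0]:05d}"
                cat = HGT_CATEGORIES[int(rng.integers(0, len(HGT_CATEGORIES)))]
                seq = None
                if config.sequences:
                    seq = _random_cds(rng, _draw_length(rng, config))
                    truth.ancestor_seqs[fam] = seq
                genes[fam] = [SimGene(fam, 0, seq, mobile_category=cat)]
                truth.mobile_category[fam] = cat
                ev["acquisitions"].append(fam)
            truth.events[label] = ev
        if node is mrca:
            for fam in root_genes:
                truth.ancestral[fam] = fam in genes
            for fam in genes:
                truth.ancestral.setdefault(fam, True)
        if node.is_leaf():
            leaf_states[label] = {f: [g.clone() for g in gs] for f, gs in genes.items()}
        else:
            for child in node.child_nodes():
                evolve(child, {f: [g.clone() for g in gs] for f, gs in genes.items()})

    leaf_states: dict[str, dict[str, list[SimGene]]] = {}
    evolve(tree.tree.seed_node, root_genes)
    for fam in root_genes:
        truth.ancestral.setdefault(fam, False)
    for fam in truth.mobile_category:
        truth.ancestral.setdefault(fam, False)

    # materialise GeneRecords
    genomes: dict[str, list[GeneRecord]] = {}
    roles = {g: ("ingroup" if g in ingroup else "outgroup") for g in leaves}
    for genome in leaves:
        recs: list[GeneRecord] = []
        pos = 1
        for fam in sorted(leaf_states.get(genome, {})):
            copies = leaf_states[genome][fam]
            any_intact = any(not g.pseudo for g in copies)
            truth.states[(fam, genome)] = "intact" if any_intact else "pseudogene"
            for g in copies:
                gene_id = f"{genome}|{fam}|{g.copy_id}"
                truth.family_members.setdefault(fam, set()).add(gene_id)
                if config.sequences:
                    nt = g.seq if g.pseudo else g.seq + "TAA"
                    aa = translate_cds(nt, trim_stop=True)
                    status = _annotation_status(nt)
                    rec = GeneRecord(
                        gene_id=gene_id,
                        genome_id=genome,
                        contig_id=f"{genome}_c1",
                        start=pos,
                        end=pos + len(nt) - 1,
                        strand="+",
                        nt_seq=nt,
                        aa_seq=aa,
                        status=status,
                        mobile_category=g.mobile_category,
                        domains=list(g.domains),
                    )
                    pos += len(nt) + 100
                    truth.substitutions[gene_id] = list(g.subs)
                else:
                    rec = GeneRecord(
                        gene_id=gene_id,
                        genome_id=genome,
                        contig_id=f"{genome}_c1",
                        start=pos,
                        end=pos + 2,
                        status="intact" if not g.pseudo else "pseudogene",
                        mobile_category=g.mobile_category,
                        domains=list(g.domains),
                    )
                    pos += 103
                recs.append(rec)
        genomes[genome] = recs
    genomeset = GenomeSet(genomes, roles, config.clades)
    return genomeset, truth


def _annotation_status(nt: str) -> str:
    """What a structure-only gene caller would report: ``intact`` for a
    start..stop ORF with no internal stop, else ``unclassified``."""
    if len(nt) % 3 != 0 or len(nt) < 6:
        return "unclassified"
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons[0] not in ("ATG", "GTG", "TTG"):
        return "unclassified"
    if codons[-1] not in STOP_CODONS:
        return "unclassified"
    if any(c in STOP_CODONS for c in codons[1:-1]):
        return "unclassified"
    return "intact"


def replay_substitutions(ancestor_seq: str, subs: list[Substitution]) -> str:
    """Apply recorded substitutions to the ancestral CDS (bookkeeping
    check: reproduces the extant sense-codon sequence exactly for intact
    genes)."""
    chars = list(ancestor_seq)
    for s in subs:
        if chars[s.position] != s.old:
            raise ValueError(f"replay mismatch at {s.position}")
        chars[s.position] = s.new
    return "".join(chars)


# ---------------------------------------------------------------------------
# Truth replay: what states can the annotation rules possibly recover?
# ---------------------------------------------------------------------------


def observable_states(genomeset: GenomeSet, truth: TruthTable):
    """The per-(family, genome) states an ideal run of the triage rules can
    recover, derived from truth alone.

    A true pseudogene is only *detectably* a pseudogene when the family has
    an intact member in some other genome (the 80% rule needs a reference)
    and the truncation did not preserve every ancestral domain (the domain
    exception keeps such copies intact). Undetectable pseudogenes surface
    as putatively intact, exactly as the annotation default treats them.
    """
    from .families import StateMatrix

    sm = StateMatrix(genome_ids=genomeset.genome_ids)
    idx = genomeset.gene_index()
    for fam, members in truth.family_members.items():
        by_genome: dict[str, list[str]] = {}
        for gid in members:
            by_genome.setdefault(idx[gid].genome_id, []).append(gid)
        intact_genomes = {
            g for g in by_genome if truth.state(fam, g) == "intact"
        }
        ancestral_domains: Optional[frozenset] = None
        intact_members = [
            gid
            for g in intact_genomes
            for gid in by_genome[g]
            # copies can mix states after duplication; keep intact ones
            if not _is_true_pseudo(idx[gid])
        ]
        if intact_members:
            ancestral_domains = frozenset.intersection(
                *[idx[gid].domain_ids for gid in intact_members]
            )
        for genome, gids in by_genome.items():
            if truth.state(fam, genome) == "intact":
                state = "intact"
            else:
                has_ref = bool(intact_genomes - {genome})
                seen_intact = False
                for gid in gids:
                    if not has_ref:
                        seen_intact = True  # no reference: stays unclassified
                    elif (
                        ancestral_domains
                        and ancestral_domains <= idx[gid].domain_ids
                    ):
                        seen_intact = True  # domain exception
                state = "intact" if seen_intact else "pseudogene"
            sm.states[(fam, genome)] = state
            sm.member_counts[(fam, genome)] = len(gids)
    return sm


def _is_true_pseudo(rec: GeneRecord) -> bool:
    # a truncated simulated CDS carries no terminal stop codon
    return rec.nt_seq is not None and (
        len(rec.nt_seq) % 3 != 0 or rec.nt_seq[-3:] not in STOP_CODONS
    )


def emit(
    genomeset: GenomeSet,
    truth: TruthTable,
    tree: Optional[SpeciesTree],
    outdir: str | Path,
    config: Optional[EvolutionConfig] = None,
) -> None:
    """Write per-genome FASTAs and gene tables, the tree, and truth TSVs."""
    outdir = Path(outdir)
    if tree is None and config is not None:
        tree = SpeciesTree.from_newick(config.tree_newick)
    save_genome_set(genomeset, tree, outdir)
    truthdir = outdir / "truth"
    truthdir.mkdir(parents=True, exist_ok=True)
    with open(truthdir / "family_states.tsv", "w", newline="\n") as fh:
        fh.write("family_id\tancestral\t" + "\t".join(truth.genome_ids) + "\n")
        for fam in sorted(truth.family_members):
            row = [fam, str(truth.ancestral.get(fam, False)).lower()]
            row += [truth.state(fam, g) for g in truth.genome_ids]
            fh.write("\t".join(row) + "\n")
    with open(truthdir / "branch_events.tsv", "w", newline="\n") as fh:
        fh.write("branch\tevent\tfamily_id\n")
        for branch in sorted(truth.events):
            for event, fams in sorted(truth.events[branch].items()):
                for fam in fams:
                    fh.write(f"{branch}\t{event}\t{fam}\n")
    with open(truthdir / "substitutions.tsv", "w", newline="\n") as fh:
        fh.write("gene_id\tposition\told\tnew\tkind\n")
        for gid in sorted(truth.substitutions):
            for s in truth.substitutions[gid]:
                fh.write(f"{gid}\t{s.position}\t{s.old}\t{s.new}\t{s.kind}\n")
    with open(truthdir / "families.tsv", "w", newline="\n") as fh:
        fh.write("family_id\tgene_id\n")
        for fam in sorted(truth.family_members):
            for gid in sorted(truth.family_members[fam]):
                fh.write(f"{fam}\t{gid}\n")
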