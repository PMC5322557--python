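"""Parameter-recovery experiments against the simulator's truth tables.

Each function runs one seeded replicate (or batch) of a fixed study
condition and reports how well the corresponding inference stage recovered
the truth. The conditions — tree shape, event probabilities, gene sizes —
are the simulator defaults; deviations are stated per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestor import (
    assign_lineage_events,
    call_ancestral,
    compare_loss_counts,
    mobile_excluded_families,
)
from .families import FamilyPartition
from .kaks import kaks_pair
from .pipeline import RunConfig, run
from .simulate import (
    SENSE_CODONS,
    EvolutionConfig,
    mutate_cds,
    observable_states,
    simulate,
)


def _truth_reference_calls(genomeset, truth, clade_presence: str = "any"):
    """Ancestral calls an ideal pipeline would produce, replayed from the
    truth tables: true families, recoverable states, same presence rules."""
    sm = observable_states(genomeset, truth)
    partition = FamilyPartition({f: set(m) for f, m in truth.family_members.items()})
    excluded = mobile_excluded_families(partition, genomeset)
    calls = call_ancestral(
        sm, genomeset.lineages(), genomeset.outgroup_ids, excluded, clade_presence
    )
    return calls, partition, sm


@dataclass
class AncestralRecovery:
    seed: int
    n_ancestral_inferred: int
    n_ancestral_expected: int
    ancestral_sets_equal: bool
    inactivated_flags_equal: bool
    loss_counts_equal: bool


def ancestral_recovery_replicate(
    seed: int, ancestral_size: int = 1265
) -> AncestralRecovery:
    """One zero-divergence replicate of the reconstruction experiment.

    The default ingroup/outgroup topology with per-branch loss 0.15 and
    pseudogenization 0.05; sequences do not diverge, so clustering is exact
    and any disagreement with the truth-replayed reference calls is an
    inference defect.
    """
    cfg = EvolutionConfig(
        ancestral_size=ancestral_size,
        loss_prob=0.15,
        pseudo_prob=0.05,
        seed=seed,
    )
    res = run(RunConfig(simulation=cfg, seed=seed))
    expected_calls, _, expected_sm = _truth_reference_calls(res.genomeset, res.truth)
    expected = {c.family_id: c for c in expected_calls}

    truth_of = res.truth.true_partition()
    inferred_ancestral: set[str] = set()
    inferred_inactivated: set[str] = set()
    for c in res.reconstruction.calls:
        members = res.partition.members(c.family_id)
        truth_ids = {truth_of[g] for g in members}
        if len(truth_ids) != 1:  # clustering error: fail the comparison
            return AncestralRecovery(seed, -1, len(expected), False, False, False)
        tid = truth_ids.pop()
        if c.ancestral:
            inferred_ancestral.add(tid)
        if c.ancestrally_inactivated:
            inferred_inactivated.add(tid)
    expected_ancestral = {f for f, c in expected.items() if c.ancestral}
    expected_inactivated = {f for f, c in expected.items() if c.ancestrally_inactivated}

    lineages = res.genomeset.lineages()
    expected_events = assign_lineage_events(
        expected_calls, expected_sm, lineages, res.genomeset.outgroup_ids
    )
    losses_equal = all(
        len(res.reconstruction.events.losses[lin]) == len(expected_events.losses[lin])
        for lin in lineages
    )
    return AncestralRecovery(
        seed=seed,
        n_ancestral_inferred=len(inferred_ancestral),
        n_ancestral_expected=len(expected_ancestral),
        ancestral_sets_equal=inferred_ancestral == expected_ancestral,
        inactivated_flags_equal=inferred_inactivated == expected_inactivated,
        loss_counts_equal=losses_equal,
    )


def clustering_ari_replicate(seed: int, n_families: int = 200) -> float:
    """Adjusted Rand index between the inferred partition and the
    recoverable true partition under divergence (0.05 substitutions per
    synonymous and nonsynonymous site per branch), intact-gene evolution
    only.

    The reference is the true family partition restricted to what a
    cross-genome search can express: within-genome co-membership only ever
    arises transitively through another genome, so a family whose
    surviving members all sit in one genome decomposes into singletons.
    Genes flagged as artifacts are scored as singleton families.
    """
    from sklearn.metrics import adjusted_rand_score

    cfg = EvolutionConfig(
        ancestral_size=n_families,
        loss_prob=0.15,
        pseudo_prob=0.0,
        syn_rate=0.05,
        nonsyn_rate=0.05,
        seed=seed,
    )
    res = run(RunConfig(simulation=cfg, seed=seed))
    idx = res.genomeset.gene_index()
    reference: dict[str, str] = {}
    for fam, members in res.truth.family_members.items():
        genomes = {idx[g].genome_id for g in members}
        for g in members:
            reference[g] = fam if len(genomes) > 1 else f"single:{g}"
    inferred = res.partition.as_labeling()
    genes = sorted(reference)
    return float(
        adjusted_rand_score(
            [reference[g] for g in genes],
            [inferred.get(g, f"singleton:{g}") for g in genes],
        )
    )


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def kaks_ratio_replicates(
    n_replicates: int,
    syn_rate: float,
    nonsyn_rate: float,
    n_codons: int = 500,
    seed: int = 0,
) -> list[float]:
    """dN/dS estimates for independently diverged copies of random genes.

    Each replicate draws one ancestral CDS and evolves two copies
    independently at the given per-site rates; the estimator sees only the
    two extant sequences."""
    rng = np.random.default_rng(seed)
    ratios: list[float] = []
    while len(ratios) < n_replicates:
        anc = random_cds(rng, n_codons)
        a, _ = mutate_cds(anc, syn_rate, nonsyn_rate, rng)
        b, _ = mutate_cds(anc, syn_rate, nonsyn_rate, rng)
        res = kaks_pair(a + "TAA", b + "TAA")
        if res.valid:
            ratios.append(res.ratio)
    return ratios


def loss_power_replicate(
    seed: int,
    loss_a: float = 0.3,
    loss_b: float = 0.1,
    ancestral_size: int = 1000,
) -> float:
    """p-value of the lineage loss-count comparison for one content-only
    replicate with asymmetric loss on the two ingroup lineage stems."""
    cfg = EvolutionConfig(
        ancestral_size=ancestral_size,
        sequences=False,
        loss_prob={"cladeA": loss_a, "sym3": loss_b, "default": 0.0},
        pseudo_prob=0.0,
        hgt_rate=0.0,
        dup_prob=0.0,
        seed=seed,
    )
    genomeset, truth = simulate(cfg)
    calls, _, sm = _truth_reference_calls(genomeset, truth)
    lineages = genomeset.lineages()
    events = assign_lineage_events(calls, sm, lineages, genomeset.outgroup_ids)
    cmp = compare_loss_counts(events, "cladeA", "sym3")
    return cmp.p_value if cmp.valid else 1.0


def clade_signal_alignment(
    seed: int,
    n_private: int = 30,
    length: int = 1000,
    taxa: tuple[str, ...] = ("A", "B", "C", "D", "O"),
    clade: tuple[str, ...] = ("A", "B"),
) -> dict[str, str]:
    """Nucleotide alignment with a clean shared-substitution signal for the
    designated clade, light private noise on every taxon, and a diverged
    outgroup (the last taxon)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=length)
    seqs = {t: anc.copy() for t in taxa}
    for s in rng.choice(length, size=n_private, replace=False):
        new = bases[bases != anc[s]][int(rng.integers(0, 3))]
        for t in clade:
            seqs[t][s] = new
    for t in taxa:
        for s in rng.choice(length, size=5, replace=False):
            seqs[t][s] = rng.choice(bases[bases != seqs[t][s]])
    out = taxa[-1]
    for s in rng.choice(length, size=length // 15, replace=False):
        seqs[out][s] = rng.choice(bases[bases != seqs[out][s]])
    return {t: "".join(s) for t, s in seqs.items()}
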