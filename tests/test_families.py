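"""Best-hit clustering, alignment search and the state matrix."""

import numpy as np
import pytest

from symbevol import (
    GenomeSet,
    ScoringConfig,
    all_vs_all_align,
    best_hit_edges,
    build_state_matrix,
    cluster,
)
from symbevol.align import bitscore, diagonal_score, local_align, make_aligner
from symbevol.records import SimilarityHit

from conftest import make_gene


def oracle_transitive_closure(edges, genes):
    """Brute-force components by repeated boolean matrix squaring."""
    genes = sorted(genes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adj = np.eye(n, dtype=bool)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    while True:
        nxt = adj @ adj
        if (nxt == adj).all():
            break
        adj = nxt
    comps = {}
    for i, g in enumerate(genes):
        key = tuple(np.flatnonzero(adj[i]))
        comps.setdefault(key, set()).add(g)
    return sorted(sorted(c) for c in comps.values())


def random_aa(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestCluster:
    def test_transitive_relation_joins_a_b_c(self):
        part = cluster([("a", "b"), ("a", "c")], ["a", "b", "c"])
        assert part.members(part.family_of("a")) == {"a", "b", "c"}

    def test_no_edges_gives_singletons(self):
        part = cluster([], list("abcde"))
        assert len(part) == 5

    def test_matches_bruteforce_oracle_on_random_graphs(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            genes = [f"g{i}" for i in range(n)]
            m = int(rng.integers(0, 2 * n))
            edges = [
                tuple(sorted(rng.choice(genes, size=2, replace=False)))
                for _ in range(m)
            ]
            part = cluster(edges, genes)
            got = sorted(sorted(part.members(f)) for f in part.family_ids)
            assert got == oracle_transitive_closure(edges, genes)

    def test_order_independence(self, rng):
        genes = [f"g{i}" for i in range(20)]
        edges = [("g0", "g5"), ("g5", "g9"), ("g1", "g2"), ("g9", "g12")]
        a = cluster(edges, genes)
        b = cluster(list(reversed(edges)), genes)
        assert a.families == b.families

    def test_unknown_gene_in_edge_is_error(self):
        with pytest.raises(ValueError, match="unknown gene"):
            cluster([("a", "zz")], ["a", "b"])


class TestBestHitEdges:
    @staticmethod
    def _hit(q, s, bits, ev=1e-30, ident=90.0):
        return SimilarityHit(q, s, ident, 100, 5, 0, 1, 100, 1, 100, ev, bits)

    @staticmethod
    def _gs():
        genomes = {
            "A": [make_gene("a", "A", 100)],
            "B": [make_gene("b1", "B", 100), make_gene("b2", "B", 100)],
        }
        return GenomeSet(genomes, {"A": "ingroup", "B": "ingroup"})

    def test_single_best_hit_per_genome(self):
        edges = best_hit_edges(
            [self._hit("a", "b1", 200), self._hit("a", "b2", 150)], self._gs()
        )
        assert edges == [("a", "b1")]

    def test_tie_broken_lexicographically(self):
        edges = best_hit_edges(
            [self._hit("a", "b2", 200), self._hit("a", "b1", 200)], self._gs()
        )
        assert edges == [("a", "b1")]

    def test_lower_evalue_beats_lexicographic(self):
        edges = best_hit_edges(
            [self._hit("a", "b1", 200, ev=1e-20), self._hit("a", "b2", 200, ev=1e-30)],
            self._gs(),
        )
        assert edges == [("a", "b2")]


class TestAllVsAllAlign:
    def test_identical_proteins_reciprocal_hits(self, rng):
        seq = random_aa(rng, 300)
        gs = GenomeSet(
            {"A": [make_gene("a", "A", aa_seq=seq)], "B": [make_gene("b", "B", aa_seq=seq)]},
            {"A": "ingroup", "B": "ingroup"},
        )
        hits = all_vs_all_align(gs)
        assert {(h.query_id, h.subject_id) for h in hits} == {("a", "b"), ("b", "a")}
        h1, h2 = hits
        assert h1.bitscore == h2.bitscore
        assert h1.identity_pct == 100.0

    def test_unrelated_random_proteins_produce_no_hits(self, rng):
        # empirical check on many independent pairs: the expected number of
        # >=50-bit local matches between unrelated 300-aa proteins is ~0
        n_pairs = 200
        genomes = {
            "A": [make_gene(f"a{i}", "A", aa_seq=random_aa(rng, 300)) for i in range(n_pairs)],
            "B": [make_gene(f"b{i}", "B", aa_seq=random_aa(rng, 300)) for i in range(n_pairs)],
        }
        gs = GenomeSet(genomes, {"A": "ingroup", "B": "ingroup"})
        assert all_vs_all_align(gs) == []

    def test_truncated_copy_hit_covers_prefix(self, rng):
        seq = random_aa(rng, 300)
        half = seq[:150]
        gs = GenomeSet(
            {"A": [make_gene("full", "A", aa_seq=seq)], "B": [make_gene("half", "B", aa_seq=half)]},
            {"A": "ingroup", "B": "ingroup"},
        )
        hits = {h.query_id: h for h in all_vs_all_align(gs)}
        assert hits["full"].qend == 150 and hits["full"].qstart == 1
        # oracle: exhaustive Smith-Waterman on the pair
        aligner = make_aligner(ScoringConfig(), mode="local")
        assert hits["full"].bitscore == pytest.approx(
            bitscore(aligner.score(seq, half)), abs=0.01
        )

    def test_substring_fast_path_equals_dp_score(self, rng):
        aligner = make_aligner(ScoringConfig(), mode="local")
        for _ in range(10):
            seq = random_aa(rng, 120)
            frag = seq[10:70]
            assert diagonal_score(frag) == pytest.approx(aligner.score(seq, frag))

    def test_missing_sequence_is_error(self):
        gs = GenomeSet(
            {"A": [make_gene("a", "A", 100)], "B": [
                make_gene("b", "B", aa_seq=None)
            ]},
            {"A": "ingroup", "B": "ingroup"},
        )
        gs.genomes["B"][0].aa_seq = None
        with pytest.raises(ValueError, match="amino-acid sequence"):
            all_vs_all_align(gs)


class TestStateMatrix:
    def _setup(self):
        genomes = {
            "A": [
                make_gene("a1", "A", 100, status="intact"),
                make_gene("a2", "A", 50, status="pseudogene"),
            ],
            "B": [make_gene("b1", "B", 60, status="pseudogene")],
            "C": [make_gene("c1", "C", 90, status="artifact")],
        }
        gs = GenomeSet(genomes, {g: "ingroup" for g in genomes})
        part = cluster([("a1", "b1"), ("a2", "a1"), ("b1", "c1")],
                       ["a1", "a2", "b1", "c1"])
        return gs, part

    def test_intact_dominates_pseudogene(self):
        gs, part = self._setup()
        sm = build_state_matrix(part, gs)
        fid = part.family_of("a1")
        assert sm.state(fid, "A") == "intact"
        assert sm.state(fid, "B") == "pseudogene"

    def test_artifacts_never_counted(self):
        gs, part = self._setup()
        sm = build_state_matrix(part, gs)
        assert sm.state(part.family_of("a1"), "C") == "absent"

    def test_absent_families(self):
        gs, part = self._setup()
        sm = build_state_matrix(part, gs)
        assert not sm.present(part.family_of("a1"), "D") if "D" in sm.genome_ids else True
        assert sm.state("FAM99999", "A") == "absent"

    def test_report_tokens_and_fragmented_flag(self, tmp_path):
        gs, part = self._setup()
        sm = build_state_matrix(part, gs)
        p = tmp_path / "sm.tsv"
        sm.write_tsv(p)
        text = p.read_text()
        assert "Intact" in text and "Pseudogene" in text and "Absent" in text
        assert "(Fg)" in text  # a1+a2 share family and genome A


class TestSymmetry:
    def test_genome_relabeling_permutes_but_preserves_families(self, rng):
        seqs = {f"f{i}": random_aa(rng, 150) for i in range(5)}
        def build(names):
            genomes = {
                n: [make_gene(f"{n}_{f}", n, aa_seq=s) for f, s in seqs.items()]
                for n in names
            }
            return GenomeSet(genomes, {n: "ingroup" for n in names})

        gs1, gs2 = build(["X", "Y"]), build(["P", "Q"])
        p1 = all_vs_all_align(gs1)
        p2 = all_vs_all_align(gs2)
        part1 = cluster(best_hit_edges(p1, gs1), [r.gene_id for r in gs1.all_records()])
        part2 = cluster(best_hit_edges(p2, gs2), [r.gene_id for r in gs2.all_records()])
        strip1 = sorted(sorted(g.split("_", 1)[1] for g in part1.members(f)) for f in part1.family_ids)
        strip2 = sorted(sorted(g.split("_", 1)[1] for g in part2.members(f)) for f in part2.family_ids)
        assert strip1 == strip2
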