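"""Annotation triage rules: artifacts, the 80% rule, 5' rescue, contig edge."""

import pytest

from symbevol import (
    GenomeSet,
    classify_pseudogenes,
    flag_artifacts,
    rescue_five_prime,
    apply_contig_edge_rule,
    apply_status_rules,
    cluster,
)
from symbevol.status import truncation_side

from conftest import make_gene


class TestArtifacts:
    def test_short_gene_without_evidence_is_artifact(self):
        g = make_gene("g", "A", 90)
        (call,) = flag_artifacts([g], {})
        assert call.new_status == "artifact"
        assert call.rule_fired == "artifact_short_no_evidence"
        assert g.status == "artifact"

    def test_short_gene_with_domain_is_kept(self):
        g = make_gene("g", "A", 90, domains=[("d1", 1, 20)])
        (call,) = flag_artifacts([g], {})
        assert call.rule_fired == "no_change" and g.status != "artifact"

    def test_short_gene_with_hit_is_kept(self):
        g = make_gene("g", "A", 90)
        (call,) = flag_artifacts([g], {"g": True})
        assert call.rule_fired == "no_change"

    def test_threshold_is_strictly_below_100(self):
        g = make_gene("g", "A", 100)
        (call,) = flag_artifacts([g], {})
        assert call.rule_fired == "no_change"

    def test_missing_sequence_is_error(self):
        g = make_gene("g", "A", 90)
        g.aa_seq = None
        with pytest.raises(ValueError, match="g"):
            flag_artifacts([g], {})


class TestLengthRule:
    def _family(self, member_len, ref_lens=(300, 310), member_domains=(),
                ref_domains=()):
        refs = [
            make_gene(f"r{i}", f"R{i}", n, status="intact", domains=ref_domains)
            for i, n in enumerate(ref_lens)
        ]
        m = make_gene("m", "M", member_len, domains=member_domains)
        return [m] + refs, m

    def test_truncated_member_becomes_pseudogene(self):
        members, m = self._family(150)
        calls = {c.gene_id: c for c in classify_pseudogenes(members)}
        assert m.status == "pseudogene"
        assert calls["m"].rule_fired == "length_lt_80"
        assert calls["m"].reference_length == 305
        assert calls["m"].length_ratio == pytest.approx(150 / 305)

    @pytest.mark.parametrize(
        "member_len,expected_status",
        [(241, "pseudogene"), (244, "unclassified"), (247, "unclassified")],
    )
    def test_threshold_is_strict_less_than_80_percent(self, member_len, expected_status):
        # reference median 305: ratios 0.790, 0.8000, 0.810
        members, m = self._family(member_len)
        classify_pseudogenes(members)
        assert m.status == expected_status

    def test_domain_exception_preserves_intact_status(self):
        members, m = self._family(
            150,
            member_domains=[("core", 10, 100)],
            ref_domains=[("core", 10, 100)],
        )
        calls = {c.gene_id: c for c in classify_pseudogenes(members)}
        assert m.status == "intact"
        assert calls["m"].rule_fired == "domain_exception"

    def test_missing_ancestral_domain_still_pseudogene(self):
        members, m = self._family(
            150,
            member_domains=[("other", 1, 10)],
            ref_domains=[("core", 10, 100)],
        )
        classify_pseudogenes(members)
        assert m.status == "pseudogene"

    def test_no_cross_genome_reference_leaves_unchanged(self):
        a = make_gene("a", "A", 100)
        b = make_gene("b", "A", 300, status="intact")  # same genome: not a reference
        calls = {c.gene_id: c for c in classify_pseudogenes([a, b])}
        assert a.status == "unclassified"
        assert calls["a"].rule_fired == "no_change"

    def test_intact_annotated_member_can_be_demoted(self):
        # the rule also demotes a short member the annotation called intact
        refs = [make_gene(f"r{i}", f"R{i}", 300, status="intact") for i in range(2)]
        m = make_gene("m", "M", 150, status="intact")
        classify_pseudogenes([m] + refs)
        assert m.status == "pseudogene"


class TestFivePrimeRescue:
    def _build(self, ext_codons_to_atg=30, stop_before_start=False):
        # contig: 40 upstream codons then the annotated gene (50 codons)
        up = ["GAA"] * 40
        up[40 - ext_codons_to_atg] = "ATG"
        if stop_before_start:
            up[40 - ext_codons_to_atg + 5] = "TAA"
        gene_nt = "ATGGCT" + "GCT" * 48
        contig = "".join(up) + gene_nt
        gene = make_gene(
            "p", "A", aa_seq="MA" + "A" * 48, status="pseudogene"
        )
        gene.start, gene.end = 121, 121 + len(gene_nt) - 1
        gene.nt_seq = gene_nt
        gene.contig_id = "c1"
        return gene, contig

    def test_upstream_start_restores_intact(self):
        gene, contig = self._build(ext_codons_to_atg=30)
        call = rescue_five_prime(gene, contig, reference_length=100, side="5prime")
        assert call.rule_fired == "five_prime_rescue"
        assert gene.status == "intact"
        assert gene.start == 121 - 90  # extended by 30 codons

    def test_in_frame_stop_blocks_rescue(self):
        gene, contig = self._build(ext_codons_to_atg=30, stop_before_start=True)
        call = rescue_five_prime(gene, contig, reference_length=100, side="5prime")
        assert call.rule_fired == "no_change" and gene.status == "pseudogene"

    def test_three_prime_truncation_not_rescued(self):
        gene, contig = self._build()
        call = rescue_five_prime(gene, contig, reference_length=100, side="3prime")
        assert call.rule_fired == "no_change" and gene.status == "pseudogene"

    def test_insufficient_extension_not_rescued(self):
        gene, contig = self._build(ext_codons_to_atg=10)  # reaches 60 < 80 aa
        call = rescue_five_prime(gene, contig, reference_length=100, side="5prime")
        assert call.rule_fired == "no_change"

    def test_missing_contig_skips_with_warning(self, caplog):
        gene, _ = self._build()
        with caplog.at_level("WARNING"):
            call = rescue_five_prime(gene, None, reference_length=100, side="5prime")
        assert call.rule_fired == "no_change"
        assert "skipped" in caplog.text

    def test_truncation_side_detects_missing_5prime(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(aas, size=300))
        ref = make_gene("r", "R", aa_seq=seq, status="intact")
        frag = make_gene("f", "F", aa_seq=seq[150:])
        assert truncation_side(frag, ref) == "5prime"
        frag3 = make_gene("f3", "F", aa_seq=seq[:150])
        assert truncation_side(frag3, ref) == "3prime"


class TestContigEdgeRule:
    def test_edge_gene_without_stop_is_active(self):
        g = make_gene("g", "A", aa_seq="MA" * 50, status="pseudogene",
                      contig_edge=True)
        g.nt_seq = "ATGGCT" * 50  # no stop codons anywhere
        call = apply_contig_edge_rule(g)
        assert call.rule_fired == "contig_edge_active"
        assert g.status == "intact"

    def test_internal_stop_keeps_pseudogene(self):
        g = make_gene("g", "A", aa_seq="MA" * 50, status="pseudogene",
                      contig_edge=True)
        g.nt_seq = "ATGGCT" * 20 + "TAA" + "GCT" * 29
        call = apply_contig_edge_rule(g)
        assert call.rule_fired == "no_change" and g.status == "pseudogene"

    def test_non_edge_gene_untouched(self):
        g = make_gene("g", "A", aa_seq="MA" * 50, status="pseudogene")
        g.nt_seq = "ATGGCT" * 50
        call = apply_contig_edge_rule(g)
        assert call.rule_fired == "no_change" and g.status == "pseudogene"

    def test_trailing_partial_codon_ignored(self):
        g = make_gene("g", "A", aa_seq="MA" * 50, status="pseudogene",
                      contig_edge=True)
        g.nt_seq = "ATGGCT" * 50 + "TA"  # broken end
        apply_contig_edge_rule(g)
        assert g.status == "intact"


class TestFixedOrderPipeline:
    def _genomeset(self):
        seq = "MKVLADGRTE" * 30  # 300 aa
        genomes = {
            "A": [make_gene("a_full", "A", aa_seq=seq, status="intact")],
            "B": [make_gene("b_full", "B", aa_seq=seq, status="intact"),
                  make_gene("b_orphan", "B", 50)],
            "C": [make_gene("c_trunc", "C", aa_seq=seq[:150])],
        }
        return GenomeSet(genomes, {g: "ingroup" for g in genomes})

    def test_rules_apply_in_order_and_idempotently(self):
        gs = self._genomeset()
        edges = [("a_full", "b_full"), ("a_full", "c_trunc")]
        part = cluster(edges, [r.gene_id for r in gs.all_records()])
        has_hit = {"a_full": True, "b_full": True, "c_trunc": True}
        apply_status_rules(gs, part, has_hit)
        statuses = {r.gene_id: r.status for r in gs.all_records()}
        assert statuses["b_orphan"] == "artifact"
        assert statuses["c_trunc"] == "pseudogene"
        assert statuses["a_full"] == "intact"
        apply_status_rules(gs, part, has_hit)  # re-application: no change
        assert {r.gene_id: r.status for r in gs.all_records()} == statuses
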