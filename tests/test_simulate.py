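"""The gene-content evolution simulator and its truth bookkeeping."""

import numpy as np
import pytest

from symbevol import (
    EvolutionConfig,
    emit,
    mutate_cds,
    replay_substitutions,
    simulate,
)
from symbevol.io import load_genome_set
from symbevol.kaks import codon_sites
from symbevol.records import STOP_CODONS


def quiet_config(**kw):
    base = dict(
        ancestral_size=40,
        loss_prob=0.0,
        pseudo_prob=0.0,
        hgt_rate=0.0,
        dup_prob=0.0,
        syn_rate=0.0,
        nonsyn_rate=0.0,
        seed=42,
    )
    base.update(kw)
    return EvolutionConfig(**base)


class TestIdentityAndDeterminism:
    def test_no_events_gives_identical_genomes(self):
        gs, truth = simulate(quiet_config())
        seqs = {
            g: sorted(r.nt_seq for r in recs) for g, recs in gs.genomes.items()
        }
        ref = next(iter(seqs.values()))
        assert all(s == ref for s in seqs.values())
        assert all(s == "intact" for s in truth.states.values())
        assert all(truth.ancestral.values())

    def test_same_seed_same_output(self, tmp_path):
        cfg = EvolutionConfig(ancestral_size=30, seed=9, syn_rate=0.02,
                              nonsyn_rate=0.01)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        for out in (out1, out2):
            cfg_copy = EvolutionConfig(**{**cfg.__dict__})
            gs, truth = simulate(cfg_copy)
            emit(gs, truth, None, out, cfg_copy)
        files1 = sorted(p.name for p in out1.rglob("*") if p.is_file())
        files2 = sorted(p.name for p in out2.rglob("*") if p.is_file())
        assert files1 == files2
        for name in files1:
            a = next(out1.rglob(name)).read_bytes()
            b = next(out2.rglob(name)).read_bytes()
            assert a == b, name

    def test_invalid_probabilities_rejected_before_generation(self):
        with pytest.raises(ValueError, match="loss_prob"):
            simulate(quiet_config(loss_prob=1.4))
        with pytest.raises(ValueError, match="loss_prob \\+ pseudo_prob"):
            simulate(quiet_config(loss_prob=0.7, pseudo_prob=0.5))
        with pytest.raises(ValueError, match="syn_rate"):
            simulate(quiet_config(syn_rate=-0.1))


class TestEventModel:
    def test_total_loss_on_leaf_branch_empties_that_genome(self):
        cfg = quiet_config(loss_prob={"sym3": 1.0, "default": 0.0})
        gs, truth = simulate(cfg)
        assert gs.genomes["sym3"] == []
        assert len(truth.losses_on_branch("sym3")) == 40
        assert len(gs.genomes["sym1"]) == 40

    def test_conservation_no_resurrection(self):
        cfg = EvolutionConfig(ancestral_size=300, loss_prob=0.2, pseudo_prob=0.1,
                              hgt_rate=0.0, dup_prob=0.0, sequences=False, seed=5)
        gs, truth = simulate(cfg)
        # path from root to each leaf in the default topology
        paths = {
            "sym1": ["ingroup", "cladeA", "sym1"],
            "sym2": ["ingroup", "cladeA", "sym2"],
            "sym3": ["ingroup", "sym3"],
            "out1": ["outs", "out1"],
            "out2": ["outs", "out2"],
        }
        for genome, path in paths.items():
            lost = set()
            for branch in path:
                lost |= set(truth.losses_on_branch(branch))
            present = {
                fam
                for fam in truth.ancestral
                if fam.startswith("AF") and truth.state(fam, genome) != "absent"
            }
            assert len(present) + len(lost) == 300
            assert not (present & lost)

    def test_pseudogene_truncation_strictly_below_80_percent(self):
        cfg = quiet_config(ancestral_size=150, pseudo_prob=0.3, seed=17)
        gs, truth = simulate(cfg)
        ancestors = truth.ancestor_seqs
        n_pseudo = 0
        for recs in gs.genomes.values():
            for r in recs:
                fam = r.gene_id.split("|")[1]
                if truth.state(fam, r.genome_id) == "pseudogene":
                    n_pseudo += 1
                    ratio = len(r.nt_seq) / len(ancestors[fam])
                    assert ratio < 0.80
                    assert ratio >= 0.18
                    assert r.status == "unclassified"
                    # truncated CDS contains no stop codon at all
                    codons = {r.nt_seq[i:i + 3] for i in range(0, len(r.nt_seq), 3)}
                    assert not (codons & STOP_CODONS)
        assert n_pseudo > 50

    def test_hgt_families_are_mobile_and_never_ancestral(self):
        cfg = quiet_config(hgt_rate=2.0, seed=3)
        gs, truth = simulate(cfg)
        hgt_fams = {f for f in truth.family_members if f.startswith("HF")}
        assert hgt_fams
        for fam in hgt_fams:
            assert truth.mobile_category[fam] in (
                "phage", "plasmid", "transposase", "toxin_antitoxin"
            )
        below_mrca = {
            f for f in hgt_fams
            if not any(
                f in truth.events.get(b, {}).get("acquisitions", [])
                for b in ("ingroup",)
            )
        }
        for fam in below_mrca - {None}:
            acquired_on = [
                b for b, ev in truth.events.items()
                if fam in ev.get("acquisitions", [])
            ]
            if acquired_on != ["ingroup"]:
                assert not truth.ancestral[fam]

    def test_duplication_adds_same_family_copy(self):
        cfg = quiet_config(dup_prob=0.3, seed=8)
        gs, truth = simulate(cfg)
        multi = [f for f, m in truth.family_members.items()
                 if any(sum(1 for g in m if g.startswith(gen + "|")) > 1
                        for gen in gs.genome_ids)]
        assert multi  # at least one within-genome duplicate pair exists


class TestSubstitutionBookkeeping:
    def test_replay_reproduces_extant_cds(self):
        cfg = quiet_config(ancestral_size=30, syn_rate=0.05, nonsyn_rate=0.05,
                           seed=21)
        gs, truth = simulate(cfg)
        checked = 0
        for recs in gs.genomes.values():
            for r in recs:
                fam = r.gene_id.split("|")[1]
                expected = replay_substitutions(
                    truth.ancestor_seqs[fam], truth.substitutions[r.gene_id]
                )
                assert r.nt_seq[:-3] == expected  # minus terminal stop
                checked += 1
        assert checked > 100

    def test_mutate_cds_respects_class_labels(self, rng):
        from symbevol.kaks import translate_codon

        cfg = quiet_config(ancestral_size=1)
        gs, _ = simulate(cfg)
        seq = gs.genomes["sym1"][0].nt_seq[:-3]
        mutated, subs = mutate_cds(seq, 0.05, 0.02, rng)
        cur = list(seq)
        for s in subs:
            codon_i = s.position // 3
            old_codon = "".join(cur[3 * codon_i : 3 * codon_i + 3])
            cur[s.position] = s.new
            new_codon = "".join(cur[3 * codon_i : 3 * codon_i + 3])
            same_aa = translate_codon(old_codon) == translate_codon(new_codon)
            assert (s.kind == "syn") == same_aa
        assert "".join(cur) == mutated

    def test_mean_substitution_count_tracks_rate(self, rng):
        cfg = quiet_config(ancestral_size=1, codon_len_mean=500, codon_len_min=500)
        gs, _ = simulate(cfg)
        seq = gs.genomes["sym1"][0].nt_seq[:-3]
        S = sum(codon_sites(seq[i:i + 3])[0] for i in range(0, len(seq), 3))
        counts = [len(mutate_cds(seq, 0.04, 0.0, rng)[1]) for _ in range(50)]
        expected = 0.04 * S
        se = np.sqrt(expected / 50)
        assert abs(np.mean(counts) - expected) < 4 * se


class TestBranchLossExpectation:
    def test_mean_losses_match_binomial_expectation(self):
        # oracle: losses on one branch ~ Binomial(n_at_branch, p)
        n, p, reps = 1000, 0.2, 60
        losses = []
        for seed in range(reps):
            cfg = EvolutionConfig(
                ancestral_size=n, sequences=False, seed=seed,
                loss_prob={"sym3": p, "default": 0.0}, pseudo_prob=0.0,
                hgt_rate=0.0, dup_prob=0.0,
            )
            _, truth = simulate(cfg)
            losses.append(len(truth.losses_on_branch("sym3")))
        se = np.sqrt(n * p * (1 - p) / reps)
        assert abs(np.mean(losses) - n * p) < 3 * se


class TestEmit:
    def test_roundtrip_reproduces_genomeset(self, tmp_path):
        cfg = quiet_config(ancestral_size=25, pseudo_prob=0.2, hgt_rate=0.5,
                           domain_frac=0.5, seed=13)
        gs, truth = simulate(cfg)
        emit(gs, truth, None, tmp_path / "out", cfg)
        back = load_genome_set(tmp_path / "out")
        assert back.genome_ids == gs.genome_ids
        assert back.roles == gs.roles and back.clades == gs.clades
        for g in gs.genome_ids:
            orig = {r.gene_id: r for r in gs.genomes[g]}
            readback = {r.gene_id: r for r in back.genomes[g]}
            assert orig.keys() == readback.keys()
            for gid, r in orig.items():
                rb = readback[gid]
                assert (rb.nt_seq, rb.aa_seq, rb.status) == (r.nt_seq, r.aa_seq, r.status)
                assert rb.domains == r.domains

    def test_truth_files_written(self, tmp_path):
        cfg = quiet_config(seed=1)
        gs, truth = simulate(cfg)
        emit(gs, truth, None, tmp_path / "o", cfg)
        for name in ("family_states.tsv", "branch_events.tsv",
                     "substitutions.tsv", "families.tsv"):
            assert (tmp_path / "o" / "truth" / name).exists()

    def test_emitted_status_is_structure_derived(self, tmp_path):
        cfg = quiet_config(ancestral_size=60, pseudo_prob=0.4, seed=4)
        gs, truth = simulate(cfg)
        for recs in gs.genomes.values():
            for r in recs:
                fam = r.gene_id.split("|")[1]
                true_state = truth.state(fam, r.genome_id)
                if true_state == "pseudogene":
                    assert r.status == "unclassified"
                else:
                    assert r.status == "intact"
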