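"""Generator contracts: planted truth, determinism, offspring and reads."""

import numpy as np
import pytest

from tandemscan.compare import translate_cds
from tandemscan.seqio import read_fasta, read_gff3
from tandemscan.synthetic import (
    DivergenceSpec,
    GeneStructure,
    ScenarioParameterError,
    generate_scenario,
    sample_offspring,
    simulate_reads,
    write_scenario,
)


class TestGenerateScenario:
    def test_planted_divergence_matches_spec(self, scenario):
        cat = scenario.truth_catalog
        div = scenario.divergence
        assert len(cat.coding_substitutions) == div.n_coding_snvs
        assert len({s.feature for s in cat.coding_substitutions}) == div.n_affected_exons
        assert [i.length for i in cat.coding_indels] == [div.coding_indel_len]
        assert cat.coding_indels[0].bearer == "a_lacks"
        assert len(cat.noncoding_indels) == div.n_noncoding_indels
        lo, hi = div.noncoding_indel_len_range
        assert all(lo <= i.length <= hi for i in cat.noncoding_indels)

    def test_locus_layout(self, scenario):
        # geneA then intergenic then geneB on the same strand, flanked
        assert scenario.true_locus.count(scenario.unit_a) == 1
        assert scenario.true_locus.count(scenario.unit_b) == 1
        assert scenario.true_locus.index(scenario.unit_a) < scenario.true_locus.index(
            scenario.unit_b)
        assert scenario.truth["stop_to_start_intergenic_len"] == 1511

    def test_collapsed_reference_is_chimera(self, scenario):
        s, e = scenario.truth["inserted_interval_locus"]
        assert e - s == scenario.truth["collapse_length"]
        assert len(scenario.true_locus) - len(scenario.collapsed_reference) == e - s
        assert scenario.collapsed_reference == (
            scenario.true_locus[:s] + scenario.true_locus[e:])

    def test_cdna_lengths_differ_by_coding_indel(self, scenario):
        assert len(scenario.cdna_b) - len(scenario.cdna_a) == 12
        assert len(scenario.cds_a) == 2478
        assert len(scenario.cds_b) == 2490

    def test_cds_translates_cleanly(self, scenario):
        assert len(translate_cds(scenario.cds_a)) == 825
        assert len(translate_cds(scenario.cds_b)) == 829

    def test_zero_divergence_gives_identical_paralogs(self):
        div = DivergenceSpec(n_coding_snvs=0, n_affected_exons=0, coding_indel_len=0,
                             n_noncoding_indels=0, n_nonsyn_subs=0, intron_sub_rate=0.0,
                             restriction_marker=False)
        sc = generate_scenario(divergence=div, seed=3)
        assert sc.unit_a == sc.unit_b
        assert not sc.truth_catalog.substitutions
        assert not sc.truth_catalog.indels

    def test_determinism_byte_identical(self, tmp_path):
        d1 = write_scenario(generate_scenario(seed=11), tmp_path / "s1")
        d2 = write_scenario(generate_scenario(seed=11), tmp_path / "s2")
        for name in ("truth_locus.fasta", "collapsed_ref.fasta", "annotations.gff3",
                     "cdna_a.fasta", "cdna_b.fasta", "outgroup.fasta", "reads.fasta",
                     "truth.json", "offspring.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self):
        assert generate_scenario(seed=1).true_locus != generate_scenario(seed=2).true_locus

    def test_infeasible_divergence_raises(self):
        with pytest.raises(ScenarioParameterError):
            DivergenceSpec(n_coding_snvs=3, n_nonsyn_subs=5)
        with pytest.raises(ScenarioParameterError):
            DivergenceSpec(coding_indel_len=10)
        with pytest.raises(ScenarioParameterError):
            GeneStructure(n_exons=2, exon_lengths=(10, 10), intron_lengths=(50,),
                          utr5_len=10, utr3_len=10)   # CDS not divisible by 3

    def test_scenario_directory_roundtrip(self, scenario, tmp_path):
        d = write_scenario(scenario, tmp_path / "scen")
        assert read_fasta(d / "truth_locus.fasta")["true_locus"] == scenario.true_locus
        assert read_fasta(d / "cdna_a.fasta")["cdna_a"] == scenario.cdna_a
        feats = read_gff3(d / "annotations.gff3")
        genes = [f for f in feats if f.ftype == "gene"]
        assert [g.name for g in genes] == ["geneA", "geneB"]
        # GFF3 round-trip preserves 0-based internal coordinates
        by_name = {f.name: f for f in scenario.features}
        for g in genes:
            assert (g.start, g.end) == (by_name[g.name].start, by_name[g.name].end)


class TestSampleOffspring:
    def test_homozygote_breeds_true(self):
        assert sample_offspring("hom_mut", 100, seed=1) == (0, 0, 100)
        assert sample_offspring("hom_wt", 50, seed=1) == (50, 0, 0)

    def test_heterozygote_large_sample_proportions(self):
        n = 100_000
        ww, wm, mm = sample_offspring("het", n, seed=5)
        assert ww + wm + mm == n
        # 3 sigma around the 1:2:1 expectation
        for obs, p in ((ww, 0.25), (wm, 0.5), (mm, 0.25)):
            sd = (n * p * (1 - p)) ** 0.5
            assert abs(obs - n * p) < 3 * sd

    def test_matches_multinomial_oracle(self):
        got = sample_offspring("het", 114, seed=42)
        oracle = np.random.default_rng(42).multinomial(114, (0.25, 0.5, 0.25))
        assert got == tuple(oracle)

    def test_parameter_validation(self):
        with pytest.raises(ScenarioParameterError):
            sample_offspring("het", 0, seed=1)
        with pytest.raises(ScenarioParameterError):
            sample_offspring("tetraploid", 10, seed=1)


class TestSimulateReads:
    def test_expected_interior_depth(self):
        template = "".join(
            "ACGT"[i] for i in np.random.default_rng(0).integers(0, 4, size=10_000))
        reads = simulate_reads(template, read_len=100, depth=30, seed=9)
        depth = np.zeros(len(template))
        for seq in reads.values():
            # error-free reads: locate by exact match against either strand
            from tandemscan.coverage import revcomp
            i = template.find(seq)
            if i < 0:
                i = template.find(revcomp(seq))
            assert i >= 0
            depth[i:i + 100] += 1
        interior = depth[500:-500]
        assert abs(interior.mean() - 30) < 5 * np.sqrt(30 / len(interior) * 100)

    def test_single_read(self):
        template = "ACGTACGTACGTACGTACGT" * 10
        reads = simulate_reads(template, read_len=50, depth=50 / len(template), seed=0)
        assert len(reads) == 1

    def test_determinism_and_errors(self):
        t = "ACGT" * 100
        assert simulate_reads(t, 50, 5, seed=3) == simulate_reads(t, 50, 5, seed=3)
        with pytest.raises(ScenarioParameterError):
            simulate_reads(t, 50, 0, seed=1)
        with pytest.raises(ScenarioParameterError):
            simulate_reads(t, 1000, 5, seed=1)
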