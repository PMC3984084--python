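"""In-silico PCR: site finding vs brute force, products, arrangement logic."""

import numpy as np
import pytest

from tandemscan.pcr import (
    Primer,
    arrangement_truth_table,
    classify_arrangement,
    design_discriminating_primers,
    find_sites,
    predict_products,
    revcomp,
    toy_template,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_sites(primer: Primer, template: str):
    """Independent position-by-position scan with the same annealing rules."""
    hits = []
    m = len(primer.sequence)
    for strand in "+-":
        for i in range(len(template) - m + 1):
            window = template[i:i + m]
            probe = window if strand == "+" else revcomp(window)
            mism = [k for k in range(m)
                    if probe[k] not in IUPAC.get(primer.sequence[k], "")
                    or probe[k] not in "ACGT"]
            if any(k >= m - primer.anchor3_len for k in mism):
                continue
            if len(mism) > primer.max_mismatches:
                continue
            pos3 = i + m - 1 if strand == "+" else i
            hits.append((strand, pos3, len(mism)))
    return sorted(hits)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestFindSites:
    def test_unique_plus_site(self, rng):
        t = random_dna(rng, 400)
        p = Primer("p", t[100:120])
        sites = find_sites(p, t)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1 and plus[0].pos3 == 119 and plus[0].mismatches == 0

    def test_reverse_complement_site(self, rng):
        t = random_dna(rng, 400)
        p = Primer("p", revcomp(t[200:220]))
        sites = [s for s in find_sites(p, t) if s.strand == "-"]
        assert len(sites) == 1 and sites[0].pos3 == 200

    def test_internal_mismatch_tolerance(self, rng):
        t = random_dna(rng, 300)
        probe = list(t[50:70])
        orig = probe[5]
        probe[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
        strict = Primer("s", "".join(probe), max_mismatches=0)
        loose = Primer("l", "".join(probe), max_mismatches=1)
        assert not [s for s in find_sites(strict, t) if s.strand == "+" and s.pos3 == 69]
        hit = [s for s in find_sites(loose, t) if s.strand == "+" and s.pos3 == 69]
        assert len(hit) == 1 and hit[0].mismatches == 1

    def test_three_prime_anchor_rejects_terminal_mismatch(self, rng):
        t = random_dna(rng, 300)
        probe = list(t[50:70])
        probe[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[probe[-1]]
        p = Primer("p", "".join(probe), max_mismatches=2)
        assert not [s for s in find_sites(p, t) if s.strand == "+" and s.pos3 == 69]

    def test_degenerate_codes_match_compatible_bases(self):
        t = "CCCCCCCCCCAGTCAGTCAGTCCCCCCCCCC"
        p = Primer("p", "AGTCAGTCAGTC".replace("G", "R", 1) + "CCC")
        assert any(s.strand == "+" for s in find_sites(p, t))

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(60):
            t = random_dna(rng, 250)
            m = int(rng.integers(18, 26))
            if rng.random() < 0.7:
                start = int(rng.integers(0, len(t) - m))
                seq = list(t[start:start + m])
                for _ in range(int(rng.integers(0, 3))):
                    k = int(rng.integers(0, m))
                    seq[k] = "ACGT"[int(rng.integers(0, 4))]
                seq = "".join(seq)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
            else:
                seq = random_dna(rng, m)
            p = Primer("p", seq, max_mismatches=int(rng.integers(0, 3)))
            got = sorted((s.strand, s.pos3, s.mismatches) for s in find_sites(p, t))
            assert got == oracle_sites(p, t)


class TestPredictProducts:
    def test_convergent_pair_yields_exact_slice(self, rng):
        t = random_dna(rng, 600)
        fwd = Primer("f", t[100:120])
        rev = Primer("r", revcomp(t[400:420]))
        res = predict_products([fwd, rev], t)
        assert len(res.amplicons) == 1
        a = res.amplicons[0]
        assert (a.start, a.end, a.length) == (100, 420, 320)
        assert a.sequence == t[100:420]

    def test_same_primer_pair_amplifies(self, rng):
        t = random_dna(rng, 600)
        core = random_dna(rng, 20)
        t = t[:100] + core + t[120:300] + revcomp(core) + t[320:]
        res = predict_products([Primer("p", core)], t)
        assert len(res.amplicons) == 1
        assert res.amplicons[0].length == 320 - 100

    def test_divergent_and_same_strand_never_amplify(self, rng):
        t = random_dna(rng, 600)
        # outward-facing on a single-copy template
        a = Primer("a", revcomp(t[50:70]))
        b = Primer("b", t[500:520])
        assert not predict_products([a, b], t).amplicons
        # two forward primers
        assert not predict_products([Primer("x", t[50:70]), Primer("y", t[300:320])],
                                    t).amplicons

    def test_max_product_len_is_enforced(self, rng):
        t = random_dna(rng, 3000)
        fwd = Primer("f", t[0:20])
        rev = Primer("r", revcomp(t[2500:2520]))
        assert predict_products([fwd, rev], t, max_product_len=2520).amplicons
        assert not predict_products([fwd, rev], t, max_product_len=2000).amplicons


class TestArrangementDiagnosis:
    def test_truth_table_rows(self):
        table = arrangement_truth_table()
        assert table["single"] == {"A": False, "B": False, "A+B": False}
        assert table["head_to_tail"] == {"A": False, "B": False, "A+B": True}
        assert table["head_to_head"]["A"] and not table["head_to_head"]["B"]
        assert table["tail_to_tail"]["B"] and not table["tail_to_tail"]["A"]

    @pytest.mark.parametrize("arrangement", ["single", "head_to_tail",
                                             "head_to_head", "tail_to_tail"])
    @pytest.mark.parametrize("spacer,flank", [(200, 300), (454, 127), (901, 50)])
    def test_classifier_inverts_predictor(self, arrangement, spacer, flank):
        from tandemscan.pcr import _toy_parts
        _, pa, pb = _toy_parts()
        tmpl = toy_template(arrangement, spacer_len=spacer, flank_len=flank)
        ev = {"A": predict_products([pa], tmpl).has_product,
              "B": predict_products([pb], tmpl).has_product,
              "A+B": predict_products([pa, pb], tmpl).has_product}
        assert classify_arrangement(ev).arrangement == arrangement

    def test_unenumerated_pattern_is_inconsistent(self):
        assert classify_arrangement(
            {"A": True, "B": True, "A+B": True}).arrangement == "inconsistent"

    def test_missing_reaction_raises(self):
        with pytest.raises(ValueError):
            classify_arrangement({"A": True, "B": False})

    def test_scenario_locus_is_head_to_tail(self, scenario):
        pa = Primer("A", scenario.primers["A"])
        pb = Primer("B", scenario.primers["B"])
        ev = {"A": predict_products([pa], scenario.true_locus).has_product,
              "B": predict_products([pb], scenario.true_locus).has_product,
              "A+B": predict_products([pa, pb], scenario.true_locus).has_product}
        assert ev == {"A": False, "B": False, "A+B": True}
        assert classify_arrangement(ev).arrangement == "head_to_tail"
        # the single product spans the intergenic region
        amp = predict_products([pa, pb], scenario.true_locus).amplicons[0]
        assert amp.length == scenario.truth["stop_to_start_intergenic_len"] + 2 * 40

    def test_collapsed_reference_looks_single(self, scenario):
        pa = Primer("A", scenario.primers["A"])
        pb = Primer("B", scenario.primers["B"])
        ev = {"A": predict_products([pa], scenario.collapsed_reference).has_product,
              "B": predict_products([pb], scenario.collapsed_reference).has_product,
              "A+B": predict_products([pa, pb], scenario.collapsed_reference).has_product}
        assert classify_arrangement(ev).arrangement == "single"


class TestDiscriminatingPrimers:
    def test_identical_paralogs_yield_nothing(self, rng):
        s = random_dna(rng, 800)
        res = design_discriminating_primers(s, s)
        assert res == {"a": [], "b": []}

    def test_single_divergent_position_anchors_all_candidates(self, rng):
        a = random_dna(rng, 500)
        b = list(a)
        b[250] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[250]]
        b = "".join(b)
        res = design_discriminating_primers(a, b)
        for key, pos in (("a", 250), ("b", 250)):
            for pair in res[key]:
                assert pair.discriminating_end == pos

    def test_scenario_candidates_are_specific(self, scenario):
        res = design_discriminating_primers(scenario.cdna_a, scenario.cdna_b)
        assert res["a"] and res["b"]
        targets = {"a": (scenario.cdna_a, scenario.cdna_b),
                   "b": (scenario.cdna_b, scenario.cdna_a)}
        for key, (target, off) in targets.items():
            for pair in res[key]:
                on = predict_products([pair.fwd, pair.rev], target)
                cross = predict_products([pair.fwd, pair.rev], off)
                assert on.has_product and not cross.has_product
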