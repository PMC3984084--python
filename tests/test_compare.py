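"""Alignment, identity bookkeeping, diff catalogs, protein diffs, trio."""

import numpy as np
import pytest

from tandemscan.compare import (
    NT_GAP_EXTEND,
    NT_GAP_OPEN,
    NT_MATCH,
    NT_MISMATCH,
    align_pair,
    catalog_diffs,
    feature_identity,
    protein_diff,
    translate_cds,
    trio_analysis,
)

NEG = float("-inf")


def oracle_affine_score(a, b):
    """Exhaustive three-state affine-gap DP with the same scoring convention
    (a gap of length k costs open + (k-1)*extend; end gaps penalised)."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)   # a[i-1] aligned to b[j-1]
    X = np.full((n + 1, m + 1), NEG)   # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)   # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = NT_MATCH if a[i - 1] == b[j - 1] else NT_MISMATCH
                M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            if i > 0:
                X[i, j] = max(M[i - 1, j] + NT_GAP_OPEN,
                              X[i - 1, j] + NT_GAP_EXTEND,
                              Y[i - 1, j] + NT_GAP_OPEN)
            if j > 0:
                Y[i, j] = max(M[i, j - 1] + NT_GAP_OPEN,
                              Y[i, j - 1] + NT_GAP_EXTEND,
                              X[i, j - 1] + NT_GAP_OPEN)
    return max(M[n, m], X[n, m], Y[n, m])


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestAlignPair:
    def test_identical_sequences(self, rng):
        s = random_dna(rng, 200)
        aln = align_pair(s, s)
        assert "-" not in aln.aligned_a and "-" not in aln.aligned_b
        assert aln.identity() == 100.0

    def test_single_clean_deletion(self, rng):
        b = random_dna(rng, 300)
        a = b[:140] + b[152:]
        aln = align_pair(a, b)
        gaps_a = aln.aligned_a.count("-")
        assert gaps_a == 12 and aln.aligned_b.count("-") == 0
        mismatches = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                         if "-" not in (x, y) and x != y)
        assert mismatches == 0

    def test_coordinate_maps_are_mutually_inverse(self, rng):
        b = random_dna(rng, 250)
        a = b[:100] + b[110:200] + "ACGTACGT" + b[200:]
        aln = align_pair(a, b)
        for pa in range(0, len(a), 7):
            pb = aln.map_a_to_b(pa)
            if pb >= 0:
                assert aln.map_b_to_a(pb) == pa

    def test_score_matches_dp_oracle(self, rng):
        for _ in range(80):
            a = random_dna(rng, int(rng.integers(1, 61)))
            b = random_dna(rng, int(rng.integers(1, 61)))
            assert align_pair(a, b).score == pytest.approx(oracle_affine_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestFeatureIdentity:
    def test_long_gap_columns_are_excluded(self):
        # b carries a 3-bp segment absent from a; flanks identical
        b = "ACGTACGTAA" + "GGG" + "TTACGTACGT"
        a = "ACGTACGTAA" + "TTACGTACGT"
        aln = align_pair(a, b)
        fi = feature_identity(aln, [("all", 0, len(a))])[0]
        assert fi.long_indel_columns_excluded == 3
        assert fi.identity == 100.0
        assert fi.columns_counted == len(a)

    def test_single_base_gap_counts_as_mismatch(self):
        b = "ACGTACGTAA" + "G" + "TTACGTACGT"
        a = "ACGTACGTAA" + "TTACGTACGT"
        aln = align_pair(a, b)
        fi = feature_identity(aln, [("all", 0, len(a))])[0]
        assert fi.long_indel_columns_excluded == 0
        assert fi.columns_counted == len(a) + 1
        assert fi.identity == pytest.approx(100.0 * len(a) / (len(a) + 1))

    def test_identity_is_symmetric(self, rng):
        b = random_dna(rng, 400)
        a_l = list(b)
        for p in rng.choice(400, 12, replace=False):
            a_l[p] = "ACGT"[(("ACGT".index(a_l[p])) + 1) % 4]
        a = "".join(a_l)
        ab = feature_identity(align_pair(a, b), [("all", 0, len(a))])[0]
        ba = feature_identity(align_pair(b, a), [("all", 0, len(b))])[0]
        assert ab.identity == pytest.approx(ba.identity)

    def test_feature_outside_span_reports_error(self, rng):
        s = random_dna(rng, 100)
        fi = feature_identity(align_pair(s, s), [("bad", 50, 400)])[0]
        assert fi.error

    def test_scenario_exon_identities(self, scenario):
        aln = align_pair(scenario.unit_a, scenario.unit_b)
        per = feature_identity(aln, scenario.unit_features_a)
        by = {f.feature: f for f in per}
        affected = {s.feature for s in scenario.truth_catalog.coding_substitutions}
        for lab, fi in by.items():
            if not lab.startswith("exon"):
                continue
            if lab in affected:
                assert fi.identity < 100.0
            elif lab == "exon16":
                assert fi.identity == 100.0    # indel columns excluded
            else:
                assert fi.identity == 100.0


class TestCatalogDiffs:
    def test_identical_catalog_empty(self, rng):
        s = random_dna(rng, 300)
        cat = catalog_diffs(align_pair(s, s))
        assert not cat.substitutions and not cat.indels

    @pytest.mark.parametrize("seed", [0, 13, 99])
    def test_scenario_roundtrip_exact(self, seed):
        from tandemscan.synthetic import generate_scenario
        sc = generate_scenario(seed=seed)
        aln = align_pair(sc.unit_a, sc.unit_b)
        rec = catalog_diffs(aln, sc.unit_features_a)
        truth = sc.truth_catalog
        assert ({(s.pos_a, s.base_a, s.base_b) for s in rec.substitutions}
                == {(s.pos_a, s.base_a, s.base_b) for s in truth.substitutions})
        assert ({(i.pos_a, i.length, i.bearer) for i in rec.indels}
                == {(i.pos_a, i.length, i.bearer) for i in truth.indels})

    def test_positions_strictly_increasing(self, scenario):
        aln = align_pair(scenario.unit_a, scenario.unit_b)
        cat = catalog_diffs(aln, scenario.unit_features_a)
        pos = [s.pos_a for s in cat.substitutions]
        assert pos == sorted(pos) and len(set(pos)) == len(pos)


class TestProteinDiff:
    def test_identical_cds_empty(self):
        cds = "ATG" + "GCT" * 50 + "TAA"
        d = protein_diff(cds, cds)
        assert not d.substitutions and not d.indels

    def test_internal_stop_is_an_error(self):
        cds = "ATG" + "GCT" * 10 + "TAA" + "GCT" * 10 + "TAA"
        with pytest.raises(ValueError, match="stop"):
            translate_cds(cds)

    def test_scenario_tokens_and_indel(self, scenario):
        d = protein_diff(scenario.cds_a, scenario.cds_b)
        assert sorted(d.tokens) == sorted(scenario.truth["expected_protein_tokens"])
        assert len(d.substitutions) == scenario.divergence.n_nonsyn_subs
        assert len(d.indels) == 1
        ind = d.indels[0]
        assert ind.bearer == "a_lacks" and len(ind.residues) == 4


class TestTrioAnalysis:
    def test_recent_duplication_topology(self, rng):
        anc = random_dna(rng, 600)
        out_l = list(anc)
        for p in rng.choice(600, 48, replace=False):
            out_l[p] = "ACGT"[(("ACGT".index(out_l[p])) + 1) % 4]
        a_l = list(anc)
        for p in rng.choice(600, 6, replace=False):
            a_l[p] = "ACGT"[(("ACGT".index(a_l[p])) + 2) % 4]
        v = trio_analysis("".join(a_l), anc, "".join(out_l))
        assert v.topology == "post_speciation_duplication"
        assert v.pairwise_identities["ab"] > v.pairwise_identities["a_out"]

    def test_identical_trio_unresolved(self, rng):
        s = random_dna(rng, 300)
        assert trio_analysis(s, s, s).topology == "unresolved"

    def test_scenario_trio_and_indel_polarity(self, scenario):
        v = trio_analysis(scenario.unit_a, scenario.unit_b, scenario.outgroup_gene)
        assert v.topology == "post_speciation_duplication"
        # the coding indel: outgroup retains the segment => deletion in a
        aln = align_pair(scenario.unit_a, scenario.unit_b)
        cat = catalog_diffs(aln, scenario.unit_features_a)
        coding_idx = [k for k, ind in enumerate(cat.indels) if ind.length == 12
                      and ind.bearer == "a_lacks"]
        assert any(v.indel_polarity[k] == "deletion_in_a" for k in coding_idx)
        # overall: a_lacks indels polarise as deletions in a, b_lacks as
        # insertions in a (the outgroup matches the pre-duplication state)
        for k, ind in enumerate(cat.indels):
            expect = "deletion_in_a" if ind.bearer == "a_lacks" else "insertion_in_a"
            assert v.indel_polarity[k] in (expect, "unresolved")
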