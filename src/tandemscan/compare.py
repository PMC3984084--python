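"""Pairwise divergence analysis of two paralogous genes.

Given two paralog sequences (and optionally an outgroup homolog), this module
computes a global alignment, a feature-resolved percent-identity table, a
catalog of substitutions and indels, the predicted protein-level differences,
and a three-taxon verdict on duplication timing and indel polarity.

Conventions
-----------
* Internally all positions are 0-based; human-readable outputs (protein
  substitution tokens, TSV reports) are 1-based.
* Substitutions are oriented a -> b: ``(position on a, base_a, base_b)``.
* An indel's ``bearer`` names the sequence that LACKS the segment
  (``a_lacks`` means a carries a gap where b has sequence).
* Percent identity follows the "ignore long indels" rule: alignment columns
  that fall inside a gap run longer than ``long_indel_cutoff`` (default 1) are
  excluded from both numerator and denominator; gaps of length <= cutoff count
  as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# Nucleotide scoring: slightly mismatch-averse with affine gaps, suited to
# closely related paralogs where indels are discrete events.
NT_MATCH = 2
NT_MISMATCH = -3
NT_GAP_OPEN = -8
NT_GAP_EXTEND = -1

PROT_GAP_OPEN = -11
PROT_GAP_EXTEND = -1


@dataclass(frozen=True)
class Substitution:
    pos_a: int
    base_a: str
    base_b: str
    pos_b: int = -1
    feature: str = ""
    coding: bool = False


@dataclass(frozen=True)
class Indel:
    pos_a: int          # on a: first base of the extra segment (b_lacks) or the junction (a_lacks)
    length: int
    bearer: str         # "a_lacks" | "b_lacks"
    pos_b: int = -1
    feature: str = ""
    coding: bool = False


@dataclass
class FeatureIdentity:
    feature: str
    identity: float           # percent, 0..100
    columns_counted: int
    long_indel_columns_excluded: int
    error: str = ""


@dataclass
class DiffCatalog:
    substitutions: list[Substitution] = field(default_factory=list)
    indels: list[Indel] = field(default_factory=list)
    per_feature: list[FeatureIdentity] = field(default_factory=list)

    @property
    def coding_substitutions(self) -> list[Substitution]:
        return [s for s in self.substitutions if s.coding]

    @property
    def coding_indels(self) -> list[Indel]:
        return [i for i in self.indels if i.coding]

    @property
    def noncoding_indels(self) -> list[Indel]:
        return [i for i in self.indels if not i.coding]

    def summary(self) -> dict:
        coding_sub_feats = {s.feature for s in self.coding_substitutions}
        return {
            "n_substitutions": len(self.substitutions),
            "n_coding_substitutions": len(self.coding_substitutions),
            "n_affected_coding_features": len(coding_sub_feats),
            "n_indels": len(self.indels),
            "n_coding_indels": len(self.coding_indels),
            "n_noncoding_indels": len(self.noncoding_indels),
            "indel_length_range": (
                [min(i.length for i in self.indels), max(i.length for i in self.indels)]
                if self.indels else [0, 0]
            ),
        }


@dataclass(frozen=True)
class ProteinSub:
    token: str      # e.g. "G4R": residue on a, 1-based position on a, residue on b
    pos_a: int      # 0-based
    aa_a: str
    aa_b: str


@dataclass(frozen=True)
class ProteinIndel:
    pos: int        # 1-based residue position on the carrier protein
    residues: str
    bearer: str     # which protein lacks the residues


@dataclass
class ProteinDiff:
    substitutions: list[ProteinSub] = field(default_factory=list)
    indels: list[ProteinIndel] = field(default_factory=list)

    @property
    def tokens(self) -> list[str]:
        return [s.token for s in self.substitutions]


@dataclass
class TrioVerdict:
    pairwise_identities: dict[str, float]
    topology: str                       # post_speciation_duplication | pre_speciation | unresolved
    indel_polarity: dict[int, str]      # keyed by indel index in the a/b catalog


class PairwiseAlignment:
    """A computed global alignment with coordinate maps between a and b."""

    def __init__(self, seq_a: str, seq_b: str, aligned_a: str, aligned_b: str, score: float):
        if len(aligned_a) != len(aligned_b):
            raise ValueError("aligned strings must have equal length")
        self.seq_a = seq_a
        self.seq_b = seq_b
        self.aligned_a = aligned_a
        self.aligned_b = aligned_b
        self.score = score
        self._build_maps()

    def _build_maps(self) -> None:
        # col_a[c] / col_b[c]: 0-based residue index consumed *at* column c, or -1 for a gap
        col_a, col_b = [], []
        a_to_col, b_to_col = [], []
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-":
                col_a.append(-1)
            else:
                col_a.append(ia)
                a_to_col.append(len(col_a) - 1)
                ia += 1
            if cb == "-":
                col_b.append(-1)
            else:
                col_b.append(ib)
                b_to_col.append(len(col_b) - 1)
                ib += 1
        self.col_a = col_a
        self.col_b = col_b
        self.a_to_col = a_to_col
        self.b_to_col = b_to_col

    def __len__(self) -> int:
        return len(self.aligned_a)

    def map_a_to_b(self, pos_a: int) -> int:
        """Residue on b aligned to ``pos_a`` on a, or -1 if a gap."""
        return self.col_b[self.a_to_col[pos_a]]

    def map_b_to_a(self, pos_b: int) -> int:
        return self.col_a[self.b_to_col[pos_b]]

    def identity(self, long_indel_cutoff: int = 1) -> float:
        """Full-length percent identity under the long-indel exclusion rule."""
        fi = feature_identity(self, [("all", 0, len(self.seq_a))], long_indel_cutoff)[0]
        return fi.identity


def _aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if mode == "nt":
        al.match_score = NT_MATCH
        al.mismatch_score = NT_MISMATCH
        al.open_gap_score = NT_GAP_OPEN
        al.extend_gap_score = NT_GAP_EXTEND
    else:
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = PROT_GAP_OPEN
        al.extend_gap_score = PROT_GAP_EXTEND
    return al


def align_pair(seq_a: str, seq_b: str, mode: str = "nt") -> PairwiseAlignment:
    """Global pairwise alignment with affine gap penalties.

    ``mode`` is ``"nt"`` (match/mismatch scoring) or ``"protein"`` (BLOSUM62).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    al = _aligner(mode)
    res = al.align(seq_a, seq_b)
    best = res[0]
    sa, sb = str(best[0]), str(best[1])
    return PairwiseAlignment(seq_a, seq_b, sa, sb, best.score)


def _gap_run_lengths(aln: PairwiseAlignment) -> list[int]:
    """Per-column length of the gap run the column belongs to (0 = no gap)."""
    n = len(aln)
    runlen = [0] * n
    c = 0
    while c < n:
        if aln.aligned_a[c] == "-" or aln.aligned_b[c] == "-":
            which = "a" if aln.aligned_a[c] == "-" else "b"
            j = c
            while j < n and (aln.aligned_a[j] == "-" if which == "a" else aln.aligned_b[j] == "-"):
                j += 1
            for k in range(c, j):
                runlen[k] = j - c
            c = j
        else:
            c += 1
    return runlen


def feature_identity(
    aln: PairwiseAlignment,
    features: list[tuple[str, int, int]],
    long_indel_cutoff: int = 1,
) -> list[FeatureIdentity]:
    """Percent identity per feature interval (0-based half-open, on a).

    Columns inside gap runs longer than ``long_indel_cutoff`` are excluded
    from both numerator and denominator; short gaps count as mismatches.
    """
    runlen = _gap_run_lengths(aln)
    out = []
    for label, start, end in features:
        if start < 0 or end > len(aln.seq_a) or end <= start:
            out.append(FeatureIdentity(label, 0.0, 0, 0, error="feature outside alignment span"))
            continue
        c0 = aln.a_to_col[start]
        c1 = aln.a_to_col[end - 1] + 1
        matches = counted = excluded = 0
        for c in range(c0, c1):
            if runlen[c] > long_indel_cutoff:
                excluded += 1
                continue
            counted += 1
            if aln.aligned_a[c] == aln.aligned_b[c]:
                matches += 1
        if counted == 0:
            out.append(FeatureIdentity(label, 0.0, 0, excluded, error="no countable columns"))
        else:
            out.append(FeatureIdentity(label, 100.0 * matches / counted, counted, excluded))
    return out


def _feature_of(pos: int, features: list[tuple[str, int, int]] | None) -> tuple[str, bool]:
    if not features:
        return "", False
    for label, start, end in features:
        if start <= pos < end:
            coding = label.startswith("exon") or label.startswith("CDS")
            return label, coding
    return "", False


def catalog_diffs(
    aln: PairwiseAlignment,
    features: list[tuple[str, int, int]] | None = None,
) -> DiffCatalog:
    """Inventory every difference in an alignment.

    Each mismatch column becomes one substitution; each maximal gap run
    becomes one indel. Feature labels (intervals on a, 0-based half-open) are
    attached when given; features named ``exonN``/``CDS...`` are coding.
    """
    cat = DiffCatalog()
    n = len(aln)
    ia = ib = 0
    c = 0
    while c < n:
        ca, cb = aln.aligned_a[c], aln.aligned_b[c]
        if ca != "-" and cb != "-":
            if ca != cb:
                feat, coding = _feature_of(ia, features)
                cat.substitutions.append(Substitution(ia, ca, cb, ib, feat, coding))
            ia += 1
            ib += 1
            c += 1
        elif ca == "-":
            j = c
            while j < n and aln.aligned_a[j] == "-":
                j += 1
            length = j - c
            feat, coding = _feature_of(min(ia, len(aln.seq_a) - 1), features)
            cat.indels.append(Indel(ia, length, "a_lacks", ib, feat, coding))
            ib += length
            c = j
        else:
            j = c
            while j < n and aln.aligned_b[j] == "-":
                j += 1
            length = j - c
            feat, coding = _feature_of(ia, features)
            cat.indels.append(Indel(ia, length, "b_lacks", ib, feat, coding))
            ia += length
            c = j
    if features:
        cat.per_feature = feature_identity(aln, features)
    return cat


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code; trailing stop is dropped.

    Raises ``ValueError`` on a length not divisible by 3 or an internal stop,
    naming the offending codon position.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError(f"internal stop codon at codon {prot.index('*') + 1}")
    return prot


def protein_diff(cds_a: str, cds_b: str) -> ProteinDiff:
    """Protein-level differences between two coding sequences.

    Substitution tokens are ``<resA><pos><resB>`` with 1-based positions on
    protein a; indel residues are reported with the protein that lacks them.
    """
    pa = translate_cds(cds_a)
    pb = translate_cds(cds_b)
    diff = ProteinDiff()
    if pa == pb:
        return diff
    aln = align_pair(pa, pb, mode="protein")
    ia = ib = 0
    c = 0
    n = len(aln)
    while c < n:
        ca, cb = aln.aligned_a[c], aln.aligned_b[c]
        if ca != "-" and cb != "-":
            if ca != cb:
                diff.substitutions.append(ProteinSub(f"{ca}{ia + 1}{cb}", ia, ca, cb))
            ia += 1
            ib += 1
            c += 1
        elif ca == "-":
            j = c
            while j < n and aln.aligned_a[j] == "-":
                j += 1
            diff.indels.append(ProteinIndel(ib + 1, pb[ib:ib + (j - c)], "a_lacks"))
            ib += j - c
            c = j
        else:
            j = c
            while j < n and aln.aligned_b[j] == "-":
                j += 1
            diff.indels.append(ProteinIndel(ia + 1, pa[ia:ia + (j - c)], "b_lacks"))
            ia += j - c
            c = j
    return diff


def trio_analysis(
    seq_a: str,
    seq_b: str,
    outgroup: str,
    margin: float = 0.5,
    long_indel_cutoff: int = 1,
    min_outgroup_identity: float = 55.0,
) -> TrioVerdict:
    """Three-taxon comparison of two paralogs against an outgroup homolog.

    Topology is ``post_speciation_duplication`` when the a<->b identity
    exceeds both paralog<->outgroup identities by at least ``margin``
    percentage points (the duplication postdates the speciation that
    separated the outgroup); the reverse pattern gives ``pre_speciation``;
    anything else, or an effectively unalignable outgroup, is unresolved.

    For every indel between a and b, the aligned outgroup state arbitrates
    its polarity: if the outgroup carries the segment the indel is a deletion
    in the paralog lacking it; if the outgroup also lacks it, it is an
    insertion in the paralog bearing it.
    """
    aln_ab = align_pair(seq_a, seq_b)
    aln_ao = align_pair(seq_a, outgroup)
    aln_bo = align_pair(seq_b, outgroup)
    id_ab = aln_ab.identity(long_indel_cutoff)
    id_ao = aln_ao.identity(long_indel_cutoff)
    id_bo = aln_bo.identity(long_indel_cutoff)
    idents = {"ab": id_ab, "a_out": id_ao, "b_out": id_bo}

    if max(id_ao, id_bo) < min_outgroup_identity:
        topology = "unresolved"
    elif id_ab >= id_ao + margin and id_ab >= id_bo + margin:
        topology = "post_speciation_duplication"
    elif id_ao >= id_ab + margin and id_bo >= id_ab + margin:
        topology = "pre_speciation"
    else:
        topology = "unresolved"

    cat = catalog_diffs(aln_ab)
    polarity: dict[int, str] = {}
    outgroup_usable = max(id_ao, id_bo) >= min_outgroup_identity
    for idx, indel in enumerate(cat.indels):
        if indel.bearer == "a_lacks":
            carrier, lacker, aln_lo = "b", "a", aln_ao
            junction = indel.pos_a
        else:
            carrier, lacker, aln_lo = "a", "b", aln_bo
            junction = indel.pos_b
        if not outgroup_usable:
            polarity[idx] = "unresolved"
            continue
        # Extra outgroup bases in a window around the lacker's junction:
        # ~length if the outgroup carries the segment (so the indel is a
        # deletion in the lacker), ~0 if it also lacks it (an insertion in
        # the carrier). Judged on the lacker<->outgroup alignment; the
        # window tolerates gap placement drifting a few bases through
        # mismatch-noisy flanks.
        n_extra = _extra_bases_near(aln_lo, junction)
        if n_extra is None:
            polarity[idx] = "unresolved"
        elif n_extra >= max(1, indel.length / 2):
            polarity[idx] = f"deletion_in_{lacker}"
        else:
            polarity[idx] = f"insertion_in_{carrier}"
    return TrioVerdict(idents, topology, polarity)


def _extra_bases_near(aln: PairwiseAlignment, junction: int,
                      window: int = 10) -> int | None:
    """Outgroup-minus-lacker length difference across ``junction`` +/- window.

    Anchored at the nearest aligned positions just outside the window; a
    positive value means the outgroup carries extra sequence there.
    """
    la = max(0, junction - window)
    ra = min(len(aln.seq_a) - 1, junction + window - 1)
    if ra <= la:
        return None
    oa = ob = -1
    for p in range(la, junction):           # nearest aligned base moving inward
        oa = aln.map_a_to_b(p)
        if oa >= 0:
            la = p
            break
    for p in range(ra, junction - 1, -1):
        ob = aln.map_a_to_b(p)
        if ob >= 0:
            ra = p
            break
    if oa < 0 or ob < 0 or ob <= oa:
        return None
    return (ob - oa) - (ra - la)
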