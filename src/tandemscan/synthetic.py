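"""Seeded synthetic tandem-duplication scenarios with full ground truth.

The generator emulates a recently duplicated plant gene pair that was
collapsed into a single chimeric gene in a reference assembly:

* two paralogous genes (``geneA`` upstream, ``geneB`` downstream) in
  head-to-tail tandem, each a "repeat unit" of promoter, 5' UTR, coding
  exons, introns and 3' UTR;
* divergence between the paralogs concentrated where real paralog pairs
  diverge — synonymous-biased substitutions in a subset of coding exons, one
  in-frame coding indel, and many short indels in non-coding DNA;
* a collapsed chimeric reference equal to the true locus minus one fixed-
  length segment, so the reference gene is geneA's body joined to geneB's
  3' UTR tail;
* spliced cDNAs for both paralogs, an outgroup homolog that diverged before
  the duplication, T-DNA insertion alleles, selfing offspring draws, and
  error-free shotgun reads.

Every planted difference is recorded in a ground-truth
:class:`~tandemscan.compare.DiffCatalog`, so downstream analyses can be
scored exactly. Identical seeds give byte-identical outputs.

Planted events are kept mutually separated and "slide-proof" (an indel's
boundaries are arranged so the optimal alignment cannot shift the gap),
which makes exact recovery of the truth catalog a well-posed requirement
rather than a statistical accident.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from . import digest as _digest
from .compare import DiffCatalog, Indel, Substitution, translate_cds
from .seqio import Feature, write_fasta, write_gff3

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
# minimum separation between any two planted events; wide enough that the
# affine aligner cannot merge or reinterpret neighbouring events
MIN_EVENT_GAP = 14
EXON_SUB_MARGIN = 6     # planted coding subs keep this distance from exon edges
NONCODING_EDGE_MARGIN = 14

# Type-IIS marker sites planted in the CDS (0-based CDS coordinates) so that
# the downstream paralog's coding sequence carries one extra BpiI/BbsI site.
SHARED_SITE_STARTS = (70, 384, 673)
B_ONLY_SITE_CONTEXT = (1857, "CTGAAGAC")   # in-frame CTG ensures the
B_ONLY_SITE_SUB_POS = 1859                 # disabling G->A change is silent
B_ONLY_SITE_SUB_BASE = "A"

TDNA_LEFT_BORDER = "GTTTACCCGCCAATATATCCTGTCA"
TDNA_RIGHT_BORDER = "TGACAGGATATATTGGCGGGTAAAC"


class ScenarioParameterError(ValueError):
    """Raised when a scenario specification is infeasible."""


class _RetryGeneration(Exception):
    """Internal: a stochastic constraint failed; redraw with advanced RNG."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneStructure:
    """Exon/intron/UTR layout of one gene copy (lengths in bp).

    ``exon_lengths`` are CDS lengths per exon; UTRs are contiguous with the
    terminal exons (no UTR introns).
    """

    n_exons: int = 24
    exon_lengths: tuple[int, ...] = tuple([104] * 23 + [98])
    intron_lengths: tuple[int, ...] = tuple([126] * 23)
    utr5_len: int = 150
    utr3_len: int = 200

    def __post_init__(self):
        if self.n_exons < 1:
            raise ScenarioParameterError("n_exons must be >= 1")
        if len(self.exon_lengths) != self.n_exons:
            raise ScenarioParameterError("exon_lengths must have n_exons entries")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ScenarioParameterError("intron_lengths must have n_exons - 1 entries")
        if any(x <= 0 for x in (*self.exon_lengths, *self.intron_lengths,
                                self.utr5_len, self.utr3_len)):
            raise ScenarioParameterError("all lengths must be > 0")
        if self.cds_len % 3 != 0:
            raise ScenarioParameterError("total CDS length must be divisible by 3")

    @property
    def cds_len(self) -> int:
        return sum(self.exon_lengths)

    @property
    def transcript_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def body_len(self) -> int:
        return self.cds_len + sum(self.intron_lengths)


@dataclass(frozen=True)
class DivergenceSpec:
    """How far apart the two paralogs are, and where.

    The defaults emulate a very recent tandem duplication: ~1% coding
    divergence with mostly silent substitutions confined to half the exons,
    a single in-frame coding indel, and many short non-coding indels whose
    lengths follow a truncated geometric law (most indels are 1-4 bp, with a
    tail out to ``noncoding_indel_len_range[1]``).
    """

    n_coding_snvs: int = 27
    n_affected_exons: int = 12
    coding_indel_len: int = 12
    coding_indel_exon: int = 16        # 1-based exon carrying the indel
    n_noncoding_indels: int = 40
    noncoding_indel_len_range: tuple[int, int] = (1, 35)
    n_nonsyn_subs: int = 5
    intron_sub_rate: float = 0.03
    indel_len_geometric_p: float = 0.25
    restriction_marker: bool = True    # plant BpiI sites; one site is b-specific

    def __post_init__(self):
        if self.coding_indel_len % 3 != 0:
            raise ScenarioParameterError("coding_indel_len must be a multiple of 3")
        if self.n_nonsyn_subs > self.n_coding_snvs:
            raise ScenarioParameterError("n_nonsyn_subs cannot exceed n_coding_snvs")
        lo, hi = self.noncoding_indel_len_range
        if not (1 <= lo <= hi):
            raise ScenarioParameterError("invalid noncoding_indel_len_range")


@dataclass
class SyntheticScenario:
    """A generated locus with full ground truth for scoring every stage."""

    seed: int
    structure: GeneStructure
    divergence: DivergenceSpec
    true_locus: str
    features: list[Feature]
    collapsed_reference: str
    unit_a: str
    unit_b: str
    unit_features_a: list[tuple[str, int, int]]
    unit_features_b: list[tuple[str, int, int]]
    cdna_a: str
    cdna_b: str
    cds_a: str
    cds_b: str
    outgroup_gene: str
    tdna_alleles: dict[str, tuple[str, int, str]]
    primers: dict[str, str]
    truth: dict = field(default_factory=dict)

    @property
    def truth_catalog(self) -> DiffCatalog:
        return self.truth["catalog"]


# ---------------------------------------------------------------------------
# sequence building blocks


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS: ATG start, TAA stop, no internal stop codons."""
    n_codons = length // 3
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _plant_marker_sites(cds: list[str], divergence: DivergenceSpec) -> None:
    """Overwrite CDS positions with the type-IIS marker sites (in place).

    A site planted mid-codon can complete a stop codon with flanking bases
    (e.g. T + GA); any such codon is repaired at a base outside the site
    (no stop codon contains C, so C is always a safe repair).
    """
    blocks = [(s, 6) for s in SHARED_SITE_STARTS]
    pos, ctx = B_ONLY_SITE_CONTEXT
    blocks.append((pos, len(ctx)))
    for start in SHARED_SITE_STARTS:
        cds[start:start + 6] = list("GAAGAC")
    cds[pos:pos + len(ctx)] = list(ctx)
    planted = {i for s, L in blocks for i in range(s, s + L)}
    for s, L in blocks:
        for ci in range(s // 3, (s + L - 1) // 3 + 1):
            codon = "".join(cds[3 * ci:3 * ci + 3])
            if codon in STOP_CODONS:
                free = [k for k in range(3 * ci, 3 * ci + 3) if k not in planted]
                cds[free[0]] = "C"


def _codon_substitution_options(cds: str, pos: int, synonymous: bool) -> list[str]:
    """Single-base alternatives at ``pos`` that are (non)synonymous, non-stop."""
    ci = pos // 3
    codon = cds[3 * ci:3 * ci + 3]
    aa = str(Seq(codon).translate())
    out = []
    for b in BASES:
        if b == cds[pos]:
            continue
        new = codon[:pos - 3 * ci] + b + codon[pos - 3 * ci + 1:]
        if new in STOP_CODONS:
            continue
        new_aa = str(Seq(new).translate())
        if (new_aa == aa) == synonymous:
            out.append(b)
    return out


class _Occupancy:
    """Sorted footprint registry enforcing the minimum event separation."""

    def __init__(self, min_gap: int = MIN_EVENT_GAP):
        self.spans: list[tuple[int, int]] = []
        self.min_gap = min_gap

    def clear(self, start: int, end: int) -> bool:
        for s, e in self.spans:
            if start < e + self.min_gap and s < end + self.min_gap:
                return False
        return True

    def add(self, start: int, end: int) -> None:
        self.spans.append((start, end))


# ---------------------------------------------------------------------------
# the generator


class _UnitLayout:
    """Coordinate bookkeeping for one repeat unit (promoter..3'UTR)."""

    def __init__(self, structure: GeneStructure, promoter_len: int):
        self.structure = structure
        self.promoter_len = promoter_len
        pos = promoter_len
        self.utr5 = (pos, pos + structure.utr5_len)
        pos = self.utr5[1]
        self.exons: list[tuple[int, int]] = []
        self.introns: list[tuple[int, int]] = []
        for i in range(structure.n_exons):
            e = (pos, pos + structure.exon_lengths[i])
            self.exons.append(e)
            pos = e[1]
            if i < structure.n_exons - 1:
                it = (pos, pos + structure.intron_lengths[i])
                self.introns.append(it)
                pos = it[1]
        self.utr3 = (pos, pos + structure.utr3_len)
        self.length = self.utr3[1]
        # CDS coordinate -> unit coordinate
        self.cds_starts = np.cumsum([0] + list(structure.exon_lengths[:-1]))

    def cds_to_unit(self, cds_pos: int) -> int:
        ei = int(np.searchsorted(self.cds_starts, cds_pos, side="right") - 1)
        return self.exons[ei][0] + (cds_pos - int(self.cds_starts[ei]))

    def exon_of_cds(self, cds_pos: int) -> int:
        """1-based exon index containing a CDS position."""
        return int(np.searchsorted(self.cds_starts, cds_pos, side="right"))

    def features(self) -> list[tuple[str, int, int]]:
        feats = [("promoter", 0, self.promoter_len), ("5'UTR", *self.utr5)]
        for i, e in enumerate(self.exons):
            feats.append((f"exon{i + 1}", *e))
            if i < len(self.introns):
                feats.append((f"intron{i + 1}", *self.introns[i]))
        feats.append(("3'UTR", *self.utr3))
        return feats


def _build_unit(rng: np.random.Generator, layout: _UnitLayout,
                divergence: DivergenceSpec) -> list[str]:
    st = layout.structure
    cds = list(_random_cds(rng, st.cds_len))
    if divergence.restriction_marker:
        _plant_marker_sites(cds, divergence)
    seq = list(_random_seq(rng, layout.promoter_len))
    seq += list(_random_seq(rng, st.utr5_len))
    cds_str = "".join(cds)
    for i in range(st.n_exons):
        a, b = int(layout.cds_starts[i]), int(layout.cds_starts[i]) + st.exon_lengths[i]
        seq += list(cds_str[a:b])
        if i < st.n_exons - 1:
            seq += list("GT" + _random_seq(rng, st.intron_lengths[i] - 4) + "AG")
    seq += list(_random_seq(rng, st.utr3_len))
    return seq


def _cds_occurrence_check(cds_a: str, cds_b: str, divergence: DivergenceSpec) -> bool:
    """The b paralog's CDS must carry exactly one extra marker cut."""
    enz = _digest.ENZYMES["BpiI"]
    cuts_b = _digest.digest(cds_b, enz).cut_positions
    cuts_a = _digest.digest(cds_a, enz).cut_positions
    return cuts_b == [78, 392, 681, 1867] and cuts_a == [78, 392, 681]


def _place_indel_positions(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    lengths: list[int],
    min_gap: int,
    occupied: _Occupancy,
    max_tries: int = 2000,
) -> list[int]:
    """Spaced, interval-respecting positions for indel footprints.

    Sorted uniform draws in a "compressed" axis are expanded by the
    cumulative footprints, guaranteeing pairwise separation; draws are
    rejected until no footprint straddles an interval boundary or an
    already-occupied zone.
    """
    ivs = sorted(intervals)
    iv_lens = [e - s for s, e in ivs]
    total = sum(iv_lens)
    n = len(lengths)
    for _ in range(max_tries):
        order = list(rng.permutation(n))
        foot = [lengths[i] + min_gap for i in order]
        slack = total - sum(foot)
        if slack <= n:
            raise ScenarioParameterError("not enough non-coding space for requested indels")
        u = np.sort(rng.integers(0, slack, size=n))
        concat_pos = [int(u[k]) + sum(foot[:k]) for k in range(n)]
        unit_pos: list[int] = [0] * n
        ok = True
        for k, cp in enumerate(concat_pos):
            # locate interval
            acc = 0
            upos = -1
            for (s, e), L in zip(ivs, iv_lens):
                if cp < acc + L:
                    upos = s + (cp - acc)
                    if upos + lengths[order[k]] > e:   # straddles a boundary
                        ok = False
                    break
                acc += L
            if upos < 0 or not ok:
                ok = False
                break
            if not occupied.clear(upos, upos + lengths[order[k]]):
                ok = False
                break
            unit_pos[order[k]] = upos
        if ok:
            return unit_pos
    raise _RetryGeneration


def _generate_once(
    structure: GeneStructure,
    divergence: DivergenceSpec,
    promoter_len: int,
    flank_len: int,
    collapse_len: int,
    rngs: dict[str, np.random.Generator],
    seed: int,
) -> SyntheticScenario:
    st = structure
    layout = _UnitLayout(st, promoter_len)
    rng = rngs["sequence"]
    ancestor = _build_unit(rng, layout, divergence)

    drng = rngs["divergence"]
    occupied = _Occupancy()
    cds_b = _extract_cds(ancestor, layout)

    # --- coding indel: in-frame deletion in one exon of paralog a ----------
    indel_exon = min(divergence.coding_indel_exon, st.n_exons) - 1
    ex_lo, ex_hi = int(layout.cds_starts[indel_exon]), \
        int(layout.cds_starts[indel_exon]) + st.exon_lengths[indel_exon]
    dlen = divergence.coding_indel_len
    del_cds_start = None
    if dlen > 0:
        if ex_hi - ex_lo < dlen + 2 * EXON_SUB_MARGIN:
            raise ScenarioParameterError("coding indel does not fit in its exon")
        cand = [p for p in range(ex_lo + EXON_SUB_MARGIN, ex_hi - dlen - EXON_SUB_MARGIN + 1)
                if p % 3 == 0]
        drng.shuffle(cand)
        prot_b = translate_cds(cds_b)
        for p in cand:
            u = layout.cds_to_unit(p)
            # nucleotide-level anti-slide guards
            if ancestor[u - 1] == ancestor[u + dlen - 1] or ancestor[u] == ancestor[u + dlen]:
                continue
            # protein-level guards so the 4-residue gap cannot slide either
            ci = p // 3
            nres = dlen // 3
            if prot_b[ci - 1] == prot_b[ci + nres - 1] or prot_b[ci] == prot_b[ci + nres]:
                continue
            del_cds_start = p
            break
        if del_cds_start is None:
            raise _RetryGeneration
        u = layout.cds_to_unit(del_cds_start)
        occupied.add(u, u + dlen)

    # --- coding substitutions ----------------------------------------------
    marker_exon = None
    forced_subs: list[tuple[int, str, bool]] = []   # (cds_pos, new_base, nonsyn)
    if divergence.restriction_marker:
        marker_exon = layout.exon_of_cds(B_ONLY_SITE_SUB_POS)
        forced_subs.append((B_ONLY_SITE_SUB_POS, B_ONLY_SITE_SUB_BASE, False))
        u = layout.cds_to_unit(B_ONLY_SITE_SUB_POS)
        occupied.add(u, u + 1)
        for s0 in SHARED_SITE_STARTS + (B_ONLY_SITE_CONTEXT[0],):
            u0 = layout.cds_to_unit(s0)
            occupied.add(u0, u0 + 8)    # keep planted sites intact in both copies

    candidates = [e for e in range(2, st.n_exons)
                  if e != divergence.coding_indel_exon]
    n_aff = divergence.n_affected_exons
    if n_aff > st.n_exons:
        raise ScenarioParameterError("n_affected_exons exceeds n_exons")
    affected: list[int] = []
    if marker_exon is not None:
        affected.append(marker_exon)
        candidates = [e for e in candidates if e != marker_exon]
    if n_aff - len(affected) > len(candidates):
        raise ScenarioParameterError("too many affected exons for this structure")
    affected += sorted(drng.choice(candidates, size=n_aff - len(affected),
                                   replace=False).tolist())
    affected = sorted(affected)

    n_subs = divergence.n_coding_snvs
    if n_subs < n_aff:
        raise ScenarioParameterError("need at least one substitution per affected exon")
    quota = {e: 1 for e in affected}
    if marker_exon is not None:
        quota[marker_exon] = 1  # the forced marker substitution fills this slot
    extra = n_subs - n_aff
    for e in drng.choice(affected, size=extra, replace=True).tolist():
        quota[e] += 1

    n_forced = len(forced_subs)
    n_free = n_subs - n_forced
    nonsyn_slots = set(drng.choice(n_free, size=divergence.n_nonsyn_subs,
                                   replace=False).tolist()) if n_free else set()

    coding_subs: list[tuple[int, str, bool]] = list(forced_subs)
    slot = 0
    for e in affected:
        want = quota[e] - (n_forced if e == marker_exon else 0)
        lo = int(layout.cds_starts[e - 1])
        hi = lo + st.exon_lengths[e - 1]
        placed = 0
        tries = 0
        while placed < want:
            tries += 1
            if tries > 4000:
                raise _RetryGeneration
            p = int(drng.integers(lo + EXON_SUB_MARGIN, hi - EXON_SUB_MARGIN))
            u = layout.cds_to_unit(p)
            if not occupied.clear(u, u + 1):
                continue
            nonsyn = slot in nonsyn_slots
            opts = _codon_substitution_options(cds_b, p, synonymous=not nonsyn)
            if not opts:
                continue
            base = opts[int(drng.integers(0, len(opts)))]
            coding_subs.append((p, base, nonsyn))
            occupied.add(u, u + 1)
            placed += 1
            slot += 1

    # --- non-coding events --------------------------------------------------
    # Indels go to the promoter and introns; UTRs are transcribed, and keeping
    # them indel-free pins the spliced-cDNA length difference to the coding
    # indel alone.
    m = NONCODING_EDGE_MARGIN
    intron_iv = [(s + 2 + m, e - 2 - m) for s, e in layout.introns]
    noncoding_iv = [(0 + m, layout.promoter_len - m)] + intron_iv

    lo, hi = divergence.noncoding_indel_len_range
    lens: list[int] = []
    while len(lens) < divergence.n_noncoding_indels:
        L = int(drng.geometric(divergence.indel_len_geometric_p))
        if lo <= L <= hi:
            lens.append(L)
    # guarantee the configured range is actually exercised
    if lens and divergence.n_noncoding_indels >= 2:
        lens[0], lens[1] = lo, hi

    indel_pos = _place_indel_positions(drng, noncoding_iv, lens, MIN_EVENT_GAP, occupied)
    noncoding_indels: list[tuple[int, int, str]] = []   # (unit pos, len, bearer)
    for p, L in zip(indel_pos, lens):
        occupied.add(p, p + L)
        bearer = "a_lacks" if drng.integers(0, 2) == 0 else "b_lacks"
        noncoding_indels.append((p, L, bearer))

    total_intron = sum(st.intron_lengths)
    n_intron_subs = int(round(divergence.intron_sub_rate * total_intron))
    intron_subs: list[tuple[int, str]] = []
    tries = 0
    iv_arr = intron_iv
    while len(intron_subs) < n_intron_subs:
        tries += 1
        if tries > 20000:
            raise _RetryGeneration
        iv = iv_arr[int(drng.integers(0, len(iv_arr)))]
        p = int(drng.integers(iv[0], iv[1]))
        if not occupied.clear(p, p + 1):
            continue
        cur = ancestor[p]
        base = BASES[int(drng.integers(0, 4))]
        if base == cur:
            continue
        intron_subs.append((p, base))
        occupied.add(p, p + 1)

    # --- assemble the edit list and derive paralog a ------------------------
    # kinds: sub (1 bp), del (a lacks ancestor[p:p+L]), ins (a carries extra seq)
    edits: list[tuple[int, str, object]] = []
    for p, base, nonsyn in coding_subs:
        edits.append((layout.cds_to_unit(p), "sub", base))
    for p, base in intron_subs:
        edits.append((p, "sub", base))
    if del_cds_start is not None:
        edits.append((layout.cds_to_unit(del_cds_start), "del", dlen))
    for p, L, bearer in noncoding_indels:
        if bearer == "a_lacks":
            # anti-slide: rewrite the (deleted) segment's end bases in the
            # ancestor so neither 1-step slide reproduces the same alignment
            last_ok = [b for b in BASES if b != ancestor[p - 1]]
            first_ok = [b for b in BASES if b != ancestor[p + L]]
            if L == 1:
                both = [b for b in BASES if b != ancestor[p - 1] and b != ancestor[p + L]]
                ancestor[p] = both[int(drng.integers(0, len(both)))]
            else:
                if ancestor[p + L - 1] == ancestor[p - 1]:
                    ancestor[p + L - 1] = last_ok[int(drng.integers(0, len(last_ok)))]
                if ancestor[p] == ancestor[p + L]:
                    ancestor[p] = first_ok[int(drng.integers(0, len(first_ok)))]
            edits.append((p, "del", L))
        else:
            ins = list(_random_seq(drng, L))
            cand0 = [b for b in BASES if b != ancestor[p]]
            candL = [b for b in BASES if b != ancestor[p - 1]]
            if L == 1:
                both = [b for b in cand0 if b in candL]
                ins[0] = both[int(drng.integers(0, len(both)))]
            else:
                if ins[0] == ancestor[p]:
                    ins[0] = cand0[int(drng.integers(0, len(cand0)))]
                if ins[-1] == ancestor[p - 1]:
                    ins[-1] = candL[int(drng.integers(0, len(candL)))]
            edits.append((p, "ins", "".join(ins)))
    edits.sort(key=lambda t: t[0])

    unit_b = "".join(ancestor)
    a_parts: list[str] = []
    prev = 0
    shifts: list[tuple[int, int]] = [(0, 0)]   # (ancestor pos, cumulative a-b shift)
    shift = 0
    catalog = DiffCatalog()
    for p, kind, payload in edits:
        a_parts.append(unit_b[prev:p])
        if kind == "sub":
            a_parts.append(payload)            # type: ignore[arg-type]
            prev = p + 1
        elif kind == "del":
            L = int(payload)                    # type: ignore[arg-type]
            prev = p + L
            shift -= L
            shifts.append((p + L, shift))
        else:
            s = str(payload)
            a_parts.append(s)
            prev = p
            shift += len(s)
            shifts.append((p, shift))
    a_parts.append(unit_b[prev:])
    unit_a = "".join(a_parts)

    shift_pos = [sp for sp, _ in shifts]

    def anc_to_a(pos: int) -> int:
        i = int(np.searchsorted(shift_pos, pos, side="right") - 1)
        return pos + shifts[i][1]

    feats_b = layout.features()
    feats_a = [(lab, anc_to_a(s), anc_to_a(e)) for lab, s, e in feats_b]

    def feat_of_b(pos: int) -> tuple[str, bool]:
        for lab, s, e in feats_b:
            if s <= pos < e:
                return lab, lab.startswith("exon")
        return "", False

    for p, kind, payload in edits:
        lab, coding = feat_of_b(p)
        if kind == "sub":
            catalog.substitutions.append(
                Substitution(anc_to_a(p), str(payload), unit_b[p], p, lab, coding))
        elif kind == "del":
            catalog.indels.append(
                Indel(anc_to_a(p + int(payload)), int(payload), "a_lacks", p, lab, coding))
        else:
            # anc_to_a(p) lands after the inserted segment; back up to its start
            L = len(str(payload))
            catalog.indels.append(
                Indel(anc_to_a(p) - L, L, "b_lacks", p, lab, coding))
    catalog.substitutions.sort(key=lambda s: s.pos_a)
    catalog.indels.sort(key=lambda i: i.pos_a)

    # --- derived sequences ---------------------------------------------------
    cds_a = _extract_cds_from(unit_a, feats_a)
    cds_b_check = _extract_cds_from(unit_b, feats_b)
    assert cds_b_check == cds_b
    try:
        prot_a = translate_cds(cds_a)
        prot_b = translate_cds(cds_b)
    except ValueError:
        raise _RetryGeneration
    if divergence.restriction_marker and not _cds_occurrence_check(cds_a, cds_b, divergence):
        raise _RetryGeneration

    cdna_a = _extract_transcript(unit_a, feats_a)
    cdna_b = _extract_transcript(unit_b, feats_b)

    # --- outgroup: the pre-duplication ancestor plus heavier noise -----------
    orng = rngs["outgroup"]
    out = list(unit_b)
    protected = _Occupancy(min_gap=2)
    for ind in catalog.indels:
        protected.add(ind.pos_b - MIN_EVENT_GAP, ind.pos_b + ind.length + MIN_EVENT_GAP)
    n_out_coding = int(round(0.02 * st.cds_len))
    n_out_noncoding = int(round(0.08 * (layout.length - st.cds_len)))
    coding_positions = set()
    for lab, s, e in feats_b:
        if lab.startswith("exon"):
            coding_positions.update(range(s, e))
    all_pos = orng.permutation(layout.length)
    placed_c = placed_n = 0
    for p in all_pos:
        p = int(p)
        if placed_c >= n_out_coding and placed_n >= n_out_noncoding:
            break
        is_c = p in coding_positions
        if is_c and placed_c >= n_out_coding:
            continue
        if not is_c and placed_n >= n_out_noncoding:
            continue
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[int(orng.integers(0, 3))]
        if is_c:
            placed_c += 1
        else:
            placed_n += 1
    # a few outgroup-private indels, away from the planted a/b indel loci
    out_iv = [(s, e) for s, e in noncoding_iv]
    out_lens = [int(orng.integers(1, 7)) for _ in range(8)]
    try:
        out_pos = _place_indel_positions(orng, out_iv, out_lens, MIN_EVENT_GAP, protected,
                                         max_tries=500)
        out_edits = sorted(zip(out_pos, out_lens))
        for p, L in reversed(out_edits):
            if orng.integers(0, 2) == 0:
                del out[p:p + L]
            else:
                out[p:p] = list(_random_seq(orng, L))
    except (_RetryGeneration, ScenarioParameterError):
        pass    # outgroup indels are decoration; substitutions suffice
    outgroup = "".join(out)

    # --- the locus and its collapsed reference -------------------------------
    frng = rngs["flanks"]
    flank5 = _random_seq(frng, flank_len)
    flank3 = _random_seq(frng, flank_len)
    true_locus = flank5 + unit_a + unit_b + flank3
    off_a = flank_len
    off_b = flank_len + len(unit_a)

    utr3_a = next((s, e) for lab, s, e in feats_a if lab == "3'UTR")
    utr3_b = next((s, e) for lab, s, e in feats_b if lab == "3'UTR")
    s_cut = off_a + utr3_a[0]
    e_cut = s_cut + collapse_len
    b3s, b3e = off_b + utr3_b[0], off_b + utr3_b[1]
    if not (b3s <= e_cut < b3e):
        raise ScenarioParameterError(
            f"collapse_len={collapse_len} does not place the chimera breakpoint inside "
            f"the downstream paralog's 3' UTR (needs {b3s - s_cut}..{b3e - s_cut - 1})")
    collapsed_reference = true_locus[:s_cut] + true_locus[e_cut:]

    features = _locus_features(layout, feats_a, feats_b, off_a, off_b, "true_locus")

    # --- T-DNA insertion alleles --------------------------------------------
    trng = rngs["tdna"]
    cassette = TDNA_LEFT_BORDER + _random_seq(trng, 4000 - len(TDNA_LEFT_BORDER)
                                              - len(TDNA_RIGHT_BORDER)) + TDNA_RIGHT_BORDER
    atg = layout.utr5[1]

    def _offset(unit_feats, lab, frac):
        s, e = next((s, e) for l, s, e in unit_feats if l == lab)
        return s + int((e - s) * frac) - atg

    n_int = len(layout.introns)
    intron_mid = f"intron{min(6, n_int)}" if n_int else "exon1"
    tdna = {
        "line_a1": ("geneA", _offset(feats_a, intron_mid, 0.35), cassette),
        "line_a2": ("geneA", _offset(feats_a, intron_mid, 0.70), cassette),
        "line_b1": ("geneB", _offset(feats_b, f"exon{min(2, st.n_exons)}", 0.50), cassette),
        "line_b2": ("geneB", _offset(feats_b, f"exon{min(14, st.n_exons)}", 0.50), cassette),
    }

    # --- default outward-facing diagnostic primers ---------------------------
    # A: first coding exon, pointing upstream; B: last exon, pointing
    # downstream. Both regions are identical between the paralogs.
    e1 = feats_b[[lab for lab, _, _ in feats_b].index("exon1")]
    eN = feats_b[[lab for lab, _, _ in feats_b].index(f"exon{st.n_exons}")]
    a_start = e1[1] + 20
    primer_A = revcomp(unit_b[a_start:a_start + 20])
    b_start = eN[2] - 40
    primer_B = unit_b[b_start:b_start + 20]
    primers = {"A": primer_A, "B": primer_B}

    expected_tokens = []
    for p, base, nonsyn in coding_subs:
        if not nonsyn:
            continue
        pa = p if del_cds_start is None or p < del_cds_start else p - dlen
        expected_tokens.append(f"{prot_a[pa // 3]}{pa // 3 + 1}{prot_b[p // 3]}")
    expected_tokens.sort(key=lambda t: int(t[1:-1]))

    stop_to_start = (off_b + layout.utr5[1]) - (off_a + utr3_a[0])

    truth = {
        "catalog": catalog,
        "inserted_interval_locus": (s_cut, e_cut),
        "breakpoint_reference": s_cut,
        "collapse_length": collapse_len,
        "expected_protein_tokens": expected_tokens,
        "expected_protein_indel_len": (dlen // 3 if dlen else 0),
        "coding_deletion_cds_start": del_cds_start,
        "unit_a_interval_locus": (off_a, off_a + len(unit_a)),
        "unit_b_interval_locus": (off_b, off_b + len(unit_b)),
        "stop_to_start_intergenic_len": stop_to_start,
        "affected_exons": affected,
    }

    return SyntheticScenario(
        seed=seed, structure=st, divergence=divergence,
        true_locus=true_locus, features=features,
        collapsed_reference=collapsed_reference,
        unit_a=unit_a, unit_b=unit_b,
        unit_features_a=feats_a, unit_features_b=feats_b,
        cdna_a=cdna_a, cdna_b=cdna_b, cds_a=cds_a, cds_b=cds_b,
        outgroup_gene=outgroup, tdna_alleles=tdna, primers=primers, truth=truth,
    )


def _extract_cds(ancestor: list[str], layout: _UnitLayout) -> str:
    return "".join("".join(ancestor[s:e]) for lab, s, e in layout.features()
                   if lab.startswith("exon"))


def _extract_cds_from(unit: str, feats: list[tuple[str, int, int]]) -> str:
    return "".join(unit[s:e] for lab, s, e in feats if lab.startswith("exon"))


def _extract_transcript(unit: str, feats: list[tuple[str, int, int]]) -> str:
    utr5 = next((s, e) for lab, s, e in feats if lab == "5'UTR")
    utr3 = next((s, e) for lab, s, e in feats if lab == "3'UTR")
    return unit[utr5[0]:utr5[1]] + _extract_cds_from(unit, feats) + unit[utr3[0]:utr3[1]]


def _locus_features(layout, feats_a, feats_b, off_a, off_b, seqid) -> list[Feature]:
    out = []
    for gname, feats, off in (("geneA", feats_a, off_a), ("geneB", feats_b, off_b)):
        gs = next(s for lab, s, e in feats if lab == "5'UTR")
        ge = next(e for lab, s, e in feats if lab == "3'UTR")
        out.append(Feature(seqid, "gene", off + gs, off + ge, "+", gname))
        out.append(Feature(seqid, "mRNA", off + gs, off + ge, "+", f"{gname}.1"))
        for lab, s, e in feats:
            if lab == "5'UTR":
                out.append(Feature(seqid, "five_prime_UTR", off + s, off + e, "+",
                                   f"{gname}.utr5"))
            elif lab == "3'UTR":
                out.append(Feature(seqid, "three_prime_UTR", off + s, off + e, "+",
                                   f"{gname}.utr3"))
            elif lab.startswith("exon"):
                out.append(Feature(seqid, "CDS", off + s, off + e, "+",
                                   f"{gname}.{lab}"))
            elif lab.startswith("intron"):
                out.append(Feature(seqid, "intron", off + s, off + e, "+",
                                   f"{gname}.{lab}"))
    return out


def generate_scenario(
    structure: GeneStructure | None = None,
    divergence: DivergenceSpec | None = None,
    intergenic_len: int = 1511,
    seed: int = 0,
    collapse_len: int = 7000,
    flank_len: int = 12000,
) -> SyntheticScenario:
    """Generate a seeded collapsed-tandem-duplication scenario.

    ``intergenic_len`` is the distance from the upstream paralog's stop codon
    to the downstream paralog's start codon (3' UTR + promoter + 5' UTR), the
    quantity an outward-facing-primer product measures. ``collapse_len`` is
    the exact length of the segment missing from the chimeric reference; the
    chimera keeps geneA up to the start of its 3' UTR and resumes inside
    geneB's 3' UTR.
    """
    structure = structure or GeneStructure()
    divergence = divergence or DivergenceSpec()
    promoter_len = intergenic_len - structure.utr3_len - structure.utr5_len
    if promoter_len < 200:
        raise ScenarioParameterError(
            "intergenic_len leaves too little promoter space "
            f"(needs > {structure.utr3_len + structure.utr5_len + 200})")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(5)
    rngs = {name: np.random.default_rng(child)
            for name, child in zip(("sequence", "divergence", "outgroup",
                                    "tdna", "flanks"), children)}
    last_err: Exception | None = None
    for _ in range(60):
        try:
            return _generate_once(structure, divergence, promoter_len, flank_len,
                                  collapse_len, rngs, seed)
        except _RetryGeneration as err:
            last_err = err
            continue
    raise RuntimeError(f"scenario generation failed to converge: {last_err!r}")


def sample_offspring(parent_genotype: str, n: int, seed: int) -> tuple[int, int, int]:
    """Draw (n_ww, n_wm, n_mm) genotype counts among selfed offspring.

    A selfed heterozygote segregates 1:2:1; a homozygote breeds true.
    """
    if n <= 0:
        raise ScenarioParameterError("n must be > 0")
    probs = {
        "het": (0.25, 0.5, 0.25),
        "hom_mut": (0.0, 0.0, 1.0),
        "hom_wt": (1.0, 0.0, 0.0),
    }.get(parent_genotype)
    if probs is None:
        raise ScenarioParameterError(f"unknown parent genotype {parent_genotype!r}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return int(counts[0]), int(counts[1]), int(counts[2])


def simulate_reads(template: str, read_len: int, depth: float, seed: int,
                   prefix: str = "read") -> dict[str, str]:
    """Error-free shotgun reads: uniform starts, random strand.

    The read count is ``round(depth * len(template) / read_len)`` so the
    expected interior per-base depth equals ``depth``.
    """
    if depth <= 0:
        raise ScenarioParameterError("depth must be > 0")
    if read_len > len(template):
        raise ScenarioParameterError("read_len exceeds template length")
    rng = np.random.default_rng(seed)
    n_reads = max(1, int(round(depth * len(template) / read_len)))
    starts = rng.integers(0, len(template) - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads = {}
    for i, (s, st) in enumerate(zip(starts, strands)):
        seq = template[int(s):int(s) + read_len]
        if st:
            seq = revcomp(seq)
        reads[f"{prefix}_{i}"] = seq
    return reads


# ---------------------------------------------------------------------------
# serialization


def catalog_to_json(cat: DiffCatalog) -> dict:
    return {
        "substitutions": [asdict(s) for s in cat.substitutions],
        "indels": [asdict(i) for i in cat.indels],
    }


def write_scenario(scenario: SyntheticScenario, outdir: str | Path,
                   reads_depth: float = 30.0, read_len: int = 100,
                   offspring_n: int = 120) -> Path:
    """Write a scenario directory with every standard-format artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "truth_locus.fasta", {"true_locus": scenario.true_locus})
    write_fasta(outdir / "collapsed_ref.fasta", {"collapsed_ref": scenario.collapsed_reference})
    write_fasta(outdir / "cdna_a.fasta", {"cdna_a": scenario.cdna_a})
    write_fasta(outdir / "cdna_b.fasta", {"cdna_b": scenario.cdna_b})
    write_fasta(outdir / "cds.fasta", {"cds_a": scenario.cds_a, "cds_b": scenario.cds_b})
    write_fasta(outdir / "outgroup.fasta", {"outgroup": scenario.outgroup_gene})
    write_gff3(outdir / "annotations.gff3", scenario.features)
    reads = simulate_reads(scenario.true_locus, read_len, reads_depth,
                           seed=scenario.seed + 1)
    write_fasta(outdir / "reads.fasta", reads)
    with open(outdir / "primers.tsv", "w") as fh:
        fh.write("name\tsequence\n")
        for name, seq in scenario.primers.items():
            fh.write(f"{name}\t{seq}\n")
    truth = dict(scenario.truth)
    truth["catalog"] = catalog_to_json(scenario.truth_catalog)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    with open(outdir / "offspring.tsv", "w") as fh:
        fh.write("line\tn_ww\tn_wm\tn_mm\n")
        for i, line in enumerate(sorted(scenario.tdna_alleles)):
            c = sample_offspring("het", offspring_n, seed=scenario.seed + 100 + i)
            fh.write(f"{line}\t{c[0]}\t{c[1]}\t{c[2]}\n")
    return outdir
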