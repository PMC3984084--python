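"""In-silico PCR: primer site search, product prediction, arrangement
diagnosis with outward-facing primers, and paralog-discriminating design.

The outward-facing-primer diagnostic: two primers anchored at opposite ends
of a gene, both pointing *away* from it, yield no product on a single-copy
locus; a second tandem copy places some primer pair convergently, and which
reaction (A alone, B alone, or A+B) produces a product identifies the
arrangement (head-to-tail, head-to-head, or tail-to-tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from .digest import IUPAC

ARRANGEMENTS = ("single", "head_to_tail", "head_to_head", "tail_to_tail")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str               # 5'->3', IUPAC allowed
    max_mismatches: int = 0
    anchor3_len: int = 3        # 3'-terminal bases where no mismatch is tolerated

    def __post_init__(self):
        if len(self.sequence) < 15:
            raise ValueError(f"primer {self.name}: length must be >= 15")
        if self.anchor3_len > len(self.sequence):
            raise ValueError(f"primer {self.name}: anchor3_len exceeds primer length")

    @property
    def tm(self) -> float:
        """Wallace rule 2*(A+T) + 4*(G+C); used for design filtering only."""
        s = self.sequence.upper()
        at = sum(s.count(b) for b in "ATW")
        gc = sum(s.count(b) for b in "GCS")
        return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PrimerSite:
    primer: str
    template: str
    strand: str                 # "+" or "-"
    pos3: int                   # 0-based coordinate of the 3'-end base (forward strand)
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    fwd_site: PrimerSite
    rev_site: PrimerSite
    start: int                  # 5' end of the forward primer's span
    end: int                    # one past the 5' end of the reverse primer's span
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReactionResult:
    primers: tuple[str, ...]
    template: str
    amplicons: list[Amplicon] = field(default_factory=list)

    @property
    def has_product(self) -> bool:
        return bool(self.amplicons)


@dataclass
class ArrangementCall:
    arrangement: str
    evidence: dict[str, bool]
    expected_table: dict[str, dict[str, bool]]


def _mismatch_ok(primer: Primer, window: str) -> int:
    """Mismatch count of primer vs window, or -1 if the site is rejected.

    ``window`` is the template slice read in the primer's 5'->3' direction.
    Degenerate IUPAC codes in the primer match any compatible template base;
    template characters outside ACGT never match.
    """
    seq = primer.sequence.upper()
    mm = 0
    n = len(seq)
    for k in range(n):
        p, t = seq[k], window[k]
        if t not in "ACGT" or t not in IUPAC.get(p, ""):
            if k >= n - primer.anchor3_len:
                return -1
            mm += 1
            if mm > primer.max_mismatches:
                return -1
    return mm


def find_sites(primer: Primer, template: str) -> list[PrimerSite]:
    """All annealing sites of a primer on both strands of a template.

    A site on ``+`` extends rightward (3' end at ``pos3 = offset + len - 1``);
    a site on ``-`` extends leftward (3' end at ``pos3 = offset`` of the
    reverse-complement match).
    """
    if not template:
        raise ValueError("template must be non-empty")
    template = template.upper()
    n, m = len(template), len(primer.sequence)
    sites = []
    for i in range(n - m + 1):
        mm = _mismatch_ok(primer, template[i:i + m])
        if mm >= 0:
            sites.append(PrimerSite(primer.name, "template", "+", i + m - 1, mm))
    # a minus-strand site is a plus-strand match on the reverse complement
    rc_t = revcomp(template)
    for j in range(n - m + 1):
        mm = _mismatch_ok(primer, rc_t[j:j + m])
        if mm >= 0:
            sites.append(PrimerSite(primer.name, "template", "-", n - j - m, mm))
    sites.sort(key=lambda s: (s.pos3, s.strand))
    return sites


def predict_products(
    primers: list[Primer] | set[Primer],
    template: str,
    max_product_len: int = 6000,
    template_label: str = "template",
) -> ReactionResult:
    """Predict all products of a primer set on a linear template.

    Every convergent (+ then −) site pair within ``max_product_len`` yields
    one amplicon, including pairs of the same primer; divergent and
    same-strand pairs never amplify.
    """
    primers = list(primers)
    if not primers:
        raise ValueError("at least one primer required")
    template = template.upper()
    plen = {p.name: len(p.sequence) for p in primers}
    all_sites = [s for p in primers for s in find_sites(p, template)]
    fwd = [s for s in all_sites if s.strand == "+"]
    rev = [s for s in all_sites if s.strand == "-"]
    result = ReactionResult(tuple(p.name for p in primers), template_label)
    for f in fwd:
        f5 = f.pos3 - plen[f.primer] + 1
        for r in rev:
            r5 = r.pos3 + plen[r.primer] - 1
            if f.pos3 > r.pos3:          # not convergent
                continue
            length = r5 - f5 + 1
            if length < max(plen[f.primer], plen[r.primer]) or length > max_product_len:
                continue
            result.amplicons.append(
                Amplicon(f, r, f5, r5 + 1, template[f5:r5 + 1]))
    result.amplicons.sort(key=lambda a: (a.start, a.end))
    return result


# ---------------------------------------------------------------------------
# arrangement diagnosis


def _toy_gene(seed: int = 20240411, n: int = 600) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@lru_cache(maxsize=None)
def _toy_parts() -> tuple[str, Primer, Primer]:
    gene = _toy_gene()
    # outward-facing: A near the gene start pointing upstream (minus strand),
    # B near the gene end pointing downstream (plus strand)
    primer_a = Primer("A", revcomp(gene[30:50]))
    primer_b = Primer("B", gene[550:570])
    return gene, primer_a, primer_b


def toy_template(arrangement: str, spacer_len: int = 300, flank_len: int = 400) -> str:
    """A canonical toy locus for each arrangement of two gene copies."""
    gene, _, _ = _toy_parts()
    rng = np.random.default_rng(7)
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank_len))
    spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=spacer_len))
    if arrangement == "single":
        return flank + gene + flank
    if arrangement == "head_to_tail":
        return flank + gene + spacer + gene + flank
    if arrangement == "head_to_head":
        return flank + revcomp(gene) + spacer + gene + flank
    if arrangement == "tail_to_tail":
        return flank + gene + spacer + revcomp(gene) + flank
    raise ValueError(f"unknown arrangement {arrangement!r}")


REACTIONS = ("A", "B", "A+B")


@lru_cache(maxsize=None)
def arrangement_truth_table(max_product_len: int = 6000) -> dict[str, dict[str, bool]]:
    """Product presence/absence per reaction, derived by running the
    predictor on canonical toy templates — never hard-coded."""
    _, pa, pb = _toy_parts()
    table: dict[str, dict[str, bool]] = {}
    for arr in ARRANGEMENTS:
        tmpl = toy_template(arr)
        table[arr] = {
            "A": predict_products([pa], tmpl, max_product_len).has_product,
            "B": predict_products([pb], tmpl, max_product_len).has_product,
            "A+B": predict_products([pa, pb], tmpl, max_product_len).has_product,
        }
    rows = [tuple(v[r] for r in REACTIONS) for v in table.values()]
    assert len(set(rows)) == len(rows), "arrangement truth table is degenerate"
    return table


def classify_arrangement(evidence: dict[str, bool]) -> ArrangementCall:
    """Map observed reaction outcomes to the unique matching arrangement.

    ``evidence`` maps each reaction name ("A", "B", "A+B") to product
    presence. A pattern matching no enumerated arrangement returns
    ``inconsistent``.
    """
    missing = [r for r in REACTIONS if r not in evidence]
    if missing:
        raise ValueError(f"evidence missing reactions: {missing}")
    table = arrangement_truth_table()
    obs = tuple(bool(evidence[r]) for r in REACTIONS)
    matches = [arr for arr, row in table.items()
               if tuple(row[r] for r in REACTIONS) == obs]
    arr = matches[0] if len(matches) == 1 else "inconsistent"
    return ArrangementCall(arr, {r: bool(evidence[r]) for r in REACTIONS}, table)


# ---------------------------------------------------------------------------
# paralog-discriminating primer design


@dataclass(frozen=True)
class PrimerPair:
    fwd: Primer
    rev: Primer
    product_len: int
    discriminating_end: int     # template position of the allele-specific 3' end


def design_discriminating_primers(
    seq_a: str,
    seq_b: str,
    primer_len: int = 20,
    tm_range: tuple[float, float] = (50.0, 68.0),
    max_product_len: int = 2000,
    max_pairs: int = 5,
) -> dict[str, list[PrimerPair]]:
    """Design primer pairs that amplify one paralog but not the other.

    Each candidate's 3'-terminal base sits on a position where the paralogs
    differ (or inside a paralog-specific segment), so the off-target
    template carries a 3' mismatch; with the default zero-mismatch site
    model such primers cannot anneal off-target at all. Every emitted pair
    is verified with :func:`find_sites` to bind its target exactly once and
    its off-target never.
    """
    from .compare import align_pair

    out: dict[str, list[PrimerPair]] = {"a": [], "b": []}
    if seq_a == seq_b:
        return out
    aln = align_pair(seq_a, seq_b)
    # divergent template positions per sequence: mismatch columns plus the
    # bases inside segments absent from the other paralog
    div = {"a": [], "b": []}
    ia = ib = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            if ca != cb:
                div["a"].append(ia)
                div["b"].append(ib)
            ia += 1
            ib += 1
        elif ca == "-":
            div["b"].append(ib)
            ib += 1
        else:
            div["a"].append(ia)
            ia += 1
    seqs = {"a": (seq_a, seq_b), "b": (seq_b, seq_a)}
    for key, (target, off) in seqs.items():
        pairs = []
        for p in div[key]:
            if p < primer_len - 1:
                continue
            fwd_seq = target[p - primer_len + 1:p + 1]
            try:
                fwd = Primer(f"{key}_fwd_{p}", fwd_seq)
            except ValueError:
                continue
            if not (tm_range[0] <= fwd.tm <= tm_range[1]):
                continue
            if len(find_sites(fwd, target)) != 1 or find_sites(fwd, off):
                continue
            # pair with a downstream reverse primer; prefer one that is
            # itself discriminating, fall back to any specific reverse
            rev = _pick_reverse(target, off, p, primer_len, tm_range, max_product_len)
            if rev is None:
                continue
            product_len = rev[1] - (p - primer_len + 1) + 1
            pairs.append(PrimerPair(fwd, rev[0], product_len, p))
            if len(pairs) >= max_pairs:
                break
        out[key] = pairs
    return out


def _pick_reverse(target: str, off: str, fwd_pos3: int, primer_len: int,
                  tm_range: tuple[float, float], max_product_len: int):
    lo = fwd_pos3 + 80
    hi = min(len(target) - 1, fwd_pos3 + max_product_len - 1)
    for q5 in range(hi, lo, -37):           # coarse scan keeps design fast
        q3 = q5 - primer_len + 1
        if q3 <= fwd_pos3:
            break
        rev_seq = revcomp(target[q3:q5 + 1])
        try:
            rev = Primer(f"rev_{q3}", rev_seq)
        except ValueError:
            continue
        if not (tm_range[0] <= rev.tm <= tm_range[1]):
            continue
        if len(find_sites(rev, target)) != 1 or find_sites(rev, off):
            continue
        return rev, q5
    return None
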