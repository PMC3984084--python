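"""Restriction digestion simulation, including type-IIS enzymes.

Cut offsets are expressed relative to the 3' end of the recognition sequence
on the strand that carries the site: ``cut_offset_top`` is where the
site-carrying strand is cleaved, ``cut_offset_bottom`` where the complement
is cleaved. A type-IIS enzyme such as BpiI/BbsI (GAAGAC 2/6) has positive
offsets — it cuts downstream of its site; an ordinary palindromic cutter has
negative offsets placing the cut inside the site (EcoRI G^AATTC is -5/-1).

A cut coordinate ``k`` is a 0-based gap coordinate: cleavage between bases
``k-1`` and ``k`` of the top strand. Only top-strand cuts define fragment
boundaries (single-stranded overhangs are below gel resolution); bottom-
strand cut positions are derivable from the offsets but not tracked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class EnzymeDef:
    name: str
    recognition: str            # IUPAC, read 5'->3' on the site-carrying strand
    cut_offset_top: int         # bp downstream of the recognition 3' end
    cut_offset_bottom: int

    @property
    def site_len(self) -> int:
        return len(self.recognition)


def _enz(name, rec, top, bottom):
    return EnzymeDef(name, rec, top, bottom)


# Built-in table: the type-IIS discriminator plus common six-cutters.
ENZYMES: dict[str, EnzymeDef] = {
    e.name: e
    for e in [
        _enz("BpiI", "GAAGAC", 2, 6),
        _enz("BbsI", "GAAGAC", 2, 6),
        _enz("EcoRI", "GAATTC", -5, -1),
        _enz("BamHI", "GGATCC", -5, -1),
        _enz("HindIII", "AAGCTT", -5, -1),
        _enz("XbaI", "TCTAGA", -5, -1),
        _enz("PstI", "CTGCAG", -1, -5),
        _enz("SmaI", "CCCGGG", -3, -3),
    ]
}


@dataclass
class DigestPattern:
    template: str                   # label
    cut_positions: list[int]        # sorted 0-based top-strand gap coordinates
    fragment_lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.fragment_lengths:
            raise ValueError("fragment_lengths required")


def _iupac_match(pattern: str, text: str) -> bool:
    return all(c in IUPAC[p] for p, c in zip(pattern, text))


def _find_sites(template: str, pattern: str) -> list[int]:
    n, m = len(template), len(pattern)
    return [i for i in range(n - m + 1) if _iupac_match(pattern, template[i:i + m])]


def digest(template: str, enzyme: EnzymeDef, label: str = "template") -> DigestPattern:
    """Digest a linear template, returning cut coordinates and fragments.

    Sites are searched on both strands independently. A cleavage coordinate
    that falls outside the template (site too close to an end) is skipped
    with a warning.
    """
    template = template.upper()
    L = len(template)
    rec = enzyme.recognition.upper()
    rc_rec = str(Seq(rec).reverse_complement())
    cuts: set[int] = set()
    for i in _find_sites(template, rec):
        c = i + enzyme.site_len + enzyme.cut_offset_top
        if 0 < c < L:
            cuts.add(c)
        else:
            warnings.warn(f"{enzyme.name} site at {i} cuts outside the template; skipped")
    for i in _find_sites(template, rc_rec):
        # recognition on the bottom strand, 3' end at top coordinate i;
        # the top strand here is the complement strand of the site
        c = i - enzyme.cut_offset_bottom
        if 0 < c < L:
            cuts.add(c)
        else:
            warnings.warn(f"{enzyme.name} bottom-strand site at {i} cuts outside; skipped")
    cut_list = sorted(cuts)
    bounds = [0] + cut_list + [L]
    frags = [bounds[k + 1] - bounds[k] for k in range(len(bounds) - 1)]
    return DigestPattern(label, cut_list, frags)


def classify_by_pattern(
    observed: DigestPattern,
    references: dict[str, DigestPattern],
    tolerance: int = 0,
) -> str:
    """Assign an observed fragment pattern to the unique matching reference.

    Fragment multisets match when they have the same count and every sorted
    length agrees within ``tolerance`` bp. Returns the matching label, or
    ``"ambiguous"`` when zero or several references match.
    """
    if not references:
        raise ValueError("at least one reference pattern required")
    obs = sorted(observed.fragment_lengths)
    matches = []
    for label, ref in references.items():
        rf = sorted(ref.fragment_lengths)
        if len(rf) == len(obs) and all(abs(a - b) <= tolerance for a, b in zip(obs, rf)):
            matches.append(label)
    return matches[0] if len(matches) == 1 else "ambiguous"
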