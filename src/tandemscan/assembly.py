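"""Overlap merging of cloned amplicons and collapsed-segment detection.

`assemble_overlaps` chains error-free fragments into a single contig by
exact suffix–prefix overlaps, optionally auto-orienting fragments. It is the
in-silico analog of manually assembling a locus that was cloned in a few
overlapping PCR products.

`detect_collapsed_segment` compares a reassembled locus against a reference
and reports the maximal segment present in the assembly but absent from the
reference. Because such a segment sits inside a tandem repeat, its
breakpoint on the reference is not unique: every placement within the
repeated flank is equivalent, and the report carries that whole interval
rather than a single arbitrary point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class AssemblyError(ValueError):
    pass


class DisconnectedError(AssemblyError):
    def __init__(self, components):
        self.components = components
        super().__init__(f"fragments do not chain into one contig; components: {components}")


class AmbiguousLayoutError(AssemblyError):
    def __init__(self, layouts):
        self.layouts = layouts
        super().__init__(f"{len(layouts)} distinct layouts are consistent with the overlaps")


@dataclass
class Layout:
    order: list[str]                 # fragment labels, left to right
    orientations: list[str]          # "+" or "-" per fragment
    offsets: list[int]               # contig start offset per fragment
    contig: str


def _suffix_prefix_overlap(x: str, y: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with x[-k:] == y[:k] (0 when none)."""
    best = 0
    seed = x[-min_overlap:]
    start = 0
    while True:
        j = y.find(seed, start)
        if j < 0:
            break
        k = j + min_overlap
        if k <= len(x) and k <= len(y) and x[-k:] == y[:k]:
            best = max(best, k)
        start = j + 1
    return best


def assemble_overlaps(
    fragments: list[tuple[str, str]],
    min_overlap: int = 100,
    auto_orient: bool = True,
) -> Layout:
    """Merge fragments into one contig via exact suffix–prefix overlaps.

    Fragments may be given in any order and (with ``auto_orient``) in either
    orientation. Raises :class:`DisconnectedError` when no single chain
    exists and :class:`AmbiguousLayoutError` when the overlap graph admits
    more than one distinct contig (e.g. a repeated block longer than
    ``min_overlap`` shared by several fragments).
    """
    n = len(fragments)
    if n == 0:
        raise AssemblyError("no fragments")
    labels = [lab for lab, _ in fragments]
    if n == 1:
        return Layout(labels, ["+"], [0], fragments[0][1].upper())
    if n > 12:
        raise AssemblyError("assembler is designed for small clone sets (<= 12 fragments)")
    variants = {lab: {"+": seq.upper(), "-": revcomp(seq.upper())}
                for lab, seq in fragments}
    orient_choices = [["+", "-"] if auto_orient else ["+"]] * n

    layouts: dict[str, Layout] = {}
    seen_components: list[list[str]] = []

    def overlap(i, oi, j, oj):
        return _suffix_prefix_overlap(variants[labels[i]][oi], variants[labels[j]][oj],
                                      min_overlap)

    for orients in itertools.product(*orient_choices):
        # overlap graph for this orientation assignment
        edges = {}
        for i in range(n):
            for j in range(n):
                if i != j:
                    k = overlap(i, orients[i], j, orients[j])
                    if k:
                        edges[(i, j)] = k
        # search Hamiltonian chains
        for chain in _hamiltonian_chains(n, edges):
            contig_parts = []
            offsets = [0] * n
            pos = 0
            prev = None
            for idx in chain:
                seq = variants[labels[idx]][orients[idx]]
                if prev is None:
                    contig_parts.append(seq)
                    offsets[idx] = 0
                    pos = len(seq)
                else:
                    k = edges[(prev, idx)]
                    offsets[idx] = pos - k
                    contig_parts.append(seq[k:])
                    pos += len(seq) - k
                prev = idx
            contig = "".join(contig_parts)
            key = min(contig, revcomp(contig))   # a chain and its mirror are one layout
            if key not in layouts:
                layouts[key] = Layout(
                    [labels[i] for i in chain],
                    [orients[i] for i in chain],
                    [offsets[i] for i in chain],
                    contig,
                )

    if len(layouts) == 1:
        return next(iter(layouts.values()))
    if len(layouts) > 1:
        raise AmbiguousLayoutError(list(layouts.values()))
    # no chain in any orientation: report connected components of the
    # undirected overlap graph in the all-forward orientation
    comp = _components(n, labels, variants, min_overlap)
    raise DisconnectedError(comp)


def _hamiltonian_chains(n: int, edges: dict[tuple[int, int], int]):
    chains = []

    def extend(chain, used):
        if len(chain) == n:
            chains.append(list(chain))
            return
        for j in range(n):
            if j not in used and (chain[-1], j) in edges:
                chain.append(j)
                used.add(j)
                extend(chain, used)
                chain.pop()
                used.remove(j)

    for start in range(n):
        extend([start], {start})
    return chains


def _components(n, labels, variants, min_overlap):
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for oi in variants[labels[i]]:
                for oj in variants[labels[j]]:
                    if _suffix_prefix_overlap(variants[labels[i]][oi],
                                              variants[labels[j]][oj], min_overlap):
                        adj[i].add(j)
                        adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(labels[k])
            stack.extend(adj[k] - seen)
        comps.append(sorted(comp))
    return comps


# ---------------------------------------------------------------------------
# collapse detection


@dataclass
class CollapseReport:
    inserted_segment: tuple[int, int]       # on the assembled sequence, leftmost placement
    length: int
    placement_interval: tuple[int, int]     # equivalent breakpoints on the reference
    flanking_identity: float
    breakpoint_reference: int               # leftmost equivalent breakpoint

    @property
    def placement_width(self) -> int:
        return self.placement_interval[1] - self.placement_interval[0]

    @property
    def empty(self) -> bool:
        return self.length == 0

    def to_dict(self) -> dict:
        return {
            "inserted_segment": list(self.inserted_segment),
            "length": self.length,
            "placement_interval": list(self.placement_interval),
            "placement_width": self.placement_width,
            "flanking_identity": self.flanking_identity,
            "breakpoint_reference": self.breakpoint_reference,
        }


def _empty_report() -> CollapseReport:
    return CollapseReport((0, 0), 0, (0, 0), 1.0, 0)


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    lo, hi = 0, n
    while lo < hi:                       # binary search using slice equality
        mid = (lo + hi + 1) // 2
        if a[:mid] == b[:mid]:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _common_suffix(a: str, b: str) -> int:
    return _common_prefix(a[::-1], b[::-1])


def _shared_unique_anchors(assembled: str, reference: str, anchor_len: int) -> list[tuple[int, int]]:
    def unique_kmers(s):
        pos: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(0, len(s) - anchor_len + 1):
            k = s[i:i + anchor_len]
            if k in pos or k in dup:
                dup.add(k)
                pos.pop(k, None)
            else:
                pos[k] = i
        return pos

    ka = unique_kmers(assembled)
    kr = unique_kmers(reference)
    return sorted((ka[k], kr[k]) for k in ka.keys() & kr.keys())


def detect_collapsed_segment(
    assembled: str,
    reference: str,
    anchor_len: int = 50,
) -> CollapseReport:
    """Find the maximal segment of ``assembled`` missing from ``reference``.

    Shared unique exact anchors establish collinearity (and that the inputs
    are related at all); the breakpoint is then refined to base precision by
    maximal exact flank extension. Every equivalent breakpoint placement on
    the reference is reported as ``placement_interval`` — its width is the
    length of the repeated flank across which the insertion can slide. The
    canonical ``inserted_segment``/``breakpoint_reference`` use the leftmost
    placement.
    """
    assembled = assembled.upper()
    reference = reference.upper()
    if assembled == reference:
        return _empty_report()
    anchors = _shared_unique_anchors(assembled, reference, anchor_len)
    if not anchors:
        raise ValueError("unrelated sequences: no shared unique anchors "
                         f"of length {anchor_len}")
    d = len(assembled) - len(reference)
    if d <= 0:
        # reference carries extra sequence instead; not an assembly collapse
        return _empty_report()

    p = _common_prefix(assembled, reference)
    q = _common_suffix(assembled, reference)
    if p + q >= len(reference):
        # clean single insertion: breakpoints r in [len(ref)-q, p] are equivalent
        r_left = len(reference) - q
        r_right = p
        return CollapseReport(
            inserted_segment=(r_left, r_left + d),
            length=d,
            placement_interval=(r_left, r_right),
            flanking_identity=1.0,
            breakpoint_reference=r_left,
        )

    # flanks are not exact end to end: locate the largest anchor-offset jump
    # and extend exact matches inward from the bracketing anchors
    jumps = []
    for (a0, r0), (a1, r1) in zip(anchors, anchors[1:]):
        off0, off1 = a0 - r0, a1 - r1
        if off1 != off0:
            jumps.append((off1 - off0, (a0, r0), (a1, r1)))
    if not jumps:
        raise ValueError("length difference without an anchor offset jump; "
                         "sequences differ in an unanchored region")
    gain, (a0, r0), (a1, r1) = max(jumps, key=lambda t: t[0])
    # extend the left flank right from anchor (a0, r0)
    i, j = a0, r0
    while i < len(assembled) and j < len(reference) and assembled[i] == reference[j]:
        i += 1
        j += 1
    left_a, left_r = i, j
    # extend the right flank left from anchor (a1, r1)
    i, j = a1 + anchor_len, r1 + anchor_len
    while i > 0 and j > 0 and assembled[i - 1] == reference[j - 1]:
        i -= 1
        j -= 1
    right_a, right_r = i, j
    length = max(0, (right_a - left_a) - max(0, right_r - left_r))
    if length == 0:
        return _empty_report()
    r_left = min(left_r, right_r)
    r_right = max(left_r, right_r) if right_r >= left_r else left_r
    a_left = r_left + (left_a - left_r)
    ident = _flank_identity(assembled, reference, a_left, r_left, length)
    return CollapseReport(
        inserted_segment=(a_left, a_left + length),
        length=length,
        placement_interval=(r_left, r_right if right_r >= left_r else r_left),
        flanking_identity=ident,
        breakpoint_reference=r_left,
    )


def _flank_identity(assembled, reference, a_left, r_left, length, w: int = 200) -> float:
    la = assembled[max(0, a_left - w):a_left]
    lr = reference[max(0, r_left - w):r_left]
    ra = assembled[a_left + length:a_left + length + w]
    rr = reference[r_left:r_left + w]
    pairs = list(zip(la[::-1], lr[::-1])) + list(zip(ra, rr))
    if not pairs:
        return 1.0
    return sum(a == b for a, b in pairs) / len(pairs)


@dataclass
class _FragmentSpec:
    label: str
    start: int
    end: int


def tile_fragments(sequence: str, n_fragments: int = 4, overlap: int = 150,
                   labels: list[str] | None = None) -> list[tuple[str, str]]:
    """Cut a locus into overlapping clone-like fragments (for demos/tests)."""
    L = len(sequence)
    n = n_fragments
    core = (L + (n - 1) * overlap) // n + 1
    frags = []
    start = 0
    for i in range(n):
        end = min(L, start + core)
        if i == n - 1:
            end = L
        lab = labels[i] if labels else f"frag_{i + 1}"
        frags.append((lab, sequence[start:end]))
        start = end - overlap
    return frags
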