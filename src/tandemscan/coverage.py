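"""Read-depth scanning for collapsed duplications.

When two near-identical tandem copies are collapsed into one in a reference,
reads from *both* true copies map onto the single reference copy, roughly
doubling its depth. Mapping reads back and flagging windows of excess
depth relative to the genome median therefore highlights candidate collapsed
duplications for manual inspection.

The mapper here is deliberately minimal — full-length placement of
error-free reads, exact by default, optionally tolerant up to an edit
budget — because the module demonstrates the detection principle, not a
production aligner. Multi-mapping reads contribute fractional depth (1/k at
each of k best placements) so total depth mass is conserved. In exact mode,
reads spanning a paralog-specific variant fail to cross-map, which locally
depresses the ratio below 2; an edit budget restores them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.Seq import Seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class CoverageProfile:
    reference: str              # label
    window: int
    depths: np.ndarray          # mean depth per window
    genome_median: float

    @property
    def ratios(self) -> np.ndarray:
        return self.depths / self.genome_median


@dataclass
class DuplicationCall:
    interval: tuple[int, int]   # bp interval on the reference
    mean_ratio: float
    n_windows: int


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _edlib_spans(read: str, reference: str, max_edits: int,
                 offset: int = 0) -> list[tuple[int, int, int]]:
    """Best-scoring (start, end, distance) placements within the budget."""
    res = edlib.align(read, reference, mode="HW", task="locations", k=max_edits)
    d = res["editDistance"]
    if d < 0:
        return []
    spans = []
    for s, e in res["locations"]:
        s = 0 if s is None else s
        spans.append((s + offset, e + 1 + offset, d))
    return sorted(set(spans))


SEED_LEN = 20


def _seeded_spans(read: str, reference: str, seed_index: dict[str, list[int]],
                  max_edits: int) -> list[tuple[int, int]]:
    """Seed-and-extend placement of a read that has no exact hit.

    Several spaced seeds tolerate variants corrupting any one seed; each
    seed hit nominates a candidate window which is aligned with edlib. All
    placements achieving the best edit distance within the budget are kept.
    """
    L = len(read)
    n_seeds = max(2, L // 25)
    offsets = [round(i * (L - SEED_LEN) / (n_seeds - 1)) for i in range(n_seeds)]
    cand_starts: set[int] = set()
    for o in offsets:
        for h in seed_index.get(read[o:o + SEED_LEN], []):
            cand_starts.add(h - o)
    best: list[tuple[int, int, int]] = []
    pad = max_edits + 4
    seen_windows: set[tuple[int, int]] = set()
    for cs in sorted(cand_starts):
        w0 = max(0, cs - pad)
        w1 = min(len(reference), cs + L + pad)
        if (w0, w1) in seen_windows:
            continue
        seen_windows.add((w0, w1))
        best.extend(_edlib_spans(read, reference[w0:w1], max_edits, offset=w0))
    if not best:
        return []
    d_min = min(d for _, _, d in best)
    return sorted({(s, e) for s, e, d in best if d == d_min})


def map_reads(
    reads: dict[str, str] | list[str],
    reference: str,
    max_edits: int = 0,
) -> np.ndarray:
    """Per-base depth of full-length read placements on a reference.

    Each read (either strand) is placed at all its best-scoring locations
    within ``max_edits`` edit distance (exact occurrences when the budget is
    0); a read with k placements adds 1/k depth across each. Reads longer
    than the reference are skipped with a warning.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    seqs = list(reads.values()) if isinstance(reads, dict) else list(reads)
    if not seqs:
        raise ValueError("no reads")
    reference = reference.upper()
    depth = np.zeros(len(reference))
    # exact lookup index per read length present (reads are typically uniform)
    lengths = {len(s) for s in seqs if len(s) <= len(reference)}
    index: dict[int, dict[str, list[int]]] = {}
    for L in lengths:
        idx: dict[str, list[int]] = {}
        for i in range(len(reference) - L + 1):
            idx.setdefault(reference[i:i + L], []).append(i)
        index[L] = idx
    seed_index: dict[str, list[int]] = {}
    if max_edits > 0:
        for i in range(len(reference) - SEED_LEN + 1):
            seed_index.setdefault(reference[i:i + SEED_LEN], []).append(i)
    for seq in seqs:
        seq = seq.upper()
        if len(seq) > len(reference):
            warnings.warn("read longer than reference; skipped")
            continue
        spans: list[tuple[int, int]] = []
        inexact: list[tuple[int, int]] = []
        for variant in (seq, revcomp(seq)):
            exact = index[len(variant)].get(variant, [])
            if exact:
                spans.extend((i, i + len(variant)) for i in exact)
            elif max_edits > 0:
                inexact.extend(_seeded_spans(variant, reference, seed_index, max_edits))
        # exact placements outrank budgeted ones (best-score semantics)
        if not spans:
            spans = inexact
        if not spans:
            continue
        spans = sorted(set(spans))
        w = 1.0 / len(spans)
        for s, e in spans:
            depth[s:e] += w
    return depth


def profile_from_depth(depth: np.ndarray, window: int = 100,
                       label: str = "reference") -> CoverageProfile:
    if window <= 0:
        raise ValueError("window must be > 0")
    n = len(depth) // window
    if n == 0:
        raise ValueError("reference shorter than one window")
    means = depth[:n * window].reshape(n, window).mean(axis=1)
    return CoverageProfile(label, window, means, float(np.median(means)))


def call_duplications(
    profile: CoverageProfile,
    threshold_ratio: float = 1.75,
    min_windows: int = 3,
) -> list[DuplicationCall]:
    """Maximal runs of elevated-depth windows.

    A call is a run of at least ``min_windows`` windows whose depth ratio
    (window depth / genome median) meets ``threshold_ratio``; runs separated
    by a single sub-threshold window are merged.
    """
    if profile.genome_median <= 0:
        raise ValueError("genome median depth is zero")
    if len(profile.depths) < min_windows:
        raise ValueError("profile shorter than min_windows")
    ratios = profile.ratios
    return _calls_from_ratios(ratios, profile.window, threshold_ratio, min_windows)


def _calls_from_ratios(ratios, window, threshold_ratio, min_windows):
    hot = ratios >= threshold_ratio
    # merge runs separated by exactly one cold window
    merged = hot.copy()
    for i in range(1, len(hot) - 1):
        if not hot[i] and hot[i - 1] and hot[i + 1]:
            merged[i] = True
    calls = []
    i = 0
    n = len(merged)
    while i < n:
        if not merged[i]:
            i += 1
            continue
        j = i
        while j < n and merged[j]:
            j += 1
        if j - i >= min_windows:
            w = window
            calls.append(DuplicationCall(
                interval=(i * w, j * w),
                mean_ratio=float(ratios[i:j].mean()),
                n_windows=j - i,
            ))
        i = j
    return calls


def single_copy_baseline(profile: CoverageProfile,
                         calls: list[DuplicationCall]) -> float:
    """Median window depth outside called intervals.

    The plain genome median is biased upward when duplicated windows make up
    an appreciable fraction of the reference; masking called regions and
    re-estimating gives an unbiased single-copy baseline (the usual two-pass
    practice in read-depth copy-number analysis).
    """
    w = profile.window
    mask = np.ones(len(profile.depths), dtype=bool)
    for c in calls:
        mask[c.interval[0] // w:c.interval[1] // w] = False
    if not mask.any():
        return profile.genome_median
    return float(np.median(profile.depths[mask]))


def scan_duplications(
    depth: np.ndarray,
    window: int = 100,
    threshold_ratio: float = 1.75,
    min_windows: int = 3,
    label: str = "reference",
) -> tuple[CoverageProfile, list[DuplicationCall]]:
    """Two-pass duplication scan from a per-base depth vector.

    Pass one calls against the raw genome median; the baseline is then
    re-estimated from non-called windows and the calls recomputed against
    the corrected median.
    """
    prof = profile_from_depth(depth, window, label)
    calls = call_duplications(prof, threshold_ratio, min_windows)
    baseline = single_copy_baseline(prof, calls)
    if baseline <= 0:
        return prof, calls
    prof = CoverageProfile(label, window, prof.depths, baseline)
    calls = call_duplications(prof, threshold_ratio, min_windows)
    return prof, calls
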