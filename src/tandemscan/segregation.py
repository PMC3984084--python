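"""Segregation genetics of T-DNA insertion alleles with a hidden paralog.

Selfing a heterozygote for a null insertion allele yields offspring in a
1:2:1 ratio of wild-type homozygotes : heterozygotes : mutant homozygotes
(w/w : w/m : m/m). PCR genotyping scores each plant by the presence of a
wild-type band and an insertion band. If the wild-type primers also amplify
an intact *paralog* of the disrupted gene (a non-discriminating assay),
every plant shows a wild-type band, so true m/m plants are miscalled w/m:
the true 1:2:1 appears as 1:3:0, and offspring of a true m/m parent
(mistyped as heterozygous) appear 0:1:0. This module tests observed counts
against Mendelian expectations and ranks competing explanations of a
distorted ratio by multinomial likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats


@dataclass(frozen=True)
class AssayModel:
    """Genotyping assay behaviour.

    With ``discriminating=False`` the wild-type reaction amplifies from an
    intact paralog in every plant, so no plant can be scored m/m.
    """

    discriminating: bool = True


@dataclass(frozen=True)
class GenotypeCounts:
    n_ww: int
    n_wm: int
    n_mm: int
    assay: AssayModel = AssayModel()

    def __post_init__(self):
        if min(self.n_ww, self.n_wm, self.n_mm) < 0 or self.total == 0:
            raise ValueError("counts must be >= 0 with a positive total")

    @property
    def total(self) -> int:
        return self.n_ww + self.n_wm + self.n_mm

    @property
    def triple(self) -> tuple[int, int, int]:
        return (self.n_ww, self.n_wm, self.n_mm)


@dataclass
class SegregationResult:
    chi2: float
    df: int
    p: float
    expected_ratio: tuple[float, float, float]
    verdict: str                # "consistent" | "distorted" | "incompatible"


# Candidate explanations for an observed w/w:w/m:m/m pattern. Ratios are the
# *apparent* class probabilities each hypothesis predicts.
#   normal_1_2_1              — Mendelian selfed heterozygote, honest assay
#   hidden_paralog_het_parent — selfed het, paralog masks m/m as w/m (1:3:0)
#   hidden_paralog_hom_parent — parent was in fact m/m; all offspring m/m,
#                               all appear w/m (0:1:0)
#   embryo_lethal             — m/m dies as embryo: 1:2:0
#   male_gametophytic         — mutant pollen fails: 1:1:0
DEFAULT_HYPOTHESES: dict[str, tuple[float, float, float]] = {
    "normal_1_2_1": (1, 2, 1),
    "hidden_paralog_het_parent": (1, 3, 0),
    "hidden_paralog_hom_parent": (0, 1, 0),
    "embryo_lethal": (1, 2, 0),
    "male_gametophytic": (1, 1, 0),
}


@dataclass
class HypothesisRanking:
    ranking: list[tuple[str, float]]       # (name, log-likelihood), best first
    best: str
    close_call: bool                       # top two within 2 log-units
    loglik: dict[str, float] = field(default_factory=dict)


def _normalize(ratio) -> tuple[float, float, float]:
    total = float(sum(ratio))
    if total <= 0 or any(r < 0 for r in ratio):
        raise ValueError("expected ratio must be non-negative with a positive sum")
    return tuple(r / total for r in ratio)  # type: ignore[return-value]


def chisq_gof(counts: GenotypeCounts, expected_ratio=(1, 2, 1),
              alpha: float = 0.05) -> SegregationResult:
    """Chi-square goodness of fit of genotype counts to an expected ratio.

    Classes with expected proportion 0 are excluded and the degrees of
    freedom reduced accordingly; an observed count in such a class is
    categorical evidence against the model (verdict ``incompatible``,
    p = 0). No continuity correction is applied.
    """
    probs = _normalize(expected_ratio)
    if sum(p > 0 for p in probs) < 2:
        raise ValueError("expected ratio needs at least two positive classes")
    obs = counts.triple
    n = counts.total
    if any(o > 0 and p == 0 for o, p in zip(obs, probs)):
        return SegregationResult(math.inf, sum(p > 0 for p in probs) - 1, 0.0,
                                 probs, "incompatible")
    chi2 = 0.0
    k = 0
    for o, p in zip(obs, probs):
        if p == 0:
            continue
        e = n * p
        chi2 += (o - e) ** 2 / e
        k += 1
    df = k - 1
    p_val = float(stats.chi2.sf(chi2, df))
    verdict = "consistent" if p_val >= alpha else "distorted"
    return SegregationResult(chi2, df, p_val, probs, verdict)


def apparent_ratio(true_ratio, assay: AssayModel) -> tuple[float, float, float]:
    """Project a true genotype ratio through the genotyping assay.

    A non-discriminating assay folds the m/m class into w/m (the intact
    paralog contributes the wild-type band); projecting twice equals
    projecting once.
    """
    r = _normalize(true_ratio)
    if assay.discriminating:
        return r
    return (r[0], r[1] + r[2], 0.0)


def select_hypothesis(
    counts: GenotypeCounts,
    hypotheses: dict[str, tuple[float, float, float]] | None = None,
) -> HypothesisRanking:
    """Rank candidate segregation models by multinomial log-likelihood.

    All candidates are parameter-free, so raw log-likelihood is the model
    score (equal priors); a hypothesis giving probability 0 to an observed
    class scores -inf. ``close_call`` flags a top-two gap below 2 log-units.
    """
    hyps = hypotheses if hypotheses is not None else DEFAULT_HYPOTHESES
    if len(hyps) < 2:
        raise ValueError("need at least two hypotheses")
    obs = counts.triple
    logliks: dict[str, float] = {}
    for name, ratio in hyps.items():
        probs = _normalize(ratio)
        if any(o > 0 and p == 0 for o, p in zip(obs, probs)):
            logliks[name] = -math.inf
            continue
        kept = [(o, p) for o, p in zip(obs, probs) if p > 0]
        logliks[name] = float(stats.multinomial.logpmf(
            [o for o, _ in kept], counts.total, [p for _, p in kept]))
    ranking = sorted(logliks.items(), key=lambda t: t[1], reverse=True)
    gap = ranking[0][1] - ranking[1][1]
    close = (not math.isinf(ranking[0][1])) and gap < 2.0
    return HypothesisRanking(ranking, ranking[0][0], close, logliks)
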