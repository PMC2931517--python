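"""The four feature-architecture similarity scores.

Given a query architecture Q and a subject architecture P, four scoring
functions quantify how similar their feature arrangements are, each in
[0, 1]:

* **MLS** — modified Lin score: a Jaccard index over feature contents
  plus a duplication-similarity term, combined with fixed coefficients
  0.365 and 0.635.  Features present in only one protein reduce it.
* **MS_uni** — multiplicity similarity with uniform weights 1/N^Q: for
  every shared feature the agreement of instance counts,
  N_i^P · N_i^Q / max(N_i^P, N_i^Q)².  Only shared features contribute.
* **MS_st** — the same sum with proteome-frequency weights derived from
  a reference proteome.
* **CS** — clan similarity: the multiplicity agreement computed on Pfam
  clan instance counts, normalised by the query's clan count.
* **PS** — positional similarity: per shared feature, one minus the
  minimal distance between each query instance's relative center and the
  subject's instance centers, weighted like MS_st.

The composite score is the convex combination

    FACT = alpha · MS_st + beta · CS + gamma · PS,

with alpha : beta : gamma defaulting to 3 : 1 : 1 (0.6, 0.2, 0.2).  The
component weights are deliberately not tuned.

Degenerate cases are explicit: a featureless query or subject scores 0
everywhere with ``degenerate=True``; a query with no clan-mapped Pfam
domains gets CS = 0 by convention (constant within one search, so
rankings are unaffected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional

from .architecture_model import (
    ClanProfile,
    CountProfile,
    FeatureArchitecture,
    FeatureCatalog,
    PositionProfile,
    clan_profile,
    count_profile,
    position_profile,
    shared_features,
)
from .annotation_io import Proteome

__all__ = [
    "WeightVector",
    "ScoreWeights",
    "ScoreBreakdown",
    "mls",
    "uniform_weights",
    "proteome_weights",
    "multiplicity_similarity",
    "clan_similarity",
    "positional_similarity",
    "fact_score",
]

WeightScheme = Literal["uniform", "proteome-frequency", "inverse-frequency"]


@dataclass
class WeightVector:
    """Per-feature weights ω_i over the query's features.

    ``degenerate`` is set when the weights could not be normalised (empty
    query, or none of the query's features occurs in the reference set);
    all weights are then zero.
    """

    weights: Dict[str, float] = field(default_factory=dict)
    scheme: WeightScheme = "uniform"
    degenerate: bool = False

    def __getitem__(self, feature_id: str) -> float:
        return self.weights.get(feature_id, 0.0)


@dataclass
class ScoreWeights:
    """Coefficients of the composite score and the MLS constants.

    alpha, beta, gamma weight MS_st, CS and PS and must sum to one;
    jaccard_coef/duplication_coef are the two MLS mixing constants.
    """

    alpha: float = 0.6
    beta: float = 0.2
    gamma: float = 0.2
    jaccard_coef: float = 0.365
    duplication_coef: float = 0.635

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")
        total = self.alpha + self.beta + self.gamma
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"alpha + beta + gamma must equal 1, got {total}")


@dataclass
class ScoreBreakdown:
    """All similarity scores for one query–subject pair."""

    ms_uni: float
    ms_st: float
    cs: float
    ps: float
    mls: float
    fact: float
    weights: WeightVector
    n_p: int
    n_q: int
    n_pq: int
    degenerate: bool = False

    def score(self, name: str) -> float:
        return {
            "ms_uni": self.ms_uni,
            "ms_st": self.ms_st,
            "cs": self.cs,
            "ps": self.ps,
            "mls": self.mls,
            "fact": self.fact,
        }[name]


#: Scoring-function names accepted wherever a selector is expected.
SCORE_NAMES = ("mls", "ms_uni", "ms_st", "cs", "ps", "fact")


def mls(p: CountProfile, q: CountProfile, w: Optional[ScoreWeights] = None) -> float:
    """Modified Lin score between two count profiles.

    The Jaccard term is N^PQ / (N^P + N^Q − N^PQ); the duplication term
    is exp(−Σ_i |N_i^P − N_i^Q| / N_max) with N_max = Σ_i max(N_i^P, N_i^Q),
    both sums over the union of feature types (absent features count 0).
    Two empty profiles score 0 (degenerate).
    """
    w = w or ScoreWeights()
    union = set(p.counts) | set(q.counts)
    if not union:
        return 0.0
    n_pq = len(shared_features(p, q))
    jaccard = n_pq / (p.n_features + q.n_features - n_pq)
    diff = sum(abs(p[f] - q[f]) for f in union)
    n_max = sum(max(p[f], q[f]) for f in union)
    duplication = math.exp(-diff / n_max)
    return w.jaccard_coef * jaccard + w.duplication_coef * duplication


def uniform_weights(q: CountProfile) -> WeightVector:
    """Equal weighting of all the query's features: ω_i = 1/N^Q.

    Summed over shared features only, the uniform-weight multiplicity
    similarity reaches 1 exactly when all of Q's features are shared.
    """
    if q.n_features == 0:
        return WeightVector({}, scheme="uniform", degenerate=True)
    w = 1.0 / q.n_features
    return WeightVector({f: w for f in q.counts}, scheme="uniform")


def proteome_weights(
    q: CountProfile,
    ref: Proteome,
    scheme: Literal["frequency", "inverse"] = "frequency",
) -> WeightVector:
    """Weights from feature frequencies in a reference proteome.

    The default scheme sets ω_i proportional to the total instance count
    of feature i over the whole reference set, normalised over the
    query's features so Σ ω_i = 1.  The ``inverse`` scheme instead makes
    ω_i proportional to the reciprocal of that total, so architectures
    sharing features that are *rare* in the search proteome score higher
    (see the methods note on why both directions are offered).  Features
    of Q absent from the reference get weight 0; if none of Q's features
    occurs, the vector is all-zero and flagged degenerate.
    """
    if len(ref) == 0:
        raise ValueError("reference proteome is empty")
    label: WeightScheme = (
        "proteome-frequency" if scheme == "frequency" else "inverse-frequency"
    )
    if q.n_features == 0:
        return WeightVector({}, scheme=label, degenerate=True)
    totals = {f: ref.feature_total(f) for f in q.counts}
    if scheme == "frequency":
        denom = sum(totals.values())
        if denom == 0:
            return WeightVector(dict.fromkeys(q.counts, 0.0), label, degenerate=True)
        return WeightVector({f: t / denom for f, t in totals.items()}, label)
    if scheme != "inverse":
        raise ValueError(f"unknown weight scheme {scheme!r}")
    inv = {f: (1.0 / t if t > 0 else 0.0) for f, t in totals.items()}
    denom = sum(inv.values())
    if denom == 0:
        return WeightVector(dict.fromkeys(q.counts, 0.0), label, degenerate=True)
    return WeightVector({f: v / denom for f, v in inv.items()}, label)


def multiplicity_similarity(
    p: CountProfile, q: CountProfile, w: WeightVector
) -> float:
    """Weighted agreement of instance counts over shared features.

    Each shared feature contributes ω_i · N_i^P·N_i^Q / max(N_i^P, N_i^Q)²;
    the instance-count ratio is 1 when the counts agree.
    """
    total = 0.0
    for f in shared_features(p, q):
        np_, nq = p[f], q[f]
        total += w[f] * (np_ * nq) / max(np_, nq) ** 2
    return total


def clan_similarity(cp: ClanProfile, cq: ClanProfile) -> float:
    """Instance-count agreement over shared Pfam clans, normalised by C^Q.

    Credits different domains from the same clan: structurally related
    families count toward the same clan total.  A query without clans
    scores 0 by convention.
    """
    if cq.n_clans == 0:
        return 0.0
    total = 0.0
    for clan in set(cp.counts) & set(cq.counts):
        ci_p, ci_q = cp[clan], cq[clan]
        total += (ci_p * ci_q) / max(ci_p, ci_q) ** 2
    return total / cq.n_clans


def positional_similarity(
    pp: PositionProfile,
    pq: PositionProfile,
    counts_q: CountProfile,
    w: WeightVector,
) -> float:
    """Agreement of relative feature positions between subject and query.

    For every instance j of a shared feature in Q, the closest instance
    of the same feature in P determines a similarity 1 − |q_j − p_l|;
    these are averaged over Q's instances of the feature and combined
    with the (proteome-frequency) feature weights.
    """
    total = 0.0
    for f in pq:
        p_centers = pp[f]
        if not p_centers:
            continue
        q_centers = pq[f]
        inner = sum(
            1.0 - min(abs(qc - pc) for pc in p_centers) for qc in q_centers
        )
        total += (w[f] / counts_q[f]) * inner
    return total


def fact_score(
    p: FeatureArchitecture,
    q: FeatureArchitecture,
    ref: Proteome,
    catalog: FeatureCatalog,
    w: Optional[ScoreWeights] = None,
    weight_scheme: Literal["frequency", "inverse"] = "frequency",
) -> ScoreBreakdown:
    """Full score breakdown between a subject P and a query Q.

    ``ref`` supplies the feature totals for the proteome-frequency
    weights behind MS_st and PS; when the query belongs to the search
    proteome it contributes to those totals like any other member (it is
    never added if absent).  If either architecture has no features at
    all, every score is 0 and the breakdown is flagged degenerate.
    """
    w = w or ScoreWeights()
    cp, cq = count_profile(p), count_profile(q)
    if cp.n_features == 0 or cq.n_features == 0:
        empty = WeightVector({}, scheme="proteome-frequency", degenerate=True)
        return ScoreBreakdown(
            ms_uni=0.0, ms_st=0.0, cs=0.0, ps=0.0, mls=0.0, fact=0.0,
            weights=empty, n_p=cp.n_features, n_q=cq.n_features, n_pq=0,
            degenerate=True,
        )
    wv_uni = uniform_weights(cq)
    wv_st = proteome_weights(cq, ref, scheme=weight_scheme)
    ms_uni = multiplicity_similarity(cp, cq, wv_uni)
    ms_st = multiplicity_similarity(cp, cq, wv_st)
    cs = clan_similarity(clan_profile(p, catalog), clan_profile(q, catalog))
    ps = positional_similarity(
        position_profile(p), position_profile(q), cq, wv_st
    )
    composite = w.alpha * ms_st + w.beta * cs + w.gamma * ps
    return ScoreBreakdown(
        ms_uni=ms_uni,
        ms_st=ms_st,
        cs=cs,
        ps=ps,
        mls=mls(cp, cq, w),
        fact=composite,
        weights=wv_st,
        n_p=cp.n_features,
        n_q=cq.n_features,
        n_pq=len(shared_features(cp, cq)),
        degenerate=wv_st.degenerate,
    )
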