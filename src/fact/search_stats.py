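"""Proteome-wide ranked search and the beta-distribution p-value.

A query architecture is scored against every member of a pre-annotated
search proteome.  Because all similarity scores live in [0, 1] and their
histograms take many shapes, a beta distribution fitted to the full
score list by the method of moments serves as the per-query null: the
top hit's p-value is one minus the fitted CDF at its score.  A small
p-value means the best hit stands out from the bulk of the proteome, so
an annotation transfer onto the query is more credible.

Rankings are deterministic: score descending, ties share a competition
rank, protein id ascending within ties.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, IO, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .architecture_model import FeatureArchitecture, FeatureCatalog
from .annotation_io import Proteome
from .scoring import ScoreBreakdown, ScoreWeights, fact_score

__all__ = [
    "BetaFit",
    "RankedHit",
    "SearchResult",
    "SearchConfig",
    "fit_beta_moments",
    "p_value",
    "rank_proteome",
    "search",
    "write_report_tsv",
    "write_report_json",
]

logger = logging.getLogger(__name__)

#: Scoring functions a search ranks by, in report order.
DEFAULT_SCORERS = ("mls", "ms_uni", "ms_st", "fact")


@dataclass
class BetaFit:
    """Method-of-moments beta fit to a score sample.

    With sample mean m and unbiased sample variance v, the common factor
    is c = m(1−m)/v − 1 and the shapes are a = m·c, b = (1−m)·c.  The fit
    is degenerate when v = 0 or c ≤ 0 (shapes undefined).
    """

    shape1: float
    shape2: float
    sample_mean: float
    sample_variance: float
    degenerate: bool = False


@dataclass(frozen=True)
class RankedHit:
    rank: int
    protein_id: str
    score: float
    tie_group: int


@dataclass
class SearchConfig:
    """Knobs of a proteome search.

    ``exclude_self`` removes the query from its own ranking;
    ``exclude_top_from_fit`` drops the top score from the beta-fit
    sample; ``drop_degenerate_from_fit`` excludes scores of flagged
    degenerate pairs (featureless subjects) from the fit.
    """

    scorers: Tuple[str, ...] = DEFAULT_SCORERS
    top_k: int = 100
    exclude_self: bool = False
    exclude_top_from_fit: bool = False
    drop_degenerate_from_fit: bool = False
    weight_scheme: str = "frequency"


@dataclass
class SearchResult:
    """Scores, rankings, beta fits and top-hit p-values for one query."""

    query_id: str
    breakdowns: Dict[str, ScoreBreakdown]
    rankings: Dict[str, List[RankedHit]] = field(default_factory=dict)
    fits: Dict[str, BetaFit] = field(default_factory=dict)
    top_p_values: Dict[str, float] = field(default_factory=dict)
    top_k: int = 100

    def ranking(self, scorer: str) -> List[RankedHit]:
        return self.rankings[scorer]

    def top_hits(self, scorer: str) -> List[RankedHit]:
        """All hits sharing rank 1 under the given scoring function."""
        ranked = self.rankings[scorer]
        return [h for h in ranked if h.rank == 1]

    def tie_group_size(self, scorer: str) -> int:
        return self.rankings[scorer][0].tie_group if self.rankings[scorer] else 0


def fit_beta_moments(scores: Sequence[float]) -> BetaFit:
    """Fit beta shape parameters to scores in [0, 1] by matching moments."""
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to fit a beta distribution")
    arr = np.asarray(scores, dtype=float)
    m = float(arr.mean())
    v = float(arr.var(ddof=1))
    # constant samples leave rounding residue well below this threshold
    if v <= 1e-14:
        return BetaFit(math.nan, math.nan, m, v, degenerate=True)
    c = m * (1.0 - m) / v - 1.0
    if c <= 0.0:
        return BetaFit(math.nan, math.nan, m, v, degenerate=True)
    return BetaFit(m * c, (1.0 - m) * c, m, v)


def p_value(x: float, fit: BetaFit) -> float:
    """Upper-tail probability of the fitted beta at score ``x``.

    Returns NaN (with a warning) for a degenerate fit; ``x`` is clamped
    to [0, 1] first.
    """
    if fit.degenerate:
        logger.warning("p-value undefined: degenerate beta fit")
        return math.nan
    x = min(max(x, 0.0), 1.0)
    return float(stats.beta.sf(x, fit.shape1, fit.shape2))


def _rank(scored: List[Tuple[str, float]]) -> List[RankedHit]:
    """Competition-rank (1,1,3,...) by score desc, protein id asc in ties."""
    ordered = sorted(scored, key=lambda t: (-t[1], t[0]))
    # tie groups by exact score equality
    hits: List[RankedHit] = []
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j][1] == ordered[i][1]:
            j += 1
        for pid, score in ordered[i:j]:
            hits.append(RankedHit(i + 1, pid, score, j - i))
        i = j
    return hits


def _score_all(
    q: FeatureArchitecture,
    ref: Proteome,
    catalog: FeatureCatalog,
    w: ScoreWeights,
    config: SearchConfig,
) -> Dict[str, ScoreBreakdown]:
    if len(ref) == 0:
        raise ValueError("search proteome is empty")
    breakdowns: Dict[str, ScoreBreakdown] = {}
    for subject in ref:
        if config.exclude_self and subject.protein_id == q.protein_id:
            continue
        breakdowns[subject.protein_id] = fact_score(
            subject, q, ref, catalog, w, weight_scheme=config.weight_scheme
        )
    return breakdowns


def rank_proteome(
    q: FeatureArchitecture,
    ref: Proteome,
    scorer: str,
    w: Optional[ScoreWeights] = None,
    catalog: Optional[FeatureCatalog] = None,
    config: Optional[SearchConfig] = None,
) -> SearchResult:
    """Score every proteome member and rank by one scoring function.

    Self-comparison is included when the query is a member, unless the
    config excludes it.  No beta fit is performed here; see :func:`search`.
    """
    w = w or ScoreWeights()
    catalog = catalog or FeatureCatalog()
    config = config or SearchConfig()
    breakdowns = _score_all(q, ref, catalog, w, config)
    scored = [(pid, b.score(scorer)) for pid, b in breakdowns.items()]
    return SearchResult(
        query_id=q.protein_id,
        breakdowns=breakdowns,
        rankings={scorer: _rank(scored)},
        top_k=config.top_k,
    )


def search(
    q: FeatureArchitecture,
    ref: Proteome,
    catalog: Optional[FeatureCatalog] = None,
    w: Optional[ScoreWeights] = None,
    config: Optional[SearchConfig] = None,
) -> SearchResult:
    """Full search: rankings, beta fits and top-hit p-values per scorer."""
    w = w or ScoreWeights()
    catalog = catalog or FeatureCatalog()
    config = config or SearchConfig()
    breakdowns = _score_all(q, ref, catalog, w, config)
    result = SearchResult(
        query_id=q.protein_id, breakdowns=breakdowns, top_k=config.top_k
    )
    for scorer in config.scorers:
        scored = [(pid, b.score(scorer)) for pid, b in breakdowns.items()]
        ranked = _rank(scored)
        result.rankings[scorer] = ranked
        fit_sample = [
            b.score(scorer)
            for b in breakdowns.values()
            if not (config.drop_degenerate_from_fit and b.degenerate)
        ]
        if config.exclude_top_from_fit and ranked and ranked[0].score in fit_sample:
            fit_sample.remove(ranked[0].score)
        if len(fit_sample) >= 2:
            fit = fit_beta_moments(fit_sample)
        else:
            fit = BetaFit(math.nan, math.nan, math.nan, math.nan, degenerate=True)
        result.fits[scorer] = fit
        result.top_p_values[scorer] = (
            p_value(ranked[0].score, fit) if ranked else math.nan
        )
    return result


# ---------------------------------------------------------------------------
# Reports

_TSV_COLUMNS = (
    "rank",
    "protein_id",
    "ms_uni",
    "ms_st",
    "cs",
    "ps",
    "mls",
    "fact",
    "tie_group",
)


def write_report_tsv(
    result: SearchResult, sink: IO[str], scorer: str = "fact"
) -> None:
    """Top-k report ordered by the given scoring function; deterministic."""
    sink.write("# query: %s\n" % result.query_id)
    sink.write("\t".join(_TSV_COLUMNS) + "\n")
    for hit in result.rankings[scorer][: result.top_k]:
        b = result.breakdowns[hit.protein_id]
        sink.write(
            "\t".join(
                [
                    str(hit.rank),
                    hit.protein_id,
                    f"{b.ms_uni:.6f}",
                    f"{b.ms_st:.6f}",
                    f"{b.cs:.6f}",
                    f"{b.ps:.6f}",
                    f"{b.mls:.6f}",
                    f"{b.fact:.6f}",
                    str(hit.tie_group),
                ]
            )
            + "\n"
        )


def _fit_dict(fit: BetaFit) -> dict:
    def clean(x: float):
        return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x

    return {
        "shape1": clean(fit.shape1),
        "shape2": clean(fit.shape2),
        "sample_mean": clean(fit.sample_mean),
        "sample_variance": clean(fit.sample_variance),
        "degenerate": fit.degenerate,
    }


def write_report_json(result: SearchResult, sink: IO[str]) -> None:
    """JSON mirror of the report with beta fits and top-hit p-values."""
    doc = {
        "query": result.query_id,
        "scorers": {},
    }
    for scorer, ranked in result.rankings.items():
        pv = result.top_p_values.get(scorer)
        doc["scorers"][scorer] = {
            "beta_fit": _fit_dict(result.fits[scorer])
            if scorer in result.fits
            else None,
            "top_p_value": None
            if pv is None or (isinstance(pv, float) and math.isnan(pv))
            else pv,
            "rank1_tie_group": ranked[0].tie_group if ranked else 0,
            "top_hits": [
                {"rank": h.rank, "protein_id": h.protein_id, "score": h.score}
                for h in ranked[: result.top_k]
            ],
        }
    json.dump(doc, sink, indent=2, sort_keys=True)
    sink.write("\n")
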