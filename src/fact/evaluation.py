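"""Benchmarking feature-architecture search against EC-number labels.

Two proteins are treated as *functional equivalents* when they share an
EC (Enzyme Commission) number — a four-field dotted code whose first
field is the main reaction class.  The *fidelity* of a scoring function
is the fraction of queries for which a functional equivalent attains the
best score; the *strict* variant additionally requires the top rank to
be held by a single protein.  The module also relates the architecture
search's p-values to the E-values of a sequence-similarity search
(BLAST-style best-hit tables) via threshold curves, a binned comparison
matrix and a correlation coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _scipy_stats

from .annotation_io import HitTable
from .search_stats import RankedHit, SearchResult

__all__ = [
    "ScorerFidelity",
    "FidelityReport",
    "ComparisonMatrix",
    "fidelity",
    "pvalue_threshold_curve",
    "comparison_matrix",
    "correlation",
    "median_tie_group",
    "DEFAULT_E_BIN_EDGES",
    "DEFAULT_P_BIN_EDGES",
]

logger = logging.getLogger(__name__)

#: Decade-structured bin upper edges; the last bin is "greater than the
#: last edge".  An E-value of exactly 0 falls in the smallest bin.
DEFAULT_E_BIN_EDGES = (1e-20, 1e-15, 1e-10, 1e-5, 1e-1)
DEFAULT_P_BIN_EDGES = (1e-11, 1e-9, 1e-7, 1e-5, 1e-3, 1e-1)


def ec_match(code_a: str, code_b: str, level: int) -> bool:
    """Field-wise prefix comparison of two dotted EC codes (never numeric)."""
    if not 1 <= level <= 4:
        raise ValueError("EC level must be in 1..4")
    return code_a.split(".")[:level] == code_b.split(".")[:level]


def _top_group(result: SearchResult, scorer: str) -> List[RankedHit]:
    """Rank-1 tie group with the query's self-hit removed."""
    hits = [h for h in result.rankings[scorer] if h.protein_id != result.query_id]
    if not hits:
        return []
    best = hits[0].score
    return [h for h in hits if h.score == best]


def _require_labels(results: Sequence[SearchResult], ec: Dict[str, str]) -> None:
    missing = sorted({r.query_id for r in results} - set(ec))
    if missing:
        raise KeyError(f"queries missing from EC map: {', '.join(missing)}")


@dataclass
class ScorerFidelity:
    """Fidelity of one scoring function over a query set."""

    n_queries: int
    any_tie_count: int
    strict_count: int
    median_tie_group: float
    level: int

    @property
    def any_tie_fidelity(self) -> float:
        return self.any_tie_count / self.n_queries if self.n_queries else math.nan

    @property
    def strict_fidelity(self) -> float:
        return self.strict_count / self.n_queries if self.n_queries else math.nan


@dataclass
class FidelityReport:
    """Per-scoring-function fidelity at one EC level."""

    level: int
    per_scorer: Dict[str, ScorerFidelity] = field(default_factory=dict)

    def __getitem__(self, scorer: str) -> ScorerFidelity:
        return self.per_scorer[scorer]


def fidelity(
    results: Sequence[SearchResult],
    ec: Dict[str, str],
    level: int = 4,
    scorers: Optional[Sequence[str]] = None,
) -> FidelityReport:
    """Fidelity under both success criteria for each scoring function.

    The query's self-hit is removed from its ranking before counting.
    *Any-tie* success: some protein in the rank-1 tie group shares the
    query's EC prefix at ``level``.  *Strict* success: the top rank is a
    single protein and it matches.  Subjects appearing in a top group
    must carry an EC label.
    """
    results = list(results)
    _require_labels(results, ec)
    if scorers is None:
        scorers = sorted(results[0].rankings) if results else []
    report = FidelityReport(level=level)
    for scorer in scorers:
        any_tie = strict = 0
        tie_sizes: List[int] = []
        for res in results:
            group = _top_group(res, scorer)
            tie_sizes.append(len(group))
            if not group:
                continue
            labels = []
            for hit in group:
                if hit.protein_id not in ec:
                    raise KeyError(
                        f"subject missing from EC map: {hit.protein_id}"
                    )
                labels.append(ec[hit.protein_id])
            q_code = ec[res.query_id]
            if any(ec_match(q_code, lab, level) for lab in labels):
                any_tie += 1
                if len(group) == 1:
                    strict += 1
        report.per_scorer[scorer] = ScorerFidelity(
            n_queries=len(results),
            any_tie_count=any_tie,
            strict_count=strict,
            median_tie_group=float(np.median(tie_sizes)) if tie_sizes else math.nan,
            level=level,
        )
    return report


def median_tie_group(
    results: Sequence[SearchResult], scorer: str = "fact"
) -> float:
    """Median rank-1 tie-group size (self-hit excluded) over a query set."""
    sizes = [len(_top_group(r, scorer)) for r in results]
    return float(np.median(sizes)) if sizes else math.nan


@dataclass(frozen=True)
class ThresholdPoint:
    threshold: float
    coverage: int
    fidelity: Optional[float]  # None when no query passes the cutoff


def pvalue_threshold_curve(
    results: Sequence[SearchResult],
    ec: Dict[str, str],
    thresholds: Sequence[float],
    scorer: str = "fact",
    level: int = 4,
    strict: bool = False,
) -> List[ThresholdPoint]:
    """Coverage/fidelity trade-off along descending p-value cutoffs.

    Per cutoff t: coverage is the number of queries whose top-hit
    p-value is below t, and fidelity is computed on that subset only.
    Tightening the cutoff usually raises fidelity at the cost of
    coverage, but monotonicity is not assumed — the observed values are
    reported as they are.
    """
    results = list(results)
    _require_labels(results, ec)
    points: List[ThresholdPoint] = []
    for t in thresholds:
        subset = [
            r
            for r in results
            if not math.isnan(r.top_p_values.get(scorer, math.nan))
            and r.top_p_values[scorer] < t
        ]
        if not subset:
            points.append(ThresholdPoint(t, 0, None))
            continue
        rep = fidelity(subset, ec, level=level, scorers=[scorer])[scorer]
        frac = rep.strict_fidelity if strict else rep.any_tie_fidelity
        points.append(ThresholdPoint(t, len(subset), frac))
    return points


@dataclass
class ComparisonMatrix:
    """Query counts binned by best-hit E-value × top-hit p-value.

    ``totals[i][j]`` counts queries in E-bin i and p-bin j;
    ``arch_equiv`` counts those where the architecture search's top hit
    is a functional equivalent (strict criterion), ``seq_equiv`` those
    where the hit table's best hit is.  Bin i covers values ≤ edge i,
    with a final overflow bin above the last edge.
    """

    e_edges: Tuple[float, ...]
    p_edges: Tuple[float, ...]
    totals: np.ndarray
    arch_equiv: np.ndarray
    seq_equiv: np.ndarray


def _bin_index(value: float, edges: Sequence[float]) -> int:
    for i, edge in enumerate(edges):
        if value <= edge:
            return i
    return len(edges)


def comparison_matrix(
    results: Sequence[SearchResult],
    hits: HitTable,
    ec: Dict[str, str],
    e_edges: Sequence[float] = DEFAULT_E_BIN_EDGES,
    p_edges: Sequence[float] = DEFAULT_P_BIN_EDGES,
    scorer: str = "fact",
    level: int = 4,
) -> ComparisonMatrix:
    """Contrast architecture search and sequence search per E/p-value cell.

    Every query must appear in both the search results and the hit
    table; hit tables are assumed to exclude self-hits already.  An
    E-value of exactly 0 lands in the smallest bin.
    """
    results = list(results)
    if not results or len(hits) == 0:
        raise ValueError("need non-empty search results and hit table")
    _require_labels(results, ec)
    missing = sorted(r.query_id for r in results if r.query_id not in hits)
    if missing:
        raise ValueError(
            f"queries missing from hit table: {', '.join(missing)}"
        )
    shape = (len(e_edges) + 1, len(p_edges) + 1)
    totals = np.zeros(shape, dtype=int)
    arch_eq = np.zeros(shape, dtype=int)
    seq_eq = np.zeros(shape, dtype=int)
    for res in results:
        subject, evalue = hits[res.query_id]
        pv = res.top_p_values.get(scorer, math.nan)
        i = _bin_index(evalue, e_edges)
        j = _bin_index(pv, p_edges) if not math.isnan(pv) else len(p_edges)
        totals[i, j] += 1
        group = _top_group(res, scorer)
        if (
            len(group) == 1
            and group[0].protein_id in ec
            and ec_match(ec[res.query_id], ec[group[0].protein_id], level)
        ):
            arch_eq[i, j] += 1
        if subject in ec and ec_match(ec[res.query_id], ec[subject], level):
            seq_eq[i, j] += 1
    return ComparisonMatrix(
        tuple(e_edges), tuple(p_edges), totals, arch_eq, seq_eq
    )


def correlation(
    evals: Sequence[float], pvals: Sequence[float], log: bool = False
) -> float:
    """Pearson correlation between paired E-values and p-values.

    With ``log=True`` both vectors are log10-transformed first;
    non-positive entries are floored to a tenth of the smallest positive
    value in their vector.  Returns NaN (with a warning) when either
    vector has zero variance.
    """
    if len(evals) != len(pvals):
        raise ValueError("E-value and p-value vectors must have equal length")
    if len(evals) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.asarray(evals, dtype=float)
    y = np.asarray(pvals, dtype=float)
    if log:
        x, y = _safe_log10(x), _safe_log10(y)
    if np.var(x) == 0 or np.var(y) == 0:
        logger.warning("correlation undefined: zero variance in one vector")
        return math.nan
    r, _ = _scipy_stats.pearsonr(x, y)
    return float(r)


def _safe_log10(v: np.ndarray) -> np.ndarray:
    positive = v[v > 0]
    if positive.size == 0:
        raise ValueError("cannot log-transform a vector with no positive values")
    floor = positive.min() / 10.0
    return np.log10(np.maximum(v, floor))
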