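"""Evidence lines for the authenticity of species-specific genes.

Three lines of support: (1) annotation-quality (AED) distributions of
conserved vs. specific genes compared with a two-sample KS test;
(2) outgroup membership of OGs missing one ingroup species (gene loss
rather than annotation artifact); (3) functional matches of specific
genes against external annotated proteins. Plus GO-category enrichment
with one-sided Fisher's exact tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._core import InputError
from .ortholog_groups import OrthoGroup
from .pairwise_align import HitRecord
from .specificity import MatchCriteria, is_significant

Interval = tuple[int, int]  # 0-based half-open


def _union_length(intervals: Sequence[Interval]) -> int:
    merged = _merge(intervals)
    return sum(e - s for s, e in merged)


def _merge(intervals: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise InputError(f"malformed interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    ma, mb = _merge(a), _merge(b)
    total = 0
    i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if s < e:
            total += e - s
        if ma[i][1] < mb[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass(frozen=True)
class GeneEvidence:
    """A gene model's annotated intervals, its evidence intervals and AED."""

    gene_id: str
    annotated: tuple[Interval, ...]
    evidence: tuple[Interval, ...]
    aed: float


def compute_aed(annotated_intervals: Sequence[Interval],
                evidence_intervals: Sequence[Interval]) -> float:
    """Annotation edit distance: 1 - (sensitivity + specificity)/2.

    Sensitivity = overlap / evidence bases, specificity = overlap /
    annotation bases, both on the unions of the interval sets. 0 is
    perfect congruence with the evidence; 1 is no overlap at all (also
    returned when there is no evidence).
    """
    if not annotated_intervals:
        raise InputError("empty annotation")
    ann_len = _union_length(annotated_intervals)
    if not evidence_intervals:
        return 1.0
    ev_len = _union_length(evidence_intervals)
    overlap = _overlap_length(annotated_intervals, evidence_intervals)
    sn = overlap / ev_len
    sp = overlap / ann_len
    return 1.0 - (sn + sp) / 2.0


@dataclass(frozen=True)
class AedComparison:
    """Group AED summaries plus the two-sample KS test."""

    mean_conserved: float
    mean_specific: float
    frac_below_half_conserved: float
    frac_below_half_specific: float
    n_conserved: int
    n_specific: int
    ks_statistic: float
    ks_pvalue: float


def compare_aed_groups(aed_conserved: Sequence[float],
                       aed_specific: Sequence[float]) -> AedComparison:
    """Two-sample Kolmogorov-Smirnov comparison of AED distributions.

    D = sup |ECDF1 - ECDF2|; p from the asymptotic Kolmogorov
    distribution with effective n = n1*n2/(n1+n2).
    """
    x = np.asarray(aed_conserved, dtype=float)
    y = np.asarray(aed_specific, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both AED samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return AedComparison(
        mean_conserved=float(x.mean()),
        mean_specific=float(y.mean()),
        frac_below_half_conserved=float((x < 0.5).mean()),
        frac_below_half_specific=float((y < 0.5).mean()),
        n_conserved=int(x.size),
        n_specific=int(y.size),
        ks_statistic=float(res.statistic),
        ks_pvalue=float(res.pvalue),
    )


@dataclass(frozen=True)
class OutgroupSupport:
    """OGs missing one ingroup species and how many carry the outgroup."""

    n_ogs_without_b: int          # OGs (size >= 2) with A genes, no B genes
    n_without_b_with_outgroup: int
    n_ogs_without_a: int
    n_without_a_with_outgroup: int


def outgroup_support(ogs: Sequence[OrthoGroup]) -> OutgroupSupport:
    """Count OGs missing one ingroup species but retaining the outgroup.

    Only multi-member clusters count as OGs here; an OG "without B" has
    genes of A, none of B.
    """
    if not any(og.n_out > 0 for og in ogs):
        raise InputError(
            "no outgroup genes in any OG; rerun clustering with the "
            "outgroup proteome included")
    without_b = [og for og in ogs if len(og.members) > 1
                 and og.n_a > 0 and og.n_b == 0]
    without_a = [og for og in ogs if len(og.members) > 1
                 and og.n_b > 0 and og.n_a == 0]
    return OutgroupSupport(
        n_ogs_without_b=len(without_b),
        n_without_b_with_outgroup=sum(1 for og in without_b if og.n_out > 0),
        n_ogs_without_a=len(without_a),
        n_without_a_with_outgroup=sum(1 for og in without_a if og.n_out > 0),
    )


def functional_support(final_specific_genes: set[str],
                       external_hits: Sequence[HitRecord],
                       evalue_max: float = 1.0e-5,
                       criteria: MatchCriteria | None = None
                       ) -> tuple[int, list[str]]:
    """Species-specific genes with >= 1 qualifying external-protein match.

    Default is the E-value-only existence test; pass full
    :class:`MatchCriteria` to apply the four-part definition instead.
    """
    supported: set[str] = set()
    for h in external_hits:
        if h.query_id not in final_specific_genes:
            continue
        if criteria is not None:
            ok = is_significant(h, criteria)
        else:
            ok = h.evalue <= evalue_max
        if ok:
            supported.add(h.query_id)
    return len(supported), sorted(supported)


# ---------------------------------------------------------------------------
# GO enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's 2x2 over-representation test."""

    go_term: str
    in_set_with: int
    in_set_without: int
    out_set_with: int
    out_set_without: int
    odds_ratio: float
    pvalue: float
    significant: bool


def go_enrichment(gene_set: set[str], universe: set[str],
                  go_table: pd.DataFrame, alpha: float = 0.01,
                  bh_correct: bool = False) -> list[EnrichmentResult]:
    """Per-term one-sided Fisher's exact tests for over-representation of
    ``gene_set`` genes among term carriers.

    ``go_table`` has columns (gene_id, go_term). Terms carried only by
    genes outside the universe are skipped with a warning. No multiple-
    testing correction by default (Benjamini-Hochberg behind
    ``bh_correct``); ``significant`` means p < alpha (raw or adjusted).
    """
    if not gene_set <= universe:
        raise InputError("gene_set must be a subset of the universe")
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha outside (0, 1)")
    carriers: dict[str, set[str]] = {}
    outside_terms = set()
    for row in go_table.itertuples(index=False):
        if row.gene_id not in universe:
            outside_terms.add(row.go_term)
            continue
        carriers.setdefault(row.go_term, set()).add(row.gene_id)
    skipped = outside_terms - set(carriers)
    if skipped:
        warnings.warn(
            f"{len(skipped)} GO terms only annotate genes outside the "
            f"universe and were skipped", stacklevel=2)
    n_set = len(gene_set)
    n_universe = len(universe)
    results = []
    for term in sorted(carriers):
        with_term = carriers[term]
        a = len(with_term & gene_set)
        b = n_set - a
        c = len(with_term) - a
        d = (n_universe - n_set) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append([term, a, b, c, d, float(odds), float(p)])
    if bh_correct and results:
        order = np.argsort([r[6] for r in results])
        m = len(results)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, results[idx][6] * m / (rank_pos + 1))
            adj[idx] = running
        for i, r in enumerate(results):
            r[6] = float(adj[i])
    out = [EnrichmentResult(term, a, b, c, d, odds, p, p < alpha)
           for term, a, b, c, d, odds, p in results]
    out.sort(key=lambda r: (r.pvalue, r.go_term))
    return out


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    pd.DataFrame(
        [(r.go_term, r.in_set_with, r.in_set_without, r.out_set_with,
          r.out_set_without, r.odds_ratio, r.pvalue, int(r.significant))
         for r in results],
        columns=["go_term", "in_set_with", "in_set_without", "out_set_with",
                 "out_set_without", "odds_ratio", "pvalue", "significant"],
    ).to_csv(path, sep="\t", index=False)
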