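"""Data-driven identity threshold and genome-level rescue of presumptive
species-specific genes.

The significant-match identity floor is the 5th percentile of the percent
identities of one-to-one orthologs; a presumptive species-specific gene
with at least one significant protein-vs-genome match in the partner
genome is rescued (missing annotation rather than true absence).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._core import InputError
from .ortholog_groups import OrthoGroup
from .pairwise_align import HitRecord


@dataclass(frozen=True)
class MatchCriteria:
    """The four-part significant-match definition."""

    identity_min: float
    evalue_max: float = 1.0e-5
    alignment_length_min: int = 30
    query_coverage_min: float = 0.5
    percentile: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.identity_min <= 100.0:
            raise InputError("identity_min outside [0, 100]")
        if not 0.0 < self.percentile < 100.0:
            raise InputError("percentile outside (0, 100)")


@dataclass(frozen=True)
class SpecificityCall:
    """Final specificity status of one presumptive species-specific gene."""

    gene_id: str
    species: str
    presumptive: bool
    n_significant_genome_matches: int
    rescued: bool
    final_specific: bool


def one_to_one_identities(ogs: Sequence[OrthoGroup],
                          hits: Sequence[HitRecord],
                          species_of: Mapping[str, str],
                          species_a: str = "A", species_b: str = "B",
                          mode: str = "mean") -> list[float]:
    """Percent identities of 1:1 ortholog pairs.

    For every OG with exactly one gene from each compared species, report
    the identity of the pair: the mean of the two directions' reported
    identities (default), or one direction only (``a2b`` / ``b2a``).
    """
    if mode not in ("mean", "a2b", "b2a"):
        raise InputError(f"unknown identity mode {mode!r}")
    by_dir: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = by_dir.get(key)
        if prev is None or (h.bitscore, -h.evalue) > (prev.bitscore, -prev.evalue):
            by_dir[key] = h
    identities = []
    for og in ogs:
        if og.n_a != 1 or og.n_b != 1:
            continue
        a = next(g for g in og.members if species_of[g] == species_a)
        b = next(g for g in og.members if species_of[g] == species_b)
        fwd, rev = by_dir.get((a, b)), by_dir.get((b, a))
        if fwd is None and rev is None:
            raise InputError(
                f"1:1 OG {og.og_id} ({a}, {b}) has no stored hit; "
                "graph and hit table are inconsistent")
        if mode == "a2b":
            chosen = fwd if fwd is not None else rev
            identities.append(chosen.percent_identity)
        elif mode == "b2a":
            chosen = rev if rev is not None else fwd
            identities.append(chosen.percent_identity)
        else:
            vals = [h.percent_identity for h in (fwd, rev) if h is not None]
            identities.append(sum(vals) / len(vals))
    return identities


def derive_threshold(identities: Sequence[float], percentile: float = 5.0) -> float:
    """Empirical percentile of the 1:1 identity distribution, linear
    interpolation between order statistics. Refuses below 20 values."""
    if len(identities) < 20:
        raise InputError(
            f"only {len(identities)} one-to-one identities; too few to "
            "derive a percentile threshold - supply identity_min manually")
    if not 0.0 < percentile < 100.0:
        raise InputError("percentile outside (0, 100)")
    return float(np.percentile(np.asarray(identities, dtype=float),
                               percentile, method="linear"))


def is_significant(hit: HitRecord, criteria: MatchCriteria) -> bool:
    """All four criteria, inclusive comparisons."""
    if hit.query_coverage is None:
        raise InputError(f"hit {hit.query_id}->{hit.subject_id} lacks query coverage")
    return (hit.percent_identity >= criteria.identity_min
            and hit.evalue <= criteria.evalue_max
            and hit.alignment_length >= criteria.alignment_length_min
            and hit.query_coverage >= criteria.query_coverage_min)


def apply_criteria(genome_hits: Iterable[HitRecord],
                   criteria: MatchCriteria) -> dict[str, int]:
    """Count significant genome matches per query gene. Overlapping hits
    are not merged; only existence matters downstream."""
    counts: Counter[str] = Counter()
    for hit in genome_hits:
        if is_significant(hit, criteria):
            counts[hit.query_id] += 1
    return dict(counts)


def partition_specific(presumptive_pool: set[str],
                       match_counts: Mapping[str, int],
                       species: str) -> tuple[list[SpecificityCall], dict]:
    """Split the presumptive pool into rescued and final species-specific.

    rescued + final = presumptive, exactly. Genes in the match table but
    not in the pool are ignored with a warning.
    """
    stray = set(match_counts) - presumptive_pool
    if stray:
        warnings.warn(
            f"{len(stray)} genes in the match table are not in the "
            f"presumptive pool and were ignored", stacklevel=2)
    calls = []
    for gene in sorted(presumptive_pool):
        n = int(match_counts.get(gene, 0))
        rescued = n >= 1
        calls.append(SpecificityCall(gene, species, True, n, rescued,
                                     not rescued))
    summary = {
        "presumptive": len(calls),
        "rescued": sum(1 for c in calls if c.rescued),
        "final_specific": sum(1 for c in calls if c.final_specific),
    }
    assert summary["rescued"] + summary["final_specific"] == summary["presumptive"]
    return calls, summary


def write_calls(calls: Sequence[SpecificityCall], path: str | Path) -> None:
    pd.DataFrame(
        [(c.gene_id, c.species, int(c.presumptive),
          c.n_significant_genome_matches, int(c.rescued),
          int(c.final_specific)) for c in calls],
        columns=["gene_id", "species", "presumptive", "n_matches",
                 "rescued", "final_specific"],
    ).to_csv(path, sep="\t", index=False)
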