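"""Wilcoxon rank-sum comparisons of gene classes, networks and SNP types.

The Mann-Whitney U statistic is implemented here rather than delegated: its
calibration (exact small-sample p-values, tie handling, type-I error) is
part of what this pipeline is tested on.  p-values are two-sided.  For
small tie-free samples (n1 + n2 <= 12) the p-value is exact, by full
enumeration of the C(n1+n2, n1) group labelings; otherwise a normal
approximation with tie correction and continuity correction is used.
No multiple-testing correction is applied by default; significance tiers
mirror the conventional 0.05 / 0.001 asterisks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .tables import GeneAnnotation

__all__ = [
    "wilcoxon_rank_sum",
    "ComparisonResult",
    "compare_gene_classes",
    "compare_window_strata",
    "STATISTICS",
]

EXACT_MAX_TOTAL = 12

STATISTICS = ["pi", "pi_syn", "pi_nonsyn", "theta_w", "tajimas_d", "K", "K_syn", "K_nonsyn"]


def _clean(values) -> np.ndarray:
    arr = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=np.float64,
    )
    return arr


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U, p) with U = #{(i,j): x_i > y_j} + 0.5 #{x_i = y_j}.  Missing
    values (None/NaN) are dropped.  Exact p by enumeration for tie-free
    samples with n1 + n2 <= 12, else normal approximation with tie and
    continuity corrections.
    """
    x = _clean(x)
    y = _clean(y)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(n1 + n2, dtype=np.float64)
    ranks[order] = np.arange(1, n1 + n2 + 1)
    # average ranks within tie groups
    sorted_vals = combined[order]
    i = 0
    tie_sizes = []
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = (i + 1 + j + 1) / 2.0
            tie_sizes.append(j - i + 1)
        i = j + 1
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    no_ties = not tie_sizes
    if n1 + n2 <= EXACT_MAX_TOTAL and no_ties:
        p = _exact_p(n1, n2, u)
    else:
        p = _normal_p(n1, n2, u, tie_sizes)
    return float(u), float(p)


def _exact_p(n1: int, n2: int, u: float) -> float:
    """Exact two-sided p: share of labelings at least as extreme as |U - mu|."""
    n = n1 + n2
    ranks = range(1, n + 1)
    offset = n1 * (n1 + 1) / 2.0
    mu2 = n1 * n2  # 2 * mu, kept integral
    obs = abs(2 * u - mu2)
    hits = 0
    total = 0
    for combo in combinations(ranks, n1):
        u_perm = sum(combo) - offset
        if abs(2 * u_perm - mu2) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def _normal_p(n1: int, n2: int, u: float, tie_sizes) -> float:
    """Normal approximation with continuity correction; on tie-free samples
    an Edgeworth term for the U distribution's negative excess kurtosis
    (kappa4 = -n1 n2 (N+1)(n1^2 + n2^2 + n1 n2 + n1 + n2)/120) sharpens the
    small-sample agreement with the exact distribution."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = sum(t**3 - t for t in tie_sizes) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)  # continuity correction
    tail = 0.5 * math.erfc(z / math.sqrt(2.0))
    if not tie_sizes:
        k4 = -n1 * n2 * (n + 1) * (n1 * n1 + n2 * n2 + n1 * n2 + n1 + n2) / 120.0
        gamma2 = k4 / (var * var)
        phi = math.exp(-z * z / 2.0) / math.sqrt(2.0 * math.pi)
        corrected = tail + phi * (gamma2 / 24.0) * (z**3 - 3.0 * z)
        # Edgeworth expansions can turn negative in the extreme tail; fall
        # back to the plain normal tail there
        if corrected > 0.0:
            tail = corrected
    p = 2.0 * tail
    return min(1.0, max(p, 5e-324))


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    comparison: str
    statistic: str
    population_id: str | None  # None for the species-level comparison
    n1: int
    n2: int
    U: float
    p: float
    median_1: float
    median_2: float
    direction: str  # greater | less | equal (group 1 median vs group 2)
    tier: str

    @staticmethod
    def from_samples(comparison, statistic, x, y, population_id=None) -> "ComparisonResult":
        x = _clean(x)
        y = _clean(y)
        u, p = wilcoxon_rank_sum(x, y)
        m1, m2 = float(np.median(x)), float(np.median(y))
        direction = "greater" if m1 > m2 else ("less" if m1 < m2 else "equal")
        return ComparisonResult(
            comparison=comparison,
            statistic=statistic,
            population_id=population_id,
            n1=len(x),
            n2=len(y),
            U=u,
            p=p,
            median_1=m1,
            median_2=m2,
            direction=direction,
            tier=significance_tier(p),
        )


def _grouping(annotations: list[GeneAnnotation]) -> dict[str, list[str]]:
    """Gene-id groups for the four standing comparisons.

    Regulatory vs functional runs over candidate genes only (the single
    sensory gene is excluded); network strata are compared against the
    reference genes.
    """
    by = {
        "candidate": [],
        "reference": [],
        "regulatory": [],
        "functional": [],
        "network_AREB1": [],
        "network_JERF1": [],
    }
    for ann in annotations:
        by[ann.gene_class].append(ann.gene_id)
        if ann.subclass in ("regulatory", "functional"):
            by[ann.subclass].append(ann.gene_id)
        for net in ann.networks:
            by[f"network_{net}"].append(ann.gene_id)
    return by


_COMPARISON_PAIRS = [
    ("candidate_vs_reference", "candidate", "reference"),
    ("regulatory_vs_functional", "regulatory", "functional"),
    ("AREB1_network_vs_reference", "network_AREB1", "reference"),
    ("JERF1_network_vs_reference", "network_JERF1", "reference"),
]


def compare_gene_classes(
    stats_records: list,
    annotations: list[GeneAnnotation],
    mode: str = "pooled",
    statistics: list[str] | None = None,
) -> list[ComparisonResult]:
    """Species-level comparisons of per-gene statistics between gene groups.

    ``mode='pooled'`` (default) treats each gene x population value as one
    observation; ``mode='mean'`` first averages each gene over populations;
    ``mode='per-population'`` runs the comparisons separately within every
    population.  Statistics with an empty side are skipped silently only
    when the group itself is empty in the study design, never when values
    are merely missing.
    """
    if mode not in ("pooled", "mean", "per-population"):
        raise ValueError(f"unknown mode {mode!r}")
    statistics = statistics or STATISTICS
    known = {a.gene_id for a in annotations}
    for rec in stats_records:
        if rec.gene_id not in known:
            raise ValueError(f"gene {rec.gene_id!r} has no class label")
    groups = _grouping(annotations)

    def values(gene_ids, stat, population=None):
        vals = {}
        for rec in stats_records:
            if rec.gene_id not in gene_ids:
                continue
            if population is not None and rec.population_id != population:
                continue
            vals.setdefault(rec.gene_id, []).append(getattr(rec, stat))
        if mode == "mean":
            out = []
            for gid, vs in vals.items():
                clean = _clean(vs)
                if len(clean):
                    out.append(float(clean.mean()))
            return out
        return [v for vs in vals.values() for v in vs]

    results: list[ComparisonResult] = []
    populations = (
        sorted({r.population_id for r in stats_records}) if mode == "per-population" else [None]
    )
    for pop in populations:
        for label, g1, g2 in _COMPARISON_PAIRS:
            ids1, ids2 = set(groups[g1]), set(groups[g2])
            if not ids1 or not ids2:
                continue
            for stat in statistics:
                x = values(ids1, stat, pop)
                y = values(ids2, stat, pop)
                if not len(_clean(x)) or not len(_clean(y)):
                    continue  # statistic undefined throughout one side
                results.append(ComparisonResult.from_samples(label, stat, x, y, pop))
    return results


def compare_window_strata(window_long: pd.DataFrame) -> list[ComparisonResult]:
    """Comparisons of SNP-neighbourhood pi across strata.

    For each gene stratum, SNP types are compared pairwise (int vs S, int
    vs NS, S vs NS); for each SNP type, candidate genes and both networks
    are compared against the reference genes.
    """
    results: list[ComparisonResult] = []

    def pull(stratum, snp_type):
        sub = window_long[
            (window_long.stratum == stratum) & (window_long.snp_type == snp_type)
        ]
        return sub.window_pi.to_numpy(dtype=float)

    for stratum in ("reference", "candidate", "network_AREB1", "network_JERF1"):
        for t1, t2 in (("int", "S"), ("int", "NS"), ("S", "NS")):
            x, y = pull(stratum, t1), pull(stratum, t2)
            if len(x) and len(y):
                results.append(
                    ComparisonResult.from_samples(
                        f"{stratum}:{t1}_vs_{t2}", "window_pi", x, y
                    )
                )
    for snp_type in ("int", "S", "NS"):
        ref = pull("reference", snp_type)
        for stratum in ("candidate", "network_AREB1", "network_JERF1"):
            x = pull(stratum, snp_type)
            if len(x) and len(ref):
                results.append(
                    ComparisonResult.from_samples(
                        f"{stratum}_vs_reference:{snp_type}", "window_pi", x, ref
                    )
                )
    return results
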