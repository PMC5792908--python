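"""Per-gene, per-population diversity and divergence statistics.

All estimators treat read fractions as plug-in allele-frequency estimates.
The sample size entering every small-sample correction is the number of
pooled chromosomes (n_alleles, 50 in the study design), never the read
depth: reads resample the same n chromosomes, and at depths of several
thousand the read-sampling noise is second order.  PoPoolation-style
pool-seq corrections are deliberately out of scope.

Divergence K to the outgroup is a raw per-site proportion (no multiple-hit
correction).  F_ST uses Hudson's 1 - H_w/H_b over SNP sites shared between
the two populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codon import CodonClassifier, SiteClassCounts
from .tables import SNP, MaskState, PositionTable, seq_to_codes

__all__ = [
    "harmonic_number",
    "harmonic_number_2",
    "tajima_constants",
    "site_heterozygosity",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "divergence",
    "pairwise_fst",
    "FstResult",
    "FstMatrix",
    "fst_matrix",
    "PopGenStats",
    "gene_population_stats",
]


def harmonic_number(n_alleles: int) -> float:
    """a1(n) = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n_alleles)))


def harmonic_number_2(n_alleles: int) -> float:
    """a2(n) = sum_{i=1}^{n-1} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, n_alleles)))


def tajima_constants(n: int) -> dict[str, float]:
    """The constants of Tajima's D variance normalisation for sample size n."""
    a1 = harmonic_number(n)
    a2 = harmonic_number_2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def site_heterozygosity(base_counts, n_alleles: int) -> float:
    """Per-site heterozygosity h = n/(n-1) * (1 - sum_b p_b^2).

    p_b are plug-in read fractions over the four base counts; n is the pool
    chromosome count, giving the unbiased pairwise-difference estimate when
    fractions equal true pool frequencies.
    """
    counts = np.asarray(base_counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("site has zero coverage; masked sites must not reach here")
    p = counts / total
    return float(n_alleles / (n_alleles - 1.0) * (1.0 - (p * p).sum()))


def watterson_theta(S: int, n_alleles: int, L: float) -> float | None:
    """Per-site Watterson estimator S / (a1(n) * L); None when L == 0."""
    if L <= 0:
        return None
    return S / (harmonic_number(n_alleles) * L)


def tajimas_d(pi_sum: float, S: int, n_alleles: int) -> float | None:
    """Tajima's D from the locus-summed pairwise diversity and S.

    Undefined (None) when S == 0: the variance normalisation vanishes and
    the statistic carries no information.
    """
    if S == 0:
        return None
    c = tajima_constants(n_alleles)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi_sum - S / c["a1"]) / math.sqrt(var))


# ---------------------------------------------------------------------------
# Class-aware diversity and divergence
# ---------------------------------------------------------------------------


def _denominator_mask(class_filter: str, counts: SiteClassCounts) -> np.ndarray:
    if class_filter == "all":
        return counts.codon_callable | counts.noncoding_callable
    if class_filter in ("synonymous", "nonsynonymous"):
        return counts.codon_callable
    raise ValueError(f"unknown class filter {class_filter!r}")


def _class_length(class_filter: str, counts: SiteClassCounts) -> float:
    return {
        "all": counts.L_total,
        "synonymous": counts.L_syn,
        "nonsynonymous": counts.L_nonsyn,
    }[class_filter]


def _snp_in_class(snp: SNP, class_filter: str) -> bool:
    if class_filter == "all":
        return True
    return snp.site_class == class_filter


def nucleotide_diversity(
    table: PositionTable,
    snps: list[SNP],
    class_filter: str,
    class_counts: SiteClassCounts,
    n_alleles: int,
) -> float | None:
    """Per-site pi for one site class: sum of SNP heterozygosities over the
    class's callable length.  Monomorphic sites contribute zero to the
    numerator and their weight to the denominator.  None when the class has
    no callable sites."""
    L = _class_length(class_filter, class_counts)
    if L <= 0:
        return None
    mask = _denominator_mask(class_filter, class_counts)
    total = 0.0
    for snp in snps:
        if not _snp_in_class(snp, class_filter):
            continue
        if not mask[snp.position - 1]:
            continue  # numerator restricted to denominator-backed sites
        i = table.index_of(snp.position)
        total += site_heterozygosity(table.counts[i], n_alleles)
    return total / L


def divergence(
    table: PositionTable,
    outgroup_seq: str,
    class_filter: str,
    class_counts: SiteClassCounts,
    classifier: CodonClassifier | None = None,
) -> float | None:
    """Per-site divergence K to the outgroup for one site class.

    Per unmasked site the contribution is 1 minus the read fraction of the
    outgroup base (a raw proportion; no multiple-hit correction).  Sites
    where the outgroup base is N are excluded from numerator and
    denominator.  For the synonymous/nonsynonymous split, each diverged CDS
    site is assigned the class of substituting the most frequent
    non-outgroup base into the reference codon.
    """
    og = seq_to_codes(outgroup_seq)
    if len(og) != len(table):
        raise ValueError("outgroup sequence length does not match the table")
    mask = _denominator_mask("all", class_counts) & (og < 4)
    totals = table.counts.sum(axis=1).astype(np.float64)
    contrib = np.zeros(len(table), dtype=np.float64)
    idx = np.flatnonzero(mask & (totals > 0))
    contrib[idx] = 1.0 - table.counts[idx, og[idx]] / totals[idx]

    if class_filter == "all":
        L = float(mask.sum())
        return contrib.sum() / L if L > 0 else None

    if classifier is None:
        raise ValueError("classifier required for class-specific divergence")
    # adjust fractional denominators for outgroup-N sites
    fsyn = classifier.position_fsyn()
    cds_mask = class_counts.codon_callable & (og < 4)
    L_syn = float(fsyn[cds_mask].sum())
    L_nonsyn = float(cds_mask.sum()) - L_syn
    num_syn = 0.0
    num_nonsyn = 0.0
    for i in np.flatnonzero(cds_mask & (contrib > 0)):
        row = table.counts[i]
        order = sorted(range(4), key=lambda b: (-row[b], b))
        top = next(b for b in order if b != og[i])
        cls = classifier.classify_outgroup_change(int(table.positions[i]), top)
        if cls == "synonymous":
            num_syn += contrib[i]
        elif cls == "nonsynonymous":
            num_nonsyn += contrib[i]
    if class_filter == "synonymous":
        return num_syn / L_syn if L_syn > 0 else None
    return num_nonsyn / L_nonsyn if L_nonsyn > 0 else None


# ---------------------------------------------------------------------------
# Pairwise F_ST (Hudson 1 - Hw/Hb)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FstResult:
    value: float  # clamped to [0, 1]
    raw: float  # pre-clamp, kept for audit
    n_sites: int


def pairwise_fst(
    table_a: PositionTable,
    table_b: PositionTable,
    snp_union: list[int],
    n_alleles_a: int = 50,
    n_alleles_b: int = 50,
) -> FstResult | None:
    """Hudson-style F_ST = 1 - H_w/H_b over shared SNP sites.

    ``snp_union`` lists 1-based positions that are SNPs in either population;
    sites masked in either population are excluded.  None when no usable
    site remains or H_b is zero.
    """
    hw = 0.0
    hb = 0.0
    used = 0
    for pos in snp_union:
        ia = table_a.index_of(pos)
        ib = table_b.index_of(pos)
        if (
            table_a.mask_state[ia] != MaskState.PASS
            or table_b.mask_state[ib] != MaskState.PASS
        ):
            continue
        ca = table_a.counts[ia].astype(np.float64)
        cb = table_b.counts[ib].astype(np.float64)
        ta, tb = ca.sum(), cb.sum()
        if ta <= 0 or tb <= 0:
            continue
        pa, pb = ca / ta, cb / tb
        hw += 0.5 * (
            site_heterozygosity(ca, n_alleles_a) + site_heterozygosity(cb, n_alleles_b)
        )
        hb += 1.0 - float((pa * pb).sum())
        used += 1
    if used == 0 or hb == 0.0:
        return None
    raw = 1.0 - hw / hb
    return FstResult(value=min(1.0, max(0.0, raw)), raw=raw, n_sites=used)


@dataclass
class FstMatrix:
    gene_id: str
    population_ids: list
    matrix: np.ndarray  # clamped values, diagonal 0, NaN where undefined
    raw_matrix: np.ndarray

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("F_ST matrix not symmetric")
        if not np.all(np.diag(m) == 0):
            raise ValueError("F_ST diagonal must be 0")


def fst_matrix(
    gene_id: str,
    tables_by_pop: dict[str, PositionTable],
    snps_by_pop: dict[str, list[SNP]],
    n_alleles_by_pop: dict[str, int],
) -> FstMatrix:
    pops = list(tables_by_pop)
    k = len(pops)
    mat = np.zeros((k, k))
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = pops[i], pops[j]
            union = sorted(
                {s.position for s in snps_by_pop.get(a, [])}
                | {s.position for s in snps_by_pop.get(b, [])}
            )
            res = pairwise_fst(
                tables_by_pop[a],
                tables_by_pop[b],
                union,
                n_alleles_by_pop[a],
                n_alleles_by_pop[b],
            )
            if res is None:
                mat[i, j] = mat[j, i] = np.nan
                raw[i, j] = raw[j, i] = np.nan
            else:
                mat[i, j] = mat[j, i] = res.value
                raw[i, j] = raw[j, i] = res.raw
    out = FstMatrix(gene_id=gene_id, population_ids=pops, matrix=mat, raw_matrix=raw)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Per gene x population summary
# ---------------------------------------------------------------------------


@dataclass
class PopGenStats:
    gene_id: str
    population_id: str
    n_alleles: int
    S: int
    pi: float | None
    pi_syn: float | None
    pi_nonsyn: float | None
    theta_w: float | None
    tajimas_d: float | None
    K: float | None
    K_syn: float | None
    K_nonsyn: float | None
    L_total: float
    L_syn: float
    L_nonsyn: float
    L_noncoding: float


def gene_population_stats(
    table: PositionTable,
    snps: list[SNP],
    classifier: CodonClassifier,
    class_counts: SiteClassCounts,
    outgroup_seq: str | None,
    n_alleles: int,
) -> PopGenStats:
    """Assemble the full per-gene x population statistic record.

    S, the locus pi sum feeding Tajima's D, and all per-site rates are
    restricted to denominator-backed callable sites so numerators and
    denominators stay consistent.
    """
    mask = _denominator_mask("all", class_counts)
    usable = [s for s in snps if mask[s.position - 1]]
    S = len(usable)
    pi_sum = sum(
        site_heterozygosity(table.counts[table.index_of(s.position)], n_alleles)
        for s in usable
    )
    L_total = class_counts.L_total
    K = K_syn = K_nonsyn = None
    if outgroup_seq is not None:
        K = divergence(table, outgroup_seq, "all", class_counts)
        K_syn = divergence(table, outgroup_seq, "synonymous", class_counts, classifier)
        K_nonsyn = divergence(
            table, outgroup_seq, "nonsynonymous", class_counts, classifier
        )
    return PopGenStats(
        gene_id=table.gene_id,
        population_id=table.population_id,
        n_alleles=n_alleles,
        S=S,
        pi=(pi_sum / L_total) if L_total > 0 else None,
        pi_syn=nucleotide_diversity(table, usable, "synonymous", class_counts, n_alleles),
        pi_nonsyn=nucleotide_diversity(
            table, usable, "nonsynonymous", class_counts, n_alleles
        ),
        theta_w=watterson_theta(S, n_alleles, L_total),
        tajimas_d=tajimas_d(pi_sum, S, n_alleles),
        K=K,
        K_syn=K_syn,
        K_nonsyn=K_nonsyn,
        L_total=class_counts.L_total,
        L_syn=class_counts.L_syn,
        L_nonsyn=class_counts.L_nonsyn,
        L_noncoding=class_counts.L_noncoding,
    )
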