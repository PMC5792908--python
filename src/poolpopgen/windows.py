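"""Nucleotide diversity in 40-bp neighbourhoods around individual SNPs.

The window spans ``half_width`` (default 20) usable positions on each side
of the focal SNP; the focal site itself is excluded, so the default window
evaluates exactly 40 positions.  A window is excluded when more than
``max_masked`` of its positions are masked, or when the focal SNP is a
species-wide fixed difference to the outgroup (every population carries a
base different from the outgroup's), as such sites predate the
within-species history.  Windows truncated by the locus edge are kept with
the denominator reduced and flagged, which allows reproducing a
drop-instead policy downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stats import site_heterozygosity
from .tables import SNP, MaskState, PositionTable, seq_to_codes

__all__ = [
    "WindowRecord",
    "window_pi",
    "compute_windows",
    "species_fixed_differences",
    "flag_fixed_differences",
    "stratify_windows",
]


@dataclass
class WindowRecord:
    gene_id: str
    population_id: str
    position: int  # focal SNP
    snp_class: str
    window_start: int
    window_end: int
    n_masked_in_window: int
    window_pi: float | None
    excluded: bool
    exclusion_reason: str  # too_many_masked | fixed_difference | none
    truncated: bool


def _site_h_array(table: PositionTable, snps: list[SNP], n_alleles: int) -> np.ndarray:
    """Heterozygosity per position: nonzero only at called SNP sites."""
    h = np.zeros(len(table), dtype=np.float64)
    for s in snps:
        i = table.index_of(s.position)
        h[i] = site_heterozygosity(table.counts[i], n_alleles)
    return h


def window_pi(
    snp: SNP,
    table: PositionTable,
    snps: list[SNP],
    n_alleles: int = 50,
    half_width: int = 20,
    max_masked: int = 3,
) -> WindowRecord:
    """Window record for one focal SNP (see module docstring for the rules)."""
    h = _site_h_array(table, snps, n_alleles)
    masked = np.asarray(table.mask_state) != MaskState.PASS
    return _one_window(table, snp, h, masked, half_width, max_masked)


def _one_window(
    table: PositionTable,
    snp: SNP,
    h: np.ndarray,
    masked: np.ndarray,
    half_width: int,
    max_masked: int,
) -> WindowRecord:
    focal = table.index_of(snp.position)
    lo = max(0, focal - half_width)
    hi = min(len(table) - 1, focal + half_width)
    idx = np.r_[lo:focal, focal + 1 : hi + 1]
    truncated = len(idx) < 2 * half_width
    n_masked = int(masked[idx].sum())

    reason = "none"
    if n_masked > max_masked:
        reason = "too_many_masked"
    elif snp.fixed_vs_outgroup:
        reason = "fixed_difference"
    pi = None
    if reason == "none":
        usable = len(idx) - n_masked
        pi = float(h[idx][~masked[idx]].sum() / usable) if usable > 0 else None
        if pi is None:
            reason = "too_many_masked"
    return WindowRecord(
        gene_id=table.gene_id,
        population_id=table.population_id,
        position=snp.position,
        snp_class=snp.site_class,
        window_start=int(table.positions[lo]),
        window_end=int(table.positions[hi]),
        n_masked_in_window=n_masked,
        window_pi=pi,
        excluded=reason != "none",
        exclusion_reason=reason,
        truncated=truncated,
    )


def compute_windows(
    table: PositionTable,
    snps: list[SNP],
    n_alleles: int = 50,
    half_width: int = 20,
    max_masked: int = 3,
) -> list[WindowRecord]:
    """Window records for every called SNP of one population x gene table."""
    h = _site_h_array(table, snps, n_alleles)
    masked = np.asarray(table.mask_state) != MaskState.PASS
    return [_one_window(table, s, h, masked, half_width, max_masked) for s in snps]


def species_fixed_differences(
    tables_by_pop: dict[str, PositionTable],
    outgroup_seq: str,
    maf_min: float = 0.01,
) -> np.ndarray:
    """Boolean array (per locus position): species-wide fixed difference.

    A site qualifies when, in every population where it passes masking, the
    outgroup base's read fraction is below ``maf_min`` (i.e. the outgroup
    allele is absent species-wide), with at least one assessable population.
    Outgroup-N sites never qualify.
    """
    og = seq_to_codes(outgroup_seq)
    L = len(og)
    assessable = np.zeros(L, dtype=bool)
    all_absent = np.ones(L, dtype=bool)
    for table in tables_by_pop.values():
        if len(table) != L:
            raise ValueError("table length does not match the outgroup sequence")
        totals = table.counts.sum(axis=1).astype(np.float64)
        ok = (np.asarray(table.mask_state) == MaskState.PASS) & (totals > 0)
        frac = np.zeros(L)
        idx = np.flatnonzero(ok & (og < 4))
        frac[idx] = table.counts[idx, og[idx]] / totals[idx]
        assessable |= ok
        all_absent &= ~ok | (frac < maf_min)
    return assessable & all_absent & (og < 4)


def flag_fixed_differences(snps: list[SNP], fixed: np.ndarray) -> list[SNP]:
    """Return SNPs with ``fixed_vs_outgroup`` set from the species-wide scan."""
    out = []
    for s in snps:
        flag = bool(fixed[s.position - 1])
        out.append(s if s.fixed_vs_outgroup == flag else replace(s, fixed_vs_outgroup=flag))
    return out


_SNP_TYPE = {
    "intronic": "int",
    "intergenic": "int",
    "synonymous": "S",
    "nonsynonymous": "NS",
}


def stratify_windows(
    records: list[WindowRecord],
    gene_classes: dict[str, str],
    gene_networks: dict[str, frozenset],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group included windows into SNP-type x gene-stratum strata.

    SNP types are int (intronic/intergenic pooled), S (synonymous) and NS
    (nonsynonymous); gene strata are reference, candidate, and the two
    regulatory networks (network genes appear both as candidates and in
    their network strata).  Returns (long per-window frame, stratum summary
    with counts and medians); empty strata appear with count 0.
    """
    rows = []
    for r in records:
        if r.excluded or r.snp_class not in _SNP_TYPE:
            continue
        gclass = gene_classes.get(r.gene_id)
        if gclass is None:
            raise ValueError(f"gene {r.gene_id!r} has no class label")
        strata = [gclass]
        for net in sorted(gene_networks.get(r.gene_id, frozenset())):
            strata.append(f"network_{net}")
        for stratum in strata:
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "population_id": r.population_id,
                    "position": r.position,
                    "snp_type": _SNP_TYPE[r.snp_class],
                    "stratum": stratum,
                    "window_pi": r.window_pi,
                }
            )
    long = pd.DataFrame(
        rows,
        columns=["gene_id", "population_id", "position", "snp_type", "stratum", "window_pi"],
    )
    all_strata = ["reference", "candidate", "network_AREB1", "network_JERF1"]
    summary_rows = []
    for stratum in all_strata:
        for snp_type in ("int", "S", "NS"):
            sub = long[(long.stratum == stratum) & (long.snp_type == snp_type)]
            summary_rows.append(
                {
                    "stratum": stratum,
                    "snp_type": snp_type,
                    "n": len(sub),
                    "median_window_pi": float(sub.window_pi.median()) if len(sub) else float("nan"),
                }
            )
    return long, pd.DataFrame(summary_rows)
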