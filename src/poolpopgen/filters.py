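"""Masking and SNP calling for pooled read-count tables.

Sites with depth below the threshold or an upstream quality flag are masked
(kept in the table so windows can count masked neighbours).  A passing site
is called a SNP when its second most frequent base reaches the minimum read
fraction; rarer bases are treated as sequencing errors.  Thresholds are
inclusive on the keep side: depth exactly at the minimum passes, and a minor
read fraction exactly at the threshold is called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import BASES, MaskState, PositionTable, SNP

__all__ = ["FilterConfig", "mask_positions", "call_snps"]


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 2000
    maf_min: float = 0.01

    def __post_init__(self):
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def mask_positions(table: PositionTable, cfg: FilterConfig) -> PositionTable:
    """Return a copy of `table` with mask_state set; no records are removed."""
    out = table.copy()
    out.mask_state[:] = MaskState.PASS
    out.mask_state[out.qual_masked] = MaskState.LOW_QUALITY
    out.mask_state[out.depth < cfg.min_depth] = MaskState.LOW_DEPTH
    return out


def _ranked_bases(counts_row: np.ndarray) -> list[int]:
    """Base indices ordered by count descending, ties broken alphabetically."""
    return sorted(range(4), key=lambda b: (-counts_row[b], b))


def call_snps(table: PositionTable, cfg: FilterConfig) -> list[SNP]:
    """Call biallelic SNPs on passing sites of a masked table.

    A site is a SNP iff the second most frequent base has read fraction
    >= ``maf_min`` over the four base counts.  Multi-allelic sites (third
    base also at/above threshold) are kept, represented by their top two
    bases and flagged.
    """
    passing = table.mask_state == MaskState.PASS
    totals = table.counts.sum(axis=1)
    candidate = passing & (totals > 0)
    if not candidate.any():
        return []
    counts = table.counts[candidate].astype(np.float64)
    tot = totals[candidate].astype(np.float64)
    # second-largest count per site; cheap vectorised pre-screen
    part = np.partition(counts, 2, axis=1)
    second = part[:, 2]
    is_snp = second / tot >= cfg.maf_min
    idx = np.flatnonzero(candidate)[is_snp]

    snps: list[SNP] = []
    for i in idx:
        row = table.counts[i]
        total = int(row.sum())
        order = _ranked_bases(row)
        major, minor = order[0], order[1]
        frac = row[minor] / total
        multi = row[order[2]] / total >= cfg.maf_min
        snps.append(
            SNP(
                gene_id=table.gene_id,
                position=int(table.positions[i]),
                major_base=BASES[major],
                minor_base=BASES[minor],
                minor_read_fraction=float(frac),
                multiallelic=bool(multi),
            )
        )
    return snps
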