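"""Codon-aware site classification and synonymous/nonsynonymous site counting.

SNPs falling in coding sequence are classified by translating the reference
codon and the codon with the variant base substituted (strand-aware).  Site
opportunities for the per-site denominators of pi_s, pi_a, K_s and K_a are
counted Nei-Gojobori style: each position of a callable codon contributes
the fraction of its three possible single-base changes that are synonymous
to the synonymous site total, and the complement to the nonsynonymous total.

Only the standard nuclear genetic code is supported.  A stop codon is
treated as a 21st residue state, so stop gain/loss counts as nonsynonymous
and stop-to-stop changes as synonymous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tables import BASES, GeneAnnotation, MaskState, SNP

__all__ = [
    "GENETIC_CODE",
    "SiteClassCounts",
    "CodonClassifier",
    "classify_snp",
    "count_syn_nonsyn_sites",
    "synonymous_fraction_table",
]

# Standard genetic code (NCBI translation table 1), '*' = stop.
_B1 = "TTTTTTTTTTTTTTTTCCCCCCCCCCCCCCCCAAAAAAAAAAAAAAAAGGGGGGGGGGGGGGGG"
_B2 = "TTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGG"
_B3 = "TCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: aa for b1, b2, b3, aa in zip(_B1, _B2, _B3, _AA)
}


def _codon_index(c0: int, c1: int, c2: int) -> int:
    return 16 * c0 + 4 * c1 + c2


# amino acid (as a small int) per codon index 0..63, ACGT base order
_AA_CODE = np.zeros(64, dtype=np.int8)
for _i0 in range(4):
    for _i1 in range(4):
        for _i2 in range(4):
            codon = BASES[_i0] + BASES[_i1] + BASES[_i2]
            _AA_CODE[_codon_index(_i0, _i1, _i2)] = ord(GENETIC_CODE[codon])


def synonymous_fraction_table() -> np.ndarray:
    """(64, 3) array: fraction of the 3 single-base changes at each codon
    position that are synonymous, per codon index (16*c0 + 4*c1 + c2)."""
    fsyn = np.zeros((64, 3), dtype=np.float64)
    for idx in range(64):
        codes = [(idx >> 4) & 3, (idx >> 2) & 3, idx & 3]
        aa = _AA_CODE[idx]
        for k in range(3):
            syn = 0
            for b in range(4):
                if b == codes[k]:
                    continue
                mut = codes.copy()
                mut[k] = b
                if _AA_CODE[_codon_index(*mut)] == aa:
                    syn += 1
            fsyn[idx, k] = syn / 3.0
    return fsyn


_FSYN = synonymous_fraction_table()
_FSYN_CODON_TOTAL = _FSYN.sum(axis=1)

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N

_KIND_CODE = {"CDS": 0, "intron": 1, "flank": 2}


@dataclass
class SiteClassCounts:
    """Callable-site totals used as per-site denominators.

    ``L_syn``/``L_nonsyn`` are fractional Nei-Gojobori opportunities over
    CDS codons whose three positions all pass masking; codons touching any
    masked position are excluded entirely.  The boolean masks record which
    locus positions back each denominator so numerators can be restricted
    to the same sites.
    """

    L_total: float
    L_syn: float
    L_nonsyn: float
    L_noncoding: float
    codon_callable: np.ndarray  # per locus position: inside a fully callable codon
    noncoding_callable: np.ndarray  # per locus position: callable intron/flank site


class CodonClassifier:
    """Precomputed coding-coordinate map for one gene against its reference."""

    def __init__(self, ann: GeneAnnotation, ref_codes: np.ndarray):
        if len(ref_codes) != ann.total_length:
            raise ValueError(
                f"{ann.gene_id}: reference length {len(ref_codes)} != "
                f"annotated {ann.total_length}"
            )
        self.ann = ann
        self.ref_codes = np.asarray(ref_codes, dtype=np.uint8)
        self.kind_by_pos = np.empty(ann.total_length, dtype=np.uint8)
        for seg in ann.segments:
            self.kind_by_pos[seg.start - 1 : seg.end] = _KIND_CODE[seg.kind]
        # CDS positions in coding (translation) order
        cds_pos = ann.cds_positions()
        if ann.strand == "-":
            cds_pos = cds_pos[::-1]
        self.coding_positions = cds_pos  # 1-based, coding order
        codes = self.ref_codes[cds_pos - 1]
        if ann.strand == "-":
            codes = _COMPLEMENT[codes]
        self.coding_codes = codes
        # coding index per locus position (-1 = noncoding)
        self.coding_index = np.full(ann.total_length, -1, dtype=np.int64)
        self.coding_index[cds_pos - 1] = np.arange(len(cds_pos))

    def classify(self, snp: SNP, table_ref_base: str | None = None) -> SNP:
        """Return a copy of `snp` with ``site_class`` assigned."""
        pos = snp.position
        if not (1 <= pos <= self.ann.total_length):
            raise ValueError(f"{self.ann.gene_id}: SNP position {pos} outside locus")
        ref_code = int(self.ref_codes[pos - 1])
        ref_base = "ACGTN"[ref_code]
        if table_ref_base is not None and table_ref_base != ref_base:
            raise ValueError(
                f"{self.ann.gene_id}: table reference base {table_ref_base!r} at "
                f"position {pos} disagrees with reference sequence {ref_base!r}"
            )
        kind = self.kind_by_pos[pos - 1]
        if kind == _KIND_CODE["intron"]:
            return snp.with_class("intronic")
        if kind == _KIND_CODE["flank"]:
            return snp.with_class("intergenic")

        ci = int(self.coding_index[pos - 1])
        j, k = divmod(ci, 3)
        codon = self.coding_codes[3 * j : 3 * j + 3].copy()
        if (codon == 4).any() or ref_code == 4:
            warnings.warn(
                f"{self.ann.gene_id}: codon at position {pos} contains N; "
                "SNP left unassigned",
                stacklevel=2,
            )
            return snp.with_class("unassigned")
        # substitute the allele that differs from the reference
        alt = snp.minor_base if snp.minor_base != ref_base else snp.major_base
        alt_code = BASES.index(alt)
        if self.ann.strand == "-":
            alt_code = int(_COMPLEMENT[alt_code])
        mutated = codon.copy()
        mutated[k] = alt_code
        aa_ref = _AA_CODE[_codon_index(*codon)]
        aa_alt = _AA_CODE[_codon_index(*mutated)]
        return snp.with_class("synonymous" if aa_ref == aa_alt else "nonsynonymous")

    def site_counts(self, mask_state: np.ndarray) -> SiteClassCounts:
        """Nei-Gojobori site opportunities over the callable locus."""
        if len(mask_state) != self.ann.total_length:
            raise ValueError("mask array length does not match the locus")
        callable_ = np.asarray(mask_state) == MaskState.PASS
        noncoding_callable = callable_ & (self.kind_by_pos != _KIND_CODE["CDS"])
        L_noncoding = float(noncoding_callable.sum())

        codon_callable = np.zeros(self.ann.total_length, dtype=bool)
        L_syn = 0.0
        n_codons = len(self.coding_codes) // 3
        if n_codons:
            pos3 = self.coding_positions.reshape(n_codons, 3)
            codes3 = self.coding_codes.reshape(n_codons, 3)
            ok = callable_[pos3 - 1].all(axis=1) & (codes3 < 4).all(axis=1)
            idx = (
                16 * codes3[ok, 0].astype(np.int64)
                + 4 * codes3[ok, 1].astype(np.int64)
                + codes3[ok, 2].astype(np.int64)
            )
            L_syn = float(_FSYN_CODON_TOTAL[idx].sum())
            codon_callable[(pos3[ok] - 1).ravel()] = True
        n_cds_callable = float(codon_callable.sum())
        return SiteClassCounts(
            L_total=n_cds_callable + L_noncoding,
            L_syn=L_syn,
            L_nonsyn=n_cds_callable - L_syn,
            L_noncoding=L_noncoding,
            codon_callable=codon_callable,
            noncoding_callable=noncoding_callable,
        )

    def position_fsyn(self) -> np.ndarray:
        """Per locus position: fraction of single-base changes that are
        synonymous (0 at noncoding positions and codons containing N)."""
        out = np.zeros(self.ann.total_length, dtype=np.float64)
        n_codons = len(self.coding_codes) // 3
        if not n_codons:
            return out
        pos3 = self.coding_positions.reshape(n_codons, 3)
        codes3 = self.coding_codes.reshape(n_codons, 3)
        ok = (codes3 < 4).all(axis=1)
        idx = (
            16 * codes3[ok, 0].astype(np.int64)
            + 4 * codes3[ok, 1].astype(np.int64)
            + codes3[ok, 2].astype(np.int64)
        )
        out[(pos3[ok] - 1).ravel()] = _FSYN[idx].ravel()
        return out

    def classify_outgroup_change(self, position: int, pop_base_code: int) -> str:
        """Class of a population-vs-outgroup difference at a CDS position.

        ``pop_base_code`` is the (plus-strand) base carried by the population
        that differs from the outgroup; classification substitutes it into
        the reference codon.  Noncoding positions return their region class.
        """
        kind = self.kind_by_pos[position - 1]
        if kind == _KIND_CODE["intron"]:
            return "intronic"
        if kind == _KIND_CODE["flank"]:
            return "intergenic"
        ci = int(self.coding_index[position - 1])
        j, k = divmod(ci, 3)
        codon = self.coding_codes[3 * j : 3 * j + 3]
        if (codon == 4).any() or pop_base_code >= 4:
            return "unassigned"
        code = pop_base_code
        if self.ann.strand == "-":
            code = int(_COMPLEMENT[code])
        mutated = codon.copy()
        mutated[k] = code
        same = _AA_CODE[_codon_index(*codon)] == _AA_CODE[_codon_index(*mutated)]
        return "synonymous" if same else "nonsynonymous"


def classify_snp(snp: SNP, ann: GeneAnnotation, ref_seq: str, table_ref_base: str | None = None) -> SNP:
    from .tables import seq_to_codes

    return CodonClassifier(ann, seq_to_codes(ref_seq)).classify(snp, table_ref_base)


def count_syn_nonsyn_sites(ann: GeneAnnotation, ref_seq: str, mask_state: np.ndarray) -> SiteClassCounts:
    from .tables import seq_to_codes

    return CodonClassifier(ann, seq_to_codes(ref_seq)).site_counts(mask_state)
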