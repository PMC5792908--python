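import numpy as np
import pytest

from poolpopgen import GeneAnnotation, PositionTable, Segment
from poolpopgen.tables import seq_to_codes


@pytest.fixture
def table_factory():
    """Build small position tables: all reads on the reference base unless
    a per-position count override is given."""

    def make(
        ref: str,
        depth: int = 4000,
        gene_id: str = "g1",
        population_id: str = "p1",
        overrides: dict | None = None,  # position -> {base: count}
        depths: dict | None = None,  # position -> depth
        qual_masked: set | None = None,
    ):
        codes = seq_to_codes(ref)
        L = len(codes)
        depth_arr = np.full(L, depth, dtype=np.int64)
        for pos, d in (depths or {}).items():
            depth_arr[pos - 1] = d
        counts = np.zeros((L, 4), dtype=np.int64)
        counts[np.arange(L), codes] = depth_arr
        for pos, alloc in (overrides or {}).items():
            i = pos - 1
            counts[i] = 0
            for base, c in alloc.items():
                counts[i, "ACGT".index(base)] = c
        qm = np.zeros(L, dtype=bool)
        for pos in qual_masked or ():
            qm[pos - 1] = True
        return PositionTable(
            gene_id=gene_id,
            population_id=population_id,
            positions=np.arange(1, L + 1, dtype=np.int64),
            ref_codes=codes,
            depth=depth_arr,
            counts=counts,
            qual_masked=qm,
        )

    return make


@pytest.fixture
def simple_annotation():
    """60-bp gene: 12 bp flank, 30 bp CDS (10 codons), 9 bp intron, 9 bp flank."""
    return GeneAnnotation(
        gene_id="g1",
        total_length=60,
        strand="+",
        segments=(
            Segment(1, 12, "flank"),
            Segment(13, 42, "CDS", frame=0),
            Segment(43, 51, "intron"),
            Segment(52, 60, "flank"),
        ),
        gene_class="candidate",
        subclass="functional",
    )
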