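"""Synthetic study generator: neutral haplotypes, outgroup, pooled read counts.

The simulator emulates the data this pipeline consumes: per-population pools
of n alleles re-sequenced to high depth at ~1-5 kb loci with mixed
CDS/intron/flank structure, an outgroup diverged by a fixed number of
substitutions, and a study of 23 populations in four groups typing 16
candidate plus 14 reference genes.

Haplotypes follow a neutral infinite-sites construction: the number of
segregating sites S is Poisson with mean theta_per_site * L * a1(n),
a1(n) = sum_{i<n} 1/i, and each site's derived-allele count is drawn from
the neutral folded-free spectrum P(i) proportional to 1/i.  This yields the
correct marginal site-frequency spectrum for estimator calibration; linkage
between sites is NOT coalescent-faithful (sites are exchangeable), which is
documented as a limitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon import CodonClassifier
from .stats import harmonic_number
from .tables import (
    GeneAnnotation,
    PositionTable,
    Segment,
    codes_to_seq,
    read_annotation,
    read_fasta,
    read_position_table,
    seq_to_codes,
    write_annotation,
    write_fasta,
    write_position_table,
)

__all__ = [
    "SimulationConfig",
    "HaplotypeSet",
    "Population",
    "GeneSpec",
    "StudyConfig",
    "LocusTruth",
    "StudyBundle",
    "generate_haplotypes",
    "add_outgroup",
    "pool_sequencing",
    "build_study",
    "default_study_config",
    "write_bundle",
    "read_bundle",
    "harmonic_number",
]


@dataclass
class SimulationConfig:
    """Parameters for one simulated locus/pool."""

    theta_per_site: float = 0.01
    n_alleles: int = 50
    L: int = 2000
    mean_depth: float = 4000.0
    error_rate: float = 0.001
    outgroup_subs: int = 60
    coding_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.theta_per_site <= 1.0):
            raise ValueError("theta_per_site must be in [0, 1]")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        if self.n_alleles < 2:
            raise ValueError("n_alleles must be >= 2")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")


@dataclass
class HaplotypeSet:
    """n sampled haplotypes at one locus under infinite sites.

    ``allele_matrix[a, s]`` is 1 where allele ``a`` carries the derived base
    at the s-th segregating position.
    """

    n: int
    L: int
    segregating_positions: np.ndarray  # 1-based, strictly increasing
    allele_matrix: np.ndarray  # (n, S) uint8
    reference_codes: np.ndarray  # (L,) uint8 ancestral/reference sequence
    derived_codes: np.ndarray  # (S,) uint8 derived base per segregating site

    @property
    def S(self) -> int:
        return len(self.segregating_positions)

    @property
    def reference_seq(self) -> str:
        return codes_to_seq(self.reference_codes)

    @property
    def derived_bases(self) -> str:
        return codes_to_seq(self.derived_codes)

    def derived_counts(self) -> np.ndarray:
        return self.allele_matrix.sum(axis=0).astype(np.int64)

    def true_pi_sum(self) -> float:
        """Mean pairwise difference count between alleles, summed over sites.

        At a site with i derived copies among n alleles the probability two
        distinct alleles differ is 2 i (n-i) / (n (n-1)).
        """
        i = self.derived_counts().astype(np.float64)
        n = self.n
        return float((2.0 * i * (n - i) / (n * (n - 1))).sum())

    def validate(self) -> None:
        i = self.derived_counts()
        if self.S and not ((i >= 1) & (i <= self.n - 1)).all():
            raise ValueError("segregating site with 0 or n derived copies")
        if self.S and not (np.diff(self.segregating_positions) > 0).all():
            raise ValueError("positions not strictly increasing")
        ref_at = self.reference_codes[self.segregating_positions - 1]
        if self.S and (ref_at == self.derived_codes).any():
            raise ValueError("derived base equals reference base")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_haplotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    reference_codes: np.ndarray | None = None,
    site_weights: np.ndarray | None = None,
    base_weights: np.ndarray | None = None,
) -> HaplotypeSet:
    """Draw a neutral infinite-sites sample of ``config.n_alleles`` haplotypes.

    ``site_weights`` (length L) optionally scales the local mutation rate,
    and ``base_weights`` (L, 4) the relative rate toward each derived base;
    both default to uniform.  Used to plant class-specific diversity effects.
    """
    rng = _rng(config.seed) if rng is None else rng
    n, L = config.n_alleles, config.L
    if reference_codes is None:
        reference_codes = rng.integers(0, 4, size=L, dtype=np.uint8)
    if site_weights is None:
        w = np.ones(L, dtype=np.float64)
    else:
        w = np.asarray(site_weights, dtype=np.float64)
        if w.shape != (L,) or (w < 0).any():
            raise ValueError("site_weights must be a nonnegative length-L array")
    a1 = harmonic_number(n)
    expected_S = config.theta_per_site * a1 * float(w.sum())
    S = int(rng.poisson(expected_S))
    if S > L:
        raise ValueError(
            f"drawn S={S} exceeds locus length L={L}: the infinite-sites "
            "assumption (at most one mutation per site) is violated; "
            "lower theta_per_site or enlarge L"
        )
    if S == 0:
        return HaplotypeSet(
            n=n,
            L=L,
            segregating_positions=np.array([], dtype=np.int64),
            allele_matrix=np.zeros((n, 0), dtype=np.uint8),
            reference_codes=reference_codes,
            derived_codes=np.array([], dtype=np.uint8),
        )
    p = w / w.sum()
    sites = np.sort(rng.choice(L, size=S, replace=False, p=p)) + 1

    # neutral frequency spectrum: P(i copies) ~ 1/i, 1 <= i <= n-1
    spectrum = 1.0 / np.arange(1, n, dtype=np.float64)
    spectrum /= spectrum.sum()
    copies = rng.choice(np.arange(1, n), size=S, p=spectrum)

    matrix = np.zeros((n, S), dtype=np.uint8)
    for s in range(S):
        carriers = rng.permutation(n)[: copies[s]]
        matrix[carriers, s] = 1

    ref_at = reference_codes[sites - 1].astype(np.int64)
    derived = np.empty(S, dtype=np.uint8)
    for s in range(S):
        choices = [b for b in range(4) if b != ref_at[s]]
        if base_weights is None:
            derived[s] = rng.choice(choices)
        else:
            bw = np.asarray(base_weights[sites[s] - 1], dtype=np.float64)[choices]
            derived[s] = rng.choice(choices, p=bw / bw.sum())

    haps = HaplotypeSet(
        n=n,
        L=L,
        segregating_positions=sites.astype(np.int64),
        allele_matrix=matrix,
        reference_codes=reference_codes,
        derived_codes=derived,
    )
    haps.validate()
    return haps


def add_outgroup(
    reference_seq: str,
    n_subs: int,
    seed,
    return_positions: bool = False,
):
    """Derive an outgroup sequence differing at exactly ``n_subs`` positions."""
    codes = seq_to_codes(reference_seq)
    L = len(codes)
    if n_subs > L:
        raise ValueError(f"n_subs={n_subs} exceeds sequence length {L}")
    rng = _rng(seed)
    positions = np.sort(rng.choice(L, size=n_subs, replace=False)) + 1
    out = codes.copy()
    for pos in positions:
        old = int(out[pos - 1])
        choices = [b for b in range(4) if b != old]
        out[pos - 1] = rng.choice(choices)
    seq = codes_to_seq(out)
    if return_positions:
        return seq, positions.astype(np.int64)
    return seq


def pool_sequencing(
    haps: HaplotypeSet,
    mean_depth: float,
    error_rate: float,
    seed,
    gene_id: str = "locus",
    population_id: str = "pool",
    qual_mask_rate: float = 0.0,
    exact: bool = False,
) -> PositionTable:
    """Simulate pooled re-sequencing of a haplotype set into a position table.

    Per site, depth is Poisson(mean_depth) and each read samples a uniform
    haplotype's base, miscalled to a uniform different base with probability
    ``error_rate``.  With ``exact=True`` read sampling is bypassed: depth is
    fixed at n * round(mean_depth / n) and base counts are exactly
    proportional to pool allele frequencies (requires error_rate == 0).
    """
    if haps.n < 1:
        raise ValueError("empty haplotype set")
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    if exact and error_rate != 0.0:
        raise ValueError("exact mode requires error_rate == 0")
    rng = _rng(seed)
    L, n = haps.L, haps.n
    ref = haps.reference_codes.astype(np.int64)
    sp = haps.segregating_positions - 1  # 0-based indices
    derived_n = haps.derived_counts()

    if exact:
        per_allele = max(1, round(mean_depth / n))
        depth = np.full(L, per_allele * n, dtype=np.int64)
        counts = np.zeros((L, 4), dtype=np.int64)
        counts[np.arange(L), ref] = depth
        d = derived_n * per_allele
        counts[sp, ref[sp]] -= d
        counts[sp, haps.derived_codes.astype(np.int64)] += d
    else:
        depth = rng.poisson(mean_depth, size=L).astype(np.int64)
        counts = np.zeros((L, 4), dtype=np.int64)
        counts[np.arange(L), ref] = depth
        if len(sp):
            d = rng.binomial(depth[sp], derived_n / n)
            counts[sp, ref[sp]] -= d
            counts[sp, haps.derived_codes.astype(np.int64)] += d
        if error_rate > 0.0:
            others = [[b for b in range(4) if b != src] for src in range(4)]
            third = np.full(3, 1.0 / 3.0)
            for src in range(4):
                errs = rng.binomial(counts[:, src], error_rate)
                if errs.sum() == 0:
                    continue
                counts[:, src] -= errs
                dist = rng.multinomial(errs, third)
                for j, dst in enumerate(others[src]):
                    counts[:, dst] += dist[:, j]

    qual_masked = (
        rng.random(L) < qual_mask_rate
        if qual_mask_rate > 0.0
        else np.zeros(L, dtype=bool)
    )
    return PositionTable(
        gene_id=gene_id,
        population_id=population_id,
        positions=np.arange(1, L + 1, dtype=np.int64),
        ref_codes=haps.reference_codes,
        depth=depth,
        counts=counts,
        qual_masked=qual_masked,
    )


# ---------------------------------------------------------------------------
# Full study bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    population_id: str
    group: str  # NG | CG | SLG | SHG
    n_alleles: int = 50


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    gene_class: str  # candidate | reference
    subclass: str = "none"
    networks: frozenset = field(default_factory=frozenset)
    strand: str = "+"
    target_length: int = 3000
    theta_multiplier: float = 1.0  # overall scaling of this locus's theta


@dataclass
class StudyConfig:
    populations: list
    genes: list
    theta_per_site: float = 0.01
    n_alleles: int = 50
    mean_depth: float = 4000.0
    error_rate: float = 0.001
    qual_mask_rate: float = 0.002
    outgroup_divergence: float = 0.03  # substitutions per site to the outgroup
    candidate_nonsyn_factor: float = 1.0  # scales nonsynonymous theta in candidates

    def validate(self) -> None:
        pop_ids = [p.population_id for p in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            raise ValueError("duplicate population ids")
        gene_ids = [g.gene_id for g in self.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids")


@dataclass
class LocusTruth:
    """Generator-side ground truth for one population x gene pool."""

    theta_per_site: float
    n_alleles: int
    L: int
    S: int
    segregating_positions: list
    derived_counts: list
    true_pi_sum: float

    def to_json(self) -> dict:
        return {
            "theta_per_site": self.theta_per_site,
            "n_alleles": self.n_alleles,
            "L": self.L,
            "S": self.S,
            "segregating_positions": [int(x) for x in self.segregating_positions],
            "derived_counts": [int(x) for x in self.derived_counts],
            "true_pi_sum": self.true_pi_sum,
        }


@dataclass
class StudyBundle:
    populations: list
    genes: list  # GeneAnnotation
    ref_seqs: dict  # gene_id -> str
    outgroup_seqs: dict  # gene_id -> str
    tables: dict  # (population_id, gene_id) -> PositionTable
    truth: dict  # (population_id, gene_id) -> LocusTruth

    @property
    def total_alleles_per_gene(self) -> int:
        return sum(p.n_alleles for p in self.populations)

    @property
    def total_genotypes_per_gene(self) -> int:
        return sum(p.n_alleles // 2 for p in self.populations)


# Population groups of the study design: a northern group, a central group,
# a southern low-altitude group, and a southern high-altitude group.
STUDY_POPULATIONS: list[tuple[str, str]] = [
    ("LA1930", "NG"),
    ("LA3784", "NG"),
    ("LA0456", "CG"),
    ("LA0458", "CG"),
    ("LA1958", "CG"),
    ("LA1963", "CG"),
    ("LA1968", "CG"),
    ("LA2747", "CG"),
    ("LA2748", "CG"),
    ("LA2753", "CG"),
    ("LA2755", "CG"),
    ("LA2765", "CG"),
    ("LA2773", "CG"),
    ("LA2931", "CG"),
    ("LA3111", "CG"),
    ("LA2750", "SLG"),
    ("LA2932", "SLG"),
    ("LA4107", "SLG"),
    ("LA4108", "SLG"),
    ("LA2880", "SHG"),
    ("LA4118", "SHG"),
    ("LA4119", "SHG"),
    ("LA4332", "SHG"),
]

# 16 abiotic stress-responsive candidate genes: one sensory, five regulatory,
# ten functional; two regulators define gene networks with the functional
# genes they induce.
_CANDIDATE_GENES: list[tuple[str, str, tuple[str, ...]]] = [
    ("NtC7", "sensory", ()),
    ("AREB1", "regulatory", ("AREB1",)),
    ("AREB2", "regulatory", ()),
    ("JERF1", "regulatory", ("JERF1",)),
    ("JERF3", "regulatory", ()),
    ("DREB3", "regulatory", ()),
    ("CT208", "functional", ()),
    ("dhn1", "functional", ("AREB1",)),
    ("ER5", "functional", ()),
    ("His1", "functional", ()),
    ("le25", "functional", ("AREB1",)),
    ("LTP", "functional", ("JERF1",)),
    ("pLC30-15", "functional", ("AREB1", "JERF1")),
    ("TAS14", "functional", ("AREB1",)),
    ("TPP", "functional", ("AREB1",)),
    ("TSW12", "functional", ()),
]

# 14 reference genes representing the genomic background.  Only GBSSI is a
# published id; ref01..ref13 are synthetic stand-ins for the study's
# single-copy cDNA markers.
_REFERENCE_GENES = ["GBSSI"] + [f"ref{i:02d}" for i in range(1, 14)]


def default_study_config(
    theta_per_site: float = 0.01,
    candidate_nonsyn_factor: float = 1.0,
    mean_depth: float = 4000.0,
    error_rate: float = 0.001,
) -> StudyConfig:
    """Full-scale study design: 23 populations x (16 candidate + 14 reference)."""
    pops = [Population(pid, grp, n_alleles=50) for pid, grp in STUDY_POPULATIONS]
    genes: list[GeneSpec] = []
    lengths = [1200, 1800, 2400, 3000, 3600, 4200, 4800]
    for k, (gid, subclass, nets) in enumerate(_CANDIDATE_GENES):
        genes.append(
            GeneSpec(
                gene_id=gid,
                gene_class="candidate",
                subclass=subclass,
                networks=frozenset(nets),
                strand="+" if k % 3 else "-",
                target_length=lengths[k % len(lengths)],
            )
        )
    for k, gid in enumerate(_REFERENCE_GENES):
        genes.append(
            GeneSpec(
                gene_id=gid,
                gene_class="reference",
                strand="+" if k % 2 else "-",
                target_length=lengths[(k + 3) % len(lengths)],
            )
        )
    return StudyConfig(
        populations=pops,
        genes=genes,
        theta_per_site=theta_per_site,
        mean_depth=mean_depth,
        error_rate=error_rate,
        candidate_nonsyn_factor=candidate_nonsyn_factor,
    )


def _make_gene_structure(spec: GeneSpec, rng: np.random.Generator) -> GeneAnnotation:
    """Random exon/intron/flank architecture around the requested length."""
    target = spec.target_length
    segments: list[Segment] = []
    pos = 1
    flank5 = int(rng.integers(100, 301))
    segments.append(Segment(pos, pos + flank5 - 1, "flank"))
    pos += flank5
    n_exons = max(1, round((target - 600) / 900))
    cds_cum = 0
    for e in range(n_exons):
        cds_len = int(rng.integers(50, 201)) * 3
        segments.append(Segment(pos, pos + cds_len - 1, "CDS", frame=cds_cum % 3))
        cds_cum += cds_len
        pos += cds_len
        if e < n_exons - 1:
            intron_len = int(rng.integers(80, 401))
            segments.append(Segment(pos, pos + intron_len - 1, "intron"))
            pos += intron_len
    flank3 = int(rng.integers(100, 301))
    segments.append(Segment(pos, pos + flank3 - 1, "flank"))
    pos += flank3
    return GeneAnnotation(
        gene_id=spec.gene_id,
        total_length=pos - 1,
        strand=spec.strand,
        segments=tuple(segments),
        gene_class=spec.gene_class,
        subclass=spec.subclass,
        networks=spec.networks,
    )


def _nonsyn_weights(
    classifier: CodonClassifier, factor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site and per-base mutation-rate weights planting a nonsynonymous
    theta elevation by ``factor`` at CDS positions (synonymous and noncoding
    changes keep weight 1)."""
    L = classifier.ann.total_length
    base_w = np.ones((L, 4), dtype=np.float64)
    ref = classifier.ref_codes
    for i in np.flatnonzero(classifier.coding_index >= 0):
        pos = i + 1
        for b in range(4):
            if b == ref[i]:
                base_w[i, b] = 0.0
                continue
            cls = classifier.classify_outgroup_change(pos, b)
            if cls == "nonsynonymous":
                base_w[i, b] = factor
    # at noncoding sites zero out only the reference base
    noncoding = classifier.coding_index < 0
    base_w[noncoding, ref[noncoding]] = 0.0
    site_w = base_w.sum(axis=1) / 3.0
    return site_w, base_w


def build_study(config: StudyConfig, seed: int = 0) -> StudyBundle:
    """Generate a full multi-population, multi-gene study bundle."""
    config.validate()
    root = np.random.SeedSequence(seed)
    gene_seeds = root.spawn(len(config.genes))

    genes: list[GeneAnnotation] = []
    ref_seqs: dict[str, str] = {}
    outgroup_seqs: dict[str, str] = {}
    tables: dict[tuple[str, str], PositionTable] = {}
    truth: dict[tuple[str, str], LocusTruth] = {}

    for gspec, gseed in zip(config.genes, gene_seeds):
        grng = np.random.default_rng(gseed)
        ann = _make_gene_structure(gspec, grng)
        genes.append(ann)
        L = ann.total_length
        ref_codes = grng.integers(0, 4, size=L, dtype=np.uint8)
        ref_seq = codes_to_seq(ref_codes)
        ref_seqs[ann.gene_id] = ref_seq
        n_subs = int(round(config.outgroup_divergence * L))
        outgroup_seqs[ann.gene_id] = add_outgroup(ref_seq, n_subs, grng)

        theta = config.theta_per_site * gspec.theta_multiplier
        site_w = base_w = None
        if gspec.gene_class == "candidate" and config.candidate_nonsyn_factor != 1.0:
            classifier = CodonClassifier(ann, ref_codes)
            site_w, base_w = _nonsyn_weights(classifier, config.candidate_nonsyn_factor)

        sim_cfg = SimulationConfig(
            theta_per_site=theta,
            n_alleles=config.n_alleles,
            L=L,
            mean_depth=config.mean_depth,
            error_rate=config.error_rate,
        )
        for pop in config.populations:
            prng = grng  # sequential draws keep the bundle reproducible
            haps = generate_haplotypes(
                sim_cfg,
                rng=prng,
                reference_codes=ref_codes,
                site_weights=site_w,
                base_weights=base_w,
            )
            table = pool_sequencing(
                haps,
                mean_depth=config.mean_depth,
                error_rate=config.error_rate,
                seed=prng,
                gene_id=ann.gene_id,
                population_id=pop.population_id,
                qual_mask_rate=config.qual_mask_rate,
            )
            tables[(pop.population_id, ann.gene_id)] = table
            truth[(pop.population_id, ann.gene_id)] = LocusTruth(
                theta_per_site=theta,
                n_alleles=haps.n,
                L=L,
                S=haps.S,
                segregating_positions=list(haps.segregating_positions),
                derived_counts=list(haps.derived_counts()),
                true_pi_sum=haps.true_pi_sum(),
            )

    return StudyBundle(
        populations=list(config.populations),
        genes=genes,
        ref_seqs=ref_seqs,
        outgroup_seqs=outgroup_seqs,
        tables=tables,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Bundle directory layout
# ---------------------------------------------------------------------------


def write_bundle(bundle: StudyBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.ref_seqs, out / "ref.fasta")
    write_fasta(bundle.outgroup_seqs, out / "outgroup.fasta")
    write_annotation(bundle.genes, out / "annotation.tsv")
    with open(out / "populations.tsv", "w") as fh:
        fh.write("population_id\tgroup\tn_alleles\n")
        for p in bundle.populations:
            fh.write(f"{p.population_id}\t{p.group}\t{p.n_alleles}\n")
    for (pop, gene), table in bundle.tables.items():
        d = out / "tables" / pop
        d.mkdir(parents=True, exist_ok=True)
        write_position_table(table, d / f"{gene}.tsv")
    truth_json = {f"{pop}\t{gene}": t.to_json() for (pop, gene), t in bundle.truth.items()}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh)


def read_bundle(indir) -> StudyBundle:
    ind = Path(indir)
    ref_seqs = read_fasta(ind / "ref.fasta")
    outgroup_seqs = read_fasta(ind / "outgroup.fasta")
    genes = read_annotation(ind / "annotation.tsv")
    populations = []
    with open(ind / "populations.tsv") as fh:
        header = fh.readline()
        for line in fh:
            pid, grp, n = line.rstrip("\n").split("\t")
            populations.append(Population(pid, grp, int(n)))
    tables = {}
    for p in populations:
        for g in genes:
            path = ind / "tables" / p.population_id / f"{g.gene_id}.tsv"
            tables[(p.population_id, g.gene_id)] = read_position_table(path)
    truth = {}
    truth_path = ind / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            raw = json.load(fh)
        for key, t in raw.items():
            pop, gene = key.split("\t")
            truth[(pop, gene)] = LocusTruth(**t)
    return StudyBundle(
        populations=populations,
        genes=genes,
        ref_seqs=ref_seqs,
        outgroup_seqs=outgroup_seqs,
        tables=tables,
        truth=truth,
    )
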