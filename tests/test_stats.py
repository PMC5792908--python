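import itertools
import math

import numpy as np
import pytest

from poolpopgen import (
    CodonClassifier,
    FilterConfig,
    GeneAnnotation,
    Segment,
    SimulationConfig,
    call_snps,
    divergence,
    generate_haplotypes,
    harmonic_number,
    mask_positions,
    nucleotide_diversity,
    pairwise_fst,
    pool_sequencing,
    site_heterozygosity,
    tajima_constants,
    tajimas_d,
    watterson_theta,
)
from poolpopgen.codon import count_syn_nonsyn_sites
from poolpopgen.tables import seq_to_codes


# ---------------------------------------------------------------------------
# site heterozygosity
# ---------------------------------------------------------------------------


def test_monomorphic_site_heterozygosity_zero():
    assert site_heterozygosity([100, 0, 0, 0], 50) == 0.0


def test_heterozygosity_equals_exact_pairwise_value():
    # oracle: count mismatching pairs among all C(50,2) pairs of alleles
    # for a 25/25 split
    alleles = [0] * 25 + [1] * 25
    mismatches = sum(a != b for a, b in itertools.combinations(alleles, 2))
    exact = mismatches / math.comb(50, 2)
    assert exact == 625 / 1225
    h = site_heterozygosity([500, 500, 0, 0], 50)
    assert h == pytest.approx(exact, abs=1e-12)
    assert h == pytest.approx((50 / 49) * 0.5)


def test_heterozygosity_large_n_limit():
    assert site_heterozygosity([500, 500, 0, 0], 10**9) == pytest.approx(0.5, abs=1e-6)


def test_heterozygosity_rejects_empty_site():
    with pytest.raises(ValueError, match="zero coverage"):
        site_heterozygosity([0, 0, 0, 0], 50)


# ---------------------------------------------------------------------------
# Watterson theta and Tajima's D
# ---------------------------------------------------------------------------


def test_watterson_theta_values():
    assert watterson_theta(0, 50, 1000) == 0.0
    assert watterson_theta(7, 2, 100) == pytest.approx(7 / 100)  # a1(2) = 1
    a1_direct = sum(1.0 / i for i in range(1, 50))
    assert watterson_theta(10, 50, 1000) == pytest.approx(10 / (a1_direct * 1000))
    assert watterson_theta(5, 50, 0) is None


def _assemble_d(pi_sum, S, n):
    """Independent assembly of D from scratch for the oracle."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_against_independent_assembly():
    assert tajimas_d(1.5, 3, 4) == pytest.approx(-0.754, abs=5e-4)
    for pi_sum, S, n in [(1.5, 3, 4), (10.0, 45, 50), (2.0, 2, 10), (0.5, 1, 6)]:
        assert tajimas_d(pi_sum, S, n) == pytest.approx(_assemble_d(pi_sum, S, n), abs=1e-12)


def test_tajimas_d_zero_when_pi_equals_watterson():
    n = 50
    S = 12
    pi_sum = S / harmonic_number(n)
    assert tajimas_d(pi_sum, S, n) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_undefined_without_segregating_sites():
    assert tajimas_d(0.0, 0, 50) is None


def test_tajima_constants_reference_values():
    c = tajima_constants(4)
    assert c["a1"] == pytest.approx(1 + 1 / 2 + 1 / 3)
    assert c["b1"] == pytest.approx(5 / 9)


# ---------------------------------------------------------------------------
# class-aware pi and divergence on constructed tables
# ---------------------------------------------------------------------------


def _flat_gene(L):
    return GeneAnnotation("g1", L, "+", (Segment(1, L, "flank"),), "reference")


def _counts_for(ann, ref, table):
    return count_syn_nonsyn_sites(ann, ref, table.mask_state)


def test_pi_zero_without_snps(table_factory):
    ref = "A" * 100
    t = mask_positions(table_factory(ref), FilterConfig())
    ann = _flat_gene(100)
    counts = _counts_for(ann, ref, t)
    assert nucleotide_diversity(t, [], "all", counts, 50) == 0.0


def test_pi_single_snp_arithmetic(table_factory):
    ref = "A" * 1000
    t = table_factory(ref, depth=4000, overrides={17: {"A": 2000, "G": 2000}})
    t = mask_positions(t, FilterConfig())
    fc = FilterConfig()
    snps = call_snps(t, fc)
    ann = _flat_gene(1000)
    counts = _counts_for(ann, ref, t)
    h = site_heterozygosity([2000, 0, 2000, 0], 50)
    pi = nucleotide_diversity(t, snps, "all", counts, 50)
    assert pi == pytest.approx(h / 1000)
    assert pi == pytest.approx((50 / 49) * 0.5 / 1000)


def test_pi_absent_when_class_has_no_sites(table_factory):
    ref = "A" * 100
    t = mask_positions(table_factory(ref), FilterConfig())
    counts = _counts_for(_flat_gene(100), ref, t)  # no CDS at all
    assert nucleotide_diversity(t, [], "synonymous", counts, 50) is None


def test_divergence_examples(table_factory):
    ref = "A" * 100
    ann = _flat_gene(100)
    t = mask_positions(table_factory(ref, depth=4000), FilterConfig())
    counts = _counts_for(ann, ref, t)
    # population identical to outgroup -> K = 0
    assert divergence(t, ref, "all", counts) == 0.0
    # 5 fixed differences over 100 callable sites -> K = 0.05
    og = "C" * 5 + "A" * 95
    assert divergence(t, og, "all", counts) == pytest.approx(0.05)
    # polymorphic site 0.8/0.2 with outgroup carrying the 0.8 base:
    # oracle = mean pairwise difference between population reads and the
    # outgroup base = 0.2
    t2 = table_factory(ref, depth=4000, overrides={1: {"A": 3200, "G": 800}})
    t2 = mask_positions(t2, FilterConfig())
    counts2 = _counts_for(ann, ref, t2)
    assert divergence(t2, ref, "all", counts2) == pytest.approx(0.2 / 100)


def test_divergence_excludes_outgroup_n_sites(table_factory):
    ref = "A" * 10
    ann = _flat_gene(10)
    t = mask_positions(table_factory(ref, depth=4000), FilterConfig())
    counts = _counts_for(ann, ref, t)
    og = "N" + "C" + "A" * 8  # N site dropped from numerator and denominator
    assert divergence(t, og, "all", counts) == pytest.approx(1 / 9)


def test_class_split_divergence(table_factory, simple_annotation):
    # CDS ATG TTT ...: a TTT->TTC change is synonymous
    ref = "A" * 12 + "ATGTTTGGATCACTGAAGCCCGGGTTTAAA" + "C" * 9 + "G" * 9
    ann = simple_annotation
    og = ref[:17] + "C" + ref[18:]  # outgroup TTC at codon 2
    t = mask_positions(table_factory(ref, depth=4000), FilterConfig())
    classifier = CodonClassifier(ann, seq_to_codes(ref))
    counts = classifier.site_counts(t.mask_state)
    k_syn = divergence(t, og, "synonymous", counts, classifier)
    k_nonsyn = divergence(t, og, "nonsynonymous", counts, classifier)
    assert k_syn == pytest.approx(1.0 / counts.L_syn)
    assert k_nonsyn == 0.0


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def test_fst_zero_for_identical_frequencies(table_factory):
    a = table_factory("A" * 50, depth=4000, overrides={10: {"A": 2000, "C": 2000}},
                      population_id="p1")
    b = table_factory("A" * 50, depth=4000, overrides={10: {"A": 2000, "C": 2000}},
                      population_id="p2")
    fc = FilterConfig()
    a, b = mask_positions(a, fc), mask_positions(b, fc)
    res = pairwise_fst(a, b, [10])
    assert res.value == 0.0
    assert res.raw <= 0.0  # finite-n correction makes Hw slightly exceed Hb


def test_fst_one_for_fixed_difference(table_factory):
    a = table_factory("A" * 50, depth=4000, population_id="p1")
    b = table_factory("A" * 50, depth=4000, overrides={10: {"C": 4000}}, population_id="p2")
    fc = FilterConfig()
    res = pairwise_fst(mask_positions(a, fc), mask_positions(b, fc), [10])
    assert res.value == 1.0 and res.raw == 1.0


def test_fst_intermediate_frequencies_sign_and_magnitude(table_factory):
    # pA = pB = 0.5: Hb = 0.5 and Hw = (n/(n-1)) * 0.5, so raw F_ST is the
    # small negative finite-n value -1/(n-1), clamped to 0
    a = table_factory("A" * 10, depth=4000, overrides={5: {"A": 2000, "G": 2000}})
    b = table_factory("A" * 10, depth=4000, overrides={5: {"A": 2000, "G": 2000}},
                      population_id="p2")
    fc = FilterConfig()
    res = pairwise_fst(mask_positions(a, fc), mask_positions(b, fc), [5], 50, 50)
    assert res.raw == pytest.approx(-1 / 49)
    assert res.value == 0.0


def test_fst_symmetry_and_masking(table_factory):
    rng = np.random.default_rng(12)
    fc = FilterConfig()
    for _ in range(10):
        L = 30
        ref = "A" * L
        ov_a = {int(p): {"A": int(c), "T": 4000 - int(c)}
                for p, c in zip(rng.choice(L, 6, replace=False) + 1, rng.integers(100, 3900, 6))}
        ov_b = {int(p): {"A": int(c), "T": 4000 - int(c)}
                for p, c in zip(rng.choice(L, 6, replace=False) + 1, rng.integers(100, 3900, 6))}
        a = mask_positions(table_factory(ref, overrides=ov_a), fc)
        b = mask_positions(table_factory(ref, overrides=ov_b, population_id="p2"), fc)
        union = sorted(set(ov_a) | set(ov_b))
        r1 = pairwise_fst(a, b, union)
        r2 = pairwise_fst(b, a, union)
        assert r1.raw == r2.raw and r1.value == r2.value


def test_fst_absent_without_shared_sites(table_factory):
    fc = FilterConfig()
    a = mask_positions(table_factory("A" * 10, depths={5: 100}), fc)  # masked in A
    b = mask_positions(table_factory("A" * 10, overrides={5: {"A": 2000, "C": 2000}}), fc)
    assert pairwise_fst(a, b, [5]) is None


# ---------------------------------------------------------------------------
# estimator calibration against generator truth
# ---------------------------------------------------------------------------


def test_pooled_estimators_match_haplotype_truth_exactly_without_read_noise():
    # read sampling bypassed -> pi, S, theta_w, D all match the direct
    # haplotype computation exactly
    fc = FilterConfig()
    rng = np.random.default_rng(31)
    for _ in range(10):
        cfg = SimulationConfig(theta_per_site=0.01, n_alleles=50, L=1500)
        haps = generate_haplotypes(cfg, rng=rng)
        t = pool_sequencing(haps, mean_depth=4000, error_rate=0.0, seed=rng, exact=True)
        t = mask_positions(t, fc)
        snps = call_snps(t, fc)
        assert len(snps) == haps.S
        pi_sum = sum(
            site_heterozygosity(t.counts[t.index_of(s.position)], 50) for s in snps
        )
        assert pi_sum == pytest.approx(haps.true_pi_sum(), abs=1e-9)
        d_pool = tajimas_d(pi_sum, len(snps), 50)
        d_true = tajimas_d(haps.true_pi_sum(), haps.S, 50)
        if d_true is None:
            assert d_pool is None
        else:
            assert d_pool == pytest.approx(d_true, abs=1e-9)


def test_mean_tajimas_d_near_zero_under_neutrality():
    # scaled-down version of the neutrality calibration (the full-size run
    # lives in the acceptance suite)
    rng = np.random.default_rng(8)
    cfg = SimulationConfig(theta_per_site=0.01, n_alleles=50, L=1000)
    ds = []
    for _ in range(300):
        haps = generate_haplotypes(cfg, rng=rng)
        d = tajimas_d(haps.true_pi_sum(), haps.S, 50)
        if d is not None:
            ds.append(d)
    se = np.std(ds) / np.sqrt(len(ds))
    assert abs(np.mean(ds)) < max(0.05, 3 * se)


def test_tajimas_d_normalisation_calibrated_on_coalescent_samples():
    """Under genealogy-faithful neutral coalescent samples the normalised D
    should be approximately standard normal (variance in [0.7, 1.3]).  The
    package's own generator draws sites independently, which reproduces the
    neutral SFS but not the between-site covariance the normalisation
    accounts for, so the variance check uses msprime samples."""
    msprime = pytest.importorskip("msprime")
    n, L, theta = 50, 1000, 10.0
    ds = []
    for rep in range(400):
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1, sequence_length=L, random_seed=rep + 1
        )
        mts = msprime.sim_mutations(
            ts, rate=theta / (2 * L), random_seed=rep + 1, discrete_genome=False
        )
        i = np.array([v.genotypes.sum() for v in mts.variants()])
        i = i[(i > 0) & (i < n)]
        if len(i) == 0:
            continue
        pi_sum = float((2 * i * (n - i) / (n * (n - 1))).sum())
        ds.append(tajimas_d(pi_sum, len(i), n))
    assert 0.7 <= np.var(ds) <= 1.3


def test_pi_invariant_under_orientation_reversal(table_factory):
    ref = "ACGTACGTAC" * 10
    ov = {11: {"A": 3000, "T": 1000}, 40: {"C": 2000, "G": 2000}}
    t = mask_positions(table_factory(ref, overrides=ov), FilterConfig())
    fc = FilterConfig()
    snps = call_snps(t, fc)
    ann = _flat_gene(100)
    counts = count_syn_nonsyn_sites(ann, ref, t.mask_state)
    pi = nucleotide_diversity(t, snps, "all", counts, 50)

    # reversed locus
    import numpy as np
    rev = t.copy()
    rev.ref_codes = t.ref_codes[::-1].copy()
    rev.counts = t.counts[::-1].copy()
    rev.depth = t.depth[::-1].copy()
    rev.mask_state = t.mask_state[::-1].copy()
    snps_rev = call_snps(rev, fc)
    counts_rev = count_syn_nonsyn_sites(ann, ref[::-1], rev.mask_state)
    pi_rev = nucleotide_diversity(rev, snps_rev, "all", counts_rev, 50)
    assert pi_rev == pytest.approx(pi, abs=1e-15)
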