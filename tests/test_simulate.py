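import numpy as np
import pytest
from scipy import stats as sps

from poolpopgen import (
    HaplotypeSet,
    SimulationConfig,
    add_outgroup,
    build_study,
    default_study_config,
    generate_haplotypes,
    pool_sequencing,
    read_bundle,
    write_bundle,
)
from poolpopgen.pipeline import study_config_from_options
from poolpopgen.simulate import Population, StudyConfig


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


def test_zero_theta_gives_no_segregating_sites():
    haps = generate_haplotypes(SimulationConfig(theta_per_site=0.0, L=500, seed=3))
    assert haps.S == 0
    assert haps.allele_matrix.shape == (50, 0)


def test_two_alleles_only_singletons():
    cfg = SimulationConfig(theta_per_site=0.05, n_alleles=2, L=2000, seed=5)
    haps = generate_haplotypes(cfg)
    assert haps.S > 0
    assert (haps.derived_counts() == 1).all()


def test_segregating_site_count_matches_expectation():
    # oracle: E[S] = theta * L * a1(n) with a1 by direct harmonic summation
    n, L, theta, reps = 50, 1000, 0.01, 1000
    expected = theta * L * harmonic(n)
    rng = np.random.default_rng(42)
    cfg = SimulationConfig(theta_per_site=theta, n_alleles=n, L=L)
    s_vals = [generate_haplotypes(cfg, rng=rng).S for _ in range(reps)]
    se = np.sqrt(expected / reps)  # Poisson standard error of the mean
    assert abs(np.mean(s_vals) - expected) < 3 * se


def test_site_frequency_spectrum_is_neutral():
    # chi-square goodness of fit of derived-allele counts against P(i) ~ 1/i
    n = 20
    rng = np.random.default_rng(7)
    cfg = SimulationConfig(theta_per_site=0.02, n_alleles=n, L=1000)
    counts = np.concatenate(
        [generate_haplotypes(cfg, rng=rng).derived_counts() for _ in range(300)]
    )
    observed = np.bincount(counts, minlength=n)[1:n]
    probs = (1.0 / np.arange(1, n)) / harmonic(n)
    _, p = sps.chisquare(observed, probs * observed.sum())
    assert p > 1e-3


def test_infinite_sites_violation_raises():
    cfg = SimulationConfig(theta_per_site=1.0, n_alleles=50, L=20, seed=0)
    with pytest.raises(ValueError, match="infinite-sites"):
        generate_haplotypes(cfg)


def test_haplotype_invariants_hold():
    cfg = SimulationConfig(theta_per_site=0.02, n_alleles=10, L=500, seed=11)
    haps = generate_haplotypes(cfg)
    i = haps.derived_counts()
    assert ((i >= 1) & (i <= 9)).all()
    assert (np.diff(haps.segregating_positions) > 0).all()
    ref_at = haps.reference_codes[haps.segregating_positions - 1]
    assert (ref_at != haps.derived_codes).all()


@pytest.mark.parametrize("n_subs", [0, 5, 100])
def test_outgroup_hamming_distance_exact(n_subs):
    ref = "ACGT" * 25
    out = add_outgroup(ref, n_subs, seed=9)
    assert sum(a != b for a, b in zip(ref, out)) == n_subs


def test_outgroup_too_many_substitutions_raises():
    with pytest.raises(ValueError, match="exceeds"):
        add_outgroup("ACGT", 5, seed=0)


def test_pool_sequencing_error_free_monomorphic_sites():
    haps = generate_haplotypes(SimulationConfig(theta_per_site=0.0, L=300, seed=1))
    t = pool_sequencing(haps, mean_depth=500, error_rate=0.0, seed=2)
    ref = haps.reference_codes
    assert (t.counts[np.arange(300), ref] == t.depth).all()


def test_pool_sequencing_read_fraction_converges_to_pool_frequency():
    # 25 of 50 alleles derived; at large depth the derived read fraction -> 0.5
    L, n = 200, 50
    rng = np.random.default_rng(0)
    ref = np.zeros(L, dtype=np.uint8)  # all A
    matrix = np.zeros((n, L), dtype=np.uint8)
    matrix[:25, :] = 1
    haps = HaplotypeSet(
        n=n, L=L,
        segregating_positions=np.arange(1, L + 1),
        allele_matrix=matrix,
        reference_codes=ref,
        derived_codes=np.full(L, 2, dtype=np.uint8),  # G
    )
    depth = 100_000
    t = pool_sequencing(haps, mean_depth=depth, error_rate=0.0, seed=rng)
    frac = t.counts[:, 2] / t.depth
    se = np.sqrt(0.25 / depth)
    assert abs(frac.mean() - 0.5) < 3 * se / np.sqrt(L)


def test_pool_sequencing_error_rate_recovered():
    # oracle: each read miscalls with probability e, so the expected
    # non-reference fraction at monomorphic sites is e
    e, depth, L = 0.01, 2000, 3000
    haps = generate_haplotypes(SimulationConfig(theta_per_site=0.0, L=L, seed=4))
    t = pool_sequencing(haps, mean_depth=depth, error_rate=e, seed=8)
    ref = haps.reference_codes
    nonref = t.depth - t.counts[np.arange(L), ref]
    frac = nonref.sum() / t.depth.sum()
    se = np.sqrt(e * (1 - e) / t.depth.sum())
    assert abs(frac - e) < 3 * se


def test_pool_sequencing_exact_mode_matches_true_frequencies():
    cfg = SimulationConfig(theta_per_site=0.01, n_alleles=50, L=500, seed=6)
    haps = generate_haplotypes(cfg)
    t = pool_sequencing(haps, mean_depth=4000, error_rate=0.0, seed=0, exact=True)
    sp = haps.segregating_positions - 1
    frac = t.counts[sp, haps.derived_codes] / t.depth[sp]
    assert np.allclose(frac, haps.derived_counts() / 50, atol=1e-12)


def test_pool_sequencing_rejects_empty_pool_and_bad_error_rate():
    haps = generate_haplotypes(SimulationConfig(theta_per_site=0.0, L=10, seed=1))
    empty = HaplotypeSet(
        n=0, L=10,
        segregating_positions=np.array([], dtype=np.int64),
        allele_matrix=np.zeros((0, 0), dtype=np.uint8),
        reference_codes=haps.reference_codes,
        derived_codes=np.array([], dtype=np.uint8),
    )
    with pytest.raises(ValueError, match="empty"):
        pool_sequencing(empty, 100, 0.0, seed=0)
    with pytest.raises(ValueError, match="error_rate"):
        pool_sequencing(haps, 100, 0.3, seed=0)


def _mini_config(**kw):
    return study_config_from_options(
        dict(n_populations=2, n_candidate_genes=2, n_reference_genes=2, **kw)
    )


def test_build_study_shapes_and_truth():
    cfg = _mini_config()
    bundle = build_study(cfg, seed=3)
    assert len(bundle.tables) == 2 * 4
    assert set(bundle.truth) == set(bundle.tables)
    for (pop, gene), table in bundle.tables.items():
        truth = bundle.truth[(pop, gene)]
        assert len(table) == truth.L
        assert truth.S == len(truth.segregating_positions)


def test_build_study_single_pair():
    cfg = study_config_from_options(
        dict(n_populations=1, n_candidate_genes=1, n_reference_genes=0)
    )
    bundle = build_study(cfg, seed=0)
    assert len(bundle.tables) == 1


def test_build_study_rejects_duplicate_ids():
    cfg = _mini_config()
    cfg.populations = [Population("LA1930", "NG"), Population("LA1930", "NG")]
    with pytest.raises(ValueError, match="duplicate"):
        build_study(cfg, seed=0)


def test_default_config_matches_study_design():
    cfg = default_study_config()
    assert len(cfg.populations) == 23
    assert sum(p.n_alleles for p in cfg.populations) == 1150
    assert sum(p.n_alleles // 2 for p in cfg.populations) == 575
    cands = [g for g in cfg.genes if g.gene_class == "candidate"]
    refs = [g for g in cfg.genes if g.gene_class == "reference"]
    assert (len(cands), len(refs)) == (16, 14)
    assert sorted(g.subclass for g in cands).count("regulatory") == 5
    assert sorted(g.subclass for g in cands).count("functional") == 10
    assert sorted(g.subclass for g in cands).count("sensory") == 1
    areb1 = {g.gene_id for g in cfg.genes if "AREB1" in g.networks}
    jerf1 = {g.gene_id for g in cfg.genes if "JERF1" in g.networks}
    assert areb1 == {"AREB1", "dhn1", "le25", "pLC30-15", "TAS14", "TPP"}
    assert jerf1 == {"JERF1", "LTP", "pLC30-15"}
    groups = [p.group for p in cfg.populations]
    assert (groups.count("NG"), groups.count("CG"), groups.count("SLG"), groups.count("SHG")) == (2, 13, 4, 4)


def test_same_seed_reproduces_identical_bundle(tmp_path):
    cfg = _mini_config()
    b1 = build_study(cfg, seed=17)
    b2 = build_study(cfg, seed=17)
    assert b1.ref_seqs == b2.ref_seqs
    assert b1.outgroup_seqs == b2.outgroup_seqs
    for key in b1.tables:
        assert b1.tables[key] == b2.tables[key]
        assert b1.truth[key].to_json() == b2.truth[key].to_json()


def test_bundle_roundtrip(tmp_path):
    bundle = build_study(_mini_config(), seed=5)
    write_bundle(bundle, tmp_path / "b")
    back = read_bundle(tmp_path / "b")
    assert back.ref_seqs == bundle.ref_seqs
    assert back.genes == bundle.genes
    assert set(back.tables) == set(bundle.tables)
    for key in bundle.tables:
        assert back.tables[key] == bundle.tables[key]
        assert back.truth[key].to_json() == bundle.truth[key].to_json()
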