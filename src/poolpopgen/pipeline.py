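"""End-to-end pipeline: simulate/load -> mask -> SNPs -> classify -> stats
-> F_ST -> SNP windows -> class comparisons, with a checksummed manifest.

Single-threaded reference implementation; the per population x gene work is
embarrassingly parallel but correctness, determinism (same config + seed =>
identical checksums) and auditability (per-stage record counts in the log
and manifest) come first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .codon import CodonClassifier
from .comparisons import compare_gene_classes, compare_window_strata
from .filters import FilterConfig, call_snps, mask_positions
from .simulate import (
    StudyBundle,
    StudyConfig,
    build_study,
    default_study_config,
    read_bundle,
    write_bundle,
)
from .stats import fst_matrix, gene_population_stats
from .tables import MaskState, seq_to_codes
from .windows import (
    compute_windows,
    flag_fixed_differences,
    species_fixed_differences,
    stratify_windows,
)

logger = logging.getLogger("poolpopgen")

__all__ = ["PipelineConfig", "run_pipeline", "analyze_bundle", "AnalysisResult"]

_STAT_COLUMNS = [
    "gene_id",
    "population_id",
    "n_alleles",
    "S",
    "pi",
    "pi_syn",
    "pi_nonsyn",
    "theta_w",
    "tajimas_d",
    "K",
    "K_syn",
    "K_nonsyn",
    "L_total",
    "L_syn",
    "L_nonsyn",
    "L_noncoding",
]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    input_dir: str | None = None  # load an existing bundle instead of simulating
    simulate: dict = field(default_factory=dict)  # StudyConfig overrides
    min_depth: int = 2000
    maf_min: float = 0.01
    half_width: int = 20
    max_masked: int = 3
    compare_mode: str = "pooled"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def study_config_from_options(options: dict) -> StudyConfig:
    """Build a StudyConfig from YAML-style overrides of the default design.

    ``n_populations`` / ``n_candidate_genes`` / ``n_reference_genes`` subset
    the full study design for scaled-down runs; the remaining keys override
    generator rates.
    """
    cfg = default_study_config(
        theta_per_site=options.get("theta_per_site", 0.01),
        candidate_nonsyn_factor=options.get("candidate_nonsyn_factor", 1.0),
        mean_depth=options.get("mean_depth", 4000.0),
        error_rate=options.get("error_rate", 0.001),
    )
    if "n_populations" in options:
        cfg.populations = cfg.populations[: options["n_populations"]]
    cands = [g for g in cfg.genes if g.gene_class == "candidate"]
    refs = [g for g in cfg.genes if g.gene_class == "reference"]
    if "n_candidate_genes" in options:
        cands = cands[: options["n_candidate_genes"]]
    if "n_reference_genes" in options:
        refs = refs[: options["n_reference_genes"]]
    cfg.genes = cands + refs
    for key in ("qual_mask_rate", "outgroup_divergence"):
        if key in options:
            setattr(cfg, key, options[key])
    cfg.validate()
    return cfg


@dataclass
class AnalysisResult:
    """In-memory products of the mask/call/classify/stats stages."""

    stats_records: list
    masked_tables: dict  # (pop, gene) -> PositionTable
    snps: dict  # (pop, gene) -> list[SNP], classified and fixed-flagged
    classifiers: dict  # gene -> CodonClassifier
    window_records: list
    window_long: object  # pandas DataFrame
    window_summary: object
    counters: dict


def analyze_bundle(
    bundle: StudyBundle,
    filter_cfg: FilterConfig,
    half_width: int = 20,
    max_masked: int = 3,
    with_windows: bool = True,
) -> AnalysisResult:
    """Run masking, SNP calling, classification, per-locus statistics and
    (optionally) SNP-neighbourhood windows over every population x gene
    table."""
    n_by_pop = {p.population_id: p.n_alleles for p in bundle.populations}
    classifiers = {
        ann.gene_id: CodonClassifier(ann, seq_to_codes(bundle.ref_seqs[ann.gene_id]))
        for ann in bundle.genes
    }
    counters = {
        "sites_total": 0,
        "sites_masked_low_depth": 0,
        "sites_masked_low_quality": 0,
        "snps_called": 0,
        "windows_total": 0,
        "windows_excluded_too_many_masked": 0,
        "windows_excluded_fixed_difference": 0,
    }
    masked_tables = {}
    snps_by = {}
    stats_records = []
    window_records = []

    for ann in bundle.genes:
        gid = ann.gene_id
        classifier = classifiers[gid]
        outgroup = bundle.outgroup_seqs.get(gid)
        gene_tables = {}
        gene_snps = {}
        for pop in bundle.populations:
            pid = pop.population_id
            table = mask_positions(bundle.tables[(pid, gid)], filter_cfg)
            counters["sites_total"] += len(table)
            counters["sites_masked_low_depth"] += int(
                (table.mask_state == MaskState.LOW_DEPTH).sum()
            )
            counters["sites_masked_low_quality"] += int(
                (table.mask_state == MaskState.LOW_QUALITY).sum()
            )
            snps = [
                classifier.classify(s, table_ref_base="ACGTN"[table.ref_codes[table.index_of(s.position)]])
                for s in call_snps(table, filter_cfg)
            ]
            counters["snps_called"] += len(snps)
            gene_tables[pid] = table
            gene_snps[pid] = snps

        fixed = (
            species_fixed_differences(gene_tables, outgroup, filter_cfg.maf_min)
            if outgroup is not None
            else np.zeros(ann.total_length, dtype=bool)
        )
        for pop in bundle.populations:
            pid = pop.population_id
            table = gene_tables[pid]
            snps = flag_fixed_differences(gene_snps[pid], fixed)
            gene_snps[pid] = snps
            class_counts = classifier.site_counts(table.mask_state)
            stats_records.append(
                gene_population_stats(
                    table, snps, classifier, class_counts, outgroup, n_by_pop[pid]
                )
            )
            if with_windows:
                recs = compute_windows(
                    table, snps, n_by_pop[pid], half_width=half_width, max_masked=max_masked
                )
                window_records.extend(recs)
                counters["windows_total"] += len(recs)
                for r in recs:
                    if r.exclusion_reason != "none":
                        counters[f"windows_excluded_{r.exclusion_reason}"] += 1
            masked_tables[(pid, gid)] = table
            snps_by[(pid, gid)] = snps
        logger.info("gene %s: analysed %d populations", gid, len(bundle.populations))

    gene_classes = {a.gene_id: a.gene_class for a in bundle.genes}
    gene_networks = {a.gene_id: a.networks for a in bundle.genes}
    window_long, window_summary = stratify_windows(window_records, gene_classes, gene_networks)
    return AnalysisResult(
        stats_records=stats_records,
        masked_tables=masked_tables,
        snps=snps_by,
        classifiers=classifiers,
        window_records=window_records,
        window_long=window_long,
        window_summary=window_summary,
        counters=counters,
    )


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def _write_stats(records, out_path: Path) -> None:
    with open(out_path, "w") as fh:
        fh.write("\t".join(_STAT_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in _STAT_COLUMNS) + "\n")


def _write_fst(mat, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#gene={mat.gene_id}\n")
        fh.write("population\t" + "\t".join(mat.population_ids) + "\n")
        for i, pid in enumerate(mat.population_ids):
            row = "\t".join(_fmt(float(x)) if not np.isnan(x) else "NA" for x in mat.matrix[i])
            fh.write(f"{pid}\t{row}\n")


def _write_windows(records, path: Path) -> None:
    cols = [
        "gene_id",
        "population_id",
        "position",
        "snp_class",
        "window_start",
        "window_end",
        "n_masked_in_window",
        "window_pi",
        "excluded",
        "exclusion_reason",
        "truncated",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    _fmt(int(v)) if isinstance(v, bool) else _fmt(v)
                    for v in (getattr(r, c) for c in cols)
                )
                + "\n"
            )


def _write_comparisons(results, path: Path) -> None:
    cols = ["comparison", "statistic", "population_id", "n1", "n2", "U", "p", "median_1", "median_2", "direction", "tier"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in cols) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return (and write) the output manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: dict[str, str] = {}

    if cfg.input_dir is not None:
        logger.info("stage simulate: skipped, loading bundle from %s", cfg.input_dir)
        bundle = read_bundle(cfg.input_dir)
    else:
        study_cfg = study_config_from_options(cfg.simulate)
        logger.info(
            "stage simulate: %d populations x %d genes, seed %d",
            len(study_cfg.populations),
            len(study_cfg.genes),
            cfg.seed,
        )
        bundle = build_study(study_cfg, seed=cfg.seed)
        write_bundle(bundle, out / "bundle")

    filter_cfg = FilterConfig(min_depth=cfg.min_depth, maf_min=cfg.maf_min)
    result = analyze_bundle(
        bundle, filter_cfg, half_width=cfg.half_width, max_masked=cfg.max_masked
    )
    for key, val in result.counters.items():
        logger.info("counter %s = %d", key, val)

    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for pop in bundle.populations:
        pid = pop.population_id
        _write_stats([r for r in result.stats_records if r.population_id == pid], stats_dir / f"{pid}.tsv")

    # per-gene site-class audit table
    with open(out / "site_counts.tsv", "w") as fh:
        fh.write("population_id\tgene_id\tL_total\tL_syn\tL_nonsyn\tL_noncoding\n")
        for r in result.stats_records:
            fh.write(
                f"{r.population_id}\t{r.gene_id}\t{_fmt(r.L_total)}\t{_fmt(r.L_syn)}"
                f"\t{_fmt(r.L_nonsyn)}\t{_fmt(r.L_noncoding)}\n"
            )

    if len(bundle.populations) >= 2:
        fst_dir = out / "fst"
        fst_dir.mkdir(exist_ok=True)
        n_by_pop = {p.population_id: p.n_alleles for p in bundle.populations}
        for ann in bundle.genes:
            gid = ann.gene_id
            mat = fst_matrix(
                gid,
                {p.population_id: result.masked_tables[(p.population_id, gid)] for p in bundle.populations},
                {p.population_id: result.snps[(p.population_id, gid)] for p in bundle.populations},
                n_by_pop,
            )
            _write_fst(mat, fst_dir / f"{gid}.tsv")
    else:
        notes["fst"] = "absent: needs at least 2 populations"
        logger.info("stage fst: %s", notes["fst"])

    windows_dir = out / "windows"
    windows_dir.mkdir(exist_ok=True)
    for pop in bundle.populations:
        pid = pop.population_id
        _write_windows([r for r in result.window_records if r.population_id == pid], windows_dir / f"{pid}.tsv")
    result.window_summary.to_csv(out / "window_strata.tsv", sep="\t", index=False)

    gene_classes = {a.gene_class for a in bundle.genes}
    comparisons = []
    if gene_classes >= {"candidate", "reference"}:
        comparisons.extend(
            compare_gene_classes(result.stats_records, bundle.genes, mode=cfg.compare_mode)
        )
        comparisons.extend(compare_window_strata(result.window_long))
    if comparisons:
        _write_comparisons(comparisons, out / "comparisons.tsv")
    else:
        notes["comparisons"] = "absent: needs both candidate and reference genes"
        logger.info("stage compare: %s", notes.get("comparisons", ""))

    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "counters": result.counters,
        "notes": notes,
        "files": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d output files", len(files))
    return manifest
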