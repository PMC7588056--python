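"""End-to-end orchestration: simulate-or-load, scan, select, genotype,
trees, Ks classification, and truth/reference comparison.

Every stage persists its artifact (window TSV, block BED, genotype TSV,
newick trees, Ks matrix TSV) so any step can be audited or rerun in
isolation, and the machine-readable run report only contains numbers that
are re-derivable from those files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import MultipleAlignment
from .ks import ks_distance_matrix
from .markers import (blocks_to_bed, build_genotype_matrix, collect_blocks,
                      select_blocks)
from .popgen import window_scan, window_stats_frame
from .simulate import (SimulationTruth, default_region_plan, evolve_alignment,
                       evolve_codon_genes, simulate_species_tree)
from .trees import (bootstrap_support, hamming_distance_matrix,
                    neighbor_joining, read_newick, robinson_foulds, upgma,
                    write_newick)

logger = logging.getLogger("plastomarkers.pipeline")

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

_DEFAULTS: dict = {
    "mode": "synthetic",
    # synthetic-mode simulation parameters
    "n_ingroup": 16,
    "n_clades": 4,
    "depth": 0.05,
    "total_length": 50_000,
    "neutral_fraction": 0.2,
    "n_neutral_regions": 4,
    "neutral_rate": 0.1,
    "constrained_rate": 0.02,
    "terminal_bias": 0.95,
    "boundary_gap_run": 10,
    "tree_seed": 1,
    "seed": 42,
    "n_genes": 57,
    "syn_rate": 2.0,
    "nonsyn_rate": 0.4,
    "gene_length": 300,
    # real-mode inputs
    "alignment_fasta": None,
    "genes_dir": None,
    "reference_tree": None,
    "genbank_dir": None,
    # scan / selection
    "window": 500,
    "step": 100,
    "max_gap_fraction": 0.2,
    "min_usable": 100,
    "block_min_length": 150,
    "block_max_gap_fraction": 0.1,
    "d_threshold": -0.5,
    "d_upper": None,
    # Ks
    "ks_method": "histogram",
    "ks_binwidth": 0.005,
    "run_ks": True,
    # trees
    "tree_builder": "nj",
    "n_bootstrap": 1000,
    # output
    "out_dir": "results/pipeline",
}

_RANGES = {
    "max_gap_fraction": (0.0, 1.0),
    "block_max_gap_fraction": (0.0, 1.0),
    "neutral_fraction": (0.0, 1.0),
    "terminal_bias": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``_DEFAULTS`` for the full key set)."""

    values: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def __getattr__(self, name):
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)


class ConfigError(ValueError):
    pass


def _validate_values(values: dict) -> PipelineConfig:
    violations = []
    unknown = set(values) - set(_DEFAULTS)
    if unknown:
        violations.append(f"unknown keys: {sorted(unknown)}")
    merged = dict(_DEFAULTS)
    merged.update({k: v for k, v in values.items() if k in _DEFAULTS})
    for key in ("depth", "window", "step", "n_bootstrap", "total_length",
                "n_ingroup", "n_clades", "n_genes", "gene_length"):
        v = merged[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or v <= 0:
            violations.append(f"{key} must be a positive number (got {v!r})")
    for key in ("d_threshold",):
        if not isinstance(merged[key], (int, float)) or isinstance(merged[key], bool):
            violations.append(f"{key} must be a number (got {merged[key]!r})")
    for key, (lo, hi) in _RANGES.items():
        v = merged[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or not (lo <= v <= hi):
            violations.append(f"{key} must lie in [{lo}, {hi}] (got {v!r})")
    if merged["mode"] not in ("synthetic", "real"):
        violations.append(f"mode must be 'synthetic' or 'real' (got {merged['mode']!r})")
    if merged["tree_builder"] not in ("nj", "upgma"):
        violations.append(f"tree_builder must be 'nj' or 'upgma'")
    if isinstance(merged.get("window"), (int, float)) and \
       isinstance(merged.get("step"), (int, float)) and \
       not (merged["window"] >= merged["step"] >= 1):
        violations.append("require window >= step >= 1")
    if merged["mode"] == "real" and not merged["alignment_fasta"]:
        violations.append("real mode requires alignment_fasta")
    if violations:
        raise ConfigError("; ".join(violations))
    for key in ("alignment_fasta", "genes_dir", "reference_tree", "genbank_dir"):
        if merged[key] is not None:
            merged[key] = str(Path(merged[key]).expanduser())
    return PipelineConfig(values=merged)


def validate_config(path: str | Path | dict) -> PipelineConfig:
    """Load and validate a YAML config (or an in-memory dict); fills
    defaults, checks ranges, rejects unknown keys, and reports *all*
    violations at once."""
    if isinstance(path, dict):
        return _validate_values(path)
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return _validate_values(raw)


@dataclass
class RunReport:
    config: dict
    version: str
    stage_counts: dict
    selection: dict | None = None
    rf_to_reference: dict | None = None
    ks_nearest_neighbors: dict | None = None
    truth_recovery: dict | None = None
    timings_s: dict = field(default_factory=dict)

    def write_json(self, path: str | Path, include_timings: bool = True) -> None:
        payload = asdict(self)
        if not include_timings:
            payload.pop("timings_s")
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, persisting intermediate artifacts under
    ``config.out_dir``. Synthetic mode additionally records truth-recovery
    metrics (selected-column regime purity and RF to the true tree)."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    report = RunReport(config=dict(cfg.values), version=__version__,
                       stage_counts=counts, timings_s=timings)

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("[%s] start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("[%s] failed: %s", name, exc)
                else:
                    logger.info("[%s] done in %.2fs", name, timings[name])
                return False
        return _T()

    truth: SimulationTruth | None = None
    reference_tree = None
    gene_sets = None
    gene_names = None

    with stage("input"):
        if cfg.mode == "synthetic":
            tree = simulate_species_tree(cfg.n_ingroup, cfg.n_clades, cfg.depth,
                                         seed=cfg.tree_seed)
            plan = default_region_plan(
                total_length=cfg.total_length,
                neutral_fraction=cfg.neutral_fraction,
                n_neutral_regions=cfg.n_neutral_regions,
                neutral_rate=cfg.neutral_rate,
                constrained_rate=cfg.constrained_rate,
                terminal_bias=cfg.terminal_bias,
            )
            aln, truth = evolve_alignment(tree, plan, seed=cfg.seed,
                                          boundary_gap_run=cfg.boundary_gap_run)
            aln.write_fasta(out / "alignment.fasta")
            truth.write_json(out / "truth.json")
            truth.write_bed(out / "truth_regions.bed")
            (out / "true_tree.nwk").write_text(tree.newick_string + "\n")
            reference_tree = tree.tree()
        else:
            aln = MultipleAlignment.read_fasta(cfg.alignment_fasta)
            if cfg.reference_tree:
                reference_tree = read_newick(cfg.reference_tree)
        counts["alignment_taxa"] = aln.n_taxa
        counts["alignment_columns"] = aln.length

    with stage("scan"):
        windows = window_scan(aln, cfg.window, cfg.step,
                              cfg.max_gap_fraction, cfg.min_usable)
        df = window_stats_frame(windows)
        header = (f"# window={cfg.window} step={cfg.step} "
                  f"max_gap_fraction={cfg.max_gap_fraction} min_usable={cfg.min_usable}\n")
        with open(out / "window_stats.tsv", "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
        counts["windows"] = len(windows)

    with stage("select"):
        blocks = collect_blocks(aln, cfg.block_min_length, cfg.block_max_gap_fraction)
        selected = select_blocks(blocks, cfg.d_threshold, cfg.d_upper)
        blocks_to_bed(blocks, out / "blocks.bed")
        blocks_to_bed(selected, out / "selected_blocks.bed")
        counts["blocks"] = len(blocks)
        counts["blocks_selected"] = len(selected)

    with stage("genotype"):
        gm, sel_report = build_genotype_matrix(aln, selected, cfg.d_threshold)
        sel_report.params = {
            "block_min_length": cfg.block_min_length,
            "block_max_gap_fraction": cfg.block_max_gap_fraction,
            "d_threshold": cfg.d_threshold,
            "d_upper": cfg.d_upper,
        }
        gm.write_tsv(out / "genotype_matrix.tsv")
        sel_report.write_json(out / "selection_report.json")
        counts["segregating_sites"] = gm.n_sites
        report.selection = {
            "n_blocks_selected": sel_report.n_blocks_selected,
            "total_length": sel_report.total_length,
            "n_segregating": sel_report.n_segregating,
        }

    with stage("tree"):
        boot = bootstrap_support(gm, cfg.tree_builder, cfg.n_bootstrap, seed=cfg.seed)
        write_newick(boot, out / f"genotype_{cfg.tree_builder}_bootstrap.nwk")
        cluster = upgma(hamming_distance_matrix(gm))
        write_newick(cluster, out / "genotype_upgma.nwk")
        point = neighbor_joining(hamming_distance_matrix(gm))
        write_newick(point, out / "genotype_nj.nwk")

    with stage("compare"):
        if reference_tree is not None:
            rf, norm = robinson_foulds(point, reference_tree)
            report.rf_to_reference = {"rf": rf, "normalized": norm,
                                      "builder": "nj"}
        if truth is not None:
            labels = np.asarray(truth.region_labels)
            purity = float(np.mean([labels[c] == "neutral" for _, c in gm.sites]))
            report.truth_recovery = {
                "selected_neutral_column_fraction": purity,
                "n_selected_columns": gm.n_sites,
            }

    with stage("ks"):
        if cfg.mode == "synthetic" and cfg.run_ks:
            gd = evolve_codon_genes(
                simulate_species_tree(cfg.n_ingroup, cfg.n_clades, cfg.depth,
                                      seed=cfg.tree_seed),
                n_genes=cfg.n_genes, syn_rate=cfg.syn_rate,
                nonsyn_rate=cfg.nonsyn_rate, gene_length=cfg.gene_length,
                seed=cfg.seed,
            )
            gene_sets, gene_names = gd.gene_sets, gd.gene_names
        elif cfg.mode == "real" and cfg.genes_dir:
            gene_sets, gene_names = _load_gene_dir(cfg.genes_dir)
        else:
            logger.warning("[ks] no gene inputs; Ks stage skipped")
        if gene_sets is not None:
            km = ks_distance_matrix(gene_sets, gene_names,
                                    cfg.ks_method, cfg.ks_binwidth)
            km.to_frame().to_csv(out / "modal_ks_matrix.tsv", sep="\t")
            report.ks_nearest_neighbors = km.nearest_neighbors()
            counts["ks_genes"] = len(gene_names)

    report.write_json(out / "run_report.json")
    return report


def _load_gene_dir(directory: str | Path):
    """Per-gene codon-alignment FASTAs -> per-species gene sets."""
    from .simulate import SimulatedGeneSet

    directory = Path(directory)
    per_species: dict[str, dict[str, str]] = {}
    gene_names = []
    for path in sorted(directory.glob("*.fasta")):
        gene = path.stem
        gene_names.append(gene)
        aln = MultipleAlignment.read_fasta(path)
        for i, taxon in enumerate(aln.taxa):
            per_species.setdefault(taxon, {})[gene] = aln.row(i)
    gene_sets = [SimulatedGeneSet(sp, genes) for sp, genes in sorted(per_species.items())]
    return gene_sets, gene_names
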