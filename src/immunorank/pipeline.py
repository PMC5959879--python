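"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes, in order: survival preprocessing, subtype
assignment, subtype aggregation, hybrid gene selection, clustering and the
heat-map split, the batch survival screen on the upper portion (log-rank
p < 0.05), immune density scoring and CD14 scores, and (optionally) the
mouse-pattern and cross-species stages.  Every intermediate is written as
TSV under the output directory and the run report records stage timings,
output hashes and all effective parameters, so identical configs and seeds
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    cluster_structure,
    core_io,
    gene_selection,
    immunome,
    mouse_patterns,
    subtypes,
    survival,
    synthetic,
)

log = logging.getLogger("immunorank")


@dataclass
class PipelineConfig:
    """All stage parameters and toggles of a pipeline run."""

    out_dir: str = "immunorank_out"
    seed: int = 0
    # synthetic cohort (used when no input files are given)
    n_samples: int = 200
    n_genes: int = 300
    noise_sd: float = 0.5
    zero_rate: float = 0.02
    planted_hr: float = 2.0
    coupling: float = 0.9
    # input files (optional; synthetic when absent)
    expression_path: str | None = None
    clinical_path: str | None = None
    centroid_path: str | None = None
    signature_path: str | None = None
    # stage parameters
    selection: gene_selection.SelectionParams = field(
        default_factory=gene_selection.SelectionParams
    )
    scan_window: tuple[int, int] | None = None
    scan_tolerance: int = 3
    survival_alpha: float = 0.05
    # stage toggles
    run_clustering: bool = True
    run_mouse: bool = False
    explicit_survival_genes: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sel = raw.pop("selection", None)
        cfg = cls(**raw)
        if sel:
            cfg.selection = gene_selection.SelectionParams(**sel)
        return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the structured run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": _config_dict(config), "outputs": {}}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                status = "failed" if exc_type else "completed"
                report["stages"][name] = {
                    "status": status,
                    "seconds": round(time.perf_counter() - self.t0, 3),
                }
                log.info("stage %s: %s", name, status)
                return False

        return _Timer()

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", na_rep="NA")
        report["outputs"][name] = _hash_file(path)

    try:
        # --- inputs -------------------------------------------------------
        with _stage("inputs"):
            if config.expression_path:
                matrix = core_io.read_expression_table(config.expression_path)
                centroids = core_io.read_centroid_table(config.centroid_path)
                raw_clin = core_io.read_clinical_table(config.clinical_path)
                clinical, _disc = survival.preprocess_survival(raw_clin)
                sig_matrix, signature = matrix, core_io.read_signature_file(
                    config.signature_path
                )
                labels = None
            else:
                matrix, labels, centroids, _truth = synthetic.generate_cohort(
                    n_samples=config.n_samples,
                    n_genes=config.n_genes,
                    noise_sd=config.noise_sd,
                    zero_rate=config.zero_rate,
                    seed=config.seed,
                )
                sig_matrix, signature, _sig_truth = synthetic.generate_signature_cohort(
                    n_samples=config.n_samples,
                    coupling=config.coupling,
                    seed=config.seed + 1,
                )
                cd14 = sig_matrix.values.loc["CD14|929"]
                clinical = synthetic.generate_survival(
                    cd14, hr=config.planted_hr, seed=config.seed + 2
                )
            core_io.write_expression_table(matrix, out / "expression.tsv")
            report["outputs"]["expression"] = _hash_file(out / "expression.tsv")

        # --- subtypes -----------------------------------------------------
        with _stage("subtype_assignment"):
            assignment = subtypes.assign_subtypes(matrix, centroids)
            _write(
                "subtype_assignments",
                assignment.correlations.assign(label=assignment.labels),
            )
            agg = subtypes.aggregate_subtypes(matrix, assignment.labels)
            classes = subtypes.aggregate_classes(assignment.labels, agg.aggregates)

        # --- gene selection ----------------------------------------------
        with _stage("gene_selection"):
            g1 = [s for s in matrix.samples if classes[s] == 0]
            g2 = [s for s in matrix.samples if classes[s] == 1]
            selection = gene_selection.hybrid_select(
                matrix, g1, g2, config.selection
            )
            _write("gene_selection", selection.table)
            selected_rows = [
                i
                for i, k in enumerate(matrix.gene_keys())
                if selection.table["selected"].iloc[i]
            ]

        # --- clustering / split ------------------------------------------
        if config.run_clustering and len(selected_rows) >= 8:
            with _stage("clustering"):
                sub = matrix.subset_genes(selected_rows)
                cm = cluster_structure.log_center(sub, mode="mean")
                cm = cluster_structure.hierarchical_order(cm, axes="rows")
                n_sel = len(selected_rows)
                window = config.scan_window or (
                    max(0, n_sel // 2 - n_sel // 8),
                    min(n_sel - 1, n_sel // 2 + n_sel // 8),
                )
                split = cluster_structure.heatmap_split(
                    cm, assignment.labels, window=window,
                    tolerance=config.scan_tolerance,
                )
                ordered_keys = [sub.gene_keys()[i] for i in cm.row_order]
                _write(
                    "heatmap_split",
                    pd.DataFrame(
                        {"delta_cb_ps": split.delta.to_numpy()},
                        index=split.delta.index,
                    ),
                )
                if split.no_split:
                    upper_genes = [ordered_keys[i] for i in range(n_sel)]
                else:
                    upper_genes = [ordered_keys[i] for i in split.upper]
        else:
            report["stages"]["clustering"] = {"status": "skipped", "seconds": 0.0}
            upper_genes = config.explicit_survival_genes or [
                matrix.gene_keys()[i] for i in selected_rows
            ]

        # --- batch survival screen ---------------------------------------
        n_significant = None
        with _stage("batch_survival"):
            if upper_genes:
                screen = survival.batch_gene_survival(
                    matrix, clinical.aligned(matrix.samples), list(dict.fromkeys(upper_genes))
                )
                survival.write_screen_table(screen, out / "survival_screen.tsv")
                report["outputs"]["survival_screen"] = _hash_file(
                    out / "survival_screen.tsv"
                )
                n_significant = int(
                    (screen.table["logrank_p"] < config.survival_alpha).sum()
                )
        if n_significant is not None:
            report["stages"]["batch_survival"]["n_significant"] = n_significant

        # --- immunome -----------------------------------------------------
        with _stage("immunome"):
            density = immunome.density_scores(sig_matrix, signature)
            _write("density_scores", density.scores)
            cd14_row = None
            for i, g in enumerate(sig_matrix.genes):
                if g.symbol == "CD14" or g.entrez == 929:
                    cd14_row = i
                    break
            if cd14_row is not None and set(immunome.CD14_CELL_TYPES) <= set(
                density.scores.columns
            ):
                cd14_vals = sig_matrix.values.iloc[cd14_row]
                table = immunome.cd14_scores(
                    density,
                    cd14_vals,
                    clinical.aligned(density.scores.index),
                )
                _write("cd14_scores", table.table)
            corr = immunome.celltype_correlations(density)
            _write("celltype_correlations", corr.matrix)

        # --- mouse patterns (optional) -----------------------------------
        if config.run_mouse:
            with _stage("mouse_patterns"):
                mouse, _mt = synthetic.generate_mouse_arrays(seed=config.seed + 3)
                sel = mouse_patterns.select_pattern_genes(mouse)
                _write("mouse_pattern_selection", sel.table)
        else:
            report["stages"]["mouse_patterns"] = {"status": "skipped", "seconds": 0.0}
    except Exception as exc:  # stage failure: keep partial outputs
        report["error"] = f"{type(exc).__name__}: {exc}"
        raise

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
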