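"""End-to-end pipeline: chains the stages and writes per-stage outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import diversity as div
from . import growth as gr
from . import models, otu
from .config import PipelineConfig
from .containers import OtuTable
from .core import compare_cores, core_by_period
from .io import (read_fastq, read_growth_table, read_otu_table, write_fastq,
                 write_otu_table)
from .qc import filter_reads
from .simulate import SimParams, generate_design, generate_otu_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig,
                 otu_path=None, metadata_path=None,
                 growth_path=None, fastq_path=None,
                 simulate: bool = False) -> dict:
    """Run every stage on the given inputs (or a simulated dataset).

    Writes TSV/JSON outputs per stage under ``config.output_dir`` plus a
    run log recording the seed and full configuration; returns a dict of
    in-memory stage results. Identical config and seed give identical
    outputs. Any stage failure raises :class:`StageError` naming the
    stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                logger.info("running stage %s", name)
                results[name] = fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        return deco

    table: OtuTable | None = None

    if fastq_path is not None:
        @stage("qc")
        def _qc():
            kept, stats = filter_reads(
                read_fastq(fastq_path),
                threshold=config.quality_threshold,
                max_bad_run=config.max_bad_run,
                min_fraction=config.min_fraction)
            write_fastq(kept, out / "reads_kept.fastq")
            payload = {"n_input": stats.n_input, "n_kept": stats.n_kept,
                       "n_failed": stats.n_failed,
                       "retention_rate": stats.retention_rate}
            (out / "qc_stats.json").write_text(json.dumps(payload, indent=2))
            return stats

    if simulate:
        @stage("simulate")
        def _simulate():
            params = SimParams(seed=config.seed)
            design = generate_design(params)
            tbl, truth = generate_otu_table(design, params)
            write_otu_table(tbl, out / "simulated_otu_table.tsv",
                            out / "simulated_metadata.tsv")
            truth["library_sizes"].to_csv(out / "truth_library_sizes.tsv",
                                          sep="\t")
            return tbl
        table = results["simulate"]
    elif otu_path is not None:
        @stage("read")
        def _read():
            return read_otu_table(otu_path, metadata_path)
        table = results["read"]

    if table is not None:
        @stage("filter")
        def _filter():
            filtered = otu.filter_otus(table, config.min_total,
                                       config.min_samples)
            write_otu_table(filtered, out / "filtered_table.tsv")
            return filtered
        filtered = results["filter"]

        @stage("normalize")
        def _normalize():
            norm = otu.css_normalize(filtered, config.css_quantile,
                                     config.css_scale)
            _write_tsv(norm.values, out / "normalized_table.tsv")
            return norm
        norm = results["normalize"]

        @stage("core")
        def _core():
            cores = core_by_period(filtered, config.core_prevalence)
            for period, cs in cores.items():
                _write_tsv(cs.entries, out / f"core_{period}.tsv")
            comparison = compare_cores(cores["pre"], cores["post"])
            (out / "core_comparison.json").write_text(
                json.dumps(comparison, indent=2))
            return {"cores": cores, "comparison": comparison}

        @stage("diversity")
        def _diversity():
            alpha = div.alpha_table(filtered, norm)
            _write_tsv(alpha, out / "alpha_indices.tsv")
            adjusted = div.baseline_adjust(alpha, filtered.metadata)
            _write_tsv(adjusted, out / "alpha_adjusted.tsv")
            fits = {}
            for index in alpha.columns:
                fit = models.fit_repeated_model(
                    adjusted[index], filtered.metadata,
                    factors=("treatment", "period"))
                fits[index] = {
                    "p_treatment": fit.terms.loc["treatment", "p_value"],
                    "p_weaning": fit.terms.loc["period", "p_value"],
                }
            _write_tsv(pd.DataFrame.from_dict(fits, orient="index"),
                       out / "alpha_models.tsv")
            return {"alpha": alpha, "adjusted": adjusted, "models": fits}

        @stage("betadiv")
        def _betadiv():
            dm = div.bray_curtis(norm)
            _write_tsv(pd.DataFrame(dm.data, index=list(dm.ids),
                                    columns=list(dm.ids)),
                       out / "bray_curtis.tsv")
            coords, stress = div.nmds(dm, seed=config.seed)
            _write_tsv(coords, out / "nmds.tsv")
            meta = norm.metadata
            tests = {
                "treatment": div.permanova(dm, meta["treatment"],
                                           config.n_permutations,
                                           config.seed),
                "weaning": div.permanova(dm, meta["period"],
                                         config.n_permutations, config.seed),
                "treatment_by_period": div.permanova(
                    dm, meta["treatment"].astype(str) + "/"
                    + meta["period"].astype(str),
                    config.n_permutations, config.seed),
            }
            (out / "permanova.json").write_text(
                json.dumps({"stress": stress, "tests": tests}, indent=2))
            return {"distance": dm, "nmds": coords, "stress": stress,
                    "permanova": tests}

        @stage("fit")
        def _fit():
            tests = models.per_otu_tests(norm, config.significance_alpha)
            _write_tsv(tests, out / "per_otu_tests.tsv", index=False)
            return tests

        @stage("fb")
        def _fb():
            fb = models.fb_ratio(norm)
            _write_tsv(fb, out / "fb_ratio.tsv")
            fit = models.fb_model(fb, norm.metadata)
            _write_tsv(fit.terms, out / "fb_model.tsv")
            return {"fb": fb, "fit": fit}

        @stage("bootstrap")
        def _bootstrap():
            boot = models.bootstrap_fb(norm, n_boot=config.n_bootstrap,
                                       seed=config.seed)
            _write_tsv(boot.replicate_terms, out / "bootstrap_replicates.tsv")
            _write_tsv(boot.term_summary, out / "bootstrap_terms.tsv")
            _write_tsv(boot.cell_summary, out / "bootstrap_cells.tsv",
                       index=False)
            return boot

    if growth_path is not None:
        @stage("growth")
        def _growth():
            records = read_growth_table(growth_path)
            summary, pvals = gr.group_summary(records)
            _write_tsv(summary, out / "growth_summary.tsv")
            if pvals is not None:
                _write_tsv(pvals.rename("p_value").to_frame(),
                           out / "growth_pvalues.tsv")
            return {"summary": summary, "pvalues": pvals}

    (out / "run_log.json").write_text(json.dumps(
        {"seed": config.seed, "config": asdict(config),
         "stages": sorted(results)}, indent=2))
    return results
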