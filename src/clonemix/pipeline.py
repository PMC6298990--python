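"""End-to-end run: mixture fit -> outlier screen -> cohort statistics.

Produces CSV outputs (genotypes, fractions, outlier calls, cohort tests,
correlation matrix) and a plain-markdown summary. Runs are fully determined
by the input files and configuration; any stage failure aborts the run,
removing partial outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import io as io_mod
from . import mixture as mixture_mod
from . import outliers as outliers_mod
from .outliers import MixingLine

log = logging.getLogger("clonemix")

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline", "read_lines_config"]


@dataclass
class RunConfig:
    measurements: str
    panel: str
    metadata: str | None = None
    lines: str | None = None
    anchor: str = mixture_mod.DEFAULT_ANCHOR_MARKER
    anchor_values: tuple[float, float] = mixture_mod.DEFAULT_ANCHOR_VALUES
    fraction_gene: str | None = None
    z_threshold: float = outliers_mod.DEFAULT_Z_THRESHOLD
    d_threshold: float = outliers_mod.DEFAULT_D_THRESHOLD
    alpha: float = 0.05
    outdir: str = "deconstruct_out"
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.d_threshold <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "anchor_values" in doc:
            doc["anchor_values"] = tuple(float(v) for v in doc["anchor_values"])
        return cls(**doc)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_lines_config(path) -> list[MixingLine]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("lines", doc)
    return [
        MixingLine(
            x_marker=str(d["x_marker"]),
            y_marker=str(d["y_marker"]),
            endpoint_a=tuple(float(v) for v in d["endpoint_a"]),
            endpoint_b=tuple(float(v) for v in d["endpoint_b"]),
        )
        for d in doc
    ]


def _genotype_frame(calls) -> pd.DataFrame:
    rows = []
    for gene in sorted(calls.subclone1.loci):
        r1, r2 = calls.residuals.get(gene, (math.nan, math.nan))
        rows.append(
            {
                "gene": gene,
                "subclone1_mutant": calls.subclone1.loci[gene].mutant_copies,
                "subclone1_total": calls.subclone1.loci[gene].total_copies,
                "subclone1_mean_cn": calls.subclone1.mean_cn.get(gene, math.nan),
                "subclone1_residual": r1,
                "subclone2_mutant": calls.subclone2.loci[gene].mutant_copies,
                "subclone2_total": calls.subclone2.loci[gene].total_copies,
                "subclone2_mean_cn": calls.subclone2.mean_cn.get(gene, math.nan),
                "subclone2_residual": r2,
                "assumed_diploid": gene in calls.assumed_diploid,
                "cn_only": gene in calls.cn_only,
            }
        )
    return pd.DataFrame(rows)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a dict of in-memory results and output paths."""
    logging.basicConfig(
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage = "read_inputs"
    try:
        panel = io_mod.read_panel(config.panel)
        table = io_mod.read_measurements(config.measurements, panel)
        if config.metadata:
            metadata = io_mod.read_sample_metadata(config.metadata)
            table = table.with_metadata(metadata)
        log.info(
            "inputs: %d samples x %d markers; anchor=%s at %s; z>%g, D>%g, alpha=%g; seed=%d",
            len(table.samples),
            len(table.markers),
            config.anchor,
            config.anchor_values,
            config.z_threshold,
            config.d_threshold,
            config.alpha,
            config.seed,
        )

        stage = "mixture_fit"
        fit = mixture_mod.fit_two_subclone_model(
            table,
            anchor=config.anchor,
            anchor_values=config.anchor_values,
            fraction_gene=config.fraction_gene,
        )
        geno_df = _genotype_frame(fit.genotype_calls)
        emit("genotypes.csv", lambda p: geno_df.to_csv(p, index=False))
        emit(
            "fractions.csv",
            lambda p: fit.fractions.rename_axis("sample_id").to_csv(p, na_rep="NA"),
        )

        stage = "outliers"
        lines = read_lines_config(config.lines) if config.lines else None
        calls = outliers_mod.classify_outliers(
            table,
            mixing_lines=lines,
            z_threshold=config.z_threshold,
            d_threshold=config.d_threshold,
        )
        emit("outliers.csv", lambda p: calls.calls.rename_axis("sample_id").to_csv(p))

        stage = "cohort_analysis"
        corr = cohort_mod.correlation_matrix(table)
        emit("corr.csv", lambda p: corr.r.rename_axis("marker_id").to_csv(p, na_rep="NA"))
        emit(
            "corr_pvalues.csv",
            lambda p: corr.p.rename_axis("marker_id").to_csv(p, na_rep="NA"),
        )
        tests = cohort_mod.cohort_differential_tests(table, alpha=config.alpha)
        tests_df = pd.DataFrame([dataclasses.asdict(t) for t in tests])
        emit("tests.csv", lambda p: tests_df.to_csv(p, index=False))
        prevalence = cohort_mod.prevalence_by_cohort(fit, table.samples)

        stage = "report"
        summary = _summary_text(config, table, fit, calls, corr, tests, prevalence)
        emit("summary.md", lambda p: p.write_text(summary, encoding="utf-8"))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return {
        "table": table,
        "fit": fit,
        "outliers": calls,
        "correlations": corr,
        "tests": tests,
        "prevalence": prevalence,
        "outputs": {p.name: p for p in written},
    }


def _summary_text(config, table, fit, calls, corr, tests, prevalence) -> str:
    lines = ["# Subclone deconstruction summary", ""]
    lines.append(
        f"- inputs: {len(table.samples)} samples x {len(table.markers)} markers"
    )
    lines.append(
        f"- anchor: {config.anchor} at AF {config.anchor_values}; "
        f"thresholds |z| > {config.z_threshold}, D > {config.d_threshold}, "
        f"alpha = {config.alpha}; seed = {config.seed}"
    )
    lines += ["", "## Subclone genotypes (mutant/total per locus)", ""]
    for gene in sorted(fit.subclone1.loci):
        a, b = fit.subclone1.loci[gene], fit.subclone2.loci[gene]
        note = " (assumed diploid)" if gene in fit.genotype_calls.assumed_diploid else ""
        lines.append(
            f"- {gene}: subclone 1 = {a.mutant_copies}/{a.total_copies}, "
            f"subclone 2 = {b.mutant_copies}/{b.total_copies}{note}"
        )
    lines += ["", "## Mixing fractions", ""]
    frac = fit.fractions.dropna()
    if len(frac):
        lines.append(
            f"- subclone-1 fraction: mean {frac.mean():.3f}, "
            f"range [{frac.min():.3f}, {frac.max():.3f}] over {len(frac)} samples"
        )
    for cohort, mean in sorted(prevalence.items()):
        lines.append(f"- mean prevalence, {cohort}: {mean:.3f}")
    lines += ["", "## Outliers", ""]
    lines.append(
        f"- flagged samples: {calls.n_flagged} of {len(table.samples)}; "
        f"max dimensions per sample: {calls.max_dims_per_sample}; "
        f"distinct patterns: {calls.n_patterns}"
    )
    lines += ["", "## Headline correlations", ""]
    r = corr.r
    pairs = [
        (a, b)
        for i, a in enumerate(r.index)
        for b in r.columns[i + 1 :]
        if np.isfinite(r.loc[a, b])
    ]
    for a, b in sorted(pairs, key=lambda ab: -abs(r.loc[ab[0], ab[1]]))[:5]:
        lines.append(f"- r({a}, {b}) = {r.loc[a, b]:+.3f}")
    sig = [t for t in tests if t.significant]
    lines += ["", f"## Cohort tests: {len(sig)} significant at q <= {config.alpha}", ""]
    for t in sig[:10]:
        lines.append(
            f"- {t.marker_id}: {t.cohort_a} vs {t.cohort_b}, "
            f"t = {t.welch_t:+.2f}, p = {t.p_value:.2e}, q = {t.q_value:.3g}"
        )
    return "\n".join(lines) + "\n"
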