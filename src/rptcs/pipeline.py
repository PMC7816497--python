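"""End-to-end analysis pipeline with logged provenance.

Stages, in cohort-analysis order: inclusion filters -> Kaplan-Meier curves
and smoothed hazards -> univariable Cox screen -> multivariable Cox fits ->
conditional-survival matrix, CS3 series, stratified series and standardized
differences.  Every table is written to the output directory and listed in
a manifest with content hashes; identical configuration and seed give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .cohort_io import apply_inclusion_filters, read_case_listing, write_case_listing
from .conditional import (
    CS3Series,
    cs3_series,
    conditional_matrix,
    d_series,
    stratified_cs3,
)
from .cox import fit_cox, univariable_screen
from .survival import km_curve, median_followup, smoothed_hazard

log = logging.getLogger("rptcs")

__all__ = ["PipelineConfig", "run_pipeline", "render_conditional_matrix", "render_cs3_table"]

_DEFAULT_OS_COVARIATES = (
    "age_group",
    "sex",
    "marital_status",
    "fnclcc_grade",
    "size_class",
    "multifocality",
    "histology",
    "chemotherapy",
)
_DEFAULT_CSS_COVARIATES = tuple(
    c for c in _DEFAULT_OS_COVARIATES if c != "marital_status"
)
_DEFAULT_SCREEN_COVARIATES = _DEFAULT_OS_COVARIATES + (
    "race",
    "radiation",
    "chemoradiotherapy",
    "extent_of_resection",
)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a case-listing CSV) or ``simulation``
    (a :class:`~rptcs.synthetic.SimulationConfig`) supplies the cohort;
    with neither set, the calibrated default simulation is used.
    """

    input_path: str | None = None
    simulation: synthetic.SimulationConfig | None = None
    endpoints: tuple[str, ...] = ("OS", "CSS")
    os_covariates: tuple[str, ...] = _DEFAULT_OS_COVARIATES
    css_covariates: tuple[str, ...] = _DEFAULT_CSS_COVARIATES
    screen_covariates: tuple[str, ...] = _DEFAULT_SCREEN_COVARIATES
    cs_window: int = 3
    x_max: int = 5
    stratify_factors: tuple[str, ...] = ("fnclcc_grade", "chemotherapy")
    comparisons: dict[str, tuple[tuple[str, str], ...]] = field(
        default_factory=lambda: {
            "fnclcc_grade": (("I", "III"),),
            "chemotherapy": (("no", "yes"),),
        }
    )
    hazard_bandwidth: float = 12.0
    outdir: str = "rptcs_out"
    seed: int = 0
    percent_decimals: int = 1
    d_decimals: int = 2
    make_plots: bool = False

    def model_covariates(self, endpoint: str) -> tuple[str, ...]:
        return self.os_covariates if endpoint == "OS" else self.css_covariates


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_conditional_matrix(matrix, decimals: int = 1) -> pd.DataFrame:
    """Table-layout rendering: one-decimal percents, an exact ``100``
    diagonal, blank cells where the conditional is undefined."""
    tab = matrix.table
    out = pd.DataFrame(index=tab.index, columns=tab.columns, dtype=object)
    for total in tab.index:
        for x in tab.columns:
            v = tab.loc[total, x]
            if pd.isna(v):
                out.loc[total, x] = ""
            elif x == total:
                out.loc[total, x] = "100"
            else:
                out.loc[total, x] = f"{v:.{decimals}f}"
    return out


def render_cs3_table(
    pooled: dict[str, CS3Series],
    stratified: dict[str, dict[str, CS3Series]],
    differences: dict[str, dict],
    x_max: int,
    percent_decimals: int = 1,
    d_decimals: int = 2,
) -> pd.DataFrame:
    """Stratified CS3 + standardized-difference table, one row per level
    and one signed-d row per comparison, per endpoint."""
    xs = list(range(x_max + 1))
    rows = []

    def pct_row(endpoint, variable, level, series):
        row = {"endpoint": endpoint, "variable": variable, "level": level}
        for x in xs:
            row[f"x{x}"] = (
                f"{series.at(x):.{percent_decimals}f}" if x in series.x_years else ""
            )
        return row

    for endpoint, pooled_series in pooled.items():
        rows.append(pct_row(endpoint, "Overall", "", pooled_series))
        for factor, by_level in stratified[endpoint].items():
            for level, series in by_level.items():
                rows.append(pct_row(endpoint, factor, str(level), series))
            for (a, b), seq in differences[endpoint].get(factor, {}).items():
                row = {
                    "endpoint": endpoint,
                    "variable": factor,
                    "level": f"d ({a} vs. {b})",
                }
                values = dict(seq)
                for x in xs:
                    row[f"x{x}"] = (
                        f"{values[x].d:.{d_decimals}f}" if x in values else ""
                    )
                rows.append(row)
    return pd.DataFrame(rows, columns=["endpoint", "variable", "level"] + [f"x{x}" for x in xs])


def _cox_payload(fit) -> dict:
    return {
        "endpoint": fit.endpoint,
        "ties_method": fit.ties_method,
        "n_events": fit.n_events,
        "log_partial_likelihood": fit.log_partial_likelihood,
        "converged": fit.converged,
        "warnings": fit.warnings,
        "terms": [t.__dict__ for t in fit.terms],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    Any stage failure aborts with the stage name; tables already written
    are left in place for inspection.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    outputs: list[Path] = []
    stage = "load"
    try:
        if config.input_path is not None:
            cohort = read_case_listing(config.input_path)
        else:
            sim = config.simulation or synthetic.default_config()
            sim = sim.replace(seed=config.seed)
            cohort = synthetic.generate_cohort(sim)
        manifest["stages"]["load"] = {"n": len(cohort)}
        log.info("load: %d records", len(cohort))

        stage = "filter"
        cohort, report = apply_inclusion_filters(cohort)
        path = outdir / "cohort.csv"
        write_case_listing(cohort, path)
        outputs.append(path)
        report.to_json(outdir / "attrition.json")
        outputs.append(outdir / "attrition.json")
        manifest["stages"]["filter"] = {
            "n": len(cohort),
            "excluded": report.n_input - report.n_output,
        }
        log.info("filter: %d retained", len(cohort))

        stage = "kaplan-meier"
        curves = {}
        for endpoint in config.endpoints:
            curve = km_curve(cohort, endpoint)
            curves[endpoint] = curve
            path = outdir / f"km_{endpoint.lower()}.csv"
            curve.to_frame().to_csv(path, index=False)
            outputs.append(path)
            hz = smoothed_hazard(cohort, endpoint, config.hazard_bandwidth)
            path = outdir / f"hazard_{endpoint.lower()}.csv"
            pd.DataFrame({"time": hz.grid_times, "hazard": hz.hazard}).to_csv(
                path, index=False
            )
            outputs.append(path)
        manifest["stages"]["kaplan-meier"] = {
            "median_followup_months": median_followup(cohort)
        }

        stage = "cox"
        for endpoint in config.endpoints:
            screen = univariable_screen(cohort, config.screen_covariates, endpoint)
            path = outdir / f"univariable_{endpoint.lower()}.json"
            path.write_text(
                json.dumps(
                    [
                        {
                            "covariate": r.covariate,
                            "significant": r.significant,
                            "fit": _cox_payload(r.fit),
                        }
                        for r in screen
                    ],
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
            outputs.append(path)
            fit = fit_cox(cohort, config.model_covariates(endpoint), endpoint)
            path = outdir / f"cox_{endpoint.lower()}.json"
            path.write_text(json.dumps(_cox_payload(fit), indent=2, sort_keys=True) + "\n")
            outputs.append(path)
            fit.to_frame().to_csv(outdir / f"cox_{endpoint.lower()}.csv", index=False)
            outputs.append(outdir / f"cox_{endpoint.lower()}.csv")
        manifest["stages"]["cox"] = {"endpoints": list(config.endpoints)}

        stage = "conditional-survival"
        pooled, stratified, differences = {}, {}, {}
        for endpoint in config.endpoints:
            max_total = config.x_max + config.cs_window
            available = int(curves[endpoint].max_time // 12)
            if max_total > available:
                warnings.warn(
                    f"{endpoint} follow-up supports only {available} total years; "
                    f"conditional matrix truncated from {max_total}",
                    stacklevel=2,
                )
                log.warning(
                    "%s conditional matrix truncated to %d years", endpoint, available
                )
                max_total = max(available, 1)
            matrix = conditional_matrix(curves[endpoint], max_total)
            path = outdir / f"cs_matrix_{endpoint.lower()}.csv"
            render_conditional_matrix(matrix, config.percent_decimals).to_csv(path)
            outputs.append(path)
            pooled[endpoint] = cs3_series(curves[endpoint], config.x_max, config.cs_window)
            stratified[endpoint] = {}
            differences[endpoint] = {}
            for factor in config.stratify_factors:
                per_level = stratified_cs3(
                    cohort, factor, endpoint, config.x_max, config.cs_window
                )
                stratified[endpoint][factor] = per_level
                pairs = config.comparisons.get(factor, ())
                if pairs:
                    differences[endpoint][factor] = d_series(
                        per_level, pooled[endpoint], pairs
                    )
        table = render_cs3_table(
            pooled,
            stratified,
            differences,
            config.x_max,
            config.percent_decimals,
            config.d_decimals,
        )
        path = outdir / "cs3_table.csv"
        table.to_csv(path, index=False)
        outputs.append(path)
        manifest["stages"]["conditional-survival"] = {
            "x_max": config.x_max,
            "window": config.cs_window,
        }

        if config.make_plots:
            stage = "plots"
            _make_plots(outdir, curves, cohort, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in outputs}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _make_plots(outdir: Path, curves, cohort, config: PipelineConfig) -> None:
    """KM and hazard figures; presentation artifacts only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for endpoint, curve in curves.items():
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        ax1.step(
            [0, *curve.event_times], [1.0, *curve.survival], where="post"
        )
        ax1.set(xlabel="months", ylabel=f"{endpoint} probability", ylim=(0, 1.02))
        hz = smoothed_hazard(cohort, endpoint, config.hazard_bandwidth)
        ax2.plot(hz.grid_times, hz.hazard)
        ax2.set(xlabel="months", ylabel="hazard per month")
        fig.tight_layout()
        fig.savefig(outdir / f"fig_{endpoint.lower()}.png", dpi=120)
        plt.close(fig)
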