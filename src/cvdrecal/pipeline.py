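"""End-to-end study orchestration: score, validate, recalibrate, validate.

Runs the two-component external-validation design on a (usually
synthetic) multi-region cohort: predictions from a universal
non-laboratory model are validated per region and overall, then
recalibrated — either against a single super-region external parameter
table, or empirically within each region — and validated again.  The
report mirrors the shape of a regional validation table: one row per
region x sex x stage plus combined (meta) and overall rows.

All randomness flows from one top-level seed through named sub-streams,
and a re-run with the same config byte-reproduces the metrics CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .cohort import (
    DEFINITION_WEIGHTS,
    SEXES,
    apply_eligibility_filters,
    default_regions,
    default_truth,
    first_event_outcome,
    generate_cohort,
    read_cohort,
    regions_from_config,
    truth_from_config,
)
from .metrics import (
    ConcordanceResult,
    calibration_table,
    harrell_c,
    nam_dagostino,
    po_ratio,
    pool_c_indices,
)
from .recalibration import (
    DEFAULT_AGE_BANDS,
    StratumScheme,
    estimate_recalibration_table,
    load_recalibration_table,
    recalibrate,
)
from .risk import RiskModel, default_model, score_cohort

__all__ = [
    "StudyConfig",
    "ValidationReport",
    "run_study",
    "outcome_definition_sensitivity",
    "render_report",
]

OUTCOME_DEFINITIONS = ("total_cvd", "coronary_only", "stroke_only")


@dataclass
class StudyConfig:
    """Everything needed to reproduce one validation study."""

    seed: int = 0
    cohort_source: str = "simulate"  # "simulate" | "file"
    cohort_csv: str | None = None
    n_per_region: int = 2000
    regions: list | None = None  # list of dicts (RegionSpec schema); None -> defaults
    truth: dict | None = None  # TrueHazardSpec overrides; None -> defaults
    model_file: str | None = None  # None -> illustrative default model
    recalibration_mode: str = "per_region_empirical"  # | "external_table"
    table_file: str | None = None
    vintage: str = "2017"
    outcome_definition: str = "total_cvd"
    definition_variant: str = "recalibration_process"
    t0: float = 10.0
    n_groups: int = 10
    age_bands: tuple = DEFAULT_AGE_BANDS
    combine_rule: str = "complement_product"
    nd_df_mode: str = "groups"
    out_dir: str = "results/study"

    def validate(self) -> None:
        if self.cohort_source not in ("simulate", "file"):
            raise ValueError("cohort_source must be 'simulate' or 'file'")
        if self.cohort_source == "file" and not self.cohort_csv:
            raise ValueError("cohort_source='file' needs cohort_csv")
        if self.recalibration_mode not in ("external_table", "per_region_empirical"):
            raise ValueError(f"unknown recalibration_mode: {self.recalibration_mode!r}")
        if self.recalibration_mode == "external_table" and not self.table_file:
            raise ValueError("recalibration_mode='external_table' needs table_file")
        if self.outcome_definition not in OUTCOME_DEFINITIONS:
            raise ValueError(f"unknown outcome definition: {self.outcome_definition!r}")
        if self.definition_variant not in DEFINITION_WEIGHTS:
            raise ValueError(f"unknown definition variant: {self.definition_variant!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_bands"] = [list(b) for b in self.age_bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "age_bands" in d:
            d["age_bands"] = tuple(tuple(b) for b in d["age_bands"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    """Per-stratum metrics for both stages, plus pooled rows and metadata."""

    metrics: pd.DataFrame
    calibration: pd.DataFrame
    exclusions: dict[str, int]
    concordance: dict[tuple[str, str, str], ConcordanceResult]
    meta: dict
    config: StudyConfig


class StageError(RuntimeError):
    """An error in a named pipeline stage, with stratum context where known."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def _sub_seed(seed: int, stream: str) -> int:
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@_stage("cohort")
def _obtain_cohort(config: StudyConfig) -> pd.DataFrame:
    if config.cohort_source == "file":
        return read_cohort(config.cohort_csv)
    regions = regions_from_config(config.regions) if config.regions else default_regions()
    truth = truth_from_config(config.truth) if config.truth else default_truth()
    return generate_cohort(
        regions, truth, config.n_per_region, _sub_seed(config.seed, "simulation")
    )


def _strata_iter(cohort: pd.DataFrame):
    for sex in SEXES:
        for region in sorted(cohort["region_id"].unique()):
            yield region, sex, (cohort["region_id"] == region) & (cohort["sex"] == sex)
        yield "overall", sex, cohort["sex"] == sex


@_stage("validate")
def _validate_stage(
    cohort: pd.DataFrame,
    outcome: pd.DataFrame,
    predictions: pd.DataFrame,
    stage: str,
    config: StudyConfig,
):
    metric_rows, calib_rows = [], []
    concordance = {}
    time = outcome["time"].to_numpy()
    event = outcome["event"].to_numpy()
    risk = predictions["p_total"].to_numpy()
    for region, sex, mask in _strata_iter(cohort):
        m = mask.to_numpy()
        t, e, p = time[m], event[m], risk[m]
        try:
            cres = harrell_c(t, e, p)
        except ValueError as exc:
            raise StageError(f"stage 'validate' ({region}, {sex}, {stage}): {exc}") from exc
        concordance[(region, sex, stage)] = cres
        po = po_ratio(t, e, p, config.t0)
        tab = calibration_table(t, e, p, config.t0, config.n_groups)
        nd = nam_dagostino(tab, df_mode=config.nd_df_mode)
        metric_rows.append(
            dict(
                region=region, sex=sex, stage=stage, n=int(m.sum()),
                events=int(e.sum()), c=cres.c, c_lo=cres.ci_lo, c_hi=cres.ci_hi,
                c_var=cres.variance, po_ratio=po, nd_chi2=nd.chi2, nd_df=nd.df,
                nd_p=nd.p_value, nd_merged=nd.n_merged,
            )
        )
        tab = tab.assign(region=region, sex=sex, stage=stage)
        calib_rows.append(tab)
    return metric_rows, pd.concat(calib_rows, ignore_index=True), concordance


@_stage("recalibrate")
def _recalibrate_stage(config, cohort, predictions):
    if config.recalibration_mode == "external_table":
        table = load_recalibration_table(config.table_file)
    else:
        scheme = StratumScheme(age_bands=config.age_bands, by_region=True)
        table = estimate_recalibration_table(
            cohort, predictions, scheme, t0=config.t0,
            provenance=f"empirical-{config.vintage}",
            subtype_weights=DEFINITION_WEIGHTS[config.definition_variant],
        )
    return recalibrate(predictions, table, cohort, config.combine_rule), table


def run_study(config: StudyConfig) -> ValidationReport:
    """Execute the full before/after validation study for one config."""
    config.validate()

    raw = _obtain_cohort(config)
    cohort, exclusions = apply_eligibility_filters(raw)
    cohort = cohort.reset_index(drop=True)

    outcome = first_event_outcome(
        cohort, config.outcome_definition, DEFINITION_WEIGHTS[config.definition_variant]
    )

    model = RiskModel.load(config.model_file) if config.model_file else default_model()
    predictions = score_cohort(cohort, model, config.combine_rule)

    rows_before, calib_before, conc_before = _validate_stage(
        cohort, outcome, predictions, "uncalibrated", config
    )
    recalibrated, _table = _recalibrate_stage(config, cohort, predictions)
    rows_after, calib_after, conc_after = _validate_stage(
        cohort, outcome, recalibrated, "recalibrated", config
    )

    metrics = pd.DataFrame(rows_before + rows_after)
    concordance = {**conc_before, **conc_after}

    # combined (meta) row per sex and stage: DL pooling of regional C indices
    pooled_rows = []
    regions = [r for r in metrics["region"].unique() if r != "overall"]
    if len(regions) >= 2:
        for stage in ("uncalibrated", "recalibrated"):
            for sex in SEXES:
                per_region = [concordance[(r, sex, stage)] for r in regions]
                pooled = pool_c_indices(per_region)
                sub = metrics[
                    (metrics.sex == sex) & (metrics.stage == stage)
                    & (metrics.region != "overall")
                ]
                pooled_rows.append(
                    dict(
                        region="combined_meta", sex=sex, stage=stage,
                        n=int(sub["n"].sum()), events=int(sub["events"].sum()),
                        c=pooled.c, c_lo=pooled.ci_lo, c_hi=pooled.ci_hi,
                        c_var=pooled.variance, po_ratio=np.nan, nd_chi2=np.nan,
                        nd_df=np.nan, nd_p=np.nan, nd_merged=np.nan,
                        tau2=pooled.tau2,
                    )
                )
    metrics = pd.concat([metrics, pd.DataFrame(pooled_rows)], ignore_index=True)
    calibration = pd.concat([calib_before, calib_after], ignore_index=True)

    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_raw": len(raw),
        "n_analysed": len(cohort),
    }
    return ValidationReport(
        metrics=metrics,
        calibration=calibration,
        exclusions=exclusions,
        concordance=concordance,
        meta=meta,
        config=config,
    )


def outcome_definition_sensitivity(
    config: StudyConfig, variants: list[str]
) -> tuple[dict[str, ValidationReport], pd.DataFrame]:
    """Re-run the study under alternative outcome definitions.

    Each variant is either an outcome definition (``total_cvd``,
    ``coronary_only``, ``stroke_only``) or a definition-variant label
    (``recalibration_process``, ``derivation_process``, ``ckb``) that
    changes the subtype inclusion weights.  Returns per-variant reports
    and a side-by-side summary of the overall rows.
    """
    if not variants:
        raise ValueError("need at least one outcome-definition variant")
    reports: dict[str, ValidationReport] = {}
    summaries = []
    for label in variants:
        cfg = dataclasses.replace(config)
        if label in OUTCOME_DEFINITIONS:
            cfg.outcome_definition = label
        elif label in DEFINITION_WEIGHTS:
            cfg.definition_variant = label
        else:
            raise ValueError(f"unknown outcome-definition variant: {label!r}")
        report = reports[label] = run_study(cfg)
        overall = report.metrics[report.metrics.region == "overall"].copy()
        overall.insert(0, "variant", label)
        summaries.append(overall)
    return reports, pd.concat(summaries, ignore_index=True)


# ---------------------------------------------------------------------------
# reporting


def _plot_calibration(sub: pd.DataFrame, region: str, sex: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    for stage, marker in (("uncalibrated", "o"), ("recalibrated", "s")):
        s = sub[sub.stage == stage]
        ax.plot(s["mean_predicted"], s["observed_risk"], marker, ms=4, label=stage)
    lim = max(0.02, sub[["mean_predicted", "observed_risk"]].to_numpy().max() * 1.1)
    ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="ideal")
    ax.set_xlabel("mean predicted 10-year risk")
    ax.set_ylabel("observed 10-year risk (KM)")
    ax.set_title(f"{region}, {sex}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _table2_markdown(metrics: pd.DataFrame) -> str:
    lines = []
    for sex in SEXES:
        lines.append(f"\n### {sex.capitalize()}\n")
        lines.append("| Region | Cases | C before (95% CI) | C after (95% CI) | P/O before | P/O after |")
        lines.append("|---|---|---|---|---|---|")
        sub = metrics[metrics.sex == sex]
        order = [r for r in sub.region.unique() if r not in ("overall", "combined_meta")]
        order += [r for r in ("combined_meta", "overall") if r in set(sub.region)]
        for region in order:
            b = sub[(sub.region == region) & (sub.stage == "uncalibrated")].iloc[0]
            a = sub[(sub.region == region) & (sub.stage == "recalibrated")].iloc[0]
            po_b = "" if pd.isna(b.po_ratio) else f"{b.po_ratio:.3f}"
            po_a = "" if pd.isna(a.po_ratio) else f"{a.po_ratio:.3f}"
            lines.append(
                f"| {region} | {b.events} | {b.c:.3f} ({b.c_lo:.3f}-{b.c_hi:.3f}) "
                f"| {a.c:.3f} ({a.c_lo:.3f}-{a.c_hi:.3f}) | {po_b} | {po_a} |"
            )
    return "\n".join(lines)


def render_report(report: ValidationReport, out_dir=None) -> list[Path]:
    """Write metrics/calibration CSVs, per-stratum plots and a summary.

    Idempotent: re-rendering overwrites, and the CSVs are byte-identical
    across runs of the same config.
    """
    out = Path(out_dir if out_dir is not None else report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    metrics_path = out / "metrics.csv"
    report.metrics.to_csv(metrics_path, index=False, float_format="%.10g")
    written.append(metrics_path)

    calib_path = out / "calibration.csv"
    report.calibration.to_csv(calib_path, index=False, float_format="%.10g")
    written.append(calib_path)

    excl_path = out / "exclusions.csv"
    pd.DataFrame(
        [{"reason": k, "n_excluded": v} for k, v in report.exclusions.items()]
    ).to_csv(excl_path, index=False)
    written.append(excl_path)

    for (region, sex), sub in report.calibration.groupby(["region", "sex"]):
        p = out / f"calibration_{region}_{sex}.svg"
        _plot_calibration(sub, region, sex, p)
        written.append(p)

    lock_path = out / "config.lock.yaml"
    with open(lock_path, "w") as fh:
        yaml.safe_dump({"config": report.config.to_dict(), "meta": report.meta}, fh,
                       sort_keys=True)
    written.append(lock_path)

    md = [
        "# Validation report",
        "",
        f"- config hash: `{report.meta['config_hash']}`",
        f"- seed: {report.meta['seed']}; software version: {report.meta['version']}",
        f"- participants analysed: {report.meta['n_analysed']} of {report.meta['n_raw']}"
        f" (excluded: {report.exclusions})",
        _table2_markdown(report.metrics),
        "",
    ]
    md_path = out / "report.md"
    md_path.write_text("\n".join(md))
    written.append(md_path)
    return written
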