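"""End-to-end study pipeline.

Mirrors the analysis flow of a cross-sectional diet-quality study: load or
simulate a cohort, exclude participants with missing exposure (diet) or
outcome (depressive-symptom) data, score the diet index and the HPL scale,
describe the sample by diet-score quartile, fit the two covariate-adjusted
Quade ANCOVA models plus a complete-case sensitivity model, and run
quantile regression at the configured quantiles.  Everything is
deterministic given the run seed; outputs are CSV tables plus a structured
JSON metadata/report file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import ancova as _ancova
from .ancova import AncovaResult, impute_covariates, quartile_groups, run_ancova
from .cohort import generate_cohort, inject_missingness, read_cohort_csv, write_cohort_csv
from .config import SyntheticConfig
from .diet_score import INTAKE_COLUMNS, compute_hnds
from .hpl import HPL_ITEM_COLUMNS, score_hpl
from .quantreg import DEFAULT_TAUS, QuantRegResult, fit_quantile

__all__ = [
    "RunConfig",
    "StudyReport",
    "apply_exclusions",
    "score_cohort",
    "descriptives_by_quartile",
    "run_study",
]

_CONTINUOUS_DESCRIPTIVES = (
    "age", "bmi", "energy_kj", "ltpa_kj", "ses", "ethanol", "hpl_total",
)
_CATEGORICAL_DESCRIPTIVES = ("smoking", "marital", "cvd_history", "mental_illness_history", "hpl_case")

# ordinal level order where alphabetical sorting would scramble it (the
# linear-by-linear trend test scores rows by position)
_CATEGORY_ORDER = {"smoking": ("never", "previous", "current")}


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    synthetic: SyntheticConfig | None = None
    csv_path: str | None = None
    models: tuple[str, ...] = ("model1", "model2")
    taus: tuple[float, ...] = DEFAULT_TAUS
    n_bootstrap: int = 1000
    seed: int = 0
    output_dir: str = "study_output"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.csv_path is None):
            raise ValueError("exactly one input mode: set synthetic config OR csv_path")
        self.models = tuple(self.models)
        self.taus = tuple(self.taus)
        for t in self.taus:
            if not 0.0 < t < 1.0:
                raise ValueError(f"tau must be in (0, 1), got {t}")


@dataclass
class StudyReport:
    """Machine-readable record of one study run."""

    n_loaded: int
    n_excluded: int
    n_analyzed: int
    quartile_sizes: dict[int, int]
    imputations: dict[str, int]
    descriptives: pd.DataFrame
    ancova: dict[str, AncovaResult]
    sensitivity: AncovaResult | None
    n_complete_cases: int
    quantreg: list[QuantRegResult]
    provenance: dict = field(default_factory=dict)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records with missing diet components or missing HPL outcome.

    Covariate missingness is NOT an exclusion criterion (it is handled by
    single-value imputation later).  Returns the retained cohort and the
    number excluded.
    """
    diet_missing = cohort.loc[:, list(INTAKE_COLUMNS)].isna().any(axis=1)
    hpl_missing = cohort.loc[:, list(HPL_ITEM_COLUMNS)].isna().any(axis=1)
    keep = ~(diet_missing | hpl_missing)
    return cohort.loc[keep].copy(), int((~keep).sum())


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach diet-score points, HNDS total, HPL total/case columns."""
    scored = pd.concat([cohort, compute_hnds(cohort), score_hpl(cohort)], axis=1)
    scored["hnds_quartile"] = quartile_groups(scored["hnds_total"])
    return scored


def descriptives_by_quartile(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sample characteristics by diet-score quartile, with univariate tests.

    Continuous variables: per-quartile mean and SD, and a linear-regression
    p-value (variable on quartile index).  Categorical variables:
    per-quartile percentages, a chi-squared test p and a Mantel-Haenszel
    style linear-by-linear association p.  Quartiles with no participants
    are reported as absent.
    """
    groups = cohort["hnds_quartile"].to_numpy()
    levels = sorted(pd.unique(groups))
    single = len(levels) < 2
    rows = []

    for var in _CONTINUOUS_DESCRIPTIVES:
        if var not in cohort.columns:
            continue
        vals = pd.to_numeric(cohort[var], errors="coerce")
        row = {"variable": var, "kind": "continuous"}
        for g in levels:
            sel = vals[groups == g]
            row[f"q{g}_mean"] = float(sel.mean())
            row[f"q{g}_sd"] = float(sel.std(ddof=1)) if len(sel) > 1 else np.nan
        if single or vals.dropna().nunique() < 2:
            row["p_linear"] = np.nan
        else:
            ok = vals.notna()
            row["p_linear"] = float(
                stats.linregress(groups[ok.to_numpy()], vals[ok].to_numpy()).pvalue
            )
        rows.append(row)

    for var in _CATEGORICAL_DESCRIPTIVES:
        if var not in cohort.columns:
            continue
        vals = cohort[var]
        if var in _CATEGORY_ORDER:
            cats = [c for c in _CATEGORY_ORDER[var] if c in set(vals.dropna())]
        else:
            cats = sorted(vals.dropna().unique(), key=str)
        for cat in cats:
            row = {"variable": f"{var}={cat}", "kind": "categorical"}
            for g in levels:
                sel = vals[groups == g].dropna()
                row[f"q{g}_pct"] = 100.0 * float((sel == cat).mean()) if len(sel) else np.nan
            rows.append(row)
        # tests on the full contingency table (rows in ordinal order)
        table = pd.crosstab(vals, pd.Series(groups, index=cohort.index, name="q"))
        table = table.reindex([c for c in cats if c in table.index])
        if single or table.shape[0] < 2 or table.shape[1] < 2:
            p_chi2 = p_mh = np.nan
        else:
            p_chi2 = float(stats.chi2_contingency(table.to_numpy())[1])
            p_mh = _linear_by_linear_p(table)
        for row in rows[-len(cats):]:
            row["p_chi2"] = p_chi2
            row["p_mantel_haenszel"] = p_mh
    return pd.DataFrame(rows)


def _linear_by_linear_p(table: pd.DataFrame) -> float:
    """Mantel-Haenszel linear-by-linear association test (integer scores)."""
    counts = table.to_numpy(dtype=float)
    r_scores = np.arange(1, counts.shape[0] + 1, dtype=float)
    c_scores = np.asarray(table.columns, dtype=float)
    n = counts.sum()
    obs = np.outer(r_scores, c_scores)
    r = _pearson_from_counts(counts, r_scores, c_scores)
    m2 = (n - 1) * r * r
    return float(stats.chi2.sf(m2, df=1))


def _pearson_from_counts(counts, r_scores, c_scores) -> float:
    n = counts.sum()
    pr = counts.sum(axis=1) / n
    pc = counts.sum(axis=0) / n
    mr = (r_scores * pr).sum()
    mc = (c_scores * pc).sum()
    sr = np.sqrt(((r_scores - mr) ** 2 * pr).sum())
    sc = np.sqrt(((c_scores - mc) ** 2 * pc).sum())
    cov = (counts * np.outer(r_scores - mr, c_scores - mc)).sum() / n
    if sr == 0 or sc == 0:
        return 0.0
    return cov / (sr * sc)


def _ancova_to_dict(res: AncovaResult) -> dict:
    return {
        "model": res.model,
        "quade_F": res.quade_F,
        "quade_p": res.quade_p,
        "df": list(res.df),
        "extreme_diff": res.extreme_diff,
        "extreme_ci": list(res.extreme_ci),
        "extreme_p": res.extreme_p,
        "p_trend": res.p_trend,
        "adjusted_means": res.adjusted_means.to_dict(orient="records"),
    }


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full analysis chain and write all outputs.

    Stages: load/simulate -> exclusions -> scoring -> descriptives ->
    covariate imputation -> Quade ANCOVA per model -> complete-case
    sensitivity (final model) -> quantile regression (complete cases).
    Any stage failure aborts with a stage-labelled diagnostic and removes
    partial outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_study_inner(config, outdir, written)
    except Exception as exc:
        for p in written:
            if p.exists():
                p.unlink()
        raise


def _run_study_inner(config: RunConfig, outdir: Path, written: list[Path]) -> StudyReport:
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stage = "load"
    try:
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            cohort = inject_missingness(generate_cohort(syn), syn)
            log(f"simulated cohort: n={len(cohort)} (seed {config.seed})")
        else:
            cohort = read_cohort_csv(config.csv_path)
            log(f"loaded cohort from {config.csv_path}: n={len(cohort)}")
        n_loaded = len(cohort)

        stage = "exclusions"
        cohort, n_excluded = apply_exclusions(cohort)
        log(f"excluded {n_excluded} records with missing diet or HPL data; "
            f"{len(cohort)} retained")
        if cohort.empty:
            log("WARNING: no participants remain after exclusions")

        stage = "scoring"
        scored = score_cohort(cohort)
        qsizes = scored["hnds_quartile"].value_counts().sort_index().to_dict()
        log(f"quartile sizes: {qsizes}")

        stage = "descriptives"
        desc = descriptives_by_quartile(scored)

        stage = "imputation"
        complete_mask = scored["ltpa_kj"].notna() & scored["marital"].notna()
        n_complete = int(complete_mask.sum())
        imputed, imput_counts = impute_covariates(scored)
        log(f"imputed covariates: {imput_counts} (complete cases n={n_complete})")

        stage = "ancova"
        ancova_results = {m: run_ancova(imputed, imputed["hnds_quartile"], covariate_set=m)
                          for m in config.models}
        for m, res in ancova_results.items():
            log(f"{m}: Quade F={res.quade_F:.3f} p={res.quade_p:.4f} "
                f"extreme diff={res.extreme_diff:.3f} "
                f"CI=({res.extreme_ci[0]:.3f}, {res.extreme_ci[1]:.3f}) "
                f"p_trend={res.p_trend:.4f}")

        stage = "sensitivity"
        sensitivity = None
        if config.models:
            final = config.models[-1]
            cc = imputed.loc[complete_mask]
            if cc["hnds_quartile"].nunique() >= 2:
                sensitivity = run_ancova(cc, cc["hnds_quartile"], covariate_set=final)
                sensitivity.model = f"{final}_complete_case"
                log(f"sensitivity ({final}, complete cases n={len(cc)}): "
                    f"extreme diff={sensitivity.extreme_diff:.3f}")
            else:
                log("WARNING: sensitivity analysis skipped (degenerate complete-case cohort)")

        stage = "quantreg"
        cc = imputed.loc[complete_mask]
        qr_results = [
            fit_quantile(cc, tau, "model2" if "model2" in config.models else config.models[-1],
                         n_bootstrap=config.n_bootstrap, seed=config.seed + 1)
            for tau in config.taus
        ]
        for res in qr_results:
            log(f"quantile tau={res.tau:g}: beta={res.beta_hnds:.4f} "
                f"CI=({res.ci_low:.4f}, {res.ci_high:.4f}) p={res.p_value:.4g}")

        stage = "report"
        report = StudyReport(
            n_loaded=n_loaded, n_excluded=n_excluded, n_analyzed=len(scored),
            quartile_sizes={int(k): int(v) for k, v in qsizes.items()},
            imputations=imput_counts, descriptives=desc, ancova=ancova_results,
            sensitivity=sensitivity, n_complete_cases=n_complete, quantreg=qr_results,
        )
        report.provenance = _provenance(config)
        _write_outputs(report, imputed, qr_results, outdir, written, log_lines, config)
        return report
    except Exception as exc:
        raise RuntimeError(f"study failed at stage '{stage}': {exc}") from exc


def _provenance(config: RunConfig) -> dict:
    from . import __version__

    cfg = {
        "seed": config.seed,
        "models": list(config.models),
        "taus": list(config.taus),
        "n_bootstrap": config.n_bootstrap,
        "input": "synthetic" if config.synthetic is not None else str(config.csv_path),
    }
    if config.synthetic is not None:
        cfg["synthetic"] = config.synthetic.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {"version": __version__, "config_hash": digest, **cfg}


def _write_outputs(report: StudyReport, scored: pd.DataFrame, qr_results,
                   outdir: Path, written: list[Path], log_lines, config: RunConfig) -> None:
    def _path(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    write_cohort_csv(scored, _path("scored_cohort.csv"))
    report.descriptives.to_csv(_path("descriptives_by_quartile.csv"), index=False)

    rows = []
    for res in list(report.ancova.values()) + ([report.sensitivity] if report.sensitivity else []):
        for rec in res.adjusted_means.to_dict(orient="records"):
            rows.append({"model": res.model, **rec})
    pd.DataFrame(rows).to_csv(_path("adjusted_means.csv"), index=False)

    summary = [
        {"model": res.model, "quade_F": res.quade_F, "quade_p": res.quade_p,
         "df_num": res.df[0], "df_den": res.df[1], "extreme_diff": res.extreme_diff,
         "extreme_ci_low": res.extreme_ci[0], "extreme_ci_high": res.extreme_ci[1],
         "extreme_p": res.extreme_p, "p_trend": res.p_trend}
        for res in list(report.ancova.values()) + ([report.sensitivity] if report.sensitivity else [])
    ]
    pd.DataFrame(summary).to_csv(_path("ancova_summary.csv"), index=False)

    qr_rows = []
    for res in qr_results:
        for term, est in res.coefficients.items():
            qr_rows.append({"tau": res.tau, "term": term, "estimate": float(est),
                            "ci_low": res.ci_low if term == "hnds_total" else np.nan,
                            "ci_high": res.ci_high if term == "hnds_total" else np.nan,
                            "p": res.p_value if term == "hnds_total" else np.nan})
    pd.DataFrame(qr_rows).to_csv(_path("quantile_regression.csv"), index=False)

    meta = {
        "provenance": report.provenance,
        "n_loaded": report.n_loaded,
        "n_excluded": report.n_excluded,
        "n_analyzed": report.n_analyzed,
        "n_complete_cases": report.n_complete_cases,
        "quartile_sizes": report.quartile_sizes,
        "imputations": report.imputations,
        "ancova": {m: _ancova_to_dict(r) for m, r in report.ancova.items()},
        "sensitivity": _ancova_to_dict(report.sensitivity) if report.sensitivity else None,
        "quantreg": [
            {"tau": r.tau, "beta_hnds": r.beta_hnds, "ci_low": r.ci_low,
             "ci_high": r.ci_high, "p_value": r.p_value, "n": r.n,
             "n_bootstrap": r.n_bootstrap}
            for r in qr_results
        ],
    }
    with open(_path("report.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    with open(_path("run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
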