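"""End-to-end pipeline: stratify → proxy validation → clinical association
→ optional drug repurposing, with per-subtype result tables and a run
manifest.

Subtype strata that are too small for a given analysis (e.g. a HER2 arm
with fewer than two patients in one group) are recorded as skipped rows in
the output tables rather than aborting the run; a genuine stage failure
(missing input, malformed data) aborts with the stage name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataValidationError, UbistratError
from . import io as uio
from .clinical import chi_square_independence, fit_negbin_glm, km_estimate, logrank_test
from .proxy import lfc_concordance, fit_gene_lfc, moderated_t, one_way_anova, welch_t_test, pooled_t_test
from .repurpose import build_query_signature, compare_ic50, connectivity_screen, significance_stars
from .stratify import GROUPS, SUBTYPES, UNCLASSIFIED, stratify_cohort


@dataclass
class RunConfig:
    """Paths, mode flags and thresholds for a pipeline run."""

    cohort_path: str
    out_dir: str
    expr_path: Optional[str] = None
    refs_path: Optional[str] = None
    ic50_path: Optional[str] = None
    ic50_reference: str = "tamoxifen"
    mode: str = "cn_usp10"
    three_group_survival: bool = False
    pooled_t: bool = False
    fdr: float = 0.05
    alpha: float = 0.05
    max_set: Optional[int] = 100
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fdr < 1 or not 0 < self.alpha < 1:
            raise DataValidationError("thresholds must lie in (0, 1)")
        if not Path(self.cohort_path).exists():
            raise DataValidationError(f"cohort file not found: {self.cohort_path}")
        for label, p in (
            ("expression", self.expr_path),
            ("reference-profile", self.refs_path),
            ("IC50", self.ic50_path),
        ):
            if p is not None and not Path(p).exists():
                raise DataValidationError(f"{label} file not found: {p}")


@dataclass
class ReportBundle:
    tables: dict = field(default_factory=dict)  # name → DataFrame
    manifest: dict = field(default_factory=dict)


class StageError(UbistratError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _subtype_frames(strat: pd.DataFrame):
    """Yield ('aggregate', all-classified) then each defined subtype."""
    classified = strat[strat["ubiq_group"] != UNCLASSIFIED]
    yield "aggregate", classified
    for st in SUBTYPES:
        yield st, classified[classified["subtype"] == st]


def _survival_rows(strat: pd.DataFrame, three_group: bool):
    rows, km_rows = [], []
    for name, sub in _subtype_frames(strat):
        groups = list(GROUPS) if three_group else ["high", "low"]
        sub = sub[sub["ubiq_group"].isin(groups)]
        ok = len(sub) and all((sub["ubiq_group"] == g).sum() >= 1 for g in groups)
        if not ok or sub["os_event"].sum() == 0 or sub["ubiq_group"].nunique() < 2:
            rows.append({"subtype": name, "n": len(sub), "chi2": np.nan,
                         "df": np.nan, "p": np.nan, "note": "skipped: insufficient data"})
            continue
        res = logrank_test(sub["os_time"], sub["os_event"], sub["ubiq_group"])
        rows.append({"subtype": name, "n": len(sub), "chi2": res.chi2,
                     "df": res.df, "p": res.p, "note": ""})
        for g in sorted(sub["ubiq_group"].unique()):
            arm = sub[sub["ubiq_group"] == g]
            curve = km_estimate(arm["os_time"], arm["os_event"])
            for t, s, r in zip(curve.event_times, curve.survival, curve.at_risk):
                km_rows.append({"subtype": name, "ubiq_group": g, "time": t,
                                "survival": s, "at_risk": r})
    return pd.DataFrame(rows), pd.DataFrame(km_rows)


def _chisq_rows(strat: pd.DataFrame, column: str):
    rows = []
    for name, sub in _subtype_frames(strat):
        sub = sub[sub[column].notna() & (sub[column].astype(str) != "unknown")]
        if len(sub) == 0:
            rows.append({"subtype": name, "n": 0, "chi2": np.nan, "df": np.nan,
                         "p": np.nan, "low_expected": "", "note": "skipped: no data"})
            continue
        table = pd.crosstab(sub["ubiq_group"], sub[column])
        table = table.loc[[g for g in GROUPS if g in table.index]]
        table = table.loc[:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append({"subtype": name, "n": len(sub), "chi2": np.nan, "df": np.nan,
                         "p": np.nan, "low_expected": "",
                         "note": "skipped: degenerate table"})
            continue
        res = chi_square_independence(table.to_numpy())
        rows.append({"subtype": name, "n": len(sub), "chi2": res.chi2, "df": res.df,
                     "p": res.p, "low_expected": str(res.low_expected).lower(),
                     "note": ""})
    return pd.DataFrame(rows)


def _nb_rows(strat: pd.DataFrame):
    rows = []
    for name, sub in _subtype_frames(strat):
        sub = sub[sub["positive_nodes"].notna()]
        counts = sub["positive_nodes"].to_numpy(int) if len(sub) else np.array([])
        enough = (
            len(sub) >= 10
            and sub["ubiq_group"].nunique() >= 2
            and "high" in set(sub["ubiq_group"])
            and counts.sum() > 0
        )
        if not enough:
            rows.append({"subtype": name, "level": "", "estimate": np.nan,
                         "std_error": np.nan, "z": np.nan, "p": np.nan,
                         "stars": "", "theta": np.nan,
                         "note": "skipped: insufficient data"})
            continue
        fit = fit_negbin_glm(counts, sub["ubiq_group"], baseline="high")
        label = {"intercept": "high (intercept)"}
        for lv in fit.coefficients:
            rows.append({
                "subtype": name, "level": label.get(lv, lv),
                "estimate": fit.coefficients[lv],
                "std_error": fit.std_errors[lv],
                "z": fit.z_values[lv], "p": fit.p_values[lv],
                "stars": significance_stars(fit.p_values[lv]),
                "theta": fit.theta, "note": "" if fit.converged else "not converged",
            })
    return pd.DataFrame(rows)


def _p27_rows(strat: pd.DataFrame, pooled: bool):
    rows = []
    ttest = pooled_t_test if pooled else welch_t_test
    for name, sub in _subtype_frames(strat):
        sub = sub[sub["p27"].notna()]
        ok = all((sub["ubiq_group"] == g).sum() >= 2 for g in GROUPS)
        if not ok:
            rows.append({"subtype": name, "n": len(sub), "F": np.nan,
                         "df_between": np.nan, "df_within": np.nan, "anova_p": np.nan,
                         "mean_high": np.nan, "mean_intermediate": np.nan,
                         "mean_low": np.nan, "t_high_vs_low": np.nan,
                         "t_p": np.nan, "note": "skipped: insufficient data"})
            continue
        res = one_way_anova(sub["p27"].to_numpy(float), sub["ubiq_group"].to_numpy())
        t, _, tp = ttest(
            sub.loc[sub["ubiq_group"] == "high", "p27"].to_numpy(float),
            sub.loc[sub["ubiq_group"] == "low", "p27"].to_numpy(float),
        )
        rows.append({"subtype": name, "n": len(sub), "F": res.F,
                     "df_between": res.df_between, "df_within": res.df_within,
                     "anova_p": res.p,
                     "mean_high": res.group_means.get("high", np.nan),
                     "mean_intermediate": res.group_means.get("intermediate", np.nan),
                     "mean_low": res.group_means.get("low", np.nan),
                     "t_high_vs_low": t, "t_p": tp, "note": ""})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis; writes all tables plus manifest.json."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    manifest = bundle.manifest
    manifest["config"] = {k: getattr(config, k) for k in vars(config)}
    manifest["versions"] = {
        "ubistrat": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest["seed"] = config.seed
    manifest["stages"] = []

    def stage(name):
        manifest["stages"].append(name)

    try:
        return _run_stages(config, bundle, stage, out_dir)
    except StageError as exc:
        manifest["failed_stage"] = exc.stage
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        raise


def _run_stages(config: RunConfig, bundle: ReportBundle, stage, out_dir: Path) -> ReportBundle:
    manifest = bundle.manifest

    # --- stratify -----------------------------------------------------
    stage("stratify")
    try:
        cohort = uio.read_cohort(config.cohort_path)
        expr = uio.read_expression(config.expr_path) if config.expr_path else None
        strat, counts = stratify_cohort(
            cohort, mode=config.mode,
            expr=expr if config.mode == "expression" else None,
        )
    except UbistratError as exc:
        raise StageError("stratify", exc) from exc
    n_total = len(strat)
    n_unclassified = int((strat["ubiq_group"] == UNCLASSIFIED).sum())
    manifest["rows"] = {
        "input": n_total,
        "classified": n_total - n_unclassified,
        "unclassified": n_unclassified,
    }
    bundle.tables["stratified_cohort"] = strat
    bundle.tables["group_counts"] = counts.reset_index()

    # --- proxy validation ---------------------------------------------
    stage("proxy_validation")
    try:
        bundle.tables["anova_p27"] = _p27_rows(strat, config.pooled_t)
        de_result = None
        if expr is not None:
            classified = strat[strat["ubiq_group"].isin(("high", "low"))]
            labels = classified["ubiq_group"].tolist()
            # signature DE oriented low-minus-high: positive lfc = higher in
            # the low-ubiquitination (SKP2-high) state
            de = fit_gene_lfc(expr.loc[:, classified["patient_id"]], labels)
            if de.attrs["groups"][0] != "low":
                de["lfc"] = -de["lfc"]
                de.attrs["groups"] = ("low", "high")
            de_result = moderated_t(de)
            bundle.tables["de_signature"] = de_result.table.reset_index()

            cn = strat["cn_skp2"].to_numpy(float)
            labels_b = np.where(cn >= 1, "cn_high", "cn_normal_low")
            de_b = fit_gene_lfc(expr.loc[:, strat["patient_id"]], labels_b)
            if de_b.attrs["groups"][0] != "cn_high":
                de_b["lfc"] = -de_b["lfc"]
            bundle.tables["de_skp2cn"] = moderated_t(de_b).table.reset_index()

            conc_rows = []
            for name, sub in _subtype_frames(strat):
                try:
                    conc = lfc_concordance(expr, sub)
                    conc_rows.append({"subtype": name, "n_patients": len(sub),
                                      "n_genes": conc.n_genes, "rho": conc.rho,
                                      "p": conc.p, "note": ""})
                except DataValidationError:
                    conc_rows.append({"subtype": name, "n_patients": len(sub),
                                      "n_genes": np.nan, "rho": np.nan, "p": np.nan,
                                      "note": "skipped: insufficient data"})
            bundle.tables["concordance"] = pd.DataFrame(conc_rows)
    except UbistratError as exc:
        raise StageError("proxy_validation", exc) from exc

    # --- clinical association -----------------------------------------
    stage("clinical_association")
    try:
        surv, km = _survival_rows(strat, config.three_group_survival)
        bundle.tables["survival_bygroup"] = surv
        bundle.tables["km_curves"] = km
        if "stage" in strat.columns:
            bundle.tables["stage_chisq"] = _chisq_rows(strat, "stage")
        if "grade" in strat.columns:
            bundle.tables["grade_chisq"] = _chisq_rows(strat, "grade")
        if "positive_nodes" in strat.columns:
            bundle.tables["nodes_nbfit"] = _nb_rows(strat)
    except UbistratError as exc:
        raise StageError("clinical_association", exc) from exc

    # --- drug repurposing ----------------------------------------------
    if config.refs_path is not None:
        stage("drug_repurposing")
        try:
            if de_result is None:
                raise DataValidationError(
                    "repurposing requires an expression matrix for the query signature"
                )
            refs = uio.read_reference_profiles(config.refs_path)
            query = build_query_signature(
                de_result, fdr_cutoff=config.fdr, max_set=config.max_set
            )
            results = connectivity_screen(
                query, refs, n_perm=config.n_perm, seed=config.seed,
                fdr_threshold=config.fdr,
            )
            bundle.tables["connectivity"] = pd.DataFrame(
                [vars(r) for r in results]
            ).sort_values(["score", "drug"]).reset_index(drop=True)
        except UbistratError as exc:
            raise StageError("drug_repurposing", exc) from exc

    if config.ic50_path is not None:
        stage("ic50")
        try:
            ic50 = uio.read_ic50(config.ic50_path)
            comp = compare_ic50(ic50, config.ic50_reference)
            pw = comp.pairwise.reset_index()
            pw["anova_F"] = comp.anova.F
            pw["anova_p"] = comp.anova.p
            bundle.tables["ic50_comparison"] = pw
        except UbistratError as exc:
            raise StageError("ic50", exc) from exc

    # --- write ----------------------------------------------------------
    for name, table in bundle.tables.items():
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
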