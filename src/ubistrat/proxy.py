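"""Proxy validation of the signature: p27 comparisons and LFC concordance.

Two lines of indirect evidence connect the copy-number signature to SKP2
activity.  First, p27 — the canonical SKP2 ubiquitination substrate — should
decrease monotonically from the high- to the low-ubiquitination group; this
is tested with a one-way ANOVA across the three groups and a two-sample t
test between the extremes.  Second, the genome-wide log fold changes between
the signature's high and low groups should correlate (Spearman) with the log
fold changes between SKP2 copy-number-high and -normal/low patients, since
both contrasts are surrogates for the same underlying SKP2 activity.

The differential-expression stage is an empirical-Bayes moderated t: per-gene
residual variances are shrunk toward a pooled prior whose degrees of freedom
d0 and scale s0² are estimated by method of moments on log s² using the
scaled-F marginal distribution of sample variances, and the moderated
statistic lfc / √(s̃² · v_c) is referred to a t distribution on df + d0
degrees of freedom.  Multiplicity is handled by Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DataValidationError


# ---------------------------------------------------------------------------
# classical tests

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise DataValidationError("values and groups must have equal length")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise DataValidationError("ANOVA needs at least 2 groups")
    chunks = [values[groups == lv] for lv in levels]
    for lv, c in zip(levels, chunks):
        if len(c) < 2:
            raise DataValidationError(f"group {lv!r} has fewer than 2 observations")
    grand = values.mean()
    ssb = sum(len(c) * (c.mean() - grand) ** 2 for c in chunks)
    ssw = sum(((c - c.mean()) ** 2).sum() for c in chunks)
    dfb = len(levels) - 1
    dfw = len(values) - len(levels)
    if ssw == 0.0:
        if ssb == 0.0:
            f = 0.0
        else:
            f = np.inf
    else:
        f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return AnovaResult(
        F=float(f),
        df_between=dfb,
        df_within=dfw,
        p=p,
        group_means={lv: float(c.mean()) for lv, c in zip(levels, chunks)},
    )


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite df; returns (t, df, p two-tailed)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise DataValidationError("each sample needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise DataValidationError("degenerate variance")
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Student's pooled-variance two-sample t; returns (t, df, p two-tailed)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise DataValidationError("each sample needs at least 2 values")
    df = len(x) + len(y) - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(df), 1.0
        raise DataValidationError("degenerate variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    return float(t), float(df), 2.0 * float(stats.t.sf(abs(t), df))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; p via the t approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise DataValidationError("vectors must have equal length")
    if len(x) < 3:
        raise DataValidationError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0.0 or ry.std() == 0.0:
        raise DataValidationError("undefined under zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, p


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, capped at 1 and monotone in p-rank."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# differential expression

def fit_gene_lfc(expr: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Per-gene two-group contrast: lfc (mean A − mean B on the log2 scale),
    pooled residual variance s² and its df = nA + nB − 2.

    ``labels`` aligns with the expression columns and must contain exactly
    two distinct non-null values; label order (first-seen) defines group A.
    """
    labels = pd.Series(list(labels))
    if len(labels) != expr.shape[1]:
        raise DataValidationError("labels must align with expression columns")
    levels = [lv for lv in pd.unique(labels.dropna())]
    if len(levels) != 2:
        raise DataValidationError(f"need exactly 2 groups, got {levels!r}")
    a = expr.loc[:, (labels == levels[0]).to_numpy()].to_numpy(float)
    b = expr.loc[:, (labels == levels[1]).to_numpy()].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DataValidationError("each group needs at least 2 samples")
    lfc = a.mean(axis=1) - b.mean(axis=1)
    df = a.shape[1] + b.shape[1] - 2
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    out = pd.DataFrame(
        {"lfc": lfc, "s2": ss / df, "df": df}, index=expr.index.copy()
    )
    out.attrs["contrast_var"] = 1.0 / a.shape[1] + 1.0 / b.shape[1]
    out.attrs["groups"] = (levels[0], levels[1])
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0²).

    Under the hierarchical model s² | σ² ~ σ²·χ²_df/df with 1/σ² scaled
    chi-squared, log s² has a shifted log-F distribution; matching its mean
    and variance through digamma/trigamma identities yields d0 and s0².
    d0 = ∞ (variances identical up to sampling noise) is a valid outcome.
    """
    s2 = np.maximum(np.asarray(s2, float), 1e-12)
    df = np.asarray(df, float)
    if s2.size < 10:
        raise DataValidationError("need at least 10 genes to estimate the prior")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


@dataclass
class DEResult:
    """Moderated-t differential expression results for one contrast."""

    table: pd.DataFrame  # columns: lfc, s2, df, s2_post, t_mod, p, p_adj
    d0: float
    s0_sq: float
    contrast_var: float

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def moderated_t(
    de: pd.DataFrame,
    contrast_var: Optional[float] = None,
    d0: Optional[float] = None,
    s0_sq: Optional[float] = None,
) -> DEResult:
    """Empirical-Bayes moderated t from per-gene (lfc, s2, df).

    Posterior variance s̃² = (d0·s0² + df·s²)/(d0 + df); the moderated
    statistic lfc/√(s̃²·v_c) is referred to t on df + d0 degrees of freedom
    (normal when d0 = ∞).  ``d0``/``s0_sq`` may be forced, e.g. d0 = 0
    recovers the ordinary t and d0 = ∞ complete shrinkage.
    """
    if contrast_var is None:
        contrast_var = de.attrs.get("contrast_var")
    if contrast_var is None or contrast_var <= 0:
        raise DataValidationError("contrast_var must be positive")
    s2 = de["s2"].to_numpy(float)
    df = de["df"].to_numpy(float)
    lfc = de["lfc"].to_numpy(float)
    if d0 is None:
        d0, s0_est = estimate_prior(s2, df)
        if s0_sq is None:
            s0_sq = s0_est
    elif s0_sq is None:
        s0_sq = float(np.mean(s2)) if not np.isinf(d0) else float(np.exp(np.mean(np.log(np.maximum(s2, 1e-12)))))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = lfc / np.sqrt(s2_post * contrast_var)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    table = de.copy()
    table["s2_post"] = s2_post
    table["t_mod"] = t_mod
    table["p"] = p
    table["p_adj"] = benjamini_hochberg(p)
    return DEResult(table=table, d0=float(d0), s0_sq=float(s0_sq),
                    contrast_var=float(contrast_var))


# ---------------------------------------------------------------------------
# LFC concordance between the signature contrast and the SKP2-CN contrast

@dataclass(frozen=True)
class ConcordanceResult:
    rho: float
    p: float
    n_genes: int
    lfc_signature: np.ndarray
    lfc_skp2cn: np.ndarray


def lfc_concordance(expr: pd.DataFrame, cohort: pd.DataFrame) -> ConcordanceResult:
    """Spearman correlation between two genome-wide LFC vectors.

    Contrast A: signature low- vs high-ubiquitination group (intermediate/
    unclassified excluded).  Contrast B: SKP2 copy-number level ≥ 1 vs ≤ 0.
    Both vectors are oriented along *increasing SKP2 activity* — the
    signature's low-ubiquitination group is its SKP2-high state — so a
    signature that truly tracks SKP2 produces a positive rank correlation.
    Both LFC vectors cover all genes (no significance filtering).
    """
    for col in ("ubiq_group", "cn_skp2"):
        if col not in cohort.columns:
            raise DataValidationError(f"cohort lacks column {col!r}")
    ids = list(cohort["patient_id"])
    missing = [p for p in ids if p not in expr.columns]
    if missing:
        raise DataValidationError(
            f"{len(missing)} cohort patients absent from expression matrix"
        )
    expr = expr.loc[:, ids]

    grp = cohort["ubiq_group"].to_numpy()
    mask_a = np.isin(grp, ("high", "low"))
    labels_a = pd.Series(np.where(grp[mask_a] == "high", "high", "low"))
    if (labels_a == "high").sum() < 2 or (labels_a == "low").sum() < 2:
        raise DataValidationError("signature contrast arm has fewer than 2 samples")
    de_a = fit_gene_lfc(expr.loc[:, mask_a], labels_a)
    if de_a.attrs["groups"][0] != "low":
        de_a["lfc"] = -de_a["lfc"]

    cn = cohort["cn_skp2"].to_numpy(float)
    labels_b = pd.Series(np.where(cn >= 1, "cn_high", "cn_normal_low"))
    if (labels_b == "cn_high").sum() < 2 or (labels_b == "cn_normal_low").sum() < 2:
        raise DataValidationError("SKP2-CN contrast arm has fewer than 2 samples")
    de_b = fit_gene_lfc(expr, labels_b)
    # group A of contrast B must be the CN-high arm for the sign to match
    if de_b.attrs["groups"][0] != "cn_high":
        de_b["lfc"] = -de_b["lfc"]

    rho, p = spearman(de_a["lfc"].to_numpy(), de_b["lfc"].to_numpy())
    return ConcordanceResult(
        rho=rho,
        p=p,
        n_genes=expr.shape[0],
        lfc_signature=de_a["lfc"].to_numpy(),
        lfc_skp2cn=de_b["lfc"].to_numpy(),
    )
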