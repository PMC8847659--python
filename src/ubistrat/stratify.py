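"""SKP2-ubiquitination signature classifiers and IHC subtype assignment.

The two-gene signature compares the discrete copy-number level of FZR1 (the
APC/C co-activator that targets SKP2 for degradation) against that of a
deubiquitinase (USP10 by default, USP13/USP14 as alternatives).  A patient
whose FZR1 level exceeds the USP level is expected to ubiquitinate (and hence
degrade) more SKP2 — the "high ubiquitination" group — which should translate
into *low* SKP2 activity, high p27, and better prognosis.  Equality gives the
intermediate group, and FZR1 < USP the low-ubiquitination group.

Copy-number levels follow the cBioPortal discrete convention: −2 deep loss,
−1 shallow loss, 0 diploid, 1 low-level gain, 2 high-level amplification.

An expression-based variant of the signature (for datasets without CN calls)
splits FZR1 and USP10 expression at their dataset-wide medians: FZR1 ≤ median
with USP10 > median is "low", the mirror image is "high", everything else —
including patients exactly at both medians — is "intermediate".
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataValidationError

CN_LEVELS = (-2, -1, 0, 1, 2)
GROUPS = ("high", "intermediate", "low")
UNCLASSIFIED = "unclassified"
SUBTYPES = ("luminal", "HER2", "TNBC", "other")

#: group step index used throughout the package: the NB regression, the
#: proportional-odds stage/grade model and the simulator all treat "high"
#: as the baseline level 0.
GROUP_STEP = {"high": 0, "intermediate": 1, "low": 2}

STRATIFY_MODES = ("cn_usp10", "cn_usp13", "cn_usp14", "expression")


def _check_level(level, name: str) -> Optional[int]:
    """Validate a copy-number level; return int or None for missing."""
    if level is None:
        return None
    if isinstance(level, float) and math.isnan(level):
        return None
    if level is pd.NA:
        return None
    lv = int(level)
    if lv != level or lv not in CN_LEVELS:
        raise DataValidationError(
            f"invalid copy-number level for {name}: {level!r} (must be in -2..2)"
        )
    return lv


def classify_cn(fzr1_level, usp_level) -> str:
    """Classify one patient by the copy-number signature.

    Parameters
    ----------
    fzr1_level, usp_level : int or None
        cBioPortal discrete copy-number levels in {−2, −1, 0, 1, 2};
        ``None``/NaN means missing.

    Returns
    -------
    str
        ``"high"`` if FZR1 > USP, ``"intermediate"`` on equality, ``"low"``
        if FZR1 < USP, ``"unclassified"`` when either level is missing.
    """
    f = _check_level(fzr1_level, "FZR1")
    u = _check_level(usp_level, "USP")
    if f is None or u is None:
        return UNCLASSIFIED
    if f > u:
        return "high"
    if f < u:
        return "low"
    return "intermediate"


def classify_expression(
    fzr1_expr: float, usp10_expr: float, fzr1_median: float, usp10_median: float
) -> str:
    """Classify one patient by the expression-median signature.

    The medians must be computed over the full dataset being classified.
    FZR1 ≤ median with USP10 > median → low; USP10 ≤ median with
    FZR1 > median → high; all other patients → intermediate.
    """
    vals = (fzr1_expr, usp10_expr, fzr1_median, usp10_median)
    if not all(math.isfinite(v) for v in vals):
        raise DataValidationError(f"non-finite expression input: {vals!r}")
    if fzr1_expr <= fzr1_median and usp10_expr > usp10_median:
        return "low"
    if usp10_expr <= usp10_median and fzr1_expr > fzr1_median:
        return "high"
    return "intermediate"


def assign_subtype(er: str, pr: str, her2: str) -> str:
    """IHC subtype from receptor statuses.

    ER+ → luminal; ER−/PR−/HER2+ → HER2; ER−/PR−/HER2− → TNBC; any other
    combination (including unknowns) → other.  Total function: never raises.
    """
    if er == "positive":
        return "luminal"
    if er == "negative" and pr == "negative":
        if her2 == "positive":
            return "HER2"
        if her2 == "negative":
            return "TNBC"
    return "other"


def stratify_cohort(
    cohort: pd.DataFrame,
    mode: str = "cn_usp10",
    expr: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add ``ubiq_group`` and ``subtype`` columns to a cohort table.

    Parameters
    ----------
    cohort : DataFrame
        One row per patient with ``cn_fzr1``, ``cn_usp10``/``cn_usp13``/
        ``cn_usp14`` (as required by ``mode``) and ``er``/``pr``/``her2``.
    mode : str
        ``cn_usp10`` (default), ``cn_usp13``, ``cn_usp14`` or ``expression``.
    expr : DataFrame, optional
        Genes × samples log2 expression (index = gene ids, columns matching
        ``patient_id``); required for ``expression`` mode, which needs the
        ``FZR1`` and ``USP10`` rows.

    Returns
    -------
    (stratified, counts)
        The cohort copy with the two new columns, and a group × subtype
        contingency table of patient counts (unclassified rows kept as their
        own group level, never dropped).
    """
    if mode not in STRATIFY_MODES:
        raise DataValidationError(f"unknown stratification mode: {mode!r}")
    out = cohort.copy()

    if mode == "expression":
        if expr is None:
            raise DataValidationError("expression mode requires an expression matrix")
        for gene in ("FZR1", "USP10"):
            if gene not in expr.index:
                raise DataValidationError(f"expression matrix lacks gene {gene!r}")
        missing = [p for p in out["patient_id"] if p not in expr.columns]
        if missing:
            raise DataValidationError(
                f"{len(missing)} patients absent from expression matrix "
                f"(first: {missing[0]!r})"
            )
        fzr1 = expr.loc["FZR1", out["patient_id"]].to_numpy(float)
        usp10 = expr.loc["USP10", out["patient_id"]].to_numpy(float)
        med_f = float(np.median(expr.loc["FZR1"]))
        med_u = float(np.median(expr.loc["USP10"]))
        out["ubiq_group"] = [
            classify_expression(f, u, med_f, med_u) for f, u in zip(fzr1, usp10)
        ]
    else:
        usp_col = {"cn_usp10": "cn_usp10", "cn_usp13": "cn_usp13", "cn_usp14": "cn_usp14"}[mode]
        for col in ("cn_fzr1", usp_col):
            if col not in out.columns:
                raise DataValidationError(f"cohort lacks required column {col!r}")
        out["ubiq_group"] = [
            classify_cn(f, u) for f, u in zip(out["cn_fzr1"], out[usp_col])
        ]

    out["subtype"] = [
        assign_subtype(e, p, h) for e, p, h in zip(out["er"], out["pr"], out["her2"])
    ]

    counts = (
        out.groupby(["ubiq_group", "subtype"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(GROUPS) + [UNCLASSIFIED], columns=list(SUBTYPES), fill_value=0)
    )
    counts.index.name = "ubiq_group"
    return out, counts
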