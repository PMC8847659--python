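"""Connectivity-map style screening and IC50 comparison.

A query signature (up- and down-regulated gene sets from the signature's
differential-expression contrast) is scored against each ranked reference
perturbation profile with a bidirectional Kolmogorov–Smirnov statistic: a
drug whose profile pushes the query's up-genes to the bottom of its ranking
and the down-genes to the top *reverses* the signature (score −1 at the
extreme) and is a repurposing candidate; a drug mimicking the signature
scores +1.  Significance comes from a permutation null over random gene sets
of the same sizes, with Benjamini–Hochberg FDR across drugs; candidates are
labelled "recommended" when score < 0 and FDR < threshold.

The per-set KS statistic is the signed supremum of F_set(i) − i/n over list
positions i, where F_set is the within-set cumulative fraction.  This
symmetric form is exactly antisymmetric under reversal of the reference
ranking and under swapping the up/down sets, and the raw bidirectional score
(ks_up − ks_down when the two have opposite signs, else 0) is normalized by
its maximum attainable value (2 − (t_up + t_down)/n) so the output lies in
[−1, 1] with ±1 reached by perfectly concordant/reversing profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .proxy import DEResult, benjamini_hochberg, one_way_anova, welch_t_test, AnovaResult
from .simulate import ReferenceSet


@dataclass(frozen=True)
class QuerySignature:
    up_genes: tuple[str, ...]  # higher in the low-ubiquitination group
    down_genes: tuple[str, ...]
    fdr_cutoff: float
    max_set: Optional[int]


def build_query_signature(
    de: DEResult, fdr_cutoff: float = 0.05, max_set: Optional[int] = None
) -> QuerySignature:
    """Select up/down gene sets from a moderated-t DE result.

    Genes with adjusted p below ``fdr_cutoff`` split by LFC sign; each set is
    truncated to the ``max_set`` genes with largest |t_mod|.
    """
    t = de.table
    sig = t[t["p_adj"] < fdr_cutoff]
    up = sig[sig["lfc"] > 0].sort_values("t_mod", key=np.abs, ascending=False)
    down = sig[sig["lfc"] < 0].sort_values("t_mod", key=np.abs, ascending=False)
    if max_set is not None:
        up = up.head(max_set)
        down = down.head(max_set)
    if len(up) == 0 or len(down) == 0:
        raise DataValidationError("no significant signature")
    return QuerySignature(
        up_genes=tuple(up.index),
        down_genes=tuple(down.index),
        fdr_cutoff=fdr_cutoff,
        max_set=max_set,
    )


def _ks_signed(positions: np.ndarray, n: int) -> float:
    """Signed sup-norm KS statistic for a set at 1-based ``positions``.

    d+ = max_j (j/t − p_j/n) over the sorted positions, d− = max over the
    flat stretches of i/n − F_set(i); returns d+ if it dominates, −d−
    otherwise, 0 on an exact tie.
    """
    p = np.sort(np.asarray(positions, dtype=np.int64))
    t = len(p)
    j = np.arange(1, t + 1, dtype=np.int64)
    # exact integer numerators over the common denominator n*t, so that the
    # d+/d− comparison (and hence the sign) is immune to float rounding
    num_plus = max(int(np.max(j * n - p * t)), 0)
    num_minus = max(int(np.max((p - 1) * t - (j - 1) * n)), 0)
    if num_plus > num_minus:
        return num_plus / (n * t)
    if num_minus > num_plus:
        return -num_minus / (n * t)
    return 0.0


def _score_from_positions(
    up_pos: np.ndarray, down_pos: np.ndarray, n: int
) -> tuple[float, float]:
    ks_up = _ks_signed(up_pos, n)
    ks_down = _ks_signed(down_pos, n)
    raw = ks_up - ks_down if ks_up * ks_down < 0 else 0.0
    max_raw = (1.0 - len(up_pos) / n) + (1.0 - len(down_pos) / n)
    return raw, raw / max_raw


def connectivity_score(
    up: Sequence[str], down: Sequence[str], ranked_reference: Sequence[str]
) -> tuple[float, float]:
    """Bidirectional KS connectivity of (up, down) against one ranked list.

    Returns ``(raw, normalized)`` with normalized in [−1, 1]: +1 when the
    profile mimics the query (up-set on top, down-set at bottom), −1 when it
    perfectly reverses it.
    """
    up, down = set(up), set(down)
    if up & down:
        raise DataValidationError("up and down sets overlap")
    if not up or not down:
        raise DataValidationError("up and down sets must be non-empty")
    pos = {g: i + 1 for i, g in enumerate(ranked_reference)}
    missing = (up | down) - pos.keys()
    if missing:
        raise DataValidationError(
            f"{len(missing)} query genes absent from the reference universe"
        )
    n = len(ranked_reference)
    up_pos = np.array([pos[g] for g in up])
    down_pos = np.array([pos[g] for g in down])
    return _score_from_positions(up_pos, down_pos, n)


@dataclass(frozen=True)
class ConnectivityResult:
    drug: str
    cell_line: str
    score: float
    p: float
    fdr: float
    direction: str  # negative_recommended | positive | null


def connectivity_screen(
    query: QuerySignature,
    refs: ReferenceSet,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> list[ConnectivityResult]:
    """Score every reference profile and attach permutation p-values and FDR.

    The permutation null draws random up/down position sets of the observed
    sizes from the common universe (shared across profiles, which all rank
    the same genes); the p-value is two-sided on |score| with the +1
    pseudo-count, and FDR is Benjamini–Hochberg across profiles.
    """
    if n_perm < 100:
        raise DataValidationError("n_perm must be at least 100")
    if len(refs.entries) < 2:
        raise DataValidationError("need at least 2 reference entries")
    rng = np.random.default_rng(seed)
    n = len(refs.universe)
    t_up, t_down = len(query.up_genes), len(query.down_genes)
    if t_up + t_down > n:
        raise DataValidationError("query sets larger than the universe")

    # shared null distribution of |normalized score| (same n, t_up, t_down
    # for every entry because all profiles rank the same universe)
    null_abs = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)[: t_up + t_down] + 1
        _, s = _score_from_positions(perm[:t_up], perm[t_up:], n)
        null_abs[i] = abs(s)

    scores = []
    for entry in refs.entries:
        _, s = connectivity_score(query.up_genes, query.down_genes, entry.ranked_genes)
        scores.append(s)
    pvals = np.array(
        [(1.0 + np.sum(null_abs >= abs(s) - 1e-12)) / (1.0 + n_perm) for s in scores]
    )
    fdrs = benjamini_hochberg(pvals)

    out = []
    for entry, s, p, q in zip(refs.entries, scores, pvals, fdrs):
        if s < 0 and q < fdr_threshold:
            direction = "negative_recommended"
        elif s > 0 and q < fdr_threshold:
            direction = "positive"
        else:
            direction = "null"
        out.append(
            ConnectivityResult(
                drug=entry.drug,
                cell_line=entry.cell_line,
                score=float(s),
                p=float(p),
                fdr=float(q),
                direction=direction,
            )
        )
    return out


# ---------------------------------------------------------------------------
# IC50 comparison

def significance_stars(p: float) -> str:
    """Asterisk code: *** p<0.001, ** 0.001≤p<0.01, * 0.01≤p<0.05, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class IC50Comparison:
    anova: AnovaResult
    pairwise: pd.DataFrame  # index drug; columns t, df, p, stars, mean_ln_ic50


def compare_ic50(table: pd.DataFrame, reference_drug: str) -> IC50Comparison:
    """ANOVA across drugs on ln IC50 plus pairwise Welch t vs the reference.

    ``table`` has columns drug, cell_line, ln_ic50 (natural-log scale, the
    GDSC convention); every drug needs at least two cell lines.
    """
    for col in ("drug", "cell_line", "ln_ic50"):
        if col not in table.columns:
            raise DataValidationError(f"IC50 table lacks column {col!r}")
    if not np.all(np.isfinite(table["ln_ic50"].to_numpy(float))):
        raise DataValidationError("ln_ic50 values must be finite")
    drugs = list(pd.unique(table["drug"]))
    if reference_drug not in drugs:
        raise DataValidationError(f"reference drug {reference_drug!r} absent")
    anova = one_way_anova(table["ln_ic50"].to_numpy(float), table["drug"].to_numpy())

    ref_vals = table.loc[table["drug"] == reference_drug, "ln_ic50"].to_numpy(float)
    rows = []
    for drug in drugs:
        if drug == reference_drug:
            continue
        vals = table.loc[table["drug"] == drug, "ln_ic50"].to_numpy(float)
        t, df, p = welch_t_test(vals, ref_vals)
        rows.append(
            {
                "drug": drug,
                "t": t,
                "df": df,
                "p": p,
                "stars": significance_stars(p),
                "mean_ln_ic50": float(vals.mean()),
            }
        )
    pairwise = pd.DataFrame(rows).set_index("drug")
    return IC50Comparison(anova=anova, pairwise=pairwise)
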