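"""Synthetic breast-cancer cohort and reference-data generator.

Emulates the statistical structure of the public cohorts the signature
analysis assumes — discrete copy-number calls, IHC subtype mixture, a p27
protein readout, overall survival with censoring, ordinal stage/grade,
overdispersed positive-lymph-node counts, a log2 expression matrix driven by
a latent SKP2-activity factor, and ranked drug-perturbation profiles with
planted signature reversers — so every downstream stage can be exercised and
calibrated without any download.

Model sketch (g = group step: high = 0, intermediate = 1, low = 2; by
default, clinical effects apply to luminal patients only, mirroring the
luminal-specific associations the signature is designed around):

* copy-number levels drawn independently per gene from ``cn_marginals``;
* ubiquitination group derived internally with the FZR1-vs-USP10 rule;
* ``latent_skp2`` = (g − 1) + centered SKP2 CN level + N(0, 1) — lower
  ubiquitination means more SKP2, and SKP2 copy number feeds the same latent
  activity, which is what makes the two differential-expression contrasts of
  the proxy-validation stage concordant;
* p27 decreases by ``p27_effect`` per group step (high group has most p27);
* survival is exponential; the low group's hazard is multiplied by
  ``hazard_ratio_low_vs_high``; censoring is uniform on [0, T] with T set by
  bisection on the analytic censoring probability to hit
  ``censor_fraction_target``;
* stage and grade follow proportional-odds multinomials shifted by
  ``stage_grade_shift`` log-odds per group step;
* positive node counts are NB2 with log-mean ``nb_coefficients`` · design
  (baseline = high) and dispersion ``nb_theta`` (var = μ + μ²/θ).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .stratify import CN_LEVELS, GROUP_STEP, classify_cn, assign_subtype

SIGNATURE_GENES = ("FZR1", "USP10", "USP13", "SKP2")

# Symmetric marginal giving roughly a 25/50/25 high/intermediate/low split
# under independence (P(equal) = Σp² ≈ 0.52).
_DEFAULT_MARGINAL = (0.02, 0.13, 0.70, 0.13, 0.02)

# Baseline ordinal distributions (stage I–IV, grade 1–3) for the high group.
_STAGE_BASE = (0.18, 0.55, 0.22, 0.05)
_GRADE_BASE = (0.20, 0.45, 0.35)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults plant the luminal-row node-count coefficients (0.43, 0.29,
    0.58 on the log scale, high group as baseline) with dispersion
    θ = 0.25, a low-vs-high hazard ratio of 1.8, a 30% censoring target,
    and a subtype mixture dominated by luminal disease as in large
    breast-cancer registries.
    """

    n_patients: int = 2000
    subtype_proportions: tuple[float, float, float] = (0.75, 0.07, 0.16)
    cn_marginals: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {g: _DEFAULT_MARGINAL for g in SIGNATURE_GENES}
    )
    p27_effect: float = 0.3
    p27_sd: float = 1.0
    n_genes: int = 2000
    frac_responsive: float = 0.2
    expr_effect_sd: float = 0.3
    baseline_hazard: float = 0.006
    hazard_ratio_low_vs_high: float = 1.8
    censor_fraction_target: float = 0.30
    stage_grade_shift: float = 0.5
    nb_coefficients: tuple[float, float, float] = (0.43, 0.29, 0.58)
    nb_theta: float = 0.25
    luminal_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 10:
            raise DataValidationError("cohort too small")
        props = np.asarray(self.subtype_proportions, float)
        if props.min() < 0 or props.sum() > 1 + 1e-9:
            raise DataValidationError(
                "subtype_proportions must be nonnegative and sum to at most 1"
            )
        for gene in SIGNATURE_GENES:
            if gene not in self.cn_marginals:
                raise DataValidationError(f"cn_marginals missing gene {gene!r}")
            p = np.asarray(self.cn_marginals[gene], float)
            if p.shape != (5,) or p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise DataValidationError(
                    f"cn_marginals[{gene!r}] must be 5 probabilities summing to 1"
                )
        if self.p27_sd <= 0:
            raise DataValidationError("p27_sd must be positive")
        if self.baseline_hazard <= 0:
            raise DataValidationError("baseline_hazard must be positive")
        if self.hazard_ratio_low_vs_high <= 0:
            raise DataValidationError("hazard_ratio_low_vs_high must be positive")
        if not 0 <= self.censor_fraction_target < 1:
            raise DataValidationError("censor_fraction_target must be in [0, 1)")
        if self.nb_theta <= 0:
            raise DataValidationError("nb_theta must be positive")
        if not 0 <= self.frac_responsive <= 1:
            raise DataValidationError("frac_responsive must be in [0, 1]")
        if self.n_genes < 1:
            raise DataValidationError("n_genes must be positive")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def derive_theta(mean: float, variance: float) -> float:
    """NB2 dispersion from moments via var = μ + μ²/θ, i.e. θ = μ²/(var − μ).

    Raises if the data are not overdispersed (variance ≤ mean), where the
    NB2 model reduces to or below the Poisson.
    """
    if mean <= 0:
        raise DataValidationError("mean must be positive")
    if variance <= mean:
        raise DataValidationError("not overdispersed; NB reduces to/below Poisson")
    return mean * mean / (variance - mean)


def sample_negbin(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 draws via the gamma–Poisson mixture: λ ~ Gamma(θ, μ/θ), y ~ Poisson(λ)."""
    mu = np.asarray(mu, float)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def _censor_horizon(hazards: np.ndarray, target: float) -> float:
    """Upper end T of the uniform censoring window, by bisection.

    With C ~ U(0, T) independent of an exponential event time with hazard h,
    P(censored) = (1 − e^{−hT})/(hT).  The cohort-average censoring
    probability is decreasing in T, so bisection on T is monotone.
    """

    def censor_prob(T: float) -> float:
        x = hazards * T
        return float(np.mean(-np.expm1(-x) / x))

    lo, hi = 1e-9, 1.0
    while censor_prob(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censor_prob(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_ordinal(
    rng: np.random.Generator, base_probs: Sequence[float], eta: np.ndarray
) -> np.ndarray:
    """Proportional-odds draw: logit P(Y ≤ j) = α_j − η, α from base_probs."""
    cum = np.cumsum(np.asarray(base_probs, float))[:-1]
    alpha = np.log(cum / (1.0 - cum))  # baseline cumulative logits
    # cumulative probabilities per patient, shape (n, k-1)
    cdf = 1.0 / (1.0 + np.exp(-(alpha[None, :] - eta[:, None])))
    u = rng.uniform(size=len(eta))
    return (u[:, None] > cdf).sum(axis=1)  # 0-based category index


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a synthetic per-patient clinical/genomic table.

    Returns a DataFrame with one row per patient: copy-number calls for the
    four signature genes, receptor statuses, p27, overall survival time
    (months) and event flag, stage, grade, positive-node count, and the
    simulation-only ``latent_skp2`` column.  Identical config (including
    seed) gives a bit-identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    cn = {}
    for gene in SIGNATURE_GENES:
        p = np.asarray(config.cn_marginals[gene], float)
        cn[gene] = rng.choice(CN_LEVELS, size=n, p=p)

    # subtype → receptor statuses consistent with the IHC definitions
    props = list(config.subtype_proportions)
    probs = props + [1.0 - sum(props)]
    subtype_idx = rng.choice(4, size=n, p=np.asarray(probs) / np.sum(probs))
    er = np.where(subtype_idx == 0, "positive", "negative")
    pr = np.full(n, "negative", dtype=object)
    her2 = np.full(n, "negative", dtype=object)
    lum = subtype_idx == 0
    pr[lum] = np.where(rng.uniform(size=int(lum.sum())) < 0.8, "positive", "negative")
    her2[lum] = np.where(rng.uniform(size=int(lum.sum())) < 0.15, "positive", "negative")
    her2[subtype_idx == 1] = "positive"
    pr[subtype_idx == 3] = "positive"  # ER−/PR+ falls outside all three definitions

    groups = np.array([classify_cn(f, u) for f, u in zip(cn["FZR1"], cn["USP10"])])
    g = np.array([GROUP_STEP[x] for x in groups])
    affected = lum if config.luminal_only else np.ones(n, bool)
    g_eff = np.where(affected, g, 0)

    latent_skp2 = (g - 1.0) + cn["SKP2"] + rng.normal(size=n)

    p27 = 0.5 - config.p27_effect * g_eff + rng.normal(scale=config.p27_sd, size=n)

    hazards = config.baseline_hazard * np.where(
        (g_eff == 2), config.hazard_ratio_low_vs_high, 1.0
    )
    event_time = rng.exponential(scale=1.0 / hazards)
    if config.censor_fraction_target <= 0:
        os_time, os_event = event_time, np.ones(n, int)
    else:
        horizon = _censor_horizon(hazards, config.censor_fraction_target)
        censor_time = rng.uniform(0.0, horizon, size=n)
        os_event = (event_time <= censor_time).astype(int)
        os_time = np.minimum(event_time, censor_time)

    stage_idx = _draw_ordinal(rng, _STAGE_BASE, config.stage_grade_shift * g_eff)
    grade_idx = _draw_ordinal(rng, _GRADE_BASE, config.stage_grade_shift * g_eff)

    b0, b_int, b_low = config.nb_coefficients
    log_mu = b0 + b_int * (g_eff == 1) + b_low * (g_eff == 2)
    positive_nodes = sample_negbin(rng, np.exp(log_mu), config.nb_theta)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "cn_fzr1": cn["FZR1"],
            "cn_usp10": cn["USP10"],
            "cn_usp13": cn["USP13"],
            "cn_skp2": cn["SKP2"],
            "er": er,
            "pr": pr,
            "her2": her2,
            "p27": p27,
            "os_time": os_time,
            "os_event": os_event,
            "stage": np.array(["I", "II", "III", "IV"])[stage_idx],
            "grade": grade_idx + 1,
            "positive_nodes": positive_nodes,
            "latent_skp2": latent_skp2,
        }
    )


def simulate_expression(config: SimConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Genes × samples log2 expression matrix tied to the cohort.

    A ``frac_responsive`` fraction of genes loads on the hidden SKP2-activity
    factor with gene weights β_g ~ N(0, ``expr_effect_sd``²); the rest are
    pure noise.  The four signature genes get dedicated rows: FZR1/USP10/
    USP13 expression increases with the gene's own copy-number level, and
    the SKP2 row tracks ``latent_skp2`` directly.
    """
    config.validate()
    if "latent_skp2" not in cohort.columns:
        raise DataValidationError("cohort lacks latent_skp2 column")
    rng = np.random.default_rng(config.seed + 1)
    n = len(cohort)
    latent = cohort["latent_skp2"].to_numpy(float)

    n_generic = max(config.n_genes - len(SIGNATURE_GENES), 0)
    gene_ids = list(SIGNATURE_GENES[: config.n_genes]) + [
        f"G{i + 1:05d}" for i in range(n_generic)
    ]
    values = np.empty((len(gene_ids), n))

    baseline = rng.normal(loc=7.0, scale=1.0, size=len(gene_ids))
    noise_sd = 0.5
    values[:] = baseline[:, None] + rng.normal(scale=noise_sd, size=(len(gene_ids), n))

    for row, gene in enumerate(SIGNATURE_GENES[: config.n_genes]):
        cn_col = f"cn_{gene.lower()}"
        if gene == "SKP2":
            values[row] += 1.0 * latent
        else:
            values[row] += 0.5 * cohort[cn_col].to_numpy(float)

    if n_generic:
        n_resp = int(round(config.frac_responsive * n_generic))
        resp_rows = len(SIGNATURE_GENES[: config.n_genes]) + rng.choice(
            n_generic, size=n_resp, replace=False
        )
        beta = rng.normal(scale=config.expr_effect_sd, size=n_resp)
        values[resp_rows] += beta[:, None] * latent[None, :]

    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=list(cohort["patient_id"]))


@dataclass(frozen=True)
class PerturbationEntry:
    drug: str
    cell_line: str
    ranked_genes: tuple[str, ...]  # most up-regulated first


@dataclass(frozen=True)
class ReferenceSet:
    """Ranked perturbation profiles over a common gene universe."""

    entries: tuple[PerturbationEntry, ...]
    universe: tuple[str, ...]

    def validate(self) -> None:
        ref = sorted(self.universe)
        for e in self.entries:
            if sorted(e.ranked_genes) != ref:
                raise DataValidationError(
                    f"ranked list for {e.drug}/{e.cell_line} is not a permutation "
                    "of the gene universe"
                )


def simulate_reference_profiles(
    universe: Sequence[str],
    query_up: Sequence[str],
    query_down: Sequence[str],
    n_drugs: int,
    n_reversers: int,
    seed: int,
    cell_line: str = "MCF7",
) -> ReferenceSet:
    """Reference perturbation profiles with planted signature reversers.

    The first ``n_reversers`` drugs rank the query's down-genes at the very
    top and its up-genes at the very bottom (a perfectly reversing profile);
    the remaining drugs are uniform random permutations.
    """
    up, down = set(query_up), set(query_down)
    if up & down:
        raise DataValidationError("query up/down gene sets overlap")
    if not up <= set(universe) or not down <= set(universe):
        raise DataValidationError("query sets must be subsets of the universe")
    if n_reversers > n_drugs:
        raise DataValidationError("n_reversers cannot exceed n_drugs")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    middle = [gene for gene in universe if gene not in up and gene not in down]

    entries = []
    for i in range(n_drugs):
        if i < n_reversers:
            top = list(rng.permutation(sorted(down)))
            mid = list(rng.permutation(middle))
            bottom = list(rng.permutation(sorted(up)))
            ranked = top + mid + bottom
            name = f"reverser_{i + 1:02d}"
        else:
            ranked = list(rng.permutation(universe))
            name = f"drug_{i + 1:03d}"
        entries.append(PerturbationEntry(name, cell_line, tuple(ranked)))
    return ReferenceSet(tuple(entries), tuple(universe))
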