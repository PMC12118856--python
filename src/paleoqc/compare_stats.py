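"""Statistical comparison of extraction protocols.

The centrepiece is a linear mixed-effects model for per-peptide responses
(GRAVY or pI): protocol enters as a fixed effect and protein as a random
intercept, acknowledging that peptides from the same protein are not
independent and that all protocols were applied to the same material. The
model is fit by REML; pairwise protocol contrasts use Satterthwaite
degrees of freedom and Bonferroni adjustment over the full family of
pairwise comparisons (55 for ten protocols plus the common-proteome
reference group).

Satterthwaite df are computed by the standard delta-method recipe: with
variance components theta = (tau^2, sigma^2) estimated by REML, a contrast
c has variance f(theta) = c' (X'V^-1 X)^-1 c, and

    df = 2 f^2 / (g' A g),

where g is the gradient of f in theta (finite differences on the log
scale) and A the asymptotic covariance of the REML estimates (inverse of
the negative REML-likelihood Hessian, also finite-differenced). For a
single random intercept the per-group inverse of V = sigma^2 I + tau^2 J
has a closed form, which keeps all of this cheap.

Also here: Shapiro-Wilk and Levene pre-checks, a generic Fisher
over/under-representation test with fold enrichment, and the
contaminant-abundance risk grading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class StatsResult:
    name: str
    statistic: float
    df: int
    pvalue: float


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    estimate: float
    se: float
    df: float
    t: float
    pvalue: float
    pvalue_adj: float
    family_size: int


@dataclass
class LmmResult:
    response: str
    levels: list[str]
    effects: dict[str, float]  # estimated mean response per level
    tau2: float  # random-intercept (protein) variance
    sigma2: float  # residual variance
    contrasts: list[ContrastResult]
    n_obs: int
    singular: bool = False

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": [c.pair[0] for c in self.contrasts],
                "b": [c.pair[1] for c in self.contrasts],
                "estimate": [c.estimate for c in self.contrasts],
                "se": [c.se for c in self.contrasts],
                "df": [c.df for c in self.contrasts],
                "t": [c.t for c in self.contrasts],
                "pvalue": [c.pvalue for c in self.contrasts],
                "pvalue_adj": [c.pvalue_adj for c in self.contrasts],
                "family_size": [c.family_size for c in self.contrasts],
            }
        )


# ---------------------------------------------------------------------------
# Distribution pre-checks


def distribution_checks(
    values: Sequence[float], groups: Sequence
) -> list[StatsResult]:
    """Shapiro-Wilk normality check on the pooled values and Levene's test
    (median-centred) for homogeneity of variance across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for Levene's test")
    arrays = [values[groups == g] for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    sample = values
    if len(sample) > 4999:  # Shapiro-Wilk's implementation limit
        sample = np.random.default_rng(0).choice(sample, 4999, replace=False)
    w, p_w = stats.shapiro(sample)
    f, p_f = stats.levene(*arrays, center="median")
    return [
        StatsResult("shapiro_wilk", float(w), len(sample), float(p_w)),
        StatsResult("levene", float(f), len(labels), float(p_f)),
    ]


# ---------------------------------------------------------------------------
# Linear mixed model with Satterthwaite contrasts


def _group_blocks(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    blocks = []
    for g in np.unique(codes):
        idx = codes == g
        blocks.append((X[idx], y[idx]))
    return blocks


def _vbeta_and_gls(theta, blocks):
    """(X'V^-1X)^-1 and the GLS quantities for V = sigma2 I + tau2 J."""
    tau2, sigma2 = theta
    p = blocks[0][0].shape[1]
    M = np.zeros((p, p))
    b = np.zeros(p)
    for Xg, yg in blocks:
        ng = len(yg)
        shrink = tau2 / (sigma2 + ng * tau2)
        xsum = Xg.sum(axis=0)
        ysum = yg.sum()
        M += (Xg.T @ Xg - shrink * np.outer(xsum, xsum)) / sigma2
        b += (Xg.T @ yg - shrink * xsum * ysum) / sigma2
    vbeta = np.linalg.inv(M)
    beta = vbeta @ b
    return vbeta, beta, M


def _reml_loglik(theta, blocks):
    tau2, sigma2 = theta
    if tau2 < 0 or sigma2 <= 0:
        return -np.inf
    vbeta, beta, M = _vbeta_and_gls(theta, blocks)
    logdet_v = 0.0
    quad = 0.0
    for Xg, yg in blocks:
        ng = len(yg)
        denom = sigma2 + ng * tau2
        logdet_v += (ng - 1) * np.log(sigma2) + np.log(denom)
        r = yg - Xg @ beta
        quad += (r @ r - (tau2 / denom) * r.sum() ** 2) / sigma2
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet_v + logdet_m + quad)


def _numeric_hessian(fun, x, h=1e-3):
    """Central-difference Hessian of ``fun`` at ``x`` (log-scale coords)."""
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = h, h
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def _satterthwaite_df(c, theta, blocks, cov_theta_log, h=1e-3):
    log_theta = np.log(theta)

    def f(lt):
        vbeta, _, _ = _vbeta_and_gls(np.exp(lt), blocks)
        return float(c @ vbeta @ c)

    f0 = f(log_theta)
    grad = np.zeros(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h
        grad[i] = (f(log_theta + e) - f(log_theta - e)) / (2 * h)
    denom = float(grad @ cov_theta_log @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return np.inf
    return 2.0 * f0 * f0 / denom


def fit_protocol_lmm(
    table: pd.DataFrame,
    response: str = "gravy",
    protocol_col: str = "protocol",
    protein_col: str = "protein",
    family_size: int | None = None,
) -> LmmResult:
    """Fit ``response ~ protocol + (1 | protein)`` by REML and return all
    pairwise protocol contrasts with Satterthwaite df and Bonferroni
    adjustment.

    The protocol factor may include the common-proteome reference as its
    own group. When the random-intercept variance collapses to zero the
    model degenerates to ordinary least squares (flagged ``singular``,
    residual df used) with a warning.
    """
    import statsmodels.api as sm

    needed = {response, protocol_col, protein_col}
    if not needed <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(needed)}")
    data = table.dropna(subset=[response]).copy()
    levels = sorted(data[protocol_col].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 protocols")
    level_idx = {lv: i for i, lv in enumerate(levels)}
    codes = data[protocol_col].astype(str).map(level_idx).to_numpy()
    y = data[response].to_numpy(float)
    n, p = len(y), len(levels)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for i in range(1, p):
        X[codes == i, i] = 1.0
    protein_codes = pd.factorize(data[protein_col])[0]

    family = (
        family_size
        if family_size is not None
        else len(levels) * (len(levels) - 1) // 2
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=protein_codes)
        fit = model.fit(reml=True)
        if not fit.converged:
            fit = model.fit(reml=True, method="powell")
    tau2 = float(np.asarray(fit.cov_re)[0, 0])
    sigma2 = float(fit.scale)
    beta = np.asarray(fit.fe_params, dtype=float)

    singular = bool(tau2 < 1e-8 * max(sigma2, np.var(y)))
    if not fit.converged and not singular:
        # optimiser stalls are almost always the tau2 -> 0 boundary; a
        # genuinely unconverged fit with non-trivial variance is an error
        if tau2 < 1e-3 * max(sigma2, np.var(y)):
            singular = True
        else:
            raise RuntimeError(
                "mixed model failed to converge; "
                f"n_obs={n}, levels={levels}, "
                f"proteins={protein_codes.max() + 1}"
            )
    pairs = list(combinations(levels, 2))
    contrasts: list[ContrastResult] = []

    if singular:
        warnings.warn(
            "random-intercept variance is ~0; falling back to a "
            "fixed-effects (OLS) model",
            stacklevel=2,
        )
        ols = sm.OLS(y, X).fit()
        beta = ols.params
        vbeta = ols.cov_params()
        df_resid = float(ols.df_resid)
        for a, b in pairs:
            c = np.zeros(p)
            if level_idx[a] > 0:
                c[level_idx[a]] = 1.0
            if level_idx[b] > 0:
                c[level_idx[b]] -= 1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ vbeta @ c))
            t = est / se if se > 0 else 0.0
            pv = 2 * stats.t.sf(abs(t), df_resid)
            contrasts.append(
                ContrastResult(
                    (a, b), est, se, df_resid, t, pv, min(1.0, pv * family),
                    family,
                )
            )
    else:
        blocks = _group_blocks(X, y, protein_codes)
        theta = np.array([tau2, sigma2])
        log_theta = np.log(theta)
        H = _numeric_hessian(
            lambda lt: _reml_loglik(np.exp(lt), blocks), log_theta
        )
        try:
            cov_theta_log = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov_theta_log = np.full((2, 2), np.nan)
        vbeta, beta_gls, _ = _vbeta_and_gls(theta, blocks)
        beta = beta_gls
        n_proteins = int(protein_codes.max()) + 1
        df_fallback = float(n - p - n_proteins + 1)
        for a, b in pairs:
            c = np.zeros(p)
            if level_idx[a] > 0:
                c[level_idx[a]] = 1.0
            if level_idx[b] > 0:
                c[level_idx[b]] -= 1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ vbeta @ c))
            df = _satterthwaite_df(c, theta, blocks, cov_theta_log)
            if not np.isfinite(df) or df <= 0:
                df = max(df_fallback, 1.0)
            t = est / se if se > 0 else 0.0
            pv = 2 * stats.t.sf(abs(t), df)
            contrasts.append(
                ContrastResult(
                    (a, b), est, se, float(df), t, pv,
                    min(1.0, pv * family), family,
                )
            )

    effects = {
        lv: float(beta[0] + (beta[level_idx[lv]] if level_idx[lv] > 0 else 0.0))
        for lv in levels
    }
    return LmmResult(
        response=response,
        levels=levels,
        effects=effects,
        tau2=tau2,
        sigma2=sigma2,
        contrasts=contrasts,
        n_obs=n,
        singular=singular,
    )


def peptide_response_table(
    rows: pd.DataFrame,
    database,
    response: str = "gravy",
    reference_label: str = "common_proteome",
) -> pd.DataFrame:
    """Build the per-peptide LMM input restricted to common-proteome
    proteins, with the common proteome itself included as a protein-level
    reference group."""
    from .damage_metrics import common_proteome
    from .proteome_core import STANDARD_AA, gravy, isoelectric_point

    score = gravy if response == "gravy" else isoelectric_point
    shared = common_proteome(rows)
    sub = rows[rows["leader"].isin(shared)]
    records = []
    for run, run_rows in sub.groupby("run"):
        seen = run_rows.drop_duplicates("stripped_sequence")
        for pep, leader in zip(seen["stripped_sequence"], seen["leader"]):
            if set(pep) <= STANDARD_AA:
                records.append(
                    {
                        "protocol": run,
                        "protein": leader,
                        response: score(pep),
                    }
                )
    for acc in sorted(shared):
        rec = database.get(acc)
        if rec is not None and set(rec.sequence) <= STANDARD_AA:
            records.append(
                {
                    "protocol": reference_label,
                    "protein": acc,
                    response: score(rec.sequence),
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Enrichment


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    fold_enrichment: float
    direction: str
    pvalue: float
    pvalue_adj: float


def enrichment_test(
    set_counts: Mapping[str, int],
    background_counts: Mapping[str, int],
    set_total: int | None = None,
    background_total: int | None = None,
) -> list[EnrichmentResult]:
    """Fisher's exact over/under-representation per category with
    Bonferroni adjustment. Fold enrichment FE = (k/n) / (K/N); direction is
    'over' when FE > 1, 'under' when FE < 1."""
    n = set_total if set_total is not None else sum(set_counts.values())
    N = (
        background_total
        if background_total is not None
        else sum(background_counts.values())
    )
    missing = [c for c in set_counts if c not in background_counts]
    if missing:
        raise KeyError(f"categories absent from background: {missing}")
    results = []
    m = len(set_counts)
    for category, k in sorted(set_counts.items()):
        K = background_counts[category]
        if k > K or n > N:
            raise ValueError(f"set exceeds background for {category!r}")
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        expected = n * K / N
        fe = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
        direction = "over" if fe > 1 else ("under" if fe < 1 else "none")
        results.append(
            EnrichmentResult(
                category, k, expected, fe, direction, float(p),
                min(1.0, float(p) * m),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Contamination risk


RISK_LABELS = {1: "very low", 2: "low", 3: "medium", 4: "high", 5: "very high"}
DEFAULT_RISK_THRESHOLDS = (1e-4, 1e-3, 1e-2, 5e-2)


@dataclass
class RiskAssessment:
    """Per-contaminant risk levels (1 very low ... 5 very high) graded on
    relative abundance — the contaminant's share of a protocol's total
    signal — plus the per-protocol global level (the worst contaminant)."""

    levels: pd.DataFrame  # contaminant x protocol integer risk levels
    relative_abundance: pd.DataFrame
    global_level: pd.Series  # per protocol
    thresholds: tuple[float, ...] = DEFAULT_RISK_THRESHOLDS

    def label(self, level: int) -> str:
        return RISK_LABELS[int(level)]


def contamination_risk(
    abundance_table: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_RISK_THRESHOLDS,
    total_signal: pd.Series | None = None,
) -> RiskAssessment:
    """Grade contaminant abundances into risk levels.

    ``abundance_table`` is contaminant x protocol with nonnegative total
    abundances. Relative abundance is the contaminant's fraction of
    ``total_signal`` per protocol (defaulting to the table's column sums
    when the full run signal is not supplied). Risk level = 1 + number of
    threshold cut points strictly below the relative abundance.
    """
    if (abundance_table < 0).any().any():
        raise ValueError("negative contaminant abundance")
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    totals = (
        total_signal.reindex(abundance_table.columns)
        if total_signal is not None
        else abundance_table.sum(axis=0)
    )
    rel = abundance_table.div(totals.where(totals > 0, np.nan), axis=1).fillna(
        0.0
    )
    levels = rel.copy()
    for col in levels.columns:
        levels[col] = 1 + sum(
            (rel[col] > t).astype(int) for t in thresholds
        )
    levels = levels.astype(int)
    global_level = levels.max(axis=0)
    return RiskAssessment(levels, rel, global_level, thresholds)
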