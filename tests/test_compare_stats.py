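"""Distribution checks, mixed-model contrasts, enrichment and risk grading."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, spearmanr

import paleoqc as pq
from paleoqc.compare_stats import (
    DEFAULT_RISK_THRESHOLDS,
    contamination_risk,
    distribution_checks,
    enrichment_test,
    fit_protocol_lmm,
)


# ---------------------------------------------------------------------------
# Distribution checks


def test_shapiro_type_i_calibration():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500)
        g = np.repeat(["a", "b"], 250)
        res = distribution_checks(x, g)
        if res[0].pvalue > 0.05:
            hits += 1
    assert hits >= 90


def test_levene_detects_variance_ratio():
    detected = 0
    for seed in range(30):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 5, 100)])
        g = np.repeat(["a", "b"], 100)
        res = distribution_checks(x, g)
        if res[1].pvalue < 0.01:
            detected += 1
    assert detected >= 29  # >= 95% power at this separation


def test_levene_identical_groups_statistic_zero():
    x = np.tile(np.arange(50, dtype=float), 2)
    g = np.repeat(["a", "b"], 50)
    res = distribution_checks(x, g)
    assert res[1].statistic == pytest.approx(0.0, abs=1e-12)


def test_distribution_checks_degenerate_inputs():
    with pytest.raises(ValueError):
        distribution_checks([1.0, 2.0], ["a", "b"])
    with pytest.raises(ValueError):
        distribution_checks([1.0, 2.0, 3.0], ["a", "a", "a"])


# ---------------------------------------------------------------------------
# Mixed model


def _lmm_data(rng, shifts, n_proteins=15, peptides_per=8, tau=0.3, sigma=0.5):
    rows = []
    protein_effect = rng.normal(0, tau, n_proteins)
    for name, shift in shifts.items():
        for prot in range(n_proteins):
            for _ in range(peptides_per):
                rows.append(
                    {
                        "protocol": name,
                        "protein": f"prot{prot}",
                        "gravy": shift
                        + protein_effect[prot]
                        + rng.normal(0, sigma),
                    }
                )
    return pd.DataFrame(rows)


def test_duplicated_protocols_give_zero_contrast():
    rng = np.random.default_rng(0)
    base = _lmm_data(rng, {"A": 0.0})
    dup = base.assign(protocol="B")
    res = fit_protocol_lmm(pd.concat([base, dup]), "gravy")
    (c,) = res.contrasts
    assert c.estimate == pytest.approx(0.0, abs=1e-10)


def test_lmm_detects_shifted_protocol():
    hits = 0
    for seed in range(12):
        rng = np.random.default_rng(seed)
        data = _lmm_data(
            rng,
            {"A": 0.0, "B": 0.0, "C": 0.25},  # +0.5 residual SD
            n_proteins=20,
            peptides_per=10,
        )
        res = fit_protocol_lmm(data, "gravy")
        sig = {
            c.pair
            for c in res.contrasts
            if c.pvalue_adj < 0.05
        }
        if {("A", "C"), ("B", "C")} <= sig:
            hits += 1
    assert hits >= 10  # >= 80% power


def test_lmm_familywise_type_i_under_null():
    """With every protocol drawn from the same distribution the fraction of
    families containing any Bonferroni-adjusted p < .05 stays at or below
    10%."""
    false_alarms = 0
    reps = 100
    for seed in range(reps):
        rng = np.random.default_rng(1000 + seed)
        data = _lmm_data(
            rng,
            {f"P{i}": 0.0 for i in range(5)},
            n_proteins=12,
            peptides_per=6,
        )
        res = fit_protocol_lmm(data, "gravy")
        if any(c.pvalue_adj < 0.05 for c in res.contrasts):
            false_alarms += 1
    assert false_alarms <= 10


def test_bonferroni_monotone_and_family_size():
    rng = np.random.default_rng(2)
    data = _lmm_data(rng, {"A": 0.0, "B": 0.1, "C": 0.2, "D": 0.0})
    res = fit_protocol_lmm(data, "gravy")
    assert all(c.pvalue_adj >= c.pvalue for c in res.contrasts)
    assert all(c.family_size == 6 for c in res.contrasts)
    raw = sorted(res.contrasts, key=lambda c: c.pvalue)
    adj = [c.pvalue_adj for c in raw]
    assert adj == sorted(adj)


def test_singular_random_effect_falls_back_to_ols():
    # identical per-protein means force the variance component to the
    # boundary (tau2 = 0), degenerating the model to OLS
    rows = []
    for prot in range(10):
        for protocol, shift in [("A", 0.0), ("B", 0.6)]:
            rows.extend(
                {
                    "protocol": protocol,
                    "protein": f"prot{prot}",
                    "gravy": shift + eps,
                }
                for eps in (-1.0, 1.0)
            )
    data = pd.DataFrame(rows)
    with pytest.warns(UserWarning, match="falling back"):
        res = fit_protocol_lmm(data, "gravy")
    assert res.singular
    assert res.contrasts[0].estimate == pytest.approx(-0.6)


@pytest.mark.skipif(
    shutil.which("Rscript") is None, reason="Rscript not available"
)
def test_satterthwaite_contrasts_match_lmerTest(tmp_path):
    """Independent oracle: lme4/lmerTest + emmeans on the same data must
    reproduce the contrast estimates, standard errors, Satterthwaite df and
    Bonferroni p-values."""
    rng = np.random.default_rng(7)
    data = _lmm_data(
        rng, {"A": 0.0, "B": 0.15, "C": -0.1}, n_proteins=12, peptides_per=6
    )
    csv = tmp_path / "d.csv"
    data.to_csv(csv, index=False)
    script = tmp_path / "check.R"
    script.write_text(
        """
suppressMessages({library(lmerTest); library(emmeans)})
args <- commandArgs(trailingOnly=TRUE)
d <- read.csv(args[1])
m <- lmer(gravy ~ protocol + (1|protein), data=d, REML=TRUE)
em <- emmeans(m, 'protocol', lmer.df='satterthwaite')
pr <- summary(pairs(em, adjust='bonferroni'))
write.csv(pr[, c('contrast','estimate','SE','df','p.value')],
          args[2], row.names=FALSE)
"""
    )
    out_csv = tmp_path / "r.csv"
    subprocess.run(
        ["Rscript", str(script), str(csv), str(out_csv)],
        check=True,
        capture_output=True,
    )
    r = pd.read_csv(out_csv)
    r_by_pair = {
        tuple(sorted(c.split(" - "))): row
        for c, row in zip(r["contrast"], r.to_dict("records"))
    }
    res = fit_protocol_lmm(data, "gravy")
    for c in res.contrasts:
        ref = r_by_pair[tuple(sorted(c.pair))]
        assert abs(c.estimate) == pytest.approx(abs(ref["estimate"]), rel=1e-4)
        assert c.se == pytest.approx(ref["SE"], rel=1e-3)
        assert c.df == pytest.approx(ref["df"], rel=0.02)
        assert c.pvalue_adj == pytest.approx(ref["p.value"], abs=1e-3)


def test_lmm_recovers_simulated_bias_ordering(sim_experiment):
    filtered = sim_experiment["filtered"]
    db = sim_experiment["database"]
    table = pq.peptide_response_table(filtered, db, response="gravy")
    table = table[table["protocol"] != "common_proteome"]
    res = fit_protocol_lmm(table, "gravy")
    true_bias = {
        name: truth.profile["bias_gravy"]
        for name, truth in sim_experiment["truths"].items()
        if name in res.effects
    }
    # Spearman rho = 1 is only defined for distinct true coefficients; the
    # fixture's "shallow" protocol duplicates bias 0, so drop it here.
    true_bias.pop("shallow", None)
    names = sorted(true_bias)
    rho, _ = spearmanr(
        [true_bias[n] for n in names], [res.effects[n] for n in names]
    )
    assert rho == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Enrichment


def test_enrichment_fold_and_direction():
    res = enrichment_test({"cat": 5}, {"cat": 10}, set_total=10, background_total=100)
    assert res[0].fold_enrichment == pytest.approx(5.0)
    assert res[0].direction == "over"
    res = enrichment_test({"cat": 0}, {"cat": 10}, set_total=10, background_total=100)
    assert res[0].fold_enrichment == 0.0 and res[0].direction == "under"


def test_enrichment_missing_category_errors():
    with pytest.raises(KeyError, match="cat"):
        enrichment_test({"cat": 1}, {}, set_total=5, background_total=50)


def _fisher_enumeration(k, n, K, N):
    """Two-sided Fisher p by direct enumeration of the hypergeometric
    support: sum the probabilities of all tables at most as likely."""
    lo = max(0, n - (N - K))
    hi = min(n, K)
    p_obs = hypergeom.pmf(k, N, K, n)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom.pmf(x, N, K, n)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


@pytest.mark.parametrize("seed", range(10))
def test_fisher_p_matches_hypergeometric_enumeration(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(20, 200))
    K = int(rng.integers(1, N))
    n = int(rng.integers(1, N))
    lo, hi = max(0, n - (N - K)), min(n, K)
    k = int(rng.integers(lo, hi + 1))
    res = enrichment_test(
        {"cat": k}, {"cat": K}, set_total=n, background_total=N
    )
    assert res[0].pvalue == pytest.approx(
        _fisher_enumeration(k, n, K, N), rel=1e-9
    )


def test_fisher_symmetric_under_complement_swap():
    N, K, n, k = 120, 30, 40, 17
    over = enrichment_test({"c": k}, {"c": K}, n, N)[0]
    comp = enrichment_test({"c": n - k}, {"c": N - K}, n, N)[0]
    assert over.pvalue == pytest.approx(comp.pvalue, rel=1e-9)
    assert {over.direction, comp.direction} == {"over", "under"}


# ---------------------------------------------------------------------------
# Contamination risk


def test_risk_floor_and_ceiling():
    table = pd.DataFrame(
        {"p1": [0.0, 5.0], "p2": [500.0, 500.0]}, index=["PEG", "Tween"]
    )
    total = pd.Series({"p1": 1000.0, "p2": 1000.0})
    risk = contamination_risk(table, total_signal=total)
    assert risk.levels.loc["PEG", "p1"] == 1  # zero abundance -> floor
    # Tween in p1: 5e-3 of the signal -> above the 1e-4 and 1e-3 cuts
    assert risk.levels.loc["Tween", "p1"] == 1 + 2
    assert risk.levels.loc["Tween", "p2"] == 5  # 50% of signal -> ceiling
    assert risk.global_level["p2"] == 5


def test_risk_scale_invariance_and_monotonicity():
    rng = np.random.default_rng(4)
    table = pd.DataFrame(
        rng.uniform(0, 100, size=(6, 3)),
        index=[f"c{i}" for i in range(6)],
        columns=["a", "b", "c"],
    )
    base = contamination_risk(table)
    doubled = contamination_risk(table * 2)
    pd.testing.assert_frame_equal(base.levels, doubled.levels)
    # monotone: raising one contaminant's share cannot lower its level
    bumped = table.copy()
    bumped.loc["c0", "a"] *= 10
    more = contamination_risk(bumped)
    assert more.levels.loc["c0", "a"] >= base.levels.loc["c0", "a"]


def test_risk_rejects_negative():
    table = pd.DataFrame({"a": [-1.0]}, index=["x"])
    with pytest.raises(ValueError):
        contamination_risk(table)


def test_risk_labels():
    table = pd.DataFrame({"a": [1.0]}, index=["x"])
    risk = contamination_risk(table)
    assert risk.label(risk.levels.loc["x", "a"]) == "very high"
    assert risk.thresholds == DEFAULT_RISK_THRESHOLDS
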