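"""Quantification matrix chain and multivariate comparisons."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import paleoqc as pq
from paleoqc.proteome_core import ProteinRecord
from paleoqc.quant_profile import (
    ProteinQuantMatrix,
    log2_transform,
    presence_sets,
)


def _rows(entries):
    return pd.DataFrame(
        [
            {
                "run": run,
                "leader": leader,
                "stripped_sequence": f"PEP{i}K",
                "intensity": intensity,
                "contaminant": False,
                "reverse": False,
            }
            for i, (run, leader, intensity) in enumerate(entries)
        ]
    )


# ---------------------------------------------------------------------------
# iBAQ


def test_ibaq_sum_over_theoretical_peptides():
    # protein "MKGGGGGGK" digests to two in-bounds theoretical peptides at
    # bounds (1, 30): "MK" and "GGGGGGK"
    db = {"P1": ProteinRecord("P1", "", "MKGGGGGGK")}
    rows = _rows([("r1", "P1", 600.0), ("r1", "P1", 400.0)])
    m = pq.compute_ibaq(rows, db, bounds=(1, 30))
    assert m.data.loc["P1", "r1"] == pytest.approx(500.0)

    doubled = rows.assign(intensity=rows["intensity"] * 2)
    m2 = pq.compute_ibaq(doubled, db, bounds=(1, 30))
    assert m2.data.loc["P1", "r1"] == pytest.approx(1000.0)


def test_ibaq_missing_cell_is_nan_not_zero():
    db = {
        "P1": ProteinRecord("P1", "", "MKGGGGGGK"),
        "P2": ProteinRecord("P2", "", "AAAAKGGGGR"),
    }
    rows = _rows([("r1", "P1", 100.0), ("r2", "P1", 100.0), ("r1", "P2", 50.0)])
    m = pq.compute_ibaq(rows, db, bounds=(1, 30))
    assert np.isnan(m.data.loc["P2", "r2"])
    assert m.missing_mask.loc["P2", "r2"]


def test_ibaq_unknown_leader_errors():
    rows = _rows([("r1", "PX", 100.0)])
    with pytest.raises(KeyError, match="PX"):
        pq.compute_ibaq(rows, {}, bounds=(1, 30))


# ---------------------------------------------------------------------------
# QRILC


def _censored_matrix(seed, n=400, mu=20.0, sd=1.0, censor_q=0.3):
    rng = np.random.default_rng(seed)
    x = rng.normal(mu, sd, size=n)
    cut = np.quantile(x, censor_q)
    observed = np.where(x < cut, np.nan, x)
    df = pd.DataFrame({"c1": observed, "c2": rng.normal(mu, sd, size=n)})
    return ProteinQuantMatrix(df, "log2"), x, cut


def test_qrilc_identity_without_missing():
    m = ProteinQuantMatrix(
        pd.DataFrame({"a": [1.0, 2.0, 3.0]}), "log2"
    )
    out = pq.impute_qrilc(m, seed=0)
    pd.testing.assert_frame_equal(out.data, m.data)


def test_qrilc_deterministic_under_seed():
    m, _, _ = _censored_matrix(0)
    a = pq.impute_qrilc(m, seed=5)
    b = pq.impute_qrilc(m, seed=5)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_qrilc_truncated_normal_oracle():
    """Across replicates the imputed mean tracks the truncated-normal
    expectation mu + sd * (-phi(z_q)/Phi(z_q)) of the estimated column
    normal, and always sits below the observed mean."""
    z_q = norm.ppf(0.01)
    lam = norm.pdf(z_q) / norm.cdf(z_q)  # inverse Mills ratio at the cut
    imputed_means, oracle_means = [], []
    for seed in range(200):
        m, truth, cut = _censored_matrix(seed)
        out = pq.impute_qrilc(m, quantile=0.01, seed=seed)
        miss = m.data["c1"].isna()
        obs = m.data["c1"].dropna()
        imp = out.data.loc[miss, "c1"]
        assert imp.mean() < obs.mean()
        imputed_means.append(imp.mean())
        oracle_means.append(20.0 - 1.0 * lam)  # true mu=20, sd=1
    # average over replicates within half an SD of the oracle expectation
    assert abs(np.mean(imputed_means) - np.mean(oracle_means)) < 0.5


def test_qrilc_stage_guard_and_sparse_column_fallback(caplog):
    raw = ProteinQuantMatrix(pd.DataFrame({"a": [1.0, np.nan]}), "raw")
    with pytest.raises(ValueError):
        pq.impute_qrilc(raw, seed=0)
    sparse = ProteinQuantMatrix(
        pd.DataFrame(
            {
                "a": [20.0, np.nan, np.nan, np.nan, np.nan],
                "b": [19.0, 20.0, 21.0, 20.5, 19.5],
            }
        ),
        "log2",
    )
    with caplog.at_level("WARNING"):
        out = pq.impute_qrilc(sparse, seed=0)
    assert not out.data.isna().any().any()
    assert any("global estimate" in r.message for r in caplog.records)


def test_missingness_drives_negative_z_share():
    """Once imputation dominates a column's low tail, the share of negative
    z-scores tracks the missingness rate: the few observed (high) values
    pull the column mean above the tight imputed cluster, so nearly every
    imputed cell standardises below zero."""
    rng = np.random.default_rng(1)
    n = 600
    base = rng.normal(20, 1.5, size=(n, 3))
    df = pd.DataFrame(base, columns=["half", "sparse", "very_sparse"])
    for col, q in [("half", 0.5), ("sparse", 0.7), ("very_sparse", 0.88)]:
        cut = df[col].quantile(q)
        df.loc[df[col] < cut, col] = np.nan
    m = ProteinQuantMatrix(df, "log2")
    z = pq.zscore_columns(pq.impute_qrilc(m, seed=3))
    shares = (z.data < 0).mean()
    assert shares["half"] < shares["sparse"] < shares["very_sparse"]
    # and the share is close to the censored fraction itself
    assert shares["very_sparse"] == pytest.approx(0.88, abs=0.06)


# ---------------------------------------------------------------------------
# z-scores


def test_zscore_example_and_definitional_invariants():
    m = ProteinQuantMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), "imputed")
    z = pq.zscore_columns(m)
    assert z.data["a"].tolist() == [-1.0, 0.0, 1.0]
    rng = np.random.default_rng(0)
    m2 = ProteinQuantMatrix(
        pd.DataFrame(rng.normal(5, 3, size=(50, 4))), "imputed"
    )
    z2 = pq.zscore_columns(m2)
    assert np.all(np.abs(z2.data.mean()) < 1e-9)
    assert np.all(np.abs(z2.data.std(ddof=1) - 1) < 1e-9)


def test_zscore_affine_invariance():
    rng = np.random.default_rng(2)
    x = pd.DataFrame({"a": rng.normal(size=30)})
    za = pq.zscore_columns(ProteinQuantMatrix(x, "imputed"))
    zb = pq.zscore_columns(ProteinQuantMatrix(3.5 * x + 11.0, "imputed"))
    pd.testing.assert_frame_equal(za.data, zb.data)


def test_zscore_constant_column_errors():
    m = ProteinQuantMatrix(pd.DataFrame({"a": [2.0, 2.0, 2.0]}), "imputed")
    with pytest.raises(ValueError, match="zero-variance"):
        pq.zscore_columns(m)


def test_stage_transitions_only_forward():
    m = ProteinQuantMatrix(pd.DataFrame({"a": [1.0, 2.0]}), "log2")
    with pytest.raises(ValueError):
        m.advance(m.data, "raw")


# ---------------------------------------------------------------------------
# Correlation / clustering / MDS


def test_correlation_examples_and_psd():
    rng = np.random.default_rng(0)
    x = rng.normal(size=60)
    df = pd.DataFrame({"a": x, "b": x, "c": -x, "d": rng.normal(size=60)})
    corr = pq.correlation_matrix(df)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    # independent textbook formula
    y = df["d"].to_numpy()
    manual = ((x - x.mean()) * (y - y.mean())).sum() / (
        np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    )
    assert corr.loc["a", "d"] == pytest.approx(manual)
    eigs = np.linalg.eigvalsh(corr.to_numpy())
    assert eigs.min() >= -1e-8


def test_hierarchical_cluster_line_example():
    df = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
    res = pq.hierarchical_cluster(df, axis="rows", metric="euclidean",
                                  linkage="complete")
    first = res.linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}  # a and b merge first
    assert first[2] == pytest.approx(1.0)
    # Manhattan distance is identical in 1-D: same topology
    res_m = pq.hierarchical_cluster(df, axis="rows", metric="manhattan",
                                    linkage="complete")
    assert np.allclose(res.linkage[:, :2], res_m.linkage[:, :2])


def test_hierarchical_cluster_identical_items_merge_at_zero():
    df = pd.DataFrame({"x": [1.0, 1.0, 5.0]}, index=["a", "b", "c"])
    res = pq.hierarchical_cluster(df, axis="rows")
    assert res.linkage[0][2] == pytest.approx(0.0)


def test_hierarchical_cluster_needs_two_items():
    with pytest.raises(ValueError):
        pq.hierarchical_cluster(pd.DataFrame({"x": [1.0]}), axis="rows")


def test_mds_two_points_exact():
    df = pd.DataFrame({"p": [0.0, 0.0], "q": [3.0, 4.0]})
    coords, stress = pq.metric_mds(df, metric="euclidean", dims=1)
    d = abs(coords.loc["p", "dim1"] - coords.loc["q", "dim1"])
    assert d == pytest.approx(5.0)
    assert stress == pytest.approx(0.0, abs=1e-9)


def test_mds_three_points_reproduce_distances():
    # Euclidean-embeddable triangle: classical scaling is exact in 2-D.
    pts = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
    df = pd.DataFrame(pts.T, columns=["a", "b", "c"])
    coords, stress = pq.metric_mds(df, metric="euclidean", dims=2)
    from scipy.spatial.distance import pdist

    got = pdist(coords.to_numpy())
    want = pdist(pts)
    assert np.allclose(np.sort(got), np.sort(want), atol=1e-8)
    assert coords.iloc[0, 0] >= 0  # pinned sign convention


def test_mds_duplicate_points_coincide():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [5.0, 9.0]})
    coords, _ = pq.metric_mds(df, metric="manhattan", dims=2)
    assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-6)


# ---------------------------------------------------------------------------
# Intersections


def _powerset_oracle(sets):
    names = sorted(sets)
    union = set().union(*sets.values())
    counts = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            exact = set(union)
            for n in combo:
                exact &= sets[n]
            for n in names:
                if n not in combo:
                    exact -= sets[n]
            counts[";".join(combo)] = len(exact)
    return counts


def test_intersection_example_and_partition():
    table = pq.intersection_counts({"A": {"p", "q"}, "B": {"q"}})
    counts = dict(zip(table["protocols"], table["count"]))
    assert counts == {"A": 1, "B": 0, "A;B": 1}
    assert table["count"].sum() == 2  # |A u B|


def test_intersections_match_powerset_oracle():
    rng = np.random.default_rng(9)
    universe = list(range(40))
    sets = {
        name: set(rng.choice(universe, size=rng.integers(5, 25), replace=False))
        for name in "ABCD"
    }
    table = pq.intersection_counts(sets)
    got = dict(zip(table["protocols"], table["count"]))
    assert got == _powerset_oracle(sets)
    assert table["count"].sum() == len(set().union(*sets.values()))


def test_presence_sets(sim_experiment):
    sets = presence_sets(sim_experiment["filtered"])
    assert set(sets) == set(sim_experiment["filtered"]["run"].unique())
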