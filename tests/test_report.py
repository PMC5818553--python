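"""Aggregation grains, Bonferroni arithmetic, table rendering, test routing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcampflux import report


def _table(rows):
    return pd.DataFrame(rows, columns=["genotype", "terminal_type",
                                       "frequency_hz", "nmj_id", "max_dff"])


def test_single_nmj_aggregation():
    df = _table([("wt", "Ib", 40, 0, v) for v in (0.1, 0.2, 0.3)])
    out = report.aggregate(df, ["genotype", "terminal_type", "frequency_hz"])
    assert out.nmj.iloc[0]["mean"] == pytest.approx(0.2)
    assert out.nmj.iloc[0]["N"] == 1
    assert out.nmj.iloc[0]["n"] == 3


def test_nmj_grain_weighs_terminals_equally():
    rows = ([("wt", "Ib", 40, 0, 0.2)] * 5 + [("wt", "Ib", 40, 1, 0.4)])
    out = report.aggregate(_table(rows), ["genotype"])
    assert out.nmj.iloc[0]["mean"] == pytest.approx(0.3)   # not 0.233
    assert out.bouton.iloc[0]["mean"] == pytest.approx((5 * 0.2 + 0.4) / 6)
    assert out.nmj.iloc[0]["N"] <= out.nmj.iloc[0]["n"]


def brute_force_aggregate(df, keys, value="max_dff"):
    """Independent two-pass group-by: explicit loops, no pandas groupby."""

    cells = {}
    for _, row in df.iterrows():
        cells.setdefault(tuple(row[k] for k in keys), []).append(
            (row["nmj_id"], row[value]))
    out = {}
    for key, obs in cells.items():
        vals = [v for _, v in obs]
        per_nmj = {}
        for nmj, v in obs:
            per_nmj.setdefault(nmj, []).append(v)
        nmj_means = [np.mean(v) for v in per_nmj.values()]
        out[key] = (np.mean(vals), np.mean(nmj_means), len(vals), len(per_nmj))
    return out


@pytest.mark.parametrize("seed", range(5))
def test_aggregation_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 60
    df = _table(list(zip(
        rng.choice(["wt", "mut"], n),
        rng.choice(["Ib", "Is", "II"], n),
        rng.choice([10, 20, 40], n),
        rng.integers(0, 4, n),
        rng.normal(0.3, 0.1, n),
    )))
    keys = ["genotype", "terminal_type", "frequency_hz"]
    out = report.aggregate(df, keys)
    oracle = brute_force_aggregate(df, keys)
    for _, row in out.bouton.iterrows():
        key = tuple(row[k] for k in keys)
        mean_b, mean_n, n_obs, n_nmj = oracle[key]
        assert row["mean"] == pytest.approx(mean_b)
        assert row["n"] == n_obs and row["N"] == n_nmj
    for _, row in out.nmj.iterrows():
        key = tuple(row[k] for k in keys)
        assert row["mean"] == pytest.approx(oracle[key][1])


def test_bonferroni_arithmetic_exact():
    assert report.bonferroni(0.01, 6) == pytest.approx(0.06)
    assert report.bonferroni(0.4, 6) == 1.0
    assert report.bonferroni(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        report.bonferroni(0.05, 0)


def test_stars_at_standard_levels():
    assert report.stars(0.0004) == "***"
    assert report.stars(0.004) == "**"
    assert report.stars(0.04) == "*"
    assert report.stars(0.06) == ""


def test_identical_samples_not_significant():
    x = np.arange(1, 21, dtype=float)
    res, = report.run_tests({"a": x, "b": x.copy()}, [("a", "b")],
                            test="kruskal_wallis_bonferroni")
    assert res.adjusted_p > 0.9
    assert res.stars == ""


def test_bonferroni_family_scales_raw_p():
    rng = np.random.default_rng(0)
    groups = {f"g{i}": rng.normal(0, 1, 20) for i in range(4)}
    plan = [("g0", "g1"), ("g0", "g2"), ("g0", "g3"),
            ("g1", "g2"), ("g1", "g3"), ("g2", "g3")]
    results = report.run_tests(groups, plan, test="t_test_bonferroni")
    for r in results:
        assert r.adjusted_p == pytest.approx(min(1.0, 6 * r.raw_p))


def test_degenerate_group_skipped_with_reason():
    res, = report.run_tests({"a": np.array([1.0]), "b": np.arange(5.0)},
                            [("a", "b")])
    assert np.isnan(res.raw_p)
    assert "degenerate" in res.note


def test_fisher_lsd_uses_pooled_variance():
    rng = np.random.default_rng(1)
    groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(0.3, 1, 15),
              "c": rng.normal(2.0, 1, 15)}
    res = report.run_tests(groups, [("a", "c")], test="anova_fisher_lsd")[0]
    # LSD p differs from the two-sample t p because df and MSE pool all groups
    t_p = stats.ttest_ind(groups["a"], groups["c"]).pvalue
    assert res.raw_p < 0.001
    assert res.raw_p != pytest.approx(t_p, rel=1e-6)


def test_rejection_rate_tracks_permutation_oracle():
    """t test vs a permutation oracle on shifted normals (2 SD, n=30)."""

    rng = np.random.default_rng(2)
    reps, n, shift = 300, 30, 2.0
    rej_t = rej_perm = 0
    for _ in range(reps):
        a = rng.normal(0, 1, n)
        b = rng.normal(shift, 1, n)
        rej_t += stats.ttest_ind(a, b).pvalue < 0.05
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        for _ in range(99):
            rng.shuffle(pooled)
            count += abs(pooled[:n].mean() - pooled[n:].mean()) >= obs
        rej_perm += (count + 1) / 100 < 0.05
    assert abs(rej_t - rej_perm) / reps <= 0.03


def test_cell_rendering_convention():
    assert report.format_cell(0.16, 0.11, 53, 9) == "0.16 ± 0.11 (53, 9)"
    assert report.format_cell(1.0, 0.333, 18, 3) == "1.00 ± 0.33 (18, 3)"


def test_render_tables_with_and_without_stars():
    summary = pd.DataFrame([
        {"genotype": "wt", "mean": 0.16, "sd": 0.11, "sem": 0.02, "n": 53, "N": 9},
    ])
    df, text = report.render_tables(summary, keys=["genotype"])
    assert "0.16 ± 0.11 (53, 9)" in text
    assert "*" not in text
    starred, text2 = report.render_tables(
        summary, keys=["genotype"], star_map={("wt",): "***"})
    assert starred["cell"].iloc[0].endswith("***")
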