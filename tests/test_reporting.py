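"""Paired-run orchestration, summaries, age shares and the CLI."""

import numpy as np
import pandas as pd
import pytest

from ncd_excess import age_share, run_projection, summarise_runs
from ncd_excess.cli import cli_main
from ncd_excess.config_io import AGE_STRATA
from ncd_excess.reporting import percentile_interval


def _age_dists(bundle):
    return {d.id: d.age_dist for d in bundle.diseases}


def test_percentile_interval_recovers_normal_quantiles():
    x = np.random.default_rng(0).standard_normal(10_000)
    lo, hi = percentile_interval(x)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_single_run_gives_degenerate_interval(small_bundle):
    bundle, _ = small_bundle
    ledgers = run_projection(bundle, "status_quo", mode="expectation")
    summary = summarise_runs(ledgers, bundle.grid, _age_dists(bundle))
    assert np.allclose(summary.table["mean"], summary.table.pi_lo)
    assert np.allclose(summary.table["mean"], summary.table.pi_hi)


def test_subperiod_means_sum_to_total(small_bundle):
    bundle, _ = small_bundle
    ledgers = run_projection(bundle, "escalation", mode="stochastic", n_runs=20)
    summary = summarise_runs(ledgers, bundle.grid, _age_dists(bundle))
    t = summary.table[summary.table.stratum == "all"]
    for disease in t.disease.unique():
        sub = t[t.disease == disease].set_index("sub_period")["mean"]
        assert sub["total"] == pytest.approx(
            sub["to_date"] + sub["proj_m1_3"] + sub["proj_m4_6"], abs=1e-6
        )


def test_projection_is_seed_deterministic(small_bundle):
    bundle, _ = small_bundle
    a = run_projection(bundle, "ceasefire", mode="stochastic", n_runs=10)
    b = run_projection(bundle, "ceasefire", mode="stochastic", n_runs=10)
    for la, lb in zip(a, b):
        for d in la.crisis:
            assert np.array_equal(la.crisis[d], lb.crisis[d])
            assert np.array_equal(la.counterfactual[d], lb.counterfactual[d])
        assert la.coverage == lb.coverage


def test_excess_is_translation_consistent(small_bundle):
    bundle, _ = small_bundle
    led = run_projection(bundle, "ceasefire", mode="stochastic", n_runs=3)[0]
    d = next(iter(led.crisis))
    before = led.excess(d).copy()
    led.crisis[d] += 7.0
    led.counterfactual[d] += 7.0
    assert np.allclose(led.excess(d), before)


def test_crisis_equals_counterfactual_under_baseline_coverage(small_bundle):
    """With phi = 1 and crisis coverage at baseline, the arms coincide."""
    from ncd_excess import generate_inputs

    bundle, _ = generate_inputs(1, "small")
    for key in list(bundle.coverage.ranges):
        d = key[0]
        bundle.coverage.ranges[key] = bundle.coverage.range_for(d, "baseline")
    ledgers = run_projection(bundle, "status_quo", mode="stochastic", n_runs=20)
    summary = summarise_runs(ledgers, bundle.grid, _age_dists(bundle))
    t = summary.table[(summary.table.stratum == "all")]
    assert np.allclose(t["mean_crisis"], t["mean_counterfactual"])


def test_age_share_degenerate_and_mapping():
    shares = {s: 0.0 for s in AGE_STRATA}
    shares["80+"] = 123.0
    assert age_share(shares, "50-59") == 100
    with pytest.raises(ValueError, match="missing"):
        age_share({"0-9": 1.0}, "50-59")
    with pytest.raises(ValueError, match="unknown age stratum"):
        age_share({"0-9": 1.0, "weird": 2.0}, "0-9")


def test_summary_age_rows_cover_all_strata(small_bundle):
    bundle, _ = small_bundle
    ledgers = run_projection(bundle, "ceasefire", mode="expectation")
    summary = summarise_runs(ledgers, bundle.grid, _age_dists(bundle))
    age_rows = summary.table[
        (summary.table.disease == "all")
        & (summary.table.stratum != "all")
        & (summary.table.sub_period == "total")
    ]
    assert set(age_rows.stratum) == set(AGE_STRATA)
    total_row = summary.table[
        (summary.table.disease == "all")
        & (summary.table.stratum == "all")
        & (summary.table.sub_period == "total")
    ]["mean"].iloc[0]
    assert age_rows["mean"].sum() == pytest.approx(total_row, rel=1e-9)
    assert 0 < age_share(summary, "50-59") <= 100


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_synthetic_run_and_determinism(tmp_path):
    args = ["--synthetic", "--profile", "small", "--runs", "10", "--seed", "1",
            "--scenario", "ceasefire", "--out", str(tmp_path / "a")]
    assert cli_main(args) == 0
    out = tmp_path / "a" / "ceasefire"
    for name in ("excess_by_disease.csv", "excess_by_age.csv", "monthly_deaths.csv"):
        assert (out / name).exists()
    assert (tmp_path / "a" / "run_metadata.json").exists()

    args2 = args[:-1] + [str(tmp_path / "b")]
    assert cli_main(args2) == 0
    a = (tmp_path / "a" / "summary_all.csv").read_bytes()
    b = (tmp_path / "b" / "summary_all.csv").read_bytes()
    assert a == b


def test_cli_rejects_unknown_scenario(tmp_path, capsys):
    code = cli_main(["--synthetic", "--profile", "small", "--scenario", "truce",
                     "--out", str(tmp_path)])
    assert code == 2
    err = capsys.readouterr().err
    assert "ceasefire" in err and "escalation" in err


def test_cli_requires_config_or_synthetic(tmp_path):
    assert cli_main(["--out", str(tmp_path)]) == 2
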