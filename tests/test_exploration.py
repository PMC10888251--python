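"""Scans, noisy sampling, fitting and reporting."""

import numpy as np
import pytest

from unicyc import (
    NoiseSpec,
    SampleTable,
    best_point,
    build_rate_set,
    concentration_scan,
    evaluate_point,
    fold_report,
    linear_fit,
    load_enzyme,
    noisy_sample,
    steady_state,
    stepwise_scan,
)


@pytest.fixture(scope="module")
def fig2_scan(tpi, tpi_rates):
    return stepwise_scan(
        tpi_rates, tpi.environment, target=7, start=10.0, step=10.0,
        n_steps=1000, params=tpi,
    )


def test_scan_reaches_published_efficiency_maximum(fig2_scan):
    row = fig2_scan.data[fig2_scan.data.k7 == 10000.0].iloc[0]
    assert row.specificity == pytest.approx(1.25e6, rel=1e-3)
    best = best_point(fig2_scan, "max_specificity")
    assert best.k7 == 10000.0  # efficiency rises monotonically with k7 here


def test_positive_force_filter_never_grows_table(fig2_scan):
    filtered = fig2_scan.positive_force()
    assert len(filtered) <= len(fig2_scan)
    assert (filtered.data.x_tot > 0).all()


def test_rows_are_recomputable_from_stored_rates(fig2_scan, tpi):
    sample = fig2_scan.data.iloc[[3, 500, 999]]
    for _, row in sample.iterrows():
        rates = fig2_scan.rate_set(row, n_states=4)
        fresh = evaluate_point(rates, tpi.environment, params=tpi)
        for col in ("flux", "x_tot", "entropy_production", "kcat", "specificity"):
            assert fresh[col] == pytest.approx(row[col], rel=1e-12), col


def test_fixed_K_scan_keeps_force_constant(tpi, tpi_rates):
    tab = stepwise_scan(
        tpi_rates, tpi.environment, target=7, start=10.0, step=10.0,
        n_steps=200, couple_fixed_K=True, params=tpi,
    )
    assert np.ptp(tab.data.x_tot.to_numpy()) < 1e-10
    np.testing.assert_allclose(tab.data.k7 / tab.data.k8, 156.25, rtol=1e-12)


def test_concentration_scan_conserves_ligand_sum():
    bg = load_enzyme("beta_gal")
    tab = concentration_scan(bg, n_steps=50)
    total = bg.environment.substrate_conc + bg.environment.product_conc
    sums = tab.data.substrate_conc + tab.data.product_conc
    np.testing.assert_allclose(sums, total, rtol=1e-12)
    # row 0 reproduces the reference block
    row0 = tab.data.iloc[0]
    assert row0.x_tot == pytest.approx(16.81, abs=0.01)
    # X_tot/RT strictly decreases as [P]/[S] grows along the scan
    assert (np.diff(tab.data.x_tot.to_numpy()) < 0).all()


def test_concentration_scan_rejects_depletion(tpi):
    with pytest.raises(ValueError, match="concentration"):
        concentration_scan(tpi, n_steps=10, substrate_step=tpi.environment.substrate_conc)


def test_noisy_sample_is_seed_deterministic(tpi, tpi_rates):
    spec = NoiseSpec(
        shift=0.0, draw_policy="per_constant", mask=tuple(range(1, 9)),
        constraint="replace_nonpositive_with_observed",
    )
    a = noisy_sample(tpi_rates, tpi_rates, tpi.environment, spec, 50, seed=123)
    b = noisy_sample(tpi_rates, tpi_rates, tpi.environment, spec, 50, seed=123)
    assert a.data.equals(b.data)
    c = noisy_sample(tpi_rates, tpi_rates, tpi.environment, spec, 50, seed=124)
    assert not a.data.equals(c.data)


def test_shared_fixed_K_noise_has_constant_efficiency_dissipation_ratio(tpi, tpi_rates):
    spec = NoiseSpec(
        shift=2.0, draw_policy="shared", mask=(1, 3, 5, 7),
        constraint="fixed_step_equilibria",
    )
    tab = noisy_sample(tpi_rates, tpi_rates, tpi.environment, spec, 100, seed=7)
    ratio = tab.data.specificity / tab.data.entropy_production
    assert np.ptp(ratio.to_numpy()) / ratio.mean() < 1e-12
    fit = linear_fit(tab, through_origin=True)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fixed_total_force_sampling_shows_interior_dissipation_maximum(tpi, tpi_rates):
    """With X_tot pinned and the K1-K4 pair varied, dissipation peaks at an
    intermediate K4 rather than growing monotonically."""
    # shift-2 multipliers drift the walk from the observed K4 = 156 down
    # through the dissipation peak near K4 ~ 10 and far beyond it
    spec = NoiseSpec(shift=2.0, constraint="fixed_total_force", force_pair=(1, 4))
    tab = noisy_sample(tpi_rates, tpi_rates, tpi.environment, spec, 300, seed=3,
                       params=tpi, cumulative=True)
    assert np.ptp(tab.data.x_tot.to_numpy()) < 1e-10
    d = tab.data.assign(K4=tab.data.k7 / tab.data.k8).sort_values("K4")
    peak = d.entropy_production.idxmax()
    K4_at_peak = d.loc[peak, "K4"]
    assert d.K4.min() < K4_at_peak < d.K4.max()
    # and the dissipation at the edges is well below the peak
    edge = max(d.entropy_production.iloc[0], d.entropy_production.iloc[-1])
    assert d.entropy_production.max() > 1.5 * edge


def test_best_point_single_row_and_tie_break(tpi, tpi_rates):
    one = SampleTable(
        data=stepwise_scan(
            tpi_rates, tpi.environment, 7, 4000.0, 1.0, 1, params=tpi
        ).data
    )
    row = best_point(one, "max_kcat")
    assert row.step == 0
    dup = SampleTable(data=one.data.loc[[0, 0]].assign(step=[0, 1]))
    assert best_point(dup, "max_specificity").step == 0  # earliest step wins


def test_best_point_empty_table_raises():
    with pytest.raises(ValueError):
        best_point(SampleTable(data=__import__("pandas").DataFrame()))


def test_linear_fit_recovers_exact_line():
    import pandas as pd

    x = np.linspace(1, 10, 20)
    tab = SampleTable(
        data=pd.DataFrame(
            {"entropy_production": x, "specificity": 3 * x + 1, "x_tot": 1.0}
        )
    )
    fit = linear_fit(tab)
    assert fit.slope == pytest.approx(3.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="degenerate"):
        linear_fit(
            SampleTable(
                data=pd.DataFrame(
                    {"entropy_production": [1.0, 1.0], "specificity": [1.0, 2.0],
                     "x_tot": [1.0, 1.0]}
                )
            )
        )


def test_fold_report_identity_and_co_movement(tpi, tpi_rates, fig2_scan):
    obs = fig2_scan.data.iloc[0]
    assert all(v == 1.0 for k, v in fold_report(obs, obs).items())
    best = best_point(fig2_scan, "max_specificity")
    folds = fold_report(fig2_scan.data.iloc[398], best)  # k7 = 4000 row = observed
    assert folds["specificity"] == pytest.approx(1.25e6 / 7.86e5, rel=1e-2)
    assert folds["entropy_production"] > 1.0


def test_fixed_K_rows_share_one_fold_factor(tpi, tpi_rates):
    """Under pinned equilibria and a shared multiplier, flux, kcat,
    efficiency and dissipation all move by the same factor."""
    spec = NoiseSpec(shift=2.0, draw_policy="shared", mask=(1, 3, 5, 7),
                     constraint="fixed_step_equilibria")
    tab = noisy_sample(tpi_rates, tpi_rates, tpi.environment, spec, 50, seed=31)
    obs = evaluate_point(tpi_rates, tpi.environment, params=tpi)
    for _, row in tab.data.iloc[:10].iterrows():
        folds = fold_report(__import__("pandas").Series(obs), row)
        assert folds["specificity"] == pytest.approx(folds["flux"], rel=1e-9)
        assert folds["specificity"] == pytest.approx(folds["kcat"], rel=1e-9)
        assert folds["specificity"] == pytest.approx(
            folds["entropy_production"], rel=1e-9
        )
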