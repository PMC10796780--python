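import numpy as np
import pandas as pd
import pytest

from hrfprobe.deconvolution import (SingularDesignError, build_fir_design,
                                    fit_fir, group_hrf_summary,
                                    hrf_features, roi_timecourse)
from hrfprobe.events import EVENT_COLUMNS, generate_event_schedule
from hrfprobe.hrf import HRFParams
from hrfprobe.simulate import (ActivationSpec, ActiveRegion, BoldRun,
                               sample_hrf_at_tr, simulate_run)


def events(rows):
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def make_run(rng, shape=(4, 4, 4), n=40):
    return BoldRun(data=rng.normal(100, 1, size=(*shape, n)), tr_ms=2500.0,
                   subject_id="sub-000", group="control")


# ------------------------------------------------------ ROI timecourse
def test_single_voxel_mask_returns_that_series(rng):
    run = make_run(rng)
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1, 2, 3] = True
    assert np.array_equal(roi_timecourse(run, mask), run.data[1, 2, 3])


def test_two_voxel_mask_matches_mean_oracle(rng):
    run = make_run(rng)
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = mask[3, 3, 3] = True
    oracle = (run.data[0, 0, 0] + run.data[3, 3, 3]) / 2.0
    assert np.max(np.abs(roi_timecourse(run, mask) - oracle)) < 1e-12


def test_empty_mask_rejected(rng):
    with pytest.raises(ValueError, match="empty"):
        roi_timecourse(make_run(rng), np.zeros((4, 4, 4), dtype=bool))


# ------------------------------------------------------------- design
def test_coverage_20s_at_tr_2500_gives_8_lags():
    sched = events([(10000.0, 400.0, "submax", "left")])
    design = build_fir_design(sched, 2500.0, 40, coverage_s=20.0)
    assert design.n_lags == 8
    assert np.allclose(design.lag_times_s, np.arange(8) * 2.5)


def test_single_event_columns_have_one_stick_each():
    sched = events([(10000.0, 400.0, "submax", "left")])
    design = build_fir_design(sched, 2500.0, 40)
    X = design.matrix
    assert design.column_names[0] == "intercept"
    for lag in range(8):
        col = X[:, 1 + lag]
        assert col.sum() == 1.0
        assert col[4 + lag] == 1.0


def test_overlapping_events_column_sums_match_enumeration_oracle():
    sched = generate_event_schedule(3, rng_seed=0)
    design = build_fir_design(sched, 2500.0, 48)
    # enumeration oracle: occurrences of each (type, lag) within the run
    for et in design.event_types:
        for lag in range(design.n_lags):
            j = design.column_names.index(f"{et}_lag{lag}")
            expected = sum(
                1 for _, ev in sched.iterrows()
                if f"{ev['condition']}_{ev['hemifield']}" == et
                and int(round(ev["onset_ms"] / 2500.0)) + lag < 48)
            assert design.matrix[:, j].sum() == expected


def test_collinear_design_raises_naming_columns():
    rows = [(10000.0, 400.0, "submax", "left"),
            (10000.0, 400.0, "threshold", "left")]  # identical onsets
    with pytest.raises(SingularDesignError, match="collinear"):
        build_fir_design(events(rows), 2500.0, 40)


# ------------------------------------------------------------- fitting
def test_noiseless_linear_model_recovered_exactly(rng):
    sched = generate_event_schedule(4, rng_seed=0)
    design = build_fir_design(sched, 2500.0, 120)
    beta_true = rng.normal(size=design.matrix.shape[1])
    y = design.matrix @ beta_true
    est = fit_fir(design, y)
    fitted = est.betas.set_index(["event_type", "lag_s"])["beta"]
    for k, et in enumerate(design.event_types):
        for lag in range(design.n_lags):
            j = design.column_names.index(f"{et}_lag{lag}")
            assert fitted[(et, lag * 2.5)] == pytest.approx(
                beta_true[j], abs=1e-8)


def test_isolated_events_recover_tr_sampled_response():
    """Noiseless run with events spaced beyond coverage: betas equal the
    TR-sampled ground-truth HRF."""
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1, 1, 1] = True
    spec = ActivationSpec(regions=[ActiveRegion(mask=mask,
                                                hemifield="left")],
                          noise_sd=0.0)
    sched = events([(10000.0 + 25000.0 * i, 400.0, "submax", "left")
                    for i in range(3)])
    run = simulate_run(sched, spec, HRFParams(), n_volumes=50,
                       volume_shape=(4, 4, 4))
    design = build_fir_design(sched, 2500.0, run.n_volumes)
    est = fit_fir(design, roi_timecourse(run, mask))
    betas = est.betas["beta"].to_numpy()
    truth = sample_hrf_at_tr(HRFParams(), 2500.0)
    assert np.max(np.abs(betas - truth)) < 1e-8


def test_ols_matches_statsmodels_oracle(rng):
    sched = generate_event_schedule(4, rng_seed=1)
    design = build_fir_design(sched, 2500.0, 120)
    y = rng.normal(size=120)
    est = fit_fir(design, y)
    import statsmodels.api as sm
    fit = sm.OLS(y, design.matrix).fit()
    ours = np.empty(design.matrix.shape[1])
    ses = np.empty_like(ours)
    fitted = est.betas.set_index(["event_type", "lag_s"])
    for et in design.event_types:
        for lag in range(design.n_lags):
            j = design.column_names.index(f"{et}_lag{lag}")
            ours[j] = fitted.loc[(et, lag * 2.5), "beta"]
            ses[j] = fitted.loc[(et, lag * 2.5), "se"]
    stim = [j for j in range(design.matrix.shape[1])
            if design.column_names[j] != "intercept"]
    assert np.max(np.abs(ours[stim] - fit.params[stim])) < 1e-8
    assert np.max(np.abs(ses[stim] - fit.bse[stim])) < 1e-8


def test_residuals_orthogonal_to_design(rng):
    sched = generate_event_schedule(3, rng_seed=2)
    design = build_fir_design(sched, 2500.0, 80)
    y = rng.normal(size=80)
    est = fit_fir(design, y)
    # rebuild residuals from the full beta vector via lstsq equivalence
    beta, *_ = np.linalg.lstsq(design.matrix, y, rcond=None)
    resid = y - design.matrix @ beta
    inner = design.matrix.T @ resid
    scale = np.linalg.norm(resid) * np.linalg.norm(design.matrix, axis=0)
    assert np.max(np.abs(inner) / np.maximum(scale, 1e-30)) < 1e-8


def test_underdetermined_fit_rejected(rng):
    sched = events([(0.0, 400.0, "submax", "left")])
    design = build_fir_design(sched, 2500.0, 9)
    with pytest.raises(ValueError, match="more volumes"):
        fit_fir(design, rng.normal(size=9))


# ------------------------------------------------------------- summary
def _estimate(rng, group="control", roi=1, sid="sub-000", betas=None):
    lags = np.arange(8) * 2.5
    b = betas if betas is not None else rng.normal(size=8)
    df = pd.DataFrame({"event_type": "submax_left", "lag_s": lags,
                       "beta": b, "se": 0.1})
    from hrfprobe.deconvolution import HRFEstimate
    return HRFEstimate(betas=df, roi_id=roi, subject_id=sid, group=group)


def test_identical_estimates_have_zero_sd(rng):
    b = rng.normal(size=8)
    ests = [_estimate(rng, sid=f"s{i}", betas=b.copy()) for i in range(4)]
    out = group_hrf_summary(ests)
    assert np.allclose(out["sd"], 0.0)
    assert np.allclose(out["mean"], np.sort(b)[np.argsort(np.argsort(b))])


def test_two_estimate_summary_matches_closed_forms(rng):
    b1, b2 = rng.normal(size=8), rng.normal(size=8)
    out = group_hrf_summary([_estimate(rng, sid="a", betas=b1),
                             _estimate(rng, sid="b", betas=b2)])
    out = out.sort_values("lag_s")
    assert np.allclose(out["mean"], (b1 + b2) / 2)
    assert np.allclose(out["sd"], np.abs(b1 - b2) / np.sqrt(2))


def test_summary_requires_two_per_group(rng):
    with pytest.raises(ValueError):
        group_hrf_summary([_estimate(rng)])


# ------------------------------------------------------------ features
def test_features_of_stated_beta_vector():
    feats = hrf_features(np.array([0, 1, 3, 2, 0, -1, -0.2, 0.0]),
                         tr_s=2.5)
    assert feats.time_to_peak_s == pytest.approx(5.0)
    assert feats.peak_amplitude == pytest.approx(3.0)
    assert feats.undershoot_depth == pytest.approx(1.0)


def test_nonnegative_betas_have_zero_undershoot():
    feats = hrf_features(np.array([0, 1, 2, 1, 0.5, 0.2, 0.1, 0.0]), 2.5)
    assert feats.undershoot_depth == 0.0


def test_all_equal_betas_rejected():
    with pytest.raises(ValueError):
        hrf_features(np.ones(8), 2.5)


def test_injected_latency_recovered_at_lag_resolution():
    """Simulator round trip: a +2.5 s patient latency appears as a
    +2.5 s raw time-to-peak difference."""
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1, 1, 1] = True
    spec = ActivationSpec(regions=[ActiveRegion(mask=mask,
                                                hemifield="left")],
                          noise_sd=0.0)
    sched = events([(10000.0 + 25000.0 * i, 400.0, "submax", "left")
                    for i in range(3)])
    times = {}
    for name, params in (("control", HRFParams()),
                         ("patient", HRFParams(latency_shift=2.5))):
        run = simulate_run(sched, spec, params, n_volumes=50,
                           volume_shape=(4, 4, 4))
        design = build_fir_design(sched, 2500.0, run.n_volumes)
        est = fit_fir(design, roi_timecourse(run, mask))
        times[name] = hrf_features(est.betas["beta"].to_numpy(),
                                   2.5).time_to_peak_s
    assert times["patient"] - times["control"] == pytest.approx(2.5)
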