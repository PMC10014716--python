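"""Generator unit tests: marginal matching, calibration algebra, determinism."""

import numpy as np
import pandas as pd
import pytest

from riskbn import synthdata
from riskbn._discrete import DiscreteScaleDistribution, fit_scale_pmf
from riskbn._discrete import ScaleFitError
from riskbn.synthdata import (CalibrationTargets, ConfigurationError, TRAITS,
                              default_config, default_latent_corr,
                              generate_survey, simulate_prevalences)

ALL_SCALES = [(c, col, m, sd) for c in ("austria", "uk")
              for col, (m, sd) in synthdata._SCALE_MOMENTS[c].items()]


@pytest.mark.parametrize("country,col,mean,sd", ALL_SCALES,
                         ids=[f"{c}-{col}" for c, col, _, _ in ALL_SCALES])
def test_scale_pmf_matches_printed_moments(country, col, mean, sd):
    lo, hi = synthdata.SCALE_SUPPORT[col]
    pmf = fit_scale_pmf(mean, sd, lo, hi)
    ks = np.arange(lo, hi + 1)
    m = ks @ pmf
    s = np.sqrt(pmf @ (ks - m) ** 2)
    assert m == pytest.approx(mean, abs=1e-6)
    assert s == pytest.approx(sd, abs=1e-6)
    assert pmf.min() >= 0


def test_scale_pmf_rejects_unattainable_moments():
    with pytest.raises(ScaleFitError):
        fit_scale_pmf(1.0, 10.0, 0, 24)  # variance beyond two-point bound
    with pytest.raises(ScaleFitError):
        fit_scale_pmf(30.0, 2.0, 0, 24)  # mean outside support


def test_tilt_moves_tail_mass_but_not_moments():
    base = DiscreteScaleDistribution(5.93, 5.0, 0, 24)
    tilted = DiscreteScaleDistribution(5.93, 5.0, 0, 24, tilt_at=10, tilt=-0.6)
    assert tilted.moments[0] == pytest.approx(5.93, abs=1e-6)
    assert tilted.moments[1] == pytest.approx(5.0, abs=1e-6)
    assert tilted.tail_prob(10) < base.tail_prob(10)


def test_latent_corr_default_is_valid_correlation():
    C = default_latent_corr()
    assert np.allclose(C, C.T)
    assert np.allclose(np.diag(C), 1.0)
    assert np.linalg.eigvalsh(C).min() > 0
    i, j = TRAITS.index("depression"), TRAITS.index("anxiety")
    assert C[i, j] == 0.7


def test_generate_survey_is_deterministic_and_schema_complete(austria_config):
    a = generate_survey(austria_config, seed=42)
    b = generate_survey(austria_config, seed=42)
    c = generate_survey(austria_config, seed=43)
    pd.testing.assert_frame_equal(a, b)
    assert not a.equals(c)
    assert list(a.columns) == synthdata.SCHEMA_COLUMNS
    assert len(a) == austria_config.n
    assert not a.isna().any().any()


def test_scores_respect_instrument_supports(austria_survey):
    for col, (lo, hi) in synthdata.SCALE_SUPPORT.items():
        if col == "phq8":
            continue
        assert austria_survey[col].between(lo, hi).all(), col
    items = austria_survey[[f"phq_i{i}" for i in range(1, 10)]]
    assert items.isin([0, 1, 2, 3]).all().all()
    total = items.sum(axis=1)
    assert total.between(0, 27).all()


def test_identity_latent_corr_gives_uncorrelated_scales():
    cfg = default_config("austria", n=4000)
    cfg.latent_corr = np.eye(len(TRAITS))
    df = generate_survey(cfg, seed=5)
    r = np.corrcoef(df["gad7"], df["loneliness"])[0, 1]
    r2 = np.corrcoef(df["isi"], df["cdrisc"])[0, 1]
    assert abs(r) < 0.06
    assert abs(r2) < 0.06


def test_null_outcome_model_gives_logistic_intercept_prevalence():
    cfg = default_config("austria", n=1005)
    cfg.outcome_model.beta = {t: 0.0 for t in TRAITS}
    cfg.outcome_model.beta0 = 0.0  # P(endorse) = 1/2 for everyone
    got = simulate_prevalences(cfg, mc_n=50_000, seed=3)
    assert got["p_si"] == pytest.approx(0.5, abs=0.01)
    # with no trait effects the only remaining separation is the mechanical
    # coupling of item 9 into its own PHQ-9 >= 10 conditioning total; it is
    # symmetric around the marginal and far smaller than any calibrated gap
    gap = got["p_si_dep"] - got["p_si_nondep"]
    assert 0 <= gap < 0.15
    assert got["p_si_dep"] + got["p_si_nondep"] == pytest.approx(2 * got["p_si"],
                                                                 abs=0.06)

    cfg.outcome_model.beta0 = -30.0  # limit: nobody endorses
    df = generate_survey(cfg, seed=4)
    assert (df["phq_i9"] == 0).all()


def test_separation_monotone_in_depression_coefficient():
    cfg = default_config("austria", n=1005)
    gaps = []
    for bdep in (0.0, 0.8, 1.6):
        cfg.outcome_model.beta["depression"] = bdep
        got = simulate_prevalences(cfg, mc_n=60_000, seed=9)
        gaps.append(got["p_si_dep"] - got["p_si_nondep"])
    assert gaps[0] < gaps[1] < gaps[2]


@pytest.mark.parametrize("targets,expected", [
    ((0.173, 0.550, 0.073), 0.20964),
    ((0.317, 0.645, 0.088), 0.41113),
])
def test_implied_depression_rate_total_probability(targets, expected):
    # independent closed form: p_si = p_dep*p_si_dep + (1-p_dep)*p_si_nondep
    p_si, p_si_dep, p_si_nondep = targets
    closed = (p_si - p_si_nondep) / (p_si_dep - p_si_nondep)
    ct = CalibrationTargets(*targets)
    assert ct.p_dep == pytest.approx(closed, abs=1e-12)
    assert ct.p_dep == pytest.approx(expected, abs=1e-4)


def test_calibrated_config_hits_targets_on_fresh_sample(austria_config):
    got = simulate_prevalences(austria_config, mc_n=150_000, seed=777)
    t = austria_config.calibration_targets
    assert got["p_si"] == pytest.approx(t.p_si, abs=0.01)
    assert got["p_si_dep"] == pytest.approx(t.p_si_dep, abs=0.015)
    assert got["p_si_nondep"] == pytest.approx(t.p_si_nondep, abs=0.01)
    assert got["p_dep"] == pytest.approx(t.p_dep, abs=0.01)


def test_uk_helplessness_depends_on_age(uk_config):
    df = generate_survey(uk_config, seed=31)
    young = df.loc[df["age_group"] == "18-24", "pss_helplessness"].mean()
    old = df.loc[df["age_group"] == "65+", "pss_helplessness"].mean()
    assert young > old


def test_config_yaml_round_trip(tmp_path, austria_config):
    path = tmp_path / "cfg.yaml"
    austria_config.to_yaml(path)
    back = synthdata.GeneratorConfig.from_yaml(path)
    pd.testing.assert_frame_equal(generate_survey(back, seed=8),
                                  generate_survey(austria_config, seed=8))


def test_csv_output_is_byte_identical(tmp_path, austria_config):
    df = generate_survey(austria_config, seed=12)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    synthdata.write_survey_csv(df, p1)
    synthdata.write_survey_csv(generate_survey(austria_config, seed=12), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_invalid_configs_rejected():
    cfg = default_config("austria")
    bad = cfg.latent_corr.copy()
    bad[0, 1] = bad[1, 0] = 0.999999
    bad[0, 2] = bad[2, 0] = -0.999999
    bad[1, 2] = bad[2, 1] = 0.999999
    with pytest.raises(ConfigurationError):
        synthdata.GeneratorConfig(
            country="austria", n=10, scale_specs=cfg.scale_specs,
            latent_corr=bad, outcome_model=cfg.outcome_model,
            calibration_targets=cfg.calibration_targets,
            demographics=cfg.demographics)
    with pytest.raises(ConfigurationError):
        synthdata.GeneratorConfig(
            country="austria", n=0, scale_specs=cfg.scale_specs,
            latent_corr=cfg.latent_corr, outcome_model=cfg.outcome_model,
            calibration_targets=cfg.calibration_targets,
            demographics=cfg.demographics)
    with pytest.raises(ConfigurationError):
        CalibrationTargets(0.5, 0.4, 0.45)  # marginal not between conditionals
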