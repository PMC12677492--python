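"""Engine-level checks: discrepancy, implied moments, fitting, indices, SEs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paneltri import sem_core as sc
from paneltri.sem_core import (SampleMoments, SemModelSpec, fit, fit_indices,
                               fml_discrepancy, implied_moments,
                               independence_spec, saturated_spec)


def _moments(cov, n=400, names=None):
    cov = np.asarray(cov, dtype=float)
    names = names or [f"v{i}" for i in range(cov.shape[0])]
    return SampleMoments(cov=cov, mean=np.zeros(cov.shape[0]), n=n, var_names=names)


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def test_implied_moments_no_structure_is_diagonal():
    spec = SemModelSpec(variables=["a", "b"], observed=["a", "b"],
                        covs={("a", "a"): "va", ("b", "b"): "vb"})
    Sigma, mu = implied_moments(spec, np.array([1.0, 1.0]))
    assert np.allclose(Sigma, np.eye(2))
    assert np.allclose(mu, 0)


def test_implied_moments_single_indicator_factor():
    spec = SemModelSpec(variables=["obs", "eta"], observed=["obs"],
                        paths={("obs", "eta"): 1.0},
                        covs={("eta", "eta"): "v", ("obs", "obs"): "u"})
    Sigma, _ = implied_moments(spec, np.array([2.0, 0.5]))
    assert Sigma.shape == (1, 1)
    assert Sigma[0, 0] == pytest.approx(2.5)


def test_unit_gain_feedback_loop_raises_with_cycle():
    spec = SemModelSpec(variables=["a", "b"], observed=["a", "b"],
                        paths={("a", "b"): 1.0, ("b", "a"): 1.0},
                        covs={("a", "a"): "va", ("b", "b"): "vb"})
    with pytest.raises(np.linalg.LinAlgError, match="->"):
        implied_moments(spec, np.array([1.0, 1.0]))


# ---------------------------------------------------------------------------
# discrepancy
# ---------------------------------------------------------------------------

def test_fml_zero_iff_perfect_fit():
    S = np.array([[2.0, 0.5], [0.5, 1.0]])
    assert fml_discrepancy(S, None, S, None, 2) == pytest.approx(0.0, abs=1e-12)
    assert fml_discrepancy(S, None, S * 1.3, None, 2) > 0


def test_fml_hand_value_univariate():
    # ln(1) + 2/1 - ln(2) - 1 = 1 - ln 2
    f = fml_discrepancy(np.array([[2.0]]), None, np.array([[1.0]]), None, 1)
    assert f == pytest.approx(1.0 - math.log(2.0), abs=1e-12)


def test_fml_mean_term():
    S = np.array([[1.0]])
    f = fml_discrepancy(S, np.array([0.3]), S, np.array([0.0]), 1)
    assert f == pytest.approx(0.09, abs=1e-12)


def test_fml_nonpd_sigma_penalised_not_raised():
    S = np.array([[1.0, 0.0], [0.0, 1.0]])
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    val = fml_discrepancy(S, None, bad, None, 2)
    assert np.isfinite(val) and val > 1e6


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=5), st.integers(min_value=0, max_value=10 ** 6))
def test_fml_invariant_under_common_reordering(p, seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(p + 3, p))
    S = a.T @ a / (p + 2)
    b = rng.normal(size=(p + 3, p))
    Sigma = b.T @ b / (p + 2) + np.eye(p)
    perm = rng.permutation(p)
    f1 = fml_discrepancy(S, None, Sigma, None, p)
    f2 = fml_discrepancy(S[np.ix_(perm, perm)], None, Sigma[np.ix_(perm, perm)], None, p)
    assert f1 == pytest.approx(f2, rel=1e-9, abs=1e-10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_saturated_model_perfect_fit():
    rng = np.random.default_rng(5)
    a = rng.normal(size=(50, 3))
    mom = _moments(np.cov(a, rowvar=False))
    res = fit(saturated_spec(mom.var_names), mom)
    assert res.converged
    assert res.df == 0
    assert res.chi2 == pytest.approx(0.0, abs=1e-6)
    Sigma, _ = res.implied()
    assert np.allclose(Sigma, mom.cov, atol=1e-6)


def test_one_factor_triad_closed_form():
    # with three standardized indicators the loading solution is
    # lambda_1 = sqrt(r12 r13 / r23), and the model is just-identified
    r12, r13, r23 = 0.42, 0.30, 0.35
    S = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    spec = SemModelSpec(
        variables=["i1", "i2", "i3", "eta"], observed=["i1", "i2", "i3"],
        paths={("i1", "eta"): "l1", ("i2", "eta"): "l2", ("i3", "eta"): "l3"},
        covs={("eta", "eta"): 1.0, ("i1", "i1"): "u1", ("i2", "i2"): "u2",
              ("i3", "i3"): "u3"},
        starts={"l1": 0.5, "l2": 0.5, "l3": 0.5})
    res = fit(spec, _moments(S, names=["i1", "i2", "i3"]))
    assert res.converged
    assert res.df == 0
    assert res.chi2 == pytest.approx(0.0, abs=1e-5)
    lam1 = math.sqrt(r12 * r13 / r23)
    assert abs(res.estimate("l1")) == pytest.approx(lam1, abs=1e-4)


def test_identification_error_when_df_negative():
    over = SemModelSpec(variables=["a", "eta"], observed=["a"],
                        paths={("a", "eta"): "l"},
                        covs={("eta", "eta"): "v", ("a", "a"): "u"})
    with pytest.raises(sc.IdentificationError):
        fit(over, _moments(np.array([[2.0]]), names=["a"]))


def test_chi2_permutation_invariance(mosla_population_moments, layout):
    from paneltri import build_mosla
    spec = build_mosla(layout)
    rng = np.random.default_rng(11)
    noisy = mosla_population_moments.cov + 0.02 * np.eye(6)
    mom = _moments(noisy, names=mosla_population_moments.var_names)
    fit1 = fit(spec, mom, compute_se=False, standardized=False)
    perm = rng.permutation(6)
    mom2 = mom.reorder([mom.var_names[i] for i in perm])
    fit2 = fit(spec, mom2, compute_se=False, standardized=False)
    assert fit1.chi2 == pytest.approx(fit2.chi2, rel=1e-5, abs=1e-7)


def test_chi2_scale_switch(mosla_population_moments, layout):
    from paneltri import build_mosla
    spec = build_mosla(layout)
    mom = _moments(mosla_population_moments.cov + 0.02 * np.eye(6),
                   names=mosla_population_moments.var_names, n=401)
    f_nm1 = fit(spec, mom, compute_se=False, standardized=False, chi2_scale="n-1")
    f_n = fit(spec, mom, compute_se=False, standardized=False, chi2_scale="n")
    assert f_n.chi2 == pytest.approx(f_nm1.chi2 * 401 / 400, rel=1e-6)


def test_baseline_closed_form_matches_engine():
    rng = np.random.default_rng(7)
    a = rng.normal(size=(200, 4))
    a[:, 1] += 0.5 * a[:, 0]
    mom = _moments(np.cov(a, rowvar=False))
    res = fit(independence_spec(mom.var_names), mom, compute_se=False,
              standardized=False)
    R = np.corrcoef(a, rowvar=False)
    expected = -np.linalg.slogdet(R)[1] * (mom.n - 1)
    assert res.chi2 == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def test_exact_fit_boundary():
    cfi, tli, rmsea, ci, p, df0 = fit_indices(12.0, 12, 300.0, 15, 400)
    assert rmsea == 0.0
    assert cfi == 1.0
    assert ci[0] <= ci[1]


def test_reference_rmsea_value():
    # chi2 = 25.7 on df = 12 at n = 400 prints RMSEA 0.05 [0.02; 0.08]
    cfi, tli, rmsea, ci, p, df0 = fit_indices(25.7, 12, 500.0, 15, 400)
    assert rmsea == pytest.approx(math.sqrt((25.7 - 12) / (12 * 399)), abs=1e-12)
    assert round(rmsea, 2) == 0.05
    assert round(ci[0], 2) == 0.02
    assert round(ci[1], 2) == 0.08
    assert p == pytest.approx(stats.chi2.sf(25.7, 12))


def test_tli_can_exceed_one_and_go_negative():
    # better-than-expected fit: chi2 < df pushes TLI above 1
    _, tli_hi, *_ = fit_indices(2.10, 5, 400.0, 15, 400)
    assert tli_hi > 1.0
    # baseline ratio smaller than target ratio: TLI below 0, unclamped
    _, tli_lo, *_ = fit_indices(80.0, 10, 22.0, 15, 400)
    assert tli_lo < 0.0


def test_df_zero_rmsea_flagged():
    cfi, tli, rmsea, ci, p, df0 = fit_indices(0.0, 0, 100.0, 10, 200)
    assert df0 and rmsea == 0.0


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardized_equals_unstandardized_for_unit_variances():
    spec = SemModelSpec(
        variables=["a", "b"], observed=["a", "b"],
        paths={("b", "a"): "beta"},
        covs={("a", "a"): 1.0, ("b", "b"): "u"})
    S = np.array([[1.0, 0.6], [0.6, 1.0]])
    res = fit(spec, _moments(S, names=["a", "b"]))
    est, se = res.std_path("b", "a")
    # var(a)=1, var(b)=1 at the solution, so standardized == raw
    assert est == pytest.approx(res.estimate("beta"), abs=1e-6)
    assert est == pytest.approx(0.6, abs=1e-4)


def test_standardization_rescaling_arithmetic():
    # raw path 1 with sd(source) 2 and sd(target) 4 -> standardized 0.5
    spec = SemModelSpec(
        variables=["a", "b"], observed=["a", "b"],
        paths={("b", "a"): "beta"},
        covs={("a", "a"): "va", ("b", "b"): "u"})
    S = np.array([[4.0, 4.0], [4.0, 16.0]])  # b = 1*a + e, var(e)=12
    res = fit(spec, _moments(S, names=["a", "b"]))
    assert res.estimate("beta") == pytest.approx(1.0, abs=1e-5)
    assert res.std_path("b", "a")[0] == pytest.approx(0.5, abs=1e-5)


def test_standardized_covariances_are_correlations(mosla_population_moments, layout):
    from paneltri import build_mosla
    res = fit(build_mosla(layout), mosla_population_moments)
    est, _ = res.std_cov("g_x", "g_y")
    raw = res.estimate("c_g")
    vx, vy = res.estimate("v_gx"), res.estimate("v_gy")
    assert est == pytest.approx(raw / math.sqrt(vx * vy), abs=1e-6)
    assert -1 <= est <= 1


def test_riclpm_standardization_brute_force(mosla_population_moments, layout):
    """Standardized RI-CLPM solution equals direct rescaling from the
    implied full covariance matrix."""
    from paneltri import build_riclpm
    from paneltri.sem_core import implied_full_cov
    spec = build_riclpm(layout)
    res = fit(spec, mosla_population_moments)
    V = implied_full_cov(spec, res.theta_hat)
    sd = np.sqrt(np.diag(V))
    iv = {v: i for i, v in enumerate(spec.variables)}
    for (tgt, src), entry in spec.paths.items():
        if not isinstance(entry, str):
            continue
        raw = res.estimate(entry)
        expected = raw * sd[iv[src]] / sd[iv[tgt]]
        assert res.std_path(tgt, src)[0] == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# uncertainty calibration (stochastic)
# ---------------------------------------------------------------------------

def test_ci_coverage_on_simulated_path_model():
    """95% CIs from the observed information cover generating parameters at a
    nominal-compatible rate on a small recursive path model (x -> m -> y)."""
    b1, b2 = 0.5, 0.4
    spec = SemModelSpec(
        variables=["x", "m", "y"], observed=["x", "m", "y"],
        paths={("m", "x"): "b1", ("y", "m"): "b2"},
        covs={("x", "x"): "vx", ("m", "m"): "vm", ("y", "y"): "vy"})
    rng = np.random.default_rng(2024)
    hits = {"b1": 0, "b2": 0}
    reps = 200
    for _ in range(reps):
        x = rng.normal(size=400)
        m = b1 * x + rng.normal(size=400)
        y = b2 * m + rng.normal(size=400)
        S = np.cov(np.column_stack([x, m, y]), rowvar=False)
        res = fit(spec, _moments(S, names=["x", "m", "y"]), n_starts=1, standardized=False)
        for lab, truth in (("b1", b1), ("b2", b2)):
            est, se = res.estimate(lab), res.se_of(lab)
            if abs(est - truth) <= 1.959963984540054 * se:
                hits[lab] += 1
    for lab in hits:
        assert 0.90 <= hits[lab] / reps <= 0.99


# ---------------------------------------------------------------------------
# moments container
# ---------------------------------------------------------------------------

def test_sample_moments_validation():
    with pytest.raises(ValueError, match="symmetric"):
        SampleMoments(np.array([[1.0, 0.5], [0.1, 1.0]]), np.zeros(2), 50, ["a", "b"])
    with pytest.raises(ValueError, match="too small"):
        SampleMoments(np.eye(3), np.zeros(3), 3, ["a", "b", "c"])


def test_sample_moments_csv_round_trip(tmp_path):
    mom = _moments(np.array([[2.0, 0.3], [0.3, 1.0]]), n=123, names=["p", "q"])
    path = tmp_path / "mom.csv"
    mom.to_csv(path)
    back = SampleMoments.read_csv(path)
    assert back.n == 123 and back.var_names == ["p", "q"]
    assert np.allclose(back.cov, mom.cov)
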