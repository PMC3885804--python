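import numpy as np
import pandas as pd
import pytest

from pprpanel.gmm import (GMMSpec, fit_system_gmm, instrument_columns,
                          within_groups)
from pprpanel.synth import TruthParameters, simulate_panel


def _ar_panel(N, T, seed, a1=0.5, a2=0.0, b0=10.0, sl=5.0, su=3.0, burn=50,
              ma=0.0):
    """Pure autoregressive panel with fixed effects (independent generator)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(N):
        lam = rng.normal(0, sl)
        mu = (b0 + lam) / (1 - a1 - a2)
        y1 = y2 = mu
        e_prev = 0.0
        for t in range(1 - burn, T + 1):
            e = rng.normal(0, su)
            y = b0 + a1 * y1 + a2 * y2 + lam + e + ma * e_prev
            e_prev = e
            y2, y1 = y1, y
            if t >= 1:
                rows.append((f"P{i:04d}", t, y))
    return pd.DataFrame(rows, columns=["patient_id", "t", "ppr"])


def enumerate_moment_columns(panel, spec):
    """Brute-force instrument enumeration from first principles.

    Walks every patient's period structure directly and counts the
    distinct non-empty instrument columns the moment conditions imply,
    independent of the estimator's matrix construction.
    """
    p = spec.dep_lags
    regs = list(spec.exogenous) + list(spec.endogenous) + list(spec.predetermined)
    pats = {}
    for pid, grp in panel.groupby("patient_id"):
        g = grp.sort_values("t")
        pats[pid] = (dict(zip(g["t"], g[spec.dependent])),
                     {v: dict(zip(g["t"], g[v])) for v in regs})
    cols = set()
    for pid, (y, vals) in pats.items():
        ts = sorted(y)
        lvl = [t for t in ts if all(t - j in y for j in range(1, p + 1))]
        has_diff_block = p or spec.endogenous or spec.predetermined
        diff = [t for t in lvl if t - 1 in lvl] if has_diff_block else []
        gmm_vars = ([("dep", None, 2)] if p else []) \
            + [("end", v, 2) for v in spec.endogenous] \
            + [("pre", v, 1) for v in spec.predetermined]
        for t in diff:
            for kind, v, lag0 in gmm_vars:
                series = y if v is None else vals[v]
                for lag in range(lag0, lag0 + spec.max_lag_depth):
                    if t - lag in series:
                        cols.add(("d", kind, v, lag) if spec.collapse
                                 else ("d", kind, v, lag, t))
            for x in spec.exogenous:
                cols.add(("d", "iv", x))
        for t in lvl:
            if has_diff_block:
                for kind, v, _ in gmm_vars:
                    series = y if v is None else vals[v]
                    if t - 1 in series and t - 2 in series:
                        cols.add(("l", kind, v) if spec.collapse
                                 else ("l", kind, v, t))
            for x in spec.exogenous:
                cols.add(("l", "iv", x))
        if lvl:
            cols.add(("l", "iv", "const"))
    return cols


class TestInstrumentCounts:
    def test_ar1_balanced_hand_enumeration(self):
        # 3 patients, T=4, AR(1): difference rows t=3,4
        panel = _ar_panel(3, 4, seed=1)
        spec = GMMSpec(dep_lags=1, exogenous=(), endogenous=(),
                       predetermined=(), min_obs_ratio=0)
        cols = instrument_columns(panel, spec)
        diff_cols = [c for c in cols if c[0] == "d"]
        # collapsed: usable lag distances are 2 (t=3,4) and 3 (t=4)
        assert len(diff_cols) == 2
        spec_u = GMMSpec(dep_lags=1, exogenous=(), endogenous=(),
                         predetermined=(), collapse=False, min_obs_ratio=0)
        cols_u = instrument_columns(panel, spec_u)
        diff_u = [c for c in cols_u if c[0] == "d"]
        # uncollapsed: y1 for t=3; y1, y2 for t=4
        assert len(diff_u) == 3

    @pytest.mark.parametrize("collapse", [True, False])
    @pytest.mark.parametrize("classes", [
        dict(exogenous=(), endogenous=(), predetermined=()),
        dict(exogenous=("x1",), endogenous=(), predetermined=()),
        dict(exogenous=(), endogenous=("w1",), predetermined=("v1",)),
        dict(exogenous=("x1",), endogenous=("w1",), predetermined=("v1",)),
    ])
    def test_counts_match_enumeration_oracle_on_unbalanced_panels(
            self, collapse, classes):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(5):
            T = int(rng.integers(3, 7))
            skip = int(rng.integers(0, T + 1))  # punch a hole in some panels
            for t in range(1, T + 1):
                if t == skip:
                    continue
                rows.append((f"P{i}", t, rng.normal(), rng.normal(),
                             rng.normal(), rng.normal()))
        panel = pd.DataFrame(rows, columns=["patient_id", "t", "ppr",
                                            "x1", "w1", "v1"])
        spec = GMMSpec(dep_lags=2, collapse=collapse, min_obs_ratio=0,
                       max_lag_depth=3, **classes)
        got = instrument_columns(panel, spec)
        expect = enumerate_moment_columns(panel, spec)
        assert len(got) == len(expect)


class TestExactAndDegenerate:
    def test_noiseless_data_recovered_to_machine_tolerance(self):
        truth = TruthParameters(n_patients=400, sigma_lambda=0, sigma_u=0,
                                seed=5)
        panel, _ = simulate_panel(truth)
        res = fit_system_gmm(panel, GMMSpec(min_obs_ratio=0))
        err = (res.params.reindex(truth.coefficients().index)
               - truth.coefficients()).abs().max()
        assert err < 1e-6

    def test_static_exogenous_model_equals_pooled_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 300
        df = pd.DataFrame({
            "patient_id": np.repeat([f"P{i}" for i in range(60)], 5),
            "t": np.tile(np.arange(1, 6), 60),
            "x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["ppr"] = 2.0 + 1.5 * df["x1"] - 0.7 * df["x2"] + rng.normal(size=n)
        spec = GMMSpec(dep_lags=0, exogenous=("x1", "x2"), endogenous=(),
                       predetermined=(), min_obs_ratio=0)
        res = fit_system_gmm(df, spec)
        ols = sm.OLS(df["ppr"], sm.add_constant(df[["x1", "x2"]])).fit()
        assert res.params["x1"] == pytest.approx(ols.params["x1"], abs=1e-8)
        assert res.params["x2"] == pytest.approx(ols.params["x2"], abs=1e-8)
        assert res.params["const"] == pytest.approx(ols.params["const"], abs=1e-8)
        assert res.hansen_df == 0

    def test_underidentification_guard(self):
        panel = _ar_panel(3, 3, seed=2)
        spec = GMMSpec(min_obs_ratio=10.0)
        with pytest.raises(ValueError):
            fit_system_gmm(panel, spec)


class TestInvariances:
    def test_estimates_invariant_to_patient_relabelling_and_t_shift(self):
        panel = _ar_panel(150, 6, seed=3, a2=0.1)
        spec = GMMSpec(exogenous=(), endogenous=(), predetermined=(),
                       min_obs_ratio=0)
        base = fit_system_gmm(panel, spec)
        relabel = {p: f"Z{i:05d}" for i, p in
                   enumerate(reversed(sorted(panel["patient_id"].unique())))}
        shuffled = panel.assign(patient_id=panel["patient_id"].map(relabel),
                                t=panel["t"] + 7)
        shuffled = shuffled.sample(frac=1.0, random_state=0)
        alt = fit_system_gmm(shuffled, spec)
        assert np.allclose(base.params, alt.params, atol=1e-8)
        assert np.allclose(base.se, alt.se, atol=1e-8)


class TestComparators:
    def test_within_groups_shows_nickell_bias_system_gmm_does_not(self):
        truth = TruthParameters(n_patients=1500, seed=6, t_min=3, t_max=6)
        panel, _ = simulate_panel(truth)
        gmm = fit_system_gmm(panel)
        wg = within_groups(panel)
        assert wg["ppr_lag1"] < gmm.params["ppr_lag1"] - 0.05
        assert abs(gmm.params["ppr_lag1"] - truth.alpha1) < \
            abs(wg["ppr_lag1"] - truth.alpha1)

    def test_ar2_test_detects_injected_ma_errors(self):
        spec = GMMSpec(exogenous=(), endogenous=(), predetermined=(),
                       min_obs_ratio=0)
        clean = fit_system_gmm(_ar_panel(800, 7, seed=4, a2=0.1), spec)
        dirty = fit_system_gmm(_ar_panel(800, 7, seed=4, a2=0.1, ma=0.5), spec)
        assert clean.ar1_p < 0.01          # differencing induces MA(1)
        assert abs(dirty.ar2_z) > abs(clean.ar2_z)
        assert dirty.ar2_p < 0.05
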