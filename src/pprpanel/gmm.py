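"""System GMM (Blundell-Bond) for unbalanced dynamic panels.

Estimates the dynamic fixed-effects adherence model

.. code-block:: text

    y_it = a1 y_{i,t-1} + ... + ap y_{i,t-p} + x_it' b + lam_i + u_it

by stacking the first-differenced equation (which removes the patient
fixed effect ``lam_i``) with the level equation, instrumenting each with
moment conditions appropriate to the regressor class:

* difference equation — lagged *levels*: the dependent variable and
  endogenous regressors from lag 2 up to lag ``1 + max_lag_depth``,
  predetermined regressors from lag 1 up to ``max_lag_depth``; strictly
  exogenous regressors instrument themselves by their own differences;
* level equation — lag-1 *differences* of the dependent, endogenous and
  predetermined variables, plus levels of the exogenous regressors and the
  intercept (the intercept enters the level equation only).

``collapse=True`` stacks the lag columns across periods into one column
per (variable, lag distance), curbing instrument proliferation in long
panels; missing instrument cells are zero-filled, which is the standard
treatment of unbalancedness in this estimator family. Exactly duplicated
instrument columns (e.g. two regressors whose differences coincide) are
removed deterministically.

One-step estimation uses the standard initial weighting (first-difference
covariance pattern on the difference block, identity on the level block);
two-step uses the clustered optimal weight from one-step residuals, with
Windmeijer's finite-sample correction of the two-step standard errors.
Overidentification is assessed by the Hansen J statistic and serial
correlation of the differenced residuals by the Arellano-Bond AR(1)/AR(2)
tests.

Degenerate case: with no dynamics and no endogenous or predetermined
regressors there is nothing to difference out, and the estimator reduces
to the exactly identified level equation (pooled IV = OLS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pprpanel.synth import TABLE_ORDER

DEFAULT_EXOGENOUS = ("age_years", "years_in_study", "saba_high",
                     "step3", "step4", "step5", "step_change")
DEFAULT_ENDOGENOUS = ("exac_total",)
DEFAULT_PREDETERMINED = ("prior_hosp", "prior_primary", "prior_interaction")


@dataclass(frozen=True)
class GMMSpec:
    dependent: str = "ppr"
    dep_lags: int = 2
    exogenous: tuple = DEFAULT_EXOGENOUS
    endogenous: tuple = DEFAULT_ENDOGENOUS
    predetermined: tuple = DEFAULT_PREDETERMINED
    max_lag_depth: int = 4
    collapse: bool = True
    steps: str = "two"              # "one" | "two"
    windmeijer: bool = True
    min_obs_ratio: float = 10.0     # estimable obs per parameter guard

    def __post_init__(self):
        if self.dep_lags < 0:
            raise ValueError("dep_lags must be >= 0")
        if self.max_lag_depth < 1:
            raise ValueError("max_lag_depth must be >= 1")
        if self.steps not in ("one", "two"):
            raise ValueError("steps must be 'one' or 'two'")
        classes = (set(self.exogenous) | set(self.endogenous)
                   | set(self.predetermined))
        if len(classes) != (len(self.exogenous) + len(self.endogenous)
                            + len(self.predetermined)):
            raise ValueError("regressor classes must be disjoint")

    @property
    def param_names(self) -> list[str]:
        lags = [f"{self.dependent}_lag{j}" for j in range(1, self.dep_lags + 1)]
        return lags + list(self.exogenous) + list(self.endogenous) \
            + list(self.predetermined) + ["const"]

    @property
    def has_difference_block(self) -> bool:
        return bool(self.dep_lags or self.endogenous or self.predetermined)


@dataclass
class GMMResult:
    params: pd.Series
    se: pd.Series
    tstats: pd.Series
    vcov: pd.DataFrame
    params_onestep: pd.Series
    hansen_j: float
    hansen_df: int
    hansen_p: float
    ar1_z: float
    ar1_p: float
    ar2_z: float
    ar2_p: float
    n_obs: int
    n_diff_obs: int
    n_patients: int
    n_instruments: int
    instrument_labels: list
    weighting_flags: list = field(default_factory=list)
    spec: GMMSpec | None = None

    def summary(self) -> pd.DataFrame:
        """Estimates and t-statistics in the conventional reporting order."""
        order = [n for n in TABLE_ORDER if n in self.params.index]
        order += [n for n in self.params.index if n not in order]
        return pd.DataFrame({"estimate": self.params[order],
                             "se": self.se[order],
                             "t_stat": self.tstats[order]})


def _robust_inv(mat: np.ndarray, flags: list, label: str) -> np.ndarray:
    """Symmetric inverse with escalating ridge for singular matrices."""
    m = mat.shape[0]
    tr = float(np.trace(mat))
    if not np.isfinite(tr) or tr <= 0:
        flags.append(f"{label}: zero/invalid weighting, identity substituted")
        return np.eye(m)
    scale = tr / m
    ridge = 0.0
    for k in range(12):
        try:
            c = np.linalg.cholesky(mat + ridge * np.eye(m))
            inv = np.linalg.inv(c)
            if ridge > 0:
                flags.append(f"{label}: ridge {ridge:.2e} applied")
            return inv.T @ inv
        except np.linalg.LinAlgError:
            ridge = scale * 10.0 ** (-10 + k)
    flags.append(f"{label}: pseudo-inverse fallback")
    return np.linalg.pinv(mat, hermitian=True)


class _PatientBlock:
    __slots__ = ("Z", "X", "y", "Hd", "n_diff", "diff_ts", "lvl_ts")


def _build_blocks(panel: pd.DataFrame, spec: GMMSpec):
    """Per-patient system matrices and the global instrument registry."""
    p = spec.dep_lags
    regs = list(spec.exogenous) + list(spec.endogenous) + list(spec.predetermined)
    need = ["patient_id", "t", spec.dependent] + regs
    missing = [c for c in need if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks columns {missing}")

    df = panel.sort_values(["patient_id", "t"], kind="mergesort")
    patients = []
    for pid, grp in df.groupby("patient_id", sort=False):
        ts = grp["t"].to_numpy(dtype=int)
        y = dict(zip(ts, grp[spec.dependent].to_numpy(dtype=float)))
        vals = {v: dict(zip(ts, grp[v].to_numpy(dtype=float))) for v in regs}
        ok = {int(t): (np.isfinite(y[t])
                       and all(np.isfinite(vals[v][t]) for v in regs))
              for t in ts}
        lvl_ts = [t for t in ts
                  if ok.get(t, False)
                  and all(t - j in y and np.isfinite(y[t - j])
                          for j in range(1, p + 1))]
        diff_ts = [t for t in lvl_ts if (t - 1) in lvl_ts] \
            if spec.has_difference_block else []
        if lvl_ts:
            patients.append((pid, y, vals, lvl_ts, diff_ts))

    # global instrument registry (deterministic order)
    all_diff_ts = sorted({t for *_, d in patients for t in d})
    all_lvl_ts = sorted({t for *_, l, _ in patients for t in l})
    gmm_vars_diff = ([("dep", None)] if p else []) \
        + [("var", v) for v in spec.endogenous]
    pre_vars = [("var", v) for v in spec.predetermined]
    columns: list[tuple] = []
    if spec.has_difference_block:
        for kind, v in gmm_vars_diff:
            for lag in range(2, spec.max_lag_depth + 2):
                if spec.collapse:
                    columns.append(("d", kind, v, lag, None))
                else:
                    columns.extend(("d", kind, v, lag, t) for t in all_diff_ts)
        for kind, v in pre_vars:
            for lag in range(1, spec.max_lag_depth + 1):
                if spec.collapse:
                    columns.append(("d", kind, v, lag, None))
                else:
                    columns.extend(("d", kind, v, lag, t) for t in all_diff_ts)
        for x in spec.exogenous:
            columns.append(("d", "iv", x, 0, None))
        for kind, v in gmm_vars_diff + pre_vars:
            if spec.collapse:
                columns.append(("l", kind, v, 1, None))
            else:
                columns.extend(("l", kind, v, 1, t) for t in all_lvl_ts)
    for x in spec.exogenous:
        columns.append(("l", "iv", x, 0, None))
    columns.append(("l", "iv", "const", 0, None))
    col_index = {c: j for j, c in enumerate(columns)}
    m = len(columns)
    k = len(spec.param_names)

    blocks = []
    for pid, y, vals, lvl_ts, diff_ts in patients:
        def series(kind, v):
            return y if kind == "dep" else vals[v]

        n_l, n_d = len(lvl_ts), len(diff_ts)
        Xl = np.empty((n_l, k))
        yl = np.empty(n_l)
        lvl_pos = {t: i for i, t in enumerate(lvl_ts)}
        for i, t in enumerate(lvl_ts):
            row = [y[t - j] for j in range(1, p + 1)] \
                + [vals[v][t] for v in regs] + [1.0]
            Xl[i] = row
            yl[i] = y[t]
        Xd = np.empty((n_d, k))
        yd = np.empty(n_d)
        for i, t in enumerate(diff_ts):
            Xd[i] = Xl[lvl_pos[t]] - Xl[lvl_pos[t - 1]]
            yd[i] = yl[lvl_pos[t]] - yl[lvl_pos[t - 1]]

        Z = np.zeros((n_d + n_l, m))
        for i, t in enumerate(diff_ts):
            for kind, v in gmm_vars_diff:
                s = series(kind, v)
                for lag in range(2, spec.max_lag_depth + 2):
                    val = s.get(t - lag)
                    if val is not None and np.isfinite(val):
                        key = ("d", kind, v, lag, None if spec.collapse else t)
                        Z[i, col_index[key]] = val
            for kind, v in pre_vars:
                s = series(kind, v)
                for lag in range(1, spec.max_lag_depth + 1):
                    val = s.get(t - lag)
                    if val is not None and np.isfinite(val):
                        key = ("d", kind, v, lag, None if spec.collapse else t)
                        Z[i, col_index[key]] = val
            for x in spec.exogenous:
                Z[i, col_index[("d", "iv", x, 0, None)]] = \
                    vals[x][t] - vals[x][t - 1]
        for i, t in enumerate(lvl_ts):
            r = n_d + i
            if spec.has_difference_block:
                for kind, v in gmm_vars_diff + pre_vars:
                    s = series(kind, v)
                    v1, v2 = s.get(t - 1), s.get(t - 2)
                    if v1 is not None and v2 is not None \
                            and np.isfinite(v1) and np.isfinite(v2):
                        key = ("l", kind, v, 1, None if spec.collapse else t)
                        Z[r, col_index[key]] = v1 - v2
            for x in spec.exogenous:
                Z[r, col_index[("l", "iv", x, 0, None)]] = vals[x][t]
            Z[r, col_index[("l", "iv", "const", 0, None)]] = 1.0

        blk = _PatientBlock()
        blk.Z = Z
        blk.X = np.vstack([Xd, Xl])
        blk.y = np.concatenate([yd, yl])
        blk.n_diff = n_d
        blk.diff_ts = diff_ts
        blk.lvl_ts = lvl_ts
        Hd = 2.0 * np.eye(n_d)
        for a in range(n_d):
            for b_ in range(a + 1, n_d):
                if abs(diff_ts[a] - diff_ts[b_]) == 1:
                    Hd[a, b_] = Hd[b_, a] = -1.0
        blk.Hd = Hd
        blocks.append(blk)
    return blocks, columns


def _prune_columns(blocks, columns):
    """Drop all-zero and exactly duplicated instrument columns."""
    if not blocks:
        return columns, []
    Zall = np.vstack([b.Z for b in blocks])
    keep = []
    seen = {}
    for j in range(Zall.shape[1]):
        col = Zall[:, j]
        if not np.any(col):
            continue
        key = np.round(col, 12).tobytes()
        if key in seen:
            continue
        seen[key] = j
        keep.append(j)
    for b in blocks:
        b.Z = b.Z[:, keep]
    return [columns[j] for j in keep], keep


def instrument_columns(panel: pd.DataFrame, spec: GMMSpec) -> list[tuple]:
    """Labels of the instrument columns actually used (after pruning).

    Each label is ``(block, kind, variable, lag, period)`` with block
    ``'d'``/``'l'`` and ``period`` None when collapsed.
    """
    blocks, columns = _build_blocks(panel, spec)
    cols, _ = _prune_columns(blocks, columns)
    return cols


def fit_system_gmm(panel: pd.DataFrame, spec: GMMSpec | None = None) -> GMMResult:
    """Fit the dynamic panel model by system GMM.

    ``panel`` needs ``patient_id``, ``t``, the dependent column and every
    regressor the spec names; lag availability is derived from the
    per-patient period structure (a gap year breaks the chain).
    """
    spec = spec or GMMSpec()
    blocks, columns = _build_blocks(panel, spec)
    columns, _ = _prune_columns(blocks, columns)
    if not blocks:
        raise ValueError("no estimable observations")
    names = spec.param_names
    k = len(names)
    m = len(columns)
    n_lvl = sum(len(b.lvl_ts) for b in blocks)
    n_diff = sum(b.n_diff for b in blocks)
    if spec.min_obs_ratio and n_lvl < spec.min_obs_ratio * k:
        raise ValueError(
            f"only {n_lvl} estimable observations for {k} parameters "
            f"(need >= {spec.min_obs_ratio:g} per parameter)")
    if m < k:
        raise ValueError(f"underidentified: {m} instruments < {k} parameters")

    flags: list[str] = []
    A1 = np.zeros((m, m))
    G = np.zeros((m, k))
    bvec = np.zeros(m)
    for b in blocks:
        Zd, Zl = b.Z[:b.n_diff], b.Z[b.n_diff:]
        A1 += Zd.T @ b.Hd @ Zd + Zl.T @ Zl
        G += b.Z.T @ b.X
        bvec += b.Z.T @ b.y
    W1 = _robust_inv(A1, flags, "one-step weighting")

    def _solve(W):
        # theta minimizes (b - G theta)' W (b - G theta); least squares on
        # the normal equations tolerates near-collinear regressor columns
        GW = G.T @ W
        A = GW @ G
        theta, *_ = np.linalg.lstsq(A, GW @ bvec, rcond=None)
        M = np.linalg.pinv(A, hermitian=True)
        return theta, M, GW

    theta1, M1, GW1 = _solve(W1)

    ZU1 = np.stack([b.Z.T @ (b.y - b.X @ theta1) for b in blocks])
    omega1 = ZU1.T @ ZU1
    V1r = M1 @ (GW1 @ omega1 @ GW1.T) @ M1

    if spec.steps == "two":
        W2 = _robust_inv(omega1, flags, "two-step weighting")
        theta, M2, GW2 = _solve(W2)
        V2 = M2
        resid = [b.y - b.X @ theta for b in blocks]
        ZU2 = np.stack([b.Z.T @ r for b, r in zip(blocks, resid)])
        g2 = ZU2.sum(axis=0)
        if spec.windmeijer:
            ZXs = np.stack([b.Z.T @ b.X for b in blocks])      # (P, m, k)
            Q = np.einsum("pmk,pn->kmn", ZXs, ZU1)
            a_vec = W2 @ g2
            S_a = (np.einsum("kmn,n->km", Q, a_vec)
                   + np.einsum("kmn,m->kn", Q, a_vec))          # (k, m)
            D = M2 @ (GW2 @ S_a.T)
            V = V2 + D @ V2 + V2 @ D.T + D @ V1r @ D.T
            if np.any(np.diag(V) <= 0):
                flags.append("windmeijer: non-PSD corrected variance, "
                             "uncorrected two-step variance reported")
                V = V2
        else:
            V = V2
        W_fin, M_fin, GW_fin = W2, M2, GW2
    else:
        theta = theta1
        V = V1r
        resid = [b.y - b.X @ theta for b in blocks]
        ZU2 = np.stack([b.Z.T @ r for b, r in zip(blocks, resid)])
        g2 = ZU2.sum(axis=0)
        W_fin, M_fin, GW_fin = W1, M1, GW1

    # Hansen J from the optimal weighting at the final estimates
    if m > k:
        omega2 = ZU2.T @ ZU2
        Wj = _robust_inv(omega2, flags, "hansen weighting")
        j_stat = float(g2 @ Wj @ g2)
        j_df = m - k
        j_p = float(stats.chi2.sf(j_stat, j_df))
    else:
        j_stat, j_df, j_p = 0.0, 0, float("nan")

    ar = {}
    for order in (1, 2):
        ar[order] = _arellano_bond(blocks, resid, ZU2, M_fin, GW_fin, V, order)

    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(se > 0, theta / se, np.nan)

    idx = pd.Index(names)
    return GMMResult(
        params=pd.Series(theta, index=idx),
        se=pd.Series(se, index=idx),
        tstats=pd.Series(tstats, index=idx),
        vcov=pd.DataFrame(V, index=idx, columns=idx),
        params_onestep=pd.Series(theta1, index=idx),
        hansen_j=j_stat, hansen_df=j_df, hansen_p=j_p,
        ar1_z=ar[1][0], ar1_p=ar[1][1], ar2_z=ar[2][0], ar2_p=ar[2][1],
        n_obs=n_lvl, n_diff_obs=n_diff, n_patients=len(blocks),
        n_instruments=m, instrument_labels=columns,
        weighting_flags=flags, spec=spec)


def _arellano_bond(blocks, resid, ZU, M, GW, V, order: int):
    """Serial-correlation z-test of order `order` on differenced residuals."""
    d0 = 0.0
    t1 = 0.0
    c = None
    q = None
    used = 0
    for b, r, zu in zip(blocks, resid, ZU):
        if b.n_diff == 0:
            continue
        v = r[:b.n_diff]
        pos = {t: i for i, t in enumerate(b.diff_ts)}
        w = np.zeros_like(v)
        hit = False
        for i, t in enumerate(b.diff_ts):
            j = pos.get(t - order)
            if j is not None:
                w[i] = v[j]
                hit = True
        if not hit:
            continue
        used += 1
        wv = float(w @ v)
        d0 += wv
        t1 += wv * wv
        Xd = b.X[:b.n_diff]
        ci = Xd.T @ w
        c = ci if c is None else c + ci
        qi = zu * wv
        q = qi if q is None else q + qi
    if used == 0 or t1 <= 0:
        return float("nan"), float("nan")
    var = t1 - 2.0 * float(c @ (M @ (GW @ q))) + float(c @ V @ c)
    if var <= 0:
        var = t1
    z = d0 / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def within_groups(panel: pd.DataFrame, spec: GMMSpec | None = None) -> pd.Series:
    """Within-groups (fixed-effects OLS) comparator.

    Suffers Nickell bias on short panels — the reason system GMM is used —
    but serves as a reference estimator in simulations.
    """
    spec = spec or GMMSpec()
    p = spec.dep_lags
    regs = list(spec.exogenous) + list(spec.endogenous) + list(spec.predetermined)
    df = panel.sort_values(["patient_id", "t"], kind="mergesort").copy()
    g = df.groupby("patient_id", sort=False)
    for j in range(1, p + 1):
        lag = g[spec.dependent].shift(j)
        consec = (df["t"] - g["t"].shift(j)) == j
        df[f"_lag{j}"] = lag.where(consec)
    cols = [f"_lag{j}" for j in range(1, p + 1)] + regs
    sub = df.dropna(subset=cols + [spec.dependent])
    ybar = sub.groupby("patient_id")[spec.dependent].transform("mean")
    y = sub[spec.dependent] - ybar
    X = sub[cols] - sub.groupby("patient_id")[cols].transform("mean")
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)
    names = [f"{spec.dependent}_lag{j}" for j in range(1, p + 1)] + regs
    return pd.Series(beta, index=names)


def fit_strata(panel: pd.DataFrame, spec: GMMSpec | None = None,
               by: str = "gender") -> dict[str, GMMResult]:
    """Fit the model on the pooled panel and on each stratum."""
    from pprpanel.panel import stratify

    out = {"all": fit_system_gmm(panel, spec)}
    for key, sub in stratify(panel, by).items():
        out[key] = fit_system_gmm(sub, spec)
    return out
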