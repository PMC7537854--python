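"""Weighted product-limit estimation on a discrete age grid with design-based variance.

The estimand is the survival function ``S(t) = P(T > t)``, the probability that a
girl or woman has not experienced FGM by completed age ``t``.  Ages form a discrete
grid 0..49 (events at completed years of age); the estimator is the weighted
Kaplan-Meier product limit

    S_hat(t) = prod_{a=0}^{t} (1 - d_a / n_a)

where ``d_a`` is the (weight-summed) number of FGM events at age ``a`` and ``n_a``
the weight at risk entering age ``a``.  A person censored at age ``a`` remains in
the risk set for events at ``a`` (the standard tie convention).

Design-based standard errors use influence-function linearization of
``log S_hat(t)`` with the ultimate-cluster approximation: per-record influence
contributions are aggregated to primary-sampling-unit (PSU) totals and the
variance is the stratified with-replacement between-PSU variance of those
totals.  A Rao-Wu rescaling PSU bootstrap is provided as a slower validation
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAX_AGE = 49
N_AGES = MAX_AGE + 1
AGES = np.arange(N_AGES)

#: columns every event table must carry for point estimation
CORE_COLUMNS = ("time", "event", "weight")
#: additional columns required for design-based variance
DESIGN_COLUMNS = ("stratum_id", "psu_id")


class RiskTableError(ValueError):
    """Raised when an event table or risk table is internally inconsistent."""


def _as_frame(records, *, design: bool = False) -> pd.DataFrame:
    """Validate an event table and return it as a DataFrame.

    Accepts a DataFrame or any mapping/iterable pandas can turn into one.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    required = CORE_COLUMNS + (DESIGN_COLUMNS if design else ())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RiskTableError(f"event table is missing required columns: {missing}")
    if len(df):
        t = df["time"].to_numpy()
        if t.min() < 0 or t.max() > MAX_AGE:
            raise RiskTableError(f"event times must lie in [0, {MAX_AGE}]")
        w = df["weight"].to_numpy(dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise RiskTableError("weights must be finite and nonnegative")
    return df


@dataclass
class RiskTable:
    """Weighted and unweighted counts at risk, events and censored per age 0..49.

    Satisfies the conservation identity ``n[a+1] = n[a] - d[a] - c[a]`` exactly
    in both the weighted and unweighted columns.
    """

    n: np.ndarray          # weighted at risk entering age a
    d: np.ndarray          # weighted events at age a
    c: np.ndarray          # weighted censored at age a
    n_unw: np.ndarray
    d_unw: np.ndarray
    c_unw: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": AGES,
                "n_at_risk": self.n,
                "events": self.d,
                "censored": self.c,
                "n_at_risk_unweighted": self.n_unw,
                "events_unweighted": self.d_unw,
                "censored_unweighted": self.c_unw,
            }
        )


@dataclass
class SurvivalCurve:
    """Kaplan-Meier curve over ages 0..49 with optional design-based uncertainty.

    ``s[t]`` is survival *through* completed age ``t``, i.e. P(T > t).
    """

    s: np.ndarray
    se: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_records: int = 0
    total_weight: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def age(self) -> np.ndarray:
        return AGES

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"age": AGES, "s_hat": self.s})
        for name, arr in (("se", self.se), ("ci_low", self.ci_low), ("ci_high", self.ci_high)):
            out[name] = arr if arr is not None else np.nan
        for key, val in self.meta.items():
            out[key] = val
        out["n_records"] = self.n_records
        out["total_weight"] = self.total_weight
        return out


def risk_table(records) -> RiskTable:
    """Tally the weighted risk table from an event table.

    A record ``(time=t, event, weight=w)`` contributes ``w`` to ``n_a`` for all
    ``a <= t``, and to ``d_t`` if it is an event else to ``c_t``.  An empty
    input yields an all-zero table.
    """
    df = _as_frame(records)
    if not len(df):
        z = np.zeros(N_AGES)
        return RiskTable(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy())
    t = df["time"].to_numpy(dtype=np.int64)
    e = df["event"].to_numpy(dtype=bool)
    w = df["weight"].to_numpy(dtype=float)

    def tally(weights):
        d = np.bincount(t[e], weights=weights[e], minlength=N_AGES)[:N_AGES]
        c = np.bincount(t[~e], weights=weights[~e], minlength=N_AGES)[:N_AGES]
        leaving = d + c
        n = leaving.sum() - np.concatenate(([0.0], np.cumsum(leaving)[:-1]))
        return n, d, c

    n, d, c = tally(w)
    n_u, d_u, c_u = tally(np.ones_like(w))
    return RiskTable(n, d, c, n_u, d_u, c_u)


def km_estimate(rt: RiskTable, meta: dict | None = None) -> SurvivalCurve:
    """Point estimates S_hat(t) = prod_{a<=t} (1 - d_a/n_a).

    The factor is defined as 1 where ``n_a == 0`` so the curve extends flatly
    once the risk set is exhausted.
    """
    if np.any(rt.d > rt.n * (1 + 1e-12) + 1e-9):
        raise RiskTableError("risk table has more events than persons at risk")
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(rt.n > 0, 1.0 - rt.d / np.where(rt.n > 0, rt.n, 1.0), 1.0)
    s = np.cumprod(np.clip(factor, 0.0, 1.0))
    return SurvivalCurve(
        s=s,
        n_records=int(rt.n_unw[0]),
        total_weight=float(rt.n[0]),
        meta=dict(meta or {}),
    )


def _psu_codes(df: pd.DataFrame, lonely_psu: str):
    """Factorize (stratum, PSU) pairs; handle strata with a single PSU."""
    strat = df["stratum_id"].astype(str).to_numpy()
    psu = df["psu_id"].astype(str).to_numpy()
    comb = np.char.add(np.char.add(strat, "\x1f"), psu)
    psu_codes, psu_labels = pd.factorize(comb)
    # stratum of each unique PSU
    first_idx = np.zeros(len(psu_labels), dtype=np.int64)
    first_idx[psu_codes[::-1]] = np.arange(len(psu_codes))[::-1]
    strat_of_psu_labels = strat[first_idx]
    strat_codes, strat_labels = pd.factorize(strat_of_psu_labels)
    n_h = np.bincount(strat_codes)
    lonely = [str(strat_labels[h]) for h in np.where(n_h < 2)[0]]
    if lonely:
        if lonely_psu == "error":
            raise ValueError(
                f"strata with a single PSU cannot contribute a variance estimate: {lonely}; "
                "pass lonely_psu='collapse' to merge them into one pseudo-stratum"
            )
        if lonely_psu == "collapse":
            # merge each lonely stratum with a neighbouring one (or, if every
            # stratum is lonely, pool them all) so each has >= 2 PSUs
            strat_codes = strat_codes.copy()
            non_lonely = np.where(n_h >= 2)[0]
            lonely_mask = n_h[strat_codes] < 2
            if len(non_lonely):
                target = non_lonely[0]
            else:
                target = int(strat_codes.min())
                lonely_mask = np.ones_like(lonely_mask)
            strat_codes[lonely_mask] = target
            strat_codes = pd.factorize(strat_codes)[0]
            n_h = np.bincount(strat_codes)
            if np.any(n_h < 2):
                raise ValueError("lonely-PSU collapse still leaves a single-PSU stratum")
        else:
            raise ValueError(f"unknown lonely_psu policy {lonely_psu!r}")
    return psu_codes, strat_codes, n_h


def km_variance(records, *, lonely_psu: str = "error") -> SurvivalCurve:
    """Estimate the curve with linearized design-based standard errors.

    The per-record influence on ``log S_hat(t)`` for record i with time t_i,
    event flag e_i is

        z_i(t) = sum_{a <= min(t, t_i)} [1/(n_a - d_a) - 1/n_a]  -  e_i * 1(t_i <= t) / (n_{t_i} - d_{t_i})

    The variance of ``log S_hat(t)`` is the stratified with-replacement
    between-PSU variance of the PSU totals of ``w_i * z_i(t)``; then
    ``SE(S_hat) = S_hat * SE(log S_hat)``.

    Requires at least two PSUs in every stratum (``lonely_psu='collapse'``
    pools single-PSU strata into one pseudo-stratum instead of failing).
    """
    df = _as_frame(records, design=True)
    rt = risk_table(df)
    curve = km_estimate(rt)
    if not len(df):
        curve.se = np.zeros(N_AGES)
        return curve

    n, d = rt.n, rt.d
    alive = n - d
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_alive = np.where(alive > 0, 1.0 / np.where(alive > 0, alive, 1.0), 0.0)
        inv_n = np.where(n > 0, 1.0 / np.where(n > 0, n, 1.0), 0.0)
    g = inv_alive - inv_n          # at-risk contribution per age
    G = np.cumsum(g)

    t = df["time"].to_numpy(dtype=np.int64)
    e = df["event"].to_numpy(dtype=bool)
    w = df["weight"].to_numpy(dtype=float)
    psu_codes, strat_codes, n_h = _psu_codes(df, lonely_psu)
    n_psu = int(psu_codes.max()) + 1

    # PSU totals of w_i * z_i(t) as step functions of t:
    #   records with t_i > t contribute w_i * G(t);
    #   records with t_i <= t contribute w_i * (G(t_i) - e_i / (n_{t_i} - d_{t_i})).
    w_by_age = np.zeros((n_psu, N_AGES))
    np.add.at(w_by_age, (psu_codes, t), w)
    w_cum = np.cumsum(w_by_age, axis=1)                    # weight with t_i <= t
    w_gt = w_cum[:, -1:] - w_cum                           # weight with t_i > t

    settled = w * (G[t] - np.where(e, inv_alive[t], 0.0))
    settled_by_age = np.zeros((n_psu, N_AGES))
    np.add.at(settled_by_age, (psu_codes, t), settled)
    totals = G[np.newaxis, :] * w_gt + np.cumsum(settled_by_age, axis=1)

    n_strata = int(strat_codes.max()) + 1
    sum_z = np.zeros((n_strata, N_AGES))
    sum_z2 = np.zeros((n_strata, N_AGES))
    np.add.at(sum_z, strat_codes, totals)
    np.add.at(sum_z2, strat_codes, totals**2)
    nh = n_h.astype(float)[:, np.newaxis]
    var_log = ((nh / (nh - 1.0)) * (sum_z2 - sum_z**2 / nh)).sum(axis=0)
    var_log = np.clip(var_log, 0.0, None)

    se = curve.s * np.sqrt(var_log)
    se[curve.s <= 0] = 0.0
    curve.se = se
    return curve


def confidence_interval(curve: SurvivalCurve, level: float = 0.95,
                        method: str = "log") -> SurvivalCurve:
    """Attach pointwise confidence bounds to a curve with standard errors.

    ``method='log'`` (default): symmetric normal interval on log S_hat,
    exponentiated and truncated to [0, 1].  ``method='loglog'``: interval on
    log(-log S_hat), which never needs truncation.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if curve.se is None:
        raise ValueError("curve has no standard errors; run km_variance first")
    z = stats.norm.ppf(0.5 + level / 2.0)
    s, se = curve.s, curve.se
    pos = s > 0
    se_log = np.zeros(N_AGES)
    se_log[pos] = se[pos] / s[pos]
    if method == "log":
        low = np.where(pos, s * np.exp(-z * se_log), 0.0)
        high = np.where(pos, s * np.exp(z * se_log), 0.0)
    elif method == "loglog":
        interior = pos & (s < 1)
        theta = np.zeros(N_AGES)
        theta[interior] = z * se_log[interior] / np.abs(np.log(s[interior]))
        low = np.where(interior, s ** np.exp(theta), s)
        high = np.where(interior, s ** np.exp(-theta), s)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    curve.ci_low = np.clip(low, 0.0, 1.0)
    curve.ci_high = np.clip(high, 0.0, 1.0)
    curve.meta["ci_level"] = level
    curve.meta["ci_method"] = method
    return curve


def compare_curves(curve_a: SurvivalCurve, curve_b: SurvivalCurve,
                   ages: Sequence[int]) -> pd.DataFrame:
    """Pointwise contrast of two independently estimated curves.

    Returns per requested age: S_a, S_b, difference S_a - S_b, SE of the
    difference (independence assumed; any design covariance between the two
    groups is ignored), normal z and two-sided p.  Identical curves give
    diff 0, z 0, p 1.
    """
    ages = np.asarray(ages, dtype=np.int64)
    if ages.min() < 0 or ages.max() > MAX_AGE:
        raise ValueError(f"requested ages must lie in [0, {MAX_AGE}]")
    if curve_a.se is None or curve_b.se is None:
        raise ValueError("both curves need standard errors for comparison")
    sa, sb = curve_a.s[ages], curve_b.s[ages]
    diff = sa - sb
    se = np.sqrt(curve_a.se[ages] ** 2 + curve_b.se[ages] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"age": ages, "s_a": sa, "s_b": sb, "diff": diff, "se": se, "z": z, "p": p}
    )


def bootstrap_se(records, n_replicates: int = 500, rng=None,
                 *, lonely_psu: str = "error") -> np.ndarray:
    """Rao-Wu rescaling PSU bootstrap standard error of S_hat per age.

    Within each stratum of n_h PSUs, each replicate resamples n_h - 1 PSUs
    with replacement and rescales weights by (times selected) * n_h/(n_h - 1).
    This is the validation oracle for :func:`km_variance`, not the default
    variance estimator (it is far slower).
    """
    df = _as_frame(records, design=True)
    rng = np.random.default_rng(rng)
    psu_codes, strat_codes, n_h = _psu_codes(df, lonely_psu)
    t = df["time"].to_numpy(dtype=np.int64)
    e = df["event"].to_numpy(dtype=bool)
    w = df["weight"].to_numpy(dtype=float)
    n_psu = len(strat_codes)
    psus_in_stratum = [np.where(strat_codes == h)[0] for h in range(int(strat_codes.max()) + 1)]

    reps = np.empty((n_replicates, N_AGES))
    base = pd.DataFrame({"time": t, "event": e, "weight": w})
    for r in range(n_replicates):
        mult = np.zeros(n_psu)
        for h, members in enumerate(psus_in_stratum):
            nh = len(members)
            draws = rng.integers(0, nh, size=nh - 1)
            counts = np.bincount(draws, minlength=nh)
            mult[members] = counts * (nh / (nh - 1.0))
        base["weight"] = w * mult[psu_codes]
        reps[r] = km_estimate(risk_table(base)).s
    return reps.std(axis=0, ddof=1)
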