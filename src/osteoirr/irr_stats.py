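"""Incidence rates and incidence rate ratios with exact 95% intervals.

Rates are events per 1000 person-years with an exact Poisson (Garwood)
interval on the count:

    lower = chi2.ppf(alpha/2, 2k) / 2,   upper = chi2.ppf(1-alpha/2, 2k+2) / 2

scaled by ``1000 / person_years`` (lower bound 0 when k = 0).

The IRR compares a risk window (numerator) with the baseline period
(denominator).  Conditional on the total number of events
``n = k_num + k_den``, the numerator count is binomial with success
probability ``p = PY_num * IRR / (PY_num * IRR + PY_den)``; the default
exact interval inverts a Clopper-Pearson interval on ``p`` through the
monotone map ``IRR = p / (1 - p) * PY_den / PY_num``.  A log-normal
(Wald-on-log-scale) approximation is available as an option and tagged in
the output.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .dates import DAYS_PER_YEAR
from .persontime import POST_DISC, RISK_WINDOWS


def rate_ci(events: int, person_years: float, level: float = 0.95) -> dict:
    """Exact Poisson rate per 1000 person-years with its interval."""
    if person_years <= 0:
        return {"events": int(events), "person_years": float(person_years),
                "rate_per_1000py": math.nan, "ci_low": math.nan,
                "ci_high": math.nan, "method": "garwood",
                "defined": False}
    alpha = 1.0 - level
    k = int(events)
    scale = 1000.0 / person_years
    low = 0.0 if k == 0 else float(stats.chi2.ppf(alpha / 2, 2 * k)) / 2
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * k + 2)) / 2
    return {"events": k, "person_years": float(person_years),
            "rate_per_1000py": k * scale, "ci_low": low * scale,
            "ci_high": high * scale, "method": "garwood", "defined": True}


def _exact_irr_bounds(k: int, n: int, py_num: float, py_den: float,
                      level: float) -> tuple[float, float]:
    """Clopper-Pearson bounds on p mapped to the IRR scale."""
    alpha = 1.0 - level
    if k == 0:
        p_low = 0.0
    else:
        p_low = float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    if k == n:
        p_high = 1.0
    else:
        p_high = float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    ratio = py_den / py_num
    low = 0.0 if p_low == 0.0 else p_low / (1 - p_low) * ratio
    high = math.inf if p_high == 1.0 else p_high / (1 - p_high) * ratio
    return low, high


def irr_ci(events_num: int, py_num: float, events_den: int, py_den: float,
           level: float = 0.95, method: str = "exact") -> dict:
    """Incidence rate ratio (numerator vs denominator) with 95% CI.

    ``method`` is ``"exact"`` (conditional binomial, default) or
    ``"lognormal"``.  With zero events on one side the exact method still
    yields the finite one-sided bound; the result is flagged undefined when
    the point estimate itself is not finite (no denominator events, or no
    person-time).
    """
    k_num, k_den = int(events_num), int(events_den)
    n = k_num + k_den
    base = {"events_num": k_num, "py_num": float(py_num),
            "events_den": k_den, "py_den": float(py_den),
            "method": method}
    if py_num <= 0 or py_den <= 0 or n == 0:
        return {**base, "irr": math.nan, "ci_low": math.nan,
                "ci_high": math.nan, "defined": False}
    rate_num = k_num / py_num
    rate_den = k_den / py_den
    irr = math.inf if rate_den == 0 else rate_num / rate_den

    if method == "exact":
        low, high = _exact_irr_bounds(k_num, n, py_num, py_den, level)
    elif method == "lognormal":
        if k_num == 0 or k_den == 0:
            low, high = math.nan, math.nan
        else:
            z = float(stats.norm.ppf(0.5 + level / 2))
            se = math.sqrt(1 / k_num + 1 / k_den)
            low = irr * math.exp(-z * se)
            high = irr * math.exp(z * se)
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    defined = math.isfinite(irr)
    return {**base, "irr": irr, "ci_low": low, "ci_high": high,
            "defined": defined}


def _cell_lookup(cells: pd.DataFrame):
    return {(r["cohort"], r["site_group"], r["window"], r["mode"],
             r["stratum"]): r for _, r in cells.iterrows()}


def run_all(cells: pd.DataFrame, level: float = 0.95,
            method: str = "exact") -> pd.DataFrame:
    """All own-control IRRs implied by a cell table.

    For every (cohort, site group, mode, stratum): each risk window vs
    baseline; and, when a post-discontinuation cell exists, post-disc vs
    baseline and post-disc vs the last on-treatment window (months 3-24).
    Log-transformed columns are included for forest plotting.  Undefined
    comparisons are kept, flagged ``defined=False``.
    """
    rows = []
    if cells.empty:
        return pd.DataFrame(columns=[
            "cohort", "site_group", "mode", "stratum", "comparison",
            "events_num", "py_num", "events_den", "py_den", "irr",
            "ci_low", "ci_high", "defined", "method", "log_irr",
            "log_ci_low", "log_ci_high"])
    keyed = cells.set_index(["cohort", "site_group", "mode", "stratum",
                             "window"]).sort_index()

    combos = cells[["cohort", "site_group", "mode", "stratum"]
                   ].drop_duplicates()
    for _, c in combos.iterrows():
        key = (c["cohort"], c["site_group"], c["mode"], c["stratum"])

        def cell(window, key=key):
            try:
                return keyed.loc[key + (window,)]
            except KeyError:
                return None

        base = cell("baseline")
        post = cell(POST_DISC)
        comparisons = []
        if base is not None:
            for w in RISK_WINDOWS:
                num = cell(w)
                if num is not None:
                    comparisons.append((f"{w}_vs_baseline", num, base))
            num = cell("m3_6")
            if num is not None:
                comparisons.append(("m3_6_vs_baseline", num, base))
            if post is not None:
                comparisons.append((f"{POST_DISC}_vs_baseline", post, base))
        if post is not None:
            last = cell("m3_24")
            if last is not None:
                comparisons.append((f"{POST_DISC}_vs_m3_24", post, last))

        for label, num, den in comparisons:
            res = irr_ci(num["events"], num["person_days"] / DAYS_PER_YEAR,
                         den["events"], den["person_days"] / DAYS_PER_YEAR,
                         level=level, method=method)
            res.update({"cohort": key[0], "site_group": key[1],
                        "mode": key[2], "stratum": key[3],
                        "comparison": label})
            for col, src in (("log_irr", "irr"), ("log_ci_low", "ci_low"),
                             ("log_ci_high", "ci_high")):
                v = res[src]
                res[col] = math.log(v) if (isinstance(v, float) and
                                           v > 0 and math.isfinite(v)
                                           ) else math.nan
            rows.append(res)
    cols = ["cohort", "site_group", "mode", "stratum", "comparison",
            "events_num", "py_num", "events_den", "py_den", "irr",
            "ci_low", "ci_high", "defined", "method", "log_irr",
            "log_ci_low", "log_ci_high"]
    return pd.DataFrame(rows, columns=cols)


def rates_table(cells: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Incidence per 1000 PY with exact intervals for every cell."""
    rows = []
    for _, r in cells.iterrows():
        res = rate_ci(r["events"], r["person_days"] / DAYS_PER_YEAR, level)
        res.update({"cohort": r["cohort"], "site_group": r["site_group"],
                    "window": r["window"], "mode": r["mode"],
                    "stratum": r["stratum"]})
        rows.append(res)
    cols = ["cohort", "site_group", "window", "mode", "stratum", "events",
            "person_years", "rate_per_1000py", "ci_low", "ci_high",
            "method", "defined"]
    return pd.DataFrame(rows, columns=cols)
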