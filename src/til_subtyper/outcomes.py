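"""Survival and association reporting for immune subtypes.

Event-free survival (EFS: time from surgery to relapse or death from any
cause) is summarized per subtype by Kaplan-Meier curves with pairwise and
global log-rank tests.  Feature-level prognostic scans fit one univariate
Cox proportional-hazards model per feature and report z = coef / se
(positive z: higher feature, higher hazard).  Factor-level prognosis follows
a univariate-then-multivariate Cox procedure: every factor contrast is fit
alone, and those with univariate p below the selection alpha enter a joint
model; the output mirrors the exp(-coef) / 0.95 CI / p table layout, where
the contrast "A vs. B" reports the hazard of B relative to A and excludes
samples at other levels.  Subtype-association scans use Fisher exact tests
(exact enumeration for r x c tables up to a size bound, seeded Monte Carlo
beyond) with Holm step-down adjustment per scan family and the dual
flagging rule: raw p <= 0.05, Holm-adjusted p <= 0.2.

The univariate Cox fit is a native Newton solver on the Efron partial
likelihood (fast enough for null-calibration sweeps); the multivariate model
and Kaplan-Meier machinery delegate to lifelines.
"""

from __future__ import annotations

import itertools
import warnings
from math import lgamma

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.stats import fisher_exact, norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RAW_FLAG_P",
    "HOLM_FLAG_P",
    "km_logrank",
    "cox_univariate",
    "cox_scan",
    "multivariate_cox",
    "fisher_holm_scan",
    "holm_adjust",
    "rxc_fisher_exact",
]

RAW_FLAG_P = 0.05
HOLM_FLAG_P = 0.2


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


def km_logrank(
    clinical: pd.DataFrame,
    group_col: str = "subtype",
    time_col: str = "efs_months",
    event_col: str = "event",
) -> dict:
    """Product-limit curves per group plus pairwise and global log-rank tests.

    Returns ``{"curves": long frame (group, time, survival, at_risk),
    "pairwise": frame (group_a, group_b, statistic, p), "global_p": float}``.
    """
    groups = sorted(clinical[group_col].unique())
    if len(groups) < 2:
        raise ValueError("log-rank comparison needs >= 2 groups")
    if clinical[event_col].sum() < 1:
        raise ValueError("no events observed; log-rank test undefined")
    curve_rows = []
    for g in groups:
        sub = clinical[clinical[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        sf = kmf.survival_function_
        for t, s in zip(sf.index, sf.iloc[:, 0]):
            curve_rows.append((g, float(t), float(s)))
    curves = pd.DataFrame(curve_rows, columns=["group", "time", "survival"])
    pair_rows = []
    for a, b in itertools.combinations(groups, 2):
        sa = clinical[clinical[group_col] == a]
        sb = clinical[clinical[group_col] == b]
        res = logrank_test(
            sa[time_col], sb[time_col], sa[event_col], sb[event_col]
        )
        pair_rows.append((a, b, float(res.test_statistic), float(res.p_value)))
    pairwise = pd.DataFrame(
        pair_rows, columns=["group_a", "group_b", "statistic", "p"]
    )
    glob = multivariate_logrank_test(
        clinical[time_col], clinical[group_col], clinical[event_col]
    )
    return {"curves": curves, "pairwise": pairwise,
            "global_p": float(glob.p_value)}


# ---------------------------------------------------------------------------
# univariate Cox (Efron ties, Newton)


def cox_univariate(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[float, float, bool]:
    """Single-covariate Cox PH fit on the Efron partial likelihood.

    Returns (coef, se, converged).  Degenerate inputs (constant covariate,
    no events, separation) come back unconverged.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0 or np.ptp(x) == 0:
        return np.nan, np.nan, False
    order = np.argsort(-time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    # risk set of an event time = all samples with t >= it = a prefix
    boundaries = np.flatnonzero(np.r_[True, time[1:] != time[:-1]])
    group_end = np.r_[boundaries[1:], len(time)]  # exclusive ends

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        w = np.exp(beta * x)
        xw, x2w = x * w, x * x * w
        cw, cxw, cx2w = np.cumsum(w), np.cumsum(xw), np.cumsum(x2w)
        score, info = 0.0, 0.0
        for start, end in zip(boundaries, group_end):
            deaths = np.flatnonzero(event[start:end]) + start
            d = len(deaths)
            if d == 0:
                continue
            sR = (cw[end - 1], cxw[end - 1], cx2w[end - 1])
            sD = (w[deaths].sum(), xw[deaths].sum(), x2w[deaths].sum())
            frac = np.arange(d) / d
            denom = sR[0] - frac * sD[0]
            dx = sR[1] - frac * sD[1]
            dx2 = sR[2] - frac * sD[2]
            mean = dx / denom
            score += x[deaths].sum() - mean.sum()
            info += (dx2 / denom - mean**2).sum()
        if not np.isfinite(score) or not np.isfinite(info) or info <= 0:
            return np.nan, np.nan, False
        step = score / info
        beta += step
        if abs(beta) > 50:
            return np.nan, np.nan, False
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        return np.nan, np.nan, False
    return float(beta), float(1.0 / np.sqrt(info)), True


def cox_scan(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    time_col: str = "efs_months",
    event_col: str = "event",
    min_n: int = 10,
) -> pd.DataFrame:
    """One univariate Cox fit per feature column; z, p and dual flags.

    Features with fewer than ``min_n`` non-missing samples or non-convergent
    fits are reported with ``status != 'ok'`` and excluded from the Holm
    family; the scan always continues.
    """
    rows = []
    for feat in features.columns:
        joined = pd.concat(
            [features[feat], clinical[[time_col, event_col]]], axis=1, join="inner"
        ).dropna()
        n = len(joined)
        if n < min_n:
            rows.append((feat, n, np.nan, np.nan, np.nan, np.nan, "too_few"))
            continue
        coef, se, ok = cox_univariate(
            joined[feat].to_numpy(), joined[time_col].to_numpy(),
            joined[event_col].to_numpy(),
        )
        if not ok:
            rows.append((feat, n, np.nan, np.nan, np.nan, np.nan, "failed"))
            continue
        z = coef / se
        p = 2.0 * norm.sf(abs(z))
        rows.append((feat, n, coef, se, z, p, "ok"))
    out = pd.DataFrame(
        rows, columns=["feature", "n", "coef", "se", "z", "p", "status"]
    ).set_index("feature")
    ok_mask = out["status"] == "ok"
    out["holm_p"] = np.nan
    if ok_mask.any():
        out.loc[ok_mask, "holm_p"] = holm_adjust(out.loc[ok_mask, "p"].to_numpy())
    out["flag_raw"] = out["p"] <= RAW_FLAG_P
    out["flag_holm"] = out["holm_p"] <= HOLM_FLAG_P
    return out


# ---------------------------------------------------------------------------
# univariate -> multivariate factor analysis


def _contrast_indicator(
    clinical: pd.DataFrame, column: str, first: str, second: str
) -> pd.Series:
    """1 for ``first``, 0 for ``second``, missing for any other level."""
    vals = clinical[column]
    ind = pd.Series(np.nan, index=clinical.index)
    ind[vals == first] = 1.0
    ind[vals == second] = 0.0
    return ind


def multivariate_cox(
    factors: list[tuple[str, str, str, str]],
    clinical: pd.DataFrame,
    selection_alpha: float = 0.05,
    time_col: str = "efs_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Univariate Cox per factor contrast, then a joint model of the winners.

    ``factors`` rows are ``(name, column, first_level, second_level)``; the
    contrast "first vs. second" codes ``first`` as 1 and reports
    exp(-coef) — the hazard of ``second`` relative to ``first`` — with its
    0.95 CI, excluding samples at other levels.  Factors with univariate
    p < ``selection_alpha`` enter the multivariate fit (on samples complete
    for all selected contrasts).  A rank-deficient multivariate design is an
    error naming the collinear factors.
    """
    uni_rows = {}
    indicators = {}
    for name, column, first, second in factors:
        ind = _contrast_indicator(clinical, column, first, second)
        indicators[name] = ind
        df = pd.DataFrame({
            "x": ind, "t": clinical[time_col], "e": clinical[event_col]
        }).dropna()
        coef, se, ok = cox_univariate(
            df["x"].to_numpy(), df["t"].to_numpy(), df["e"].to_numpy()
        )
        if not ok:
            uni_rows[name] = dict(contrast=f"{first} vs. {second}", n=len(df),
                                  exp_neg_coef=np.nan, lower_95=np.nan,
                                  upper_95=np.nan, p=np.nan, selected=False)
            continue
        z = coef / se
        p = 2.0 * norm.sf(abs(z))
        uni_rows[name] = dict(
            contrast=f"{first} vs. {second}", n=len(df),
            exp_neg_coef=float(np.exp(-coef)),
            lower_95=float(np.exp(-coef - 1.96 * se)),
            upper_95=float(np.exp(-coef + 1.96 * se)),
            p=p, selected=bool(p < selection_alpha),
        )
    out = pd.DataFrame(uni_rows).T
    out.index.name = "factor"
    for col in ("m_exp_neg_coef", "m_lower_95", "m_upper_95", "m_p"):
        out[col] = np.nan

    selected = [n for n in out.index if out.loc[n, "selected"]]
    if not selected:
        out.attrs["multivariate_note"] = (
            "no factor passed univariate selection; multivariate block empty"
        )
        return out
    design = pd.DataFrame({n: indicators[n] for n in selected})
    design["t"] = clinical[time_col]
    design["e"] = clinical[event_col]
    design = design.dropna()
    X = design[selected].to_numpy()
    if np.linalg.matrix_rank(np.c_[np.ones(len(X)), X]) < len(selected) + 1:
        collinear = [
            (a, b) for a, b in itertools.combinations(selected, 2)
            if np.linalg.matrix_rank(np.c_[np.ones(len(X)),
                                           design[[a, b]].to_numpy()]) < 3
        ]
        raise ValueError(
            f"multivariate design is rank deficient; collinear factors: "
            f"{collinear or selected}"
        )
    cph = CoxPHFitter()
    cph.fit(design, duration_col="t", event_col="e")
    for n in selected:
        coef = float(cph.params_[n])
        se = float(cph.standard_errors_[n])
        out.loc[n, "m_exp_neg_coef"] = np.exp(-coef)
        out.loc[n, "m_lower_95"] = np.exp(-coef - 1.96 * se)
        out.loc[n, "m_upper_95"] = np.exp(-coef + 1.96 * se)
        out.loc[n, "m_p"] = float(cph.summary.loc[n, "p"])
    return out


# ---------------------------------------------------------------------------
# Fisher exact / Holm association scans


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    return multipletests(np.asarray(p, dtype=float), method="holm")[1]


def _log_table_prob(table: np.ndarray) -> float:
    # hypergeometric probability of an r x c table given fixed margins
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    lp = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    lp -= lgamma(n + 1) + sum(lgamma(v + 1) for v in table.ravel())
    return lp


def rxc_fisher_exact(
    table: np.ndarray,
    max_total_exact: int = 80,
    n_monte_carlo: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher exact p for an r x c table.

    Exact enumeration of all margin-consistent tables when the grand total
    is <= ``max_total_exact``; otherwise a seeded Monte-Carlo estimate
    (permutation of category labels, (1 + hits) / (B + 1)).
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(fisher_exact(table, alternative="two-sided")[1])
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    obs_lp = _log_table_prob(table)
    tol = 1e-10
    if table.sum() <= max_total_exact:
        total_p = 0.0

        def recurse(r: int, remaining_cols: np.ndarray, current: list[list[int]]):
            nonlocal total_p
            if r == len(rows) - 1:
                last = remaining_cols
                if (last < 0).any():
                    return
                cand = np.array(current + [list(last)])
                if cand[-1].sum() != rows[-1]:
                    return
                lp = _log_table_prob(cand)
                if lp <= obs_lp + tol:
                    total_p += np.exp(lp)
                return
            # enumerate compositions of rows[r] over the columns, bounded by
            # the remaining column margins
            def comp(ci: int, left: int, row_acc: list[int]):
                if ci == len(cols) - 1:
                    if left <= remaining_cols[ci]:
                        recurse(r + 1,
                                remaining_cols - np.array(row_acc + [left]),
                                current + [row_acc + [left]])
                    return
                for v in range(min(left, remaining_cols[ci]) + 1):
                    comp(ci + 1, left - v, row_acc + [v])

            comp(0, rows[r], [])

        recurse(0, cols.copy(), [])
        return float(min(total_p, 1.0))
    # Monte Carlo: permute category labels, keep margins
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_monte_carlo):
        perm = rng.permutation(col_labels)
        sim = np.zeros_like(table)
        np.add.at(sim, (row_labels, perm), 1)
        if _log_table_prob(sim) <= obs_lp + tol:
            hits += 1
    return float((1 + hits) / (1 + n_monte_carlo))


def fisher_holm_scan(
    tables: dict[str, np.ndarray],
    max_total_exact: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Fisher exact test per factor with Holm adjustment across the family.

    ``tables`` maps factor name -> contingency table (factor levels x
    subtypes).  Tables with an empty margin are skipped with a warning.
    Emits raw p, Holm-adjusted p, and the two flag tiers (raw <= 0.05,
    Holm <= 0.2).
    """
    rows = []
    for name, table in tables.items():
        table = np.asarray(table, dtype=int)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            warnings.warn(f"factor {name!r} has an empty margin; skipped",
                          stacklevel=2)
            continue
        p = rxc_fisher_exact(table, max_total_exact=max_total_exact, seed=seed)
        rows.append((name, p))
    out = pd.DataFrame(rows, columns=["factor", "p"]).set_index("factor")
    if len(out):
        out["holm_p"] = holm_adjust(out["p"].to_numpy())
    else:
        out["holm_p"] = pd.Series(dtype=float)
    out["flag_raw"] = out["p"] <= RAW_FLAG_P
    out["flag_holm"] = out["holm_p"] <= HOLM_FLAG_P
    return out
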