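"""Per-metabolite statistical screens.

Mass-univariate ordinary least squares for the two-group contrasts
(disease, diet, and the within-DCM diet comparison) with age and sex as
default covariates, paired pre/post-intervention t tests, Pearson
correlation screens against a biomarker, and the cohort demographics
table (Fisher's exact / Kruskal-Wallis).

All p values are two-sided and taken from the t distribution on the
residual degrees of freedom — the groups are small (down to n = 8), so
the normal approximation would be optimistic.  Significance tiers follow
the two-band scheme: ``fdr`` below alpha/Meff, ``nominal`` in
[alpha/Meff, 0.05), ``ns`` otherwise.
"""

from __future__ import annotations

import warnings
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from dcmmet.multiplicity import MultiplicityResult, bh_adjust
from dcmmet.types import Contrast, MetaboMatrix


def classify_tier(p: float, bands: MultiplicityResult) -> str:
    """Two-tier significance call for a single p value."""
    if np.isnan(p):
        return "ns"
    if p < bands.threshold:
        return "fdr"
    if p < bands.nominal_cut:
        return "nominal"
    return "ns"


def _tier_column(p: np.ndarray, bands: MultiplicityResult | None) -> np.ndarray:
    if bands is None:
        return np.full(p.shape, "", dtype=object)
    out = np.full(p.shape, "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        out[p < bands.nominal_cut] = "nominal"
        out[p < bands.threshold] = "fdr"
    out[np.isnan(p)] = "ns"
    return out


def _ols_screen(X: np.ndarray, Y: np.ndarray, coef_idx: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorised OLS of every column of Y on the design X.

    Returns (beta, se, p, df) for the coefficient at ``coef_idx``.  This
    is the mass-univariate normal-equations route used throughout
    expression/metabolomics screens; it is cross-checked against
    statsmodels and a brute-force oracle in the test suite.
    """
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("design has no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ X.T @ Y
    resid = Y - X @ coefs
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx])
    beta = coefs[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(tstat), df)
    return beta, se, p, df


def fit_contrast(
    matrix: MetaboMatrix,
    samples: pd.DataFrame,
    contrast: Contrast,
    covariates: tuple[str, ...] = ("age", "sex"),
    bands: MultiplicityResult | None = None,
) -> pd.DataFrame:
    """Per-metabolite OLS of log abundance on a group indicator + covariates.

    ``beta`` is the group coefficient (level ``contrast.level_one`` coded
    1), with two-sided t-based p values and tiers assigned against
    ``bands``.  Zero-variance metabolites are flagged with p = 1 rather
    than rejected.
    """
    if not matrix.log_scale:
        raise ValueError("fit_contrast expects the log-transformed matrix")
    sub = contrast.select(samples[samples.timepoint == "baseline"])
    sub = sub.set_index("sample_id")
    levels = sub[contrast.variable].unique()
    indicator = (sub[contrast.variable] == contrast.level_one).astype(float)
    counts = indicator.value_counts()
    if len(levels) < 2 or counts.min() < 2 or len(counts) < 2:
        raise ValueError(f"contrast {contrast.id!r}: each group needs >= 2 samples")

    Y = matrix.values.loc[sub.index].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("abundance matrix contains missing values; run preprocessing first")
    cols = [np.ones(len(sub)), indicator.to_numpy()]
    for cov in covariates:
        if cov == "sex":
            cols.append((sub["sex"] == "female").to_numpy(dtype=float))
        else:
            cols.append(sub[cov].to_numpy(dtype=float))
    X = np.column_stack(cols)

    beta, se, p, _ = _ols_screen(X, Y, coef_idx=1)
    const = Y.var(axis=0) == 0
    note = np.where(const, "zero-variance", "")
    beta = np.where(const, 0.0, beta)
    se = np.where(const, np.nan, se)
    p = np.where(const, 1.0, p)

    out = pd.DataFrame(
        {
            "metabolite_id": matrix.metabolites,
            "beta": beta,
            "se": se,
            "p": p,
            "q": bh_adjust(p),
            "tier": _tier_column(p, bands),
            "direction": np.sign(beta).astype(int),
            "contrast": contrast.id,
            "note": note,
        }
    )
    return out


def paired_change(
    baseline: MetaboMatrix,
    followup: MetaboMatrix,
    pairs: dict[str, str],
    bands: MultiplicityResult | None = None,
) -> pd.DataFrame:
    """One-sample t test of the per-dog month9 - baseline log differences.

    Refuses to run with fewer than 3 pairs (a 2-survivor group carries no
    usable paired information).  Constant non-zero differences are
    flagged degenerate rather than assigned a p value.
    """
    if not (baseline.log_scale and followup.log_scale):
        raise ValueError("paired_change expects log-scale matrices")
    if len(pairs) < 3:
        raise ValueError("need at least 3 baseline/follow-up pairs")
    base_ids, fu_ids = zip(*sorted(pairs.items()))
    diffs = followup.values.loc[list(fu_ids)].to_numpy() - baseline.values.loc[list(base_ids)].to_numpy()
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(tstat), df)
    zero_sd = sd == 0
    degenerate = zero_sd & (mean != 0)
    tstat = np.where(zero_sd & (mean == 0), 0.0, tstat)
    p = np.where(zero_sd & (mean == 0), 1.0, p)
    p = np.where(degenerate, np.nan, p)
    out = pd.DataFrame(
        {
            "metabolite_id": baseline.metabolites,
            "mean_diff": mean,
            "t": tstat,
            "df": df,
            "p": p,
            "tier": _tier_column(p, bands),
            "note": np.where(degenerate, "degenerate: zero-variance differences", ""),
        }
    )
    return out


def biomarker_correlation(
    matrix: MetaboMatrix,
    samples: pd.DataFrame,
    biomarker: str = "ctni",
    bands: MultiplicityResult | None = None,
) -> pd.DataFrame:
    """Pearson correlation of every metabolite with a biomarker.

    Two-sided p via the exact t transform t = r sqrt(n-2) / sqrt(1-r^2)
    on n-2 degrees of freedom.
    """
    sub = samples[samples.timepoint == "baseline"].set_index("sample_id")
    y = sub[biomarker].astype(float)
    y = y[y.notna()]
    if len(y) < 3:
        raise ValueError("biomarker present for fewer than 3 samples")
    if y.nunique() == 1:
        raise ValueError("constant biomarker")
    X = matrix.values.loc[y.index].to_numpy(dtype=float)
    n = len(y)
    yv = y.to_numpy()
    yc = yv - yv.mean()
    xc = X - X.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(tstat), df)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    const = sx == 0
    r = np.where(const, np.nan, r)
    p = np.where(const, np.nan, p)
    out = pd.DataFrame(
        {
            "metabolite_id": matrix.metabolites,
            "r": r,
            "p": p,
            "n": n,
            "tier": _tier_column(p, bands),
            "note": np.where(const, "constant metabolite", ""),
        }
    )
    return out


# ---------------------------------------------------------------------------
# demographics


def _log_table_prob(table: np.ndarray, lg_margins: float, lg_n: float) -> float:
    return lg_margins - lg_n - sum(lgamma(v + 1) for v in table.ravel())


def fisher_exact_rxc(table) -> float:
    """Two-sided Fisher's exact test for a small r x c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one — the
    standard two-sided convention.  Intended for the small demographic
    tables at hand; enumeration size grows quickly with the margins.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a non-negative 2-D array")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("empty table")
    lg_margins = sum(lgamma(v + 1) for v in rows) + sum(lgamma(v + 1) for v in cols)
    lg_n = lgamma(n + 1)
    logp_obs = _log_table_prob(obs, lg_margins, lg_n)

    r, c = obs.shape
    total = 0.0

    def recurse(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> None:
        nonlocal total
        if i == r - 1:
            last = remaining_cols
            if (last < 0).any() or last.sum() != rows[-1]:
                return
            cand = np.vstack(acc + [last])
            logp = _log_table_prob(cand, lg_margins, lg_n)
            if logp <= logp_obs + 1e-9:
                total += np.exp(logp)
            return
        for combo in _row_fills(rows[i], remaining_cols):
            recurse(i + 1, remaining_cols - combo, acc + [combo])

    def _row_fills(row_total: int, col_caps: np.ndarray):
        caps = col_caps.tolist()

        def gen(j: int, left: int, cur: list[int]):
            if j == len(caps) - 1:
                if left <= caps[j]:
                    yield np.array(cur + [left])
                return
            for v in range(min(left, caps[j]) + 1):
                yield from gen(j + 1, left - v, cur + [v])

        yield from gen(0, int(row_total), [])

    recurse(0, cols.copy(), [])
    return float(min(total, 1.0))


def cohort_summary(
    samples: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "body_weight", "ctni"),
    categorical: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Baseline demographics across the four disease x diet groups.

    Continuous variables: Kruskal-Wallis (chi-square approximation with
    tie correction) plus median (min-max) per group.  Categorical
    variables: Fisher's exact test on the level x group table.  A
    variable with a single observed level is omitted with a warning.
    """
    base = samples[samples.timepoint == "baseline"].copy()
    base["group"] = base.disease.str.replace("control", "C") + "-" + base.diet
    group_names = sorted(base.group.unique())
    rows = []
    for var in continuous:
        vals = [base.loc[base.group == g, var].dropna().to_numpy() for g in group_names]
        if any(len(v) == 0 for v in vals):
            warnings.warn(f"{var}: empty group, omitted", stacklevel=2)
            continue
        try:
            stat, p = stats.kruskal(*vals)
        except ValueError:  # all values identical
            stat, p = 0.0, 1.0
        summary = {
            g: f"{np.median(v):.1f} ({v.min():.1f}-{v.max():.1f})" for g, v in zip(group_names, vals)
        }
        rows.append({"variable": var, "test": "kruskal-wallis", "statistic": stat, "p": p, **summary})
    for var in categorical:
        levels = sorted(base[var].dropna().unique())
        if len(levels) < 2:
            warnings.warn(f"{var}: single level, omitted", stacklevel=2)
            continue
        table = np.array(
            [[int(((base.group == g) & (base[var] == lv)).sum()) for g in group_names] for lv in levels]
        )
        p = fisher_exact_rxc(table)
        summary = {
            g: "/".join(str(int(((base.group == g) & (base[var] == lv)).sum())) for lv in levels)
            for g in group_names
        }
        rows.append({"variable": var, "test": "fisher-exact", "statistic": np.nan, "p": p, **summary})
    return pd.DataFrame(rows)
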