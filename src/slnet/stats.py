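"""Family-level bootstrap inference and covariate-adjusted correlations.

The exchangeable resampling unit is the *family*, not the subject: each
bootstrap replicate draws families with replacement up to the original family
count and retrieves every observation (all members, all repeated measures) of
the drawn families. This keeps the within-family covariance structure intact
on average. Confidence intervals use the bias-corrected and accelerated (BCa)
adjustment, with the acceleration estimated from a leave-one-family-out
jackknife to match the resampling unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recording import CohortDataset, ConfigurationError


class DegenerateDistributionWarning(UserWarning):
    pass


class ReplicateFailureError(RuntimeError):
    """Raised when more than 1% of bootstrap replicates fail."""


@dataclass
class BootstrapResult:
    """Bootstrap distribution of a statistic under family resampling."""

    values: np.ndarray
    observed: float
    jackknife: np.ndarray
    n_flagged: int = 0

    @property
    def se(self) -> float:
        return float(self.values.std(ddof=1))


@dataclass
class GroupComparison:
    """One group-pair contrast with its BCa interval."""

    group_a: str
    group_b: str
    step: int
    observed: float
    ci_low: float
    ci_high: float
    alpha: float

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def _table(data) -> pd.DataFrame:
    return data.table if isinstance(data, CohortDataset) else data


def _family_rows(df: pd.DataFrame) -> list[np.ndarray]:
    codes, _ = pd.factorize(df["family_id"])
    return [np.flatnonzero(codes == f) for f in range(codes.max() + 1)]


def family_bootstrap(data, statistic, n_boot: int = 2000,
                     seed: int = 0) -> BootstrapResult:
    """Bootstrap a statistic by resampling families with replacement.

    ``statistic`` maps a DataFrame (same columns as the input table) to a
    float. Replicates where the statistic raises are flagged (not silently
    dropped); the run fails if more than 1% are flagged. The jackknife
    (leave one family out) values used for the BCa acceleration are computed
    alongside.
    """
    df = _table(data).reset_index(drop=True)
    fams = _family_rows(df)
    if len(fams) < 1:
        raise ConfigurationError("no families in data")
    rng = np.random.default_rng(seed)
    observed = float(statistic(df))
    values = np.empty(n_boot)
    flagged = 0
    n_fam = len(fams)
    for b in range(n_boot):
        pick = rng.integers(n_fam, size=n_fam)
        rows = np.concatenate([fams[f] for f in pick])
        try:
            values[b] = statistic(df.take(rows))
        except Exception:
            values[b] = np.nan
            flagged += 1
    if flagged > 0.01 * n_boot:
        raise ReplicateFailureError(
            f"{flagged}/{n_boot} bootstrap replicates failed"
        )
    jack = np.empty(n_fam)
    for f in range(n_fam):
        rows = np.concatenate([fams[g] for g in range(n_fam) if g != f]) \
            if n_fam > 1 else fams[0]
        jack[f] = statistic(df.take(rows))
    return BootstrapResult(values=values[~np.isnan(values)], observed=observed,
                           jackknife=jack, n_flagged=flagged)


def bca_interval(distribution: np.ndarray, observed: float,
                 jackknife: np.ndarray, alpha: float = 0.01
                 ) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    z0 comes from the proportion of replicates below the observed value, the
    acceleration from the jackknife skewness; the returned endpoints are the
    correspondingly adjusted quantiles of the bootstrap distribution. A
    degenerate distribution yields a zero-width interval with a warning.
    """
    dist = np.asarray(distribution, dtype=float)
    if dist.size < 2 or np.ptp(dist) == 0:
        warnings.warn("degenerate bootstrap distribution; zero-width interval",
                      DegenerateDistributionWarning, stacklevel=2)
        v = float(dist[0]) if dist.size else observed
        return (v, v)
    prop = np.mean(dist < observed) + 0.5 * np.mean(dist == observed)
    prop = np.clip(prop, 1.0 / (dist.size + 1), dist.size / (dist.size + 1.0))
    z0 = sps.norm.ppf(prop)
    jm = jackknife.mean()
    num = ((jm - jackknife) ** 3).sum()
    den = 6.0 * (((jm - jackknife) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = z0 + sps.norm.ppf(q)
        adj = sps.norm.cdf(z0 + z / (1.0 - a * z))
        out.append(float(np.quantile(dist, adj)))
    return out[0], out[1]


def _group_sums(df: pd.DataFrame, metric: str, groups: list[str]
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-family, per-group sums and counts of the metric (F x G arrays)."""
    fam_codes, _ = pd.factorize(df["family_id"])
    g_index = {g: i for i, g in enumerate(groups)}
    g_codes = df["group"].map(g_index).to_numpy()
    v = df[metric].to_numpy(dtype=float)
    n_fam = fam_codes.max() + 1
    sums = np.zeros((n_fam, len(groups)))
    cnts = np.zeros((n_fam, len(groups)))
    np.add.at(sums, (fam_codes, g_codes), v)
    np.add.at(cnts, (fam_codes, g_codes), 1.0)
    return sums, cnts, n_fam


def bootstrap_group_means(data, metric: str, n_boot: int = 2000,
                          seed: int = 0) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized family bootstrap of all group means at once.

    Returns (groups, observed G-vector, replicate (B, G) matrix, jackknife
    (F, G) matrix). Family draws are realized as multinomial counts, which is
    exactly sampling F families with replacement. Replicates where a group
    receives no observations yield NaN for that group's mean.
    """
    df = _table(data).reset_index(drop=True)
    groups = list(dict.fromkeys(df["group"]))
    sums, cnts, n_fam = _group_sums(df, metric, groups)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_fam, np.full(n_fam, 1.0 / n_fam), size=n_boot)
    rep_sum = draws @ sums
    rep_cnt = draws @ cnts
    with np.errstate(invalid="ignore", divide="ignore"):
        replicates = np.where(rep_cnt > 0, rep_sum / rep_cnt, np.nan)
        tot_s, tot_c = sums.sum(0), cnts.sum(0)
        observed = tot_s / tot_c
        jack = np.where(tot_c - cnts > 0,
                        (tot_s - sums) / (tot_c - cnts), np.nan)
    return groups, observed, replicates, jack


def group_differences(data, metric: str, alpha: float = 0.01,
                      n_boot: int = 2000, seed: int = 0
                      ) -> list[GroupComparison]:
    """Bootstrap contrasts between adjacent groups and groups two steps apart.

    Groups are taken in their order of first appearance in the table; the
    contrast is (later group mean) - (earlier group mean). Significance means
    the BCa interval at ``alpha`` excludes zero. Empty groups are excluded
    with a warning; replicates that empty a group are flagged and the run
    fails if more than 1% of them do.
    """
    df = _table(data)
    counts = df.groupby("group", sort=False)[metric].count()
    empty = [g for g in counts.index if counts[g] == 0]
    if empty:
        warnings.warn(f"excluding empty groups: {empty}", stacklevel=2)
        df = df[~df["group"].isin(empty)]
    groups, observed, reps, jack = bootstrap_group_means(
        df, metric, n_boot=n_boot, seed=seed)
    out: list[GroupComparison] = []
    for i in range(len(groups)):
        for step in (1, 2):
            j = i + step
            if j >= len(groups):
                continue
            d_obs = float(observed[j] - observed[i])
            d_rep = reps[:, j] - reps[:, i]
            bad = np.isnan(d_rep)
            if bad.sum() > 0.01 * len(d_rep):
                raise ReplicateFailureError(
                    f"{bad.sum()}/{len(d_rep)} replicates emptied a group "
                    f"for contrast {groups[i]} vs {groups[j]}"
                )
            d_jack = jack[:, j] - jack[:, i]
            lo, hi = bca_interval(d_rep[~bad], d_obs,
                                  d_jack[~np.isnan(d_jack)], alpha=alpha)
            out.append(GroupComparison(
                group_a=groups[i], group_b=groups[j], step=step,
                observed=d_obs, ci_low=lo, ci_high=hi, alpha=alpha))
    return out


def significance_tier(distribution: np.ndarray, observed: float,
                      jackknife: np.ndarray,
                      alphas: tuple[float, ...] = (0.01, 0.001, 0.0001)
                      ) -> float | None:
    """Smallest alpha among ``alphas`` whose BCa interval excludes zero.

    Figure-hook helper: nested intervals give the p < .01 / .001 / .0001
    tiers. Returns None when even the loosest interval covers zero.
    """
    best = None
    for a in sorted(alphas, reverse=True):
        lo, hi = bca_interval(distribution, observed, jackknife, alpha=a)
        if lo <= 0.0 <= hi:
            break
        best = a
    return best


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(x, y, covariates, data=None, n_boot: int = 2000,
                        seed: int = 0, alpha: float = 0.05):
    """Correlation of x and y after regressing covariates out of both.

    ``x``, ``y`` are arrays or column names of ``data``; ``covariates`` is a
    2-D array (or list of column names) whose columns are removed from both
    variables by least squares before the Pearson correlation. When ``data``
    carries a family_id column the confidence interval comes from the
    family-level bootstrap, otherwise each observation is its own family.

    Returns (r, (ci_low, ci_high)).
    """
    if data is not None:
        df = _table(data).reset_index(drop=True)
        xv = df[x].to_numpy(dtype=float) if isinstance(x, str) else np.asarray(x, float)
        yv = df[y].to_numpy(dtype=float) if isinstance(y, str) else np.asarray(y, float)
        cov_cols = [covariates] if isinstance(covariates, str) else list(covariates)
        if cov_cols and isinstance(cov_cols[0], str):
            cov = np.column_stack([
                pd.factorize(df[c])[0] if df[c].dtype == object
                else df[c].to_numpy(dtype=float) for c in cov_cols])
        else:
            cov = np.atleast_2d(np.asarray(covariates, float).T).T
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        df = pd.DataFrame({"_x": xv, "_y": yv,
                           "family_id": [f"f{i}" for i in range(len(xv))]})
        for k in range(cov.shape[1]):
            df[f"_c{k}"] = cov[:, k]

    if len(xv) < cov.shape[1] + 3:
        raise ConfigurationError("need at least 3 more observations than covariates")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ConfigurationError("constant input: partial correlation undefined")

    def stat(frame: pd.DataFrame) -> float:
        if data is not None:
            fx = frame[x].to_numpy(float) if isinstance(x, str) else xv[frame.index]
            fy = frame[y].to_numpy(float) if isinstance(y, str) else yv[frame.index]
            if cov_cols and isinstance(cov_cols[0], str):
                fc = np.column_stack([
                    pd.factorize(frame[c])[0] if frame[c].dtype == object
                    else frame[c].to_numpy(dtype=float) for c in cov_cols])
            else:
                fc = cov[frame.index]
        else:
            fx = frame["_x"].to_numpy(float)
            fy = frame["_y"].to_numpy(float)
            fc = frame[[f"_c{k}" for k in range(cov.shape[1])]].to_numpy(float)
        rx = _residualize(fx, fc)
        ry = _residualize(fy, fc)
        return float(np.corrcoef(rx, ry)[0, 1])

    r = stat(df)
    boot = family_bootstrap(df, stat, n_boot=n_boot, seed=seed)
    ci = bca_interval(boot.values, r, boot.jackknife, alpha=alpha)
    return r, ci


def transform_for_normality(values, which: str) -> np.ndarray:
    """Skew-reducing transforms: sl -> log(sl), L -> -1/L, C untouched.

    Both transforms are strictly increasing on positive inputs (the negation
    in -1/x keeps correlation directions intact), so significance and sign of
    downstream correlations are preserved.
    """
    v = np.asarray(values, dtype=float)
    if which == "sl":
        if (v <= 0).any():
            raise ConfigurationError("log transform requires positive SL values")
        return np.log(v)
    if which == "L":
        if (v <= 0).any():
            raise ConfigurationError("-1/x transform requires positive L values")
        return -1.0 / v
    if which == "C":
        return v.copy()
    raise ConfigurationError(f"unknown metric kind {which!r}")


def paired_bias(scores_a, scores_b) -> tuple[float, np.ndarray]:
    """Systematic offset between paired scorings and the corrected B scores.

    Used to remove the small but systematic bias that lead substitution
    introduces: bias = mean(A - B), corrected B = B + bias. Inputs must be
    complete pairs in matching subject order.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired scores must have identical shape")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ConfigurationError("unpaired (missing) subject in paired scores")
    bias = float(np.mean(a - b))
    return bias, b + bias


def outlier_policy(values, z_cut: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Indices retained / flagged by the |z| > z_cut rule on any metric.

    ``values`` is (n_obs,) or (n_obs, n_metrics); an observation is flagged
    when any of its metrics deviates more than ``z_cut`` standard deviations
    from that metric's mean. Analyses are meant to be reported both with and
    without the flagged observations.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float).T).T
    if v.shape[0] < 3:
        raise ConfigurationError("need at least 3 observations")
    sd = v.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = np.abs((v - v.mean(axis=0)) / sd)
    flagged = np.flatnonzero((z > z_cut).any(axis=1))
    retained = np.setdiff1d(np.arange(v.shape[0]), flagged)
    return retained, flagged
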