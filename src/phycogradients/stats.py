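"""Quantification layer: growth rates, geometric summaries, distance
responses, and the significance tests applied to abundance tables.

Bacterial and algal counts carry multiplicative error, so summaries are
geometric (geometric mean / geometric SD) and two-sample comparisons
default to log-transformed densities.  The Welch t-test and the
balanced two-way ANOVA are implemented from their defining formulas
(only the t- and F-distribution tail functions come from scipy); a
distribution-free permutation trend test covers small unbalanced
distance designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GrowthRateResult",
    "SpatialResponse",
    "WelchResult",
    "TrendResult",
    "specific_growth_rate",
    "geometric_stats",
    "fold_change_by_distance",
    "welch_t_test",
    "welch_t_test_batch",
    "two_way_anova_interaction",
    "permutation_trend_test",
    "permutation_trend_pvalues_batch",
    "bh_fdr",
]


@dataclass(frozen=True)
class GrowthRateResult:
    """Specific growth rate over a log-linear window, per replicate."""

    mu_mean: float  # d⁻¹
    mu_sd: float
    window: tuple[float, float]
    replicate_mus: tuple[float, ...]


def specific_growth_rate(densities: pd.DataFrame, t1: float, t2: float) -> GrowthRateResult:
    """µ = (ln N(t2) − ln N(t1)) / (t2 − t1), replicate-wise.

    ``densities`` is indexed by time (d) with one column per replicate;
    densities at t1 and t2 are linearly interpolated in log space from
    the surrounding samples.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    t = densities.index.to_numpy(dtype=float)
    if t1 < t[0] or t2 > t[-1]:
        raise ValueError(f"window ({t1}, {t2}) outside series ({t[0]}, {t[-1]})")
    mus = []
    for col in densities.columns:
        n = densities[col].to_numpy(dtype=float)
        if np.any(n <= 0):
            raise ValueError(f"replicate {col!r} has non-positive densities")
        log_n = np.log(n)
        mus.append((np.interp(t2, t, log_n) - np.interp(t1, t, log_n)) / (t2 - t1))
    mus = np.asarray(mus)
    return GrowthRateResult(
        mu_mean=float(mus.mean()),
        mu_sd=float(mus.std(ddof=1)) if mus.size > 1 else 0.0,
        window=(t1, t2),
        replicate_mus=tuple(float(m) for m in mus),
    )


def geometric_stats(values) -> dict[str, float]:
    """Geometric mean and geometric SD of strictly positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(v <= 0):
        raise ValueError("geometric statistics require strictly positive values")
    logs = np.log(v)
    geo_sd = float(np.exp(logs.std(ddof=1))) if v.size > 1 else 1.0
    return {"geo_mean": float(np.exp(logs.mean())), "geo_sd": geo_sd}


@dataclass(frozen=True)
class SpatialResponse:
    """Distance response of one taxon: fold-change and monotone trend."""

    taxon: str
    fold_decrease: float  # innermost / outermost geometric means
    statistic: float  # Spearman rho of abundance vs distance
    p_value: float
    n_per_location: dict[float, int]
    at_detection_floor: bool = False


def fold_change_by_distance(
    table: pd.DataFrame,
    taxon: str,
    t: float | None = None,
    *,
    floor: float = 1e3,
    n_perm: int = 999,
    seed: int | None = None,
) -> SpatialResponse:
    """Innermost/outermost geometric-mean ratio plus a trend test.

    Abundances below the detection floor (default 10³ cells ml⁻¹) are
    clamped to it before taking geometric means, keeping folds finite
    for taxa with negligible outer-well growth.  The trend statistic is
    the Spearman correlation of abundance with distance, with a
    permutation p-value (seeded).
    """
    sub = table[table["taxon"] == taxon]
    if sub.empty:
        raise KeyError(f"taxon {taxon!r} not in table")
    if t is not None:
        sub = sub[np.isclose(sub["timepoint"].to_numpy(dtype=float), t)]
        if sub.empty:
            raise ValueError(f"no rows at timepoint {t}")
    dist = sub["distance_mm"].to_numpy(dtype=float)
    dens = np.maximum(sub["absolute_density"].to_numpy(dtype=float), floor)
    groups = sorted(set(dist))
    if len(groups) < 2:
        raise ValueError("need >= 2 distance groups")
    geo = {d: geometric_stats(dens[dist == d])["geo_mean"] for d in groups}
    n_per = {float(d): int(np.sum(dist == d)) for d in groups}
    inner, outer = geo[groups[0]], geo[groups[-1]]
    at_floor = bool(np.isclose(outer, floor))
    if at_floor:
        warnings.warn(
            f"outermost geometric mean sits at the detection floor ({floor:g});"
            " the fold-change is a lower bound", RuntimeWarning, stacklevel=2)
    trend = permutation_trend_test(dens, dist, n_perm=n_perm, seed=seed) \
        if seed is not None else TrendResult(
            statistic=float(sps.spearmanr(dens, dist).statistic)
            if np.ptp(dens) > 0 else 0.0,
            p_value=float("nan"), n_perm=0)
    return SpatialResponse(
        taxon=taxon,
        fold_decrease=float(inner / outer),
        statistic=trend.statistic,
        p_value=trend.p_value,
        n_per_location=n_per,
        at_detection_floor=at_floor,
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_tailed: float


def welch_t_test(a, b) -> WelchResult:
    """Two-sample t-test with Welch's unequal-variance correction.

    t = (x̄_a − x̄_b) / √(s²_a/n_a + s²_b/n_b), with Welch–Satterthwaite
    degrees of freedom; two-tailed p.  Two zero-variance samples with
    equal means give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, df = _welch_t_df(a.mean(), a.var(ddof=1), a.size,
                        b.mean(), b.var(ddof=1), b.size)
    if np.isnan(t):  # both variances zero
        if np.isclose(a.mean(), b.mean()):
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p_two_tailed=1.0)
        return WelchResult(t=np.inf if a.mean() > b.mean() else -np.inf,
                           df=float(a.size + b.size - 2), p_two_tailed=0.0)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p_two_tailed=min(p, 1.0))


def _welch_t_df(ma, va, na, mb, vb, nb):
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def welch_t_test_batch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test along the last axis; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, df = _welch_t_df(a.mean(-1), a.var(-1, ddof=1), a.shape[-1],
                        b.mean(-1), b.var(-1, ddof=1), b.shape[-1])
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, np.minimum(p, 1.0)


def two_way_anova_interaction(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("layer", "treatment"),
) -> dict[str, dict[str, float]]:
    """Balanced two-way fixed-effects ANOVA from sums of squares.

    Returns per-term ``{F, p, df, ss}`` for the two main effects, their
    interaction, and the residual.  The balanced decomposition
    SS_total = SS_A + SS_B + SS_AB + SS_error is exact; unbalanced or
    empty cells raise an error pointing to the permutation trend test.
    """
    fa, fb = factors
    y = table[response].to_numpy(dtype=float)
    a_lv = pd.unique(table[fa])
    b_lv = pd.unique(table[fb])
    if len(a_lv) < 2 or len(b_lv) < 2:
        raise ValueError("both factors need >= 2 levels")
    counts = table.groupby([fa, fb], observed=True).size()
    if len(counts) != len(a_lv) * len(b_lv) or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design or empty cells; use permutation_trend_test "
            "or subsample to a balanced design")
    n_rep = int(counts.iloc[0])
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per cell")

    grand = y.mean()
    cell = table.groupby([fa, fb], observed=True)[response].mean()
    mean_a = table.groupby(fa, observed=True)[response].mean()
    mean_b = table.groupby(fb, observed=True)[response].mean()
    n_a, n_b = len(a_lv), len(b_lv)

    ss_a = n_rep * n_b * float(((mean_a - grand) ** 2).sum())
    ss_b = n_rep * n_a * float(((mean_b - grand) ** 2).sum())
    ss_cells = n_rep * float(((cell - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cells

    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_err = n_a * n_b * (n_rep - 1)

    def term(ss, df):
        if ss_tot == 0.0:
            return {"F": 0.0, "p": 1.0, "df": float(df), "ss": 0.0,
                    "degenerate": True}
        ms_err = ss_err / df_err
        if ms_err == 0.0:
            warnings.warn("zero residual variance: F undefined, p set to 0 "
                          "for nonzero effects", RuntimeWarning, stacklevel=3)
            f = np.inf if ss > 0 else 0.0
            return {"F": float(f), "p": 0.0 if ss > 0 else 1.0,
                    "df": float(df), "ss": float(ss)}
        f = (ss / df) / ms_err
        return {"F": float(f), "p": float(sps.f.sf(f, df, df_err)),
                "df": float(df), "ss": float(ss)}

    return {
        fa: term(ss_a, df_a),
        fb: term(ss_b, df_b),
        f"{fa}:{fb}": term(ss_ab, df_ab),
        "residual": {"F": float("nan"), "p": float("nan"),
                     "df": float(df_err), "ss": float(ss_err)},
        "total": {"F": float("nan"), "p": float("nan"),
                  "df": float(len(y) - 1), "ss": float(ss_tot)},
    }


@dataclass(frozen=True)
class TrendResult:
    statistic: float  # Spearman rho
    p_value: float
    n_perm: int


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, axis=-1)


def permutation_trend_test(abundance, distance, n_perm: int = 999,
                           seed: int | None = None) -> TrendResult:
    """Two-sided permutation test of the Spearman abundance-distance trend.

    p = (1 + #{|ρ*| ≥ |ρ|}) / (n_perm + 1); constant abundance gives
    ρ = 0, p = 1.  Requires a seed (unseeded stochastic calls are an
    error) and n_perm ≥ 999.
    """
    a = np.asarray(abundance, dtype=float)
    d = np.asarray(distance, dtype=float)
    if a.size != d.size or a.size < 4:
        raise ValueError("need matched samples with n >= 4")
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    if seed is None:
        raise ValueError("seed is required")
    if np.ptp(a) == 0 or np.ptp(d) == 0:
        return TrendResult(statistic=0.0, p_value=1.0, n_perm=n_perm)
    ra, rd = _rank(a), _rank(d)
    rho = _pearson(ra, rd)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ra, (n_perm, 1)), axis=1)
    rho_null = _pearson(perms, rd)
    p = (1.0 + np.sum(np.abs(rho_null) >= abs(rho) - 1e-12)) / (n_perm + 1.0)
    return TrendResult(statistic=float(rho), p_value=float(p), n_perm=n_perm)


def _pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(-1, keepdims=True)
    yc = y - y.mean(-1, keepdims=True)
    return (xc * yc).sum(-1) / np.sqrt((xc ** 2).sum(-1) * (yc ** 2).sum(-1))


def permutation_trend_pvalues_batch(
    abundances: np.ndarray, distance: np.ndarray, n_perm: int = 999,
    seed: int | None = None, chunk: int = 500,
) -> np.ndarray:
    """Permutation trend p-values for many datasets (rows) at once.

    Used for null-calibration studies; same p-value definition as
    :func:`permutation_trend_test`.
    """
    if seed is None:
        raise ValueError("seed is required")
    ab = np.asarray(abundances, dtype=float)
    rd = _rank(np.asarray(distance, dtype=float))
    rng = np.random.default_rng(seed)
    out = np.empty(ab.shape[0])
    for lo in range(0, ab.shape[0], chunk):
        block = ab[lo:lo + chunk]
        ra = _rank(block)
        rho = _pearson(ra, rd)
        tiled = np.repeat(ra[:, None, :], n_perm, axis=1)
        perms = rng.permuted(tiled, axis=2)
        rho_null = _pearson(perms, rd)
        out[lo:lo + chunk] = (
            1.0 + np.sum(np.abs(rho_null) >= np.abs(rho)[:, None] - 1e-12, axis=1)
        ) / (n_perm + 1.0)
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
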