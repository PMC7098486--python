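"""Differential-abundance statistics: Welch's t test with an S0 fudge
constant, SAM-style permutation FDR, volcano classification, and organelle
distribution shifts.

The moderated statistic is Tusher-style: ``d = (meanA - meanB) / (s0 +
sqrt(varA/nA + varB/nB))`` on log2 data, so S0 de-emphasizes features whose
variance is accidentally tiny.  p values use the Welch-Satterthwaite
degrees of freedom of the unmodified denominator; with ``s0 = 0`` the test
reduces exactly to classical Welch.  FDR control is SAM-like: the null |d|
distribution is built from group-label permutations (exhaustive when few
enough exist, otherwise sampled with a seed), the estimated FDR at a
cutoff is the median permuted exceedance count over the observed count,
and the significant set is the largest set whose estimate stays at or
below the nominal level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsParams",
    "welch_s0",
    "welch_s0_matrix",
    "permutation_fdr",
    "diff_test",
    "volcano_classify",
    "organelle_shift",
]


@dataclass
class StatsParams:
    s0: float = 1.0
    fdr_level: float = 0.01
    n_permutations: int = 250
    seed: int = 17
    log2_threshold: float = 1.0
    p_threshold: float = 0.05
    max_exhaustive: int = 1000

    def __post_init__(self):
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def welch_s0(group_a, group_b, s0: float = 0.0) -> tuple[float, float]:
    """Moderated Welch statistic and two-sided p value for two samples.

    Both groups need n >= 2.  With zero variance in both groups and
    ``s0 = 0`` the statistic is undefined and (nan, nan) is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group requires at least 2 values")
    d, p = _welch_core(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size, s0
    )
    return float(d), float(p)


def _welch_core(ma, va, na, mb, vb, nb, s0):
    sa, sb = va / na, vb / nb
    se = np.sqrt(sa + sb)
    denom = s0 + se
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, (ma - mb) / denom, np.nan)
        df = np.where(
            se > 0,
            (sa + sb) ** 2
            / (sa**2 / np.maximum(na - 1, 1) + sb**2 / np.maximum(nb - 1, 1)),
            np.nan,
        )
    p = np.where(
        np.isfinite(d) & np.isfinite(df),
        2.0 * sps.t.sf(np.abs(np.where(np.isfinite(d), d, 0.0)), np.where(np.isfinite(df), df, 1.0)),
        np.nan,
    )
    # zero variance everywhere: statistic defined only if s0 > 0, and then
    # the reference distribution degenerates; report p as nan
    return d, p


def welch_s0_matrix(
    values: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise moderated Welch test on a features x samples array.

    NaN-aware per-feature complete-case analysis; rows with fewer than two
    finite values in either group yield (nan, nan).
    """
    A = values[:, cols_a]
    B = values[:, cols_b]
    na = np.isfinite(A).sum(axis=1)
    nb = np.isfinite(B).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(A, axis=1)
        mb = np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)
    ok = (na >= 2) & (nb >= 2)
    d = np.full(values.shape[0], np.nan)
    p = np.full(values.shape[0], np.nan)
    if ok.any():
        d_ok, p_ok = _welch_core(
            ma[ok], va[ok], na[ok], mb[ok], vb[ok], nb[ok], s0
        )
        d[ok], p[ok] = d_ok, p_ok
    return d, p


def _label_permutations(n_total: int, n_a: int, params: StatsParams, rng):
    """Index sets assigned to group A under label permutation."""
    n_distinct = math.comb(n_total, n_a)
    if n_distinct < 2:
        raise ValueError("fewer than 2 distinct label permutations exist")
    if n_distinct <= params.max_exhaustive:
        return [np.array(c) for c in itertools.combinations(range(n_total), n_a)]
    perms = []
    seen = set()
    while len(perms) < params.n_permutations:
        c = tuple(sorted(rng.choice(n_total, size=n_a, replace=False)))
        if c not in seen:
            seen.add(c)
            perms.append(np.array(c))
    return perms


def permutation_fdr(
    values: np.ndarray,
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    params: StatsParams,
) -> tuple[np.ndarray, dict]:
    """SAM-style permutation FDR on a features x samples log2 array.

    Returns a boolean significant-flag vector and a detail dict with the
    chosen |d| cutoff, the estimated FDR at that cutoff, and the observed
    statistics.
    """
    cols_a = np.asarray(cols_a)
    cols_b = np.asarray(cols_b)
    rng = np.random.default_rng(params.seed)
    d_obs, _ = welch_s0_matrix(values, cols_a, cols_b, params.s0)
    obs_abs = np.abs(d_obs)
    finite = np.isfinite(obs_abs)

    pooled_cols = np.concatenate([cols_a, cols_b])
    perms = _label_permutations(pooled_cols.size, cols_a.size, params, rng)
    perm_abs_sorted = []
    for idx_a in perms:
        pa = pooled_cols[idx_a]
        pb = np.delete(pooled_cols, idx_a)
        d_p, _ = welch_s0_matrix(values, pa, pb, params.s0)
        pa_abs = np.abs(d_p)
        perm_abs_sorted.append(np.sort(pa_abs[np.isfinite(pa_abs)]))

    cutoffs = np.sort(obs_abs[finite])[::-1]
    obs_sorted = np.sort(obs_abs[finite])
    chosen_cut = np.inf
    chosen_fdr = np.nan
    # walk cutoffs from the most extreme observed |d| downward, keeping the
    # largest set whose estimated FDR stays within the nominal level
    for c in cutoffs:
        n_obs = obs_sorted.size - np.searchsorted(obs_sorted, c, side="left")
        if n_obs == 0:
            continue
        exceed = [arr.size - np.searchsorted(arr, c, side="left")
                  for arr in perm_abs_sorted]
        fdr = float(np.median(exceed)) / n_obs
        if fdr <= params.fdr_level:
            chosen_cut, chosen_fdr = float(c), fdr
        else:
            break
    significant = finite & (obs_abs >= chosen_cut)
    detail = {
        "cutoff": chosen_cut,
        "estimated_fdr": chosen_fdr,
        "d": d_obs,
        "n_permutations": len(perms),
        "exhaustive": math.comb(pooled_cols.size, cols_a.size)
        <= params.max_exhaustive,
    }
    return significant, detail


def diff_test(
    matrix: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    params: StatsParams | None = None,
    log2_input: bool = False,
) -> pd.DataFrame:
    """Per-feature differential test of group A (e.g. depolarized) against
    group B (e.g. untreated) with permutation-FDR significance flags.

    Intensity matrices are log2-transformed unless ``log2_input``; zeros
    become missing values first.  The result carries log2 ratio, moderated
    statistic ``d``, p value, FDR-significant flag, direction, and the
    volcano category under the threshold rule.
    """
    params = params or StatsParams()
    sub = matrix[cols_a + cols_b].astype(float)
    values = sub.to_numpy()
    if not log2_input:
        with np.errstate(divide="ignore"):
            values = np.log2(np.where(values > 0, values, np.nan))
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols_a) + len(cols_b))
    d, p = welch_s0_matrix(values, ia, ib, params.s0)
    significant, detail = permutation_fdr(values, ia, ib, params)
    with np.errstate(invalid="ignore"):
        log2_ratio = np.nanmean(values[:, ia], axis=1) - np.nanmean(
            values[:, ib], axis=1
        )
    result = pd.DataFrame(
        {
            "log2_ratio": log2_ratio,
            "d": d,
            "p": p,
            "significant": significant,
            "direction": np.where(
                ~np.isfinite(d), "na", np.where(d > 0, "up", np.where(d < 0, "down", "none"))
            ),
        },
        index=matrix.index,
    )
    result["category"] = [
        volcano_classify(lr, pv, params)
        for lr, pv in zip(result["log2_ratio"], result["p"])
    ]
    result.attrs["permutation_fdr"] = {
        k: v for k, v in detail.items() if k != "d"
    }
    return result


def volcano_classify(log2_ratio: float, p: float, params: StatsParams | None = None) -> str:
    """Volcano-plot category under the threshold rule: ``up`` when log2
    ratio > threshold with p below the p threshold, ``down`` for the
    mirrored case, ``ns`` otherwise (inequalities are strict)."""
    params = params or StatsParams()
    if not (np.isfinite(log2_ratio) and np.isfinite(p)):
        return "ns"
    if p < params.p_threshold:
        if log2_ratio > params.log2_threshold:
            return "up"
        if log2_ratio < -params.log2_threshold:
            return "down"
    return "ns"


def organelle_shift(
    log2_ratios: pd.Series,
    annotation: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-organelle summary of protein log2 abundance changes.

    Each organelle class's mean log2 ratio is compared against zero
    (no change) with a two-sided one-sample t test; classes are corrected
    across one another by Benjamini-Hochberg.  Single-protein classes have
    no variance estimate and are never called significant.
    """
    joined = pd.DataFrame({"ratio": log2_ratios, "organelle": annotation}).dropna()
    rows = []
    for organelle, grp in joined.groupby("organelle"):
        vals = grp["ratio"].to_numpy()
        n = vals.size
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan
        if n > 1 and vals.std(ddof=1) > 0:
            p = float(sps.ttest_1samp(vals, 0.0).pvalue)
        else:
            p = np.nan
        rows.append(
            {"organelle": organelle, "n": n, "mean_log2": mean, "sem": sem, "p": p}
        )
    out = pd.DataFrame(rows).set_index("organelle")
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["significant"] = (out["q"] < alpha).fillna(False)
    return out
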