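"""Treatment-comparison statistics and the printed-contrast report.

Covers one-way ANOVA with Duncan's multiple range test (letter display),
orthogonal contrasts of the organic-replacement treatments against the
chemical-fertilizer control, Spearman correlation grids with
Benjamini-Hochberg adjustment, variance partitioning of community
composition by redundancy analysis, and the fold-change report that
restates group-mean ratios against the control.

Duncan's procedure compares the range of every set of p adjacent ordered
means against the least significant range

    R_p = q(1 - alpha_p, p, df_error) * sqrt(MSE / n)

where alpha_p = 1 - (1 - alpha)^(p-1) is Duncan's protection level, so
the critical value is the studentized-range quantile at cumulative
probability (1 - alpha)^(p-1).  Critical values are computed from
``scipy.stats.studentized_range`` rather than digitized tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import table1

STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class AnovaDuncanResult:
    f_statistic: float
    p_value: float
    means: dict          # group -> mean
    letters: dict        # group -> letter string, 'a' = highest mean
    alpha: float
    mse: float
    df_error: int


@dataclass
class ContrastResult:
    coefficients: dict
    estimate: float
    t_statistic: float
    p_value: float
    df: int


@dataclass
class VPAResult:
    fractions: dict      # frozenset of group names -> unique/shared fraction
    unique: dict         # group name -> unique adjusted R^2
    residual: float
    adjusted_r2_full: float


def duncan_critical_range(alpha: float, p: int, df: int, mse: float,
                          n: float) -> float:
    """Least significant range for p ordered means."""
    q = stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df)
    return q * np.sqrt(mse / n)


def _letters_from_nonsig(means_sorted: list, nonsig: set) -> dict:
    """Letter display via the standard insert-and-absorb sweep.

    ``nonsig`` holds unordered pairs of group names that are NOT
    significantly different.  Groups sharing a letter form a maximal run
    of mutually non-distinguishable adjacent means.
    """
    names = [g for g, _ in means_sorted]
    k = len(names)
    # maximal intervals [i, j] of adjacent means that are pairwise non-sig
    intervals = []
    i = 0
    for i in range(k):
        j = i
        while j + 1 < k and all(
                frozenset((names[a], names[b])) in nonsig
                for a in range(i, j + 2) for b in range(a + 1, j + 2)):
            j += 1
        intervals.append((i, j))
    # drop intervals contained in an earlier one
    kept = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] for o in kept):
            kept.append(iv)
    letters = {g: "" for g in names}
    for letter, (i, j) in zip("abcdefghijklmnopqrstuvwxyz", kept):
        for idx in range(i, j + 1):
            letters[names[idx]] += letter
    return letters


def anova_duncan(values, groups, alpha: float = 0.05) -> AnovaDuncanResult:
    """One-way ANOVA followed by Duncan's multiple range test.

    Letters are assigned over means sorted descending, 'a' marking the
    highest-mean run.  When every group has zero within-group variance
    the letters fall back to exact equality of means.
    """
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "g": np.asarray(groups)})
    counts = df.groupby("g")["y"].count()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    means = df.groupby("g")["y"].mean()
    groups_u = list(means.index)
    n_total = len(df)
    g = len(groups_u)
    df_err = n_total - g
    ss_within = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    mse = ss_within / df_err
    grand = df["y"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    if mse == 0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p_val = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / (g - 1)) / mse
        p_val = float(stats.f.sf(f_stat, g - 1, df_err))
    means_sorted = sorted(means.items(), key=lambda kv: -kv[1])
    nonsig: set = set()
    if mse == 0:
        for (ga, ma), (gb, mb) in itertools.combinations(means_sorted, 2):
            if ma == mb:
                nonsig.add(frozenset((ga, gb)))
    else:
        n_h = stats.hmean(counts.to_numpy())
        names = [x[0] for x in means_sorted]
        vals = [x[1] for x in means_sorted]
        for i, j in itertools.combinations(range(g), 2):
            p_span = j - i + 1
            r_p = duncan_critical_range(alpha, p_span, df_err, mse, n_h)
            if vals[i] - vals[j] <= r_p:
                nonsig.add(frozenset((names[i], names[j])))
        # Duncan convention: two means are declared non-significant if any
        # enclosing range is non-significant (protects against letter gaps)
        changed = True
        while changed:
            changed = False
            for i, j in itertools.combinations(range(g), 2):
                if frozenset((names[i], names[j])) in nonsig:
                    for a in range(i, j + 1):
                        for b in range(a + 1, j + 1):
                            pair = frozenset((names[a], names[b]))
                            if pair not in nonsig:
                                nonsig.add(pair)
                                changed = True
    letters = _letters_from_nonsig(means_sorted, nonsig)
    return AnovaDuncanResult(f_statistic=float(f_stat), p_value=p_val,
                             means=dict(means), letters=letters,
                             alpha=alpha, mse=mse, df_error=df_err)


def orthogonal_contrast(values, groups, coefficients: dict) -> ContrastResult:
    """Single-df contrast among group means using the ANOVA pooled MSE.

    ``coefficients`` maps group -> contrast weight and must sum to zero
    (e.g. control +3, each organic treatment -1).
    """
    coefs = dict(coefficients)
    if abs(sum(coefs.values())) > 1e-9:
        raise ValueError("contrast coefficients must sum to 0")
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "g": np.asarray(groups)})
    missing = set(coefs) - set(df["g"].unique())
    if missing:
        raise ValueError(f"groups not in data: {sorted(missing)}")
    means = df.groupby("g")["y"].mean()
    counts = df.groupby("g")["y"].count()
    g = df["g"].nunique()
    df_err = len(df) - g
    mse = float(((df["y"] - df["g"].map(means)) ** 2).sum()) / df_err
    est = float(sum(c * means[grp] for grp, c in coefs.items()))
    se = np.sqrt(mse * sum(c ** 2 / counts[grp]
                           for grp, c in coefs.items()))
    if se == 0:
        t = np.inf if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    else:
        t = est / se
        p = float(2 * stats.t.sf(abs(t), df_err))
    return ContrastResult(coefficients=coefs, estimate=est,
                          t_statistic=float(t), p_value=p, df=df_err)


def significance_stars(p: float) -> str:
    return "".join("*" for lvl in STAR_LEVELS if p < lvl)


def spearman_matrix(block_a: pd.DataFrame, block_b: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Spearman rho between every variable of two blocks (variables x
    samples), BH-adjusted across the whole grid.

    Returns a long frame with columns var_a, var_b, rho, p_raw, p_adj,
    stars.  Constant variables yield NaN rho and are flagged by empty
    stars.
    """
    if list(block_a.columns) != list(block_b.columns):
        raise ValueError("blocks must share the same samples")
    if block_a.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    rows = []
    for va in block_a.index:
        for vb in block_b.index:
            x = block_a.loc[va].to_numpy(float)
            y = block_b.loc[vb].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"var_a": va, "var_b": vb, "rho": np.nan,
                             "p_raw": np.nan})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"var_a": va, "var_b": vb, "rho": float(rho),
                         "p_raw": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        _, padj, _, _ = multipletests(out.loc[ok, "p_raw"], alpha=alpha,
                                      method="fdr_bh")
        out.loc[ok, "p_adj"] = padj
    out["stars"] = out["p_adj"].map(
        lambda p: "" if pd.isna(p) else significance_stars(p))
    return out


# --- variance partitioning -------------------------------------------------

def hellinger(matrix) -> np.ndarray:
    """Hellinger transform of a samples x features abundance matrix:
    square root of row-wise proportions."""
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    sums = x.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("zero-sum sample row")
    return np.sqrt(x / sums)


def _rda_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Redundancy-analysis R^2: share of total variance of centered Y
    captured by the fitted values of a multivariate regression on X."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        raise ValueError("collinear predictors within a group")
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    yhat = xc @ beta
    tot = (yc ** 2).sum()
    if tot == 0:
        raise ValueError("response has zero variance")
    return float((yhat ** 2).sum() / tot)


def _adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment."""
    if n - m - 1 <= 0:
        raise ValueError("too few samples for the predictor count")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def variance_partition(response, predictor_groups: dict,
                       hellinger_transform: bool = True,
                       adjust: bool = True) -> VPAResult:
    """Partition community variance among named predictor groups.

    ``response`` is samples x features (abundances; Hellinger-transformed
    by default).  ``predictor_groups`` maps name -> samples x p array.
    R^2 (Ezekiel-adjusted unless ``adjust=False``) is computed for every
    non-empty subset of groups and the unique/shared fractions follow by
    inclusion-exclusion.  Small negative fractions are reported as-is:
    the Ezekiel adjustment makes shared fractions slightly negative even
    for orthogonal predictor groups, so exact zeroes appear only with
    ``adjust=False``.
    """
    names = list(predictor_groups)
    if len(names) < 2:
        raise ValueError("need >= 2 predictor groups")
    y = hellinger(response) if hellinger_transform \
        else np.asarray(response, float)
    n = y.shape[0]
    mats = {k: np.asarray(v, float) for k, v in predictor_groups.items()}
    total_p = sum(m.shape[1] for m in mats.values())
    if n < total_p + 2:
        raise ValueError("need samples >= total predictors + 2")
    subset_r2: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            x = np.hstack([mats[k] for k in combo])
            r2 = _rda_r2(y, x)
            subset_r2[frozenset(combo)] = (
                _adjusted_r2(r2, n, x.shape[1]) if adjust else r2)
    full = frozenset(names)
    # Venn decomposition: the atomic fraction a(T) attributable jointly
    # and exclusively to the groups in T satisfies
    #   sum_{nonempty U subset of S} a-atoms inside S = R2(F) - R2(F \ S)
    # and Moebius inversion gives
    #   a(T) = sum_{U subset T} (-1)^(|T|-|U|) [R2(F) - R2(F \ U)].
    atomic: dict[frozenset, float] = {}
    for t in (s for s in subset_r2 if s):
        val = 0.0
        for r in range(len(t) + 1):
            for sub in itertools.combinations(sorted(t), r):
                u = frozenset(sub)
                sign = (-1) ** (len(t) - len(u))
                val += sign * (subset_r2[full] - subset_r2[full - u])
        atomic[t] = val
    unique = {g: atomic[frozenset([g])] for g in names}
    residual = 1.0 - subset_r2[full]
    return VPAResult(fractions=atomic, unique=unique, residual=residual,
                     adjusted_r2_full=subset_r2[full])


def fold_change_report(summary: pd.DataFrame,
                       control: str = "NPK") -> dict:
    """Group-mean ratio report against the control treatment.

    ``summary`` is long format (variable, year, treatment, mean).  For
    every variable the report gives per-(treatment, year) organic/control
    ratios, the control-minus-organic difference for pH, and min-max
    ranges across treatments and years, rounded half-up to 2 decimals.
    """
    req = {"variable", "year", "treatment", "mean"}
    if not req.issubset(summary.columns):
        raise ValueError(f"summary needs columns {sorted(req)}")
    report: dict = {}
    for var, sub in summary.groupby("variable"):
        ratios = {}
        diffs = {}
        for year, ysub in sub.groupby("year"):
            ysub = ysub.set_index("treatment")["mean"]
            if control not in ysub.index:
                raise ValueError(f"no {control} mean for {var} in {year}")
            ref = ysub[control]
            for trt, m in ysub.items():
                if trt == control:
                    continue
                ratios[(trt, int(year))] = _round2(m / ref)
                diffs[(trt, int(year))] = _round2(ref - m)
        entry = {"ratios": ratios,
                 "ratio_min": min(ratios.values()),
                 "ratio_max": max(ratios.values())}
        if var == "pH":
            entry["differences"] = diffs
            entry["difference_min"] = min(diffs.values())
            entry["difference_max"] = max(diffs.values())
        report[var] = entry
    return report


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (printed-table style)."""
    return float(np.floor(abs(x) * 100 + 0.5) / 100 * np.sign(x))
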