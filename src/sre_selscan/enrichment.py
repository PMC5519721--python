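"""Stratified enrichment statistics for SRE vs non-SRE SNP sets.

Covers F_ST binning with odds ratios (probability-ratio form, equal to
ad/bc), conditional odds ratios within feature strata, the
Cochran–Mantel–Haenszel common odds ratio over background-selection strata,
empirical p-values from feature-matched random SNP sets, and the
rank/distribution comparisons (Mann–Whitney U, Kolmogorov–Smirnov) used
throughout the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from .types import ConfigurationError, HaplotypePanel

logger = logging.getLogger(__name__)

EXTREME_HIGH_FST = 0.70
EXTREME_LOW_FST = 0.05
LD_BIN_EDGES = (0.0, 50.0, 85.0, 110.0, 140.0, np.inf)


# ---------------------------------------------------------------------------
# LD extent

def ld_extent(panel: HaplotypePanel, site: int, window_bp: int = 200_000) -> float:
    """L = sum of squared haplotype correlations r^2 between the focal SNP
    and every other biallelic SNP within +/- window_bp.  NaN for a
    monomorphic focal SNP; monomorphic neighbours contribute nothing."""
    H = panel.haplotypes
    pos = panel.positions
    x = H[:, site].astype(float)
    sx = x.std()
    if sx == 0:
        return np.nan
    lo = int(np.searchsorted(pos, pos[site] - window_bp, side="left"))
    hi = int(np.searchsorted(pos, pos[site] + window_bp, side="right"))
    block = H[:, lo:hi].astype(float)
    xm = x - x.mean()
    bm = block - block.mean(axis=0)
    ss = (bm**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (bm.T @ xm) / np.sqrt((xm**2).sum() * ss)
    r2 = np.where(ss > 0, r**2, 0.0)
    r2[site - lo] = 0.0  # exclude the focal SNP itself
    return float(r2.sum())


def ld_extent_all(panel: HaplotypePanel, window_bp: int = 200_000) -> np.ndarray:
    return np.array([ld_extent(panel, j, window_bp) for j in range(panel.n_sites)])


# ---------------------------------------------------------------------------
# Odds ratios

@dataclass
class OddsRatio:
    table: tuple[int, int, int, int]  # a, b, c, d
    oddsratio: float
    pvalue: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to a zero cell


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> OddsRatio:
    """OR = (a d)/(b c) with a two-sided Fisher exact p-value; a 0.5
    continuity correction is applied (and flagged) when any cell is zero."""
    if a + b == 0 or c + d == 0:
        raise ConfigurationError("empty set or complement in 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    return OddsRatio((a, b, c, d), (a_ * d_) / (b_ * c_), float(p), corrected)


def fst_bin_table(
    fst: np.ndarray, in_set: np.ndarray, bin_width: float = 0.1
) -> pd.DataFrame:
    """Counts of S and S^c per F_ST bin (width 0.1 over [0,1], last bin
    closed) plus rows for the extreme flags F_ST > 0.70 and F_ST < 0.05.
    Negative estimates are clipped to the [0, 0.1) bin."""
    fst = np.asarray(fst, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    ok = np.isfinite(fst)
    f = np.clip(fst[ok], 0.0, 1.0)
    s = in_set[ok]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    idx = np.minimum(np.floor(f / bin_width).astype(int), len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        rows.append(
            {
                "bin": f"[{edges[b]:.1f},{edges[b+1]:.1f})" if b < len(edges) - 2 else f"[{edges[b]:.1f},1.0]",
                "lo": edges[b],
                "hi": edges[b + 1],
                "n_set": int(np.sum(s & (idx == b))),
                "n_comp": int(np.sum(~s & (idx == b))),
            }
        )
    for name, mask in (
        (f"fst>{EXTREME_HIGH_FST}", f > EXTREME_HIGH_FST),
        (f"fst<{EXTREME_LOW_FST}", f < EXTREME_LOW_FST),
    ):
        rows.append(
            {"bin": name, "lo": np.nan, "hi": np.nan,
             "n_set": int(np.sum(s & mask)), "n_comp": int(np.sum(~s & mask))}
        )
    return pd.DataFrame(rows)


def odds_ratio(bin_table: pd.DataFrame, bin_label: str) -> OddsRatio:
    """Odds ratio of membership in the named F_ST bin for S vs S^c."""
    row = bin_table.loc[bin_table["bin"] == bin_label]
    if row.empty:
        raise KeyError(f"no bin {bin_label!r}")
    a = int(row["n_set"].iloc[0])
    c = int(row["n_comp"].iloc[0])
    # the width-0.1 bins partition the universe, so totals come from them
    b = int(bin_table.loc[~bin_table["lo"].isna(), "n_set"].sum()) - a
    d = int(bin_table.loc[~bin_table["lo"].isna(), "n_comp"].sum()) - c
    return odds_ratio_2x2(a, b, c, d)


def conditional_odds_ratio(
    fst: np.ndarray,
    in_set: np.ndarray,
    bin_label: str,
    stratum_mask: np.ndarray,
    bin_width: float = 0.1,
) -> OddsRatio:
    """OR(F; S, Delta): the F_ST-bin odds ratio within a feature stratum."""
    stratum_mask = np.asarray(stratum_mask, dtype=bool)
    if stratum_mask.sum() == 0 or in_set[stratum_mask].all() or not in_set[stratum_mask].any():
        raise ConfigurationError("degenerate stratum for conditional odds ratio")
    table = fst_bin_table(fst[stratum_mask], in_set[stratum_mask], bin_width)
    return odds_ratio(table, bin_label)


# ---------------------------------------------------------------------------
# Cochran-Mantel-Haenszel

@dataclass
class CMHResult:
    common_or: float
    pvalue: float
    crude_or: float
    n_strata_used: int
    n_strata_dropped: int


def cmh_common_or(strata: list[tuple[int, int, int, int]]) -> CMHResult:
    """Mantel–Haenszel common odds ratio over 2x2 strata (a, b, c, d) with
    the CMH chi-square p-value (continuity-corrected).  Strata with an empty
    margin are dropped with a log entry; the crude (pooled) odds ratio is
    reported alongside so confounding inflation is visible."""
    usable = []
    dropped = 0
    for (a, b, c, d) in strata:
        if min(a + b, c + d, a + c, b + d) == 0:
            dropped += 1
            continue
        usable.append((a, b, c, d))
    if dropped:
        logger.info("cmh_common_or: dropped %d degenerate strata", dropped)
    if not usable:
        raise ConfigurationError("all strata degenerate")
    arr = np.array(usable, dtype=float).T.reshape(2, 2, -1)
    st = StratifiedTable(arr)
    common = float(st.oddsratio_pooled)
    if len(usable) == 1:
        a, b, c, d = usable[0]
        p = odds_ratio_2x2(a, b, c, d).pvalue
    else:
        p = float(st.test_null_odds(correction=True).pvalue)
    A = sum(t[0] for t in usable)
    B = sum(t[1] for t in usable)
    C = sum(t[2] for t in usable)
    D = sum(t[3] for t in usable)
    crude = odds_ratio_2x2(A, B, C, D).oddsratio
    return CMHResult(common, p, crude, len(usable), dropped)


# ---------------------------------------------------------------------------
# Matched-null empirical p-values

def assign_match_bins(
    features: pd.DataFrame,
    b_width: float = 100.0,
    daf_width: float = 0.05,
    ld_edges: tuple[float, ...] = LD_BIN_EDGES,
    maf_width: float = 0.05,
    n_gene_size_bins: int = 5,
    n_junction_bins: int = 4,
) -> pd.Series:
    """Per-variant matching key from binned features.

    Expected columns (used if present): ``bvalue`` (width-100 bins), ``daf``
    (width-0.05 bins), ``ld`` (the [0,50), [50,85), [85,110), [110,140),
    >=140 intervals), ``maf`` (width 0.05), ``gene_size`` (pool quintiles),
    ``junction_distance`` (pool quartiles)."""
    keys = []
    if "bvalue" in features:
        keys.append(np.floor(features["bvalue"] / b_width).astype(int))
    if "daf" in features:
        keys.append(np.floor(features["daf"] / daf_width).astype(int))
    if "ld" in features:
        keys.append(np.searchsorted(np.asarray(ld_edges[1:-1]), features["ld"], side="right"))
    if "maf" in features:
        keys.append(np.floor(features["maf"] / maf_width).astype(int))
    if "gene_size" in features:
        keys.append(pd.qcut(features["gene_size"], n_gene_size_bins, labels=False, duplicates="drop"))
    if "junction_distance" in features:
        keys.append(pd.qcut(features["junction_distance"], n_junction_bins, labels=False, duplicates="drop"))
    if not keys:
        raise ConfigurationError("no matchable feature columns present")
    return pd.Series(list(zip(*[np.asarray(k) for k in keys])), index=features.index)


def matched_null_pvalue(
    values: np.ndarray,
    is_target: np.ndarray,
    match_keys: pd.Series | np.ndarray,
    rng: np.random.Generator,
    statistic=np.sum,
    n_sets: int = 1000,
    pool_mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Empirical enrichment p-value from feature-matched random SNP sets.

    Draws ``n_sets`` random sets from the pool (default: all non-target
    SNPs) with exactly the target's per-bin composition, evaluates
    ``statistic`` (a numpy-style reduction over the set's ``values``) on
    each, and returns (p, null statistics, observed statistic) with
    p = (#{null >= observed} + 1) / (n_sets + 1).

    A bin cell with no pool candidates raises; a cell with fewer candidates
    than needed samples with replacement and logs the fact.
    """
    values = np.asarray(values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    codes, uniques = pd.factorize(pd.Series(list(match_keys)))
    pool = ~is_target if pool_mask is None else (np.asarray(pool_mask, dtype=bool) & ~is_target)
    observed = float(statistic(values[is_target]))

    target_counts: dict[int, int] = {}
    for k in codes[is_target]:
        target_counts[k] = target_counts.get(k, 0) + 1
    pieces = []
    for code, need in target_counts.items():
        k = uniques[code]
        cand = np.flatnonzero(pool & (codes == code))
        if len(cand) == 0:
            raise ConfigurationError(f"no pool candidates in matching cell {k!r}")
        if len(cand) < need:
            logger.warning(
                "matched_null_pvalue: cell %r has %d candidates for %d targets; "
                "sampling with replacement", k, len(cand), need
            )
            pick = rng.integers(0, len(cand), size=(n_sets, need))
        else:
            r = rng.random((n_sets, len(cand)))
            pick = np.argpartition(r, need - 1, axis=1)[:, :need]
        pieces.append(values[cand[pick]])
    null_matrix = np.concatenate(pieces, axis=1)
    null_stats = statistic(null_matrix, axis=1)
    p = (float(np.sum(null_stats >= observed)) + 1.0) / (n_sets + 1.0)
    return p, null_stats, observed


# ---------------------------------------------------------------------------
# Rank and distribution comparisons

def rank_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact enumeration when both n <= 12 (and
    no ties), else the tie-corrected normal approximation.  All-tied data
    yields p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("empty sample in rank comparison")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and len(np.unique(pooled)) == len(pooled)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def distribution_compare_ks(
    a: np.ndarray, b: np.ndarray | None = None
) -> tuple[float, float]:
    """Two-sample KS, or one-sample KS against Uniform(0,1) when b is None
    (for p-value enrichment against the uniform null)."""
    a = np.asarray(a, dtype=float)
    if len(a) == 0:
        raise ConfigurationError("empty sample in KS comparison")
    if b is None:
        res = stats.kstest(a, "uniform")
    else:
        res = stats.ks_2samp(a, np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)


def qq_table(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for Q-Q plotting."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.maximum(p, 1e-300)),
        }
    )
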