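"""Per-variant differentiation and haplotype selection statistics.

Implements the Weir–Cockerham (1984) two-population per-locus F_ST estimator
on haplotype counts, derived allele frequencies, extended haplotype
homozygosity (EHH) with integrated scores iHS and XP-EHH, within-bin score
standardization, a cross-population composite likelihood ratio (XP-CLR)
against a truncated-normal drift model, and a composite likelihood combining
the empirical densities of the three cross-population metrics.

Sign conventions: iHS puts the ancestral-background integral in the
numerator, so extended homozygosity on the derived background gives negative
raw iHS; XP-EHH is log(integral in P1 / integral in P2), positive when the
longer haplotypes (sweep signal) are in P1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .types import ConfigurationError, HaplotypePanel

EHH_STOP = 0.05


# ---------------------------------------------------------------------------
# F_ST

def wc_fst_components(n1, x1, n2, x2):
    """Weir–Cockerham (1984) variance components (a, b) for two populations
    from haploid allele counts; theta-hat = a / (a + b).  The within-
    individual component is zero under the haploid convention."""
    n1 = np.asarray(n1, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = x1 / n1, x2 / n2
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (x1 + x2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0)
    return a, b


def wc_fst_multilocus(n1, x1, n2, x2):
    """Combined Weir–Cockerham estimate over loci: sum(a) / sum(a + b).

    This ratio-of-sums form is the standard multi-locus estimator; averaging
    per-locus ratios is downward-biased at small sample sizes."""
    a, b = wc_fst_components(n1, x1, n2, x2)
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.sum(a[ok]) / np.sum(a[ok] + b[ok]))


def wc_fst(n1, x1, n2, x2):
    """Weir–Cockerham per-locus theta-hat for two populations from haploid
    (haplotype) allele counts: ``x_i`` copies of the allele among ``n_i``
    sampled haplotypes.  The heterozygosity component is zero under the
    haploid convention, so theta = a / (a + b).

    Accepts scalars or arrays; returns NaN where undefined (n_i < 2 or the
    locus is monomorphic across both samples).  Estimates may be negative.
    """
    n1 = np.asarray(n1, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = x1 / n1, x2 / n2
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (x1 + x2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0)
        theta = a / (a + b)
    bad = (n1 < 2) | (n2 < 2) | (pbar <= 0) | (pbar >= 1)
    theta = np.where(bad, np.nan, theta)
    return float(theta) if theta.ndim == 0 else theta


def derived_allele_freq(panel: HaplotypePanel, site: int, ancestral_is_ref: bool) -> float:
    """Frequency of the non-ancestral allele at a site (ALT coded 1)."""
    f_alt = float(panel.haplotypes[:, site].mean())
    return f_alt if ancestral_is_ref else 1.0 - f_alt


# ---------------------------------------------------------------------------
# EHH

@dataclass
class EHHCurve:
    distances: np.ndarray  # cM from the core, non-negative
    ehh: np.ndarray
    truncated: bool        # hit the chromosome end with EHH >= stop threshold

    def integral(self) -> float:
        return float(np.trapezoid(self.ehh, self.distances))


def ehh_curve(
    panel: HaplotypePanel, core_site: int, core_allele: int, direction: int,
    stop: float = EHH_STOP,
) -> EHHCurve | None:
    """EHH among carriers of ``core_allele``, walking site by site in
    ``direction`` (+1 right, -1 left) until EHH < ``stop`` or the end.

    EHH at distance d is the probability that two distinct random carrier
    haplotypes are identical at every site between the core and d.  Returns
    None when fewer than two haplotypes carry the core allele.
    """
    H = panel.haplotypes
    carriers = np.flatnonzero(H[:, core_site] == core_allele)
    n = len(carriers)
    if n < 2:
        return None
    sub = H[carriers]
    denom = n * (n - 1)
    group = np.zeros(n, dtype=np.int64)
    g0 = panel.genetic_pos[core_site]
    dists = [0.0]
    vals = [1.0]
    j = core_site
    truncated = False
    while True:
        j += direction
        if j < 0 or j >= H.shape[1]:
            truncated = vals[-1] >= stop
            break
        key = group * 2 + sub[:, j]
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        h = float((counts * (counts - 1)).sum()) / denom
        dists.append(abs(panel.genetic_pos[j] - g0))
        vals.append(h)
        if h < stop:
            break
    return EHHCurve(np.asarray(dists), np.asarray(vals), truncated)


def ehh_integral(
    panel: HaplotypePanel, core_site: int, core_allele: int, stop: float = EHH_STOP
) -> tuple[float, bool] | None:
    """Two-sided trapezoid integral of EHH over genetic distance (cM)."""
    left = ehh_curve(panel, core_site, core_allele, -1, stop)
    right = ehh_curve(panel, core_site, core_allele, +1, stop)
    if left is None or right is None:
        return None
    return left.integral() + right.integral(), left.truncated or right.truncated


def ihs(
    panel: HaplotypePanel, site: int, ancestral_is_ref: bool
) -> tuple[float, str]:
    """Unstandardized iHS: log(integral_ancestral / integral_derived).

    Returns (value, reason); NaN with a reason code when either allele has
    fewer than two carriers or an integral vanishes.
    """
    anc_allele = 0 if ancestral_is_ref else 1
    ia = ehh_integral(panel, site, anc_allele)
    idv = ehh_integral(panel, site, 1 - anc_allele)
    if ia is None or idv is None:
        return np.nan, "lt2_carriers"
    if ia[0] <= 0 or idv[0] <= 0:
        return np.nan, "zero_integral"
    return float(np.log(ia[0] / idv[0])), ""


def xp_ehh(
    panel1: HaplotypePanel, panel2: HaplotypePanel, site: int,
    allele: int = 1,
) -> tuple[float, str]:
    """Unstandardized XP-EHH: log(integral_P1 / integral_P2) for the
    designated core allele (default ALT; callers pass the derived allele
    when the ancestral state is known)."""
    i1 = ehh_integral(panel1, site, allele)
    i2 = ehh_integral(panel2, site, allele)
    if i1 is None or i2 is None:
        return np.nan, "lt2_carriers"
    if i2[0] <= 0 or i1[0] <= 0:
        return np.nan, "zero_integral"
    return float(np.log(i1[0] / i2[0])), ""


# ---------------------------------------------------------------------------
# Standardization

def standardize_scores(
    raw: np.ndarray,
    bin_variable: np.ndarray | None = None,
    bin_width: float = 0.05,
    min_per_bin: int = 20,
) -> np.ndarray:
    """Within-bin z-scores: subtract the bin mean, divide by the bin SD.

    ``bin_variable`` (e.g., derived allele frequency for iHS) is cut into
    bins of ``bin_width``; bins with fewer than ``min_per_bin`` defined
    scores are merged with their left neighbour (leftmost merges right).
    With no bin variable a single global bin is used.  NaNs propagate; a bin
    with zero variance yields NaN for its members.
    """
    raw = np.asarray(raw, dtype=float)
    out = np.full_like(raw, np.nan)
    defined = np.isfinite(raw)
    if bin_variable is None:
        idx = np.zeros(len(raw), dtype=int)
    else:
        bv = np.asarray(bin_variable, dtype=float)
        defined = defined & np.isfinite(bv)
        idx = np.floor(np.where(np.isfinite(bv), bv, 0.0) / bin_width).astype(int)
    # greedy left-to-right merge of sparse bins
    uniq = np.unique(idx[defined])
    group_of: dict[int, int] = {}
    gid = 0
    count = 0
    for u in uniq:
        group_of[u] = gid
        count += int(np.sum(defined & (idx == u)))
        if count >= min_per_bin:
            gid += 1
            count = 0
    if count and gid > 0:  # trailing sparse group folds into the previous one
        for u in uniq:
            if group_of[u] == gid:
                group_of[u] = gid - 1
    groups = np.array([group_of.get(i, -1) for i in idx])
    for g in np.unique(groups[defined]):
        sel = defined & (groups == g)
        mu = raw[sel].mean()
        sd = raw[sel].std()
        if sd > 0:
            out[sel] = (raw[sel] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# XP-CLR

@dataclass
class DriftModel:
    """Neutral drift scale for the truncated-normal allele-frequency model.

    omega = t_split / (2 Ne): variance of the P2 frequency about the shared
    ancestral frequency, in units of p0(1-p0)."""

    omega: float
    window_snps: int = 50
    grid_step: int = 10
    s_grid: tuple[float, ...] = tuple(np.arange(0.0, 0.51, 0.05))
    delta_grid_cm: tuple[float, ...] = (0.01, 0.1, 1.0)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ConfigurationError("omega must be positive")
        if self.window_snps < 1:
            raise ConfigurationError("window must contain at least one SNP")


def calibrate_omega(panel1: HaplotypePanel, panel2: HaplotypePanel) -> float:
    """Method-of-moments drift scale from putatively neutral SNPs:
    mean squared frequency difference, corrected for binomial sampling
    noise, in units of pbar(1-pbar).  Floored at 1e-6."""
    p1 = panel1.alt_freq()
    p2 = panel2.alt_freq()
    n1, n2 = panel1.n_hap, panel2.n_hap
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    poly = (pbar > 0) & (pbar < 1)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = pbar * (1 - pbar)
    omega = num[poly].mean() / den[poly].mean()
    return max(float(omega), 1e-6)


def _truncnorm_logpdf(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    sd = np.sqrt(var)
    z = (x - mu) / sd
    norm = ndtr((1.0 - mu) / sd) - ndtr((0.0 - mu) / sd)
    norm = np.maximum(norm, 1e-300)
    return -0.5 * z**2 - 0.5 * np.log(2 * np.pi * var) - np.log(norm)


def xpclr_windows(
    panel1: HaplotypePanel, panel2: HaplotypePanel, drift: DriftModel
) -> pd.DataFrame:
    """Composite likelihood ratio per sliding window of k contiguous SNPs.

    Null: the P2 frequency at each SNP is truncated-normal about the P1
    sample frequency.  The variance is evaluated at the pooled sample
    frequency, (omega + 1/n1 + 1/n2) * pbar(1-pbar): pooling keeps the
    scale finite when P1 is near fixation (p0(1-p0) would degenerate and
    produce runaway scores at neutral sites), and the 1/n terms carry the
    binomial sampling noise of both sample frequencies.

    Alternative (hitchhiking approximation): with sweep strength
    s = s_g * exp(-d/delta) at distance d from the window centre, a linked
    neutral allele rides the sweeping haplotype with probability p0 and is
    pushed toward 1, otherwise toward 0, giving the per-SNP mixture
    p0 * f(p2; p0 + s(1-p0)) + (1-p0) * f(p2; p0(1-s)).  The (s_g, delta)
    grid contains the null (s_g = 0), so CLR = 2 log(max alt / null) >= 0.
    Monomorphic windows score 0.
    """
    n1, n2 = panel1.n_hap, panel2.n_hap
    f1, f2 = panel1.alt_freq(), panel2.alt_freq()
    p0 = np.clip(f1, 1.0 / (2 * n1), 1 - 1.0 / (2 * n1))
    p2 = np.clip(f2, 1.0 / (2 * n2), 1 - 1.0 / (2 * n2))
    pbar = np.clip((f1 * n1 + f2 * n2) / (n1 + n2), 1.0 / (n1 + n2), 1 - 1.0 / (n1 + n2))
    gpos = panel1.genetic_pos
    m = len(p0)
    k = min(drift.window_snps, m)
    var = (drift.omega + 1.0 / n1 + 1.0 / n2) * pbar * (1 - pbar)
    null_ll = _truncnorm_logpdf(p2, p0, var)
    rows = []
    for start in range(0, max(m - k + 1, 1), drift.grid_step):
        sl = slice(start, start + k)
        center = start + k // 2
        d = np.abs(gpos[sl] - gpos[center])
        ll0 = null_ll[sl].sum()
        best = ll0
        P0, P2w, Vw = p0[sl], p2[sl], var[sl]
        log_w_up, log_w_dn = np.log(P0), np.log(1 - P0)
        for delta in drift.delta_grid_cm:
            decay = np.exp(-d / delta)
            for s in drift.s_grid:
                if s == 0.0:
                    continue
                shift = s * decay
                up = _truncnorm_logpdf(P2w, P0 + shift * (1 - P0), Vw)
                dn = _truncnorm_logpdf(P2w, P0 * (1 - shift), Vw)
                ll = float(np.logaddexp(log_w_up + up, log_w_dn + dn).sum())
                if ll > best:
                    best = ll
        rows.append(
            {
                "start_idx": start,
                "end_idx": start + k,
                "center_idx": center,
                "clr": 2.0 * (best - ll0),
            }
        )
    return pd.DataFrame(rows)


def xpclr_per_variant(windows: pd.DataFrame, n_variants: int) -> np.ndarray:
    """Per-variant XP-CLR: max over the windows covering the variant."""
    out = np.full(n_variants, np.nan)
    for start, end, clr in zip(windows["start_idx"], windows["end_idx"], windows["clr"]):
        sl = slice(int(start), int(end))
        cur = out[sl]
        out[sl] = np.where(np.isnan(cur) | (clr > cur), clr, cur)
    return out


# ---------------------------------------------------------------------------
# Composite likelihood (empirical-density product)

def _hist_density(values: np.ndarray, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    v = values[np.isfinite(values)]
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    counts = counts.astype(float) + 1.0  # add-one smoothing
    width = edges[1] - edges[0]
    dens = counts / (counts.sum() * width)
    return edges, dens


def _density_lookup(edges: np.ndarray, dens: np.ndarray, x: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(dens) - 1)
    out = dens[idx]
    out[~np.isfinite(x)] = np.nan
    return out


def composite_likelihood(
    fst: np.ndarray,
    xpehh: np.ndarray,
    xpclr: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    n_bins: int = 50,
) -> np.ndarray:
    """log L(x) = alpha log f_FST + beta log f_XPEHH + gamma log f_XPCLR,
    with each density estimated from the panel-wide empirical distribution
    (histogram, ``n_bins`` bins, add-one smoothing).  Undefined components
    make the composite undefined for that variant."""
    logl = np.zeros(len(fst), dtype=float)
    for vals, w in ((fst, alpha), (xpehh, beta), (xpclr, gamma)):
        vals = np.asarray(vals, dtype=float)
        if w == 0.0:
            continue
        edges, dens = _hist_density(vals, n_bins)
        f = _density_lookup(edges, dens, vals)
        logl = logl + w * np.log(f)
    return logl


# ---------------------------------------------------------------------------
# Panel-wide scan

def scan_panels(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    ancestral_is_ref: np.ndarray | None = None,
    drift: DriftModel | None = None,
    ihs_panel: str = "P1",
    daf_bin_width: float = 0.05,
) -> pd.DataFrame:
    """Full per-variant score table for a pair of panels.

    ``ancestral_is_ref`` is a boolean array (True: REF is ancestral) with
    missing ancestral states as NaN/None handled by masking; variants with
    unknown ancestral state are excluded from iHS and DAF columns but keep
    F_ST, XP-EHH (ALT-anchored) and XP-CLR.
    """
    m = panel1.n_sites
    x1, x2 = panel1.alt_count(), panel2.alt_count()
    n1 = np.full(m, panel1.n_hap)
    n2 = np.full(m, panel2.n_hap)
    fst = wc_fst(n1, x1, n2, x2)

    anc_known = (
        np.zeros(m, dtype=bool)
        if ancestral_is_ref is None
        else np.isfinite(np.asarray(ancestral_is_ref, dtype=float))
    )
    anc_ref = np.asarray(ancestral_is_ref, dtype=float) if ancestral_is_ref is not None else np.zeros(m)

    daf1 = np.where(anc_known, np.where(anc_ref == 1, x1 / panel1.n_hap, 1 - x1 / panel1.n_hap), np.nan)
    daf2 = np.where(anc_known, np.where(anc_ref == 1, x2 / panel2.n_hap, 1 - x2 / panel2.n_hap), np.nan)

    focal = panel1 if ihs_panel == "P1" else panel2
    ihs_raw = np.full(m, np.nan)
    reasons = np.full(m, "", dtype=object)
    for j in range(m):
        if not anc_known[j]:
            reasons[j] = "ancestral_unknown"
            continue
        val, why = ihs(focal, j, bool(anc_ref[j] == 1))
        ihs_raw[j] = val
        if why:
            reasons[j] = why

    xpehh_raw = np.full(m, np.nan)
    for j in range(m):
        allele = 1
        if anc_known[j]:
            allele = 1 if anc_ref[j] == 1 else 0  # derived allele
        val, why = xp_ehh(panel1, panel2, j, allele)
        xpehh_raw[j] = val
        if why and not reasons[j]:
            reasons[j] = why

    daf_focal = daf1 if ihs_panel == "P1" else daf2
    ihs_std = standardize_scores(ihs_raw, daf_focal, bin_width=daf_bin_width)
    xpehh_std = standardize_scores(xpehh_raw)  # single global bin

    if drift is None:
        drift = DriftModel(omega=calibrate_omega(panel1, panel2))
    wins = xpclr_windows(panel1, panel2, drift)
    xpclr = xpclr_per_variant(wins, m)

    log_comp = composite_likelihood(fst, xpehh_raw, xpclr)
    return pd.DataFrame(
        {
            "pos": panel1.positions,
            "fst": fst,
            "daf_P1": daf1,
            "daf_P2": daf2,
            "ihs_raw": ihs_raw,
            "ihs_std": ihs_std,
            "xpehh_raw": xpehh_raw,
            "xpehh_std": xpehh_std,
            "xpclr": xpclr,
            "log_composite": log_comp,
            "reason": reasons,
        }
    )
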