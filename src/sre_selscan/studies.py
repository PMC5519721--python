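"""End-to-end study drivers over the synthetic generator.

Each function runs one self-contained study at explicitly stated problem
sizes and returns plain numbers, so the numbered analysis scripts, the test
suite and the acceptance script all exercise exactly the same code paths.
All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from . import annotate, enrichment, models, selection, simulate


# ---------------------------------------------------------------------------
# Estimator / brute-force agreement

def _wc_fst_bruteforce(n1, x1, n2, x2):
    """Textbook transcription of the Weir-Cockerham (1984) two-population
    estimator on haploid counts (independent of the vectorised path)."""
    p1, p2 = x1 / n1, x2 / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a / (a + b)


def _ehh_bruteforce_integral(H, gpos, core, allele):
    """Pairwise-comparison EHH in both directions + trapezoid integral."""
    carriers = np.flatnonzero(H[:, core] == allele)
    n = len(carriers)
    total = 0.0
    for direction in (+1, -1):
        js, vals = [core], [1.0]
        j = core
        while True:
            j += direction
            if j < 0 or j >= H.shape[1]:
                break
            lo, hi = sorted((core, j))
            same = sum(
                1
                for a, b in itertools.combinations(carriers, 2)
                if np.array_equal(H[a, lo : hi + 1], H[b, lo : hi + 1])
            )
            vals.append(2 * same / (n * (n - 1)))
            js.append(j)
            if vals[-1] < 0.05:
                break
        d = np.abs(gpos[js] - gpos[core])
        total += float(np.trapezoid(vals, d))
    return total


def oracle_equivalence_study(seed: int, n_instances: int = 50) -> dict[str, float]:
    """Maximum absolute disagreement between each core estimator and an
    independent brute-force implementation over random small instances."""
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}

    diffs = []
    while len(diffs) < n_instances:
        n1, n2 = rng.integers(4, 200, size=2)
        x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        if x1 + x2 in (0, n1 + n2):
            continue
        diffs.append(
            abs(selection.wc_fst(n1, x1, n2, x2) - _wc_fst_bruteforce(n1, x1, n2, x2))
        )
    out["fst"] = float(max(diffs))

    diffs = []
    for _ in range(n_instances):
        H = (rng.random((8, 24)) < 0.5).astype(np.int8)
        gpos = np.arange(24) * 5e-5
        panel = selection.HaplotypePanel("P", H, np.arange(1, 25) * 50, gpos)
        core = 12
        allele = int(H[0, core])
        got = selection.ehh_integral(panel, core, allele)
        want = _ehh_bruteforce_integral(H, gpos, core, allele)
        diffs.append(abs(got[0] - want))
    out["ehh_integral"] = float(max(diffs))

    diffs = []
    while len(diffs) < n_instances:
        panels, _, _ = simulate.simulate_panels(40, 0.2, 24, rng)
        P = panels["P1"]
        j = int(rng.integers(0, 40))
        Hf = P.haplotypes.astype(float)
        if Hf[:, j].std() == 0:
            continue
        acc = 0.0
        for k in range(40):
            if k == j or abs(int(P.positions[k]) - int(P.positions[j])) > 10_000:
                continue
            if Hf[:, k].std() == 0:
                continue
            acc += float(np.corrcoef(Hf[:, j], Hf[:, k])[0, 1] ** 2)
        diffs.append(abs(enrichment.ld_extent(P, j, 10_000) - acc))
    out["ld_r2"] = float(max(diffs))

    diffs = []
    for _ in range(n_instances):
        G = rng.integers(0, 3, size=(12, 30)).astype(float)
        A, _ = models.compute_grm(G)
        p = G.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        Gk, pk = G[:, keep], p[keep]
        Z = (Gk - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
        oracle = np.zeros((12, 12))
        for i in range(12):
            for j in range(12):
                oracle[i, j] = float(np.dot(Z[i], Z[j])) / Gk.shape[1]
        diffs.append(float(np.max(np.abs(A - oracle))))
    out["grm"] = float(max(diffs))

    diffs = []
    for _ in range(n_instances):
        a = rng.random(4)
        b = rng.random(4)
        _, p = enrichment.rank_compare(a, b)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n1 = len(a)

        def ustat(idx):
            u1 = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            return min(u1, len(a) * len(b) - u1)

        obs = ustat(range(n1))
        hits = sum(
            1
            for idx in itertools.combinations(range(len(pooled)), n1)
            if ustat(idx) <= obs
        )
        total = sum(1 for _ in itertools.combinations(range(len(pooled)), n1))
        diffs.append(abs(p - hits / total))
    out["mannwhitney_exact_p"] = float(max(diffs))
    return out


# ---------------------------------------------------------------------------
# F_ST recovery

def fst_recovery_study(
    seed: int,
    cs: tuple[float, ...] = (0.05, 0.15, 0.30),
    n_snps: int = 20_000,
    n_hap: int = 100,
) -> dict[float, float]:
    """Multi-locus Weir-Cockerham estimate on Balding-Nichols panels of
    ``n_hap`` haplotypes (50 diploids) per population, one per divergence c."""
    rng = np.random.default_rng(seed)
    out = {}
    n = np.full(n_snps, n_hap)
    for c in cs:
        panels, _, _ = simulate.simulate_panels(n_snps, c, n_hap, rng)
        out[c] = selection.wc_fst_multilocus(
            n, panels["P1"].alt_count(), n, panels["P2"].alt_count()
        )
    return out


# ---------------------------------------------------------------------------
# Sweep detection

def sweep_detection_study(
    seed: int,
    n_seeds: int = 20,
    n_snps: int = 1500,
    n_hap: int = 100,
    c: float = 0.05,
    carrier_fraction: float = 0.8,
    window_sites: int = 100,
) -> dict[str, float]:
    """Detection rates for planted sweeps across replicate panels.

    Per replicate: two neutral panels diverged at ``c``; a sweep on the
    majority core allele in P1 (carrier fraction 0.8 over +/-100 sites).
    XP-EHH success: panel-standardized score at the core exceeds 2.
    XP-CLR success: the core's score lands in the top 1% of the CLR
    distribution from the pre-sweep (null) panels.
    """
    hits_xpehh = hits_xpclr = 0
    core = n_snps // 2
    for rep in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * (rep + 1))
        panels, _, _ = simulate.simulate_panels(n_snps, c, n_hap, rng)
        P1, P2 = panels["P1"], panels["P2"]
        allele = 1 if P1.alt_count()[core] >= n_hap // 2 else 0
        P1s = simulate.plant_sweep(P1, core, allele, carrier_fraction, rng, window_sites)

        xpe = np.full(n_snps, np.nan)
        for j in range(n_snps):
            xpe[j], _ = selection.xp_ehh(P1s, P2, j, allele)
        z = selection.standardize_scores(xpe)
        if np.isfinite(z[core]) and z[core] > 2:
            hits_xpehh += 1

        om = selection.calibrate_omega(P1, P2)
        drift = selection.DriftModel(omega=om, grid_step=5)
        null_clr = selection.xpclr_windows(P1, P2, drift)["clr"].to_numpy()
        swept = selection.xpclr_per_variant(
            selection.xpclr_windows(P1s, P2, drift), n_snps
        )
        if swept[core] >= np.quantile(null_clr, 0.99):
            hits_xpclr += 1
    return {
        "xpehh_rate": hits_xpehh / n_seeds,
        "xpclr_rate": hits_xpclr / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Standardization contract

def standardization_study(seed: int, n: int = 5000) -> dict[str, float]:
    """Per-bin first and second moments of standardized scores."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(n) * 2.5 - 0.4
    daf = rng.random(n)
    z_binned = selection.standardize_scores(raw, daf, bin_width=0.05)
    z_global = selection.standardize_scores(rng.standard_normal(n) * 1.7)
    worst_mean, worst_var = 0.0, 0.0
    idx = np.floor(daf / 0.05).astype(int)
    for b in np.unique(idx):
        sel = (idx == b) & np.isfinite(z_binned)
        if sel.sum() >= 20:
            worst_mean = max(worst_mean, abs(float(z_binned[sel].mean())))
            worst_var = max(worst_var, abs(float(z_binned[sel].var()) - 1.0))
    worst_mean = max(worst_mean, abs(float(z_global.mean())))
    worst_var = max(worst_var, abs(float(z_global.var()) - 1.0))
    return {"max_abs_bin_mean": worst_mean, "max_abs_bin_var_dev": worst_var}


# ---------------------------------------------------------------------------
# CMH de-confounding

def cmh_confounding_study(seed: int, stratum_or: float = 1.2) -> dict[str, float]:
    """Crude vs Mantel-Haenszel common OR on a B-value-confounded fixture."""
    rng = np.random.default_rng(seed)
    tables = simulate.confounded_strata(rng, stratum_or=stratum_or)
    res = enrichment.cmh_common_or(tables)
    return {
        "common_or": res.common_or,
        "crude_or": res.crude_or,
        "pvalue": res.pvalue,
        "generating_or": stratum_or,
    }


# ---------------------------------------------------------------------------
# Matched-null calibration

def matched_null_calibration_study(
    seed: int, n_replicates: int = 200, n_sets: int = 200, n_pool: int = 3000
) -> dict[str, float]:
    """KS uniformity of the empirical p-value when the target set is itself
    a random draw from the matched pool."""
    pvals = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 7919 * (rep + 1))
        values = rng.random(n_pool)
        keys = rng.integers(0, 20, size=n_pool)
        is_target = np.zeros(n_pool, bool)
        is_target[rng.choice(n_pool, 100, replace=False)] = True
        p, _, _ = enrichment.matched_null_pvalue(
            values, is_target, keys, rng, np.sum, n_sets=n_sets
        )
        pvals.append(p)
    ks_stat, ks_p = stats.kstest(pvals, "uniform")
    return {"ks_stat": float(ks_stat), "ks_p": float(ks_p)}


# ---------------------------------------------------------------------------
# Model parameter recovery

def logistic_recovery_study(
    seed: int, n: int = 50_000, beta_fst: float = 0.5
) -> dict[str, float]:
    """Recovery of the F_ST coefficient in the logistic overlap model."""
    rng = np.random.default_rng(seed)
    beta = np.array([0.3, beta_fst, -0.4, 0.2])
    D, y = simulate.simulate_logistic_overlap(n, -2.0, beta, rng)
    fit = models.fit_sre_logistic(y, D, ["daf", "fst", "bvalue", "ld"])
    return {
        "beta_fst_hat": float(fit.coef[1]),
        "beta_fst_se": float(fit.se[1]),
        "beta_fst_true": beta_fst,
        "within_2se": float(abs(fit.coef[1] - beta_fst) <= 2 * fit.se[1]),
    }


def reml_recovery_study(
    seed: int,
    n_seeds: int = 50,
    n: int = 2000,
    m_sre: int = 2500,
    m_non: int = 2500,
    h2_sre: float = 0.3,
) -> dict[str, float]:
    """Coverage of the true SRE heritability by +/- 2 SE intervals across
    replicate GREML fits (trait: 0.3 / 0.2 / 0.5 variance split)."""
    covered = 0
    ests = []
    for rep in range(n_seeds):
        rng = np.random.default_rng(seed + 104729 * (rep + 1))
        Gs, Gn, y = simulate.simulate_two_vc_trait(n, m_sre, m_non, h2_sre, 0.2, 0.5, rng)
        A1, _ = models.compute_grm(Gs)
        A2, _ = models.compute_grm(Gn)
        vc = models.reml_two_vc(y, A1, A2)
        ests.append(vc.h2_sre)
        if vc.converged and abs(vc.h2_sre - h2_sre) <= 2 * vc.h2_se:
            covered += 1
    return {
        "cover_rate": covered / n_seeds,
        "mean_h2": float(np.mean(ests)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Annotation truth

def annotation_truth_study(seed: int, n_seeds: int = 10) -> dict[str, float]:
    """Sensitivity/specificity of the SRE annotation against planted truth
    over independent fixture seeds (worst seed reported)."""
    sens, spec = [], []
    for rep in range(n_seeds):
        fix = simulate.simulate_fixture(simulate.SimulationConfig(seed=seed + 31 * rep))
        ann = annotate.annotate_all(fix.variants, fix.genes, fix.motifs, {"1": fix.sequence})
        m = fix.truth_frame().merge(ann, on="vid", suffixes=("_t", "_a"))
        truth = m["is_sre_t"].to_numpy()
        called = m["is_sre_a"].to_numpy()
        sens.append(float(called[truth].mean()))
        spec.append(float((~called[~truth]).mean()))
    return {"sensitivity": min(sens), "specificity": min(spec), "n_seeds": n_seeds}
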