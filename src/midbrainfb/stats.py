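"""Group-level inference: distributional tests, correlations, bootstrap,
comparison of independent correlations, conjunction/disjunction, BH-FDR.

The group table holds one SubjectSummary row per subject grouped by feedback
arm and study; every analysis can partial out the study indicator as a
covariate (the two datasets may differ in global signal level).  Correlation
p-values use the t approximation (exact permutation below n = 10 for
Spearman); independent correlations are compared with the Fisher
z transform; region-level multiplicity is controlled with Benjamini-Hochberg
FDR (the region-resolved stand-in for voxelwise cluster correction, which is
out of scope here).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


@dataclass
class CorrelationResult:
    coefficient: float
    n: int
    p: float
    alternative: str
    method: str
    ci: tuple | None = None
    ci_level: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12:
            raise StatsError("correlation coefficient outside [-1, 1]")


def _clean_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-d arrays of equal length")
    if x.size < min_n:
        raise StatsError(f"need at least {min_n} pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input: correlation undefined")
    return x, y


def _exact_spearman_p(x, y, rho: float, alternative: str) -> float:
    """Exact permutation p for small n (all n! permutations of the y ranks)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    perms = np.array(list(itertools.permutations(ry)))
    perms = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(
        axis=1, keepdims=True)
    rhos = perms @ rx / x.size
    if alternative == "two-sided":
        return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    if alternative == "greater":
        return float(np.mean(rhos >= rho - 1e-12))
    return float(np.mean(rhos <= rho + 1e-12))


def spearman(x, y, alternative: str = "two-sided", *,
             n_boot: int | None = None, seed: int | None = None,
             ci_level: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation (midranks for ties); t-approximation
    p-value, exact permutation below n = 10."""
    x, y = _clean_pair(x, y, 3)
    rho = float(sps.spearmanr(x, y).statistic)
    if x.size < 10:
        p = _exact_spearman_p(x, y, rho, alternative)
    else:
        res = sps.spearmanr(x, y, alternative=alternative)
        p = float(res.pvalue)
    out = CorrelationResult(rho, x.size, p, alternative, "spearman")
    if n_boot:
        out.ci = bootstrap_ci(x, y, "spearman", reps=n_boot, level=ci_level,
                              seed=seed if seed is not None else 0)
        out.ci_level, out.n_boot, out.seed = ci_level, n_boot, seed
    return out


def pearson(x, y, alternative: str = "two-sided", *,
            n_boot: int | None = None, seed: int | None = None,
            ci_level: float = 0.95) -> CorrelationResult:
    """Pearson product-moment correlation with t-approximation p-value."""
    x, y = _clean_pair(x, y, 3)
    res = sps.pearsonr(x, y, alternative=alternative)
    out = CorrelationResult(float(res.statistic), x.size, float(res.pvalue),
                            alternative, "pearson")
    if n_boot:
        out.ci = bootstrap_ci(x, y, "pearson", reps=n_boot, level=ci_level,
                              seed=seed if seed is not None else 0)
        out.ci_level, out.n_boot, out.seed = ci_level, n_boot, seed
    return out


def fisher_z_diff(r1: float, n1: int, r2: float, n2: int,
                  side: str = "one") -> dict:
    """Compare two correlations from independent samples via Fisher's z.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); ``side='one'``
    tests r1 > r2.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise StatsError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise StatsError("each sample needs n > 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    if side == "one":
        p = float(sps.norm.sf(z))
    elif side == "two":
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise StatsError("side must be 'one' or 'two'")
    return {"z": float(z), "p": p, "side": side}


def anova_oneway(groups) -> dict:
    """One-way ANOVA; F with (k-1, N-k) degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise StatsError("need >= 2 groups with n >= 2 each")
    res = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    f = float(res.statistic)
    if np.isnan(f):  # zero within-group variance everywhere, equal means
        f, pval = 0.0, 1.0
    else:
        pval = float(res.pvalue)
    return {"F": f, "df": (k - 1, n - k), "p": pval}


def kruskal_wallis(groups) -> dict:
    """Kruskal-Wallis rank test with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise StatsError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise StatsError("all values identical: ranks undefined")
    res = sps.kruskal(*groups)
    return {"H": float(res.statistic), "df": len(groups) - 1,
            "p": float(res.pvalue)}


def two_sample_t(a, b) -> dict:
    """Pooled-variance two-sample t test, df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        raise StatsError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "df": a.size + b.size - 2,
            "p": float(res.pvalue)}


_STAT_FUNCS = {
    "spearman": lambda x, y: sps.spearmanr(x, y).statistic,
    "pearson": lambda x, y: sps.pearsonr(x, y).statistic,
}


def bootstrap_ci(x, y, statistic="spearman", *, reps: int = 10000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile CI of a paired statistic under case resampling
    (seed-deterministic)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise StatsError("bootstrap needs n >= 4")
    if reps < 1:
        raise StatsError("reps must be >= 1")
    func = _STAT_FUNCS.get(statistic, statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    vals = np.empty(reps)
    for i, row in enumerate(idx):
        v = func(x[row], y[row])
        vals[i] = v if np.isfinite(v) else 0.0
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1.0 - alpha)))


def partial_covariate(x, y, covariate, method: str = "pearson",
                      alternative: str = "two-sided") -> CorrelationResult:
    """Correlation after regressing the covariate out of both variables.

    A constant covariate is a no-op (plain correlation); a covariate
    collinear with x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == c.shape):
        raise StatsError("x, y and covariate must have equal length")
    design = np.column_stack([np.ones_like(c), c])

    def _resid(v):
        beta, _, _, _ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx = _resid(x)
    if np.allclose(rx, 0.0, atol=1e-10 * max(1.0, float(np.abs(x).max()))):
        raise StatsError("covariate is collinear with x")
    ry = _resid(y)
    func = spearman if method == "spearman" else pearson
    return func(rx, ry, alternative=alternative)


def conjunction_disjunction(results_a: dict, results_b: dict,
                            threshold: float) -> dict:
    """Partition a region universe by thresholded effects in two analyses.

    conjunction: regions whose statistic passes ``threshold`` (in the stated
    positive direction) in both analyses; disjunction: in exactly one;
    neither: in none.
    """
    if set(results_a) != set(results_b):
        raise StatsError("region universes differ between the two analyses")
    conjunction, disjunction, neither = set(), set(), set()
    for region in results_a:
        a = results_a[region] >= threshold
        b = results_b[region] >= threshold
        if a and b:
            conjunction.add(region)
        elif a or b:
            disjunction.add(region)
        else:
            neither.add(region)
    return {"conjunction": conjunction, "disjunction": disjunction,
            "neither": neither}


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def group_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Validate a SubjectSummary table as a group table (arm x study)."""
    for col in ("subject_id", "arm", "study_id"):
        if col not in summaries.columns:
            raise StatsError(f"group table missing column {col!r}")
    if summaries["subject_id"].duplicated().any():
        raise StatsError("duplicate subject ids")
    return summaries
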