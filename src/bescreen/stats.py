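"""Sort-seq and fitness screen statistics.

Per-guide differential abundance between GFP-high and GFP-low pools is
estimated with a two-group Poisson GLM (log link, log-size-factor offset):
the group-coefficient MLE has the closed form ln((sum H / sum s_H)/(sum L /
sum s_L)) and its Wald standard error is sqrt(1/sum H + 1/sum L), which is
what this module computes exactly. Multiple testing is controlled with
Storey q-values; gene-level effects combine guide p-values with Fisher's
method and take the lower of the combined q and the best-guide q. The
fitness analysis computes log2 fold changes against a reference time point
with a pseudocount, and a control-based empirical FDR for depletion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class StatsParams:
    significance_fdr: float = 0.05
    degenerate_log2fc_replacement: float = 3.0
    dropout_log2fc_threshold: float = -0.5
    fitness_pseudocount: float = 0.5


def guide_effect_glm(
    high_counts,
    low_counts,
    sf_high=None,
    sf_low=None,
    replacement: float = 3.0,
) -> tuple[float, float, bool]:
    """Per-guide high-vs-low effect from the two-group Poisson GLM.

    Returns (log2fc, p, degenerate). The estimate is the exact MLE of the
    Poisson regression of counts on a high/low indicator with log(size
    factor) offset; p is the two-sided Wald test on the group coefficient.
    When one group's total is zero (complete separation) log2fc is set to
    +/-``replacement`` with a continuity-corrected p (0.5 added to both
    group totals).
    """
    h = np.asarray(high_counts, dtype=float)
    l = np.asarray(low_counts, dtype=float)
    sh = np.ones_like(h) if sf_high is None else np.asarray(sf_high, dtype=float)
    sl = np.ones_like(l) if sf_low is None else np.asarray(sf_low, dtype=float)
    H, L = h.sum(), l.sum()
    SH, SL = sh.sum(), sl.sum()
    if H == 0 and L == 0:
        raise ValueError("both groups all-zero: effect undefined")
    if H == 0 or L == 0:
        beta = math.log(((H + 0.5) / SH) / ((L + 0.5) / SL))
        se = math.sqrt(1.0 / (H + 0.5) + 1.0 / (L + 0.5))
        p = 2.0 * sps.norm.sf(abs(beta / se))
        return (replacement if H > L else -replacement, float(p), True)
    beta = math.log((H / SH) / (L / SL))
    se = math.sqrt(1.0 / H + 1.0 / L)
    z = beta / se
    p = 2.0 * sps.norm.sf(abs(z))
    return (beta / _LN2, float(p), False)


def estimate_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey pi0: smooth #{p > lambda}/(m(1-lambda)) over the lambda grid
    with a cubic spline and evaluate at the largest lambda; fall back to 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_hat = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    try:
        from scipy.interpolate import UnivariateSpline

        spline = UnivariateSpline(lambdas, pi0_hat, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:  # degenerate grids
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = 1.0
    return min(pi0, 1.0)


def qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with pi0=1 this reduces exactly to Benjamini-Hochberg.

    q_(i) = min_{j>=i} pi0 * m * p_(j) / j over sorted p-values; output is
    monotone nondecreasing in p and clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def combine_pvalues_fisher(pvals) -> float:
    """Fisher's method: -2*sum(ln p) against chi-square with 2k df."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p == 0).any():
        logger.warning("zero p-values clamped for Fisher combination")
        p = np.clip(p, np.finfo(float).tiny, None)
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, 2 * p.size))


def guide_effects_table(
    matrix, high_samples: list[str], low_samples: list[str],
    params: StatsParams | None = None,
) -> pd.DataFrame:
    """Per-guide GLM effects from a CountMatrix (columns guide_id, log2fc, p,
    q, degenerate). Guides with zero counts in both groups are excluded."""
    params = params or StatsParams()
    counts = matrix.counts
    sf = matrix.size_factors
    rows = []
    for gid, row in counts.iterrows():
        h = row[high_samples].to_numpy(dtype=float)
        l = row[low_samples].to_numpy(dtype=float)
        if h.sum() == 0 and l.sum() == 0:
            continue
        lfc, p, degen = guide_effect_glm(
            h, l, sf[high_samples].to_numpy(), sf[low_samples].to_numpy(),
            replacement=params.degenerate_log2fc_replacement,
        )
        rows.append({"guide_id": gid, "log2fc": lfc, "p": p, "degenerate": degen})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = qvalues(df["p"].to_numpy())
    return df


def gene_level_effects(
    guide_effects: pd.DataFrame, params: StatsParams | None = None
) -> pd.DataFrame:
    """Aggregate guide effects per gene.

    Per gene: log2fc and q_best come from the guide with the largest absolute
    fold change (ties: smaller q, then guide id); q_combined re-controls the
    Fisher-combined gene p-values across genes; q_final = min(q_combined,
    q_best). Requires columns guide_id, gene, log2fc, p, q.
    """
    params = params or StatsParams()
    rows = []
    for gene, grp in guide_effects.groupby("gene", sort=True):
        grp = grp.sort_values(
            by=["log2fc", "q", "guide_id"],
            key=lambda s: -s.abs() if s.name == "log2fc" else s,
        )
        best = grp.iloc[0]
        p_comb = combine_pvalues_fisher(grp["p"].to_numpy())
        rows.append(
            {
                "gene": gene,
                "log2fc": best["log2fc"],
                "best_guide": best["guide_id"],
                "q_best": best["q"],
                "p_combined": p_comb,
                "n_guides": len(grp),
            }
        )
    genes = pd.DataFrame(rows)
    if genes.empty:
        return genes
    genes["q_combined"] = qvalues(genes["p_combined"].to_numpy())
    genes["q_final"] = np.minimum(genes["q_combined"], genes["q_best"])
    return genes


def fitness_effects(
    matrix, sample_map: dict[str, dict[str, str]],
    reference_timepoint: str = "pre",
    guide_to_gene: dict[str, str] | None = None,
    params: StatsParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-guide (and optionally per-gene) fitness log2 fold changes.

    ``sample_map`` maps replicate -> timepoint -> sample column. For each
    replicate and time point, log2((count_t + 0.5)/(count_ref + 0.5)) on
    size-factor-normalized counts, then averaged across replicates. The gene
    level takes the guide with the largest absolute log2fc per time point.
    """
    params = params or StatsParams()
    pc = params.fitness_pseudocount
    norm = matrix.counts.div(matrix.size_factors, axis=1)
    timepoints = sorted(
        {tp for reps in sample_map.values() for tp in reps if tp != reference_timepoint}
    )
    per_rep: dict[str, list[pd.Series]] = {tp: [] for tp in timepoints}
    for rep, tps in sample_map.items():
        if reference_timepoint not in tps:
            raise ValueError(f"replicate {rep} lacks reference time point {reference_timepoint}")
        ref = norm[tps[reference_timepoint]]
        for tp in timepoints:
            if tp in tps:
                per_rep[tp].append(np.log2((norm[tps[tp]] + pc) / (ref + pc)))
    guide_lfc = pd.DataFrame(
        {tp: pd.concat(series, axis=1).mean(axis=1) for tp, series in per_rep.items()}
    )
    guide_lfc.index.name = "guide_id"

    gene_lfc = None
    if guide_to_gene:
        genes = pd.Series(guide_to_gene).reindex(guide_lfc.index)
        recs = []
        for gene, grp in guide_lfc.groupby(genes):
            rec = {"gene": gene}
            for tp in timepoints:
                rec[tp] = grp[tp].loc[grp[tp].abs().idxmax()]
            recs.append(rec)
        gene_lfc = pd.DataFrame(recs).set_index("gene")
    return guide_lfc, gene_lfc


def depletion_fdr(
    guide_log2fc: pd.Series, control_log2fc: pd.Series, min_controls: int = 50
) -> pd.DataFrame:
    """Control-based empirical depletion significance (reconstructed procedure).

    One-sided empirical p = (1 + #{controls <= observed})/(n_controls + 1),
    then Storey q-values. The screen's own neutral guide sets serve as the
    empirical null.
    """
    ctrl = np.sort(np.asarray(control_log2fc, dtype=float))
    if ctrl.size < min_controls:
        raise ValueError(f"need >= {min_controls} control guides, got {ctrl.size}")
    obs = guide_log2fc.to_numpy(dtype=float)
    p = (1 + np.searchsorted(ctrl, obs, side="right")) / (ctrl.size + 1)
    q = qvalues(p)
    return pd.DataFrame({"log2fc": obs, "p": p, "q": q}, index=guide_log2fc.index)


def exact_binomial_direction(n_down: int, n_up: int) -> float:
    """Exact two-sided binomial test of direction balance at null 0.5."""
    n = n_down + n_up
    if n < 1:
        raise ValueError("need at least one observation")
    return float(sps.binomtest(n_down, n, 0.5, alternative="two-sided").pvalue)


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence without continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def pooled_t_test(x, y) -> tuple[float, int, float]:
    """Two-sided Student t-test with pooled variance; df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), x.size + y.size - 2, float(res.pvalue)
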