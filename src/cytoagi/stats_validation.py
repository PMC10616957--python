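"""Method-comparison and reproducibility statistics.

Per-population agreement between two analysis strategies (e.g. automated
classification vs expert Boolean gating) is summarised by the squared
Pearson correlation of paired counts across samples, restricted to samples
where the population is quantifiable (>50 cells, or >20 for plasma-cell
subsets). Reproducibility across replicate analyses is summarised as the
coefficient of variation (CV = 100 * SD / mean) per population, and paired
bias between methods via Bland-Altman statistics. P-values are reported
raw; an optional Benjamini-Hochberg adjustment is available but off by
default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .taxonomy import PopulationTaxonomy

__all__ = [
    "per_population_r2", "reproducibility_cv", "compare_cv",
    "bland_altman_bias", "compare_methods", "bh_adjust",
]

MIN_PAIRS = 3


def _quantifiable_threshold(tax: PopulationTaxonomy | None, population: str) -> int:
    if tax is not None and population in tax:
        return tax.node(population).min_quantifiable
    for agg in (tax.aggregates if tax is not None else []):
        if agg.name == population:
            return 20 if agg.compartment == "PC" else 50
    return 50


def per_population_r2(a: pd.DataFrame, b: pd.DataFrame,
                      tax: PopulationTaxonomy | None = None) -> pd.DataFrame:
    """Squared Pearson correlation of paired per-sample counts.

    ``a`` and ``b`` are samples x populations count tables with identical
    index/columns. A sample enters a population's pair set only when the
    population is quantifiable in both tables; populations with fewer than
    3 quantifiable pairs, or zero variance in either vector, are flagged
    not evaluable (r2 = NaN).
    """
    if list(a.index) != list(b.index) or set(a.columns) != set(b.columns):
        raise ValueError("count tables must share samples and populations")
    rows = []
    for pop in a.columns:
        thr = _quantifiable_threshold(tax, pop)
        av, bv = a[pop].to_numpy(float), b[pop].to_numpy(float)
        keep = (av > thr) & (bv > thr)
        av, bv = av[keep], bv[keep]
        row = {"population": pop, "n_pairs": int(keep.sum()),
               "r2": np.nan, "slope": np.nan, "p": np.nan, "evaluable": False}
        if keep.sum() >= MIN_PAIRS and av.std() > 0 and bv.std() > 0:
            r, p = sps.pearsonr(av, bv)
            slope = np.polyfit(av, bv, 1)[0]
            row.update(r2=r ** 2, slope=slope, p=p, evaluable=True)
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")


def reproducibility_cv(replicates: pd.DataFrame, method: str = "") -> pd.DataFrame:
    """CV (%) and SD per population across replicate analyses.

    ``replicates``: populations x replicates counts, >= 2 replicates.
    Populations with zero mean have undefined CV and are flagged.
    """
    if replicates.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    mean = replicates.mean(axis=1)
    sd = replicates.std(axis=1, ddof=1)
    cv = pd.Series(np.where(mean > 0, 100.0 * sd / mean.replace(0, np.nan), np.nan),
                   index=replicates.index)
    return pd.DataFrame({"method": method, "mean": mean, "sd": sd,
                         "cv_pct": cv, "defined": mean > 0})


def compare_cv(report_a: pd.DataFrame, report_b: pd.DataFrame) -> dict:
    """Paired t-test between two methods' per-population CVs."""
    joined = report_a[["cv_pct"]].join(report_b[["cv_pct"]],
                                       lsuffix="_a", rsuffix="_b").dropna()
    if len(joined) < 2:
        raise ValueError("need >= 2 populations with defined CV in both")
    a, b = joined["cv_pct_a"], joined["cv_pct_b"]
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    return {"median_cv_a": float(a.median()), "median_cv_b": float(b.median()),
            "t": float(t), "p": float(p), "n": len(joined)}


def bland_altman_bias(pairs) -> tuple[float, tuple[float, float]]:
    """Mean difference and 95% limits of agreement of paired measurements."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need >= 2 (a, b) pairs")
    diff = arr[:, 0] - arr[:, 1]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def compare_methods(a, b, paired: bool = False) -> dict:
    """Rank-based location comparison of two result vectors.

    Unpaired data get the Mann-Whitney U test, paired data the Wilcoxon
    signed-rank test (the paired analogue); the Kruskal-Wallis statistic is
    reported alongside in both cases. P-values are raw (no multiplicity
    adjustment), matching common flow-cytometry reporting practice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    out = {}
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal lengths")
        if np.allclose(a, b):
            out["wilcoxon"] = (0.0, 1.0)
        else:
            w, p = sps.wilcoxon(a, b)
            out["wilcoxon"] = (float(w), float(p))
    else:
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        out["mannwhitneyu"] = (float(u), float(p))
    h, p = sps.kruskal(a, b)
    out["kruskal"] = (float(h), float(p))
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default in
    all reports)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
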