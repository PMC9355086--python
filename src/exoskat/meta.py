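"""Fisher's combined-probability meta-analysis across cohort strata.

Per gene, the minimum p-value across weighting schemes within each
stratum is combined as ``X2 = -2 * sum(ln p_i) ~ chi2(2k)`` and the
combined p-value is Bonferroni-adjusted for the number of genes carried
into the meta-analysis.  Combination happens on the natural-log scale so
inputs as small as 1e-250 lose no precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_combine", "bonferroni_adjust", "stratified_meta", "MetaRecord"]


@dataclass
class MetaRecord:
    """One gene's meta-analysis line."""

    gene: str
    stratum_pvalues: dict[str, float]
    chi2: float
    df: int
    p_meta: float
    p_adjusted: float


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns ``(X2, df, p)`` with ``X2 = -2 sum(ln p_i)``, ``df = 2k`` and
    ``p`` the chi-square survival probability.  All inputs must lie in
    (0, 1].
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return x2, df, float(stats.chi2.sf(x2, df))


def bonferroni_adjust(p: float, m: int) -> float:
    """``min(1, p * m)``."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def stratified_meta(results_by_stratum: dict[str, pd.DataFrame], m: int) -> pd.DataFrame:
    """Meta-analyze per-gene minimum p-values across strata.

    ``results_by_stratum`` maps a stratum label to a table with columns
    ``gene`` and ``p`` (already the within-stratum minimum across
    schemes; a long scheme-level table works too, the minimum is taken
    here).  Genes missing from any stratum are dropped and reported in
    the ``n_strata`` bookkeeping; genes present in no shared stratum
    raise.  ``m`` is the Bonferroni multiplier, conventionally the count
    of primary-significant genes.
    """
    if not results_by_stratum:
        raise ValueError("need at least one stratum")
    mins: dict[str, pd.Series] = {}
    for label, df in results_by_stratum.items():
        ok = df
        if "status" in df.columns:
            ok = df[df["status"] == "ok"]
        mins[label] = ok.groupby("gene")["p"].min()

    shared = sorted(set.intersection(*(set(s.index) for s in mins.values())))
    if not shared:
        raise ValueError("no genes shared across all strata")

    labels = list(mins)
    rows = []
    for gene in shared:
        ps = [float(mins[lab][gene]) for lab in labels]
        x2, df_, p_meta = fisher_combine(ps)
        row = {"gene": gene}
        for lab, p in zip(labels, ps):
            row[f"p_{lab}"] = p
        row.update(
            chi2_meta=x2,
            df_meta=df_,
            p_meta=p_meta,
            p_adjusted=bonferroni_adjust(p_meta, m) if p_meta > 0 else 0.0,
        )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("p_meta").reset_index(drop=True)
    return out
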