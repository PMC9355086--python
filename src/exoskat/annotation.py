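"""Variant consequence classification, allele frequencies, and the
inclusion filter for gene-based tests.

Consequence terms follow the Ensembl VEP controlled vocabulary.  Only
autosomal variants whose predicted consequence falls in the high- or
moderate-impact tier, and which carry a gene assignment, enter the
kernel tests; everything else is dropped with a recorded reason.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = [
    "HIGH_IMPACT",
    "MODERATE_IMPACT",
    "classify_impact",
    "compute_maf",
    "dosage_maf",
    "filter_for_gene_tests",
]

#: High-impact consequence stems (``_variant`` suffix stripped).
HIGH_IMPACT = frozenset(
    {
        "transcript_ablation",
        "splice_acceptor",
        "splice_donor",
        "stop_gained",
        "frameshift",
        "stop_lost",
        "start_lost",
        "transcript_amplification",
    }
)

#: Moderate-impact consequence stems.
MODERATE_IMPACT = frozenset(
    {
        "inframe_insertion",
        "inframe_deletion",
        "missense",
        "protein_altering",
    }
)

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def _normalise(term: str) -> str:
    # VEP emits snake_case ("stop_gained"); human-written tables may use
    # spaces, hyphens or capitals ("Stop gained", "in-frame insertion").
    t = re.sub(r"[\s\-]+", "_", term.strip().lower())
    t = t.removesuffix("_variant")
    t = t.replace("in_frame", "inframe")
    return t


def classify_impact(consequence: str) -> str:
    """Map a consequence term to its impact tier.

    Returns ``"high"``, ``"moderate"`` or ``"other"``.  Unknown terms are
    ``"other"`` by contract, so new VEP vocabulary never raises.
    """
    if not isinstance(consequence, str) or not consequence.strip():
        raise ValueError("consequence term must be a non-empty string")
    stem = _normalise(consequence)
    if stem in HIGH_IMPACT:
        return "high"
    if stem in MODERATE_IMPACT:
        return "moderate"
    return "other"


def compute_maf(dosages) -> tuple[float, float]:
    """Minor allele frequency and call rate from a dosage vector.

    ``dosages`` holds values in ``{0, 1, 2}`` with ``NaN`` for missing
    calls.  The allele frequency is computed over non-missing entries and
    folded to the minor allele (``maf <= 0.5``); the call rate is the
    fraction of non-missing entries.

    Raises
    ------
    ValueError
        If the vector is empty or every entry is missing.
    """
    d = np.asarray(dosages, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty dosage vector")
    called = ~np.isnan(d)
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    af = float(d[called].sum()) / (2 * n_called)
    return min(af, 1.0 - af), n_called / d.size


def dosage_maf(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`compute_maf` over the columns of ``G``.

    Columns with no called genotypes get ``maf = NaN`` and
    ``call_rate = 0`` instead of raising, so callers can filter.
    """
    G = np.asarray(G, dtype=float)
    called = ~np.isnan(G)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.nansum(G, axis=0) / (2 * n_called)
    maf = np.minimum(af, 1.0 - af)
    maf[n_called == 0] = np.nan
    return maf, n_called / G.shape[0]


def filter_for_gene_tests(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the gene-test inclusion filter to an annotated variant table.

    Keeps autosomal variants with impact in {high, moderate} and a gene
    assignment, preserving input order.  Returns ``(kept, report)`` where
    ``report`` has one row per input variant with columns ``id``,
    ``kept`` and ``reason`` (empty string for kept variants) — every
    variant lands in exactly one of kept / dropped-with-reason.
    """
    if len(variants) == 0:
        empty = variants.copy()
        report = pd.DataFrame(columns=["id", "kept", "reason"])
        return empty, report

    chrom = variants["chrom"].astype(str).str.removeprefix("chr")
    impact = variants["consequence"].map(classify_impact)
    gene = variants["gene"]

    reasons = np.full(len(variants), "", dtype=object)
    autosomal = chrom.isin(_AUTOSOMES).to_numpy()
    has_gene = (~gene.isna() & (gene.astype(str) != "")).to_numpy()
    qualifying = impact.isin(["high", "moderate"]).to_numpy()

    reasons[~qualifying] = "impact-other"
    reasons[~has_gene] = "no-gene"
    reasons[~autosomal] = "non-autosomal"

    keep = autosomal & has_gene & qualifying
    report = pd.DataFrame(
        {"id": variants["id"].to_numpy(), "kept": keep, "reason": reasons}
    )
    kept = variants.loc[keep].copy()
    kept["impact"] = impact[keep]
    return kept, report
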