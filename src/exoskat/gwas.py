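"""Single-marker scan with variant QC filters and iterative conditional
selection of lead SNPs.

The scan mirrors standard array-GWAS practice for quantitative traits:
per-SNP ordinary least squares of the transformed phenotype on dosage
plus covariates, restricted to variants with MAF > 1%, an exact
Hardy-Weinberg equilibrium p-value >= 1e-10 and missingness < 1%.
Significant SNPs (p < 5e-8) are grouped into loci and, per locus, lead
variants are selected iteratively: the most significant SNP joins the
covariates and the locus is rescanned until nothing remains significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import dosage_maf
from .association import NullModel, fit_null
from .cohort import CohortData

__all__ = [
    "GWAS_THRESHOLD",
    "hwe_exact_test",
    "single_marker_scan",
    "select_lead_snps",
    "LeadSnpSet",
]

GWAS_THRESHOLD = 5e-8
MAF_FILTER = 0.01        # keep MAF > 1%
HWE_FILTER = 1e-10       # drop exact-test p below this
MISSINGNESS_FILTER = 0.01  # keep missingness < 1%

_TIE_EPS = 1e-12  # relative tolerance when comparing genotype-table probabilities


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------
def _het_log_probabilities(n: int, minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every heterozygote count compatible with the
    allele counts (``n`` genotypes, ``minor`` minor-allele copies).

    Uses the conditional distribution of the heterozygote count given the
    allele counts under random union of gametes:

        P(h) = n! 2^h / (n_aa! h! n_AA!) * C(2n, minor)^-1 * ...

    computed directly with log-gamma terms and normalised.
    """
    h_min = minor % 2
    h_max = min(minor, 2 * n - minor)
    hs = np.arange(h_min, h_max + 1, 2)
    n_min_hom = (minor - hs) // 2
    n_maj_hom = n - n_min_hom - hs
    lg = lambda k: np.array([lgamma(v + 1.0) for v in k], dtype=float)
    logp = hs * log(2.0) - lg(n_min_hom) - lg(hs) - lg(n_maj_hom)
    logp -= logp.max()
    logp -= np.log(np.exp(logp).sum())
    return hs, logp


def hwe_exact_pvalues(n: int, minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact-test p-values for every heterozygote count at fixed allele counts.

    Returns ``(het_counts, pvalues)`` where ``pvalues[i]`` is the exact
    conditional p-value of observing ``het_counts[i]`` heterozygotes given
    ``n`` genotypes and ``minor`` minor-allele copies.  Computing the whole
    group at once amortises the enumeration when many variants share the
    same allele counts.
    """
    hs, logp = _het_log_probabilities(n, minor)
    probs = np.exp(logp)
    order = np.argsort(probs, kind="stable")
    csum = np.cumsum(probs[order])
    # p(h) = sum of probabilities <= prob(h) (with a tie tolerance)
    ranks = np.searchsorted(probs[order], probs * (1.0 + _TIE_EPS), side="right")
    pvals = np.minimum(csum[ranks - 1], 1.0)
    return hs, pvals


def hwe_exact_test(counts) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test.

    ``counts`` is ``(hom_ref, het, hom_alt)``.  The p-value is the sum of
    probabilities of heterozygote counts no more probable than the one
    observed, conditional on the allele counts.  Monomorphic sites have a
    single attainable configuration and return 1.
    """
    hom_ref, het, hom_alt = (int(c) for c in counts)
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")
    alt = 2 * hom_alt + het
    minor = min(alt, 2 * n - alt)
    hs, pvals = hwe_exact_pvalues(n, minor)
    return float(pvals[np.searchsorted(hs, het)])


# ----------------------------------------------------------------------
# Single-marker scan
# ----------------------------------------------------------------------
def _genotype_counts(G: np.ndarray) -> np.ndarray:
    """Per-column (hom_ref, het, hom_alt) counts over non-missing calls."""
    counts = np.empty((G.shape[1], 3), dtype=int)
    for k, val in enumerate((0.0, 1.0, 2.0)):
        counts[:, k] = np.nansum(G == val, axis=0)
    return counts


def _ols_scan(G: np.ndarray, null: NullModel) -> tuple[np.ndarray, ...]:
    """Vectorised per-SNP OLS of the residualised phenotype on the
    residualised dosage; returns ``(beta, se, p)``.

    A SNP whose dosage is (numerically) inside the covariate span gets
    ``beta = 0, se = inf, p = 1`` by convention — this is what makes a
    lead SNP's own re-test return 1 after conditioning on it.
    """
    n = G.shape[0]
    Gt = null.project_off(G)
    den = np.einsum("ij,ij->j", Gt, Gt)
    num = Gt.T @ null.resid
    df = n - null.rank - 1
    tot = float(null.resid @ null.resid)

    tol = n * np.finfo(float).eps * max(tot, 1.0)
    ok = den > tol
    beta = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.inf)
    p = np.ones(G.shape[1])
    beta[ok] = num[ok] / den[ok]
    rss = tot - beta[ok] * num[ok]
    sigma2 = np.maximum(rss, 0.0) / df
    se[ok] = np.sqrt(sigma2 / den[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se[ok] > 0, beta[ok] / se[ok], 0.0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def single_marker_scan(
    cohort: CohortData,
    null: NullModel,
    *,
    maf_min: float = MAF_FILTER,
    hwe_min: float = HWE_FILTER,
    miss_max: float = MISSINGNESS_FILTER,
    threshold: float = GWAS_THRESHOLD,
) -> pd.DataFrame:
    """Scan every variant in the cohort against the null model.

    The phenotype enters through ``null`` (fit on the INT phenotype and
    the standard covariates).  Variants failing any of the MAF / HWE /
    missingness filters are excluded with a reason; the filters commute,
    so the recorded reason is the first in MAF -> missingness -> HWE
    order.  Returns one row per variant.
    """
    G = np.asarray(cohort.genotypes, dtype=float)
    maf, call_rate = dosage_maf(G)
    missingness = 1.0 - call_rate
    counts = _genotype_counts(G)
    hwe_p = np.array([hwe_exact_test(c) if c.sum() else 1.0 for c in counts])

    status = np.full(cohort.n_variants, "tested", dtype=object)
    status[hwe_p < hwe_min] = "hwe_p < 1e-10"
    status[missingness >= miss_max] = "missingness >= 1%"
    status[~(maf > maf_min)] = "MAF <= 1%"
    tested = status == "tested"

    beta = np.full(cohort.n_variants, np.nan)
    se = np.full(cohort.n_variants, np.nan)
    p = np.full(cohort.n_variants, np.nan)
    if tested.any():
        Gi, _ = _imputed(G[:, tested])
        beta[tested], se[tested], p[tested] = _ols_scan(Gi, null)

    out = pd.DataFrame(
        {
            "snp": cohort.variants["id"].to_numpy(),
            "chrom": cohort.variants["chrom"].to_numpy(),
            "pos": cohort.variants["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "maf": maf,
            "hwe_p": hwe_p,
            "missingness": missingness,
            "status": status,
        }
    )
    out["significant"] = tested & (p < threshold)
    return out


def _imputed(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    G = np.array(G, dtype=float, copy=True)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        means = np.nanmean(G, axis=0)
        G[nan_mask] = np.take(means, np.nonzero(nan_mask)[1])
    return G, nan_mask


# ----------------------------------------------------------------------
# Lead-SNP selection
# ----------------------------------------------------------------------
@dataclass
class LeadSnpSet:
    """Iteratively selected GWAS lead variants.

    ``table`` has columns (locus, snp, chrom, pos, round, p); ``dosages``
    is the mean-imputed n x n_leads dosage matrix aligned with the table
    rows.  An empty set has a (n, 0) dosage matrix.
    """

    table: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_leads(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp"])


def _chrom_sort_key(c: str):
    c = str(c).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def _cluster_snps(sig: pd.DataFrame, window: int) -> list[pd.DataFrame]:
    """Greedy distance clustering: a gap > window starts a new locus."""
    loci = []
    for _, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window) + 1
        for chunk in np.split(np.arange(len(sub)), breaks):
            loci.append(sub.iloc[chunk])
    loci.sort(key=lambda d: (_chrom_sort_key(d["chrom"].iloc[0]), int(d["pos"].min())))
    return loci


def select_lead_snps(
    results: pd.DataFrame,
    cohort: CohortData,
    null: NullModel,
    *,
    threshold: float = GWAS_THRESHOLD,
    window: int = 1_000_000,
    max_rounds: int = 20,
) -> LeadSnpSet:
    """Iterative conditional selection of lead SNPs per locus.

    Significant SNPs from the scan are grouped into loci (inter-SNP gap
    > ``window`` starts a new locus).  Within a locus, the most
    significant SNP becomes the lead (ties broken by smaller position),
    its dosage is appended to the covariates, and the locus is rescanned
    until no SNP is significant.  Raises ``RuntimeError`` if a locus does
    not converge within ``max_rounds`` rounds.
    """
    sig = results[results["significant"]].copy()
    rows: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    y = null.resid + null.X @ null.coef  # reconstruct the fitted phenotype
    X_base = null.X

    id_to_col = {s: i for i, s in enumerate(cohort.variants["id"])}
    for locus_id, locus in enumerate(_cluster_snps(sig, window)):
        cols = [id_to_col[s] for s in locus["snp"]]
        Gl, _ = _imputed(np.asarray(cohort.genotypes[:, cols], dtype=float))
        lead_dosages: list[np.ndarray] = []
        for round_no in range(1, max_rounds + 1):
            X = X_base if not lead_dosages else np.hstack([X_base, np.column_stack(lead_dosages)])
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # collinear leads are dropped silently here
                null_l = fit_null(y, X)
            _, _, p = _ols_scan(Gl, null_l)
            hit = p < threshold
            if not hit.any():
                break
            order = np.lexsort((locus["pos"].to_numpy(), p))
            best = order[0]
            lead_dosages.append(Gl[:, best])
            rows.append(
                {
                    "locus": locus_id,
                    "snp": locus["snp"].iloc[best],
                    "chrom": locus["chrom"].iloc[best],
                    "pos": int(locus["pos"].iloc[best]),
                    "round": round_no,
                    "p": float(p[best]),
                }
            )
            dosage_cols.append(Gl[:, best])
        else:
            raise RuntimeError(
                f"lead selection did not converge in {max_rounds} rounds at locus "
                f"{locus_id} ({locus['chrom'].iloc[0]}:{int(locus['pos'].min())}-"
                f"{int(locus['pos'].max())})"
            )

    table = pd.DataFrame(rows, columns=["locus", "snp", "chrom", "pos", "round", "p"])
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((cohort.n_samples, 0))
    )
    return LeadSnpSet(table, dosages)
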