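"""Discovery orchestration: scheme battery, multiple-testing threshold,
gene-locus clustering, GWAS-overlap classification, conditional re-tests,
and the rare-variant cascade.

The discovery logic is:

1.  Filter variants (autosomal, high/moderate impact, gene-assigned) and
    run all five weighting schemes on every gene against the
    inverse-normal-transformed phenotype.
2.  Call a gene significant when its best p-value across schemes beats
    the Bonferroni threshold ``0.05 / (n_genes x n_schemes)``.
3.  Cluster significant genes into loci: per chromosome, the lowest-p
    unassigned gene leads a locus and all unassigned significant genes
    within 10 Mb of it join; repeat until none remain.
4.  Run the single-marker scan, select lead SNPs by iterative
    conditioning, and flag genes more than 5 Mb from every lead SNP as
    non-GWAS-overlapping.
5.  Re-test significant genes with lead-SNP dosages appended to the
    covariates, and run the RareOnly cascade at seven MAF cutoffs with
    and without that conditioning.  A gene is rare-driven when any
    conditioned cascade test beats the downstream threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from .annotation import dosage_maf, filter_for_gene_tests
from .association import (
    SCHEME_NAMES,
    GeneTestResult,
    NullModel,
    fit_null,
    gene_test,
    inverse_normal_transform,
    rare_only_test,
)
from .cohort import CohortData
from .gwas import LeadSnpSet, select_lead_snps, single_marker_scan

__all__ = [
    "CASCADE_CUTOFFS",
    "significance_threshold",
    "run_gene_tests",
    "cluster_gene_loci",
    "classify_gwas_overlap",
    "conditional_gene_tests",
    "rare_cascade",
    "run_discovery",
    "DiscoveryResult",
]

#: RareOnly cascade cutoffs: 0.01%, 0.1%, 0.3%, 0.5%, 1%, 3%, 5%.
CASCADE_CUTOFFS: tuple[float, ...] = (0.0001, 0.001, 0.003, 0.005, 0.01, 0.03, 0.05)

#: Downstream model count used for the re-corrected threshold:
#: 5 conditional schemes + 7 cascade cutoffs x {unconditioned, conditioned}.
N_DOWNSTREAM_MODELS = len(SCHEME_NAMES) + 2 * len(CASCADE_CUTOFFS)

GENE_LOCUS_WINDOW = 10_000_000
GWAS_OVERLAP_RADIUS = 5_000_000


def significance_threshold(n_genes: int, n_models: int) -> float:
    """Bonferroni threshold ``0.05 / (n_genes x n_models)``."""
    if n_genes < 1 or n_models < 1:
        raise ValueError("n_genes and n_models must be >= 1")
    return 0.05 / (n_genes * n_models)


# ----------------------------------------------------------------------
# Scheme battery
# ----------------------------------------------------------------------
def run_gene_tests(
    cohort: CohortData,
    null: NullModel,
    *,
    genes: list[str] | None = None,
    schemes: tuple[str, ...] = SCHEME_NAMES,
    conditioning_id: str = "none",
    variant_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the scheme battery over genes and return a long results table.

    MAF and weights are computed on the analysis sample.  ``variant_mask``
    restricts which columns may enter (the annotation filter); when None
    it is computed here.
    """
    if variant_mask is None:
        kept, _ = filter_for_gene_tests(cohort.variants)
        variant_mask = np.zeros(cohort.n_variants, dtype=bool)
        variant_mask[kept.index.to_numpy()] = True

    gene_list = genes if genes is not None else list(cohort.genes["gene"])
    rows = []
    for gname in gene_list:
        idx = cohort.gene_variant_indices(gname)
        idx = idx[variant_mask[idx]]
        if idx.size == 0:
            for s in schemes:
                rows.append(
                    assoc._no_test(gname, s, "no qualifying variants",
                                   conditioning_id=conditioning_id).to_dict()
                )
            continue
        G = cohort.dosages(idx)
        maf, _ = dosage_maf(G)
        cadd = cohort.variants["cadd"].to_numpy(dtype=float)[idx]
        poly = ~np.isnan(maf) & (maf > 0)
        G, maf, cadd = G[:, poly], maf[poly], cadd[poly]
        for s in schemes:
            if maf.size == 0:
                res = assoc._no_test(gname, s, "no polymorphic variants",
                                     conditioning_id=conditioning_id)
            else:
                res = gene_test(G, maf, cadd, s, null, gene=gname,
                                conditioning_id=conditioning_id)
            rows.append(res.to_dict())
    return pd.DataFrame(rows)


def _min_p_per_gene(results: pd.DataFrame) -> pd.DataFrame:
    ok = results[results["status"] == "ok"]
    if len(ok) == 0:
        return pd.DataFrame(columns=["gene", "p", "scheme"])
    idx = ok.groupby("gene")["p"].idxmin()
    out = ok.loc[idx, ["gene", "p", "scheme"]].reset_index(drop=True)
    return out


# ----------------------------------------------------------------------
# Locus clustering and overlap
# ----------------------------------------------------------------------
def cluster_gene_loci(significant: pd.DataFrame, window: int = GENE_LOCUS_WINDOW) -> pd.DataFrame:
    """Cluster significant genes into loci by iterative lead selection.

    ``significant`` needs columns ``gene``, ``chrom``, ``pos`` (a single
    anchor coordinate, by convention the interval midpoint) and ``p``.
    Per chromosome the lowest-p unassigned gene becomes a lead and every
    unassigned gene within ``window`` of it joins the locus, repeating
    until all genes are assigned.  Returns one row per locus with the
    lead gene, member list, and span.
    """
    if significant["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in locus clustering input")
    loci = []
    for chrom, sub in significant.groupby("chrom", sort=False):
        sub = sub.copy()
        unassigned = sub.index.to_list()
        while unassigned:
            block = sub.loc[unassigned]
            lead_idx = block["p"].idxmin()
            lead = sub.loc[lead_idx]
            members = block[(block["pos"] - lead["pos"]).abs() <= window]
            loci.append(
                {
                    "chrom": chrom,
                    "lead_gene": lead["gene"],
                    "lead_p": float(lead["p"]),
                    "members": sorted(members["gene"]),
                    "n_genes": len(members),
                    "span_min": int(members["pos"].min()),
                    "span_max": int(members["pos"].max()),
                }
            )
            unassigned = [i for i in unassigned if i not in set(members.index)]
    loci.sort(key=lambda d: d["lead_p"])
    out = pd.DataFrame(
        loci,
        columns=["chrom", "lead_gene", "lead_p", "members", "n_genes", "span_min", "span_max"],
    )
    out.insert(0, "locus", range(len(out)))
    return out


def classify_gwas_overlap(
    genes: pd.DataFrame,
    leads: LeadSnpSet,
    radius: int = GWAS_OVERLAP_RADIUS,
) -> pd.DataFrame:
    """Distance of each gene to the nearest lead SNP, and the overlap flag.

    Distance is 0 when a lead SNP lies inside ``[start, stop]``, else the
    gap to the nearest interval edge; a gene is non-GWAS-overlapping iff
    its distance to every lead exceeds ``radius`` (strict ``>``).  Genes
    on chromosomes without any lead have infinite distance.
    """
    rows = []
    lead_tbl = leads.table
    for _, g in genes.iterrows():
        if g["stop"] < g["start"]:
            raise ValueError(f"gene {g['gene']}: stop < start")
        same = lead_tbl[lead_tbl["chrom"].astype(str) == str(g["chrom"])]
        if len(same) == 0:
            dist = np.inf
        else:
            pos = same["pos"].to_numpy()
            below = np.maximum(g["start"] - pos, 0)
            above = np.maximum(pos - g["stop"], 0)
            dist = float(np.min(below + above))
        rows.append(
            {
                "gene": g["gene"],
                "distance_to_lead": dist,
                "non_gwas_overlapping": bool(dist > radius),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Conditional analyses
# ----------------------------------------------------------------------
def conditional_null_model(cohort: CohortData, y: np.ndarray, leads: LeadSnpSet) -> NullModel:
    """Refit the null model with lead-SNP dosages appended to the design."""
    extra = leads.dosages if leads.n_leads else None
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear leads dropped per the rank rule
        return fit_null(y, cohort.covariate_matrix(extra=extra))


def conditional_gene_tests(
    cohort: CohortData,
    leads: LeadSnpSet,
    y: np.ndarray,
    *,
    genes: list[str],
    schemes: tuple[str, ...] = SCHEME_NAMES,
    variant_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Re-run the scheme battery with lead dosages as extra covariates.

    With an empty lead set this reduces exactly to the primary run.
    """
    null_c = conditional_null_model(cohort, y, leads)
    cond_id = "leads:" + ",".join(leads.snp_ids) if leads.n_leads else "none"
    return run_gene_tests(
        cohort, null_c, genes=genes, schemes=schemes,
        conditioning_id=cond_id, variant_mask=variant_mask,
    )


def rare_cascade(
    cohort: CohortData,
    genes: list[str],
    null_primary: NullModel,
    null_conditional: NullModel,
    threshold: float,
    *,
    cutoffs: tuple[float, ...] = CASCADE_CUTOFFS,
    variant_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RareOnly cascade over seven MAF cutoffs, +/- GWAS conditioning.

    Returns ``(cascade, classification)``: the long table of every
    (gene, cutoff, conditioned) test, and one row per gene with the
    ``rare_driven`` flag (any conditioned cascade p below ``threshold``)
    and the minimum qualifying cutoff.
    """
    if variant_mask is None:
        kept, _ = filter_for_gene_tests(cohort.variants)
        variant_mask = np.zeros(cohort.n_variants, dtype=bool)
        variant_mask[kept.index.to_numpy()] = True

    rows = []
    for gname in genes:
        idx = cohort.gene_variant_indices(gname)
        idx = idx[variant_mask[idx]]
        G = cohort.dosages(idx) if idx.size else np.empty((cohort.n_samples, 0))
        maf, _ = dosage_maf(G) if idx.size else (np.empty(0), np.empty(0))
        poly = ~np.isnan(maf) & (maf > 0)
        G, maf = G[:, poly], maf[poly]
        for conditioned, null in ((False, null_primary), (True, null_conditional)):
            for cutoff in cutoffs:
                if maf.size == 0:
                    res = assoc._no_test(gname, "rare_only", "no qualifying variants", cutoff)
                else:
                    res = rare_only_test(
                        G, maf, cutoff, null, gene=gname,
                        conditioning_id="leads" if conditioned else "none",
                    )
                d = res.to_dict()
                d["conditioned"] = conditioned
                rows.append(d)
    cascade = pd.DataFrame(rows)

    cls_rows = []
    for gname in genes:
        sub = cascade[(cascade["gene"] == gname) & cascade["conditioned"]]
        hits = sub[(sub["status"] == "ok") & (sub["p"] < threshold)]
        cls_rows.append(
            {
                "gene": gname,
                "rare_driven": len(hits) > 0,
                "min_rare_cutoff": float(hits["cutoff"].min()) if len(hits) else np.nan,
            }
        )
    return cascade, pd.DataFrame(cls_rows)


# ----------------------------------------------------------------------
# End-to-end discovery
# ----------------------------------------------------------------------
@dataclass
class DiscoveryResult:
    """Everything the discovery run produced, in analysis order."""

    primary: pd.DataFrame
    primary_threshold: float
    downstream_threshold: float
    significant_genes: list[str]
    gwas_scan: pd.DataFrame
    leads: LeadSnpSet
    loci: pd.DataFrame
    overlap: pd.DataFrame
    conditional: pd.DataFrame
    cascade: pd.DataFrame
    classification: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.primary.to_csv(outdir / "gene_tests_primary.tsv", sep="\t", index=False)
        self.gwas_scan.to_csv(outdir / "gwas_scan.tsv", sep="\t", index=False)
        self.leads.table.to_csv(outdir / "lead_snps.tsv", sep="\t", index=False)
        loci = self.loci.copy()
        if len(loci):
            loci["members"] = loci["members"].map(",".join)
        loci.to_csv(outdir / "gene_loci.tsv", sep="\t", index=False)
        self.conditional.to_csv(outdir / "gene_tests_conditional.tsv", sep="\t", index=False)
        self.cascade.to_csv(outdir / "rare_cascade.tsv", sep="\t", index=False)
        self.classification.to_csv(outdir / "classification.tsv", sep="\t", index=False)


def run_discovery(
    cohort: CohortData,
    *,
    n_downstream_models: int = N_DOWNSTREAM_MODELS,
    gene_window: int = GENE_LOCUS_WINDOW,
    overlap_radius: int = GWAS_OVERLAP_RADIUS,
) -> DiscoveryResult:
    """Execute the full discovery logic on one cohort.

    The primary threshold is ``0.05 / (n_genes_tested x 5)``; downstream
    (conditional and cascade) analyses are re-corrected over the
    significant genes times ``n_downstream_models``.
    """
    kept, _ = filter_for_gene_tests(cohort.variants)
    variant_mask = np.zeros(cohort.n_variants, dtype=bool)
    variant_mask[kept.index.to_numpy()] = True

    y = inverse_normal_transform(cohort.samples["phenotype"].to_numpy(dtype=float))
    null = fit_null(y, cohort.covariate_matrix())

    primary = run_gene_tests(cohort, null, variant_mask=variant_mask)
    tested_genes = primary[primary["status"] == "ok"]["gene"].nunique()
    thr = significance_threshold(max(tested_genes, 1), len(SCHEME_NAMES))
    best = _min_p_per_gene(primary)
    sig = best[best["p"] < thr]
    sig_genes = sorted(sig["gene"])

    scan = single_marker_scan(cohort, null)
    leads = select_lead_snps(scan, cohort, null)

    gene_info = cohort.genes.set_index("gene")
    if len(sig):
        anchors = pd.DataFrame(
            {
                "gene": sig["gene"].to_numpy(),
                "chrom": gene_info.loc[sig["gene"], "chrom"].to_numpy(),
                "pos": (
                    (gene_info.loc[sig["gene"], "start"].to_numpy()
                     + gene_info.loc[sig["gene"], "stop"].to_numpy()) // 2
                ),
                "p": sig["p"].to_numpy(),
            }
        )
        loci = cluster_gene_loci(anchors, window=gene_window)
    else:
        loci = cluster_gene_loci(
            pd.DataFrame(columns=["gene", "chrom", "pos", "p"]), window=gene_window
        )

    overlap = classify_gwas_overlap(
        cohort.genes[cohort.genes["gene"].isin(sig_genes)].reset_index(drop=True),
        leads,
        radius=overlap_radius,
    )

    down_thr = significance_threshold(max(len(sig_genes), 1), n_downstream_models)
    conditional = conditional_gene_tests(
        cohort, leads, y, genes=sig_genes, variant_mask=variant_mask
    )
    null_c = conditional_null_model(cohort, y, leads)
    cascade, cascade_cls = rare_cascade(
        cohort, sig_genes, null, null_c, down_thr, variant_mask=variant_mask
    )

    best_cond = _min_p_per_gene(conditional)
    cls = pd.DataFrame({"gene": sorted(cohort.genes["gene"])})
    cls["significant_primary"] = cls["gene"].isin(sig_genes)
    cls = cls.merge(best.rename(columns={"p": "min_p_primary", "scheme": "best_scheme"}),
                    on="gene", how="left")
    cls = cls.merge(
        best_cond[["gene", "p"]].rename(columns={"p": "min_p_conditional"}),
        on="gene", how="left",
    )
    cls["significant_after_gwas_adjustment"] = cls["significant_primary"] & (
        cls["min_p_conditional"] < down_thr
    )
    cls = cls.merge(overlap, on="gene", how="left")
    cls = cls.merge(cascade_cls, on="gene", how="left")
    cls["rare_driven"] = cls["rare_driven"].notna() & cls["rare_driven"].eq(True)

    return DiscoveryResult(
        primary=primary,
        primary_threshold=thr,
        downstream_threshold=down_thr,
        significant_genes=sig_genes,
        gwas_scan=scan,
        leads=leads,
        loci=loci,
        overlap=overlap,
        conditional=conditional,
        cascade=cascade,
        classification=cls,
    )
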