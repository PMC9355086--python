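"""In-memory cohort container shared by every pipeline stage.

A :class:`CohortData` bundles the genotype dosage matrix with three
aligned tables: per-variant annotation, per-sample phenotype/covariates,
and gene intervals.  All downstream stages (annotation filtering, the
kernel association engine, the single-marker scan, the discovery
pipeline) read from this one hub and never re-parse files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Covariates used in every null model, in design-matrix order.
COVARIATE_COLUMNS = ["age", "sex", "bmi", "smoking", "pc1", "pc2", "pc3", "pc4", "pc5"]

#: Columns required in the variant table.
VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "consequence", "cadd", "gene"]

#: Columns required in the gene table (1-based inclusive coordinates).
GENE_COLUMNS = ["gene", "chrom", "start", "stop"]


@dataclass
class CohortData:
    """Genotypes plus aligned variant, sample, and gene tables.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_variants)`` array of alt-allele dosages in
        ``{0, 1, 2}`` with ``NaN`` marking missing calls.  Stored as
        float32 to keep large simulated cohorts affordable; analysis
        code promotes slices to float64.
    variants
        One row per genotype column, same order, with columns
        :data:`VARIANT_COLUMNS`.
    samples
        One row per genotype row with ``sample_id``, ``phenotype``,
        the :data:`COVARIATE_COLUMNS` and ``stratum``.
    genes
        Gene intervals, 1-based inclusive, columns :data:`GENE_COLUMNS`.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        """Raise ``ValueError`` on shape/column mismatches."""
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x variants matrix")
        if len(self.variants) != self.n_variants:
            raise ValueError(
                f"variant table has {len(self.variants)} rows for "
                f"{self.n_variants} genotype columns"
            )
        if len(self.samples) != self.n_samples:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for "
                f"{self.n_samples} genotype rows"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variant table missing column {col!r}")
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise ValueError(f"gene table missing column {col!r}")
        missing = [c for c in COVARIATE_COLUMNS + ["phenotype"] if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns {missing}")

    # ------------------------------------------------------------------
    def covariate_matrix(self, extra: np.ndarray | None = None) -> np.ndarray:
        """Design matrix: intercept + standard covariates (+ optional extras).

        ``extra`` columns (e.g. lead-SNP dosages for conditional analyses)
        are appended after the standard covariates.
        """
        cols = [np.ones(self.n_samples)]
        for c in COVARIATE_COLUMNS:
            cols.append(self.samples[c].to_numpy(dtype=float))
        X = np.column_stack(cols)
        if extra is not None:
            extra = np.atleast_2d(np.asarray(extra, dtype=float))
            if extra.shape[0] != self.n_samples:
                extra = extra.T
            X = np.hstack([X, extra])
        return X

    def gene_variant_indices(self, gene: str) -> np.ndarray:
        """Column indices of all variants assigned to ``gene``."""
        return np.flatnonzero((self.variants["gene"] == gene).to_numpy())

    def dosages(self, indices: np.ndarray) -> np.ndarray:
        """Float64 dosage slice for the given variant columns."""
        return np.asarray(self.genotypes[:, indices], dtype=np.float64)

    def subset_samples(self, mask: np.ndarray) -> "CohortData":
        """New cohort restricted to samples where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            genotypes=self.genotypes[mask],
            samples=self.samples.loc[mask].reset_index(drop=True),
        )
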