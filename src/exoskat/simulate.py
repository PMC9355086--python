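"""Synthetic cohort generator.

Emulates the data layout of a large whole-exome-sequencing study of a
quantitative blood trait: a skewed site-frequency spectrum containing
both very rare (MAF < 0.1%) and common variants, VEP-style consequence
classes with CADD-like deleteriousness scores, Hardy-Weinberg genotypes,
covariate-dependent phenotypes, two ancestry strata with mildly
perturbed allele frequencies, and per-gene causal architectures
(rare-driven, common-driven, mixed, or null).  A master seed fully
determines every output, and the generator records a ground-truth
manifest so downstream discovery logic can be scored against it.

The generator deliberately omits linkage disequilibrium between sites:
independent sites are sufficient to exercise every statistic in the
pipeline, and the conditional-analysis machinery is probed by placing a
common causal variant near a rare-driven gene rather than by an LD
model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import COVARIATE_COLUMNS, CohortData

__all__ = [
    "ArchitectureSpec",
    "SimConfig",
    "TruthManifest",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
    "standard_cohort_config",
]

_HIGH_TERMS = (
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_lost",
    "start_lost",
)
_MODERATE_TERMS = (
    "missense_variant",
    "inframe_deletion",
    "inframe_insertion",
    "protein_altering_variant",
)
_OTHER_TERMS = (
    "synonymous_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
)
_BASES = ("A", "C", "G", "T")


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Causal architecture of one gene.

    ``rare`` causal variants have their MAF drawn inside the config's
    rare causal band (below 0.5%) and ``common`` causal variants inside
    the common band (above 1%); effect magnitudes are in phenotype-SD
    units per alt allele, with signs drawn independently per variant.
    """

    label: str
    n_causal_rare: int = 0
    n_causal_common: int = 0
    rare_effect_sd: float = 0.0
    common_effect_sd: float = 0.0

    @staticmethod
    def from_label(label: str) -> "ArchitectureSpec":
        presets = {
            "null": ArchitectureSpec("null"),
            "rare_driven": ArchitectureSpec("rare_driven", n_causal_rare=30, rare_effect_sd=1.2),
            "common_driven": ArchitectureSpec(
                "common_driven", n_causal_common=1, common_effect_sd=0.35
            ),
            "mixed": ArchitectureSpec(
                "mixed", n_causal_rare=12, n_causal_common=1,
                rare_effect_sd=1.0, common_effect_sd=0.3,
            ),
        }
        try:
            return presets[label]
        except KeyError:
            raise ConfigError(f"unknown architecture label {label!r}") from None


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    The defaults describe the package's standard study conditions: 4,000
    samples, 30 genes over four chromosomes, a log-uniform MAF spectrum
    on [1e-5, 0.5], ~94% / 6% ancestry strata, and unit residual noise.
    ``architectures`` maps gene index to a label or
    :class:`ArchitectureSpec`; unlisted genes are null.
    """

    n_samples: int = 4000
    n_genes: int = 30
    variants_per_gene: tuple[int, int] = (12, 20)
    chrom_layout: tuple[tuple[str, int], ...] = (
        ("1", 1_200_000),
        ("2", 1_200_000),
        ("3", 1_200_000),
        ("9", 1_200_000),
    )
    maf_min: float = 1e-5
    maf_max: float = 0.5
    impact_probs: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.08, "moderate": 0.62, "other": 0.30}
    )
    cadd_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "high": (33.0, 6.0),
            "moderate": (22.0, 5.0),
            "other": (6.0, 4.0),
        }
    )
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.004,
            "sex": -0.10,
            "bmi": 0.012,
            "smoking": 0.08,
            "pc1": 0.02,
            "pc2": -0.01,
            "pc3": 0.01,
            "pc4": 0.0,
            "pc5": 0.0,
        }
    )
    architectures: Mapping[int, "str | ArchitectureSpec"] = field(default_factory=dict)
    rare_causal_maf: tuple[float, float] = (0.0001, 0.00025)
    common_causal_maf: tuple[float, float] = (0.15, 0.40)
    stratum_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"EUR": 0.94, "nonEUR": 0.06}
    )
    stratum_maf_log_sd: float = 0.3
    missing_rate: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    # ------------------------------------------------------------------
    def resolved_architectures(self) -> dict[int, ArchitectureSpec]:
        out: dict[int, ArchitectureSpec] = {}
        for idx, spec in self.architectures.items():
            if isinstance(spec, str):
                spec = ArchitectureSpec.from_label(spec)
            out[int(idx)] = spec
        return out

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ConfigError("n_samples and n_genes must be positive")
        lo, hi = self.variants_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError("variants_per_gene must be a positive (lo, hi) range")
        if not (0.0 < self.maf_min < self.maf_max <= 0.5):
            raise ConfigError("need 0 < maf_min < maf_max <= 0.5")
        for name, probs in (("impact_probs", self.impact_probs),
                            ("stratum_fractions", self.stratum_fractions)):
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-8 or any(v < 0 for v in probs.values()):
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        if self.noise_sd < 0 or self.missing_rate < 0 or self.missing_rate >= 1:
            raise ConfigError("noise_sd must be >= 0 and missing_rate in [0, 1)")
        for k, v in self.covariate_effects.items():
            if not np.isfinite(v):
                raise ConfigError(f"covariate effect {k!r} is not finite")
        archs = self.resolved_architectures()
        for idx, spec in archs.items():
            if not 0 <= idx < self.n_genes:
                raise ConfigError(f"architecture refers to gene index {idx} out of range")
            if not np.isfinite(spec.rare_effect_sd) or not np.isfinite(spec.common_effect_sd):
                raise ConfigError(f"gene {idx}: effect parameters must be finite")
            gene = f"GENE{idx:04d}"
            if spec.n_causal_rare > 0:
                lo_r, hi_r = self.rare_causal_maf
                if lo_r < self.maf_min or hi_r > self.maf_max:
                    raise ConfigError(
                        f"gene {gene}: rare_driven architecture requested but the MAF "
                        f"spectrum [{self.maf_min}, {self.maf_max}] excludes the rare "
                        f"causal band [{lo_r}, {hi_r}]"
                    )
            if spec.n_causal_common > 0:
                lo_c, hi_c = self.common_causal_maf
                if lo_c < self.maf_min or hi_c > self.maf_max:
                    raise ConfigError(
                        f"gene {gene}: common_driven architecture requested but the MAF "
                        f"spectrum excludes the common causal band [{lo_c}, {hi_c}]"
                    )
            if spec.n_causal_rare + spec.n_causal_common > lo:
                raise ConfigError(
                    f"gene {gene}: {spec.n_causal_rare + spec.n_causal_common} causal "
                    f"variants requested but genes may have as few as {lo} variants"
                )

    @staticmethod
    def from_dict(d: Mapping) -> "SimConfig":
        d = dict(d)
        if "variants_per_gene" in d:
            v = d["variants_per_gene"]
            d["variants_per_gene"] = (v, v) if isinstance(v, int) else tuple(v)
        if "chrom_layout" in d:
            d["chrom_layout"] = tuple((str(c), int(s)) for c, s in d["chrom_layout"])
        for key in ("rare_causal_maf", "common_causal_maf"):
            if key in d:
                d[key] = tuple(d[key])
        if "architectures" in d:
            d["architectures"] = {int(k): v for k, v in dict(d["architectures"]).items()}
        return SimConfig(**d)


@dataclass
class TruthManifest:
    """Ground truth behind a generated cohort."""

    architectures: dict[str, str]
    causal_variants: list[dict]
    covariate_effects: dict[str, float]
    stratum_counts: dict[str, int]
    seed: int

    def causal_ids(self, gene: str | None = None) -> list[str]:
        return [
            c["variant_id"] for c in self.causal_variants if gene is None or c["gene"] == gene
        ]

    def genes_with(self, label: str) -> list[str]:
        return sorted(g for g, l in self.architectures.items() if l == label)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "TruthManifest":
        return TruthManifest(**json.loads(text))


def standard_cohort_config(seed: int = 2026) -> SimConfig:
    """The documented standard synthetic cohort.

    10,000 samples; 30 genes over four chromosomes: two rare-driven, two
    common-driven, one mixed, 25 null.  Gene 3 (rare-driven) and gene 7
    (common-driven) share chromosome 9 about 1.2 Mb apart, so a rare
    signal sits next to a common GWAS lead — the configuration the
    conditional analysis must disentangle.  Rare causal variants sit at
    MAF 0.01-0.025% — below the weighted schemes' rare cutoff, where the
    frequency weights concentrate — with 1.2-SD per-allele effects; gene
    size, sample size and effect scale were fixed together by a power
    analysis so the rare architectures are detectable at Bonferroni
    stringency.
    """
    return SimConfig(
        n_samples=10_000,
        variants_per_gene=(50, 70),
        architectures={
            0: "rare_driven",
            3: "rare_driven",
            7: "common_driven",
            12: "common_driven",
            18: "mixed",
        },
        seed=seed,
    )


# ----------------------------------------------------------------------
# Generation
# ----------------------------------------------------------------------
def _log_uniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_cohort(config: SimConfig) -> tuple[CohortData, TruthManifest]:
    """Generate a cohort and its ground-truth manifest.

    Genotypes are Binomial(2, maf) per variant and sample (Hardy-Weinberg
    proportions), with stratum-specific allele frequencies for nonEUR
    samples obtained by jittering the EUR MAF on the log scale.  The
    phenotype is the covariate linear predictor plus the causal genetic
    component plus Gaussian noise.  Identical configs and seeds give
    byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    archs = config.resolved_architectures()

    # --- gene intervals -------------------------------------------------
    layout = config.chrom_layout
    gene_rows = []
    for i in range(config.n_genes):
        chrom, spacing = layout[i % len(layout)]
        j = i // len(layout)
        start = 1_000_000 + j * spacing
        length = int(rng.integers(5_000, 50_000))
        gene_rows.append({"gene": f"GENE{i:04d}", "chrom": chrom,
                          "start": start, "stop": start + length - 1})
    genes = pd.DataFrame(gene_rows)

    # --- variants -------------------------------------------------------
    lo, hi = config.variants_per_gene
    counts = rng.integers(lo, hi + 1, config.n_genes)
    impact_labels = list(config.impact_probs)
    impact_p = np.array([config.impact_probs[k] for k in impact_labels], dtype=float)

    var_rows = []
    causal_records = []
    causal_cols: list[int] = []
    causal_effects: list[float] = []
    col = 0
    maf_eur_all: list[float] = []
    for i, g in genes.iterrows():
        m = int(counts[i])
        span = g["stop"] - g["start"] + 1
        offsets = np.sort(rng.choice(span, size=min(m, span), replace=False))
        m = len(offsets)
        maf = _log_uniform(rng, config.maf_min, config.maf_max, m)
        impact = rng.choice(impact_labels, size=m, p=impact_p)
        cadd = np.empty(m)
        for cls, (mu, sd) in config.cadd_params.items():
            sel = impact == cls
            cadd[sel] = np.clip(rng.normal(mu, sd, int(sel.sum())), 0.01, 99.0)
        consequence = np.empty(m, dtype=object)
        for cls, terms in (("high", _HIGH_TERMS), ("moderate", _MODERATE_TERMS),
                           ("other", _OTHER_TERMS)):
            sel = impact == cls
            consequence[sel] = rng.choice(terms, size=int(sel.sum()))
        ref = rng.choice(_BASES, size=m)
        alt = np.array([rng.choice([b for b in _BASES if b != r]) for r in ref])

        spec = archs.get(i, ArchitectureSpec("null"))
        n_causal = spec.n_causal_rare + spec.n_causal_common
        if n_causal > m:
            raise ConfigError(
                f"gene {g['gene']}: {n_causal} causal variants requested but only "
                f"{m} variant sites fit in the gene"
            )
        if n_causal:
            chosen = rng.choice(m, size=n_causal, replace=False)
            rare_idx = chosen[: spec.n_causal_rare]
            common_idx = chosen[spec.n_causal_rare:]
            # Causal variants are placed in the requested frequency band and
            # forced to a qualifying (moderate-impact) consequence so they
            # survive the gene-test inclusion filter.
            for idx_set, band, eff in (
                (rare_idx, config.rare_causal_maf, spec.rare_effect_sd),
                (common_idx, config.common_causal_maf, spec.common_effect_sd),
            ):
                for v in idx_set:
                    maf[v] = _log_uniform(rng, band[0], band[1], 1)[0]
                    if impact[v] == "other":
                        impact[v] = "moderate"
                        consequence[v] = "missense_variant"
                        mu, sd = config.cadd_params["moderate"]
                        cadd[v] = float(np.clip(rng.normal(mu, sd), 0.01, 99.0))
                    effect = eff * (1.0 if rng.random() < 0.5 else -1.0)
                    causal_cols.append(col + v)
                    causal_effects.append(effect)
                    causal_records.append(
                        {"gene": g["gene"], "variant_index": int(col + v),
                         "effect": float(effect), "maf": float(maf[v])}
                    )

        for v in range(m):
            var_rows.append(
                {
                    "id": f"v{col + v:06d}",
                    "chrom": g["chrom"],
                    "pos": int(g["start"] + offsets[v]),
                    "ref": ref[v],
                    "alt": alt[v],
                    "consequence": consequence[v],
                    "cadd": float(cadd[v]),
                    "gene": g["gene"],
                }
            )
        maf_eur_all.extend(maf.tolist())
        col += m

    variants = pd.DataFrame(var_rows)
    n_var = len(variants)
    maf_eur = np.array(maf_eur_all)

    for rec in causal_records:
        rec["variant_id"] = variants["id"].iloc[rec.pop("variant_index")]

    # --- strata and stratum-specific allele frequencies -----------------
    strat_labels = list(config.stratum_fractions)
    strat_p = np.array([config.stratum_fractions[k] for k in strat_labels], dtype=float)
    stratum = rng.choice(strat_labels, size=config.n_samples, p=strat_p)
    jitter = rng.normal(0.0, config.stratum_maf_log_sd, n_var)
    maf_noneur = np.clip(np.exp(np.log(maf_eur) + jitter), config.maf_min / 10, 0.5)

    # --- genotypes ------------------------------------------------------
    n = config.n_samples
    is_noneur = stratum == "nonEUR"
    G = np.empty((n, n_var), dtype=np.float32)
    chunk = max(1, 4_000_000 // max(n, 1))
    for a in range(0, n_var, chunk):
        b = min(a + chunk, n_var)
        P = np.where(is_noneur[:, None], maf_noneur[a:b][None, :], maf_eur[a:b][None, :])
        G[:, a:b] = rng.binomial(2, P).astype(np.float32)

    genetic = np.zeros(n)
    for c, eff in zip(causal_cols, causal_effects):
        genetic += eff * G[:, c].astype(float)

    if config.missing_rate > 0:
        mask = rng.random((n, n_var)) < config.missing_rate
        G[mask] = np.nan

    # --- covariates and phenotype --------------------------------------
    samples = pd.DataFrame({"sample_id": [f"S{k:06d}" for k in range(n)]})
    samples["age"] = rng.uniform(38, 72, n)
    samples["sex"] = (rng.random(n) < 0.55).astype(int)
    samples["bmi"] = rng.normal(27.0, 4.0, n)
    samples["smoking"] = (rng.random(n) < 0.30).astype(int)
    pcs = rng.normal(0.0, 1.0, (n, 5))
    pcs[:, 0] += 2.0 * is_noneur
    for k in range(5):
        samples[f"pc{k + 1}"] = pcs[:, k]
    samples["stratum"] = stratum

    linear = np.zeros(n)
    for name, coef in config.covariate_effects.items():
        linear += coef * samples[name].to_numpy(dtype=float)
    noise = config.noise_sd * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
    samples.insert(1, "phenotype", linear + genetic + noise)

    cohort = CohortData(G, variants, samples, genes)
    cohort.validate()
    truth = TruthManifest(
        architectures={
            genes["gene"].iloc[i]: archs.get(i, ArchitectureSpec("null")).label
            for i in range(config.n_genes)
        },
        causal_variants=causal_records,
        covariate_effects=dict(config.covariate_effects),
        stratum_counts={k: int((stratum == k).sum()) for k in strat_labels},
        seed=config.seed,
    )
    for rec in truth.causal_variants:
        assert rec["variant_id"] in set(variants["id"])
    return cohort, truth


# ----------------------------------------------------------------------
# I/O: VCF + TSV + BED + JSON
# ----------------------------------------------------------------------
_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])


def write_cohort(cohort: CohortData, outdir, truth: TruthManifest | None = None) -> dict:
    """Write a cohort as text files and return the path map.

    Emits ``genotypes.vcf`` (VCFv4.2, GT field, ``./.`` for missing),
    ``variants.tsv`` (id, gene, consequence, cadd), ``samples.tsv``
    (phenotype, covariates, stratum), ``genes.bed`` (0-based half-open)
    and, when provided, ``truth.json``.  Variant records are written in
    cohort column order so a read-back reproduces the matrix exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "variants": outdir / "variants.tsv",
        "samples": outdir / "samples.tsv",
        "genes": outdir / "genes.bed",
    }

    codes = np.asarray(cohort.genotypes, dtype=float)
    idx = np.where(np.isnan(codes), 3, codes).astype(int)
    gt = _GT_STRINGS[idx]  # (n_samples, n_variants)

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exoskat-simulate\n")
        for chrom in dict.fromkeys(cohort.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        sample_ids = list(cohort.samples["sample_id"].astype(str))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        v = cohort.variants
        for j in range(cohort.n_variants):
            row = v.iloc[j]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gt[:, j]) + "\n"
            )

    cohort.variants[["id", "gene", "consequence", "cadd"]].to_csv(
        paths["variants"], sep="\t", index=False
    )
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:
        for _, g in cohort.genes.iterrows():
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['stop']}\t{g['gene']}\n")
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(truth.to_json())
    return paths


def load_cohort(outdir) -> tuple[CohortData, TruthManifest | None]:
    """Read a cohort previously written by :func:`write_cohort`.

    Genotypes are parsed with cyvcf2 (an independent VCF reader), so the
    round-trip doubles as a format check.
    """
    from cyvcf2 import VCF

    outdir = Path(outdir)
    vcf = VCF(str(outdir / "genotypes.vcf"), gts012=True)
    rows = []
    dosage_cols = []
    for rec in vcf:
        rows.append(
            {"id": rec.ID, "chrom": rec.CHROM, "pos": rec.POS,
             "ref": rec.REF, "alt": rec.ALT[0] if rec.ALT else "."}
        )
        d = rec.gt_types.astype(np.float32)
        d[d == 3] = np.nan
        dosage_cols.append(d)
    vcf.close()

    genotypes = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((0, 0), dtype=np.float32)
    )
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    ann = pd.read_csv(outdir / "variants.tsv", sep="\t", dtype={"id": str, "gene": str})
    variants = variants.merge(ann, on="id", how="left") if len(variants) else variants.reindex(
        columns=["id", "chrom", "pos", "ref", "alt", "gene", "consequence", "cadd"]
    )
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
    if genotypes.size == 0:
        genotypes = np.empty((len(samples), 0), dtype=np.float32)

    bed = pd.read_csv(
        outdir / "genes.bed", sep="\t", header=None,
        names=["chrom", "bed_start", "bed_stop", "gene"], dtype={"chrom": str},
    )
    genes = pd.DataFrame(
        {"gene": bed["gene"], "chrom": bed["chrom"],
         "start": bed["bed_start"] + 1, "stop": bed["bed_stop"]}
    )

    truth = None
    truth_path = outdir / "truth.json"
    if truth_path.exists():
        truth = TruthManifest.from_json(truth_path.read_text())

    cohort = CohortData(genotypes, variants, samples, genes)
    cohort.validate()
    return cohort, truth
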