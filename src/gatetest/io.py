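"""File formats, quality control and the multi-variant scan driver.

Phenotypes are a TSV with a sample-ID first column and one header-named
column per trait; genotypes are either a variant-major TSV (rows = variants,
columns = samples, additive dosages 0/1/2, NA for missing) or a VCF whose GT
fields are converted to ALT-allele counts.  QC follows the usual order for
this kind of study: drop over-missing traits, then samples with any remaining
missing phenotype, then variants by missingness and folded MAF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NullDistribution, gate_pvalue, gate_statistic
from . import comparators as cmp
from .pca import TraitMatrix, pca
from .wald import GenotypeVector, wald_statistics

log = logging.getLogger("gatetest")

__all__ = ["ScanConfig", "read_phenotypes", "read_genotypes", "qc_filter",
           "run_scan", "write_scan_results"]


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV -> samples x traits DataFrame (NaN marks missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric phenotype entry in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def _read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df = df.astype(float)
    bad = df.stack().dropna()
    if not bad.isin([0.0, 1.0, 2.0]).all():
        raise ValueError(f"genotype entries outside {{0,1,2,NA}} in {path}")
    df.columns = df.columns.astype(str)
    return df


def _read_genotypes_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional dependency, imported on demand

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record {var.ID or var.POS}")
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = var.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3],
                           [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dosage)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    return pd.DataFrame(rows, index=ids, columns=samples, dtype=float)


def read_genotypes(path, format: str = "tsv") -> pd.DataFrame:
    """Genotypes -> variants x samples DataFrame of additive dosages."""
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def align_samples(pheno: pd.DataFrame, geno: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to the shared sample IDs, in phenotype order."""
    shared = [s for s in pheno.index if s in set(geno.columns)]
    if not shared:
        missing = list(pheno.index[:5])
        raise ValueError(
            f"no shared sample IDs between phenotypes and genotypes "
            f"(first phenotype IDs: {missing})")
    return pheno.loc[shared], geno[shared]


def qc_filter(pheno: pd.DataFrame, geno: pd.DataFrame,
              trait_miss: float = 0.01, var_miss: float = 0.15,
              maf_floor: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Quality control in the fixed order traits -> samples -> variants.

    1. drop traits with missingness > ``trait_miss``;
    2. drop samples with any remaining missing phenotype;
    3. drop variants (on the retained samples) with missingness >
       ``var_miss`` or folded MAF < ``maf_floor``.
    """
    report = {"traits_in": pheno.shape[1], "samples_in": pheno.shape[0],
              "variants_in": geno.shape[0]}
    keep_traits = pheno.isna().mean(axis=0) <= trait_miss
    pheno = pheno.loc[:, keep_traits]
    report["traits_dropped"] = int((~keep_traits).sum())

    keep_samples = pheno.notna().all(axis=1)
    pheno = pheno.loc[keep_samples]
    report["samples_dropped"] = int((~keep_samples).sum())

    geno = geno[pheno.index]
    miss = geno.isna().mean(axis=1)
    freq = geno.mean(axis=1, skipna=True) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_vars = (miss <= var_miss) & (maf >= maf_floor)
    report["variants_dropped_missing"] = int((miss > var_miss).sum())
    report["variants_dropped_maf"] = int(
        ((miss <= var_miss) & (maf < maf_floor)).sum())
    geno = geno.loc[keep_vars]
    report["traits_out"] = pheno.shape[1]
    report["samples_out"] = pheno.shape[0]
    report["variants_out"] = geno.shape[0]
    if pheno.empty or pheno.shape[1] < 2 or geno.empty:
        raise ValueError(f"QC left no analyzable data: {report}")
    log.info("QC report: %s", report)
    return pheno, geno, report


@dataclass
class ScanConfig:
    """Configuration of a multi-variant association scan."""

    pheno_path: str
    geno_path: str
    geno_format: str = "tsv"
    covar_path: str | None = None
    methods: tuple = ("GATE",)
    B: int = 10000
    k_max: int = 2
    alpha: float = 0.05
    seed: int = 0
    trait_miss: float = 0.01
    var_miss: float = 0.15
    maf_floor: float = 0.05
    out_path: str | None = None
    cache_dir: str | None = None
    paper_formula: bool = False
    impute_missing: bool = True   # mean-impute retained variants' missing calls
    report: dict = field(default_factory=dict)


def _variant_dosage(row: np.ndarray, impute: bool) -> np.ndarray | None:
    """Resolve missing calls for one retained variant.

    Mean imputation (the default) keeps the per-variant sample set identical
    to the PCA sample set, which the shared GATE null assumes; returning None
    signals a complete-case caller to subset samples instead.
    """
    if not np.isnan(row).any():
        return row
    if impute:
        filled = row.copy()
        filled[np.isnan(row)] = np.nanmean(row)
        return filled
    return None


def run_scan(config: ScanConfig) -> pd.DataFrame:
    """QC, PCA once, then per-variant tests; one output row per variant."""
    pheno = read_phenotypes(config.pheno_path)
    geno = read_genotypes(config.geno_path, config.geno_format)
    pheno, geno = align_samples(pheno, geno)
    pheno, geno, report = qc_filter(
        pheno, geno, config.trait_miss, config.var_miss, config.maf_floor)
    config.report = report

    covar = None
    if config.covar_path:
        covar_df = read_phenotypes(config.covar_path).loc[pheno.index]
        if covar_df.isna().any().any():
            raise ValueError("missing covariate values for retained samples")
        covar = covar_df.to_numpy()

    traits = TraitMatrix(pheno.to_numpy(), sample_ids=list(pheno.index),
                         trait_ids=list(pheno.columns))
    decomp = pca(traits)
    trait_corr = np.corrcoef(traits.values, rowvar=False)

    null = None
    if "GATE" in config.methods:
        null = NullDistribution.cached(traits.m, config.k_max, config.B,
                                       config.seed, config.cache_dir)

    rows = []
    for variant_id, row in geno.iterrows():
        dosage = _variant_dosage(row.to_numpy(dtype=float),
                                 config.impute_missing)
        if dosage is None:
            # complete-case mode: drop samples with a missing call here
            keep = ~np.isnan(row.to_numpy(dtype=float))
            sub_traits = TraitMatrix(traits.values[keep])
            sub = {"traits": sub_traits, "decomp": pca(sub_traits),
                   "g": row.to_numpy(dtype=float)[keep],
                   "covar": None if covar is None else covar[keep]}
        else:
            sub = {"traits": traits, "decomp": decomp, "g": dosage,
                   "covar": covar}
        try:
            gv = GenotypeVector(sub["g"], variant_id=str(variant_id))
            out = {"variant": str(variant_id), "maf": gv.maf}
            wald = None
            if {"GATE", "FCT", "mCPC"} & set(config.methods):
                wald = wald_statistics(sub["decomp"], gv, sub["covar"])
            if "GATE" in config.methods:
                res = gate_statistic(wald.t, null)
                gate_pvalue(res, null, paper_formula=config.paper_formula)
                out["GATE_eta0"] = res.eta0
                out["GATE_p"] = res.p_value
                for k, info in res.per_k.items():
                    out[f"GATE_K{k}_xi"] = info["xi"]
                    out[f"GATE_K{k}_comp"] = ",".join(
                        map(str, info["composition"]))
            if "FCT" in config.methods:
                r = cmp.fct_test(wald)
                out["FCT_stat"], out["FCT_p"] = r.statistic, r.p_value
            if "mCPC" in config.methods:
                r = cmp.mcpc_test(wald, sub["decomp"].eigenvalues)
                out["mCPC_stat"], out["mCPC_p"] = r.statistic, r.p_value
            if "MANOVA" in config.methods:
                r = cmp.manova_test(sub["traits"], gv)
                out["MANOVA_wilks"], out["MANOVA_p"] = r.statistic, r.p_value
            if "TATES" in config.methods:
                up = cmp.univariate_trait_tests(sub["traits"], gv)
                corr = trait_corr if dosage is not None else np.corrcoef(
                    sub["traits"].values, rowvar=False)
                r = cmp.tates_test(up, corr)
                out["TATES_p"] = r.p_value
            if "MultiPhen" in config.methods:
                r = cmp.multiphen_test(sub["traits"], gv)
                out["MultiPhen_stat"], out["MultiPhen_p"] = (r.statistic,
                                                             r.p_value)
            rows.append(out)
        except Exception as exc:  # per-variant failures do not stop the scan
            log.warning("variant %s failed: %s", variant_id, exc)
            rows.append({"variant": str(variant_id), "error": str(exc)})
    results = pd.DataFrame(rows)
    if config.out_path:
        write_scan_results(results, config)
    return results


def write_scan_results(results: pd.DataFrame, config: ScanConfig) -> None:
    """TSV output with a provenance header and the Bonferroni threshold."""
    n_var = int(results["variant"].notna().sum())
    with open(config.out_path, "w") as fh:
        fh.write(f"# gatetest scan: {config.geno_path} x {config.pheno_path}\n")
        fh.write(f"# methods={','.join(config.methods)} B={config.B} "
                 f"k_max={config.k_max} seed={config.seed}\n")
        fh.write(f"# QC: {config.report}\n")
        if n_var:
            fh.write(f"# Bonferroni-adjusted significance threshold: "
                     f"{config.alpha}/{n_var} = {config.alpha / n_var:.3g}\n")
        results.to_csv(fh, sep="\t", index=False)
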