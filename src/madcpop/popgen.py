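"""Dosage calling, genotype/phenotype PCA, and Weir–Cockerham FST.

Diploid dosages are maximum-likelihood calls under binomial read sampling with
a per-read error rate; population differentiation uses the Weir & Cockerham
(1984) method-of-moments decomposition into variance components a (among
populations), b (among individuals within populations) and c (within
individuals), with the weighted mean FST = Σa / Σ(a+b+c) pooled over SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snps import VariantRecord

logger = logging.getLogger(__name__)

MISSING = np.nan


@dataclass
class DosageMatrix:
    """Samples x SNPs alternate-allele dosage: 0/1/2 or NaN (missing)."""

    values: pd.DataFrame
    min_depth: int
    error_rate: float

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.columns)


def call_dosage(
    variants: list[VariantRecord],
    samples: list[str],
    min_depth: int = 10,
    error_rate: float = 0.01,
) -> DosageMatrix:
    """ML diploid dosage from allele depths.

    Each SNP is collapsed to biallelic: the most-read alternate vs everything
    else.  With a alt reads out of n, the three genotypes imply alt-read
    fractions {ε, 1/2, 1−ε}; the dosage with the highest binomial likelihood is
    called, ties resolved to the heterozygote.  Samples with DP below
    ``min_depth`` are missing.
    """
    eps = error_rate
    fractions = np.array([eps, 0.5, 1.0 - eps])
    cols = {}
    for v in variants:
        n = v.ad.sum(axis=1).astype(np.float64)
        alt = v.ad[:, 1].astype(np.float64) if v.ad.shape[1] > 1 else np.zeros_like(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = alt[:, None] * np.log(fractions) + (n - alt)[:, None] * np.log(1.0 - fractions)
        # ties -> heterozygote: scan dosages in order 1, 0, 2 and keep the best
        best = np.full(len(n), 1)
        best_ll = ll[:, 1].copy()
        for d in (0, 2):
            better = ll[:, d] > best_ll + 1e-12
            best[better] = d
            best_ll[better] = ll[better, d]
        dosage = best.astype(np.float64)
        dosage[n < min_depth] = MISSING
        cols[v.vcf_id] = dosage
    values = pd.DataFrame(cols, index=list(samples))
    return DosageMatrix(values, min_depth, error_rate)


def _pca(matrix: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered SVD PCA with a fixed sign convention (largest-|loading| positive)."""
    centered = matrix - matrix.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    total_var = float((s**2).sum())
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, frac


def genotype_pca(dm: DosageMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the dosage matrix with per-SNP mean imputation of missing calls."""
    values = dm.values.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("genotype_pca needs >=2 samples and >=2 SNPs")
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        logger.info("genotype_pca: dropping %d all-missing SNP(s)", int(all_missing.sum()))
        values = values[:, ~all_missing]
    n_missing = int(np.isnan(values).sum())
    col_means = np.nanmean(values, axis=0)
    idx = np.where(np.isnan(values))
    values[idx] = col_means[idx[1]]
    if n_missing:
        logger.info("genotype_pca: mean-imputed %.2f%% of entries", 100 * n_missing / values.size)
    scores, frac = _pca(values, n_components)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=dm.values.index, columns=cols), frac


def phenotype_pca(
    traits: pd.DataFrame, complete_cases_only: bool = True, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a mixed categorical/quantitative descriptor table.

    Categorical traits expand to full one-hot indicator columns; all columns
    are standardised to unit variance; rows with any missing trait are dropped
    when ``complete_cases_only``.
    """
    df = traits.dropna(axis=0, how="any") if complete_cases_only else traits.copy()
    cat_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    encoded = pd.get_dummies(df, columns=cat_cols, prefix_sep="=", dtype=float)
    variances = encoded.var(axis=0, ddof=0)
    zero_var = variances[variances == 0].index
    if len(zero_var):
        logger.info("phenotype_pca: dropping %d zero-variance column(s)", len(zero_var))
        encoded = encoded.drop(columns=zero_var)
    standardised = (encoded - encoded.mean()) / encoded.std(ddof=0)
    scores, frac = _pca(standardised.to_numpy(dtype=float), n_components)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=df.index, columns=cols), frac


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    snp_ids: list[str]
    a: np.ndarray  # among-population variance component per SNP
    b: np.ndarray  # among-individual-within component
    c: np.ndarray  # within-individual component
    weighted: float  # Σa / Σ(a+b+c)

    @property
    def per_snp(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def weir_components(dosages: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) a, b, c per SNP from per-population dosage arrays.

    Each array is (n_individuals, n_snps) with values 0/1/2/NaN.  SNPs lacking
    two genotyped individuals in any population get NaN components.
    """
    r = len(dosages)
    n_i = np.stack([(~np.isnan(d)).sum(axis=0) for d in dosages]).astype(float)  # r x m
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nansum(d, axis=0) for d in dosages]) / (2.0 * n_i)
        h_i = np.stack([np.nansum(d == 1, axis=0) for d in dosages]) / n_i
    valid = (n_i >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n_i.sum(axis=0)
        nbar = n_sum / r
        nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    for comp in (a, b, c):
        comp[~valid] = np.nan
    return a, b, c


def weir_fst(dm: DosageMatrix, labels: pd.Series, pop_a: str, pop_b: str) -> FstResult:
    """Pairwise weighted Weir–Cockerham FST between two labelled populations.

    ``labels`` maps sample id -> population label; samples with other labels
    are ignored.  Weighted mean = Σa / Σ(a+b+c) over SNPs with defined,
    non-zero denominator (monomorphic SNPs contribute nothing).
    """
    groups = []
    for pop in (pop_a, pop_b):
        ids = [s for s in dm.samples if labels.get(s) == pop]
        if len(ids) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples in the dosage matrix")
        sub = dm.values.loc[ids].to_numpy(dtype=float)
        if np.isnan(sub).all():
            raise ValueError(f"population {pop!r} has no genotypes")
        groups.append(sub)
    a, b, c = weir_components(groups)
    denom = a + b + c
    use = ~np.isnan(denom) & (denom != 0)
    weighted = float(a[use].sum() / denom[use].sum()) if use.any() else float("nan")
    return FstResult(pop_a, pop_b, dm.snp_ids, a, b, c, weighted)


def fst_matrix(dm: DosageMatrix, metadata: pd.DataFrame, level: str = "species") -> pd.DataFrame:
    """All pairwise weighted FST among species (or source-within-species) groups.

    Pairs lacking two genotyped samples on either side are reported missing
    (NaN; rendered as '–' in exported tables).  Diagonal is 0.
    """
    meta = metadata.set_index("sample_id")
    if level == "species":
        labels = meta["species"]
    elif level == "source":
        labels = meta["species"] + "/" + meta["source"]
    else:
        raise ValueError("level must be 'species' or 'source'")
    labels = labels.reindex(dm.samples)
    groups = sorted(labels.dropna().unique())
    out = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for g in groups:
        out.loc[g, g] = 0.0
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            try:
                res = weir_fst(dm, labels, ga, gb)
            except ValueError:
                logger.info("fst_matrix: pair (%s, %s) lacks samples, reported missing", ga, gb)
                continue
            out.loc[ga, gb] = out.loc[gb, ga] = res.weighted
    return out
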