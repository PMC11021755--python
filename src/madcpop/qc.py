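"""Microhaplotype-level cleaning and single-plant vs bulked-sample diversity accounting.

Counts with read depth 1 are treated as sequencing errors and zeroed; a
sample's genetic diversity is summarised as its number of surviving
microhaplotypes.  Each accession's three single-plant replicates are compared
against its 7-plant bulk (median single count vs bulk count), optionally after
pooling the singles' reads into one consolidated pseudo-sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import MadcTable, ROLE_BULK, ROLE_SINGLE

logger = logging.getLogger(__name__)


class InsufficientReplicatesError(ValueError):
    pass


def zero_singletons(table: MadcTable) -> MadcTable:
    """Set every read count of exactly 1 to 0 (depth-1 observations are treated
    as sequencing error); idempotent."""
    out = table.copy()
    values = out.counts.to_numpy()
    values[values == 1] = 0
    out.counts = pd.DataFrame(values, index=out.counts.index, columns=out.counts.columns)
    return out


def count_microhaplotypes(table: MadcTable, sample_id: str) -> int:
    """Number of microhaplotype records with a positive count for one sample."""
    if sample_id not in table.counts.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    return int((table.counts[sample_id] > 0).sum())


def _singles_of(metadata: pd.DataFrame, accession_id: str) -> list[str]:
    sel = (metadata["accession_id"] == accession_id) & (metadata["role"] == ROLE_SINGLE)
    return metadata.loc[sel, "sample_id"].tolist()


def consolidate_singles(table: MadcTable, metadata: pd.DataFrame, accession_id: str) -> pd.Series:
    """Pool the accession's single-plant samples (sum of read counts), then
    re-apply singleton zeroing so the pooled pseudo-sample faces the same error
    model as any real sample."""
    singles = _singles_of(metadata, accession_id)
    singles = [s for s in singles if s in table.counts.columns]
    if len(singles) < 2:
        raise InsufficientReplicatesError(f"{accession_id}: needs >=2 single-plant samples, has {len(singles)}")
    pooled = table.counts[singles].sum(axis=1)
    pooled[pooled == 1] = 0
    pooled.name = f"{accession_id}_consolidated"
    return pooled


@dataclass(frozen=True)
class DiversityRecord:
    accession_id: str
    median_single_count: int
    bulk_count: int
    consolidated_count: int
    delta: int  # bulk_count - median_single_count


def compare_single_vs_bulk(table: MadcTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """One row per accession with 3 singles + 1 bulk: median single-sample
    microhaplotype count, bulk count, consolidated-singles count, and the
    bulk-minus-median delta.  Ineligible accessions are skipped (logged)."""
    positive = table.counts > 0
    per_sample = positive.sum(axis=0)
    rows = []
    skipped = 0
    for accession_id, grp in metadata.groupby("accession_id", sort=True):
        singles = grp.loc[grp["role"] == ROLE_SINGLE, "sample_id"].tolist()
        bulks = grp.loc[grp["role"] == ROLE_BULK, "sample_id"].tolist()
        if len(singles) != 3 or len(bulks) != 1:
            skipped += 1
            continue
        counts = sorted(int(per_sample[s]) for s in singles)
        median_single = counts[1]
        bulk_count = int(per_sample[bulks[0]])
        consolidated = int((consolidate_singles(table, metadata, accession_id) > 0).sum())
        rows.append(
            {
                "accession_id": accession_id,
                "median_single_count": median_single,
                "bulk_count": bulk_count,
                "consolidated_count": consolidated,
                "delta": bulk_count - median_single,
            }
        )
    if skipped:
        logger.info("compare_single_vs_bulk: skipped %d accession(s) without 3 singles + 1 bulk", skipped)
    return pd.DataFrame(rows)


def lowess_trend(records: pd.DataFrame, frac: float = 2 / 3, it: int = 3) -> np.ndarray:
    """LOWESS-smoothed single-plant microhaplotype counts across accessions
    ordered by their bulk count (tricube-weighted local linear fit with
    robustness iterations).  Returns one smoothed value per input row."""
    if len(records) < 5:
        raise ValueError(f"lowess_trend needs >=5 accessions, got {len(records)}")
    ordered = records.sort_values("bulk_count", kind="stable")
    x = np.arange(len(ordered), dtype=float)  # rank along the bulk-count ordering
    y = ordered["median_single_count"].to_numpy(dtype=float)
    smoothed = _sm_lowess(y, x, frac=frac, it=it, return_sorted=False)
    out = np.empty(len(records))
    out[np.argsort(records["bulk_count"].to_numpy(), kind="stable")] = smoothed
    return out


def per_marker_hap_proportion(table: MadcTable, metadata: pd.DataFrame, group: str) -> pd.Series:
    """Mean observed microhaplotype count per locus in the chosen replicate
    group ('singles' or 'bulks'), scaled by the total number of distinct
    microhaplotypes of that locus across the entire population (range [0,1])."""
    role = {"singles": ROLE_SINGLE, "bulks": ROLE_BULK}[group]
    samples = metadata.loc[metadata["role"] == role, "sample_id"].tolist()
    samples = [s for s in samples if s in table.counts.columns]
    positive = table.counts > 0
    pop_total = positive.any(axis=1).groupby(level="locus_id", sort=False).sum()
    observed = positive[samples].groupby(level="locus_id", sort=False).sum()
    keep = pop_total > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("per_marker_hap_proportion: excluded %d locus/loci with no population-wide haplotypes", dropped)
    mean_obs = observed.loc[keep].mean(axis=1)
    return (mean_obs / pop_total.loc[keep]).rename("hap_proportion")


def replicate_correlations(table: MadcTable, metadata: pd.DataFrame, accession_id: str) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-locus total read counts among an
    accession's replicate samples (singles and bulk).  Only loci where at least
    one replicate has reads contribute; zero-variance vectors give NaN."""
    samples = metadata.loc[metadata["accession_id"] == accession_id, "sample_id"].tolist()
    samples = [s for s in samples if s in table.counts.columns]
    if len(samples) < 2:
        raise InsufficientReplicatesError(f"{accession_id}: needs >=2 samples for correlations")
    totals = table.locus_totals()[samples]
    totals = totals.loc[totals.sum(axis=1) > 0]
    corr = totals.corr(method="pearson")  # pandas leaves NaN for zero-variance columns
    for s in corr.columns:
        corr.loc[s, s] = 1.0
    if corr.isna().any().any():
        logger.info("replicate_correlations(%s): zero-variance replicate(s) give undefined entries", accession_id)
    return corr


def mean_replicate_r2(table: MadcTable, metadata: pd.DataFrame) -> float:
    """Average squared Pearson correlation over all replicate pairs of all
    accessions with >=2 samples (reproducibility summary)."""
    r2s = []
    for accession_id in metadata["accession_id"].unique():
        try:
            corr = replicate_correlations(table, metadata, accession_id)
        except InsufficientReplicatesError:
            continue
        vals = corr.to_numpy()
        iu = np.triu_indices_from(vals, k=1)
        pair = vals[iu]
        r2s.extend((pair[~np.isnan(pair)] ** 2).tolist())
    return float(np.mean(r2s)) if r2s else float("nan")
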