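"""Locus presence/missingness filters, presence curves, and the Hind/HE SNP filter.

Presence is strict: a locus has data for a sample when its total read count
exceeds ``min_reads`` (default 10), and a presence-curve entry at t% counts
loci present in more than t% of samples.  Hind/HE is the ratio of
within-individual read-pair heterozygosity to expected heterozygosity,
computed from allele depths without genotype calls: for a diploid outcrosser
it centres on (ploidy−1)/ploidy = 0.5; low values indicate
inbreeding/error-dominated alleles, values above 1 paralog collapse.  SNPs
with ratio in [0.1, 1.0] are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import MadcTable
from .snps import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    values: pd.DataFrame  # loci x samples, bool
    min_reads: int

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def presence_matrix(table: MadcTable, presence_min_reads: int = 10) -> PresenceMatrix:
    """Presence = per-locus total read count strictly greater than the threshold."""
    totals = table.locus_totals()
    return PresenceMatrix(totals > presence_min_reads, presence_min_reads)


def presence_curve(pm: PresenceMatrix, thresholds=range(5, 101, 5)) -> pd.DataFrame:
    """Number of loci present in more than t% of samples, for each threshold t.

    The comparison is strict except at t=100, where it degenerates to
    "present in every sample" (a strict rule would make the last entry
    vacuously zero).
    """
    if len(pm.samples) == 0:
        raise ValueError("presence_curve requires at least one sample")
    frac = pm.values.mean(axis=1)
    rows = [
        {"percent": t, "locus_count": int(((frac >= 1.0) if t >= 100 else (frac > t / 100.0)).sum())}
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def select_common_loci(pm: PresenceMatrix, panel=None, percent: float = 95) -> tuple[list[str], pd.DataFrame]:
    """Loci present in > percent% of samples, with a per-chromosome summary.

    The summary has one row per chromosome: selected count, panel count, and
    their ratio (panel required for chromosome assignments; otherwise empty).
    """
    frac = pm.values.mean(axis=1)
    selected = [l for l in pm.loci if frac[l] > percent / 100.0]
    if not selected:
        logger.warning("select_common_loci: no locus present in >%s%% of samples", percent)
    if panel is None:
        return selected, pd.DataFrame(columns=["chromosome", "selected", "panel", "ratio"])
    chrom = panel.table["chromosome"]
    sel_counts = chrom.loc[[l for l in selected if l in panel]].value_counts().sort_index()
    panel_counts = panel.per_chromosome_counts()
    summary = pd.DataFrame(
        {
            "chromosome": panel_counts.index,
            "selected": [int(sel_counts.get(c, 0)) for c in panel_counts.index],
            "panel": panel_counts.to_numpy(),
        }
    )
    summary["ratio"] = summary["selected"] / summary["panel"]
    return selected, summary


def missingness_by_sample(pm: PresenceMatrix, panel_size: int) -> pd.Series:
    """Missing-locus count per sample: panel size minus present loci."""
    present = pm.values.sum(axis=0)
    if panel_size < present.max():
        raise ValueError("panel_size smaller than observed locus count")
    return (panel_size - present).rename("missing_loci")


def hind_he_sample(ad_row: np.ndarray) -> float:
    """Within-sample read-pair heterozygosity from one allele-depth vector:
    probability that two reads drawn without replacement carry distinct alleles."""
    n = int(ad_row.sum())
    if n < 2:
        return float("nan")
    return float((n * n - np.sum(ad_row.astype(np.int64) ** 2)) / (n * (n - 1)))


def hind_he(variants: list[VariantRecord], sample_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP Hind (mean read-pair heterozygosity over contributing samples),
    HE (1 − Σ p̂², pooled read-fraction frequencies), and their ratio.

    ``sample_mask`` selects contributing samples (e.g. to exclude bulks, whose
    14 allele copies inflate within-sample heterozygosity).  Samples with fewer
    than 2 reads are skipped; monomorphic SNPs get an undefined (NaN) ratio.
    """
    rows = []
    for v in variants:
        ad = v.ad if sample_mask is None else v.ad[np.asarray(sample_mask)]
        n = ad.sum(axis=1)
        contrib = n >= 2
        if contrib.any():
            sub = ad[contrib].astype(np.float64)
            ns = n[contrib].astype(np.float64)
            hind_vals = (ns**2 - (sub**2).sum(axis=1)) / (ns * (ns - 1))
            hind = float(hind_vals.mean())
            pooled = sub.sum(axis=0)
            p = pooled / pooled.sum()
            he = float(1.0 - np.sum(p**2))
        else:
            hind, he = float("nan"), float("nan")
        ratio = hind / he if he and he > 0 else float("nan")
        rows.append(
            {
                "snp_id": v.vcf_id,
                "locus_id": v.locus_id,
                "is_target": v.is_target,
                "n_samples": int(contrib.sum()),
                "hind": hind,
                "he": he,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows).set_index("snp_id")


def filter_by_hindhe(results: pd.DataFrame, low: float = 0.1, high: float = 1.0) -> list[str]:
    """SNP ids with low <= Hind/HE <= high; undefined ratios are dropped."""
    ratio = results["ratio"]
    keep = results.index[(ratio >= low) & (ratio <= high)].tolist()
    logger.info(
        "filter_by_hindhe: retained %d of %d SNPs (%d undefined ratios dropped)",
        len(keep),
        len(results),
        int(ratio.isna().sum()),
    )
    return keep


@dataclass
class SharedSnpReport:
    per_species: dict[str, set]
    unique_counts: pd.Series  # SNPs found in exactly one species
    pairwise: pd.DataFrame  # symmetric intersection counts


def species_shared_snps(dosage: pd.DataFrame, metadata: pd.DataFrame) -> SharedSnpReport:
    """Polymorphic-SNP sets per species and their pairwise intersections.

    A SNP is polymorphic within a species when its samples show at least two
    distinct non-missing dosage classes.  Species with fewer than 2 accessions
    are excluded.
    """
    acc_per_species = metadata.groupby("species")["accession_id"].nunique()
    species = [s for s in acc_per_species.index if acc_per_species[s] >= 2]
    per_species: dict[str, set] = {}
    for s in species:
        samples = [x for x in metadata.loc[metadata["species"] == s, "sample_id"] if x in dosage.index]
        sub = dosage.loc[samples]
        poly = sub.nunique(dropna=True) >= 2
        per_species[s] = set(sub.columns[poly])
    all_sets = list(per_species.items())
    unique = {}
    for s, snps in all_sets:
        others = set().union(*(o for t, o in all_sets if t != s)) if len(all_sets) > 1 else set()
        unique[s] = len(snps - others)
    pairwise = pd.DataFrame(0, index=species, columns=species, dtype=int)
    for s in species:
        pairwise.loc[s, s] = len(per_species[s])
    for a, b in combinations(species, 2):
        n = len(per_species[a] & per_species[b])
        pairwise.loc[a, b] = n
        pairwise.loc[b, a] = n
    return SharedSnpReport(per_species, pd.Series(unique, name="unique_snps"), pairwise)
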