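"""Readers and writers for MADC count tables, panel definitions, and sample metadata.

The MADC ("missing allele discovery counts") report is the per-sample read-count
table produced by targeted amplicon genotyping: every observed microhaplotype
sequence is listed under its marker locus, with one count column per sample.
This module fixes a canonical CSV dialect: three leading columns

    AlleleID   = "<locus_id>|<hap_id>"
    CloneID    = "<locus_id>"
    AlleleSequence = the microhaplotype sequence

followed by one integer column per sample.  Additional annotation columns that
some report versions interleave before the sample block can be named via
``annotation_cols`` and are ignored (logged), so the parser is robust to report
drift.  Panel positions are 1-based (VCF convention); amplicon offsets 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MADC_LEAD_COLS = ("AlleleID", "CloneID", "AlleleSequence")

#: annotation columns seen in public DArT reports; ignored if present
DEFAULT_ANNOTATION_COLS = frozenset(
    {"ClusterConsensusSequence", "CallRate", "OneRatioRef", "OneRatioSnp", "Chrom", "ChromPos"}
)

ROLE_SINGLE = "single"
ROLE_BULK = "bulk"
BULK_PLANT_COUNT = 7


class MadcFormatError(ValueError):
    """Raised when an MADC or panel file violates the documented dialect."""


class MetadataError(ValueError):
    """Raised when sample metadata violates the accession/replicate contract."""


@dataclass(frozen=True)
class MarkerLocus:
    """One targeted amplicon of the panel.

    ``position`` is the 1-based coordinate of the target SNP on ``chromosome``;
    ``target_offset`` is the 0-based offset of that SNP within ``ref_amplicon``.
    """

    locus_id: str
    chromosome: str
    position: int
    ref_amplicon: str
    target_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.target_offset < len(self.ref_amplicon)):
            raise ValueError(
                f"{self.locus_id}: target_offset {self.target_offset} outside amplicon "
                f"of length {len(self.ref_amplicon)}"
            )


class PanelDefinition:
    """The marker panel: locus coordinates plus reference microhaplotype sequences."""

    COLUMNS = ("chromosome", "position", "ref_amplicon", "target_offset")

    def __init__(self, loci: Iterable[MarkerLocus]):
        loci = list(loci)
        ids = [l.locus_id for l in loci]
        if len(set(ids)) != len(ids):
            raise MadcFormatError("duplicate locus_id in panel definition")
        self.table = pd.DataFrame(
            {
                "chromosome": [l.chromosome for l in loci],
                "position": [l.position for l in loci],
                "ref_amplicon": [l.ref_amplicon for l in loci],
                "target_offset": [l.target_offset for l in loci],
            },
            index=pd.Index(ids, name="locus_id"),
        )

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.table.index

    def get(self, locus_id: str) -> MarkerLocus:
        row = self.table.loc[locus_id]
        return MarkerLocus(
            locus_id, row["chromosome"], int(row["position"]), row["ref_amplicon"], int(row["target_offset"])
        )

    def per_chromosome_counts(self) -> pd.Series:
        return self.table["chromosome"].value_counts().sort_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PanelDefinition":
        df = pd.read_csv(path, index_col="locus_id", dtype={"chromosome": str, "ref_amplicon": str})
        return cls(
            MarkerLocus(str(lid), row["chromosome"], int(row["position"]), row["ref_amplicon"], int(row["target_offset"]))
            for lid, row in df.iterrows()
        )


@dataclass
class MadcTable:
    """Per-sample microhaplotype read counts nested under marker loci.

    ``counts`` is indexed by (locus_id, hap_id) with one integer column per
    sample; ``sequences`` shares that index.  ``unknown_loci`` lists loci seen
    in the report but absent from the panel (kept, with coordinates unset).
    """

    counts: pd.DataFrame
    sequences: pd.Series
    panel: PanelDefinition | None = None
    unknown_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.sequences.index):
            raise MadcFormatError("counts and sequences index mismatch")
        if (self.counts.to_numpy() < 0).any():
            raise MadcFormatError("negative read count")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index.get_level_values("locus_id").unique())

    def locus_totals(self) -> pd.DataFrame:
        """Total read count per locus x sample (sum over microhaplotypes)."""
        return self.counts.groupby(level="locus_id", sort=False).sum()

    def copy(self) -> "MadcTable":
        return MadcTable(self.counts.copy(), self.sequences.copy(), self.panel, self.unknown_loci)


def _split_allele_id(allele_id: str) -> tuple[str, str]:
    if "|" not in allele_id:
        raise MadcFormatError(f"AlleleID {allele_id!r} is not of the form '<locus>|<hap>'")
    locus, _, hap = allele_id.partition("|")
    return locus, hap


def read_madc(path, panel: PanelDefinition | None = None, annotation_cols=DEFAULT_ANNOTATION_COLS) -> MadcTable:
    """Parse an MADC CSV.  Never silently drops rows: parsed-vs-input row counts are logged."""
    df = pd.read_csv(path, dtype={c: str for c in MADC_LEAD_COLS})
    for col in MADC_LEAD_COLS:
        if col not in df.columns:
            raise MadcFormatError(f"missing required column {col!r}")
    ignored = [c for c in df.columns if c in annotation_cols]
    if ignored:
        logger.info("ignoring %d annotation column(s): %s", len(ignored), ", ".join(ignored))
    sample_cols = [c for c in df.columns if c not in MADC_LEAD_COLS and c not in annotation_cols]
    if not sample_cols:
        raise MadcFormatError("MADC file contains no sample columns")
    dup = df["AlleleID"][df["AlleleID"].duplicated()]
    if len(dup):
        raise MadcFormatError(f"duplicate AlleleID(s): {', '.join(sorted(set(dup)))}")

    pairs = [_split_allele_id(a) for a in df["AlleleID"]]
    for (locus, _), clone in zip(pairs, df["CloneID"]):
        if locus != clone:
            raise MadcFormatError(f"AlleleID locus {locus!r} disagrees with CloneID {clone!r}")
    index = pd.MultiIndex.from_tuples(pairs, names=("locus_id", "hap_id"))

    counts = df[sample_cols].copy()
    for col in sample_cols:
        numeric = pd.to_numeric(counts[col], errors="coerce")
        if numeric.isna().any() or (numeric % 1 != 0).any():
            bad = df["AlleleID"][numeric.isna() | (numeric % 1 != 0)].iloc[0]
            raise MadcFormatError(f"non-integer count in sample column {col!r} at {bad}")
        counts[col] = numeric.astype(np.int64)
    counts.index = index
    sequences = pd.Series(df["AlleleSequence"].to_numpy(), index=index, name="sequence")

    unknown: tuple[str, ...] = ()
    if panel is not None:
        seen = index.get_level_values("locus_id").unique()
        unknown = tuple(l for l in seen if l not in panel)
        if unknown:
            logger.info("%d locus/loci in MADC absent from panel (kept, unplaced)", len(unknown))
    logger.info("read_madc: %d input rows -> %d parsed records, %d samples", len(df), len(counts), len(sample_cols))
    return MadcTable(counts, sequences, panel=panel, unknown_loci=unknown)


def write_madc(table: MadcTable, path) -> None:
    """Write the canonical MADC CSV: deterministic row order (locus_id, then hap_id)."""
    idx = table.counts.index.sortlevel(["locus_id", "hap_id"])[0]
    out = pd.DataFrame(
        {
            "AlleleID": [f"{l}|{h}" for l, h in idx],
            "CloneID": idx.get_level_values("locus_id"),
            "AlleleSequence": table.sequences.loc[idx].to_numpy(),
        }
    )
    out = pd.concat([out, table.counts.loc[idx].reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    accession_id: str
    species: str
    source: str  # "Collection" | "Genebank"
    role: str  # "single" | "bulk"
    plant_count: int

    def __post_init__(self) -> None:
        if self.role not in (ROLE_SINGLE, ROLE_BULK):
            raise MetadataError(f"{self.sample_id}: unknown role {self.role!r}")
        expected = 1 if self.role == ROLE_SINGLE else BULK_PLANT_COUNT
        if self.plant_count != expected:
            raise MetadataError(
                f"{self.sample_id}: plant_count {self.plant_count} inconsistent with role {self.role!r}"
            )


METADATA_COLUMNS = ("sample_id", "accession_id", "species", "source", "role", "plant_count")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Enforce the replicate design: each accession has at most 3 singles and 1 bulk."""
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise MetadataError(f"metadata missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise MetadataError(f"duplicate sample_id {dup!r}")
    for row in meta.itertuples(index=False):
        SampleInfo(row.sample_id, row.accession_id, row.species, row.source, row.role, int(row.plant_count))
    by_acc = meta.groupby("accession_id")["role"]
    singles = by_acc.apply(lambda r: (r == ROLE_SINGLE).sum())
    bulks = by_acc.apply(lambda r: (r == ROLE_BULK).sum())
    bad = singles[singles > 3].index.tolist() + bulks[bulks > 1].index.tolist()
    if bad:
        raise MetadataError(f"accession(s) violate replicate design (<=3 singles, <=1 bulk): {sorted(set(bad))}")
    return meta.reset_index(drop=True)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={c: str for c in METADATA_COLUMNS if c != "plant_count"})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.loc[:, METADATA_COLUMNS].to_csv(path, index=False)
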