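"""Target and off-target SNP extraction from microhaplotypes, and VCF emission.

Each observed microhaplotype is globally aligned to its locus's reference
amplicon; substitution columns across the locus's haplotypes become SNPs.  Read
counts collapse onto alleles: a sample's allele depth (AD) at a column is the
sum of its microhaplotype read counts carrying that base there.  The designed
target column is always emitted (flagged), even when monomorphic.  Low-identity
haplotypes are flagged as putative paralogs and excluded from the collapse;
indel columns are aligned through but never emitted (SNPs only).

Coordinates: VCF position = locus position + (column offset − target offset),
with panel positions 1-based and amplicon offsets 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import MadcTable, PanelDefinition

logger = logging.getLogger(__name__)

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _aligner()


@dataclass
class AlignmentResult:
    locus_id: str
    hap_id: str
    aligned_ref: str
    aligned_hap: str
    substitutions: list[tuple[int, str, str]]  # (amplicon offset, ref base, observed base)
    identity: float


def align_to_reference(ref_amplicon: str, hap_sequence: str, locus_id: str = "", hap_id: str = "") -> AlignmentResult:
    """Global pairwise alignment of a microhaplotype against its reference amplicon.

    Substitutions are reported at reference offsets; gap and N columns are
    skipped.  Identity is matches over alignment columns.
    """
    if not ref_amplicon or not hap_sequence:
        raise ValueError("align_to_reference requires nonempty sequences")
    aln = _ALIGNER.align(ref_amplicon, hap_sequence)[0]
    aligned_ref, aligned_hap = str(aln[0]), str(aln[1])
    subs: list[tuple[int, str, str]] = []
    matches = 0
    ref_offset = -1
    for r, h in zip(aligned_ref, aligned_hap):
        if r != "-":
            ref_offset += 1
        if r == "-" or h == "-":
            continue
        if r == h:
            matches += 1
        elif r != "N" and h != "N":
            subs.append((ref_offset, r, h))
    identity = matches / len(aligned_ref)
    return AlignmentResult(locus_id, hap_id, aligned_ref, aligned_hap, subs, identity)


def _base_at_offsets(result: AlignmentResult) -> dict[int, str]:
    """Map reference offset -> hap base for aligned (non-gap) columns."""
    out: dict[int, str] = {}
    ref_offset = -1
    for r, h in zip(result.aligned_ref, result.aligned_hap):
        if r == "-":
            continue
        ref_offset += 1
        if h != "-":
            out[ref_offset] = h
    return out


@dataclass
class VariantRecord:
    """One SNP with collapsed per-sample read depths.

    ``alleles`` = [ref] + alts; ``ad`` has shape (n_samples, n_alleles);
    DP = AD row sum, RA = AD of the reference allele.
    """

    chromosome: str
    position: int
    locus_id: str
    offset: int  # 0-based column within the amplicon
    ref_base: str
    alt_bases: list[str]
    is_target: bool
    ad: np.ndarray

    @property
    def alleles(self) -> list[str]:
        return [self.ref_base, *self.alt_bases]

    @property
    def dp(self) -> np.ndarray:
        return self.ad.sum(axis=1)

    @property
    def ra(self) -> np.ndarray:
        return self.ad[:, 0]

    @property
    def vcf_id(self) -> str:
        return f"{self.locus_id}:{self.offset}"


def extract_snps(
    table: MadcTable,
    panel: PanelDefinition,
    min_identity: float = 0.5,
    locus_subset=None,
) -> tuple[list[VariantRecord], list[tuple[str, str]]]:
    """Collapse microhaplotype read counts into per-SNP allele depths.

    Returns (variants sorted by chromosome/position, putative-paralog flags as
    (locus_id, hap_id) pairs).  The table should already be singleton-zeroed
    and, typically, restricted to presence-filtered loci via ``locus_subset``.
    """
    n_samples = len(table.samples)
    variants: list[VariantRecord] = []
    paralogs: list[tuple[str, str]] = []
    counts = table.counts
    wanted = set(locus_subset) if locus_subset is not None else None
    for locus_id in table.locus_ids:
        if locus_id not in panel:
            logger.info("extract_snps: locus %s absent from panel, skipped (no coordinates)", locus_id)
            continue
        if wanted is not None and locus_id not in wanted:
            continue
        locus = panel.get(locus_id)
        block = counts.xs(locus_id, level="locus_id")
        seqs = table.sequences.xs(locus_id, level="locus_id")
        base_maps: dict[str, dict[int, str]] = {}
        sub_offsets: set[int] = set()
        for hap_id, seq in seqs.items():
            res = align_to_reference(locus.ref_amplicon, seq, locus_id, hap_id)
            if res.identity < min_identity:
                paralogs.append((locus_id, hap_id))
                logger.info("extract_snps: %s|%s identity %.2f < %.2f, flagged as putative paralog", locus_id, hap_id, res.identity, min_identity)
                continue
            base_maps[hap_id] = _base_at_offsets(res)
            sub_offsets.update(o for o, _, _ in res.substitutions)
        columns = sorted(sub_offsets | {locus.target_offset})
        for o in columns:
            ref_base = locus.ref_amplicon[o]
            allele_depth: dict[str, np.ndarray] = {}
            for hap_id, bases in base_maps.items():
                b = bases.get(o)
                if b is None or b == "N":
                    continue  # gap or ambiguous: these reads carry no call here
                vec = block.loc[hap_id].to_numpy()
                if b in allele_depth:
                    allele_depth[b] = allele_depth[b] + vec
                else:
                    allele_depth[b] = vec.astype(np.int64)
            alts = [b for b in allele_depth if b != ref_base]
            # alt order: descending pooled depth, then alphabetical (stable)
            alts.sort(key=lambda b: (-int(allele_depth[b].sum()), b))
            is_target = o == locus.target_offset
            if not alts and not is_target:
                continue  # monomorphic off-target column: nothing to report
            alleles = [ref_base, *alts]
            ad = np.zeros((n_samples, len(alleles)), dtype=np.int64)
            for j, b in enumerate(alleles):
                if b in allele_depth:
                    ad[:, j] = allele_depth[b]
            variants.append(
                VariantRecord(
                    chromosome=locus.chromosome,
                    position=locus.position + (o - locus.target_offset),
                    locus_id=locus_id,
                    offset=o,
                    ref_base=ref_base,
                    alt_bases=alts,
                    is_target=is_target,
                    ad=ad,
                )
            )
    variants.sort(key=lambda v: (v.chromosome, v.position, v.locus_id, v.offset))
    return variants, paralogs


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=LID,Number=1,Type=String,Description="Marker locus id">
##INFO=<ID=TGT,Number=0,Type=Flag,Description="Designed target SNP of the locus">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=RA,Number=1,Type=Integer,Description="Reference allele read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth for each allele">
"""


def emit_vcf(variants: list[VariantRecord], samples: list[str], path) -> None:
    """Write VCF 4.2 with FORMAT DP:RA:AD; zero-depth calls are encoded '.'.

    Input must be sorted by chromosome then position.  Records sharing a
    (chromosome, position) stay distinguishable through their locus-id ID field
    (logged).
    """
    keys = [(v.chromosome, v.position) for v in variants]
    if keys != sorted(keys):
        raise ValueError("emit_vcf requires variants sorted by (chromosome, position)")
    seen: set[tuple[str, int]] = set()
    contigs = sorted({v.chromosome for v in variants})
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in variants:
            if (v.chromosome, v.position) in seen:
                logger.info("emit_vcf: duplicate site %s:%d disambiguated by ID %s", v.chromosome, v.position, v.vcf_id)
            seen.add((v.chromosome, v.position))
            alt = ",".join(v.alt_bases) if v.alt_bases else "."
            info = f"LID={v.locus_id}" + (";TGT" if v.is_target else "")
            fields = [v.chromosome, str(v.position), v.vcf_id, v.ref_base, alt, ".", ".", info, "DP:RA:AD"]
            dp = v.dp
            for i in range(v.ad.shape[0]):
                if dp[i] == 0:
                    fields.append(".")
                else:
                    fields.append(f"{dp[i]}:{v.ad[i, 0]}:" + ",".join(str(x) for x in v.ad[i]))
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    """Read back a DP:RA:AD VCF produced by :func:`emit_vcf` (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    for rec in vcf:
        ad = rec.format("AD")
        n_alleles = 1 + len(rec.ALT)
        if ad is None:
            ad_arr = np.zeros((len(samples), n_alleles), dtype=np.int64)
        else:
            ad_arr = np.array(ad, dtype=np.int64)[:, :n_alleles]
            ad_arr[ad_arr < 0] = 0  # cyvcf2 encodes '.' as a negative sentinel
        lid = rec.INFO.get("LID")
        offset = int(rec.ID.rsplit(":", 1)[1]) if rec.ID and ":" in rec.ID else 0
        variants.append(
            VariantRecord(
                chromosome=rec.CHROM,
                position=rec.POS,
                locus_id=lid if lid else (rec.ID or ""),
                offset=offset,
                ref_base=rec.REF,
                alt_bases=list(rec.ALT),
                is_target=rec.INFO.get("TGT") is not None,
                ad=ad_arr,
            )
        )
    return variants, samples
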