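"""Distance-based phylogeny and taxonomic mislabel flagging.

SNP genotypes are rendered as per-sample concatenated base strings (read-majority
base for heterozygotes, N for missing), pairwise distances use the Tamura–Nei
(TN93) model — distinct purine and pyrimidine transition rates with unequal base
frequencies — and trees are built by Saitou–Nei neighbor joining with optional
SNP-resampling bootstrap support.  A species-level tree can be built from a
pairwise FST matrix, and accessions whose nearest neighbours overwhelmingly
belong to a different species are flagged as likely mislabels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .popgen import DosageMatrix
from .snps import VariantRecord

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """TN93 log argument fell to or below zero: distance undefined."""


def sample_sequences(
    dm: DosageMatrix, variants: list[VariantRecord], ad_sample_order: list[str] | None = None
) -> dict[str, str]:
    """One concatenated base per SNP per sample.

    dosage 0 → reference base, 2 → alternate base, 1 → whichever allele has the
    higher read count (tie → reference), missing → N.  When the dosage matrix
    covers a subset of the samples the variants were extracted from, pass the
    variants' sample order as ``ad_sample_order``.
    """
    ids = [v.vcf_id for v in variants]
    if ids != dm.snp_ids:
        raise ValueError("variants do not match dosage matrix columns")
    n_samples = len(dm.samples)
    if ad_sample_order is None:
        rows = np.arange(n_samples)
    else:
        pos = {s: i for i, s in enumerate(ad_sample_order)}
        rows = np.array([pos[s] for s in dm.samples])
    chars = np.full((n_samples, len(variants)), "N", dtype="U1")
    values = dm.values.to_numpy(dtype=float)
    for j, v in enumerate(variants):
        ref = v.ref_base
        alt = v.alt_bases[0] if v.alt_bases else v.ref_base
        col = values[:, j]
        chars[col == 0, j] = ref
        chars[col == 2, j] = alt
        het = col == 1
        if het.any():
            ad = v.ad[rows]
            alt_reads = ad[:, 1] if ad.shape[1] > 1 else np.zeros(n_samples, dtype=int)
            major_alt = alt_reads > ad[:, 0]
            chars[het & major_alt, j] = alt
            chars[het & ~major_alt, j] = ref
    return {s: "".join(chars[i]) for i, s in enumerate(dm.samples)}


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def tamura_nei_distance(seq_a: str, seq_b: str) -> float:
    """TN93 distance between two equal-length sequences (pairwise N deletion).

    Uses the closed form with P1 (purine-transition proportion), P2
    (pyrimidine-transition proportion), Q (transversion proportion), and base
    frequencies averaged over both sequences at the compared sites.  Raises
    :class:`SaturationError` when a logarithm argument is non-positive.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    ok = (a != b"N") & (b != b"N")
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (non-N) sites")
    a, b = a[ok], b[ok]
    counts = Counter(a.tobytes().decode()) + Counter(b.tobytes().decode())
    total = 2 * n
    gA, gC, gG, gT = (counts.get(x, 0) / total for x in "ACGT")
    gR, gY = gA + gG, gC + gT
    diff = a != b
    a_s = a.astype("U1")
    b_s = b.astype("U1")
    is_purine_a = np.isin(a_s, list(_PURINES))
    is_purine_b = np.isin(b_s, list(_PURINES))
    p1 = float(np.sum(diff & is_purine_a & is_purine_b)) / n  # A<->G
    p2 = float(np.sum(diff & ~is_purine_a & ~is_purine_b)) / n  # C<->T
    q = float(np.sum(diff & (is_purine_a != is_purine_b))) / n  # transversions
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    if gR == 0 or gY == 0 or gA * gG == 0 and p1 > 0 or gC * gT == 0 and p2 > 0:
        raise SaturationError("degenerate base composition for observed differences")
    k1 = 2 * gA * gG / gR if gA * gG > 0 else 0.0
    k2 = 2 * gC * gT / gY if gC * gT > 0 else 0.0
    arg1 = 1 - p1 / k1 - q / (2 * gR) if k1 > 0 else 1.0
    arg2 = 1 - p2 / k2 - q / (2 * gY) if k2 > 0 else 1.0
    arg3 = 1 - q / (2 * gR * gY)
    if arg1 <= 0 or arg2 <= 0 or arg3 <= 0:
        raise SaturationError("distance saturated (log argument <= 0)")
    term3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * np.log(arg3)
    d = -(k1 * np.log(arg1)) - (k2 * np.log(arg2)) - term3
    return float(d)


def distance_matrix(sequences: dict[str, str], on_error: str = "raise") -> pd.DataFrame:
    """Symmetric TN93 distance matrix over samples.

    ``on_error='nan'`` records saturated/uncomputable pairs as NaN instead of
    raising.
    """
    names = list(sequences)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            try:
                d = tamura_nei_distance(sequences[x], sequences[y])
            except (SaturationError, ValueError):
                if on_error == "raise":
                    raise
                d = np.nan
            out.loc[x, y] = out.loc[y, x] = d
    return out


def prune_missing(dist: pd.DataFrame) -> pd.DataFrame:
    """Drop samples until no NaN pairs remain (greedy: remove the sample with
    the most undefined distances first).  Logged."""
    out = dist.copy()
    while out.isna().any().any():
        worst = out.isna().sum(axis=1).idxmax()
        logger.info("prune_missing: dropping %s (%d undefined distances)", worst, int(out.isna().sum(axis=1).max()))
        out = out.drop(index=worst, columns=worst)
    return out


@dataclass
class PhyloTree:
    """Unrooted tree as newick text plus its taxa; thin dendropy bridge."""

    newick: str
    taxa: list[str]
    support: dict[str, float] = field(default_factory=dict)  # bipartition key -> % support
    n_clamped: int = 0  # negative NJ branch lengths clamped to zero

    def as_dendropy(self, tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick", taxon_namespace=tns or dendropy.TaxonNamespace(self.taxa)
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick if self.newick.endswith("\n") else self.newick + "\n")


def _fmt(x: float) -> str:
    return f"{x:.17g}"  # full double precision so path lengths survive the round trip


def _quote(label: str) -> str:
    """Newick-quote a taxon label (spaces/punctuation are common in species names)."""
    return "'" + label.replace("'", "''") + "'"


def nj_tree(dist: pd.DataFrame) -> PhyloTree:
    """Saitou–Nei neighbor joining on the Q-criterion.

    Ties break on the smallest (i, j) index pair of the current working matrix;
    negative branch lengths are clamped to 0 (counted in ``n_clamped``).
    Exact on additive matrices.
    """
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    if np.isnan(arr).any():
        missing = [
            (str(dist.index[i]), str(dist.columns[j]))
            for i, j in zip(*np.where(np.isnan(arr)))
            if i < j
        ]
        raise ValueError(f"distance matrix has missing entries: {missing}")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("nj_tree needs >=3 taxa")
    labels = [str(x) for x in dist.index]
    nodes = [_quote(x) for x in labels]
    D = arr.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min((int(p[0]), int(p[1])) for p in ties if p[0] < p[1])
        li = clamp(0.5 * D[i, j] + (R[i] - R[j]) / (2 * (m - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (R[i] - R[j]) / (2 * (m - 2))))
        new_node = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)], d_new[keep, None]]), np.hstack([d_new[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [new_node]
    la = clamp(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    lb = clamp(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    lc = clamp(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    newick = f"({nodes[0]}:{_fmt(la)},{nodes[1]}:{_fmt(lb)},{nodes[2]}:{_fmt(lc)});"
    if clamped:
        logger.info("nj_tree: clamped %d negative branch length(s) to 0", clamped)
    return PhyloTree(newick, labels, n_clamped=clamped)


def _nontrivial_bitmasks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    n = len(tree.taxon_namespace)
    out = set()
    for bp in tree.bipartition_encoding:
        mask = bp.split_bitmask
        size = bin(mask).count("1")
        if 1 < size < n - 1:
            out.add(mask)
    return out


def bootstrap_support(
    dm: DosageMatrix,
    variants: list[VariantRecord],
    n_reps: int = 100,
    seed: int = 0,
    support_threshold: float = 50.0,
    ad_sample_order: list[str] | None = None,
) -> PhyloTree:
    """NJ tree with SNP-resampling bootstrap support.

    Columns are resampled with replacement ``n_reps`` times; support for each
    internal bipartition of the point-estimate tree is the percentage of
    completed replicates containing it (replicates with saturated distances are
    skipped and the denominator adjusted).  Supports at or above
    ``support_threshold`` are written as internal node labels.
    """
    seqs = sample_sequences(dm, variants, ad_sample_order)
    point = nj_tree(distance_matrix(seqs))
    if n_reps == 0:
        return point
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(point.taxa)
    t0 = point.as_dendropy(tns)
    target = _nontrivial_bitmasks(t0)
    counts: Counter = Counter()
    completed = 0
    n_snps = len(variants)
    for _ in range(n_reps):
        idx = rng.integers(0, n_snps, size=n_snps)
        rep_variants = [variants[i] for i in idx]
        rep_dm = DosageMatrix(dm.values.iloc[:, idx], dm.min_depth, dm.error_rate)
        rep_dm.values.columns = [v.vcf_id for v in rep_variants]
        try:
            rep_seqs = sample_sequences(rep_dm, rep_variants, ad_sample_order)
            rep_tree = nj_tree(distance_matrix(rep_seqs))
        except (SaturationError, ValueError):
            logger.info("bootstrap_support: replicate skipped (saturated distances)")
            continue
        completed += 1
        counts.update(_nontrivial_bitmasks(rep_tree.as_dendropy(tns)) & target)
    support: dict[str, float] = {}
    for edge in t0.preorder_edge_iter():
        bp = edge.bipartition
        if bp is None:
            continue
        mask = bp.split_bitmask
        size = bin(mask).count("1")
        if not (1 < size < len(tns)):
            continue
        pct = 100.0 * counts.get(mask, 0) / completed if completed else float("nan")
        support[format(mask, "x")] = pct
        if pct >= support_threshold:
            edge.head_node.label = str(int(round(pct)))
    newick = t0.as_string(schema="newick", suppress_rooting=True)
    return PhyloTree(newick.strip(), point.taxa, support=support, n_clamped=point.n_clamped)


def fst_species_tree(fst: pd.DataFrame, root_species: str) -> PhyloTree:
    """NJ tree on a pairwise FST matrix, rooted on the edge leading to
    ``root_species`` (outgroup rooting).  Missing entries are an error."""
    if fst.isna().any().any():
        pairs = [(str(i), str(j)) for i in fst.index for j in fst.columns if pd.isna(fst.loc[i, j])]
        raise ValueError(f"FST matrix has missing entries: {pairs}")
    if root_species not in fst.index:
        raise KeyError(root_species)
    unrooted = nj_tree(fst)
    tree = unrooted.as_dendropy()
    node = tree.find_node_with_taxon_label(str(root_species))
    edge_len = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=edge_len / 2, length2=edge_len / 2, update_bipartitions=False)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return PhyloTree(newick, unrooted.taxa, n_clamped=unrooted.n_clamped)


def flag_outliers(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    k: int = 5,
    majority: float = 0.8,
    margin: float = 0.9,
) -> pd.DataFrame:
    """Nearest-neighbour species vote for taxonomic mislabels.

    For each sample, take its k nearest neighbours by genetic distance,
    excluding replicates of the same accession; if one *other* species holds at
    least ``majority`` of the neighbours, flag the accession with that assigned
    species.  Species represented by fewer than 2 accessions cannot be an
    assignment target (logged).

    ``margin`` guards against ambiguous assignments between weakly separated
    species: a flag is only raised when the mean distance to the voting
    neighbours is below ``margin`` times the mean distance to the sample's
    k nearest own-species samples (vacuous when the own species has no other
    samples).
    """
    meta = metadata.set_index("sample_id")
    samples = [s for s in dist.index if s in meta.index]
    if len(samples) < k + 1:
        raise ValueError("flag_outliers needs at least k+1 samples")
    acc_counts = metadata.groupby("species")["accession_id"].nunique()
    eligible = set(acc_counts.index[acc_counts >= 2])
    if len(eligible) < len(acc_counts):
        logger.info(
            "flag_outliers: species with <2 accessions excluded as targets: %s",
            sorted(set(acc_counts.index) - eligible),
        )
    flags = {}
    for s in samples:
        own_acc = meta.loc[s, "accession_id"]
        own_species = meta.loc[s, "species"]
        others = [t for t in samples if meta.loc[t, "accession_id"] != own_acc]
        nn = sorted(others, key=lambda t: (float(dist.loc[s, t]), t))[:k]
        votes = Counter(meta.loc[t, "species"] for t in nn)
        top_species, top_n = votes.most_common(1)[0]
        if top_species == own_species or top_species not in eligible or top_n < majority * k:
            continue
        assigned_mean = float(np.mean([dist.loc[s, t] for t in nn if meta.loc[t, "species"] == top_species]))
        own_pool = sorted(
            (float(dist.loc[s, t]) for t in others if meta.loc[t, "species"] == own_species)
        )[:k]
        if own_pool and assigned_mean >= margin * float(np.mean(own_pool)):
            logger.info("flag_outliers: %s ambiguous between %s and %s, suppressed", s, own_species, top_species)
            continue
        flags.setdefault(own_acc, (own_species, top_species))
    rows = [
        {"accession_id": acc, "labeled_species": lab, "assigned_species": asg}
        for acc, (lab, asg) in sorted(flags.items())
    ]
    return pd.DataFrame(rows, columns=["accession_id", "labeled_species", "assigned_species"])
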