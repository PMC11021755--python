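"""Synthetic MADC data with the statistical structure of a cross-species panel transfer.

The generator emulates genotyping many related, highly selfing diploid species
on a fixed ~3,000-locus amplicon panel that was designed for a single species:

* loci drop out of divergent species with a logistic probability in the
  species' genetic divergence from the design species (missingness grows with
  divergence);
* allele frequencies differentiate among species under the Balding–Nichols
  model (Beta around an ancestral frequency, differentiation ``theta`` equal
  to the model FST), and again between seed sources within a species;
* each accession is sampled as 3 single plants plus 1 bulk of 7 plants;
* amplicons carry a target SNP and 0–3 linked off-target SNPs, so the observed
  sequences are microhaplotypes (complete linkage within the short amplicon);
* read depths are negative-binomial, reads split multinomially across the
  allele copies in the sample (2 for a single plant, 14 for a bulk), and a
  depth-1 error haplotype appears with a small per-locus probability;
* species-label swaps can be injected to exercise mislabel detection.

Everything is driven by one integer seed; same config + seed gives
byte-identical MADC and truth files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MadcTable, MarkerLocus, PanelDefinition, validate_metadata

BASES = np.array(list("ACGT"))

#: per-chromosome locus counts of the reference 3K panel (8 chromosomes)
PANEL_3K_DISTRIBUTION = (414, 364, 419, 426, 390, 210, 367, 410)
DEFAULT_CHROMOSOMES = tuple(f"chr{i}.1" for i in range(1, 9))


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesGroup:
    """One species x seed-source stratum of the sampling design."""

    name: str
    divergence: float  # genetic distance from the panel's design species, >= 0
    n_accessions: int
    source: str = "Collection"  # "Collection" | "Genebank"


def _default_species() -> tuple[SpeciesGroup, ...]:
    # 10 annual-medic-like species spanning the divergence gradient, two seed
    # sources where both exist; 192 accessions in total.
    spec = [
        ("M. cretacea", 0.25, 1, 1),
        ("M. arabica", 0.45, 6, 6),
        ("M. rigidula", 0.55, 18, 12),
        ("M. rigiduloides", 0.58, 6, 5),
        ("M. praecox", 0.62, 6, 6),
        ("M. polymorpha", 0.72, 12, 10),
        ("M. orbicularis", 0.82, 18, 16),
        ("M. minima", 0.92, 15, 14),
        ("M. lupulina", 1.02, 16, 14),
        ("M. monspeliaca", 1.20, 0, 10),
    ]
    groups: list[SpeciesGroup] = []
    for name, d, n_coll, n_gene in spec:
        if n_coll:
            groups.append(SpeciesGroup(name, d, n_coll, "Collection"))
        if n_gene:
            groups.append(SpeciesGroup(name, d, n_gene, "Genebank"))
    return tuple(groups)


@dataclass(frozen=True)
class SimulationConfig:
    n_loci: int = 3000
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES
    amplicon_len: int = 81
    species_spec: tuple[SpeciesGroup, ...] = field(default_factory=_default_species)
    theta_between: float = 0.30
    theta_within: float = 0.03
    selfing_F: float = 0.7
    depth_mean: float = 60.0
    depth_dispersion: float = 30.0
    depth_locus_sigma: float = 1.3  # lognormal spread of per-locus amplification efficiency
    dropout_a: float = 0.8
    dropout_b: float = 1.2
    error_rate: float = 0.05
    n_offtarget_max: int = 3
    mislabel_swaps: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chromosomes) != 8:
            raise ConfigurationError(f"exactly 8 chromosomes required, got {len(self.chromosomes)}")
        if self.n_loci < 8:
            raise ConfigurationError("n_loci must be >= 8")
        if not (0 <= self.theta_between < 1) or not (0 <= self.theta_within < 1):
            raise ConfigurationError("theta parameters must lie in [0, 1)")
        if not (0 <= self.selfing_F <= 1):
            raise ConfigurationError("selfing_F must lie in [0, 1]")
        if not (0 <= self.error_rate <= 1):
            raise ConfigurationError("error_rate must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("depth parameters must be positive")
        for g in self.species_spec:
            if g.divergence < 0:
                raise ConfigurationError(f"{g.name}: divergence must be >= 0")

    @property
    def species_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.species_spec:
            if g.name not in seen:
                seen.append(g.name)
        return seen

    def divergence_of(self, species: str) -> float:
        for g in self.species_spec:
            if g.name == species:
                return g.divergence
        raise KeyError(species)


def accession_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic accession roster (true labels) implied by the config."""
    rows = []
    i = 0
    for g in config.species_spec:
        for _ in range(g.n_accessions):
            i += 1
            rows.append({"accession_id": f"ACC{i:04d}", "species": g.name, "source": g.source})
    return pd.DataFrame(rows)


def sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample-level metadata with any configured label swaps applied.

    Each accession contributes 3 single-plant samples (P1–P3) and one bulk of 7
    plants; swapped accessions carry the wrong species label (the truth set
    keeps the real one).
    """
    acc = accession_table(config)
    labels = dict(zip(acc["accession_id"], acc["species"]))
    for accession_id, wrong in config.mislabel_swaps:
        if accession_id not in labels:
            raise ConfigurationError(f"mislabel swap references unknown accession {accession_id!r}")
        labels[accession_id] = wrong
    rows = []
    for row in acc.itertuples(index=False):
        for p in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"{row.accession_id}_P{p}",
                    "accession_id": row.accession_id,
                    "species": labels[row.accession_id],
                    "source": row.source,
                    "role": "single",
                    "plant_count": 1,
                }
            )
        rows.append(
            {
                "sample_id": f"{row.accession_id}_B",
                "accession_id": row.accession_id,
                "species": labels[row.accession_id],
                "source": row.source,
                "role": "bulk",
                "plant_count": 7,
            }
        )
    return validate_metadata(pd.DataFrame(rows))


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stream]))


def simulate_panel(config: SimulationConfig) -> PanelDefinition:
    """Draw a panel: loci spread over the 8 chromosomes in the 3K panel's proportions.

    Largest-remainder apportionment of ``n_loci`` against the reference
    distribution, random amplicon sequences, and a random target-SNP offset per
    locus.  Positions are increasing along each chromosome.
    """
    rng = _rng(config.seed, 1)
    total = sum(PANEL_3K_DISTRIBUTION)
    quotas = np.array(PANEL_3K_DISTRIBUTION, dtype=float) * config.n_loci / total
    counts = np.floor(quotas).astype(int)
    order = np.argsort(-(quotas - counts), kind="stable")
    for j in order[: config.n_loci - counts.sum()]:
        counts[j] += 1
    loci: list[MarkerLocus] = []
    i = 0
    for chrom, n_chrom in zip(config.chromosomes, counts):
        positions = np.cumsum(rng.integers(500, 50_000, size=n_chrom)) + 1
        for pos in positions:
            i += 1
            seq = "".join(BASES[rng.integers(0, 4, size=config.amplicon_len)])
            offset = int(rng.integers(0, config.amplicon_len))
            loci.append(MarkerLocus(f"L{i:05d}", chrom, int(pos), seq, offset))
    return PanelDefinition(loci)


def simulate_dropout(
    panel: PanelDefinition,
    divergence: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-locus amplification flags for one species.

    Each locus amplifies independently with probability
    ``sigmoid(dropout_a - dropout_b * divergence)``, so expected missingness is
    non-decreasing in divergence.
    """
    if config.dropout_b <= 0:
        raise ConfigurationError("dropout_b must be > 0")
    if rng is None:
        rng = _rng(config.seed, 2)
    p = amplification_probability(divergence, config)
    return rng.random(len(panel)) < p


def amplification_probability(divergence: float, config: SimulationConfig) -> float:
    x = config.dropout_a - config.dropout_b * divergence
    return float(1.0 / (1.0 + np.exp(-x)))


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, theta: float) -> np.ndarray:
    """Beta(p0(1-θ)/θ, (1-p0)(1-θ)/θ) draw; θ=0 returns p0 exactly."""
    if theta >= 1:
        raise ConfigurationError("theta must be < 1")
    if theta == 0:
        return p0.copy()
    scale = (1.0 - theta) / theta
    out = p0.copy()
    interior = (p0 > 0) & (p0 < 1)  # alleles fixed upstream stay fixed
    out[interior] = rng.beta(p0[interior] * scale, (1.0 - p0[interior]) * scale)
    return out


@dataclass
class FrequencyModel:
    """Variant sites of every locus plus hierarchical alternate-allele frequencies."""

    sites: pd.DataFrame  # locus_id, offset, ref, alt, is_target (one row per SNP site)
    p0: np.ndarray  # ancestral alternate-allele frequency per site
    species_freq: dict[str, np.ndarray]
    group_freq: dict[tuple[str, str], np.ndarray]  # (species, source) -> freqs

    def locus_site_index(self) -> dict[str, np.ndarray]:
        return {lid: idx.to_numpy() for lid, idx in self.sites.groupby("locus_id", sort=False).groups.items()}


def simulate_frequencies(
    panel: PanelDefinition,
    species_spec: Sequence[SpeciesGroup],
    theta_between: float,
    theta_within: float,
    seed: int,
    n_offtarget_max: int = 3,
) -> FrequencyModel:
    """Draw variant sites and Balding–Nichols allele frequencies.

    Per locus: the designed target SNP plus ``~min(TruncPoisson(1), cap)``
    off-target SNPs at distinct offsets.  Ancestral alternate-allele
    frequencies are Uniform(0.05, 0.95); species frequencies are
    Balding–Nichols around the ancestral with per-species differentiation
    ``theta_between * divergence / mean(divergence)`` (so differentiation
    tracks the divergence gradient and averages to ``theta_between``);
    source-level frequencies are Balding–Nichols around the species with
    ``theta_within``.
    """
    rng = _rng(seed, 3)
    # species-level differentiation scales with divergence from the design
    # species (mean-normalised), so genetic distance and marker transferability
    # decay together along the gradient
    divergence = {}
    for g in species_spec:
        divergence.setdefault(g.name, g.divergence)
    mean_d = float(np.mean(list(divergence.values()))) or 1.0
    theta_of = {name: min(theta_between * d / mean_d, 0.95) for name, d in divergence.items()}
    rows = []
    for lid in panel.locus_ids:
        locus = panel.get(lid)
        amp = locus.ref_amplicon
        n_off = min(int(rng.poisson(1.0)), n_offtarget_max)
        candidates = np.setdiff1d(np.arange(len(amp)), [locus.target_offset])
        off = np.sort(rng.choice(candidates, size=min(n_off, len(candidates)), replace=False))
        offsets = sorted([locus.target_offset, *off.tolist()])
        for o in offsets:
            ref = amp[o]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append({"locus_id": lid, "offset": int(o), "ref": ref, "alt": alt, "is_target": o == locus.target_offset})
    sites = pd.DataFrame(rows)
    n_sites = len(sites)
    p0 = rng.uniform(0.05, 0.95, size=n_sites)
    species_freq: dict[str, np.ndarray] = {}
    group_freq: dict[tuple[str, str], np.ndarray] = {}
    names: list[str] = []
    for g in species_spec:
        if g.name not in names:
            names.append(g.name)
    for name in names:
        species_freq[name] = _balding_nichols(rng, p0, theta_of[name])
    for g in species_spec:
        group_freq[(g.name, g.source)] = _balding_nichols(rng, species_freq[g.name], theta_within)
    return FrequencyModel(sites, p0, species_freq, group_freq)


N_PLANTS_PER_ACCESSION = 10
SINGLE_PLANTS = (0, 1, 2)  # plants 1-3 are the single-plant samples
BULK_PLANTS = tuple(range(3, 10))  # plants 4-10 form the bulk of 7


@dataclass
class TruthSet:
    """Ground truth behind a simulated dataset.

    ``genotypes[locus_id]`` has shape (n_accessions, 10 plants, 2 copies) and
    holds haplotype bitmasks over the locus's variant sites (bit j set = the
    alternate allele at the locus's j-th site, sites in offset order).
    """

    config: SimulationConfig
    accessions: pd.DataFrame  # accession_id, species (true), source
    amplification: dict[str, np.ndarray]  # species -> per-locus bool flags
    frequencies: FrequencyModel
    genotypes: dict[str, np.ndarray]
    mislabels: tuple[tuple[str, str], ...]

    def true_species_of(self, accession_id: str) -> str:
        row = self.accessions.loc[self.accessions["accession_id"] == accession_id]
        return str(row["species"].iloc[0])

    def dosage(self, locus_id: str, site_pos: int) -> np.ndarray:
        """True per-plant alternate dosage (n_accessions, 10) at one site of a locus."""
        g = self.genotypes[locus_id]
        bit = 1 << site_pos
        return ((g & bit) > 0).sum(axis=2)


def simulate_accessions(
    frequencies: FrequencyModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Draw per-plant diploid genotypes with selfing F and species-level dropout.

    With probability F a plant's two haplotypes at a locus are identical by
    descent (one population draw, duplicated), otherwise two independent draws;
    per site this yields genotype probabilities (p²+Fp(1−p), 2p(1−p)(1−F),
    (1−p)²+Fp(1−p)).  Haplotypes are drawn allele-by-allele from the group's
    frequencies, so within-amplicon linkage is complete on each chromosome copy.
    """
    if rng is None:
        rng = _rng(config.seed, 4)
    acc = accession_table(config)
    n_acc = len(acc)
    F = config.selfing_F
    locus_sites = frequencies.locus_site_index()
    locus_ids = list(locus_sites)

    amplification = {
        name: simulate_dropout(_SizedLoci(locus_ids), config.divergence_of(name), config, rng)
        for name in config.species_names
    }

    group_rows = {
        key: acc.index[(acc["species"] == key[0]) & (acc["source"] == key[1])].to_numpy()
        for key in frequencies.group_freq
    }
    genotypes: dict[str, np.ndarray] = {
        lid: np.zeros((n_acc, N_PLANTS_PER_ACCESSION, 2), dtype=np.int16) for lid in locus_ids
    }
    for key, rows_idx in group_rows.items():
        if len(rows_idx) == 0:
            continue
        freqs = frequencies.group_freq[key]
        n_pl = len(rows_idx) * N_PLANTS_PER_ACCESSION
        for lid in locus_ids:
            site_idx = locus_sites[lid]
            p = freqs[site_idx]
            k = len(site_idx)
            draws = (rng.random((n_pl, 2, k)) < p).astype(np.int64)  # alternate-allele indicators
            masks = (draws << np.arange(k)).sum(axis=2).astype(np.int16)
            ibd = rng.random(n_pl) < F
            masks[ibd, 1] = masks[ibd, 0]
            genotypes[lid][rows_idx] = masks.reshape(len(rows_idx), N_PLANTS_PER_ACCESSION, 2)
    return TruthSet(config, acc, amplification, frequencies, genotypes, config.mislabel_swaps)


class _SizedLoci:
    """Minimal sized object so simulate_dropout can run from a locus list."""

    def __init__(self, locus_ids: Sequence[str]):
        self._n = len(locus_ids)

    def __len__(self) -> int:
        return self._n


def _mutate_sequence(seq: str, rng: np.random.Generator, forbidden: set[int]) -> str:
    pos_candidates = [i for i in range(len(seq)) if i not in forbidden]
    pos = int(rng.choice(pos_candidates)) if pos_candidates else int(rng.integers(len(seq)))
    alt = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
    return seq[:pos] + alt + seq[pos + 1 :]


def simulate_reads(
    truth: TruthSet,
    panel: PanelDefinition,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_depths: bool = False,
):
    """Emit the MADC table: negative-binomial depths split multinomially over
    the allele copies carried by each sample (2 for singles, 14 for bulks),
    plus occasional depth-1 error haplotypes.  Non-amplified loci are all-zero.
    """
    if rng is None:
        rng = _rng(config.seed, 5)
    meta = sample_metadata(config)
    samples = meta["sample_id"].tolist()
    n_samples = len(samples)
    acc = truth.accessions
    acc_of_sample = meta["accession_id"].to_numpy()
    acc_pos = {a: i for i, a in enumerate(acc["accession_id"])}
    sample_acc_idx = np.array([acc_pos[a] for a in acc_of_sample])
    sample_species = acc["species"].to_numpy()[sample_acc_idx]  # true species drives amplification
    role = meta["role"].to_numpy()
    plant_sets = [SINGLE_PLANTS[:1], SINGLE_PLANTS[1:2], SINGLE_PLANTS[2:3], BULK_PLANTS]
    sample_plants = []
    for i, r in enumerate(role):
        if r == "single":
            p_index = int(meta["sample_id"].iloc[i].rsplit("_P", 1)[1]) - 1
            sample_plants.append(plant_sets[p_index])
        else:
            sample_plants.append(BULK_PLANTS)
    single_rows = np.flatnonzero(role == "single")
    single_plant = np.array([sample_plants[i][0] for i in single_rows], dtype=np.intp)
    bulk_rows = np.flatnonzero(role == "bulk")

    locus_sites = truth.frequencies.locus_site_index()
    sites = truth.frequencies.sites
    disp, mean = config.depth_dispersion, config.depth_mean
    # per-locus amplification efficiency, shared across samples: this is what
    # makes replicate read-count profiles correlate across loci
    sigma = config.depth_locus_sigma
    efficiency = rng.lognormal(-sigma**2 / 2, sigma, size=len(panel)) if sigma > 0 else np.ones(len(panel))
    species_names = config.species_names
    species_of_sample_idx = np.array([species_names.index(s) for s in sample_species])
    amp_matrix = np.stack([truth.amplification[s] for s in species_names])  # species x loci

    records: list[tuple[str, str]] = []
    seq_list: list[str] = []
    count_blocks: list[np.ndarray] = []
    depth_blocks: dict[str, np.ndarray] = {}

    for li, lid in enumerate(panel.locus_ids):
        locus = panel.get(lid)
        site_idx = locus_sites[lid]
        loc_sites = sites.iloc[site_idx]
        offsets = loc_sites["offset"].to_numpy()
        alts = loc_sites["alt"].to_numpy()
        target_bit_pos = int(np.flatnonzero(loc_sites["is_target"].to_numpy())[0])
        k = len(site_idx)

        geno = truth.genotypes[lid]  # (n_acc, 10, 2)
        # copy counts per sample x haplotype bitmask (2 copies for singles, 14 for bulks)
        n_haps = 1 << k
        copies = np.zeros((n_samples, n_haps), dtype=np.int32)
        sm = geno[sample_acc_idx[single_rows], single_plant, :]  # (n_singles, 2)
        np.add.at(copies, (np.repeat(single_rows, 2), sm.ravel()), 1)
        bm = geno[sample_acc_idx[bulk_rows]][:, BULK_PLANTS, :]  # (n_bulks, 7, 2)
        np.add.at(copies, (np.repeat(bulk_rows, 14), bm.reshape(len(bulk_rows), -1).ravel()), 1)
        amplified = amp_matrix[species_of_sample_idx, li]
        p_nb = disp / (disp + mean * efficiency[li])
        depth = np.where(amplified, rng.negative_binomial(disp, p_nb, size=n_samples), 0).astype(np.int64)
        if return_depths:
            depth_blocks[lid] = depth

        # multinomial split of depth across haplotype columns via sequential binomials
        total_copies = copies.sum(axis=1)
        counts = np.zeros_like(copies, dtype=np.int64)
        remaining = depth.copy()
        copies_left = total_copies.astype(np.float64)
        for h in range(n_haps):
            col = copies[:, h].astype(np.float64)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(copies_left > 0, col / copies_left, 0.0)
            draw = rng.binomial(remaining, np.clip(frac, 0.0, 1.0))
            counts[:, h] = draw
            remaining -= draw
            copies_left -= col

        # depth-1 error haplotypes on amplified loci
        err_mask = amplified & (rng.random(n_samples) < config.error_rate)
        err_seqs: dict[int, str] = {}
        err_counts: dict[str, np.ndarray] = {}
        if err_mask.any():
            forbidden = set(int(o) for o in offsets)
            variants = [_mutate_sequence(locus.ref_amplicon, rng, forbidden) for _ in range(3)]
            choice = rng.integers(0, 3, size=n_samples)
            for v_i, v_seq in enumerate(variants):
                sel = err_mask & (choice == v_i)
                if sel.any():
                    vec = np.zeros(n_samples, dtype=np.int64)
                    vec[sel] = 1
                    err_counts[v_seq] = vec

        observed = np.flatnonzero(counts.sum(axis=0) > 0)
        # stable haplotype naming: Ref, Alt (target-only alternate), Other_k
        hap_names = {}
        other_i = 0
        for h in observed:
            if h == 0:
                hap_names[h] = "Ref"
            elif h == (1 << target_bit_pos):
                hap_names[h] = "Alt"
            else:
                other_i += 1
                hap_names[h] = f"Other_{other_i:02d}"
        for h in observed:
            seq = list(locus.ref_amplicon)
            for j in range(k):
                if h & (1 << j):
                    seq[offsets[j]] = alts[j]
            records.append((lid, hap_names[h]))
            seq_list.append("".join(seq))
            count_blocks.append(counts[:, h])
        for e_i, (v_seq, vec) in enumerate(err_counts.items(), start=1):
            records.append((lid, f"Err_{e_i:02d}"))
            seq_list.append(v_seq)
            count_blocks.append(vec)

    if records:
        index = pd.MultiIndex.from_tuples(records, names=("locus_id", "hap_id"))
    else:
        index = pd.MultiIndex.from_arrays([[], []], names=("locus_id", "hap_id"))
    counts_df = pd.DataFrame(
        np.vstack(count_blocks) if count_blocks else np.zeros((0, n_samples), dtype=np.int64),
        index=index,
        columns=samples,
    )
    table = MadcTable(counts_df, pd.Series(seq_list, index=index, name="sequence"), panel=panel)
    if return_depths:
        return table, depth_blocks
    return table


@dataclass
class SimulatedDataset:
    madc: MadcTable
    metadata: pd.DataFrame  # reported labels (mislabels applied)
    panel: PanelDefinition
    truth: TruthSet


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end generation: panel → frequencies → genotypes → reads."""
    panel = simulate_panel(config)
    freqs = simulate_frequencies(
        panel, config.species_spec, config.theta_between, config.theta_within, config.seed, config.n_offtarget_max
    )
    truth = simulate_accessions(freqs, config)
    madc = simulate_reads(truth, panel, config)
    meta = sample_metadata(config)
    return SimulatedDataset(madc, meta, panel, truth)


# ---------------------------------------------------------------------------
# truth sidecar (lossless JSON round trip)

def write_truth(truth: TruthSet, path) -> None:
    cfg = truth.config
    payload = {
        "config": {
            "n_loci": cfg.n_loci,
            "chromosomes": list(cfg.chromosomes),
            "amplicon_len": cfg.amplicon_len,
            "species_spec": [[g.name, g.divergence, g.n_accessions, g.source] for g in cfg.species_spec],
            "theta_between": cfg.theta_between,
            "theta_within": cfg.theta_within,
            "selfing_F": cfg.selfing_F,
            "depth_mean": cfg.depth_mean,
            "depth_dispersion": cfg.depth_dispersion,
            "depth_locus_sigma": cfg.depth_locus_sigma,
            "dropout_a": cfg.dropout_a,
            "dropout_b": cfg.dropout_b,
            "error_rate": cfg.error_rate,
            "n_offtarget_max": cfg.n_offtarget_max,
            "mislabel_swaps": [list(m) for m in cfg.mislabel_swaps],
            "seed": cfg.seed,
        },
        "accessions": truth.accessions.to_dict(orient="list"),
        "amplification": {s: flags.astype(int).tolist() for s, flags in truth.amplification.items()},
        "sites": truth.frequencies.sites.to_dict(orient="list"),
        "p0": truth.frequencies.p0.tolist(),
        "species_freq": {s: f.tolist() for s, f in truth.frequencies.species_freq.items()},
        "group_freq": {f"{s}\t{src}": f.tolist() for (s, src), f in truth.frequencies.group_freq.items()},
        "genotypes": {
            lid: ["".join(f"{m:02x}" for m in g.ravel()) for g in arr] for lid, arr in truth.genotypes.items()
        },
        "mislabels": [list(m) for m in truth.mislabels],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path) -> TruthSet:
    with open(path) as fh:
        payload = json.load(fh)
    c = payload["config"]
    cfg = SimulationConfig(
        n_loci=c["n_loci"],
        chromosomes=tuple(c["chromosomes"]),
        amplicon_len=c["amplicon_len"],
        species_spec=tuple(SpeciesGroup(*g) for g in c["species_spec"]),
        theta_between=c["theta_between"],
        theta_within=c["theta_within"],
        selfing_F=c["selfing_F"],
        depth_mean=c["depth_mean"],
        depth_dispersion=c["depth_dispersion"],
        depth_locus_sigma=c["depth_locus_sigma"],
        dropout_a=c["dropout_a"],
        dropout_b=c["dropout_b"],
        error_rate=c["error_rate"],
        n_offtarget_max=c["n_offtarget_max"],
        mislabel_swaps=tuple(tuple(m) for m in c["mislabel_swaps"]),
        seed=c["seed"],
    )
    sites = pd.DataFrame(payload["sites"])
    freqs = FrequencyModel(
        sites,
        np.array(payload["p0"]),
        {s: np.array(f) for s, f in payload["species_freq"].items()},
        {tuple(k.split("\t")): np.array(f) for k, f in payload["group_freq"].items()},
    )
    genotypes = {
        lid: np.array(
            [[int(row[i : i + 2], 16) for i in range(0, len(row), 2)] for row in rows], dtype=np.int16
        ).reshape(len(rows), N_PLANTS_PER_ACCESSION, 2)
        for lid, rows in payload["genotypes"].items()
    }
    return TruthSet(
        cfg,
        pd.DataFrame(payload["accessions"]),
        {s: np.array(flags, dtype=bool) for s, flags in payload["amplification"].items()},
        freqs,
        genotypes,
        tuple(tuple(m) for m in payload["mislabels"]),
    )
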