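"""End-to-end orchestration: simulate/ingest → QC → SNP extraction → filtering →
structure → phylogeny → mislabel flags, with a machine-readable run report.

Every stage logs in/out counts that must reconcile (in = out + dropped), all
randomness flows from one seed, and rerunning the same config + seed
reproduces byte-identical CSV/VCF/newick/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import filtering, groupstats, phylo, popgen, qc, snps
from .io import (
    PanelDefinition,
    read_madc,
    read_metadata,
    write_madc,
    write_metadata,
)
from .simulate import SimulationConfig, SpeciesGroup, simulate_dataset, write_truth

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    presence_min_reads: int = 10
    presence_percent: float = 5.0
    common_percent: float = 95.0
    hindhe_low: float = 0.1
    hindhe_high: float = 1.0
    min_depth: int = 10
    dosage_error_rate: float = 0.01
    bootstrap_reps: int = 100
    outlier_k: int = 5
    outlier_majority: float = 0.8


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig | None = None
    madc_path: str | None = None
    panel_path: str | None = None
    metadata_path: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        if self.simulation is None and not (self.madc_path and self.panel_path and self.metadata_path):
            raise ValueError("config needs either a simulation block or madc/panel/metadata paths")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    sim = None
    if "simulation" in raw:
        s = dict(raw["simulation"])
        if "species" in s:
            s["species_spec"] = tuple(
                SpeciesGroup(g["name"], float(g["divergence"]), int(g["n_accessions"]), g.get("source", "Collection"))
                for g in s.pop("species")
            )
        if "mislabel_swaps" in s:
            s["mislabel_swaps"] = tuple(tuple(m) for m in s["mislabel_swaps"])
        if "chromosomes" in s:
            s["chromosomes"] = tuple(s["chromosomes"])
        s.setdefault("seed", seed)
        sim = SimulationConfig(**s)
    inputs = raw.get("inputs", {})
    for key in ("madc", "panel", "metadata"):
        if key in inputs and not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input path does not exist: {inputs[key]}")
    params = PipelineParams(**raw.get("params", {}))
    return PipelineConfig(
        seed=seed,
        simulation=sim,
        madc_path=inputs.get("madc"),
        panel_path=inputs.get("panel"),
        metadata_path=inputs.get("metadata"),
        params=params,
    )


@dataclass
class RunResult:
    report: dict
    out_dir: Path
    presence_curve: pd.DataFrame
    per_chromosome: pd.DataFrame
    fst_species: pd.DataFrame
    fst_source: pd.DataFrame | None
    outliers: pd.DataFrame
    diversity: pd.DataFrame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(report: dict, name: str, n_in: int, n_out: int) -> None:
    report["stages"].append({"stage": name, "in": int(n_in), "out": int(n_out), "dropped": int(n_in - n_out)})


def run_pipeline(config: PipelineConfig | str | Path, out_dir) -> RunResult:
    """Execute all stages in fixed order and write every artifact under out_dir."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: getattr(params, k) for k in vars(params)},
        "stages": [],
        "inputs": {},
        "outputs": {},
    }

    # --- stage 0: data ---------------------------------------------------
    if config.simulation is not None:
        ds = simulate_dataset(config.simulation)
        table, metadata, panel = ds.madc, ds.metadata, ds.panel
        write_madc(table, out / "madc.csv")
        panel.to_csv(out / "panel.csv")
        write_metadata(metadata, out / "metadata.csv")
        write_truth(ds.truth, out / "truth.json")
        report["inputs"]["simulated"] = True
        for name in ("madc.csv", "panel.csv", "metadata.csv"):
            report["inputs"][name] = _sha256(out / name)
        truth = ds.truth
    else:
        panel = PanelDefinition.from_csv(config.panel_path)
        table = read_madc(config.madc_path, panel)
        metadata = read_metadata(config.metadata_path)
        for key, p in (("madc", config.madc_path), ("panel", config.panel_path), ("metadata", config.metadata_path)):
            report["inputs"][key] = _sha256(Path(p))
        truth = None

    # --- stage 1: singleton zeroing --------------------------------------
    n_records = len(table.counts)
    table = qc.zero_singletons(table)
    _stage(report, "zero_singletons", n_records, n_records)

    # --- stage 2: presence filter ----------------------------------------
    pm = filtering.presence_matrix(table, params.presence_min_reads)
    frac = pm.values.mean(axis=1)
    retained_loci = [l for l in pm.loci if frac[l] > params.presence_percent / 100.0]
    _stage(report, "presence_filter_loci", len(pm.loci), len(retained_loci))
    curve = filtering.presence_curve(pm)
    common_loci, per_chrom = filtering.select_common_loci(pm, panel, params.common_percent)
    report["n_common_loci"] = len(common_loci)
    missing = filtering.missingness_by_sample(pm, len(panel))

    # --- stage 3: SNP extraction -----------------------------------------
    variants, paralogs = snps.extract_snps(table, panel, locus_subset=retained_loci)
    n_retained_records = int(table.counts.index.get_level_values("locus_id").isin(retained_loci).sum())
    _stage(report, "snp_extraction_paralog_haplotypes", n_retained_records, n_retained_records - len(paralogs))
    report["n_snps_extracted"] = len(variants)
    snps.emit_vcf(variants, table.samples, out / "variants.vcf")

    # --- stage 4: Hind/HE filter ------------------------------------------
    meta_idx = metadata.set_index("sample_id").reindex(table.samples)
    single_mask = (meta_idx["role"] == "single").to_numpy()
    hh = filtering.hind_he(variants, sample_mask=single_mask)
    kept_ids = set(filtering.filter_by_hindhe(hh, params.hindhe_low, params.hindhe_high))
    variants_kept = [v for v in variants if v.vcf_id in kept_ids]
    _stage(report, "hindhe_filter_snps", len(variants), len(variants_kept))
    hh.to_csv(out / "hind_he.csv")

    # --- stage 5: dosage calling ------------------------------------------
    dm = popgen.call_dosage(variants_kept, table.samples, params.min_depth, params.dosage_error_rate)
    report["dosage_missing_fraction"] = float(dm.values.isna().to_numpy().mean()) if len(variants_kept) else None

    # --- stage 6: diversity accounting and replicate correlations ---------
    diversity = qc.compare_single_vs_bulk(table, metadata)
    if len(diversity) >= 5:
        diversity = diversity.assign(lowess_single=qc.lowess_trend(diversity))
    diversity.to_csv(out / "diversity.csv", index=False)
    report["mean_replicate_r2"] = qc.mean_replicate_r2(table, metadata)

    # --- stage 7: missingness statistics -----------------------------------
    missing_df = pd.DataFrame({"sample_id": missing.index, "missing_loci": missing.to_numpy()})
    missing_df = missing_df.merge(metadata[["sample_id", "species", "source"]], on="sample_id")
    missing_df.to_csv(out / "missingness.csv", index=False)
    group_tests: dict = {}
    try:
        w, p = groupstats.levene_test(missing_df["missing_loci"], missing_df["species"])
        group_tests["levene"] = {"W": w, "p": p}
        res = groupstats.welch_anova(missing_df["missing_loci"], missing_df["species"])
        group_tests["welch"] = {"F": res.f_star, "df1": res.df1, "df2": res.df2, "p": res.p_value}
        gh = groupstats.games_howell(missing_df["missing_loci"], missing_df["species"])
        gh.to_csv(out / "games_howell.csv", index=False)
        group_tests["games_howell_letters"] = gh.attrs["letters"]
    except ValueError as exc:
        group_tests["error"] = str(exc)
        logger.info("group statistics skipped: %s", exc)
    report["group_tests"] = group_tests

    # --- stage 8: one representative single per accession ------------------
    if variants_kept:
        dp_total = np.sum([v.dp for v in variants_kept], axis=0)
    else:
        dp_total = np.zeros(len(table.samples))
    depth_by_sample = pd.Series(dp_total, index=table.samples)
    reps = []
    for accession_id, grp in metadata.groupby("accession_id", sort=True):
        singles = grp.loc[grp["role"] == "single", "sample_id"]
        if len(singles) == 0:
            continue
        reps.append(depth_by_sample[singles].sort_values(ascending=False, kind="stable").index[0])
    report["n_representatives"] = len(reps)

    # --- stage 9: structure (PCA + FST) ------------------------------------
    fst_species = pd.DataFrame()
    fst_source = None
    outliers = pd.DataFrame(columns=["accession_id", "labeled_species", "assigned_species"])
    rep_meta = metadata[metadata["sample_id"].isin(reps)].reset_index(drop=True)
    if len(variants_kept) >= 2 and len(reps) >= 3:
        rep_dm = popgen.DosageMatrix(dm.values.loc[reps], dm.min_depth, dm.error_rate)
        try:
            scores, var_frac = popgen.genotype_pca(rep_dm)
            scores.to_csv(out / "pca_scores.csv")
            report["pca_variance_fractions"] = [float(x) for x in var_frac]
        except ValueError as exc:
            logger.info("PCA skipped: %s", exc)
        fst_species = popgen.fst_matrix(rep_dm, rep_meta, level="species")
        fst_species.to_csv(out / "fst_species.csv")
        fst_source = popgen.fst_matrix(rep_dm, rep_meta, level="source")
        fst_source.to_csv(out / "fst_source.csv")

        # taxonomy-grade genetic distances use ALL extracted SNPs: the Hind/HE
        # filter removes fixed interspecies differences by construction, which
        # compresses between-species FST and distances
        dm_all = popgen.call_dosage(variants, table.samples, params.min_depth, params.dosage_error_rate)
        rep_dm_all = popgen.DosageMatrix(dm_all.values.loc[reps], dm_all.min_depth, dm_all.error_rate)
        fst_species_all = popgen.fst_matrix(rep_dm_all, rep_meta, level="species")

        # missingness vs FST distance to the least-missing (reference-like) species
        by_species = missing_df.groupby("species")["missing_loci"].mean()
        if len(by_species) >= 2 and not fst_species_all.empty:
            ref = by_species.idxmin()
            fst_to_ref = fst_species_all[ref].drop(index=ref).dropna()
            shared = [s for s in fst_to_ref.index if s in by_species.index]
            if len(shared) >= 2:
                trend, rho = groupstats.missingness_vs_fst(by_species[shared], fst_to_ref[shared])
                trend.to_csv(out / "missingness_vs_fst.csv")
                report["missingness_fst_spearman"] = rho
                report["reference_species"] = str(ref)

        # --- stage 10: phylogeny + outlier flags ---------------------------
        rep_variants = variants_kept
        seqs = phylo.sample_sequences(rep_dm, rep_variants, ad_sample_order=table.samples)
        dist = phylo.prune_missing(phylo.distance_matrix(seqs, on_error="nan"))
        _stage(report, "distance_matrix_samples", len(reps), len(dist))
        if len(dist) >= 3:
            tree_dm = popgen.DosageMatrix(rep_dm.values.loc[list(dist.index)], dm.min_depth, dm.error_rate)
            tree = phylo.bootstrap_support(
                tree_dm, rep_variants, n_reps=params.bootstrap_reps, seed=config.seed, ad_sample_order=table.samples
            )
            tree.write(out / "tree.nwk")
            report["tree_clamped_branches"] = tree.n_clamped
            if not fst_species.isna().any().any() and len(fst_species) >= 3:
                ref = report.get("reference_species", str(fst_species.index[0]))
                sp_tree = phylo.fst_species_tree(fst_species, ref)
                sp_tree.write(out / "species_tree.nwk")
        else:
            logger.info("phylogeny skipped: too few samples with computable distances")
        # mislabel flagging likewise uses the all-SNP distances
        seqs_all = phylo.sample_sequences(rep_dm_all, variants, ad_sample_order=table.samples)
        dist_all = phylo.prune_missing(phylo.distance_matrix(seqs_all, on_error="nan"))
        if len(dist_all) >= 2:
            k = min(params.outlier_k, len(dist_all) - 1)
            outliers = phylo.flag_outliers(dist_all, rep_meta, k=k, majority=params.outlier_majority)
    outliers.to_csv(out / "outliers.csv", index=False)
    report["flagged_accessions"] = outliers["accession_id"].tolist()
    if truth is not None:
        report["injected_mislabels"] = [list(m) for m in truth.mislabels]

    # --- tables + report ----------------------------------------------------
    curve.to_csv(out / "presence_curve.csv", index=False)
    per_chrom.to_csv(out / "per_chromosome.csv", index=False)
    make_tables(curve, per_chrom, fst_source, out)
    report["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in {".csv", ".vcf", ".nwk", ".json"} and p.name != "report.json"
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return RunResult(report, out, curve, per_chrom, fst_species, fst_source, outliers, diversity)


def make_tables(curve: pd.DataFrame, per_chrom: pd.DataFrame, fst_source: pd.DataFrame | None, out_dir) -> None:
    """CSV analogues of the headline summary tables: the presence curve, the
    per-chromosome distribution of common loci (with a totals row), and the
    per-species source-vs-source FST table ('–' marks unavailable pairs)."""
    out = Path(out_dir)
    curve.to_csv(out / "table1_presence_curve.csv", index=False)
    totals = pd.DataFrame(
        [
            {
                "chromosome": "Total",
                "selected": per_chrom["selected"].sum(),
                "panel": per_chrom["panel"].sum(),
                "ratio": per_chrom["selected"].sum() / per_chrom["panel"].sum() if per_chrom["panel"].sum() else np.nan,
            }
        ]
    )
    pd.concat([per_chrom, totals], ignore_index=True).to_csv(out / "table2_per_chromosome.csv", index=False)
    rows = []
    if fst_source is not None:
        species = sorted({g.rsplit("/", 1)[0] for g in fst_source.index})
        for sp in species:
            a, b = f"{sp}/Genebank", f"{sp}/Collection"
            if a in fst_source.index and b in fst_source.index and not pd.isna(fst_source.loc[a, b]):
                rows.append({"species": sp, "fst_genebank_vs_collection": f"{fst_source.loc[a, b]:.3f}"})
            else:
                rows.append({"species": sp, "fst_genebank_vs_collection": "–"})
    pd.DataFrame(rows, columns=["species", "fst_genebank_vs_collection"]).to_csv(
        out / "table3_source_fst.csv", index=False
    )
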