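import json

import numpy as np
import pytest

from madcpop.io import write_madc
from madcpop.simulate import (
    PANEL_3K_DISTRIBUTION,
    ConfigurationError,
    SimulationConfig,
    SpeciesGroup,
    _balding_nichols,
    amplification_probability,
    read_truth,
    sample_metadata,
    simulate_dataset,
    simulate_dropout,
    simulate_frequencies,
    simulate_panel,
    simulate_reads,
    write_truth,
)


def _cfg(**kw):
    kw.setdefault("n_loci", 40)
    kw.setdefault(
        "species_spec",
        (SpeciesGroup("A", 0.3, 3, "Collection"), SpeciesGroup("B", 0.8, 3, "Collection")),
    )
    return SimulationConfig(**kw)


class TestPanel:
    def test_counts_conserved_and_match_reference_distribution(self):
        panel = simulate_panel(SimulationConfig(n_loci=3000))
        by_chrom = panel.per_chromosome_counts()
        assert int(by_chrom.sum()) == 3000
        assert tuple(by_chrom[c] for c in sorted(by_chrom.index)) == PANEL_3K_DISTRIBUTION

    def test_minimal_panel_puts_one_locus_per_chromosome(self):
        panel = simulate_panel(_cfg(n_loci=8))
        assert (panel.per_chromosome_counts() == 1).all()

    def test_same_seed_identical_panels(self, tmp_path):
        a, b = (simulate_panel(_cfg(seed=9)) for _ in range(2))
        (tmp_path / "a.csv").write_text("")
        a.to_csv(tmp_path / "a.csv")
        b.to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_wrong_chromosome_count_rejected(self):
        with pytest.raises(ConfigurationError, match="8 chromosomes"):
            SimulationConfig(chromosomes=("chr1", "chr2"))

    def test_target_offsets_within_amplicon(self):
        panel = simulate_panel(_cfg(n_loci=50, amplicon_len=54))
        assert (panel.table["target_offset"] >= 0).all()
        assert (panel.table["target_offset"] < 54).all()


class TestDropout:
    def test_zero_divergence_large_intercept_all_amplify(self):
        cfg = _cfg(dropout_a=30.0)
        panel = simulate_panel(cfg)
        flags = simulate_dropout(panel, 0.0, cfg)
        assert flags.all()

    def test_amplification_probability_at_zero_logit_is_half(self):
        cfg = _cfg(dropout_a=0.0)
        assert amplification_probability(0.0, cfg) == pytest.approx(0.5)

    def test_missingness_monotone_in_divergence(self):
        # Monte-Carlo check against the closed-form sigmoid ordering (10k draws per divergence)
        cfg = _cfg(n_loci=40)
        panel = simulate_panel(cfg)
        rng = np.random.default_rng(0)
        d1, d2 = 0.3, 1.0
        miss1 = np.mean([(~simulate_dropout(panel, d1, cfg, rng)).sum() for _ in range(250)])
        miss2 = np.mean([(~simulate_dropout(panel, d2, cfg, rng)).sum() for _ in range(250)])
        p1, p2 = (1 - amplification_probability(d, cfg) for d in (d1, d2))
        assert miss1 < miss2
        assert miss1 == pytest.approx(len(panel) * p1, abs=3 * np.sqrt(len(panel) * p1 / 250) + 1)
        assert miss2 == pytest.approx(len(panel) * p2, abs=3 * np.sqrt(len(panel) * p2 / 250) + 1)


class TestFrequencies:
    def test_theta_zero_returns_ancestral_exactly(self):
        panel = simulate_panel(_cfg())
        fm = simulate_frequencies(panel, _cfg().species_spec, 0.0, 0.0, seed=1)
        for f in fm.species_freq.values():
            assert np.array_equal(f, fm.p0)

    def test_balding_nichols_variance_matches_closed_form(self):
        # Var = theta * p0 * (1 - p0); at p0=0.5, theta=0.5 this is 0.125
        rng = np.random.default_rng(12)
        draws = _balding_nichols(rng, np.full(40000, 0.5), 0.5)
        assert draws.var() == pytest.approx(0.125, abs=0.004)

    def test_theta_one_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError):
            _balding_nichols(rng, np.array([0.5]), 1.0)

    def test_offtarget_count_capped(self):
        cfg = _cfg(n_loci=200, n_offtarget_max=2)
        panel = simulate_panel(cfg)
        fm = simulate_frequencies(panel, cfg.species_spec, 0.2, 0.0, seed=3, n_offtarget_max=2)
        per_locus = fm.sites.groupby("locus_id").size()
        assert per_locus.max() <= 3  # target + at most 2 off-target
        assert fm.sites.groupby("locus_id")["is_target"].sum().eq(1).all()


class TestGenotypes:
    def test_full_selfing_gives_no_heterozygotes(self):
        cfg = _cfg(selfing_F=1.0)
        ds = simulate_dataset(cfg)
        for arr in ds.truth.genotypes.values():
            assert np.array_equal(arr[:, :, 0], arr[:, :, 1])

    def test_outcrossing_heterozygosity_matches_frequencies(self):
        # With F=0 the per-site het fraction should match mean 2p(1-p)
        cfg = _cfg(n_loci=150, selfing_F=0.0, species_spec=(SpeciesGroup("A", 0.2, 8, "Collection"),))
        ds = simulate_dataset(cfg)
        fm = ds.truth.frequencies
        site_index = fm.locus_site_index()
        p = fm.group_freq[("A", "Collection")]
        het_obs, het_exp, n_sites = 0.0, 0.0, 0
        for lid, idx in site_index.items():
            g = ds.truth.genotypes[lid]
            for j, site in enumerate(idx):
                bit = 1 << j
                het_obs += (((g & bit) > 0)[:, :, 0] != ((g & bit) > 0)[:, :, 1]).mean()
                het_exp += 2 * p[site] * (1 - p[site])
                n_sites += 1
        assert het_obs / n_sites == pytest.approx(het_exp / n_sites, abs=0.01)

    def test_design_is_three_singles_plus_bulk_of_seven(self):
        meta = sample_metadata(_cfg())
        by_acc = meta.groupby("accession_id")
        assert (by_acc["role"].apply(lambda r: (r == "single").sum()) == 3).all()
        assert (by_acc["role"].apply(lambda r: (r == "bulk").sum()) == 1).all()
        assert set(meta.loc[meta["role"] == "bulk", "plant_count"]) == {7}


class TestReads:
    def test_read_counts_conserve_drawn_depth(self):
        cfg = _cfg(error_rate=0.3)
        panel = simulate_panel(cfg)
        fm = simulate_frequencies(panel, cfg.species_spec, cfg.theta_between, cfg.theta_within, cfg.seed)
        from madcpop.simulate import simulate_accessions

        truth = simulate_accessions(fm, cfg)
        table, depths = simulate_reads(truth, panel, cfg, return_depths=True)
        err_mask = table.counts.index.get_level_values("hap_id").str.startswith("Err")
        real = table.counts[~err_mask].groupby(level="locus_id", sort=False).sum()
        for lid in panel.locus_ids:
            expected = depths[lid]
            got = real.loc[lid].to_numpy() if lid in real.index else np.zeros_like(expected)
            assert np.array_equal(got, expected)
        # error haplotypes have exactly depth 1 per sample
        err = table.counts[err_mask]
        assert err.to_numpy().max() <= 1

    def test_error_rate_one_every_amplified_locus_has_error_read(self):
        cfg = _cfg(error_rate=1.0)
        ds = simulate_dataset(cfg)
        err = ds.madc.counts[ds.madc.counts.index.get_level_values("hap_id").str.startswith("Err")]
        err_by_locus = err.groupby(level="locus_id", sort=False).sum()
        amp = np.stack([ds.truth.amplification[s] for s in cfg.species_names])
        for li, lid in enumerate(ds.panel.locus_ids):
            if amp[:, li].any():
                assert lid in err_by_locus.index and err_by_locus.loc[lid].sum() > 0

    def test_reads_trace_to_truth_genotypes(self):
        # without error reads, a single plant's counts land only on its own two haplotypes
        cfg = _cfg(error_rate=0.0)
        ds = simulate_dataset(cfg)
        truth, panel = ds.truth, ds.panel
        sites = truth.frequencies.locus_site_index()
        meta = ds.metadata
        acc_pos = {a: i for i, a in enumerate(truth.accessions["accession_id"])}
        for sample in [s for s in ds.madc.samples if s.endswith("_P1")][:5]:
            acc = meta.loc[meta["sample_id"] == sample, "accession_id"].iloc[0]
            emitted = set(ds.madc.counts.index.get_level_values("locus_id"))
            for lid in [l for l in panel.locus_ids if l in emitted][:10]:
                block = ds.madc.counts.xs(lid, level="locus_id")[sample]
                observed = set(block[block > 0].index)
                masks = set(truth.genotypes[lid][acc_pos[acc], 0, :].tolist())
                locus = panel.get(lid)
                offsets = truth.frequencies.sites.iloc[sites[lid]]["offset"].to_numpy()
                alts = truth.frequencies.sites.iloc[sites[lid]]["alt"].to_numpy()
                allowed = set()
                for m in masks:
                    seq = list(locus.ref_amplicon)
                    for j in range(len(offsets)):
                        if m & (1 << j):
                            seq[offsets[j]] = alts[j]
                    allowed.add("".join(seq))
                seqs = ds.madc.sequences.xs(lid, level="locus_id")
                assert {seqs[h] for h in observed} <= allowed


class TestDeterminismAndTruth:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = _cfg(seed=77, mislabel_swaps=(("ACC0002", "B"),))
        for tag in ("x", "y"):
            ds = simulate_dataset(cfg)
            write_madc(ds.madc, tmp_path / f"{tag}.csv")
            write_truth(ds.truth, tmp_path / f"{tag}.json")
        assert (tmp_path / "x.csv").read_bytes() == (tmp_path / "y.csv").read_bytes()
        assert (tmp_path / "x.json").read_bytes() == (tmp_path / "y.json").read_bytes()

    def test_truth_round_trip(self, tmp_path):
        cfg = _cfg(seed=5, mislabel_swaps=(("ACC0001", "B"),))
        ds = simulate_dataset(cfg)
        write_truth(ds.truth, tmp_path / "truth.json")
        back = read_truth(tmp_path / "truth.json")
        assert back.mislabels == (("ACC0001", "B"),)
        assert back.config == cfg
        assert set(back.genotypes) == set(ds.truth.genotypes)
        for lid in ds.truth.genotypes:
            assert np.array_equal(back.genotypes[lid], ds.truth.genotypes[lid])
        for sp in ds.truth.amplification:
            assert np.array_equal(back.amplification[sp], ds.truth.amplification[sp])
        assert np.allclose(back.frequencies.p0, ds.truth.frequencies.p0)

    def test_empty_mislabels_round_trip(self, tmp_path):
        ds = simulate_dataset(_cfg(seed=6))
        write_truth(ds.truth, tmp_path / "truth.json")
        assert json.loads((tmp_path / "truth.json").read_text())["mislabels"] == []

    def test_bulk_composition_is_plants_4_to_10(self):
        meta = sample_metadata(_cfg())
        bulk = meta[meta["role"] == "bulk"].iloc[0]
        assert bulk["plant_count"] == 7
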