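"""Generate a small synthetic MADC dataset and look at what it contains.

Builds a 3-species panel-transfer scenario (300 loci, selfing diploids,
3 singles + 1 bulk per accession), writes the MADC CSV, panel, metadata and
truth sidecar, and prints the headline sizes.
"""

from pathlib import Path

from madcpop import SimulationConfig, SpeciesGroup, simulate_dataset, write_madc, write_metadata, write_truth

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(
    n_loci=300,
    species_spec=(
        SpeciesGroup("M. alpha", 0.3, 6, "Collection"),
        SpeciesGroup("M. beta", 0.6, 6, "Collection"),
        SpeciesGroup("M. gamma", 0.9, 6, "Genebank"),
    ),
    seed=11,
)
ds = simulate_dataset(config)
write_madc(ds.madc, out / "madc.csv")
ds.panel.to_csv(out / "panel.csv")
write_metadata(ds.metadata, out / "metadata.csv")
write_truth(ds.truth, out / "truth.json")

n_records = len(ds.madc.counts)
n_samples = len(ds.madc.samples)
print(f"panel: {len(ds.panel)} loci on {ds.panel.table['chromosome'].nunique()} chromosomes")
print(f"MADC: {n_records} microhaplotype records x {n_samples} samples -> {out / 'madc.csv'}")
for species, flags in ds.truth.amplification.items():
    print(f"  {species}: {int((~flags).sum())} of {len(flags)} loci dropped (divergence-dependent)")
# Each accession contributes 3 single-plant samples and 1 bulk of 7 plants;
# more divergent species lose more loci, which is the signal the downstream
# missingness analyses quantify.
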