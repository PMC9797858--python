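"""Simulate a grouped gut-microbiome study with a known assembly regime.

Generates a 6-source x 3-replicate OTU table (100 taxa, 5,000 reads per
sample) under divergent environmental filtering, writes the three
standard input files, and prints the design summary.
"""

from ecoassembly import ScenarioConfig, simulate_scenario, write_inputs

cfg = ScenarioConfig(
    n_taxa=100, depth=5000, regime="filtering_divergent", seed=42
)
truth = simulate_scenario(cfg)
paths = write_inputs(truth, "scratch/example_inputs")

rel = truth.table.relative().counts
dominant = rel[:, truth.metacommunity.argmax()]
print(f"samples: {truth.table.n_samples}  taxa: {truth.table.n_taxa}")
print(f"groups: {sorted(set(truth.metadata.data['group']))}")
print(f"dominant taxon share per sample: {dominant.min():.2f}-{dominant.max():.2f}")
print(f"expected between-source process: {truth.expected_between_processes}")
print("wrote:", ", ".join(paths.values()))
# The dominant generalist spans every source (like Enterococcus in real
# lepidopteran guts); the minor taxa are confined to one of two lineages
# per source, which is what the assembly inference should detect.
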