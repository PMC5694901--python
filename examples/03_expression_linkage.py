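"""Link enhancer activity to nearest-gene expression in rank bins.

With expression coupled to open-enhancer activity, the median RPKM of
nearest genes increases monotonically across five activity rank bins.
"""
from starrkit import expression_by_bins
from starrkit.calling import EnhancerPeak
from starrkit.simulate import SimulationConfig, simulate_expression_and_tsa, simulate_genome

config = SimulationConfig(
    seed=3, n_enhancers=100, genome_length=50_000_000, n_genes=1000,
    fraction_open=1.0, n_input_fragments=0, n_output_fragments=0,
)
truth = simulate_genome(config)
expression, _ = simulate_expression_and_tsa(config, truth)
peaks = [EnhancerPeak(e.region, 10, 5, e.activity, 1e-4, 1e-4) for e in truth.enhancers]

summary = expression_by_bins(
    peaks, truth.genes, expression, n_bins=5,
    samples=[c for c in expression.counts.columns if c.startswith("vehicle")],
).sort_values("activity_bin")

print("activity bin (0 = weakest) -> nearest-gene RPKM")
for _, row in summary.iterrows():
    print(f"  bin {int(row['activity_bin'])}: n={int(row['n']):3d}  "
          f"median {row['median']:8.1f}  mean {row['mean']:8.1f}")
print("medians rise with enhancer strength: stronger reporters sit near "
      "more highly expressed genes")
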