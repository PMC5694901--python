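"""Simulate a STARR-seq study, deduplicate, and call enhancer peaks.

Builds a 10-Mb synthetic genome with 100 planted enhancers (activity
fold 3), samples index-multiplexed input/output fragment libraries,
collapses PCR duplicates per index sublibrary, pools distinct fragments,
and calls peaks by Poisson enrichment of output over input.
"""
import numpy as np

from starrkit import call_enhancers, enhancer_activity, overlaps_any
from starrkit.simulate import SimulationConfig, simulate_fragment_libraries, simulate_genome

config = SimulationConfig(
    seed=1,
    n_enhancers=100,
    activity_fixed=3.0,
    n_input_fragments=250_000,
    n_output_fragments=250_000,
)
truth = simulate_genome(config)
input_set, output_set = simulate_fragment_libraries(config, truth)
print(f"raw reads: input {len(input_set):,}, output {len(output_set):,}")

input_lib = input_set.dedup_pool("input")
output_lib = output_set.dedup_pool("output")
print(f"pooled distinct fragments: input {input_lib.library_size:,}, "
      f"output {output_lib.library_size:,}")

peaks = call_enhancers(output_lib, input_lib, config.genome)
planted = [e.region for e in truth.enhancers]
recall = overlaps_any(planted, [p.interval for p in peaks]).mean()
est = np.mean([enhancer_activity(e.region, output_lib, input_lib) for e in truth.enhancers])

print(f"called {len(peaks)} peaks for {len(planted)} planted enhancers "
      f"(recall {100 * recall:.1f}%)")
print(f"mean estimated activity over planted regions: {est:.2f} (planted fold 3.0; "
      "the slight deficit is fragment-overhang dilution at the region edges)")
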