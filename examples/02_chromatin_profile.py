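"""Classify enhancers by accessibility and profile a chromatin mark.

Open enhancers (those overlapping an accessibility peak by >= 1 bp)
should carry the active mark; the meta-profile shows its signal-over-
input fold enrichment in 100-bp bins across +/-10 kb of peak centers.
"""
import numpy as np

from starrkit import classify_by_accessibility, meta_profile
from starrkit.calling import EnhancerPeak
from starrkit.simulate import SimulationConfig, simulate_genome, simulate_signal_reads

config = SimulationConfig(seed=2, n_enhancers=200, n_input_fragments=0, n_output_fragments=0)
truth = simulate_genome(config)
peaks = [EnhancerPeak(e.region, 10, 5, e.activity, 1e-4, 1e-4) for e in truth.enhancers]

classify_by_accessibility(peaks, truth.accessibility_peaks)
n_open = sum(p.accessibility_class == "open" for p in peaks)
print(f"{n_open}/{len(peaks)} enhancers are open "
      f"({100 * n_open / len(peaks):.1f}%; the generator plants 12.7%)")

signal, chromatin_input = simulate_signal_reads(config, truth, "active_mark")
open_regions = [p.interval for p in peaks if p.accessibility_class == "open"]
closed_regions = [p.interval for p in peaks if p.accessibility_class == "closed"]
for label, regions in (("open", open_regions), ("closed", closed_regions)):
    prof = meta_profile(regions, signal, chromatin_input, genome=config.genome)
    central = prof.fold_enrichment[95:105].mean()
    flank = np.r_[prof.fold_enrichment[:20], prof.fold_enrichment[-20:]].mean()
    print(f"{label:>6} enhancers: central fold enrichment {central:.2f}, "
          f"flanks {flank:.2f}  (n={prof.n_regions})")
print("the active mark piles up only at open enhancers; flanks sit near 1.0")
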