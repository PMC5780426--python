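"""Over-representation analysis with the fold-above-mean filter.

Builds annotations with one strongly planted term among 49 null terms,
tests the consensus target genes against them, and shows how the
data-driven fold threshold (mean + 1 SD of fold over non-empty terms)
combines with the p < 1e-6 cutoff.
"""

import exocargo as ec
from exocargo.simulate import (SimConfig, simulate_target_db,
                               simulate_annotations, _gene_ids, _mirna_ids)

cfg = SimConfig(seed=1, planted_terms=(("T050", "strong"),))
cargo_mirnas = _mirna_ids(23)
db, truth = simulate_target_db(cfg, cargo_mirnas)
annotations, _ = simulate_annotations(cfg, _gene_ids(cfg.n_genes),
                                      truth.true_edges, cargo_mirnas)
cts = ec.consensus_filter(db, cargo_mirnas, min_support=5)

result = ec.bespoke_filter(ec.run_ora(cts.genes, annotations))
print(f"query: {len(cts.genes)} consensus target genes; "
      f"{len(result.table)} terms tested")
print(f"fold distribution: mean {result.summary['fold_mean']:.2f}, "
      f"sd {result.summary['fold_sd']:.2f} "
      f"-> threshold {result.summary['fold_threshold']:.2f}")

sig = result.table[result.table["significant"]]
cols = ["term_id", "k", "K", "fold", "p", "q"]
print("\nsignificant terms (fold > threshold AND p < 1e-6):")
print(sig[cols].to_string(index=False))
print("\ntrend terms (miss significance, 1e-6 <= p < 0.1):")
print(ec.trend_report(result)[cols].head(5).to_string(index=False))
print("\nThe planted term T050 should be the lone significant hit; null")
print("terms hover at fold ~1 and never clear the extreme p cutoff.")
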