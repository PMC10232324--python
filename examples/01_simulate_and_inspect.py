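"""Generate a synthetic enzyme dataset with planted, motif-bound EC labels.

Builds a small hierarchical label space, simulates sequences, and shows
that the planted motifs determine the labels exactly when noise is off.
"""

import enzannot as ez

config = ez.SimConfig(
    n_records=200,
    length_range=(60, 120),
    label_counts=(2, 2, 1, 2),  # 8 depth-4 EC labels
    motif_len=6,
    non_enzyme_fraction=0.3,
    mutation_rate=0.0,
    seed=7,
)
space = ez.build_label_space(2, 2, 1, 2, motif_len=6, seed=7)
table, truth = ez.simulate_records(config, space)

n_enz = sum(1 for r in table if r.is_enzyme)
print(f"{len(table)} records: {n_enz} enzymes, {len(table) - n_enz} non-enzymes")
print(f"label space: {[str(ec) for ec in space.labels]}")

r = next(iter(table))
print(f"\nexample enzyme {r.id}: labels {[str(e) for e in r.ec_numbers]}")
for entry in truth:
    if entry.record_id == r.id:
        print(f"  motif {entry.motif} for {entry.ec} planted at {entry.position}")

# with mutation_rate=0 the motif-matching oracle is perfect: this is the
# ceiling any trained model can reach on this data
predicted = {r.id: ez.motif_oracle(r.sequence, space) for r in table}
rep = ez.evaluate_predictions(table, predicted, task=3)
print(f"\nmotif-oracle macro-F1 at zero noise: {rep['mf1']:.3f} (the ceiling)")
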