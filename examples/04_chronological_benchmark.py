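"""Build a chronological benchmark: date-based split, overlap filtering,
novel-label exclusion — the honest way to test annotation tools on
"future" proteins."""

import datetime as dt

import enzannot as ez
from enzannot.ec import parse_ec
from enzannot.metrics import chronological_split, filter_novel_labels
from enzannot.records import AnnotationTable, ProteinRecord

config = ez.SimConfig(n_records=300, test_fraction=0.3, seed=21)
space = ez.standard_benchmark_space(config)
table, _ = ez.simulate_records(config, space)

# two hand-made "future" records: one re-deposits a training sequence
# under a new id, one carries an EC number absent from training
old = next(r for r in table if r.date_added <= config.cutoff and r.is_enzyme)
later = config.cutoff + dt.timedelta(days=400)
table = AnnotationTable(
    table.records
    + [
        ProteinRecord("redeposit", old.sequence, old.is_enzyme,
                      old.ec_numbers, later),
        ProteinRecord("novel_ec", "MKLV" * 20, True,
                      (parse_ec("9.9.9.9"),), later),
    ]
)

train, (test,), log = chronological_split(
    table, config.cutoff,
    [(config.cutoff + dt.timedelta(days=1), config.cutoff + dt.timedelta(days=999))],
)
w = log["windows"][0]
print(f"train (dated <= {config.cutoff}): {len(train)} records")
print(f"test window: {w['candidates']} candidates, "
      f"{w['removed_overlap']} removed as exact-sequence re-depositions, "
      f"{w['kept']} kept")

kept, excluded = filter_novel_labels(test, set(train.vocabulary))
print(f"novel-EC exclusion: {len(excluded)} records carry ECs unseen in "
      f"training and cannot be scored fairly; {len(kept)} remain evaluable")
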