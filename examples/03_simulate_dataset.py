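"""Generate a synthetic four-library SuperSAGE dataset with ground truth.

Writes a toy genome, gene models (GFF3), transcripts, four tag-count
libraries (TS/TC/SS/SC: tolerant and sensitive accessions, stress and
control) and a truth table into a directory, then prints what was planted.
"""

import tempfile
from pathlib import Path

import pandas as pd

from supersage import SimulationConfig, simulate_dataset

config = SimulationConfig(
    n_chromosomes=4,
    chromosome_length=150_000,
    n_loci=40,
    families={"TPS": 4, "IMP": 3, "P5CS": 2},
    library_depth=100_000,
    seed=11,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = simulate_dataset(config, Path(tmp) / "sim")
    truth = pd.read_csv(paths["truth"], sep="\t")
    counts = pd.read_csv(paths["tags_TS"], sep="\t")
    print("files written:", sorted(p.name for p in (Path(tmp) / "sim").iterdir()))
    print("TS library:", counts["count"].sum(), "tags in", len(counts), "unitags")
    print("truth rows by mechanism:")
    print(truth["kind"].value_counts().to_string())
    spiked = truth[truth.spiked_fc > 1]
    print("spiked tags:", len(spiked), "with fold changes",
          sorted(float(f) for f in spiked.spiked_fc.unique()))
print()
print("Every non-noise tag is traceable to its source transcript and anchor;")
print("the truth table also records per-contrast regulation classes.")
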