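"""Anchor gene loci on chromosomes, call clusters and synteny links.

Places the simulated loci on their pseudochromosomes, classifies arm
positions (subterminal / intercalary / pericentromeric), chains loci into
max-gap clusters, reports cross-chromosome family redundancy as synteny
links, and writes Circos-format karyotype/links/tile files.
"""

import tempfile
from pathlib import Path

import pandas as pd

from supersage import (
    SimulationConfig,
    anchor_loci,
    call_clusters,
    distribution_summary,
    find_synteny_links,
    generate_genome,
    write_circos,
)

config = SimulationConfig(
    n_chromosomes=4, chromosome_length=150_000, n_loci=40,
    families={"TPS": 4, "IMP": 3, "P5CS": 2}, library_depth=100_000, seed=11,
)
genome = generate_genome(config)
loci = pd.DataFrame(genome.loci)
lengths = {c: len(s) for c, s in genome.chromosomes.items()}

anchors, unplaced = anchor_loci(
    loci[["locus_id", "family", "chrom", "start", "end"]], lengths
)
summary = distribution_summary(anchors, lengths)
print(f"{summary['n_loci']} loci on {summary['chromosomes_with_loci']} of "
      f"{summary['n_chromosomes']} chromosomes; arm classes: {summary['arm_classes']}")

clusters = call_clusters(anchors, max_gap=30_000, min_size=2)
for cluster in clusters:
    print(f"cluster on {cluster.chromosome} [{cluster.start}-{cluster.end}] "
          f"with {len(cluster)} loci, families {cluster.families or ('-',)}")

links = find_synteny_links(anchors)
print(f"{len(links)} synteny links from families shared across chromosomes")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_circos(anchors, links, lengths, Path(tmp))
    print("Circos karyotype line:", paths["karyotype"].read_text().splitlines()[0])
    print("Circos link line:     ", paths["links"].read_text().splitlines()[0])
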