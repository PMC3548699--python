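"""Chromosomal distribution of matched loci.

Anchors gene loci onto (pseudo)chromosomes using their gene-model
coordinates, classifies each anchor's arm position (subterminal: midpoint
within the outer fraction of an arm; pericentromeric: midpoint within a
window around the centromere; intercalary otherwise), calls gene clusters
by max-gap chaining, reports cross-chromosome family redundancy as
"synteny" links (family-level, not alignment-based collinearity), and
exports Circos plain-text karyotype / links / tile files.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from supersage.models import AnchorRecord, Cluster, SyntenyLink

ARM_SUBTERMINAL = "subterminal"
ARM_INTERCALARY = "intercalary"
ARM_PERICENTROMERIC = "pericentromeric"

# fixed palette for Circos output; families beyond the list reuse grey
_FAMILY_COLORS = {
    "P5CS": "red", "P5CR": "dred", "TPS": "green", "TPP": "dgreen",
    "BADH": "purple", "CMO": "dpurple", "MIPS": "orange", "IMP": "dorange",
}
_DEFAULT_COLOR = "grey"


def classify_arm_position(
    midpoint: float,
    chromosome_length: int,
    centromere_fraction: float = 0.5,
    subterminal_fraction: float = 0.15,
    pericentromere_fraction: float = 0.05,
) -> str:
    """Arm position class of a locus midpoint.

    Pericentromeric wins when the midpoint falls within +-
    ``pericentromere_fraction`` of the chromosome length around the
    centromere; subterminal when it lies within the outer
    ``subterminal_fraction`` of its arm (measured from the telomere).
    """
    cen = centromere_fraction * chromosome_length
    if abs(midpoint - cen) <= pericentromere_fraction * chromosome_length:
        return ARM_PERICENTROMERIC
    if midpoint < cen:
        arm_len, dist = cen, midpoint
    else:
        arm_len, dist = chromosome_length - cen, chromosome_length - midpoint
    if arm_len > 0 and dist <= subterminal_fraction * arm_len:
        return ARM_SUBTERMINAL
    return ARM_INTERCALARY


def anchor_loci(
    locus_table: list[dict] | pd.DataFrame,
    chromosome_lengths: dict[str, int],
    centromere_fraction: float = 0.5,
    subterminal_fraction: float = 0.15,
    pericentromere_fraction: float = 0.05,
) -> tuple[list[AnchorRecord], list[dict]]:
    """One anchor per locus from gene-model coordinates.

    ``locus_table`` rows need locus_id, family, chrom, start, end (0-based
    half-open, as read from the GFF3 by :func:`supersage.io.read_locus_table`).
    Loci on sequences absent from ``chromosome_lengths`` are returned
    separately as unplaced.  A locus without coordinates is an error.
    """
    if isinstance(locus_table, pd.DataFrame):
        locus_table = locus_table.to_dict("records")
    records: list[AnchorRecord] = []
    unplaced: list[dict] = []
    for row in locus_table:
        if row.get("start") is None or row.get("end") is None:
            raise ValueError(f"locus {row.get('locus_id')!r} has no coordinates")
        if row["chrom"] not in chromosome_lengths:
            unplaced.append(row)
            continue
        length = chromosome_lengths[row["chrom"]]
        midpoint = (row["start"] + row["end"]) / 2
        records.append(
            AnchorRecord(
                locus_id=row["locus_id"],
                family=row.get("family"),
                chromosome=row["chrom"],
                start=row["start"] + 1,
                end=row["end"],
                arm_class=classify_arm_position(
                    midpoint, length, centromere_fraction,
                    subterminal_fraction, pericentromere_fraction,
                ),
            )
        )
    records.sort(key=lambda r: (r.chromosome, r.start, r.locus_id))
    return records, unplaced


def call_clusters(
    anchors: list[AnchorRecord], max_gap: int = 1_000_000, min_size: int = 2
) -> list[Cluster]:
    """Maximal runs of anchors with inter-locus gap <= max_gap, kept when
    they contain >= min_size members.  Deterministic: anchors are processed
    sorted by (chromosome, start)."""
    by_chrom: dict[str, list[AnchorRecord]] = defaultdict(list)
    for anchor in anchors:
        by_chrom[anchor.chromosome].append(anchor)
    clusters = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda a: (a.start, a.locus_id))
        run = [members[0]]
        for anchor in members[1:]:
            gap = max(0, anchor.start - run[-1].end - 1)
            if gap <= max_gap:
                run.append(anchor)
            else:
                if len(run) >= min_size:
                    clusters.append(Cluster(chromosome=chrom, members=run))
                run = [anchor]
        if len(run) >= min_size:
            clusters.append(Cluster(chromosome=chrom, members=run))
    return clusters


def find_synteny_links(anchors: list[AnchorRecord]) -> list[SyntenyLink]:
    """Cross-chromosome family redundancy.

    For each family, the loci on one chromosome are merged into a single
    family interval (min start to max end); every unordered pair of
    chromosomes holding the family yields one link between the two
    intervals.  Unlabelled loci (no family) produce no links.
    """
    spans: dict[str, dict[str, tuple[int, int]]] = defaultdict(dict)
    for anchor in anchors:
        if not anchor.family:
            continue
        current = spans[anchor.family].get(anchor.chromosome)
        if current is None:
            spans[anchor.family][anchor.chromosome] = (anchor.start, anchor.end)
        else:
            spans[anchor.family][anchor.chromosome] = (
                min(current[0], anchor.start),
                max(current[1], anchor.end),
            )
    links = []
    for family in sorted(spans):
        chroms = sorted(spans[family])
        for i in range(len(chroms)):
            for j in range(i + 1, len(chroms)):
                sa = spans[family][chroms[i]]
                sb = spans[family][chroms[j]]
                links.append(
                    SyntenyLink(
                        family=family,
                        chromosome_a=chroms[i], start_a=sa[0], end_a=sa[1],
                        chromosome_b=chroms[j], start_b=sb[0], end_b=sb[1],
                    )
                )
    return links


def distribution_summary(
    anchors: list[AnchorRecord], chromosome_lengths: dict[str, int]
) -> dict:
    """Per-chromosome locus counts, empty chromosomes, arm-class tallies."""
    per_chrom = {c: 0 for c in sorted(chromosome_lengths)}
    arm_classes = {ARM_SUBTERMINAL: 0, ARM_INTERCALARY: 0, ARM_PERICENTROMERIC: 0}
    for anchor in anchors:
        per_chrom[anchor.chromosome] = per_chrom.get(anchor.chromosome, 0) + 1
        arm_classes[anchor.arm_class] += 1
    occupied = [c for c, n in per_chrom.items() if n > 0]
    return {
        "n_loci": len(anchors),
        "per_chromosome": per_chrom,
        "chromosomes_with_loci": len(occupied),
        "n_chromosomes": len(per_chrom),
        "empty_chromosomes": [c for c, n in per_chrom.items() if n == 0],
        "arm_classes": arm_classes,
    }


# ---------------------------------------------------------------------------
# Circos plain-text export

def write_circos(
    anchors: list[AnchorRecord],
    links: list[SyntenyLink],
    chromosome_lengths: dict[str, int],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write Circos karyotype, links and tile files (1-based inclusive).

    Karyotype lines follow the plain-text dialect
    ``chr - <id> <label> <start> <end> <color>``; link lines are
    ``<chrA> <startA> <endA> <chrB> <startB> <endB> color=<family color>``;
    tiles mark gene positions.  A link on a chromosome missing from the
    karyotype is an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for link in links:
        for chrom in (link.chromosome_a, link.chromosome_b):
            if chrom not in chromosome_lengths:
                raise ValueError(
                    f"link chromosome {chrom} absent from the karyotype"
                )
    paths = {
        "karyotype": outdir / "karyotype.txt",
        "links": outdir / "links.txt",
        "tiles": outdir / "tiles.txt",
    }
    karyotype = [
        f"chr - {chrom} {chrom} 1 {length} grey"
        for chrom, length in sorted(chromosome_lengths.items())
    ]
    paths["karyotype"].write_text("\n".join(karyotype) + "\n" if karyotype else "")
    link_lines = [
        f"{l.chromosome_a} {l.start_a} {l.end_a} {l.chromosome_b} {l.start_b} "
        f"{l.end_b} color={_FAMILY_COLORS.get(l.family, _DEFAULT_COLOR)}"
        for l in links
    ]
    paths["links"].write_text("\n".join(link_lines) + "\n" if link_lines else "")
    tile_lines = [
        f"{a.chromosome} {a.start} {a.end} "
        f"fill_color={_FAMILY_COLORS.get(a.family, _DEFAULT_COLOR)}"
        for a in anchors
    ]
    paths["tiles"].write_text("\n".join(tile_lines) + "\n" if tile_lines else "")
    return paths


def read_circos_karyotype(path: str | Path) -> dict[str, int]:
    lengths = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split()
        if fields[0] != "chr" or fields[1] != "-":
            raise ValueError(f"not a karyotype line: {line!r}")
        lengths[fields[2]] = int(fields[5])
    return lengths


def read_circos_links(path: str | Path) -> list[tuple[str, int, int, str, int, int]]:
    links = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split()
        links.append(
            (fields[0], int(fields[1]), int(fields[2]),
             fields[3], int(fields[4]), int(fields[5]))
        )
    return links


def read_circos_tiles(path: str | Path) -> list[tuple[str, int, int]]:
    tiles = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split()
        tiles.append((fields[0], int(fields[1]), int(fields[2])))
    return tiles


def anchors_to_frame(anchors: list[AnchorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": a.locus_id,
                "family": a.family or "",
                "chromosome": a.chromosome,
                "start": a.start,
                "end": a.end,
                "arm_class": a.arm_class,
            }
            for a in anchors
        ],
        columns=["locus_id", "family", "chromosome", "start", "end", "arm_class"],
    )
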