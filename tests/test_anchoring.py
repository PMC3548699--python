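"""Arm position classes, max-gap clusters, synteny links, Circos files."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_clusters
from supersage.anchoring import (
    ARM_INTERCALARY,
    ARM_PERICENTROMERIC,
    ARM_SUBTERMINAL,
    anchor_loci,
    anchors_to_frame,
    call_clusters,
    classify_arm_position,
    distribution_summary,
    find_synteny_links,
    read_circos_karyotype,
    read_circos_links,
    read_circos_tiles,
    write_circos,
)
from supersage.models import AnchorRecord


def _anchor(locus, chrom, start, end, family=None, arm=ARM_INTERCALARY):
    return AnchorRecord(locus_id=locus, family=family, chromosome=chrom,
                        start=start, end=end, arm_class=arm)


def test_arm_position_classes():
    # outer 15% of a 500 kb arm on a 1 Mb chromosome
    assert classify_arm_position(1050, 1_000_000) == ARM_SUBTERMINAL
    assert classify_arm_position(999_000, 1_000_000) == ARM_SUBTERMINAL
    assert classify_arm_position(505_000, 1_000_000) == ARM_PERICENTROMERIC
    assert classify_arm_position(300_000, 1_000_000) == ARM_INTERCALARY


def test_anchor_loci_classifies_and_reports_unplaced():
    table = [
        {"locus_id": "L1", "family": "TPS", "chrom": "Chr01", "start": 99, "end": 2000},
        {"locus_id": "L2", "family": None, "chrom": "scaffold_7", "start": 0, "end": 100},
    ]
    anchors, unplaced = anchor_loci(table, {"Chr01": 1_000_000})
    assert len(anchors) == 1 and anchors[0].arm_class == ARM_SUBTERMINAL
    assert anchors[0].start == 100 and anchors[0].end == 2000  # 1-based out
    assert [u["locus_id"] for u in unplaced] == ["L2"]
    assert anchor_loci([], {"Chr01": 10})[0] == []
    with pytest.raises(ValueError, match="no coordinates"):
        anchor_loci([{"locus_id": "L3", "chrom": "Chr01", "start": None, "end": None}],
                    {"Chr01": 10})


def test_call_clusters_simple_cases():
    anchors = [
        _anchor("A", "Chr01", 10_000, 11_000),
        _anchor("B", "Chr01", 20_000, 21_000),
        _anchor("C", "Chr01", 500_000, 501_000),
    ]
    clusters = call_clusters(anchors, max_gap=100_000, min_size=2)
    assert len(clusters) == 1
    assert {m.locus_id for m in clusters[0].members} == {"A", "B"}
    assert call_clusters(anchors, max_gap=1_000, min_size=2) == []


def test_clusters_match_brute_force_oracle():
    rng = np.random.default_rng(23)
    for _ in range(30):
        n = int(rng.integers(2, 60))
        anchors = []
        for i in range(n):
            start = int(rng.integers(1, 900_000))
            anchors.append(
                _anchor(f"L{i}", f"Chr{int(rng.integers(1, 4))}", start,
                        start + int(rng.integers(500, 3_000)))
            )
        max_gap = int(rng.integers(1_000, 200_000))
        clusters = call_clusters(anchors, max_gap=max_gap, min_size=2)
        got = {frozenset(m.locus_id for m in c.members) for c in clusters}
        assert got == brute_force_clusters(anchors, max_gap, 2)


def test_cluster_membership_partitions_anchors():
    rng = np.random.default_rng(31)
    anchors = []
    for i in range(50):
        start = int(rng.integers(1, 400_000))
        anchors.append(_anchor(f"L{i}", "Chr01", start, start + 1000))
    clusters = call_clusters(anchors, max_gap=20_000, min_size=2)
    clustered = [m.locus_id for c in clusters for m in c.members]
    assert len(clustered) == len(set(clustered))  # each anchor in <= 1 cluster
    singletons = {a.locus_id for a in anchors} - set(clustered)
    assert len(clustered) + len(singletons) == len(anchors)


def test_synteny_links_per_family():
    anchors = [
        _anchor("L1", "Chr02", 100, 200, family="TPS"),
        _anchor("L2", "Chr14", 300, 400, family="TPS"),
        _anchor("L3", "Chr05", 1, 50, family="IMP"),
        _anchor("L4", "Chr01", 9, 90),  # unlabelled: never linked
    ]
    links = find_synteny_links(anchors)
    assert len(links) == 1
    link = links[0]
    assert link.family == "TPS"
    assert {link.chromosome_a, link.chromosome_b} == {"Chr02", "Chr14"}


def test_planted_redundant_families_are_recovered(small_dataset):
    genome, _transcripts, _counts, _truth = small_dataset
    loci = pd.DataFrame(genome.loci)
    anchors, _ = anchor_loci(
        loci[["locus_id", "family", "chrom", "start", "end"]],
        {c: len(s) for c, s in genome.chromosomes.items()},
    )
    links = find_synteny_links(anchors)
    linked_families = {l.family for l in links}
    redundant = {
        fam: set(group.chrom)
        for fam, group in loci[loci.family.notna()].groupby("family")
        if group.chrom.nunique() >= 2
    }
    assert redundant, "generator should plant multi-chromosome families"
    assert set(redundant) <= linked_families


def test_distribution_summary_names_empty_chromosomes():
    lengths = {f"Chr0{i}": 100_000 for i in range(1, 5)}
    anchors = [
        _anchor("L1", "Chr01", 1, 10, arm=ARM_SUBTERMINAL),
        _anchor("L2", "Chr02", 1, 10, arm=ARM_SUBTERMINAL),
        _anchor("L3", "Chr03", 1, 10, arm=ARM_SUBTERMINAL),
    ]
    summary = distribution_summary(anchors, lengths)
    assert summary["chromosomes_with_loci"] == 3
    assert summary["empty_chromosomes"] == ["Chr04"]
    assert sum(summary["per_chromosome"].values()) == summary["n_loci"] == 3
    assert summary["arm_classes"][ARM_SUBTERMINAL] == 3


def test_circos_files_round_trip(tmp_path):
    lengths = {"Chr01": 500_000, "Chr02": 400_000}
    anchors = [
        _anchor("L1", "Chr01", 100, 1200, family="TPS"),
        _anchor("L2", "Chr02", 5000, 6000, family="TPS"),
    ]
    links = find_synteny_links(anchors)
    paths = write_circos(anchors, links, lengths, tmp_path)
    karyotype = paths["karyotype"].read_text().splitlines()
    assert len(karyotype) == 2
    assert karyotype[0].startswith("chr - Chr01 Chr01 1 500000")
    assert read_circos_karyotype(paths["karyotype"]) == lengths
    parsed_links = read_circos_links(paths["links"])
    assert parsed_links == [("Chr01", 100, 1200, "Chr02", 5000, 6000)]
    assert read_circos_tiles(paths["tiles"]) == [
        ("Chr01", 100, 1200), ("Chr02", 5000, 6000)
    ]
    # empty links are a valid (empty) file
    paths = write_circos(anchors, [], lengths, tmp_path / "empty")
    assert read_circos_links(paths["links"]) == []


def test_circos_rejects_unknown_link_chromosome(tmp_path):
    anchors = [_anchor("L1", "Chr01", 1, 10, family="TPS"),
               _anchor("L2", "Chr09", 1, 10, family="TPS")]
    links = find_synteny_links(anchors)
    with pytest.raises(ValueError, match="absent from the karyotype"):
        write_circos(anchors, links, {"Chr01": 100}, tmp_path)


def test_anchors_frame_columns():
    frame = anchors_to_frame([_anchor("L1", "Chr01", 1, 10, family="TPS")])
    assert list(frame.columns) == [
        "locus_id", "family", "chromosome", "start", "end", "arm_class"
    ]
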