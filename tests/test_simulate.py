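"""Synthetic dataset generator: determinism, structure, truth semantics."""

import numpy as np
import pandas as pd
import pytest

from supersage import io as sio
from supersage.annotate import TranscriptIndex, match_tag
from supersage.simulate import (
    LIBRARIES,
    PackingError,
    SimulationConfig,
    generate_genome,
    generate_transcripts,
    simulate_dataset,
    simulate_libraries,
)
from supersage.tags import canonical_tag


def test_config_validation():
    with pytest.raises(ValueError, match="strictly positive"):
        SimulationConfig(n_chromosomes=0)
    with pytest.raises(ValueError, match="outside"):
        SimulationConfig(de_fraction=1.5)
    with pytest.raises(ValueError, match="utr3_length"):
        SimulationConfig(utr3_length=20)
    with pytest.raises(ValueError, match="exceed n_loci"):
        SimulationConfig(n_loci=3, families={"TPS": 5})


def test_empty_genome_has_sequences_but_no_loci():
    cfg = SimulationConfig(n_chromosomes=2, chromosome_length=10_000, n_loci=0,
                           families={})
    genome = generate_genome(cfg)
    assert len(genome.chromosomes) == 2
    assert genome.loci == []
    assert all(len(seq) == 10_000 for seq in genome.sequences().values())


def test_infeasible_packing_raises_named_error():
    cfg = SimulationConfig(n_chromosomes=1, chromosome_length=3_000, n_loci=20,
                           families={})
    with pytest.raises(PackingError, match="pack|crowded"):
        generate_genome(cfg)


def test_subterminal_placement_fraction(small_config):
    cfg = SimulationConfig(
        n_chromosomes=4, chromosome_length=500_000, n_loci=20, families={},
        subterminal_placement_fraction=0.6, seed=1,
    )
    genome = generate_genome(cfg)
    outer = 0
    for locus in genome.loci:
        length = cfg.chromosome_length
        cen = cfg.centromere_fraction * length
        mid = (locus["start"] + locus["end"]) / 2
        arm_len, dist = (cen, mid) if mid < cen else (length - cen, length - mid)
        if dist <= cfg.subterminal_arm_fraction * arm_len:
            outer += 1
    assert outer >= 12  # 60% of 20 planted subterminal


def test_same_seed_same_bytes(tmp_path, small_config):
    paths_a = simulate_dataset(small_config, tmp_path / "a")
    paths_b = simulate_dataset(small_config, tmp_path / "b")
    for name in paths_a:
        assert paths_a[name].read_bytes() == paths_b[name].read_bytes(), name


def test_gene_models_tile_transcripts(small_dataset):
    _genome, transcripts, _counts, _truth = small_dataset
    for t in transcripts:
        assert t.cds[0] == 0
        if t.utr3 is not None:
            assert t.cds[1] == t.utr3[0]  # no gap, no overlap
            assert t.utr3[1] == len(t.sequence)
        else:
            assert t.cds[1] == len(t.sequence)


def test_written_models_round_trip(tmp_path, small_config, small_dataset):
    genome, transcripts, _counts, _truth = small_dataset
    paths = simulate_dataset(small_config, tmp_path / "ds")
    models = sio.read_gene_models(paths["transcripts"], paths["gff3"])
    by_id = {t.transcript_id: t for t in transcripts}
    assert set(by_id) == {m.transcript_id for m in models}
    sequences = sio.read_fasta(paths["genome"])
    for m in models:
        original = by_id[m.transcript_id]
        assert m.sequence == original.sequence
        assert m.cds == original.cds and m.utr3 == original.utr3
        assert m.locus_id == original.locus_id and m.family == original.family
    # transcripts are genomic slices of the emitted chromosomes
    for entry in genome.gff_entries:
        chrom_seq = sequences[entry["chrom"]]
        assert (
            chrom_seq[entry["start"] : entry["end"]]
            == by_id[entry["transcript_id"]].sequence
        )


def test_isoforms_share_canonical_tag(small_dataset):
    _genome, transcripts, _counts, _truth = small_dataset
    by_locus = {}
    for t in transcripts:
        by_locus.setdefault(t.locus_id, []).append(t)
    multi = [ts for ts in by_locus.values() if len(ts) > 1]
    assert multi, "expected at least one multi-isoform locus"
    for ts in multi:
        tags = {canonical_tag(t) for t in ts}
        assert len(tags) == 1


def test_structural_flag_classes_exist(small_dataset):
    genome, transcripts, _counts, truth = small_dataset
    flags = pd.DataFrame(genome.loci)
    assert (~flags.has_utr3).any(), "expected a no-3'UTR transcript"
    assert (flags.has_utr3 & ~flags.catg_in_utr3).any(), "expected a CDS-only-CATG transcript"
    assert (~flags.taggable).any(), "expected an untaggable transcript"
    assert (truth.kind == "untaggable_locus").any()


def test_truth_table_invariants(small_dataset):
    _genome, _transcripts, counts, truth = small_dataset
    real = truth[truth.kind.isin(["canonical", "partial", "sister"])]
    assert real.tag.is_unique
    unspiked = real[real.spiked_fc == 1.0]
    for a, b in [("TS", "TC"), ("SS", "SC"), ("TS", "SS"), ("TC", "SC")]:
        assert (unspiked[f"true_fc_{a}_vs_{b}"] == 1.0).all()
        assert (unspiked[f"true_class_{a}_vs_{b}"] == "ns").all()
    sisters = real[real.kind == "sister"]
    for _, row in sisters.iterrows():
        diff = [i for i, (a, b) in enumerate(zip(row.tag, row.sister_partner)) if a != b]
        assert diff == [row.sister_position - 1]
        assert row.sister_position >= 5  # never inside the CATG anchor


def test_library_totals_near_target_depth(small_dataset, small_config):
    _genome, _transcripts, counts, _truth = small_dataset
    for lib in LIBRARIES:
        total = sum(counts[lib].values())
        assert abs(total - small_config.library_depth) <= 0.05 * small_config.library_depth


def test_no_spikes_means_all_ns():
    cfg = SimulationConfig(n_chromosomes=2, chromosome_length=100_000, n_loci=20,
                           families={}, library_depth=50_000, de_fraction=0.0, seed=3)
    transcripts = generate_transcripts(generate_genome(cfg), cfg)
    _counts, truth = simulate_libraries(transcripts, cfg)
    for a, b in [("TS", "TC"), ("SS", "SC"), ("TS", "SS"), ("TC", "SC")]:
        assert (truth[f"true_class_{a}_vs_{b}"] == "ns").all()


def test_spiked_counts_track_true_fold_change():
    cfg = SimulationConfig(n_chromosomes=2, chromosome_length=200_000, n_loci=40,
                           families={}, library_depth=500_000, de_fraction=0.4, seed=9)
    transcripts = generate_transcripts(generate_genome(cfg), cfg)
    counts, truth = simulate_libraries(transcripts, cfg)
    spiked = truth[
        (truth.kind == "canonical")
        & (truth.true_fc_TS_vs_TC.abs() >= 4)
        & (truth.baseline_tpm >= 100)
    ]
    assert len(spiked) >= 2
    for _, row in spiked.iterrows():
        x = counts["TS"].get(row.tag, 0)
        y = counts["TC"].get(row.tag, 0)
        observed = (x + 1) / (y + 1)
        expected = row.true_fc_TS_vs_TC
        expected = expected if expected > 0 else -1 / expected
        assert 0.5 * expected <= observed <= 2.0 * expected


def test_depth_too_small_for_spikes_raises():
    cfg = SimulationConfig(n_chromosomes=2, chromosome_length=200_000, n_loci=60,
                           families={}, library_depth=40, de_fraction=0.5, seed=2)
    transcripts = generate_transcripts(generate_genome(cfg), cfg)
    with pytest.raises(ValueError, match="too small to place spike-ins"):
        simulate_libraries(transcripts, cfg)


def test_emitted_tags_are_derivable_from_transcripts(small_dataset):
    """Closure: every non-noise tag in the count tables is reachable from a
    transcript under the matching rules, at its recorded anchor."""
    _genome, transcripts, counts, truth = small_dataset
    index = TranscriptIndex(transcripts)
    emitted = set().union(*(set(c) for c in counts.values()))
    real = truth[truth.kind.isin(["canonical", "partial", "sister"])]
    for _, row in real.iterrows():
        if row.tag not in emitted:
            continue
        expected_mm = 1 if row.kind == "sister" else 0
        hits = [
            m
            for m in match_tag(row.tag, index)
            if m.transcript_id == row.transcript_id
            and m.offset == row.anchor_offset
            and m.mismatches == expected_mm
        ]
        assert hits, f"{row.kind} tag {row.tag} not recovered at its anchor"
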