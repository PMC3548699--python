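"""Anchored tag matching, region classes, sisters and locus collapsing."""

import numpy as np
import pytest

from oracles import brute_force_matches
from supersage.annotate import (
    REGION_CDS,
    REGION_JUNCTION,
    REGION_NO_UTR,
    REGION_UTR3,
    REGION_UTR5,
    TranscriptIndex,
    classify_region,
    collapse_to_loci,
    detect_sister_tags,
    match_all,
    match_tag,
)
from supersage.models import TagMatch, TranscriptModel
from supersage.tags import canonical_tag, enumerate_candidate_tags


def _transcript(tid, seq, locus=None, cds=None, utr3=None):
    return TranscriptModel(
        transcript_id=tid, locus_id=locus or tid.split(".")[0], sequence=seq,
        cds=cds, utr3=utr3,
    )


@pytest.fixture(scope="module")
def toy_index():
    rng = np.random.default_rng(3)
    bases = "ACGT"
    seqs = []
    for i in range(5):
        seq = "".join(bases[b] for b in rng.integers(0, 4, 300))
        seq = seq[:100] + "CATG" + seq[104:250] + "CATG" + seq[254:]
        seqs.append(_transcript(f"T{i}.1", seq, locus=f"T{i}"))
    return TranscriptIndex(seqs), seqs


def test_exact_match_found_at_last_catg(toy_index):
    index, seqs = toy_index
    tag = canonical_tag(seqs[0])
    matches = [m for m in match_tag(tag, index) if m.transcript_id == "T0.1"]
    assert matches
    best = matches[0]
    assert best.mismatches == 0
    assert best.is_last_catg
    assert not best.is_partial_digestion_candidate


def test_mismatch_inside_anchor_is_rejected(toy_index):
    index, seqs = toy_index
    tag = canonical_tag(seqs[0])
    # a tag whose second base differs is not a valid CATG tag at all
    with pytest.raises(ValueError):
        match_tag("C" + "G" + tag[2:], index)
    # a window whose anchor bases would have to mismatch never matches:
    # mutate the transcript instead and look the original tag up
    mutated = seqs[0].sequence.replace(tag, "CTTG" + tag[4:])
    index2 = TranscriptIndex([_transcript("M.1", mutated)])
    assert all(m.offset != seqs[0].sequence.find(tag) for m in match_tag(tag, index2))


def test_two_mismatches_are_rejected(toy_index):
    index, seqs = toy_index
    tag = canonical_tag(seqs[0])
    variant = tag[:7] + ("A" if tag[7] != "A" else "C") + tag[8:18] + (
        "A" if tag[18] != "A" else "C"
    ) + tag[19:]
    assert [m for m in match_tag(variant, index) if m.transcript_id == "T0.1"] == []


def test_single_mismatch_outside_anchor_matches(toy_index):
    index, seqs = toy_index
    tag = canonical_tag(seqs[1])
    variant = tag[:10] + ("A" if tag[10] != "A" else "C") + tag[11:]
    hits = [m for m in match_tag(variant, index) if m.transcript_id == "T1.1"]
    assert hits and hits[0].mismatches == 1 and hits[0].mismatch_position == 11


def test_matcher_agrees_with_brute_force_scan():
    rng = np.random.default_rng(17)
    bases = "ACGT"
    transcripts = []
    for i in range(40):
        seq = "".join(bases[b] for b in rng.integers(0, 4, int(rng.integers(60, 800))))
        transcripts.append(_transcript(f"R{i}.1", seq))
    index = TranscriptIndex(transcripts)
    probes = []
    windows = [w for t in transcripts for w, _, _ in enumerate_candidate_tags(t)]
    for w in windows[:30]:  # planted exact and 1-mismatch probes
        probes.append(w)
        pos = int(rng.integers(4, 26))
        probes.append(w[:pos] + bases[int(rng.integers(0, 4))] + w[pos + 1 :])
    for _ in range(30):  # random probes, mostly no hits
        probes.append("CATG" + "".join(bases[b] for b in rng.integers(0, 4, 22)))
    for tag in probes:
        got = {(m.transcript_id, m.offset, m.mismatches) for m in match_tag(tag, index)}
        assert got == brute_force_matches(tag, transcripts)


def test_region_classification():
    seq = "A" * 100  # sequence content is irrelevant here
    cases = [
        ((0, 60), (60, 100), 70, REGION_UTR3),
        ((0, 60), (60, 100), 40, REGION_JUNCTION),  # straddles the boundary
        ((0, 60), (60, 100), 10, REGION_CDS),
        ((20, 60), (60, 100), 34, REGION_CDS),  # ends exactly at the boundary
        ((20, 60), (60, 100), 35, REGION_JUNCTION),
        ((40, 74), (74, 100), 0, REGION_UTR5),  # wholly before the CDS? no:
    ]
    # the last case: interval [0,26) vs CDS [40,74) -> no overlap -> UTR5
    for cds, utr3, offset, expected in cases:
        t = _transcript("X.1", seq, cds=cds, utr3=utr3)
        m = TagMatch(tag="CATG" + "A" * 22, transcript_id="X.1", locus_id="X",
                     offset=offset, mismatches=0)
        assert classify_region(m, t) == expected
    no_utr = _transcript("Y.1", seq, cds=(0, 100), utr3=None)
    m = TagMatch(tag="CATG" + "A" * 22, transcript_id="Y.1", locus_id="Y",
                 offset=10, mismatches=0)
    assert classify_region(m, no_utr) == REGION_NO_UTR


def test_partial_digestion_flags_follow_rank():
    seq = "GG" + "CATG" + "A" * 40 + "CATG" + "C" * 30
    t = _transcript("P.1", seq)
    index = TranscriptIndex([t])
    upstream, downstream = (
        seq[2 : 2 + 26],
        seq[46 : 46 + 26],
    )
    (up_match,) = match_tag(upstream, index)
    (down_match,) = match_tag(downstream, index)
    assert down_match.is_last_catg and not down_match.is_partial_digestion_candidate
    assert up_match.is_partial_digestion_candidate and up_match.rank_from_3prime == 2


def test_sister_pairs_require_distance_one_and_shared_transcript():
    seq = "TT" + "CATG" + "ACGT" * 10
    t = _transcript("S.1", seq)
    other = _transcript("O.1", "CC" + "CATG" + "TGCA" * 10)
    index = TranscriptIndex([t, other])
    tag = canonical_tag(t)
    sister = tag[:12] + ("A" if tag[12] != "A" else "G") + tag[13:]
    distance2 = sister[:20] + ("A" if sister[20] != "A" else "G") + sister[21:]
    unrelated = canonical_tag(other)
    unitags = [tag, sister, distance2, unrelated]
    matches = match_all(unitags, index)
    pairs = detect_sister_tags(unitags, matches)
    found = {(p.tag_1, p.tag_2) for p in pairs}
    assert tuple(sorted((tag, sister))) in found
    # tags at Hamming distance 2 pair with neither end
    assert not any(distance2 in pair for pair in found)
    # distance-1 tags mapping to disjoint transcripts are not sisters
    lonely = unrelated[:8] + ("A" if unrelated[8] != "A" else "G") + unrelated[9:]
    pairs = detect_sister_tags([tag, lonely], match_all([tag, lonely], index))
    assert pairs == []


def test_collapse_to_loci_counts_isoforms_once():
    shared = "CATG" + "ACGTAC" * 8
    isoforms = [
        _transcript(f"L1.{k}", ("G" * (10 * k)) + shared, locus="L1") for k in (1, 2, 3)
    ]
    solo = _transcript("L2.1", "AA" + "CATG" + "TGCATG" * 8, locus="L2")
    index = TranscriptIndex(isoforms + [solo])
    unitags = [canonical_tag(isoforms[0]), canonical_tag(solo)]
    table = collapse_to_loci(match_all(unitags, index))
    assert len(table) == 2
    row = table.set_index("locus_id").loc["L1"]
    assert row["n_transcripts"] == 3 and row["n_tags"] == 1


def test_collapse_rejects_unknown_locus():
    match = TagMatch(tag="CATG" + "A" * 22, transcript_id="T.1", locus_id="",
                     offset=0, mismatches=0)
    with pytest.raises(ValueError, match="no locus"):
        collapse_to_loci({match.tag: [match]})
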