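"""Tag-to-transcript annotation.

Replaces the tag-hit BLASTn step with exact anchored matching: a 26-bp tag
matches a transcript wherever the transcript carries a 26-base window that
starts with CATG at the aligned first four positions and differs from the
tag at no more than one of positions 5-26 (plus strand only).  For a fixed
length 26-mer with an exact 4-base anchor and at most one mismatch this
direct search is complete and deterministic, and any such hit trivially
passes a BLASTn e-value cutoff of 1e-4, so no separate e-value filter is
needed.

Matches are classified by the transcript region the 26-base interval
overlaps (CDS, 3'UTR, the CDS/3'UTR junction, 5'UTR, or
``no_UTR_annotation`` when the transcript has no annotated 3'UTR), flagged
as partial-digestion candidates when anchored at a non-3'-most CATG,
scanned for "sister tags" (unitag pairs one substitution apart sharing a
transcript — putative SNPs), and collapsed from transcripts to gene loci
to expose alternative-isoform multiplicity.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from supersage.models import SisterPair, TagMatch, TranscriptModel
from supersage.tags import ANCHOR, TAG_LENGTH

REGION_CDS = "CDS"
REGION_UTR3 = "UTR3"
REGION_JUNCTION = "CDS_UTR3_junction"
REGION_UTR5 = "UTR5"
REGION_NO_UTR = "no_UTR_annotation"

_ALPHABET = "ACGT"


class TranscriptIndex:
    """Exact-window index over all anchored 26-base windows of a transcript
    set, supporting 0- and 1-mismatch lookup of CATG-anchored tags."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self._windows: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self._last_catg: dict[str, int] = {}
        self._rank: dict[tuple[str, int], int] = {}
        for t in transcripts:
            seq = t.sequence.upper()
            positions = []
            start = seq.find(ANCHOR)
            while start != -1:
                if start + TAG_LENGTH <= len(seq):
                    positions.append(start)
                start = seq.find(ANCHOR, start + 1)
            n = len(positions)
            for i, p in enumerate(positions):
                self._windows[seq[p : p + TAG_LENGTH]].append((t.transcript_id, p))
                self._rank[(t.transcript_id, p)] = n - i
            if positions:
                self._last_catg[t.transcript_id] = positions[-1]

    def rank(self, transcript_id: str, offset: int) -> int:
        return self._rank[(transcript_id, offset)]

    def lookup(self, window: str) -> list[tuple[str, int]]:
        return self._windows.get(window, [])


def match_tag(tag: str, index: TranscriptIndex) -> list[TagMatch]:
    """All transcript positions matching ``tag`` with the four CATG bases
    exact and at most one mismatch among positions 5-26, plus strand only.

    Partial-digestion flags are filled from the anchor's rank: a match not
    at the transcript's 3'-most usable CATG is a partial-digestion candidate.
    """
    tag = tag.upper()
    if len(tag) != TAG_LENGTH or not tag.startswith(ANCHOR):
        raise ValueError(f"not a valid tag: {tag!r}")
    hits: dict[tuple[str, int], tuple[int, int | None]] = {}
    for tid, offset in index.lookup(tag):
        hits[(tid, offset)] = (0, None)
    for pos in range(len(ANCHOR), TAG_LENGTH):
        for base in _ALPHABET:
            if base == tag[pos]:
                continue
            variant = tag[:pos] + base + tag[pos + 1 :]
            for tid, offset in index.lookup(variant):
                hits.setdefault((tid, offset), (1, pos + 1))
    matches = []
    for (tid, offset), (n_mm, mm_pos) in sorted(hits.items()):
        transcript = index.transcripts[tid]
        rank = index.rank(tid, offset)
        match = TagMatch(
            tag=tag,
            transcript_id=tid,
            locus_id=transcript.locus_id,
            offset=offset,
            mismatches=n_mm,
            mismatch_position=mm_pos,
            is_last_catg=rank == 1,
            is_partial_digestion_candidate=rank != 1,
            rank_from_3prime=rank,
        )
        match.region = classify_region(match, transcript)
        matches.append(match)
    return matches


def classify_region(match: TagMatch, transcript: TranscriptModel) -> str:
    """Region of the transcript overlapped by the tag's 26-base interval."""
    start, end = match.offset, match.offset + TAG_LENGTH
    assert 0 <= start and end <= len(transcript.sequence), "tag interval outside transcript"
    if transcript.utr3 is None:
        return REGION_NO_UTR
    u0, u1 = transcript.utr3
    in_utr3 = start < u1 and end > u0
    in_cds = False
    if transcript.cds is not None:
        c0, c1 = transcript.cds
        in_cds = start < c1 and end > c0
    if in_cds and in_utr3:
        return REGION_JUNCTION
    if in_utr3:
        return REGION_UTR3
    if in_cds:
        return REGION_CDS
    return REGION_UTR5


def flag_partial_digestion(
    matches: list[TagMatch], index: TranscriptIndex
) -> list[TagMatch]:
    """(Re)compute last-CATG and partial-digestion flags for a match list."""
    for match in matches:
        rank = index.rank(match.transcript_id, match.offset)
        match.rank_from_3prime = rank
        match.is_last_catg = rank == 1
        match.is_partial_digestion_candidate = rank != 1
    return matches


def match_all(
    unitags: list[str], index: TranscriptIndex
) -> dict[str, list[TagMatch]]:
    """Match every unitag; tags with no hit map to an empty list."""
    return {tag: match_tag(tag, index) for tag in sorted(set(unitags))}


def detect_sister_tags(
    unitags: list[str], matches: dict[str, list[TagMatch]]
) -> list[SisterPair]:
    """All unordered unitag pairs at Hamming distance exactly 1 (the
    difference outside the CATG anchor) that share a matched transcript."""
    buckets: dict[tuple[int, str], list[str]] = defaultdict(list)
    tags = sorted(set(unitags))
    for tag in tags:
        for pos in range(len(ANCHOR), TAG_LENGTH):
            buckets[(pos, tag[:pos] + "*" + tag[pos + 1 :])].append(tag)
    pairs = []
    seen: set[tuple[str, str]] = set()
    for (pos, _masked), members in sorted(buckets.items()):
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                t1, t2 = sorted((members[i], members[j]))
                if (t1, t2) in seen:
                    continue
                shared = {m.transcript_id for m in matches.get(t1, [])} & {
                    m.transcript_id for m in matches.get(t2, [])
                }
                if shared:
                    seen.add((t1, t2))
                    pairs.append(
                        SisterPair(
                            tag_1=t1,
                            tag_2=t2,
                            position=pos + 1,
                            shared_transcripts=tuple(sorted(shared)),
                        )
                    )
    pairs.sort(key=lambda p: (p.tag_1, p.tag_2))
    return pairs


def collapse_to_loci(matches: dict[str, list[TagMatch]]) -> pd.DataFrame:
    """Collapse transcript-level matches to gene loci.

    Alternative isoforms of one locus frequently share tag hits, so the
    locus count is at most the transcript count.  Returns one row per locus
    with its matched tags, transcripts and isoform multiplicity.
    """
    per_locus: dict[str, dict[str, set]] = defaultdict(
        lambda: {"tags": set(), "transcripts": set()}
    )
    for tag, tag_matches in matches.items():
        for m in tag_matches:
            if not m.locus_id:
                raise ValueError(
                    f"transcript {m.transcript_id} has no locus assignment"
                )
            per_locus[m.locus_id]["tags"].add(tag)
            per_locus[m.locus_id]["transcripts"].add(m.transcript_id)
    rows = [
        {
            "locus_id": locus,
            "n_tags": len(data["tags"]),
            "n_transcripts": len(data["transcripts"]),
            "tags": ",".join(sorted(data["tags"])),
            "transcripts": ",".join(sorted(data["transcripts"])),
        }
        for locus, data in sorted(per_locus.items())
    ]
    return pd.DataFrame(
        rows, columns=["locus_id", "n_tags", "n_transcripts", "tags", "transcripts"]
    )


def matches_to_frame(matches: dict[str, list[TagMatch]]) -> pd.DataFrame:
    """Flatten a match dict to a report table (1-based offsets)."""
    rows = []
    for tag in sorted(matches):
        for m in matches[tag]:
            rows.append(
                {
                    "tag": tag,
                    "transcript_id": m.transcript_id,
                    "locus_id": m.locus_id,
                    "position": m.offset + 1,
                    "mismatches": m.mismatches,
                    "mismatch_position": m.mismatch_position or 0,
                    "region": m.region,
                    "is_last_catg": m.is_last_catg,
                    "is_partial_digestion_candidate": m.is_partial_digestion_candidate,
                    "n_transcript_hits": len(matches[tag]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tag", "transcript_id", "locus_id", "position", "mismatches",
            "mismatch_position", "region", "is_last_catg",
            "is_partial_digestion_candidate", "n_transcript_hits",
        ],
    )


def annotation_report(
    matches: dict[str, list[TagMatch]],
    contrast_results: dict[str, pd.DataFrame] | None = None,
    tpm: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Annotation table with optional per-library tpm and per-contrast DE
    columns merged in (one row per tag-transcript hit)."""
    frame = matches_to_frame(matches)
    if tpm:
        for lib in sorted(tpm):
            frame[f"tpm_{lib}"] = frame["tag"].map(tpm[lib]).fillna(0.0)
    if contrast_results:
        for name in sorted(contrast_results):
            result = contrast_results[name].set_index("tag")
            frame[f"fc_{name}"] = frame["tag"].map(result["fold_change"])
            frame[f"reg_{name}"] = frame["tag"].map(result["regulation"])
    return frame


def write_report(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
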