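"""Shared domain types.

Coordinates are 0-based half-open everywhere in memory; report and GFF3
output is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with CDS / 3'UTR annotation.

    ``cds`` and ``utr3`` are transcript-relative half-open intervals.
    ``utr3 is None`` means no 3'UTR was annotated for the transcript (which
    downstream region classification reports as ``no_UTR_annotation``).
    """

    transcript_id: str
    locus_id: str
    sequence: str
    cds: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.cds is not None and self.cds[0] > self.cds[1]:
            raise ValueError(f"invalid CDS span {self.cds} on {self.transcript_id}")
        if self.utr3 is not None and self.utr3[0] > self.utr3[1]:
            raise ValueError(f"invalid 3'UTR span {self.utr3} on {self.transcript_id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TagMatch:
    """One tag <-> transcript alignment under the anchored matching rules.

    ``offset`` is the 0-based start of the 26-base window on the transcript
    plus strand.  ``mismatch_position`` is 1-based within the tag (5..26) or
    None for a perfect match.  A match whose anchor is not the transcript's
    3'-most usable CATG is a partial-digestion candidate.
    """

    tag: str
    transcript_id: str
    locus_id: str
    offset: int
    mismatches: int
    mismatch_position: int | None = None
    region: str | None = None
    is_last_catg: bool | None = None
    is_partial_digestion_candidate: bool | None = None
    rank_from_3prime: int | None = None


@dataclass(frozen=True)
class SisterPair:
    """Two unitags differing by a single substitution (a putative SNP) that
    share at least one matched transcript."""

    tag_1: str
    tag_2: str
    position: int  # 1-based differing position within the tag (5..26)
    shared_transcripts: tuple[str, ...]


@dataclass(frozen=True)
class AnchorRecord:
    """A locus anchored on a chromosome, with its arm position class."""

    locus_id: str
    family: str | None
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    arm_class: str  # subterminal | intercalary | pericentromeric

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"anchor {self.locus_id}: start {self.start} > end {self.end}"
            )


@dataclass
class Cluster:
    """A maximal max-gap run of anchored loci on one chromosome."""

    chromosome: str
    members: list[AnchorRecord] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(m.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted({m.family for m in self.members if m.family}))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SyntenyLink:
    """A cross-chromosome pairing of regions holding members of one gene
    family (family-level redundancy, not alignment-based collinearity)."""

    family: str
    chromosome_a: str
    start_a: int
    end_a: int
    chromosome_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.chromosome_a == self.chromosome_b:
            raise ValueError("synteny link endpoints must be on different chromosomes")
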