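"""Virtual NlaIII digestion and unitag counting.

A SuperSAGE tag is the 26-base sequence starting at a CATG anchoring-enzyme
site.  Complete digestion releases the tag at the 3'-most CATG of a
transcript (the *canonical* tag); incomplete digestion can release tags at
upstream sites.  Counting is per library: distinct tag sequences are
*unitags*, tags seen exactly once (*singlets*) are excluded as likely
noise, and retained counts are normalised to tags per million (tpm).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from supersage.models import TranscriptModel

TAG_LENGTH = 26
ANCHOR = "CATG"

_VALID_BASES = frozenset("ACGT")


def _sequence_of(transcript: TranscriptModel | str) -> str:
    if isinstance(transcript, TranscriptModel):
        return transcript.sequence.upper()
    return str(transcript).upper()


def enumerate_candidate_tags(
    transcript: TranscriptModel | str,
) -> list[tuple[str, int, int]]:
    """All candidate tags of a transcript, one per usable CATG site.

    A CATG occurrence is usable when 26 bases fit between its start and the
    transcript end; shorter 3' tails yield no candidate (the protocol cannot
    release a truncated 26-bp tag).  Returns ``(tag, anchor_position,
    rank_from_3prime)`` tuples in 5'->3' positional order; rank 1 is the
    3'-most site.  Plus strand only.
    """
    seq = _sequence_of(transcript)
    positions = []
    start = seq.find(ANCHOR)
    while start != -1:
        if start + TAG_LENGTH <= len(seq):
            positions.append(start)
        start = seq.find(ANCHOR, start + 1)
    n = len(positions)
    return [(seq[p : p + TAG_LENGTH], p, n - i) for i, p in enumerate(positions)]


def canonical_tag(transcript: TranscriptModel | str) -> str | None:
    """The tag at the 3'-most usable CATG — the expected product of complete
    NlaIII digestion — or None when the transcript has no usable site."""
    candidates = enumerate_candidate_tags(transcript)
    if not candidates:
        return None
    return candidates[-1][0]


@dataclass
class UnitagTable:
    """Per-library unitag counts, optionally singlet-filtered and normalised.

    ``counts`` maps unitag -> raw count.  ``total`` is the library total over
    the current (possibly filtered) unitag set.  ``tpm`` is filled by
    :func:`normalize_tpm`.
    """

    library: str
    counts: dict[str, int] = field(default_factory=dict)
    tpm: dict[str, float] | None = None
    singlets_excluded: int = 0
    rejects: list[tuple[str, str]] = field(default_factory=list)
    filtered: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unitags(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts)
        frame = pd.DataFrame(
            {"tag": rows, "count": [self.counts[t] for t in rows]}
        )
        if self.tpm is not None:
            frame["tpm"] = [self.tpm[t] for t in rows]
        return frame


def _validate_tag(record: str) -> str | None:
    """Return a reject reason, or None for a well-formed tag."""
    if len(record) != TAG_LENGTH:
        return f"length {len(record)} != {TAG_LENGTH}"
    if not record.startswith(ANCHOR):
        return "missing CATG anchor"
    if not _VALID_BASES.issuperset(record):
        return "non-ACGT character"
    return None


def count_tags(tag_stream: Iterable[str], library: str) -> UnitagTable:
    """Count a stream of tag sequences into a unitag table.

    Input is case-insensitive.  Malformed records (wrong length, missing
    CATG anchor, ambiguity codes) are routed to the table's rejects report,
    never silently dropped: retained counts + rejects = stream length.
    """
    counts: Counter[str] = Counter()
    rejects: list[tuple[str, str]] = []
    for record in tag_stream:
        tag = str(record).upper()
        reason = _validate_tag(tag)
        if reason is None:
            counts[tag] += 1
        else:
            rejects.append((tag, reason))
    return UnitagTable(library=library, counts=dict(counts), rejects=rejects)


def exclude_singlets(table: UnitagTable) -> UnitagTable:
    """Drop unitags counted only once; record how many were excluded."""
    kept = {t: c for t, c in table.counts.items() if c >= 2}
    n_singlets = len(table.counts) - len(kept)
    return UnitagTable(
        library=table.library,
        counts=kept,
        singlets_excluded=table.singlets_excluded + n_singlets,
        rejects=list(table.rejects),
        filtered=True,
    )


def normalize_tpm(table: UnitagTable) -> UnitagTable:
    """Attach tags-per-million: tpm = count / library_total * 1e6.

    The denominator is the table's current total, i.e. the post-filter total
    when the table has been singlet-filtered.
    """
    total = table.total
    if total <= 0:
        raise ValueError(
            f"library {table.library!r}: cannot normalise an empty table (total 0)"
        )
    tpm = {t: c / total * 1_000_000.0 for t, c in table.counts.items()}
    return UnitagTable(
        library=table.library,
        counts=dict(table.counts),
        tpm=tpm,
        singlets_excluded=table.singlets_excluded,
        rejects=list(table.rejects),
        filtered=table.filtered,
    )


# ---------------------------------------------------------------------------
# TSV I/O

def read_counts_tsv(path: str | Path, library: str | None = None) -> UnitagTable:
    """Read a tag-count TSV (columns: tag, count)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    if not {"tag", "count"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns 'tag' and 'count'")
    counts = dict(zip(frame["tag"].str.upper(), frame["count"]))
    return UnitagTable(library=library or path.stem, counts=counts)


def write_counts_tsv(table: UnitagTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_rejects_tsv(table: UnitagTable, path: str | Path) -> None:
    pd.DataFrame(table.rejects, columns=["record", "reason"]).to_csv(
        path, sep="\t", index=False
    )
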