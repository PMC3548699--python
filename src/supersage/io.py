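"""FASTA / GFF3 helpers shared by the pipeline stages.

All in-memory coordinates are 0-based half-open; GFF3 output follows the
format's 1-based inclusive convention.  Gene models are single-exon on the
plus strand (gene > mRNA > CDS / three_prime_UTR).
"""

from __future__ import annotations

from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from supersage.models import TranscriptModel


def write_fasta(sequences: dict[str, str], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(
    transcripts: list[dict],
    chromosome_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write gene models as GFF3.

    Each entry of ``transcripts`` is a dict with keys: transcript_id,
    locus_id, chrom, start, end (0-based half-open genomic), cds and utr3
    (0-based half-open genomic or None), family (or None).  Gene features
    span the union of their mRNAs.
    """
    by_locus: dict[str, list[dict]] = {}
    for tr in transcripts:
        by_locus.setdefault(tr["locus_id"], []).append(tr)
    lines = ["##gff-version 3"]
    for chrom in sorted(chromosome_lengths):
        lines.append(f"##sequence-region {chrom} 1 {chromosome_lengths[chrom]}")
    for locus_id in sorted(by_locus):
        isoforms = sorted(by_locus[locus_id], key=lambda t: t["transcript_id"])
        chrom = isoforms[0]["chrom"]
        gene_start = min(t["start"] for t in isoforms)
        gene_end = max(t["end"] for t in isoforms)
        family = isoforms[0].get("family")
        attrs = f"ID={locus_id}"
        if family:
            attrs += f";family={family}"
        lines.append(
            f"{chrom}\tsupersage\tgene\t{gene_start + 1}\t{gene_end}\t.\t+\t.\t{attrs}"
        )
        for tr in isoforms:
            tid = tr["transcript_id"]
            mattrs = f"ID={tid};Parent={locus_id}"
            if family:
                mattrs += f";family={family}"
            lines.append(
                f"{chrom}\tsupersage\tmRNA\t{tr['start'] + 1}\t{tr['end']}\t.\t+\t.\t{mattrs}"
            )
            if tr.get("cds") is not None:
                c0, c1 = tr["cds"]
                lines.append(
                    f"{chrom}\tsupersage\tCDS\t{c0 + 1}\t{c1}\t.\t+\t0\tID={tid}.cds;Parent={tid}"
                )
            if tr.get("utr3") is not None:
                u0, u1 = tr["utr3"]
                lines.append(
                    f"{chrom}\tsupersage\tthree_prime_UTR\t{u0 + 1}\t{u1}\t.\t+\t.\tID={tid}.utr3;Parent={tid}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_chromosome_lengths(gff3_path: str | Path) -> dict[str, int]:
    """Chromosome lengths from ##sequence-region pragmas."""
    lengths: dict[str, int] = {}
    with open(gff3_path) as handle:
        for line in handle:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                lengths[chrom] = int(end)
            elif not line.startswith("#"):
                break
    return lengths


def read_gene_models(
    transcripts_fasta: str | Path, gff3_path: str | Path
) -> list[TranscriptModel]:
    """Rebuild transcript models (with transcript-relative CDS / 3'UTR spans)
    from a transcripts FASTA and the gene-model GFF3."""
    sequences = read_fasta(transcripts_fasta)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        if tid not in sequences:
            raise ValueError(f"transcript {tid} in GFF3 but absent from FASTA")
        locus = mrna.attributes.get("Parent", [None])[0]
        if locus is None:
            raise ValueError(f"mRNA {tid} has no Parent locus")
        family = mrna.attributes.get("family", [None])[0]
        offset = mrna.start - 1  # genomic -> transcript-relative (single exon, + strand)
        cds = None
        utr3 = None
        for child in db.children(mrna, featuretype="CDS"):
            cds = (child.start - 1 - offset, child.end - offset)
        for child in db.children(mrna, featuretype="three_prime_UTR"):
            utr3 = (child.start - 1 - offset, child.end - offset)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                locus_id=locus,
                sequence=sequences[tid],
                cds=cds,
                utr3=utr3,
                family=family,
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def read_locus_table(gff3_path: str | Path) -> list[dict]:
    """Gene (locus) coordinates and families from the GFF3; 0-based half-open."""
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    loci = []
    for gene in db.features_of_type("gene"):
        loci.append(
            {
                "locus_id": gene.id,
                "family": gene.attributes.get("family", [None])[0],
                "chrom": gene.seqid,
                "start": gene.start - 1,
                "end": gene.end,
            }
        )
    loci.sort(key=lambda g: g["locus_id"])
    return loci
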