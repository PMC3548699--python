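"""Synthetic SuperSAGE dataset generator with ground truth.

Emulates a four-library drought-stress tag-profiling design on a toy
multi-chromosome genome: a tolerant and a sensitive accession, each with a
stressed library and its control (TS/TC and SS/SC).  The generator plants

* gene loci (optionally labelled with osmoprotectant-biosynthesis family
  names) placed without overlap, a configurable fraction of them in the
  subterminal portion of a chromosome arm, and multi-member families spread
  over at least two chromosomes so that true cross-chromosome redundancy
  ("synteny") links exist;
* alternative isoforms per locus that share the 3'UTR (hence the canonical
  tag), transcripts whose only usable CATG lies in the CDS, transcripts
  with no annotated 3'UTR, and untaggable transcripts with no CATG at all;
* four tag-count libraries with spike-in up/down regulation, SNP "sister"
  tags, partial-digestion tags anchored at a non-3'-most CATG, and
  count-one singlet noise;
* a truth table recording, per emitted tag, its source transcript and
  anchor, its mechanism, and its true fold change and regulation class in
  every contrast.

Counts are drawn from a negative binomial around per-tag means (Poisson in
the default dispersion->0 limit, matching the multinomial sampling of a
single sequencing library).  Spiked loci are selected in pairs with equal
baseline abundance and the same fold change, one regulated up (stress mean
multiplied by f) and one down (control mean multiplied by f), so library
composition stays balanced and unspiked tags keep a true frequency ratio
of exactly one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from supersage.models import TranscriptModel
from supersage.tags import ANCHOR, TAG_LENGTH, enumerate_candidate_tags
from supersage import io as sio

LIBRARIES = ("TS", "TC", "SS", "SC")
CONTRASTS = (("TS", "TC"), ("SS", "SC"), ("TS", "SS"), ("TC", "SC"))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PackingError(RuntimeError):
    """Raised when loci cannot be placed on the configured chromosomes."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults are scaled to a desk-size experiment: 20 chromosomes of 500 kb,
    200 gene loci (45 of them carrying osmoprotectant family labels with the
    same relative family sizes reported for soybean roots under water
    deficit), four libraries of 600,000 tags (about a quarter of the 2.55 M
    post-singlet tags of the real study), and a differential fraction of
    0.28 matching the observed DE fraction of the tolerant stress-vs-control
    contrast.
    """

    n_chromosomes: int = 20
    chromosome_length: int = 500_000
    n_loci: int = 200
    families: dict[str, int] = field(
        default_factory=lambda: {
            "P5CS": 6, "P5CR": 2, "TPS": 17, "TPP": 1,
            "BADH": 4, "CMO": 2, "MIPS": 3, "IMP": 10,
        }
    )
    isoform_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.10, 4: 0.05}
    )
    isoform_step: int = 90
    cds_length: int = 900
    utr3_length: int = 200
    library_depth: int = 600_000
    de_fraction: float = 0.28
    true_fc_values: tuple[float, ...] = (2.0, 4.0, 8.0)
    dispersion: float = 0.0
    baseline_sigma: float = 1.2
    snp_sister_rate: float = 0.03
    sister_mass_fraction: float = 0.3
    partial_digestion_rate: float = 0.02
    singlet_rate: float = 0.01
    subterminal_placement_fraction: float = 0.6
    subterminal_arm_fraction: float = 0.15
    centromere_fraction: float = 0.5
    pericentromere_fraction: float = 0.05
    frac_no_utr3: float = 0.05
    frac_cds_only_catg: float = 0.05
    frac_no_catg: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length", "cds_length",
                     "utr3_length", "library_depth", "isoform_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_loci < 0:
            raise ValueError("n_loci must be non-negative")
        for name in ("de_fraction", "snp_sister_rate", "partial_digestion_rate",
                     "singlet_rate", "subterminal_placement_fraction",
                     "subterminal_arm_fraction", "centromere_fraction",
                     "pericentromere_fraction", "frac_no_utr3",
                     "frac_cds_only_catg", "frac_no_catg",
                     "sister_mass_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.utr3_length < 30:
            raise ValueError(
                "utr3_length must be >= 30 so a 26-bp tag fits in the 3'UTR"
            )
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if sum(self.families.values()) > self.n_loci:
            raise ValueError("family locus counts exceed n_loci")
        total = sum(self.isoform_distribution.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("isoform_distribution probabilities must sum to 1")
        if any(f <= 1 for f in self.true_fc_values):
            raise ValueError("true_fc_values must all exceed 1")

    def to_dict(self) -> dict:
        data = asdict(self)
        data["true_fc_values"] = list(self.true_fc_values)
        return data


def spike_recovery_config(seed: int = 42) -> SimulationConfig:
    """Benchmark conditions for spike-in recovery: deep libraries (1e6 tags)
    and a dense, composition-balanced spike set so that detection sensitivity
    and empirical FDR can be measured with useful precision."""
    return SimulationConfig(library_depth=1_000_000, de_fraction=0.5, seed=seed)


# ---------------------------------------------------------------------------
# Genome


@dataclass
class SyntheticGenome:
    """Chromosome sequences (mutable uint8 ASCII arrays) plus locus layout."""

    chromosomes: dict[str, np.ndarray]
    loci: list[dict]
    config: SimulationConfig

    def sequences(self) -> dict[str, str]:
        return {c: a.tobytes().decode() for c, a in self.chromosomes.items()}

    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.chromosomes.items()}


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _gene_length(flags: dict, config: SimulationConfig) -> int:
    return config.cds_length + (config.utr3_length if flags["has_utr3"] else 0)


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Random chromosomes plus non-overlapping locus placements.

    A configurable fraction of loci is placed with its midpoint in the outer
    ``subterminal_arm_fraction`` of a chromosome arm (emulating subterminal
    gene clustering); every family with >= 2 members is spread over at least
    two chromosomes so that true cross-chromosome redundancy exists.
    """
    rng = np.random.default_rng([config.seed, 0])
    chrom_names = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chromosomes = {
        name: _random_bases(rng, config.chromosome_length) for name in chrom_names
    }

    # per-locus structure flags drive gene length, so decide them first
    width = max(4, len(str(config.n_loci)))
    flags_list = []
    for i in range(config.n_loci):
        has_utr3 = rng.random() >= config.frac_no_utr3
        flags_list.append(
            {
                "locus_id": f"L{i + 1:0{width}d}",
                "has_utr3": has_utr3,
                "catg_in_utr3": has_utr3 and rng.random() >= config.frac_cds_only_catg,
                "taggable": rng.random() >= config.frac_no_catg,
                "n_isoforms": int(
                    rng.choice(
                        list(config.isoform_distribution),
                        p=list(config.isoform_distribution.values()),
                    )
                ),
            }
        )

    total_gene = sum(_gene_length(f, config) for f in flags_list)
    total_genome = config.n_chromosomes * config.chromosome_length
    if total_gene > 0.5 * total_genome:
        raise PackingError(
            f"cannot pack {config.n_loci} loci totalling {total_gene} bases into "
            f"{total_genome} bases of genome (packing would exceed 50% occupancy); "
            "increase chromosome_length or n_chromosomes, or reduce n_loci"
        )

    # family -> chromosome assignment: multi-member families span >= 2 chromosomes
    family_labels: list[str | None] = []
    for fam, count in config.families.items():
        family_labels.extend([fam] * count)
    family_labels.extend([None] * (config.n_loci - len(family_labels)))

    chrom_of: list[str] = [""] * config.n_loci
    pos = 0
    for fam, count in config.families.items():
        n_chroms = min(config.n_chromosomes, max(2, min(4, count)))
        picks = rng.choice(config.n_chromosomes, size=n_chroms, replace=False)
        for j in range(count):
            chrom_of[pos + j] = chrom_names[picks[j % n_chroms]]
        pos += count
    for i in range(pos, config.n_loci):
        chrom_of[i] = chrom_names[rng.integers(config.n_chromosomes)]

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def _try_place(chrom: str, glen: int, subterminal: bool) -> int | None:
        length = config.chromosome_length
        cen = config.centromere_fraction * length
        for _ in range(300):
            if subterminal:
                left = rng.random() < 0.5
                arm_len = cen if left else length - cen
                dist = rng.random() * config.subterminal_arm_fraction * arm_len
                mid = dist if left else length - dist
                start = int(round(mid - glen / 2))
            else:
                start = int(rng.integers(0, max(1, length - glen)))
            start = min(max(start, 0), length - glen)
            end = start + glen
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                return start
        return None

    loci: list[dict] = []
    for i, flags in enumerate(flags_list):
        glen = _gene_length(flags, config)
        subterminal = rng.random() < config.subterminal_placement_fraction
        start = _try_place(chrom_of[i], glen, subterminal)
        if start is None and subterminal:
            # the outer arm windows can fill up on small chromosomes; fall
            # back to an unconstrained position rather than failing the run
            subterminal = False
            start = _try_place(chrom_of[i], glen, False)
        if start is None:
            raise PackingError(
                f"could not place locus {flags['locus_id']} (length {glen}) on "
                f"{chrom_of[i]} after 300 attempts: chromosome too crowded "
                f"(chromosome_length={config.chromosome_length}, n_loci={config.n_loci})"
            )
        loci.append(
            {
                **flags,
                "family": family_labels[i],
                "chrom": chrom_of[i],
                "start": start,
                "end": start + glen,
                "subterminal_planted": subterminal,
            }
        )
    return SyntheticGenome(chromosomes=chromosomes, loci=loci, config=config)


# ---------------------------------------------------------------------------
# Transcripts


def _strip_catg(seq: list[str], lo: int, hi: int, rng: np.random.Generator) -> None:
    """Remove every CATG occurrence overlapping [lo, hi) in place."""
    for _ in range(80):
        text = "".join(seq)
        hits = []
        start = text.find(ANCHOR)
        while start != -1:
            if start < hi and start + 4 > lo:
                hits.append(start)
            start = text.find(ANCHOR, start + 1)
        if not hits:
            return
        for p in hits:
            seq[p + 2] = "ACG"[rng.integers(3)]  # replace the T
    raise RuntimeError("failed to remove CATG sites (should not happen)")


def _ensure_catg(seq: list[str], lo: int, hi: int, rng: np.random.Generator) -> None:
    """Guarantee a CATG start in [lo, hi] (inclusive)."""
    text = "".join(seq)
    start = text.find(ANCHOR, lo)
    if start != -1 and start <= hi:
        return
    p = int(rng.integers(lo, hi + 1))
    seq[p : p + 4] = list(ANCHOR)


def generate_transcripts(
    genome: SyntheticGenome, config: SimulationConfig
) -> list[TranscriptModel]:
    """Build gene sequences satisfying each locus's structural flags, splice
    them into the chromosomes, and derive isoform transcript models.

    Isoforms of a locus are progressively 5'-truncated forms sharing the 3'
    end (hence the 3'UTR and the canonical tag).  Transcript-relative CDS and
    3'UTR spans tile each transcript with no gap or overlap.
    """
    rng = np.random.default_rng([config.seed, 1])
    models: list[TranscriptModel] = []
    gff_entries: list[dict] = []
    for locus in genome.loci:
        glen = locus["end"] - locus["start"]
        cds_len = config.cds_length if locus["has_utr3"] else glen
        seq = list(_random_bases(rng, glen).tobytes().decode())
        if not locus["taggable"]:
            _strip_catg(seq, 0, glen, rng)
        elif locus["has_utr3"] and locus["catg_in_utr3"]:
            _ensure_catg(seq, cds_len, glen - TAG_LENGTH, rng)
        elif locus["has_utr3"]:
            _strip_catg(seq, cds_len, glen, rng)
            _ensure_catg(seq, 0, min(cds_len - 4, glen - TAG_LENGTH), rng)
        else:
            _ensure_catg(seq, 0, glen - TAG_LENGTH, rng)
        gene_seq = "".join(seq)
        arr = genome.chromosomes[locus["chrom"]]
        arr[locus["start"] : locus["end"]] = np.frombuffer(
            gene_seq.encode(), dtype=np.uint8
        )
        max_d = max(0, cds_len - 150)
        offsets = []
        for k in range(locus["n_isoforms"]):
            d = min(k * config.isoform_step, max_d)
            if d in offsets:
                break  # CDS too short for further distinct isoforms
            offsets.append(d)
        for k, d in enumerate(offsets):
            tid = f"{locus['locus_id']}.{k + 1}"
            tseq = gene_seq[d:]
            cds = (0, cds_len - d)
            utr3 = (cds_len - d, glen - d) if locus["has_utr3"] else None
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    locus_id=locus["locus_id"],
                    sequence=tseq,
                    cds=cds,
                    utr3=utr3,
                    family=locus["family"],
                )
            )
            g0 = locus["start"] + d
            gff_entries.append(
                {
                    "transcript_id": tid,
                    "locus_id": locus["locus_id"],
                    "family": locus["family"],
                    "chrom": locus["chrom"],
                    "start": g0,
                    "end": locus["end"],
                    "cds": (g0, g0 + (cds_len - d)),
                    "utr3": (g0 + (cds_len - d), locus["end"])
                    if locus["has_utr3"]
                    else None,
                }
            )
    genome.gff_entries = gff_entries  # type: ignore[attr-defined]

    # canonical tags must be unique across loci for an unambiguous truth table
    seen: dict[str, str] = {}
    for m in models:
        if not m.transcript_id.endswith(".1"):
            continue
        tag = None
        cands = enumerate_candidate_tags(m)
        if cands:
            tag = cands[-1][0]
        if tag is None:
            continue
        if tag in seen and seen[tag] != m.locus_id:
            raise RuntimeError(
                f"canonical tag collision between loci {seen[tag]} and {m.locus_id}; "
                "re-run with a different seed"
            )
        seen[tag] = m.locus_id
    return models


# ---------------------------------------------------------------------------
# Libraries


def _contrast_truth(mult: dict[str, float]) -> dict[str, object]:
    out: dict[str, object] = {}
    for a, b in CONTRASTS:
        ratio = mult[a] / mult[b]
        if ratio > 1:
            fc, cls = ratio, "UR"
        elif ratio < 1:
            fc, cls = -1.0 / ratio, "DR"
        else:
            fc, cls = 1.0, "ns"
        out[f"true_fc_{a}_vs_{b}"] = fc
        out[f"true_class_{a}_vs_{b}"] = cls
    return out


def _random_tags(rng: np.random.Generator, n: int, forbidden: set[str]) -> list[str]:
    tags: list[str] = []
    seen = set(forbidden)
    while len(tags) < n:
        block = rng.integers(0, 4, (n - len(tags) + 16, TAG_LENGTH - 4))
        for row in block:
            tag = ANCHOR + "".join("ACGT"[b] for b in row)
            if tag not in seen:
                seen.add(tag)
                tags.append(tag)
                if len(tags) == n:
                    break
    return tags


def simulate_libraries(
    transcripts: list[TranscriptModel], config: SimulationConfig
) -> tuple[dict[str, dict[str, int]], pd.DataFrame]:
    """Draw the four per-library tag-count tables and the truth table.

    Returns ``(counts, truth)`` where ``counts`` maps library label (TS, TC,
    SS, SC) to {tag: raw count} including singlet noise, and ``truth`` has
    one row per emitted non-noise tag (plus rows for singlet noise tags and
    untaggable loci) with true per-contrast fold changes and classes.
    """
    rng = np.random.default_rng([config.seed, 2])
    representatives = [t for t in transcripts if t.transcript_id.endswith(".1")]
    rep_by_locus = {t.locus_id: t for t in representatives}
    loci = sorted(rep_by_locus)

    canonical: dict[str, tuple[str, int]] = {}
    partial: dict[str, tuple[str, int, int]] = {}
    untaggable: list[str] = []
    for locus in loci:
        cands = enumerate_candidate_tags(rep_by_locus[locus])
        if not cands:
            untaggable.append(locus)
            continue
        tag, pos, _rank = cands[-1]
        canonical[locus] = (tag, pos)
        if len(cands) >= 2 and cands[-2][0] != tag:
            ptag, ppos, prank = cands[-2]
            partial[locus] = (ptag, ppos, prank)

    taggable = [l for l in loci if l in canonical]
    n_tag = len(taggable)
    if n_tag == 0:
        raise ValueError("no taggable transcripts: cannot simulate libraries")

    shares = rng.lognormal(0.0, config.baseline_sigma, n_tag)
    shares /= shares.sum()

    mult = {lib: np.ones(n_tag) for lib in LIBRARIES}
    n_de = int(config.de_fraction * n_tag)
    n_de -= n_de % 2
    spiked_fc = np.ones(n_tag)
    if n_de > 0:
        chosen = rng.choice(n_tag, size=n_de, replace=False)
        chosen = chosen[np.argsort(shares[chosen])]
        depth_eff = config.library_depth * (1.0 - config.singlet_rate)
        if depth_eff * shares[chosen].min() < 2.0:
            raise ValueError(
                "library_depth too small to place spike-ins: the least-expressed "
                f"spiked locus would have an expected count below 2 "
                f"(depth={config.library_depth}, n_loci={n_tag})"
            )
        n_pairs = n_de // 2
        # regime layout (pairs are in ascending-abundance order): the
        # accession-specific regimes alternate over the low-abundance half so
        # the TS-only and SS-only groups carry matched mass; high-abundance
        # pairs get the "both" regime, which loads all four libraries equally.
        # Together with the equal-share up/down pairing this keeps every
        # contrast composition-balanced, so unspiked tags have a true
        # frequency ratio of ~1.
        n_lower = n_pairs // 2
        regimes = ["TS" if k % 2 == 0 else "SS" for k in range(n_lower)]
        regimes += ["both"] * (n_pairs - n_lower)
        regime_counts: dict[str, int] = {}
        for pair_index in range(n_pairs):
            i, j = chosen[2 * pair_index], chosen[2 * pair_index + 1]
            gm = math.sqrt(shares[i] * shares[j])
            shares[i] = shares[j] = gm
            regime = regimes[pair_index]
            # cycle fold changes within each regime group, aligned between
            # the TS-only and SS-only groups
            k = regime_counts.get(regime, 0)
            regime_counts[regime] = k + 1
            f = float(config.true_fc_values[k % len(config.true_fc_values)])
            up, down = (i, j) if rng.random() < 0.5 else (j, i)
            stress, control = {
                "both": (("TS", "SS"), ("TC", "SC")),
                "TS": (("TS",), ("TC",)),
                "SS": (("SS",), ("SC",)),
            }[regime]
            for lib in stress:
                mult[lib][up] *= f
            for lib in control:
                mult[lib][down] *= f
            spiked_fc[up] = f
            spiked_fc[down] = f
        shares /= shares.sum()

    sister_of: dict[str, tuple[str, int]] = {}
    n_sis = int(round(config.snp_sister_rate * n_tag))
    all_real = {canonical[l][0] for l in taggable} | {p[0] for p in partial.values()}
    if n_sis > 0:
        carriers = rng.choice(n_tag, size=n_sis, replace=False)
        for idx in sorted(carriers):
            locus = taggable[idx]
            base_tag = canonical[locus][0]
            for _ in range(50):
                p = int(rng.integers(4, TAG_LENGTH))  # never inside the CATG anchor
                new = "ACGT"[int(rng.integers(4))]
                if new == base_tag[p]:
                    continue
                sister = base_tag[:p] + new + base_tag[p + 1 :]
                if sister not in all_real:
                    all_real.add(sister)
                    sister_of[locus] = (sister, p + 1)  # 1-based position
                    break

    # per-tag emission records: (tag, kind, locus_index, mass fraction of locus)
    emissions: list[tuple[str, str, int, float]] = []
    for idx, locus in enumerate(taggable):
        fr_partial = config.partial_digestion_rate if locus in partial else 0.0
        fr_sister = config.sister_mass_fraction if locus in sister_of else 0.0
        emissions.append(
            (canonical[locus][0], "canonical", idx, (1 - fr_partial) * (1 - fr_sister))
        )
        if locus in sister_of:
            emissions.append(
                (sister_of[locus][0], "sister", idx, (1 - fr_partial) * fr_sister)
            )
        if locus in partial:
            emissions.append((partial[locus][0], "partial", idx, fr_partial))

    mass_base = np.array([shares[e[2]] * e[3] for e in emissions])
    depth_eff = config.library_depth * (1.0 - config.singlet_rate)
    n_singlets = int(round(config.singlet_rate * config.library_depth))

    counts: dict[str, dict[str, int]] = {}
    for lib in LIBRARIES:
        lib_mult = np.array([mult[lib][e[2]] for e in emissions])
        mass = mass_base * lib_mult
        mu = mass / mass.sum() * depth_eff
        if config.dispersion > 0:
            size = 1.0 / config.dispersion
            drawn = rng.negative_binomial(size, size / (size + mu))
        else:
            drawn = rng.poisson(mu)
        table = {
            e[0]: int(c) for e, c in zip(emissions, drawn) if c > 0
        }
        for tag in _random_tags(rng, n_singlets, all_real | set(table)):
            table[tag] = 1
        counts[lib] = table

    rows: list[dict] = []
    for tag, kind, idx, frac in emissions:
        locus = taggable[idx]
        rep = rep_by_locus[locus]
        if kind == "partial":
            _ptag, pos, rank = partial[locus]
        else:
            pos = canonical[locus][1]
            rank = 1
        locus_mult = {lib: float(mult[lib][idx]) for lib in LIBRARIES}
        row = {
            "tag": tag,
            "kind": kind,
            "locus_id": locus,
            "transcript_id": rep.transcript_id,
            "family": rep.family or "",
            "anchor_offset": pos,
            "rank_from_3prime": rank,
            "is_partial": kind == "partial",
            "sister_partner": "",
            "sister_position": 0,
            "baseline_tpm": shares[idx] * frac * 1e6,
            "spiked_fc": float(spiked_fc[idx]),
            **_contrast_truth(locus_mult),
        }
        if kind == "sister":
            row["sister_partner"] = canonical[locus][0]
            row["sister_position"] = sister_of[locus][1]
        elif locus in sister_of and kind == "canonical":
            row["sister_partner"] = sister_of[locus][0]
            row["sister_position"] = sister_of[locus][1]
        rows.append(row)

    neutral = _contrast_truth({lib: 1.0 for lib in LIBRARIES})
    singlet_tags = sorted(
        {t for lib in LIBRARIES for t, c in counts[lib].items() if c == 1}
        - {e[0] for e in emissions}
    )
    for tag in singlet_tags:
        rows.append(
            {
                "tag": tag, "kind": "singlet", "locus_id": "", "transcript_id": "",
                "family": "", "anchor_offset": -1, "rank_from_3prime": 0,
                "is_partial": False, "sister_partner": "", "sister_position": 0,
                "baseline_tpm": 0.0, "spiked_fc": 1.0, **neutral,
            }
        )
    for locus in untaggable:
        rows.append(
            {
                "tag": "", "kind": "untaggable_locus", "locus_id": locus,
                "transcript_id": rep_by_locus[locus].transcript_id,
                "family": rep_by_locus[locus].family or "", "anchor_offset": -1,
                "rank_from_3prime": 0, "is_partial": False, "sister_partner": "",
                "sister_position": 0, "baseline_tpm": 0.0, "spiked_fc": 1.0,
                **neutral,
            }
        )
    truth = pd.DataFrame(rows)
    return counts, truth


# ---------------------------------------------------------------------------
# One-call dataset


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate genome, gene models, transcripts, four libraries and the
    truth table, and write everything under ``outdir``.

    Identical (config, seed) produce byte-identical files.
    Returns the mapping of output names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    transcripts = generate_transcripts(genome, config)
    counts, truth = simulate_libraries(transcripts, config)

    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    sio.write_fasta(genome.sequences(), paths["genome"])
    sio.write_fasta(
        {t.transcript_id: t.sequence for t in transcripts},
        paths["transcripts"],
        descriptions={
            t.transcript_id: f"locus={t.locus_id} family={t.family or 'NA'}"
            for t in transcripts
        },
    )
    sio.write_gff3(genome.gff_entries, genome.chromosome_lengths(), paths["gff3"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    for lib in LIBRARIES:
        path = outdir / f"tags_{lib}.tsv"
        frame = pd.DataFrame(
            sorted(counts[lib].items()), columns=["tag", "count"]
        )
        frame.to_csv(path, sep="\t", index=False)
        paths[f"tags_{lib}"] = path
    return paths
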