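"""Post-alignment iCLIP analytics.

Works downstream of adapter trimming and genome alignment, on BED-like read
records carrying a random (PCR) barcode, a sample barcode, and an alignment
score.  Implements the filtering and quantification rules of a PAR-iCLIP
analysis:

* PCR duplicates collapse on (chromosome, start, strand, random barcode);
* reads shorter than 18 nt or scoring below 10 are discarded;
* the cross-link site is the reverse-transcription truncation position, the
  nucleotide immediately 5' of the read start in transcript orientation;
* reads overlapping on one strand merge into clusters, retained at >= 5
  reads;
* fold enrichment per genomic category = percent of reads assigned to the
  category / percent of genomic nucleotides it occupies;
* cross-link sites inside tRNA genes are re-indexed so the anticodon
  occupies positions 1-3 (5' positions run 0, -1, -2, ...).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = (
    "exon", "intron", "lincRNA", "snRNA", "rRNA", "miRNA", "tRNA", "intergenic"
)
# Single-category assignment for overlapping annotations: small-RNA classes
# take priority so tRNA/rRNA reads inside host genes are not swallowed by
# exon or intron.
DEFAULT_PRECEDENCE = (
    "tRNA", "rRNA", "miRNA", "snRNA", "lincRNA", "exon", "intron", "intergenic"
)

MIN_READ_LENGTH = 18
MIN_ALIGNMENT_SCORE = 10
MIN_CLUSTER_READS = 5


@dataclass(frozen=True)
class AlignedRead:
    """One aligned sequencing read (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    score: int
    random_barcode: str
    sample_barcode: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read start must be below end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    position: int
    strand: str
    count: int = 1
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be non-negative")


@dataclass
class GenomeAnnotation:
    """Category-labelled interval sets over a (toy) genome.

    ``intervals`` maps category -> list of (chrom, start, end); intergenic is
    implicit, defined as the complement of all annotated intervals.
    """

    intervals: dict[str, list[tuple[str, int, int]]]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for cat, ivs in self.intervals.items():
            if cat not in CATEGORIES or cat == "intergenic":
                raise ValueError(f"unknown annotation category {cat!r}")
            for chrom, start, end in ivs:
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"interval on unknown chromosome {chrom!r}")
                if not 0 <= start < end <= self.chrom_lengths[chrom]:
                    raise ValueError(
                        f"interval [{start}, {end}) outside {chrom!r} bounds"
                    )

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def category_lengths(self) -> dict[str, int]:
        """Nucleotides per category; intergenic is the unannotated rest.

        Overlaps between categories are resolved by the same precedence used
        for read assignment so category totals partition the genome.
        """
        occupied: dict[str, np.ndarray] = {
            chrom: np.zeros(length, dtype=bool)
            for chrom, length in self.chrom_lengths.items()
        }
        lengths = {cat: 0 for cat in CATEGORIES}
        for cat in DEFAULT_PRECEDENCE:
            if cat == "intergenic":
                continue
            for chrom, start, end in self.intervals.get(cat, []):
                span = occupied[chrom][start:end]
                lengths[cat] += int((~span).sum())
                span[:] = True
        annotated = sum(v.sum() for v in occupied.values())
        lengths["intergenic"] = self.genome_length - int(annotated)
        return lengths

    def assign(self, site: CrosslinkSite,
               precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> str:
        for cat in precedence:
            if cat == "intergenic":
                continue
            for chrom, start, end in self.intervals.get(cat, []):
                if chrom == site.chrom and start <= site.position < end:
                    return cat
        return "intergenic"


def preprocess_reads(
    reads: list[AlignedRead],
    min_length: int = MIN_READ_LENGTH,
    min_score: int = MIN_ALIGNMENT_SCORE,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Deduplicate and filter reads; returns (kept, unbarcoded).

    PCR duplicates (identical chromosome, start, strand and random barcode)
    collapse to a single read.  Reads shorter than ``min_length`` or with
    alignment score below ``min_score`` are removed.  Reads with no random
    barcode cannot be deduplicated and are routed to the ``unbarcoded`` bin
    rather than silently dropped.  The result is independent of input order.
    """
    unbarcoded = [r for r in reads if not r.random_barcode]
    candidates = [
        r for r in reads
        if r.random_barcode and r.length >= min_length and r.score >= min_score
    ]
    survivors: dict[tuple, AlignedRead] = {}
    for read in candidates:
        key = (read.chrom, read.start, read.strand, read.random_barcode)
        prev = survivors.get(key)
        if prev is None or (read.end, read.name) < (prev.end, prev.name):
            survivors[key] = read
    kept = sorted(
        survivors.values(),
        key=lambda r: (r.chrom, r.start, r.end, r.strand, r.random_barcode),
    )
    return kept, unbarcoded


def crosslink_site(read: AlignedRead) -> CrosslinkSite:
    """Truncation position of a read: the nucleotide immediately 5' of its
    5' end in transcript orientation.  A site falling before the chromosome
    start is clamped to 0 and marked."""
    if read.strand == "+":
        pos = read.start - 1
    else:
        pos = read.end
    clamped = pos < 0
    return CrosslinkSite(
        chrom=read.chrom, position=max(pos, 0), strand=read.strand,
        clamped=clamped,
    )


def crosslink_sites(reads: list[AlignedRead]) -> list[CrosslinkSite]:
    """Aggregate per-read truncation positions into supported sites."""
    counts: Counter = Counter()
    clamped: set = set()
    for read in reads:
        site = crosslink_site(read)
        key = (site.chrom, site.position, site.strand)
        counts[key] += 1
        if site.clamped:
            clamped.add(key)
    return [
        CrosslinkSite(chrom=c, position=p, strand=s, count=n,
                      clamped=(c, p, s) in clamped)
        for (c, p, s), n in sorted(counts.items())
    ]


def enrichment_table(
    reads: list[AlignedRead],
    annotation: GenomeAnnotation,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Per-category read percentage, genome percentage and fold enrichment.

    Each read is assigned exactly one category through its cross-link site,
    so read percentages sum to 100.  Fold = read% / genome%; a category with
    reads but zero genomic extent is flagged infinite rather than crashing.
    """
    if not reads:
        raise ValueError("no reads to tabulate")
    assigned = Counter(
        annotation.assign(crosslink_site(read), precedence) for read in reads
    )
    lengths = annotation.category_lengths()
    genome_total = annotation.genome_length
    n_reads = len(reads)
    rows = []
    for cat in CATEGORIES:
        read_pct = 100.0 * assigned.get(cat, 0) / n_reads
        genome_pct = 100.0 * lengths[cat] / genome_total
        if genome_pct > 0:
            fold = read_pct / genome_pct
            infinite = False
        else:
            fold = np.inf if read_pct > 0 else np.nan
            infinite = read_pct > 0
        rows.append(
            dict(category=cat, read_count=assigned.get(cat, 0),
                 read_pct=read_pct, genome_pct=genome_pct, fold=fold,
                 infinite=infinite)
        )
    return pd.DataFrame(rows)


@dataclass
class ReadCluster:
    chrom: str
    strand: str
    start: int
    end: int
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.reads)


def cluster_reads(
    reads: list[AlignedRead], min_reads: int = MIN_CLUSTER_READS
) -> list[ReadCluster]:
    """Single-linkage merge of same-strand reads overlapping by >= 1 nt;
    clusters supported by fewer than ``min_reads`` reads are discarded.
    Output is invariant to the input ordering."""
    by_group: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for read in reads:
        by_group[(read.chrom, read.strand)].append(read)
    clusters: list[ReadCluster] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda r: (r.start, r.end, r.random_barcode, r.name))
        current: ReadCluster | None = None
        for read in group:
            if current is not None and read.start < current.end:
                current.end = max(current.end, read.end)
                current.reads.append(read)
            else:
                if current is not None:
                    clusters.append(current)
                current = ReadCluster(
                    chrom=chrom, strand=strand, start=read.start,
                    end=read.end, reads=[read],
                )
        if current is not None:
            clusters.append(current)
    return [c for c in clusters if c.count >= min_reads]


@dataclass
class TRNAModel:
    """A tRNA gene with per-position structural-element labels.

    ``element_labels`` has one entry per transcript position (5'->3');
    ``anticodon`` holds the three transcript indices (0-based) of the
    anticodon, which must lie inside the anticodon loop.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    element_labels: tuple[str, ...]
    anticodon: tuple[int, int, int]

    def __post_init__(self) -> None:
        n = self.end - self.start
        if len(self.sequence) != n or len(self.element_labels) != n:
            raise ValueError("sequence/labels must cover the gene span")
        a0, a1, a2 = self.anticodon
        if not (a0 + 1 == a1 and a1 + 1 == a2):
            raise ValueError("anticodon indices must be consecutive")
        for idx in self.anticodon:
            if self.element_labels[idx] != "anticodon_loop":
                raise ValueError("anticodon must lie inside the anticodon loop")

    def transcript_position(self, genomic_pos: int) -> int | None:
        if not self.start <= genomic_pos < self.end:
            return None
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos


@dataclass
class PositionalProfile:
    """Cross-link histogram on the anticodon-anchored coordinate (anticodon
    = positions 1-3; 5' positions 0, -1, -2, ...)."""

    positions: Counter
    element_counts: Counter
    unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(self.positions.values())

    @property
    def mode(self) -> int:
        return max(self.positions, key=lambda k: (self.positions[k], -k))


def trna_positional_profile(
    sites: list[CrosslinkSite], models: list[TRNAModel]
) -> PositionalProfile:
    """Map cross-link sites into anticodon-relative coordinates.

    Each site contributes its supporting count.  Sites outside every provided
    tRNA gene go to the ``unassigned`` bin.
    """
    positions: Counter = Counter()
    elements: Counter = Counter()
    unassigned = 0
    for site in sites:
        hit = None
        for model in models:
            if model.chrom != site.chrom or model.strand != site.strand:
                continue
            p = model.transcript_position(site.position)
            if p is not None:
                hit = (model, p)
                break
        if hit is None:
            unassigned += site.count
            continue
        model, p = hit
        rel = p - model.anticodon[0] + 1
        positions[rel] += site.count
        elements[model.element_labels[p]] += site.count
    return PositionalProfile(
        positions=positions, element_counts=elements, unassigned=unassigned
    )


def abundance_compare(
    clip_counts: dict[str, float],
    background_counts: dict[str, float],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene pool fractions and log2(CLIP / background) ratio.

    Genes absent from one pool receive ``pseudocount`` reads in that pool and
    are flagged ``pseudocount_dependent``; genes observed in both pools use
    raw fractions.
    """
    if not clip_counts or not background_counts:
        raise ValueError("both pools must be non-empty")
    genes = sorted(set(clip_counts) | set(background_counts))
    clip = np.array([clip_counts.get(g, 0.0) for g in genes], dtype=float)
    back = np.array([background_counts.get(g, 0.0) for g in genes], dtype=float)
    flagged = (clip == 0) | (back == 0)
    clip_adj = np.where(clip == 0, pseudocount, clip)
    back_adj = np.where(back == 0, pseudocount, back)
    clip_frac = clip_adj / clip_adj.sum()
    back_frac = back_adj / back_adj.sum()
    table = pd.DataFrame(
        dict(
            gene=genes, clip_count=clip, background_count=back,
            clip_fraction=clip_frac, background_fraction=back_frac,
            log2_ratio=np.log2(clip_frac / back_frac),
            pseudocount_dependent=flagged,
        )
    )
    return table.sort_values("log2_ratio", ascending=False, ignore_index=True)
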