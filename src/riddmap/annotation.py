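"""Gene models, exon-bin flattening, and coordinate arithmetic.

Poly(A)-selected RNA-seq of an in vitro IRE1 cleavage reaction reads out
endonucleolytic cleavage as a loss of coverage 5' of the cut.  To test that
signal per exon region, overlapping transcript annotations are flattened into
disjoint counting bins (the DEXSeq-style preprocessing step): every maximal
genomic interval covered by a constant set of (gene, transcript) memberships
becomes one bin, and bins are split at every exon boundary of any overlapping
transcript.  Bins touched by two or more genes are flagged *ambiguous* and are
excluded from testing downstream.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open internally; GTF I/O converts from/to
the 1-based inclusive convention of the format.  Transcript coordinates are
1-based (position 1 = the transcript's 5'-most nucleotide), matching how
cleavage sites are cited in the RIDD literature (e.g. "guanine 444" of
BLOC1S1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "TranscriptModel",
    "ExonBin",
    "flatten_gene_models",
    "order_bins",
    "bins_for_gene",
    "genomic_to_transcript",
    "transcript_to_genomic",
    "spliced_sequence",
]

_RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class CoordinateError(ValueError):
    """A genomic/transcript position falls outside the queried model."""


class GtfParseError(ValueError):
    """A GTF record could not be parsed (reported with its line number)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure plus (optionally) its spliced sequence.

    Parameters
    ----------
    gene_id, transcript_id : str
        Identifiers; unique within a run.
    chrom : str
        Reference sequence name.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Genomic half-open intervals, sorted, non-overlapping.
    sequence : str or None
        Spliced mRNA sequence, 5'->3', RNA alphabet (ACGU).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValueError(f"exon with end <= start: ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != exonic length {self.length}"
                )
            bad = set(self.sequence) - _RNA_ALPHABET
            if bad:
                raise ValueError(f"sequence contains non-RNA characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def with_sequence(self, sequence: str) -> "TranscriptModel":
        return replace(self, sequence=sequence)


@dataclass
class ExonBin:
    """A disjoint counting bin produced by flattening gene models."""

    bin_id: str
    gene_ids: tuple[str, ...]
    chrom: str
    start: int
    end: int
    strand: str
    rank_5to3: int | None = None
    ambiguous: bool = field(default=False)

    def __post_init__(self) -> None:
        self.gene_ids = tuple(sorted(set(self.gene_ids)))
        self.ambiguous = len(self.gene_ids) >= 2

    @property
    def length(self) -> int:
        return self.end - self.start


def flatten_gene_models(models: list[TranscriptModel]) -> list[ExonBin]:
    """Flatten transcript exons into disjoint counting bins.

    Every exon boundary of any transcript on a chromosome introduces a split;
    each resulting atomic interval covered by at least one exon becomes one
    bin carrying the set of genes whose exons cover it.  Bins overlapping
    two or more genes are flagged ambiguous.  Output is sorted genomically
    (chromosome, then start).
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    bins: list[ExonBin] = []
    for chrom in sorted(by_chrom):
        chrom_models = by_chrom[chrom]
        boundaries: set[int] = set()
        for m in chrom_models:
            for s, e in m.exons:
                boundaries.add(s)
                boundaries.add(e)
        cuts = sorted(boundaries)
        for a, b in zip(cuts[:-1], cuts[1:]):
            covering = [
                m for m in chrom_models if any(s <= a and b <= e for s, e in m.exons)
            ]
            if not covering:
                continue
            genes = tuple(sorted({m.gene_id for m in covering}))
            strands = {m.strand for m in covering}
            strand = strands.pop() if len(strands) == 1 else "."
            bins.append(
                ExonBin(
                    bin_id=f"{'+'.join(genes)}:{chrom}:{a}-{b}",
                    gene_ids=genes,
                    chrom=chrom,
                    start=a,
                    end=b,
                    strand=strand,
                )
            )
    bins.sort(key=lambda x: (x.chrom, x.start))
    return bins


def bins_for_gene(bins: list[ExonBin], gene_id: str) -> list[ExonBin]:
    """All bins touching *gene_id*, in genomic order."""
    return [b for b in bins if gene_id in b.gene_ids]


def order_bins(bins: list[ExonBin], strand: str) -> list[ExonBin]:
    """Assign 5'->3' ranks to the bins of one gene and return them in rank order.

    Rank 1 is the 5'-most bin: genomic leftmost on the plus strand, rightmost
    on the minus strand.
    """
    genes = {g for b in bins for g in b.gene_ids}
    # every bin must share at least one gene; mixing genes makes ranks meaningless
    common = set(bins[0].gene_ids) if bins else set()
    for b in bins:
        common &= set(b.gene_ids)
    if bins and not common:
        raise ValueError(f"order_bins called with bins from unrelated genes: {sorted(genes)}")
    ordered = sorted(bins, key=lambda b: b.start, reverse=(strand == "-"))
    out = []
    for rank, b in enumerate(ordered, start=1):
        out.append(replace_rank(b, rank))
    return out


def replace_rank(b: ExonBin, rank: int) -> ExonBin:
    new = ExonBin(
        bin_id=b.bin_id,
        gene_ids=b.gene_ids,
        chrom=b.chrom,
        start=b.start,
        end=b.end,
        strand=b.strand,
        rank_5to3=rank,
    )
    return new


def genomic_to_transcript(t: TranscriptModel, gpos: int) -> int:
    """Map a 0-based genomic position inside an exon to a 1-based transcript coordinate.

    On the minus strand the transcript runs right-to-left, so the rightmost
    exonic base is transcript position 1.  Raises :class:`CoordinateError`
    for intronic or out-of-range positions.
    """
    if t.strand == "+":
        offset = 0
        for s, e in t.exons:
            if s <= gpos < e:
                return offset + (gpos - s) + 1
            offset += e - s
    else:
        offset = 0
        for s, e in reversed(t.exons):
            if s <= gpos < e:
                return offset + (e - 1 - gpos) + 1
            offset += e - s
    raise CoordinateError(
        f"genomic position {gpos} is not exonic in transcript {t.transcript_id}"
    )


def transcript_to_genomic(t: TranscriptModel, tpos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` (1-based transcript -> 0-based genomic)."""
    if not 1 <= tpos <= t.length:
        raise CoordinateError(
            f"transcript position {tpos} outside 1..{t.length} of {t.transcript_id}"
        )
    remaining = tpos - 1
    exon_iter = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    for s, e in exon_iter:
        n = e - s
        if remaining < n:
            return s + remaining if t.strand == "+" else (e - 1) - remaining
        remaining -= n
    raise AssertionError("unreachable")  # pragma: no cover


def spliced_sequence(t: TranscriptModel, chrom_seq: str) -> str:
    """Build the spliced 5'->3' mRNA sequence from a chromosome sequence.

    *chrom_seq* may be DNA or RNA; T is converted to U.  Minus-strand
    transcripts are reverse-complemented.
    """
    parts = [chrom_seq[s:e] for s, e in t.exons]
    seq = "".join(parts).upper().replace("T", "U")
    if t.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq
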