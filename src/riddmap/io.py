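"""Readers and writers for the pipeline's on-disk formats.

GTF is read and written 1-based inclusive (the format's convention) and
converted to/from the package's internal 0-based half-open intervals.
Transcript FASTA is written with U->T (DNA alphabet, as sequence databases
store mRNA) and converted back to RNA on read.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import ExonBin, GtfParseError, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    """Write exon features, one line per exon, with gene_id/transcript_id attributes."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\triddmap\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features of a GTF into transcript models (without sequences).

    Only ``exon`` features are used.  Malformed lines raise
    :class:`~riddmap.annotation.GtfParseError` with the 1-based line number.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if e <= s:
                raise GtfParseError(f"line {lineno}: exon end <= start")
            attr_map = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr_map or "transcript_id" not in attr_map:
                raise GtfParseError(f"line {lineno}: missing gene_id/transcript_id")
            tx = attr_map["transcript_id"]
            rec = per_tx.setdefault(
                tx, {"gene_id": attr_map["gene_id"], "chrom": chrom, "strand": strand, "exons": []}
            )
            rec["exons"].append((s, e))
    models = []
    for tx, rec in per_tx.items():
        models.append(
            TranscriptModel(
                gene_id=rec["gene_id"],
                transcript_id=tx,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.exons[0][0]))
    return models


def write_transcript_fasta(models: list[TranscriptModel], path: str | Path) -> None:
    """Write spliced transcript sequences; RNA U is stored as DNA T."""
    records = []
    for m in models:
        if m.sequence is None:
            raise ValueError(f"transcript {m.transcript_id} has no sequence")
        records.append(
            SeqRecord(
                Seq(m.sequence.replace("U", "T")),
                id=m.transcript_id,
                description=f"gene={m.gene_id}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def read_transcript_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences keyed by id, converted to the RNA alphabet."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def attach_sequences(
    models: list[TranscriptModel], sequences: dict[str, str]
) -> list[TranscriptModel]:
    return [m.with_sequence(sequences[m.transcript_id]) for m in models]


def write_bins_tsv(bins: list[ExonBin], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "bin_id": [b.bin_id for b in bins],
            "gene_ids": ["+".join(b.gene_ids) for b in bins],
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "strand": [b.strand for b in bins],
            "rank_5to3": [b.rank_5to3 if b.rank_5to3 is not None else -1 for b in bins],
            "ambiguous": [int(b.ambiguous) for b in bins],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_bins_tsv(path: str | Path) -> list[ExonBin]:
    df = pd.read_csv(path, sep="\t")
    bins = []
    for row in df.itertuples(index=False):
        b = ExonBin(
            bin_id=row.bin_id,
            gene_ids=tuple(str(row.gene_ids).split("+")),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            rank_5to3=None if row.rank_5to3 == -1 else int(row.rank_5to3),
        )
        bins.append(b)
    return bins


def write_counts_tsv(counts: pd.DataFrame, gene_ids: pd.Series, path: str | Path) -> None:
    """Write a bin x sample count table (bin_id, gene_id, one column per sample)."""
    out = counts.copy()
    out.insert(0, "gene_id", gene_ids)
    out.index.name = "bin_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="bin_id")
    gene_ids = df.pop("gene_id")
    return df.astype(int), gene_ids


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
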