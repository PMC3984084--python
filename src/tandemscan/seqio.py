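"""Standard-format I/O helpers: FASTA, GFF3, and TSV.

All internal coordinates are 0-based, half-open. GFF3 is written and read
1-based inclusive per the standard; the conversion happens exactly here, at
the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Feature:
    """A located annotation interval, 0-based half-open on ``seqid``."""

    seqid: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict.

    Wrapping and case are tolerated; sequences are upper-cased.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | os.PathLike, records: dict[str, str], width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_gff3(path: str | os.PathLike, features: Iterable[Feature], source: str = "tandemscan") -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            attrs = f"ID={f.name or f'{f.ftype}_{i}'};Name={f.name}" if f.name else f"ID={f.ftype}_{i}"
            fh.write(
                f"{f.seqid}\t{source}\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | os.PathLike) -> list[Feature]:
    """Read GFF3 features back into 0-based half-open :class:`Feature` objects."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    feats = []
    for f in db.all_features(order_by=("seqid", "start")):
        name = f.attributes.get("Name", f.attributes.get("ID", [""]))[0]
        feats.append(
            Feature(seqid=f.seqid, ftype=f.featuretype, start=f.start - 1, end=f.end,
                    strand=f.strand or "+", name=name)
        )
    return feats


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(path: str | os.PathLike, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    """Write (chrom, start, end, name) intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            out.append((chrom, start, end, name))
    return out
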