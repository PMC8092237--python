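"""File input/output: FASTA, FASTQ, locus sheets, and minimal VCF.

FASTA/FASTQ go through Biopython's SeqIO with transparent gzip handling.
SNV lists are exchanged as minimal VCF (CHROM/POS/ID/REF/ALT/QUAL/FILTER/
INFO) read via cyvcf2, or as TSV.  All records come back as plain Python
containers so the rest of the package stays format-agnostic.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into {id: sequence}."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]):
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with _open_text(path, "wt") as handle:
        SeqIO.write(recs, handle, "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred qualities) from a (gzipped) FASTQ."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations[
                "phred_quality"
            ]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, list[int]]]):
    with _open_text(path, "wt") as handle:
        for name, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{name}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# Locus sheets: name, reference id, protospacer interval, strand, editor.


def read_locus_sheet(path: str | Path) -> pd.DataFrame:
    """Read a locus sheet (TSV or JSON list of objects) into a DataFrame.

    Required columns: name, reference, proto_start, proto_end, strand,
    editor.  Coordinates are 1-based inclusive on the reference.
    """
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"name", "reference", "proto_start", "proto_end", "strand", "editor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus sheet missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Minimal VCF.


@dataclass
class SNVRecord:
    """A point variant; classification is filled in by the classifier."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    frequency: float | None = None
    classification: str | None = None  # on_target | sgRNA_dependent | sgRNA_independent
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"SNV ref == alt at {self.contig}:{self.pos}")


def read_snvs(path: str | Path) -> list[SNVRecord]:
    """Read SNVs from a minimal VCF (via cyvcf2) or a TSV."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz"):
        from cyvcf2 import VCF

        out = []
        for v in VCF(str(path)):
            for alt in v.ALT:
                if len(v.REF) != 1 or len(alt) != 1:
                    continue  # SNVs only
                af = v.INFO.get("AF")
                out.append(SNVRecord(v.CHROM, v.POS, v.REF, alt, frequency=af))
        return out
    df = pd.read_csv(path, sep="\t")
    return [
        SNVRecord(
            str(r["contig"]),
            int(r["pos"]),
            str(r["ref"]),
            str(r["alt"]),
            frequency=float(r["frequency"]) if "frequency" in df.columns else None,
        )
        for _, r in df.iterrows()
    ]


def write_vcf(
    path: str | Path, snvs: Iterable[SNVRecord], contigs: dict[str, int] | None = None
):
    """Write SNVs as a minimal VCF 4.2 file (uncompressed text)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
    for name, length in (contigs or {}).items():
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for s in sorted(snvs, key=lambda s: (s.contig, s.pos, s.alt)):
        info = f"AF={s.frequency:.4f}" if s.frequency is not None else "."
        buf.write(f"{s.contig}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t{info}\n")
    Path(path).write_text(buf.getvalue())
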