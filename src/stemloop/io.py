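"""File-format adapters: FASTA/FASTQ readers, collapsed FASTA, references.

FASTQ qualities are ignored throughout (the pipeline works on
sequences and counts).  The collapsed-FASTA dialect stores the read
multiplicity after the last underscore of the header (``>id_count``).
Mature miRNA references use miRBase-style headers; sequences are
normalized U->T on input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .preprocess import ReadRecord, collapse
from .seqs import normalize


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA -> {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_genome(path):
    """Genome FASTA with an on-disk index (pyfaidx), str-indexable by contig."""
    import pyfaidx

    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def read_reads(path) -> list[ReadRecord]:
    """Read a library as FASTQ or (collapsed) FASTA, collapsing duplicates.

    FASTA headers of the form ``id_count`` contribute ``count`` copies;
    other headers count once.
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    records = []
    for rec in SeqIO.parse(str(path), fmt):
        count = 1
        if fmt == "fasta" and "_" in rec.id:
            tail = rec.id.rsplit("_", 1)[1]
            if tail.isdigit():
                count = int(tail)
        records.append(ReadRecord(rec.id, str(rec.seq).upper(), count))
    return collapse(records)


def write_collapsed_fasta(path, records: Iterable[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            fh.write(f">t{i:07d}_{rec.count}\n{rec.sequence}\n")


def load_mature_fasta(path, species: str | None = None) -> dict[str, str]:
    """miRBase-dialect mature FASTA -> {name: DNA sequence}.

    ``species`` keeps only entries whose name starts with that prefix
    (e.g. ``"bra"``); sequences are U->T normalized and uppercased.
    """
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if species is not None and not name.startswith(species + "-"):
            continue
        out[name] = normalize(str(rec.seq))
    return out


def read_degradome_reads(path) -> list[tuple[str, int]]:
    """Degradome library -> [(sequence, count)] with duplicates merged."""
    return [(r.sequence, r.count) for r in read_reads(path)]


def read_homology_map(path) -> dict:
    """TSV (transcript_id, at_gene_id, known_target_flag) -> homology entries."""
    import pandas as pd

    from .degradome import HomologyEntry

    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        flag = row.get("known_target_flag", False)
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("1", "true", "y", "yes")
        out[str(row["transcript_id"])] = HomologyEntry(
            at_gene=str(row["at_gene_id"]), known_target_flag=bool(flag)
        )
    return out
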