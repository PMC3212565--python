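"""FASTA/FASTQ and tabular input/output (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ReadSet, SequenceRead


def write_fasta(path: str | Path, items, width: int = 70) -> None:
    """Write (id, sequence) pairs, SequenceReads or a ReadSet as FASTA."""
    records = []
    for item in items:
        if isinstance(item, SequenceRead):
            rid, seq = item.id, item.bases
        else:
            rid, seq = item
        records.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SequenceRead]:
    return [SequenceRead(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(path: str | Path, reads: ReadSet) -> None:
    """Write a short-read batch as Sanger FASTQ (Phred+33)."""
    if reads.qualities is None:
        raise ValueError("FASTQ output requires qualities")
    records = []
    for i in range(len(reads)):
        rec = SeqRecord(Seq(reads.seqs[i]), id=reads.ids[i], description="")
        rec.letter_annotations["phred_quality"] = reads.qualities[i].tolist()
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> ReadSet:
    ids, seqs, quals = [], [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        quals.append(rec.letter_annotations["phred_quality"])
    qmat = np.asarray(quals, dtype=np.int16) if quals else None
    return ReadSet(ids, seqs, qmat)


def write_tags_tsv(path: str | Path, tags: list[str], prefix: str = "tag") -> None:
    with open(path, "w") as fh:
        fh.write("id\tsequence\n")
        for i, t in enumerate(tags):
            fh.write(f"{prefix}_{i}\t{t}\n")


def read_tags_tsv(path: str | Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return df["sequence"].astype(str).tolist()


def write_membership_tsv(path: str | Path, clusters) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcluster_id\n")
        for cl in clusters:
            for rid in cl.members:
                fh.write(f"{rid}\t{cl.id}\n")


def read_membership_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["read_id"], df["cluster_id"]))


def write_edges_tsv(path: str | Path, edges) -> None:
    with open(path, "w") as fh:
        fh.write("read_a\tread_b\tidentity\tshorter_coverage\tscore\tstrand\n")
        for e in edges:
            fh.write(f"{e.read_a}\t{e.read_b}\t{e.identity:.4f}\t"
                     f"{e.shorter_coverage:.4f}\t{e.score}\t{e.strand}\n")
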