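"""File formats: FASTA/FASTQ sequences and reads, layout TSVs, fixtures.

FASTA/FASTQ parsing goes through Biopython; records are uppercased on the
way in.  Read layouts (read id, start, length) are plain 3-column TSVs so a
coverage profile can be recomputed from files alone.  `generate_fixtures`
writes a self-contained set of model matrices, simulated sequences, and a
small read set for offline tests and demos.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import DNA
from .markov_model import (
    PERTURB_SECOND_ORDER,
    SequenceRecord,
    simulate_sequence,
    table1_model,
    table2_model,
    write_model_tsv,
)
from .ngs_sim import ReadSet, sample_reads_homogeneous


def _sniff_format(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    raise ValueError(f"{path} is empty")


def read_fasta(path, alphabet: str = DNA) -> list[SequenceRecord]:
    """All records of a FASTA file as :class:`SequenceRecord` (uppercased)."""
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper(), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.symbols[i : i + width] + "\n")


def read_reads(path, alphabet: str = DNA, layout=None) -> ReadSet:
    """A FASTA or FASTQ file of equal-length reads (qualities ignored).

    ``layout`` optionally names a layout TSV written by
    :func:`write_layout_tsv`; its start positions are attached so the
    coverage profile becomes recomputable.
    """
    fmt = _sniff_format(path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), fmt):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"no reads in {path}")
    starts = source_length = None
    if layout is not None:
        layout_ids, starts, lengths, source_length = read_layout_tsv(layout)
        if layout_ids != ids:
            raise ValueError("layout read ids do not match the read file")
        if any(n != len(s) for n, s in zip(lengths, seqs)):
            raise ValueError("layout read lengths do not match the read file")
    return ReadSet.from_strings(seqs, alphabet, starts, source_length, ids)


def write_reads(readset: ReadSet, path, fmt: str | None = None) -> None:
    """Write reads as FASTA or FASTQ (constant quality 'I'); format from suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    ids = readset.ids or [f"read_{i}" for i in range(readset.M)]
    with open(path, "w") as fh:
        for rid, seq in zip(ids, readset.reads):
            if fmt == "fastq":
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            else:
                fh.write(f">{rid}\n{seq}\n")


def write_layout_tsv(readset: ReadSet, path) -> None:
    if readset.starts is None:
        raise ValueError("read set has no recorded start positions")
    ids = readset.ids or [f"read_{i}" for i in range(readset.M)]
    with open(path, "w") as fh:
        fh.write(f"# source_length={readset.source_length}\n")
        fh.write("read\tstart\tlength\n")
        for rid, start in zip(ids, readset.starts):
            fh.write(f"{rid}\t{int(start)}\t{readset.kappa}\n")


def read_layout_tsv(path):
    source_length = None
    ids, starts, lengths = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "source_length=" in line:
                    value = line.split("source_length=")[1].strip()
                    source_length = None if value == "None" else int(value)
                continue
            if not line or line.startswith("read\t"):
                continue
            rid, start, length = line.split("\t")
            ids.append(rid)
            starts.append(int(start))
            lengths.append(int(length))
    return ids, np.asarray(starts, dtype=np.int64), lengths, source_length


def generate_fixtures(out_dir, seed: int = 0) -> list[str]:
    """Write a deterministic, self-contained fixture set; returns the manifest.

    Contents: the two built-in model matrices, a null pair of first-order
    sequences, a first-vs-second-order pair, and a small homogeneous read
    set with its layout.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    kid = iter(ss.spawn(5))

    manifest: list[str] = []

    def emit(name):
        manifest.append(name)
        return out / name

    write_model_tsv(table1_model(), emit("table1_model.tsv"))
    write_model_tsv(table2_model(), emit("table2_zero_model.tsv"))

    m1 = table1_model()
    null_pair = [
        simulate_sequence(m1, 10_000, next(kid), record_id=f"null_{s}") for s in (1, 2)
    ]
    write_fasta(null_pair, emit("null_pair.fasta"))

    order_pair = [
        simulate_sequence(m1, 10_000, next(kid), record_id="order1"),
        simulate_sequence(table2_model(PERTURB_SECOND_ORDER), 10_000, next(kid), record_id="order2"),
    ]
    write_fasta(order_pair, emit("order_pair.fasta"))

    reads = sample_reads_homogeneous(null_pair[0], M=100, kappa=200, seed=next(kid))
    reads.ids = [f"read_{i}" for i in range(reads.M)]
    write_reads(reads, emit("reads.fastq"))
    write_layout_tsv(reads, emit("reads_layout.tsv"))

    with open(out / "manifest.txt", "w") as fh:
        for name in manifest:
            digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
            fh.write(f"{name}\t{digest}\n")
    manifest.append("manifest.txt")
    return manifest
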