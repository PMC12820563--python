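"""Readers and writers for the plain-text formats the pipeline consumes.

BED intervals are held as pandas DataFrames with pyranges-style column names
(``Chromosome``, ``Start``, ``End`` and optionally ``Name``, ``Score``,
``Strand``) so they can be handed to :mod:`pyranges` directly.  Coverage
tracks are dense per-chromosome ``float64`` arrays keyed by chromosome name.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

BED_COLUMNS = ["Chromosome", "Start", "End", "Name", "Score", "Strand"]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-6 column BED file into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, : min(df.shape[1], 6)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read an (uncompressed) FASTA file into name -> uppercase sequence."""
    seqs: dict[str, list[str]] = {}
    name = None
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                seqs[name].append(line.upper())
    return {n: "".join(parts) for n, parts in seqs.items()}


def open_fasta(path: str | Path):
    """Open a FASTA with indexed random access (pyfaidx).

    The returned object maps contig name -> sliceable sequence record and
    can be passed wherever the scanners take a genome mapping.
    """
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str | None]]:
    """Yield (id, sequence, quality-string) records; gz-aware.

    Files named ``*.fa``/``*.fasta`` are parsed as FASTA and yield
    ``quality=None`` so downstream code can skip the Phred filter.
    """
    stem = Path(path).name.removesuffix(".gz")
    with _open_text(path) as fh:
        if stem.endswith((".fa", ".fasta", ".fna")):
            name, chunks = None, []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        yield name, "".join(chunks), None
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
            if name is not None:
                yield name, "".join(chunks), None
        else:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def phred_scores(qual: str) -> np.ndarray:
    """Decode a Phred+33 quality string to integer scores."""
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-chromosome coverage arrays."""
    cov = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["Chromosome", "Start", "End", "Value"],
    )
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom in cov:
            cov[chrom][start:end] += value
    return cov


def write_bedgraph(cov: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode dense coverage; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in cov:
            arr = np.asarray(cov[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.12g}\n")
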