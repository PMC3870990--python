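"""File-format helpers shared across the pipeline.

Sequence files (FASTA/FASTQ) go through Biopython's ``SeqIO``; tabular
files through pandas.  Genomic intervals are 0-based half-open everywhere
in memory; GFF3 (1-based, inclusive) is converted at the boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA into (id, description, sequence) tuples (uppercased)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, rec.description, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, description, sequence) tuples as FASTA."""
    seqs = []
    for rid, desc, seq in records:
        rec = SeqRecord(Seq(seq), id=rid, description=desc)
        seqs.append(rec)
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ into (id, sequence) tuples; qualities are ignored."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path, quality: str = "I") -> None:
    """Write (id, sequence) tuples as FASTQ with a constant quality char."""
    seqs = []
    for rid, seq in records:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(quality) - 33] * len(seq)
        seqs.append(rec)
    SeqIO.write(seqs, str(path), "fastq")


def parse_description_fields(description: str) -> dict[str, str]:
    """Extract ``key=value`` tokens from a FASTA description line."""
    fields: dict[str, str] = {}
    for token in description.split():
        if "=" in token:
            key, _, value = token.partition("=")
            fields[key] = value
    return fields


# -- GFF3 -------------------------------------------------------------------

def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a DataFrame with 0-based half-open coordinates.

    Columns follow the nine GFF3 fields plus ``start0``/``end0`` carrying
    the converted interval.  Comment and directive lines are skipped.
    """
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "source": str, "type": str, "strand": str,
               "score": str, "phase": str, "attributes": str},
    )
    df["start0"] = df["start"].astype(int) - 1
    df["end0"] = df["end"].astype(int)
    return df


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature DataFrame (0-based half-open ``start0``/``end0``) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in features.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(row["seqid"]),
                        str(row.get("source", "mirquest")),
                        str(row["type"]),
                        str(int(row["start0"]) + 1),
                        str(int(row["end0"])),
                        str(row.get("score", ".")),
                        str(row["strand"]),
                        str(row.get("phase", ".")),
                        str(row.get("attributes", ".")),
                    ]
                )
                + "\n"
            )


def gff3_attributes(pairs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs.items())


# -- Vienna structure files -------------------------------------------------

def read_vienna(path: str | Path) -> list[tuple[str, str, str, float | None]]:
    """Read Vienna-style records: name line, sequence line, structure line.

    The structure line may carry a trailing ``(energy)`` in kcal/mol.
    Returns (name, sequence, dot_bracket, energy-or-None) tuples.
    """
    records = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        name = lines[i][1:].strip() if lines[i].startswith(">") else f"record{len(records) + 1}"
        if lines[i].startswith(">"):
            i += 1
        seq = lines[i].strip()
        struct_line = lines[i + 1].strip()
        energy: float | None = None
        if "(" in struct_line and struct_line.rstrip().endswith(")"):
            head, _, tail = struct_line.rpartition(" ")
            if head and tail.startswith("(") and tail.endswith(")"):
                try:
                    energy = float(tail[1:-1])
                    struct_line = head.strip()
                except ValueError:
                    energy = None
        records.append((name, seq, struct_line, energy))
        i += 2
    return records


def write_vienna(
    records: Iterable[tuple[str, str, str, float | None]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq, db, energy in records:
            fh.write(f">{name}\n{seq}\n{db}")
            if energy is not None:
                fh.write(f" ({energy:.2f})")
            fh.write("\n")


# -- checksums / manifest ---------------------------------------------------

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(files: dict[str, str | Path], path: str | Path, extra: dict | None = None) -> dict:
    """Write a JSON manifest listing files with their SHA-256 checksums."""
    manifest = {
        "files": {
            name: {"path": str(Path(p).name), "sha256": sha256_of(p)}
            for name, p in sorted(files.items())
        }
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
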