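"""Readers/writers for the standard text formats the pipeline exchanges:
FASTA (60-column wrap), BED (0-based half-open), TSV with header, JSON with
stable key order, and minimal SAM (POS/FLAG/SEQ are consumed)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import TableError


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_bed(path, intervals: dict[str, tuple[int, int]], chrom: str = "ref") -> None:
    """Write named 0-based half-open intervals as BED4."""
    with open(path, "w") as fh:
        for name, (start, end) in intervals.items():
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TableError(f"{path}:{lineno}: BED needs 4 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TableError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end <= start:
                raise TableError(f"{path}:{lineno}: invalid interval [{start},{end})")
            rows.append((fields[0], start, end, fields[3]))
    return rows


def write_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if required_columns:
        missing = [c for c in required_columns if c not in frame.columns]
        if missing:
            raise TableError(f"{path}: missing required column(s): {missing}")
    return frame


def write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_sam(path, placements, reads: list[tuple[str, str]], reference_name: str,
              reference_length: int) -> None:
    """Minimal SAM for placed reads (FLAG carries strand, CIGAR is full-match)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference_name}\tLN:{reference_length}\n")
        for start, length, strand, read_idx in zip(
            placements.starts, placements.lengths, placements.strands,
            placements.read_indices,
        ):
            name, seq = reads[read_idx] if read_idx < len(reads) else (f"read_{read_idx}", "*")
            flag = 16 if strand else 0
            fh.write(
                f"{name}\t{flag}\t{reference_name}\t{start + 1}\t60\t{length}M\t*\t0\t0\t"
                f"{seq}\t*\n"
            )


def read_sam_placements(path):
    """Parse placements (POS/FLAG/read length) from a SAM file via pysam."""
    import pysam

    from .coverage_cn import PlacementTable

    starts, lengths, strands = [], [], []
    n_unplaced = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unplaced += 1
                continue
            starts.append(rec.reference_start)
            lengths.append(rec.query_length or rec.infer_query_length() or 0)
            strands.append(1 if rec.is_reverse else 0)
    return PlacementTable(
        np.asarray(starts, dtype=int),
        np.asarray(lengths, dtype=int),
        np.asarray(strands, dtype=int),
        n_unplaced,
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
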