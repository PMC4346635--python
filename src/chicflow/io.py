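"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Biopython; BED/bedGraph and pairs-style tables via pandas.  All
interval formats are 0-based half-open, matching the internal convention.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ditags import DITAG_COLUMNS

__all__ = [
    "read_fasta", "write_fasta",
    "read_bed", "read_bedgraph", "write_bed",
    "read_pairs", "write_pairs",
]


def read_fasta(path) -> Dict[str, str]:
    """Multi-record FASTA (wrapped or unwrapped) as chrom -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> List[Tuple[str, int, int]]:
    """BED intervals (first three columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_bedgraph(path) -> Dict[str, List[Tuple[int, int, float]]]:
    """bedGraph as chrom -> [(start, end, score)] (e.g. a mapability track)."""
    out: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split("\t")[:4]
            out.setdefault(c, []).append((int(s), int(e), float(v)))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_pairs(path) -> pd.DataFrame:
    """Pairs-style TSV with the ditag columns (header optional)."""
    with open(path) as fh:
        first = fh.readline()
    has_header = first.strip().startswith("read_id")
    df = pd.read_csv(
        path, sep="\t",
        header=0 if has_header else None,
        names=None if has_header else DITAG_COLUMNS,
    )
    return df[DITAG_COLUMNS]


def write_pairs(ditags: pd.DataFrame, path) -> None:
    ditags[DITAG_COLUMNS].to_csv(path, sep="\t", index=False)
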