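"""Readers and writers for the standard formats used throughout the toolkit.

Conventions
-----------
* Internally every interval is 0-based half-open and stranded.
* GTF on disk is 1-based closed and converted on read/write.
* 5'-end tracks on disk are BED6+2: the two extra columns are the read
  count and the fraction of reads at that base carrying a non-genomic 5' G.
* The 5' end of a minus-strand interval is its 3'-most genomic coordinate;
  "upstream"/"downstream" are always transcript-oriented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr
from pyfaidx import Fasta

__all__ = [
    "Transcript",
    "Gene",
    "Annotation",
    "load_annotation",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_end5_bed",
    "write_end5_bed",
    "read_table",
    "write_table",
    "provenance_block",
    "write_json",
]

END5_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "count", "g_fraction"]


# ---------------------------------------------------------------------------
# Gene/transcript model
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """One annotated transcript: exon chain plus optional CDS span.

    ``exons`` are genomic 0-based half-open intervals sorted by genomic start;
    ``cds`` is the genomic span of the coding region (first to last coding
    base, half-open) or ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcript's 5'-most base."""
        return self.start if self.strand == "+" else self.end - 1

    def exonic_positions(self) -> np.ndarray:
        """Genomic positions of exonic bases in transcript (5'->3') order."""
        pos = np.concatenate([np.arange(a, b) for a, b in self.exons])
        return pos if self.strand == "+" else pos[::-1]

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        seq = "".join(str(genome[self.chrom][a:b]) for a, b in self.exons)
        return seq if self.strand == "+" else _revcomp(seq)

    def cds_offset(self) -> int | None:
        """Transcript-coordinate offset (nt from 5' end) of the CDS start."""
        if self.cds is None:
            return None
        cds_start = self.cds[0] if self.strand == "+" else self.cds[1] - 1
        pos = self.exonic_positions()
        hits = np.nonzero(pos == cds_start)[0]
        return int(hits[0]) if hits.size else None

    def cds_length(self) -> int | None:
        if self.cds is None:
            return None
        pos = self.exonic_positions()
        inside = (pos >= self.cds[0]) & (pos < self.cds[1])
        return int(inside.sum())


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


class Annotation:
    """A set of genes and transcripts with fast per-chromosome lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self.transcripts: dict[str, Transcript] = {
            t.transcript_id: t for g in self.genes.values() for t in g.transcripts
        }
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.gene_id))

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def annotated_tss_positions(self, chrom: str, strand: str) -> np.ndarray:
        """All annotated transcript 5' ends on one chromosome strand."""
        out = [
            t.tss
            for g in self.genes_on(chrom)
            if g.strand == strand
            for t in g.transcripts
        ]
        return np.array(sorted(out), dtype=int)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def load_annotation(path: str | Path) -> Annotation:
    """Read a GTF into the internal 0-based half-open gene model.

    Requires ``gene_id`` on every feature and ``transcript_id`` on
    transcript/exon/CDS features; a violating line is reported by number.
    """
    path = Path(path)
    gr = pr.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else gr
    required = {"Feature", "Chromosome", "Start", "End", "Strand", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GTF {path} lacks required fields: {sorted(missing)}")
    feats = df[df.Feature.isin(["transcript", "exon", "CDS"])]
    if "transcript_id" not in df.columns or feats["transcript_id"].isna().any():
        lineno = _first_bad_line(path)
        raise ValueError(f"GTF {path}: missing transcript_id attribute (line {lineno})")

    transcripts: dict[str, Transcript] = {}
    for tid, sub in df[df.Feature == "exon"].groupby("transcript_id", sort=True):
        row = sub.iloc[0]
        transcripts[tid] = Transcript(
            transcript_id=str(tid),
            gene_id=str(row["gene_id"]),
            chrom=str(row["Chromosome"]),
            strand=str(row["Strand"]),
            exons=list(zip(sub.Start.astype(int), sub.End.astype(int))),
        )
    for tid, sub in df[df.Feature == "CDS"].groupby("transcript_id", sort=True):
        if tid in transcripts:
            transcripts[tid].cds = (int(sub.Start.min()), int(sub.End.max()))

    genes: dict[str, Gene] = {}
    for t in transcripts.values():
        g = genes.get(t.gene_id)
        if g is None:
            genes[t.gene_id] = Gene(t.gene_id, t.chrom, t.strand, t.start, t.end, [t])
        else:
            g.start = min(g.start, t.start)
            g.end = max(g.end, t.end)
            g.transcripts.append(t)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return Annotation(genes.values())


def _first_bad_line(path: Path) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                return i
            feature, attrs = fields[2], fields[8]
            if "gene_id" not in attrs:
                return i
            if feature in ("transcript", "exon", "CDS") and "transcript_id" not in attrs:
                return i
    return 0


def write_gtf(annotation: Annotation, path: str | Path, source: str = "hp5kit") -> None:
    """Write the annotation as 1-based closed GTF (gene/transcript/exon/CDS)."""
    lines = []

    def rec(chrom, feat, start, end, strand, attrs):
        a = " ".join(f'{k} "{v}";' for k, v in attrs)
        lines.append(f"{chrom}\t{source}\t{feat}\t{start + 1}\t{end}\t.\t{strand}\t.\t{a}")

    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        rec(g.chrom, "gene", g.start, g.end, g.strand, [("gene_id", gid)])
        for t in g.transcripts:
            at = [("gene_id", gid), ("transcript_id", t.transcript_id)]
            rec(g.chrom, "transcript", t.start, t.end, g.strand, at)
            for a, b in t.exons:
                rec(g.chrom, "exon", a, b, g.strand, at)
            if t.cds is not None:
                for a, b in t.exons:
                    ca, cb = max(a, t.cds[0]), min(b, t.cds[1])
                    if ca < cb:
                        rec(g.chrom, "CDS", ca, cb, g.strand, at)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into plain uppercase strings (desk-scale genomes)."""
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# ---------------------------------------------------------------------------
# 5'-end tracks (BED6+2) and generic tables
# ---------------------------------------------------------------------------

def write_end5_bed(track: pd.DataFrame, path: str | Path) -> None:
    """Write a per-base 5'-end track (chrom,pos,strand,count,g_fraction)."""
    df = track.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(int),
            "end": df["pos"].astype(int) + 1,
            "name": ".",
            "score": df["count"].astype(int),
            "strand": df["strand"],
            "count": df["count"].astype(int),
            "g_fraction": df["g_fraction"].map(lambda x: f"{x:.6f}"),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_end5_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=END5_COLUMNS)
    return pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["start"].astype(int),
            "strand": df["strand"].astype(str),
            "count": df["count"].astype(int),
            "g_fraction": df["g_fraction"].astype(float),
        }
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def provenance_block(seed: int | None = None, **params) -> dict:
    from hp5kit import __version__

    return {"tool": "hp5kit", "version": __version__, "seed": seed, "parameters": params}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
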