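"""Gene and repeat annotations.

Genes are held as :class:`GeneModel` records with exons ordered 5'→3' on
the gene's own strand; all internal coordinates are 0-based half-open on
the plus strand (GFF3's 1-based closed convention is converted at the
boundary). Multi-transcript genes collapse to their longest transcript,
since every downstream computation is per gene (TSS–TTS).

Repeat annotations are a plain frame (chrom, start, end, te_class);
overlaps between repeat copies are permitted (nested repeats).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd

from .errors import DataError

REPEAT_COLUMNS = ["chrom", "start", "end", "te_class"]


@dataclass
class GeneModel:
    """One protein-coding gene: span, strand, and exon structure.

    ``start``/``end`` bound the gene body (TSS to TTS) in plus-strand
    coordinates; ``tss``/``tts`` are strand-aware anchors (for a minus
    gene the TSS is the right edge, so ``tss > tts``). ``exons`` are
    (start, end) pairs ordered 5'→3' along the gene, i.e. reversed
    plus-strand order for minus genes; exon rank 1 is the 5'-most exon.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise DataError(f"gene {self.gene_id}: end must exceed start")
        plus_sorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(plus_sorted, plus_sorted[1:]):
            if s2 < e1:
                raise DataError(f"gene {self.gene_id}: overlapping exons")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise DataError(f"gene {self.gene_id}: exon outside gene span")
        want = plus_sorted if self.strand == "+" else plus_sorted[::-1]
        if self.exons != want:
            self.exons = want

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def promoter(self, promoter_bp: int = 200) -> tuple[int, int]:
        """Strand-adjusted promoter window upstream of the TSS."""
        if self.strand == "+":
            return (max(0, self.start - promoter_bp), self.start)
        return (self.end, self.end + promoter_bp)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals ordered 5'→3'; rank i lies after exon i."""
        plus = sorted(self.exons)
        out = [(e1, s2) for (_, e1), (s2, _) in zip(plus, plus[1:]) if s2 > e1]
        return out if self.strand == "+" else out[::-1]


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from GFF3 into GeneModel records.

    The longest transcript is kept for multi-transcript genes. An exon
    whose Parent cannot be resolved to a gene is an error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for exon in db.features_of_type("exon"):
        if not list(db.parents(exon)):
            raise DataError(f"exon without resolvable parent: {exon.id}")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if transcripts:
            tx = max(transcripts, key=lambda t: (t.end - t.start, t.id))
            exon_feats = list(db.children(tx, featuretype="exon"))
        else:
            exon_feats = list(db.children(gene, featuretype="exon"))
        exons = sorted((f.start - 1, f.end) for f in exon_feats)
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Write genes as gene/mRNA/exon GFF3 (1-based closed on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            base = f"{g.chrom}\tmethylant\t"
            fh.write(
                f"{base}gene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.e{i};Parent={mrna}\n"
                )


def read_repeats_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a repeat BED (3 or 6 columns; column 4 is the TE class)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "te_class": df[3].astype(str) if df.shape[1] > 3 else "repeat",
        }
    )
    if (out["end"] <= out["start"]).any():
        raise DataError(f"{path}: interval with end <= start")
    return out.sort_values(["chrom", "start", "end"], ignore_index=True)


def write_repeats_bed(repeats: pd.DataFrame, path: str | os.PathLike) -> None:
    df = repeats.sort_values(["chrom", "start", "end"])
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.te_class}\t0\t+\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_bed3(intervals, path: str | os.PathLike, scores=None) -> None:
    """Write (chrom, start, end) triples as BED3 (+score column if given)."""
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(intervals):
            if scores is not None:
                fh.write(f"{chrom}\t{s}\t{e}\t{scores[i]:.6g}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed3(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
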