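"""Readers and writers for the interchange formats used by the pipeline.

FASTA goes through Biopython, GFF3 through gffutils' stream iterator, BED6 and
TSV tables through pandas. All in-memory coordinates are 0-based half-open; GFF3
records are converted to/from 1-based inclusive at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import IOR, Feature, GenomeAnnotation, Operon

log = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    """Write a BED6 table; expects the standard chrom/start/end/name/score/strand."""
    df.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def features_to_bed(contig_id: str, features: list[Feature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": contig_id,
            "start": [f.start for f in features],
            "end": [f.end for f in features],
            "name": [f.feature_id for f in features],
            "score": 0,
            "strand": [f.strand for f in features],
        }
    )


def bed_to_features(df: pd.DataFrame) -> list[Feature]:
    strands = df["strand"] if "strand" in df else ["."] * len(df)
    return [
        Feature(feature_id=str(n), start=int(s), end=int(e), strand=str(st))
        for n, s, e, st in zip(df["name"], df["start"], df["end"], strands)
    ]


def write_annotation_gff3(path: str | Path, annotation: GenomeAnnotation) -> None:
    """Emit ORFs (gene), operons (operon) and sRNA tracks (ncRNA) as GFF3."""
    lines = ["##gff-version 3"]
    lines.append(f"##sequence-region {annotation.contig_id} 1 {annotation.contig_length}")

    def row(ftype: str, start: int, end: int, strand: str, attrs: str) -> str:
        return "\t".join(
            [
                annotation.contig_id,
                "srnome",
                ftype,
                str(start + 1),
                str(end),
                ".",
                strand,
                ".",
                attrs,
            ]
        )

    for f in annotation.orfs:
        lines.append(row("gene", f.start, f.end, f.strand, f"ID={f.feature_id}"))
    for op in annotation.operons:
        members = ",".join(op.member_orf_ids)
        lines.append(
            row("operon", op.start, op.end, op.strand, f"ID={op.operon_id};members={members}")
        )
    for f in annotation.known_srnas:
        lines.append(
            row("ncRNA", f.start, f.end, f.strand, f"ID={f.feature_id};class=known_srna")
        )
    for f in annotation.predicted_srnas:
        lines.append(
            row("ncRNA", f.start, f.end, f.strand, f"ID={f.feature_id};class=predicted_srna")
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_gff3(
    path: str | Path, contig_length: int, sequence: str | None = None
) -> GenomeAnnotation:
    """Rebuild a :class:`GenomeAnnotation` from the GFF3 written by this package."""
    orfs: list[Feature] = []
    operons: list[Operon] = []
    known: list[Feature] = []
    predicted: list[Feature] = []
    contig_id = None
    for rec in gffutils.iterators.DataIterator(str(path)):
        contig_id = rec.seqid
        start, end = rec.start - 1, rec.end  # to 0-based half-open
        fid = rec.attributes["ID"][0]
        if rec.featuretype == "gene":
            orfs.append(Feature(fid, start, end, rec.strand))
        elif rec.featuretype == "operon":
            members = tuple(rec.attributes["members"])  # gffutils splits on ","
            operons.append(Operon(fid, members, start, end, rec.strand))
        elif rec.featuretype == "ncRNA":
            klass = rec.attributes.get("class", ["known_srna"])[0]
            target = known if klass == "known_srna" else predicted
            target.append(Feature(fid, start, end, rec.strand))
        else:
            log.warning("ignoring GFF3 feature type %s", rec.featuretype)
    if contig_id is None:
        raise ValueError(f"no features found in {path}")
    ann = GenomeAnnotation(
        contig_id=contig_id,
        contig_length=contig_length,
        sequence=sequence,
        orfs=orfs,
        operons=operons,
        known_srnas=known,
        predicted_srnas=predicted,
    )
    ann.validate()
    return ann


def write_ior_table(path: str | Path, iors: list[IOR]) -> None:
    pd.DataFrame(
        {
            "ior_id": [r.ior_id for r in iors],
            "start": [r.start for r in iors],
            "end": [r.end for r in iors],
            "left_neighbor": [r.left_neighbor or "" for r in iors],
            "right_neighbor": [r.right_neighbor or "" for r in iors],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ior_table(path: str | Path) -> list[IOR]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        IOR(
            ior_id=r.ior_id,
            start=int(r.start),
            end=int(r.end),
            left_neighbor=r.left_neighbor or None,
            right_neighbor=r.right_neighbor or None,
        )
        for r in df.itertuples()
    ]
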