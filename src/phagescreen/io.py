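"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Bio.SeqIO (wrapped at 60 columns). The GFF3 subset used
here (9 tab-separated columns, 1-based inclusive coordinates, strand in
column 7, ``ID=`` and ``product=`` attributes) is parsed strictly with
line-numbered errors so malformed annotations fail loudly. TSV goes through
pandas; JSON through the standard library with sorted keys so output bytes
are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneFeature, GenomeRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered {header: sequence} mapping (full header line)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        out[header] = str(rec.seq)
    return out


def write_fasta(records: dict[str, str], path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=header.split()[0] if header else "",
                  description=header[len(header.split()[0]):].strip() if header else "")
        for header, seq in records.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


class GFF3ParseError(ValueError):
    pass


def write_gff3(genomes: list[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            fh.write(f"##sequence-region {g.id} 1 {len(g.sequence)}\n")
            for feat in g.genes:
                attrs = f"ID={g.id}|{feat.gene_index};product={feat.product}"
                fh.write(
                    "\t".join(
                        [
                            g.id,
                            "phagescreen",
                            "CDS",
                            str(feat.start),
                            str(feat.end),
                            ".",
                            feat.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gff3(path) -> dict[str, list[GeneFeature]]:
    """Features grouped by replicon id, in file order.

    Raises :class:`GFF3ParseError` naming the offending line on malformed
    records (wrong column count, start > end, bad strand).
    """
    features: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, _type, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GFF3ParseError(f"{path}: line {lineno}: invalid interval {start}..{end}")
            if strand not in ("+", "-"):
                raise GFF3ParseError(f"{path}: line {lineno}: invalid strand {strand!r}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            product = attr_map.get("product", "")
            feat_id = attr_map.get("ID", "")
            try:
                gene_index = int(feat_id.rsplit("|", 1)[1]) if "|" in feat_id else len(
                    features.get(seqid, [])
                )
            except ValueError:
                gene_index = len(features.get(seqid, []))
            features.setdefault(seqid, []).append(
                GeneFeature(gene_index=gene_index, start=start, end=end, strand=strand, product=product)
            )
    return features


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
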