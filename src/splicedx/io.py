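"""Readers for transcript models and variant tables.

Transcripts come from GTF/GFF3 (exon + CDS features, via gffutils) or a
plain exon table TSV; variants from a TSV (variant_id, transcript_id,
hgvs_c) or a VCF whose INFO field carries the transcript and HGVS c.
description (keys ``TRANSCRIPT`` and ``HGVSC``).
"""

from __future__ import annotations

import pandas as pd

from .transcript_model import CVariant, TranscriptModel, parse_hgvs_c


def read_transcripts_tsv(path) -> dict[str, TranscriptModel]:
    """Exon-table TSV with header: transcript_id, exon_start, exon_end, strand.

    Optional columns: gene_id, chrom, cds_start_c (constant per transcript).
    Exons may appear in any order; they are sorted into transcript
    orientation by strand.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "exon_start", "exon_end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript TSV missing columns: {sorted(missing)}")
    out: dict[str, TranscriptModel] = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        strands = set(grp["strand"])
        if len(strands) != 1:
            raise ValueError(f"{tid}: inconsistent strand values {sorted(strands)}")
        strand = strands.pop()
        exons = sorted(
            ((int(a), int(b)) for a, b in zip(grp["exon_start"], grp["exon_end"])),
            key=lambda e: e[0],
            reverse=(strand == "-"),
        )
        out[str(tid)] = TranscriptModel(
            transcript_id=str(tid),
            gene_id=str(grp["gene_id"].iloc[0]) if "gene_id" in grp else str(tid),
            strand=strand,
            exons=tuple(exons),
            cds_start_c=int(grp["cds_start_c"].iloc[0]) if "cds_start_c" in grp else 1,
            chrom=str(grp["chrom"].iloc[0]) if "chrom" in grp else "chr1",
        )
    return out


def write_transcripts_tsv(transcripts: dict[str, TranscriptModel], path) -> None:
    rows = []
    for tm in transcripts.values():
        for lo, hi in tm.exons:
            rows.append(
                {
                    "transcript_id": tm.transcript_id,
                    "gene_id": tm.gene_id,
                    "chrom": tm.chrom,
                    "exon_start": lo,
                    "exon_end": hi,
                    "strand": tm.strand,
                    "cds_start_c": tm.cds_start_c,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcripts_gtf(path) -> dict[str, TranscriptModel]:
    """Build transcript models from GTF/GFF3 exon and CDS features."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    out: dict[str, TranscriptModel] = {}
    by_tid: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent") or []
        for tid in tids:
            rec = by_tid.setdefault(
                tid, {"exons": [], "cds": [], "strand": feat.strand, "chrom": feat.seqid,
                      "gene": (feat.attributes.get("gene_id") or [tid])[0]}
            )
            target = rec["exons"] if feat.featuretype == "exon" else rec["cds"]
            target.append((feat.start, feat.end))
    for tid, rec in by_tid.items():
        strand = rec["strand"]
        exons = sorted(rec["exons"], key=lambda e: e[0], reverse=(strand == "-"))
        tm = TranscriptModel(
            transcript_id=tid, gene_id=rec["gene"], strand=strand,
            exons=tuple(exons), cds_start_c=1, chrom=rec["chrom"],
        )
        if rec["cds"]:
            cds_first_g = (
                min(lo for lo, _ in rec["cds"]) if strand == "+" else max(hi for _, hi in rec["cds"])
            )
            t = tm.genomic_to_tx(cds_first_g)
            if t is None:
                raise ValueError(f"{tid}: CDS start {cds_first_g} is not exonic")
            tm = TranscriptModel(
                transcript_id=tid, gene_id=rec["gene"], strand=strand,
                exons=tuple(exons), cds_start_c=t, chrom=rec["chrom"],
            )
        out[tid] = tm
    return out


def read_variants_tsv(path) -> pd.DataFrame:
    """Variant table: variant_id, transcript_id, hgvs_c (extra columns kept)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "transcript_id", "hgvs_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    return df


def read_variants_vcf(path, transcript_key: str = "TRANSCRIPT", hgvs_key: str = "HGVSC") -> pd.DataFrame:
    """Variants from a VCF; transcript and HGVS c. read from INFO."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            if transcript_key not in info or hgvs_key not in info:
                raise ValueError(
                    f"VCF record {rec.chrom}:{rec.pos} lacks INFO/{transcript_key} or INFO/{hgvs_key}"
                )
            tid = info[transcript_key]
            hgvs = info[hgvs_key]
            tid = tid[0] if isinstance(tid, tuple) else tid
            hgvs = hgvs[0] if isinstance(hgvs, tuple) else hgvs
            rows.append(
                {
                    "variant_id": rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{rec.alts[0]}",
                    "transcript_id": tid,
                    "hgvs_c": hgvs,
                }
            )
    return pd.DataFrame(rows)


def parse_variant_table(df: pd.DataFrame) -> dict[str, CVariant]:
    """variant_id -> parsed CVariant for a variant table."""
    return {row["variant_id"]: parse_hgvs_c(row["hgvs_c"]) for _, row in df.iterrows()}
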