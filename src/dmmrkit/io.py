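"""Readers and writers for the pipeline's file formats.

Coordinate conventions: BED is 0-based half-open; MAF-like tables and VCF are
1-based.  All bespoke tables are plain TSV with documented headers, so every
writer round-trips losslessly through its reader.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyfaidx
import pysam

from .msi import HISTOGRAM_COLUMNS, MicrosatelliteLocus
from .variants import MAF_COLUMNS

__all__ = [
    "read_fasta", "write_fasta",
    "read_bed", "write_bed",
    "read_histograms", "write_histograms",
    "read_maf", "write_maf",
    "read_vcf_minimal", "write_vcf_minimal",
    "read_tsv_matrix", "write_tsv_matrix",
    "validate_against_reference",
]


# -- FASTA ------------------------------------------------------------------

def write_fasta(reference: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> pyfaidx.Fasta:
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


# -- BED (loci) -------------------------------------------------------------

def write_bed(loci: list[MicrosatelliteLocus], path) -> None:
    """Six-column BED: chrom, start, end, locus_id, repeat_unit, ref repeats."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}"
                f"\t{locus.repeat_unit}\t{locus.reference_repeat_count}\n"
            )


def read_bed(path) -> list[MicrosatelliteLocus]:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >=4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            loci.append(MicrosatelliteLocus(
                locus_id=parts[3], chrom=parts[0], start=start, end=end,
                repeat_unit=parts[4] if len(parts) > 4 else "A",
                reference_repeat_count=int(parts[5]) if len(parts) > 5 else end - start,
            ))
    return loci


# -- histogram TSV ----------------------------------------------------------

def write_histograms(hist: pd.DataFrame, path) -> None:
    hist[HISTOGRAM_COLUMNS].to_csv(path, sep="\t", index=False)


def read_histograms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"sample_id": str, "locus_id": str,
                            "repeat_length": int, "read_count": int})
    missing = set(HISTOGRAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing histogram columns {sorted(missing)}")
    return df[HISTOGRAM_COLUMNS]


# -- MAF-like TSV -----------------------------------------------------------

def write_maf(records: pd.DataFrame, path) -> None:
    records[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing MAF columns {sorted(missing)}")
    df = df[MAF_COLUMNS].copy()
    for col in ("multiallelic", "poorly_sequenced_site"):
        df[col] = df[col].astype(bool)
    df["gene"] = df["gene"].fillna("").astype(str)
    return df


# -- minimal VCF ------------------------------------------------------------

_VCF_INFO = [
    ("SID", "String", "Sample identifier"),
    ("VT", "String", "Variant type (SNV or indel)"),
    ("DP", "Integer", "Coverage depth"),
    ("ALTR", "Integer", "Alternate-allele read count"),
    ("MQ", "Float", "Mapping quality"),
    ("HS", "Float", "Haplotype score"),
    ("CAF", "Float", "Cohort allele frequency"),
    ("DBH", "Integer", "Population databases containing the variant"),
    ("COSM", "Integer", "COSMIC somatic occurrence count"),
    ("GENE", "String", "Gene symbol"),
    ("MA", "Flag", "Multiallelic call"),
    ("PSS", "Flag", "Known poorly sequenced site"),
]


def write_vcf_minimal(records: pd.DataFrame, path, contigs: dict[str, int] | None = None) -> None:
    """One VCF record per table row with all filter annotations in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for key, typ, desc in _VCF_INFO:
            number = "0" if typ == "Flag" else "1"
            fh.write(f'##INFO=<ID={key},Number={number},Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in records.itertuples(index=False):
            info = [
                f"SID={row.sample_id}", f"VT={row.variant_type}",
                f"DP={int(row.depth)}", f"ALTR={int(row.alt_reads)}",
                f"MQ={row.mapq:g}", f"HS={row.haplotype_score:g}",
                f"CAF={row.cohort_af:g}", f"DBH={int(row.db_hits)}",
                f"COSM={int(row.cosmic_count)}",
            ]
            if row.gene:
                info.append(f"GENE={row.gene}")
            if row.multiallelic:
                info.append("MA")
            if row.poorly_sequenced_site:
                info.append("PSS")
            fh.write(f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t{';'.join(info)}\n")


def read_vcf_minimal(path) -> pd.DataFrame:
    """Read a minimal VCF (as written by :func:`write_vcf_minimal`) into the
    MAF-like table schema."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            rows.append({
                "sample_id": info.get("SID"),
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "",
                "variant_type": info.get("VT", "SNV"),
                "depth": info.get("DP"),
                "alt_reads": info.get("ALTR"),
                "mapq": info.get("MQ"),
                "haplotype_score": info.get("HS"),
                "cohort_af": info.get("CAF"),
                "db_hits": info.get("DBH"),
                "cosmic_count": info.get("COSM"),
                "multiallelic": bool(info.get("MA", False)),
                "poorly_sequenced_site": bool(info.get("PSS", False)),
                "gene": info.get("GENE", "") or "",
            })
    return pd.DataFrame(rows, columns=MAF_COLUMNS)


# -- matrices and generic tables -------------------------------------------

def write_tsv_matrix(matrix: pd.DataFrame, path, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def validate_against_reference(records: pd.DataFrame, reference) -> None:
    """Check every record's REF base against the FASTA; raise on mismatch."""
    for row in records.itertuples(index=False):
        seq = reference[row.chrom][int(row.pos) - 1:int(row.pos) - 1 + len(str(row.ref))]
        if not isinstance(seq, str):
            seq = str(seq)
        if seq.upper() != str(row.ref).upper():
            raise ValueError(
                f"REF mismatch at {row.chrom}:{row.pos}: table {row.ref}, FASTA {seq}"
            )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
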