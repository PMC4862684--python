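"""File-format plumbing: VCF (via pysam), FASTA, and the package's TSV/BED dialects.

Coordinate conventions, applied consistently everywhere:

* VCF and genotype tables are 1-based (``pos``).
* Segment tables and BED files are 0-based half-open (``start``, ``end``);
  the segment TSV header documents this.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

from .catalog import MutationCatalog

log = logging.getLogger(__name__)

GENOTYPE_COLUMNS = ["probe_id", "chrom", "pos", "allele_a", "allele_b", "genotype", "gencall"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "copy_number"]


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_fasta_seq(path: str | Path, name: str | None = None) -> str:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    key = name if name is not None else list(fa.keys())[0]
    return str(fa[key][:]).upper()


# ---------------------------------------------------------------- VCF

def _vcf_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("AF", number="A", type="Float", description="Somatic allele fraction")
    header.info.add("PROCESS", number=1, type="String",
                    description="Generating process label for simulated records")
    return header


def write_vcf(catalog: MutationCatalog, path: str | Path, contigs: dict[str, int]) -> None:
    """Write a sites-only VCF v4.2 (uncompressed text, 1-based positions)."""
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        df = catalog.df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        for row in df.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            if pd.notna(row.af):
                rec.info["AF"] = float(row.af)
            if isinstance(row.process, str):
                rec.info["PROCESS"] = row.process
            out.write(rec)


def read_vcf(path: str | Path, sample: str | None = None, af_field: str = "AF") -> MutationCatalog:
    """Read a VCF into a catalog, splitting multi-allelic records.

    ``af_field`` names the allele-fraction field; it is looked up in INFO
    first and then in the first sample's FORMAT fields.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        name = sample or Path(path).stem
        has_af = af_field in vcf.header.info
        has_fmt_af = af_field in vcf.header.formats
        has_process = "PROCESS" in vcf.header.info
        for rec in vcf:
            alts = rec.alts or ()
            af = rec.info.get(af_field) if has_af else None
            if af is None and has_fmt_af and rec.samples:
                af = rec.samples[0].get(af_field)
            afs = af if isinstance(af, tuple) else (af,) * max(len(alts), 1)
            for i, alt in enumerate(alts):
                a = afs[i] if i < len(afs) else None
                records.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "af": float(a) if a is not None else float("nan"),
                        "kind": "snv" if len(rec.ref) == 1 and len(alt) == 1 else "indel",
                        "process": rec.info.get("PROCESS") if has_process else None,
                    }
                )
    return MutationCatalog.from_records(name, records)


# ---------------------------------------------------------------- genotype TSV

def write_genotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df[GENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "genotype": str})
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype table {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------- segment TSV

def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# segment coordinates are 0-based half-open [start, end)\n")
        df[SEGMENT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED4 file (0-based half-open) into chrom/start/end/name."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: BED end < start")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)
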