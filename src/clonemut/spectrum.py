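"""Trinucleotide-context mutation spectra.

Converts mutation catalogs into the standard 96-channel matrix — six
pyrimidine-reference substitution classes x 16 flanking-base contexts,
channel-major order C>A, C>G, C>T, T>A, T>C, T>G with contexts lexicographic
— plus the 48-channel cytosine-only view (3 C classes x 16 contexts) used
for cytosine-focused displays. Counts are raw observed counts; no
genome-composition normalization is applied.
"""

from __future__ import annotations

import logging


import pandas as pd

from .catalog import MutationCatalog
from .seqtools import BASES, CLASSES, COMPLEMENT, revcomp

log = logging.getLogger(__name__)

#: all 96 channel labels, e.g. "A[C>A]A", class-major, context lexicographic
CHANNELS_96 = [
    f"{l}[{cls}]{r}" for cls in CLASSES for l in BASES for r in BASES
]
#: cytosine-only 48-channel view (C>A, C>G, C>T)
CHANNELS_48 = [ch for ch in CHANNELS_96 if "[C" in ch]

CYTOSINE_CLASSES = ["C>A", "C>G", "C>T"]


class EdgeContextError(ValueError):
    """Mutation at a contig edge: no full trinucleotide context."""


class DataIntegrityError(ValueError):
    """Catalog ref allele disagrees with the reference sequence."""


def _ref_base(reference, chrom: str, pos0: int) -> str:
    if isinstance(reference, str):
        return reference[pos0]
    return str(reference[chrom][pos0]).upper()


def _contig_len(reference, chrom: str) -> int:
    if isinstance(reference, str):
        return len(reference)
    return len(reference[chrom])


def normalize_to_pyrimidine(record, reference) -> tuple[str, str]:
    """Strand-collapse one SNV record to (class, context).

    ``record`` needs chrom/pos/ref/alt attributes (1-based pos);
    ``reference`` is either a plain sequence string (single contig) or a
    pyfaidx.Fasta. A purine reference base reverse-complements ref, alt and
    the flanking trinucleotide, so G-to-A inside 5'-CGA becomes C-to-T in
    context TCG.
    """
    chrom, pos, ref, alt = record.chrom, int(record.pos), record.ref.upper(), record.alt.upper()
    pos0 = pos - 1
    if pos0 < 1 or pos0 >= _contig_len(reference, chrom) - 1:
        raise EdgeContextError(f"{chrom}:{pos} has no full trinucleotide context")
    tri = "".join(_ref_base(reference, chrom, p) for p in (pos0 - 1, pos0, pos0 + 1))
    if tri[1] != ref:
        raise DataIntegrityError(
            f"{chrom}:{pos} ref allele {ref!r} does not match reference base {tri[1]!r}")
    if ref in "AG":
        ref, alt, tri = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(tri)
    return f"{ref}>{alt}", tri


def build_spectrum(catalogs: list[MutationCatalog], reference) -> pd.DataFrame:
    """96-channel x samples count matrix from SNV catalogs.

    Contig-edge SNVs are skipped with a logged count; per-sample channel
    sums therefore equal the number of context-resolvable SNVs. A ref-base
    mismatch raises :class:`DataIntegrityError` naming the record.
    """
    mat = pd.DataFrame(0, index=CHANNELS_96, columns=[c.sample for c in catalogs], dtype=int)
    for cat in catalogs:
        skipped = 0
        for row in cat.snvs.itertuples(index=False):
            try:
                cls, tri = normalize_to_pyrimidine(row, reference)
            except EdgeContextError:
                skipped += 1
                continue
            mat.loc[f"{tri[0]}[{cls}]{tri[2]}", cat.sample] += 1
        if skipped:
            log.info("build_spectrum: %s: skipped %d contig-edge records", cat.sample, skipped)
    return mat


def cytosine_view(spectrum96: pd.DataFrame) -> pd.DataFrame:
    """48-channel cytosine-only view: row selection, no recounting."""
    return spectrum96.loc[CHANNELS_48]


def class_proportions(catalog: MutationCatalog, reference,
                      cytosine_only: bool = False) -> pd.Series:
    """Fraction of SNVs in each strand-collapsed class (sums to 1)."""
    if len(catalog.snvs) == 0:
        raise ValueError(f"catalog {catalog.sample!r} has no SNVs")
    counts = dict.fromkeys(CLASSES, 0)
    for row in catalog.snvs.itertuples(index=False):
        try:
            cls, _ = normalize_to_pyrimidine(row, reference)
        except EdgeContextError:
            continue
        counts[cls] += 1
    s = pd.Series(counts, dtype=float)
    if cytosine_only:
        s = s[CYTOSINE_CLASSES]
    total = s.sum()
    if total == 0:
        raise ValueError("no context-resolvable SNVs in the requested classes")
    return s / total


def flag_tc_context(record, reference) -> bool:
    """True iff the pyrimidine-normalized 5' neighbor of a cytosine mutation is T."""
    cls, tri = normalize_to_pyrimidine(record, reference)
    if not cls.startswith("C"):
        raise ValueError(f"flag_tc_context applies to cytosine-class mutations, got {cls}")
    return tri[0] == "T"


def spectrum_class_totals(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Collapse a channel x sample matrix to class x sample totals."""
    cls = [ch.split("[")[1].split("]")[0] for ch in spectrum.index]
    return spectrum.groupby(cls).sum()


def context_counts(spectrum: pd.DataFrame, cls: str) -> pd.DataFrame:
    """16-context x sample counts for one substitution class."""
    rows = [ch for ch in spectrum.index if f"[{cls}]" in ch]
    out = spectrum.loc[rows].copy()
    out.index = [ch[0] + cls[0] + ch[-1] for ch in rows]
    return out


def write_spectrum(spectrum: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# channels: pyrimidine-reference class-major "
                 "(C>A,C>G,C>T,T>A,T>C,T>G) x lexicographic flanking context\n")
        spectrum.to_csv(fh, sep="\t", index_label="channel")


def read_spectrum(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="channel")
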