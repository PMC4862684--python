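"""Sequence utilities: strand collapsing and trinucleotide-context scans.

All mutation reporting in this package uses the pyrimidine-strand
convention: a substitution whose reference base is a purine is
reverse-complemented (ref, alt and flanking context) so that opposite-strand
events collapse into six classes with a C or T reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: six strand-collapsed substitution classes, conventional order
CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: the 16 cytosine-centered trinucleotide contexts, lexicographic
CYTOSINE_CONTEXTS = [l + "C" + r for l in BASES for r in BASES]

_CODE = {b: i for i, b in enumerate(BASES)}
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G on codes


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to int8 codes 0..3 (other symbols -> -1)."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pyrimidine_sites(seq: str, base: str) -> np.ndarray:
    """0-based positions whose pyrimidine-normalized reference base is `base`.

    ``base="C"`` returns positions holding C or G; ``base="T"`` positions
    holding T or A. Contig-edge positions (no flanking base) are excluded
    so every returned site has a full trinucleotide context.
    """
    codes = encode(seq)
    if base == "C":
        mask = (codes == _CODE["C"]) | (codes == _CODE["G"])
    elif base == "T":
        mask = (codes == _CODE["T"]) | (codes == _CODE["A"])
    else:
        raise ValueError(f"base must be the pyrimidine C or T, got {base!r}")
    mask[0] = mask[-1] = False
    return np.flatnonzero(mask)


def cytosine_context_codes(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Pyrimidine-normalized context codes for every internal C/G site.

    Returns ``(positions, context_codes)`` where ``context_codes`` indexes
    :data:`CYTOSINE_CONTEXTS` (5' neighbor * 4 + 3' neighbor after
    normalizing G sites to the opposite strand).
    """
    codes = encode(seq)
    pos = pyrimidine_sites(seq, "C")
    left = codes[pos - 1]
    right = codes[pos + 1]
    is_g = codes[pos] == _CODE["G"]
    # opposite strand: 5' neighbor = complement of the 3' base and vice versa
    norm_left = np.where(is_g, _COMP_CODE[right], left)
    norm_right = np.where(is_g, _COMP_CODE[left], right)
    return pos, (norm_left * 4 + norm_right).astype(np.int16)


def genomic_context_counts(seq: str) -> pd.Series:
    """Counts of genomic cytosine sites per NCN context (both strands)."""
    _, ctx = cytosine_context_codes(seq)
    counts = np.bincount(ctx, minlength=16)
    return pd.Series(counts, index=CYTOSINE_CONTEXTS, name="sites")


def expand_iupac_motif(motif: str) -> list[str]:
    """Expand a cytosine-centered motif with IUPAC flanks (e.g. TCW, NCG)."""
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
        "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    motif = motif.upper()
    if len(motif) != 3 or motif[1] != "C":
        raise ValueError(f"motif must be a cytosine-centered NCN triplet, got {motif!r}")
    return [l + "C" + r for l in iupac[motif[0]] for r in iupac[motif[2]]]
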