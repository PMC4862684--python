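"""Core in-memory containers shared by every pipeline stage.

The universal currency between stages is the :class:`MutationCatalog`: a
per-clone table of somatic SNV/indel records (chromosome, 1-based position,
ref, alt, allele fraction) carried as a pandas DataFrame, optionally labeled
by the process that generated each record when the catalog comes from the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical column order of a catalog DataFrame
CATALOG_COLUMNS = ["chrom", "pos", "ref", "alt", "af", "kind", "process"]


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=int),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "af": pd.Series(dtype=float),
            "kind": pd.Series(dtype=str),
            "process": pd.Series(dtype=object),
        }
    )


@dataclass
class MutationCatalog:
    """Somatic mutation records for one clone.

    Parameters
    ----------
    sample:
        Clone / sample identifier.
    df:
        DataFrame with columns ``chrom, pos, ref, alt, af, kind, process``.
        ``pos`` is 1-based (VCF convention); ``kind`` is ``"snv"`` or
        ``"indel"``; ``process`` is the generating-process label for
        simulated records (``"a3b"`` / ``"background"``) and ``None`` for
        real data.
    """

    sample: str
    df: pd.DataFrame = field(default_factory=_empty_frame)

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.df.columns]
        for c in missing:
            self.df[c] = float("nan") if c == "af" else None
        if "kind" in missing:
            self.df["kind"] = [
                "snv" if len(r) == 1 and len(a) == 1 else "indel"
                for r, a in zip(self.df["ref"], self.df["alt"])
            ]
        self.df = self.df[CATALOG_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snvs(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "snv"]

    @property
    def indels(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "indel"]

    def subset(self, mask) -> "MutationCatalog":
        return MutationCatalog(self.sample, self.df[mask].reset_index(drop=True))

    @classmethod
    def from_records(cls, sample: str, records: list[dict]) -> "MutationCatalog":
        if not records:
            return cls(sample)
        return cls(sample, pd.DataFrame.from_records(records))

    def concat(self, other: "MutationCatalog") -> "MutationCatalog":
        df = pd.concat([self.df, other.df], ignore_index=True)
        df = df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        return MutationCatalog(self.sample, df.reset_index(drop=True))
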