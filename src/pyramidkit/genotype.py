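"""Bin-marker genotype matrices for biparental RIL populations.

A recombinant inbred line (RIL) genome is represented as a mosaic of
parental blocks over a bin map: each *bin* is a genomic interval within
which every line carries a single parental origin.  Codes are ``F`` for
the female parent, ``M`` for the male parent and ``NA`` for
recombination-breakpoint or missing regions.  Coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, LocusError

CODES = ("F", "M", "NA")
PARENTS = ("F", "M")


@dataclass(frozen=True)
class Bin:
    """One bin of the genetic map: a 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"bin {self.key}: start > end")
        if self.start < 1:
            raise FormatError(f"bin {self.key}: coordinates are 1-based")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end

    @classmethod
    def from_key(cls, key: str) -> "Bin":
        try:
            chrom, span = key.rsplit(":", 1)
            start, end = span.split("-", 1)
            return cls(chrom, int(start), int(end))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"malformed bin coordinate {key!r}") from exc


@dataclass(frozen=True)
class GeneLocus:
    """A candidate gene region, optionally with a focal QTN position.

    ``qtn_pos`` may fall outside [start, end] for regulatory variants
    near the gene; such loci are flagged rather than rejected.
    """

    gene: str
    chrom: str
    start: int
    end: int
    qtn_pos: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"locus {self.gene}: start > end")

    @property
    def qtn_is_regulatory(self) -> bool:
        """True when the QTN lies outside the gene body."""
        return self.qtn_pos is not None and not (self.start <= self.qtn_pos <= self.end)

    def qtn_locus(self) -> "GeneLocus":
        """The QTN as a 1-bp locus (for point genotyping)."""
        if self.qtn_pos is None:
            raise LocusError(f"locus {self.gene} has no QTN position")
        return GeneLocus(self.gene, self.chrom, self.qtn_pos, self.qtn_pos)


@dataclass
class BinGenotypeMatrix:
    """Per-line, per-bin parental-origin codes.

    ``codes`` is a string DataFrame (lines x bins) over {F, M, NA}; its
    columns are the ``chrom:start-end`` keys of ``bins`` in map order.
    """

    bins: list[Bin]
    codes: pd.DataFrame
    _bin_index: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        keys = [b.key for b in self.bins]
        if list(self.codes.columns) != keys:
            raise FormatError("codes columns do not match bin keys")
        bad = ~self.codes.isin(CODES)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"unknown genotype code {self.codes.iat[r, c]!r} at line "
                f"{self.codes.index[r]!r}, bin {keys[c]!r}"
            )
        self._bin_index = {}
        for i, b in enumerate(self.bins):
            self._bin_index.setdefault(b.chrom, []).append(i)
        for chrom, idx in self._bin_index.items():
            prev: Bin | None = None
            for i in idx:
                b = self.bins[i]
                if prev is not None and b.start <= prev.end:
                    raise FormatError(
                        f"bins {prev.key} and {b.key} overlap or are unsorted"
                    )
                prev = b

    @property
    def lines(self) -> list[str]:
        return list(self.codes.index)

    @property
    def n_lines(self) -> int:
        return len(self.codes.index)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bin_index)

    def bins_overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        return [
            i
            for i in self._bin_index.get(chrom, [])
            if self.bins[i].overlaps(chrom, start, end)
        ]


def write_bin_matrix(matrix: BinGenotypeMatrix, path, header_comment: str | None = None) -> None:
    """Write a bin matrix as TSV: ``line_id`` then one column per bin."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = matrix.codes.copy()
        out.insert(0, "line_id", out.index)
        out.to_csv(fh, sep="\t", index=False)


def read_bin_matrix(path) -> BinGenotypeMatrix:
    """Read a bin-matrix TSV, validating codes and bin coordinates."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)  # 'NA' is a genotype code, not NaN
    if df.columns[0] != "line_id":
        raise FormatError(f"{path}: first column must be 'line_id'")
    df = df.set_index("line_id")
    bins = [Bin.from_key(k) for k in df.columns]
    for row, col in zip(*np.where(~df.isin(CODES))):
        raise FormatError(
            f"{path}: unknown code {df.iat[row, col]!r} at line "
            f"{df.index[row]!r}, bin {df.columns[col]!r}"
        )
    return BinGenotypeMatrix(bins=bins, codes=df)


def read_loci(path) -> list[GeneLocus]:
    """Read a gene-locus TSV (gene, chrom, start, end[, qtn_pos]); 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    loci = []
    for _, row in df.iterrows():
        qtn = None
        if "qtn_pos" in df.columns and pd.notna(row["qtn_pos"]):
            qtn = int(row["qtn_pos"])
        loci.append(
            GeneLocus(str(row["gene"]), str(row["chrom"]), int(row["start"]), int(row["end"]), qtn)
        )
    return loci


def write_loci(loci: Iterable[GeneLocus], path, header_comment: str | None = None) -> None:
    rows = [
        {"gene": l.gene, "chrom": l.chrom, "start": l.start, "end": l.end,
         "qtn_pos": l.qtn_pos if l.qtn_pos is not None else ""}
        for l in loci
    ]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def genotype_at_locus(matrix: BinGenotypeMatrix, locus: GeneLocus) -> pd.Series:
    """Resolve each line's parental origin over a gene region.

    A line is ``F`` (resp. ``M``) iff *every* bin overlapping the locus
    carries that code; any disagreement between overlapping bins, or any
    overlapping ``NA`` bin, yields ``NA`` — recombinant regions are
    treated conservatively as unknown.
    """
    if locus.chrom not in matrix._bin_index:
        raise LocusError(f"chromosome {locus.chrom!r} absent from bin matrix")
    idx = matrix.bins_overlapping(locus.chrom, locus.start, locus.end)
    if not idx:
        raise LocusError(
            f"locus {locus.gene} ({locus.chrom}:{locus.start}-{locus.end}) "
            f"overlaps no bin on {locus.chrom}"
        )
    sub = matrix.codes.iloc[:, idx]
    arr = sub.to_numpy()
    all_f = (arr == "F").all(axis=1)
    all_m = (arr == "M").all(axis=1)
    out = np.where(all_f, "F", np.where(all_m, "M", "NA"))
    return pd.Series(out, index=matrix.codes.index, name=locus.gene)


def genotype_table(matrix: BinGenotypeMatrix, loci: Iterable[GeneLocus]) -> pd.DataFrame:
    """Lines x genes table of resolved parental origins."""
    return pd.DataFrame({l.gene: genotype_at_locus(matrix, l) for l in loci})


def consanguinity_rate(matrix: BinGenotypeMatrix, parent: str) -> pd.Series:
    """Length-weighted fraction of each line's genome from one parent.

    rate = sum(bp of bins coded ``parent``) / sum(bp of non-NA bins);
    NA bins are excluded from numerator and denominator.  Lines with no
    non-NA bin are undefined and reported as NaN.
    """
    if parent not in PARENTS:
        raise FormatError(f"parent must be one of {PARENTS}, got {parent!r}")
    lengths = np.array([b.length for b in matrix.bins], dtype=float)
    arr = matrix.codes.to_numpy()
    num = ((arr == parent) * lengths).sum(axis=1)
    den = ((arr != "NA") * lengths).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(den > 0, num / den, np.nan)
    return pd.Series(rate, index=matrix.codes.index, name=f"consanguinity_{parent}")
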