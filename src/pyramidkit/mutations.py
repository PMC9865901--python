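"""Protein-change notation parsing and PROVEAN deleteriousness calls.

Parses the compact single-letter protein-change grammar used for
parental coding differences (``D74E`` missense, ``L3fs`` frameshift,
``E346del`` / ``T131_P138del`` in-frame deletions, ``T201dup`` /
``H65_H66dup`` in-frame duplications, ``A124_V125insAAAAAV`` in-frame
insertions, ``A12_G14delinsW`` deletion-insertions) and applies the
PROVEAN convention: a variant scoring <= -2.5 is predicted deleterious,
anything above is neutral.  Frameshifts are treated as deleterious
regardless of score by default, since substitution-style scores do not
apply to them.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ParseError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

PROVEAN_THRESHOLD = -2.5

MUTATION_CLASSES = (
    "missense",
    "frameshift",
    "inframe_deletion",
    "inframe_duplication",
    "inframe_insertion",
    "deletion_insertion",
)

_AA = r"([A-Z])"
_POS = r"(\d+)"
_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(rf"^{_AA}{_POS}{_AA}$"), "missense"),
    (re.compile(rf"^{_AA}{_POS}fs$"), "frameshift"),
    (re.compile(rf"^{_AA}{_POS}_{_AA}{_POS}delins([A-Z]+)$"), "deletion_insertion"),
    (re.compile(rf"^{_AA}{_POS}_{_AA}{_POS}ins([A-Z]+)$"), "inframe_insertion"),
    (re.compile(rf"^{_AA}{_POS}_{_AA}{_POS}del$"), "inframe_deletion"),
    (re.compile(rf"^{_AA}{_POS}del$"), "inframe_deletion"),
    (re.compile(rf"^{_AA}{_POS}_{_AA}{_POS}dup$"), "inframe_duplication"),
    (re.compile(rf"^{_AA}{_POS}dup$"), "inframe_duplication"),
]


@dataclass
class MutationRecord:
    """One parsed protein change, optionally with a PROVEAN call."""

    gene: str
    notation: str
    mutation_class: str
    start_pos: int
    start_ref: str
    end_pos: int | None = None
    end_ref: str | None = None
    alt: str | None = None  # substituted/inserted residues
    provean_score: float | None = None
    deleterious: bool | None = None

    def format(self) -> str:
        """Reconstruct the notation string (parser round-trip)."""
        head = f"{self.start_ref}{self.start_pos}"
        span = head if self.end_pos is None else f"{head}_{self.end_ref}{self.end_pos}"
        if self.mutation_class == "missense":
            return f"{head}{self.alt}"
        if self.mutation_class == "frameshift":
            return f"{head}fs"
        if self.mutation_class == "inframe_deletion":
            return f"{span}del"
        if self.mutation_class == "inframe_duplication":
            return f"{span}dup"
        if self.mutation_class == "inframe_insertion":
            return f"{span}ins{self.alt}"
        return f"{span}delins{self.alt}"


def _check_aa(token: str, letters: Iterable[str]) -> None:
    bad = [a for a in letters if a not in AMINO_ACIDS]
    if bad:
        raise ParseError(f"{token!r}: invalid amino-acid letter(s) {bad} "
                         "(single-letter codes only)")


def parse_protein_change(notation: str, gene: str = "") -> MutationRecord:
    """Parse one protein-change token into a structured record."""
    token = notation.strip()
    for pattern, klass in _PATTERNS:
        m = pattern.match(token)
        if not m:
            continue
        g = m.groups()
        if klass in ("missense", "frameshift"):
            ref, pos = g[0], int(g[1])
            alt = g[2] if klass == "missense" else None
            _check_aa(token, [ref] + ([alt] if alt else []))
            return MutationRecord(gene, token, klass, pos, ref, alt=alt)
        if len(g) == 2:  # single-residue del/dup
            ref, pos = g[0], int(g[1])
            _check_aa(token, [ref])
            return MutationRecord(gene, token, klass, pos, ref)
        ref1, pos1, ref2, pos2 = g[0], int(g[1]), g[2], int(g[3])
        alt = g[4] if len(g) > 4 else None
        _check_aa(token, [ref1, ref2] + list(alt or ""))
        if pos2 <= pos1:
            raise ParseError(f"{token!r}: residue range must be increasing")
        return MutationRecord(gene, token, klass, pos1, ref1,
                              end_pos=pos2, end_ref=ref2, alt=alt)
    raise ParseError(f"unparseable protein-change notation {notation!r}")


def classify_provean(score: float | None) -> str | None:
    """'deleterious' iff score <= -2.5, 'neutral' above; None when unscored."""
    if score is None or pd.isna(score):
        return None
    return "deleterious" if score <= PROVEAN_THRESHOLD else "neutral"


def annotate(record: MutationRecord,
             frameshift_deleterious: bool = True) -> MutationRecord:
    """Fill the record's deleterious flag from its score/class.

    Priority: an explicit flag stands; else the PROVEAN call; else
    frameshifts are deleterious by class (when enabled).
    """
    if record.deleterious is None:
        call = classify_provean(record.provean_score)
        if call is not None:
            record.deleterious = call == "deleterious"
        elif frameshift_deleterious and record.mutation_class == "frameshift":
            record.deleterious = True
    return record


def read_mutation_table(path, frameshift_deleterious: bool = True
                        ) -> list[MutationRecord]:
    """Read a mutation TSV: gene, notation[, deleterious][, provean_score]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "notation"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns gene, notation")
    records = []
    for _, row in df.iterrows():
        rec = parse_protein_change(str(row["notation"]), gene=str(row["gene"]))
        if "provean_score" in df.columns and pd.notna(row.get("provean_score")):
            rec.provean_score = float(row["provean_score"])
        if "deleterious" in df.columns and pd.notna(row.get("deleterious")):
            rec.deleterious = bool(int(row["deleterious"]))
        records.append(annotate(rec, frameshift_deleterious))
    return records


def severe_gene_flags(records: Iterable[MutationRecord]) -> dict[str, bool]:
    """Flag each gene carrying at least one deleterious change."""
    flags: dict[str, bool] = {}
    for rec in records:
        flags.setdefault(rec.gene, False)
        if rec.deleterious:
            flags[rec.gene] = True
    return flags


def load_reference_mutations(frameshift_deleterious: bool = True
                             ) -> list[MutationRecord]:
    """The bundled parental-difference mutation table (Luohui 9 vs RPY
    geng coding changes with published deleteriousness calls)."""
    ref = importlib.resources.files("pyramidkit.data") / "gene_mutations.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_mutation_table(path, frameshift_deleterious)


def write_flags(flags: Mapping[str, bool], path,
                header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(
            [{"gene": g, "severe": int(v)} for g, v in flags.items()]
        ).to_csv(fh, sep="\t", index=False)
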