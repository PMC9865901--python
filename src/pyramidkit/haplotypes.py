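"""Gene-region haplotype analysis of a variety panel.

A variety's haplotype at a gene is the string of its (homozygous)
alleles at the biallelic SNPs inside the gene region, ordered by
position.  Identical strings are grouped; groups reaching a minimum
sample count (default 10) are labeled T1, T2, ... in descending count
order (ties by lexicographic SNP string) and smaller groups are pooled
as "rare".  Varieties with a heterozygous or missing call at any
in-region site are left unassigned — inbred panels are expected
homozygous and partial strings would create spurious haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .contrasts import ContrastResult, contrast_single_locus
from .errors import DegenerateContrastError, FormatError, LabelError, LocusError
from .genotype import GeneLocus
from .synthetic import SUBPOPULATIONS

logger = logging.getLogger(__name__)

RARE_LABEL = "rare"

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3


@dataclass
class GeneHaplotypes:
    """Haplotype calls for one gene over a variety panel."""

    gene: str
    sites: list[tuple[str, int]]  # (chrom, pos) of the in-region SNPs used
    definitions: dict[str, str]  # retained label -> allele string
    assignments: pd.Series  # variety -> label (retained, 'rare', or NaN)
    counts: pd.Series  # retained label -> n
    rare_count: int
    unassigned: list[str]
    min_count: int

    @property
    def retained(self) -> list[str]:
        return list(self.counts.index)


def call_haplotypes(vcf_path, locus: GeneLocus, min_count: int = 10) -> GeneHaplotypes:
    """Group varieties by their SNP-allele string over a gene region.

    Only biallelic SNPs with position inside ``[locus.start, locus.end]``
    are used; multiallelic or non-SNP records are skipped with a
    warning.  Raises :class:`LocusError` when the region contains no
    usable SNP.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    site_alleles: list[np.ndarray] = []
    sites: list[tuple[str, int]] = []
    for v in vcf:
        if v.CHROM != locus.chrom or not (locus.start <= v.POS <= locus.end):
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            logger.warning("skipping non-biallelic-SNP record %s:%d", v.CHROM, v.POS)
            continue
        gt = np.asarray(v.gt_types)
        alleles = np.full(len(samples), "?", dtype="<U1")
        alleles[gt == _HOM_REF] = v.REF
        alleles[gt == _HOM_ALT] = v.ALT[0]
        site_alleles.append(alleles)
        sites.append((v.CHROM, v.POS))
    vcf.close()
    if not sites:
        raise LocusError(
            f"no biallelic SNP inside {locus.gene} "
            f"({locus.chrom}:{locus.start}-{locus.end})"
        )

    strings = np.array(["".join(col) for col in np.array(site_alleles).T])
    usable = np.array(["?" not in s for s in strings])
    unassigned = [s for s, u in zip(samples, usable) if not u]

    counts: dict[str, int] = {}
    for s in strings[usable]:
        counts[s] = counts.get(s, 0) + 1
    retained = sorted(
        (s for s, n in counts.items() if n >= min_count),
        key=lambda s: (-counts[s], s),
    )
    labels = {s: f"T{i + 1}" for i, s in enumerate(retained)}
    rare_count = sum(n for s, n in counts.items() if n < min_count)

    assign = pd.Series(np.nan, index=pd.Index(samples, name="variety_id"),
                       dtype=object, name=locus.gene)
    for s, string, u in zip(samples, strings, usable):
        if u:
            assign[s] = labels.get(string, RARE_LABEL)
    return GeneHaplotypes(
        gene=locus.gene,
        sites=sites,
        definitions={lab: s for s, lab in labels.items()},
        assignments=assign,
        counts=pd.Series({labels[s]: counts[s] for s in retained}, dtype=int),
        rare_count=rare_count,
        unassigned=unassigned,
        min_count=min_count,
    )


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Enforce the strict subpopulation vocabulary; unknown labels are a
    hard format error rather than being coerced."""
    if "subpopulation" in metadata.columns:
        unknown = set(metadata["subpopulation"].dropna()) - set(SUBPOPULATIONS)
        if unknown:
            raise FormatError(
                f"unknown subpopulation label(s) {sorted(unknown)}; "
                f"expected one of {SUBPOPULATIONS}"
            )
    return metadata


@dataclass
class HaplotypeSummary:
    gene: str
    trait: str
    table: pd.DataFrame  # retained label x (n, mean, sd)
    contrast: ContrastResult | None = None  # Welch tests + letters, if testable


def haplotype_trait_summary(
    haps: GeneHaplotypes, metadata: pd.DataFrame, trait: str = "gnpp",
    alpha: float = 0.05,
) -> HaplotypeSummary:
    """Per-haplotype trait summary with Welch-test letters.

    Mean, sd and n are computed over varieties with a non-missing trait
    value; sd is reported only for n >= 2.  Rare-pooled and unassigned
    varieties are excluded.
    """
    if trait not in metadata.columns:
        raise FormatError(f"trait {trait!r} absent from metadata")
    common = haps.assignments.index.intersection(metadata.index)
    assign = haps.assignments.loc[common]
    values = metadata.loc[common, trait]
    rows = []
    for label in haps.retained:
        v = values[(assign == label) & values.notna()]
        rows.append({
            "haplotype": label,
            "n": len(v),
            "mean": float(v.mean()) if len(v) else np.nan,
            "sd": float(v.std(ddof=1)) if len(v) >= 2 else np.nan,
        })
    table = pd.DataFrame(rows).set_index("haplotype")
    contrast = None
    retained_mask = assign.isin(haps.retained)
    try:
        contrast = contrast_single_locus(values[retained_mask], assign[retained_mask],
                                         alpha=alpha)
        table["letters"] = contrast.summary["letters"].reindex(table.index)
    except DegenerateContrastError:
        logger.warning("gene %s: too few testable haplotypes for contrasts", haps.gene)
    return HaplotypeSummary(gene=haps.gene, trait=trait, table=table, contrast=contrast)


def superior_haplotype(
    summary: HaplotypeSummary, direction: str = "max"
) -> str | None:
    """The haplotype with the extreme trait mean.

    Ties break toward larger n, then label order.  Returns None (with a
    warning) when no haplotype has a trait record.
    """
    t = summary.table.dropna(subset=["mean"])
    if t.empty:
        logger.warning("gene %s: no trait records for any haplotype", summary.gene)
        return None
    sign = -1.0 if direction == "max" else 1.0
    order = sorted(t.index, key=lambda h: (sign * t.at[h, "mean"], -t.at[h, "n"], h))
    return order[0]


def composition_tables(
    haps: GeneHaplotypes, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Haplotype x subpopulation and haplotype x origin contingency counts.

    Row sums equal the per-haplotype counts over varieties present in
    the metadata.  The subpopulation vocabulary is validated strictly.
    """
    validate_metadata(metadata)
    common = haps.assignments.index.intersection(metadata.index)
    assign = haps.assignments.loc[common]
    keep = assign.isin(haps.retained)
    sub = pd.crosstab(assign[keep], metadata.loc[common, "subpopulation"][keep])
    sub = sub.reindex(index=haps.retained, columns=list(SUBPOPULATIONS), fill_value=0)
    ori = pd.crosstab(assign[keep], metadata.loc[common, "origin"][keep])
    ori = ori.reindex(index=haps.retained, fill_value=0)
    return sub, ori


def _assignments(panel) -> pd.Series:
    if isinstance(panel, GeneHaplotypes):
        return panel.assignments
    return pd.Series(panel)


def co_occurrence(panel_a, panel_b, hap_a: str, hap_b: str) -> tuple[list[str], int]:
    """Varieties carrying haplotype ``hap_a`` at gene A and ``hap_b`` at gene B.

    Accepts :class:`GeneHaplotypes` or plain variety->label mappings.
    Unknown labels raise :class:`LabelError`.
    """
    a = _assignments(panel_a)
    b = _assignments(panel_b)
    for hap, assign, which in ((hap_a, a, "A"), (hap_b, b, "B")):
        known = set(assign.dropna().unique())
        if hap not in known:
            raise LabelError(f"haplotype {hap!r} unknown at gene {which} "
                             f"(known: {sorted(known)})")
    common = a.index.intersection(b.index)
    hit = common[(a.loc[common] == hap_a) & (b.loc[common] == hap_b)]
    varieties = [str(v) for v in hit]
    return varieties, len(varieties)


def write_assignments(panels: Mapping[str, GeneHaplotypes], path,
                      header_comment: str | None = None) -> None:
    """Long-format haplotype assignment TSV (variety, gene, label)."""
    rows = []
    for gene, haps in panels.items():
        for variety, label in haps.assignments.items():
            rows.append({"variety_id": variety, "gene": gene,
                         "haplotype": label if isinstance(label, str) else "NA"})
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
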