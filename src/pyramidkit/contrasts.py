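"""Single- and two-locus genotype contrasts on a quantitative trait.

Group means are compared pairwise with Welch's unequal-variance t-test
and summarized with a compact letter display: groups sharing a letter
are not significantly different at the chosen alpha.  No
multiple-testing correction is applied by default (a Bonferroni option
is provided); alpha defaults to 0.05 and the p < 0.001 tier is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateContrastError


@dataclass
class ContrastResult:
    summary: pd.DataFrame  # group x (n, mean, sd, letters); descending mean order
    pvalues: pd.DataFrame  # symmetric group x group Welch p-values (NaN untested)
    letters: dict[str, str]
    alpha: float
    best_group: str | None = None  # highest tested mean
    untested: list[str] = field(default_factory=list)  # groups with n < 2


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided Welch t-test (statistic, p-value)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compact_letter_display(
    groups: list[str], significant: set[frozenset]
) -> dict[str, str]:
    """Greedy insert-and-absorb compact letter display.

    ``groups`` must be ordered (by descending mean, ties by label);
    ``significant`` holds the pairs that differ at alpha.  Guarantees
    that two groups share a letter iff their pair is not significant.
    """

    def sig(a: str, b: str) -> bool:
        return frozenset((a, b)) in significant

    def compatible(g: str, col: set) -> bool:
        return all(not sig(g, m) for m in col)

    cols: list[set] = []
    for g in groups:
        placed = False
        for col in cols:
            if compatible(g, col):
                col.add(g)
                placed = True
        if not placed:
            new = {g}
            for m in groups:
                if m != g and not sig(m, g) and compatible(m, new):
                    new.add(m)
            cols.append(new)
    # repair: every non-significant pair must share a column
    for a, b in combinations(groups, 2):
        if not sig(a, b) and not any(a in c and b in c for c in cols):
            new = {a, b}
            for m in groups:
                if m not in new and compatible(m, new):
                    new.add(m)
            cols.append(new)
    # absorb subset columns
    cols = [c for i, c in enumerate(cols)
            if not any(c < d or (c == d and i > j) for j, d in enumerate(cols))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {
        g: "".join(alphabet[j % len(alphabet)] for j, c in enumerate(cols) if g in c)
        for g in groups
    }


def _contrast(values_by_group: dict[str, np.ndarray], alpha: float,
              bonferroni: bool) -> ContrastResult:
    tested = {g: v for g, v in values_by_group.items() if len(v) >= 2}
    untested = sorted(set(values_by_group) - set(tested))
    if len(tested) < 2:
        raise DegenerateContrastError(
            f"need >= 2 groups with n >= 2; usable: {sorted(tested)}"
        )
    all_groups = sorted(
        values_by_group,
        key=lambda g: (-float(np.mean(values_by_group[g])) if len(values_by_group[g]) else np.inf, g),
    )
    n_pairs = len(list(combinations(tested, 2)))
    thresh = alpha / n_pairs if bonferroni else alpha

    pmat = pd.DataFrame(np.nan, index=all_groups, columns=all_groups)
    significant: set[frozenset] = set()
    for a, b in combinations(sorted(tested), 2):
        _, p = welch_t(tested[a], tested[b])
        pmat.at[a, b] = pmat.at[b, a] = p
        if p < thresh:
            significant.add(frozenset((a, b)))

    tested_order = [g for g in all_groups if g in tested]
    letters = compact_letter_display(tested_order, significant)
    rows = []
    for g in all_groups:
        v = values_by_group[g]
        rows.append({
            "group": g,
            "n": len(v),
            "mean": float(np.mean(v)) if len(v) else np.nan,
            "sd": float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan,
            "letters": letters.get(g, ""),
        })
    summary = pd.DataFrame(rows).set_index("group")
    best = tested_order[0] if tested_order else None
    return ContrastResult(summary=summary, pvalues=pmat, letters=letters,
                          alpha=alpha, best_group=best, untested=untested)


def contrast_single_locus(
    phenotype: pd.Series, alleles: pd.Series, alpha: float = 0.05,
    bonferroni: bool = False,
) -> ContrastResult:
    """Contrast phenotype between the allele classes of one locus.

    ``phenotype`` maps line to trait value, ``alleles`` maps line to an
    allele/genotype label; lines labeled ``NA`` or missing either value
    are excluded.  Requires >= 2 classes with n >= 2.
    """
    common = phenotype.index.intersection(alleles.index)
    pheno = phenotype.loc[common]
    alle = alleles.loc[common].astype(str)
    ok = pheno.notna() & (alle != "NA") & (alle != "nan")
    groups = {
        str(a): pheno[ok & (alle == a)].to_numpy(dtype=float)
        for a in sorted(alle[ok].unique())
    }
    return _contrast(groups, alpha, bonferroni)


def contrast_two_locus(
    phenotype: pd.Series, alleles_a: pd.Series, alleles_b: pd.Series,
    alpha: float = 0.05, bonferroni: bool = False, sep: str = "/",
) -> ContrastResult:
    """Contrast phenotype across the four two-locus genotype combinations.

    Lines NA at either locus are excluded; combination groups are
    labeled ``alleleA/alleleB``.  Groups with n < 2 are reported but
    excluded from testing and best-group selection.
    """
    common = phenotype.index.intersection(alleles_a.index).intersection(alleles_b.index)
    pheno = phenotype.loc[common]
    a = alleles_a.loc[common].astype(str)
    b = alleles_b.loc[common].astype(str)
    ok = pheno.notna() & ~a.isin(("NA", "nan")) & ~b.isin(("NA", "nan"))
    combo = a[ok] + sep + b[ok]
    groups = {
        str(c): pheno[ok][combo == c].to_numpy(dtype=float)
        for c in sorted(combo.unique())
    }
    return _contrast(groups, alpha, bonferroni)


def write_contrast(result: ContrastResult, summary_path, pvalues_path,
                   header_comment: str | None = None) -> None:
    with open(summary_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = result.summary.copy()
        out.insert(0, "group", out.index)
        out.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    with open(pvalues_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = result.pvalues.copy()
        out.insert(0, "group", out.index)
        out.to_csv(fh, sep="\t", index=False)
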