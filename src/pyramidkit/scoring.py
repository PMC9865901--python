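"""Parental-genotype win-count scoring across environments.

For each candidate gene, the carriers of the female-parent (F, japonica
RPY geng) and male-parent (M, indica Luohui 9) genotypes are averaged
per environment, and each parental genotype is scored by the number of
environments in which its carrier mean strictly exceeds the other's
("win count").  Exact ties credit neither side, so
``score_F + score_M == n_environments`` whenever no environment ties.
Assigned per-line scores form the input matrix for the PCA stage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateClassError, FormatError


@dataclass
class GeneScoreCard:
    """Per-gene environment means for both parental genotypes plus win counts."""

    gene: str
    environments: list[str]
    mean_f: np.ndarray
    mean_m: np.ndarray
    score_f: int
    score_m: int

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def to_rows(self) -> list[dict]:
        rows = []
        for genotype, means, score in (("F", self.mean_f, self.score_f),
                                       ("M", self.mean_m, self.score_m)):
            row = {"gene": self.gene, "genotype": genotype}
            row.update({e: m for e, m in zip(self.environments, means)})
            row["score"] = score
            rows.append(row)
        return rows


@dataclass
class ScoreMatrix:
    """Lines x genes matrix of assigned parental-genotype scores.

    Cells are the scoring gene's ``score_F`` or ``score_M`` depending on
    the line's resolved parental origin; lines with unresolved (NA)
    origin at a gene hold NaN.
    """

    values: pd.DataFrame
    provenance: dict[str, GeneScoreCard] = field(default_factory=dict)


def env_genotype_means(
    phenotypes: pd.DataFrame, genotypes: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Per-environment mean phenotype of F- and M-genotype carriers.

    ``phenotypes`` is lines x environments; ``genotypes`` maps line to
    {F, M, NA}.  NA-genotype lines are excluded.  An environment where
    either carrier class is empty (no carrier with a recorded phenotype)
    raises :class:`DegenerateClassError`.
    """
    common = phenotypes.index.intersection(genotypes.index)
    pheno = phenotypes.loc[common]
    geno = genotypes.loc[common]
    means = {}
    for parent in ("F", "M"):
        sub = pheno.loc[geno == parent]
        counts = sub.notna().sum(axis=0)
        if len(sub) == 0 or (counts == 0).any():
            empty = list(pheno.columns) if len(sub) == 0 else list(counts.index[counts == 0])
            raise DegenerateClassError(
                f"gene {genotypes.name!r}: no {parent}-genotype carriers with "
                f"phenotype in environment(s) {empty}"
            )
        means[parent] = sub.mean(axis=0)
    return means["F"], means["M"]


def win_count_scores(
    mean_f: Sequence[float], mean_m: Sequence[float]
) -> tuple[int, int]:
    """Count the environments each parental genotype strictly wins.

    Exact ties increment neither score.
    """
    f = np.asarray(mean_f, dtype=float)
    m = np.asarray(mean_m, dtype=float)
    if f.shape != m.shape:
        raise ConfigError("mean vectors must have equal length")
    return int((f > m).sum()), int((m > f).sum())


def build_score_card(
    gene: str, phenotypes: pd.DataFrame, genotypes: pd.Series
) -> GeneScoreCard:
    """Compute a gene's score card from phenotypes and resolved genotypes."""
    mean_f, mean_m = env_genotype_means(phenotypes, genotypes)
    score_f, score_m = win_count_scores(mean_f.to_numpy(), mean_m.to_numpy())
    return GeneScoreCard(
        gene=gene,
        environments=list(phenotypes.columns),
        mean_f=mean_f.to_numpy(),
        mean_m=mean_m.to_numpy(),
        score_f=score_f,
        score_m=score_m,
    )


def assign_scores(
    cards: Mapping[str, GeneScoreCard], genotypes: pd.DataFrame | Mapping[str, pd.Series]
) -> ScoreMatrix:
    """Assign each line its carried genotype's score at every gene.

    ``genotypes`` is lines x genes over {F, M, NA} (DataFrame or mapping
    of per-gene Series).  Every gene column must have a score card.
    """
    if not isinstance(genotypes, pd.DataFrame):
        genotypes = pd.DataFrame(dict(genotypes))
    missing = [g for g in genotypes.columns if g not in cards]
    if missing:
        raise ConfigError(f"no score card for gene(s): {missing}")
    cols = {}
    for gene in genotypes.columns:
        card = cards[gene]
        geno = genotypes[gene]
        col = pd.Series(np.nan, index=genotypes.index, dtype=float)
        col[geno == "F"] = card.score_f
        col[geno == "M"] = card.score_m
        cols[gene] = col
    return ScoreMatrix(values=pd.DataFrame(cols), provenance=dict(cards))


# ---------------------------------------------------------------------------
# IO and bundled reference data


def cards_to_frame(cards: Mapping[str, GeneScoreCard]) -> pd.DataFrame:
    rows = []
    for card in cards.values():
        rows.extend(card.to_rows())
    return pd.DataFrame(rows)


def write_score_cards(cards: Mapping[str, GeneScoreCard], path,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cards_to_frame(cards).to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_score_cards(path) -> dict[str, GeneScoreCard]:
    """Read a score-card TSV (gene, genotype, one column per environment, score)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = {"gene", "genotype", "score"}
    if not meta.issubset(df.columns):
        raise FormatError(f"{path}: expected columns gene, genotype, <envs...>, score")
    envs = [c for c in df.columns if c not in meta]
    cards: dict[str, GeneScoreCard] = {}
    for gene, grp in df.groupby("gene", sort=False):
        by_geno = grp.set_index("genotype")
        if not {"F", "M"}.issubset(by_geno.index):
            raise FormatError(f"{path}: gene {gene!r} needs both F and M rows")
        cards[str(gene)] = GeneScoreCard(
            gene=str(gene),
            environments=envs,
            mean_f=by_geno.loc["F", envs].to_numpy(dtype=float),
            mean_m=by_geno.loc["M", envs].to_numpy(dtype=float),
            score_f=int(by_geno.loc["F", "score"]),
            score_m=int(by_geno.loc["M", "score"]),
        )
    return cards


def write_score_matrix(matrix: ScoreMatrix, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = matrix.values.copy()
        out.insert(0, "line_id", out.index)
        out.to_csv(fh, sep="\t", index=False)


def read_score_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("line_id")


def load_reference_means() -> pd.DataFrame:
    """The published per-environment GNPP means and scores for the 19
    parentally differential candidate genes of the Luohui 9 x RPY geng
    RIL population (bundled reference table)."""
    ref = importlib.resources.files("pyramidkit.data") / "ril_genotype_gnpp_means.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def reference_score_cards() -> dict[str, GeneScoreCard]:
    """Score cards recomputed from the bundled reference means.

    The win counts are recomputed from the mean columns, not copied from
    the published score column, so the table doubles as a regression
    fixture for :func:`win_count_scores`.
    """
    df = load_reference_means()
    envs = [c for c in df.columns if c not in ("gene", "genotype", "score")]
    cards = {}
    for gene, grp in df.groupby("gene", sort=False):
        by_geno = grp.set_index("genotype")
        mean_f = by_geno.loc["F", envs].to_numpy(dtype=float)
        mean_m = by_geno.loc["M", envs].to_numpy(dtype=float)
        score_f, score_m = win_count_scores(mean_f, mean_m)
        cards[str(gene)] = GeneScoreCard(str(gene), envs, mean_f, mean_m, score_f, score_m)
    return cards
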