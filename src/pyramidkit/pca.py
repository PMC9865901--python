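"""Key-gene selection by PCA of the assigned score matrix, and
hierarchical phenotype grouping.

The score matrix (lines x genes of assigned parental-genotype scores)
is mean-imputed and column-centered, then decomposed by PCA; genes
with the largest-magnitude PC1 loadings are the "key genes" driving
the population's phenotypic spread.  Lines are grouped
Low/Middle/High by Ward hierarchical clustering of their
per-environment phenotype vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .errors import ConfigError
from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # lines x components
    loadings: pd.DataFrame  # genes x components (unit-norm columns)
    explained_variance_ratio: np.ndarray
    imputation: dict[str, dict] = field(default_factory=dict)  # gene -> {fill, n_filled}
    dropped_genes: list[str] = field(default_factory=list)


def run_pca(scores: ScoreMatrix | pd.DataFrame, n_components: int | None = None,
            standardize: bool = False) -> PCAResult:
    """PCA of the centered score matrix.

    Missing cells are imputed with the gene's mean assigned score and
    columns are centered; zero-variance columns are dropped with a
    warning.  Columns are deliberately *not* scaled to unit variance by
    default: an assigned score column takes only two values, so after
    unit-variance scaling every gene column collapses to the same
    two-level pattern and the decomposition becomes blind to the win
    counts — the spread between ``score_F`` and ``score_M`` *is* the
    signal that separates consistently winning genes from indifferent
    ones.  ``standardize=True`` restores correlation-matrix PCA for
    inputs whose columns are on genuinely different scales.  Each
    component is oriented so its largest-magnitude loading is positive,
    making signs deterministic.
    """
    df = scores.values if isinstance(scores, ScoreMatrix) else scores
    df = df.astype(float)

    imputation: dict[str, dict] = {}
    filled = df.copy()
    for gene in df.columns:
        n_missing = int(df[gene].isna().sum())
        if n_missing:
            fill = float(df[gene].mean())
            filled[gene] = df[gene].fillna(fill)
            imputation[gene] = {"fill": fill, "n_filled": n_missing}

    sd = filled.std(ddof=1)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        logger.warning("dropping zero-variance gene column(s): %s", dropped)
        filled = filled.drop(columns=dropped)
    if filled.shape[1] < 2:
        raise ConfigError("need >= 2 genes with non-zero variance for PCA")

    z = filled - filled.mean()
    if standardize:
        z = z / filled.std(ddof=1)
    k = n_components or min(z.shape)
    k = min(k, min(z.shape))
    pca = PCA(n_components=k, svd_solver="full")
    comp_scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T  # genes x components, rows of components_ are unit-norm

    # orient each component so its largest-|loading| entry is positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            comp_scores[:, j] *= -1

    comps = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(comp_scores, index=z.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=z.columns, columns=comps),
        explained_variance_ratio=pca.explained_variance_ratio_,
        imputation=imputation,
        dropped_genes=dropped,
    )


@dataclass
class KeyGeneSelection:
    ranked: list[str]  # k genes by descending |PC1 loading|
    pc1_max: str  # gene attaining the maximum (signed) PC1 loading
    pc2_min: str  # gene attaining the minimum (signed) PC2 loading


def select_key_genes(pca: PCAResult, k: int = 8) -> KeyGeneSelection:
    """The k genes contributing most to the PC1-PC2 loading plane.

    Genes are ranked by their variance contribution over the first two
    components, ``lambda_1 * l_1g^2 + lambda_2 * l_2g^2`` — distance
    from the origin in the (eigenvalue-weighted) loading biplot.
    Ranking on PC1 alone is unreliable here: linked genes form
    correlated score-column blocks, and when two blocks have comparable
    variance one lands on PC1 and the other on PC2, so a single
    component never sees both.  Ties break by |PC1 loading| then gene
    id.  Also names the genes at the maximum PC1 loading and the
    minimum PC2 loading — the two extremes that single out the
    strongest antagonistic pair.
    """
    if pca.loadings.shape[1] < 2:
        raise ConfigError("key-gene selection needs >= 2 components")
    lo = pca.loadings
    if k > len(lo.index):
        logger.warning("k=%d exceeds %d genes; truncating", k, len(lo.index))
        k = len(lo.index)
    lam = pca.explained_variance_ratio[:2]  # proportional to eigenvalues
    contrib = lam[0] * lo["PC1"] ** 2 + lam[1] * lo["PC2"] ** 2
    order = sorted(
        lo.index,
        key=lambda g: (-contrib[g], -abs(lo.at[g, "PC1"]), g),
    )
    return KeyGeneSelection(
        ranked=order[:k],
        pc1_max=lo["PC1"].idxmax(),
        pc2_min=lo["PC2"].idxmin(),
    )


@dataclass
class PhenotypeGrouping:
    assignments: pd.Series  # line -> group label
    group_means: pd.Series  # label -> mean phenotype (over environments)
    group_sizes: pd.Series  # label -> n
    linkage_method: str
    metric: str
    excluded: list[str] = field(default_factory=list)  # lines with missing envs

    @property
    def labels(self) -> list[str]:
        return list(self.group_means.index)


def cluster_phenotype_groups(
    phenotypes: pd.DataFrame, k: int = 3, linkage_method: str = "ward",
    metric: str = "euclidean",
) -> PhenotypeGrouping:
    """Agglomerative clustering of lines on per-environment phenotypes.

    Ward linkage on Euclidean distances between environment vectors,
    tree cut at ``k`` clusters; clusters are relabeled by ascending mean
    phenotype — L/M/H for k=3, else G1..Gk.  Lines with any missing
    environment are excluded and reported.
    """
    complete = phenotypes.dropna()
    excluded = [str(l) for l in phenotypes.index.difference(complete.index)]
    if excluded:
        logger.warning("excluding %d line(s) with missing environments", len(excluded))
    if len(complete) < k:
        raise ConfigError(f"need >= {k} complete lines, have {len(complete)}")
    if k == 1:
        raw = np.ones(len(complete), dtype=int)
    else:
        Z = linkage(complete.to_numpy(), method=linkage_method, metric=metric)
        raw = fcluster(Z, t=k, criterion="maxclust")
    line_mean = complete.mean(axis=1)
    cluster_means = pd.Series(line_mean.to_numpy()).groupby(raw).mean()
    order = cluster_means.sort_values(kind="stable").index  # ascending mean
    labels = ["L", "M", "H"] if k == 3 else [f"G{i + 1}" for i in range(k)]
    relabel = {c: labels[i] for i, c in enumerate(order)}
    assigned = pd.Series([relabel[c] for c in raw], index=complete.index, name="group")
    group_means = line_mean.groupby(assigned).mean().reindex(labels[:k])
    group_sizes = assigned.value_counts().reindex(labels[:k]).astype(int)
    return PhenotypeGrouping(
        assignments=assigned,
        group_means=group_means,
        group_sizes=group_sizes,
        linkage_method=linkage_method,
        metric=metric,
        excluded=excluded,
    )


def group_frequency_table(
    grouping: PhenotypeGrouping,
    genotypes: pd.DataFrame | Mapping[str, pd.Series],
    superior: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group frequency of each gene's superior parental genotype.

    Returns genes x groups fractions over non-NA lines; a group with no
    non-NA line for a gene reports NaN.
    """
    if not isinstance(genotypes, pd.DataFrame):
        genotypes = pd.DataFrame(dict(genotypes))
    common = grouping.assignments.index.intersection(genotypes.index)
    groups = grouping.assignments.loc[common]
    out = {}
    for gene in genotypes.columns:
        if gene not in superior:
            raise ConfigError(f"no superior-genotype designation for gene {gene!r}")
        geno = genotypes[gene].loc[common]
        usable = geno != "NA"
        freq = {}
        for label in grouping.labels:
            in_group = (groups == label) & usable
            n = int(in_group.sum())
            freq[label] = float((geno[in_group] == superior[gene]).mean()) if n else np.nan
        out[gene] = freq
    return pd.DataFrame(out).T.reindex(columns=grouping.labels)
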