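"""Synthetic RIL populations and variety panels.

The generators emulate the statistical structure the analysis assumes:

* a biparental population of fully homozygous recombinant inbred lines
  (high-generation, >F15, so residual heterozygosity is folded into the
  NA fraction), each chromosome a two-state Markov mosaic of female (F)
  and male (M) parental blocks with a Poisson-distributed crossover
  count and crossover positions uniform over bin boundaries (no
  interference);
* additive per-gene effects on grain number per panicle (GNPP) over
  several environments with Gaussian noise; and
* a variety panel with per-gene haplotype structure, subpopulation
  labels, geographic origins and haplotype-dependent trait means,
  written as a minimal homozygous-GT VCF plus a metadata table.

Defaults put the phenotype on the scale of the Luohui 9 x RPY geng RIL
study: 272 lines, five environments whose baselines are the column
means of the published per-genotype GNPP table, and eight effect genes
(two large, six moderate) among nineteen candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, LocusError
from .genotype import Bin, BinGenotypeMatrix, GeneLocus, genotype_at_locus
from .scoring import load_reference_means

#: Default seed (date-derived provenance constant recorded in outputs).
DEFAULT_SEED = 20230114

ENVIRONMENTS = ("HN19", "EZ18", "EZ17", "LS17", "EZ16")

SUBPOPULATIONS = ("Aus", "Indica", "Japonica", "Intermediate")

#: Superior parent and additive effect (grains) for the default effect genes:
#: two large-effect loci and six moderate ones, superior-parent assignment
#: following the study's conclusion (PYL1/LAX1/DTH8/OSH1 superior from the
#: japonica F parent; PYL4/SP1/DST/GNP1 from the indica M parent).
DEFAULT_GENE_EFFECTS: dict[str, tuple[str, float]] = {
    "LAX1": ("F", 15.0),
    "GNP1": ("M", 15.0),
    "PYL1": ("F", 5.0),
    "OSH1": ("F", 5.0),
    "DTH8": ("F", 5.0),
    "PYL4": ("M", 5.0),
    "SP1": ("M", 5.0),
    "DST": ("M", 5.0),
}


def default_env_baselines() -> list[float]:
    """Per-environment baseline GNPP: column means of the bundled
    reference genotype-mean table, keeping synthetic output on the
    published scale."""
    df = load_reference_means()
    return [round(float(df[e].mean()), 4) for e in ENVIRONMENTS]


@dataclass
class SimConfig:
    """Configuration of the RIL population simulator."""

    n_lines: int = 272
    n_chromosomes: int = 12
    bins_per_chromosome: int = 40
    bin_length: int = 250_000  # bp
    expected_crossovers_per_chromosome: float = 3.0
    na_fraction: float = 0.02
    n_environments: int = 5
    env_names: list[str] = field(default_factory=lambda: list(ENVIRONMENTS))
    env_baselines: list[float] = field(default_factory=default_env_baselines)
    gene_effects: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_EFFECTS)
    )
    noise_sd: float = 30.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_chromosomes", "bins_per_chromosome",
                     "bin_length", "n_environments"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 <= self.na_fraction < 0.5:
            raise ConfigError("na_fraction must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.expected_crossovers_per_chromosome < 0:
            raise ConfigError("expected_crossovers_per_chromosome must be >= 0")
        if len(self.env_names) != self.n_environments:
            raise ConfigError("env_names length must equal n_environments")
        if len(self.env_baselines) != self.n_environments:
            raise ConfigError("env_baselines length must equal n_environments")
        for gene, (parent, _) in self.gene_effects.items():
            if parent not in ("F", "M"):
                raise ConfigError(f"gene {gene}: superior parent must be F or M")

    @property
    def chromosome_length(self) -> int:
        return self.bins_per_chromosome * self.bin_length


#: Default genomic placement of the candidate grain-number genes:
#: chromosome and relative position along it, following the genes' rice
#: genome locations (locus identifiers; scaled into the simulated
#: chromosome length).  The map deliberately keeps the real linkage
#: structure: LAX1 sits next to PYL1 on chromosome 1 (coupling-phase
#: neighbours, both japonica-superior by default) and GNP1 next to DST
#: and OSH1 on chromosome 3 (indica-superior block) — correlated score
#: columns from these blocks are what the PCA stage exploits.
DEFAULT_GENE_MAP: dict[str, tuple[int, float]] = {
    "Gn1a": (1, 0.12), "NOG1": (1, 0.55), "PYL1": (1, 0.615),
    "LAX1": (1, 0.63),
    "LP": (2, 0.16),
    "PYL4": (3, 0.186), "OSH1": (3, 0.517), "DST": (3, 0.572),
    "GNP1": (3, 0.64),
    "An-1": (4, 0.283), "LAX2": (4, 0.325),
    "APO1": (6, 0.455),
    "DTH7": (7, 0.495),
    "DTH8": (8, 0.077), "PAY1": (8, 0.315), "GAD1": (8, 0.379),
    "IPA1": (8, 0.399),
    "DEP1": (9, 0.27),
    "TAW1": (10, 0.338),
    "SP1": (11, 0.127),
}


def default_loci(config: SimConfig, genes: Sequence[str] | None = None) -> list[GeneLocus]:
    """Place candidate genes deterministically across the simulated genome.

    Genes in :data:`DEFAULT_GENE_MAP` whose chromosome exists in the
    config are placed at their mapped relative position (a short locus
    around it, QTN at its centre); other genes are spread round-robin
    over chromosomes, one per interior bin.
    """
    if genes is None:
        genes = list(load_reference_means()["gene"].unique())
    loci = []
    fallback_slot = 0
    n_slots = config.n_chromosomes * max(config.bins_per_chromosome - 2, 1)
    half_width = max(config.bin_length // 10, 1)
    for gene in genes:
        mapped = DEFAULT_GENE_MAP.get(gene)
        if mapped and mapped[0] <= config.n_chromosomes:
            chrom_i, frac = mapped
            pos = max(1 + half_width, int(frac * config.chromosome_length))
            pos = min(pos, config.chromosome_length - half_width)
            loci.append(GeneLocus(gene, f"chr{chrom_i}", pos - half_width,
                                  pos + half_width, qtn_pos=pos))
        else:
            if fallback_slot >= n_slots:
                raise ConfigError(
                    f"cannot place {len(genes)} genes on {n_slots} interior bins")
            chrom = f"chr{fallback_slot % config.n_chromosomes + 1}"
            bin_idx = 1 + (fallback_slot // config.n_chromosomes) * 3 \
                % max(config.bins_per_chromosome - 2, 1)
            bin_start = bin_idx * config.bin_length + 1
            start = bin_start + 2 * config.bin_length // 5
            end = bin_start + 3 * config.bin_length // 5
            loci.append(GeneLocus(gene, chrom, start, end, qtn_pos=(start + end) // 2))
            fallback_slot += 1
    return loci


def simulate_bin_matrix(config: SimConfig, rng: np.random.Generator | None = None
                        ) -> BinGenotypeMatrix:
    """Simulate homozygous F/M genome mosaics over a regular bin map.

    Each line x chromosome draws its starting parent uniformly, a
    Poisson crossover count, and crossover positions uniformly (without
    replacement) over the interior bin boundaries; the parental state
    alternates at each crossover.  A random ``na_fraction`` of all cells
    is then masked NA.  Deterministic for a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_bins = config.bins_per_chromosome
    bins: list[Bin] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for b in range(n_bins):
            start = b * config.bin_length + 1
            bins.append(Bin(chrom, start, start + config.bin_length - 1))

    codes = np.empty((config.n_lines, config.n_chromosomes * n_bins), dtype="<U2")
    n_boundaries = n_bins - 1
    for i in range(config.n_lines):
        for c in range(config.n_chromosomes):
            state = "F" if rng.random() < 0.5 else "M"
            n_cross = min(rng.poisson(config.expected_crossovers_per_chromosome),
                          n_boundaries)
            cuts = np.sort(rng.choice(n_boundaries, size=n_cross, replace=False)) + 1 \
                if n_cross > 0 else np.array([], dtype=int)
            chrom_codes = np.empty(n_bins, dtype="<U2")
            prev = 0
            for cut in list(cuts) + [n_bins]:
                chrom_codes[prev:cut] = state
                state = "M" if state == "F" else "F"
                prev = cut
            codes[i, c * n_bins:(c + 1) * n_bins] = chrom_codes
    if config.na_fraction > 0:
        mask = rng.random(codes.shape) < config.na_fraction
        codes[mask] = "NA"

    lines = [f"RIL{i + 1:03d}" for i in range(config.n_lines)]
    df = pd.DataFrame(codes, index=pd.Index(lines, name="line_id"),
                      columns=[b.key for b in bins])
    return BinGenotypeMatrix(bins=bins, codes=df)


def simulate_phenotypes(
    bins: BinGenotypeMatrix,
    loci: Sequence[GeneLocus],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Additive multi-environment GNPP for a simulated population.

    GNPP(line, env) = baseline(env) + sum over effect genes of
    effect * [line carries the superior parent's allele] + Gaussian
    noise.  Lines NA at a gene receive no contribution from it.  Values
    are reported to 4 decimals.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    by_gene = {l.gene: l for l in loci}
    missing = [g for g in config.gene_effects if g not in by_gene]
    if missing:
        raise LocusError(f"gene_effects gene(s) absent from loci table: {missing}")

    genetic = np.zeros(bins.n_lines)
    for gene, (parent, effect) in config.gene_effects.items():
        geno = genotype_at_locus(bins, by_gene[gene])
        genetic += np.where(geno.to_numpy() == parent, effect, 0.0)

    baselines = np.asarray(config.env_baselines, dtype=float)
    values = baselines[None, :] + genetic[:, None]
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    df = pd.DataFrame(np.round(values, 4), index=bins.codes.index,
                      columns=config.env_names)
    return df


# ---------------------------------------------------------------------------
# Variety panel


@dataclass
class PanelConfig:
    """Configuration of the variety-panel simulator.

    Haplotypes are drawn independently per gene from ``haplotype_freqs``
    and realised as distinct homozygous SNP strings.  Subpopulation,
    origin and the trait mean of a variety follow its haplotype at the
    ``anchor_gene`` (default: first gene), emulating the
    indica/japonica-structured germplasm panels the analysis targets.
    Haplotypes are keyed ``H1..Hn`` in frequency-list order.
    """

    n_varieties: int = 500
    haplotype_freqs: dict[str, list[float]] = field(
        default_factory=lambda: {"LAX1": [0.6, 0.3, 0.1], "GNP1": [0.5, 0.3, 0.2]}
    )
    subpop_assignment: dict[str, dict[str, float]] = field(default_factory=dict)
    origin_assignment: dict[str, dict[str, float]] = field(default_factory=dict)
    haplotype_trait_means: dict[str, float] = field(default_factory=dict)
    trait_sd: float = 25.0
    n_snps_per_gene: int = 6
    anchor_gene: str | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_varieties < 1:
            raise ConfigError("n_varieties must be >= 1")
        if self.trait_sd < 0:
            raise ConfigError("trait_sd must be >= 0")
        if not self.haplotype_freqs:
            raise ConfigError("haplotype_freqs must name at least one gene")
        for gene, freqs in self.haplotype_freqs.items():
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ConfigError(f"gene {gene}: haplotype frequencies must sum to 1")
            if any(f < 0 for f in freqs):
                raise ConfigError(f"gene {gene}: negative haplotype frequency")
            if len(freqs) > 2 ** self.n_snps_per_gene:
                raise ConfigError(
                    f"gene {gene}: {len(freqs)} haplotypes cannot be distinguished "
                    f"by {self.n_snps_per_gene} SNPs"
                )
        if self.anchor_gene is None:
            self.anchor_gene = next(iter(self.haplotype_freqs))
        if self.anchor_gene not in self.haplotype_freqs:
            raise ConfigError(f"anchor gene {self.anchor_gene!r} not in haplotype_freqs")
        anchor_haps = {f"H{i + 1}" for i in range(len(self.haplotype_freqs[self.anchor_gene]))}
        if not self.haplotype_trait_means:
            # spread means 10 grains apart, highest for H1, around 130 grains
            self.haplotype_trait_means = {
                h: 130.0 - 10.0 * i for i, h in enumerate(sorted(anchor_haps))
            }
        for mapping, what in ((self.subpop_assignment, "subpop_assignment"),
                              (self.origin_assignment, "origin_assignment")):
            for hap, dist in mapping.items():
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ConfigError(f"{what}[{hap}]: probabilities must sum to 1")
        for dist in self.subpop_assignment.values():
            unknown = set(dist) - set(SUBPOPULATIONS)
            if unknown:
                raise ConfigError(f"unknown subpopulation label(s): {sorted(unknown)}")


@dataclass
class PanelSim:
    """Result bundle of the panel simulator."""

    vcf_path: str
    metadata: pd.DataFrame  # variety_id index: subpopulation, origin, gnpp
    loci: list[GeneLocus]
    truth: pd.DataFrame  # variety x gene planted haplotype keys (H1..)
    haplotype_strings: dict[str, dict[str, str]]  # gene -> key -> SNP string


def _hap_strings(n_haps: int, n_snps: int) -> list[str]:
    """Distinct homozygous allele strings: haplotype i is the binary
    pattern of i over the SNP sites (0 = REF, 1 = ALT)."""
    return [format(i, f"0{n_snps}b") for i in range(n_haps)]


_DEFAULT_SUBPOP = {"Aus": 0.05, "Indica": 0.45, "Japonica": 0.45, "Intermediate": 0.05}
_DEFAULT_ORIGINS = {"China": 0.4, "Japan": 0.2, "India": 0.2, "Southeast Asia": 0.2}


def simulate_variety_panel(config: PanelConfig, vcf_path) -> PanelSim:
    """Simulate a germplasm panel: homozygous VCF + metadata table.

    Each variety draws one haplotype per gene; haplotypes are realised
    as distinct homozygous SNP strings over ``n_snps_per_gene`` in-gene
    sites (REF=A, ALT=G).  Metadata carries subpopulation, origin and a
    GNPP drawn from Normal(anchor-haplotype mean, trait_sd^2).  The VCF
    sample order matches the metadata row order.
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.haplotype_freqs)
    varieties = [f"VAR{i + 1:04d}" for i in range(config.n_varieties)]

    # one gene per chromosome; SNPs spaced 100 bp starting at 10_001
    loci = []
    positions: dict[str, list[int]] = {}
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi + 1}"
        start = 10_001
        pos = [start + 100 * j for j in range(config.n_snps_per_gene)]
        positions[gene] = pos
        loci.append(GeneLocus(gene, chrom, start, pos[-1] + 50))

    truth = {}
    hapstrings: dict[str, dict[str, str]] = {}
    for gene in genes:
        freqs = config.haplotype_freqs[gene]
        keys = [f"H{i + 1}" for i in range(len(freqs))]
        strings = _hap_strings(len(freqs), config.n_snps_per_gene)
        hapstrings[gene] = dict(zip(keys, strings))
        draws = rng.choice(len(freqs), size=config.n_varieties, p=freqs)
        truth[gene] = [keys[d] for d in draws]
    truth_df = pd.DataFrame(truth, index=pd.Index(varieties, name="variety_id"))

    anchor = truth_df[config.anchor_gene]
    subpop, origin, gnpp = [], [], []
    for hap in anchor:
        sp_dist = config.subpop_assignment.get(hap, _DEFAULT_SUBPOP)
        or_dist = config.origin_assignment.get(hap, _DEFAULT_ORIGINS)
        subpop.append(rng.choice(list(sp_dist), p=list(sp_dist.values())))
        origin.append(rng.choice(list(or_dist), p=list(or_dist.values())))
        mean = config.haplotype_trait_means[hap]
        gnpp.append(mean + (rng.normal(0, config.trait_sd) if config.trait_sd > 0 else 0.0))
    metadata = pd.DataFrame(
        {"subpopulation": subpop, "origin": origin, "gnpp": np.round(gnpp, 4)},
        index=truth_df.index,
    )

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=pyramidkit-panel-sim(seed={config.seed})\n")
        for gi in range(len(genes)):
            fh.write(f"##contig=<ID=chr{gi + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(varieties) + "\n")
        for gi, gene in enumerate(genes):
            chrom = f"chr{gi + 1}"
            strings = hapstrings[gene]
            var_alleles = np.array(
                [list(strings[h]) for h in truth_df[gene]]
            )  # varieties x snps of '0'/'1'
            for j, pos in enumerate(positions[gene]):
                gts = "\t".join(
                    "0/0" if a == "0" else "1/1" for a in var_alleles[:, j]
                )
                fh.write(f"{chrom}\t{pos}\t{gene}_snp{j + 1}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")

    return PanelSim(
        vcf_path=str(vcf_path),
        metadata=metadata,
        loci=loci,
        truth=truth_df,
        haplotype_strings=hapstrings,
    )


def write_phenotypes(phenotypes: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Phenotype CSV: line_id then one column per environment."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = phenotypes.copy()
        out.insert(0, "line_id", out.index)
        out.to_csv(fh, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return df.set_index("line_id")


def write_metadata(metadata: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = metadata.copy()
        out.insert(0, "variety_id", out.index)
        out.to_csv(fh, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("variety_id")
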