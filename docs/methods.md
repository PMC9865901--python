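# Methods

This note documents the models, numerical choices and known limitations
behind `pyramidkit`. It is written for users who want to know what the
pipeline assumes, what its synthetic data do and do not emulate, and
why the open design questions were resolved the way they were.

## Study design being modelled

A biparental rice population of high-generation (>F15) recombinant
inbred lines (RILs): each line is essentially fully homozygous, and its
genome is a mosaic of female-parent (`F`, *japonica*) and male-parent
(`M`, *indica*) blocks over a bin-marker map. Grain number per panicle
(GNPP) is recorded for every line in several environments
(year × site combinations). A set of candidate genes with parental
protein differences is screened for allele effects, and a large
germplasm panel with haplotype, subpopulation, origin and trait records
is used to generalise beyond the cross.

## Synthetic data generator

**Genome mosaic.** Per line and chromosome, the starting parent is
drawn uniformly, the crossover count is Poisson with mean
`expected_crossovers_per_chromosome` (default 3), and crossover
positions are uniform without replacement over interior bin boundaries
— a two-state Markov mosaic with no interference. The default map is
12 chromosomes × 40 bins × 250 kb. Lines are simulated fully
homozygous; residual heterozygosity and recombinant intervals are
folded into an NA mask applied to a random `na_fraction` (default 2%)
of cells, matching the three-state (F/M/NA) representation of real bin
maps.

**Gene placement.** `DEFAULT_GENE_MAP` places the 20 candidate genes on
their real rice chromosomes at scaled positions from their locus
identifiers, keeping the genuine linkage structure: PYL1 and LAX1 are
neighbours on chromosome 1, and OSH1, DST and GNP1 share chromosome 3.
This matters: the PCA stage works through correlated score-column
blocks (below), and a map that scatters the genes over unlinked
positions produces an eigen-degenerate top subspace in which component
directions are arbitrary. One coordinate ambiguity had to be resolved:
the LAX1 QTN is printed both as chr3 and as Chr1-35558484 in the source
material, and LAX1's locus identifier (LOC_Os01g61480) is on
chromosome 1. The chr1 placement is used. The alternative —
LAX1 adjacent to GNP1 on chr3 — is untenable in simulation: the two
large effects have opposite superior parents, and tight repulsion-phase
linkage makes their contributions cancel line-by-line, driving both
genes' win counts to ~3/2 and erasing the signal the study reports.

**Phenotypes.** GNPP(line, env) = baseline(env) + Σ<sub>g</sub>
effect<sub>g</sub> · 1[line carries gene g's superior allele] + ε,
ε ~ N(0, noise_sd²), reported to 4 decimals. Defaults: five
environments whose baselines are the column means of the bundled
reference genotype-mean table (≈ 211, 207, 199, 192, 262 grains), two
+15-grain genes (LAX1 via F, GNP1 via M), six +5-grain genes
(PYL1/OSH1/DTH8 via F, PYL4/SP1/DST via M) following the study's
superior-parent conclusions, and noise sd 30 grains — chosen so that a
single large effect is comfortably but not trivially detectable at
n = 272 (per-environment Welch power ≈ 98%). Not modelled: dominance,
epistasis, genotype × environment interaction, read-level sequencing.
The true effect sizes of the real genes are unknown (the study reports
none); the defaults are chosen for testability, so passing recovery
tests demonstrates that the pipeline detects effects of this magnitude
under additive genetics, not that the real genes have these effects.

**Variety panel.** Each variety draws one haplotype per gene
independently from the configured frequencies; haplotypes are realised
as distinct homozygous SNP strings (binary patterns over
`n_snps_per_gene` sites, REF=A/ALT=G, positions 100 bp apart), written
as a plain-text VCF 4.2 with GT-only FORMAT. Subpopulation, origin and
the GNPP mean of a variety follow its haplotype at a designated anchor
gene, emulating the *indica*/*japonica* population structure of real
panels. Because genes are drawn independently, cross-gene haplotype
correlation (the geographic-isolation signal seen in real panels) is
not emulated; co-occurrence counts on synthetic panels test the
counting machinery, not population history. The default seed, 20230114,
is recorded in generated VCF headers for provenance.

## Win-count scoring

score<sub>P</sub> = number of environments where P-carriers' mean GNPP
strictly exceeds the other genotype's; ties credit neither. The rule is
inferred from the published score table — recomputing all 38 printed
cells from the printed means reproduces them exactly, with no ties at
printed precision — and is deliberately per-environment: several
printed rows (e.g. 4/1, 3/2) cannot arise from any rule applied to the
grand mean alone. Scores are computed over whatever environment columns
are supplied; the package takes no position on which seasons "count".
NA-genotype lines are excluded per gene; an environment with an empty
carrier class is a hard error naming gene and environment.

## PCA and key-gene selection

Missing score cells are imputed with the gene's mean assigned score
(deterministic, reported in the result). Columns are **centered but not
scaled**. This deviates from the obvious "standardize first"
convention on purpose: an assigned score column takes exactly two
values, so unit-variance scaling maps every non-degenerate gene to the
same two-level pattern and the decomposition retains only linkage
information, none of the win counts. The variance of a centered column
is (score<sub>F</sub> − score<sub>M</sub>)² p(1−p) — the spread between
the two scores, i.e. how consistently one allele wins, is exactly the
signal — so covariance PCA is the only version of the procedure that
can rank genes by effect consistency. `standardize=True` is available
for inputs whose columns are on genuinely different scales.

Decomposition is by SVD (scikit-learn, full solver) of the centered
matrix; each component is oriented so its largest-magnitude loading is
positive, making signs deterministic. Zero-variance columns are dropped
with a logged warning.

**Selection rule.** Genes are ranked by
λ₁·l²<sub>1g</sub> + λ₂·l²<sub>2g</sub>, their variance contribution
over the first two components — distance from the origin in the
eigenvalue-weighted loading biplot (ties by |PC1| then gene id; the
genes attaining the maximum PC1 loading and minimum PC2 loading are
also named). Ranking on |PC1| alone was rejected after analysis:
linked genes form correlated blocks, and when two blocks (e.g. the
chr1 and chr3 clusters) have comparable variance, one captures PC1 and
the other PC2, so no single component sees both. With k = 8 at study
scale (272 lines, 2 × (+15) + 6 × (+5) planted genes among 20, noise
sd 30), both +15 genes are recovered in 19/20 seeded replicates and
5.8 of the 8 effect genes on average.

A structural limit worth knowing: win counts saturate at 5/0, and a
null gene's five environment wins are independent coin flips whatever
the noise level, so each null reaches a 5/0 score with probability
≈ 2·(1/2)⁵ ≈ 6% per replicate. A lone 5/0 null is indistinguishable
from a large-effect gene by its column alone; only linkage structure
(correlated blocks of consistent winners) separates them. Recovery
guarantees therefore need k comfortably above the number of planted
large effects.

## Clustering and group frequencies

Ward linkage on Euclidean distances between per-environment GNPP
vectors (scipy), tree cut at k = 3, clusters relabelled L/M/H by
ascending mean. Lines with missing environments are excluded and
reported. The linkage/metric are recorded in the result and
configurable; Ward/Euclidean is the canonical default where the source
procedure names only a package default. Per-group superior-genotype
frequencies are fractions over non-NA lines; with a strong single gene
(+30 grains vs sd-30 noise, n = 272) the L→M→H frequency gradient is
monotone in 20/20 seeded replicates, but when the effect is large
relative to noise the phenotype becomes bimodal and the three-way cut
(hence the M group's composition) is intrinsically unstable — the
grouping is a description of the phenotype distribution, not an
inference procedure.

## Contrasts

Welch's unequal-variance t-test (scipy), two-sided, for all pairs of
allele classes (single locus) or of the four two-locus combinations;
classes with n < 2 are reported but untested. No multiple-testing
correction by default, matching the source analysis; a Bonferroni flag
exists. α defaults to 0.05. Letters come from a greedy
insert-and-absorb compact letter display with an explicit repair pass,
guaranteeing that two tested groups share a letter iff their pairwise
p ≥ α (verified property-based over random significance graphs,
including non-transitive ones). Group order is by descending mean,
ties by label.

## Haplotype panel

A variety's haplotype at a gene is the concatenation of its homozygous
alleles at the biallelic in-region SNPs, ordered by position;
multiallelic or non-SNP records are skipped with a warning, and a
heterozygous or missing call at any site leaves the variety unassigned
for that gene (partial strings would fabricate haplotypes in inbred
panels). Groups with n ≥ `min_count` (default 10) are labelled T1…Tn
by descending count, ties by lexicographic string; smaller groups pool
into a "rare" class excluded from summaries. Labels are therefore a
frequency convention of this package: on a real panel they need not
coincide with labels assigned by any external database. Superior
haplotype = extreme trait mean among retained haplotypes, ties toward
larger n then label order. Subpopulation vocabulary is strictly
{Aus, Indica, Japonica, Intermediate}; unknown labels are a format
error rather than being coerced, since silent coercion would corrupt
the composition tables.

## Mutation parsing and severity

The single-letter protein-change grammar covers missense (`D74E`),
frameshift (`L3fs`), in-frame deletion (`E346del`, `T131_P138del`),
duplication (`T201dup`, `H65_H66dup`), insertion
(`A124_V125insAAAAAV`) and deletion-insertion (`A12_G14delinsW`).
Three-letter amino-acid codes are rejected, not converted. PROVEAN
calls: deleterious iff score ≤ −2.5; the published rule's complement is
read as "> −2.5 ⇒ neutral" (the printed "> 2.5" would leave scores in
(−2.5, 2.5] unclassifiable and is taken as a sign typo). Frameshifts
are deleterious by class regardless of score (configurable off) —
substitution-style scores do not apply to them, and every published
frameshift record in this gene set carries the deleterious mark. The
bundled mutation table is encoded exactly as published: eight genes
carry a deleterious record (nine records in total); the narrative
summaries that name a ninth gene (DTH7, whose only change is an
unannotated D68E) or count ten deleterious mutations disagree with the
record-level annotation, and the package preserves rather than
resolves that discrepancy.

## Pipeline and reproducibility

All randomness flows from a single integer seed through
`numpy.random.default_rng`; stage seeds are derived by fixed offsets.
Identical config + seed gives byte-identical artifacts and report
(modulo the runtime field). Every written table carries the config
hash (SHA-256 of the config minus the output directory, truncated to
12 hex digits) in a `#` header comment. Default problem sizes — 272
lines, 480 bins, five environments, 20 genes, 500-variety panels, and
20-replicate recovery experiments — run the full pipeline in under a
second and the whole test suite in well under a minute on one CPU.

## Known limitations

- The win-count statistic discards effect magnitude beyond win/lose
  per environment; two genes winning all five environments are
  indistinguishable however different their effects.
- Mean imputation of missing scores shrinks variance slightly for
  genes with many NA lines; the imputation report makes this auditable.
- The panel simulator draws genes independently, so it cannot generate
  the between-gene haplotype associations that geographic isolation
  creates in real germplasm.
- Bin-level genotypes bound the resolution of QTN contrasts: a "QTN"
  genotype is the parental origin of its containing bin, not a
  sequenced base.
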