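"""Haplotype calling, summaries, composition and co-occurrence."""

import importlib.resources

import numpy as np
import pandas as pd
import pytest

from pyramidkit import (
    FormatError,
    GeneLocus,
    LabelError,
    LocusError,
    PanelConfig,
    call_haplotypes,
    co_occurrence,
    composition_tables,
    haplotype_trait_summary,
    simulate_variety_panel,
    superior_haplotype,
)
from pyramidkit.haplotypes import validate_metadata


def write_vcf(path, samples, records):
    """records: list of (chrom, pos, ref, alt, [gt strings])."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


LOCUS = GeneLocus("LAX1", "chr1", 100, 400)


class TestCallHaplotypes:
    def test_single_shared_string(self, tmp_path):
        samples = [f"V{i}" for i in range(12)]
        write_vcf(tmp_path / "p.vcf", samples,
                  [("chr1", 150, "A", "G", ["0/0"] * 12),
                   ("chr1", 250, "C", "T", ["1/1"] * 12)])
        haps = call_haplotypes(tmp_path / "p.vcf", LOCUS, min_count=10)
        assert haps.retained == ["T1"]
        assert haps.counts["T1"] == 12
        assert haps.definitions["T1"] == "AT"

    def test_below_min_count_pooled_rare(self, tmp_path):
        samples = [f"V{i}" for i in range(9)]
        write_vcf(tmp_path / "p.vcf", samples,
                  [("chr1", 150, "A", "G", ["0/0"] * 9)])
        haps = call_haplotypes(tmp_path / "p.vcf", LOCUS, min_count=10)
        assert haps.retained == []
        assert haps.rare_count == 9
        assert (haps.assignments == "rare").all()

    def test_het_or_missing_unassigned(self, tmp_path):
        samples = ["V0", "V1", "V2"]
        write_vcf(tmp_path / "p.vcf", samples,
                  [("chr1", 150, "A", "G", ["0/0", "0/1", "./."])])
        haps = call_haplotypes(tmp_path / "p.vcf", LOCUS, min_count=1)
        assert sorted(haps.unassigned) == ["V1", "V2"]
        assert haps.assignments["V0"] == "T1"

    def test_no_inregion_snp_raises(self, tmp_path):
        write_vcf(tmp_path / "p.vcf", ["V0"], [("chr1", 999, "A", "G", ["0/0"])])
        with pytest.raises(LocusError):
            call_haplotypes(tmp_path / "p.vcf", LOCUS)

    def test_planted_frequencies_and_labels(self, tmp_path):
        cfg = PanelConfig(n_varieties=1000,
                          haplotype_freqs={"LAX1": [0.6, 0.3, 0.1]}, seed=21)
        sim = simulate_variety_panel(cfg, tmp_path / "p.vcf")
        haps = call_haplotypes(tmp_path / "p.vcf", sim.loci[0], min_count=10)
        # frequency-ranked labels must match the planted descending frequencies
        for label, key, p in (("T1", "H1", 0.6), ("T2", "H2", 0.3), ("T3", "H3", 0.1)):
            planted_n = int((sim.truth["LAX1"] == key).sum())
            assert haps.counts[label] == planted_n
            assert abs(planted_n - 1000 * p) < 3 * np.sqrt(1000 * p * (1 - p))

    def test_conservation(self, tmp_path):
        """Retained + rare + unassigned = panel size."""
        cfg = PanelConfig(n_varieties=500,
                          haplotype_freqs={"LAX1": [0.7, 0.28, 0.02]}, seed=22)
        sim = simulate_variety_panel(cfg, tmp_path / "p.vcf")
        # inject a heterozygous call for the first variety
        text = (tmp_path / "p.vcf").read_text().splitlines()
        body = text[-1].split("\t")
        body[9] = "0/1"
        text[-1] = "\t".join(body)
        (tmp_path / "p.vcf").write_text("\n".join(text) + "\n")
        haps = call_haplotypes(tmp_path / "p.vcf", sim.loci[0], min_count=30)
        total = int(haps.counts.sum()) + haps.rare_count + len(haps.unassigned)
        assert total == 500

    def test_label_order_invariant_to_sample_order(self, tmp_path):
        gts = ["0/0"] * 7 + ["1/1"] * 5
        samples = [f"V{i}" for i in range(12)]
        write_vcf(tmp_path / "a.vcf", samples, [("chr1", 150, "A", "G", gts)])
        write_vcf(tmp_path / "b.vcf", samples[::-1], [("chr1", 150, "A", "G", gts[::-1])])
        a = call_haplotypes(tmp_path / "a.vcf", LOCUS, min_count=1)
        b = call_haplotypes(tmp_path / "b.vcf", LOCUS, min_count=1)
        assert a.definitions == b.definitions
        pd.testing.assert_series_equal(a.assignments.sort_index(),
                                       b.assignments.sort_index())


class TestSummaries:
    def _panel(self, tmp_path, n=200, trait_sd=25.0, seed=30):
        cfg = PanelConfig(n_varieties=n,
                          haplotype_freqs={"LAX1": [0.55, 0.35, 0.1]},
                          haplotype_trait_means={"H1": 150.0, "H2": 110.0, "H3": 130.0},
                          trait_sd=trait_sd, seed=seed)
        sim = simulate_variety_panel(cfg, tmp_path / "p.vcf")
        haps = call_haplotypes(tmp_path / "p.vcf", sim.loci[0], min_count=10)
        return sim, haps

    def test_zero_sd_gives_exact_means(self, tmp_path):
        sim, haps = self._panel(tmp_path, trait_sd=0.0)
        summary = haplotype_trait_summary(haps, sim.metadata)
        assert summary.table.at["T1", "mean"] == pytest.approx(150.0)
        assert summary.table.at["T2", "mean"] == pytest.approx(110.0)

    def test_sd_missing_for_single_record(self, tmp_path):
        write_vcf(tmp_path / "p.vcf", ["V0", "V1"],
                  [("chr1", 150, "A", "G", ["0/0", "1/1"])])
        haps = call_haplotypes(tmp_path / "p.vcf", LOCUS, min_count=1)
        meta = pd.DataFrame({"gnpp": [123.0, 145.0]},
                            index=pd.Index(["V0", "V1"], name="variety_id"))
        summary = haplotype_trait_summary(haps, meta)
        assert (summary.table["n"] == 1).all()
        assert summary.table["sd"].isna().all()

    def test_means_match_groupby_oracle(self, tmp_path):
        sim, haps = self._panel(tmp_path)
        summary = haplotype_trait_summary(haps, sim.metadata)
        oracle = sim.metadata["gnpp"].groupby(haps.assignments).mean()
        for label in haps.retained:
            assert summary.table.at[label, "mean"] == pytest.approx(oracle[label])

    def test_superior_haplotype_simple_and_tie(self):
        from pyramidkit.haplotypes import HaplotypeSummary
        table = pd.DataFrame({"n": [50, 10], "mean": [120.0, 150.0], "sd": [5.0, 5.0]},
                             index=pd.Index(["T1", "T2"], name="haplotype"))
        assert superior_haplotype(HaplotypeSummary("g", "gnpp", table)) == "T2"
        tied = table.assign(mean=[150.0, 150.0])
        assert superior_haplotype(HaplotypeSummary("g", "gnpp", tied)) == "T1"

    def test_planted_superior_recovered(self, tmp_path):
        """The planted best haplotype is identified in >= 95% of panels
        (n=500, +20-grain edge, sd 25)."""
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            cfg = PanelConfig(
                n_varieties=500, haplotype_freqs={"LAX1": [0.5, 0.3, 0.2]},
                haplotype_trait_means={"H1": 130.0, "H2": 150.0, "H3": 130.0},
                trait_sd=25.0, seed=4000 + rep)
            sim = simulate_variety_panel(cfg, tmp_path / f"p{rep}.vcf")
            haps = call_haplotypes(tmp_path / f"p{rep}.vcf", sim.loci[0], min_count=10)
            summary = haplotype_trait_summary(haps, sim.metadata)
            # H2 is the second most frequent planted haplotype -> label T2
            hits += superior_haplotype(summary) == "T2"
        assert hits >= 0.95 * n_reps


class TestComposition:
    def test_single_subpopulation_column(self, tmp_path):
        write_vcf(tmp_path / "p.vcf", ["V0", "V1"],
                  [("chr1", 150, "A", "G", ["0/0", "0/0"])])
        haps = call_haplotypes(tmp_path / "p.vcf", LOCUS, min_count=1)
        meta = pd.DataFrame(
            {"subpopulation": ["Japonica", "Japonica"], "origin": ["China", "Japan"]},
            index=pd.Index(["V0", "V1"], name="variety_id"))
        sub, ori = composition_tables(haps, meta)
        assert sub.loc["T1", "Japonica"] == 2
        assert sub.drop(columns="Japonica").to_numpy().sum() == 0
        assert ori.loc["T1"].sum() == 2

    def test_row_sums_equal_counts(self, tmp_path):
        cfg = PanelConfig(n_varieties=300, haplotype_freqs={"LAX1": [0.6, 0.4]},
                          seed=31)
        sim = simulate_variety_panel(cfg, tmp_path / "p.vcf")
        haps = call_haplotypes(tmp_path / "p.vcf", sim.loci[0], min_count=10)
        sub, ori = composition_tables(haps, sim.metadata)
        for label in haps.retained:
            assert sub.loc[label].sum() == haps.counts[label]
            assert ori.loc[label].sum() == haps.counts[label]

    def test_planted_subpop_split_recovered(self, tmp_path):
        cfg = PanelConfig(
            n_varieties=500, haplotype_freqs={"LAX1": [1.0]},
            subpop_assignment={"H1": {"Japonica": 0.9, "Indica": 0.1}},
            seed=32)
        sim = simulate_variety_panel(cfg, tmp_path / "p.vcf")
        haps = call_haplotypes(tmp_path / "p.vcf", sim.loci[0], min_count=10)
        sub, _ = composition_tables(haps, sim.metadata)
        se = np.sqrt(500 * 0.9 * 0.1)
        assert abs(sub.loc["T1", "Japonica"] - 450) < 3 * se

    def test_unknown_subpopulation_rejected(self):
        meta = pd.DataFrame({"subpopulation": ["Wild"]},
                            index=pd.Index(["V0"], name="variety_id"))
        with pytest.raises(FormatError, match="Wild"):
            validate_metadata(meta)


class TestCoOccurrence:
    def test_disjoint_and_full(self):
        idx = pd.Index(["V0", "V1", "V2"], name="variety_id")
        a = pd.Series(["T1", "T2", "T1"], index=idx)
        b = pd.Series(["T2", "T1", "T2"], index=idx)
        _, n = co_occurrence(a, b, "T1", "T1")
        assert n == 0
        varieties, n = co_occurrence(a, b, "T1", "T2")
        assert n == 2 and varieties == ["V0", "V2"]

    def test_unknown_label_raises(self):
        idx = pd.Index(["V0"], name="variety_id")
        a = pd.Series(["T1"], index=idx)
        with pytest.raises(LabelError, match="T9"):
            co_occurrence(a, a, "T9", "T1")

    def test_planted_joint_frequency(self, tmp_path):
        cfg = PanelConfig(
            n_varieties=1000,
            haplotype_freqs={"LAX1": [0.9, 0.1], "GNP1": [0.9, 0.1]}, seed=33)
        sim = simulate_variety_panel(cfg, tmp_path / "p.vcf")
        a = call_haplotypes(tmp_path / "p.vcf", sim.loci[0], min_count=10)
        b = call_haplotypes(tmp_path / "p.vcf", sim.loci[1], min_count=10)
        # genes drawn independently: joint frequency 0.1 * 0.1 = 0.01
        _, n = co_occurrence(a, b, "T2", "T2")
        assert abs(n - 10) < 3 * np.sqrt(1000 * 0.01 * 0.99)

    def test_reference_high_gnpp_varieties(self):
        """The bundled table of high-grain-number varieties yields exactly
        22 carriers of LAX1-T2 together with GNP1-T1 (independent hand
        tally of the printed rows)."""
        ref = importlib.resources.files("pyramidkit.data") / "high_gnpp_varieties.tsv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#").set_index("variety")
        varieties, n = co_occurrence(df["LAX1"], df["GNP1"], "T2", "T1")
        assert n == 22
        assert "NingGeng28Hao" in varieties and "ZhongHan502" not in varieties
        validate_metadata(df)  # vocabulary of the bundled table is strict
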