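import filecmp
import math

import numpy as np
import pytest

from pirna_immunity import mapping as mp, pingpong as pp, quant as qt, simulate as sim


class TestSimulateGenome:
    def test_count_bookkeeping(self, tmp_path):
        ds = sim.simulate_genome(
            sim.PanelSpec(n_te=5), sim.ClusterSpec(n_dual=1, n_uni_germline=0, n_uni_somatic=0, n_genic=0), seed=7
        )
        assert len(ds.te_panel) == 5
        assert len(ds.clusters) == 1
        paths = ds.write(tmp_path / "out")
        from pirna_immunity.io import read_bed, read_fasta

        assert len(read_bed(paths["clusters"])) == 1
        assert len(read_fasta(paths["te_panel"])) == 5

    def test_determinism_byte_identical(self, tmp_path):
        for name in ("a", "b"):
            ds = sim.simulate_genome(sim.PanelSpec(), sim.ClusterSpec(), seed=7)
            strain = sim.StrainModel("s1")
            sim.simulate_small_rna_library(ds, strain, "ovary", 2000, seed=7)
            sim.simulate_dnaseq(ds, strain, 500, seed=7)
            ds.write(tmp_path / name)
        compare = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not compare.diff_files and not compare.left_only and not compare.right_only

    def test_all_zero_cluster_spec(self):
        ds = sim.simulate_genome(
            sim.PanelSpec(),
            sim.ClusterSpec(n_dual=0, n_uni_germline=0, n_uni_somatic=0, n_genic=0),
            seed=3,
        )
        assert ds.clusters == []
        # no clusters -> no primary source -> ancestral element gets no reads
        lib = sim.simulate_small_rna_library(ds, sim.StrainModel("s"), "ovary", 5000, seed=3)
        alignments = mp.map_to_canonical(lib.reads, ds.te_panel, 3)
        counts = qt.te_read_counts(alignments, (24, 29))
        assert counts.get(sim.ANCESTRAL_TE, 0.0) == 0.0

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            sim.simulate_genome(sim.PanelSpec(), sim.ClusterSpec(), seed=None)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sim.PanelSpec(n_te=0)
        with pytest.raises(ValueError):
            sim.PanelSpec(te_length=50)
        with pytest.raises(ValueError):
            sim.ClusterSpec(n_dual=-1)

    def test_ancestral_element_structure(self, small_dataset):
        ds = small_dataset
        ancestral = ds.te(sim.ANCESTRAL_TE)
        assert not ancestral.active
        dual_tes = {
            f.te_id for c in ds.clusters if c.cluster_type == "dual" for f in c.fragments
        }
        assert sim.ANCESTRAL_TE in dual_tes
        somatic_ids = {te.id for te in ds.te_panel if te.deposition_class == "somatic"}
        for cluster in ds.clusters:
            frag_ids = {f.te_id for f in cluster.fragments}
            if cluster.cluster_type == "uni_somatic":
                assert frag_ids <= somatic_ids
            else:
                assert not (frag_ids & somatic_ids)

    def test_fragment_lengths_within_bounds(self, small_dataset):
        for cluster in small_dataset.clusters:
            for frag in cluster.fragments:
                te = small_dataset.te(frag.te_id)
                frac = (frag.end - frag.start) / te.length
                assert 0.29 <= frac <= 0.81

    def test_fragments_are_genuine_substrings(self, small_dataset):
        from pirna_immunity._seq import revcomp

        genome = small_dataset.genome[sim.CHROM]
        for cluster in small_dataset.clusters:
            for frag in cluster.fragments:
                te = small_dataset.te(frag.te_id)
                genomic = genome[frag.start : frag.end]
                canonical = te.sequence[frag.te_start : frag.te_end]
                assert genomic == (canonical if frag.orientation == "+" else revcomp(canonical))


class TestStrainModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            sim.StrainModel("x", primary_efficiency=0)
        with pytest.raises(ValueError):
            sim.StrainModel("x", pingpong_gain=-1)
        with pytest.raises(ValueError):
            sim.StrainModel("x", maternal_transmission=1.5)
        with pytest.raises(ValueError):
            sim.StrainModel("x", reactivity_slope=-0.1)
        with pytest.raises(ValueError):
            sim.StrainModel("x", te_copy_numbers={"te": -2})

    def test_unknown_te_rejected_at_use(self, small_dataset):
        strain = sim.StrainModel("x", te_copy_numbers={"made-up": 3})
        with pytest.raises(ValueError):
            sim.simulate_small_rna_library(small_dataset, strain, "ovary", 100, seed=1)
        with pytest.raises(ValueError):
            sim.simulate_dnaseq(small_dataset, strain, 100, seed=1)


class TestSmallRnaLibrary:
    def test_tissue_validated(self, small_dataset):
        with pytest.raises(ValueError):
            sim.simulate_small_rna_library(
                small_dataset, sim.StrainModel("s"), "larva", 100, seed=1
            )

    def test_rate_recovery_within_three_se(self, small_dataset):
        n = 100_000
        strain = sim.StrainModel("s", primary_efficiency=1.0, pingpong_gain=1.0)
        lib = sim.simulate_small_rna_library(small_dataset, strain, "ovary", n, seed=5)
        alignments = mp.map_to_canonical(lib.reads, small_dataset.te_panel, 3)
        observed = qt.te_read_counts(alignments, (24, 29))
        truth = small_dataset.truth_rates[("s", "ovary")]
        for te_id, row in truth.iterrows():
            rate = row["rate"]
            se = math.sqrt(rate * (1 - rate) * n)
            got = observed.get(te_id, 0.0)
            # 3 SE plus a 5% slack for fragment edge effects
            assert abs(got - rate * n) <= 3 * se + 0.05 * rate * n, te_id

    def test_epsilon_ratio_five_log2(self, small_dataset):
        n = 100_000
        rpm = {}
        for name, eps in (("weak", 5.0), ("strong", 1.0)):
            strain = sim.StrainModel(name, primary_efficiency=eps, pingpong_gain=0.0)
            lib = sim.simulate_small_rna_library(small_dataset, strain, "ovary", n, seed=17)
            alignments = mp.map_to_canonical(lib.reads, small_dataset.te_panel, 3)
            counts = qt.te_read_counts(alignments, (24, 29))
            rpm[name] = counts[sim.ANCESTRAL_TE] / lib.depth * 1e6
        log2_ratio = math.log2(rpm["weak"] / rpm["strong"])
        assert abs(log2_ratio - math.log2(5)) <= 0.3

    def test_maternal_zero_embryo_is_background_only(self, small_dataset):
        strain = sim.StrainModel("s", maternal_transmission=0.0)
        lib = sim.simulate_small_rna_library(
            small_dataset, strain, "embryo_0_2h", 5000, seed=9
        )
        alignments = mp.map_to_canonical(lib.reads, small_dataset.te_panel, 3)
        counts = qt.te_read_counts(alignments, (24, 29))
        assert counts.sum() == 0.0
        truth = small_dataset.truth_rates[("s", "embryo_0_2h")]
        assert (truth["rate"] == 0).all()

    def test_maternal_transmission_scales_rpm(self, small_dataset):
        n = 60_000
        strain = sim.StrainModel("mt", maternal_transmission=0.25, pingpong_gain=0.0)
        out = {}
        for tissue in ("ovary", "embryo_0_2h"):
            lib = sim.simulate_small_rna_library(small_dataset, strain, tissue, n, seed=21)
            alignments = mp.map_to_canonical(lib.reads, small_dataset.te_panel, 3)
            counts = qt.te_read_counts(alignments, (24, 29))
            out[tissue] = counts.reindex(small_dataset.te_ids, fill_value=0.0) / n
        total_ov = out["ovary"].sum()
        total_em = out["embryo_0_2h"].sum()
        assert total_em / total_ov == pytest.approx(0.25, rel=0.1)

    def test_forced_u_bias_is_exact(self, small_dataset):
        cfg = sim.LibraryConfig(p1u=1.0, error_rate=0.0)
        strain = sim.StrainModel("u", pingpong_gain=0.0)
        lib = sim.simulate_small_rna_library(
            small_dataset, strain, "ovary", 20_000, seed=13, config=cfg
        )
        alignments = mp.map_to_canonical(lib.reads, small_dataset.te_panel, 3)
        reads = {r.id: r.sequence for r in lib.reads}
        bias = qt.u1_bias(alignments, reads)
        assert bias["+"] == 1.0

    def test_pingpong_injection(self, small_dataset):
        for gamma, check in ((0.0, lambda z: abs(z) < 3), (1.5, lambda z: z > 3)):
            strain = sim.StrainModel("g", pingpong_gain=gamma)
            lib = sim.simulate_small_rna_library(small_dataset, strain, "ovary", 15_000, seed=29)
            alignments = mp.map_to_canonical(lib.reads, small_dataset.te_panel, 3)
            table = pp.pingpong_table(alignments)
            active = [te.id for te in small_dataset.te_panel if te.active]
            for te_id in active:
                z10 = table.set_index("te_id").loc[te_id, "z10"]
                assert check(z10), (gamma, te_id, z10)

    def test_library_determinism(self, small_dataset):
        strain = sim.StrainModel("d")
        lib1 = sim.simulate_small_rna_library(small_dataset, strain, "ovary", 1000, seed=4)
        lib2 = sim.simulate_small_rna_library(small_dataset, strain, "ovary", 1000, seed=4)
        assert [r.sequence for r in lib1.reads] == [r.sequence for r in lib2.reads]


class TestDnaSeq:
    def test_copy_ratio_two(self):
        # fragment-free genome so copies are the only mappable source
        ds = sim.simulate_genome(
            sim.PanelSpec(n_te=3, te_length=600, n_somatic=0),
            sim.ClusterSpec(n_dual=0, n_uni_germline=0, n_uni_somatic=0, n_genic=0),
            seed=12,
            tail_length=60_000,  # copies must stay small next to the genome
        )
        te_id = "TE_g1"
        rpm = {}
        for name, cn in (("cnA", 4), ("cnB", 2)):
            strain = sim.StrainModel(name, te_copy_numbers={te_id: cn})
            reads = sim.simulate_dnaseq(ds, strain, 40_000, seed=6)
            alignments = mp.map_to_canonical(reads, ds.te_panel, 3)
            counts = qt.te_read_counts(alignments)
            rpm[name] = counts[te_id] / len(reads) * 1e6
        assert rpm["cnA"] / rpm["cnB"] == pytest.approx(2.0, rel=0.15)

    def test_observed_matches_truth_expectation(self, small_dataset):
        strain = sim.StrainModel("truthy", te_copy_numbers={"TE_g1": 3})
        reads = sim.simulate_dnaseq(small_dataset, strain, 30_000, seed=14)
        alignments = mp.map_to_canonical(reads, small_dataset.te_panel, 3)
        counts = qt.te_read_counts(alignments)
        truth = small_dataset.truth_dna["truthy"]
        for te_id, row in truth.iterrows():
            expected = row["rate"] * len(reads)
            se = (row["rate"] * (1 - row["rate"]) * len(reads)) ** 0.5
            got = counts.get(te_id, 0.0)
            assert abs(got - expected) <= 3 * se + 0.05 * expected, te_id

    def test_zero_copy_te_without_fragments_unmapped(self):
        # somatic element with no somatic cluster and no copies: nothing maps
        ds = sim.simulate_genome(
            sim.PanelSpec(n_te=3, n_somatic=1),
            sim.ClusterSpec(n_dual=1, n_uni_germline=0, n_uni_somatic=0, n_genic=0),
            seed=8,
        )
        reads = sim.simulate_dnaseq(ds, sim.StrainModel("z"), 5000, seed=8, error_rate=0.0)
        alignments = mp.map_to_canonical(reads, ds.te_panel, 0)
        counts = qt.te_read_counts(alignments)
        assert counts.get("TE_s1", 0.0) == 0.0

    def test_determinism(self, small_dataset):
        strain = sim.StrainModel("d2", te_copy_numbers={"TE_g1": 2})
        r1 = sim.simulate_dnaseq(small_dataset, strain, 1000, seed=2)
        r2 = sim.simulate_dnaseq(small_dataset, strain, 1000, seed=2)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]

    def test_short_read_len_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            sim.simulate_dnaseq(small_dataset, sim.StrainModel("x"), 100, read_len=20, seed=1)

    def test_truth_tracks_copy_number(self, small_dataset):
        strain = sim.StrainModel("t", te_copy_numbers={"TE_g1": 3, "TE_g2": 0})
        sim.simulate_dnaseq(small_dataset, strain, 1000, seed=3)
        truth = small_dataset.truth_dna["t"]
        assert truth.loc["TE_g1", "rate"] > truth.loc["TE_g2", "rate"]


class TestReactivity:
    def test_zero_rpm_full_reactivity(self):
        strain = sim.StrainModel("r", reactivity_noise_sd=0.0)
        res = sim.simulate_reactivity(strain, 0.0, seed=1)
        assert res.percent == pytest.approx(100.0)

    def test_large_slope_zero(self):
        strain = sim.StrainModel("r", reactivity_slope=100.0, reactivity_noise_sd=0.0)
        res = sim.simulate_reactivity(strain, 10.0, seed=1)
        assert res.percent == pytest.approx(0.0)

    def test_monotone_panel_gives_rho_minus_one(self):
        from pirna_immunity import stats as st

        rpms = [10.0, 50.0, 200.0, 1000.0, 4000.0]
        percents = []
        for i, rpm in enumerate(rpms):
            strain = sim.StrainModel(
                f"s{i}", reactivity_slope=0.001, reactivity_noise_sd=0.0
            )
            percents.append(sim.simulate_reactivity(strain, rpm, seed=1).percent)
        res = st.correlate_reactivity(rpms, percents)
        assert res.rho == pytest.approx(-1.0)

    def test_negative_rpm_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_reactivity(sim.StrainModel("r"), -1.0, seed=1)

    def test_three_replicates_returned(self):
        res = sim.simulate_reactivity(sim.StrainModel("r"), 100.0, seed=2)
        assert len(res.replicates) == 3 and res.n == 300
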