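import numpy as np
import pytest

from capmap.cgi_annotation import classify_cgi
from capmap.cpg_metrics import cpg_stats
from capmap.intervals import GenomeInterval
from capmap.scenarios import write_fixture_bundle
from capmap.simulate import (
    AssayParams,
    TruthRecord,
    assign_methylation,
    gen_background_genome,
    gen_gene_models,
    markov_sequence,
    plant_islands,
    simulate_cap_stringency_pair,
    simulate_track,
)


class TestBackgroundGenome:
    def test_deterministic_per_seed(self):
        a = gen_background_genome(20_000, rng=7)
        b = gen_background_genome(20_000, rng=7)
        assert a == b
        assert a != gen_background_genome(20_000, rng=8)

    def test_composition_targets(self):
        g = gen_background_genome(1_000_000, rng=3)["chr1"]
        st = cpg_stats(g)
        assert 0.18 <= st.oe <= 0.24
        assert abs((st.n_c + st.n_g) / st.length - 0.40) < 0.01

    def test_independence_limit(self, rng):
        st = cpg_stats(markov_sequence(200_000, 0.5, 1.0, rng))
        assert st.oe == pytest.approx(1.0, abs=0.05)

    def test_infeasible_combination_rejected(self, rng):
        with pytest.raises(ValueError, match="infeasible"):
            markov_sequence(100, 0.99, 5.0, rng)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            gen_background_genome(100)


@pytest.fixture(scope="module")
def small_planted():
    rng = np.random.default_rng(11)
    genome = gen_background_genome(300_000, rng=rng)
    genes = gen_gene_models({"chr1": 300_000}, 12, rng, min_len=8_000, max_len=15_000)
    genome, truth = plant_islands(genome, 20, rng, genes)
    return genome, genes, truth


class TestPlantIslands:
    def test_zero_islands_leaves_genome_unchanged(self, rng):
        genome = gen_background_genome(20_000, rng=4)
        planted, truth = plant_islands(genome, 0, rng)
        assert planted == genome and truth == []

    def test_truth_classes_reproduced_by_classifier(self, small_planted):
        genome, genes, truth = small_planted
        for rec in truth:
            assert classify_cgi(rec.interval, genes) == rec.cgi_class

    def test_realised_island_oe_near_target(self, small_planted):
        genome, _, truth = small_planted
        for rec in truth:
            seq = genome[rec.interval.chrom][rec.interval.start : rec.interval.end]
            assert cpg_stats(seq).oe == pytest.approx(rec.target_oe, abs=0.15)

    def test_islands_separated(self, small_planted):
        _, _, truth = small_planted
        ivs = sorted((r.interval for r in truth), key=lambda v: v.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.distance(b) >= 2000

    def test_class_mix_respected(self, small_planted):
        _, _, truth = small_planted
        counts = {c: sum(r.cgi_class == c for r in truth) for c in ("ATSS", "Intragenic", "Intergenic")}
        assert counts == {"ATSS": 10, "Intragenic": 5, "Intergenic": 5}


class TestAssignMethylation:
    def make_truth(self, n, cls="Intragenic"):
        return [
            TruthRecord(GenomeInterval("c", i * 3000, i * 3000 + 1000, name=f"cgi{i}"),
                        0.8, 8.0, cls)
            for i in range(n)
        ]

    def test_rate_extremes(self, rng):
        truth = self.make_truth(50)
        assign_methylation(truth, ("sperm", "blood"), rng, class_rates={"Intragenic": 0.0})
        assert not any(r.meth["blood"] for r in truth)
        assign_methylation(truth, ("sperm", "blood"), rng, class_rates={"Intragenic": 1.0})
        assert all(r.meth["blood"] for r in truth)

    def test_germline_always_unmethylated(self, rng):
        truth = self.make_truth(200)
        assign_methylation(truth, ("sperm", "blood"), rng, class_rates={"Intragenic": 1.0})
        assert not any(r.meth["sperm"] for r in truth)

    def test_realised_rates_within_three_se(self, rng):
        for cls, rate in (("ATSS", 0.03), ("Intragenic", 0.24), ("Intergenic", 0.14)):
            truth = self.make_truth(1000, cls)
            assign_methylation(truth, ("sperm", "blood"), rng)
            realised = np.mean([r.meth["blood"] for r in truth])
            se = np.sqrt(rate * (1 - rate) / 1000)
            assert abs(realised - rate) <= 3 * se

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_methylation(self.make_truth(1), ("sperm", "b"), rng,
                               class_rates={"Intragenic": 1.5})

    def test_duplicate_tissue_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_methylation(self.make_truth(1), ("b", "b"), rng)


class TestSimulateTrack:
    def island_fixture(self, rng, meth):
        genome = gen_background_genome(60_000, rng=rng)
        genome, truth = plant_islands(genome, 3, rng, (), class_mix=(0, 0, 1), min_gap=5000)
        for rec in truth:
            rec.meth["t"] = meth
            rec.active["t"] = not meth
        return genome, truth

    def test_zero_depth_all_zero(self, rng):
        genome, truth = self.island_fixture(rng, meth=False)
        p = AssayParams("CAP", mean_depth=0.0, background_depth=0.0)
        assert simulate_track(genome, truth, p, "t", rng).total() == 0

    def test_cap_enriches_unmethylated_islands(self, rng):
        genome, truth = self.island_fixture(rng, meth=False)
        track = simulate_track(genome, truth, AssayParams("CAP", cap_stringency_mid=3.5),
                               "t", rng)
        island_mean = np.mean([track.slice(r.interval).mean() for r in truth])
        genome_mean = track.data["chr1"].mean()
        assert island_mean > 5 * genome_mean

    def test_map_ignores_unmethylated_islands(self, rng):
        genome, truth = self.island_fixture(rng, meth=False)
        track = simulate_track(genome, truth, AssayParams("MAP"), "t", rng)
        island_mean = np.mean([track.slice(r.interval).mean() for r in truth])
        assert island_mean < track.data["chr1"].mean()

    def test_map_enriches_methylated_islands(self, rng):
        genome, truth = self.island_fixture(rng, meth=True)
        track = simulate_track(genome, truth, AssayParams("MAP"), "t", rng)
        island_mean = np.mean([track.slice(r.interval).mean() for r in truth])
        assert island_mean > 5 * track.data["chr1"].mean()

    def test_stringency_pair_pointwise_nested(self, rng):
        genome, truth = self.island_fixture(rng, meth=False)
        low, high = simulate_cap_stringency_pair(
            genome, truth,
            AssayParams("CAP", cap_stringency_mid=3.5),
            AssayParams("CAP", cap_stringency_mid=5.0),
            "t", rng,
        )
        assert np.all(high.data["chr1"] <= low.data["chr1"])

    def test_rnapii_marks_active_islands_only(self, rng):
        genome, truth = self.island_fixture(rng, meth=False)
        truth[0].active["t"] = False
        track = simulate_track(genome, truth, AssayParams("RNAPII", background_depth=0.0),
                               "t", rng)
        assert track.slice(truth[0].interval).mean() < 0.5
        assert track.slice(truth[1].interval).mean() > 2


class TestFixtureBundle:
    def test_deterministic_checksums_and_refusal(self, tmp_path):
        kwargs = dict(scenario="x_inactivation", seed=5, genome_length=40_000,
                      n_islands=4, n_female_methylated=2)
        m1 = write_fixture_bundle(tmp_path / "a", **kwargs)
        m2 = write_fixture_bundle(tmp_path / "b", **kwargs)
        assert m1["files"] == m2["files"]
        assert {"genome.fa", "truth.tsv", "manifest.json"} <= set(
            p.name for p in (tmp_path / "a").iterdir()
        )
        with pytest.raises(FileExistsError):
            write_fixture_bundle(tmp_path / "a", **kwargs)
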