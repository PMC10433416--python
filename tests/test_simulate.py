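import numpy as np
import pytest
from scipy.stats import binomtest

from cutregulon import enrichment, simulate
from cutregulon.errors import InvalidParameterError, PackingError
from cutregulon.model import SampleSpec


class TestMakeGenome:
    def test_parameter_echo(self):
        g = simulate.make_genome(1_000_000, seed=1)
        assert g.length == 1_000_000 and g.topology == "linear"

    @pytest.mark.parametrize("length", [3000, 9999])
    def test_too_short_rejected(self, length):
        with pytest.raises(InvalidParameterError):
            simulate.make_genome(length, seed=1)

    def test_deterministic(self):
        assert simulate.make_genome(10_000, 7) == simulate.make_genome(10_000, 7)


class TestPlantSites:
    def test_spacing_contract(self):
        g = simulate.make_genome(1_000_000, 1)
        sites = simulate.plant_sites(g, 10, strength=30, min_spacing=10_000, seed=3)
        pos = np.array([s.position for s in sites])
        assert len(sites) == 10
        assert (np.diff(np.sort(pos)) >= 10_000).all()

    def test_infeasible_packing(self):
        g = simulate.make_genome(10_000, 1)
        with pytest.raises(PackingError):
            simulate.plant_sites(g, 5, strength=30, min_spacing=5000, seed=1)

    def test_zero_sites(self):
        g = simulate.make_genome(1_000_000, 1)
        assert simulate.plant_sites(g, 0, 30, 10_000, seed=1) == []

    def test_reproducible(self):
        g = simulate.make_genome(500_000, 1)
        a = simulate.plant_sites(g, 5, 30, 10_000, seed=9)
        b = simulate.plant_sites(g, 5, 30, 10_000, seed=9)
        assert a == b


class TestSimulateSample:
    def test_read_count_conservation(self, sample_tag):
        g = simulate.make_genome(100_000, 1)
        sites = simulate.plant_sites(g, 3, 50, 10_000, seed=2)
        rs = simulate.simulate_sample(g, sites, sample_tag, background_depth=0.1)
        assert len(rs) == rs.n_background + sum(rs.n_site)

    def test_untagged_ignores_sites(self, sample_ctrl):
        g = simulate.make_genome(100_000, 1)
        sites = simulate.plant_sites(g, 5, 100, 5000, seed=2)
        with_sites = simulate.simulate_sample(g, sites, sample_ctrl, 0.1)
        without = simulate.simulate_sample(g, [], sample_ctrl, 0.1)
        assert np.array_equal(with_sites.starts, without.starts)
        assert np.array_equal(with_sites.ends, without.ends)
        assert np.array_equal(with_sites.strands, without.strands)

    def test_zero_depth_rejected(self, sample_tag):
        g = simulate.make_genome(100_000, 1)
        with pytest.raises(InvalidParameterError):
            simulate.simulate_sample(g, [], sample_tag, background_depth=0)

    def test_site_reads_concentrate_at_site(self):
        # one strength-100 site: ~95% of its fragments have midpoints within
        # +/-250 nt (2 midpoint-sd); background adds only ~5 there
        g = simulate.make_genome(100_000, 1)
        site = simulate.plant_sites(g, 1, 100, 1000, seed=4)[0]
        spec = SampleSpec("x", True, "DNAD", 1, seed=5)
        rs = simulate.simulate_sample(g, [site], spec, background_depth=0.01)
        mids = rs.midpoints
        near = np.sum((mids >= site.position - 250) & (mids <= site.position + 250))
        assert near >= 60

    def test_untagged_density_uniform_at_sites(self):
        # across 20 seeds, site windows of an untagged sample are binomially
        # consistent with the uniform background (alpha=0.01)
        L = 100_000
        g = simulate.make_genome(L, 1)
        sites = simulate.plant_sites(g, 10, 100, 5000, seed=6)
        rejections = 0
        for seed in range(20):
            spec = SampleSpec("wt", False, "DNAD", 1, seed=1000 + seed)
            rs = simulate.simulate_sample(g, sites, spec, background_depth=0.05)
            mids = rs.midpoints
            interior = mids[(mids >= 250) & (mids < L - 250)]
            in_windows = sum(
                int(np.sum((interior >= s.position - 250) & (interior < s.position + 251)))
                for s in sites
            )
            p = 10 * 501 / (L - 500)
            res = binomtest(in_windows, len(interior), p)
            rejections += res.pvalue < 0.01
        assert rejections <= 2

    def test_reads_sorted_and_clipped(self, sample_tag):
        g = simulate.make_genome(10_000, 1)
        sites = [simulate.PlantedSite(position=50, strength=200)]
        rs = simulate.simulate_sample(g, sites, sample_tag, 0.05)
        assert (np.diff(rs.starts) >= 0).all()
        assert rs.starts.min() >= 0 and rs.ends.max() <= g.length


class TestGeneModels:
    def test_divergent_pair_count(self):
        g = simulate.make_genome(100_000, 1)
        genes = simulate.make_gene_models(g, 20, divergent_fraction=0.2, seed=5)
        assert len(genes) == 20
        pairs = [
            (a, b) for a, b in zip(genes, genes[1:])
            if a.strand == "-" and b.strand == "+" and b.start > a.end
        ]
        assert len(pairs) == 2
        starts = np.array([g_.start for g_ in genes])
        ends = np.array([g_.end for g_ in genes])
        assert (starts[1:] >= ends[:-1]).all()  # no overlap

    def test_all_co_oriented_when_fraction_zero(self):
        g = simulate.make_genome(100_000, 1)
        genes = simulate.make_gene_models(g, 10, 0.0, seed=5)
        assert all(x.strand == "+" for x in genes)

    def test_gff3_round_trip(self, tmp_path):
        from cutregulon.annotate import read_gene_models

        g = simulate.make_genome(100_000, 1)
        genes = simulate.make_gene_models(g, 12, 0.5, seed=3)
        path = tmp_path / "genes.gff3"
        simulate.write_gene_models_gff3(genes, g, path)
        back = read_gene_models(path)
        assert [(x.gene_id, x.start, x.end, x.strand) for x in back] == \
            [(x.gene_id, x.start, x.end, x.strand) for x in genes]

    def test_packing_error(self):
        g = simulate.make_genome(10_000, 1)
        with pytest.raises(PackingError):
            simulate.make_gene_models(g, 50, 0.0, seed=1)


class TestWriters:
    def test_bed_round_trip(self, tmp_path, sample_tag):
        g = simulate.make_genome(50_000, 1)
        rs = simulate.simulate_sample(g, [], sample_tag, 0.01)
        p = tmp_path / "reads.bed"
        simulate.write_bed(rs, p)
        back = enrichment.read_alignments(p)
        assert np.array_equal(back.starts, rs.starts)
        assert np.array_equal(back.ends, rs.ends)
        assert np.array_equal(back.strands, rs.strands)

    def test_sam_round_trip(self, tmp_path, sample_tag):
        g = simulate.make_genome(50_000, 1)
        rs = simulate.simulate_sample(g, [], sample_tag, 0.01)
        p = tmp_path / "reads.sam"
        simulate.write_sam(rs, p, g)
        back = enrichment.read_alignments(p)
        assert np.array_equal(back.starts, rs.starts)
        assert np.array_equal(back.ends, rs.ends)

    def test_fixture_files_written(self, tmp_path):
        files = simulate.write_fixtures(tmp_path)
        assert sorted(f.name for f in files) == [
            "table5_act_bgc.tsv", "table6_core_regulon.tsv"
        ]
        assert all(f.stat().st_size > 100 for f in files)
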