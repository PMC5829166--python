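"""Forward simulator: determinism, tract tiling, end formation truth."""

import numpy as np
import pytest

import hydenseq as hq
from hydenseq.simulate import (
    LABELS,
    coverage_by_label,
    expected_strand_bias,
    make_genome_and_origins,
)


class TestMakeGenomeAndOrigins:
    def test_deterministic_under_seed(self, small_sim_config, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_genome_and_origins(small_sim_config, outdir=a)
        make_genome_and_origins(small_sim_config, outdir=b)
        assert (a / "genome.fa").read_bytes() == (b / "genome.fa").read_bytes()
        assert (a / "origins.bed").read_bytes() == (b / "origins.bed").read_bytes()

    def test_origin_spacing_and_alternating_strands(self):
        cfg = hq.SimConfig(seed=1, chromosome_length=200_000, n_origins_per_chromosome=4)
        _, origins = make_genome_and_origins(cfg)
        assert [o.anchor for o in origins] == [25_000, 75_000, 125_000, 175_000]
        assert [o.strand for o in origins] == ["+", "-", "+", "-"]

    def test_planted_site_count_matches_scanner(self, small_sim_config):
        genome, _ = make_genome_and_origins(small_sim_config)
        sites = hq.find_sbfi_sites(genome)
        assert len(sites) == small_sim_config.n_sbfi_sites_per_chromosome

    def test_written_fasta_round_trips_through_reader(self, small_sim_config, tmp_path):
        genome, _ = make_genome_and_origins(small_sim_config, outdir=tmp_path)
        back = hq.read_genome(tmp_path / "genome.fa")
        assert back.lengths == genome.lengths
        assert hq.find_sbfi_sites(back).sites == hq.find_sbfi_sites(genome).sites


class TestSimulateReplication:
    def test_tracts_tile_each_strand_exactly(self, small_sim_config):
        genome, origins = make_genome_and_origins(small_sim_config)
        ann = hq.simulate_replication(genome, origins, small_sim_config)
        for copy in ann.copies[:10]:
            for chrom, strands in copy.items():
                n = genome.lengths[chrom]
                for strand, tr in strands.items():
                    assert tr.start[0] == 0 and tr.end[-1] == n
                    assert np.all(tr.end[:-1] == tr.start[1:]), "gap or overlap"
                    assert np.all(tr.end > tr.start)

    def test_mirror_symmetric_tract_classes(self):
        """With deterministic priming/tracts the forward and reverse strand
        class layouts are mirror images through each origin axis."""
        cfg = hq.SimConfig(seed=3, chromosome_length=60_000,
                           n_origins_per_chromosome=1, n_cells=1,
                           alpha_start_sd=0.0, delta_tract_sd=0.0, okazaki_sd=0.0)
        genome, origins = make_genome_and_origins(cfg)
        ann = hq.simulate_replication(genome, origins, cfg)
        cov = coverage_by_label(ann)
        chrom = genome.chromosomes[0]
        a = origins.entries[0].anchor
        axis = a + cfg.symmetry_axis
        fwd, rev = cov[chrom]["fwd"], cov[chrom]["rev"]
        # leading epsilon coverage reflected around the axis lands on the
        # reverse strand's epsilon coverage (within a couple of bp of
        # integer rounding)
        i_eps = LABELS.index(("epsilon", "leading"))
        fwd_start = np.flatnonzero(fwd[i_eps])[0]
        rev_end = np.flatnonzero(rev[i_eps])[-1]
        assert abs((fwd_start - axis) + (rev_end - axis)) <= 3

    def test_model1_degenerate_tract_lengths(self):
        cfg = hq.SimConfig(seed=3, chromosome_length=60_000,
                           n_origins_per_chromosome=1, n_cells=5,
                           delta_tract_sd=0.0)
        genome, origins = make_genome_and_origins(cfg)
        ann = hq.simulate_replication(genome, origins, cfg)
        i_tract = 3  # class code origin-delta-tract
        for copy in ann.copies:
            for strands in copy.values():
                for tr in strands.values():
                    lengths = (tr.end - tr.start)[tr.cls == i_tract]
                    assert np.all(lengths == int(cfg.delta_tract_mean))

    def test_lagging_alpha_fraction_converges_to_primer_share(self, small_sim_config):
        genome, origins = make_genome_and_origins(small_sim_config)
        ann = hq.simulate_replication(genome, origins, small_sim_config)
        primer = body = 0
        for copy in ann.copies:
            for strands in copy.values():
                for tr in strands.values():
                    ln = tr.end - tr.start
                    primer += ln[tr.cls == 1].sum()  # lagging-primer
                    body += ln[tr.cls == 2].sum()  # lagging-body
        frac = primer / (primer + body)
        expected = small_sim_config.lagging_alpha_fraction
        assert frac == pytest.approx(expected, rel=0.05)

    def test_model2_plants_origin_delta_tract_without_leading_primer(self):
        cfg = hq.SimConfig(seed=3, chromosome_length=60_000,
                           n_origins_per_chromosome=1, n_cells=5, model="model2")
        genome, origins = make_genome_and_origins(cfg)
        ann = hq.simulate_replication(genome, origins, cfg)
        cov = coverage_by_label(ann)
        chrom = genome.chromosomes[0]
        i_tract = LABELS.index(("delta", "origin-delta-tract"))
        i_alead = LABELS.index(("alpha", "leading"))
        assert cov[chrom]["fwd"][i_tract].sum() > 0
        # delta tract (mean 160) displaces the 15 nt leading primer entirely
        assert cov[chrom]["fwd"][i_alead].sum() == 0


class TestIncorporateAndSample:
    def test_implied_shift_inverts_end_placement(self, small_sim_config):
        panel = hq.simulate_panel(small_sim_config, specs=[
            hq.SampleSpec(sample_id="s", variant_polymerase="pol3-L612M", rer="RER-"),
        ])
        sim = panel.samples["s"]
        shifted = hq.implied_rnmp_positions(sim.signal_track)
        expected = hq.StrandedEndTrack.zeros(panel.genome, semantics="implied-rnmp")
        for row in sim.truth.itertuples(index=False):
            arr = expected.counts[row.chrom][0 if row.strand == "+" else 1]
            arr[row.position] += row.count
        for chrom in panel.genome.chromosomes:
            n = panel.genome.lengths[chrom]
            # interior positions restore the planted coordinates exactly
            np.testing.assert_array_equal(
                shifted.counts[chrom][0][1:n - 1], expected.counts[chrom][0][1:n - 1]
            )
            np.testing.assert_array_equal(
                shifted.counts[chrom][1][1:n - 1], expected.counts[chrom][1][1:n - 1]
            )

    def test_depth_partition_and_determinism(self, small_sim_config):
        spec = hq.SampleSpec(sample_id="s", variant_polymerase="pol2-M644G", rer="RER-")
        genome, origins = make_genome_and_origins(small_sim_config)
        ann = hq.simulate_replication(genome, origins, small_sim_config)
        a = hq.incorporate_and_sample(ann, spec, small_sim_config)
        b = hq.incorporate_and_sample(ann, spec, small_sim_config)
        assert a.n_signal + a.n_background + a.n_sbfi == small_sim_config.depth
        assert a.track.total() <= small_sim_config.depth  # chromosome-end drops only
        np.testing.assert_array_equal(a.track.counts[genome.chromosomes[0]][0],
                                      b.track.counts[genome.chromosomes[0]][0])
        other = hq.incorporate_and_sample(
            ann, hq.SampleSpec(sample_id="t", variant_polymerase="pol2-M644G", rer="RER-"),
            small_sim_config,
        )
        assert not np.array_equal(a.track.counts[genome.chromosomes[0]][0],
                                  other.track.counts[genome.chromosomes[0]][0])

    def test_rer_plus_retains_fewer_signal_ends(self, small_sim_config):
        genome, origins = make_genome_and_origins(small_sim_config)
        ann = hq.simulate_replication(genome, origins, small_sim_config)
        minus = hq.incorporate_and_sample(
            ann, hq.SampleSpec(sample_id="m", variant_polymerase="pol3-L612M", rer="RER-"),
            small_sim_config)
        plus = hq.incorporate_and_sample(
            ann, hq.SampleSpec(sample_id="p", variant_polymerase="pol3-L612M", rer="RER+"),
            small_sim_config)
        # fixed sequencing depth: RER acts on the signal-to-background odds
        odds_ratio = (plus.n_signal / plus.n_background) / (
            minus.n_signal / minus.n_background
        )
        retention_ratio = (small_sim_config.rer_retention_plus
                           / small_sim_config.rer_retention_minus)
        assert odds_ratio == pytest.approx(retention_ratio, rel=0.2)

    def test_sampled_signal_matches_analytic_expectation(self, small_sim_config):
        """Total signal ends vs the closed-form weight partition (3 sigma)."""
        cfg = small_sim_config
        genome, origins = make_genome_and_origins(cfg)
        ann = hq.simulate_replication(genome, origins, cfg)
        cov = coverage_by_label(ann)
        spec = hq.SampleSpec(sample_id="s", variant_polymerase="pol3-L612M", rer="RER-")
        sim = hq.incorporate_and_sample(ann, spec, cfg, coverage=cov)
        rho = {p: cfg.rates.rho(p, p == "delta") * cfg.rate_scale
               for p in ("alpha", "delta", "epsilon")}
        w_sig = sum(
            cov[c][s][li].sum() * rho[pol]
            for c in genome.chromosomes for s in ("fwd", "rev")
            for li, (pol, _cls) in enumerate(LABELS)
        )
        w_bg = cfg.n_cells * cfg.background_rate * 2 * sum(genome.lengths.values())
        w_sbfi = cfg.sbfi_end_fraction / (1 - cfg.sbfi_end_fraction) * w_bg
        p_sig = w_sig / (w_sig + w_bg + w_sbfi)
        expect = cfg.depth * p_sig
        sd = np.sqrt(cfg.depth * p_sig * (1 - p_sig))
        assert abs(sim.n_signal - expect) < 3 * sd


class TestPanel:
    def test_write_panel_is_deterministic_and_readable(self, small_sim_config, tmp_path):
        panel = hq.simulate_panel(small_sim_config)
        out1, out2 = tmp_path / "p1", tmp_path / "p2"
        hq.write_panel(panel, out1)
        hq.write_panel(hq.simulate_panel(small_sim_config), out2)
        for name in ["genome.fa", "origins.bed", "samples.tsv"]:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        sheet = hq.read_sample_sheet(out1 / "samples.tsv")
        genome = hq.read_genome(out1 / "genome.fa")
        row = sheet.iloc[0]
        track = hq.read_end_track(out1 / row.fwd_path, out1 / row.rev_path, genome)
        orig = panel.samples[row.sample_id].track
        chrom = genome.chromosomes[0]
        np.testing.assert_array_equal(track.counts[chrom][0], orig.counts[chrom][0])

    def test_closed_form_bias_orders_genotypes(self):
        cfg = hq.SimConfig(seed=1)
        rb3 = expected_strand_bias(cfg, "pol3-L612M")
        rb1 = expected_strand_bias(cfg, "pol1-L868M")
        rb2 = expected_strand_bias(cfg, "pol2-M644G")
        assert rb3 > rb1 > 1.0 > rb2
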