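"""Synthetic genome / methylome / count / cohort generators."""

import numpy as np
import pytest

from methdual import simulate
from methdual.genome import GenomicInterval, window_frame
from methdual.simulate import (
    CohortConfig,
    DMRDesign,
    DepthConfig,
    GenomeConfig,
    LatentMethylome,
    default_state_map,
    generate_genome,
    plant_methylomes,
    simulate_chromhmm,
    simulate_counts,
    simulate_probe_cohort,
)


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        a = generate_genome(seed=1)
        b = generate_genome(seed=1)
        for chrom in a.chrom_sizes:
            assert np.array_equal(a.cpg_positions[chrom], b.cpg_positions[chrom])
            assert np.array_equal(a.mre_site_positions[chrom], b.mre_site_positions[chrom])
        assert a.cgis == b.cgis and a.te_catalog == b.te_catalog

    def test_cgi_cpg_density_at_least_3x_background(self, toy_genome):
        g = toy_genome
        for chrom, L in g.chrom_sizes.items():
            pos = g.cpg_positions[chrom]
            cgi_bp = sum(len(c) for c in g.cgis if c.chrom == chrom)
            in_cgi = 0
            for c in g.cgis:
                if c.chrom == chrom:
                    in_cgi += int(((pos >= c.start) & (pos < c.end)).sum())
            bg_density = (pos.size - in_cgi) / (L - cgi_bp)
            for c in g.cgis:
                if c.chrom != chrom:
                    continue
                dens = ((pos >= c.start) & (pos < c.end)).sum() / len(c)
                assert dens >= 3 * bg_density

    def test_promoters_are_1kb_around_tss(self, toy_genome):
        for p in toy_genome.promoters:
            assert len(p) == 1000
        tss = {(c, t) for c, t in toy_genome.tss_lists["protein_coding"]}
        for p in toy_genome.promoters:
            assert (p.chrom, p.start + 500) in tss

    def test_mre_sites_subset_of_cpgs(self, toy_genome):
        for chrom in toy_genome.chrom_sizes:
            cpg = set(toy_genome.cpg_positions[chrom].tolist())
            assert set(toy_genome.mre_site_positions[chrom].tolist()) <= cpg

    def test_annotations_within_chrom_bounds(self, toy_genome):
        for iv in toy_genome.cgis + toy_genome.promoters + \
                [t.interval for t in toy_genome.te_catalog]:
            assert 0 <= iv.start < iv.end <= toy_genome.chrom_sizes[iv.chrom]

    def test_infeasible_config_raises(self):
        cfg = GenomeConfig(chrom_length=30_000, n_cgis_per_chrom=200)
        with pytest.raises(ValueError):
            generate_genome(cfg, seed=0)


class TestPlantMethylomes:
    def test_no_planted_dmrs_means_tumor_equals_normal(self, toy_genome):
        design = DMRDesign(n_shared=0, n_eac=0, n_upsc=0, x_block_fraction=0.0,
                           sample_jitter_sd=0.0)
        latent, truth = plant_methylomes(toy_genome, design, seed=3)
        assert truth.planted == []
        for s in simulate.TUMOR_SAMPLES:
            assert np.allclose(latent.samples[s], latent.samples["NE"])

    def test_shared_hyper_raises_all_six_tumors_by_delta(self, toy_genome):
        design = DMRDesign(sample_jitter_sd=0.0)
        latent, truth = plant_methylomes(toy_genome, design, seed=3)
        ne = latent.samples["NE"]
        for p in truth.planted:
            if p.affected != "shared":
                continue
            expect = p.delta if p.direction == "hyper" else -p.delta
            for s in simulate.TUMOR_SAMPLES:
                assert latent.samples[s][p.window_index] - ne[p.window_index] == \
                    pytest.approx(expect, abs=1e-9)

    def test_truth_class_counts_match_design(self, planted):
        _, truth = planted
        d = truth.design
        assert len(truth.windows_of_class("shared")) == d.n_shared
        assert len(truth.windows_of_class("EAC")) == d.n_eac
        assert len(truth.windows_of_class("UPSC")) == d.n_upsc
        # planted windows are disjoint across classes
        assert len({p.window_index for p in truth.planted}) == len(truth.planted)

    def test_x_block_hypomethylates_upsc_only(self, toy_genome, planted):
        latent, truth = planted
        idx = toy_genome.frame.overlapping_indices(truth.x_block)
        ne = latent.samples["NE"][idx]
        for s in simulate.UPSC_SAMPLES:
            assert (latent.samples[s][idx] - ne).mean() < -0.1
        for s in simulate.EAC_SAMPLES:
            assert abs((latent.samples[s][idx] - ne).mean()) < 0.05
        assert len(truth.x_block) >= 0.5 * toy_genome.chrom_sizes[toy_genome.x_like]

    def test_directions_recoverable_by_subtraction(self, planted):
        latent, truth = planted
        ne = latent.samples["NE"]
        eac = latent.group_mean("EAC")
        upsc = latent.group_mean("UPSC")
        for p in truth.planted:
            diff = {"shared": (eac + upsc) / 2, "EAC": eac, "UPSC": upsc}[p.affected]
            delta = diff[p.window_index] - ne[p.window_index]
            assert (delta > 0.3) == (p.direction == "hyper")

    def test_h1_states_create_designed_offsets(self, toy_genome):
        design = DMRDesign(sample_jitter_sd=0.0)
        latent, truth = plant_methylomes(toy_genome, design, seed=3)
        ne, h1 = latent.samples["NE"], latent.samples["H1"]
        for p in truth.planted:
            d = h1[p.window_index] - ne[p.window_index]
            if p.h1_state == "same":
                assert d == pytest.approx(0, abs=1e-9)
            elif p.h1_state == "high":
                assert d >= 0.5
            else:
                assert d <= -0.5

    def test_cnv_factor_one_for_normal_and_h1(self, planted):
        latent, _ = planted
        assert np.all(latent.cnv["NE"] == 1)
        assert np.all(latent.cnv["H1"] == 1)
        assert all(np.all(latent.cnv[s] > 0) for s in simulate.TUMOR_SAMPLES)


class TestSimulateCounts:
    def _flat_latent(self, m_value, n=10_000):
        frame = window_frame({"c": n * 500}, 500)
        m = np.full(n, m_value)
        return LatentMethylome(frame, {"NE": m}, {"NE": np.ones(n)}, {"NE": "NE"})

    def _uniform_genome(self, frame, cpg_per_win=8, mre_per_win=2):
        class G:  # minimal duck-typed genome for count simulation
            chrom_sizes = frame.chrom_sizes

            def window_site_counts(self):
                n = len(frame)
                return np.full(n, cpg_per_win), np.full(n, mre_per_win)
        return G()

    def test_extreme_methylation_silences_one_assay(self):
        for m, assay in ((1.0, "mre"), (0.0, "medip")):
            latent = self._flat_latent(m, n=500)
            g = self._uniform_genome(latent.frame)
            tr = simulate_counts(latent, g, DepthConfig(), seed=0)["NE"]
            assert getattr(tr, assay).sum() == 0

    def test_poisson_mean_at_half_methylation(self):
        latent = self._flat_latent(0.5)
        g = self._uniform_genome(latent.frame)
        tr = simulate_counts(latent, g, DepthConfig(medip_depth=30), seed=1)["NE"]
        expected = 30 * 0.5  # density ratio is 1 for a uniform genome
        se = np.sqrt(expected / len(latent.frame))
        assert abs(tr.medip.mean() - expected) < 3 * se

    def test_zero_cpg_windows_get_zero_counts(self, toy_genome, planted):
        latent, _ = planted
        tr = simulate_counts(latent, toy_genome, seed=2)["EAC1"]
        zero = tr.cpg_count == 0
        assert zero.any()
        assert tr.medip[zero].sum() == 0 and tr.mre[zero].sum() == 0

    def test_negative_depth_rejected(self, toy_genome, planted):
        latent, _ = planted
        with pytest.raises(ValueError):
            simulate_counts(latent, toy_genome, DepthConfig(medip_depth=-1), seed=0)

    def test_deterministic(self, toy_genome, planted):
        latent, _ = planted
        a = simulate_counts(latent, toy_genome, seed=5)["UPSC2"]
        b = simulate_counts(latent, toy_genome, seed=5)["UPSC2"]
        assert np.array_equal(a.medip, b.medip) and np.array_equal(a.mre, b.mre)


class TestProbeCohort:
    def test_infinite_precision_reproduces_latent(self, toy_genome, planted):
        latent, truth = planted
        cfg = CohortConfig(n_normal=2, n_eac=2, n_upsc=2, precision=float("inf"),
                           zero_probe_fraction=0.0)
        bc = simulate_probe_cohort(latent, toy_genome, truth, cfg, seed=1)
        ne = latent.samples["NE"]
        sample = bc.samples_in_group("normal")[0]
        for _, row in bc.manifest.head(50).iterrows():
            w = latent.frame.window_of_position(row["chrom"], row["position"])
            assert bc.beta.loc[row["probe_id"], sample] == \
                pytest.approx(np.clip(ne[w], 1e-3, 1 - 1e-3))

    def test_cgi_bias_concentrates_probes(self, toy_genome, planted):
        latent, truth = planted
        cfg = CohortConfig(n_normal=1, n_eac=1, n_upsc=1, cgi_bias=3.0,
                           zero_probe_fraction=0.0, probes_per_kb=2.0)
        bc = simulate_probe_cohort(latent, toy_genome, truth, cfg, seed=2)
        from methdual.genome import intervals_to_window_indices
        low = intervals_to_window_indices(toy_genome.cgis + toy_genome.promoters,
                                          latent.frame)
        n_low = len(low)
        n_high = len(latent.frame) - n_low
        widx = np.array([latent.frame.window_of_position(r.chrom, r.position)
                         for r in bc.manifest.itertuples()])
        in_low = np.isin(widx, list(low)).sum()
        dens_ratio = (in_low / n_low) / ((len(widx) - in_low) / n_high)
        assert 2.0 < dens_ratio < 4.5

    def test_zero_probe_fraction_of_planted_windows(self, toy_genome, planted):
        latent, truth = planted
        cfg = CohortConfig(n_normal=1, n_eac=1, n_upsc=1, probes_per_kb=5.0,
                           zero_probe_fraction=0.3)
        bc = simulate_probe_cohort(latent, toy_genome, truth, cfg, seed=3)
        widx = {latent.frame.window_of_position(r.chrom, r.position)
                for r in bc.manifest.itertuples()}
        empty = sum(p.window_index not in widx for p in truth.planted)
        frac = empty / len(truth.planted)
        assert 0.25 <= frac <= 0.4  # at high probe density, misses ~= the blocked 30%

    def test_group_separation_at_planted_shared_window(self, toy_genome, planted):
        latent, truth = planted
        cfg = CohortConfig(probes_per_kb=5.0, zero_probe_fraction=0.0)
        bc = simulate_probe_cohort(latent, toy_genome, truth, cfg, seed=4)
        hyper = [p for p in truth.planted
                 if p.affected == "shared" and p.direction == "hyper"]
        checked = 0
        for p in hyper:
            probes = bc.manifest[
                (bc.manifest["chrom"] == p.interval.chrom)
                & (bc.manifest["position"] >= p.interval.start)
                & (bc.manifest["position"] < p.interval.end)]["probe_id"]
            if probes.empty:
                continue
            block = bc.beta.loc[probes]
            tumor = block[bc.samples_in_group("EAC-like")].mean().mean()
            normal = block[bc.samples_in_group("normal")].mean().mean()
            assert tumor > normal + 0.3
            checked += 1
        assert checked > 10

    def test_empty_group_rejected(self, toy_genome, planted):
        latent, truth = planted
        with pytest.raises(ValueError):
            simulate_probe_cohort(latent, toy_genome, truth,
                                  CohortConfig(n_normal=0), seed=0)


class TestChromHMM:
    def test_segments_tile_without_overlap(self, toy_genome):
        segs_by_line = simulate_chromhmm(toy_genome, seed=11)
        for segs in segs_by_line.values():
            for chrom, L in toy_genome.chrom_sizes.items():
                ivs = sorted((s.interval for s in segs if s.interval.chrom == chrom),
                             key=lambda i: i.start)
                assert ivs[0].start == 0 and ivs[-1].end == L
                for a, b in zip(ivs, ivs[1:]):
                    assert a.end == b.start

    def test_tss_windows_mostly_promoter_state_somewhere(self, toy_genome):
        segs_by_line = simulate_chromhmm(toy_genome, seed=11)
        from methdual.annotate import dominant_state
        hits = total = 0
        for chrom, tss in toy_genome.tss_lists["protein_coding"][:25]:
            win_start = (tss // 500) * 500
            w = GenomicInterval(chrom, win_start, win_start + 500)
            doms = [dominant_state(w, [s for s in segs if s.interval.chrom == chrom])
                    for segs in segs_by_line.values()]
            total += 1
            if "Tss" in doms:
                hits += 1
        assert hits / total > 0.5

    def test_deterministic_and_requires_two_lines(self, toy_genome):
        a = simulate_chromhmm(toy_genome, seed=5)
        b = simulate_chromhmm(toy_genome, seed=5)
        assert a == b
        with pytest.raises(ValueError):
            simulate_chromhmm(toy_genome, n_cell_lines=1, seed=5)

    def test_state_map_covers_vocabulary(self, toy_genome):
        segs_by_line = simulate_chromhmm(toy_genome, seed=5)
        smap = default_state_map()
        states = {s.state for segs in segs_by_line.values() for s in segs}
        assert states <= set(smap)
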