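import numpy as np
import pandas as pd
import pytest

import xeprof as xp
from xeprof.geography import FoldChangeTrack
from xeprof.simulate import CENTER_END, CENTER_START


def linear_annotation(n, chrom="chrX", spacing=1000):
    return xp.GeneAnnotation([
        xp.GeneModel(f"g{i:03d}", chrom, i * spacing, i * spacing + 500, 300)
        for i in range(n)])


def track_from(values, positions=None):
    n = len(values)
    entries = pd.DataFrame({
        "gene_id": [f"g{i:03d}" for i in range(n)],
        "position": positions if positions is not None else np.arange(n) * 1000,
        "log2fc": np.asarray(values, dtype=float)})
    return FoldChangeTrack("chrX", entries)


class TestFoldChangeTrack:
    def test_identical_to_baseline_median_gives_zero(self, rng):
        ann = linear_annotation(20)
        genes = [g.gene_id for g in ann.genes_on("chrX")]
        base = pd.DataFrame({f"b{j}": rng.uniform(5, 50, 20) for j in range(3)},
                            index=genes)
        test = base.median(axis=1)
        track = xp.fold_change_track(test, base, ann)
        np.testing.assert_allclose(track.entries["log2fc"], 0.0, atol=1e-12)

    def test_doubling_gives_about_one(self, rng):
        ann = linear_annotation(20)
        genes = [g.gene_id for g in ann.genes_on("chrX")]
        base = pd.DataFrame({"b": rng.uniform(10, 100, 20)}, index=genes)
        track = xp.fold_change_track(2 * base["b"], base, ann)
        np.testing.assert_allclose(track.entries["log2fc"], 1.0, atol=0.01)

    def test_matches_brute_force_on_random_genes(self, rng):
        ann = linear_annotation(300)
        genes = [g.gene_id for g in ann.genes_on("chrX")]
        base = pd.DataFrame({f"b{j}": rng.uniform(0, 40, 300) for j in range(5)},
                            index=genes)
        test = pd.Series(rng.uniform(0, 40, 300), index=genes)
        track = xp.fold_change_track(test, base, ann)
        got = track.values_by_gene()
        eps = 0.01
        for g in genes:
            med = float(np.median(base.loc[g]))
            if med > 1.0:
                assert got[g] == pytest.approx(
                    np.log2((test[g] + eps) / (med + eps)))
            else:
                assert g not in got.index

    def test_empty_baseline_is_error(self):
        ann = linear_annotation(5)
        test = pd.Series(1.0, index=[g.gene_id for g in ann.genes_on("chrX")])
        with pytest.raises(ValueError):
            xp.fold_change_track(test, test.to_frame().iloc[:, :0], ann)


class TestMovingAverage:
    def test_constant_signal_is_preserved(self):
        profile = xp.moving_average(track_from([3.5] * 80), window=50)
        assert len(profile) == 31
        np.testing.assert_allclose(profile.points["value"], 3.5)

    def test_window_one_is_identity(self, rng):
        values = rng.normal(size=30)
        profile = xp.moving_average(track_from(values), window=1)
        np.testing.assert_allclose(profile.points["value"], values)

    def test_matches_brute_force_windowed_mean(self, rng):
        values = rng.normal(size=200)
        positions = np.sort(rng.integers(0, 10**6, 200))
        profile = xp.moving_average(track_from(values, positions), window=50)
        assert len(profile) == 151
        for i in range(151):
            assert profile.points["value"][i] == pytest.approx(
                values[i:i + 50].mean())
            assert profile.points["center_position"][i] == pytest.approx(
                positions[i:i + 50].mean())

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError, match="window"):
            xp.moving_average(track_from([1.0] * 10), window=50)

    def test_shift_equivariance(self, rng):
        values = rng.normal(size=70)
        p1 = xp.moving_average(track_from(values), window=20)
        p2 = xp.moving_average(track_from(values + 2.5), window=20)
        np.testing.assert_allclose(p2.points["value"], p1.points["value"] + 2.5)


class TestGroupProfile:
    def test_single_sample_equals_its_own_profile(self, rng):
        values = rng.normal(size=60)
        track = track_from(values)
        grouped = xp.group_profile({"study1": [track]}, window=20)
        direct = xp.moving_average(track, window=20)
        pd.testing.assert_frame_equal(grouped.points, direct.points)

    def test_mirrored_studies_cancel(self, rng):
        values = rng.normal(size=60)
        grouped = xp.group_profile({"s1": [track_from(values)],
                                    "s2": [track_from(-values)]}, window=20)
        np.testing.assert_allclose(grouped.points["value"], 0.0, atol=1e-12)

    def test_matches_brute_force_nested_medians(self, rng):
        n = 80
        studies = {f"st{k}": [track_from(rng.normal(size=n))
                              for _ in range(int(rng.integers(1, 4)))]
                   for k in range(5)}
        grouped = xp.group_profile(studies, window=30)
        study_meds = np.array([
            np.median(np.stack([t.entries["log2fc"] for t in tracks]), axis=0)
            for tracks in studies.values()])
        group_med = np.median(study_meds, axis=0)
        expected = [group_med[i:i + 30].mean() for i in range(n - 30 + 1)]
        np.testing.assert_allclose(grouped.points["value"], expected)

    def test_invariant_to_sample_and_study_order(self, rng):
        tracks = [track_from(rng.normal(size=40)) for _ in range(4)]
        p1 = xp.group_profile({"a": tracks[:2], "b": tracks[2:]}, window=10)
        p2 = xp.group_profile({"b": tracks[2:][::-1], "a": tracks[:2][::-1]},
                              window=10)
        pd.testing.assert_frame_equal(p1.points, p2.points)


class TestRegionContrast:
    def test_uniform_values_give_zero_difference(self, rng):
        ann = linear_annotation(30)
        region = xp.RegionSpec("mid", "chrX", 10_000, 20_000)
        values = pd.DataFrame({"s1": [2.0] * 30, "s2": [2.0] * 30},
                              index=[g.gene_id for g in ann.genes_on("chrX")])
        result = xp.region_contrast(values, region, ann)
        assert result.region_mean == pytest.approx(result.chrom_mean)
        assert result.p_value == pytest.approx(1.0)

    def test_xq22_depletion_recovered_on_simulation(self, standard_cohort, standard_tpm):
        ann = standard_cohort.annotation
        region = xp.resolve_region("q22", standard_cohort.cytobands)
        meta = standard_tpm.meta
        filtered = xp.filter_genes(standard_tpm, "expressed_and_variable")
        columns = {}
        for study in ["A", "B"]:
            primed = [s for s in meta.index
                      if meta.loc[s, "state"] == "primed" and s.startswith(study)]
            for s in meta.index:
                if meta.loc[s, "state"] == "naive" and s.startswith(study):
                    track = xp.fold_change_track(
                        standard_tpm.values[s], standard_tpm.values[primed], ann,
                        gene_subset=filtered)
                    columns[s] = track.values_by_gene()
        values = pd.DataFrame(columns).dropna()
        result = xp.region_contrast(values, region, ann)
        assert result.region_mean < result.chrom_mean
        assert result.p_value < 0.05

    def test_xq22_biallelic_fraction_depleted_on_simulation(self, standard_cohort):
        region = xp.resolve_region("q22", standard_cohort.cytobands)
        snps = xp.filter_snps(standard_cohort.snps)
        ann = standard_cohort.annotation
        meta = standard_cohort.counts.meta
        xist_pos = [s for s, lvl in standard_cohort.truth["xist_level"].items()
                    if lvl > 1 and meta.loc[s, "state"] == "naive"]
        region_fr = [xp.biallelic_fraction(snps, ann, s, region) for s in xist_pos]
        chrom_fr = [xp.biallelic_fraction(snps, ann, s) for s in xist_pos]
        assert np.nanmean(region_fr) < np.nanmean(chrom_fr)


class TestProfileRecovery:
    def test_xist_pos_profile_minimum_inside_inactivated_center(self, standard_cohort,
                                                                standard_tpm):
        ann = standard_cohort.annotation
        meta = standard_tpm.meta
        filtered = xp.filter_genes(standard_tpm, "expressed_and_variable")
        by_study = {}
        for study in ["A", "B"]:
            primed = [s for s in meta.index
                      if meta.loc[s, "state"] == "primed" and s.startswith(study)]
            tracks = [xp.fold_change_track(standard_tpm.values[s],
                                           standard_tpm.values[primed], ann,
                                           gene_subset=filtered)
                      for s in meta.index
                      if meta.loc[s, "state"] == "naive" and s.startswith(study)]
            by_study[study] = tracks
        profile = xp.group_profile(by_study, window=50)
        min_pos, min_val = profile.minimum()
        assert CENTER_START <= min_pos < CENTER_END
        assert min_val < 0

    def test_primed_vs_male_tracks_simulated_erosion_dosage(self, small_cohort):
        tpm = xp.compute_tpm(small_cohort.counts, small_cohort.annotation)
        meta = tpm.meta
        primed = [s for s in meta.index if meta.loc[s, "state"] == "primed"]
        male = [s for s in meta.index if meta.loc[s, "sex"] == "male"]
        filtered = xp.filter_genes(tpm, "expressed_only")
        profile = xp.primed_vs_male_track(tpm.values[primed], tpm.values[male],
                                          small_cohort.annotation,
                                          gene_subset=filtered, window=50)
        # ground truth: primed X is uniformly eroded at dosage d_e over the
        # male single-X baseline, so the profile sits near log2(d_e) everywhere
        expected = np.log2(small_cohort.truth["config"].eroded_dosage)
        values = profile.points["value"].to_numpy()
        assert np.all(values > 0)
        assert np.median(values) == pytest.approx(expected, abs=0.1)
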