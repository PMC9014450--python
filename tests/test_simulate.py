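import math

import numpy as np
import pytest
from scipy import stats

from spothet import (
    ConfigurationError,
    SimConfig,
    make_reference,
    make_spot_counts,
    make_tissue,
)
from spothet.simulate import build_base_means
from spothet.spatial import neighbor_map

from conftest import small_sim_config


class TestSeededDeterminism:
    def test_reference_identical_across_runs(self):
        cfg = small_sim_config(seed=3)
        m1, l1 = make_reference(cfg)
        m2, l2 = make_reference(small_sim_config(seed=3))
        assert l1 == l2
        np.testing.assert_array_equal(m1.dense(), m2.dense())

    def test_tissue_and_counts_identical_across_runs(self):
        cfg = small_sim_config(seed=4)
        lat1, truth1 = make_tissue(cfg)
        lat2, truth2 = make_tissue(small_sim_config(seed=4))
        assert lat1.table.equals(lat2.table)
        c1 = make_spot_counts(lat1, truth1, cfg)
        c2 = make_spot_counts(lat2, truth2, cfg)
        np.testing.assert_array_equal(c1.dense(), c2.dense())

    def test_different_seeds_differ(self):
        m1, _ = make_reference(small_sim_config(seed=1))
        m2, _ = make_reference(small_sim_config(seed=2))
        assert not np.array_equal(m1.dense(), m2.dense())


class TestMakeReference:
    def test_sample_means_approach_base_means(self):
        # law of large numbers: near-Poisson limit, 1,000 cells of one type
        cfg = SimConfig(
            n_genes=80, cell_types={"A": {"Cortex": 1.0}},
            glomerulus_types={"A": 1.0}, macula_densa_type="A",
            n_cells_per_type=1000, nb_dispersion=1e-9, depth_cv=0.0, seed=5)
        counts, labels = make_reference(cfg)
        base = build_base_means(cfg)["A"].to_numpy()
        sample_mean = counts.dense().mean(axis=1)
        big = base > 20  # relative error bound is meaningful for expressed genes
        rel = np.abs(sample_mean[big] - base[big]) / base[big]
        assert rel.max() < 0.05

    def test_zero_cells_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="n_cells_per_type"):
            small_sim_config(n_cells_per_type=0)

    def test_labels_align_with_columns(self):
        cfg = small_sim_config(seed=0)
        counts, labels = make_reference(cfg)
        assert len(labels) == counts.n_samples
        assert set(labels) == set(cfg.type_names)


class TestMakeTissue:
    def test_zone_bands_partition_rows(self):
        cfg = small_sim_config(lattice_rows=40, lattice_cols=6, n_glomeruli=3)
        lattice, _ = make_tissue(cfg)
        one = lattice.table[lattice.table["sample_id"] == "Ctrl1"]
        zone_by_row = one.groupby("array_row")["zone"].unique()
        for r in range(40):
            (zone,) = zone_by_row[r]
            expected = ("Cortex", "OMOS", "OMIS", "IM")[r // 10]
            assert zone == expected

    def test_macula_densa_adjacent_to_glomerulus(self, small_dataset):
        cfg, _, _, lattice, truth, _ = small_dataset
        nbrs = neighbor_map(lattice)
        glom = set(lattice.glomerulus_spots()["spot_id"])
        for md in truth.macula_densa_spots:
            assert nbrs[md] & glom, f"macula densa spot {md} has no glomerulus neighbour"

    def test_planted_high_responder_count(self):
        cfg = small_sim_config(n_glomeruli=8, high_responder_frac=0.25,
                               lattice_rows=24, lattice_cols=14)
        _, truth = make_tissue(cfg)
        for sample, gids in truth.planted_high_responders.items():
            assert len(gids) == math.ceil(0.25 * 8) == 2

    def test_true_fraction_rows_sum_to_one(self, small_dataset):
        truth = small_dataset[4]
        sums = truth.true_fractions.to_frame().sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_too_many_glomeruli_rejected(self):
        with pytest.raises(ConfigurationError, match="n_glomeruli"):
            make_tissue(small_sim_config(n_glomeruli=200))


class TestMakeSpotCounts:
    def test_pure_spot_matches_type_profile(self):
        # a glomerulus profile of a single type reproduces that type's means
        cfg = small_sim_config(
            seed=9, glomerulus_types={"Podocyte": 1.0},
            nb_dispersion=1e-9, depth_cv=0.0,
            conditions={"Ctrl": 1}, n_glomeruli=8, lattice_rows=24,
            lattice_cols=20)
        lattice, truth = make_tissue(cfg)
        counts = make_spot_counts(lattice, truth, cfg)
        glom = list(lattice.glomerulus_spots()["spot_id"])
        observed = counts.subset_samples(glom).dense().mean(axis=1)
        base = truth.base_means["Podocyte"].to_numpy()
        big = base > 20
        rel = np.abs(observed[big] - base[big]) / base[big]
        assert np.median(rel) < 0.2

    def test_null_folds_leave_conditions_exchangeable(self):
        cfg = small_sim_config(seed=11, effect_ren_fold=1.0, effect_ptgs2_fold=1.0)
        lattice, truth = make_tissue(cfg)
        counts = make_spot_counts(lattice, truth, cfg)
        meta = lattice.table.set_index("spot_id")
        glom = lattice.glomerulus_spots()
        ren = counts.to_frame().loc["Ren"]
        losa = ren[glom[glom["condition"] == "Losa"]["spot_id"]]
        ctrl = ren[glom[glom["condition"] == "Ctrl"]["spot_id"]]
        _, p = stats.mannwhitneyu(losa, ctrl, alternative="two-sided")
        assert p > 0.01

    def test_planted_induction_detectable(self):
        # median Wilcoxon p over seeds, planted vs non-planted glomeruli
        pvals = []
        for seed in range(20):
            cfg = small_sim_config(
                seed=seed, n_glomeruli=8, lattice_rows=24, lattice_cols=20,
                conditions={"Losa": 3}, effect_ren_fold=5.0)
            lattice, truth = make_tissue(cfg)
            counts = make_spot_counts(lattice, truth, cfg)
            meta = lattice.table.set_index("spot_id")
            planted_g = truth.planted_glomerulus_ids()
            glom = lattice.glomerulus_spots()
            is_planted = glom["glomerulus_id"].isin(planted_g)
            ren = counts.to_frame().loc["Ren"]
            a = ren[glom[is_planted]["spot_id"]].to_numpy()
            b = ren[glom[~is_planted]["spot_id"]].to_numpy()
            _, p = stats.mannwhitneyu(a, b, alternative="greater")
            pvals.append(p)
        assert np.median(pvals) < 0.05

    def test_missing_truth_entries_rejected(self):
        cfg = small_sim_config(seed=1)
        lattice, truth = make_tissue(cfg)
        other_lattice, _ = make_tissue(small_sim_config(seed=1, lattice_rows=20))
        from spothet import ValidationError
        with pytest.raises(ValidationError, match="missing"):
            make_spot_counts(other_lattice, truth, cfg)
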