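"""Contact counting, normalisation, annulus, enrichment, leaflets."""

import numpy as np
import pytest

import lipidfp as L
from lipidfp.contacts import leaflet_assign
from lipidfp.core import STUDY_LIPIDS, build_composition
from lipidfp.synth import lipid_layout

from conftest import PLANTED_KEYS, brute_force_annulus, brute_force_contacts, toy_system


def random_small_system(rng, n_res=4, n_lip=6, n_frames=10, box=(25.0, 30.0, 28.0)):
    res = rng.uniform(0, 25, size=(n_res, 3))
    lip = rng.uniform(-10, 40, size=(n_frames, n_lip, 3))  # deliberately unwrapped
    species = rng.choice(["POPA", "POPG"], size=n_lip).tolist()
    return toy_system(res, lip, box=box, species=species)


class TestCountContacts:
    def test_beyond_cutoff_counts_nothing(self):
        model, traj = toy_system([[10.0, 10, 10]], [[[16.0, 10, 10]]])
        table = L.count_contacts(traj, model, cutoff=5.5)
        assert table.raw.sum() == 0

    def test_cg_vs_at_cutoff(self):
        """A lipid at 4.2 A counts at the coarse-grained cutoff (5.5 A)
        but not at the atomistic one (4.0 A)."""
        model, traj = toy_system([[10.0, 10, 10]], [[[14.2, 10, 10]]])
        assert L.count_contacts(traj, model, cutoff=5.5).raw.sum() == 1
        assert L.count_contacts(traj, model, cutoff=4.0).raw.sum() == 0

    def test_contact_through_periodic_boundary(self):
        model, traj = toy_system([[1.0, 10, 10]], [[[39.0, 10, 10]]],
                                 box=(40.0, 40.0, 40.0))
        # min-image distance is 2, not 38
        assert L.count_contacts(traj, model, cutoff=5.5).raw.sum() == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model, traj = random_small_system(rng)
        table = L.count_contacts(traj, model, cutoff=6.0)
        oracle = brute_force_contacts(traj, model, 6.0)
        for i, key in enumerate(table.residue_keys):
            for j, sp in enumerate(table.species):
                assert table.raw[i, j] == oracle.get((key, sp), 0)

    def test_translation_and_frame_order_invariance(self):
        rng = np.random.default_rng(5)
        model, traj = random_small_system(rng)
        raw0 = L.count_contacts(traj, model, 6.0).raw
        # rigid translation of everything
        shift = np.array([3.7, -11.2, 40.9])
        shifted_frames = np.stack(
            [f.coords + shift for f in traj.frames]
        )
        model2, traj2 = toy_system(
            model.bead_coords + shift, shifted_frames[:, model.n_beads:],
            box=tuple(traj.frames[0].box),
            species=list(traj.bead_table.species[model.n_beads:]),
        )
        assert np.array_equal(L.count_contacts(traj2, model2, 6.0).raw, raw0)
        # frame order shuffle
        perm = rng.permutation(len(traj))
        lip = np.stack([traj.frames[i].coords[model.n_beads:] for i in perm])
        model3, traj3 = toy_system(
            model.bead_coords, lip, box=tuple(traj.frames[0].box),
            species=list(traj.bead_table.species[model.n_beads:]),
        )
        assert np.array_equal(L.count_contacts(traj3, model3, 6.0).raw, raw0)

    def test_cutoff_beyond_minimum_image_rejected(self):
        model, traj = toy_system([[10.0, 10, 10]], [[[16.0, 10, 10]]],
                                 box=(20.0, 40.0, 40.0))
        with pytest.raises(ValueError, match="minimum-image"):
            L.count_contacts(traj, model, cutoff=10.0)


class TestNormalize:
    def test_stated_formula(self):
        """500 contacts over 12500 frames and 50 copies -> 8e-4."""
        model, traj = toy_system([[10.0, 10, 10]], [[[12.0, 10, 10]]])
        table = L.count_contacts(traj, model, 5.5)
        table.raw[0, 0] = 500
        table.meta["total_frames"] = 12_500
        comp = build_composition([(STUDY_LIPIDS["POPA"], 100.0)], 50)
        norm = L.normalize([table], comp)
        assert norm.normalized[0, 0] == pytest.approx(8.0e-4)

    def test_all_zero_raw(self):
        model, traj = toy_system([[10.0, 10, 10]], [[[30.0, 10, 10]]],
                                 box=(60, 60, 60))
        comp = build_composition([(STUDY_LIPIDS["POPA"], 100.0)], 10)
        norm = L.normalize([L.count_contacts(traj, model, 5.5)], comp)
        assert np.all(norm.normalized == 0.0)

    def test_replicates_equal_concatenation(self):
        rng = np.random.default_rng(7)
        res = rng.uniform(0, 25, size=(3, 3))
        lip = rng.uniform(0, 25, size=(20, 5, 3))
        model, whole = toy_system(res, lip)
        _, first = toy_system(res, lip[:12])
        _, second = toy_system(res, lip[12:])
        comp = build_composition([(STUDY_LIPIDS["POPA"], 100.0)], 5)
        via_replicates = L.normalize(
            [L.count_contacts(first, model, 6.0),
             L.count_contacts(second, model, 6.0)], comp,
        )
        via_concat = L.normalize([L.count_contacts(whole, model, 6.0)], comp)
        assert np.array_equal(via_replicates.raw, via_concat.raw)
        assert np.allclose(via_replicates.normalized, via_concat.normalized)

    def test_zero_copies_names_species(self):
        model, traj = toy_system([[10.0, 10, 10]], [[[12.0, 10, 10]]])
        comp = build_composition(
            [(STUDY_LIPIDS["POPA"], 0.0), (STUDY_LIPIDS["POPE"], 100.0)], 10
        )
        with pytest.raises(ValueError, match="POPA"):
            L.normalize([L.count_contacts(traj, model, 5.5)], comp)

    def test_normalized_bounded_by_one(self, wt_results):
        norm = wt_results[1].contact_table
        assert norm.normalized.min() >= 0.0
        assert norm.normalized.max() <= 1.0


class TestWindows:
    def test_identity_window(self):
        rng = np.random.default_rng(3)
        model, traj = random_small_system(rng, n_frames=12)
        t_end = float(traj.times[-1])
        (win,) = L.windowed_contacts(traj, model, 6.0, [(0.0, t_end)])
        assert np.array_equal(win.raw, L.count_contacts(traj, model, 6.0).raw)

    def test_disjoint_windows_are_additive(self):
        rng = np.random.default_rng(4)
        model, traj = random_small_system(rng, n_frames=12)
        times = traj.times
        mid = float(times[5])
        w1, w2 = L.windowed_contacts(
            traj, model, 6.0, [(0.0, mid), (mid + 1e-9, float(times[-1]))]
        )
        full = L.count_contacts(traj, model, 6.0)
        assert np.array_equal(w1.raw + w2.raw, full.raw)

    def test_empty_window_rejected(self):
        rng = np.random.default_rng(4)
        model, traj = random_small_system(rng)
        with pytest.raises(ValueError, match="no frames"):
            L.windowed_contacts(traj, model, 6.0, [(1e9, 2e9)])

    def test_half_vs_full_window_profiles_converged(self, wt_results):
        """On a stationary synthetic run the 0-T/2 and 0-T normalised
        fingerprints are essentially the same profile (Pearson > 0.95)."""
        r = wt_results[1]
        assert r.window_correlation is not None
        assert r.window_correlation > 0.95


class TestAnnulus:
    def test_no_lipids_in_reach(self):
        model, traj = toy_system([[10.0, 10, 10]], [[[40.0, 40, 40]]],
                                 box=(80, 80, 80))
        assert L.annulus_count(traj, model, 5.5).mean == 0.0

    def test_unique_molecule_counting(self):
        """Three lipids touch; one touches two residues but counts once."""
        res = [[10.0, 10, 10], [13.0, 10, 10]]
        lip = [[[11.5, 10, 10], [8.0, 10, 10], [16.0, 10, 10], [30.0, 30, 30]]]
        model, traj = toy_system(res, lip, box=(60, 60, 60))
        series = L.annulus_count(traj, model, 5.5)
        assert series.counts.tolist() == [3]

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        model, traj = random_small_system(rng)
        series = L.annulus_count(traj, model, 6.0)
        assert series.counts.tolist() == brute_force_annulus(traj, 6.0)


class TestFoldEnrichment:
    def _table(self, a, b):
        model, traj = toy_system(
            [[10.0, 10, 10]], [[[12.0, 10, 10], [12.0, 10, 10]]],
            species=["POPA", "POPG"],
        )
        table = L.count_contacts(traj, model, 5.5)
        table.normalized = np.array([[a, b]])
        ia = table.species.index("POPA")
        if ia != 0:
            table.normalized = table.normalized[:, ::-1]
        return table

    def test_simple_ratio(self):
        df, agg = L.fold_enrichment(self._table(0.0043, 0.0001), "POPA", "POPG")
        assert df["ratio"].iloc[0] == pytest.approx(43.0)
        assert agg == pytest.approx(43.0)

    def test_equal_profiles_give_unity(self):
        df, agg = L.fold_enrichment(self._table(0.002, 0.002), "POPA", "POPG")
        assert df["ratio"].iloc[0] == pytest.approx(1.0)
        assert agg == pytest.approx(1.0)

    def test_zero_denominator_flags(self):
        df, _ = L.fold_enrichment(self._table(0.01, 0.0), "POPA", "POPG")
        assert df["status"].iloc[0] == "unbounded"
        df, _ = L.fold_enrichment(self._table(0.0, 0.0), "POPA", "POPG")
        assert df["status"].iloc[0] == "undefined"

    def test_missing_species_raises(self):
        with pytest.raises(KeyError, match="POPS"):
            L.fold_enrichment(self._table(1e-3, 1e-3), "POPA", "POPS")


class TestLeafletAssign:
    def test_two_lipids_split_by_midplane(self):
        model, traj = toy_system([[10.0, 10, 30]],
                                 [[[10.0, 10, 10], [10.0, 10, 50]]],
                                 box=(60, 60, 60))
        labels = leaflet_assign(traj.frames[0], traj.bead_table)
        assert labels == {0: "cytoplasmic", 1: "luminal"}

    def test_all_equal_z_tie_rule(self):
        model, traj = toy_system([[10.0, 10, 30]],
                                 [[[10.0, 10, 20], [30.0, 10, 20]]],
                                 box=(60, 60, 60))
        labels = leaflet_assign(traj.frames[0], traj.bead_table)
        assert set(labels.values()) == {"cytoplasmic"}

    def test_recovers_generator_leaflets_exactly(self, wt_results):
        r = wt_results[1]
        traj = r.trajectories[0]
        layout = lipid_layout(r.config.synth)
        truth = {int(m): ("cytoplasmic" if leaf == "lower" else "luminal")
                 for m, leaf in zip(layout.mol_id, layout.leaflet)}
        for fi in (0, len(traj) // 2, len(traj) - 1):
            assert leaflet_assign(traj.frames[fi], traj.bead_table) == truth


class TestPlantedFingerprint:
    def test_planted_residues_beat_background_median(self, wt_results):
        """Every planted cationic residue shows more anionic contact than
        the median unplanted residue, in all replicate seeds."""
        for seed, r in wt_results.items():
            table = r.contact_table
            col = table.species_column("POPA", normalized=True)
            planted_rows = [i for i, k in enumerate(table.residue_keys)
                            if k in PLANTED_KEYS]
            background = [v for i, v in enumerate(col)
                          if table.residue_keys[i] not in PLANTED_KEYS]
            med = np.median(background)
            assert col[planted_rows].min() > med
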