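"""Reference-shape classification, average shapes and k-means clustering."""
import numpy as np
import pytest

import fruitmorph as fm
from fruitmorph.classify import default_side_library, default_top_library


@pytest.fixture(scope="module")
def library():
    return default_side_library()


class TestDefaultLibrary:
    def test_thirteen_mean_one_entries(self, library):
        assert len(library) == 13
        for entry in library.entries:
            assert entry.radius_profile.mean() == pytest.approx(1.0, abs=1e-9)

    def test_contains_standard_descriptor_names(self, library):
        names = library.names()
        for required in ("rectangular", "rectangular conical",
                         "flattened spherical"):
            assert required in names

    def test_classes_distinguishable(self, library):
        corr = np.corrcoef(library.matrix())
        off_diagonal = corr[~np.eye(13, dtype=bool)]
        assert off_diagonal.max() < 0.995


class TestClassify:
    def test_self_match(self, library):
        for entry in library.entries:
            result = fm.classify(entry.radius_profile, library)
            assert result.shape_class == entry.class_id
            assert result.corr == pytest.approx(1.0, abs=1e-9)
            assert result.corr == result.per_class_corr.max()

    def test_scale_invariance(self, library):
        entry = library.entries[5]
        result = fm.classify(entry.radius_profile * 2.0, library)
        assert result.shape_class == entry.class_id
        assert result.corr == pytest.approx(1.0, abs=1e-9)

    def test_noise_recovery(self, library):
        rng = np.random.default_rng(17)
        hits = total = 0
        for entry in library.entries:
            for _ in range(20):
                noisy = entry.radius_profile * (1 + 0.03 * rng.standard_normal(360))
                hits += fm.classify(noisy, library).shape_class == entry.class_id
                total += 1
        assert hits / total >= 0.95

    def test_constant_candidate_warns(self, library):
        with pytest.warns(UserWarning, match="zero-variance"):
            result = fm.classify(np.ones(360), library)
        assert -1.0 <= result.corr <= 1.0

    def test_top_library_self_match(self):
        top = default_top_library()
        for entry in top.entries:
            assert fm.classify(entry.radius_profile, top).shape_class == entry.class_id


class TestAverageShape:
    def test_identical_profiles_degenerate(self):
        profile = np.linspace(80, 120, 360)
        avg = fm.average_shape([profile] * 5)
        assert np.allclose(avg.mean_radius_deg, profile)
        assert np.allclose(avg.sd_radius_deg, 0, atol=1e-9)
        assert avg.n_fruit == 5

    def test_two_circles_closed_form(self):
        avg = fm.average_shape([np.full(360, 90.0), np.full(360, 110.0)])
        assert np.allclose(avg.mean_radius_deg, 100.0)
        # sample SD of {90, 110} is sqrt(200) = 10*sqrt(2)
        assert np.allclose(avg.sd_radius_deg, 10 * np.sqrt(2))

    def test_single_profile_sd_zero(self):
        avg = fm.average_shape([np.full(360, 95.0)])
        assert avg.n_fruit == 1
        assert np.all(avg.sd_radius_deg == 0)

    def test_mean_of_means_linearity(self):
        rng = np.random.default_rng(2)
        profiles = [50 + 10 * rng.random(360) for _ in range(7)]
        avg = fm.average_shape(profiles)
        assert avg.mean_radius_deg.mean() == pytest.approx(
            np.mean([p.mean() for p in profiles]))

    def test_mixed_views_rejected(self):
        a = fm.PolarProfile(np.full(360, 10.0), (0, 0), view="side")
        b = fm.PolarProfile(np.full(360, 10.0), (0, 0), view="top")
        with pytest.raises(ValueError, match="views"):
            fm.average_shape([a, b])


class TestClusterShapes:
    @staticmethod
    def _families(rng, n_per=20):
        circle = np.ones(360)
        theta = np.deg2rad(np.arange(360))
        tall = fm.ellipse_profile(0.7, 1.0)
        flat = fm.ellipse_profile(1.0, 0.6)
        out, families = [], []
        for fam, base in enumerate((circle, tall, flat)):
            for _ in range(n_per):
                out.append(base * (1 + 0.01 * rng.standard_normal(360)))
                families.append(fam)
        return np.array(out), np.array(families)

    def test_separated_families_recovered(self):
        rng = np.random.default_rng(31)
        profiles, families = self._families(rng)
        labels, _, _ = fm.cluster_shapes(profiles, k=3, seed=0)
        # perfect recovery up to label permutation
        for fam in range(3):
            assert len(set(labels[families == fam])) == 1
        assert len(set(labels)) == 3

    def test_k_equals_n_degenerate(self):
        rng = np.random.default_rng(32)
        profiles = np.array([1 + 0.1 * rng.random(360) for _ in range(5)])
        labels, centers, _ = fm.cluster_shapes(profiles, k=5, seed=0)
        assert len(set(labels)) == 5
        norm = profiles / profiles.mean(axis=1, keepdims=True)
        wss = sum(((norm[i] - centers[labels[i]]) ** 2).sum()
                  for i in range(5))
        assert wss == pytest.approx(0.0, abs=1e-18)

    def test_order_invariance(self):
        rng = np.random.default_rng(33)
        profiles, families = self._families(rng, n_per=10)
        labels1, _, _ = fm.cluster_shapes(profiles, k=3, seed=0)
        perm = rng.permutation(len(profiles))
        labels2, _, _ = fm.cluster_shapes(profiles[perm], k=3, seed=0)
        # same partition after canonical mapping
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels1[perm], labels2) == 1.0

    def test_wss_non_increasing_in_k(self):
        rng = np.random.default_rng(34)
        profiles, _ = self._families(rng, n_per=10)
        norm = profiles / profiles.mean(axis=1, keepdims=True)
        wss = []
        for k in range(3, 9):
            labels, centers, _ = fm.cluster_shapes(profiles, k=k, seed=0)
            wss.append(sum(((norm[i] - centers[labels[i]]) ** 2).sum()
                           for i in range(len(norm))))
        assert all(b <= a + 1e-9 for a, b in zip(wss, wss[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            fm.cluster_shapes(np.ones((4, 360)), k=5)

    def test_cultivar_count_table(self):
        rng = np.random.default_rng(35)
        profiles, families = self._families(rng, n_per=10)
        cultivars = [f"c{f}" for f in families]
        _, _, counts = fm.cluster_shapes(profiles, k=3, seed=0,
                                         cultivars=cultivars)
        assert counts.to_numpy().sum() == len(profiles)
        assert (counts.to_numpy() > 0).sum() == 3  # one cluster per family


class TestLibraryIO:
    def test_round_trip(self, library, tmp_path):
        path = tmp_path / "library.txt"
        fm.save_reference_library(library, path)
        loaded = fm.load_reference_library(path)
        assert loaded.names() == library.names()
        for a, b in zip(loaded.entries, library.entries):
            assert np.allclose(a.radius_profile, b.radius_profile, atol=1e-9)

    def test_wrong_column_count_names_row(self, tmp_path):
        path = tmp_path / "bad.txt"
        radii = " ".join(["1.0"] * 359)
        path.write_text(f"header\n1 round {radii}\n")
        with pytest.raises(ValueError, match="row 2"):
            fm.load_reference_library(path)

    def test_duplicate_class_id_rejected(self, tmp_path):
        path = tmp_path / "dup.txt"
        radii = " ".join(["1.0"] * 360)
        path.write_text(f"header\n1 a {radii}\n1 b {radii}\n")
        with pytest.raises(ValueError, match="duplicate"):
            fm.load_reference_library(path)

    def test_non_positive_radius_rejected(self, tmp_path):
        path = tmp_path / "neg.txt"
        radii = " ".join(["1.0"] * 359 + ["-0.5"])
        path.write_text(f"header\n1 a {radii}\n")
        with pytest.raises(ValueError, match="row 2"):
            fm.load_reference_library(path)
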