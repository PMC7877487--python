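"""Network construction: KDE densities, symmetric KL, KLS edges, full matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import morphnet as mn
from morphnet.network import make_shared_grid, silverman_bandwidth

from conftest import random_density


def brute_force_density(values, grid, h, floor):
    """Naive per-grid-point kernel sum (1/nh) sum_j K((g - v_j)/h)."""
    n = len(values)
    dens = np.empty(len(grid))
    for g_idx, g in enumerate(grid):
        total = 0.0
        for v in values:
            total += math.exp(-0.5 * ((g - v) / h) ** 2) / math.sqrt(2 * math.pi)
        dens[g_idx] = total / (n * h)
    dens = dens + floor
    return dens / dens.sum()


def brute_force_network(region_values, config):
    """Independent naive loops over grid points and region pairs."""
    labels = sorted(region_values)
    grid = make_shared_grid(region_values, config)
    profs = {}
    for lab in labels:
        vals = region_values[lab]
        h = (
            silverman_bandwidth(vals)
            if isinstance(config.bandwidth_rule, str)
            else config.bandwidth_rule
        )
        probs = brute_force_density(vals, grid, h, config.prob_floor)
        profs[lab] = probs
    n = len(labels)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p, q = profs[labels[i]], profs[labels[j]]
            d = 0.0
            for g in range(len(grid)):
                d += p[g] * math.log(p[g] / q[g]) + q[g] * math.log(q[g] / p[g])
            mat[i, j] = math.exp(-d)
    return labels, mat


class TestExtractRegionValues:
    def test_vermis_exclusion_gives_108_regions(self, atlas116, one_subject):
        rv = mn.extract_region_values(one_subject, atlas116)
        assert len(rv) == 108
        assert all(lab not in rv for lab in range(109, 117))
        assert list(rv) == sorted(rv)

    def test_constant_map(self, small_atlas):
        gm = mn.GMVolumeMap("c", np.full(small_atlas.label_volume.shape, 0.7))
        rv = mn.extract_region_values(gm, small_atlas, mn.NetworkConfig(excluded_labels=frozenset()))
        assert all(np.all(v == 0.7) for v in rv.values())

    def test_shape_mismatch_raises(self, small_atlas):
        gm = mn.GMVolumeMap("m", np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="shape"):
            mn.extract_region_values(gm, small_atlas)

    def test_empty_retained_region_raises_with_label(self, small_atlas):
        atlas = mn.ParcellationAtlas(
            label_volume=small_atlas.label_volume,
            label_names={**{r: f"R{r}" for r in range(1, 13)}, 13: "R13"},
        )
        gm = mn.GMVolumeMap("m", np.ones(atlas.label_volume.shape))
        with pytest.raises(ValueError, match="13"):
            mn.extract_region_values(gm, atlas, mn.NetworkConfig(excluded_labels=frozenset()))


class TestEstimateDensity:
    def test_probs_sum_to_one(self):
        rng = np.random.default_rng(0)
        prof = mn.estimate_density(rng.normal(0.5, 0.1, 200))
        assert abs(prof.probs.sum() - 1.0) < 1e-9
        assert np.all(prof.probs > 0)

    def test_single_value_peaks_at_value(self):
        with pytest.warns(RuntimeWarning, match="bandwidth"):
            prof = mn.estimate_density([0.42])
        assert np.argmax(prof.probs) == np.argmin(np.abs(prof.grid - 0.42))

    def test_matches_brute_force_kernel_sums(self):
        rng = np.random.default_rng(7)
        values = rng.gamma(4.0, 0.1, 50)
        config = mn.NetworkConfig(grid_size=64)
        prof = mn.estimate_density(values, config)
        h = silverman_bandwidth(values)
        expected = brute_force_density(values, prof.grid, h, config.prob_floor)
        assert np.max(np.abs(prof.probs - expected)) < 1e-12


class TestSymmetricKL:
    def test_identical_densities_give_zero(self):
        p = random_density(np.random.default_rng(1))
        assert mn.symmetric_kl(p, p) == 0.0

    def test_hand_case(self):
        grid = np.array([0.0, 1.0])
        p = mn.DensityProfile(grid=grid, probs=np.array([0.5, 0.5]))
        q = mn.DensityProfile(grid=grid, probs=np.array([0.9, 0.1]))
        # 0.5 ln(5/9) + 0.9 ln(9/5) + 0.5 ln 5 + 0.1 ln(1/5)
        expected = (
            0.5 * math.log(0.5 / 0.9)
            + 0.9 * math.log(0.9 / 0.5)
            + 0.5 * math.log(0.5 / 0.1)
            + 0.1 * math.log(0.1 / 0.5)
        )
        assert expected == pytest.approx(0.8789, abs=1e-4)
        assert mn.symmetric_kl(p, q) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_grids_rejected(self):
        p = random_density(np.random.default_rng(1), 16)
        q = random_density(np.random.default_rng(2), 17)
        with pytest.raises(ValueError, match="grid"):
            mn.symmetric_kl(p, q)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        p, q = random_density(rng), random_density(rng)
        d = mn.symmetric_kl(p, q)
        assert d >= 0
        assert d == pytest.approx(mn.symmetric_kl(q, p), abs=1e-12)


class TestKLS:
    def test_identity_gives_one(self):
        p = random_density(np.random.default_rng(3))
        assert mn.kls(p, p) == 1.0

    def test_divergence_ln2_gives_half(self):
        """A symmetric two-point pair (a, 1-a) vs (1-a, a) has divergence
        2(2a-1) ln(a/(1-a)); solving for ln 2 must give KLS exactly 0.5."""
        f = lambda a: 2 * (2 * a - 1) * math.log(a / (1 - a)) - math.log(2)
        a = brentq(f, 0.51, 0.99, xtol=1e-16, rtol=8.9e-16)
        grid = np.array([0.0, 1.0])
        p = mn.DensityProfile(grid=grid, probs=np.array([a, 1 - a]))
        q = mn.DensityProfile(grid=grid, probs=np.array([1 - a, a]))
        assert mn.kls(p, q) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_divergence(self):
        rng = np.random.default_rng(4)
        pairs = [(random_density(rng), random_density(rng)) for _ in range(20)]
        ds = [mn.symmetric_kl(p, q) for p, q in pairs]
        ks = [mn.kls(p, q) for p, q in pairs]
        order = np.argsort(ds)
        assert np.all(np.diff(np.array(ks)[order]) <= 0)


class TestBuildNetwork:
    def test_matrix_is_108_square_with_unit_diagonal(self, atlas116, one_subject):
        net = mn.build_network(one_subject, atlas116)
        assert net.matrix.shape == (108, 108)
        assert net.region_labels == list(range(1, 109))
        assert np.all(np.diag(net.matrix) == 1.0)
        assert np.array_equal(net.matrix, net.matrix.T)
        assert np.all(net.matrix > 0) and np.all(net.matrix <= 1)

    def test_deterministic_for_identical_inputs(self, small_atlas, small_cohort):
        gm = small_cohort[0][0]
        cfg = mn.NetworkConfig(excluded_labels=frozenset())
        a = mn.build_network(gm, small_atlas, cfg)
        b = mn.build_network(gm, small_atlas, cfg)
        assert np.array_equal(a.matrix, b.matrix)

    @pytest.mark.parametrize("bandwidth", ["silverman", 0.05])
    def test_matches_brute_force_oracle(self, bandwidth):
        """Vectorized construction equals naive loops (<= 5 regions, G = 16)."""
        rng = np.random.default_rng(42)
        atlas = mn.generate_atlas((12, 12, 12), n_regions=5, seed=2)
        gm = mn.GMVolumeMap("s", rng.gamma(4.0, 0.1, (12, 12, 12)))
        cfg = mn.NetworkConfig(
            excluded_labels=frozenset(), grid_size=16, bandwidth_rule=bandwidth
        )
        net = mn.build_network(gm, atlas, cfg)
        rv = mn.extract_region_values(gm, atlas, cfg)
        labels, expected = brute_force_network(rv, cfg)
        assert labels == net.region_labels
        assert np.max(np.abs(net.matrix - expected)) < 1e-10

    def test_permutation_equivariance(self, small_atlas, small_cohort):
        """Relabeling atlas regions permutes matrix rows/columns consistently."""
        gm = small_cohort[0][0]
        cfg = mn.NetworkConfig(excluded_labels=frozenset())
        base = mn.build_network(gm, small_atlas, cfg)
        n = len(base.region_labels)
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)  # old index -> position of new label
        lut = np.zeros(n + 1, dtype=np.int32)
        lut[1:] = perm + 1  # old label l -> new label perm[l-1]+1
        relabeled = mn.ParcellationAtlas(
            label_volume=lut[small_atlas.label_volume],
            label_names={int(perm[l - 1] + 1): f"R{l}" for l in range(1, n + 1)},
        )
        net2 = mn.build_network(gm, relabeled, cfg)
        # old region at index i now sits at index perm[i]
        assert np.allclose(net2.matrix[np.ix_(perm, perm)], base.matrix, atol=1e-12)

    def test_separated_distributions_less_similar(self):
        """N(0.3, 0.05) vs N(0.7, 0.05) must be less similar than
        N(0.3, 0.05) vs N(0.35, 0.05)."""
        rng = np.random.default_rng(8)
        a = rng.normal(0.3, 0.05, 400)
        b = rng.normal(0.7, 0.05, 400)
        c = rng.normal(0.35, 0.05, 400)
        cfg = mn.NetworkConfig()
        grid = make_shared_grid({0: a, 1: b, 2: c}, cfg)
        pa = mn.estimate_density(a, cfg, grid)
        pb = mn.estimate_density(b, cfg, grid)
        pc = mn.estimate_density(c, cfg, grid)
        assert mn.kls(pa, pb) < mn.kls(pa, pc)

    def test_tsv_roundtrip(self, tmp_path, small_atlas, small_cohort):
        gm = small_cohort[0][0]
        net = mn.build_network(gm, small_atlas, mn.NetworkConfig(excluded_labels=frozenset()))
        path = str(tmp_path / "net.tsv")
        mn.save_network(net, path)
        net2 = mn.load_network(path)
        assert net2.region_labels == net.region_labels
        assert np.allclose(net2.matrix, net.matrix, atol=1e-12)


def test_network_config_validation():
    with pytest.raises(ValueError):
        mn.NetworkConfig(grid_size=8)
    with pytest.raises(ValueError):
        mn.NetworkConfig(prob_floor=0.5)
    with pytest.raises(ValueError):
        mn.NetworkConfig(bandwidth_rule=-1.0)
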