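"""Neighborhood construction and the shrinkage predictor."""

import numpy as np
import pytest

from asbqtl._util import AsbqtlError, ConfigError
from asbqtl.blup import (
    DEFAULT_GRID_S,
    DEFAULT_GRID_U,
    BlupHyperParams,
    Neighborhood,
    blup_predict,
    blup_weights,
    build_neighborhood,
    build_neighborhoods,
    grid_search,
)
from tests.conftest import make_site


def gls_oracle(y, N, sigma_s2, sigma_u2):
    """BLUP of the scalar mean effect from the full mixed-model solution
    of y = 1u + e, Var(e) = diag(1/(4N) + sigma_s2), Var(u) = sigma_u2."""
    y = np.asarray(y, float)
    N = np.asarray(N, float)
    V = np.diag(1.0 / (4.0 * N) + sigma_s2) + sigma_u2 * np.ones((len(y), len(y)))
    return float(sigma_u2 * np.ones(len(y)) @ np.linalg.solve(V, y))


def nbhd(ys, ns):
    return Neighborhood("t", [f"m{i}" for i in range(len(ys))],
                        np.asarray(ys, float), np.asarray(ns, float),
                        np.full(len(ys), 10))


class TestBuildNeighborhood:
    def test_identical_flanks_included_with_full_match(self):
        t = make_site("t", flank5="ACGTA", flank3="TTGCA")
        m = make_site("m", pos=2000, flank5="ACGTA", flank3="TTGCA")
        nb = build_neighborhood(t, [t, m])
        assert nb.member_site_ids == ["m"]
        assert nb.match_counts.tolist() == [10]

    def test_four_mismatches_excluded(self):
        t = make_site("t", flank5="ACGTA", flank3="TTGCA")
        m = make_site("m", pos=2000, flank5="TTTTA", flank3="TTGCG")
        nb = build_neighborhood(t, [t, m])
        assert nb.n_members == 0

    def test_seven_matches_is_the_boundary(self):
        t = make_site("t", flank5="ACGTA", flank3="TTGCA")
        m = make_site("m", pos=2000, flank5="ACGTA", flank3="GGGCA")  # 8 matches
        m2 = make_site("m2", pos=3000, flank5="ACGTA", flank3="GGGGA")  # 7
        m3 = make_site("m3", pos=4000, flank5="ACGTA", flank3="GGGGG")  # 6
        nb = build_neighborhood(t, [t, m, m2, m3])
        assert set(nb.member_site_ids) == {"m", "m2"}

    def test_swapped_genotype_excluded(self):
        t = make_site("t", ref="A", alt="G")
        m = make_site("m", pos=2000, ref="G", alt="A")
        assert build_neighborhood(t, [t, m]).n_members == 0

    def test_indexed_equals_brute_force(self):
        rng = np.random.default_rng(3)
        bases = list("ACGT")
        sites = []
        for i in range(120):
            ref, alt = rng.choice(bases, 2, replace=False)
            f5 = "".join(rng.choice(list("AC"), 5))  # restricted alphabet ->
            f3 = "".join(rng.choice(list("AC"), 5))  # plenty of neighbors
            sites.append(make_site(f"s{i}", pos=i + 100, ref=ref, alt=alt,
                                   flank5=f5, flank3=f3,
                                   agg_ref=int(rng.integers(10, 100)),
                                   agg_alt=int(rng.integers(10, 100))))
        fast = build_neighborhoods(sites)
        for i, site in enumerate(sites):
            slow = build_neighborhood(site, sites)
            assert sorted(fast[i].member_site_ids) == sorted(slow.member_site_ids)
            assert fast[i].match_counts.sum() == slow.match_counts.sum()


class TestBlupPredict:
    def test_empty_neighborhood_shrinks_to_zero(self):
        p = blup_predict(nbhd([], []), BlupHyperParams(0.035, 0.001))
        assert p.u_hat == 0.0
        assert p.n_neighbors == 0

    def test_single_member_closed_form(self):
        p = blup_predict(nbhd([0.1], [100]), BlupHyperParams(0.035, 0.001))
        w = 400 / 15
        assert p.sum_weights == pytest.approx(w)
        assert p.u_hat == pytest.approx((w * 0.1) / (w + 1000))
        assert p.u_hat == pytest.approx(0.0025974, abs=1e-7)

    def test_two_member_closed_form(self):
        p = blup_predict(nbhd([0.2, -0.1], [25, 100]), BlupHyperParams(0.01, 0.01))
        assert p.u_hat == pytest.approx((10 - 8) / 230)
        assert p.u_hat == pytest.approx(0.008696, abs=1e-6)

    def test_matches_gls_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(1, 21))
            y = rng.normal(0, 0.2, n)
            N = rng.integers(10, 2000, n)
            s2 = float(rng.uniform(0.001, 0.2))
            u2 = float(rng.uniform(0.0001, 0.2))
            mine = blup_predict(nbhd(y, N), BlupHyperParams(s2, u2)).u_hat
            assert mine == pytest.approx(gls_oracle(y, N, s2, u2), abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ConfigError):
            BlupHyperParams(0.0, 0.01)

    def test_shrinkage_limits(self):
        y, N = [0.2, -0.1, 0.3], [50, 80, 200]
        tiny = blup_predict(nbhd(y, N), BlupHyperParams(0.02, 1e-12)).u_hat
        assert abs(tiny) < 1e-8
        big = blup_predict(nbhd(y, N), BlupHyperParams(0.02, 1e9)).u_hat
        w = blup_weights(np.array(N, float), 0.02)
        assert big == pytest.approx(float(w @ y / w.sum()), rel=1e-6)

    def test_prediction_bounded_by_member_magnitudes(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(-0.5, 0.5, 15)
        N = rng.integers(10, 500, 15)
        p = blup_predict(nbhd(y, N), BlupHyperParams(0.05, 0.05))
        assert abs(p.u_hat) <= np.abs(y).max()

    def test_weights_monotonic(self):
        assert blup_weights(np.array([10.0]), 0.02) < blup_weights(np.array([100.0]), 0.02)
        assert blup_weights(np.array([100.0]), 0.05) < blup_weights(np.array([100.0]), 0.01)


def _cluster_sites(rng, n_clusters, per_cluster, delta_fn, depth=200):
    """Sites in flank-sharing clusters with binomial phenotype noise."""
    sites = []
    bases = list("ACGT")
    for g in range(n_clusters):
        f5 = "".join(rng.choice(bases, 5))
        f3 = "".join(rng.choice(bases, 5))
        ref, alt = rng.choice(bases, 2, replace=False)
        delta = delta_fn(g)
        for j in range(per_cluster):
            n = depth
            alt_reads = rng.binomial(n, 0.5 + delta)
            sites.append(make_site(f"g{g}_s{j}", pos=g * 10_000 + j,
                                   ref=ref, alt=alt, agg_ref=n - alt_reads,
                                   agg_alt=alt_reads, flank5=f5, flank3=f3))
    return sites


class TestGridSearch:
    def test_default_grids_cover_reference_optima(self):
        for pair in [(0.035, 0.001), (0.07, 0.003)]:
            assert pair[0] in DEFAULT_GRID_S
            assert pair[1] in DEFAULT_GRID_U

    def test_pure_noise_gives_near_zero_correlation(self):
        rng = np.random.default_rng(42)
        sites = _cluster_sites(rng, 50, 100, lambda g: 0.0)  # 5000 sites
        _, table = grid_search(sites)
        assert table.r.abs().max() < 0.05

    def test_clustered_effects_recovered(self):
        rng = np.random.default_rng(43)
        deltas = rng.uniform(-0.3, 0.3, 25)
        sites = _cluster_sites(rng, 25, 20, lambda g: deltas[g])
        _, table = grid_search(sites)
        assert table.r.max() > 0.5

    def test_all_empty_neighborhoods_raise(self):
        sites = [make_site("a", flank5="AAAAA", flank3="AAAAA"),
                 make_site("b", pos=2000, flank5="CCCCC", flank3="CCCCC"),
                 make_site("c", pos=3000, flank5="GGGGG", flank3="GGGGG")]
        with pytest.raises(AsbqtlError):
            grid_search(sites)
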