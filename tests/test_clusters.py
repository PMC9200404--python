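"""Spatio-temporal cluster permutation test: connectivity, determinism,
planted-signal recovery, occurrence summaries."""

import numpy as np
import pytest

from spncat import (
    CatalogueError,
    ErpEpoch,
    cluster_permutation_test,
    cluster_window_spn,
    electrode_occurrence,
    most_significant_negative_cluster,
    spn_summary,
)
from spncat.clusters import SpatioTemporalCluster
from spncat.simulate import generate_experiment

from conftest import SPN_CLUSTER, SPN_WINDOW, fast_config


def noise_epochs(montage, n=8, n_samples=120, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return [
        ErpEpoch(f"p{i}", "diff", rng.normal(0, sd, (len(montage), n_samples)))
        for i in range(n)
    ]


def planted_epochs(posterior16, n=24, true_amp=-3.0, noise=0.2, seed=5):
    """Difference epochs with a sharp-edged plateau across the whole
    posterior montage, so the injected support is exactly known and
    spatially connected."""
    cfg = fast_config(
        seed=seed, noise_sd=noise, n_trials=1, between_sd=0.0,
        spn_edge_ms=0.0,
        topography={lab: 1.0 for lab in posterior16.labels},
    )
    exp = generate_experiment(
        dict(n=n, w_load=0.0, task_relevant=0, true_amp=true_amp),
        cfg, seed=seed, montage=posterior16,
    )
    out = []
    for pid, eps in exp.participants.items():
        d = eps["regular"].data - eps["random"].data
        out.append(ErpEpoch(pid, "diff", d, eps["regular"].sampling_rate,
                            eps["regular"].epoch_start))
    return cfg, out


def assert_connected(cluster, montage):
    """Graph-traversal oracle: members form one connected component."""
    import networkx as nx

    g = nx.Graph()
    members = set(cluster.members)
    g.add_nodes_from(members)
    for (e1, s1) in members:
        for (e2, s2) in members:
            if (e1 == e2 and abs(s1 - s2) == 1) or (
                s1 == s2 and e2 in montage.neighbours[e1]
            ):
                g.add_edge((e1, s1), (e2, s2))
    assert nx.is_connected(g)


class TestBasics:
    def test_single_participant_rejected(self, posterior16):
        with pytest.raises(CatalogueError, match=">= 2 participants"):
            cluster_permutation_test(noise_epochs(posterior16, n=1), posterior16)

    def test_misaligned_epochs_rejected(self, posterior16):
        eps = noise_epochs(posterior16, n=3)
        eps[1] = ErpEpoch("p1", "diff", eps[1].data[:, :-1])
        with pytest.raises(CatalogueError, match="misaligned"):
            cluster_permutation_test(eps, posterior16)

    def test_determinism_same_seed(self, posterior16):
        eps = noise_epochs(posterior16, seed=2)
        a = cluster_permutation_test(eps, posterior16, n_permutations=50, seed=9)
        b = cluster_permutation_test(eps, posterior16, n_permutations=50, seed=9)
        assert len(a.clusters) == len(b.clusters)
        for c1, c2 in zip(a.clusters, b.clusters):
            assert c1.members == c2.members
            assert c1.mass == c2.mass
            assert c1.p == c2.p

    def test_p_values_bounded_below(self, posterior16):
        eps = noise_epochs(posterior16, seed=3)
        res = cluster_permutation_test(eps, posterior16, n_permutations=40, seed=1)
        for c in res.clusters:
            assert c.p >= 1.0 / 41.0

    def test_every_cluster_connected_and_sign_pure(self, posterior16):
        eps = noise_epochs(posterior16, seed=4, n=6)
        res = cluster_permutation_test(eps, posterior16, n_permutations=20, seed=2)
        assert res.clusters, "noise at df=5 should produce some suprathreshold points"
        data = np.stack([e.data for e in eps])
        t = data.mean(0) / (data.std(0, ddof=1) / np.sqrt(len(eps)))
        for c in res.clusters:
            assert_connected(c, posterior16)
            for lab, s in c.members:
                val = t[posterior16.index(lab), s]
                assert (val < 0) == (c.sign == "negative")
            assert c.mass == pytest.approx(
                sum(t[posterior16.index(lab), s] for lab, s in c.members), rel=1e-9
            )


class TestPlantedSignal:
    def test_recovers_planted_cluster(self, posterior20):
        cfg, eps = planted_epochs(posterior20)
        res = cluster_permutation_test(eps, posterior20, n_permutations=200, seed=11)
        top = most_significant_negative_cluster(res)
        assert top is not None
        assert top.p == pytest.approx(1.0 / 201.0)
        # injected support: all posterior electrodes x plateau span
        from spncat.extraction import sample_range

        lo, hi = sample_range(
            (cfg.spn_onset_ms, cfg.spn_offset_ms), cfg.epoch_start,
            cfg.sampling_rate, cfg.n_samples,
        )
        injected = {
            (lab, s) for lab in posterior20.labels for s in range(lo, hi)
        }
        overlap = len(injected & set(top.members)) / len(injected)
        assert overlap >= 0.8

    def test_mass_monotone_in_amplitude(self, posterior20):
        masses = []
        for amp in (-1.0, -2.0, -3.0):
            _, eps = planted_epochs(posterior20, true_amp=amp, seed=7)
            res = cluster_permutation_test(eps, posterior20, n_permutations=20, seed=3)
            top = max(res.negative_clusters(), key=lambda c: abs(c.mass))
            masses.append(abs(top.mass))
        assert masses[0] <= masses[1] <= masses[2]

    def test_data_driven_amplitude_near_truth(self, posterior20):
        cfg, eps = planted_epochs(posterior20)
        res = cluster_permutation_test(eps, posterior20, n_permutations=100, seed=13)
        top = most_significant_negative_cluster(res)
        exp = generate_experiment(
            dict(n=24, w_load=0.0, task_relevant=0, true_amp=-3.0),
            cfg, seed=5, montage=posterior20,
        )
        s = cluster_window_spn(exp, top, posterior20)
        assert s.mean == pytest.approx(-3.0, rel=0.10)


class TestSelection:
    def test_no_negative_clusters_returns_none(self, posterior20):
        # strong positive signal only
        cfg, eps = planted_epochs(posterior20, true_amp=3.0, noise=0.1)
        res = cluster_permutation_test(eps, posterior20, n_permutations=50, seed=5)
        assert most_significant_negative_cluster(res) is None

    def test_equal_mass_tie_broken_by_onset(self):
        a = SpatioTemporalCluster(
            members=frozenset({("PO8", 30), ("PO8", 31)}), mass=-10.0,
            sign="negative", p=0.01,
        )
        b = SpatioTemporalCluster(
            members=frozenset({("PO7", 10), ("PO7", 11)}), mass=-10.0,
            sign="negative", p=0.01,
        )
        from spncat.clusters import ClusterTestResult

        res = ClusterTestResult(
            clusters=(a, b), cluster_alpha=0.05, n_permutations=99, seed=0,
            null_distribution_summary={},
        )
        assert most_significant_negative_cluster(res) is b


class TestOccurrence:
    def c(self, *electrodes, sample=10):
        return SpatioTemporalCluster(
            members=frozenset((e, sample) for e in electrodes),
            mass=-5.0, sign="negative", p=0.01,
        )

    def test_single_electrode_everywhere(self, posterior16):
        occ = electrode_occurrence([self.c("PO8")] * 4, posterior16)
        assert occ["PO8"] == 1.0
        assert all(v == 0.0 for lab, v in occ.items() if lab != "PO8")

    def test_partial_counts_exclude_none(self, posterior16):
        clusters = [self.c("O1"), self.c("O1", "PO7"), self.c("O1"), self.c("PO8")] + [
            self.c("PO8")
        ] * 6
        occ = electrode_occurrence(clusters + [None] * 5, posterior16)
        assert occ["O1"] == pytest.approx(0.3)
        assert occ["PO7"] == pytest.approx(0.1)

    def test_all_none_rejected(self, posterior16):
        with pytest.raises(ValueError, match="all entries are None"):
            electrode_occurrence([None, None], posterior16)


class TestClusterWindowSpn:
    def test_rectangular_cluster_equals_direct_summary(self, posterior16):
        cfg = fast_config(seed=17, noise_sd=0.8, between_sd=1.0)
        exp = generate_experiment(
            dict(n=6, w_load=0.5, task_relevant=1), cfg, seed=17, montage=posterior16
        )
        from spncat.extraction import sample_range

        lo, hi = sample_range(SPN_WINDOW, cfg.epoch_start, cfg.sampling_rate, cfg.n_samples)
        cluster = SpatioTemporalCluster(
            members=frozenset((e, s) for e in SPN_CLUSTER for s in range(lo, hi)),
            mass=-100.0, sign="negative", p=0.001,
        )
        got = cluster_window_spn(exp, cluster, posterior16)
        direct = spn_summary(exp, tuple(sorted(SPN_CLUSTER)), SPN_WINDOW, posterior16)
        assert got.mean == direct.mean
        assert got.diffs == direct.diffs

    def test_empty_cluster_rejected(self, posterior16):
        cfg = fast_config(seed=18)
        exp = generate_experiment(
            dict(n=2, w_load=0.1, task_relevant=0), cfg, seed=18, montage=posterior16
        )
        empty = SpatioTemporalCluster(frozenset(), 0.0, "negative", 1.0)
        with pytest.raises(ValueError, match="empty"):
            cluster_window_spn(exp, empty, posterior16)
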