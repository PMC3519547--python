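"""Source detection, inverse-correlation scoring and network inference."""

import numpy as np
import pytest
from scipy import stats

from lipidremodel import (
    InferenceConfig,
    TimeCourse,
    bidirectionalize,
    detect_sources,
    differs_at_one_position,
    edge_score,
    infer_network,
    neighborhood,
    parse_species,
)
from lipidremodel.lipid_model import AcylChain, Edge, RemodelingNetwork, SpeciesId
from lipidremodel.synthetic_data import make_species_grid


def _tc(series, times=(0.0, 1.0, 2.0), jitter=0.0, seed=0):
    """Build a TimeCourse from {label: per-time replicate lists}."""
    rng = np.random.default_rng(seed)
    species = tuple(parse_species(lbl) for lbl in series)
    values = {}
    for s, lbl in zip(species, series):
        per_time = []
        for reps in series[lbl]:
            arr = np.asarray(reps, dtype=float)
            if jitter:
                arr = np.abs(arr + rng.normal(0, jitter, size=arr.shape))
            per_time.append(arr)
        values[s] = tuple(per_time)
    return TimeCourse(species=species, times=times, values=values)


class TestDetectSources:
    def test_unambiguous_decrease_is_source(self):
        tc = _tc({"18:1-18:1": [[10, 10, 10], [5, 5, 5], [5, 5, 5]]})
        assert detect_sources(tc, 0, alpha=0.3) == {parse_species("18:1-18:1")}

    def test_constant_series_is_not_source(self):
        tc = _tc({"18:1-18:1": [[5, 5, 5], [5, 5, 5], [5, 5, 5]]})
        assert detect_sources(tc, 0, alpha=0.3) == set()

    def test_single_replicate_falls_back_to_margin_rule(self):
        tc = _tc({"18:1-18:1": [[10], [9.8], [9.8]]})
        # 2% decrease is below the 5% fallback margin
        assert detect_sources(tc, 0, alpha=0.3) == set()
        tc2 = _tc({"18:1-18:1": [[10], [8.0], [8.0]]})
        assert detect_sources(tc2, 0, alpha=0.3) == {parse_species("18:1-18:1")}

    def test_agrees_with_reference_t_test_on_mixed_panel(self):
        """One decaying species among five rising ones: only the decayer flags.

        Cross-checked against a direct scipy Welch-test loop as the oracle.
        """
        rng = np.random.default_rng(1)
        labels = ["18:3-18:3", "18:1-18:3", "18:3-18:1", "18:1-18:1",
                  "16:0-18:1", "16:0-18:2"]
        series = {}
        for i, lbl in enumerate(labels):
            if i == 0:
                base = [100.0, 60.0, 40.0]
            else:
                base = [5.0 + i, 8.0 + i, 12.0 + i]
            series[lbl] = [list(np.abs(b + rng.normal(0, 0.5, 3))) for b in base]
        tc = _tc(series)
        alpha = 0.3
        got = detect_sources(tc, 0, alpha=alpha)
        expected = set()
        for s in tc.species:
            a, b = tc.replicate_values(s, 0), tc.replicate_values(s, 1)
            p = stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
            if p < alpha:
                expected.add(s)
        assert got == expected == {parse_species("18:3-18:3")}


class TestNeighborhood:
    def test_definition_example(self):
        s = parse_species("18:3-18:3")
        observed = {parse_species(x) for x in
                    ["18:1-18:3", "18:3-18:1", "18:1-18:1", "16:0-20:4"]}
        assert neighborhood(s, observed) == {
            parse_species("18:1-18:3"), parse_species("18:3-18:1")
        }

    def test_lone_species_has_empty_neighborhood(self):
        s = parse_species("18:3-18:3")
        assert neighborhood(s, {s}) == set()

    def test_full_grid_neighbor_counts(self):
        """Every species on a 3x3 chain grid has (3-1)+(3-1)=4 neighbors."""
        chains = [AcylChain.parse(c) for c in ("16:0", "18:1", "18:3")]
        grid = set(make_species_grid(chains, chains))
        for s in grid:
            nbrs = neighborhood(s, grid)
            assert len(nbrs) == 4
            # enumeration oracle: count pairs differing at exactly one position
            brute = {v for v in grid if v != s
                     and differs_at_one_position(s, v) is not None}
            assert nbrs == brute


class TestEdgeScore:
    def _two_species(self, xs, xv):
        series = {
            "18:3-18:3": [[x] * 2 for x in xs],
            "18:1-18:3": [[x] * 2 for x in xv],
        }
        return _tc(series, times=tuple(float(t) for t in range(len(xs))))

    def test_perfect_anticorrelation_scores_one(self):
        tc = self._two_species([10, 6, 2], [0, 4, 8])
        s, v = tc.species
        assert edge_score(s, v, tc, (0, 2)) == pytest.approx(1.0)

    def test_co_decreasing_target_scores_nonpositive(self):
        tc = self._two_species([10, 6, 2], [8, 4, 0])
        s, v = tc.species
        assert edge_score(s, v, tc, (0, 2)) <= 0.0

    def test_zero_variance_scores_zero(self):
        tc = self._two_species([10, 6, 2], [3, 3, 3])
        s, v = tc.species
        assert edge_score(s, v, tc, (0, 2)) == 0.0

    def test_matches_brute_force_correlation(self):
        """Score equals the negated Pearson correlation computed from scratch."""
        rng = np.random.default_rng(7)
        xs = rng.uniform(1, 10, 5)
        xv = rng.uniform(1, 10, 5)
        tc = self._two_species(xs, xv)
        s, v = tc.species
        # independent oracle: direct covariance formula
        a, b = xs - xs.mean(), xv - xv.mean()
        r = float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))
        expected = -r
        if not np.any(np.diff(xv) > 0):
            expected = -abs(expected)
        assert edge_score(s, v, tc, (0, 4)) == pytest.approx(expected, abs=1e-12)


class TestInferNetwork:
    def test_noiseless_chain_recovered_exactly(self, noiseless_path):
        tc, truth = noiseless_path
        net = infer_network(tc, InferenceConfig())
        assert net.edge_keys() == truth.network.edge_keys()
        for e in net.edges:
            assert differs_at_one_position(e.source, e.target) == e.position

    def test_constant_dataset_yields_empty_network(self):
        series = {lbl: [[4.0, 4.0]] * 3 for lbl in ["18:3-18:3", "18:1-18:3"]}
        tc = _tc(series)
        net = infer_network(tc, InferenceConfig())
        assert net.n_edges == 0
        assert net.nodes == set(tc.species)

    def test_edge_count_monotone_in_threshold(self, grid_data):
        tc, _ = grid_data
        counts = [
            infer_network(tc, InferenceConfig(corr_threshold=t)).n_edges
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_noisy_chain_recovers_true_path(self, noisy_path):
        tc, truth = noisy_path
        net = infer_network(tc, InferenceConfig())
        assert truth.network.edge_keys() <= net.edge_keys()
        # no cross-position edges ever
        for e in net.edges:
            assert differs_at_one_position(e.source, e.target) is not None


class TestBidirectionalize:
    def _edge(self, a, b):
        pos = differs_at_one_position(parse_species(a), parse_species(b))
        return Edge(source=parse_species(a), target=parse_species(b), position=pos)

    def test_adds_reverse_edge(self):
        net = RemodelingNetwork.from_edges([self._edge("18:3-18:3", "18:1-18:3")])
        out = bidirectionalize(net)
        assert out.n_edges == 2
        assert out.is_bidirectional()
        rev = [e for e in out.edges if e.source == parse_species("18:1-18:3")][0]
        assert rev.score == 0.0

    def test_idempotent(self):
        net = RemodelingNetwork.from_edges([self._edge("18:3-18:3", "18:1-18:3")])
        once = bidirectionalize(net)
        twice = bidirectionalize(once)
        assert once.edge_keys() == twice.edge_keys()
        assert once.n_edges == twice.n_edges

    def test_six_forward_edges_become_twelve(self):
        pairs = [
            ("18:3-18:3", "18:1-18:3"),
            ("18:1-18:3", "18:1-18:1"),
            ("18:1-18:1", "18:0-18:1"),
            ("18:0-18:1", "18:0-18:2"),
            ("18:0-18:2", "16:1-18:2"),
            ("18:3-18:3", "18:3-18:1"),
        ]
        net = RemodelingNetwork.from_edges([self._edge(a, b) for a, b in pairs])
        assert bidirectionalize(net).n_edges == 12
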