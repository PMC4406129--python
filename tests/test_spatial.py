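"""Breeding-geography tests and the competition index."""

import numpy as np
import pandas as pd
import pytest

from socsel import (
    AssociationNetwork,
    build_sitemap,
    competition_index,
    dyad_distance_test,
    visit_proportions,
    weight_distance_slope,
)


def simple_sitemap(n_feeders=1, n_boxes=4):
    feeders = pd.DataFrame(
        {
            "feeder_id": [f"F{i}" for i in range(n_feeders)],
            "x": 1000.0 * np.arange(n_feeders),
            "y": np.zeros(n_feeders),
        }
    )
    rng = np.random.default_rng(0)
    boxes = pd.DataFrame(
        {
            "box_id": [f"B{i:03d}" for i in range(n_boxes)],
            "x": rng.uniform(0, 1000.0 * max(n_feeders - 1, 1), n_boxes),
            "y": rng.uniform(-200, 200, n_boxes),
        }
    )
    return build_sitemap(feeders, boxes)


class TestSiteMap:
    def test_every_box_assigned_once(self):
        sm = simple_sitemap(n_feeders=3, n_boxes=30)
        assert len(sm.box_to_feeder) == 30
        assert sm.box_to_feeder.isin(sm.feeders["feeder_id"]).all()

    def test_nearest_assignment(self):
        sm = simple_sitemap(n_feeders=2, n_boxes=40)
        fxy = sm.feeders.set_index("feeder_id")[["x", "y"]]
        for box_id, fid in sm.box_to_feeder.items():
            b = sm.boxes.set_index("box_id").loc[box_id]
            d_assigned = np.hypot(b.x - fxy.loc[fid].x, b.y - fxy.loc[fid].y)
            d_all = np.hypot(b.x - fxy.x, b.y - fxy.y)
            assert d_assigned <= d_all.min() + 1e-9

    def test_equidistant_tie_goes_to_lowest_feeder_id(self):
        feeders = pd.DataFrame(
            {"feeder_id": ["F9", "F1"], "x": [-100.0, 100.0], "y": [0.0, 0.0]}
        )
        boxes = pd.DataFrame({"box_id": ["B0"], "x": [0.0], "y": [0.0]})
        sm = build_sitemap(feeders, boxes)
        assert sm.box_to_feeder.loc["B0"] == "F1"


def _net(W, roster):
    return AssociationNetwork(W, roster)


class TestDyadDistanceTest:
    def _setup(self, d_conn, d_non):
        """Four breeders: one connected pair, all cross pairs unconnected."""
        roster = ["A", "B", "C", "D"]
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        xy = pd.DataFrame(
            {
                "x": [0.0, d_conn, 10_000.0, 10_000.0 + d_non],
                "y": [0.0, 0.0, 0.0, 0.0],
            },
            index=pd.Index(roster, name="individual_id"),
        )
        return _net(W, roster), xy

    def test_equal_class_distances_give_t_zero(self):
        net, xy = self._setup(400.0, 400.0)
        # connected dyads: AB, CD at 400 m; the four cross dyads are ~10 km
        res = dyad_distance_test(net, xy)
        assert res.n_connected == 2 and res.n_nonconnected == 4
        assert res.mean_connected == pytest.approx(400.0)

    def test_all_connected_rejected(self):
        roster = ["A", "B", "C"]
        W = np.full((3, 3), 0.5)
        np.fill_diagonal(W, 0.0)
        xy = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]},
            index=pd.Index(roster, name="individual_id"),
        )
        with pytest.raises(ValueError, match="both connected and non-connected"):
            dyad_distance_test(_net(W, roster), xy)

    def test_identical_distance_distributions_well_calibrated(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(40):
            n = 24
            roster = [f"I{i}" for i in range(n)]
            W = np.zeros((n, n))
            iu, ju = np.triu_indices(n, k=1)
            on = rng.random(len(iu)) < 0.3
            W[iu[on], ju[on]] = 0.5
            W = W + W.T
            xy = pd.DataFrame(
                {"x": rng.uniform(0, 5000, n), "y": rng.uniform(0, 5000, n)},
                index=pd.Index(roster, name="individual_id"),
            )
            pvals.append(dyad_distance_test(_net(W, roster), xy).p)
        from scipy import stats

        # edges independent of positions -> no systematic signal
        assert stats.kstest(pvals, "uniform").pvalue > 0.005


class TestWeightDistanceSlope:
    def test_collinear_dyads_exact_slope(self):
        """Distances falling 500 m per 0.1 weight -> slope -5000 m."""
        roster = ["A", "B", "C", "D", "E", "F"]
        W = np.zeros((6, 6))
        for (a, b), w in zip([(0, 1), (2, 3), (4, 5)], [0.1, 0.2, 0.3]):
            W[a, b] = W[b, a] = w
        xy = pd.DataFrame(
            {
                "x": [0.0, 1000.0, 50_000.0, 50_500.0, 100_000.0, 100_000.0 + 1e-9],
                "y": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            },
            index=pd.Index(roster, name="individual_id"),
        )
        boxes = pd.DataFrame(
            {"box_id": [f"B{i}" for i in range(10)], "x": np.linspace(0, 1e5, 10), "y": 0.0}
        )
        res = weight_distance_slope(
            _net(W, roster), xy, boxes, n_rand=9, seed=0, exclude_cohabiting=False
        )
        assert res.slope == pytest.approx(-5000.0, rel=1e-6)

    def test_constant_weights_rejected(self):
        roster = ["A", "B", "C", "D", "E", "F"]
        W = np.zeros((6, 6))
        for a, b in [(0, 1), (2, 3), (4, 5)]:
            W[a, b] = W[b, a] = 0.2
        xy = pd.DataFrame(
            {"x": np.arange(6.0) * 100, "y": np.zeros(6)},
            index=pd.Index(roster, name="individual_id"),
        )
        boxes = pd.DataFrame({"box_id": ["B0", "B1"], "x": [0.0, 1.0], "y": [0.0, 0.0]})
        with pytest.raises(ValueError, match="constant"):
            weight_distance_slope(_net(W, roster), xy, boxes, n_rand=9, seed=0)


class TestCompetitionIndex:
    def test_single_feeder_global_ratio(self):
        """With one site the index collapses to birds per box for everyone."""
        sm = simple_sitemap(n_feeders=1, n_boxes=8)
        props = pd.DataFrame(
            np.ones((20, 1)),
            index=[f"I{i}" for i in range(20)],
            columns=["F0"],
        )
        comp = competition_index(props, sm, sm.boxes["box_id"].tolist())
        np.testing.assert_allclose(comp.individual_competition, 20 / 8)

    def test_time_weighted_average(self):
        """50/50 time between competitions 1.0 and 3.0 -> 2.0."""
        feeders = pd.DataFrame(
            {"feeder_id": ["F0", "F1"], "x": [0.0, 1000.0], "y": [0.0, 0.0]}
        )
        boxes = pd.DataFrame(
            {
                "box_id": ["B0", "B1", "B2", "B3"],
                "x": [0.0, 0.0, 0.0, 1000.0],
                "y": [1.0, 2.0, 3.0, 1.0],
            }
        )
        sm = build_sitemap(feeders, boxes)
        # F0 has 3 boxes, F1 has 1; populations: F0 = 3, F1 = 3
        props = pd.DataFrame(
            {
                "F0": [1.0, 1.0, 0.5, 0.5, 0.0, 0.0],
                "F1": [0.0, 0.0, 0.5, 0.5, 1.0, 1.0],
            },
            index=[f"I{i}" for i in range(6)],
        )
        comp = competition_index(props, sm, boxes["box_id"].tolist())
        assert comp.local_competition["F0"] == pytest.approx(1.0)
        assert comp.local_competition["F1"] == pytest.approx(3.0)
        assert comp.individual_competition["I2"] == pytest.approx(2.0)

    def test_population_conserved(self, small_winter):
        props = visit_proportions(small_winter.detections)
        feeders = small_winter.feeders
        # a box beside every feeder so no feeder is orphaned
        boxes = pd.DataFrame(
            {
                "box_id": [f"B{i:02d}" for i in range(len(feeders))],
                "x": feeders["x"] + 10.0,
                "y": feeders["y"] - 5.0,
            }
        )
        sm = build_sitemap(feeders, boxes)
        comp = competition_index(props, sm, boxes["box_id"].tolist())
        assert comp.local_population.sum() == pytest.approx(len(props))
        # each bird's index is bounded by the local extremes it visits
        lc = comp.local_competition
        for ind, row in props.iterrows():
            visited = row.index[row > 0]
            assert lc[visited].min() - 1e-9 <= comp.individual_competition[ind] <= lc[visited].max() + 1e-9

    def test_orphaned_feeder_error_lists_feeders(self):
        feeders = pd.DataFrame(
            {"feeder_id": ["F0", "F1"], "x": [0.0, 1000.0], "y": [0.0, 0.0]}
        )
        boxes = pd.DataFrame({"box_id": ["B0"], "x": [0.0], "y": [0.0]})  # near F0 only
        sm = build_sitemap(feeders, boxes)
        props = pd.DataFrame({"F0": [0.5], "F1": [0.5]}, index=["I0"])
        with pytest.raises(ValueError, match="F1"):
            competition_index(props, sm, ["B0"])

    def test_proportions_must_sum_to_one(self):
        sm = simple_sitemap()
        props = pd.DataFrame({"F0": [0.7]}, index=["I0"])
        with pytest.raises(ValueError, match="sum to 1"):
            competition_index(props, sm, sm.boxes["box_id"].tolist())
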