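"""Theta, delta-theta and rank-product ranking."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thetascreen as ts
from thetascreen.ranking import (
    delta_theta,
    delta_theta_table,
    rank_product,
    theta_degrees,
)
from conftest import make_centered_table

angles = st.floats(min_value=0.0, max_value=360.0, exclude_max=True)


@pytest.mark.parametrize(
    "xy, expected",
    [((1, 0), 0.0), ((0, 1), 90.0), ((-1, 0), 180.0), ((0, -1), 270.0),
     ((-1, -1), 225.0), ((1, 1), 45.0)],
)
def test_theta_quadrants(xy, expected):
    assert theta_degrees(*xy) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "a, b, expected",
    [(0, 90, 90.0), (350, 10, 20.0), (45, 225, 180.0), (10, 10, 0.0), (359, 1, 2.0)],
)
def test_delta_theta_wraparound(a, b, expected):
    assert delta_theta(a, b) == pytest.approx(expected, abs=1e-12)
    assert delta_theta(b, a) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(a=angles, b=angles, c=angles)
def test_delta_theta_is_a_circular_pseudometric(a, b, c):
    dab, dbc, dac = delta_theta(a, b), delta_theta(b, c), delta_theta(a, c)
    assert 0.0 <= dab <= 180.0
    assert dac <= dab + dbc + 1e-9  # triangle inequality on the circle
    assert delta_theta(a, a) == 0.0


def test_theta_against_cosine_similarity_oracle():
    """2-D theta difference equals arccos of the normalized dot product."""
    rng = np.random.default_rng(42)
    v = rng.normal(size=(2000, 2, 2))
    t = theta_degrees(v[:, :, 0], v[:, :, 1])
    dt = np.array([delta_theta(a, b) for a, b in t])
    cos = (v[:, 0] * v[:, 1]).sum(axis=1) / (
        np.linalg.norm(v[:, 0], axis=1) * np.linalg.norm(v[:, 1], axis=1)
    )
    oracle = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    assert np.abs(dt - oracle).max() < 1e-9


class TestComputeTheta:
    def _table(self, coords, compounds, lines, reps=1):
        frames = []
        for line in lines:
            for r in range(1, reps + 1):
                t = make_centered_table(coords, compounds, cell_line=line, replicate=r)
                frames.append(t.data)
        df = pd.concat(frames, ignore_index=True)
        return ts.CenteredPCTable(data=df, offset=np.zeros(coords.shape[1]), k=coords.shape[1])

    def test_theta_and_magnitude(self):
        coords = np.array([[1.0, 0.0], [0.0, 2.0], [-3.0, -3.0]])
        table = self._table(coords, ["C1", "C2", "C3"], ["CL01"])
        th = ts.compute_theta(table)
        by = th.set_index("compound")
        assert by.loc["C1", "theta_deg"] == pytest.approx(0.0)
        assert by.loc["C2", "theta_deg"] == pytest.approx(90.0)
        assert by.loc["C3", "theta_deg"] == pytest.approx(225.0)
        assert by.loc["C3", "magnitude"] == pytest.approx(np.sqrt(18))

    def test_magnitude_floor_flags_theta_undefined(self):
        coords = np.array([[5.0, 0.0], [0.01, 0.0]])
        table = self._table(coords, ["C1", "C2"], ["CL01"])
        th = ts.compute_theta(table, magnitude_floor=1.0)
        by = th.set_index("compound")
        assert np.isfinite(by.loc["C1", "theta_deg"])
        assert np.isnan(by.loc["C2", "theta_deg"])

    def test_inactive_compound_has_undefined_theta(self):
        coords = np.array([[5.0, 0.0], [4.0, 3.0]])
        table = self._table(coords, ["C1", "C2"], ["CL01"])
        activity = pd.DataFrame(
            {"compound": ["C1", "C2"], "cell_line": "CL01", "active": [True, False]}
        )
        th = ts.compute_theta(table, activity=activity)
        by = th.set_index("compound")
        assert np.isfinite(by.loc["C1", "theta_deg"])
        assert np.isnan(by.loc["C2", "theta_deg"])

    def test_undefined_theta_propagates_to_missing_delta(self):
        coords = np.array([[5.0, 0.0], [0.001, 0.0]])
        table = self._table(coords, ["C1", "C2"], ["CL01", "CL02"])
        th = ts.compute_theta(table, magnitude_floor=1.0)
        dl = delta_theta_table(th)
        by = dl.set_index("compound")["delta_theta_deg"]
        assert np.isfinite(by["C1"])
        assert np.isnan(by["C2"])

    def test_single_component_rejected(self):
        df = make_centered_table(np.ones((3, 1)), ["C1", "C2", "C3"]).data
        table = ts.CenteredPCTable(data=df, offset=np.zeros(1), k=1)
        with pytest.raises(ts.PipelineError):
            ts.compute_theta(table)

    def test_kd_mode_matches_2d_on_two_components(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(10, 2))
        table = self._table(coords, [f"C{i}" for i in range(10)], ["CL01", "CL02"])
        # different coords per line so delta is nontrivial
        table.data.loc[table.data["cell_line"] == "CL02", ["pc_1", "pc_2"]] = rng.normal(size=(10, 2))
        th = ts.compute_theta(table)
        d2 = delta_theta_table(th, mode="2d").set_index("compound")["delta_theta_deg"]
        dk = delta_theta_table(th, mode="kd").set_index("compound")["delta_theta_deg"]
        np.testing.assert_allclose(d2.to_numpy(), dk.to_numpy(), atol=1e-9)


def test_global_rotation_leaves_delta_theta_unchanged():
    rng = np.random.default_rng(7)
    v = rng.normal(size=(200, 2))
    base = theta_degrees(v[:, 0], v[:, 1])
    d0 = np.array([delta_theta(a, b) for a, b in zip(base[::2], base[1::2])])
    for _ in range(50):
        r = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        w = v @ R.T
        t = theta_degrees(w[:, 0], w[:, 1])
        d = np.array([delta_theta(a, b) for a, b in zip(t[::2], t[1::2])])
        assert np.abs(d - d0).max() < 1e-9


class TestRankProduct:
    @staticmethod
    def _delta(records):
        return pd.DataFrame(
            records,
            columns=["compound", "cell_line_a", "cell_line_b", "replicate", "delta_theta_deg"],
        )

    def test_geometric_mean_example(self):
        # one item ranked 1, 4, 2 across three replicates -> RP = (8)^(1/3) = 2
        rows = []
        deltas = {  # item X gets rank 1, 4, 2; fillers take the other ranks
            1: {"X": 170, "A": 100, "B": 90, "C": 80},
            2: {"X": 60, "A": 170, "B": 150, "C": 100},
            3: {"X": 150, "A": 170, "B": 90, "C": 80},
        }
        for rep, d in deltas.items():
            for cpd, dt in d.items():
                rows.append((cpd, "CL01", "CL02", rep, float(dt)))
        out = rank_product(self._delta(rows)).set_index("compound")
        assert list(out.loc["X", ["rank_rep_1", "rank_rep_2", "rank_rep_3"]]) == [1.0, 4.0, 2.0]
        assert out.loc["X", "rank_product"] == 2.0

    def test_single_replicate_ordering_equals_delta_ordering(self):
        rows = [(c, "CL01", "CL02", 1, dt) for c, dt in
                [("A", 10.0), ("B", 170.0), ("C", 90.0)]]
        out = rank_product(self._delta(rows))
        assert out["compound"].tolist() == ["B", "C", "A"]
        assert out["rank_product"].tolist() == [1.0, 2.0, 3.0]

    def test_fractional_ranks_on_ties(self):
        rows = [(c, "CL01", "CL02", 1, dt) for c, dt in
                [("A", 170.0), ("B", 170.0), ("C", 90.0)]]
        out = rank_product(self._delta(rows)).set_index("compound")
        assert out.loc["A", "rank_rep_1"] == 1.5
        assert out.loc["B", "rank_rep_1"] == 1.5

    def test_item_missing_in_a_replicate_is_excluded(self):
        rows = [("A", "CL01", "CL02", 1, 90.0), ("B", "CL01", "CL02", 1, 10.0),
                ("A", "CL01", "CL02", 2, 80.0)]
        out = rank_product(self._delta(rows))
        assert out["compound"].tolist() == ["A"]

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(11)
        rows = [(f"C{i}", "CL01", "CL02", r, float(rng.uniform(0, 180)))
                for i in range(8) for r in (1, 2, 3)]
        d = self._delta(rows)
        a = rank_product(d)
        b = rank_product(d.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(a, b)

    def test_monotone_transform_invariance(self):
        """Any strictly increasing per-replicate transform preserves the ordering."""
        rng = np.random.default_rng(12)
        rows = [(f"C{i}", "CL01", "CL02", r, float(rng.uniform(0, 180)))
                for i in range(10) for r in (1, 2)]
        d = self._delta(rows)
        a = rank_product(d)
        d2 = d.copy()
        d2["delta_theta_deg"] = np.expm1(d2["delta_theta_deg"] / 30.0)
        b = rank_product(d2)
        ra = a.set_index("compound")
        rb = b.set_index("compound")
        for item in ra.index:
            assert ra.loc[item, "rank_product"] == rb.loc[item, "rank_product"]
            assert ra.loc[item, "rank_rep_1"] == rb.loc[item, "rank_rep_1"]
            assert ra.loc[item, "rank_rep_2"] == rb.loc[item, "rank_rep_2"]
        # the RP ordering itself is preserved (ties may reorder by the
        # mean-delta tie-break, which is transform-dependent by design)
        assert a["rank_product"].is_monotonic_increasing
        assert b["rank_product"].is_monotonic_increasing


class TestHitList:
    @staticmethod
    def _ranked():
        rows = [(c, "CL01", "CL02", 1, dt) for c, dt in
                [("A", 170.0), ("B", 150.0), ("C", 120.0), ("D", 30.0)]]
        d = pd.DataFrame(rows, columns=["compound", "cell_line_a", "cell_line_b",
                                        "replicate", "delta_theta_deg"])
        return rank_product(d)

    def test_top_n_larger_than_table_returns_everything(self):
        hits = ts.build_hit_list(self._ranked(), top_n=100)
        assert len(hits) == 4

    def test_exclusion_promotes_next_item(self, tmp_path):
        p = tmp_path / "exclude.txt"
        p.write_text("# cytotoxic\nA\n")
        from thetascreen.ranking import read_exclusion_list
        hits = ts.build_hit_list(self._ranked(), exclude=read_exclusion_list(p))
        assert hits.iloc[0]["compound"] == "B"
        assert hits.iloc[0]["final_rank"] == 1

    def test_unknown_excluded_compound_ignored(self):
        hits = ts.build_hit_list(self._ranked(), exclude=["NOPE"])
        assert len(hits) == 4

    def test_restricted_to_pan_active(self):
        hits = ts.build_hit_list(self._ranked(), active_compounds=["B", "D"])
        assert hits["compound"].tolist() == ["B", "D"]
        assert hits["final_rank"].tolist() == [1, 2]
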