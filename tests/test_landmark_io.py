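"""TPS round trips, curve resampling and metadata merging."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomorph.errors import DegenerateCurveError, StructureError, TPSParseError
from paleomorph.landmark_io import (
    attach_metadata,
    read_tps,
    resample_curve,
    write_tps,
)

from conftest import random_dataset


class TestReadWrite:
    @pytest.mark.parametrize("structured", [True, False])
    def test_round_trip_identity(self, rng, tmp_path, structured):
        """write_tps then read_tps reproduces coordinates to 6 decimals."""
        ds = random_dataset(rng, n=3)
        path = tmp_path / "rt.tps"
        write_tps(ds, path, structured=structured)
        back = read_tps(path, y_flip=False)
        assert back.specimen_ids == ds.specimen_ids
        for a, b in zip(ds, back):
            np.testing.assert_allclose(a.points, b.points, atol=5e-7)

    def test_structured_record_layout(self, rng, tmp_path):
        """Structured records declare the fixed count and one curve block."""
        ds = random_dataset(rng, n=1, n_fixed=7, n_curve=38)
        path = tmp_path / "s.tps"
        write_tps(ds, path)
        text = path.read_text()
        assert "LM=7" in text and "CURVES=1" in text and "POINTS=38" in text
        back = read_tps(path, y_flip=False)
        assert back[0].n_points == 45
        assert back[0].n_fixed == 7
        assert back[0].curves == [(7, 45)]

    def test_flattened_equals_structured(self, rng, tmp_path):
        ds = random_dataset(rng, n=2)
        write_tps(ds, tmp_path / "a.tps", structured=True)
        write_tps(ds, tmp_path / "b.tps", structured=False)
        a = read_tps(tmp_path / "a.tps", y_flip=False)
        b = read_tps(tmp_path / "b.tps", y_flip=False)
        for ca, cb in zip(a, b):
            np.testing.assert_allclose(ca.points, cb.points)
        assert (tmp_path / "b.tps").read_text().splitlines()[0] == "LM=45"

    def test_y_flip_negates_y(self, rng, tmp_path):
        ds = random_dataset(rng, n=1)
        path = tmp_path / "f.tps"
        write_tps(ds, path)
        flipped = read_tps(path, y_flip=True)
        plain = read_tps(path, y_flip=False)
        np.testing.assert_allclose(flipped[0].points[:, 0], plain[0].points[:, 0])
        np.testing.assert_allclose(flipped[0].points[:, 1], -plain[0].points[:, 1])

    def test_scale_applied(self, tmp_path):
        path = tmp_path / "s.tps"
        path.write_text("LM=3\n1 2\n3 4\n5 6\nID=a\nSCALE=0.5\n")
        ds = read_tps(path, y_flip=False)
        np.testing.assert_allclose(ds[0].points, [[0.5, 1], [1.5, 2], [2.5, 3]])
        assert ds[0].scale == 0.5

    def test_malformed_count_names_record(self, tmp_path):
        path = tmp_path / "bad.tps"
        path.write_text("LM=3\n1 2\n3 4\nID=a\n\nLM=4\n1 1\n2 2\n3 3\nID=b\n")
        with pytest.raises(TPSParseError, match="#1"):
            read_tps(path)

    def test_inconsistent_point_counts_lists_offenders(self, tmp_path):
        path = tmp_path / "mix.tps"
        path.write_text(
            "LM=3\n1 2\n3 4\n5 6\nID=a\nLM=4\n1 1\n2 2\n3 3\n4 4\nID=b\n"
        )
        with pytest.raises(StructureError, match="b"):
            read_tps(path)

    def test_empty_file(self, tmp_path, caplog):
        path = tmp_path / "empty.tps"
        path.write_text("")
        with caplog.at_level(logging.WARNING):
            ds = read_tps(path)
        assert len(ds) == 0
        assert any("no records" in r.message for r in caplog.records)
        write_tps(ds, tmp_path / "out.tps")
        assert (tmp_path / "out.tps").read_text() == ""


def brute_force_arc_positions(polyline, fractions):
    """Independent arc-length walk along a dense polyline."""
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0], np.cumsum(seg)])
    out = []
    for f in fractions:
        target = f * cum[-1]
        i = np.searchsorted(cum, target, side="right") - 1
        i = min(i, len(seg) - 1)
        t = (target - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        out.append(polyline[i] + t * (polyline[i + 1] - polyline[i]))
    return np.array(out)


class TestResampleCurve:
    def test_segment_analytic(self):
        out = resample_curve(np.array([[0.0, 0.0], [1.0, 0.0]]), 3)
        np.testing.assert_allclose(out, [[0, 0], [0.5, 0], [1, 0]])

    def test_semicircle_matches_arc_angles(self):
        """Equal arc-length points on a unit semicircle sit at 0/45/90/135/180 deg."""
        theta = np.linspace(0, np.pi, 1000)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        out = resample_curve(circle, 5)
        expected_angles = np.deg2rad([0, 45, 90, 135, 180])
        expected = np.column_stack([np.cos(expected_angles), np.sin(expected_angles)])
        np.testing.assert_allclose(out, expected, atol=1e-3)
        # and against the independent arc-length walker
        oracle = brute_force_arc_positions(circle, np.linspace(0, 1, 5))
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_output_count_and_endpoints(self, rng):
        curve = rng.uniform(0, 10, size=(17, 2))
        out = resample_curve(curve, 38)
        assert out.shape == (38, 2)
        np.testing.assert_array_equal(out[0], curve[0])
        np.testing.assert_array_equal(out[-1], curve[-1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 40))
    def test_equal_arc_length_gaps(self, seed, n_out):
        """Consecutive output points are equally spaced in arc length."""
        r = np.random.default_rng(seed)
        # monotone-x polyline: no self-intersection, so arc positions of the
        # outputs can be recovered unambiguously by projection
        x = np.cumsum(r.uniform(0.1, 1.0, size=12))
        y = r.uniform(-1, 1, size=12)
        curve = np.column_stack([x, y])
        out = resample_curve(curve, n_out)
        gaps = []
        for a, b in zip(out[:-1], out[1:]):
            gaps.append(np.linalg.norm(b - a))
        # chord lengths equal arc lengths here because outputs subdivide
        # straight input segments densely enough only approximately; use the
        # true arc-length positions instead
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        total = seg.sum()
        positions = [0.0]
        for p in out[1:-1]:
            # locate p's arc position by projecting onto the polyline
            best = None
            cum = 0.0
            for i in range(len(curve) - 1):
                d = curve[i + 1] - curve[i]
                L = np.linalg.norm(d)
                if L > 0:
                    t = np.clip(np.dot(p - curve[i], d) / L**2, 0, 1)
                    cand = curve[i] + t * d
                    err = np.linalg.norm(cand - p)
                    if best is None or err < best[0]:
                        best = (err, cum + t * L)
                cum += L
            positions.append(best[1])
        positions.append(total)
        gaps = np.diff(positions)
        np.testing.assert_allclose(gaps, total / (n_out - 1), rtol=1e-6, atol=1e-9)

    def test_densification_invariance(self):
        """Refining the input polyline barely changes the output for smooth curves."""
        theta_coarse = np.linspace(0, np.pi, 200)
        theta_fine = np.linspace(0, np.pi, 5000)
        a = resample_curve(
            np.column_stack([np.cos(theta_coarse), np.sin(theta_coarse)]), 38
        )
        b = resample_curve(
            np.column_stack([np.cos(theta_fine), np.sin(theta_fine)]), 38
        )
        assert np.abs(a - b).max() < 1e-4

    def test_zero_length_curve_raises(self):
        with pytest.raises(DegenerateCurveError):
            resample_curve(np.ones((5, 2)), 3)


class TestAttachMetadata:
    def make_table(self, ds, n_guilds=3):
        return pd.DataFrame(
            {
                "specimen_id": ds.specimen_ids,
                "guild": [f"guild_{i % n_guilds}" for i in range(len(ds))],
                "age_ka": [1.0 * i for i in range(len(ds))],
            }
        )

    def test_merge_and_guild_labels(self, rng):
        ds = random_dataset(rng, n=18)
        table = self.make_table(ds, n_guilds=18)
        merged = attach_metadata(ds, table)
        guilds = {c.meta["guild"] for c in merged}
        assert len(guilds) == 18
        assert merged[3].meta["age_ka"] == 3.0

    def test_row_order_invariance(self, rng):
        ds = random_dataset(rng, n=6)
        table = self.make_table(ds)
        shuffled = table.sample(frac=1, random_state=7).reset_index(drop=True)
        a = attach_metadata(ds, table)
        b = attach_metadata(ds, shuffled)
        assert [c.meta for c in a] == [c.meta for c in b]

    def test_duplicate_keys_raise(self, rng):
        ds = random_dataset(rng, n=3)
        table = self.make_table(ds)
        table.loc[1, "specimen_id"] = table.loc[0, "specimen_id"]
        with pytest.raises(ValueError, match="duplicate"):
            attach_metadata(ds, table)

    def test_invalid_age_names_row(self, rng):
        ds = random_dataset(rng, n=3)
        table = self.make_table(ds)
        table["age_ka"] = table["age_ka"].astype(object)
        table.loc[2, "age_ka"] = "old"
        with pytest.raises(ValueError, match="spec_2"):
            attach_metadata(ds, table)

    def test_empty_table_warns_and_leaves_unchanged(self, rng, caplog):
        ds = random_dataset(rng, n=3)
        with caplog.at_level(logging.WARNING):
            merged = attach_metadata(ds, pd.DataFrame({"specimen_id": []}))
        assert [c.meta for c in merged] == [c.meta for c in ds]
        assert any("empty" in r.message for r in caplog.records)

    def test_missing_specimens_reported(self, rng, caplog):
        ds = random_dataset(rng, n=4)
        table = self.make_table(ds).iloc[:2]
        with caplog.at_level(logging.WARNING):
            merged = attach_metadata(ds, table)
        assert merged[3].meta == {}
        assert any("missing" in r.message for r in caplog.records)
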