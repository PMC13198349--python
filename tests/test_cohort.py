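"""Cohort aggregation: regional stats, trends, contrasts, prevalence maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lpmsim.cohort import (
    ALL_SEPTUM,
    cohort_prevalence_map,
    collision_free_fraction,
    length_trend,
    pairwise_device_compare,
    regional_stats,
    risks_to_frame,
)
from lpmsim.regional import RegionLabels, SeptalCoordinates


def _labels(patients, n_nodes=12, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for p in patients:
        out[p] = RegionLabels(
            node_ids=np.arange(n_nodes),
            aha=rng.choice([2, 3, 8, 9, 14], n_nodes),
            lbbap=rng.choice(["LAF", "none"], n_nodes),
            tv_band=rng.random(n_nodes) < 0.3,
        )
    return out


def _records(patients, n_nodes=12, device="devA", fill=None, seed=1):
    rng = np.random.default_rng(seed)
    rows = []
    for p in patients:
        for node in range(n_nodes):
            pos = bool(rng.random() < 0.5) if fill is None else bool(fill(p, node))
            rows.append({
                "patient": p, "node": node, "device": device,
                "length_mm": 30.0, "diameter_mm": 6.0,
                "rv_wall": pos, "pm": False, "tv": False, "combined": pos,
            })
    return pd.DataFrame(rows)


class TestRegionalStats:
    def test_all_positive_gives_100_pm_0(self):
        patients = ["a", "b", "c"]
        df = _records(patients, fill=lambda p, n: True)
        risks = regional_stats(df, _labels(patients))
        for r in risks:
            if r.structure in ("RV_WALL", "COMBINED"):
                assert r.mean == 100.0 and r.sd == 0.0

    def test_two_patients_half_split(self):
        patients = ["a", "b"]
        df = _records(patients, fill=lambda p, n: p == "a")
        risks = regional_stats(df, _labels(patients))
        allsep = next(r for r in risks
                      if r.region == ALL_SEPTUM and r.structure == "COMBINED")
        assert allsep.mean == pytest.approx(50.0)
        assert allsep.sd == pytest.approx(50.0)  # population SD of {100, 0}
        assert allsep.n_patients == 2

    def test_matches_brute_force_tabulation(self):
        """Module output equals a direct recomputation from the flat table."""
        patients = [f"p{i}" for i in range(5)]
        labels = _labels(patients, seed=3)
        df = _records(patients, seed=4)
        risks = risks_to_frame(regional_stats(df, labels))
        lab = pd.concat([
            pd.DataFrame({"patient": p, "node": l.node_ids, "aha": l.aha})
            for p, l in labels.items()
        ])
        merged = df.merge(lab, on=["patient", "node"])
        for seg in sorted(merged.aha.unique()):
            sub = merged[merged.aha == seg]
            per_pat = sub.groupby("patient").combined.mean() * 100
            row = risks[(risks.region == str(seg)) & (risks.structure == "COMBINED")]
            assert row["mean"].iloc[0] == pytest.approx(per_pat.mean())
            assert row["sd"].iloc[0] == pytest.approx(per_pat.std(ddof=0))

    def test_combined_bounded_by_structures(self):
        """COMBINED >= each structure and <= their sum, per region."""
        patients = ["a", "b", "c"]
        rng = np.random.default_rng(9)
        rows = []
        for p in patients:
            for node in range(20):
                w, m, t = rng.random(3) < 0.3
                rows.append({"patient": p, "node": node, "device": "d",
                             "length_mm": 30.0, "diameter_mm": 6.0,
                             "rv_wall": w, "pm": m, "tv": t,
                             "combined": bool(w | m | t)})
        risks = risks_to_frame(regional_stats(pd.DataFrame(rows),
                                              _labels(patients, n_nodes=20)))
        for region, sub in risks.groupby("region"):
            by = sub.set_index("structure")["mean"]
            parts = by[["RV_WALL", "PM", "TV"]]
            assert by["COMBINED"] >= parts.max() - 1e-9
            assert by["COMBINED"] <= parts.sum() + 1e-9

    def test_all_septum_is_site_weighted_average_of_aha(self):
        patients = ["a", "b"]
        labels = _labels(patients, n_nodes=30, seed=5)
        df = _records(patients, n_nodes=30, seed=6)
        lab = pd.concat([
            pd.DataFrame({"patient": p, "node": l.node_ids, "aha": l.aha})
            for p, l in labels.items()
        ])
        merged = df.merge(lab, on=["patient", "node"])
        for p, sub in merged.groupby("patient"):
            total = sub.combined.mean()
            weighted = (sub.groupby("aha").combined.agg(["mean", "size"])
                        .pipe(lambda t: (t["mean"] * t["size"]).sum() / t["size"].sum()))
            assert total == pytest.approx(weighted, abs=1e-12)


class TestLengthTrend:
    @staticmethod
    def _sweep(slopefn):
        rows = []
        for L in (15.0, 20.0, 25.0, 30.0):
            frac = slopefn(L)
            for p in ("a", "b"):
                for node in range(20):
                    pos = node < round(frac * 20)
                    rows.append({"patient": p, "node": node, "device": f"L{L}",
                                 "length_mm": L, "diameter_mm": 6.0,
                                 "rv_wall": pos, "pm": False, "tv": False,
                                 "combined": pos})
        return pd.DataFrame(rows)

    def test_exactly_linear_risk_r_one(self):
        df = self._sweep(lambda L: L / 50.0)
        trends = length_trend(df, _labels(["a", "b"], n_nodes=20))
        t = next(x for x in trends
                 if x.region == ALL_SEPTUM and x.structure == "COMBINED")
        assert t.pearson_r == pytest.approx(1.0)
        assert t.slope_per_5mm == pytest.approx(10.0)  # 2%/mm * 5

    def test_constant_risk_zero_slope_nan_r(self):
        df = self._sweep(lambda L: 0.5)
        trends = length_trend(df, _labels(["a", "b"], n_nodes=20))
        t = next(x for x in trends
                 if x.region == ALL_SEPTUM and x.structure == "COMBINED")
        assert t.slope_per_5mm == 0.0
        assert np.isnan(t.pearson_r)

    def test_matches_hand_ols(self):
        df = self._sweep(lambda L: 0.1 + 0.012 * L + (0.05 if L == 25 else 0))
        trends = length_trend(df, _labels(["a", "b"], n_nodes=20))
        t = next(x for x in trends
                 if x.region == ALL_SEPTUM and x.structure == "COMBINED")
        xs = np.array(t.lengths)
        ys = np.array([
            df[df.length_mm == L].groupby("patient").combined.mean().mean() * 100
            for L in xs
        ])
        slope = ((xs - xs.mean()) * (ys - ys.mean())).sum() / ((xs - xs.mean()) ** 2).sum()
        assert t.slope_per_5mm == pytest.approx(5 * slope, abs=1e-9)
        assert t.pearson_r == pytest.approx(np.corrcoef(xs, ys)[0, 1], abs=1e-12)

    def test_needs_three_lengths(self):
        df = self._sweep(lambda L: 0.5)
        df = df[df.length_mm.isin([15.0, 20.0])]
        with pytest.raises(ValueError):
            length_trend(df, _labels(["a", "b"], n_nodes=20))


class TestCollisionFree:
    def test_all_negative_is_100(self):
        patients = ["a", "b"]
        df = _records(patients, fill=lambda p, n: False)
        assert collision_free_fraction(df, _labels(patients), ALL_SEPTUM) == 100.0

    def test_complement_identity(self):
        patients = ["a", "b", "c"]
        df = _records(patients, seed=8)
        labels = _labels(patients)
        cf = collision_free_fraction(df, labels, ALL_SEPTUM)
        pooled_prevalence = 100.0 * df.combined.mean()
        assert cf == pytest.approx(100.0 - pooled_prevalence, abs=1e-9)

    def test_pooled_differs_from_per_patient_mean_on_unequal_regions(self):
        # patient a: 2 region sites 100% positive; patient b: 8 sites all negative
        rows = []
        for node in range(2):
            rows.append({"patient": "a", "node": node, "device": "d",
                         "length_mm": 30.0, "diameter_mm": 6.0, "rv_wall": True,
                         "pm": False, "tv": False, "combined": True})
        for node in range(8):
            rows.append({"patient": "b", "node": node, "device": "d",
                         "length_mm": 30.0, "diameter_mm": 6.0, "rv_wall": False,
                         "pm": False, "tv": False, "combined": False})
        df = pd.DataFrame(rows)
        labels = {
            "a": RegionLabels(np.arange(2), np.full(2, 14), np.full(2, "none"),
                              np.zeros(2, bool)),
            "b": RegionLabels(np.arange(8), np.full(8, 14), np.full(8, "none"),
                              np.zeros(8, bool)),
        }
        pooled = collision_free_fraction(df, labels, "14")
        assert pooled == pytest.approx(80.0)  # 8 of 10 sites free
        per_patient_mean = 50.0  # (0% + 100%) / 2
        assert pooled != per_patient_mean


class TestPairwiseCompare:
    def _two_device_records(self, risk_a, risk_b):
        rows = []
        for i, (ra, rb) in enumerate(zip(risk_a, risk_b)):
            p = f"p{i}"
            for dev, frac in (("A", ra), ("B", rb)):
                for node in range(10):
                    pos = node < round(frac * 10)
                    rows.append({"patient": p, "node": node, "device": dev,
                                 "length_mm": 30.0, "diameter_mm": 6.0,
                                 "rv_wall": pos, "pm": False, "tv": False,
                                 "combined": pos})
        return pd.DataFrame(rows)

    def test_identical_risks_t_zero_p_one(self):
        df = self._two_device_records([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        labels = _labels([f"p{i}" for i in range(3)], n_nodes=10)
        res = pairwise_device_compare(df, labels, "A", "B")
        assert res.t_statistic == 0.0 and res.p_adjusted == 1.0

    def test_constant_shift_degenerate(self):
        df = self._two_device_records([0.4, 0.6, 0.8], [0.3, 0.5, 0.7])
        labels = _labels([f"p{i}" for i in range(3)], n_nodes=10)
        res = pairwise_device_compare(df, labels, "A", "B")
        assert res.degenerate
        assert res.mean_difference == pytest.approx(10.0)

    def test_matches_textbook_t(self):
        rng = np.random.default_rng(12)
        ra = rng.uniform(0.2, 0.9, 10)
        rb = np.clip(ra - rng.uniform(0.0, 0.3, 10), 0, 1)
        df = self._two_device_records(ra, rb)
        labels = _labels([f"p{i}" for i in range(10)], n_nodes=10)
        res = pairwise_device_compare(df, labels, "A", "B", n_comparisons=3)
        pa = df[df.device == "A"].groupby("patient").combined.mean() * 100
        pb = df[df.device == "B"].groupby("patient").combined.mean() * 100
        d = (pa - pb).to_numpy()
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-9)
        p_hand = stats.ttest_rel(pa, pb).pvalue
        assert res.p_adjusted == pytest.approx(min(1.0, 3 * p_hand), abs=1e-12)

    def test_needs_two_patients(self):
        df = self._two_device_records([0.5], [0.4])
        labels = _labels(["p0"], n_nodes=10)
        with pytest.raises(ValueError):
            pairwise_device_compare(df, labels, "A", "B")


class TestPrevalenceMap:
    def _coords(self, patients, n_nodes=16, seed=0):
        rng = np.random.default_rng(seed)
        return {
            p: SeptalCoordinates(np.arange(n_nodes), rng.uniform(0, 1, n_nodes),
                                 rng.uniform(0, 1, n_nodes))
            for p in patients
        }

    def test_single_patient_map_equals_binary_grid(self):
        df = _records(["a"], n_nodes=16, seed=2)
        coords = self._coords(["a"])
        counts, coverage, proportion, overlay = cohort_prevalence_map(
            df, coords, (5, 5))
        assert set(np.unique(counts[coverage > 0])) <= {0.0, 1.0}
        np.testing.assert_array_equal(coverage > 0, ~np.isnan(proportion))

    def test_six_of_ten_in_overlay(self):
        patients = [f"p{i}" for i in range(10)]
        df = _records(patients, n_nodes=4, fill=lambda p, n: int(p[1:]) < 6)
        coords = {
            p: SeptalCoordinates(np.arange(4), np.full(4, 0.5), np.full(4, 0.5))
            for p in patients
        }
        counts, coverage, proportion, overlay = cohort_prevalence_map(df, coords, (4, 4))
        cell = (2, 2)
        assert counts[cell] == 6 and coverage[cell] == 10
        assert proportion[cell] == pytest.approx(0.6)
        assert overlay[cell]

    def test_overlay_area_monotone_in_threshold(self):
        patients = [f"p{i}" for i in range(6)]
        df = _records(patients, n_nodes=30, seed=13)
        coords = self._coords(patients, n_nodes=30, seed=14)
        areas = []
        for thr in (0.2, 0.4, 0.6, 0.8):
            *_, overlay = cohort_prevalence_map(df, coords, (6, 6), threshold=thr)
            areas.append(overlay.sum())
        assert all(a >= b for a, b in zip(areas, areas[1:]))
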