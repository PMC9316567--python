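"""Background, normalization, bounds, classification, Exchange Units, binning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cartplot.data_model import (
    EU_DOMAINS,
    AnalysisConfig,
    BackgroundEstimate,
    ControlBounds,
    Group,
    Role,
)
from cartplot.synthetic import SyntheticConfig, generate_coculture, generate_controls
from cartplot.transfer import (
    analyze_coculture,
    bin_eu,
    classify_cell,
    derive_bounds,
    estimate_background,
    exchange_units,
    flip_orientation,
    normalize,
    subtract_background,
)


def _cells(role, green, red, area=None):
    n = len(green)
    area = area if area is not None else [100.0] * n
    return pd.DataFrame({
        "cell_id": [f"{role}_{i}" for i in range(n)],
        "experiment_id": "e",
        "role": role,
        "green_raw": np.asarray(green, dtype=float),
        "red_raw": np.asarray(red, dtype=float),
        "area": np.asarray(area, dtype=float),
        "perimeter": np.sqrt(4 * np.pi * np.asarray(area, dtype=float) / 0.8),
        "f5mc": np.nan,
        "fpi": np.nan,
    })


class TestBackground:
    def test_rate_arithmetic(self):
        cg = _cells("control_green", green=[500, 600], red=[10, 20], area=[100, 100])
        cr = _cells("control_red", green=[0, 0], red=[700, 800], area=[100, 100])
        bg = estimate_background(cg, cr)
        assert bg.red_bg_rate == pytest.approx(0.15)
        assert bg.green_bg_rate == pytest.approx(0.0)

    def test_zero_opposite_channel_gives_zero_rate(self):
        cg = _cells("control_green", [500], [0])
        cr = _cells("control_red", [0], [700])
        bg = estimate_background(cg, cr)
        assert bg.red_bg_rate == 0.0 and bg.green_bg_rate == 0.0

    def test_recovers_injected_rate(self):
        """With no bleed-through the cross-channel estimate equals the
        injected background rate up to sampling error."""
        cfg = SyntheticConfig(seed=11, n_control_green=200, n_control_red=200,
                              bleed_level=0.0, bg_green_rate=0.05, bg_red_rate=0.05)
        cg, cr = generate_controls(cfg)
        bg = estimate_background(cg, cr)
        assert bg.red_bg_rate == pytest.approx(0.05, rel=1e-9)
        assert bg.green_bg_rate == pytest.approx(0.05, rel=1e-9)

    def test_empty_controls_rejected(self):
        cg = _cells("control_green", [500], [0])
        with pytest.raises(ValueError):
            estimate_background(cg.iloc[:0], cg)

    def test_subtraction_and_clamp(self):
        bg = BackgroundEstimate(green_bg_rate=0.15, red_bg_rate=0.15)
        g, r = subtract_background(100.0, 10.0, 100.0, bg)
        assert g == pytest.approx(85.0)
        assert r == 0.0  # clamped
        g0, r0 = subtract_background(100.0, 10.0, 100.0, BackgroundEstimate(0.0, 0.0))
        assert (g0, r0) == (100.0, 10.0)


class TestNormalize:
    def test_worked_example(self):
        cg = _cells("control_green", [50, 100, 150], [0, 0, 0])
        cr = _cells("control_red", [0, 0, 0], [50, 100, 150])
        cc = _cells("cocultured", [200], [100])
        out, med_g, med_r = normalize(cc, cg, cr, BackgroundEstimate(0.0, 0.0))
        cell = out[out["role"] == "cocultured"].iloc[0]
        assert med_g == 100.0
        assert cell["green_norm"] == pytest.approx(200.0)

    def test_control_median_is_exactly_100(self, sim_tables):
        cg, cr, cc, _ = sim_tables
        bg = estimate_background(cg, cr)
        out, _, _ = normalize(cc, cg, cr, bg)
        g = out.loc[out["role"] == Role.CONTROL_GREEN.value, "green_norm"]
        r = out.loc[out["role"] == Role.CONTROL_RED.value, "red_norm"]
        assert float(np.median(g)) == pytest.approx(100.0, abs=1e-9)
        assert float(np.median(r)) == pytest.approx(100.0, abs=1e-9)

    def test_channel_scale_invariance(self):
        cg = _cells("control_green", [50, 100, 150], [1, 2, 3])
        cr = _cells("control_red", [1, 2, 3], [50, 100, 150])
        cc = _cells("cocultured", [200, 80], [100, 40])
        out1, _, _ = normalize(cc, cg, cr, BackgroundEstimate(0, 0))
        for df in (cg, cr, cc):
            df["green_raw"] *= 7.0
        out2, _, _ = normalize(cc, cg, cr, BackgroundEstimate(0, 0))
        np.testing.assert_allclose(out1["green_norm"], out2["green_norm"], rtol=1e-12)
        np.testing.assert_allclose(out1["red_norm"], out2["red_norm"], rtol=1e-12)

    def test_zero_control_median_rejected(self):
        cg = _cells("control_green", [0, 0, 0], [0, 0, 0])
        cr = _cells("control_red", [0, 0, 0], [50, 100, 150])
        with pytest.raises(ValueError, match="median"):
            normalize(cg.iloc[:0], cg, cr, BackgroundEstimate(0, 0))


class TestBounds:
    def test_extrema_bounds(self):
        cg = _cells("control_green", [60, 90, 140], [1, 3, 5])
        cr = _cells("control_red", [2, 3, 4], [70, 100, 150])
        cg["green_norm"], cg["red_norm"] = cg["green_raw"], cg["red_raw"]
        cr["green_norm"], cr["red_norm"] = cr["green_raw"], cr["red_raw"]
        b = derive_bounds(cg, cr)
        assert (b.green_lo, b.red_bleed_hi, b.red_lo, b.green_bleed_hi) == (60, 5, 70, 4)

    def test_trim_drops_order_statistics(self):
        vals = np.arange(1.0, 101.0)  # 1..100
        cg = _cells("control_green", vals, np.zeros(100))
        cr = _cells("control_red", np.zeros(100), vals + 200)
        for df in (cg, cr):
            df["green_norm"], df["red_norm"] = df["green_raw"], df["red_raw"]
        b = derive_bounds(cg, cr, trim=0.01)
        assert b.green_lo == 2.0          # smallest cell dropped
        assert b.red_lo == 202.0

    def test_overlapping_populations_abort(self):
        with pytest.raises(ValueError, match="overlap"):
            ControlBounds(green_lo=60, red_bleed_hi=80, red_lo=70, green_bleed_hi=4)


def _oracle_region(g, r, b: ControlBounds) -> str:
    """Independent region-membership oracle: evaluates the five region
    predicates separately and asserts exactly one fires."""
    preds = {
        "uncertain": g >= b.green_lo and r >= b.red_lo,
        "indist_green": g >= b.green_lo and r < b.red_lo and r <= b.red_bleed_hi,
        "green_some_red": g >= b.green_lo and b.red_bleed_hi < r < b.red_lo,
        "indist_red": r >= b.red_lo and g < b.green_lo and g <= b.green_bleed_hi,
        "red_some_green": r >= b.red_lo and g < b.green_lo and b.green_bleed_hi < g,
        "unclassified": g < b.green_lo and r < b.red_lo,
    }
    fired = [k for k, v in preds.items() if v]
    assert len(fired) == 1, (g, r, fired)
    return fired[0]


class TestClassification:
    @pytest.mark.parametrize("g,r,expected", [
        (90, 3, Group.INDIST_GREEN),
        (90, 40, Group.GREEN_SOME_RED),
        (90, 100, Group.UNCERTAIN),
        (2, 120, Group.INDIST_RED),
        (30, 120, Group.RED_SOME_GREEN),
        (10, 10, Group.UNCLASSIFIED),
    ])
    def test_worked_examples(self, example_bounds, g, r, expected):
        assert classify_cell(g, r, example_bounds) is expected

    def test_boundaries_closed_toward_indistinguishable(self, example_bounds):
        # exactly on the green floor and on the red bleed ceiling
        assert classify_cell(60.0, 5.0, example_bounds) is Group.INDIST_GREEN
        assert classify_cell(4.0, 70.0, example_bounds) is Group.INDIST_RED

    def test_channel_swap_symmetry(self, example_bounds):
        mirrored = ControlBounds(green_lo=70, red_bleed_hi=4, red_lo=60, green_bleed_hi=5)
        pairs = [(90, 3), (90, 40), (2, 120), (30, 120), (90, 100), (10, 10)]
        swap = {Group.INDIST_GREEN: Group.INDIST_RED,
                Group.INDIST_RED: Group.INDIST_GREEN,
                Group.GREEN_SOME_RED: Group.RED_SOME_GREEN,
                Group.RED_SOME_GREEN: Group.GREEN_SOME_RED,
                Group.UNCERTAIN: Group.UNCERTAIN,
                Group.UNCLASSIFIED: Group.UNCLASSIFIED}
        for g, r in pairs:
            assert classify_cell(r, g, mirrored) is swap[classify_cell(g, r, example_bounds)]

    @given(st.floats(0, 200), st.floats(0, 200))
    @settings(max_examples=300, deadline=None)
    def test_partition_property(self, g, r):
        """Every non-negative (g, r) point receives exactly one label, and it
        agrees with the independent predicate oracle."""
        b = ControlBounds(green_lo=60, red_bleed_hi=5, red_lo=70, green_bleed_hi=4)
        assert classify_cell(g, r, b).value == _oracle_region(g, r, b)


class TestExchangeUnits:
    def test_axis_and_diagonal_anchors(self):
        assert exchange_units(80.0, 0.0, Group.INDIST_GREEN) == 50.0
        assert exchange_units(0.0, 80.0, Group.INDIST_RED) == -50.0
        assert exchange_units(60.0, 60.0, Group.UNCERTAIN) == pytest.approx(0.0)
        # an axis-lying cell in a non-pinned group still scores the pole value
        assert exchange_units(80.0, 0.0, Group.GREEN_SOME_RED) == pytest.approx(50.0)

    def test_half_diagonal_angle(self):
        """A cell at 22.5 degrees above the green axis diverges from the
        diagonal by half of 45 degrees and scores 25 EU."""
        eu = exchange_units(1.0, math.tan(math.radians(22.5)), Group.GREEN_SOME_RED)
        assert eu == pytest.approx(25.0, abs=1e-9)

    @given(st.floats(0.01, 1000), st.floats(0.01, 1000))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_and_range(self, g, r):
        eu = exchange_units(g, r, Group.UNCERTAIN)
        mirror = exchange_units(r, g, Group.UNCERTAIN)
        assert eu == pytest.approx(-mirror, abs=1e-9)
        assert -50.0 <= eu <= 50.0

    def test_angle_oracle_agreement(self):
        """EU equals the independent arctangent mapping for random points."""
        rng = np.random.default_rng(3)
        g = rng.uniform(0.01, 500, 500)
        r = rng.uniform(0.01, 500, 500)
        for gi, ri in zip(g, r):
            theta = math.degrees(math.atan(ri / gi))
            expected = 50.0 * (45.0 - theta) / 45.0
            assert exchange_units(gi, ri, Group.UNCERTAIN) == pytest.approx(expected, abs=1e-9)

    def test_origin_unpinned_is_nan(self):
        assert math.isnan(exchange_units(0.0, 0.0, Group.UNCERTAIN))

    def test_unclassified_rejected(self):
        with pytest.raises(ValueError):
            exchange_units(10.0, 10.0, Group.UNCLASSIFIED)


class TestBinning:
    @pytest.mark.parametrize("eu,group,domain", [
        (10.0, Group.UNCERTAIN, "-10<EU<=10"),
        (10.01, Group.UNCERTAIN, "10<EU<=30"),
        (-30.0, Group.RED_SOME_GREEN, "-50<EU<=-30"),
        (-29.99, Group.RED_SOME_GREEN, "-30<EU<=-10"),
        (50.0, Group.GREEN_SOME_RED, "30<EU<50"),   # pole value, unpinned group
        (-50.0, Group.RED_SOME_GREEN, "-50<EU<=-30"),
        (50.0, Group.INDIST_GREEN, "EU=50"),
        (-50.0, Group.INDIST_RED, "EU=-50"),
    ])
    def test_boundary_semantics(self, eu, group, domain):
        assert bin_eu(eu, group) == domain

    def test_singletons_defined_by_group(self):
        """The EU=+/-50 domains contain exactly the indistinguishable groups."""
        assert bin_eu(-50.0, Group.INDIST_RED) == EU_DOMAINS[0]
        assert bin_eu(50.0, Group.INDIST_GREEN) == EU_DOMAINS[6]


class TestFlip:
    def _classified(self):
        df = _cells("cocultured", [90, 30], [40, 120])
        df["green_norm"], df["red_norm"] = df["green_raw"], df["red_raw"]
        df["group"] = ["green_some_red", "red_some_green"]
        df["eu"] = [25.0, -40.0]
        df["eu_domain"] = ["10<EU<=30", "-50<EU<=-30"]
        return df

    def test_eu_negated_and_groups_mirrored(self):
        out = flip_orientation(self._classified())
        assert list(out["eu"]) == [-25.0, 40.0]
        assert list(out["group"]) == ["red_some_green", "green_some_red"]
        assert list(out["eu_domain"]) == ["-30<EU<=-10", "30<EU<50"]

    def test_double_flip_identity(self):
        df = self._classified()
        pd.testing.assert_frame_equal(flip_orientation(flip_orientation(df)), df)


class TestAnalyzeCoculture:
    def test_zero_transfer_recovers_indistinguishable(self):
        cfg = SyntheticConfig(seed=17, transfer_fraction=0.0,
                              reverse_transfer_fraction=0.0, n_cocultured=500)
        cg, cr = generate_controls(cfg)
        cc, truth = generate_coculture(cfg)
        classified, _ = analyze_coculture(cc, cg, cr, AnalysisConfig(seed=17))
        m = classified[classified["role"] == "cocultured"].merge(truth, on="cell_id")
        correct = np.where(m["is_donor"], m["group"] == "indist_red",
                           m["group"] == "indist_green").mean()
        assert correct >= 0.95

    def test_counts_partition_input(self, sim_tables):
        cg, cr, cc, _ = sim_tables
        _, summary = analyze_coculture(cc, cg, cr, AnalysisConfig(seed=1))
        assert sum(summary.group_counts.values()) == summary.n_cocultured
        five = sum(v for k, v in summary.group_counts.items() if k != "unclassified")
        assert five == summary.n_cocultured - summary.group_counts["unclassified"]
        assert sum(summary.domain_counts.values()) == five

    def test_domain_singletons_equal_indist_groups(self, sim_tables):
        cg, cr, cc, _ = sim_tables
        _, summary = analyze_coculture(cc, cg, cr, AnalysisConfig(seed=1))
        assert summary.domain_counts["EU=-50"] == summary.group_counts["indist_red"]
        assert summary.domain_counts["EU=50"] == summary.group_counts["indist_green"]

    def test_sampling_caps_applied(self):
        cfg = SyntheticConfig(seed=19, n_control_green=150, n_control_red=150,
                              n_cocultured=1200)
        cg, cr = generate_controls(cfg)
        cc, _ = generate_coculture(cfg)
        _, summary = analyze_coculture(cc, cg, cr, AnalysisConfig(seed=19))
        assert summary.n_cocultured == 1000
        assert summary.n_control_green == 100
        assert summary.n_control_red == 100

    def test_channel_scale_invariance_end_to_end(self, sim_tables):
        """Multiplying one channel's raw fluorescence everywhere (background
        scales with the channel) changes no label and no EU."""
        cg, cr, cc, _ = sim_tables
        base, _ = analyze_coculture(cc, cg, cr, AnalysisConfig(seed=1))
        k = 7.3
        cg2, cr2, cc2 = (df.copy() for df in (cg, cr, cc))
        for df in (cg2, cr2, cc2):
            df["green_raw"] *= k
        scaled, _ = analyze_coculture(cc2, cg2, cr2, AnalysisConfig(seed=1))
        sel = base["role"] == "cocultured"
        assert list(base.loc[sel, "group"]) == list(scaled.loc[sel, "group"])
        np.testing.assert_allclose(base.loc[sel, "eu"], scaled.loc[sel, "eu"],
                                   atol=1e-9, equal_nan=True)

    def test_renormalization_fixed_point(self, sim_tables):
        """Feeding normalized values back as raw data with zero background
        reproduces them unchanged."""
        cg, cr, cc, _ = sim_tables
        bg = estimate_background(cg, cr)
        out, _, _ = normalize(cc, cg, cr, bg)
        renorm_in = out.copy()
        renorm_in["green_raw"] = out["green_norm"]
        renorm_in["red_raw"] = out["red_norm"]
        parts = {role: renorm_in[renorm_in["role"] == role] for role in
                 ("control_green", "control_red", "cocultured")}
        out2, _, _ = normalize(parts["cocultured"], parts["control_green"],
                               parts["control_red"], BackgroundEstimate(0, 0))
        merged = out.merge(out2, on="cell_id", suffixes=("", "_re"))
        np.testing.assert_allclose(merged["green_norm_re"], merged["green_norm"], rtol=1e-9)
        np.testing.assert_allclose(merged["red_norm_re"], merged["red_norm"], rtol=1e-9)

    def test_transfer_dose_tracks_eu(self):
        """More received label pulls an acceptor's EU toward the red pole:
        strong negative rank correlation at full transfer."""
        cfg = SyntheticConfig(seed=7, transfer_fraction=1.0, n_cocultured=1000)
        cg, cr = generate_controls(cfg)
        cc, truth = generate_coculture(cfg)
        classified, _ = analyze_coculture(cc, cg, cr, AnalysisConfig(seed=7))
        m = classified[classified["role"] == "cocultured"].merge(truth, on="cell_id")
        acc = m[~m["is_donor"]].dropna(subset=["eu"]).head(500)
        rho = stats.spearmanr(acc["true_received"], acc["eu"]).statistic
        assert rho <= -0.9

    def test_monotone_dose_response(self):
        """Mean acceptor EU decreases monotonically as the mean transfer
        amount grows across a 5-point dose grid."""
        means = []
        for a in (0.3, 0.6, 1.2, 2.4, 4.8):
            cfg = SyntheticConfig(seed=11, transfer_fraction=1.0, n_cocultured=400,
                                  transfer_amount_a=a, transfer_amount_b=2.4)
            cg, cr = generate_controls(cfg)
            cc, truth = generate_coculture(cfg)
            classified, _ = analyze_coculture(cc, cg, cr, AnalysisConfig(seed=11))
            m = classified[classified["role"] == "cocultured"].merge(truth, on="cell_id")
            acc = m[~m["is_donor"]]
            means.append((acc["true_amount"].mean(), acc["eu"].mean()))
        doses = [d for d, _ in means]
        eus = [e for _, e in means]
        assert doses == sorted(doses)
        assert eus == sorted(eus, reverse=True)
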