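"""Label-free quantification: normalization against brute-force oracles,
eligibility/selection rules, t-test against a textbook oracle, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trpquant import lfq
from trpquant import synthetic as syn
from trpquant.io import FEATURE_META_COLUMNS, run_columns


def make_table(abundances: dict[str, list], **meta) -> pd.DataFrame:
    """Small feature table from per-run abundance lists."""
    n = len(next(iter(abundances.values())))
    base = {
        "feature_id": [f"f{i:03d}" for i in range(n)],
        "peptide_sequence": ["PEP"] * n,
        "site_id": ["background"] * n,
        "n_phospho": [0] * n,
        "site_localized": [False] * n,
        "charge": [2] * n,
        "mz": [500.0] * n,
        "rt": [10.0] * n,
    }
    base.update(meta)
    base.update(abundances)
    return pd.DataFrame(base)[FEATURE_META_COLUMNS + list(abundances)]


def brute_force_factor(ref: np.ndarray, ab: np.ndarray, grid: np.ndarray) -> float:
    """Grid oracle: the factor minimising the median absolute log ratio
    between the rescaled run and the reference."""
    scores = [np.median(np.abs(np.log(ref) - np.log(ab * f))) for f in grid]
    return float(grid[int(np.argmin(scores))])


class TestFilterCharge:
    def test_keeps_plus2_to_plus5(self):
        table = make_table({"r1": [1.0] * 6}, charge=[1, 2, 3, 4, 5, 6])
        out = lfq.filter_charge(table)
        assert list(out["charge"]) == [2, 3, 4, 5]
        assert list(out["feature_id"]) == ["f001", "f002", "f003", "f004"]

    def test_empty_and_identity(self):
        empty = make_table({"r1": []}, charge=[])
        assert len(lfq.filter_charge(empty)) == 0
        all2 = make_table({"r1": [1.0, 2.0]})
        pd.testing.assert_frame_equal(lfq.filter_charge(all2), all2)


class TestNormalization:
    def test_pure_scaling_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(10, 1, 15)
        table = make_table({"A": a, "B": 2.0 * a})
        res = lfq.normalize_runs(table, reference_run="A")
        assert res.factors["A"] == 1.0
        assert abs(res.factors["B"] - 0.5) < 1e-12
        assert np.allclose(res.normalized["B"], table["A"], rtol=1e-12)

    def test_single_run_identity(self):
        table = make_table({"A": [1.0, 2.0, 3.0]})
        res = lfq.normalize_runs(table)
        assert res.factors == {"A": 1.0}

    def test_robust_to_minority_of_changing_features(self):
        """90% unchanged + 10% features x8 in one run: the trimmed median
        still recovers factor 1, matching the brute-force grid oracle."""
        rng = np.random.default_rng(1)
        a = rng.lognormal(10, 1, 20)
        b = a.copy()
        b[:2] *= 8.0  # 10% changers
        table = make_table({"A": a, "B": b})
        res = lfq.normalize_runs(table, reference_run="A")
        assert abs(res.factors["B"] - 1.0) < 1e-9
        grid = np.exp(np.linspace(np.log(0.05), np.log(20), 4001))
        oracle = brute_force_factor(a, b, grid)
        assert abs(math.log(res.factors["B"]) - math.log(oracle)) < 2e-3

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        table = make_table({f"r{i}": rng.lognormal(8, 1, 12) for i in range(4)})
        res1 = lfq.normalize_runs(table, reference_run="r0")
        scaled = table.copy()
        scaled["r2"] = scaled["r2"] * 37.5
        res2 = lfq.normalize_runs(scaled, reference_run="r0")
        for run in ("r1", "r2", "r3"):
            np.testing.assert_allclose(
                res1.normalized[run], res2.normalized[run], rtol=1e-9
            )

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        table = make_table(
            {f"r{i}": rng.lognormal(8, 1, 12) * (i + 1) for i in range(3)}
        )
        once = lfq.normalize_runs(table, reference_run="r0")
        twice = lfq.normalize_runs(once.normalized, reference_run="r0")
        for f in twice.factors.values():
            assert abs(f - 1.0) < 1e-9

    def test_errors_name_the_offending_run(self):
        table = make_table({"A": [1.0, 2.0, 3.0], "B": [np.nan] * 3})
        with pytest.raises(lfq.NormalizationError, match="B"):
            lfq.normalize_runs(table, reference_run="A")
        table2 = make_table({"A": [1.0, 2.0, np.nan], "B": [np.nan, np.nan, 3.0]})
        with pytest.raises(lfq.NormalizationError, match="B"):
            lfq.normalize_runs(table2, reference_run="A")


class TestEligibilityAndSelection:
    def test_exhaustive_presence_and_flag_grid(self, design_9x9):
        """A variant is eligible iff singly phosphorylated, localized, and
        detected in all 9 runs of at least one condition — checked over the
        full (n_phospho, localized, presence-count) grid."""
        light = [r.run_id for r in design_9x9 if r.condition == "light"]
        dark = [r.run_id for r in design_9x9 if r.condition == "dark"]
        rows = []
        expected = {}
        for n_phos in (1, 2):
            for loc in (True, False):
                for nl in range(10):
                    for nd in range(10):
                        sid = f"S_{n_phos}_{int(loc)}_{nl}_{nd}"
                        vals = {
                            r: (100.0 if i < nl else np.nan)
                            for i, r in enumerate(light)
                        }
                        vals.update(
                            {r: (80.0 if i < nd else np.nan) for i, r in enumerate(dark)}
                        )
                        rows.append(
                            {
                                "feature_id": sid + "_v1",
                                "peptide_sequence": "PEP",
                                "site_id": sid,
                                "n_phospho": n_phos,
                                "site_localized": loc,
                                "charge": 2,
                                "mz": 500.0,
                                "rt": 10.0,
                                **vals,
                            }
                        )
                        expected[sid] = n_phos == 1 and loc and (nl == 9 or nd == 9)
        table = pd.DataFrame(rows)[FEATURE_META_COLUMNS + light + dark]
        chosen = lfq.select_quantifiable(table, design_9x9)
        for sid, should in expected.items():
            assert (chosen[sid] is not None) == should, sid

    def test_partial_presence_boundary_cases(self, design_9x9):
        """9/9 light + 5/9 dark is eligible; 8/9 in both conditions is not."""
        light = [r.run_id for r in design_9x9 if r.condition == "light"]
        dark = [r.run_id for r in design_9x9 if r.condition == "dark"]
        vals_a = {r: 10.0 for r in light}
        vals_a.update({r: (5.0 if i < 5 else np.nan) for i, r in enumerate(dark)})
        vals_b = {r: (10.0 if i < 8 else np.nan) for i, r in enumerate(light)}
        vals_b.update({r: (5.0 if i < 8 else np.nan) for i, r in enumerate(dark)})
        table = pd.DataFrame(
            [
                {"feature_id": "a", "peptide_sequence": "P", "site_id": "SA",
                 "n_phospho": 1, "site_localized": True, "charge": 2,
                 "mz": 1.0, "rt": 1.0, **vals_a},
                {"feature_id": "b", "peptide_sequence": "P", "site_id": "SB",
                 "n_phospho": 1, "site_localized": True, "charge": 2,
                 "mz": 1.0, "rt": 1.0, **vals_b},
            ]
        )[FEATURE_META_COLUMNS + light + dark]
        chosen = lfq.select_quantifiable(table, design_9x9)
        assert chosen["SA"] == "a"
        assert chosen["SB"] is None

    def test_highest_mean_variant_wins_and_ties_break_to_lowest_id(self, design_9x9):
        runs = [r.run_id for r in design_9x9]
        def row(fid, level):
            return {
                "feature_id": fid, "peptide_sequence": "P", "site_id": "T849",
                "n_phospho": 1, "site_localized": True, "charge": 2,
                "mz": 1.0, "rt": 1.0, **{r: level for r in runs},
            }
        table = pd.DataFrame(
            [row("v_low", 100.0), row("v_high", 250.0)]
        )[FEATURE_META_COLUMNS + runs]
        assert lfq.select_quantifiable(table, design_9x9)["T849"] == "v_high"
        tied = pd.DataFrame([row("v_b", 100.0), row("v_a", 100.0)])[
            FEATURE_META_COLUMNS + runs
        ]
        assert lfq.select_quantifiable(tied, design_9x9)["T849"] == "v_a"


class TestQuantifySite:
    def _table(self, design, light_vals, dark_vals):
        light = [r.run_id for r in design if r.condition == "light"]
        dark = [r.run_id for r in design if r.condition == "dark"]
        vals = dict(zip(light, light_vals))
        vals.update(dict(zip(dark, dark_vals)))
        vals.update({r: np.nan for r in light[len(light_vals):]})
        vals.update({r: np.nan for r in dark[len(dark_vals):]})
        return pd.DataFrame(
            [{"feature_id": "f1", "peptide_sequence": "P", "site_id": "S",
              "n_phospho": 1, "site_localized": True, "charge": 2,
              "mz": 1.0, "rt": 1.0, **vals}]
        )[FEATURE_META_COLUMNS + light + dark]

    def test_fourfold_light_effect(self, design_9x9):
        jitter = np.array([0, 1e-6, -1e-6, 2e-6, -2e-6, 3e-6, -3e-6, 4e-6, -4e-6])
        table = self._table(design_9x9, 4.0 + jitter, 1.0 + jitter)
        res = lfq.quantify_site(table, "S", "f1", design_9x9)
        assert res.relative_abundance["light"] == 100.0
        assert abs(res.relative_abundance["dark"] - 25.0) < 1e-3
        assert res.light_class == "light_elevated"
        assert res.stars == "***"

    def test_identical_samples_not_light_dependent(self, design_9x9):
        table = self._table(design_9x9, [5.0] * 9, [5.0] * 9)
        res = lfq.quantify_site(table, "S", "f1", design_9x9)
        assert res.p_value == 1.0
        assert res.light_class == "not_light_dependent"

    def test_p_value_matches_textbook_pooled_t(self, design_9x9):
        light = [10.0, 12.0, 11.0, 9.0, 10.0, 11.0, 10.0, 12.0, 11.0]
        dark = [5.0, 6.0, 5.0, 7.0, 6.0, 5.0, 6.0, 5.0, 6.0]
        table = self._table(design_9x9, light, dark)
        res = lfq.quantify_site(table, "S", "f1", design_9x9)
        # independent textbook computation: pooled variance t + t CDF
        a, b = np.array(light), np.array(dark)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_oracle = 2 * stats.t.sf(abs(t), a.size + b.size - 2)
        assert abs(res.p_value - p_oracle) < 1e-12

    def test_too_few_values_not_quantifiable(self, design_9x9):
        table = self._table(design_9x9, [4.0] * 9, [1.0])
        res = lfq.quantify_site(table, "S", "f1", design_9x9)
        assert res.light_class == "not_quantifiable"
        assert math.isnan(res.p_value)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_relative_abundance_invariant_under_global_rescale(self, scale):
        design = syn.make_run_design(n_bio=1, n_tech=3)
        rng = np.random.default_rng(7)
        light_vals = rng.lognormal(2, 0.2, 3)
        dark_vals = rng.lognormal(1, 0.2, 3)
        t1 = self._table(design, light_vals, dark_vals)
        t2 = self._table(design, light_vals * scale, dark_vals * scale)
        r1 = lfq.quantify_site(t1, "S", "f1", design)
        r2 = lfq.quantify_site(t2, "S", "f1", design)
        for cond in ("light", "dark"):
            assert r1.relative_abundance[cond] == pytest.approx(
                r2.relative_abundance[cond], rel=1e-9
            )


class TestClassification:
    def test_counts_and_star_coding(self, design_9x9):
        truth = syn.default_site_truth(fold=4.0)
        cfg = syn.SimConfig(
            seed=12, n_background_features=100, noise_cv=0.2, detect_prob=1.0,
            charge_weights={2: 0.5, 3: 0.5},
        )
        table, _ = syn.simulate_feature_table(truth, design_9x9, cfg)
        results, _ = lfq.quantify_all(table, design_9x9)
        summary = lfq.classify_sites(results).set_index("class")["n_sites"]
        assert summary["light_elevated"] == 13
        assert summary["dark_elevated"] == 1
        for r in results:
            if r.light_class.endswith("elevated"):
                assert r.stars in ("*", "**", "***")
                assert r.p_value < 0.05

    def test_empty_results_give_zero_counts(self):
        summary = lfq.classify_sites([])
        assert summary["n_sites"].sum() == 0

    def test_per_enzyme_quantification_when_two_enzymes(self):
        design = syn.make_run_design(n_bio=3, n_tech=2, enzymes=("trypsin", "chymotrypsin"))
        truth = [syn.TrueSiteState("T849", {"light": 1.0, "dark": 0.25})]
        cfg = syn.SimConfig(
            seed=4, n_background_features=60, noise_cv=0.1, detect_prob=1.0,
            charge_weights={2: 1.0}, multi_phospho_prob=0.0, ambiguous_prob=0.0,
        )
        table, _ = syn.simulate_feature_table(truth, design, cfg)
        results, _ = lfq.quantify_all(table, design)
        enzymes = sorted(r.enzyme for r in results if r.site_id == "T849")
        assert enzymes == ["chymotrypsin", "trypsin"]
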