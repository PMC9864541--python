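from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from imputebench import (AnalysisPlan, DescriptiveEstimand, MixedDataset,
                         VariableSchema, fhd_run, fractional_estimate)
from imputebench.core import ImputationError
from imputebench.estimation import estimate_all, expand_fractional
from imputebench.fhd import (CellAssignment, _apply_merge, _donor_counts,
                             _merge_candidates, collapse_cells, discretize)


def brute_force_counts(codes, donor):
    """Row-by-row wildcard-matching oracle for eligible-donor counts."""
    donors = np.flatnonzero(donor)
    out = []
    for r in np.flatnonzero(~donor):
        c = 0
        for d in donors:
            if all(codes[r, j] < 0 or codes[r, j] == codes[d, j]
                   for j in range(codes.shape[1])):
                c += 1
        out.append(c)
    return np.array(out, dtype=float)


class TestDiscretize:
    def test_binary_codes_are_levels(self):
        sch = (VariableSchema("x", "covariate", "binary", levels=("no", "yes")),)
        ds = MixedDataset(pd.DataFrame({"x": ["no", "yes", "yes"]}), sch)
        a = discretize(ds)
        np.testing.assert_array_equal(a.codes[:, 0], [0, 1, 1])

    def test_quantile_cut_uniform(self):
        rng = np.random.default_rng(1)
        sch = (VariableSchema("x", "covariate", "continuous"),)
        ds = MixedDataset(pd.DataFrame({"x": rng.random(9000)}), sch)
        a = discretize(ds, n_bins=3)
        freqs = np.bincount(a.codes[:, 0], minlength=3) / 9000
        assert np.abs(freqs - 1 / 3).max() < 0.02

    def test_semicontinuous_hand_binned_oracle(self):
        """Zeros get their own code; positives are median-split: values at or
        below the median fall in the lower bin."""
        sch = (VariableSchema("x", "outcome", "semicontinuous", zero_mass=0.5),)
        ds = MixedDataset(pd.DataFrame({"x": [0.0, 0.0, 0.0, 1.1, 2.2, 3.3]}), sch)
        a = discretize(ds, n_bins=2)
        np.testing.assert_array_equal(a.codes[:, 0], [0, 0, 0, 1, 1, 2])

    def test_missing_stays_missing(self):
        sch = (VariableSchema("x", "outcome", "continuous"),)
        ds = MixedDataset(pd.DataFrame({"x": [1.0, np.nan, 2.0]}), sch)
        a = discretize(ds)
        assert a.codes[1, 0] == -1
        assert not a.donor[1] and a.donor[0]


class TestDonorCounts:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, V = 60, 4
        n_codes = [3, 2, 4, 3]
        codes = np.column_stack([rng.integers(0, k, size=n) for k in n_codes]).astype(np.int64)
        # missing on the last two "outcome" variables
        for j in (2, 3):
            codes[rng.random(n) < 0.4, j] = -1
        donor = (codes >= 0).all(axis=1)
        if donor.all() or not donor.any():
            pytest.skip("degenerate draw")
        a = CellAssignment(codes, list("abcd"), n_codes, ["ordered"] * 4, donor)
        np.testing.assert_array_equal(_donor_counts(a), brute_force_counts(codes, donor))


class TestCollapse:
    def make_small(self):
        """One ordinal covariate (3 codes) + one outcome; donors concentrated
        so one cell is donor-poor."""
        sch = (VariableSchema("g", "covariate", "ordinal", levels=("a", "b", "c")),
               VariableSchema("y", "outcome", "continuous"))
        g = ["a"] * 6 + ["b"] * 2 + ["c"] * 4
        y = [1.0, 2, 3, 4, 5, 6, 7, np.nan, 9, 10, 11, np.nan]
        return MixedDataset(pd.DataFrame({"g": g, "y": y}), sch)

    def test_noop_when_donors_sufficient(self):
        ds = self.make_small()
        a = discretize(ds, n_bins=2)
        out = collapse_cells(a, M=1)
        assert out.merges == []
        np.testing.assert_array_equal(out.codes, a.codes)

    def test_collapse_reaches_m_and_first_merge_is_brute_force_optimal(self):
        ds = self.make_small()
        a = discretize(ds, n_bins=2)
        M = 5
        out = collapse_cells(a, M)
        assert _donor_counts(out).min() >= M
        assert len(out.merges) >= 1
        # brute-force search over all single merges for the max-min-donor merge
        best_score, best = None, None
        for idx, (j, ca, cb) in enumerate(_merge_candidates(a)):
            trial = _apply_merge(a.codes, j, ca, cb)
            nc = list(a.n_codes)
            nc[j] -= 1
            tc = brute_force_counts(trial, a.donor)
            score = (tc.min(), (tc >= M).mean(), -idx)
            if best_score is None or score > best_score:
                best_score, best = score, (a.var_names[j], ca, cb)
        assert out.merges[0] == best

    def test_too_few_donors_rejected(self):
        ds = self.make_small()
        a = discretize(ds, n_bins=2)
        with pytest.raises(ImputationError):
            collapse_cells(a, M=50)


class TestFhdRun:
    def test_fully_observed_equals_unweighted(self, small_pop):
        res = fhd_run(small_pop, seed=1)
        assert len(res.fractional.donors) == 0
        plan = AnalysisPlan((DescriptiveEstimand("age_diagnosed"),))
        est = fractional_estimate(res, plan)["mean(age_diagnosed)"]
        assert est == pytest.approx(small_pop.data["age_diagnosed"].mean(), abs=1e-12)

    def test_six_row_hand_worked_example(self):
        """Four donors in a single cell, one recipient missing two variables,
        M=2: two fractional records with weights 1/2 each, both missing
        variables copied jointly from the same donor; the weighted mean equals
        the hand-computed value."""
        sch = (VariableSchema("g", "covariate", "binary", levels=("u", "v")),
               VariableSchema("y1", "outcome", "continuous"),
               VariableSchema("y2", "outcome", "continuous"))
        df = pd.DataFrame({
            "g": ["u"] * 5,
            "y1": [1.0, 2.0, 3.0, 4.0, np.nan],
            "y2": [10.0, 20.0, 30.0, 40.0, np.nan],
        })
        ds = MixedDataset(df, sch)
        res = fhd_run(ds, seed=5, M=2)
        donors = res.fractional.donors[4]
        weights = res.fractional.weights[4]
        assert len(donors) == 2 and len(set(donors)) == 2
        assert weights == [Fraction(1, 2), Fraction(1, 2)]
        expanded, w = expand_fractional(ds, res.fractional)
        # joint-row integrity: each fractional record matches one donor row
        for k in range(2):
            rec = expanded.iloc[4 + k]
            d = donors[k]
            assert rec["y1"] == df.loc[d, "y1"] and rec["y2"] == df.loc[d, "y2"]
        est = fractional_estimate(res, AnalysisPlan((DescriptiveEstimand("y1"),)))
        hand = (1 + 2 + 3 + 4 + 0.5 * df.loc[donors[0], "y1"]
                + 0.5 * df.loc[donors[1], "y1"]) / 5
        assert est["mean(y1)"] == pytest.approx(hand, abs=1e-12)

    def test_single_complete_row_reduces_m(self):
        sch = (VariableSchema("y", "outcome", "continuous"),)
        df = pd.DataFrame({"y": [3.0, np.nan, np.nan]})
        res = fhd_run(MixedDataset(df, sch), seed=1, M=5)
        assert res.diagnostics["M_reduced_from"] == 5
        for r in (1, 2):
            assert res.fractional.donors[r] == [0]
            assert res.fractional.weights[r] == [Fraction(1)]

    def test_weight_conservation_support_and_joint_integrity(self, brfss_pop):
        from imputebench import build_amputation_configs, ampute
        from conftest import subset_dataset
        sub = subset_dataset(brfss_pop,
                             ["age_group", "bmi", "age_diagnosed", "insulin_use"])
        cfgs = build_amputation_configs(sub, "MAR")
        amp, _ = ampute(sub, cfgs, "MAR", seed=6)
        res = fhd_run(amp, seed=7)
        fa = res.fractional
        obs_vals = amp.data["age_diagnosed"].dropna().to_numpy()
        for r, donors in fa.donors.items():
            assert sum(fa.weights[r]) == 1           # exact rational arithmetic
            assert len(set(donors)) == len(donors)   # distinct donors
            for d in donors:
                assert amp.data.loc[d].notna().all()  # donors are complete rows
                if np.isnan(amp.data.loc[r, "age_diagnosed"]):
                    assert amp.data.loc[d, "age_diagnosed"] in obs_vals

    def test_single_cell_mcar_unbiased(self):
        """With one incomplete variable and a universal cell, the fractionally
        weighted mean is unbiased for the full-sample mean."""
        rng = np.random.default_rng(12)
        sch = (VariableSchema("y", "outcome", "continuous"),)
        biases = []
        n = 2000
        for rep in range(200):
            y = rng.normal(size=n)
            full_mean = y.mean()
            miss = rng.random(n) < 0.4
            df = pd.DataFrame({"y": np.where(miss, np.nan, y)})
            res = fhd_run(MixedDataset(df, sch), seed=rep, M=5)
            est = fractional_estimate(
                res, AnalysisPlan((DescriptiveEstimand("y"),)))["mean(y)"]
            biases.append(est - full_mean)
        b = np.array(biases)
        assert abs(b.mean()) < 3 * b.std(ddof=1) / np.sqrt(len(b))
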