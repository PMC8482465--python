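"""MiST component formulas checked against an independent brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmsmist.mist import (
    DEFAULT_WEIGHTS,
    MistError,
    MistWeights,
    abundance,
    normalize_runs,
    reproducibility,
    score_dataset,
    specificity,
)
from tests.conftest import make_matrix

BAITS = ["FOSL1", "FOSL2", "IgG"]


def mist_oracle(values, preys, baits, n_bio, weights):
    """Plain-loop reference implementation of the three MiST components.

    ``values`` maps (prey, bait, rep) -> log2 intensity or None. Returns
    {(bait, prey): (R, A, S, score)}. Deliberately written with dicts and
    scalar math, independent of the vectorized implementation under test.
    """
    # per-column fractions
    frac = {}
    for b in baits:
        for r in range(1, n_bio + 1):
            total = sum(
                2 ** values[(p, b, r)] for p in preys if values[(p, b, r)] is not None
            )
            for p in preys:
                v = values[(p, b, r)]
                frac[(p, b, r)] = (2 ** v / total) if v is not None else 0.0
    out = {}
    abund = {}
    for b in baits:
        for p in preys:
            a = [frac[(p, b, r)] for r in range(1, n_bio + 1)]
            t = sum(a)
            if t == 0:
                rep = 0.0
            else:
                rep = 0.0
                for ai in a:
                    if ai > 0:
                        pi = ai / t
                        rep -= pi * math.log(pi, n_bio)
            abund[(p, b)] = sum(a) / n_bio
            out[(b, p)] = [min(max(rep, 0.0), 1.0), abund[(p, b)]]
    for p in preys:
        tot = sum(abund[(p, b)] for b in baits)
        for b in baits:
            s = abund[(p, b)] / tot if tot > 0 else 0.0
            r, a = out[(b, p)]
            out[(b, p)] = (r, a, s, weights.w_R * r + weights.w_A * a + weights.w_S * s)
    return out


def random_small_matrix(rng, n_preys):
    """Coarse-grid log2 intensities with missingness; every column has signal."""
    grid = np.array([8.0, 10.0, 12.0, 14.0, 16.0])
    arr = rng.choice(grid, size=(n_preys, 9))
    mask = rng.random((n_preys, 9)) < 0.3
    # keep at least one valid value per column
    for c in range(9):
        if mask[:, c].all():
            mask[rng.integers(n_preys), c] = False
    arr[mask] = np.nan
    return arr


def assert_matches_oracle(arr, preys, weights):
    m = make_matrix(arr, preys, BAITS, 3)
    got = score_dataset(m, weights)
    values = {
        (p, b, r): (None if np.isnan(arr[i, 3 * j + r - 1]) else arr[i, 3 * j + r - 1])
        for i, p in enumerate(preys)
        for j, b in enumerate(BAITS)
        for r in (1, 2, 3)
    }
    expected = mist_oracle(values, preys, BAITS, 3, weights)
    assert len(got) == len(expected)
    for row in got.itertuples():
        er, ea, es, escore = expected[(row.bait, row.prey)]
        assert row.R == pytest.approx(er, abs=1e-12)
        assert row.A == pytest.approx(ea, abs=1e-12)
        assert row.S == pytest.approx(es, abs=1e-12)
        assert row.score == pytest.approx(escore, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_random_small_matrices(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 6))
        arr = random_small_matrix(rng, n)
        preys = [f"P{i}" for i in range(n)]
        assert_matches_oracle(arr, preys, DEFAULT_WEIGHTS)

    def test_nondefault_weights(self):
        rng = np.random.default_rng(5)
        arr = random_small_matrix(rng, 4)
        assert_matches_oracle(arr, [f"P{i}" for i in range(4)], MistWeights(1, 1, 1))


class TestReproducibility:
    def test_uniform_presence_is_one(self):
        assert reproducibility([0.02, 0.02, 0.02]) == pytest.approx(1.0, abs=1e-12)

    def test_single_replicate_presence_is_zero(self):
        assert reproducibility([0.05, 0.0, 0.0]) == 0.0

    def test_never_observed_is_zero(self):
        assert reproducibility([0.0, 0.0, 0.0]) == 0.0

    def test_half_quarter_quarter(self):
        # p = (0.5, 0.25, 0.25); entropy base 3
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25)) / math.log(3)
        assert reproducibility([0.04, 0.02, 0.02]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9464, abs=1e-4)

    def test_scale_invariant(self):
        a = [0.01, 0.003, 0.02]
        assert reproducibility(a) == pytest.approx(
            reproducibility([x * 7.3 for x in a]), abs=1e-12
        )

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(MistError):
            reproducibility([0.5])


class TestAbundanceSpecificity:
    def test_abundance_is_mean_with_zeros(self):
        assert abundance([0.1, 0.1, 0.1]) == pytest.approx(0.1)
        assert abundance([0.3, 0.0, 0.0]) == pytest.approx(0.1)
        assert abundance([0.0, 0.0, 0.0]) == 0.0

    def test_specificity_ratio(self):
        s = specificity({"FOSL1": 0.03, "FOSL2": 0.01, "IgG": 0.01})
        assert s["FOSL1"] == pytest.approx(0.6, abs=1e-12)

    def test_exclusive_prey_and_symmetry(self):
        assert specificity({"a": 0.2, "b": 0.0, "c": 0.0})["a"] == 1.0
        s = specificity({"a": 0.1, "b": 0.1, "c": 0.0})
        assert s["a"] == s["b"] == 0.5 and s["c"] == 0.0

    def test_all_zero_gives_zero(self):
        assert set(specificity({"a": 0.0, "b": 0.0}).values()) == {0.0}


class TestScoreDataset:
    def test_exclusive_uniform_prey_composes_components(self):
        # P1 only in FOSL1, equal across reps; P2 everywhere as ballast
        arr = np.array(
            [
                [10, 10, 10, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan],
                [15, 15, 15, 15, 15, 15, 15, 15, 15],
            ]
        )
        m = make_matrix(arr, ["P1", "P2"], BAITS, 3)
        rec = score_dataset(m).set_index(["bait", "prey"])
        a = 2**10 / (2**10 + 2**15)
        w = DEFAULT_WEIGHTS
        expected = w.w_R * 1.0 + w.w_A * a + w.w_S * 1.0
        assert rec.loc[("FOSL1", "P1"), "score"] == pytest.approx(expected, abs=1e-12)
        assert rec.loc[("IgG", "P1"), "score"] == 0.0

    def test_bounds_and_specificity_sum(self):
        rng = np.random.default_rng(42)
        arr = random_small_matrix(rng, 5)
        rec = score_dataset(make_matrix(arr, [f"P{i}" for i in range(5)], BAITS, 3))
        for col in ("R", "A", "S", "score"):
            assert ((rec[col] >= 0) & (rec[col] <= 1)).all()
        sums = rec.groupby("prey")["S"].sum()
        assert ((np.abs(sums - 1) < 1e-9) | (sums == 0)).all()

    def test_permuting_replicate_columns_leaves_scores_unchanged(self):
        rng = np.random.default_rng(7)
        arr = random_small_matrix(rng, 4)
        preys = [f"P{i}" for i in range(4)]
        m = make_matrix(arr, preys, BAITS, 3)
        # swap bio reps 1 and 3 within each bait
        perm = arr[:, [2, 1, 0, 5, 4, 3, 8, 7, 6]]
        m2 = make_matrix(perm, preys, BAITS, 3)
        pd.testing.assert_frame_equal(score_dataset(m), score_dataset(m2))

    def test_all_zero_column_is_an_error_naming_the_cell(self):
        arr = np.full((2, 9), np.nan)
        arr[:, :6] = 12.0
        m = make_matrix(arr, ["P1", "P2"], BAITS, 3)
        with pytest.raises(MistError, match="IgG"):
            score_dataset(m)

    def test_pairwise_group_excludes_other_bait_from_specificity(self):
        arr = np.array([[12.0] * 9])
        m = make_matrix(arr, ["P1"], BAITS, 3)
        joint = score_dataset(m).set_index("bait")
        pair = score_dataset(m, baits=["FOSL1", "IgG"]).set_index("bait")
        assert joint.loc["FOSL1", "S"] == pytest.approx(1 / 3, abs=1e-12)
        assert pair.loc["FOSL1", "S"] == pytest.approx(1 / 2, abs=1e-12)
        assert set(pair.index) == {"FOSL1", "IgG"}


class TestWeights:
    def test_renormalized_to_sum_one(self):
        w = MistWeights(3, 1, 1)
        assert w.w_R + w.w_A + w.w_S == pytest.approx(1.0, abs=1e-12)
        assert w.w_R == pytest.approx(0.6)

    def test_negative_or_zero_rejected(self):
        with pytest.raises(MistError):
            MistWeights(-0.1, 0.5, 0.6)
        with pytest.raises(MistError):
            MistWeights(0, 0, 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(min_value=0.0, max_value=1e3), min_size=3, max_size=3),
        min_size=1,
        max_size=4,
    )
)
def test_reproducibility_in_unit_interval_and_scale_invariant(rows):
    """R stays in [0,1] and is invariant to positive scaling, for any fractions."""
    for row in rows:
        r = reproducibility(row)
        assert 0.0 <= r <= 1.0
        assert reproducibility([x * 3.7 for x in row]) == pytest.approx(r, abs=1e-9)
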