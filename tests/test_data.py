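"""Core data layer: activity conversion, readers, pretreatment, splitting."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarlab import (
    DomainError,
    ParseError,
    activities_series,
    ic50_to_pic50,
    kennard_stone,
    pic50_to_ic50,
    pretreat,
    read_compound_table,
    read_descriptor_matrix,
)


class TestActivityConversion:
    @pytest.mark.parametrize(
        "ic50, pic50",
        [(1.0, 6.0), (10.0, 5.0), (7.5, 6 - np.log10(7.5))],
    )
    def test_known_values(self, ic50, pic50):
        assert ic50_to_pic50(ic50) == pytest.approx(pic50, abs=1e-9)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip(self, ic50):
        assert pic50_to_ic50(ic50_to_pic50(ic50)) == pytest.approx(
            ic50, rel=1e-9
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            ic50_to_pic50(bad)

    def test_vectorized(self):
        out = ic50_to_pic50(np.array([1.0, 10.0]))
        np.testing.assert_allclose(out, [6.0, 5.0])


class TestCompoundTable:
    def test_ic50_converted(self):
        recs = read_compound_table("compound_id,ic50\nc1,1\nc2,10\n")
        assert [r.compound_id for r in recs] == ["c1", "c2"]
        assert activities_series(recs).tolist() == pytest.approx([6.0, 5.0])

    def test_duplicate_id_named(self):
        with pytest.raises(ParseError, match="c1"):
            read_compound_table("compound_id,pic50\nc1,5\nc1,6\n")

    def test_inconsistent_pair_rejected(self):
        # IC50 of 1 uM implies pIC50 6, not 5
        with pytest.raises(ParseError, match="inconsistent"):
            read_compound_table("compound_id,ic50,pic50\nc1,1.0,5.0\n")

    def test_consistent_pair_accepted(self):
        recs = read_compound_table("compound_id,ic50,pic50\nc1,10.0,5.0\n")
        assert recs[0].pic50 == pytest.approx(5.0)

    def test_missing_activity(self):
        with pytest.raises(ParseError):
            read_compound_table("compound_id,pic50\nc1,\n")

    def test_unparsable_numeric_located(self):
        with pytest.raises(ParseError, match="ic50"):
            read_compound_table("compound_id,ic50\nc1,abc\n")


class TestDescriptorMatrixReader:
    def test_fixture_shape(self, validation_set):
        cols = ["MATS4e", "GATS5e", "SpMax4_Bhs", "RDF150u"]
        assert validation_set.shape[0] == 12
        assert validation_set[cols].notna().all().all()

    def test_round_trip_via_csv(self, validation_set):
        buf = io.StringIO()
        validation_set.drop(columns=["pic50", "y_pred_printed"]).rename_axis(
            "compound_id"
        ).to_csv(buf)
        df = read_descriptor_matrix(io.StringIO(buf.getvalue()))
        assert df.shape == (12, 4)
        assert list(df.index) == list(validation_set.index)

    def test_empty_descriptor_section(self):
        with pytest.raises(ParseError):
            read_descriptor_matrix("compound_id\nc1\n")

    def test_na_cell_named(self):
        with pytest.raises(ParseError, match=r"c2.*d1"):
            read_descriptor_matrix("compound_id,d1\nc1,1.0\nc2,NA\n")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_descriptor_matrix("compound_id,d1\nc1,1.0\nc1,2.0\n")


def brute_force_pretreat(X, variance_tol, corr_threshold):
    """Independent per-column/per-pair filter used as oracle."""
    constant = [c for c in X.columns if X[c].var(ddof=1) <= variance_tol]
    survivors = [c for c in X.columns if c not in constant]
    kept, corr_pairs = [], []
    for c in survivors:
        partner = None
        for k in kept:
            if abs(np.corrcoef(X[k], X[c])[0, 1]) >= corr_threshold:
                partner = k
                break
        if partner is None:
            kept.append(c)
        else:
            corr_pairs.append((partner, c))
    return constant, corr_pairs, kept


class TestPretreat:
    def test_constant_column_removed(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(10), "b": 2.0})
        cleaned, report = pretreat(X)
        assert report.removed_constant == ["b"]
        assert list(cleaned.columns) == ["a"]

    def test_keep_first_of_duplicates(self, rng):
        a = rng.standard_normal(10)
        X = pd.DataFrame({"a": a, "b": a.copy()})
        cleaned, report = pretreat(X)
        assert list(cleaned.columns) == ["a"]
        assert report.removed_correlated == [("a", "b")]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((10, 6)), columns=list("abcdef")
        )
        X["d"] = X["b"] * 1.0  # planted duplicate
        X["f"] = 3.14  # planted constant
        cleaned, report = pretreat(X)
        constant, corr_pairs, kept = brute_force_pretreat(X, 1e-8, 0.99)
        assert report.removed_constant == constant
        assert report.removed_correlated == corr_pairs
        assert list(cleaned.columns) == kept

    def test_idempotent(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 5)), columns=list("abcde"))
        X["dup"] = X["a"]
        once, _ = pretreat(X)
        twice, report = pretreat(once)
        pd.testing.assert_frame_equal(once, twice)
        assert not report.removed

    def test_everything_removed_errors(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ParseError):
            pretreat(X)


class TestKennardStone:
    @staticmethod
    def points_1d(vals):
        return pd.DataFrame(
            {"x": vals}, index=[str(v) for v in vals], dtype=float
        )

    def test_seed_pair_is_global_max_distance(self):
        split = kennard_stone(self.points_1d([0, 1, 2, 10]), n_train=2)
        assert sorted(split.train_ids) == ["0", "10"]

    def test_third_pick_maximises_min_distance(self):
        # point 2 has min distance 2 to {0, 10}; point 1 only 1
        split = kennard_stone(self.points_1d([0, 1, 2, 10]), n_train=3)
        assert split.train_ids == ["0", "10", "2"]
        assert split.test_ids == ["1"]

    def test_all_in_train(self):
        split = kennard_stone(self.points_1d([0, 1, 2, 10]), n_train=4)
        assert split.test_ids == []
        assert len(split.train_ids) == 4

    def test_study_sized_fraction(self, rng):
        X = pd.DataFrame(
            rng.standard_normal((39, 4)), index=[f"c{i}" for i in range(39)]
        )
        split = kennard_stone(X, train_fraction=0.7)
        assert (len(split.train_ids), len(split.test_ids)) == (27, 12)

    def test_partition_invariants(self, random_descriptors):
        split = kennard_stone(random_descriptors, n_train=12)
        train, test = set(split.train_ids), set(split.test_ids)
        assert not train & test
        assert train | test == set(random_descriptors.index)

    def test_row_permutation_invariant(self, random_descriptors):
        base = kennard_stone(random_descriptors, n_train=8)
        shuffled = random_descriptors.sample(
            frac=1.0, random_state=7
        )
        other = kennard_stone(shuffled, n_train=8)
        assert set(base.train_ids) == set(other.train_ids)

    @pytest.mark.parametrize("n_train", [0, 1, 21])
    def test_out_of_range(self, random_descriptors, n_train):
        with pytest.raises(ValueError):
            kennard_stone(random_descriptors, n_train=n_train)

    @pytest.mark.parametrize("seed", range(4))
    def test_maximin_property_re_evaluated(self, seed):
        """Every pick is re-checked against a direct distance evaluation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        X = pd.DataFrame(
            rng.standard_normal((n, 3)), index=[f"c{i}" for i in range(n)]
        )
        n_train = n // 2
        split = kennard_stone(X, n_train=n_train)
        Z = (X - X.mean()) / X.std(ddof=0)
        D = np.sqrt(
            ((Z.values[:, None, :] - Z.values[None, :, :]) ** 2).sum(-1)
        )
        pos = {cid: i for i, cid in enumerate(X.index)}
        sel = [pos[c] for c in split.train_ids]
        # first two are a globally maximally distant pair
        assert D[sel[0], sel[1]] == pytest.approx(D.max())
        # each later pick maximises min distance to the already-selected
        for step in range(2, n_train):
            chosen = sel[step]
            prior = sel[:step]
            others = [i for i in range(n) if i not in prior]
            best = max(D[i, prior].min() for i in others)
            assert D[chosen, prior].min() == pytest.approx(best)
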