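import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsfbind import (
    KdTable,
    ParameterError,
    chain_length_contrast,
    cohens_d,
    load_reference_kd_table,
    percent_difference,
    rank_order,
    species_contrasts,
)
from dsfbind.compare import classify_effect_size


@pytest.fixture(scope="module")
def reference():
    return load_reference_kd_table()


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (2.64, 1.28, 69.4),  # PFBA, human vs porcine albumin
            (0.79, 0.37, 72.4),  # PFOA, human vs porcine
            (1.68, 0.80, 71.0),  # PFBS, human vs bovine
        ],
    )
    def test_published_contrasts(self, a, b, expected):
        assert round(percent_difference(a, b), 1) == expected

    def test_identity(self):
        for x in (0.01, 1.0, 123.4):
            assert percent_difference(x, x) == 0.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ParameterError):
            percent_difference(0.0, 1.0)
        with pytest.raises(ParameterError):
            percent_difference(1.0, -2.0)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_bounded_symmetric_and_closed_form(self, a, b):
        pd_ab = percent_difference(a, b)
        assert 0.0 <= pd_ab < 200.0
        assert pd_ab == percent_difference(b, a)
        assert pd_ab == pytest.approx(200.0 * abs(a - b) / (a + b))


#: Every cross-species contrast percentage printed in the study's results,
#: keyed (ligand, other-species), values vs the human-albumin reference.
PUBLISHED_SPECIES_CONTRASTS = {
    ("PFBA", "PSA"): 69.4,
    ("PFHxA", "PSA"): 57.1,
    ("PFHxA", "BSA"): 23.7,
    ("PFOA", "PSA"): 72.4,
    ("PFOA", "RSA"): 65.5,
    ("PFOA", "BSA"): 22.5,
    ("PFBS", "BSA"): 71.0,
    ("PFBS", "PSA"): 29.4,
    ("PFBS", "RSA"): 17.5,
    ("PFOS", "PSA"): 57.9,
    ("HFPO-DA", "BSA"): 47.6,
    ("HFPO-DA", "PSA"): 29.8,
    ("6:2 FTSA", "BSA"): 108.9,
}

#: Published within-species chain-length contrasts, keyed (species, short, long).
PUBLISHED_CHAIN_CONTRASTS = {
    ("HSA", "PFBA", "PFOA"): 107.9,
    ("HSA", "PFBS", "PFOS"): 83.5,
    ("BSA", "PFBA", "PFOA"): 102.2,
    ("PSA", "PFBA", "PFOA"): 110.3,
    ("PSA", "PFBS", "PFOS"): 106.7,
    ("RSA", "PFBA", "PFOA"): 130.4,
    ("RSA", "PFBS", "PFOS"): 108.2,
}


class TestSpeciesContrasts:
    def test_reproduces_every_published_percentage(self, reference):
        results = {
            (r.ligand, r.pair[1]): round(r.percent_difference, 1)
            for r in species_contrasts(reference, reference="HSA")
        }
        for key, expected in PUBLISHED_SPECIES_CONTRASTS.items():
            assert results[key] == expected, key

    def test_direction_tracks_lower_kd(self, reference):
        for r in species_contrasts(reference, reference="HSA"):
            a_kd = reference.kd(r.pair[0], r.ligand)
            b_kd = reference.kd(r.pair[1], r.ligand)
            winner = r.pair[0] if a_kd < b_kd else r.pair[1]
            assert r.direction == f"{winner}-higher-affinity"

    def test_single_species_table_gives_empty_contrasts(self):
        table = KdTable(pd.DataFrame({
            "protein": ["HSA"], "ligand": ["PFOA"], "chain_length": [8],
            "kd_mM": [0.79], "kd_sem_mM": [0.09],
        }))
        assert species_contrasts(table, reference="HSA") == []

    def test_missing_reference_rejected(self, reference):
        with pytest.raises(ParameterError, match="XSA"):
            species_contrasts(reference, reference="XSA")

    def test_nonbinders_skipped(self, reference):
        assert not any(r.ligand == "6:2 FTOH"
                       for r in species_contrasts(reference))


class TestChainLengthContrast:
    def test_reproduces_published_percentages(self, reference):
        results = {
            (r.ligand, *r.pair): round(r.percent_difference, 1)
            for r in chain_length_contrast(reference)
        }
        for key, expected in PUBLISHED_CHAIN_CONTRASTS.items():
            assert results[key] == expected, key

    def test_equal_kd_pair_reports_tie(self):
        table = KdTable(pd.DataFrame({
            "protein": ["HSA", "HSA"], "ligand": ["PFBA", "PFOA"],
            "chain_length": [4, 8], "kd_mM": [1.0, 1.0], "kd_sem_mM": [0.1, 0.1],
        }))
        (r,) = chain_length_contrast(table, pairs=(("PFBA", "PFOA"),))
        assert r.percent_difference == 0.0
        assert r.direction == "tie"
        assert "equal" in r.note

    def test_missing_congener_skipped_with_warning(self):
        table = KdTable(pd.DataFrame({
            "protein": ["HSA"], "ligand": ["PFBA"], "chain_length": [4],
            "kd_mM": [2.64], "kd_sem_mM": [0.22],
        }))
        with pytest.warns(UserWarning, match="PFOA"):
            out = chain_length_contrast(table, pairs=(("PFBA", "PFOA"),))
        assert out == []


class TestCohensD:
    def test_equal_means_give_zero_small(self):
        d, label = cohens_d(1.0, 0.1, 6, 1.0, 0.2, 6)
        assert d == 0.0 and label == "small"

    def test_pooled_sd_formula(self):
        # SDs: 0.22*sqrt(6), 0.09*sqrt(6); pooled over 6+6-2 df
        d, label = cohens_d(2.64, 0.22, 6, 0.79, 0.09, 6)
        s_a, s_b = 0.22 * math.sqrt(6), 0.09 * math.sqrt(6)
        pooled = math.sqrt((5 * s_a**2 + 5 * s_b**2) / 10)
        assert d == pytest.approx(abs(2.64 - 0.79) / pooled)
        assert round(d, 2) == 4.49
        assert label == "large"

    def test_class_boundaries_inclusive(self):
        assert classify_effect_size(0.8) == "large"
        assert classify_effect_size(0.5) == "medium"
        assert classify_effect_size(0.2) == "small"
        assert classify_effect_size(0.79) == "medium"

    def test_zero_pooled_sd_with_unequal_means_is_infinite(self):
        d, label = cohens_d(1.0, 0.0, 6, 2.0, 0.0, 6)
        assert math.isinf(d) and label == "large"

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            cohens_d(1.0, 0.1, 1, 2.0, 0.1, 6)


class TestRankOrder:
    def test_published_pfoa_row(self, reference):
        ranks = rank_order(reference)
        row = ranks.loc["PFOA"]
        assert row["PSA"] == 1 and row["RSA"] == 2
        assert row["HSA"] == 3 and row["BSA"] == 4

    def test_nonbinders_excluded(self, reference):
        ranks = rank_order(reference)
        assert "6:2 FTOH" not in ranks.index
        assert len(ranks) == 7  # seven bound congeners

    def test_rows_are_permutations_with_mean_rank_ties(self, reference):
        ranks = rank_order(reference)
        for _, row in ranks.iterrows():
            vals = sorted(row.dropna())
            assert sum(vals) == pytest.approx(len(vals) * (len(vals) + 1) / 2)

    def test_ties_share_mean_rank(self):
        table = KdTable(pd.DataFrame({
            "protein": ["HSA", "BSA", "PSA"], "ligand": ["X"] * 3,
            "chain_length": [4] * 3, "kd_mM": [0.5, 0.5, 1.0],
            "kd_sem_mM": [0.1] * 3,
        }))
        row = rank_order(table).loc["X"]
        assert row["HSA"] == 1.5 and row["BSA"] == 1.5 and row["PSA"] == 3.0


class TestKdTableValidation:
    def test_duplicate_pairs_rejected(self):
        from dsfbind.errors import PlateValidationError

        with pytest.raises(PlateValidationError, match="duplicate"):
            KdTable(pd.DataFrame({
                "protein": ["HSA", "HSA"], "ligand": ["PFOA", "PFOA"],
                "chain_length": [8, 8], "kd_mM": [0.79, 0.8],
                "kd_sem_mM": [0.1, 0.1],
            }))

    def test_nonpositive_kd_rejected(self):
        from dsfbind.errors import PlateValidationError

        with pytest.raises(PlateValidationError, match="positive"):
            KdTable(pd.DataFrame({
                "protein": ["HSA"], "ligand": ["PFOA"], "chain_length": [8],
                "kd_mM": [-0.1], "kd_sem_mM": [0.1],
            }))
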