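"""Pair predictors, randomization nulls, stratified probabilities."""

import numpy as np
import pandas as pd
import pytest

from contamkit.barcode import ContaminationMatrix
from contamkit.labmeta import (
    empirical_pvalue,
    observed_statistic,
    pair_predictors,
    randomize_conditional,
    randomize_unconditional,
    stratified_probabilities,
    predictor_randomization_test,
    subsample_one_per_stratum,
    validate_metadata,
)
from contamkit.simulate import simulate_metadata


def meta_from_rows(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "species", "individual", "technician", "entry_date",
            "shipment_date", "center", "flowcell", "lane",
        ],
    )


@pytest.fixture
def small_meta():
    return meta_from_rows([
        ("spA", "a1", "t1", "2012-01-10", "2012-04-10", "SC1", "FC1", 1),
        ("spA", "a2", "t1", "2012-01-15", "2012-04-10", "SC1", "FC1", 2),
        ("spB", "b1", "t1", "2012-02-19", "2012-04-10", "SC1", "FC1", 1),
        ("spC", "c1", "t2", "2012-03-01", "2012-09-01", "SC1", "FC2", 1),
        ("spD", "d1", "t2", "2012-04-10", "2012-09-01", "SC2", "FC3", 1),
    ])


def matrix_for(species, ones=(), missing=()):
    S = len(species)
    m = np.zeros((S, S))
    np.fill_diagonal(m, np.nan)
    idx = {s: i for i, s in enumerate(species)}
    for a, b in missing:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = np.nan
    for a, b in ones:
        m[idx[a], idx[b]] = 1.0
    return ContaminationMatrix(species=list(species), m=m, min_reads=1)


class TestPairPredictors:
    def test_overlap_of_processing_periods(self, small_meta):
        preds = pair_predictors(small_meta)
        # spA processed 2012-01-10..2012-04-10, spC 2012-03-01..2012-09-01
        assert preds.loc[("spA", "spC"), "lab_overlap"] == 40
        # disjoint: spA ends 04-10, spD starts 04-10 -> 0 days
        assert preds.loc[("spA", "spD"), "lab_overlap"] == 0

    def test_same_shipment_requires_same_center(self, small_meta):
        preds = pair_predictors(small_meta)
        assert preds.loc[("spA", "spB"), "same_shipment"]
        # spC and spD shipped the same day but to different centers
        assert not preds.loc[("spC", "spD"), "same_shipment"]

    def test_nesting_invariant(self, small_meta):
        preds = pair_predictors(small_meta)
        seen_lane = False
        for _, row in preds.iterrows():
            if row["same_lane"] == True:  # noqa: E712 (may be NA)
                seen_lane = True
                assert row["same_flowcell"] and row["same_shipment"]
            if row["same_flowcell"] == True:  # noqa: E712
                assert row["same_shipment"]
        assert seen_lane

    def test_lane_sharing(self, small_meta):
        preds = pair_predictors(small_meta)
        assert preds.loc[("spA", "spB"), "same_lane"]  # a1 and b1: FC1 lane 1
        assert preds.loc[("spA", "spB"), "CENTER"] == "CENTER+++"

    def test_lab_variable_direction(self, small_meta):
        preds = pair_predictors(small_meta, lab_overlap_days=50)
        assert not preds.loc[("spA", "spD"), "LAB"]
        assert preds.loc[("spA", "spB"), "LAB"]  # same tech, 52-day overlap
        flipped = pair_predictors(small_meta, lab_overlap_days=50,
                                  lab_overlap_greater=False)
        assert not flipped.loc[("spA", "spB"), "LAB"]

    def test_missing_flowcell_gives_na(self, small_meta):
        meta = small_meta.copy()
        meta.loc[meta["species"] == "spB", ["flowcell", "lane"]] = [None, None]
        with pytest.raises(ValueError):
            validate_metadata(
                meta.assign(flowcell=None)  # lane without flowcell
            )
        meta2 = small_meta.copy()
        meta2.loc[meta2["species"] == "spB", "flowcell"] = None
        meta2.loc[meta2["species"] == "spB", "lane"] = None
        preds = pair_predictors(meta2)
        assert pd.isna(preds.loc[("spA", "spB"), "same_flowcell"])
        assert not preds.loc[("spA", "spB"), "info_complete"]

    def test_entry_after_shipment_rejected(self, small_meta):
        bad = small_meta.copy()
        bad.loc[0, "entry_date"] = "2013-01-01"
        with pytest.raises(ValueError):
            validate_metadata(bad)


class TestObservedStatistic:
    def test_all_contaminated_pairs_share_shipment(self, small_meta):
        preds = pair_predictors(small_meta)
        M = matrix_for(["spA", "spB", "spC", "spD"], ones=[("spA", "spB")])
        assert observed_statistic(M, preds, "same_shipment") == 1.0

    def test_mixed_pairs_average(self, small_meta):
        preds = pair_predictors(small_meta)
        M = matrix_for(
            ["spA", "spB", "spC", "spD"],
            ones=[("spA", "spB"), ("spA", "spC"), ("spB", "spC")],
        )
        assert observed_statistic(M, preds, "same_shipment") == pytest.approx(1 / 3)

    def test_empty_matrix_rejected(self, small_meta):
        preds = pair_predictors(small_meta)
        M = matrix_for(["spA", "spB", "spC", "spD"])
        with pytest.raises(ValueError):
            observed_statistic(M, preds, "same_shipment")


class TestRandomization:
    def make_setup(self, n_species=10, seed=0):
        meta = simulate_metadata(n_species, seed=seed)
        preds = pair_predictors(meta)
        species = sorted(meta["species"].unique())
        rng = np.random.default_rng(seed + 1)
        ones = []
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                if rng.random() < 0.15:
                    ones.append((a, b))
        M = matrix_for(species, ones=ones, missing=[(species[0], species[1])])
        return M, preds

    def test_expected_ones_match_p(self):
        M, preds = self.make_setup()
        rng = np.random.default_rng(7)
        reps = 400
        total_ones = 0.0
        defined = ~np.isnan(M.m)
        for _ in range(reps):
            repl = np.full(M.m.shape, np.nan)
            repl[defined] = (rng.random(int(defined.sum())) < M.p).astype(float)
            total_ones += np.nansum(repl)
        assert total_ones / reps == pytest.approx(M.p * defined.sum(), rel=0.1)

    def test_missing_cells_preserved_and_seeded(self):
        M, preds = self.make_setup()
        a = randomize_unconditional(M, preds, "same_shipment", reps=50,
                                    rng=np.random.default_rng(3))
        b = randomize_unconditional(M, preds, "same_shipment", reps=50,
                                    rng=np.random.default_rng(3))
        assert np.array_equal(a, b, equal_nan=True)

    def test_conditional_respects_strata(self):
        M, preds = self.make_setup()
        # zero out every contaminated different-shipment pair so the
        # conditional probability for that stratum is 0
        vals = preds["same_shipment"]
        idx = {s: i for i, s in enumerate(M.species)}
        for (a, b), same in vals.items():
            if not same and a in idx and b in idx:
                for i, j in ((idx[a], idx[b]), (idx[b], idx[a])):
                    if not np.isnan(M.m[i, j]):
                        M.m[i, j] = 0.0
        null = randomize_conditional(
            M, preds, "same_shipment", ["same_shipment"], reps=100,
            rng=np.random.default_rng(11),
        )
        clean = null[~np.isnan(null)]
        # ones can only appear in same-shipment cells, so the statistic is 1
        assert np.allclose(clean, 1.0)

    def test_conditional_null_centers_on_observed(self):
        # conditioning on the predictor itself makes the null reproduce the
        # observed statistic on average (law of large numbers)
        M, preds = self.make_setup(n_species=14, seed=5)
        null = randomize_conditional(M, preds, "same_shipment",
                                     ["same_shipment"], reps=600,
                                     rng=np.random.default_rng(2))
        obs = observed_statistic(M, preds, "same_shipment")
        clean = null[~np.isnan(null)]
        assert clean.mean() == pytest.approx(obs, abs=0.12)


class TestEmpiricalPvalue:
    def test_observed_above_all(self):
        assert empirical_pvalue(10.0, np.zeros(1000)) == pytest.approx(1 / 1001)

    def test_observed_at_median(self):
        null = np.arange(1001, dtype=float)
        assert empirical_pvalue(500.0, null) == pytest.approx(0.5, abs=0.01)

    def test_lower_tail(self):
        assert empirical_pvalue(-5.0, np.zeros(100), tail="upper") == pytest.approx(1.0)
        assert empirical_pvalue(-5.0, np.zeros(100), tail="lower") == pytest.approx(1 / 101)


class TestStratifiedProbabilities:
    def test_printed_ratio_form(self, small_meta):
        preds = pair_predictors(small_meta)
        M = matrix_for(["spA", "spB", "spC", "spD"], ones=[("spA", "spB")])
        table = stratified_probabilities(M, preds)
        row = table[(table["CENTER"] == "CENTER+") & (table["LAB"] == "LAB-")]
        assert row["total_pairs"].item() >= 1

    def test_cumulative_tiers_nested(self):
        meta = simulate_metadata(16, seed=3)
        preds = pair_predictors(meta)
        species = sorted(meta["species"].unique())
        rng = np.random.default_rng(4)
        ones = [
            (a, b)
            for i, a in enumerate(species)
            for b in species[i + 1:]
            if rng.random() < 0.2
        ]
        M = matrix_for(species, ones=ones)
        table = stratified_probabilities(M, preds, cumulative=True)
        for lab in ("LAB-", "LAB+"):
            tot = [
                table[(table["CENTER"] == t) & (table["LAB"] == lab)]["total_pairs"].item()
                for t in ("CENTER+", "CENTER++", "CENTER+++")
            ]
            assert tot[0] >= tot[1] >= tot[2]

    def test_disjoint_mode_partitions_cumulative(self):
        meta = simulate_metadata(12, seed=6)
        preds = pair_predictors(meta)
        species = sorted(meta["species"].unique())
        M = matrix_for(species, ones=[(species[0], species[2])])
        cum = stratified_probabilities(M, preds, cumulative=True)
        dis = stratified_probabilities(M, preds, cumulative=False)
        for lab in ("LAB-", "LAB+"):
            c = cum[(cum["CENTER"] == "CENTER+") & (cum["LAB"] == lab)]["total_pairs"].item()
            parts = sum(
                dis[(dis["CENTER"] == t) & (dis["LAB"] == lab)]["total_pairs"].item()
                for t in ("CENTER+", "CENTER++", "CENTER+++")
            )
            assert c == parts


class TestSubsample:
    def test_one_species_per_stratum(self):
        meta = simulate_metadata(20, n_technicians=3, seed=1)
        kept = subsample_one_per_stratum(meta, rng=np.random.default_rng(2))
        strata = {}
        for sp in kept:
            grp = meta[meta["species"] == sp].sort_values("shipment_date").iloc[0]
            key = (grp["technician"], grp["shipment_date"])
            assert key not in strata
            strata[key] = sp

    def test_seeded_and_reproducible(self):
        meta = simulate_metadata(20, n_technicians=3, seed=1)
        a = subsample_one_per_stratum(meta, rng=np.random.default_rng(9))
        b = subsample_one_per_stratum(meta, rng=np.random.default_rng(9))
        assert a == b

    def test_single_stratum_keeps_one(self):
        meta = simulate_metadata(
            5, n_technicians=1, shipment_dates=["2012-03-01"], seed=0,
        )
        assert len(subsample_one_per_stratum(meta, rng=np.random.default_rng(0))) == 1
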