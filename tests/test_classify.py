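"""Mislabeling classifier and audit aggregation against the survey fixture."""

import numpy as np
import pytest

import seafood_audit as sa
from seafood_audit.classify import DegenerateTableError
from seafood_audit.report import summaries_frame


def _record(name, candidates, cohort="finfish", year=2018):
    return sa.SampleRecord(
        sample_id="T-1",
        year=year,
        cohort=cohort,
        market_name_raw=name,
        barcode_candidates=frozenset(candidates),
    )


class TestClassifySample:
    @pytest.mark.parametrize(
        "cohort, name, candidates, expected",
        [
            ("invertebrate", "Surf Clam", {"Pseudocardium sachalinense"},
             "product_substitution"),
            ("finfish", "Unagi", {"Anguilla rostrata"}, "semantic"),
            ("finfish", "Freshwater Eel", {"Anguilla anguilla"},
             "product_substitution"),
            ("finfish", "Atlantic Salmon", {"Salmo salar"}, "properly_labeled"),
            ("finfish", "Hamachi– Yellow Tail Tuna",
             {"Seriola quinqueradiata"}, "invalid_name"),
            ("finfish", "Alaskan Salmon", {"Oncorhynchus nerka"},
             "invalid_name"),
            ("finfish", "Alaskan Salmon", {"Sebastes alutus"},
             "product_substitution"),
            ("invertebrate", "Seafood Medley/Mix", {"Penaeus vannamei"},
             "unregulated"),
            # genus-wide allowance: any Lutjanus passes under "snapper"
            ("finfish", "Snapper", {"Lutjanus johnii"}, "properly_labeled"),
            # multi-species barcode overlapping the acceptable set passes
            ("finfish", "Cod", {"Gadus morhua", "Oreochromis niloticus"},
             "properly_labeled"),
        ],
    )
    def test_examples(self, invertebrates, finfish, cohort, name, candidates,
                      expected):
        bundle = invertebrates if cohort == "invertebrate" else finfish
        call = sa.classify_sample(
            _record(name, candidates, cohort=cohort), bundle.authority
        )
        assert call.category == expected
        assert call.rationale  # every call carries a decision trace

    def test_unknown_name_is_configuration_error(self, finfish):
        with pytest.raises(sa.authority.AuthorityError, match="T-1"):
            sa.classify_sample(_record("qwzx fish", {"Gadus morhua"}),
                               finfish.authority)

    def test_empty_candidates_rejected_at_construction(self):
        with pytest.raises(ValueError):
            _record("Cod", set())


class TestFixtureReproduction:
    @pytest.mark.parametrize("cohort", ["invertebrates", "finfish"])
    def test_every_record_matches_the_survey_adjudication(
        self, request, cohort
    ):
        classified = request.getfixturevalue(f"classified_{cohort}")
        bundle = request.getfixturevalue(cohort)
        merged = classified.merge(
            bundle.expected[["sample_id", "expected_category"]], on="sample_id"
        )
        mismatches = merged[merged.category != merged.expected_category]
        assert mismatches.empty, mismatches.head(10).to_string()

    @pytest.mark.parametrize("cohort", ["invertebrates", "finfish"])
    def test_per_name_counts_match_the_published_tables(self, request, cohort):
        """Aggregating per-record calls reproduces every S/IN/PS cell of the
        per-market-name tables."""
        classified = request.getfixturevalue(f"classified_{cohort}")
        bundle = request.getfixturevalue(cohort)
        got = (
            classified.groupby("market_name")["category"]
            .value_counts()
            .unstack(fill_value=0)
        )
        for row in bundle.table_counts.itertuples():
            key = sa.normalize_name(row.market_name_raw)
            counts = got.loc[key]
            assert counts.sum() == row.n, key
            for col, expected in [
                ("semantic", row.semantic),
                ("invalid_name", row.invalid_name),
                ("product_substitution", row.product_substitution),
            ]:
                assert counts.get(col, 0) == expected, (key, col)

    @pytest.mark.parametrize("cohort", ["invertebrates", "finfish"])
    def test_year_rows(self, request, cohort):
        """Per-year counts exactly; percentages at the printed precision
        (the source truncates two cells of 32.258% to 32.2)."""
        classified = request.getfixturevalue(f"classified_{cohort}")
        bundle = request.getfixturevalue(cohort)
        table = summaries_frame(sa.summarize(classified, by="year"), "year")
        table["year"] = table["year"].astype(int)
        merged = table.merge(bundle.year_counts, on="year",
                             suffixes=("", "_pub"))
        assert len(merged) == len(bundle.year_counts)
        for row in merged.itertuples():
            assert row.n == row.n_pub
            assert row.semantic == row.semantic_pub
            assert row.invalid_name == row.invalid_name_pub
            assert row.product_substitution == row.product_substitution_pub
            exact_total = 100.0 * (
                row.semantic + row.invalid_name + row.product_substitution
            ) / row.n
            exact_cons = 100.0 * (
                row.invalid_name + row.product_substitution
            ) / row.n
            assert abs(exact_total - row.pct_total_pub) <= 0.06
            assert abs(exact_cons - row.pct_conservative_pub) <= 0.06


class TestSummarize:
    def test_overall_invertebrate_row(self, classified_invertebrates):
        s = sa.summarize(classified_invertebrates)[0]
        assert s.n == 109
        assert s.counts["semantic"] == 15
        assert s.counts["invalid_name"] == 0
        assert s.counts["product_substitution"] == 22
        assert round(s.pct_total_mislabeled, 1) == 33.9
        assert round(s.pct_conservative_mislabeled, 1) == 20.2

    def test_overall_finfish_row(self, classified_finfish):
        s = sa.summarize(classified_finfish)[0]
        assert (s.n, s.counts["semantic"], s.counts["invalid_name"],
                s.counts["product_substitution"]) == (347, 38, 8, 66)
        assert round(s.pct_total_mislabeled, 1) == 32.3
        assert round(s.pct_conservative_mislabeled, 1) == 21.3

    def test_all_correct_group(self, finfish):
        records = [r for r in finfish.records
                   if r.market_name_raw == "Sockeye Salmon"][:5]
        frame = sa.classify_all(records, finfish.authority)
        s = sa.summarize(frame)[0]
        assert s.pct_total_mislabeled == 0.0

    def test_conservative_never_exceeds_total(self, classified_all):
        for by in (None, "year", "taxon_group", "cohort"):
            for s in sa.summarize(classified_all, by=by):
                assert s.pct_conservative_mislabeled <= s.pct_total_mislabeled
                assert sum(s.counts.values()) == s.n

    def test_order_invariance(self, finfish):
        """The classifier is a pure per-record function: permuting input
        order leaves all summaries unchanged."""
        rng = np.random.default_rng(0)
        perm = list(finfish.records)
        rng.shuffle(perm)
        a = sa.summarize(sa.classify_all(finfish.records, finfish.authority))[0]
        b = sa.summarize(sa.classify_all(perm, finfish.authority))[0]
        assert a.counts == b.counts and a.n == b.n


class TestCrosstab:
    def test_cohort_by_conservative(self, classified_all):
        t = sa.crosstab(classified_all, "cohort", "conservative_mislabeled")
        assert t.array.astype(int).tolist() == [[22, 87], [74, 273]]

    def test_cohort_by_precision_drops_unregulated(self, classified_all):
        t = sa.crosstab(classified_all, "cohort", "precision")
        assert t.array.astype(int).tolist() == [[89, 18], [176, 169]]
        assert t.n_dropped == 4  # two unregulated products per cohort

    def test_concern_excludes_na_dd(self, classified_invertebrates):
        t = sa.crosstab(
            classified_invertebrates, "concern", "conservative_mislabeled"
        )
        assert t.array.astype(int).tolist() == [[2, 0], [6, 19]]
        assert t.n_dropped == 82  # 73 NA + 9 DD records

    def test_degenerate_table_signals(self, finfish):
        records = [r for r in finfish.records
                   if r.market_name_raw == "Atlantic Salmon"]
        frame = sa.classify_all(records, finfish.authority)
        with pytest.raises(DegenerateTableError):
            sa.crosstab(frame, "precision", "conservative_mislabeled")
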