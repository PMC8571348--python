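"""FPTM arithmetic, E factors, consistency classification, concordance."""

import numpy as np
import pandas as pd
import pytest

from secscreen.enrichment import (
    CLASS_DEPLETED,
    CLASS_ENRICHED,
    CLASS_INCONSISTENT,
    CLASS_UNCERTAIN,
    CLASS_UNDETECTED,
    ClassifierConfig,
    classify,
    compute_efactor,
    compute_fptm,
    concordance,
    coverage_fraction,
    enrich,
    flag_in_frame,
    merge_unsorted,
    stratify_independent_sets,
)


def _counts(rows: dict[str, list[int]]) -> pd.DataFrame:
    cols = [f"rep{r}_{pool}" for r in (1, 2, 3) for pool in ("unsorted", "sorted")]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis(
        "fragment_key"
    )


class TestFptm:
    def test_simple_ratio(self):
        counts = _counts({"a": [5, 1, 1, 1, 1, 1], "b": [45, 9, 9, 9, 9, 9]})
        fptm = compute_fptm(counts)
        assert fptm.loc["a", "rep1_unsorted"] == pytest.approx(1e6)

    def test_equal_counts_split_ten_million(self):
        counts = _counts({f"f{i}": [4] * 6 for i in range(8)})
        fptm = compute_fptm(counts)
        assert np.allclose(fptm.to_numpy(), 1e7 / 8)

    def test_columns_conserve_ten_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(1000, 6)),
            columns=[f"rep{r}_{p}" for r in (1, 2, 3) for p in ("unsorted", "sorted")],
        )
        fptm = compute_fptm(counts)
        assert np.allclose(fptm.sum(axis=0), 1e7, atol=1e-3)

    def test_zero_total_sample_errors(self):
        counts = _counts({"a": [0, 1, 1, 1, 1, 1]})
        counts["rep1_unsorted"] = 0
        with pytest.raises(ValueError):
            compute_fptm(counts)


class TestMergeUnsorted:
    def test_identical_replicates_equal_single(self):
        counts = _counts({"a": [10, 0, 10, 0, 10, 0], "b": [90, 5, 90, 5, 90, 5]})
        merged = merge_unsorted(counts)
        single = compute_fptm(counts)["rep1_unsorted"]
        pd.testing.assert_series_equal(merged, single, check_names=False)

    def test_merged_arithmetic(self):
        counts = _counts({"a": [10, 0, 0, 0, 0, 0], "b": [90, 1, 100, 1, 100, 1]})
        merged = merge_unsorted(counts)
        assert merged["a"] == pytest.approx(10 / 300 * 1e7)

    def test_replicate_permutation_invariance(self):
        counts = _counts({"a": [10, 1, 20, 1, 30, 1], "b": [5, 1, 15, 1, 25, 1]})
        permuted = counts.rename(
            columns={
                "rep1_unsorted": "rep3_unsorted",
                "rep3_unsorted": "rep1_unsorted",
            }
        )[counts.columns]
        pd.testing.assert_series_equal(
            merge_unsorted(counts), merge_unsorted(permuted)
        )


class TestEfactor:
    def test_basic_values(self):
        assert compute_efactor(100.0, 100.0) == 0.0
        assert compute_efactor(400.0, 100.0) == 2.0

    def test_extended_reals(self):
        assert compute_efactor(0.0, 10.0) == -np.inf
        assert compute_efactor(10.0, 0.0) == np.inf
        assert np.isnan(compute_efactor(0.0, 0.0))

    def test_zero_sorted_classifies_depleted(self):
        counts = _counts(
            {"gone": [50, 0, 50, 0, 50, 0], "rest": [50, 100, 50, 100, 50, 100]}
        )
        rec = enrich(counts)
        assert rec.loc["gone", "class"] == CLASS_DEPLETED


class TestFlagInFrame:
    def test_exhaustive_offset_length_grid(self):
        # over a 3x3 grid of start offsets and length remainders, exactly one
        # combination is in frame on both ends
        hits = 0
        for off in range(3):
            for rem in range(3):
                n, c = flag_in_frame(30 + off, 30 + off + 99 + rem, 30, 300)
                hits += n and c
                assert n == (off == 0)
                assert c == (rem == 0)
        assert hits == 1

    def test_outside_cds(self):
        assert flag_in_frame(3, 33, 12, 300) == (False, False)


def _records_from_e(e_rows: dict[str, tuple], detected=True) -> pd.DataFrame:
    rec = pd.DataFrame.from_dict(
        e_rows, orient="index", columns=["E_1", "E_2", "E_3"]
    )
    for r in (1, 2, 3):
        rec[f"detected_{r}"] = detected
    return rec


class TestClassify:
    @pytest.mark.parametrize(
        "e, expected",
        [
            ((1.5, 2.0, 1.1), CLASS_ENRICHED),
            ((1.0, 1.0, 1.0), CLASS_ENRICHED),  # inclusive threshold
            ((-2, -3, -1.5), CLASS_DEPLETED),
            ((1.2, 1.5, 0.3), CLASS_UNCERTAIN),
            ((-1.2, -1.5, 0.3), CLASS_UNCERTAIN),
            ((1.2, 1.5, -1.4), CLASS_INCONSISTENT),
            ((0.5, 0.2, -0.3), CLASS_INCONSISTENT),
            ((np.inf, 2.0, 1.0), CLASS_ENRICHED),
            ((-np.inf, -1.0, -9.0), CLASS_DEPLETED),
        ],
    )
    def test_rule_table(self, e, expected):
        rec = _records_from_e({"f": e})
        assert classify(rec)["f"] == expected

    def test_undetected_dominates(self):
        rec = _records_from_e({"f": (2.0, 2.0, 2.0)})
        rec["detected_2"] = False
        assert classify(rec)["f"] == CLASS_UNDETECTED

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        e = rng.normal(0, 2, size=(200, 3))
        e[rng.random((200, 3)) < 0.05] = np.inf
        e[rng.random((200, 3)) < 0.05] = -np.inf
        rec = _records_from_e({f"f{i}": tuple(e[i]) for i in range(200)})

        def oracle(row):
            if all(v >= 1 for v in row):
                return CLASS_ENRICHED
            if all(v <= -1 for v in row):
                return CLASS_DEPLETED
            for odd in range(3):
                rest = [row[i] for i in range(3) if i != odd]
                if -1 < row[odd] < 1 and (
                    all(v >= 1 for v in rest) or all(v <= -1 for v in rest)
                ):
                    return CLASS_UNCERTAIN
            return CLASS_INCONSISTENT

        got = classify(rec)
        for i in range(200):
            assert got[f"f{i}"] == oracle(tuple(e[i])), tuple(e[i])

    def test_partition_of_detected_fragments(self, default_records):
        detected = default_records[default_records["class"] != CLASS_UNDETECTED]
        assert set(detected["class"]) <= {
            CLASS_ENRICHED,
            CLASS_DEPLETED,
            CLASS_UNCERTAIN,
            CLASS_INCONSISTENT,
        }

    def test_monotone_in_sorted_counts(self):
        # raising a fragment's sorted counts (totals fixed elsewhere) never
        # moves it from enriched toward depleted
        order = {CLASS_DEPLETED: 0, CLASS_INCONSISTENT: 1,
                 CLASS_UNCERTAIN: 1, CLASS_ENRICHED: 2}
        last = 0
        for boost in (0, 20, 80, 300):
            counts = _counts(
                {
                    "f": [50, 10 + boost, 50, 10 + boost, 50, 10 + boost],
                    "bg": [1000, 1000, 1000, 1000, 1000, 1000],
                }
            )
            rank = order[enrich(counts).loc["f", "class"]]
            assert rank >= last
            last = rank


class TestIndependentSets:
    def test_set_assignment_cases(self):
        rec = _records_from_e(
            {
                "a": (1.2, 1.5, 0.3),     # A, enriched side
                "b": (1.2, 1.5, -1.4),    # B, enriched side
                "c": (-1.2, -1.5, 1.1),   # B, depleted side
                "d": (1.2, 1.5, 1.0),     # fully consistent: neither
                "e": (0.2, 0.1, 0.0),     # nothing consistent
            }
        )
        sets = stratify_independent_sets(rec)
        assert sets.loc["a", "independent_set"] == "A"
        assert sets.loc["a", "label"] == 1
        assert sets.loc["b", "independent_set"] == "B"
        assert sets.loc["c", "independent_set"] == "B"
        assert sets.loc["c", "label"] == 0
        assert "d" not in sets.index
        assert "e" not in sets.index

    def test_sets_disjoint(self, default_records):
        sets = stratify_independent_sets(default_records)
        a = set(sets.index[sets["independent_set"] == "A"])
        b = set(sets.index[sets["independent_set"] == "B"])
        assert not a & b


class TestConcordance:
    def test_extremes_and_identity(self):
        rec = _records_from_e({"a": (2, 2, 2), "b": (1.5, 1.2, 3.0)})
        rec["in_frame"] = True
        rec["class"] = classify(rec)
        assert concordance(rec) == 100.0

        rec2 = _records_from_e({"a": (0.5, 0.5, 0.5)})
        rec2["in_frame"] = True
        rec2["class"] = classify(rec2)
        assert concordance(rec2) == 0.0

    def test_equals_enriched_plus_depleted_fraction(self, default_records):
        mask = default_records["in_frame"] & (
            default_records["class"] != CLASS_UNDETECTED
        )
        frac = (
            default_records.loc[mask, "class"]
            .isin([CLASS_ENRICHED, CLASS_DEPLETED])
            .mean()
            * 100
        )
        assert concordance(default_records) == pytest.approx(frac)

    def test_hand_counted_toy_table(self):
        rows = {
            "e1": (2, 2, 2), "e2": (1, 1.5, 1.1),
            "d1": (-2, -2, -2),
            "u1": (1.5, 1.5, 0.0),
            "i1": (1.5, -1.5, 0.0),
        }
        rec = _records_from_e(rows)
        rec["in_frame"] = True
        rec["class"] = classify(rec)
        assert concordance(rec) == pytest.approx(3 / 5 * 100)


class TestCoverage:
    def test_half_covered_single_transcript(self):
        frags = pd.DataFrame(
            {"transcript_id": ["t"], "start": [0], "end": [50], "count": [3]}
        )
        assert coverage_fraction(frags, {"t": 100}) == 50.0

    def test_below_min_reads_ignored(self):
        frags = pd.DataFrame(
            {"transcript_id": ["t"], "start": [0], "end": [50], "count": [2]}
        )
        assert coverage_fraction(frags, {"t": 100}) == 0.0

    def test_interval_union_oracle(self):
        rng = np.random.default_rng(9)
        tlens = {f"t{i}": int(rng.integers(50, 300)) for i in range(5)}
        rows = []
        for _ in range(60):
            tid = f"t{rng.integers(0, 5)}"
            start = int(rng.integers(0, tlens[tid] - 10))
            end = start + int(rng.integers(5, 40))
            rows.append((tid, start, min(end, tlens[tid]), int(rng.integers(0, 8))))
        frags = pd.DataFrame(rows, columns=["transcript_id", "start", "end", "count"])

        covered = 0
        for tid, tlen in tlens.items():
            bases = set()
            for _, row in frags[(frags["transcript_id"] == tid) & (frags["count"] >= 3)].iterrows():
                bases.update(range(row["start"], row["end"]))
            covered += len(bases)
        expected = covered / sum(tlens.values()) * 100
        assert coverage_fraction(frags, tlens) == pytest.approx(expected)


class TestEnrichedRecoverTruth:
    def test_enriched_fragments_have_high_true_display(
        self, default_screen, default_records
    ):
        # parameter recovery: fragments the pipeline calls enriched should
        # overwhelmingly display above the truth-table median
        rec = default_records
        truth = default_screen.truth
        enr_keys = rec.index[(rec["class"] == CLASS_ENRICHED) & rec["in_frame"]]
        dep_keys = rec.index[(rec["class"] == CLASS_DEPLETED) & rec["in_frame"]]
        disp = truth["display_probability"]
        in_frame_disp = disp[disp.index.isin(rec.index[rec["in_frame"]])]
        median = in_frame_disp[in_frame_disp > 0].median()
        assert (disp[enr_keys] > median).mean() >= 0.90
        assert disp[enr_keys].mean() > disp[dep_keys].mean()
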