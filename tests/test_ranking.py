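"""Membrane filtering, ranking, aliasing, overlap and consensus."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfscreen import (
    PipelineError,
    RankedEntry,
    RankedTargetList,
    ValidationError,
    canonicalize,
    classify_family,
    consensus,
    consensus_count,
    family_breakdown,
    filter_membrane,
    rank_targets,
    shared_fraction,
)
from surfscreen.io import load_reference_list, reference_aliases, reference_families


def score_table(rows):
    """rows: (probe, symbol, fold_change, membrane-is-handled-elsewhere)."""
    return pd.DataFrame(
        {
            "probe_id": [r[0] for r in rows],
            "symbol": [r[1] for r in rows],
            "canonical": [r[1] for r in rows],
            "fold_change": [r[2] for r in rows],
        }
    )


def make_list(comparator, metric, symbols, scores=None):
    scores = scores or list(range(len(symbols), 0, -1))
    entries = tuple(
        RankedEntry(str(i + 1), "", s, s, float(sc))
        for i, (s, sc) in enumerate(zip(symbols, scores))
    )
    return RankedTargetList(comparator=comparator, metric=metric,
                            entries=entries)


class TestFilterMembrane:
    def _ann(self, flags):
        from surfscreen import ProbeAnnotation

        return ProbeAnnotation(
            table=pd.DataFrame(
                {
                    "symbol": [f"G{i}" for i in range(len(flags))],
                    "membrane": flags,
                    "family": "other",
                },
                index=pd.Index([f"p{i}" for i in range(len(flags))],
                               name="probe_id"),
            )
        )

    def test_all_membrane_is_identity(self):
        t = score_table([(f"p{i}", f"G{i}", i) for i in range(3)])
        out = filter_membrane(t, self._ann([True] * 3))
        assert list(out["probe_id"]) == list(t["probe_id"])

    def test_none_membrane_is_empty(self):
        t = score_table([(f"p{i}", f"G{i}", i) for i in range(3)])
        assert len(filter_membrane(t, self._ann([False] * 3))) == 0

    def test_mixed_preserves_relative_order(self):
        flags = [True, False, True, False, True, True]
        t = score_table([(f"p{i}", f"G{i}", i) for i in range(6)])
        out = filter_membrane(t, self._ann(flags))
        assert list(out["probe_id"]) == ["p0", "p2", "p4", "p5"]

    def test_unannotated_probe_named_in_error(self):
        t = score_table([("missing", "G", 1.0)])
        with pytest.raises(PipelineError, match="missing"):
            filter_membrane(t, self._ann([True]))


class TestRankTargets:
    def test_top1_is_maximum(self):
        t = score_table([("a", "A", 1.0), ("b", "B", 9.0), ("c", "C", 5.0)])
        lst = rank_targets(t, "fold_change", 1)
        assert lst.entries[0].probe_id == "b"

    def test_tie_broken_by_symbol(self):
        t = score_table([("x", "B", 5.0), ("y", "A", 5.0)])
        lst = rank_targets(t, "fold_change", 2)
        assert [e.symbol for e in lst.entries] == ["A", "B"]

    def test_sorting_order(self):
        t = score_table([("a", "A", 3.0), ("b", "B", 1.0), ("c", "C", 2.0)])
        lst = rank_targets(t, "fold_change", 2)
        assert [e.probe_id for e in lst.entries] == ["a", "c"]

    def test_n_larger_than_table_returns_all(self, caplog):
        t = score_table([("a", "A", 1.0)])
        assert len(rank_targets(t, "fold_change", 10)) == 1

    def test_deterministic_re_run(self):
        t = score_table([("a", "A", 3.0), ("b", "B", 3.0), ("c", "C", 2.0)])
        a = rank_targets(t, "fold_change", 3)
        b = rank_targets(t.sample(frac=1, random_state=0), "fold_change", 3)
        assert a.entries == b.entries

    def test_increasing_scores_rejected(self):
        with pytest.raises(ValidationError):
            RankedTargetList(
                comparator="c", metric="fold_change",
                entries=(RankedEntry("1", "", "A", "A", 1.0),
                         RankedEntry("2", "", "B", "B", 2.0)),
            )


class TestCanonicalize:
    @pytest.mark.parametrize(
        "symbol, expected",
        [("CD62L", "SELL"), ("MHMA1", "HMHA1"), ("CD19", "CD19"),
         ("TCRDC", "TRDC"), ("IL-7R", "IL7R")],
    )
    def test_alias_examples(self, symbol, expected):
        assert canonicalize(symbol, reference_aliases()) == expected

    def test_immunoglobulin_loci_not_merged(self):
        aliases = reference_aliases()
        assert canonicalize("IGH", aliases) == "IGH"
        assert canonicalize("IGHM", aliases) == "IGHM"


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "symbol, family",
        [("TRBC1", "TCR_chain"), ("CD247", "CD3_complex"), ("HHIP", "other")],
    )
    def test_family_examples(self, symbol, family):
        assert classify_family(symbol, reference_families()) == family


class TestSharedFraction:
    def test_identical_lists_100_percent(self):
        a = make_list("c1", "fold_change", ["X", "Y", "Z"])
        b = make_list("c2", "fold_change", ["X", "Y", "Z"])
        rep = shared_fraction(a, b)
        assert rep.shared_count == 3
        assert rep.percent_shared == 100.0

    def test_disjoint_lists_zero(self):
        a = make_list("c1", "fold_change", ["X", "Y"])
        b = make_list("c2", "fold_change", ["P", "Q"])
        rep = shared_fraction(a, b)
        assert rep.shared_count == 0
        assert rep.percent_shared == 0.0

    def test_denominator_rules(self):
        a = make_list("c1", "fold_change", ["X", "Y", "Z", "W"])
        b = make_list("c2", "fold_change", ["X", "Y"])
        assert shared_fraction(a, b, "len_a").percent_shared == 50.0
        assert shared_fraction(a, b, "len_b").percent_shared == 100.0
        assert shared_fraction(a, b, "union").percent_shared == 50.0

    @given(st.lists(st.sampled_from("ABCDEFGH"), min_size=1, max_size=8,
                    unique=True),
           st.lists(st.sampled_from("ABCDEFGH"), min_size=1, max_size=8,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_shared_count_symmetric(self, syms_a, syms_b):
        a = make_list("c1", "fold_change", syms_a)
        b = make_list("c2", "fold_change", syms_b)
        assert (shared_fraction(a, b).shared_count
                == shared_fraction(b, a).shared_count)
        assert 0 <= shared_fraction(a, b).percent_shared <= 100


class TestConsensus:
    def _three_lists(self):
        return [
            make_list("broad", "fold_change", ["HHIP", "CD3D", "X1"]),
            make_list("hsc", "fold_change", ["HHIP", "CD3D", "TSPAN7"]),
            make_list("pbmc", "fold_change", ["HHIP", "TSPAN7", "X2"]),
        ]

    def test_counts(self):
        table = consensus(self._three_lists())
        assert consensus_count(table, "HHIP") == 3
        assert consensus_count(table, "TSPAN7") == 2
        assert consensus_count(table, "ABSENT") == 0

    def test_pooled_per_comparator_counts_once(self):
        lists = self._three_lists() + [
            make_list("broad", "t_score", ["HHIP", "Y1", "Y2"])
        ]
        table = consensus(lists)
        assert consensus_count(table, "HHIP") == 3  # still 3 comparators

    def test_monotone_as_lists_added(self):
        lists = self._three_lists()
        t2 = consensus(lists[:2])
        t3 = consensus(lists)
        for sym in t2["symbol"]:
            assert consensus_count(t3, sym) >= consensus_count(t2, sym)

    def test_single_comparator_rejected(self):
        with pytest.raises(PipelineError):
            consensus([make_list("only", "fold_change", ["A"])])


class TestFamilyBreakdown:
    def test_counts_sum_to_length(self):
        lst = load_reference_list("tall_vs_normal")
        counts = family_breakdown(lst, reference_families())
        assert sum(counts.values()) == len(lst)

    def test_all_other_list(self):
        lst = make_list("c", "fold_change", ["A", "B", "C", "D", "E"])
        counts = family_breakdown(lst, {})
        assert counts == {"TCR_chain": 0, "CD3_complex": 0, "other": 5}
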