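"""Label verification: categorization, percentages, summaries, authenticity."""
from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbmark.labels import FormulationLabel
from herbmark.motu import MOTU, PooledUnique, tally_assignments
from herbmark.taxonomy import Lineage
from herbmark.verify import (
    VerificationRecord,
    authenticity_flag,
    categorize,
    percentages,
    project_label,
    report_from_counts,
    summarize,
    verify_sample,
)

from .oracles import percentage_sum_is_100_01, percentages_oracle


def _lin(family, genus, species):
    return Lineage("Plantae", "T", "M", "O", family, genus, species)


LINEAGES = {
    "Alphus primus": _lin("Alphaceae", "Alphus", "Alphus primus"),
    "Alphus secundus": _lin("Alphaceae", "Alphus", "Alphus secundus"),
    "Betus tertius": _lin("Alphaceae", "Betus", "Betus tertius"),
    "Gammus quartus": _lin("Gammaceae", "Gammus", "Gammus quartus"),
}


def _label(declared, sample_id="S1"):
    return FormulationLabel(sample_id, "P", "IN_HOUSE", "POWDER", tuple(declared))


class TestPercentages:
    @pytest.mark.parametrize(
        "a, n, p_abs, p_rel",
        [
            (17, 25, 68.0, 32.0),
            (12, 27, 44.44, 55.56),
            (4, 6, 66.67, 33.33),
            (1, 32, 3.13, 96.88),  # a half-cent tie: both terms round up
            (0, 7, 0.0, 100.0),
            (7, 7, 100.0, 0.0),
        ],
    )
    def test_examples(self, a, n, p_abs, p_rel):
        assert percentages(a, n) == (p_abs, p_rel)

    def test_validation(self):
        with pytest.raises(ValueError):
            percentages(1, 0)
        with pytest.raises(ValueError):
            percentages(5, 4)
        with pytest.raises(ValueError):
            percentages(-1, 4)

    def test_exhaustive_small_counts_match_oracle(self):
        for n in range(1, 121):
            for a in range(n + 1):
                p_abs, p_rel = percentages(a, n)
                o_abs, o_rel = percentages_oracle(a, n)
                assert f"{p_abs:.2f}" == o_abs and f"{p_rel:.2f}" == o_rel
                total = round(p_abs + p_rel, 2)
                if percentage_sum_is_100_01(a, n):
                    assert total == 100.01
                else:
                    assert total == 100.0


class TestProjectAndCategorize:
    def test_projection_to_family(self):
        label = _label(["Alphus primus", "Betus tertius", "Gammus quartus"])
        projected, unresolvable = project_label(label, "family", LINEAGES)
        assert projected == {"Alphaceae", "Gammaceae"}
        assert unresolvable == set()

    def test_unresolvable_name_counts_as_not_identified(self, caplog):
        label = _label(["Alphus primus", "Nullus ignotus"])
        cats = categorize(label, {"Alphus"}, "genus", LINEAGES)
        assert cats.identified == {"Alphus"}
        assert cats.not_identified == {"Nullus ignotus"}
        assert cats.unresolvable == {"Nullus ignotus"}

    def test_sets_disjoint_and_partition(self):
        label = _label(["Alphus primus", "Alphus secundus", "Gammus quartus"])
        detected = {"Alphus primus", "Betus tertius"}
        cats = categorize(label, detected, "species", LINEAGES)
        assert cats.identified == {"Alphus primus"}
        assert cats.not_identified == {"Alphus secundus", "Gammus quartus"}
        assert cats.other_detected == {"Betus tertius"}
        assert not cats.identified & cats.not_identified
        assert not cats.identified & cats.other_detected
        assert not cats.not_identified & cats.other_detected

    @given(
        st.sets(st.sampled_from(sorted(LINEAGES)), min_size=1),
        st.sets(st.sampled_from(sorted(LINEAGES) + ["Moldus niger"])),
        st.sampled_from(["species", "genus", "family"]),
    )
    def test_property_partition(self, declared, detected_species, rank):
        label = _label(sorted(declared))
        detected = {
            LINEAGES[s].at(rank) if s in LINEAGES else s for s in detected_species
        }
        cats = categorize(label, detected, rank, LINEAGES)
        projected, unresolvable = project_label(label, rank, LINEAGES)
        assert cats.identified | (cats.not_identified - unresolvable) == projected
        assert cats.identified <= detected
        assert not cats.other_detected & projected

    def test_bad_rank_raises(self):
        with pytest.raises(ValueError):
            project_label(_label(["Alphus primus"]), "order", LINEAGES)


def _motu_matrix():
    """S1 has Alphus primus (20 reads) + Betus tertius (7); S2 nothing."""
    from herbmark.classify import CONF_RANKS, Classification

    def cls(mid, lin, accepted="species"):
        return Classification(
            query_id=mid,
            labels=dict(zip(CONF_RANKS, lin.labels[:6])),
            confidences={r: 1.0 for r in CONF_RANKS},
            species_label=lin.species,
            accepted_rank=accepted,
        )

    m1 = MOTU("M0001", "A", [PooledUnique("A", 20, {"S1": 20})])
    m2 = MOTU("M0002", "C", [PooledUnique("C", 7, {"S1": 7})])
    classifications = {
        "M0001": cls("M0001", LINEAGES["Alphus primus"]),
        "M0002": cls("M0002", LINEAGES["Betus tertius"]),
    }
    return tally_assignments([m1, m2], classifications, ["S1", "S2"])


class TestVerifySample:
    def test_records_per_rank(self):
        matrix = _motu_matrix()
        label = _label(["Alphus primus", "Gammus quartus"])
        records = verify_sample(label, matrix, "ITS2", LINEAGES)
        by_rank = {r.rank: r for r in records}
        assert set(by_rank) == {"species", "genus", "family"}
        sp = by_rank["species"]
        assert sp.n_listed == 2 and sp.n_identified == 1
        assert sp.identified_taxa == frozenset({"Alphus primus"})
        assert sp.other_detected_taxa == frozenset({"Betus tertius"})
        assert (sp.pct_identified_absolute, sp.pct_not_identified_relative) == (50.0, 50.0)
        fam = by_rank["family"]
        assert fam.identified_taxa == frozenset({"Alphaceae"})
        assert fam.other_detected_taxa == frozenset()  # Betus is also Alphaceae

    def test_no_motu_sample_yields_no_records(self):
        matrix = _motu_matrix()
        label = _label(["Alphus primus"], sample_id="S2")
        assert verify_sample(label, matrix, "ITS2", LINEAGES) == []

    def test_min_reads_threshold_applies(self):
        matrix = _motu_matrix()
        label = _label(["Alphus primus", "Betus tertius"])
        records = verify_sample(label, matrix, "ITS2", LINEAGES, min_reads=10)
        sp = {r.rank: r for r in records}["species"]
        # Betus tertius has only 7 reads: below min_reads -> not identified
        assert sp.identified_taxa == frozenset({"Alphus primus"})
        assert sp.not_identified_taxa == frozenset({"Betus tertius"})


def _rec(sample_id, rank, identified, not_identified, locus="ITS2"):
    n = len(identified) + len(not_identified)
    p_abs, p_rel = percentages(len(identified), n)
    return VerificationRecord(
        sample_id=sample_id, locus=locus, rank=rank, n_listed=n,
        identified_taxa=frozenset(identified),
        not_identified_taxa=frozenset(not_identified),
        other_detected_taxa=frozenset(),
        pct_identified_absolute=p_abs, pct_not_identified_relative=p_rel,
    )


class TestSummarize:
    def test_percentages_from_summed_counts(self):
        labels = {
            "S1": _label(["Alphus primus"], "S1"),
            "S2": FormulationLabel("S2", "P", "REGISTERED", "CAPSULE",
                                   ("Gammus quartus",)),
        }
        records = [
            _rec("S1", "family", ["A", "B"], ["C"]),       # 2/3
            _rec("S2", "family", ["D"], ["E", "F", "G"]),  # 1/4
        ]
        out = {s.group: s for s in summarize(records, labels, "source_type")}
        assert out["IN_HOUSE"].n_listed == 3
        assert out["IN_HOUSE"].pct_identified_absolute == 66.67
        assert out["REGISTERED"].pct_identified_absolute == 25.0
        total = summarize(records, labels, "locus")[0]
        # 3/7 from summed counts, not the mean of 66.67 and 25.00
        assert total.n_identified == 3 and total.n_listed == 7
        assert total.pct_identified_absolute == 42.86

    def test_mixed_ranks_raise(self):
        labels = {"S1": _label(["Alphus primus"], "S1")}
        records = [_rec("S1", "family", ["A"], []), _rec("S1", "genus", ["A"], [])]
        with pytest.raises(ValueError, match="single rank"):
            summarize(records, labels, "locus")


class TestAuthenticity:
    def test_requires_full_identification_at_family_and_genus(self):
        full = [
            _rec("S1", "species", ["a"], ["b"]),
            _rec("S1", "genus", ["A", "B"], []),
            _rec("S1", "family", ["F"], []),
        ]
        assert authenticity_flag(full) is True
        partial = [
            _rec("S1", "genus", ["A"], ["B"]),
            _rec("S1", "family", ["F"], []),
        ]
        assert authenticity_flag(partial) is False

    def test_missing_rank_raises(self):
        with pytest.raises(ValueError, match="genus"):
            authenticity_flag([_rec("S1", "family", ["F"], [])])


class TestReportFromCounts:
    def test_groups_and_percentages(self):
        counts = pd.DataFrame(
            {
                "sample_id": ["S1", "S1", "S2", "S2"],
                "dosage_form": ["POWDER", "POWDER", "CAPSULE", "CAPSULE"],
                "source_type": ["IN_HOUSE", "IN_HOUSE", "REGISTERED", "REGISTERED"],
                "locus": ["ITS2", "RBCL", "ITS2", "RBCL"],
                "n_listed": [10, 10, 5, 5],
                "n_identified": [7, 8, 2, 5],
            }
        )
        report = report_from_counts(counts)
        per = report["per_sample"]
        assert list(per["pct_identified_absolute"]) == [70.0, 80.0, 40.0, 100.0]
        totals = report["totals"].set_index("locus")
        assert totals.loc["ITS2", "n_identified"] == 9
        assert totals.loc["ITS2", "pct_identified_absolute"] == 60.0
        assert totals.loc["RBCL", "pct_identified_absolute"] == 86.67
        by_source = report["by_source"].set_index(["locus", "source_type"])
        assert by_source.loc[("ITS2", "IN_HOUSE"), "pct_identified_absolute"] == 70.0

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing columns"):
            report_from_counts(pd.DataFrame({"sample_id": []}))
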