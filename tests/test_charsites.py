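"""Character-site detector: profiles, classification, reports.

The brute-force oracle used here applies the relaxed definition literally,
residue by residue: a symplesiomorphy needs a residue held by >50% of the
ingroup and >50% of the outgroup that no sister-group taxon carries; a
synapomorphy needs a residue held by >50% of the ingroup that no sister or
outgroup taxon carries.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralogsites import (
    Alignment,
    CharSiteParams,
    SimilarityScheme,
    TaxonGrouping,
    evaluate_site,
    group_residue_profile,
    radicality,
    scan_charsites,
    summarize_calls,
)
from paralogsites.charsites import write_charsite_report

from conftest import EIGHT_TAXA, make_columns_alignment, random_alignment


def brute_force_classify(column, grouping, ingroup, threshold=0.5):
    """Literal per-residue enumeration of the relaxed definition."""
    taxa = list(grouping.assignments)
    fam, form = ingroup
    residue_of = dict(zip(taxa, column))
    in_res = [residue_of[t] for t, (f, fo) in grouping.assignments.items() if (f, fo) == ingroup]
    sis_res = [residue_of[t] for t, (f, fo) in grouping.assignments.items() if f == fam and fo != form]
    out_res = [residue_of[t] for t, (f, _) in grouping.assignments.items() if f != fam]
    for r in sorted(set(in_res)):
        in_share = in_res.count(r) / len(in_res)
        out_share = out_res.count(r) / len(out_res)
        if in_share > threshold and r not in sis_res:
            if out_share > threshold:
                return "symplesiomorphy"
            if r not in out_res:
                return "synapomorphy"
    return "none"


class TestGroupProfile:
    def test_dominant_residue_and_percent(self):
        # 65 G and 35 assorted others: dominant G(65)
        col = "G" * 65 + "A" * 20 + "S" * 15
        aln = Alignment(tuple(f"t{i}" for i in range(100)), tuple(col))
        prof = group_residue_profile(aln, 1, aln.taxon_ids)
        assert prof.dominant_class == ("G",)
        assert prof.dominant_percent == 65
        assert prof.display() == "G(65)"

    def test_similar_residues_pool_when_both_present(self):
        col = "R" * 45 + "K" * 35 + "G" * 20
        aln = Alignment(tuple(f"t{i}" for i in range(100)), tuple(col))
        prof = group_residue_profile(aln, 1, aln.taxon_ids)
        assert set(prof.dominant_class) == {"R", "K"}
        assert prof.dominant_percent == 80
        assert prof.display() == "R/K(80)"

    def test_lone_class_member_stays_singleton(self):
        col = "R" * 60 + "G" * 40
        aln = Alignment(tuple(f"t{i}" for i in range(100)), tuple(col))
        prof = group_residue_profile(aln, 1, aln.taxon_ids)
        assert prof.dominant_class == ("R",)

    def test_all_gaps_ineligible(self):
        aln = Alignment(("a", "b"), ("-", "-"))
        prof = group_residue_profile(aln, 1, ("a", "b"))
        assert not prof.eligible and prof.dominant_class is None
        assert prof.display() == "."

    def test_x_excluded_from_counts(self):
        aln = Alignment(("a", "b", "c"), ("A", "A", "X"))
        prof = group_residue_profile(aln, 1, ("a", "b", "c"))
        assert prof.n_nongap == 2 and prof.dominant_share == 1.0

    def test_empty_taxa_rejected(self):
        aln = Alignment(("a", "b"), ("A", "A"))
        with pytest.raises(ValueError, match="empty"):
            group_residue_profile(aln, 1, ())

    def test_below_threshold_displays_not_conserved(self):
        col = "E" * 44 + "K" * 22 + "A" * 34
        aln = Alignment(tuple(f"t{i}" for i in range(100)), tuple(col))
        prof = group_residue_profile(aln, 1, aln.taxon_ids)
        assert prof.display() == "not conserved"


class TestRadicality:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("G",), ("P",), "radical"),
            (("D",), ("E",), "conservative"),
            (("L",), ("M",), "conservative"),
            (("R", "K"), ("G",), "radical"),
            (("S",), ("T",), "conservative"),
        ],
    )
    def test_examples(self, a, b, expected):
        assert radicality(a, b) == expected

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            radicality(("B",), ("A",))


class TestEvaluateSite:
    def test_symplesiomorphy_requires_outgroup_share_and_sister_absence(
        self, eight_taxon_grouping
    ):
        # rare-A taxa and both B groups share P; common A has G
        aln = make_columns_alignment(["GGPPPPPP"])
        call = evaluate_site(aln, 1, eight_taxon_grouping, ingroup=("A", "rare"))
        assert call.classification == "symplesiomorphy"
        assert call.defining_class == ("P",)
        assert not call.weak

    def test_uniform_column_is_no_call(self, eight_taxon_grouping):
        aln = make_columns_alignment(["AAAAAAAA"])
        for fam, form in [("A", "rare"), ("A", "common"), ("B", "rare")]:
            call = evaluate_site(aln, 1, eight_taxon_grouping, ingroup=(fam, form))
            assert call.classification == "none"

    def test_single_sister_carrier_vetoes(self, eight_taxon_grouping):
        # one common-A taxon carrying P blocks the rare-A symplesiomorphy
        aln = make_columns_alignment(["GPPPPPPP"])
        call = evaluate_site(aln, 1, eight_taxon_grouping, ingroup=("A", "rare"))
        assert call.classification == "none"

    def test_synapomorphy_confined_to_ingroup(self, eight_taxon_grouping):
        aln = make_columns_alignment(["GGWWPPPP"])
        call = evaluate_site(aln, 1, eight_taxon_grouping, ingroup=("A", "rare"))
        assert call.classification == "synapomorphy"
        assert call.defining_class == ("W",)

    def test_weak_call_when_outgroup_share_is_plurality_only(self):
        # outgroup P share exactly 50%: not >50%, but P is its plurality
        grouping = TaxonGrouping({t: g for t, g in EIGHT_TAXA})
        aln = make_columns_alignment(["GGPPPPGA"])
        call = evaluate_site(aln, 1, grouping, ingroup=("A", "rare"))
        assert call.classification == "symplesiomorphy" and call.weak
        report = summarize_calls([call])
        assert report.symplesiomorphy_counts == {}
        assert report.weak_counts == {("A", "rare"): 1}

    def test_low_coverage_group_blocks_call(self, eight_taxon_grouping):
        # sister group (common A) mostly gapped: column ineligible
        aln = make_columns_alignment(["--PPPPPP"])
        call = evaluate_site(aln, 1, eight_taxon_grouping, ingroup=("A", "rare"))
        assert call.classification == "none" and call.reason == "coverage"

    def test_class_level_absence_is_stricter(self, eight_taxon_grouping):
        # sister carries E while ingroup+outgroup share D: D/E are one class
        aln = make_columns_alignment(["EEDDDDDD"])
        residue_call = evaluate_site(
            aln, 1, eight_taxon_grouping, ingroup=("A", "rare")
        )
        assert residue_call.classification == "symplesiomorphy"
        class_call = evaluate_site(
            aln,
            1,
            eight_taxon_grouping,
            params=CharSiteParams(absence_scope="class"),
            ingroup=("A", "rare"),
        )
        assert class_call.classification == "none"

    def test_per_form_majority_pooling_requires_both_forms(self, eight_taxon_grouping):
        # P clears 50% pooled (3 of 4) but not within common B (1 of 2)
        aln = make_columns_alignment(["GGPPPAPP"])
        pooled = evaluate_site(aln, 1, eight_taxon_grouping, ingroup=("A", "rare"))
        assert pooled.classification == "symplesiomorphy" and not pooled.weak
        per_form = evaluate_site(
            aln,
            1,
            eight_taxon_grouping,
            params=CharSiteParams(outgroup_pooling="per-form-majority"),
            ingroup=("A", "rare"),
        )
        assert not per_form.counts_for_headline


def test_evaluate_matches_brute_force_on_all_two_letter_columns(
    eight_taxon_grouping,
):
    """Exhaustive oracle: all 2^8 A/G columns on the 8-taxon toy, all four
    ingroups; weak calls count as none, matching the literal definition."""
    ingroups = [("A", "common"), ("A", "rare"), ("B", "common"), ("B", "rare")]
    for bits in itertools.product("AG", repeat=8):
        column = "".join(bits)
        aln = make_columns_alignment([column])
        for ingroup in ingroups:
            expected = brute_force_classify(column, eight_taxon_grouping, ingroup)
            call = evaluate_site(aln, 1, eight_taxon_grouping, ingroup=ingroup)
            got = call.classification if call.counts_for_headline else "none"
            assert got == expected, (column, ingroup)


COLUMN = st.text(alphabet="AGPE-", min_size=8, max_size=8)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(columns=st.lists(COLUMN, min_size=1, max_size=4), data=st.data())
def test_taxon_permutation_never_changes_calls(
    eight_taxon_grouping, columns, data
):
    aln = make_columns_alignment(columns)
    perm = data.draw(st.permutations(range(8)))
    shuffled = Alignment(
        tuple(aln.taxon_ids[i] for i in perm), tuple(aln.rows[i] for i in perm)
    )
    for col in range(1, len(columns) + 1):
        a = evaluate_site(aln, col, eight_taxon_grouping, ingroup=("A", "rare"))
        b = evaluate_site(shuffled, col, eight_taxon_grouping, ingroup=("A", "rare"))
        assert (a.classification, a.defining_class, a.weak) == (
            b.classification,
            b.defining_class,
            b.weak,
        )


@settings(max_examples=40, derandomize=True, deadline=None)
@given(columns=st.lists(COLUMN, min_size=1, max_size=6))
def test_raising_threshold_only_shrinks_headline_calls(
    eight_taxon_grouping, columns
):
    aln = make_columns_alignment(columns)

    def headline(threshold):
        params = CharSiteParams(share_threshold=threshold)
        calls = scan_charsites(aln, eight_taxon_grouping, params=params)
        return {(c.column, c.ingroup, c.classification) for c in calls if c.counts_for_headline}

    low, mid, high = headline(0.5), headline(0.65), headline(0.8)
    assert high <= mid <= low


def test_family_label_swap_mirrors_calls(eight_taxon_grouping):
    """Swapping family labels swaps ingroup/outgroup roles symmetrically."""
    rng = np.random.default_rng(3)
    aln = random_alignment(rng, 8, 12)
    aln = Alignment(tuple(t for t, _ in EIGHT_TAXA), aln.rows)
    swapped = TaxonGrouping(
        {t: ("B" if f == "A" else "A", fo) for t, (f, fo) in eight_taxon_grouping.assignments.items()}
    )
    for col in range(1, 13):
        a = evaluate_site(aln, col, eight_taxon_grouping, ingroup=("A", "rare"))
        b = evaluate_site(aln, col, swapped, ingroup=("B", "rare"))
        assert a.classification == b.classification
        assert a.defining_class == b.defining_class


class TestScanAndSummarize:
    def test_uniform_alignment_yields_no_calls(self, eight_taxon_grouping):
        aln = make_columns_alignment(["AAAAAAAA", "GGGGGGGG"])
        assert scan_charsites(aln, eight_taxon_grouping) == []

    def test_calls_sorted_by_column(self, eight_taxon_grouping):
        aln = make_columns_alignment(["AAAAAAAA", "GGPPPPPP", "GGWWPPPP"])
        calls = scan_charsites(aln, eight_taxon_grouping)
        assert [c.column for c in calls] == sorted(c.column for c in calls)

    def test_mean_conservation_rounds_half_up(self, eight_taxon_grouping):
        # single symplesiomorphy call at 100%: mean is 100
        aln = make_columns_alignment(["GGPPPPPP"])
        calls = scan_charsites(aln, eight_taxon_grouping, ingroups=[("A", "rare")])
        report = summarize_calls(calls)
        assert report.mean_conservation["A"] == 100.0

    def test_empty_calls_give_empty_report(self):
        report = summarize_calls([])
        assert report.symplesiomorphy_counts == {}
        assert report.mean_conservation == {}

    def test_report_tsv_layout(self, tmp_path, eight_taxon_grouping):
        aln = make_columns_alignment(["GGPPPPPP"])
        calls = scan_charsites(aln, eight_taxon_grouping)
        out = tmp_path / "report.tsv"
        write_charsite_report(calls, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("site\tingroup\tclassification")
        assert any("symplesiomorphy" in line for line in lines[1:])
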