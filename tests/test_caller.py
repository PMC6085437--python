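"""Neighborhood complex calling, Hdr2 accounting, metagenome relaxations."""

import pytest

from bfscan.caller import (
    BIFURCATING,
    NON_BIFURCATING,
    build_presence_matrix,
    call_genome_complexes,
    call_metagenome_complexes,
    calls_to_dataframe,
    resolve_hdr2,
)

from conftest import toy_genome, toy_hits


def run(layout, rules, mode="genome", policy="shared"):
    genome = toy_genome(layout)
    hits = toy_hits(layout, rules)
    if mode == "metagenome":
        return call_metagenome_complexes(genome, hits, rules)
    calls = call_genome_complexes(genome, hits, rules, mode="genome")
    return resolve_hdr2(genome, calls, hits, rules, sharing_policy=policy)


def flat(calls):
    return sorted((c.complex_name, c.bf_flag, c.catalytic_gene) for c in calls)


def test_contiguous_hydABC_is_bifurcating(rules):
    layout = {"chr": [None] * 4 + ["HydA", "HydB", "HydC"] + [None] * 2}
    assert flat(run(layout, rules)) == [("Hyd", BIFURCATING, "chr_4")]


def test_lone_hydA_is_non_bifurcating(rules):
    layout = {"chr": [None, "HydA", None]}
    assert flat(run(layout, rules)) == [("Hyd", NON_BIFURCATING, "chr_1")]


def test_companions_beyond_window_violate_the_clause(rules):
    layout = {"chr": ["HydA", None, None, None, None, None, None, "HydB", "HydC"]}
    calls = run(layout, rules)
    assert flat(calls) == [("Hyd", NON_BIFURCATING, "chr_0")]
    assert set(calls[0].missing) == {"HydB", "HydC"}


def test_one_orf_inside_window_boundary_is_accepted(rules):
    layout = {"chr": ["HydA", None, None, None, None, "HydB", None, None, None, None, "HydC"]}
    # HydB at +5 (inside), HydC at +10 (outside)
    calls = run(layout, rules)
    assert flat(calls) == [("Hyd", NON_BIFURCATING, "chr_0")]
    assert calls[0].missing == ("HydC",)


def test_inserting_unrelated_gene_changes_nothing_until_window_breaks(rules):
    base = ["HydA", "HydB", "HydC"]
    for n_insert in range(0, 5):
        layout = {"chr": ["HydA"] + [None] * n_insert + ["HydB", "HydC"]}
        calls = run(layout, rules)
        # HydC sits at ordinal n_insert+2; window ±5 breaks at n_insert=4
        expected = BIFURCATING if n_insert + 2 <= 5 else NON_BIFURCATING
        assert calls[0].bf_flag == expected, n_insert
    assert base  # layout template used above


def test_mvh_with_remote_hdr_on_other_replicon(rules):
    layout = {
        "chr": [None, "MvhA", "MvhG", "MvhD", None],
        "chr2": ["HdrA", "HdrB", "HdrC"],
    }
    calls = run(layout, rules)
    assert ("Mvh", BIFURCATING, "chr_1") in flat(calls)
    mvh = next(c for c in calls if c.complex_name == "Mvh")
    assert mvh.satisfied["HdrA"] == "anywhere in genome"
    # the single HdrABC set is reserved for Mvh: no Hdr2
    assert all(c.complex_name != "Hdr2" for c in calls)


def test_catalytic_gene_joins_at_most_one_call(rules):
    # one gene eligible for both Hyd and Hyt: context decides
    layout = {
        "chr": ["FdhA", "HytE2", "HydA+HytA", "HytE1", "HytD", "HytB", "HytC"],
    }
    calls = run(layout, rules)
    assert flat(calls) == [("Hyt", BIFURCATING, "chr_2")]


def test_fdh_companion_of_called_hyt_is_not_double_reported(rules):
    layout = {"chr": ["FdhA", "HytE2", "HytA", "HytE1", "HytD", "HytB", "HytC"]}
    calls = run(layout, rules)
    assert flat(calls) == [("Hyt", BIFURCATING, "chr_2")]


def test_etfab_shared_between_bcd_and_ldh(rules):
    layout = {"chr": ["Bcd", "EtfA", "EtfB", "Ldh"]}
    calls = run(layout, rules)
    assert flat(calls) == [
        ("Bcd", BIFURCATING, "chr_0"),
        ("Ldh", BIFURCATING, "chr_3"),
    ]


# -- Hdr2 accounting --------------------------------------------------------

MVH_OPERON = ["MvhA", "MvhG", "MvhD"]


def test_hdr2_called_from_leftover_set(rules):
    layout = {
        "chr": MVH_OPERON,
        "chr2": ["HdrA", "HdrB", "HdrC", None, "HdrA", "HdrB", "HdrC"],
    }
    calls = run(layout, rules, policy="shared")
    assert ("Hdr2", BIFURCATING, "chr2_4") in flat(calls) or (
        "Hdr2",
        BIFURCATING,
        "chr2_0",
    ) in flat(calls)
    assert sum(c.complex_name == "Hdr2" for c in calls) == 1


def test_single_set_leaves_no_hdr2(rules):
    layout = {"chr": MVH_OPERON, "chr2": ["HdrA", "HdrB", "HdrC"]}
    calls = run(layout, rules, policy="shared")
    assert all(c.complex_name != "Hdr2" for c in calls)


def test_sharing_policy_arithmetic_with_two_partner_complexes(rules):
    layout = {
        "chr": MVH_OPERON + [None, "FdhB", "FdhA"],
        "chr2": ["HdrA", "HdrB", "HdrC", None, "HdrA", "HdrB", "HdrC"],
    }
    shared = run(layout, rules, policy="shared")
    per_complex = run(layout, rules, policy="per_complex")
    assert sum(c.complex_name == "Hdr2" for c in shared) == 1
    assert sum(c.complex_name == "Hdr2" for c in per_complex) == 0
    # both policies still call Mvh and Fdh
    for calls in (shared, per_complex):
        assert {("Fdh", BIFURCATING, "chr_5"), ("Mvh", BIFURCATING, "chr_0")} <= set(
            flat(calls)
        )


def test_hdr2_requires_paired_bc_genes(rules):
    # leftover set exists but HdrB/HdrC are 4 ORFs apart: no Hdr2
    layout = {
        "chr2": ["HdrA", "HdrB", None, None, None, "HdrC"],
    }
    calls = run(layout, rules, policy="shared")
    assert all(c.complex_name != "Hdr2" for c in calls)


# -- metagenome mode --------------------------------------------------------


def test_metagenome_mvh_needs_only_mvhAGD(rules):
    layout = {"c1": ["MvhA", "MvhG", "MvhD"]}
    calls = run(layout, rules, mode="metagenome")
    assert flat(calls) == [("Mvh", BIFURCATING, "c1_0")]
    assert "metagenome-mode" in calls[0].notes


def test_metagenome_fdh_needs_only_fdhAB(rules):
    layout = {"c1": ["FdhA", "FdhB"]}
    calls = run(layout, rules, mode="metagenome")
    assert flat(calls) == [("Fdh", BIFURCATING, "c1_0")]


def test_metagenome_never_calls_hdr2(rules):
    layout = {"c1": ["HdrA", "HdrB", "HdrC"]}
    assert run(layout, rules, mode="metagenome") == []


def test_metagenome_all_windows_restricted_to_contig(rules):
    # full-rule complex in metagenome mode: Hdr partners on another
    # contig do not satisfy Mvh's ALL windows in genome-mode rules,
    # but metagenome Mvh does not require them at all
    layout = {"c1": ["MvhA", "MvhG", "MvhD"], "c2": ["HdrA", "HdrB", "HdrC"]}
    calls = run(layout, rules, mode="metagenome")
    assert flat(calls) == [("Mvh", BIFURCATING, "c1_0")]


def test_split_operon_is_non_bifurcating_on_both_sides(rules):
    layout = {"c1": ["HydA", "HydB"], "c2": ["HydC"]}
    calls = run(layout, rules, mode="metagenome")
    assert flat(calls) == [("Hyd", NON_BIFURCATING, "c1_0")]


# -- output determinism -----------------------------------------------------


def test_identical_inputs_give_byte_identical_call_tables(rules):
    layout = {
        "chr": ["HydA", "HydB", "HydC", None, "NfnS", "NfnL"],
        "chr2": ["HdrA", "HdrB", "HdrC"],
    }
    a = calls_to_dataframe(run(layout, rules)).to_csv(index=False)
    b = calls_to_dataframe(run(layout, rules)).to_csv(index=False)
    assert a == b


def test_presence_matrix_counts_bifurcating_only(rules):
    layout = {"chr": ["HydA", "HydB", "HydC", None, None, None, None, None, "NfnL"]}
    calls = run(layout, rules)
    mat = build_presence_matrix(calls, ["toy"], rules.complex_names())
    assert mat.loc["toy", "Hyd"] == 1
    assert mat.loc["toy", "Nfn"] == 0  # NfnL without NfnS is non-Bf
    assert mat.to_numpy().sum() == 1
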