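"""Local alignment, E-values, threshold logic, and domtblout parsing."""

import numpy as np
import pytest

from bfscan.core_io import BaitSet, BfscanError, GeneRecord, Genome
from bfscan.homology import (
    EValueParams,
    HitRecord,
    HitTable,
    UNIT_SCORING,
    apply_thresholds,
    local_align_score,
    parse_hmmer_domtbl,
    search_homologs,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def sw_oracle(a: str, b: str) -> int:
    """Exhaustive Smith-Waterman DP under unit scoring (+1/-1, gap -1)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 1 if a[i - 1] == b[j - 1] else -1
            H[i, j] = max(0, H[i - 1, j - 1] + sub, H[i - 1, j] - 1, H[i, j - 1] - 1)
    return int(H.max())


def test_self_alignment_unit_scoring():
    score, ident = local_align_score("MKLV", "MKLV", UNIT_SCORING)
    assert score == 4 and ident == 1.0


def test_no_positive_cell_gives_empty_alignment():
    score, ident = local_align_score("MKLV", "WWWW", UNIT_SCORING)
    assert score == 0.0 and ident == 0.0


def test_local_score_matches_dp_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(60):
        a = "".join(rng.choice(list(AA), size=12))
        b = "".join(rng.choice(list(AA), size=12))
        score, _ = local_align_score(a, b, UNIT_SCORING)
        assert score == sw_oracle(a, b), (a, b)


@pytest.mark.parametrize("bad", ["", "MKB1"])
def test_illegal_sequences_are_rejected(bad):
    with pytest.raises(BfscanError):
        local_align_score(bad if bad else "", "MKLV", UNIT_SCORING)


def test_evalue_strictly_decreasing_in_score():
    p = EValueParams()
    evals = [p.evalue(s, 300, 10000) for s in range(0, 500, 25)]
    assert all(a > b for a, b in zip(evals, evals[1:]))


def _toy_proteome(proteins: dict[str, str]) -> Genome:
    genes = [
        GeneRecord(pid, "chr", i, 1 + i * 1000, i * 1000 + 900, "+", seq)
        for i, (pid, seq) in enumerate(proteins.items())
    ]
    return Genome("T", {"chr": genes})


def test_exact_bait_copy_is_hit_below_threshold(rules, baits):
    hyda = baits.sequences("HydA")[0][1]
    proteome = _toy_proteome({"p1": hyda, "p2": "MKLV" * 60})
    hits = search_homologs(proteome, baits, rules)
    assert "HydA" in hits.roles_for("T", "p1")
    assert hits.evalue("T", "p1", "HydA") < 2e-20
    assert hits.roles_for("T", "p2") == []


def test_partial_bait_set_is_fatal(rules, baits):
    proteome = _toy_proteome({"p1": "MKLV" * 20})
    with pytest.raises(BfscanError, match="without baits"):
        search_homologs(proteome, BaitSet({"HydA": baits.baits["HydA"]}), rules)


def test_shuffled_unrelated_proteins_yield_no_hits(rules, baits):
    rng = np.random.default_rng(3)
    proteins = {
        f"s{i}": "".join(rng.permutation(list("ACDEFGHIKLMNPQRSTVWY" * 12)))
        for i in range(5)
    }
    hits = search_homologs(_toy_proteome(proteins), baits, rules)
    assert len(hits) == 0


def test_threshold_comparison_is_strict_on_evalue_scale(rules):
    rec = HitRecord("p", "G", "HydA", evalue=1e-19)
    assert apply_thresholds([rec], rules) == []  # 1e-19 > 2e-20
    rec2 = HitRecord("p", "G", "HydA", evalue=2e-20)
    assert apply_thresholds([rec2], rules) == [rec2]


def test_threshold_monotonicity(rules, baits):
    """Raising a role threshold never removes hits; lowering never adds."""
    hyda = baits.sequences("HydA")[0][1]
    proteome = _toy_proteome({"p1": hyda})
    hits = search_homologs(proteome, baits, rules)
    base = {(r.protein_id, r.subunit_role) for r in hits}
    import copy

    looser = copy.deepcopy(rules)
    looser.thresholds = {k: v * 100 for k, v in rules.thresholds.items()}
    tighter = copy.deepcopy(rules)
    tighter.thresholds = {k: v / 1e30 for k, v in rules.thresholds.items()}
    up = {(r.protein_id, r.subunit_role)
          for r in search_homologs(proteome, baits, looser)}
    down = {(r.protein_id, r.subunit_role)
            for r in search_homologs(proteome, baits, tighter)}
    assert base <= up
    assert down <= base


DOMTBL_COLS = (
    "{target} - 500 {query} - 400 {evalue} {score} 0.1 1 1 "
    "1e-10 1e-9 50.0 0.1 1 400 1 500 1 500 1 500 0.9 -"
)


def _write_domtbl(path, rows):
    lines = ["# comment line", "#"]
    for target, query, evalue, score in rows:
        lines.append(
            DOMTBL_COLS.format(target=target, query=query, evalue=evalue, score=score)
        )
    path.write_text("\n".join(lines) + "\n")


def test_domtbl_parse_basic(tmp_path):
    p = tmp_path / "hits.domtbl"
    _write_domtbl(p, [("g001", "HydA_bait", "2e-21", 120.0)])
    hits = parse_hmmer_domtbl(p, {"HydA_bait": "HydA"}, genome_id="G")
    assert len(hits) == 1
    rec = hits.records[0]
    assert (rec.protein_id, rec.subunit_role, rec.evalue) == ("g001", "HydA", 2e-21)


def test_domtbl_comments_only_is_empty(tmp_path):
    p = tmp_path / "empty.domtbl"
    p.write_text("# only\n# comments\n")
    assert len(parse_hmmer_domtbl(p, {})) == 0


def test_domtbl_keeps_best_evalue_per_target_role(tmp_path):
    p = tmp_path / "dup.domtbl"
    _write_domtbl(p, [("g1", "Q", "1e-30", 90), ("g1", "Q", "1e-10", 40)])
    hits = parse_hmmer_domtbl(p, {"Q": "HydA"})
    assert len(hits) == 1 and hits.records[0].evalue == 1e-30


def test_domtbl_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.domtbl"
    p.write_text("g1 - 500 Q\n")
    with pytest.raises(BfscanError, match=":1"):
        parse_hmmer_domtbl(p, {"Q": "HydA"})


def test_domtbl_unknown_query_skipped_with_warning(tmp_path, caplog):
    p = tmp_path / "unk.domtbl"
    _write_domtbl(p, [("g1", "mystery", "1e-30", 90)])
    with caplog.at_level("WARNING"):
        hits = parse_hmmer_domtbl(p, {"Q": "HydA"})
    assert len(hits) == 0
    assert "mystery" in caplog.text


def test_backends_agree_on_verbatim_planted_copies(tmp_path, rules, baits):
    """Internal alignment backend and a real phmmer run assign the same
    (protein, role) candidates to a proteome of verbatim bait copies."""
    import shutil
    import subprocess

    planted = ["HydA", "HydB", "NfnL", "NfnS", "Bcd", "EtfA", "EtfB"]
    proteins = {f"p_{r}": baits.sequences(r)[0][1] for r in planted}
    proteome = _toy_proteome(proteins)
    internal = search_homologs(proteome, baits, rules)
    internal_set = {(r.protein_id, r.subunit_role) for r in internal}

    assert shutil.which("phmmer"), "phmmer is part of the supported toolchain"
    roles = baits.roles()
    qf, tf = tmp_path / "baits.faa", tmp_path / "prot.faa"
    qf.write_text("".join(f">{r}\n{baits.sequences(r)[0][1]}\n" for r in roles))
    tf.write_text("".join(f">{k}\n{v}\n" for k, v in proteins.items()))
    out = tmp_path / "out.domtbl"
    subprocess.run(
        ["phmmer", "--domtblout", str(out), "-E", "1000", "--max", str(qf), str(tf)],
        check=True, capture_output=True,
    )
    parsed = parse_hmmer_domtbl(out, {r: r for r in roles}, genome_id="T", rules=rules)
    phmmer_set = {(r.protein_id, r.subunit_role) for r in parsed}
    assert internal_set == phmmer_set


def test_hit_table_rejects_duplicates_and_nonpositive_evalues():
    with pytest.raises(BfscanError):
        HitRecord("p", "G", "HydA", evalue=0.0)
    recs = [HitRecord("p", "G", "HydA", 1e-30), HitRecord("p", "G", "HydA", 1e-20)]
    with pytest.raises(BfscanError, match="duplicate"):
        HitTable(recs)
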