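"""p-distances, Mantel tests (with an external cross-check), clustering."""

import numpy as np
import pytest

from bfscan.core_io import BfscanError
from bfscan.evolution import (
    DistanceMatrix,
    global_identity,
    greedy_cluster,
    mantel_test,
    p_distance_matrix,
)
from bfscan.synth import generate_coevolution_alignments

AA = list("ACDEFGHIKLMNPQRSTVWY")


def naive_p_distance(a: str, b: str) -> float:
    diff = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-.":
            continue
        comp += 1
        diff += x != y
    return diff / comp


def test_p_distance_fixture_values():
    dm = p_distance_matrix({"a": "AAAA", "b": "AATT"})
    assert dm.values[0, 1] == pytest.approx(0.5)
    dm = p_distance_matrix({"a": "A-AA", "b": "AAAA"})
    assert dm.values[0, 1] == 0.0


def test_p_distance_matches_counting_oracle_and_is_order_invariant():
    rng = np.random.default_rng(11)
    seqs = {}
    for i in range(5):
        s = rng.choice(AA + ["-"], size=60, p=[0.045] * 20 + [0.1])
        seqs[f"s{i}"] = "".join(s)
    dm = p_distance_matrix(seqs)
    for i, a in enumerate(seqs):
        for j, b in enumerate(seqs):
            if i < j:
                assert dm.values[i, j] == pytest.approx(
                    naive_p_distance(seqs[a], seqs[b]), abs=1e-12
                )
    rev = p_distance_matrix(dict(reversed(list(seqs.items()))))
    assert np.allclose(rev.reordered(dm.labels).values, dm.values)


def test_no_comparable_columns_is_an_error():
    with pytest.raises(BfscanError, match="comparable"):
        p_distance_matrix({"a": "A--", "b": "-AA"})


def random_distance_matrix(rng, labels):
    n = len(labels)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(list(labels), m)


def test_mantel_exact_identity_case():
    rng = np.random.default_rng(1)
    A = random_distance_matrix(rng, "wxyz")
    res = mantel_test(A, A, method="exact")
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 24)


def test_mantel_constant_matrix_is_degenerate():
    A = random_distance_matrix(np.random.default_rng(2), "wxyz")
    B = DistanceMatrix(list("wxyz"), np.ones((4, 4)) - np.eye(4))
    with pytest.raises(BfscanError, match="variance"):
        mantel_test(A, B)


def test_mantel_label_mismatch_is_reported():
    rng = np.random.default_rng(3)
    A = random_distance_matrix(rng, ["a", "b", "c", "d"])
    B = random_distance_matrix(rng, ["a", "b", "c", "e"])
    with pytest.raises(BfscanError, match="e"):
        mantel_test(A, B)


def test_mantel_invariant_under_joint_relabeling():
    rng = np.random.default_rng(4)
    labels = [f"t{i}" for i in range(8)]
    A = random_distance_matrix(rng, labels)
    B = random_distance_matrix(rng, labels)
    res1 = mantel_test(A, B, n_perm=499, seed=9)
    perm = list(np.random.default_rng(0).permutation(labels))
    res2 = mantel_test(A.reordered(perm), B.reordered(perm), n_perm=499, seed=9)
    assert res1.r == pytest.approx(res2.r, abs=1e-12)
    assert res1.p == pytest.approx(res2.p, abs=0.02)


def test_mantel_r_agrees_with_skbio():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(5)
    labels = [f"t{i}" for i in range(10)]
    A = random_distance_matrix(rng, labels)
    B = random_distance_matrix(rng, labels)
    ours = mantel_test(A, B, n_perm=999, seed=0)
    theirs_r, theirs_p, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(A.values, labels),
        skbio_distance.DistanceMatrix(B.values, labels),
        method="pearson",
        permutations=999,
        alternative="greater",
    )
    assert ours.r == pytest.approx(float(theirs_r), abs=1e-12)
    assert ours.p == pytest.approx(float(theirs_p), abs=0.05)


def test_coevolution_limit_case_gives_equal_matrices_and_r_one():
    a1, a2 = generate_coevolution_alignments(6, 1.0, 240, seed=8)
    d1, d2 = p_distance_matrix(a1), p_distance_matrix(a2)
    assert np.allclose(d1.values, d2.values)
    assert mantel_test(d1, d2, method="exact").r == pytest.approx(1.0)


def test_coevolved_subunits_detected_but_independent_ones_not():
    hits = 0
    for i in range(20):
        a1, a2 = generate_coevolution_alignments(20, 0.8, 200, seed=100 + i)
        res = mantel_test(
            p_distance_matrix(a1), p_distance_matrix(a2), n_perm=499, seed=i
        )
        hits += res.p < 0.05
    assert hits >= 19  # strong power at high shared signal

    null_ps = []
    for i in range(40):
        a1, a2 = generate_coevolution_alignments(12, 0.0, 150, seed=900 + i)
        res = mantel_test(
            p_distance_matrix(a1), p_distance_matrix(a2), n_perm=199, seed=i
        )
        null_ps.append(res.p)
    assert 0.1 < np.mean(null_ps) < 0.9  # no systematic association


# -- greedy identity binning ------------------------------------------------


def test_identical_sequences_form_one_cluster():
    clusters = greedy_cluster({"b": "MKLVAG", "a": "MKLVAG", "c": "MKLVAG"})
    assert len(clusters) == 1
    assert clusters[0].representative_id == "a"  # lexical tie-break
    assert sorted(clusters[0].member_ids) == ["a", "b", "c"]


def test_unrelated_sequences_stay_singletons():
    rng = np.random.default_rng(21)
    seqs = {f"u{i}": "".join(rng.choice(AA, size=50)) for i in range(3)}
    for a in seqs.values():
        for b in seqs.values():
            if a is not b:
                assert global_identity(a, b) < 0.3
    clusters = greedy_cluster(seqs, identity_threshold=0.6)
    assert len(clusters) == 3


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([c for c in AA if c != out[i]]))
    return "".join(out)


def test_two_planted_families_recovered_exactly():
    rng = np.random.default_rng(33)
    fam1 = "".join(rng.choice(AA, size=80))
    fam2 = "".join(rng.choice(AA, size=80))
    seqs = {}
    for i in range(4):
        seqs[f"a{i}"] = mutate(rng, fam1, 0.1)
        seqs[f"b{i}"] = mutate(rng, fam2, 0.1)
    clusters = greedy_cluster(seqs, identity_threshold=0.6)
    assert len(clusters) == 2
    families = [sorted(c.member_ids) for c in clusters]
    assert sorted(families) == [[f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]]
    for cl in clusters:
        assert all(ident >= 0.6 for ident in cl.identities)


def test_cluster_count_nonincreasing_in_threshold_and_union_preserved():
    rng = np.random.default_rng(44)
    base = "".join(rng.choice(AA, size=60))
    seqs = {f"m{i}": mutate(rng, base, 0.05 * i) for i in range(8)}
    prev = None
    for thr in (0.9, 0.7, 0.5, 0.3):
        clusters = greedy_cluster(seqs, identity_threshold=thr)
        members = sorted(m for c in clusters for m in c.member_ids)
        assert members == sorted(seqs)
        if prev is not None:
            assert len(clusters) <= prev
        prev = len(clusters)


def test_empty_input_gives_empty_output():
    assert greedy_cluster({}) == []


from hypothesis import given, settings, strategies as st

_seq = st.text(alphabet="ACDG-", min_size=1, max_size=20)


@settings(derandomize=True, max_examples=100)
@given(st.lists(_seq, min_size=2, max_size=6, unique=True), st.data())
def test_p_distance_is_a_bounded_symmetric_premetric(seqs, data):
    L = min(len(s) for s in seqs)
    aligned = {f"s{i}": s[:L] for i, s in enumerate(seqs)}
    try:
        dm = p_distance_matrix(aligned)
    except BfscanError:
        return  # a pair without comparable columns is a legal rejection
    assert (dm.values >= 0).all() and (dm.values <= 1).all()
    assert (dm.values == dm.values.T).all()
    assert (np.diag(dm.values) == 0).all()
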