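"""Generator determinism, truth bookkeeping, and planted-clause checks."""

import numpy as np
import pytest

from bfscan.core_io import BfscanError
from bfscan.motifs import match_motif
from bfscan.synth import (
    Ablation,
    GenomeSpec,
    PlantedItem,
    default_genome_specs,
    generate_genome_set,
    generate_metagenome,
    make_default_baits,
)


def small_specs():
    return [
        GenomeSpec("S0", [PlantedItem("Hyd", "bifurcating")], n_filler=4),
        GenomeSpec(
            "S1",
            [PlantedItem("Hyd", "non_bifurcating", Ablation("drop_subunit", role="HydB"))],
            n_filler=4,
        ),
    ]


def test_same_seed_reproduces_identical_sequences(rules, motif_config, baits):
    kw = dict(baits=baits, rules=rules, motif_config=motif_config, seed=5)
    g1, t1 = generate_genome_set(small_specs(), **kw)
    g2, t2 = generate_genome_set(small_specs(), **kw)
    for a, b in zip(g1, g2):
        assert a.replicons == b.replicons
    assert t1.expected_calls == t2.expected_calls
    assert t1.expected_roles == t2.expected_roles


def test_different_seeds_differ(rules, motif_config, baits):
    kw = dict(baits=baits, rules=rules, motif_config=motif_config)
    g1, _ = generate_genome_set(small_specs(), seed=5, **kw)
    g2, _ = generate_genome_set(small_specs(), seed=6, **kw)
    assert g1[0].replicons != g2[0].replicons


def test_shipped_baits_regenerate_bytewise(baits):
    regenerated = make_default_baits()
    assert regenerated.baits == baits.baits


def test_spec_validation_rejects_inconsistent_items():
    with pytest.raises(BfscanError):
        PlantedItem("Hyd", "non_bifurcating")  # ablation required
    with pytest.raises(BfscanError):
        PlantedItem("Hyd", "bifurcating", Ablation("drop_subunit", role="HydB"))
    with pytest.raises(BfscanError):
        PlantedItem("Hyd", "decoy", Ablation("drop_subunit", role="MetV"))
    with pytest.raises(BfscanError):
        Ablation("teleport")


def test_planted_bifurcating_items_keep_motifs_under_mutation(
    rules, motif_config, baits
):
    specs = [GenomeSpec("M0", [PlantedItem("Hyd", "bifurcating")], n_filler=3)]
    genomes, truth = generate_genome_set(
        specs, baits=baits, rules=rules, motif_config=motif_config,
        mutation_rate=0.1, seed=2,
    )
    hyda_gene = next(
        e.catalytic_gene for e in truth.expected_calls if e.complex_name == "Hyd"
    )
    protein = genomes[0].gene(hyda_gene).protein
    for motif in motif_config.motifs_for("HydA"):
        assert match_motif(protein, motif).matched
    bait_seq = baits.sequences("HydA")[0][1]
    assert protein != bait_seq  # mutation did happen outside the motifs


def test_expected_roles_match_screened_hits(study_set):
    truth, screened = study_set["truth"], study_set["screened"]
    checked = 0
    for (genome_id, gene_id), roles in truth.expected_roles.items():
        got = tuple(screened[genome_id].roles_for(genome_id, gene_id))
        assert got == tuple(sorted(roles)), (genome_id, gene_id)
        checked += 1
    assert checked > 50


def test_every_ablation_surfaces_as_its_violated_clause(study_set):
    truth, calls = study_set["truth"], study_set["calls"]
    by_key = {(c.genome_id, c.complex_name, c.catalytic_gene): c for c in calls}
    for exp in truth.non_bifurcating():
        if not exp.violated_clause or exp.complex_name == "Hdr2":
            continue
        call = by_key[(exp.genome_id, exp.complex_name, exp.catalytic_gene)]
        # dropped/displaced companions are reported as the missing clause
        expected_missing = set(exp.violated_clause.split(";"))
        assert expected_missing <= set(call.missing), exp


def test_bifurcating_calls_reverify_against_raw_feature_table(study_set, rules):
    """Independent window checker over the emitted bifurcating calls."""
    genomes = {g.genome_id: g for g in study_set["genomes"]}
    for call in study_set["calls"]:
        if not call.is_bifurcating or call.complex_name == "Hdr2":
            continue
        genome = genomes[call.genome_id]
        rule = rules.complex(call.complex_name)
        ords = {
            g.gene_id: (g.replicon_id, g.ordinal) for g in genome.genes()
        }
        cat_rep, cat_ord = ords[call.catalytic_gene]
        for comp in rule.required_companions():
            member = call.members[comp.role]
            rep, o = ords[member]
            if comp.window.kind == "orf":
                assert rep == cat_rep and abs(o - cat_ord) <= comp.window.k, call
            elif comp.window.kind == "all":
                assert member in ords, call


def test_no_split_fragmentation_matches_genome_mode_truth(rules, motif_config, baits):
    specs = default_genome_specs(0)
    kw = dict(baits=baits, rules=rules, motif_config=motif_config, seed=4)
    _, genome_truth = generate_genome_set(specs, **kw)
    _, meta_truth = generate_metagenome(specs, fragmentation=np.inf, **kw)
    g_bf = {(g, c) for g, c, _ in genome_truth.bifurcating() if c != "Hdr2"}
    m_bf = {(g, c) for g, c, _ in meta_truth.bifurcating()}
    # Hdr2 is never assessed in metagenomes; the HdrC-dropped Mvh genome
    # is upgraded because contig-level rules only require MvhAGD
    assert g_bf <= m_bf
    assert m_bf - g_bf == {("G16_Mvh_dropHdrC", "Mvh")}


def test_split_operon_loses_its_bifurcating_label(rules, motif_config, baits):
    specs = [GenomeSpec("F0", [PlantedItem("Hyt", "bifurcating")], n_filler=2)]
    kw = dict(baits=baits, rules=rules, motif_config=motif_config, seed=1)
    # very aggressive fragmentation: the 7-gene operon cannot survive
    _, truth = generate_metagenome(specs, fragmentation=1.0, **kw)
    assert truth.bifurcating() == set()
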