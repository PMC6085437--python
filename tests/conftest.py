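"""Shared fixtures: configs, synthetic study sets, and toy-genome helpers.

The full planted study set (generation + search + motif screen + calls)
is expensive, so it is built once per session and shared by the unit and
acceptance tests.
"""

from __future__ import annotations

import pytest

from bfscan.caller import call_all
from bfscan.core_io import GeneRecord, Genome, read_default_baits, read_ruleset
from bfscan.homology import HitRecord, HitTable, screen_hits, search_homologs
from bfscan.motifs import read_motif_config
from bfscan.synth import default_genome_specs, generate_genome_set, generate_metagenome

GENOME_SEED = 7
METAGENOME_SEED = 11
MUTATED_SEED = 19


@pytest.fixture(scope="session")
def rules():
    return read_ruleset()


@pytest.fixture(scope="session")
def motif_config():
    return read_motif_config()


@pytest.fixture(scope="session")
def baits():
    return read_default_baits()


def run_search_and_call(genomes, baits, rules, motif_config, sharing_policy="shared"):
    """search -> motif screen -> call for a genome collection."""
    calls, screened_tables = [], {}
    for genome in genomes:
        hits = search_homologs(genome, baits, rules)
        proteins = {g.gene_id: g.protein for g in genome.genes()}
        screened = screen_hits(hits, proteins, motif_config)
        screened_tables[genome.genome_id] = screened
        calls.extend(call_all(genome, screened, rules, sharing_policy=sharing_policy))
    return calls, screened_tables


@pytest.fixture(scope="session")
def study_set(rules, motif_config, baits):
    """Default planted study set at mutation rate 0, fully processed."""
    specs = default_genome_specs(0)
    genomes, truth = generate_genome_set(
        specs, baits=baits, rules=rules, motif_config=motif_config,
        mutation_rate=0.0, seed=GENOME_SEED,
    )
    calls, screened = run_search_and_call(genomes, baits, rules, motif_config)
    return {"specs": specs, "genomes": genomes, "truth": truth,
            "calls": calls, "screened": screened}


@pytest.fixture(scope="session")
def mutated_study_set(rules, motif_config, baits):
    """Same study set at 5% per-residue substitution."""
    specs = default_genome_specs(0)
    genomes, truth = generate_genome_set(
        specs, baits=baits, rules=rules, motif_config=motif_config,
        mutation_rate=0.05, seed=MUTATED_SEED,
    )
    calls, screened = run_search_and_call(genomes, baits, rules, motif_config)
    return {"genomes": genomes, "truth": truth, "calls": calls}


@pytest.fixture(scope="session")
def metagenome_set(rules, motif_config, baits):
    """Fragmented contig version of the study set (metagenome rules)."""
    specs = default_genome_specs(0)
    genomes, truth = generate_metagenome(
        specs, fragmentation=10.0, baits=baits, rules=rules,
        motif_config=motif_config, mutation_rate=0.0, seed=METAGENOME_SEED,
    )
    calls, screened = run_search_and_call(genomes, baits, rules, motif_config)
    return {"genomes": genomes, "truth": truth, "calls": calls}


# ---------------------------------------------------------------------------
# toy genomes for direct caller tests
# ---------------------------------------------------------------------------

_FILLER_PROTEIN = "ACDEFGHIKLMNPQRSTVWY" * 10


def toy_genome(layout: dict[str, list[str | None]], genome_id: str = "toy") -> Genome:
    """Build a genome from {replicon: [role-or-None per ordinal]}.

    Gene ids are ``<replicon>_<ordinal>``; role labels are only used by
    :func:`toy_hits` to fabricate the matching hit table.
    """
    replicons = {}
    for rep, slots in layout.items():
        genes = []
        for i, _role in enumerate(slots):
            start = 1 + i * 1000
            genes.append(
                GeneRecord(
                    gene_id=f"{rep}_{i}",
                    replicon_id=rep,
                    ordinal=i,
                    start=start,
                    end=start + 599,
                    strand="+",
                    protein=_FILLER_PROTEIN,
                )
            )
        replicons[rep] = genes
    return Genome(genome_id, replicons)


def toy_hits(
    layout: dict[str, list[str | None]],
    rules,
    genome_id: str = "toy",
) -> HitTable:
    """Hit table asserting each labelled slot as its role (E = thr/100)."""
    records = []
    for rep, slots in layout.items():
        for i, role in enumerate(slots):
            if role is None:
                continue
            for r in role.split("+"):  # one gene may carry several roles
                records.append(
                    HitRecord(
                        protein_id=f"{rep}_{i}",
                        genome_id=genome_id,
                        subunit_role=r,
                        evalue=rules.threshold(r) / 100.0,
                    )
                )
    return HitTable(records)
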