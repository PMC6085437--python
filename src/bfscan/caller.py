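"""Gene-neighborhood complex calling.

A complex is called around each catalytic-subunit gene that survived the
homology thresholds and motif screens.  Companion subunits must sit
within their configured ORF windows on the same replicon (``±k``), or
anywhere in the genome (``ALL`` -- used for the HdrABC partners of Mvh,
Fdh and Met, which are often encoded remotely).  A catalytic gene whose
required companions are all found yields a *bifurcating* call; one that
passed thresholds and motifs but fails the gene-context test yields a
*non_bifurcating* call (the denominator of homolog counts).

Stand-alone heterodisulfide reductase (Hdr2) is not called by windows
around its own catalytic subunit: HdrABC copies are inventoried, one
complete set is reserved for the genome's called Mvh/Fdh/Met complexes
(policy ``shared``; ``per_complex`` reserves one per call), and leftover
sets whose HdrB and HdrC genes are mutually within ±2 ORFs become Hdr2
calls.

Metagenome mode works per contig with the relaxed complements (MvhAGD
alone, FdhAB alone, MetF+MetV+MvhD alone; Hdr2 disabled) and restricts
``ALL`` windows of any remaining complex to the same contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import BfscanError, Companion, ComplexRule, GeneRecord, Genome, RuleSet
from .homology import HitTable

logger = logging.getLogger(__name__)

BIFURCATING = "bifurcating"
NON_BIFURCATING = "non_bifurcating"

#: tie-break priority among the formate-dehydrogenase complexes when one
#: gene is catalytic-eligible for several of them with equally many
#: co-localized companions
_FDH_PRIORITY = {"Hyt": 0, "Hyl": 1, "Fdh": 2}


@dataclass
class ComplexCall:
    genome_id: str
    complex_name: str
    bf_flag: str
    catalytic_gene: str
    members: dict[str, str] = field(default_factory=dict)  # role -> gene_id
    satisfied: dict[str, str] = field(default_factory=dict)  # role -> clause text
    missing: tuple[str, ...] = ()
    mode: str = "genome"
    notes: tuple[str, ...] = ()

    @property
    def is_bifurcating(self) -> bool:
        return self.bf_flag == BIFURCATING

    def sort_key(self):
        return (self.genome_id, self.complex_name, self.catalytic_gene)


def _gene_index(genome: Genome) -> dict[str, GeneRecord]:
    return {g.gene_id: g for g in genome.genes()}


def _window_clause(comp: Companion, mode: str) -> str:
    w = comp.window
    if w.kind == "orf":
        return f"±{w.k} ORFs"
    if w.kind == "all":
        return "anywhere on contig" if mode == "metagenome" else "anywhere in genome"
    return f"±{w.k} ORFs of {w.sibling}"


def _find_companion(
    catalytic: GeneRecord,
    comp: Companion,
    role_genes: dict[str, list[GeneRecord]],
    mode: str,
) -> GeneRecord | None:
    """Nearest gene satisfying the companion clause, or None."""
    candidates = []
    for g in role_genes.get(comp.role, []):
        if g.gene_id == catalytic.gene_id:
            continue
        w = comp.window
        if w.kind == "orf":
            if g.replicon_id != catalytic.replicon_id:
                continue
            if abs(g.ordinal - catalytic.ordinal) > w.k:
                continue
        elif w.kind == "all":
            if mode == "metagenome" and g.replicon_id != catalytic.replicon_id:
                continue
        else:  # paired windows are resolved by the Hdr2 inventory
            continue
        candidates.append(g)
    if not candidates:
        return None
    if catalytic.replicon_id is not None:
        candidates.sort(
            key=lambda g: (
                g.replicon_id != catalytic.replicon_id,
                abs(g.ordinal - catalytic.ordinal)
                if g.replicon_id == catalytic.replicon_id
                else 0,
                g.replicon_id,
                g.gene_id,
            )
        )
    return candidates[0]


def _effective_companions(rule: ComplexRule, mode: str) -> list[Companion] | None:
    """Companion list under the given mode; None when the complex is off."""
    if mode == "metagenome" and rule.metagenome is not None:
        if not rule.metagenome.get("companions"):
            return None  # disabled in metagenomes
        return list(rule.metagenome["companions"])
    return list(rule.companions)


@dataclass
class _Candidate:
    rule: ComplexRule
    rule_index: int
    call: ComplexCall
    n_satisfied: int


def _evaluate(
    genome: Genome,
    catalytic: GeneRecord,
    rule: ComplexRule,
    companions: list[Companion],
    role_genes: dict[str, list[GeneRecord]],
    mode: str,
) -> tuple[ComplexCall, int]:
    members: dict[str, str] = {rule.catalytic_role: catalytic.gene_id}
    satisfied: dict[str, str] = {}
    missing: list[str] = []
    notes: list[str] = []
    n_sat = 0
    for comp in companions:
        found = _find_companion(catalytic, comp, role_genes, mode)
        if found is not None:
            members[comp.role] = found.gene_id
            satisfied[comp.role] = _window_clause(comp, mode)
            if comp.required:
                n_sat += 1
            else:
                notes.append(f"optional {comp.role} present")
        elif comp.required:
            missing.append(comp.role)
    bf = BIFURCATING if not missing else NON_BIFURCATING
    if mode == "metagenome":
        notes.append("metagenome-mode")
    return (
        ComplexCall(
            genome_id=genome.genome_id,
            complex_name=rule.name,
            bf_flag=bf,
            catalytic_gene=catalytic.gene_id,
            members=members,
            satisfied=satisfied,
            missing=tuple(missing),
            mode=mode,
            notes=tuple(notes),
        ),
        n_sat,
    )


def _pick_winner(cands: list[_Candidate]) -> tuple[_Candidate, list[_Candidate]]:
    best_n = max(c.n_satisfied for c in cands)
    tied = [c for c in cands if c.n_satisfied == best_n]
    if len(tied) > 1 and all(c.rule.name in _FDH_PRIORITY for c in tied):
        tied.sort(key=lambda c: _FDH_PRIORITY[c.rule.name])
    else:
        tied.sort(key=lambda c: c.rule_index)
    winner = tied[0]
    losers = [c for c in cands if c is not winner]
    return winner, losers


def call_genome_complexes(
    genome: Genome,
    hits: HitTable,
    rules: RuleSet,
    mode: str = "genome",
) -> list[ComplexCall]:
    """Call complexes for one genome from its motif-screened hits.

    Every catalytic-role gene is tested against its complex rule.  When
    one gene is catalytic-eligible for several complexes (e.g. the
    homologous hydrogenase or formate-dehydrogenase families), the
    complex with the most co-localized required companions wins; ties go
    to Hyt > Hyl > Fdh among the formate dehydrogenases and to rule
    order otherwise -- a catalytic gene joins at most one call.
    Companion genes may serve several calls (shared subunits such as
    EtfAB), except HdrABC which is inventoried by :func:`resolve_hdr2`.
    Finally, a non-bifurcating bookkeeping call whose catalytic gene is
    already consumed as a companion of a bifurcating call is dropped.
    """
    genes = _gene_index(genome)
    role_genes: dict[str, list[GeneRecord]] = {}
    for rec in hits.for_genome(genome.genome_id):
        if rec.protein_id in genes:
            role_genes.setdefault(rec.subunit_role, []).append(genes[rec.protein_id])
    for lst in role_genes.values():
        lst.sort(key=lambda g: (g.replicon_id, g.ordinal))

    by_gene: dict[str, list[_Candidate]] = {}
    for idx, rule in enumerate(rules.complexes):
        if rule.special == "hdr2":
            continue  # inventoried separately
        companions = _effective_companions(rule, mode)
        if companions is None:
            continue
        for catalytic in role_genes.get(rule.catalytic_role, []):
            call, n_sat = _evaluate(
                genome, catalytic, rule, companions, role_genes, mode
            )
            by_gene.setdefault(catalytic.gene_id, []).append(
                _Candidate(rule, idx, call, n_sat)
            )

    calls: list[ComplexCall] = []
    for gene_id in sorted(by_gene):
        winner, losers = _pick_winner(by_gene[gene_id])
        if losers:
            lost = ",".join(sorted(c.rule.name for c in losers))
            winner.call.notes = winner.call.notes + (
                f"won catalytic assignment over {lost}",
            )
            logger.debug(
                "%s/%s: %s wins catalytic assignment over %s",
                genome.genome_id,
                gene_id,
                winner.rule.name,
                lost,
            )
        calls.append(winner.call)

    consumed_as_companion: set[str] = set()
    for call in calls:
        if call.is_bifurcating:
            consumed_as_companion.update(
                gid for role, gid in call.members.items() if gid != call.catalytic_gene
            )
    kept = []
    for call in calls:
        if (
            call.bf_flag == NON_BIFURCATING
            and call.catalytic_gene in consumed_as_companion
        ):
            logger.debug(
                "%s: dropping non-Bf %s bookkeeping call, %s serves a Bf call",
                genome.genome_id,
                call.complex_name,
                call.catalytic_gene,
            )
            continue
        kept.append(call)
    kept.sort(key=ComplexCall.sort_key)
    return kept


# ---------------------------------------------------------------------------
# Hdr2 leftover accounting
# ---------------------------------------------------------------------------


def resolve_hdr2(
    genome: Genome,
    calls: list[ComplexCall],
    hits: HitTable,
    rules: RuleSet,
    sharing_policy: str = "shared",
) -> list[ComplexCall]:
    """Append stand-alone Hdr2 calls from leftover HdrABC copies.

    Under ``shared`` (default) one complete HdrABC set is reserved for
    the union of the genome's called Mvh/Fdh/Met complexes -- the three
    complexes compete for the same Hdr; under ``per_complex`` one set is
    reserved per call.  Remaining complete sets whose HdrB and HdrC
    genes satisfy the mutual ±2 ORF pairing become bifurcating Hdr2
    calls.
    """
    if sharing_policy not in {"shared", "per_complex"}:
        raise BfscanError(f"unknown sharing policy {sharing_policy!r}")
    try:
        hdr2_rule = next(c for c in rules.complexes if c.special == "hdr2")
    except StopIteration:
        return list(calls)
    pair_k = max(
        (c.window.k for c in hdr2_rule.companions if c.window.kind == "paired"),
        default=2,
    )

    genes = _gene_index(genome)
    inventory: dict[str, list[GeneRecord]] = {"HdrA": [], "HdrB": [], "HdrC": []}
    for rec in hits.for_genome(genome.genome_id):
        if rec.subunit_role in inventory and rec.protein_id in genes:
            inventory[rec.subunit_role].append(genes[rec.protein_id])
    for lst in inventory.values():
        lst.sort(key=lambda g: (g.replicon_id, g.ordinal))

    complete_sets = min(len(v) for v in inventory.values())
    partner_calls = [
        c
        for c in calls
        if c.is_bifurcating and c.complex_name in {"Mvh", "Fdh", "Met"}
    ]
    if partner_calls and complete_sets == 0:
        # a bifurcating Mvh/Fdh/Met call implies the ALL-window HdrABC
        # clauses were satisfied, so a complete set must exist
        raise AssertionError(
            f"{genome.genome_id}: called {partner_calls[0].complex_name} "
            "without a complete HdrABC set"
        )
    if sharing_policy == "shared":
        reserved = 1 if partner_calls else 0
    else:
        reserved = len(partner_calls)
    reserved = min(reserved, complete_sets)
    leftover = complete_sets - reserved
    if leftover <= 0:
        return list(calls)

    # greedy disjoint pairing of HdrB/HdrC genes under the mutual ±k clause
    used_c: set[str] = set()
    pairs: list[tuple[GeneRecord, GeneRecord]] = []
    for b in inventory["HdrB"]:
        best = None
        for c in inventory["HdrC"]:
            if c.gene_id in used_c or c.replicon_id != b.replicon_id:
                continue
            if abs(c.ordinal - b.ordinal) <= pair_k:
                if best is None or abs(c.ordinal - b.ordinal) < abs(
                    best.ordinal - b.ordinal
                ):
                    best = c
        if best is not None:
            used_c.add(best.gene_id)
            pairs.append((b, best))

    n_hdr2 = min(leftover, len(pairs))
    if n_hdr2 <= 0:
        return list(calls)

    # HdrA copies not already serving a partner call's HdrA slot
    serving = {c.members.get("HdrA") for c in partner_calls}
    free_a = [g for g in inventory["HdrA"] if g.gene_id not in serving]
    if len(free_a) < n_hdr2:  # fall back: reuse sorted inventory
        free_a = inventory["HdrA"]

    out = list(calls)
    for i in range(n_hdr2):
        b, c = pairs[i]
        a = free_a[i]
        out.append(
            ComplexCall(
                genome_id=genome.genome_id,
                complex_name=hdr2_rule.name,
                bf_flag=BIFURCATING,
                catalytic_gene=a.gene_id,
                members={"HdrA": a.gene_id, "HdrB": b.gene_id, "HdrC": c.gene_id},
                satisfied={
                    "HdrB": f"±{pair_k} ORFs of HdrC",
                    "HdrC": f"±{pair_k} ORFs of HdrB",
                },
                mode="genome",
                notes=(f"leftover HdrABC set ({sharing_policy} policy)",),
            )
        )
    out.sort(key=ComplexCall.sort_key)
    return out


def call_metagenome_complexes(
    contigs: Genome, hits: HitTable, rules: RuleSet
) -> list[ComplexCall]:
    """Per-contig complex calling with the relaxed metagenome rules."""
    return call_genome_complexes(contigs, hits, rules, mode="metagenome")


def call_all(
    genome: Genome,
    hits: HitTable,
    rules: RuleSet,
    sharing_policy: str = "shared",
) -> list[ComplexCall]:
    """Full per-genome calling: window logic plus Hdr2 accounting."""
    if genome.is_metagenome:
        return call_metagenome_complexes(genome, hits, rules)
    calls = call_genome_complexes(genome, hits, rules, mode="genome")
    return resolve_hdr2(genome, calls, hits, rules, sharing_policy)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "genome_id",
    "complex",
    "bf_flag",
    "catalytic_gene",
    "members",
    "missing",
    "mode",
    "notes",
]


def calls_to_dataframe(calls: list[ComplexCall]):
    import pandas as pd

    rows = []
    for c in sorted(calls, key=ComplexCall.sort_key):
        rows.append(
            {
                "genome_id": c.genome_id,
                "complex": c.complex_name,
                "bf_flag": c.bf_flag,
                "catalytic_gene": c.catalytic_gene,
                "members": ";".join(f"{r}={g}" for r, g in sorted(c.members.items())),
                "missing": ";".join(c.missing),
                "mode": c.mode,
                "notes": "|".join(c.notes),
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def build_presence_matrix(
    calls: list[ComplexCall],
    genome_ids: list[str],
    complex_names: list[str],
    bifurcating_only: bool = True,
):
    """Binary genome x complex table feeding the co-occurrence stage."""
    import pandas as pd

    mat = pd.DataFrame(0, index=list(genome_ids), columns=list(complex_names))
    for c in calls:
        if bifurcating_only and not c.is_bifurcating:
            continue
        if c.genome_id in mat.index and c.complex_name in mat.columns:
            mat.loc[c.genome_id, c.complex_name] = 1
    mat.index.name = "genome_id"
    return mat
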