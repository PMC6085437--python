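"""Bait-based homology search with per-role E-value thresholds.

Each subunit role has one or more representative bait proteins and an
empirically chosen E-value cut-off that demarcates homologs of the
bifurcating complex's subunit from their closest paralogs.  Two backends
produce the per-protein hits:

``internal``
    Smith-Waterman local alignment (Biopython's C aligner, BLOSUM62,
    BLAST-style gap 11/1 by default) with a Karlin-Altschul style
    E-value, ``E = K * m * n * exp(-lambda * S)``, where *m* is the bait
    length and *n* the number of residues in the searched proteome.
    ``K`` and ``lambda`` are configuration constants, not fits; the
    defaults are the canonical gapped BLOSUM62-11-1 values.

``hmmer_domtbl``
    A parser for HMMER3 per-domain tabular output produced by an
    external phmmer/hmmsearch run (full-sequence E-value column).

Hits are one-way (bait -> proteome); per (protein, role) only the best
E-value is kept.  A protein may pass the thresholds of several roles
(e.g. the homologous HydA/HytA/HylA baits); all candidates are retained
here, because the motif screen is the intended disambiguator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import AA_ALPHABET, BaitSet, BfscanError, Genome, RuleSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring: substitution matrix + gap penalties.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of
    length L costs ``gap_open + L * gap_extend``.
    """

    matrix: str | None = "BLOSUM62"  # None -> match/mismatch scores
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def build_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        # PairwiseAligner charges open on the first gapped column
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


UNIT_SCORING = ScoringScheme(matrix=None, match=1, mismatch=-1, gap_open=0, gap_extend=1)


@dataclass(frozen=True)
class EValueParams:
    """Karlin-Altschul style constants for the internal backend."""

    K: float = 0.041
    lam: float = 0.267

    def evalue(self, score: float, m: int, n: int) -> float:
        e = self.K * m * n * math.exp(-self.lam * score)
        # never report exactly zero: E-values are positive by contract
        return max(e, 5e-324)


def _check_sequence(seq: str, what: str) -> str:
    if not seq:
        raise BfscanError(f"{what}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise BfscanError(f"{what}: symbol(s) outside amino-acid alphabet: {sorted(bad)}")
    return seq


def local_align_score(
    query: str,
    target: str,
    scoring: ScoringScheme = ScoringScheme(),
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, float]:
    """Maximum local alignment score and aligned identity.

    Returns ``(score, identity)`` where identity = matches / aligned
    columns of one optimal alignment (0.0 when the best local alignment
    is empty).  Deterministic for fixed inputs and scoring.
    """
    query = _check_sequence(query, "query")
    target = _check_sequence(target, "target")
    if aligner is None:
        aligner = scoring.build_aligner()
    score = aligner.score(query, target)
    if score <= 0:
        return 0.0, 0.0
    aln = next(iter(aligner.align(query, target)))
    counts = aln.counts()
    columns = counts.aligned + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    return float(score), float(identity)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    protein_id: str
    genome_id: str
    subunit_role: str
    evalue: float
    score: float = float("nan")
    backend: str = "internal"

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise BfscanError(
                f"hit {self.protein_id}/{self.subunit_role}: E-value must be > 0"
            )


@dataclass
class HitTable:
    """De-duplicated per-(protein, role) hits, deterministically ordered."""

    records: list[HitRecord] = field(default_factory=list)
    backend: str = "internal"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.genome_id, r.subunit_role, r.protein_id)
        )
        seen = set()
        for r in self.records:
            key = (r.protein_id, r.genome_id, r.subunit_role)
            if key in seen:
                raise BfscanError(f"duplicate hit for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def roles_for(self, genome_id: str, protein_id: str) -> list[str]:
        return sorted(
            r.subunit_role
            for r in self.records
            if r.genome_id == genome_id and r.protein_id == protein_id
        )

    def for_genome(self, genome_id: str) -> "HitTable":
        return HitTable(
            [r for r in self.records if r.genome_id == genome_id],
            backend=self.backend,
            provenance=self.provenance,
        )

    def by_role(self, role: str) -> list[HitRecord]:
        return [r for r in self.records if r.subunit_role == role]

    def evalue(self, genome_id: str, protein_id: str, role: str) -> float:
        for r in self.records:
            if (r.genome_id, r.protein_id, r.subunit_role) == (
                genome_id,
                protein_id,
                role,
            ):
                return r.evalue
        raise KeyError((genome_id, protein_id, role))


def _dedupe_best(records: Iterable[HitRecord]) -> list[HitRecord]:
    best: dict[tuple[str, str, str], HitRecord] = {}
    for r in records:
        key = (r.genome_id, r.protein_id, r.subunit_role)
        if key not in best or r.evalue < best[key].evalue:
            best[key] = r
    return list(best.values())


def apply_thresholds(hits: Iterable[HitRecord], rules: RuleSet) -> list[HitRecord]:
    out = []
    for r in hits:
        if r.evalue <= rules.threshold(r.subunit_role):
            out.append(r)
    return out


def search_homologs(
    proteome: Genome,
    baits: BaitSet,
    rules: RuleSet,
    backend: str = "internal",
    scoring: ScoringScheme = ScoringScheme(),
    evalue_params: EValueParams = EValueParams(),
    database_size: int | None = None,
) -> HitTable:
    """Assign candidate subunit roles to every protein in *proteome*.

    Every (protein, bait) pair is aligned; a protein is recorded for a
    role when its best E-value against any of the role's baits is at or
    below the role threshold.  The database size *n* of the E-value
    defaults to the total residue count of the searched proteome
    (per-genome search scope).
    """
    if backend != "internal":
        raise BfscanError(
            "search_homologs computes internal-backend hits; use "
            "parse_hmmer_domtbl for pre-computed HMMER3 output"
        )
    baits.validate_against(rules)
    n = database_size if database_size is not None else proteome.total_residues
    if n <= 0:
        return HitTable([], backend="internal")
    aligner = scoring.build_aligner()
    records: list[HitRecord] = []
    for gene in proteome.genes():
        if not gene.protein:
            continue
        for role in baits.roles():
            if role not in rules.thresholds:
                raise BfscanError(f"bait role {role} has no threshold")
            thr = rules.threshold(role)
            best_e, best_s = None, None
            for _acc, bait_seq in baits.sequences(role):
                score, _ident = local_align_score(
                    bait_seq, gene.protein, scoring, aligner=aligner
                )
                e = evalue_params.evalue(score, len(bait_seq), n)
                if best_e is None or e < best_e:
                    best_e, best_s = e, score
            if best_e is not None and best_e <= thr:
                records.append(
                    HitRecord(
                        protein_id=gene.gene_id,
                        genome_id=proteome.genome_id,
                        subunit_role=role,
                        evalue=best_e,
                        score=best_s,
                        backend="internal",
                    )
                )
    return HitTable(_dedupe_best(records), backend="internal")


def parse_hmmer_domtbl(
    path: str | Path,
    role_map: Mapping[str, str],
    genome_id: str = "",
    rules: RuleSet | None = None,
) -> HitTable:
    """Parse HMMER3 per-domain tabular output (``--domtblout``).

    Uses the full-sequence E-value (column 7); keeps the best E per
    (target, role).  Query names are mapped to subunit roles through
    *role_map*; unknown query names are skipped with a warning.  When
    *rules* is given the per-role thresholds are applied.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise BfscanError(
                    f"{path}:{ln}: malformed domtblout line "
                    f"({len(parts)} columns, expected >= 22)"
                )
            target, query = parts[0], parts[3]
            role = role_map.get(query)
            if role is None:
                logger.warning("%s:%d: unknown query %r skipped", path, ln, query)
                continue
            try:
                evalue = float(parts[6])
                score = float(parts[7])
            except ValueError as exc:
                raise BfscanError(f"{path}:{ln}: bad numeric field: {exc}") from exc
            records.append(
                HitRecord(
                    protein_id=target,
                    genome_id=genome_id,
                    subunit_role=role,
                    evalue=max(evalue, 5e-324),
                    score=score,
                    backend="hmmer_domtbl",
                )
            )
    records = _dedupe_best(records)
    if rules is not None:
        records = apply_thresholds(records, rules)
    return HitTable(records, backend="hmmer_domtbl", provenance=str(path))


def screen_hits(
    hits: HitTable,
    proteins: Mapping[str, str],
    motif_config,
    lowercase_policy: str = "strict",
) -> HitTable:
    """Apply the catalytic motif screens to a hit table.

    Roles present in the motif configuration are screened per protein
    (require / require-absence sets evaluated on the unaligned
    sequence); roles outside the configuration (plain companion
    subunits) pass through untouched.
    """
    from .motifs import screen_catalytic

    screened_roles = motif_config.screened_roles()
    by_protein: dict[tuple[str, str], list[HitRecord]] = {}
    for r in hits:
        by_protein.setdefault((r.genome_id, r.protein_id), []).append(r)

    kept: list[HitRecord] = []
    for (gid, pid), recs in by_protein.items():
        candidates = [r for r in recs if r.subunit_role in screened_roles]
        passthrough = [r for r in recs if r.subunit_role not in screened_roles]
        kept.extend(passthrough)
        if candidates:
            seq = proteins[pid]
            result = screen_catalytic(
                seq,
                [r.subunit_role for r in candidates],
                motif_config,
                lowercase_policy,
            )
            surv = set(result.surviving_roles)
            kept.extend(r for r in candidates if r.subunit_role in surv)
    return HitTable(
        [replace(r) for r in kept], backend=hits.backend, provenance=hits.provenance
    )
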