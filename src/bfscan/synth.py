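"""Synthetic genomes and metagenomes with planted, known ground truth.

The generator is the test bed for the whole pipeline: it plants enzyme
complex operons whose subunit complement, gene spacing and catalytic
motifs satisfy the shipped rules exactly, together with controlled
violations ("ablations") that each break exactly one clause:

``drop_subunit(role)``
    the companion gene is omitted,
``out_of_window(role, offset)``
    the companion gene exists but beyond its ORF window,
``motif_ablate(motif)``
    the catalytic protein's motif region is destroyed.

Planted proteins are point-mutated copies of the bait sequences (no
indels by default) so internal-backend E-values remain far below the
role thresholds; positions inside required motifs are never mutated, so
a planted bifurcating item keeps its motif content at any mutation
rate.  Filler genes are random sequences verified against every bait at
a conservative (small) database size, guaranteeing they pass no role
threshold.  Because the Hyd-family baits (HydA/HytA/HylA) and the
FdhA/FdhF2 baits are built from shared backbones, planted catalytic
genes cross-hit their paralog baits exactly as real homologs do, and
the motif screen plus gene context perform the disambiguation.

All randomness flows from one :func:`numpy.random.default_rng` seed;
regeneration with the same spec and seed is byte-identical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    BaitSet,
    BfscanError,
    GeneRecord,
    Genome,
    GenomeMetadata,
    RuleSet,
)
from .motifs import MotifConfig, compile_pattern, match_motif

logger = logging.getLogger(__name__)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_BAIT_SEED = 73114  # frozen: shipped baits are this stream

#: operon layouts: gene order along the chromosome; the catalytic role is
#: included.  Remote HdrABC sets are placed separately (ALL windows).
OPERON_LAYOUTS: dict[str, list[str]] = {
    "Hyd": ["HydA", "HydB", "HydC"],
    "Mvh": ["MvhA", "MvhG", "MvhD"],
    "Fdh": ["FdhB", "FdhA"],
    "Hyt": ["FdhA", "HytE2", "HytA", "HytE1", "HytD", "HytB", "HytC"],
    "Nfn": ["NfnS", "NfnL"],
    "Fix": ["FixA", "FixB", "FixC", "FixX"],
    "Bcd": ["Bcd", "EtfA", "EtfB"],
    "Car": ["CarC", "EtfB", "EtfA"],
    "Hyl": ["FdhF2", "HylA", "HylB", "HylC"],
    "Ldh": ["Ldh", "EtfA", "EtfB"],
    "Hdr2": ["HdrA", "HdrB", "HdrC"],
    "Met": ["MetF", "MetV", "MvhD"],
}

#: complexes whose HdrABC partners sit on a second replicon
REMOTE_HDR = {"Mvh", "Fdh", "Met"}

CATALYTIC = {
    "Hyd": "HydA",
    "Mvh": "MvhA",
    "Fdh": "FdhA",
    "Hyt": "HytA",
    "Nfn": "NfnL",
    "Fix": "FixA",
    "Bcd": "Bcd",
    "Car": "CarC",
    "Hyl": "HylA",
    "Ldh": "Ldh",
    "Hdr2": "HdrA",
    "Met": "MetF",
}

_BAIT_LENGTHS = {
    "HydA": 380, "HydB": 300, "HydC": 180, "HydD": 220,
    "MvhA": 400, "MvhG": 240, "MvhD": 180,
    "HdrA": 360, "HdrB": 260, "HdrC": 200,
    "FdhA": 380, "FdhB": 300,
    "HytA": 380, "HytB": 300, "HytC": 180, "HytD": 220, "HytE1": 210, "HytE2": 210,
    "NfnS": 280, "NfnL": 340,
    "FixA": 260, "FixB": 280, "FixC": 300, "FixX": 160,
    "Bcd": 340, "EtfA": 280, "EtfB": 260,
    "CarC": 340,
    "FdhF2": 380, "HylA": 380, "HylB": 300, "HylC": 180,
    "Ldh": 340, "MetF": 300, "MetV": 180,
}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _realize_motif(rng: np.random.Generator, pattern_tokens) -> str:
    out = []
    for kind, val in pattern_tokens:
        if kind in {"req", "weak"}:
            out.append(val)
        elif kind == "any":
            out.append(str(rng.choice(_AA)))
        else:
            out.append("".join(rng.choice(_AA, size=val)))
    return "".join(out)


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: set[int] | None = None,
) -> str:
    """Point substitutions at *rate*, never touching protected positions."""
    if rate <= 0:
        return seq
    chars = list(seq)
    protected = protected or set()
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < rate:
            current = chars[i]
            choices = [a for a in _AA if a != current]
            chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _motif_spans(seq: str, motifs) -> set[int]:
    """0-based positions covered by each motif's leftmost occurrence."""
    spans: set[int] = set()
    for motif in motifs:
        m = compile_pattern(motif, "strict").search(seq)
        if m:
            spans.update(range(m.start(), m.end()))
    return spans


def _ablate_motifs(rng: np.random.Generator, seq: str, motifs) -> str:
    """Rewrite motif regions with random residues until none match."""
    for _ in range(50):
        changed = False
        for motif in motifs:
            pat = compile_pattern(motif, "strict")
            m = pat.search(seq)
            if m:
                repl = _random_protein(rng, m.end() - m.start())
                seq = seq[: m.start()] + repl + seq[m.end() :]
                changed = True
        if not changed:
            return seq
    raise BfscanError("motif ablation failed to converge")


# ---------------------------------------------------------------------------
# bait construction
# ---------------------------------------------------------------------------


def make_default_baits(
    motif_config: MotifConfig | None = None, seed: int = DEFAULT_BAIT_SEED
) -> BaitSet:
    """Deterministic synthetic bait set (stand-ins for the real accessions).

    Motif-requiring catalytic baits embed their motifs; HytA and HylA
    are mutated copies of the HydA backbone (HylA with motifs ablated),
    FdhF2 a signature-ablated copy of FdhA, so the paralog families
    cross-hit exactly as the screens expect.
    """
    if motif_config is None:
        from .motifs import read_motif_config

        motif_config = read_motif_config()
    rng = np.random.default_rng(seed)
    baits: dict[str, str] = {}

    def embed(backbone: str, role: str, at: list[int]) -> str:
        motifs = [m for m in motif_config.motifs_for(role) if m.mode == "require"]
        seq = backbone
        pos = list(at)
        for motif, p in zip(motifs, pos):
            real = _realize_motif(rng, motif.tokens)
            seq = seq[:p] + real + seq[p + len(real) :]
        return seq

    for role in sorted(_BAIT_LENGTHS):
        baits[role] = _random_protein(rng, _BAIT_LENGTHS[role])

    hyd_motifs = motif_config.motifs_for("HydA")
    baits["HydA"] = embed(baits["HydA"], "HydA", [60, 140, 230])
    hyd_backbone = baits["HydA"]
    protected = _motif_spans(hyd_backbone, hyd_motifs)
    baits["HytA"] = _mutate(rng, hyd_backbone, 0.25, protected)
    baits["HylA"] = _ablate_motifs(
        rng, _mutate(rng, hyd_backbone, 0.25, protected), hyd_motifs
    )

    baits["MvhA"] = embed(baits["MvhA"], "MvhA", [80, 300])

    fdh_motifs = motif_config.motifs_for("FdhA")
    baits["FdhA"] = embed(baits["FdhA"], "FdhA", [100])
    protected = _motif_spans(baits["FdhA"], fdh_motifs)
    baits["FdhF2"] = _ablate_motifs(
        rng, _mutate(rng, baits["FdhA"], 0.25, protected), fdh_motifs
    )

    return BaitSet({role: [(f"SYN_{role}", seq)] for role, seq in sorted(baits.items())})


def write_baits(baits: BaitSet, path) -> None:
    with open(path, "w") as fh:
        for role in baits.roles():
            for acc, seq in baits.sequences(role):
                fh.write(f">{acc}|{role}\n{seq}\n")


# ---------------------------------------------------------------------------
# truth specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ablation:
    kind: str  # drop_subunit / out_of_window / motif_ablate
    role: str | None = None
    offset: int = 0
    motif: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"drop_subunit", "out_of_window", "motif_ablate"}:
            raise BfscanError(f"unknown ablation kind {self.kind!r}")


@dataclass(frozen=True)
class PlantedItem:
    """One planted complex (or violation) in one genome."""

    complex_name: str
    label: str  # bifurcating / non_bifurcating / decoy
    ablation: Ablation | None = None

    def __post_init__(self) -> None:
        if self.label not in {"bifurcating", "non_bifurcating", "decoy"}:
            raise BfscanError(f"unknown label {self.label!r}")
        if self.ablation is None and self.label != "bifurcating":
            raise BfscanError("non-bifurcating/decoy items need exactly one ablation")
        if self.ablation is not None and self.label == "bifurcating":
            raise BfscanError("bifurcating items may not carry an ablation")
        if self.complex_name not in OPERON_LAYOUTS:
            raise BfscanError(f"unknown complex {self.complex_name!r}")
        ab = self.ablation
        if ab and ab.kind in {"drop_subunit", "out_of_window"}:
            roles = set(OPERON_LAYOUTS[self.complex_name])
            if self.complex_name in REMOTE_HDR:
                roles |= {"HdrA", "HdrB", "HdrC"}
            roles.discard(CATALYTIC[self.complex_name])
            if ab.role not in roles:
                raise BfscanError(
                    f"{self.complex_name}: ablation role {ab.role!r} is not a "
                    f"companion of this complex"
                )


@dataclass
class GenomeSpec:
    genome_id: str
    items: list[PlantedItem]
    n_filler: int = 8
    extra_hdr_sets: int = 0  # extra adjacent HdrABC sets (Hdr2 accounting)
    hdr_adjacent: bool = True  # planted Hdr B/C genes mutually within ±2
    share_etf: bool = False  # Bcd and Ldh items share one EtfAB pair
    metadata: GenomeMetadata = field(default_factory=GenomeMetadata)


@dataclass(frozen=True)
class ExpectedCall:
    genome_id: str
    complex_name: str
    bf_flag: str  # bifurcating / non_bifurcating
    catalytic_gene: str
    violated_clause: str = ""
    item_index: int = -1


@dataclass
class TruthTable:
    """Expected pipeline outcome for a generated genome set."""

    expected_calls: list[ExpectedCall]
    # (genome_id, gene_id) -> surviving candidate roles after motif screen
    expected_roles: dict[tuple[str, str], tuple[str, ...]]

    def bifurcating(self) -> set[tuple[str, str, str]]:
        return {
            (e.genome_id, e.complex_name, e.catalytic_gene)
            for e in self.expected_calls
            if e.bf_flag == "bifurcating"
        }

    def non_bifurcating(self) -> list[ExpectedCall]:
        return [e for e in self.expected_calls if e.bf_flag == "non_bifurcating"]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([e.__dict__ for e in self.expected_calls])


# cross-hitting paralog families: planted role -> surviving screened roles
_SURVIVING_ROLES = {
    "HydA": ("HydA", "HytA"),
    "HytA": ("HydA", "HytA"),
    "HylA": ("HylA",),
    "FdhA": ("FdhA",),
    "FdhF2": ("FdhF2",),
}


def _surviving_roles(role: str) -> tuple[str, ...]:
    return _SURVIVING_ROLES.get(role, (role,))


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


@dataclass
class _Placed:
    role: str
    item_index: int  # -1 for filler / extra Hdr
    gene_id: str = ""
    replicon_id: str = ""
    ordinal: int = -1
    protein: str = ""


def _min_passing_score(role: str, bait_len: int, rules: RuleSet) -> float:
    """Score above which a hit could pass *role*'s threshold at a small DB."""
    import math

    n_conservative = 1000.0
    thr = rules.threshold(role)
    return (math.log(0.041 * bait_len * n_conservative) - math.log(thr)) / 0.267


def _make_filler(
    rng: np.random.Generator,
    baits: BaitSet,
    rules: RuleSet,
    aligner,
    length_range=(150, 250),
) -> str:
    """Random protein verified to pass no role threshold against any bait."""
    from .homology import local_align_score, ScoringScheme

    scoring = ScoringScheme()
    for _ in range(60):
        seq = _random_protein(rng, int(rng.integers(*length_range)))
        ok = True
        for role in baits.roles():
            for _acc, bait in baits.sequences(role):
                score, _ = local_align_score(bait, seq, scoring, aligner=aligner)
                if score >= _min_passing_score(role, len(bait), rules):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return seq
    raise BfscanError("could not draw a clean filler sequence")


def _planted_protein(
    rng: np.random.Generator,
    role: str,
    baits: BaitSet,
    motif_config: MotifConfig,
    mutation_rate: float,
    ablate_motif: str | None = None,
) -> str:
    """Mutated bait copy; motif content preserved (or ablated on request)."""
    _acc, seq = baits.sequences(role)[0]
    screened = role in motif_config.screened_roles()
    require = (
        [m for m in motif_config.motifs_for(role) if m.mode == "require"]
        if screened
        else []
    )
    absent = (
        [m for m in motif_config.motifs_for(role) if m.mode == "require_absence"]
        if screened
        else []
    )
    if ablate_motif is not None:
        names = {n.strip() for n in ablate_motif.split(",")}
        targets = [m for m in require if m.name in names]
        if len(targets) != len(names):
            missing = names - {m.name for m in targets}
            raise BfscanError(f"{role}: no required motif named {sorted(missing)}")
        seq = _ablate_motifs(rng, seq, targets)
        require = [m for m in require if m.name not in names]
        absent = absent + targets
    protected = _motif_spans(seq, require)
    for _ in range(30):
        mutated = _mutate(rng, seq, mutation_rate, protected)
        if all(match_motif(mutated, m).matched for m in require) and not any(
            match_motif(mutated, m).matched for m in absent
        ):
            return mutated
    raise BfscanError(f"{role}: mutation kept violating the motif contract")


def generate_genome_set(
    specs: list[GenomeSpec],
    baits: BaitSet | None = None,
    rules: RuleSet | None = None,
    motif_config: MotifConfig | None = None,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Genome], TruthTable]:
    """Generate annotated genomes with planted complexes and their truth.

    Planted bifurcating items satisfy every window and motif clause of
    the shipped rules; each ablation violates exactly its one clause;
    filler genes pass no threshold.  Deterministic per (spec, seed).
    """
    from .core_io import read_ruleset
    from .homology import ScoringScheme
    from .motifs import read_motif_config

    rules = rules or read_ruleset()
    motif_config = motif_config or read_motif_config()
    baits = baits or make_default_baits(motif_config)
    rng = np.random.default_rng(seed)
    aligner = ScoringScheme().build_aligner()

    genomes: list[Genome] = []
    expected_calls: list[ExpectedCall] = []
    expected_roles: dict[tuple[str, str], tuple[str, ...]] = {}

    for spec in specs:
        placed = _plan_genome(spec, rng, baits, rules, motif_config, mutation_rate, aligner)
        genome = _assemble(spec, placed)
        genomes.append(genome)
        calls, roles = _genome_truth(spec, placed, rules)
        expected_calls.extend(calls)
        expected_roles.update(roles)

    return genomes, TruthTable(expected_calls, expected_roles)


def _plan_genome(
    spec: GenomeSpec,
    rng: np.random.Generator,
    baits: BaitSet,
    rules: RuleSet,
    motif_config: MotifConfig,
    mutation_rate: float,
    aligner,
) -> list[_Placed]:
    """Lay out genes on replicons; returns placements with ordinals set."""
    chr_genes: list[_Placed] = []
    chr2_genes: list[_Placed] = []

    def filler(n: int, out: list[_Placed]) -> None:
        for _ in range(n):
            out.append(
                _Placed(
                    role="",
                    item_index=-1,
                    protein=_make_filler(rng, baits, rules, aligner),
                )
            )

    def plant(role: str, item_index: int, out: list[_Placed], ablate: str | None = None):
        out.append(
            _Placed(
                role=role,
                item_index=item_index,
                protein=_planted_protein(
                    rng, role, baits, motif_config, mutation_rate, ablate
                ),
            )
        )

    n_lead = max(2, spec.n_filler // 3)
    filler(n_lead, chr_genes)

    displaced: list[tuple[str, int]] = []  # (role, item_index) for out_of_window
    shared_etf_done = False
    for idx, item in enumerate(spec.items):
        layout = list(OPERON_LAYOUTS[item.complex_name])
        ab = item.ablation
        ablate_motif = ab.motif if ab and ab.kind == "motif_ablate" else None
        attach = False
        if spec.share_etf and item.complex_name in {"Bcd", "Ldh"}:
            if shared_etf_done:
                # reuse the EtfAB genes planted with the first partner:
                # only the catalytic gene is planted, directly adjacent
                layout = [CATALYTIC[item.complex_name]]
                attach = True
            else:
                shared_etf_done = True
        if idx > 0 and not attach:
            filler(2, chr_genes)
        for role in layout:
            if ab and ab.kind == "drop_subunit" and role == ab.role:
                continue
            if ab and ab.kind == "out_of_window" and role == ab.role:
                displaced.append((role, idx))
                continue
            plant(
                role,
                idx,
                chr_genes,
                ablate=ablate_motif if role == CATALYTIC[item.complex_name] else None,
            )
        if item.complex_name in REMOTE_HDR:
            # HdrABC partners on the second replicon (ALL windows)
            for role in ("HdrA", "HdrB", "HdrC"):
                if ab and ab.kind == "drop_subunit" and role == ab.role:
                    continue
                plant(role, idx, chr2_genes)
                if role == "HdrB" and not spec.hdr_adjacent:
                    filler(3, chr2_genes)  # push HdrC out of the ±2 pairing
            filler(1, chr2_genes)

    for _set in range(spec.extra_hdr_sets):
        for role in ("HdrA", "HdrB", "HdrC"):
            plant(role, -1, chr2_genes)
        filler(1, chr2_genes)

    filler(2, chr_genes)
    if displaced:
        filler(11, chr_genes)  # beyond every ±k window (max k = 10)
        for role, idx in displaced:
            plant(role, idx, chr_genes)
            filler(1, chr_genes)

    filler(max(1, spec.n_filler - n_lead - 1), chr_genes)

    for rep_id, out in (("chr", chr_genes), ("chr2", chr2_genes)):
        for ordinal, g in enumerate(out):
            g.replicon_id = rep_id
            g.ordinal = ordinal
            g.gene_id = f"{spec.genome_id}_{rep_id}_{ordinal:03d}"
    return chr_genes + chr2_genes


def _assemble(spec: GenomeSpec, placed: list[_Placed]) -> Genome:
    replicons: dict[str, list[GeneRecord]] = {}
    for g in placed:
        start = 1 + g.ordinal * 1500
        rec = GeneRecord(
            gene_id=g.gene_id,
            replicon_id=g.replicon_id,
            ordinal=g.ordinal,
            start=start,
            end=start + 3 * len(g.protein) - 1,
            strand="+" if g.ordinal % 2 == 0 else "-",
            protein=g.protein,
        )
        replicons.setdefault(g.replicon_id, []).append(rec)
    return Genome(spec.genome_id, replicons, metadata=spec.metadata)


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------


def _item_genes(placed: list[_Placed], item_index: int) -> dict[str, list[_Placed]]:
    out: dict[str, list[_Placed]] = {}
    for g in placed:
        if g.item_index == item_index and g.role:
            out.setdefault(g.role, []).append(g)
    return out


def _catalytic_gene(spec: GenomeSpec, placed: list[_Placed], idx: int) -> _Placed:
    role = CATALYTIC[spec.items[idx].complex_name]
    return _item_genes(placed, idx)[role][0]


def _shared_pool(spec: GenomeSpec, placed: list[_Placed]) -> dict[str, list[_Placed]]:
    """Role -> planted genes across the whole genome (for shared subunits)."""
    pool: dict[str, list[_Placed]] = {}
    for g in placed:
        if g.role:
            pool.setdefault(g.role, []).append(g)
    return pool


def _within(a: _Placed, b: _Placed, k: int) -> bool:
    return a.replicon_id == b.replicon_id and abs(a.ordinal - b.ordinal) <= k


def _companion_satisfied(
    cat: _Placed, role: str, window, pool: dict[str, list[_Placed]], same_replicon_all: bool
) -> bool:
    for g in pool.get(role, []):
        if g.gene_id == cat.gene_id:
            continue
        if window.kind == "orf":
            if _within(cat, g, window.k):
                return True
        elif window.kind == "all":
            if not same_replicon_all or g.replicon_id == cat.replicon_id:
                return True
    return False


_REQUIRED_MOTIFS = {"Hyd": {"L1", "L2", "L3"}, "Hyt": {"L1", "L2", "L3"}}


def _ablates_all_required(complex_name: str, ab: Ablation) -> bool:
    names = {n.strip() for n in (ab.motif or "").split(",")}
    return _REQUIRED_MOTIFS.get(complex_name, set()) <= names


def _expected_for_item(
    spec: GenomeSpec,
    placed: list[_Placed],
    idx: int,
    rules: RuleSet,
    mode: str,
) -> ExpectedCall | None:
    """Expected call for one planted item (None = no call at all)."""
    item = spec.items[idx]
    ab = item.ablation
    cat = _catalytic_gene(spec, placed, idx)
    pool = _shared_pool(spec, placed)
    complex_name = item.complex_name

    # motif-ablated catalytic subunits change identity or vanish
    if ab and ab.kind == "motif_ablate":
        if complex_name in {"Hyd", "Hyt"}:
            if _ablates_all_required(complex_name, ab):
                complex_name = "Hyl"  # motif-less copies resolve to HylA
            else:
                return None  # partial ablation fails HydA/HytA and HylA alike
        elif complex_name in {"Fdh", "Mvh"}:
            return None  # FdhF2 is non-catalytic; motif-less MvhA is rejected
        else:
            raise BfscanError(f"motif_ablate unsupported for {item.complex_name}")

    rule = rules.complex(complex_name)
    if mode == "metagenome" and rule.metagenome is not None:
        if not rule.metagenome.get("companions"):
            return None  # disabled (Hdr2)
        companions = rule.metagenome["companions"]
    else:
        companions = rule.required_companions()
    if rule.special == "hdr2":
        # planted stand-alone Hdr set: bifurcating iff B/C mutually paired
        k = max(c.window.k for c in rule.companions)
        b = _item_genes(placed, idx).get("HdrB", [])
        c = _item_genes(placed, idx).get("HdrC", [])
        if b and c and _within(b[0], c[0], k):
            return ExpectedCall(
                spec.genome_id, "Hdr2", "bifurcating", cat.gene_id, item_index=idx
            )
        return ExpectedCall(
            spec.genome_id,
            "Hdr2",
            "non_bifurcating",
            cat.gene_id,
            violated_clause="HdrB~HdrC pairing",
            item_index=idx,
        )

    missing = []
    for comp in companions:
        ok = _companion_satisfied(
            cat, comp.role, comp.window, pool, same_replicon_all=(mode == "metagenome")
        )
        if not ok:
            missing.append(comp.role)
    if not missing:
        return ExpectedCall(
            spec.genome_id, complex_name, "bifurcating", cat.gene_id, item_index=idx
        )

    # context failure: the hydrogenase-family tie (no co-localized
    # companions for either Hyd or Hyt) resolves to Hyd by rule order
    if complex_name == "Hyt":
        n_sat = len(companions) - len(missing)
        if n_sat == 0:
            complex_name = "Hyd"
    return ExpectedCall(
        spec.genome_id,
        complex_name,
        "non_bifurcating",
        cat.gene_id,
        violated_clause=";".join(missing),
        item_index=idx,
    )


def _genome_truth(
    spec: GenomeSpec, placed: list[_Placed], rules: RuleSet | None = None, mode: str = "genome"
) -> tuple[list[ExpectedCall], dict[tuple[str, str], tuple[str, ...]]]:
    from .core_io import read_ruleset

    rules = rules or read_ruleset()
    calls: list[ExpectedCall] = []
    for idx, item in enumerate(spec.items):
        exp = _expected_for_item(spec, placed, idx, rules, mode)
        if exp is not None:
            calls.append(exp)

    if mode == "genome":
        calls.extend(_hdr2_truth(spec, placed, calls, rules))

    roles: dict[tuple[str, str], tuple[str, ...]] = {}
    for g in placed:
        if not g.role:
            continue
        item = spec.items[g.item_index] if g.item_index >= 0 else None
        ab = item.ablation if item else None
        if (
            item
            and ab
            and ab.kind == "motif_ablate"
            and g.role == CATALYTIC[item.complex_name]
        ):
            if g.role in {"HydA", "HytA"}:
                roles[(spec.genome_id, g.gene_id)] = (
                    ("HylA",) if _ablates_all_required(item.complex_name, ab) else ()
                )
            elif g.role == "FdhA":
                roles[(spec.genome_id, g.gene_id)] = ("FdhF2",)
            else:  # MvhA loses both motifs -> no surviving role
                roles[(spec.genome_id, g.gene_id)] = ()
        else:
            roles[(spec.genome_id, g.gene_id)] = _surviving_roles(g.role)
    return calls, roles


def _hdr2_truth(
    spec: GenomeSpec, placed: list[_Placed], item_calls: list[ExpectedCall], rules: RuleSet
) -> list[ExpectedCall]:
    """Leftover-accounting expectation under the shared policy."""
    pool = _shared_pool(spec, placed)
    counts = {r: len(pool.get(r, [])) for r in ("HdrA", "HdrB", "HdrC")}
    complete = min(counts.values())
    partners = [
        c
        for c in item_calls
        if c.bf_flag == "bifurcating" and c.complex_name in {"Mvh", "Fdh", "Met"}
    ]
    # skip sets already claimed as a planted Hdr2 item
    planted_hdr2 = {
        c.catalytic_gene for c in item_calls if c.complex_name == "Hdr2"
    }
    reserved = 1 if partners else 0
    leftover = complete - reserved - len(planted_hdr2)
    if leftover <= 0:
        return []
    # leftover sets come from extra_hdr_sets blocks (B and C adjacent)
    out = []
    extra_a = [
        g
        for g in pool.get("HdrA", [])
        if g.item_index == -1 and g.gene_id not in planted_hdr2
    ]
    for g in extra_a[:leftover]:
        out.append(
            ExpectedCall(spec.genome_id, "Hdr2", "bifurcating", g.gene_id, item_index=-1)
        )
    return out


# ---------------------------------------------------------------------------
# metagenome generation
# ---------------------------------------------------------------------------


def generate_metagenome(
    specs: list[GenomeSpec],
    fragmentation: float = 12.0,
    baits: BaitSet | None = None,
    rules: RuleSet | None = None,
    motif_config: MotifConfig | None = None,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Genome], TruthTable]:
    """Fragmented contig sets with truth recomputed under metagenome rules.

    Replicons are split at random ORF boundaries (geometric contig
    lengths with the given mean); an item whose relaxed complement
    lands intact on one contig stays bifurcating, split operons become
    non-bifurcating (or uncallable) exactly as the contig-level rules
    dictate.  ``fragmentation=inf`` performs no splitting.
    """
    from .core_io import read_ruleset
    from .homology import ScoringScheme
    from .motifs import read_motif_config

    rules = rules or read_ruleset()
    motif_config = motif_config or read_motif_config()
    baits = baits or make_default_baits(motif_config)
    rng = np.random.default_rng(seed)
    aligner = ScoringScheme().build_aligner()

    genomes: list[Genome] = []
    expected_calls: list[ExpectedCall] = []
    expected_roles: dict[tuple[str, str], tuple[str, ...]] = {}

    p_break = 0.0 if not np.isfinite(fragmentation) else 1.0 / max(fragmentation, 1.0)
    for spec in specs:
        placed = _plan_genome(
            spec, rng, baits, rules, motif_config, mutation_rate, aligner
        )
        # split replicons into contigs at random ORF boundaries
        fragmented: list[_Placed] = []
        by_rep: dict[str, list[_Placed]] = {}
        for g in placed:
            by_rep.setdefault(g.replicon_id, []).append(g)
        for rep_id in sorted(by_rep):
            contig_i, ordinal = 0, 0
            for g in sorted(by_rep[rep_id], key=lambda x: x.ordinal):
                ng = _Placed(**vars(g))
                ng.replicon_id = f"{rep_id}.c{contig_i}"
                ng.ordinal = ordinal
                fragmented.append(ng)
                ordinal += 1
                if p_break and rng.random() < p_break:
                    contig_i += 1
                    ordinal = 0
        genome = _assemble(spec, fragmented)
        genome.is_metagenome = True
        genomes.append(genome)
        calls, roles = _genome_truth(spec, fragmented, rules, mode="metagenome")
        expected_calls.extend(calls)
        expected_roles.update(roles)
    return genomes, TruthTable(expected_calls, expected_roles)


# ---------------------------------------------------------------------------
# co-evolution alignment simulator
# ---------------------------------------------------------------------------


def generate_coevolution_alignments(
    n_taxa: int,
    shared_signal: float,
    length: int = 300,
    seed: int = 0,
    rate_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[dict[str, str], dict[str, str]]:
    """Two alignments over one taxon set with tunable shared structure.

    A fraction *shared_signal* of columns evolves identically in both
    alignments (one realization of per-taxon divergence from a master
    sequence); the remaining columns evolve independently per
    alignment.  The two p-distance matrices are therefore exactly
    equal at ``shared_signal=1`` and independent at 0, with expected
    Mantel correlation increasing in between.
    """
    if n_taxa < 4:
        raise BfscanError("need at least 4 taxa")
    if not (0 <= shared_signal <= 1):
        raise BfscanError("shared_signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_signal * length))
    master = rng.integers(0, 20, size=length)
    labels = [f"t{i:02d}" for i in range(n_taxa)]

    def evolve(segment: np.ndarray, rates: np.ndarray, gen: np.random.Generator):
        seqs = []
        for rate in rates:
            s = segment.copy()
            hit = gen.random(len(segment)) < rate
            shift = gen.integers(1, 20, size=len(segment))
            s[hit] = (s[hit] + shift[hit]) % 20
            seqs.append(s)
        return seqs

    shared_rates = rng.uniform(*rate_range, size=n_taxa)
    shared_seqs = evolve(master[:n_shared], shared_rates, rng)

    alignments = []
    for _k in range(2):
        rates = rng.uniform(*rate_range, size=n_taxa)
        indep = evolve(master[n_shared:], rates, rng)
        aln = {
            lab: "".join(_AA[np.concatenate([shared_seqs[i], indep[i]]).astype(int)])
            for i, lab in enumerate(labels)
        }
        alignments.append(aln)
    return alignments[0], alignments[1]


# ---------------------------------------------------------------------------
# default study set and scoring
# ---------------------------------------------------------------------------


def default_genome_specs(seed: int = 0) -> list[GenomeSpec]:
    """The shipped demo set: all 12 complexes planted bifurcating, every
    ablation type represented, plus the Hdr2-accounting and shared-EtfAB
    constructions.  Metadata (oxygen class, environment, assembly size)
    is assigned deterministically."""
    rng = np.random.default_rng(seed)

    def meta(oxy: str, env: str) -> GenomeMetadata:
        return GenomeMetadata(
            taxon=f"synthetic taxon {rng.integers(1000):03d}",
            domain="Bacteria" if rng.random() < 0.7 else "Archaea",
            oxygen_class=oxy,
            environment=env,
            assembly_mbp=float(np.round(rng.uniform(2.0, 6.0), 3)),
        )

    envs = [
        "groundwater well",
        "deep subsurface fracture fluid",
        "hydrothermal vent chimney",
        "subsurface sediment core",
        "marine sediment, 3 m below sea floor",
        "hypersaline lagoon",
        "surface water, lake",
        "agricultural soil",
    ]
    bf = [
        GenomeSpec(
            genome_id=f"G{i:02d}_{name}_bf",
            items=[PlantedItem(name, "bifurcating")],
            metadata=meta("anaerobe" if i % 5 else "facultative", envs[i % len(envs)]),
        )
        for i, name in enumerate(
            ["Hyd", "Mvh", "Fdh", "Hyt", "Nfn", "Fix", "Bcd", "Car", "Hyl", "Ldh", "Hdr2", "Met"]
        )
    ]
    ablated = [
        GenomeSpec(
            "G12_Hyd_dropB",
            [PlantedItem("Hyd", "non_bifurcating", Ablation("drop_subunit", role="HydB"))],
            metadata=meta("anaerobe", envs[0]),
        ),
        GenomeSpec(
            "G13_Hyd_oowB",
            [PlantedItem("Hyd", "non_bifurcating", Ablation("out_of_window", role="HydB", offset=3))],
            metadata=meta("aerobe", envs[6]),
        ),
        GenomeSpec(
            "G14_Hyd_noL1",
            [PlantedItem("Hyd", "decoy", Ablation("motif_ablate", motif="L1,L2,L3"))],
            metadata=meta("anaerobe", envs[1]),
        ),
        GenomeSpec(
            "G15_Fdh_noSig",
            [PlantedItem("Fdh", "decoy", Ablation("motif_ablate", motif="CysSig"))],
            hdr_adjacent=False,
            metadata=meta("anaerobe", envs[2]),
        ),
        GenomeSpec(
            "G16_Mvh_dropHdrC",
            [PlantedItem("Mvh", "non_bifurcating", Ablation("drop_subunit", role="HdrC"))],
            metadata=meta("anaerobe", envs[3]),
        ),
        GenomeSpec(
            "G17_Mvh_noL1",
            [PlantedItem("Mvh", "decoy", Ablation("motif_ablate", motif="L1"))],
            hdr_adjacent=False,
            metadata=meta("anaerobe", envs[4]),
        ),
        GenomeSpec(
            "G18_Met_oowV",
            [PlantedItem("Met", "non_bifurcating", Ablation("out_of_window", role="MetV", offset=2))],
            hdr_adjacent=False,
            metadata=meta("anaerobe", envs[5]),
        ),
    ]
    special = [
        GenomeSpec(
            "G19_Mvh_hdr2",
            [PlantedItem("Mvh", "bifurcating")],
            extra_hdr_sets=1,
            metadata=meta("anaerobe", envs[1]),
        ),
        GenomeSpec(
            "G20_BcdLdh_shared",
            [PlantedItem("Bcd", "bifurcating"), PlantedItem("Ldh", "bifurcating")],
            share_etf=True,
            metadata=meta("anaerobe", envs[7]),
        ),
    ]
    return bf + ablated + special


@dataclass(frozen=True)
class RecoveryScore:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    nonbf_expected: int
    nonbf_recovered: int


def score_calls(truth: TruthTable, calls) -> RecoveryScore:
    """Planted-truth recovery of the caller's output.

    Precision/recall are computed over bifurcating calls, identified by
    (genome, complex, catalytic gene).  Expected non-bifurcating
    bookkeeping calls are checked for presence (a planted violation
    must surface as its predicted non-Bf call, never as bifurcating).
    """
    expected_bf = truth.bifurcating()
    got_bf = {
        (c.genome_id, c.complex_name, c.catalytic_gene)
        for c in calls
        if c.is_bifurcating
    }
    tp = len(expected_bf & got_bf)
    fp = len(got_bf - expected_bf)
    fn = len(expected_bf - got_bf)
    got_nonbf = {
        (c.genome_id, c.complex_name, c.catalytic_gene)
        for c in calls
        if not c.is_bifurcating
    }
    nb = truth.non_bifurcating()
    nb_found = sum(
        1
        for e in nb
        if (e.genome_id, e.complex_name, e.catalytic_gene) in got_nonbf
    )
    return RecoveryScore(
        precision=tp / (tp + fp) if (tp + fp) else 1.0,
        recall=tp / (tp + fn) if (tp + fn) else 1.0,
        tp=tp,
        fp=fp,
        fn=fn,
        nonbf_expected=len(nb),
        nonbf_recovered=nb_found,
    )
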