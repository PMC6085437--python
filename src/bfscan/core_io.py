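"""Data model and readers/writers for genomes, baits, rules and metadata.

The pipeline works on annotated proteomes: each genome (or metagenome
assembly) is an ordered collection of gene records per replicon/contig,
each record carrying its protein sequence.  Complex-calling logic is
expressed entirely in open-reading-frame ranks (``ordinal``), never in
base-pair distances, because the screening rules count ORFs between the
catalytic gene and its companion subunits.

Canonical fixture formats are plain text: protein FASTA plus a 6-column
feature TSV (``genome_id, replicon_id, gene_id, start, end, strand``).
GFF3 (CDS features with ``ID``/``protein_id`` attributes) is accepted as
an alternative feature input.  Rules and motifs ship as JSON.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

#: environment groups treated as subsurface; all other groups are surface
SUBSURFACE_GROUPS = frozenset(
    {
        "groundwater",
        "deep_subsurface",
        "hydrothermal_vents_springs",
        "subsurface_sediments",
        "deep_marine_sediments",
    }
)

VALID_GROUPS = SUBSURFACE_GROUPS | {
    "saline",
    "surface_water",
    "soil",
    "other",
}


class BfscanError(Exception):
    """Base class for fatal input/validation errors."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One annotated protein-coding gene on a replicon.

    ``ordinal`` is the 0-based rank of the gene along its replicon by
    ascending start coordinate; neighborhood windows are differences of
    ordinals.  ``start``/``end`` are 1-based inclusive nucleotide
    coordinates (GFF3 convention).  ``protein`` may be empty for
    pseudogenes.
    """

    gene_id: str
    replicon_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise BfscanError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise BfscanError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        bad = set(self.protein) - AA_ALPHABET
        if bad:
            raise BfscanError(
                f"gene {self.gene_id}: illegal residue(s) {sorted(bad)}"
            )


@dataclass
class GenomeMetadata:
    taxon: str = "unknown"
    domain: str = "Bacteria"
    oxygen_class: str = "unknown"
    environment: str = ""
    assembly_mbp: float = 1.0

    def __post_init__(self) -> None:
        if self.domain not in {"Archaea", "Bacteria", "Eukarya", "unknown"}:
            raise BfscanError(f"unknown taxonomic domain {self.domain!r}")
        if self.oxygen_class not in {"aerobe", "anaerobe", "facultative", "unknown"}:
            raise BfscanError(f"unknown oxygen class {self.oxygen_class!r}")
        if self.assembly_mbp <= 0:
            raise BfscanError("assembly_mbp must be > 0")


@dataclass
class Genome:
    """An annotated (meta)genome: ordered gene records per replicon."""

    genome_id: str
    replicons: dict[str, list[GeneRecord]]
    metadata: GenomeMetadata = field(default_factory=GenomeMetadata)
    is_metagenome: bool = False

    def __post_init__(self) -> None:
        for rep_id, genes in self.replicons.items():
            ordinals = [g.ordinal for g in genes]
            if sorted(ordinals) != list(range(len(genes))):
                raise BfscanError(
                    f"{self.genome_id}/{rep_id}: ordinals are not 0..n-1"
                )
            for g in genes:
                if g.replicon_id != rep_id:
                    raise BfscanError(
                        f"{self.genome_id}: gene {g.gene_id} filed under "
                        f"{rep_id} but claims replicon {g.replicon_id}"
                    )

    def genes(self) -> Iterable[GeneRecord]:
        for rep_id in self.replicons:
            yield from self.replicons[rep_id]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.replicons.values())

    @property
    def total_residues(self) -> int:
        return sum(len(g.protein) for g in self.genes())


@dataclass
class BaitSet:
    """Representative bait protein(s) per subunit role."""

    baits: dict[str, list[tuple[str, str]]]  # role -> [(accession, sequence)]

    def roles(self) -> list[str]:
        return sorted(self.baits)

    def sequences(self, role: str) -> list[tuple[str, str]]:
        try:
            return self.baits[role]
        except KeyError:
            raise BfscanError(f"no bait for subunit role {role!r}") from None

    def validate_against(self, rules: "RuleSet") -> None:
        missing = sorted(set(rules.all_roles()) - set(self.baits))
        if missing:
            raise BfscanError(f"roles without baits: {missing}")


# -- rule model -------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """Where a companion gene may sit relative to the catalytic gene.

    kind ``orf``    : within ±k ORFs on the same replicon,
    kind ``all``    : anywhere in the genome,
    kind ``paired`` : within ±k ORFs of a named sibling companion.
    """

    kind: str
    k: int = 0
    sibling: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"orf", "all", "paired"}:
            raise BfscanError(f"unknown window kind {self.kind!r}")
        if self.k < 0:
            raise BfscanError(f"window k must be >= 0, got {self.k}")
        if self.kind == "paired" and not self.sibling:
            raise BfscanError("paired window requires a sibling role")


@dataclass(frozen=True)
class Companion:
    role: str
    window: Window
    required: bool = True


@dataclass
class ComplexRule:
    """Subunit-complement rule for one enzyme complex."""

    name: str
    label: str
    catalytic_role: str
    companions: list[Companion]
    special: str | None = None  # "hdr2" marks the leftover-accounting complex
    metagenome: dict | None = None  # None=full rules; {"disabled": True} or
    # {"companions": [Companion,...]} (replacement companion list)

    def required_companions(self) -> list[Companion]:
        return [c for c in self.companions if c.required]


@dataclass
class RuleSet:
    """Declarative per-complex subunit complements, windows and thresholds."""

    complexes: list[ComplexRule]
    thresholds: dict[str, float]  # role -> maximum E-value
    shared_roles: frozenset = frozenset({"EtfA", "EtfB", "MvhD"})

    def __post_init__(self) -> None:
        seen = set()
        for c in self.complexes:
            if c.name in seen:
                raise BfscanError(f"duplicate complex {c.name}")
            seen.add(c.name)
        for role, thr in self.thresholds.items():
            if thr <= 0:
                raise BfscanError(f"threshold for {role} must be > 0")
        for c in self.complexes:
            for role in [c.catalytic_role] + [x.role for x in c.companions]:
                if role not in self.thresholds:
                    raise BfscanError(
                        f"complex {c.name}: role {role} has no E-value threshold"
                    )

    def all_roles(self) -> list[str]:
        roles = set()
        for c in self.complexes:
            roles.add(c.catalytic_role)
            roles.update(x.role for x in c.companions)
        return sorted(roles)

    def threshold(self, role: str) -> float:
        try:
            return self.thresholds[role]
        except KeyError:
            raise BfscanError(f"no E-value threshold for role {role!r}") from None

    def complex(self, name: str) -> ComplexRule:
        for c in self.complexes:
            if c.name == name:
                return c
        raise KeyError(name)

    def complex_names(self) -> list[str]:
        return [c.name for c in self.complexes]


@dataclass(frozen=True)
class EnvironmentLabel:
    """Environment group plus its surface/subsurface class."""

    group: str
    surface_class: str = ""

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise BfscanError(f"unknown environment group {self.group!r}")
        expected = "subsurface" if self.group in SUBSURFACE_GROUPS else "surface"
        if not self.surface_class:
            object.__setattr__(self, "surface_class", expected)
        elif self.surface_class != expected:
            raise BfscanError(
                f"group {self.group} implies {expected}, got {self.surface_class}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["genome_id", "replicon_id", "gene_id", "start", "end", "strand"]


def _read_features_tsv(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != FEATURE_COLUMNS:
            raise BfscanError(
                f"{path}: expected header {FEATURE_COLUMNS}, got {header}"
            )
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(FEATURE_COLUMNS):
                raise BfscanError(f"{path}:{ln}: expected 6 columns")
            row = dict(zip(FEATURE_COLUMNS, parts))
            row["start"] = int(row["start"])
            row["end"] = int(row["end"])
            rows.append(row)
    return rows


def _read_features_gff3(path: Path) -> list[dict]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    rows = []
    for feat in db.features_of_type("CDS"):
        attrs = feat.attributes
        gene_id = (attrs.get("protein_id") or attrs.get("ID") or [None])[0]
        if gene_id is None:
            raise BfscanError(f"{path}: CDS without ID/protein_id at {feat.start}")
        rows.append(
            {
                "genome_id": "",
                "replicon_id": feat.seqid,
                "gene_id": gene_id,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
            }
        )
    return rows


def read_genome_bundle(
    fasta_path: str | Path,
    features_path: str | Path,
    metadata: GenomeMetadata | Mapping | None = None,
    genome_id: str | None = None,
    is_metagenome: bool = False,
) -> Genome:
    """Assemble a validated :class:`Genome` from FASTA + feature table.

    Ordinals are assigned by ascending start coordinate within each
    replicon, so the row order of the feature file is irrelevant.  FASTA
    entries without a feature row are ignored with a warning; a feature
    row without a FASTA entry is an error.
    """
    fasta_path, features_path = Path(fasta_path), Path(features_path)
    if not features_path.exists():
        raise BfscanError(f"feature file not found: {features_path}")
    if features_path.suffix.lower() in {".gff", ".gff3"}:
        rows = _read_features_gff3(features_path)
    else:
        rows = _read_features_tsv(features_path)
    if not rows:
        raise BfscanError(f"{features_path}: no features")

    proteins = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    gid = genome_id or next((r["genome_id"] for r in rows if r["genome_id"]), None)
    if gid is None:
        gid = fasta_path.stem

    seen_ids: set[str] = set()
    missing: list[str] = []
    by_replicon: dict[str, list[dict]] = {}
    for row in rows:
        if row["gene_id"] in seen_ids:
            raise BfscanError(f"duplicate gene_id {row['gene_id']!r}")
        seen_ids.add(row["gene_id"])
        if row["gene_id"] not in proteins:
            missing.append(row["gene_id"])
        by_replicon.setdefault(row["replicon_id"], []).append(row)
    if missing:
        raise BfscanError(
            f"features reference proteins absent from FASTA: {sorted(missing)}"
        )
    unmatched = set(proteins) - seen_ids
    if unmatched:
        logger.warning(
            "%s: %d FASTA entries without features ignored", gid, len(unmatched)
        )

    if isinstance(metadata, Mapping):
        metadata = GenomeMetadata(**metadata)
    replicons: dict[str, list[GeneRecord]] = {}
    for rep_id in sorted(by_replicon):
        ordered = sorted(by_replicon[rep_id], key=lambda r: (r["start"], r["end"]))
        replicons[rep_id] = [
            GeneRecord(
                gene_id=r["gene_id"],
                replicon_id=rep_id,
                ordinal=i,
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                protein=proteins[r["gene_id"]],
            )
            for i, r in enumerate(ordered)
        ]
    return Genome(
        genome_id=gid,
        replicons=replicons,
        metadata=metadata or GenomeMetadata(),
        is_metagenome=is_metagenome,
    )


def write_genome_bundle(genome: Genome, fasta_path: str | Path, features_path: str | Path) -> None:
    """Write a genome back to FASTA + feature TSV (round-trip safe)."""
    with open(fasta_path, "w") as fh:
        for g in genome.genes():
            fh.write(f">{g.gene_id}\n{g.protein}\n")
    with open(features_path, "w") as fh:
        fh.write("\t".join(FEATURE_COLUMNS) + "\n")
        for g in genome.genes():
            fh.write(
                f"{genome.genome_id}\t{g.replicon_id}\t{g.gene_id}\t"
                f"{g.start}\t{g.end}\t{g.strand}\n"
            )


def read_metadata_table(path: str | Path) -> dict[str, GenomeMetadata]:
    """Read the sample metadata TSV keyed by genome_id."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"genome_id", "taxon", "domain", "oxygen_class", "environment", "assembly_mbp"}
    if not need <= set(df.columns):
        raise BfscanError(f"{path}: metadata columns must include {sorted(need)}")
    out = {}
    for _, row in df.iterrows():
        out[row["genome_id"]] = GenomeMetadata(
            taxon=row["taxon"],
            domain=row["domain"],
            oxygen_class=row["oxygen_class"],
            environment=row["environment"] if isinstance(row["environment"], str) else "",
            assembly_mbp=float(row["assembly_mbp"]),
        )
    return out


def read_baits(path: str | Path, role_map: Mapping[str, str] | None = None) -> BaitSet:
    """Read bait FASTA; record IDs are ``<accession>|<role>`` unless a
    role_map (record id -> role) is given."""
    baits: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if role_map is not None:
            role = role_map.get(rec.id)
            if role is None:
                logger.warning("bait %s has no role mapping; skipped", rec.id)
                continue
            acc = rec.id
        else:
            if "|" not in rec.id:
                raise BfscanError(
                    f"bait id {rec.id!r} is not '<accession>|<role>'"
                )
            acc, role = rec.id.rsplit("|", 1)
        baits.setdefault(role, []).append((acc, str(rec.seq).upper()))
    return BaitSet(baits)


# -- rule config ------------------------------------------------------------

_WINDOW_RE = re.compile(r"^±?\+?-?(\d+)$")


def _parse_window(obj, where: str) -> Window:
    if isinstance(obj, str):
        token = obj.strip()
        if token.upper() == "ALL":
            return Window("all")
        m = _WINDOW_RE.match(token.replace("+/-", "±"))
        if not m or (token.lstrip("±+").startswith("-")):
            raise BfscanError(f"{where}: unknown window token {obj!r}")
        return Window("orf", k=int(m.group(1)))
    if isinstance(obj, Mapping):
        kind = obj.get("type")
        if kind == "all":
            return Window("all")
        if kind == "orf":
            return Window("orf", k=int(obj["k"]))
        if kind == "paired":
            return Window("paired", k=int(obj["k"]), sibling=obj["sibling"])
    raise BfscanError(f"{where}: unknown window spec {obj!r}")


def _parse_companions(items: Sequence[Mapping], where: str) -> list[Companion]:
    out = []
    for item in items:
        out.append(
            Companion(
                role=item["role"],
                window=_parse_window(item["window"], f"{where}/{item['role']}"),
                required=bool(item.get("required", True)),
            )
        )
    return out


def read_ruleset(path: str | Path | None = None) -> RuleSet:
    """Load the rule config (shipped default when *path* is None).

    The shipped default encodes the twelve biochemically confirmed
    bifurcating complexes: per-complex catalytic subunit, companion
    subunits with their ORF windows, per-role E-value cut-offs, and the
    metagenome-mode relaxations.
    """
    if path is None:
        text = resources.files("bfscan.data").joinpath("rules.json").read_text()
    else:
        text = Path(path).read_text()
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BfscanError(f"rule config is not valid JSON: {exc}") from exc

    thresholds = {}
    for role, thr in cfg["role_thresholds"].items():
        thr = float(thr)
        if thr <= 0:
            raise BfscanError(f"role_thresholds/{role}: non-positive threshold {thr}")
        thresholds[role] = thr

    complexes = []
    for c in cfg["complexes"]:
        where = f"complex {c.get('name', '?')}"
        meta = c.get("metagenome")
        if meta is not None and not meta.get("disabled"):
            meta = {"companions": _parse_companions(meta["companions"], where)}
        complexes.append(
            ComplexRule(
                name=c["name"],
                label=c.get("label", c["name"]),
                catalytic_role=c["catalytic"],
                companions=_parse_companions(c["companions"], where),
                special=c.get("special"),
                metagenome=meta,
            )
        )
    shared = frozenset(cfg.get("shared_roles", ["EtfA", "EtfB", "MvhD"]))
    return RuleSet(complexes=complexes, thresholds=thresholds, shared_roles=shared)


def default_bait_path() -> Path:
    with resources.as_file(
        resources.files("bfscan.data").joinpath("baits_synthetic.fasta")
    ) as p:
        return Path(p)


def read_default_baits() -> BaitSet:
    return read_baits(default_bait_path())
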