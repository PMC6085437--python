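"""End-to-end orchestration: read -> search -> screen -> call -> statistics.

Every stage emits a self-describing TSV (leading ``#`` comment lines
carry column semantics and the configuration hash) so a run is fully
reproducible and diff-able.  Reruns with identical inputs and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance as ab
from . import caller, cooccur, homology
from .core_io import (
    BfscanError,
    Genome,
    read_baits,
    read_genome_bundle,
    read_metadata_table,
    read_ruleset,
)
from .motifs import read_motif_config

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    rules_path: str | None = None
    motifs_path: str | None = None
    env_map_path: str | None = None
    baits_path: str | None = None
    backend: str = "internal"
    metagenome: bool = False
    sharing_policy: str = "shared"
    include_non_bf_abundance: bool = False
    alpha: float = 0.05
    seed: int = 0
    stages: tuple[str, ...] = ("search", "call", "cooccur", "abundance", "summarize")

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise BfscanError(f"input_dir does not exist: {self.input_dir}")
        for name in ("rules_path", "motifs_path", "env_map_path", "baits_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise BfscanError(f"{name} does not exist: {p}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        payload["stages"] = list(self.stages)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_input_dir(input_dir: str | Path, metagenome: bool = False) -> list[Genome]:
    """Load every ``<id>.faa`` + ``<id>.features.tsv`` pair, joining
    ``metadata.tsv`` when present."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.tsv"
    metadata = read_metadata_table(meta_path) if meta_path.exists() else {}
    genomes = []
    for fasta in sorted(input_dir.glob("*.faa")):
        gid = fasta.stem
        features = input_dir / f"{gid}.features.tsv"
        genomes.append(
            read_genome_bundle(
                fasta,
                features,
                metadata=metadata.get(gid),
                genome_id=gid,
                is_metagenome=metagenome,
            )
        )
    if not genomes:
        raise BfscanError(f"no genome bundles (*.faa) found in {input_dir}")
    return genomes


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    head = [f"config_hash={chash}", f"seed={config.seed}"]

    rules = read_ruleset(config.rules_path)
    motif_config = read_motif_config(config.motifs_path)
    if config.baits_path is not None:
        baits = read_baits(config.baits_path)
    else:
        from .core_io import read_default_baits

        baits = read_default_baits()
    classifier = ab.EnvironmentClassifier.from_config(config.env_map_path)

    genomes = load_input_dir(config.input_dir, metagenome=config.metagenome)
    logger.info("loaded %d genomes (%d genes)", len(genomes), sum(g.n_genes for g in genomes))

    # search + motif screen ------------------------------------------------
    all_calls: list[caller.ComplexCall] = []
    n_hits = n_screened = 0
    for genome in genomes:
        hits = homology.search_homologs(genome, baits, rules, backend=config.backend)
        n_hits += len(hits)
        proteins = {g.gene_id: g.protein for g in genome.genes()}
        screened = homology.screen_hits(hits, proteins, motif_config)
        n_screened += len(screened)
        all_calls.extend(
            caller.call_all(genome, screened, rules, sharing_policy=config.sharing_policy)
        )
    logger.info(
        "search: %d hits passed thresholds, %d survived motif screens; %d calls",
        n_hits,
        n_screened,
        len(all_calls),
    )

    calls_df = caller.calls_to_dataframe(all_calls)
    _write_tsv(
        calls_df,
        out / "calls.tsv",
        head + ["one row per complex call; members are role=gene_id pairs"],
    )

    presence = caller.build_presence_matrix(
        all_calls, [g.genome_id for g in genomes], rules.complex_names()
    )
    _write_tsv(
        presence.reset_index(),
        out / "presence.tsv",
        head + ["binary genome x complex table (bifurcating calls only)"],
    )

    if "cooccur" in config.stages:
        informative = presence[presence.sum(axis=1) >= 1]
        if len(informative) >= 2:
            results = cooccur.cooccur_analysis(informative, alpha=config.alpha)
            _write_tsv(
                cooccur.results_to_dataframe(results),
                out / "cooccur.tsv",
                head
                + [
                    "hypergeometric pairwise co-occurrence over genomes with >=1 call",
                    f"alpha={config.alpha} (two one-sided tests)",
                ],
            )

    if "abundance" in config.stages:
        rows = []
        for genome in genomes:
            env = None
            if genome.metadata.environment:
                env = classifier.classify(genome.metadata.environment)
            rec = ab.abundance_per_mbp(
                [c for c in all_calls if c.genome_id == genome.genome_id],
                genome.metadata.assembly_mbp,
                sample_id=genome.genome_id,
                environment=env,
                include_non_bifurcating=config.include_non_bf_abundance,
            )
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "env_group": env.group if env else "other",
                    "surface_class": env.surface_class if env else "surface",
                    "assembly_mbp": rec.assembly_mbp,
                    "n_bf_calls": sum(rec.counts.values()),
                    "total_per_mbp": rec.total_per_mbp,
                }
            )
        abundance_df = pd.DataFrame(rows)
        _write_tsv(
            abundance_df,
            out / "abundance.tsv",
            head + ["bifurcating-call counts normalized to assembled Mbp"],
        )

    if "summarize" in config.stages:
        metadata = {g.genome_id: g.metadata for g in genomes}
        tables = summarize_results(all_calls, metadata)
        for name, df in tables.items():
            _write_tsv(df, out / f"summary_{name}.tsv", head + [f"summary table: {name}"])

    (out / "run.log").write_text(
        f"# config_hash={chash}\nstages={','.join(config.stages)}\n"
        f"genomes={len(genomes)}\nhits={n_hits}\nscreened={n_screened}\n"
        f"calls={len(all_calls)}\n"
    )
    return out


def summarize_results(calls, metadata) -> dict[str, pd.DataFrame]:
    """Figure-level tabulations from a call list + per-genome metadata.

    ``bf_fraction``: percent of each complex's catalytic homologs that
    are predicted to bifurcate; ``oxygen``: oxygen-class percentage
    breakdown of bifurcating calls; ``env_abundance``: mean per-Mbp
    abundance of bifurcating calls per environment group.
    """
    rows = []
    by_complex: dict[str, dict[str, int]] = {}
    for c in calls:
        d = by_complex.setdefault(c.complex_name, {"bf": 0, "non_bf": 0})
        d["bf" if c.is_bifurcating else "non_bf"] += 1
    for name in sorted(by_complex):
        d = by_complex[name]
        total = d["bf"] + d["non_bf"]
        rows.append(
            {
                "complex": name,
                "n_bf": d["bf"],
                "n_non_bf": d["non_bf"],
                "pct_bf": 100.0 * d["bf"] / total if total else 0.0,
            }
        )
    bf_fraction = pd.DataFrame(rows, columns=["complex", "n_bf", "n_non_bf", "pct_bf"])

    oxy_rows = []
    classes = ["aerobe", "anaerobe", "facultative", "unknown"]
    by_oxy: dict[str, dict[str, int]] = {}
    for c in calls:
        if not c.is_bifurcating:
            continue
        meta = metadata.get(c.genome_id)
        oxy = meta.oxygen_class if meta is not None else "unknown"
        if meta is None:
            logger.warning("no metadata for %s; counted as unknown", c.genome_id)
        by_oxy.setdefault(c.complex_name, {k: 0 for k in classes})[oxy] += 1
    for name in sorted(by_oxy):
        d = by_oxy[name]
        total = sum(d.values())
        row = {"complex": name, "n_bf": total}
        for k in classes:
            row[f"pct_{k}"] = 100.0 * d[k] / total if total else 0.0
        oxy_rows.append(row)
    oxygen = pd.DataFrame(
        oxy_rows, columns=["complex", "n_bf"] + [f"pct_{k}" for k in classes]
    )

    env_rows = []
    classifier = ab.EnvironmentClassifier.from_config()
    per_genome: dict[str, int] = {}
    for c in calls:
        if c.is_bifurcating:
            per_genome[c.genome_id] = per_genome.get(c.genome_id, 0) + 1
    groups: dict[str, list[float]] = {}
    for gid, meta in metadata.items():
        env = classifier.classify(meta.environment) if meta.environment else None
        group = env.group if env else "other"
        groups.setdefault(group, []).append(
            per_genome.get(gid, 0) / meta.assembly_mbp
        )
    for group in sorted(groups):
        vals = groups[group]
        env_rows.append(
            {
                "env_group": group,
                "n_samples": len(vals),
                "mean_per_mbp": sum(vals) / len(vals),
            }
        )
    env_abundance = pd.DataFrame(
        env_rows, columns=["env_group", "n_samples", "mean_per_mbp"]
    )
    return {
        "bf_fraction": bf_fraction,
        "oxygen": oxygen,
        "env_abundance": env_abundance,
    }


def write_demo_input(out_dir: str | Path, seed: int = 0, mutation_rate: float = 0.0) -> Path:
    """Materialize the shipped synthetic demo set as an input directory."""
    from .core_io import write_genome_bundle
    from .synth import default_genome_specs, generate_genome_set

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = default_genome_specs(seed)
    genomes, truth = generate_genome_set(specs, mutation_rate=mutation_rate, seed=seed)
    meta_rows = []
    for g in genomes:
        write_genome_bundle(
            g, out_dir / f"{g.genome_id}.faa", out_dir / f"{g.genome_id}.features.tsv"
        )
        m = g.metadata
        meta_rows.append(
            f"{g.genome_id}\t{m.taxon}\t{m.domain}\t{m.oxygen_class}\t"
            f"{m.environment}\t{m.assembly_mbp}"
        )
    (out_dir / "metadata.tsv").write_text(
        "genome_id\ttaxon\tdomain\toxygen_class\tenvironment\tassembly_mbp\n"
        + "\n".join(meta_rows)
        + "\n"
    )
    truth.to_dataframe().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir
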