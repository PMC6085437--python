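"""Environment classification, per-Mbp abundance, and E-value diversity.

Metagenome samples are classified from free-text environment metadata
into eight groups, each deterministically mapped to a ``surface`` or
``subsurface`` class (groundwater, deep subsurface, hydrothermal
vents/springs, subsurface sediments and marine sediments deeper than
1 m below sea floor are subsurface; everything else, including saline
systems, surface waters and soils, is surface).  Complex-call counts
are normalized to assembled megabase pairs so samples of different
sequencing depth are comparable, and the surface/subsurface abundance
contrast is tested with Welch's two-sample t-test.

Homolog diversity within a catalytic-subunit family is summarized by
pairwise search E-values transformed as ``t = -1e4 * E``: lower
distributions of *t* indicate more diverse (less mutually similar)
homolog sets.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import BfscanError, EnvironmentLabel
from .homology import EValueParams, ScoringScheme, local_align_score

DIVERSITY_SCALE = -1e4  # printed transform of pairwise E-values

_DEPTH_RE = re.compile(r"(\d+(?:\.\d+)?)\s*m\s+below\s+(?:the\s+)?sea\s*floor")


class EnvironmentClassifier:
    """First-match keyword classifier over ordered rules."""

    def __init__(self, rules: Sequence[Mapping]):
        self.rules = [(tuple(r["contains"]), r["group"]) for r in rules]

    @classmethod
    def from_config(cls, path: str | Path | None = None) -> "EnvironmentClassifier":
        if path is None:
            text = resources.files("bfscan.data").joinpath("env_groups.json").read_text()
        else:
            text = Path(path).read_text()
        return cls(json.loads(text)["rules"])

    def classify(self, keywords: str) -> EnvironmentLabel:
        if not keywords or not keywords.strip():
            raise BfscanError("environment keywords must be non-empty")
        text = keywords.lower()
        # built-in rule: marine sediments deeper than 1 m below sea floor
        if "marine sediment" in text or "sea floor" in text:
            m = _DEPTH_RE.search(text)
            if m and float(m.group(1)) > 1.0:
                return EnvironmentLabel("deep_marine_sediments")
        for needles, group in self.rules:
            if any(n in text for n in needles):
                return EnvironmentLabel(group)
        return EnvironmentLabel("other")


def classify_environment(
    keywords: str, classifier: EnvironmentClassifier | None = None
) -> EnvironmentLabel:
    if classifier is None:
        classifier = EnvironmentClassifier.from_config()
    return classifier.classify(keywords)


# ---------------------------------------------------------------------------
# per-Mbp abundance
# ---------------------------------------------------------------------------


@dataclass
class AbundanceRecord:
    sample_id: str
    environment: EnvironmentLabel | None
    counts: dict[str, int]
    assembly_mbp: float
    per_mbp: dict[str, float] = field(init=False)
    total_per_mbp: float = field(init=False)

    def __post_init__(self) -> None:
        if self.assembly_mbp <= 0:
            raise BfscanError("assembly_mbp must be > 0")
        self.per_mbp = {k: v / self.assembly_mbp for k, v in self.counts.items()}
        self.total_per_mbp = sum(self.per_mbp.values())


def abundance_per_mbp(
    calls: Iterable,
    assembly_mbp: float,
    sample_id: str = "",
    environment: EnvironmentLabel | None = None,
    include_non_bifurcating: bool = False,
) -> AbundanceRecord:
    """Count complex calls (bifurcating only by default) per Mbp."""
    counts: dict[str, int] = {}
    for c in calls:
        if not include_non_bifurcating and not c.is_bifurcating:
            continue
        counts[c.complex_name] = counts.get(c.complex_name, 0) + 1
    return AbundanceRecord(
        sample_id=sample_id,
        environment=environment,
        counts=counts,
        assembly_mbp=assembly_mbp,
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_1: float
    mean_2: float


def compare_groups(group1: Sequence[float], group2: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (two-sided, unequal variances)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise BfscanError("both groups need n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise BfscanError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_1=float(a.mean()),
        mean_2=float(b.mean()),
    )


# ---------------------------------------------------------------------------
# pairwise E-value diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityDistribution:
    grouping: str  # genome_vs_genome / metagenome_vs_genome
    pairs: list[tuple[str, str, float, float]]  # (query, reference, E, t)

    @property
    def t_values(self) -> np.ndarray:
        return np.array([p[3] for p in self.pairs])

    def summary(self) -> dict[str, float]:
        t = self.t_values
        q1, med, q3 = np.percentile(t, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        return {
            "n_pairs": len(t),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "iqr": float(iqr),
            "n_outliers": int(((t < lo) | (t > hi)).sum()),
        }


def transform_evalue(evalue: float) -> float:
    """The printed diversity transform, t = -1e4 * E (monotone in -E)."""
    if evalue <= 0:
        raise BfscanError("E-value must be positive")
    return DIVERSITY_SCALE * evalue


def pairwise_diversity(
    query_set: Mapping[str, str],
    reference_set: Mapping[str, str] | None = None,
    scoring: ScoringScheme = ScoringScheme(),
    evalue_params: EValueParams = EValueParams(),
) -> DiversityDistribution:
    """All-pairs search E-values within/between homolog sets.

    With *reference_set* None the comparison is all-vs-all within
    *query_set* excluding self-pairs (genome-vs-genome mode); otherwise
    every ordered query->reference pair is scored
    (metagenome-vs-genome mode).  The E-value database size is the
    total residue count of the reference side, mirroring a pooled
    pairwise search.
    """
    if not query_set:
        raise BfscanError("empty query set")
    within = reference_set is None
    refs = dict(query_set) if within else dict(reference_set)
    if not refs:
        raise BfscanError("empty reference set")
    n_db = sum(len(s) for s in refs.values())
    aligner = scoring.build_aligner()
    pairs = []
    for qid in sorted(query_set):
        for rid in sorted(refs):
            if within and qid == rid:
                continue
            score, _ = local_align_score(
                query_set[qid], refs[rid], scoring, aligner=aligner
            )
            e = evalue_params.evalue(score, len(query_set[qid]), n_db)
            pairs.append((qid, rid, e, transform_evalue(e)))
    if not pairs:
        raise BfscanError("no pairs to compare (singleton set in within-mode)")
    return DiversityDistribution(
        grouping="genome_vs_genome" if within else "metagenome_vs_genome",
        pairs=pairs,
    )
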