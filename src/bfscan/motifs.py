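"""Active-site motif grammar and catalytic-subunit screens.

Catalytic-subunit families that pass the homology thresholds are
demarcated by short contiguous active-site motifs: the three L1/L2/L3
H-cluster motifs separate the NAD(H)- and NADP(H)-dependent [FeFe]-
hydrogenase catalytic subunits (HydA/HytA, motifs required) from the
formate-dehydrogenase-associated HylA (motifs must be absent); the two
[NiFe]-hydrogenase motifs demarcate the bifurcating group-3c large
subunit (MvhA); and a four-cysteine signature separates FdhA from its
paralog FdhF2 (signature absent).

Motifs are scanned directly on unaligned sequences: the patterns are
contiguous, so an alignment would only anchor their position, not change
their content.

Pattern grammar
---------------
``C``  uppercase residue: required at that position,
``x``  any residue,
``x26``  26-fold any-residue run,
``c``  lowercase residue: weakly conserved -- required under the
       ``strict`` policy (default), any residue under ``wildcard``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .core_io import BfscanError

logger = logging.getLogger(__name__)

_AA_UPPER = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str
    mode: str = "require"

    def __post_init__(self) -> None:
        if self.mode not in {"require", "require_absence"}:
            raise BfscanError(f"motif {self.name}: unknown mode {self.mode!r}")
        tokens = tokenize(self.pattern)  # validates
        if expanded_length(tokens) < 1:
            raise BfscanError(f"motif {self.name}: empty pattern")

    @property
    def tokens(self) -> list[tuple[str, str | int]]:
        return tokenize(self.pattern)


@dataclass(frozen=True)
class MotifMatch:
    """Outcome of scanning one motif against one sequence."""

    name: str
    matched: bool
    position: int | None = None  # 1-based leftmost start, None if no match


@dataclass
class ScreenResult:
    """Outcome of the per-protein catalytic-role screen."""

    surviving_roles: list[str]
    verdicts: dict[str, list[MotifMatch]] = field(default_factory=dict)

    @property
    def ambiguous(self) -> bool:
        return len(self.surviving_roles) > 1

    @property
    def rejected(self) -> bool:
        return not self.surviving_roles


_TOKEN_RE = re.compile(r"x(\d+)|x|([A-WY])|([a-wyz])|(.)")


def tokenize(pattern: str) -> list[tuple[str, str | int]]:
    """Split a pattern into (kind, value) tokens.

    kinds: ``req`` (required residue), ``weak`` (weakly conserved
    residue), ``any`` (single wildcard), ``run`` (N wildcards).
    """
    tokens: list[tuple[str, str | int]] = []
    for m in _TOKEN_RE.finditer(pattern):
        run, req, weak, bad = m.group(1), m.group(2), m.group(3), m.group(4)
        if run is not None:
            n = int(run)
            if n < 1:
                raise BfscanError(f"pattern {pattern!r}: xN with N < 1")
            tokens.append(("run", n))
        elif req is not None:
            if req not in _AA_UPPER:
                raise BfscanError(f"pattern {pattern!r}: illegal residue {req!r}")
            tokens.append(("req", req))
        elif weak is not None:
            if weak.upper() not in _AA_UPPER:
                raise BfscanError(f"pattern {pattern!r}: illegal residue {weak!r}")
            tokens.append(("weak", weak.upper()))
        elif bad is not None:
            raise BfscanError(f"pattern {pattern!r}: illegal token {bad!r}")
        else:  # bare 'x'
            tokens.append(("any", "x"))
    return tokens


def expanded_length(tokens: Iterable[tuple[str, str | int]]) -> int:
    return sum(t[1] if t[0] == "run" else 1 for t in tokens)


def compile_pattern(motif: Motif, lowercase_policy: str = "strict") -> re.Pattern:
    if lowercase_policy not in {"strict", "wildcard"}:
        raise BfscanError(f"unknown lowercase policy {lowercase_policy!r}")
    parts = []
    for kind, val in motif.tokens:
        if kind == "req":
            parts.append(re.escape(val))
        elif kind == "weak":
            parts.append("." if lowercase_policy == "wildcard" else re.escape(val))
        elif kind == "any":
            parts.append(".")
        else:
            parts.append(f".{{{val}}}")
    return re.compile("".join(parts))


def match_motif(
    sequence: str, motif: Motif, lowercase_policy: str = "strict"
) -> MotifMatch:
    """Scan *sequence* for *motif*; report the leftmost match (1-based)."""
    m = compile_pattern(motif, lowercase_policy).search(sequence.upper())
    if m is None:
        return MotifMatch(motif.name, False, None)
    return MotifMatch(motif.name, True, m.start() + 1)


# ---------------------------------------------------------------------------
# role-level screens
# ---------------------------------------------------------------------------


class MotifConfig:
    """Per-role motif requirements (shipped default = the printed screens)."""

    def __init__(self, roles: Mapping[str, list[Motif]]):
        self.roles: dict[str, list[Motif]] = {k: list(v) for k, v in roles.items()}
        for role, motifs in self.roles.items():
            if not motifs:
                logger.info(
                    "motif screen for %s is empty (no published motif): "
                    "all threshold-passing homologs pass by default",
                    role,
                )

    def screened_roles(self) -> set[str]:
        return set(self.roles)

    def motifs_for(self, role: str) -> list[Motif]:
        try:
            return self.roles[role]
        except KeyError:
            raise BfscanError(
                f"role {role!r} absent from motif configuration"
            ) from None


def read_motif_config(path: str | Path | None = None) -> MotifConfig:
    if path is None:
        text = resources.files("bfscan.data").joinpath("motifs.json").read_text()
    else:
        text = Path(path).read_text()
    cfg = json.loads(text)
    roles = {
        role: [Motif(m["name"], m["pattern"], m.get("mode", "require")) for m in items]
        for role, items in cfg["roles"].items()
    }
    return MotifConfig(roles)


def role_passes(
    protein: str,
    role: str,
    motif_config: MotifConfig,
    lowercase_policy: str = "strict",
) -> tuple[bool, list[MotifMatch]]:
    """Evaluate one role's require / require-absence motif set."""
    verdicts = []
    ok = True
    for motif in motif_config.motifs_for(role):
        res = match_motif(protein, motif, lowercase_policy)
        verdicts.append(res)
        if motif.mode == "require" and not res.matched:
            ok = False
        if motif.mode == "require_absence" and res.matched:
            ok = False
    return ok, verdicts


def screen_catalytic(
    protein: str,
    candidate_roles: Iterable[str],
    motif_config: MotifConfig,
    lowercase_policy: str = "strict",
) -> ScreenResult:
    """Resolve a protein's candidate catalytic roles by motif content.

    Each candidate role's require / require-absence motif set is
    evaluated independently; roles whose screens fail are dropped.  The
    result is order-independent in *candidate_roles*.  More than one
    surviving role is legal (flagged ambiguous) and is resolved later by
    gene context; zero surviving roles is a rejection.
    """
    surviving = []
    verdicts: dict[str, list[MotifMatch]] = {}
    for role in sorted(set(candidate_roles)):
        ok, v = role_passes(protein, role, motif_config, lowercase_policy)
        verdicts[role] = v
        if ok:
            surviving.append(role)
    return ScreenResult(surviving_roles=surviving, verdicts=verdicts)
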