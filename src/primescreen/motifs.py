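"""Signed regulatory networks and priming-motif matching.

Genes annotated with mechanism roles from the expression screen are
placed on a user-supplied signed directed network (SIF-style edge list)
to emit candidate priming motifs, i.e. (x1, x2, x3) triples whose
regulator-to-readout path signs match one of the three mechanism
templates:

- PS: an LD-induced regulator (LD+HD max above HD max) and an
  HD-responsive partner, both with net activating paths to the readout.
- AI: an LD-induced regulator (LD+HD max similar to HD max) with an
  activating path, and an HD-responsive partner with an inhibiting path.
- SD: an LD-reduced suppressor with an inhibiting path, and an LD/HD-
  responsive partner (LD+HD similar to HD) with an activating path.

Paths may be direct or pass through intermediates up to ``max_len``
edges; a pair connected by both activating and inhibiting paths is
emitted with a ``sign_ambiguous`` flag rather than silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

_SIGN_TOKENS = {
    "+": 1, "+1": 1, "1": 1, "activates": 1, "a": 1,
    "-": -1, "-1": -1, "inhibits": -1, "i": -1,
}
_PROVENANCE_RANK = {"direct": 2, "indirect": 1}


class SignedGraph:
    """Directed graph with edge signs in {+1, -1} and provenance tags."""

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    @property
    def nx_graph(self) -> nx.DiGraph:
        return self._g

    def __contains__(self, node: str) -> bool:
        return node in self._g

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> list[tuple[str, str, int, str]]:
        return [
            (u, v, d["sign"], d.get("provenance", "direct"))
            for u, v, d in self._g.edges(data=True)
        ]

    def add_edge(
        self, src: str, dst: str, sign: int, provenance: str = "direct"
    ) -> None:
        if sign not in (1, -1):
            raise ValueError("edge sign must be +1 or -1")
        if provenance not in _PROVENANCE_RANK:
            raise ValueError("provenance must be 'direct' or 'indirect'")
        existing = self._g.get_edge_data(src, dst)
        if existing is not None and existing["sign"] == sign:
            # duplicate: keep the strongest provenance
            if (
                _PROVENANCE_RANK[provenance]
                > _PROVENANCE_RANK[existing["provenance"]]
            ):
                existing["provenance"] = provenance
            return
        self._g.add_edge(src, dst, sign=sign, provenance=provenance)

    def path_signs(self, src: str, dst: str, max_len: int = 3) -> set[int]:
        """Net signs (edge-sign products) of simple paths of <= max_len edges."""
        if src not in self._g or dst not in self._g:
            return set()
        signs: set[int] = set()
        for path in nx.all_simple_paths(self._g, src, dst, cutoff=max_len):
            s = 1
            for u, v in zip(path, path[1:]):
                s *= self._g[u][v]["sign"]
            signs.add(s)
            if signs == {1, -1}:
                break
        return signs

    def shortest_path_len(self, src: str, dst: str, sign: int, max_len: int = 3) -> int | None:
        """Length of the shortest simple path of the given net sign, or None."""
        best = None
        for path in nx.all_simple_paths(self._g, src, dst, cutoff=max_len):
            s = 1
            for u, v in zip(path, path[1:]):
                s *= self._g[u][v]["sign"]
            if s == sign and (best is None or len(path) - 1 < best):
                best = len(path) - 1
        return best


def load_graph(path: str | Path) -> SignedGraph:
    """Read a SIF-style signed edge list.

    Rows are ``source<TAB>sign<TAB>target[<TAB>provenance]`` (whitespace
    separated also accepted); ``sign`` may be ``+``/``-``, ``+1``/``-1``,
    or ``activates``/``inhibits``.  Node names are case-folded for the
    duplicate check but stored as first seen.
    """
    g = SignedGraph()
    canonical: dict[str, str] = {}

    def canon(name: str) -> str:
        key = name.casefold()
        if key not in canonical:
            canonical[key] = name
        return canonical[key]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 fields, got {len(parts)}"
                )
            src, sign_tok, dst = parts[0], parts[1], parts[2]
            prov = parts[3] if len(parts) == 4 else "direct"
            if sign_tok.lower() not in _SIGN_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: malformed sign token {sign_tok!r}"
                )
            g.add_edge(canon(src), canon(dst), _SIGN_TOKENS[sign_tok.lower()], prov)
    return g


@dataclass
class PrimingMotif:
    """A matched (x1, x2, x3) candidate with its mechanism template.

    ``x1`` is the LD-responsive (or LD-reduced) regulator, ``x2`` the
    HD-responsive partner, ``x3`` the readout.
    """

    x1: str
    x2: str
    x3: str
    mechanism: str  # PS | AI | SD
    x1_sign: int
    x2_sign: int
    x1_path_len: int
    x2_path_len: int
    sign_ambiguous: bool = False
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in ("PS", "AI", "SD"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if len({self.x1, self.x2, self.x3}) != 3:
            raise ValueError("motif nodes must be distinct")

    @property
    def total_path_len(self) -> int:
        return self.x1_path_len + self.x2_path_len

    def key(self) -> tuple:
        return (self.mechanism, self.x1, self.x2, self.x3)

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "x1": self.x1,
            "x2": self.x2,
            "x3": self.x3,
            "x1_sign": self.x1_sign,
            "x2_sign": self.x2_sign,
            "x1_path_len": self.x1_path_len,
            "x2_path_len": self.x2_path_len,
            "sign_ambiguous": self.sign_ambiguous,
            "evidence": self.evidence,
        }


# role -> (x1 role needed, x2 role needed, x1 path sign, x2 path sign)
_TEMPLATES = {
    "PS": ("PS-regulator", "HD-partner", 1, 1),
    "AI": ("AI-regulator", "HD-partner", 1, -1),
    "SD": ("SD-suppressor", "HD-partner", -1, 1),
}


def find_motifs(
    graph: SignedGraph,
    roles: dict[str, set[str]],
    readouts: Iterable[str],
    max_len: int = 3,
) -> list[PrimingMotif]:
    """Match role-annotated genes onto the network.

    Parameters
    ----------
    graph
        The signed regulatory network.
    roles
        Mapping gene -> set of role labels among ``PS-regulator``,
        ``AI-regulator``, ``SD-suppressor``, ``HD-partner``.
    readouts
        Candidate readout genes (x3); readouts absent from the graph are
        skipped with a warning.
    max_len
        Maximum path length (edges) from a regulator to a readout.

    Returns motifs deduplicated and ranked by total path length (shorter
    paths = stronger evidence), then lexicographically.
    """
    readouts = list(readouts)
    if not readouts:
        raise ValueError("readout list is empty")
    by_role: dict[str, list[str]] = {}
    for gene, rs in roles.items():
        for r in rs:
            by_role.setdefault(r, []).append(gene)

    motifs: dict[tuple, PrimingMotif] = {}
    for x3 in readouts:
        if x3 not in graph:
            logger.warning("readout %s not in graph; skipped", x3)
            continue
        for mech, (role1, role2, want1, want2) in _TEMPLATES.items():
            for x1 in by_role.get(role1, []):
                s1 = graph.path_signs(x1, x3, max_len)
                if want1 not in s1 or x1 == x3:
                    continue
                for x2 in by_role.get(role2, []):
                    if x2 in (x1, x3):
                        continue
                    s2 = graph.path_signs(x2, x3, max_len)
                    if want2 not in s2:
                        continue
                    m = PrimingMotif(
                        x1=x1,
                        x2=x2,
                        x3=x3,
                        mechanism=mech,
                        x1_sign=want1,
                        x2_sign=want2,
                        x1_path_len=graph.shortest_path_len(x1, x3, want1, max_len),
                        x2_path_len=graph.shortest_path_len(x2, x3, want2, max_len),
                        sign_ambiguous=(len(s1) > 1 or len(s2) > 1),
                        evidence={"x1_role": role1, "x2_role": role2},
                    )
                    motifs.setdefault(m.key(), m)
    return sorted(
        motifs.values(), key=lambda m: (m.total_path_len, m.mechanism, m.x1, m.x2, m.x3)
    )
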