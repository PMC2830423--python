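"""Assembly-map rule sets: binding dependencies as directed acyclic graphs.

A ribosomal subunit assembly map states, for each protein, which other
proteins must already have bound before it can join the growing particle.
Reading the map as a partial order on proteins, every total order consistent
with it is a *permitted linear evolutionary order* (PLEO) — a candidate
recruitment chronology under the assumption that assembly order
recapitulates evolutionary order.

Rule sets are plain text, one protein per line::

    # comment
    @subunit LSU
    @exclude L15 L16
    L3:
    L14: L3 L24

An empty dependency list marks a protein that binds the rRNA directly.
``@exclude`` names proteins carried through the ordering but given zero
weight when usage statistics are averaged (non-orthologous displacements
whose universally conserved positions cannot be called). A JSON mirror with
keys ``subunit``/``proteins``/``dependencies``/``usage_excluded`` round-trips
the same information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "AssemblyRuleSet",
    "RuleSetError",
    "parse_ruleset",
    "load_ruleset",
    "load_builtin_ruleset",
]


class RuleSetError(ValueError):
    """Raised for malformed or inconsistent rule sets."""


@dataclass(frozen=True)
class AssemblyRuleSet:
    """A subunit assembly map: proteins plus binding-dependency DAG.

    Parameters
    ----------
    subunit_label : str
        Free-form label, conventionally ``"LSU"`` or ``"SSU"``.
    proteins : tuple of str
        Protein identifiers in declaration order (verbatim, case-sensitive).
    dependencies : mapping of str to frozenset of str
        ``dependencies[p]`` is the set of proteins that must bind before
        ``p``. Proteins with an empty set bind the rRNA directly.
    usage_excluded : frozenset of str
        Proteins kept in the ordering model but weighted zero in amino-acid
        usage averaging.
    """

    subunit_label: str
    proteins: tuple[str, ...]
    dependencies: Mapping[str, frozenset[str]] = field(default_factory=dict)
    usage_excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "proteins", tuple(self.proteins))
        deps = {p: frozenset(self.dependencies.get(p, ())) for p in self.proteins}
        object.__setattr__(self, "dependencies", deps)
        object.__setattr__(self, "usage_excluded", frozenset(self.usage_excluded))
        problems = self.validate()
        if problems:
            raise RuleSetError("; ".join(problems))

    # -- structure ---------------------------------------------------------

    def graph(self) -> "nx.DiGraph":
        """Dependency DAG with an edge prerequisite → dependent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.proteins)
        for p, pre in self.dependencies.items():
            g.add_edges_from((q, p) for q in pre)
        return g

    @property
    def n(self) -> int:
        return len(self.proteins)

    def direct_binders(self) -> tuple[str, ...]:
        """Proteins with no prerequisites: direct rRNA binders."""
        return tuple(p for p in self.proteins if not self.dependencies[p])

    def kept_proteins(self) -> tuple[str, ...]:
        """Proteins that carry weight in usage averaging."""
        return tuple(p for p in self.proteins if p not in self.usage_excluded)

    def validate(self) -> list[str]:
        """Return human-readable diagnostics; empty iff all invariants hold."""
        out: list[str] = []
        seen: set[str] = set()
        for p in self.proteins:
            if p in seen:
                out.append(f"duplicate protein {p!r}")
            seen.add(p)
        for p, pre in self.dependencies.items():
            if p not in seen:
                out.append(f"dependency entry for undeclared protein {p!r}")
            for q in sorted(pre):
                if q == p:
                    out.append(f"self-dependency: {p!r} depends on itself")
                elif q not in seen:
                    out.append(f"{p!r} depends on undeclared protein {q!r}")
        for p in sorted(self.usage_excluded):
            if p not in seen:
                out.append(f"usage_excluded names unknown protein {p!r}")
        if not out:
            g = self.graph()
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                pass
            else:
                path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
                out.append(f"cyclic dependency: {path}")
        return out

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        lines = [f"@subunit {self.subunit_label}"]
        if self.usage_excluded:
            ordered = [p for p in self.proteins if p in self.usage_excluded]
            lines.append("@exclude " + " ".join(ordered))
        for p in self.proteins:
            pre = " ".join(sorted(self.dependencies[p]))
            lines.append(f"{p}: {pre}".rstrip())
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "subunit": self.subunit_label,
                "proteins": list(self.proteins),
                "dependencies": {p: sorted(self.dependencies[p]) for p in self.proteins},
                "usage_excluded": sorted(self.usage_excluded),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "AssemblyRuleSet":
        d = json.loads(text)
        return cls(
            subunit_label=d.get("subunit", ""),
            proteins=tuple(d["proteins"]),
            dependencies={p: frozenset(v) for p, v in d.get("dependencies", {}).items()},
            usage_excluded=frozenset(d.get("usage_excluded", ())),
        )


def parse_ruleset(source: str, subunit_label: str = "") -> AssemblyRuleSet:
    """Parse the rule-set text dialect into a validated :class:`AssemblyRuleSet`.

    Raises
    ------
    RuleSetError
        On duplicate proteins, undeclared prerequisites (with the offending
        line number) or cyclic dependencies (naming the cycle).
    """
    proteins: list[str] = []
    deps: dict[str, frozenset[str]] = {}
    excluded: list[str] = []
    label = subunit_label
    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@subunit"):
            label = line.split(None, 1)[1].strip() if " " in line else ""
            continue
        if line.startswith("@exclude"):
            excluded.extend(line.split()[1:])
            continue
        if ":" not in line:
            raise RuleSetError(f"line {lineno}: expected 'NAME: dep1 dep2 ...', got {raw!r}")
        name, _, rest = line.partition(":")
        name = name.strip()
        if name in deps:
            raise RuleSetError(f"line {lineno}: duplicate protein {name!r}")
        proteins.append(name)
        deps[name] = frozenset(rest.split())
    for p, pre in deps.items():
        for q in pre:
            if q not in deps:
                lineno = next(
                    i for i, raw in enumerate(source.splitlines(), start=1)
                    if raw.split("#", 1)[0].strip().startswith(f"{p}:")
                )
                raise RuleSetError(f"line {lineno}: {p!r} depends on undeclared protein {q!r}")
    return AssemblyRuleSet(label, tuple(proteins), deps, frozenset(excluded))


def load_ruleset(path: str | Path) -> AssemblyRuleSet:
    """Load a rule set from a ``.rules`` text file or a ``.json`` mirror."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return AssemblyRuleSet.from_json(text)
    return parse_ruleset(text)


def load_builtin_ruleset(name: str) -> AssemblyRuleSet:
    """Load a rule set shipped with the package (``"LSU"`` or ``"SSU"``)."""
    fname = {"LSU": "lsu.rules", "SSU": "ssu.rules"}.get(name.upper())
    if fname is None:
        raise KeyError(f"no builtin rule set named {name!r}")
    text = resources.files("ribochron.data").joinpath(fname).read_text()
    return parse_ruleset(text)
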