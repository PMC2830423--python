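"""Shared fixtures: small hand-checkable rule sets and one simulated world."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import ribochron as rc
from ribochron.rules import AssemblyRuleSet, parse_ruleset


@pytest.fixture
def chain3() -> AssemblyRuleSet:
    """A -> B -> C: a single permitted order."""
    return parse_ruleset("A:\nB: A\nC: B\n")


@pytest.fixture
def antichain3() -> AssemblyRuleSet:
    """No dependencies: all 3! orders permitted."""
    return parse_ruleset("A:\nB:\nC:\n")


@pytest.fixture
def fork3() -> AssemblyRuleSet:
    """B and C both depend on A."""
    return parse_ruleset("A:\nB: A\nC: A\n")


@pytest.fixture
def fork5() -> AssemblyRuleSet:
    """5-protein fork: A:; B:A; C:A; D:B C; E:."""
    return parse_ruleset("A:\nB: A\nC: A\nD: B C\nE:\n")


def brute_force_extensions(rs: AssemblyRuleSet) -> list[tuple[str, ...]]:
    """All linear extensions by filtering every permutation. Oracle for n <= 8."""
    out = []
    for perm in itertools.permutations(rs.proteins):
        pos = {p: k for k, p in enumerate(perm)}
        if all(pos[q] < pos[p] for p, pre in rs.dependencies.items() for q in pre):
            out.append(perm)
    return out


def random_dag(rng: np.random.Generator, n: int, p_edge: float = 0.3) -> AssemblyRuleSet:
    """Random DAG on n labelled nodes; edges respect a random topological order."""
    labels = [f"P{k}" for k in range(n)]
    order = rng.permutation(n)
    deps: dict[str, frozenset[str]] = {}
    for k in range(n):
        earlier = [labels[order[l]] for l in range(k)]
        deps[labels[order[k]]] = frozenset(
            q for q in earlier if rng.random() < p_edge
        )
    return AssemblyRuleSet("rand", tuple(labels), deps)


@pytest.fixture(scope="session")
def default_world() -> rc.SyntheticWorld:
    return rc.simulate_world(seed=11)


@pytest.fixture(scope="session")
def world_chronology(default_world):
    """REO matrices, delta profiles and residual matrix for the default world."""
    L = default_world.subunits["LSU"]
    S = default_world.subunits["SSU"]
    reoL = rc.reo_matrix(L.ruleset)
    reoS = rc.reo_matrix(S.ruleset)
    dL = rc.delta_profile(reoL, L.usage)
    dS = rc.delta_profile(reoS, S.usage)
    raw = rc.rmsd_matrix(dL, dS)
    bg = rc.background_matrix(L.usage, S.usage, reoL, reoS, reps=200, seed=12)
    res = rc.residual_matrix(raw, bg)
    return {
        "reoL": reoL, "reoS": reoS, "dL": dL, "dS": dS,
        "raw": raw, "bg": bg, "res": res,
    }
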