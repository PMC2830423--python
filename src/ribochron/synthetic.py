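"""Synthetic worlds with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes,
at the level the pipeline consumes (counts and probability profiles — no
sequences, trees, or substitution models):

* a *code-expansion schedule*: each amino acid has an addition time and a
  modern baseline frequency;
* per-subunit protein recruitment times on a common clock, the LSU
  analogue starting ``lag`` time units before the SSU analogue;
* a binding-dependency DAG consistent with recruitment order (edges only
  from earlier to later proteins);
* usage tables in which universally conserved (U) positions are drawn
  from the code *as of recruitment time* — amino acids not yet added are
  suppressed, recently added ones under-represented, with the bias
  decaying toward modern frequencies — while domain-specific (D)
  positions are drawn from modern frequencies (they postdate the code's
  completion);
* optionally, noisy ancestral probability profiles from which the
  conserved-position caller must recover the true conserved sites.

``drift`` is the effect size: 0 gives a null world (U and D rates drawn
from identical distributions), 1 removes unavailable amino acids
entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .rules import AssemblyRuleSet
from .usage import AMINO_ACIDS, AncestralProfile, UsageTable

__all__ = [
    "CodeSchedule",
    "SubunitSim",
    "SyntheticWorld",
    "simulate_world",
    "profiles_from_world",
]

# Consensus temporal order of amino-acid addition to the code (earliest
# first), following the broad agreement of biosynthetic-complexity and
# codon-evolution rankings.
_ADDITION_ORDER = tuple("GADVPSELTRIQNKFCMHYW")

# Modern average amino-acid frequencies (overall protein composition, %),
# alphabetical one-letter order.
_MODERN_PCT = {
    "A": 8.25, "C": 1.37, "D": 5.45, "E": 6.75, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66,
    "M": 2.42, "N": 4.06, "P": 4.70, "Q": 3.93, "R": 5.53,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92,
}


@dataclass(frozen=True)
class CodeSchedule:
    """Amino-acid addition times and modern baseline frequencies."""

    addition_time: np.ndarray  # (20,), alphabetical AA order
    modern_freq: np.ndarray  # (20,), sums to 1

    def __post_init__(self) -> None:
        at = np.asarray(self.addition_time, dtype=float)
        mf = np.asarray(self.modern_freq, dtype=float)
        if at.shape != (20,) or mf.shape != (20,):
            raise ValueError("schedule arrays must have shape (20,)")
        if not np.all(np.isfinite(at)):
            raise ValueError("addition times must be finite")
        if np.any(mf <= 0) or not np.isclose(mf.sum(), 1.0):
            raise ValueError("modern frequencies must be positive and sum to 1")
        object.__setattr__(self, "addition_time", at)
        object.__setattr__(self, "modern_freq", mf / mf.sum())

    @classmethod
    def default(cls, t_first: float = -4.0, t_last: float = 10.0) -> "CodeSchedule":
        """Consensus addition order spread linearly over [t_first, t_last].

        With unit recruitment spacing starting at time 0, the earliest
        proteins see a code still missing most of its later additions,
        and the code is complete about two thirds of the way through the
        combined recruitment window — so late-added amino acids visibly
        converge toward modern usage within the observed chronologies.
        """
        times = np.empty(20)
        for rank, aa in enumerate(_ADDITION_ORDER):
            times[AMINO_ACIDS.index(aa)] = t_first + rank * (t_last - t_first) / 19
        freq = np.array([_MODERN_PCT[a] for a in AMINO_ACIDS])
        return cls(times, freq / freq.sum())

    def weights_at(
        self, t: float, drift: float, tau: float, variant: str = "exponential"
    ) -> np.ndarray:
        """Sampling weights for U positions of a protein recruited at time ``t``.

        Suppression ``s_A(t)`` is 1 before the amino acid is added and
        thereafter decays as ``exp(-(t - t_add)/tau)`` (``variant=
        "exponential"``) or drops straight to 0 (``variant="step"``); the
        weight is ``modern_A * (1 − drift * s_A(t))``, renormalised.
        """
        dt = t - self.addition_time
        if variant == "exponential":
            s = np.where(dt < 0, 1.0, np.exp(-np.maximum(dt, 0) / tau))
        elif variant == "step":
            s = (dt < 0).astype(float)
        else:
            raise ValueError(f"unknown schedule variant {variant!r}")
        w = self.modern_freq * (1.0 - drift * s)
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"no amino acids available at recruitment time {t}: "
                "drift too strong or schedule starts too late"
            )
        return w / total


@dataclass(frozen=True)
class SubunitSim:
    """One simulated subunit: recruitment times, rule set, usage and sites."""

    ruleset: AssemblyRuleSet
    recruit_times: Mapping[str, float]
    usage: UsageTable
    u_sites: Mapping[str, tuple[str, ...]]
    d_sites: Mapping[str, tuple[str, ...]]


@dataclass(frozen=True)
class SyntheticWorld:
    """Two simulated subunits plus the schedule and ground-truth block."""

    schedule: CodeSchedule
    subunits: Mapping[str, SubunitSim]
    truth: dict = field(default_factory=dict)

    def to_dir(self, path: str | Path) -> None:
        """Serialize to the formats the real pipeline reads, plus truth JSON."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for label, sub in self.subunits.items():
            (path / f"{label.lower()}.rules").write_text(sub.ruleset.to_text())
            sub.usage.to_tsv(path / f"{label.lower()}_usage.tsv")
        (path / "truth.json").write_text(json.dumps(self.truth, indent=1))


def _sample_dag(
    labels: list[str],
    dep_density: float,
    rng: np.random.Generator,
    subunit_label: str,
) -> AssemblyRuleSet:
    """Edges drawn earlier → later with probability ``dep_density``.

    The first-recruited protein is always a direct rRNA binder; proteins
    left with no edge at all are attached to a random earlier protein so
    the dependency graph stays connected.
    """
    n = len(labels)
    deps: dict[str, set[str]] = {p: set() for p in labels}
    for k in range(1, n):
        for l in range(k):
            if rng.random() < dep_density:
                deps[labels[k]].add(labels[l])
    has_out = {p: False for p in labels}
    for k, p in enumerate(labels):
        for q in deps[p]:
            has_out[q] = True
    for k in range(1, n):
        p = labels[k]
        if not deps[p] and not has_out[p]:
            q = labels[rng.integers(k)]
            deps[p].add(q)
            has_out[q] = True
    return AssemblyRuleSet(
        subunit_label, tuple(labels), {p: frozenset(v) for p, v in deps.items()}
    )


def simulate_world(
    n_proteins: tuple[int, int] = (15, 18),
    lag: float = 3.0,
    drift: float = 0.9,
    sites: tuple[int, int] = (150, 200),
    dep_density: float = 0.2,
    seed: int = 0,
    schedule: CodeSchedule | None = None,
    tau: float = 4.0,
    variant: str = "exponential",
) -> SyntheticWorld:
    """Simulate a two-subunit world under a code-expansion schedule.

    Parameters
    ----------
    n_proteins
        Proteins per subunit ``(LSU-analogue, SSU-analogue)``.
    lag
        Head start (time units = recruitment spacings) of the LSU
        analogue over the SSU analogue.
    drift
        Code-imprint effect size in [0, 1]; 0 is a null world.
    sites
        Conserved positions per protein ``(U, D)``.
    dep_density
        Probability of a dependency edge from each earlier protein.
    tau, variant
        Decay timescale and shape of the recruitment-time bias
        (see :meth:`CodeSchedule.weights_at`).
    """
    if min(n_proteins) < 1 or min(sites) < 1 or drift < 0:
        raise ValueError("sizes must be positive and drift nonnegative")
    rng = np.random.default_rng(seed)
    schedule = schedule or CodeSchedule.default()
    aas = np.array(AMINO_ACIDS)
    subunits: dict[str, SubunitSim] = {}
    for label, n, start in (("LSU", n_proteins[0], 0.0), ("SSU", n_proteins[1], lag)):
        labels = [f"{label[0]}{k + 1:02d}" for k in range(n)]
        times = {p: start + k for k, p in enumerate(labels)}
        rs = _sample_dag(labels, dep_density, rng, label)
        U = np.zeros((n, 20), dtype=np.int64)
        D = np.zeros_like(U)
        u_sites: dict[str, tuple[str, ...]] = {}
        d_sites: dict[str, tuple[str, ...]] = {}
        for k, p in enumerate(labels):
            wu = schedule.weights_at(times[p], drift, tau, variant)
            u_draw = rng.choice(20, size=sites[0], p=wu)
            d_draw = rng.choice(20, size=sites[1], p=schedule.modern_freq)
            U[k] = np.bincount(u_draw, minlength=20)
            D[k] = np.bincount(d_draw, minlength=20)
            u_sites[p] = tuple(aas[u_draw])
            d_sites[p] = tuple(aas[d_draw])
        usage = UsageTable(label, tuple(labels), U, D)
        subunits[label] = SubunitSim(rs, times, usage, u_sites, d_sites)
    truth = {
        "lag": lag,
        "drift": drift,
        "tau": tau,
        "variant": variant,
        "sites": list(sites),
        "dep_density": dep_density,
        "seed": seed,
        "recruit_times": {
            label: dict(sub.recruit_times) for label, sub in subunits.items()
        },
    }
    return SyntheticWorld(schedule, subunits, truth)


def profiles_from_world(
    world: SyntheticWorld,
    conservation_noise: float = 0.05,
    decoy_fraction: float = 0.1,
    decoy_probability: float = 0.5,
    seed: int = 0,
) -> dict[tuple[str, str], tuple[AncestralProfile, AncestralProfile]]:
    """Noisy two-node ancestral profiles per protein, for the conserved caller.

    Each true conserved site gets probability ``1 − conservation_noise``
    on its identity at both flanking nodes (the remainder spread over the
    other 19 amino acids); a ``decoy_fraction`` of extra sites peak at
    only ``decoy_probability`` and must stay below the 0.90 calling
    threshold. With ``1 − conservation_noise >= 0.9`` the caller recovers
    exactly the true conserved set.
    """
    if not 0 <= conservation_noise < 0.5:
        raise ValueError("conservation_noise must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], tuple[AncestralProfile, AncestralProfile]] = {}
    for label, sub in world.subunits.items():
        for p, site_aas in sub.u_sites.items():
            n_true = len(site_aas)
            n_decoy = int(round(decoy_fraction * n_true))
            rows = []
            for aa in site_aas:
                v = np.full(20, conservation_noise / 19)
                v[AMINO_ACIDS.index(aa)] = 1 - conservation_noise
                rows.append(v)
            for _ in range(n_decoy):
                v = np.full(20, (1 - decoy_probability) / 19)
                v[rng.integers(20)] = decoy_probability
                rows.append(v)
            sites = np.array(rows)
            prof = tuple(
                AncestralProfile(p, node, sites) for node in ("node1", "node2")
            )
            out[(label, p)] = prof  # type: ignore[assignment]
    return out
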