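"""Amino-acid usage at conserved positions along a chronology.

The imprint premise: a protein recruited while the genetic code was still
expanding carries, at its universally conserved positions, a bias toward
the amino acids available at recruitment time. Sites are called
*conserved* when the ancestral identity is confidently reconstructed
(probability >= 0.90 at both nodes flanking the root) within a domain;
sites conserved in both the bacterial and the archaeal/eukaryal ancestor
with the same identity are *universally conserved* (U), and the remainder
of each domain's conserved sites are *domain-specific* (D). Per-protein U
and D counts are normalised into usage rates, and the REO matrix turns
per-protein rate differences into a per-position profile::

    D_iA = sum_j P_ij * (rateU_jA - rateD_jA)

with a weighted standard error from binomial per-protein variances. Under
no code drift U and D rates coincide, so the expected value of every
``D_iA`` is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pleo import ReoMatrix

__all__ = [
    "AMINO_ACIDS",
    "AncestralProfile",
    "UsageTable",
    "DeltaProfile",
    "call_conserved",
    "classify_positions",
    "usage_rates",
    "delta_profile",
]

#: The 20 proteinogenic amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class AncestralProfile:
    """Per-site ancestral-state probabilities for one protein at one node.

    ``sites[s, a]`` is the posterior probability that aligned site ``s``
    (0-based row; reported 1-based) had amino acid ``AMINO_ACIDS[a]`` at
    this node. Every row sums to one.
    """

    protein: str
    node: str
    sites: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.sites, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 20:
            raise ValueError("sites must be an (n_sites, 20) array")
        if np.any(arr < 0):
            raise ValueError("negative probability in ancestral profile")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("site probability vectors must sum to 1")
        object.__setattr__(self, "sites", arr)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.sites, columns=list(AMINO_ACIDS))
        df.index = np.arange(1, self.n_sites + 1)
        df.index.name = "site"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, protein: str, node: str) -> "AncestralProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(protein, node, df[list(AMINO_ACIDS)].to_numpy())


def call_conserved(
    p1: AncestralProfile,
    p2: AncestralProfile,
    threshold: float = 0.90,
) -> set[tuple[int, str]]:
    """Call conserved sites from the two node profiles flanking a root.

    A site is conserved iff the *same* amino acid reaches probability
    ``threshold`` (inclusive, matching the "at least 90%" rule) at both
    nodes. Returns ``{(site, aa), ...}`` with 1-based site indices.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if p1.protein != p2.protein:
        raise ValueError("profiles are for different proteins")
    if p1.n_sites != p2.n_sites:
        raise ValueError(f"site count mismatch: {p1.n_sites} vs {p2.n_sites}")
    out: set[tuple[int, str]] = set()
    for s in range(p1.n_sites):
        a1 = int(np.argmax(p1.sites[s]))
        if p1.sites[s, a1] >= threshold and p2.sites[s, a1] >= threshold:
            out.add((s + 1, AMINO_ACIDS[a1]))
    return out


def classify_positions(
    bac: set[tuple[int, str]],
    arc: set[tuple[int, str]],
) -> tuple[set[tuple[int, str]], set[tuple[int, str]], set[tuple[int, str]]]:
    """Split domain-conserved sites into universal and domain-specific sets.

    A site conserved in both domains with the same identity is universally
    conserved (U). Each domain's remaining conserved sites form its
    domain-specific set; a site conserved in both domains but with
    *different* identities contributes to both domain-specific sets.

    Returns ``(U, D_bacterial, D_archaeal)``. Both inputs must use the
    same aligned coordinate system.
    """
    universal = bac & arc
    u_sites = {s for s, _ in universal}
    d_bac = {sa for sa in bac if sa[0] not in u_sites}
    d_arc = {sa for sa in arc if sa[0] not in u_sites}
    return universal, d_bac, d_arc


@dataclass(frozen=True)
class UsageTable:
    """Per-protein amino-acid counts at U and D conserved positions.

    ``U[j, a]`` (``D[j, a]``) is the number of universally conserved
    (domain-specific) positions of protein ``proteins[j]`` whose ancestral
    identity is ``AMINO_ACIDS[a]``.
    """

    subunit_label: str
    proteins: tuple[str, ...]
    U: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U)
        D = np.asarray(self.D)
        shape = (len(self.proteins), 20)
        if U.shape != shape or D.shape != shape:
            raise ValueError(f"count arrays must have shape {shape}")
        for name, arr in (("U", U), ("D", D)):
            if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(f"{name} counts must be nonnegative integers")
        object.__setattr__(self, "U", U.astype(np.int64))
        object.__setattr__(self, "D", D.astype(np.int64))
        object.__setattr__(self, "proteins", tuple(self.proteins))

    @property
    def U_total(self) -> np.ndarray:
        return self.U.sum(axis=1)

    @property
    def D_total(self) -> np.ndarray:
        return self.D.sum(axis=1)

    def subset(self, proteins: Sequence[str]) -> "UsageTable":
        idx = [self.proteins.index(p) for p in proteins]
        return UsageTable(self.subunit_label, tuple(proteins), self.U[idx], self.D[idx])

    @classmethod
    def from_sets(
        cls,
        subunit_label: str,
        universal: Mapping[str, Iterable[tuple[int, str]]],
        domain_specific: Mapping[str, Iterable[tuple[int, str]]],
    ) -> "UsageTable":
        """Tabulate counts from per-protein classified (site, aa) sets.

        ``domain_specific[j]`` should already pool both domains' D sets.
        """
        proteins = tuple(universal)
        U = np.zeros((len(proteins), 20), dtype=np.int64)
        D = np.zeros_like(U)
        for k, p in enumerate(proteins):
            for _, aa in universal[p]:
                U[k, _AA_INDEX[aa]] += 1
            for _, aa in domain_specific.get(p, ()):
                D[k, _AA_INDEX[aa]] += 1
        return cls(subunit_label, proteins, U, D)

    # TSV layout: one row per (protein, dataset in {U, D}), 20 count
    # columns plus a total column — the layout of the supplementary
    # raw-count tables this mirrors.
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in (("U", self.U), ("D", self.D)):
            df = pd.DataFrame(arr, columns=list(AMINO_ACIDS))
            df.insert(0, "dataset", name)
            df.insert(0, "protein", list(self.proteins))
            df["total"] = arr.sum(axis=1)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, subunit_label: str = "") -> "UsageTable":
        df = pd.read_csv(path, sep="\t")
        u = df[df["dataset"] == "U"].set_index("protein")
        d = df[df["dataset"] == "D"].set_index("protein")
        proteins = tuple(u.index)
        if tuple(d.index) != proteins:
            raise ValueError("U and D rows list different proteins")
        U = u[list(AMINO_ACIDS)].to_numpy()
        D = d[list(AMINO_ACIDS)].to_numpy()
        for name, arr, block in (("U", U, u), ("D", D, d)):
            if "total" in block and not np.array_equal(
                arr.sum(axis=1), block["total"].to_numpy()
            ):
                raise ValueError(f"{name} totals column disagrees with counts")
        return cls(subunit_label, proteins, U, D)


def usage_rates(
    t: UsageTable, exclude: Iterable[str] = ()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise counts into per-protein usage rates.

    Returns ``(rate_U, rate_D)`` DataFrames (proteins x amino acids), each
    row summing to one. Proteins in ``exclude`` are dropped; a zero U or D
    total for any remaining protein is an error naming the protein.
    """
    exclude = set(exclude)
    keep = [k for k, p in enumerate(t.proteins) if p not in exclude]
    for k in keep:
        if t.U_total[k] == 0 or t.D_total[k] == 0:
            raise ValueError(
                f"protein {t.proteins[k]!r} has a zero U or D total; "
                "exclude it or supply counts"
            )
    proteins = [t.proteins[k] for k in keep]
    rU = t.U[keep] / t.U_total[keep, None]
    rD = t.D[keep] / t.D_total[keep, None]
    cols = list(AMINO_ACIDS)
    return (
        pd.DataFrame(rU, index=proteins, columns=cols),
        pd.DataFrame(rD, index=proteins, columns=cols),
    )


@dataclass(frozen=True)
class DeltaProfile:
    """Weighted mean U−D usage differences along a chronology.

    ``delta[i, a]`` is the REO-probability-weighted mean difference in
    usage of amino acid ``AMINO_ACIDS[a]`` at 1-based chronology position
    ``i+1``; ``se`` is the matching weighted standard error. Under the
    default ``rate_difference`` variant each position's deltas sum to zero.
    """

    delta: np.ndarray
    se: np.ndarray
    variant: str
    subunit_label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        s = np.asarray(self.se, dtype=float)
        if d.shape != s.shape or d.ndim != 2 or d.shape[1] != 20:
            raise ValueError("delta and se must both be (n_positions, 20)")
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(s)):
            raise ValueError("non-finite entries in delta profile")
        if np.any(s < 0):
            raise ValueError("negative standard error")
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "se", s)

    @property
    def n_positions(self) -> int:
        return self.delta.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.n_positions + 1)

    def at(self, position: int, aa: str) -> tuple[float, float]:
        """(delta, se) for amino acid ``aa`` at 1-based ``position``."""
        i, a = position - 1, _AA_INDEX[aa]
        return float(self.delta[i, a]), float(self.se[i, a])

    def to_frame(self) -> pd.DataFrame:
        cols = list(AMINO_ACIDS)
        d = pd.DataFrame(self.delta, index=self.positions, columns=cols)
        s = pd.DataFrame(self.se, index=self.positions, columns=[f"se_{a}" for a in cols])
        out = pd.concat([d, s], axis=1)
        out.index.name = "position"
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, variant: str = "rate_difference", subunit_label: str = "") -> "DeltaProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        d = df[list(AMINO_ACIDS)].to_numpy()
        s = df[[f"se_{a}" for a in AMINO_ACIDS]].to_numpy()
        return cls(d, s, variant, subunit_label)


def per_protein_values(
    t: UsageTable, proteins: Sequence[str], variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein usage values v_jA and binomial variances for weighting."""
    idx = [t.proteins.index(p) for p in proteins]
    U, D = t.U[idx], t.D[idx]
    UT, DT = U.sum(axis=1), D.sum(axis=1)
    if np.any(UT == 0) or np.any(DT == 0):
        bad = [proteins[k] for k in range(len(idx)) if UT[k] == 0 or DT[k] == 0]
        raise ValueError(f"zero U or D totals for proteins {bad}")
    rU = U / UT[:, None]
    rD = D / DT[:, None]
    if variant == "rate_difference":
        v = rU - rD
    elif variant == "count_quotient":
        denom = UT - DT
        if np.any(denom == 0):
            bad = [proteins[k] for k in range(len(idx)) if denom[k] == 0]
            raise ValueError(f"count_quotient undefined: U and D totals equal for {bad}")
        v = (U - D) / denom[:, None]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    var = rU * (1 - rU) / UT[:, None] + rD * (1 - rD) / DT[:, None]
    return v, var


def delta_profile(
    reo: ReoMatrix,
    t: UsageTable,
    variant: str = "rate_difference",
) -> DeltaProfile:
    """Weight per-protein U−D usage values by REO position probabilities.

    Position ``i`` gets ``D_iA = sum_j P_ij v_jA`` with
    ``v_jA = rateU_jA − rateD_jA`` (default) or the literal count quotient
    ``(U_jA − D_jA)/(U_jT − D_jT)``, and standard error
    ``sqrt(sum_j P_ij^2 Var_j[A])`` with binomial per-protein variances.
    Proteins excluded from usage averaging must already have been removed
    from the REO matrix (see :func:`ribochron.pleo.remove_excluded`).
    """
    missing = set(reo.proteins) - set(t.proteins)
    if missing:
        raise ValueError(f"usage table lacks proteins {sorted(missing)}")
    v, var = per_protein_values(t, reo.proteins, variant)
    P = reo.P  # (n_proteins, n_positions)
    delta = P.T @ v
    se = np.sqrt((P.T ** 2) @ var)
    return DeltaProfile(delta, se, variant, subunit_label=t.subunit_label)
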