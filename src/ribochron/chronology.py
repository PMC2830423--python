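"""Pairwise chronology comparison: RMSD matrices and their null background.

Two subunits evolve under the same expanding genetic code, so positions of
similar age should show similar composite usage deltas. The raw RMSD
matrix compares every LSU position with every SSU position over all 20
amino acids. Because positions are probability-weighted mixtures of
overlapping protein sets (adjacent positions share proteins; terminal
positions average fewer proteins and are noisier), the raw matrix carries
model-induced structure even for unstructured data. A permutation null —
reassigning intact per-protein (U, D) usage-vector pairs across proteins
within each subunit — preserves exactly that weighting structure while
destroying any recruitment-time signal; averaging many permuted RMSD
matrices gives the background, and raw − background is the residual
matrix on which path fitting operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .pleo import ReoMatrix
from .usage import DeltaProfile, UsageTable, per_protein_values

__all__ = [
    "RmsdMatrix",
    "rmsd_matrix",
    "background_matrix",
    "residual_matrix",
    "randomized_residuals",
    "structure_test",
]


@dataclass(frozen=True)
class RmsdMatrix:
    """LSU-position x SSU-position distance matrix.

    ``values[iL, iS]`` compares 1-based LSU position ``iL+1`` with SSU
    position ``iS+1``; ``kind`` is ``raw``, ``background`` or ``residual``.
    """

    values: np.ndarray
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.kind not in ("raw", "background", "residual"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in ("raw", "background") and np.any(v < 0):
            raise ValueError(f"{self.kind} RMSD entries must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=np.arange(1, self.shape[0] + 1),
            columns=np.arange(1, self.shape[1] + 1),
        )
        df.index.name = "lsu_position"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str, **kw) -> "RmsdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), kind, **kw)


def rmsd_matrix(dL: DeltaProfile, dS: DeltaProfile) -> RmsdMatrix:
    """Root-mean-square distance between usage-delta vectors of all position pairs.

    Entry ``(iL, iS) = sqrt(mean_A (delta_L[iL, A] − delta_S[iS, A])^2)``
    over the 20 amino acids.
    """
    if dL.delta.shape[1] != dS.delta.shape[1]:
        raise ValueError("profiles cover different amino-acid sets")
    diff = dL.delta[:, None, :] - dS.delta[None, :, :]
    vals = np.sqrt(np.mean(diff**2, axis=2))
    return RmsdMatrix(vals, "raw")


def _rmsd_from_deltas(dL: np.ndarray, dS: np.ndarray) -> np.ndarray:
    diff = dL[:, None, :] - dS[None, :, :]
    return np.sqrt(np.mean(diff**2, axis=2))


def background_matrix(
    tL: UsageTable,
    tS: UsageTable,
    reoL: ReoMatrix,
    reoS: ReoMatrix,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    variant: str = "rate_difference",
    mode: str = "paired",
) -> RmsdMatrix:
    """Average RMSD matrix over permutation-randomized usage data.

    Per replicate, each subunit's per-protein (U, D) count-vector pairs are
    permuted across that subunit's proteins (``mode="paired"``, the
    default, keeps each protein's U and D vectors together;
    ``mode="independent"`` shuffles them separately), the delta profiles
    and RMSD matrix are recomputed, and entries are averaged over
    ``reps`` replicates. Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sides = []
    for t, reo in ((tL, reoL), (tS, reoS)):
        if len(reo.proteins) < 2:
            warnings.warn(
                f"subunit {t.subunit_label!r} has fewer than 2 proteins; "
                "permutation is vacuous and the background equals the raw matrix",
                stacklevel=2,
            )
        rU, rD, UT, DT = _rate_components(t, reo.proteins)
        sides.append((reo.P, rU, rD, UT, DT))
    acc = None
    for _ in range(reps):
        deltas = []
        for P, rU, rD, UT, DT in sides:
            n = rU.shape[0]
            if mode == "paired":
                perm = rng.permutation(n)
                v = _variant_values(rU[perm], rD[perm], UT[perm], DT[perm], variant)
            elif mode == "independent":
                pu, pd_ = rng.permutation(n), rng.permutation(n)
                v = _variant_values(rU[pu], rD[pd_], UT[pu], DT[pd_], variant)
            else:
                raise ValueError(f"unknown randomization mode {mode!r}")
            deltas.append(P.T @ v)
        m = _rmsd_from_deltas(deltas[0], deltas[1])
        acc = m if acc is None else acc + m
    return RmsdMatrix(
        acc / reps,
        "background",
        {"reps": reps, "mode": mode, "variant": variant},
    )


def _rate_components(t: UsageTable, proteins: Sequence[str]):
    idx = [t.proteins.index(p) for p in proteins]
    U, D = t.U[idx], t.D[idx]
    UT, DT = U.sum(axis=1), D.sum(axis=1)
    if np.any(UT == 0) or np.any(DT == 0):
        raise ValueError("zero U or D totals among weighted proteins")
    return U / UT[:, None], D / DT[:, None], UT, DT


def _variant_values(rU, rD, UT, DT, variant: str) -> np.ndarray:
    if variant == "rate_difference":
        return rU - rD
    if variant == "count_quotient":
        denom = (UT - DT).astype(float)
        if np.any(denom == 0):
            raise ValueError("count_quotient undefined: equal U and D totals")
        return (rU * UT[:, None] - rD * DT[:, None]) / denom[:, None]
    raise ValueError(f"unknown variant {variant!r}")


def residual_matrix(raw: RmsdMatrix, background: RmsdMatrix) -> RmsdMatrix:
    """Elementwise raw − background."""
    if raw.shape != background.shape:
        raise ValueError(f"dimension mismatch: {raw.shape} vs {background.shape}")
    return RmsdMatrix(
        raw.values - background.values,
        "residual",
        {"background": background.provenance},
    )


def randomized_residuals(
    tL: UsageTable,
    tS: UsageTable,
    reoL: ReoMatrix,
    reoS: ReoMatrix,
    background: RmsdMatrix,
    n: int,
    seed: int | np.random.Generator = 0,
    variant: str = "rate_difference",
    mode: str = "paired",
) -> list[RmsdMatrix]:
    """Residual matrices of ``n`` fresh permutation replicates.

    Each replicate's RMSD matrix (from independently permuted usage data)
    minus the supplied background: the null distribution against which the
    actual residual's structure is tested.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rep = background_matrix(
            tL, tS, reoL, reoS, reps=1, seed=rng, variant=variant, mode=mode
        )
        out.append(residual_matrix(RmsdMatrix(rep.values, "raw"), background))
    return out


def structure_test(
    residual_actual: RmsdMatrix,
    randomized_residuals: Sequence[RmsdMatrix],
) -> dict:
    """One-sample Z tests of matrix variance and mean against the permutation null.

    For each statistic (variance of entries, mean of entries) the actual
    value is compared with its distribution over randomized replicates:
    ``Z = (actual − mean_rand) / sd_rand`` with the one-tailed p-value
    ``1 − Φ(Z)`` for the "actual exceeds randomized" direction (structured
    data should show larger variance and larger mean residuals than its
    own randomizations).
    """
    if len(randomized_residuals) < 2:
        raise ValueError("need at least 2 randomized replicates")
    out: dict = {"n_randomized": len(randomized_residuals)}
    for name, fn in (("variance", lambda m: m.var()), ("mean", lambda m: m.mean())):
        actual = float(fn(residual_actual.values))
        rand = np.array([fn(r.values) for r in randomized_residuals])
        sd = rand.std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate null: randomized {name}s are constant")
        z = (actual - rand.mean()) / sd
        out[f"{name}_actual"] = actual
        out[f"{name}_rand_mean"] = float(rand.mean())
        out[f"z_{'var' if name == 'variance' else 'mean'}"] = float(z)
        out[f"p_{'var' if name == 'variance' else 'mean'}"] = float(stats.norm.sf(z))
    return out
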