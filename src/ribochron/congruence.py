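"""Per-amino-acid congruence and convergence across aligned chronologies.

If the LSU and SSU chronologies really track the same expanding genetic
code, each amino acid's usage-delta trajectory should agree between the
two subunits along the aligned positions (*congruence*), and usage should
drift toward its modern expectation (U − D = 0) over time (*convergence*).

Congruence at one aligned position ``c`` is a two-sample Z score::

    Z_c = (D_L − D_S) / sqrt(SE_L^2 + SE_S^2)

combined over the ``k`` aligned positions by a weighted Z-transform
(Stouffer) test with inverse-combined-variance weights
``w_c = 1 / (SE_L,c^2 + SE_S,c^2)``::

    Z_w = sum(w_c Z_c) / sqrt(sum(w_c^2)),   p = two-tailed normal

Convergence per chronology compares SE-scaled distance from the expected
value at the alignment's endpoints::

    Z_V = |D_last|/SE_last − |D_first|/SE_first

A position is congruent if ``|Z_c| < 1.282`` (the one-tailed 10%
quantile); a chronology is convergent if ``Z_V < −1`` and divergent if
``Z_V > 1``; an amino acid is *consistently convergent* when at least one
chronology has ``Z_V < −1``, neither has ``Z_V > 1``, and the mean of the
two is below −1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pathwalk import ChronologyAlignment
from .usage import AMINO_ACIDS, DeltaProfile

__all__ = [
    "CONGRUENCE_Z",
    "CONVERGENCE_Z",
    "CongruenceReport",
    "position_z",
    "weighted_z",
    "convergence_z",
    "congruence_table",
]

#: |Z_c| below this is congruent (one-tailed p > 0.10).
CONGRUENCE_Z = 1.282
#: Z_V below −1 is convergent; above +1 divergent.
CONVERGENCE_Z = 1.000


def position_z(dL: tuple[float, float], dS: tuple[float, float]) -> float:
    """Two-sample Z for one aligned position; inputs are (delta, se) pairs."""
    (xL, sL), (xS, sS) = dL, dS
    if sL < 0 or sS < 0:
        raise ValueError("standard errors must be nonnegative")
    denom = np.hypot(sL, sS)
    if denom == 0:
        if xL == xS:
            return 0.0
        raise ValueError("both SEs zero with unequal deltas: Z is infinite")
    return float((xL - xS) / denom)


def weighted_z(
    z: Sequence[float], se_pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Weighted Z-transform combination of per-position Z scores.

    Weights are the inverse combined error variances. Returns
    ``(Z_w, two-tailed p)``; with equal weights this reduces to the
    classic Stouffer combination ``sum(Z)/sqrt(k)``.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 1:
        raise ValueError("need at least one position")
    combined_var = np.array([sL**2 + sS**2 for sL, sS in se_pairs])
    if np.any(combined_var <= 0) or np.any(~np.isfinite(combined_var)):
        raise ValueError("weights must be positive and finite")
    w = 1.0 / combined_var
    zw = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return zw, float(2 * stats.norm.sf(abs(zw)))


def convergence_z(first: tuple[float, float], last: tuple[float, float]) -> float:
    """Change in SE-scaled distance from the expected value (U−D = 0).

    Negative values mean the final position sits closer to expectation (in
    SE units) than the first: usage converging toward modern levels.
    """
    (x0, s0), (x1, s1) = first, last
    if s0 <= 0 or s1 <= 0:
        raise ValueError("standard errors must be positive")
    return float(abs(x1) / s1 - abs(x0) / s0)


@dataclass(frozen=True)
class CongruenceReport:
    """Per-amino-acid congruence/convergence table plus grand averages.

    ``table`` is indexed by amino acid with columns ``z_w``, ``p``,
    ``congruent_positions``, ``k``, ``z_v_lsu``, ``z_v_ssu``,
    ``z_v_ave`` and boolean flags ``convergent_lsu``, ``convergent_ssu``,
    ``divergent_lsu``, ``divergent_ssu``, ``consistently_convergent``.
    """

    table: pd.DataFrame
    z_v_lsu_ave: float
    z_v_ssu_ave: float
    k: int
    position_scores: dict[str, list[float]] = field(default_factory=dict, repr=False)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(
            2, "congruent", out.pop("congruent_positions").astype(str) + "/" + str(self.k)
        )
        out.index.name = "aa"
        out.to_csv(path, sep="\t", float_format="%.6g")

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "z_v_lsu_ave": self.z_v_lsu_ave,
                "z_v_ssu_ave": self.z_v_ssu_ave,
                "per_aa": json.loads(self.table.to_json(orient="index")),
            }
        )


def _se_distance(value: tuple[float, float]) -> float:
    """|delta|/SE, treating an exactly-zero delta with zero SE as distance 0.

    A degenerate endpoint (an amino acid entirely absent from the
    contributing proteins) sits exactly at its expected value.
    """
    d, s = value
    if s == 0:
        if d == 0:
            return 0.0
        raise ValueError("zero SE with nonzero delta: SE distance undefined")
    return abs(d) / s


def congruence_table(
    dL: DeltaProfile,
    dS: DeltaProfile,
    aln: ChronologyAlignment,
) -> CongruenceReport:
    """Assemble the full 20-amino-acid congruence/convergence report.

    Per amino acid: the per-aligned-position ``Z_c`` vector, the count of
    congruent positions, the weighted combination ``Z_w`` with its
    two-tailed p, and the per-chronology convergence scores ``Z_V``
    evaluated between the first and last aligned pairs on each
    chronology's own profile.

    Degenerate cells — an amino acid absent from every contributing
    protein, giving zero delta and zero SE — count as congruent
    (``Z_c = 0``) but carry no weight in the combination; if every
    aligned position is degenerate the combined score is 0 with p = 1.
    """
    for iL, iS in aln.pairs:
        if not (1 <= iL <= dL.n_positions and 1 <= iS <= dS.n_positions):
            raise ValueError(f"aligned pair {(iL, iS)} outside the profiles")
    rows = []
    zc_store: dict[str, list[float]] = {}
    for aa in AMINO_ACIDS:
        zc, pairs_se = [], []
        for iL, iS in aln.pairs:
            vL, vS = dL.at(iL, aa), dS.at(iS, aa)
            zc.append(position_z(vL, vS))
            pairs_se.append((vL[1], vS[1]))
        usable = [k for k, (sL, sS) in enumerate(pairs_se) if sL**2 + sS**2 > 0]
        if usable:
            zw, p = weighted_z(
                [zc[k] for k in usable], [pairs_se[k] for k in usable]
            )
        else:
            zw, p = 0.0, 1.0
        congruent = int(np.sum(np.abs(zc) < CONGRUENCE_Z))
        (iL0, iS0), (iL1, iS1) = aln.pairs[0], aln.pairs[-1]
        zv_l = _se_distance(dL.at(iL1, aa)) - _se_distance(dL.at(iL0, aa))
        zv_s = _se_distance(dS.at(iS1, aa)) - _se_distance(dS.at(iS0, aa))
        zv_ave = (zv_l + zv_s) / 2
        conv_l, conv_s = zv_l < -CONVERGENCE_Z, zv_s < -CONVERGENCE_Z
        div_l, div_s = zv_l > CONVERGENCE_Z, zv_s > CONVERGENCE_Z
        rows.append(
            {
                "z_w": zw,
                "p": p,
                "congruent_positions": congruent,
                "k": len(aln),
                "z_v_lsu": zv_l,
                "z_v_ssu": zv_s,
                "z_v_ave": zv_ave,
                "convergent_lsu": conv_l,
                "convergent_ssu": conv_s,
                "divergent_lsu": div_l,
                "divergent_ssu": div_s,
                "consistently_convergent": bool(
                    (conv_l or conv_s)
                    and not (div_l or div_s)
                    and zv_ave < -CONVERGENCE_Z
                ),
            }
        )
        zc_store[aa] = zc
    table = pd.DataFrame(rows, index=list(AMINO_ACIDS))
    return CongruenceReport(
        table=table,
        z_v_lsu_ave=float(table["z_v_lsu"].mean()),
        z_v_ssu_ave=float(table["z_v_ssu"].mean()),
        k=len(aln),
        position_scores=zc_store,
    )
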