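"""Monotone random-walk alignment of two chronologies on the residual matrix.

The optimal temporal correspondence between the LSU and SSU chronologies
is searched with constrained random walks rather than a single
dynamic-programming optimum: the *landscape* of near-optimal paths — how
concentrated the best-scoring fraction of walks is — is itself the result,
showing how robust the alignment is and which regions of path space drive
the score.

Walk rules on an ``m x n`` matrix (0-based internally; I/O is 1-based):

* start uniformly on a cell of the first row or first column (the shared
  corner counted once);
* from a non-terminal cell move down, right, or diagonally, each legal
  option equally likely — except that a right step may not follow a down
  step, nor a down step a right step (this keeps every row/column pairing
  in a path exclusive);
* the walk ends the moment it occupies any cell of the last row or last
  column;
* the score is the mean residual value over visited cells (lower is
  better).
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .chronology import RmsdMatrix

__all__ = [
    "Walk",
    "PathLandscape",
    "ChronologyAlignment",
    "random_walks",
    "best_paths",
    "path_landscape",
    "extract_alignment",
    "enumerate_walks",
    "optimal_walk_score",
    "validate_walk",
]

_DOWN, _RIGHT, _DIAG, _START = 0, 1, 2, 3


@dataclass(frozen=True)
class Walk:
    """One constrained monotone walk: visited cells (0-based) and mean score."""

    cells: tuple[tuple[int, int], ...]
    score: float


def validate_walk(w: Walk, shape: tuple[int, int]) -> list[str]:
    """Diagnostics for the walk invariants; empty iff the walk is legal."""
    m, n = shape
    out: list[str] = []
    if not w.cells:
        return ["empty walk"]
    r0, c0 = w.cells[0]
    if r0 != 0 and c0 != 0:
        out.append("walk does not start in the first row or column")
    rl, cl = w.cells[-1]
    if rl != m - 1 and cl != n - 1:
        out.append("walk does not end in the last row or column")
    if len(set(w.cells)) != len(w.cells):
        out.append("repeated cell")
    last_move = _START
    for (r1, c1), (r2, c2) in zip(w.cells, w.cells[1:]):
        step = (r2 - r1, c2 - c1)
        if step == (1, 0):
            move = _DOWN
        elif step == (0, 1):
            move = _RIGHT
        elif step == (1, 1):
            move = _DIAG
        else:
            out.append(f"illegal step {step} at {(r1, c1)}")
            break
        if (move == _RIGHT and last_move == _DOWN) or (
            move == _DOWN and last_move == _RIGHT
        ):
            out.append(f"forbidden direction change at {(r1, c1)}")
        last_move = move
    for r, c in w.cells[:-1]:
        if r == m - 1 or c == n - 1:
            out.append(f"walk continued past terminal cell {(r, c)}")
            break
    return out


def _start_cells(m: int, n: int) -> list[tuple[int, int]]:
    cells = [(0, j) for j in range(n)] + [(i, 0) for i in range(1, m)]
    return cells


def random_walks(
    residual: RmsdMatrix | np.ndarray,
    n_walks: int,
    seed: int,
) -> Iterator[Walk]:
    """Generate ``n_walks`` constrained random walks, deterministically per seed."""
    values = residual.values if isinstance(residual, RmsdMatrix) else np.asarray(residual)
    m, n = values.shape
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    rng = _random.Random(seed)
    starts = _start_cells(m, n)
    vals = values.tolist()
    for _ in range(n_walks):
        r, c = starts[rng.randrange(len(starts))]
        cells = [(r, c)]
        total = vals[r][c]
        last = _START
        while r != m - 1 and c != n - 1:
            if last == _DOWN:
                moves = (_DOWN, _DIAG)
            elif last == _RIGHT:
                moves = (_RIGHT, _DIAG)
            else:
                moves = (_DOWN, _RIGHT, _DIAG)
            mv = moves[rng.randrange(len(moves))]
            if mv == _DOWN:
                r += 1
            elif mv == _RIGHT:
                c += 1
            else:
                r += 1
                c += 1
            cells.append((r, c))
            total += vals[r][c]
            last = mv
        yield Walk(tuple(cells), total / len(cells))


@dataclass(frozen=True)
class PathLandscape:
    """Per-cell frequency of membership in the best-scoring fraction of walks."""

    frequency: np.ndarray
    q: float
    n_walks: int
    n_selected: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.frequency,
            index=np.arange(1, self.frequency.shape[0] + 1),
            columns=np.arange(1, self.frequency.shape[1] + 1),
        )
        df.index.name = "lsu_position"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def best_paths(
    walks: Iterable[Walk],
    q: float,
    shape: tuple[int, int] | None = None,
    seed: int | None = None,
) -> PathLandscape:
    """Map the ``q`` best-scoring fraction of walks onto a frequency landscape.

    Selects the ``ceil(q * n)`` lowest-scoring walks (ties broken by
    generation index); each cell's frequency is the fraction of selected
    walks that visit it.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    walks = list(walks)
    if not walks:
        raise ValueError("empty walk set")
    if shape is None:
        mr = max(r for w in walks for r, _ in w.cells)
        mc = max(c for w in walks for _, c in w.cells)
        shape = (mr + 1, mc + 1)
    k = ceil(q * len(walks))
    order = sorted(range(len(walks)), key=lambda i: (walks[i].score, i))[:k]
    freq = np.zeros(shape)
    for i in order:
        for r, c in walks[i].cells:
            freq[r, c] += 1
    return PathLandscape(freq / k, q, len(walks), k, seed)


def path_landscape(
    residual: RmsdMatrix | np.ndarray,
    n_walks: int,
    seed: int,
    q: float,
) -> PathLandscape:
    """Streaming, memory-light version of ``best_paths`` over fresh walks.

    Two deterministic passes over the same seeded walk stream: the first
    collects scores to find the selection threshold, the second
    accumulates cell frequencies of the selected walks.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    values = residual.values if isinstance(residual, RmsdMatrix) else np.asarray(residual)
    scores = np.fromiter(
        (w.score for w in random_walks(values, n_walks, seed)), float, count=n_walks
    )
    k = ceil(q * n_walks)
    order = np.lexsort((np.arange(n_walks), scores))[:k]
    selected = np.zeros(n_walks, dtype=bool)
    selected[order] = True
    freq = np.zeros(values.shape)
    for i, w in enumerate(random_walks(values, n_walks, seed)):
        if selected[i]:
            for r, c in w.cells:
                freq[r, c] += 1
    return PathLandscape(freq / k, q, n_walks, k, seed)


@dataclass(frozen=True)
class ChronologyAlignment:
    """Aligned (LSU, SSU) chronology position pairs, 1-based and monotone."""

    pairs: tuple[tuple[int, int], ...]
    method: str = "best_walk"

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if a2 < a1 or b2 < b1:
                raise ValueError("alignment must be monotone nondecreasing")

    def __len__(self) -> int:
        return len(self.pairs)

    def labels(self) -> list[str]:
        """LSU-numbered labels; repeats of an LSU position carry '(k)'."""
        out, seen = [], {}
        for iL, _ in self.pairs:
            seen[iL] = seen.get(iL, 0) + 1
            out.append(f"{iL}({seen[iL]})" if seen[iL] > 1 else str(iL))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels(),
                "lsu_position": [p[0] for p in self.pairs],
                "ssu_position": [p[1] for p in self.pairs],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def extract_alignment(
    source: Iterable[Walk] | PathLandscape,
    method: str = "best_walk",
) -> ChronologyAlignment:
    """Condense walks (or a landscape) into one chronology alignment.

    ``method="best_walk"`` (default) takes the single best-scoring walk,
    breaking score ties lexicographically on the cell list. With a
    :class:`PathLandscape` input, ``method="ridge"`` runs an exact
    maximum-total-frequency monotone path (same step rules) through the
    landscape — an alternative condensation, not claimed equivalent.
    """
    if isinstance(source, PathLandscape):
        if method != "ridge":
            raise ValueError("landscape input supports method='ridge' only")
        cells = _max_weight_path(source.frequency)
        return ChronologyAlignment(
            tuple((r + 1, c + 1) for r, c in cells), method="ridge"
        )
    best: Walk | None = None
    for w in source:
        if best is None or (w.score, w.cells) < (best.score, best.cells):
            best = w
    if best is None:
        raise ValueError("no walks supplied")
    return ChronologyAlignment(
        tuple((r + 1, c + 1) for r, c in best.cells), method="best_walk"
    )


def _legal_moves(last: int) -> tuple[int, ...]:
    if last == _DOWN:
        return (_DOWN, _DIAG)
    if last == _RIGHT:
        return (_RIGHT, _DIAG)
    return (_DOWN, _RIGHT, _DIAG)


def _apply(move: int, r: int, c: int) -> tuple[int, int]:
    if move == _DOWN:
        return r + 1, c
    if move == _RIGHT:
        return r, c + 1
    return r + 1, c + 1


def enumerate_walks(values: np.ndarray, max_dim: int = 6) -> list[Walk]:
    """Every legal walk, by brute-force DFS. Oracle for small matrices only."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if max(m, n) > max_dim:
        raise ValueError(f"matrix larger than {max_dim}x{max_dim}; refusing to enumerate")
    out: list[Walk] = []

    def rec(r: int, c: int, last: int, cells: list[tuple[int, int]], total: float) -> None:
        if r == m - 1 or c == n - 1:
            out.append(Walk(tuple(cells), total / len(cells)))
            return
        for mv in _legal_moves(last):
            r2, c2 = _apply(mv, r, c)
            rec(r2, c2, mv, cells + [(r2, c2)], total + values[r2, c2])

    for r, c in _start_cells(m, n):
        rec(r, c, _START, [(r, c)], values[r, c])
    return out


def optimal_walk_score(values: np.ndarray) -> float:
    """Exact minimum mean score over all legal walks, by dynamic programming.

    Mean scores of variable-length paths are not directly composable, so
    the DP tracks the minimum *total* score per (cell, last move, path
    length) and minimizes total/length over terminal states. Polynomial in
    the matrix size; the cross-check for the random-walk search.
    """
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    best = np.inf
    # state: (r, c, last, length) -> min total
    from collections import defaultdict

    cur: dict[tuple[int, int, int], float] = defaultdict(lambda: np.inf)
    for r, c in _start_cells(m, n):
        if r == m - 1 or c == n - 1:
            best = min(best, values[r, c])
        else:
            key = (r, c, _START)
            cur[key] = min(cur[key], values[r, c])
    length = 1
    while cur:
        nxt: dict[tuple[int, int, int], float] = defaultdict(lambda: np.inf)
        for (r, c, last), total in cur.items():
            for mv in _legal_moves(last):
                r2, c2 = _apply(mv, r, c)
                t2 = total + values[r2, c2]
                if r2 == m - 1 or c2 == n - 1:
                    best = min(best, t2 / (length + 1))
                else:
                    key = (r2, c2, mv)
                    if t2 < nxt[key]:
                        nxt[key] = t2
        cur = nxt
        length += 1
    return float(best)


def _max_weight_path(freq: np.ndarray) -> list[tuple[int, int]]:
    """Monotone path (same step rules) maximizing *mean* landscape frequency.

    Mean rather than total, so a path is not rewarded merely for being
    long — mirroring the mean-residual scoring of the walks themselves.
    """
    m, n = freq.shape
    best_mean = -np.inf
    best_cells: list[tuple[int, int]] | None = None
    # DP layer by path length; states as in optimal_walk_score but maximizing
    cur: dict[tuple[int, int, int], tuple[float, tuple]] = {}
    for r, c in _start_cells(m, n):
        if r == m - 1 or c == n - 1:
            if freq[r, c] > best_mean:
                best_mean, best_cells = freq[r, c], [(r, c)]
        else:
            key = (r, c, _START)
            state = (freq[r, c], ((r, c),))
            if key not in cur or state > cur[key]:
                cur[key] = state
    length = 1
    while cur:
        nxt: dict[tuple[int, int, int], tuple[float, tuple]] = {}
        for (r, c, last), (total, cells) in cur.items():
            for mv in _legal_moves(last):
                r2, c2 = _apply(mv, r, c)
                t2 = total + freq[r2, c2]
                cells2 = cells + ((r2, c2),)
                if r2 == m - 1 or c2 == n - 1:
                    mean = t2 / (length + 1)
                    if mean > best_mean:
                        best_mean, best_cells = mean, list(cells2)
                else:
                    key = (r2, c2, mv)
                    if key not in nxt or (t2, cells2) > nxt[key]:
                        nxt[key] = (t2, cells2)
        cur = nxt
        length += 1
    assert best_cells is not None
    return best_cells
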