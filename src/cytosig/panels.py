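"""Induction matrices and minimal covering cytokine panels.

An induction matrix is a boolean stimuli × cytokines table: cell (s, c) is
TRUE when cytokine c is among the top-k significance calls for stimulus s.
A *covering panel* is a cytokine subset giving every stimulus at least one
TRUE cell — the basis for reducing a 16-plex assay to a 3- or 4-plex one.

With a 16-cytokine panel, exact search is trivial, so minimal covers are
found by exhaustive enumeration in ascending cardinality rather than a
greedy heuristic; *all* covers of the minimum size are returned, since
alternative panels are of practical interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import NoCoverError, ValidationError

MAX_EXHAUSTIVE_CYTOKINES = 24


@dataclass
class InductionMatrix:
    """Boolean stimuli × cytokines induction calls."""

    stimuli: list[str]
    cytokines: list[str]
    values: np.ndarray          # bool, shape (n_stimuli, n_cytokines)
    provenance: str = "from_grid"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.stimuli), len(self.cytokines)):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.stimuli)} stimuli x {len(self.cytokines)} cytokines")
        if len(set(self.stimuli)) != len(self.stimuli):
            raise ValidationError("duplicate stimulus rows")
        if len(set(self.cytokines)) != len(self.cytokines):
            raise ValidationError("duplicate cytokine columns")

    def row(self, stimulus: str) -> frozenset[str]:
        i = self.stimuli.index(stimulus)
        return frozenset(c for c, v in zip(self.cytokines, self.values[i]) if v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.stimuli,
                            columns=self.cytokines)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame().map(lambda v: "TRUE" if v else "FALSE")
        df.index.name = "stimulus"
        Path(path).write_text(df.to_csv(), encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path,
                 provenance: str = "from_fixture") -> "InductionMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.map(lambda v: str(v).strip().upper() == "TRUE").to_numpy()
        return cls(stimuli=list(df.index), cytokines=list(df.columns),
                   values=values, provenance=provenance)


@dataclass(frozen=True)
class PanelCover:
    """Coverage of a candidate cytokine panel against an induction matrix."""

    cytokines: frozenset[str]
    covered: frozenset[str]
    is_cover: bool
    is_minimum: bool | None = None

    @property
    def size(self) -> int:
        return len(self.cytokines)


@dataclass(frozen=True)
class MinimalCoverResult:
    minimum_size: int
    covers: tuple[tuple[str, ...], ...]   # each in matrix column order

    def to_dict(self, matrix: InductionMatrix) -> dict:
        return {
            "minimum_size": self.minimum_size,
            "n_covers": len(self.covers),
            "covers": [
                {"cytokines": list(panel),
                 "covered_stimuli": sorted(
                     verify_panel(matrix, panel).covered)}
                for panel in self.covers
            ],
        }


def matrix_from_topk(calls, panel) -> InductionMatrix:
    """Build an induction matrix from per-stimulus top-k calls.

    ``calls`` is an iterable of :class:`cytosig.signatures.TopKCall`; one
    call per stimulus.  Stimuli with an empty selection produce an all-FALSE
    row (with a warning) — such rows make a covering panel impossible.
    """
    calls = list(calls)
    stimuli = [c.stimulus for c in calls]
    if len(set(stimuli)) != len(stimuli):
        raise ValidationError("duplicate stimulus in top-k calls")
    cytokines = list(panel)
    values = np.zeros((len(calls), len(cytokines)), dtype=bool)
    for i, call in enumerate(calls):
        if not call.selected:
            warnings.warn(f"stimulus {call.stimulus!r} has no induced "
                          "cytokine; its row is all FALSE", stacklevel=2)
        for cyt in call.selected:
            values[i, cytokines.index(cyt)] = True
    return InductionMatrix(stimuli=stimuli, cytokines=cytokines,
                           values=values, provenance="from_grid")


def verify_panel(matrix: InductionMatrix, panel) -> PanelCover:
    """Which stimuli does ``panel`` cover, and is it a full cover?"""
    panel = list(panel)
    unknown = sorted(set(panel) - set(matrix.cytokines))
    if unknown:
        raise ValidationError(f"panel cytokines not in matrix: {unknown}")
    cols = [matrix.cytokines.index(c) for c in panel]
    hit = matrix.values[:, cols].any(axis=1) if cols else np.zeros(
        len(matrix.stimuli), dtype=bool)
    covered = frozenset(s for s, h in zip(matrix.stimuli, hit) if h)
    return PanelCover(cytokines=frozenset(panel), covered=covered,
                      is_cover=len(covered) == len(matrix.stimuli))


def minimal_covers(matrix: InductionMatrix,
                   max_size: int | None = None) -> MinimalCoverResult:
    """Exhaustively enumerate all minimum-cardinality covering panels.

    Searches cardinality 1, 2, ... and stops at the first cardinality
    admitting at least one cover, returning the complete enumeration at
    that size, ordered lexicographically by column (panel) order.
    """
    n_stim, n_cyt = matrix.values.shape
    empty_rows = [s for s, row in zip(matrix.stimuli, matrix.values)
                  if not row.any()]
    if empty_rows:
        raise NoCoverError(
            f"no covering panel exists; stimuli with no induced cytokine: "
            f"{empty_rows}")
    if n_cyt > MAX_EXHAUSTIVE_CYTOKINES:
        raise ValidationError(
            f"exhaustive search refused beyond {MAX_EXHAUSTIVE_CYTOKINES} "
            f"cytokines (got {n_cyt})")
    limit = n_cyt if max_size is None else min(max_size, n_cyt)
    if limit < 1:
        raise ValidationError("max_size must be >= 1")

    # column bitmasks over stimuli
    masks = [int(sum(1 << i for i in range(n_stim) if matrix.values[i, j]))
             for j in range(n_cyt)]
    full = (1 << n_stim) - 1

    for size in range(1, limit + 1):
        found: list[tuple[str, ...]] = []
        for combo in combinations(range(n_cyt), size):
            acc = 0
            for j in combo:
                acc |= masks[j]
            if acc == full:
                found.append(tuple(matrix.cytokines[j] for j in combo))
        if found:
            return MinimalCoverResult(minimum_size=size, covers=tuple(found))
    raise NoCoverError(f"no cover of size <= {limit} exists")
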