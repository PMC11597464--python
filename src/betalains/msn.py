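"""Multistage-MS (MS2/MS3/MS4) precursor-chain interpretation.

Each consecutive pair of stages in a chain defines a neutral-loss delta;
deltas are matched against a table of named residue losses, and the summed
assigned losses plus a terminal catalog match propose an elemental
composition for the parent ion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .catalog import BetalainRecord, NeutralLoss, NeutralLossTable
from .chem import ElementComposition, compose_add, ppm_error, protonated_mz

__all__ = [
    "MsnChain",
    "LossCandidate",
    "LossAssignment",
    "interpret_chain",
    "propose_composition",
    "assignments_table",
]

DEFAULT_TOL_DA = 0.005


@dataclass(frozen=True)
class MsnChain:
    """Ordered precursor m/z values, parent first, strictly decreasing."""

    stages: tuple[float, ...]
    activation: tuple[str, ...] = ()  # free-text metadata, never interpreted

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("a chain needs at least two stages")
        for a, b in zip(self.stages, self.stages[1:]):
            if b >= a:
                raise ValueError(
                    f"chain must be strictly decreasing, got {a} -> {b}"
                )

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(a - b for a, b in zip(self.stages, self.stages[1:]))


@dataclass(frozen=True)
class LossCandidate:
    loss: NeutralLoss
    deviation_mda: float  # |delta - loss mass| in mDa


@dataclass(frozen=True)
class LossAssignment:
    delta: float
    candidates: tuple[LossCandidate, ...]  # sorted by |deviation|

    @property
    def best(self) -> LossCandidate | None:
        return self.candidates[0] if self.candidates else None

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)


def interpret_chain(
    chain: MsnChain, table: NeutralLossTable, tol: float = DEFAULT_TOL_DA
) -> list[LossAssignment]:
    """One loss assignment per consecutive stage pair.

    Every loss within *tol* Da of the delta is reported, nearest first, so
    near-isobaric residues (e.g. glucuronosyl vs feruloyl, 15.2 mDa apart)
    stay distinguishable without hiding alternatives.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    assignments = []
    for delta in chain.deltas:
        hits = [
            LossCandidate(loss, abs(delta - loss.mass) * 1e3)
            for loss in table
            if abs(delta - loss.mass) <= tol
        ]
        hits.sort(key=lambda c: (c.deviation_mda, c.loss.name))
        assignments.append(LossAssignment(delta=delta, candidates=tuple(hits)))
    return assignments


def propose_composition(
    parent_mz: float,
    assignments: Sequence[LossAssignment],
    terminal_record: BetalainRecord,
) -> tuple[ElementComposition, float, float]:
    """Elemental composition for the chain parent.

    The composition is the terminal record's formula plus every assigned
    loss formula.  Returns ``(composition, theoretical_mz, ppm)`` where ppm
    compares *parent_mz* against the rebuilt theoretical m/z.
    """
    comp = terminal_record.formula
    for assignment in assignments:
        if not assignment.assigned:
            raise ValueError(
                f"unassigned neutral loss of {assignment.delta:.4f} Da; "
                "cannot propose a composition"
            )
        comp = compose_add(comp, assignment.best.loss.formula)
    theoretical = protonated_mz(comp)
    return comp, theoretical, ppm_error(parent_mz, theoretical)


def assignments_table(
    chain: MsnChain, assignments: Iterable[LossAssignment]
) -> pd.DataFrame:
    """Flat table of chain steps and their loss candidates (TSV-friendly)."""
    rows = []
    for (parent, product), assignment in zip(
        zip(chain.stages, chain.stages[1:]), assignments
    ):
        if not assignment.candidates:
            rows.append(
                {
                    "parent_mz": parent, "product_mz": product,
                    "delta_da": assignment.delta, "loss": "unassigned",
                    "loss_formula": "", "deviation_mda": float("nan"), "rank": 0,
                }
            )
            continue
        for rank, cand in enumerate(assignment.candidates, 1):
            rows.append(
                {
                    "parent_mz": parent, "product_mz": product,
                    "delta_da": assignment.delta, "loss": cand.loss.name,
                    "loss_formula": str(cand.loss.formula),
                    "deviation_mda": cand.deviation_mda, "rank": rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "parent_mz", "product_mz", "delta_da", "loss",
            "loss_formula", "deviation_mda", "rank",
        ],
    )
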