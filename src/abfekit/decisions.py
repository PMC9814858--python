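"""Classification of fragment-elaboration decisions from DDG values.

A decision is a named set of (parent, child) ligand pairs that together test
a chemical modification.  For each pair, DDG = DG(child) - DG(parent) is
formed from both the calculated and the experimental binding free energies;
the calculated DDG carries an error propagated in quadrature from the two
replica standard deviations.  A pair is

* ``supported`` when the calculated change has the experimental sign and
  exceeds its propagated error,
* ``direction_correct_within_error`` when the sign is right but the
  magnitude is within the error (sign ties on the experimental side count
  here too),
* ``direction_wrong`` on a sign mismatch.

A decision is supported only when every one of its pairs is supported: a
single insufficiently estimated DDG fails the whole decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .benchmark import LigandRecord


class Verdict(str, Enum):
    SUPPORTED = "supported"
    WITHIN_ERROR = "direction_correct_within_error"
    WRONG = "direction_wrong"


@dataclass(frozen=True)
class PairVerdict:
    """Verdict for one (parent, child) elaboration pair."""

    parent_id: str
    child_id: str
    ddg_exp: float
    ddg_calc: float
    sigma: float
    verdict: Verdict


@dataclass(frozen=True)
class DecisionVerdict:
    """Verdict for one decision (a set of pairs; all must be supported)."""

    decision_id: str
    pairs: tuple[PairVerdict, ...]
    supported: bool


def _sign(x: float) -> int:
    return int(x > 0) - int(x < 0)


def evaluate_pair(
    parent: LigandRecord, child: LigandRecord, error_multiplier: float = 1.0
) -> PairVerdict:
    """Classify one elaboration pair.

    DDG = child - parent for both calculated and experimental values; the
    calculated error is sqrt(sigma_parent^2 + sigma_child^2).  ``supported``
    requires matching signs and |DDG_calc| strictly greater than
    *error_multiplier* times the propagated error.  Records without a
    replica standard deviation raise ``ValueError`` (propagation impossible).
    """
    for rec in (parent, child):
        if rec.replica_std is None:
            raise ValueError(
                f"ligand {rec.ligand_id} has no replica std; cannot propagate DDG error"
            )
    ddg_calc = child.dg_calc - parent.dg_calc
    ddg_exp = child.dg_exp - parent.dg_exp
    sigma = math.sqrt(parent.replica_std**2 + child.replica_std**2)
    if _sign(ddg_calc) != 0 and _sign(ddg_exp) != 0 and _sign(ddg_calc) != _sign(ddg_exp):
        verdict = Verdict.WRONG
    elif abs(ddg_calc) > error_multiplier * sigma and _sign(ddg_exp) != 0:
        verdict = Verdict.SUPPORTED
    else:
        verdict = Verdict.WITHIN_ERROR
    return PairVerdict(
        parent_id=parent.ligand_id,
        child_id=child.ligand_id,
        ddg_exp=ddg_exp,
        ddg_calc=ddg_calc,
        sigma=sigma,
        verdict=verdict,
    )


def evaluate_decision(
    decision_id: str,
    pairs: list[tuple[str, str]],
    records: dict[str, LigandRecord],
    error_multiplier: float = 1.0,
) -> DecisionVerdict:
    """Classify a decision from its (parent, child) id pairs.

    A decision with no pairs, or referencing an unknown ligand id, raises
    ``ValueError`` naming the problem.  The decision is supported only when
    every pair verdict is ``supported``.
    """
    if not pairs:
        raise ValueError(f"decision {decision_id!r} contains no ligand pairs")
    verdicts = []
    for parent_id, child_id in pairs:
        for lig in (parent_id, child_id):
            if lig not in records:
                raise ValueError(f"decision {decision_id!r}: unknown ligand id {lig!r}")
        verdicts.append(
            evaluate_pair(records[parent_id], records[child_id], error_multiplier)
        )
    return DecisionVerdict(
        decision_id=decision_id,
        pairs=tuple(verdicts),
        supported=all(v.verdict is Verdict.SUPPORTED for v in verdicts),
    )


def evaluate_decision_table(
    rows: list[tuple[str, str, str]],
    records: dict[str, LigandRecord],
    error_multiplier: float = 1.0,
) -> list[DecisionVerdict]:
    """Group (decision_id, parent, child) rows and evaluate each decision,
    preserving first-appearance order of decision ids."""
    grouped: dict[str, list[tuple[str, str]]] = {}
    for decision_id, parent, child in rows:
        grouped.setdefault(decision_id, []).append((parent, child))
    return [
        evaluate_decision(decision_id, pairs, records, error_multiplier)
        for decision_id, pairs in grouped.items()
    ]


def tally(verdicts: list[DecisionVerdict]) -> dict[str, int]:
    """Summary counts over decisions and their pairs.

    ``n_pairs_direction_correct`` counts pairs whose verdict is not
    ``direction_wrong`` (the predicted sign of the affinity change matches
    experiment, whether or not it clears the error bar).
    """
    if not verdicts:
        raise ValueError("no decision verdicts to tally")
    all_pairs = [p for v in verdicts for p in v.pairs]
    return {
        "n_decisions": len(verdicts),
        "n_supported": sum(v.supported for v in verdicts),
        "n_pairs": len(all_pairs),
        "n_pairs_direction_correct": sum(
            p.verdict is not Verdict.WRONG for p in all_pairs
        ),
    }
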