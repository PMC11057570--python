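"""Interaction-term decomposition of the TAS score.

Writing each scaled value as 0.5 + alpha (alpha = deviation from the
threshold), the TAS score of a triad decomposes into three interaction
masses:

* ``i_t`` = 0.75, the reference interaction generated by the thresholds
  themselves;
* ``i_p`` >= 0, the interaction mass contributed by non-negative
  deviations (axes at or above threshold);
* ``i_n`` <= 0, the mass contributed by negative deviations, which acts
  purely as a penalty.

Then TAS = 1/2 * [ (i_t + i_p + i_n) / (i_t + i_p) + I * (4/9) * i_p ],
with I = 1 iff all three deviations are non-negative. This is an exact
algebraic reformulation of the area-based definition and serves both as
an independent cross-check and as an interpretable per-triad output: it
makes explicit that sub-threshold axes can offset supra-threshold ones
before diagnosis, while after diagnosis the positive mass counts without
penalty.

The four cases index the sign pattern: case 1 has no non-negative
deviation, case 4 has three. The case formulas assume the non-negative
deviations occupy the leading positions, so inputs are canonically
sorted (descending) before the formulas are applied; TAS itself is
permutation-invariant, so this loses nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["InteractionTerms", "decompose", "tas_via_interactions"]

I_T: float = 0.75


@dataclass(frozen=True)
class InteractionTerms:
    alpha: tuple[float, float, float]
    i_t: float
    i_p: float
    i_n: float
    indicator: int
    case_id: int


def decompose(x1: float, x2: float, x3: float) -> InteractionTerms:
    """Decompose a triad of scaled values into interaction terms."""
    for v in (x1, x2, x3):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"scaled value {v!r} outside [0, 1]")
    # sort descending so non-negative deviations lead, as the case
    # formulas require
    a1, a2, a3 = sorted((x1 - 0.5, x2 - 0.5, x3 - 0.5), reverse=True)
    n_pos = sum(a >= 0 for a in (a1, a2, a3))
    case_id = n_pos + 1
    if case_id == 1:
        i_p = 0.0
        i_n = a1 + a2 + a3 + a1 * a2 + a2 * a3 + a3 * a1
    elif case_id == 2:
        i_p = a1 + a1 * a2 + a3 * a1
        i_n = a2 + a3 + a2 * a3
    elif case_id == 3:
        i_p = a1 + a2 + a1 * a2 + a2 * a3 + a3 * a1
        i_n = a3
    else:
        i_p = a1 + a2 + a3 + a1 * a2 + a2 * a3 + a3 * a1
        i_n = 0.0
    return InteractionTerms(
        alpha=(a1, a2, a3),
        i_t=I_T,
        i_p=i_p,
        i_n=i_n,
        indicator=int(case_id == 4),
        case_id=case_id,
    )


def tas_via_interactions(terms: InteractionTerms) -> float:
    """TAS from interaction terms; agrees with the area-based score."""
    return 0.5 * (
        (terms.i_t + terms.i_p + terms.i_n) / (terms.i_t + terms.i_p)
        + terms.indicator * (4.0 / 9.0) * terms.i_p
    )
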