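"""Steady-state nascent-length-resolved folding probability.

Under steady-state translation, two-state folding and exponential dwells,
the probability that the domain is folded at the moment the ribosome
elongates away from codon ``i`` obeys the recursion

    P(0) = 0
    P(i) = P_eq,i + (P(i-1) - P_eq,i) * lambda_i,
    lambda_i = k_A,i / (k_A,i + k_F,i + k_U,i)

with ``P_eq,i = k_F,i / (k_F,i + k_U,i)`` and ``P(i) = P(i-1)`` where both
folding rates vanish (below the exit-tunnel onset).  ``lambda_i`` is the
Laplace transform of the exponential dwell evaluated at the folding
relaxation rate, i.e. the dwell-averaged memory factor.

The value at the stop codon, ``P_F,Co-T = P(M)``, is the probability that
the domain is folded when synthesis terminates; domains with
``P_F,Co-T >= 0.5`` fold predominantly co-translationally.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .constructs import FoldingKinetics
from .rate_tables import TranslationSchedule

__all__ = [
    "SteadyStateProfile",
    "FoldingClass",
    "steady_state_profile",
    "classify",
]


class FoldingClass(str, Enum):
    CO_TRANSLATIONAL = "co-translational"
    POST_TRANSLATIONAL = "post-translational"


@dataclass(frozen=True)
class SteadyStateProfile:
    """P_F,B(i) versus nascent length i = 1..M (probabilities)."""

    values: np.ndarray
    onset: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float).copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def M(self) -> int:
        return int(self.values.size)

    @property
    def p_co_t(self) -> float:
        """P_F,Co-T: folded probability at the stop codon (after its dwell)."""
        return float(self.values[-1])


def steady_state_profile(
    kinetics: FoldingKinetics,
    schedule: TranslationSchedule,
    convention: str = "departure",
) -> SteadyStateProfile:
    """Length-resolved folded probability under steady-state translation.

    ``convention`` selects what is reported per position:

    - ``"departure"``: the folded probability at the instant the ribosome
      elongates away from codon i, averaged over the exponential dwell
      (the recursion above).
    - ``"residence"``: the time-average of the folded probability over the
      occupancy of codon i.  For exponential dwells the renewal-reward
      integral reduces to exactly the same factor lambda_i, so the two
      conventions coincide; both are kept because they differ for any
      non-exponential dwell model.

    The propagated state is always the departure value.
    """
    if convention not in ("departure", "residence"):
        raise ValueError(f"unknown convention {convention!r}")
    if kinetics.M != schedule.M:
        raise ValueError(
            f"kinetics length {kinetics.M} != schedule length {schedule.M}"
        )
    kF, kU, kA = kinetics.kF, kinetics.kU, schedule.rates
    M = kinetics.M
    values = np.zeros(M)
    p = 0.0
    for i in range(M):
        K = kF[i] + kU[i]
        if K > 0.0:
            p_eq = kF[i] / K
            lam = kA[i] / (kA[i] + K)
            p_next = p_eq + (p - p_eq) * lam
            if convention == "residence":
                # time-averaged occupancy value: p_eq + (p_prev - p_eq) *
                # k_A * (1 - lam) / K  (== lam analytically)
                values[i] = p_eq + (p - p_eq) * kA[i] * (1.0 - lam) / K
            else:
                values[i] = p_next
            p = p_next
        else:
            values[i] = p  # zero below onset
    return SteadyStateProfile(values=values, onset=kinetics.onset)


def classify(
    profile: SteadyStateProfile | float, threshold: float = 0.5
) -> FoldingClass:
    """Co- vs post-translational folding from P_F,Co-T.

    ``P_F,Co-T >= threshold`` (inclusive) classifies the domain as
    predominantly co-translationally folding.
    """
    p = profile.p_co_t if isinstance(profile, SteadyStateProfile) else float(profile)
    if p >= threshold:
        return FoldingClass.CO_TRANSLATIONAL
    return FoldingClass.POST_TRANSLATIONAL
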