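"""Per-codon translation-rate tables and per-transcript schedules.

A :class:`CodonRateTable` holds literature-style per-codon elongation
estimates, either as translation times (seconds per codon) or rates (amino
acids per second).  :func:`build_schedule` maps a table onto a CDS to produce
the per-position elongation rates ``k_A,i`` (one per codon position,
including the stop codon at position ``M``); :func:`scale_to_target`
implements the global rescaling used to transfer rate estimates between
organisms (multiply every rate by ``chi`` so that the arithmetic-mean rate
over a reference CDS hits a target, e.g. 3.9 AA/s); and
:func:`recode_slowest_synonymous` substitutes every sense codon with its
slowest synonymous codon, the in-silico mutation used to probe switching
between post- and co-translational folding.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Mapping

import numpy as np

from ._codons import (
    ALL_CODONS,
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMS,
    AlphabetError,
    CodingFrameError,
    normalize_codon,
    split_codons,
)

__all__ = [
    "ValueKind",
    "MissingPolicy",
    "CodonRateTable",
    "TranslationSchedule",
    "ScalingResult",
    "build_schedule",
    "scale_to_target",
    "recode_slowest_synonymous",
    "AlphabetError",
    "CodingFrameError",
]

#: default dwell time assigned to stop codons absent from a table, seconds.
#: This is the measured mean codon translation time in CHO cells (256 ms,
#: i.e. 3.9 AA/s).
DEFAULT_STOP_TIME_S = 0.256


class ValueKind(str, Enum):
    TIME = "time"  # seconds per codon
    RATE = "rate"  # amino acids (codons) per second


class MissingPolicy(str, Enum):
    TABLE_MEAN = "table-mean"
    ERROR = "error"


@dataclass(frozen=True)
class CodonRateTable:
    """Per-codon translation time or rate estimates.

    Parameters
    ----------
    entries
        Mapping codon -> value.  Codons may be DNA or RNA; they are
        normalized to RNA.  Values must be strictly positive and finite and
        are all interpreted per ``value_kind``.
    value_kind
        Whether ``entries`` stores times (s/codon) or rates (AA/s).
    provenance
        Free-text label for the source of the estimates.
    """

    entries: Mapping[str, float]
    value_kind: ValueKind = ValueKind.TIME
    provenance: str = ""

    def __post_init__(self) -> None:
        kind = ValueKind(self.value_kind)
        norm: dict[str, float] = {}
        for codon, value in self.entries.items():
            c = normalize_codon(codon)
            v = float(value)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"value for codon {c} must be positive and finite, got {v}"
                )
            if c in norm and norm[c] != v:
                raise ValueError(f"conflicting duplicate entries for codon {c}")
            norm[c] = v
        if not norm:
            raise ValueError("rate table has no entries")
        object.__setattr__(self, "entries", norm)
        object.__setattr__(self, "value_kind", kind)

    def __contains__(self, codon: str) -> bool:
        return normalize_codon(codon) in self.entries

    @property
    def mean_value(self) -> float:
        """Mean of the stored values, in the table's own ``value_kind``."""
        return float(np.mean(list(self.entries.values())))

    def time_s(self, codon: str, default: float | None = None) -> float:
        """Translation time of ``codon`` in seconds (exact reciprocal of rate)."""
        c = normalize_codon(codon)
        v = self.entries.get(c)
        if v is None:
            if default is None:
                raise KeyError(f"codon {c} not in table")
            return default
        return v if self.value_kind is ValueKind.TIME else 1.0 / v

    def rate(self, codon: str, default: float | None = None) -> float:
        """Translation rate of ``codon`` in AA/s."""
        d = None if default is None else 1.0 / default
        return 1.0 / self.time_s(codon, default=None if d is None else 1.0 / d)

    def fallback_time_s(self) -> float:
        """Time equivalent of the table-mean value (missing-codon filler)."""
        m = self.mean_value
        return m if self.value_kind is ValueKind.TIME else 1.0 / m

    def scaled_by(self, chi: float) -> "CodonRateTable":
        """Return the table with every *rate* multiplied by ``chi``."""
        if chi <= 0:
            raise ValueError("chi must be positive")
        factor = 1.0 / chi if self.value_kind is ValueKind.TIME else chi
        return CodonRateTable(
            entries={c: v * factor for c, v in self.entries.items()},
            value_kind=self.value_kind,
            provenance=f"{self.provenance} (scaled, chi={chi:g})".strip(),
        )

    @classmethod
    def uniform(cls, time_s: float, provenance: str = "uniform") -> "CodonRateTable":
        """Complete 64-codon table with one common translation time."""
        return cls(
            entries={c: time_s for c in ALL_CODONS},
            value_kind=ValueKind.TIME,
            provenance=provenance,
        )


@dataclass(frozen=True)
class TranslationSchedule:
    """Per-position elongation rates ``k_A,i`` for codon positions 1..M.

    Position ``M`` is the stop codon; the dwell there is a real dwell during
    which folding can still occur.  ``tau_cum[i-1]`` is the cumulative mean
    time sum_{j<=i} 1/k_A,j in seconds.
    """

    rates: np.ndarray  # AA per second, length M

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 1 or r.size < 1:
            raise ValueError("schedule must be a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("all k_A,i must be positive and finite")
        r = r.copy()
        r.setflags(write=False)
        object.__setattr__(self, "rates", r)

    @property
    def M(self) -> int:
        return int(self.rates.size)

    @cached_property
    def dwell_times(self) -> np.ndarray:
        """Mean dwell time 1/k_A,i at each position, seconds."""
        d = 1.0 / self.rates
        d.setflags(write=False)
        return d

    @cached_property
    def tau_cum(self) -> np.ndarray:
        """Cumulative mean times tau_cum(i) = sum_{j<=i} 1/k_A,j, seconds."""
        t = np.cumsum(self.dwell_times)
        t.setflags(write=False)
        return t

    @property
    def total_time_s(self) -> float:
        """Mean synthesis time tau_cum(M), seconds."""
        return float(self.tau_cum[-1])

    def scaled(self, factor: float) -> "TranslationSchedule":
        """Multiply every k_A,i by ``factor`` (global speed-up/slow-down)."""
        return TranslationSchedule(self.rates * float(factor))

    @classmethod
    def uniform(cls, M: int, rate_aa_per_s: float) -> "TranslationSchedule":
        """Uniform schedule: every codon translated at the same rate."""
        return cls(np.full(int(M), float(rate_aa_per_s)))


@dataclass(frozen=True)
class ScalingResult:
    """Outcome of matching a table's CDS-mean rate to a target."""

    chi: float
    scaled_table: CodonRateTable
    achieved_mean_rate: float  # AA/s over the reference CDS
    unscaled_mean_rate: float = field(default=float("nan"))


def _position_times(
    codons: list[str],
    table: CodonRateTable,
    stop_default_time: float,
    missing_policy: MissingPolicy,
) -> np.ndarray:
    """Per-position translation times with the missing-codon fallback rules."""
    fallback = table.fallback_time_s()
    times = np.empty(len(codons))
    for i, codon in enumerate(codons):
        if codon in table:
            times[i] = table.time_s(codon)
        elif codon in STOP_CODONS:
            times[i] = stop_default_time
        elif missing_policy is MissingPolicy.ERROR:
            raise KeyError(f"codon {codon} (position {i + 1}) not in table")
        else:
            times[i] = fallback
    return times


def build_schedule(
    cds: str,
    table: CodonRateTable,
    stop_default_time: float = DEFAULT_STOP_TIME_S,
    missing_policy: MissingPolicy | str = MissingPolicy.TABLE_MEAN,
) -> TranslationSchedule:
    """Map a codon rate table onto a CDS, one rate per position incl. stop.

    Sense codons missing from the table are filled per ``missing_policy``
    (default: the table's mean value, the occupancy-1.000 convention);
    missing stop codons are filled with ``stop_default_time`` seconds.
    Internal stop codons trigger a warning only (polyproteins are in scope).
    """
    codons = split_codons(cds)
    policy = MissingPolicy(missing_policy)
    if stop_default_time <= 0:
        raise ValueError("stop_default_time must be positive")
    internal_stops = [
        i + 1 for i, c in enumerate(codons[:-1]) if c in STOP_CODONS
    ]
    if internal_stops:
        warnings.warn(
            f"internal stop codon(s) at position(s) {internal_stops}",
            stacklevel=2,
        )
    times = _position_times(codons, table, stop_default_time, policy)
    return TranslationSchedule(1.0 / times)


def scale_to_target(
    table: CodonRateTable,
    reference_cds: str,
    target_mean_rate: float,
    stop_default_time: float = DEFAULT_STOP_TIME_S,
    missing_policy: MissingPolicy | str = MissingPolicy.TABLE_MEAN,
) -> ScalingResult:
    """Rescale a table so its mean rate over ``reference_cds`` hits a target.

    The unscaled per-position rates are the reciprocals of the table's times
    matched to the CDS sense codons (a trailing stop codon is excluded; the
    reference length is the protein length).  The *arithmetic* mean of those
    rates is taken — the printed convention: sum of rates divided by the
    number of codons — and ``chi = target / mean``; every rate in the table
    is then multiplied by ``chi``.
    """
    if target_mean_rate <= 0:
        raise ValueError("target_mean_rate must be positive")
    codons = split_codons(reference_cds)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("reference CDS has no sense codons")
    times = _position_times(
        codons, table, stop_default_time, MissingPolicy(missing_policy)
    )
    unscaled_mean = float(np.mean(1.0 / times))
    chi = target_mean_rate / unscaled_mean
    scaled = table.scaled_by(chi)
    achieved = float(
        np.mean(
            1.0
            / _position_times(
                codons,
                scaled,
                stop_default_time / chi,
                MissingPolicy(missing_policy),
            )
        )
    )
    return ScalingResult(
        chi=chi,
        scaled_table=scaled,
        achieved_mean_rate=achieved,
        unscaled_mean_rate=unscaled_mean,
    )


def slowest_synonym(codon: str, table: CodonRateTable) -> str:
    """Slowest synonymous codon under ``table`` (lexicographic tie-break)."""
    c = normalize_codon(codon)
    if c in STOP_CODONS:
        return c
    fallback = table.fallback_time_s()
    candidates = SYNONYMS[CODON_TO_AA[c]]
    times = {cc: table.time_s(cc, default=fallback) for cc in candidates}
    slowest = max(times.values())
    # ties resolved by the lexicographically smallest codon, for determinism
    return min(cc for cc, t in times.items() if t == slowest)


def recode_slowest_synonymous(cds: str, table: CodonRateTable) -> str:
    """Replace every sense codon by its slowest synonymous codon.

    The encoded protein sequence is unchanged; stop codons are untouched.
    Missing codons take the table-mean fallback time, so a table need not be
    complete.  The output alphabet (DNA/RNA) follows the input.
    """
    codons = split_codons(cds)
    recoded = [slowest_synonym(c, table) for c in codons]
    out = "".join(recoded)
    if "T" in cds.upper() and "U" not in cds.upper():
        out = out.replace("U", "T")
    return out
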