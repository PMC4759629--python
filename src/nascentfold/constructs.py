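"""Protein construct geometry and per-length folding kinetics.

A :class:`Construct` couples a coding sequence's length ``M`` (stop codon
included at position ``M``) with the boundaries of the co-translationally
folding domain, the exit-tunnel linker length, the set of codon positions
whose residues carry detectable radiolabel, and the domain's bulk folding
and unfolding rates.

The model's steric assumption is encoded by :func:`folding_onset`: a domain
can only fold once it has fully emerged from the ribosome exit tunnel, i.e.
at nascent lengths >= domain_end + tunnel_length.  Below the onset both
rates are zero; at and beyond it they equal the bulk rates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Construct",
    "FoldingKinetics",
    "ConfigurationError",
    "folding_onset",
    "build_kinetics",
    "renumber_domains",
    "observable_set_from_labelled_residues",
]

#: default number of residues occluded by the ribosome exit tunnel
DEFAULT_TUNNEL_LENGTH = 30


class ConfigurationError(ValueError):
    """A construct whose geometry is internally inconsistent."""


def folding_onset(
    domain_end: int, tunnel_length: int, total_codons: int | None = None
) -> int:
    """First nascent-chain length at which the domain may fold.

    Equals ``domain_end + tunnel_length``: the domain's last residue plus the
    linker needed to clear the exit tunnel.  Folding rates are identically
    zero strictly below this length.
    """
    if domain_end < 1:
        raise ValueError("domain_end must be >= 1")
    if tunnel_length < 0:
        raise ValueError("tunnel_length must be >= 0")
    onset = int(domain_end) + int(tunnel_length)
    if total_codons is not None and onset >= total_codons:
        raise ConfigurationError(
            f"folding onset {onset} >= M={total_codons}: the domain can "
            "never fold on the ribosome"
        )
    return onset


@dataclass(frozen=True)
class Construct:
    """A protein construct as seen by the folding model.

    ``total_codons`` (M) includes the stop codon at position M; the domain
    and observable positions are sense-codon indices in ``[1, M-1]``.
    """

    name: str
    total_codons: int
    domain_start: int
    domain_end: int
    bulk_kF: float  # per second
    bulk_kU: float  # per second
    tunnel_length: int = DEFAULT_TUNNEL_LENGTH
    observable_codons: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        M = int(self.total_codons)
        if not (1 <= self.domain_start <= self.domain_end < M):
            raise ConfigurationError(
                f"require 1 <= domain_start <= domain_end < M; got "
                f"{self.domain_start}..{self.domain_end}, M={M}"
            )
        if self.tunnel_length < 0:
            raise ConfigurationError("tunnel_length must be >= 0")
        if self.bulk_kF < 0 or self.bulk_kU < 0 or (
            self.bulk_kF == 0 and self.bulk_kU == 0
        ):
            raise ConfigurationError(
                "bulk rates must be >= 0 and not both zero"
            )
        obs = self.observable_codons
        if obs is None:
            obs = frozenset(range(self.domain_start, self.domain_end + 1))
        else:
            obs = frozenset(int(i) for i in obs)
            if obs and not all(1 <= i <= M - 1 for i in obs):
                raise ConfigurationError(
                    "observable_codons must lie in [1, M-1]"
                )
        object.__setattr__(self, "observable_codons", obs)
        # validate the onset is reachable
        folding_onset(self.domain_end, self.tunnel_length, M)

    @property
    def M(self) -> int:
        return int(self.total_codons)

    @property
    def onset(self) -> int:
        return folding_onset(self.domain_end, self.tunnel_length)

    @property
    def p_eq_bulk(self) -> float:
        """Bulk equilibrium folded probability k_F / (k_F + k_U)."""
        return self.bulk_kF / (self.bulk_kF + self.bulk_kU)

    def with_rates(
        self, kF_factor: float = 1.0, kU_factor: float = 1.0
    ) -> "Construct":
        """Copy with bulk rates multiplied by the given factors."""
        return replace(
            self,
            bulk_kF=self.bulk_kF * kF_factor,
            bulk_kU=self.bulk_kU * kU_factor,
        )

    def with_tunnel(self, tunnel_length: int) -> "Construct":
        return replace(self, tunnel_length=int(tunnel_length))


@dataclass(frozen=True)
class FoldingKinetics:
    """Per-position folding/unfolding rates k_F,i, k_U,i for i = 1..M.

    Exactly two regimes: zero below ``onset`` and the bulk rates at and
    beyond it.  ``p_eq`` is k_F,i/(k_F,i+k_U,i) where the denominator is
    positive, NaN elsewhere.
    """

    kF: np.ndarray
    kU: np.ndarray
    onset: int

    def __post_init__(self) -> None:
        kF = np.asarray(self.kF, float).copy()
        kU = np.asarray(self.kU, float).copy()
        if kF.shape != kU.shape or kF.ndim != 1:
            raise ValueError("kF and kU must be 1-D arrays of equal length")
        kF.setflags(write=False)
        kU.setflags(write=False)
        object.__setattr__(self, "kF", kF)
        object.__setattr__(self, "kU", kU)

    @property
    def M(self) -> int:
        return int(self.kF.size)

    @property
    def p_eq(self) -> np.ndarray:
        total = self.kF + self.kU
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.kF / total, np.nan)

    @property
    def bulk_kF(self) -> float:
        return float(self.kF[-1])

    @property
    def bulk_kU(self) -> float:
        return float(self.kU[-1])


def build_kinetics(construct: Construct) -> FoldingKinetics:
    """Piecewise-constant rate profiles from a construct (two regimes)."""
    M = construct.M
    onset = folding_onset(construct.domain_end, construct.tunnel_length, M)
    kF = np.zeros(M)
    kU = np.zeros(M)
    kF[onset - 1 :] = construct.bulk_kF
    kU[onset - 1 :] = construct.bulk_kU
    return FoldingKinetics(kF=kF, kU=kU, onset=onset)


def renumber_domains(
    domains: Sequence[Sequence[tuple[int, int]]],
    min_length: int = 50,
    strict: bool = True,
) -> list[tuple[int, int]]:
    """Split multi-segment domains into contiguous, renumbered domains.

    ``domains`` is an ordered list of domain definitions, each a list of
    (start, end) residue intervals (1-based, inclusive).  Every contiguous
    segment becomes its own domain; segments of ``min_length`` residues or
    fewer are discarded (the rule is strict ``> min_length``; pass
    ``strict=False`` for inclusive ``>=``).  Surviving segments keep the
    original domain order, then segment order.
    """
    out: list[tuple[int, int]] = []
    for dom in domains:
        segs = [(int(s), int(e)) for s, e in dom]
        for s, e in segs:
            if s > e:
                raise ValueError(f"invalid segment ({s}, {e})")
        segs_sorted = sorted(segs)
        for (s1, e1), (s2, e2) in zip(segs_sorted, segs_sorted[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping segments ({s1},{e1}) and ({s2},{e2}) "
                    "within one domain"
                )
        for s, e in segs:
            length = e - s + 1
            if length > min_length or (not strict and length == min_length):
                out.append((s, e))
    return out


def observable_set_from_labelled_residues(
    labelled_positions: Iterable[int],
    domain: tuple[int, int],
) -> frozenset[int]:
    """Codon positions that are both labelled and inside the segment of
    interest.

    ``domain`` is the (start, end) interval of the segment whose folding is
    monitored; only labelled residues inside it make the chain visible to
    the assay.  An empty result triggers a warning (the construct would be
    invisible).
    """
    start, end = int(domain[0]), int(domain[1])
    obs = frozenset(
        int(p) for p in labelled_positions if start <= int(p) <= end
    )
    if not obs:
        warnings.warn(
            "no labelled residues inside the segment of interest: construct "
            "is invisible to the assay",
            stacklevel=2,
        )
    return obs
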