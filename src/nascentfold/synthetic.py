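"""Synthetic fixtures: CDSs, rate tables, constructs and FactSeq-like
signals, plus the published-parameter construct presets.

Every stage of the pipeline is testable offline: :func:`generate_fixture`
produces a self-consistent (CDS, rate table, construct, signal) bundle in a
chosen folding/translation timescale regime, and :func:`table1_presets`
returns the four experimentally characterized constructs (SFVP WT/dC, FRB,
HA1) and the four yeast domains with their literature bulk rates, all with
the default uniform 3.9 AA/s schedule.

Timescale regimes
-----------------
``fast_folder``   k_F far above the elongation rate: P_F,Co-T > 0.95.
``slow_folder``   k_F far below it: P_F,Co-T < 0.05.
``marginal``      k_F within 10x of the mean k_A and only a handful of
                  codon positions beyond the folding onset, so
                  0.05 < P_F,Co-T < 0.95 (rejection-sampled).  With many
                  post-onset positions a k_F ~ k_A domain saturates, which
                  is why marginal fixtures keep the onset close to the stop
                  codon, as in the yeast presets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codons import SENSE_CODONS, STOP_CODONS
from .constructs import Construct, build_kinetics
from .rate_tables import CodonRateTable, TranslationSchedule, ValueKind, build_schedule
from .steady_state import steady_state_profile

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "table1_presets"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture bundle."""

    cds_length_codons: int = 90  # including the stop codon
    regime: str = "marginal"  # fast_folder | slow_folder | marginal
    time_log_mean: float = float(np.log(0.25))  # log-normal codon times, s
    time_log_sigma: float = 0.4
    tunnel_length: int = 10
    # FactSeq-like signal parameters
    baseline_mean: float = 0.05
    baseline_sd: float = 0.03
    region3_shift: float = 0.5
    seed: int = 0
    max_tries: int = 500

    def __post_init__(self) -> None:
        if self.cds_length_codons < self.tunnel_length + 5:
            raise ValueError("CDS too short for the tunnel length")
        if self.regime not in ("fast_folder", "slow_folder", "marginal"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class Fixture:
    cds: str
    table: CodonRateTable
    construct: Construct
    schedule: TranslationSchedule
    signal: np.ndarray
    p_co_t: float


_REGIME_BANDS = {
    "fast_folder": (0.95, 1.0),
    "slow_folder": (0.0, 0.05),
    "marginal": (0.05, 0.95),
}
# log10 range of k_F relative to the mean k_A, per regime
_KF_LOG10_RANGE = {
    "fast_folder": (1.5, 3.0),
    "slow_folder": (-3.0, -1.5),
    "marginal": (-1.0, 1.0),  # within 10x of k_A
}


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a self-consistent synthetic bundle for ``spec``.

    The same seed always yields the same bundle.  The construct's bulk
    rates are rejection-sampled until P_F,Co-T lands in the regime band;
    unsatisfiable specs fail after ``max_tries`` with diagnostics.
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.cds_length_codons

    table = CodonRateTable(
        entries={
            c: float(t)
            for c, t in zip(
                SENSE_CODONS + tuple(STOP_CODONS),
                rng.lognormal(spec.time_log_mean, spec.time_log_sigma, 64),
            )
        },
        value_kind=ValueKind.TIME,
        provenance=f"synthetic log-normal (seed={spec.seed})",
    )
    sense = rng.choice(SENSE_CODONS, size=M - 1)
    stop = rng.choice(sorted(STOP_CODONS))
    cds = "".join(sense) + stop
    schedule = build_schedule(cds, table)
    mean_kA = float(np.mean(schedule.rates[:-1]))

    # geometry: few post-onset positions keep marginal fixtures unsaturated
    n_post = int(rng.integers(3, 16))
    domain_end = M - n_post - spec.tunnel_length
    if domain_end < 1:
        raise ValueError("CDS too short for the requested geometry")

    lo, hi = _REGIME_BANDS[spec.regime]
    lg_lo, lg_hi = _KF_LOG10_RANGE[spec.regime]
    tried: list[float] = []
    for _ in range(spec.max_tries):
        kF = mean_kA * 10.0 ** rng.uniform(lg_lo, lg_hi)
        kU = kF * 10.0 ** (-rng.uniform(1.5, 3.0))
        construct = Construct(
            name=f"synthetic-{spec.regime}-{spec.seed}",
            total_codons=M,
            domain_start=1,
            domain_end=domain_end,
            tunnel_length=spec.tunnel_length,
            bulk_kF=kF,
            bulk_kU=kU,
        )
        profile = steady_state_profile(build_kinetics(construct), schedule)
        p = profile.p_co_t
        tried.append(p)
        if lo < p < hi:
            signal = np.clip(
                rng.normal(spec.baseline_mean, spec.baseline_sd, M), 0.0, None
            )
            signal[construct.onset - 1 :] += spec.region3_shift
            return Fixture(
                cds=cds,
                table=table,
                construct=construct,
                schedule=schedule,
                signal=signal,
                p_co_t=p,
            )
    raise RuntimeError(
        f"regime {spec.regime!r} unsatisfiable after {spec.max_tries} tries "
        f"(seed={spec.seed}); sampled P_F,Co-T range "
        f"[{min(tried):.3g}, {max(tried):.3g}]"
    )


def table1_presets() -> dict[str, tuple[Construct, TranslationSchedule]]:
    """Published model parameters for the characterized constructs.

    Each entry maps a name to ``(construct, schedule)``, with a uniform
    3.9 AA/s schedule (the measured mean elongation rate; replace the
    schedule to drop the uniform-rate assumption).  The SFVP observable
    sets stop at the last radiolabelled (Met) position; FRB, HA1 and the
    yeast domains are observable over the whole domain.
    """
    rows: dict[str, dict] = {
        "SFVP_WT": dict(
            total_codons=1257, domain_start=1, domain_end=267,
            bulk_kF=20.0, bulk_kU=4.34e-5,
            observable_codons=frozenset(range(1, 256)),
        ),
        "SFVP_dC": dict(
            total_codons=1145, domain_start=1, domain_end=155,
            bulk_kF=20.0, bulk_kU=4.34e-5,
            observable_codons=frozenset(range(1, 144)),
        ),
        "FRB": dict(
            total_codons=379, domain_start=1, domain_end=99,
            bulk_kF=15.93, bulk_kU=0.72,
        ),
        "HA1": dict(
            total_codons=565, domain_start=53, domain_end=275,
            bulk_kF=0.1378, bulk_kU=7.58e-5,
        ),
        "DHOM": dict(
            total_codons=359, domain_start=1, domain_end=161,
            bulk_kF=0.0240, bulk_kU=2.48e-8,
        ),
        "SBA1": dict(
            total_codons=216, domain_start=1, domain_end=135,
            bulk_kF=0.0721, bulk_kU=5.40e-6,
        ),
        "EF2": dict(
            total_codons=842, domain_start=570, domain_end=721,
            bulk_kF=0.0501, bulk_kU=1.03e-7,
        ),
        "DPP3": dict(
            total_codons=711, domain_start=431, domain_end=671,
            bulk_kF=0.1811, bulk_kU=4.33e-9,
        ),
    }
    out: dict[str, tuple[Construct, TranslationSchedule]] = {}
    for name, kw in rows.items():
        construct = Construct(name=name, tunnel_length=30, **kw)
        out[name] = (
            construct,
            TranslationSchedule.uniform(construct.M, 3.9),
        )
    return out
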