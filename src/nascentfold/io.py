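"""File I/O: FASTA coding sequences, TSV rate tables, YAML run configs,
CSV curves and JSON summaries with run metadata."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .constructs import Construct
from .pulse_chase import FoldingCurve, Protocol
from .rate_tables import CodonRateTable, ValueKind

__all__ = [
    "read_cds_fasta",
    "read_rate_table",
    "write_rate_table",
    "read_config",
    "construct_from_config",
    "protocol_from_config",
    "write_curve_csv",
    "write_json",
    "run_metadata",
]

_KIND_COLUMNS = {"time_s": ValueKind.TIME, "rate_aa_per_s": ValueKind.RATE}


def read_cds_fasta(path: str | Path, record_id: str | None = None) -> str:
    """Read one CDS from a (possibly multi-record) FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path}: {len(records)} records; select one with record_id "
                f"(available: {[r.id for r in records]})"
            )
        return str(records[0].seq).upper()
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq).upper()
    raise ValueError(f"{path}: record {record_id!r} not found")


def read_rate_table(path: str | Path) -> CodonRateTable:
    """Read a TSV rate table: column ``codon`` plus ``time_s`` or
    ``rate_aa_per_s`` (the value column's name declares the kind)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "codon" not in df.columns:
        raise ValueError(f"{path}: missing required column 'codon'")
    kinds = [c for c in df.columns if c in _KIND_COLUMNS]
    if len(kinds) != 1:
        raise ValueError(
            f"{path}: expected exactly one value column of "
            f"{sorted(_KIND_COLUMNS)}, found {kinds}"
        )
    col = kinds[0]
    try:
        return CodonRateTable(
            entries=dict(zip(df["codon"], df[col].astype(float))),
            value_kind=_KIND_COLUMNS[col],
            provenance=str(path),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_rate_table(table: CodonRateTable, path: str | Path) -> None:
    col = "time_s" if table.value_kind is ValueKind.TIME else "rate_aa_per_s"
    pd.DataFrame(
        {"codon": list(table.entries), col: list(table.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a flat key-value YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping of keys to values")
    return cfg


def construct_from_config(
    cfg: dict[str, Any], total_codons: int, name: str = "construct"
) -> Construct:
    """Build a construct from flat config keys.

    Recognized keys: ``domain_start``, ``domain_end``, ``tunnel_length``,
    ``observable_last`` (observable codons 1..observable_last),
    ``bulk_kF``, ``bulk_kU``, ``name``.
    """
    required = ("domain_start", "domain_end", "bulk_kF", "bulk_kU")
    missing = [k for k in required if k not in cfg]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    obs = None
    if "observable_last" in cfg:
        obs = frozenset(range(1, int(cfg["observable_last"]) + 1))
    return Construct(
        name=str(cfg.get("name", name)),
        total_codons=total_codons,
        domain_start=int(cfg["domain_start"]),
        domain_end=int(cfg["domain_end"]),
        tunnel_length=int(cfg.get("tunnel_length", 30)),
        bulk_kF=float(cfg["bulk_kF"]),
        bulk_kU=float(cfg["bulk_kU"]),
        observable_codons=obs,
    )


def protocol_from_config(cfg: dict[str, Any]) -> Protocol:
    """Protocol from flat keys pulse_s / chase_s / delay_s / dt_s."""
    return Protocol(
        pulse_s=float(cfg.get("pulse_s", 45.0)),
        chase_s=float(cfg.get("chase_s", 360.0)),
        delay_s=float(cfg.get("delay_s", 10.0)),
        dt_s=float(cfg.get("dt_s", 0.1)),
    )


def write_curve_csv(
    curve: FoldingCurve,
    path: str | Path,
    value_name: str = "p_folded",
    dispersion: np.ndarray | None = None,
) -> None:
    data: dict[str, Any] = {"time_s": curve.times, value_name: curve.values}
    if dispersion is not None:
        data["sem"] = dispersion
    pd.DataFrame(data).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict[str, Any]) -> None:
    def _default(obj: Any) -> Any:
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")


def run_metadata(**params: Any) -> dict[str, Any]:
    """Metadata block recorded with every CLI run."""
    from . import __version__

    return {
        "tool": "nascentfold",
        "version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in params.items()
        },
    }
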