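"""Curve files, vendor-export parsing and run configuration.

The native curve format is a two-column CSV (``tau_s,signal``) preceded
by ``#``-commented header lines carrying acquisition metadata
(``field_mhz``, ``sequence_type``, ``temperature_c``) and free-form
``meta.<key>`` entries (JSON-encoded values).  Writing then reading is
lossless to better than 15 significant digits.

A reader for a Stelar-like relaxometer text export (stanza-per-field) is
provided behind the same acquisition contract.  Real export layouts vary
by firmware; the dialect implemented here is documented in
:func:`read_stelar_export` and is explicitly non-authoritative.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

import numpy as np

from .containers import RelaxAcquisition

__all__ = [
    "ParseError",
    "read_curve",
    "write_curve",
    "read_stelar_export",
    "read_matrigel_table",
    "write_matrigel_table",
    "RunConfig",
    "load_config",
    "tesla_to_mhz",
    "mhz_to_tesla",
]

#: Proton gyromagnetic ratio conversion: 1 T corresponds to ~42.577 MHz.
MHZ_PER_TESLA = 42.577


def tesla_to_mhz(b_tesla: float) -> float:
    """Convert magnetic field in tesla to proton Larmor frequency in MHz."""
    return float(b_tesla) * MHZ_PER_TESLA


def mhz_to_tesla(freq_mhz: float) -> float:
    """Convert proton Larmor frequency in MHz to magnetic field in tesla."""
    return float(freq_mhz) / MHZ_PER_TESLA


class ParseError(ValueError):
    """Malformed curve or export file; the message names the offending line."""


_HEADER_KEYS = ("field_mhz", "sequence_type", "temperature_c")


def write_curve(acq: RelaxAcquisition, path) -> None:
    """Write one acquisition as a commented-header CSV curve file."""
    path = Path(path)
    lines = ["# shutterspeed curve v1"]
    lines.append(f"# field_mhz = {acq.field_mhz:.17g}")
    lines.append(f"# sequence_type = {acq.sequence_type}")
    lines.append(f"# temperature_c = {acq.temperature_c:.17g}")
    for key in sorted(acq.meta):
        lines.append(f"# meta.{key} = {json.dumps(acq.meta[key], sort_keys=True)}")
    lines.append("tau_s,signal")
    for t, s in zip(acq.tau_s, acq.signal):
        lines.append(f"{t:.17g},{s:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_curve(path) -> RelaxAcquisition:
    """Read a curve file back into an acquisition (lossless round trip).

    Malformed rows (missing columns, non-numeric entries, NaN, negative or
    non-monotone delays) raise :class:`ParseError` citing the line number.
    """
    path = Path(path)
    header: dict[str, str] = {}
    meta: dict = {}
    taus: list[float] = []
    signals: list[float] = []
    saw_columns = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("meta."):
                try:
                    meta[key[5:]] = json.loads(value)
                except json.JSONDecodeError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad metadata value: {exc}") from exc
            else:
                header[key] = value
            continue
        if not saw_columns:
            cols = [c.strip() for c in line.split(",")]
            if cols != ["tau_s", "signal"]:
                raise ParseError(
                    f"{path}:{lineno}: expected column header "
                    f"'tau_s,signal', got {line!r}")
            saw_columns = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, "
                             f"got {len(parts)}")
        try:
            t, s = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric row "
                             f"{line!r}") from exc
        if not np.isfinite(t) or not np.isfinite(s):
            raise ParseError(f"{path}:{lineno}: non-finite value in {line!r}")
        if t < 0:
            raise ParseError(f"{path}:{lineno}: negative tau {t!r}")
        if taus and t <= taus[-1]:
            raise ParseError(f"{path}:{lineno}: tau not strictly "
                             f"increasing at {t!r}")
        taus.append(t)
        signals.append(s)
    if not saw_columns:
        raise ParseError(f"{path}: missing 'tau_s,signal' column header")
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ParseError(f"{path}: missing header keys {missing}")
    try:
        return RelaxAcquisition(
            tau_s=np.asarray(taus), signal=np.asarray(signals),
            field_mhz=float(header["field_mhz"]),
            sequence_type=header["sequence_type"],
            temperature_c=float(header["temperature_c"]),
            meta=meta)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_stelar_export(path) -> list[RelaxAcquisition]:
    """Parse a Stelar-like relaxometer text export into acquisitions.

    Implemented dialect (non-authoritative; real exports vary by
    firmware): stanzas separated by blank lines, each opening with a
    ``ZONE`` line of ``KEY=VALUE`` tokens, e.g.::

        ZONE BRLX=0.01MHz SEQ=PP/S T=25C
        0.005  1.0023
        0.012  0.9314
        ...

    ``BRLX`` is the relaxation field (MHz suffix optional), ``SEQ`` one of
    ``IR``, ``NP/S``, ``PP/S`` and ``T`` the temperature in Celsius.  Data
    rows are whitespace-separated (tau seconds, signal).
    """
    path = Path(path)
    acquisitions: list[RelaxAcquisition] = []
    zone: dict[str, str] | None = None
    taus: list[float] = []
    signals: list[float] = []

    def flush(lineno: int) -> None:
        nonlocal zone, taus, signals
        if zone is None:
            return
        if not taus:
            raise ParseError(f"{path}:{lineno}: zone with no data rows")
        seq = zone.get("SEQ", "PP/S").split("/")[0]
        try:
            acquisitions.append(RelaxAcquisition(
                tau_s=np.asarray(taus), signal=np.asarray(signals),
                field_mhz=float(zone["BRLX"].lower().removesuffix("mhz")),
                sequence_type=seq,
                temperature_c=float(zone.get("T", "25").rstrip("Cc")),
            ))
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: bad zone {zone!r}: "
                             f"{exc}") from exc
        zone, taus, signals = None, [], []

    lineno = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush(lineno)
            continue
        if line.upper().startswith("ZONE"):
            flush(lineno)
            zone = {}
            for token in line.split()[1:]:
                if "=" not in token:
                    raise ParseError(f"{path}:{lineno}: bad ZONE token "
                                     f"{token!r}")
                key, _, value = token.partition("=")
                zone[key.upper()] = value
            continue
        if zone is None:
            raise ParseError(f"{path}:{lineno}: data row before any ZONE")
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, "
                             f"got {len(parts)}")
        try:
            taus.append(float(parts[0]))
            signals.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric row "
                             f"{line!r}") from exc
    flush(lineno + 1)
    if not acquisitions:
        raise ParseError(f"{path}: no zones found")
    return acquisitions


def write_matrigel_table(table, path) -> None:
    """Write a (field MHz, r1_ex) table as a 2-column CSV."""
    arr = np.asarray(table, dtype=float)
    lines = ["field_mhz,r1_ex"]
    for f, r in arr:
        lines.append(f"{f:.17g},{r:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrigel_table(path) -> np.ndarray:
    """Read a 2-column (field_mhz, r1_ex) CSV written by the writer above."""
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if lineno == 1 and line.replace(" ", "") == "field_mhz,r1_ex":
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric row") from exc
    if len(rows) < 2:
        raise ParseError(f"{path}: need >= 2 table rows")
    return np.asarray(rows)


@dataclass
class RunConfig:
    """Validated configuration of a full simulate-fit-summarize run.

    Unknown keys in the source document are rejected.  ``data_dir=None``
    makes the pipeline simulate its own cohort (written under
    ``out_dir/data``); otherwise curves are read from ``data_dir``.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    data_dir: str | None = None
    tissue_class: str = "tumor"
    n_per_arm: int = 7
    timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    n_tau: int = 32
    noise: float = 0.02
    fields_mhz: tuple[float, ...] = (0.01, 0.02, 0.037, 0.07, 0.15, 0.39, 1.0)
    treated_kio_multipliers: tuple[float, ...] = (1.0, 0.6, 1.0, 1.0)
    treated_vex_multipliers: tuple[float, ...] = (1.0, 0.85, 1.15, 1.30)
    kio_base: float = 0.8
    vex_base: float = 0.30
    v_ex_bounds: tuple[float, float] | None = None
    tau_ex_starts: tuple[float, ...] = (0.1, 0.5, 2.5)
    v_ex_starts: tuple[float, ...] | None = None

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in doc.items()})
        if cfg.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if cfg.n_tau < 8:
            raise ValueError("n_tau must be >= 8")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config document must be a JSON object")
    return RunConfig.from_dict(doc)
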