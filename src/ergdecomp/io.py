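"""Readers and writers for the trace-file dialect and run configuration.

One file per recording (one eye).  The format is a UTF-8 CSV with a
``#``-prefixed ``key: value`` header block followed by a data table whose
first column is ``t_ms`` and whose remaining columns hold one averaged
trace per stimulus.  A JSON sidecar (``<path>.json``) mirrors the metadata
for machine use.

Floats are serialised with :func:`repr`, i.e. shortest round-tripping
representation (always >= 9 significant digits where needed), so
``read_recording(write_recording(rec))`` reproduces every value exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ParseError, ValidationError
from .types import Recording, Stimulus, Trace

_HEADER_KEYS = ("subject_id", "eye", "pressure_group", "treatment_group", "fs_hz")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_recording(rec: Recording, path) -> Path:
    """Serialise a Recording to ``path`` (CSV + JSON sidecar); returns ``path``."""
    path = Path(path)
    stims = [s for s, _ in rec.items()]
    traces = [rec.traces[s] for s in stims]

    meta = {
        "subject_id": rec.subject_id,
        "eye": rec.eye,
        "pressure_group": rec.pressure_group,
        "treatment_group": rec.treatment_group,
        "acquisition": rec.acquisition,
    }
    lines = []
    for key in ("subject_id", "eye", "pressure_group", "treatment_group"):
        lines.append(f"# {key}: {meta[key]}")
    if traces:
        lines.append(f"# fs_hz: {_fmt(traces[0].fs_hz)}")
        meta["fs_hz"] = traces[0].fs_hz
    lines.append(f"# acquisition: {json.dumps(rec.acquisition, sort_keys=True)}")
    lines.append(f"# intensity_log: {', '.join(_fmt(s.intensity_log) for s in stims)}")
    lines.append(f"# n_sweeps: {', '.join(str(s.n_sweeps) for s in stims)}")
    lines.append(f"# isi_s: {', '.join(_fmt(s.isi_s) for s in stims)}")
    meta["stimuli"] = [
        {"intensity_log": s.intensity_log, "n_sweeps": s.n_sweeps, "isi_s": s.isi_s}
        for s in stims
    ]

    if traces:
        header = ["t_ms"] + [f"i_{s.intensity_log:+.2f}" for s in stims]
        lines.append(",".join(header))
        t = traces[0].t_ms
        cols = np.column_stack([t] + [tr.v_uv for tr in traces])
        for row in cols:
            lines.append(",".join(_fmt(x) for x in row))

    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, sort_keys=True, indent=1), encoding="utf-8"
    )
    return path


def read_recording(path) -> Recording:
    """Parse a trace file written by :func:`write_recording`.

    Raises
    ------
    ParseError
        On a malformed header or data line (the message names the line).
    ValidationError
        If the parsed content violates a Recording/Trace invariant
        (non-uniform grid, duplicate intensity, ...).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    meta: dict = {}
    data_lines: list = []
    column_line = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise ParseError(f"{path}:{lineno}: header line lacks ':': {raw!r}")
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
        elif column_line is None:
            column_line = (lineno, line)
        else:
            data_lines.append((lineno, line))

    for key in ("subject_id", "eye", "pressure_group", "treatment_group"):
        if key not in meta:
            raise ParseError(f"{path}: missing required header key {key!r}")

    try:
        acquisition = json.loads(meta.get("acquisition", "{}"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: bad acquisition JSON: {exc}") from exc

    rec = Recording(
        subject_id=meta["subject_id"],
        eye=meta["eye"],
        pressure_group=meta["pressure_group"],
        treatment_group=meta["treatment_group"],
        acquisition=acquisition,
    )

    if column_line is None:  # metadata-only file: empty recording
        return rec

    def _floats(key):
        return [float(x) for x in meta[key].split(",")] if meta.get(key) else []

    try:
        intensities = _floats("intensity_log")
        sweeps = [int(x) for x in meta["n_sweeps"].split(",")] if meta.get("n_sweeps") else []
        isis = _floats("isi_s")
        fs_hz = float(meta["fs_hz"])
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed stimulus metadata: {exc}") from exc
    if not (len(intensities) == len(sweeps) == len(isis)):
        raise ParseError(f"{path}: stimulus metadata lists differ in length")

    n_cols = 1 + len(intensities)
    rows = []
    for lineno, line in data_lines:
        parts = line.split(",")
        if len(parts) != n_cols:
            raise ParseError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
    if not rows:
        raise ParseError(f"{path}: data table has a header but no rows")

    data = np.asarray(rows, dtype=float)
    t_ms = data[:, 0]
    stimuli = [
        Stimulus(intensity_log=il, n_sweeps=ns, isi_s=isi)
        for il, ns, isi in zip(intensities, sweeps, isis)
    ]
    # duplicate-intensity check happens before Trace construction so the
    # error names the real problem, not a grid artefact
    for i, a in enumerate(intensities):
        for b in intensities[i + 1:]:
            if abs(a - b) <= 1e-6:
                raise ValidationError(
                    f"{path}: duplicate trace at intensity {a:g} log cd·s/m²"
                )
    for j, stim in enumerate(stimuli):
        rec.add_trace(stim, Trace(t_ms=t_ms, v_uv=data[:, j + 1], fs_hz=fs_hz))
    return rec


def load_config(path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
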