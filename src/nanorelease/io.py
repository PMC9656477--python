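"""File formats: release-curve CSV, XYZ configurations, topology sidecars.

Release curves are delimited text with a ``#``-prefixed header block of
``key = value`` metadata lines followed by ``time_ns,f`` columns written
at full float precision, so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import (
    LABEL_KINDS,
    BeadSystem,
    NetworkTopology,
    ReleaseCurve,
    solute_labels,
)


class CurveParseError(ValueError):
    """Malformed release-curve file; message names the offending line."""


def write_release_curve(curve: ReleaseCurve, path) -> None:
    path = Path(path)
    meta = {
        "n_drug": curve.n_drug,
        "solute_diameter_nm": curve.solute_diameter,
        "mode": curve.mode,
        "loading": curve.loading,
        "first_exit": curve.first_exit,
        "replicate_ids": curve.replicate_ids,
        **{k: v for k, v in curve.meta.items()},
    }
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {json.dumps(val)}\n")
        fh.write("time_ns,f\n")
        for t, f in zip(curve.times, curve.f):
            fh.write(f"{float(t)!r},{float(f)!r}\n")


def read_release_curve(path) -> ReleaseCurve:
    path = Path(path)
    meta: dict = {}
    times, fs = [], []
    with path.open() as fh:
        lines = list(fh)
    data_started = False
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if data_started:
                raise CurveParseError(f"line {ln}: header after data")
            try:
                key, val = line[1:].split("=", 1)
            except ValueError:
                raise CurveParseError(
                    f"line {ln}: malformed header {line!r}"
                ) from None
            meta[key.strip()] = json.loads(val.strip())
            continue
        if line.replace(" ", "") == "time_ns,f":
            data_started = True
            continue
        if not data_started:
            raise CurveParseError(f"line {ln}: missing 'time_ns,f' column row")
        parts = line.split(",")
        if len(parts) != 2:
            raise CurveParseError(f"line {ln}: expected two columns")
        try:
            t, f = float(parts[0]), float(parts[1])
        except ValueError:
            raise CurveParseError(f"line {ln}: non-numeric value") from None
        if times and t <= times[-1]:
            raise CurveParseError(f"line {ln}: non-increasing time {t}")
        times.append(t)
        fs.append(f)
    if not times:
        raise CurveParseError("file contains no samples")
    known = {"n_drug", "solute_diameter_nm", "mode", "loading", "first_exit",
             "replicate_ids"}
    try:
        return ReleaseCurve(
            times=np.array(times),
            f=np.array(fs),
            n_drug=int(meta.get("n_drug", 0)),
            replicate_ids=list(meta.get("replicate_ids", [])),
            mode=str(meta.get("mode", "unknown")),
            loading=str(meta.get("loading", "unknown")),
            solute_diameter=float(meta.get("solute_diameter_nm", float("nan"))),
            first_exit=bool(meta.get("first_exit", True)),
            meta={k: v for k, v in meta.items() if k not in known},
        )
    except ValueError as exc:
        raise CurveParseError(str(exc)) from exc


def write_xyz(system: BeadSystem, path, comment: str = "") -> None:
    """One record per bead: kind label then x y z in nm."""
    path = Path(path)
    labels = solute_labels(system.kinds)
    with path.open("w") as fh:
        fh.write(f"{system.n_beads}\n{comment}\n")
        for lab, (x, y, z) in zip(labels, system.positions):
            fh.write(f"{lab} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (kinds, positions) from an XYZ file written by write_xyz."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    n = int(lines[0])
    kinds = np.empty(n, dtype=np.int64)
    pos = np.empty((n, 3))
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        kinds[i] = LABEL_KINDS[parts[0]]
        pos[i] = [float(p) for p in parts[1:4]]
    return kinds, pos


def write_topology(
    topology: NetworkTopology, system: BeadSystem, path
) -> None:
    """Structured-text sidecar: bead kinds/radii and the bond list."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# ke_kBT_per_nm2 = {topology.ke!r}\n")
        fh.write(f"# r0_nm = {topology.r0!r}\n")
        fh.write(f"# chain_count = {topology.chain_count}\n")
        fh.write("[beads]  # index kind radius_nm\n")
        labels = solute_labels(system.kinds)
        for i, (lab, r) in enumerate(zip(labels, system.radii)):
            fh.write(f"{i} {lab} {r!r}\n")
        fh.write("[bonds]  # i j\n")
        for a, b in topology.bonds:
            fh.write(f"{a} {b}\n")
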