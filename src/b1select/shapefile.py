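"""Bruker TopSpin-style (JCAMP-DX subset) shape-file reader and writer.

The writer emits the minimal JCAMP-DX record set TopSpin accepts for shaped
pulses: header records, amplitudes normalized so the maximum maps to 100.0,
and one "amplitude, phase" pair per line.  The absolute maximum amplitude in
Hz and the dwell are recorded in comment records so that reading a written
file reproduces the original pulse (self-round-trip guarantee); an optional
offset track (circular-polarized pulses) is stored in a dedicated comment
block.  Field layout beyond that subset is not interpreted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .shapes import ShapedPulse

__all__ = ["ShapeFileError", "write_shape", "read_shape"]


class ShapeFileError(ValueError):
    """Malformed shape file (parse errors name the offending line)."""


def write_shape(pulse: ShapedPulse, path, title: str = "b1select shaped pulse") -> None:
    """Write a pulse to a JCAMP-DX-style text shape file.

    Amplitudes are stored as percent of the maximum (fixed 6-decimal
    formatting); a zero-amplitude pulse cannot be normalized and raises.
    """
    if pulse.n_points == 0:
        raise ValueError("cannot write an empty pulse")
    amax = float(np.max(pulse.amplitude))
    if amax <= 0.0:
        raise ValueError("cannot normalize a zero-amplitude pulse")
    rel = 100.0 * pulse.amplitude / amax
    # fold phases that round up to 360.000000 back to 0 (circular quantity)
    ph = np.mod(np.round(pulse.phase_deg, 6), 360.0)
    lines = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00 Bruker JCAMP library",
        "##DATA TYPE= Shape Data",
        "##ORIGIN= b1select",
        "##OWNER= <b1select>",
        "##MINX= %.6f" % float(np.min(rel)),
        "##MAXX= %.6f" % float(np.max(rel)),
        "##MINY= %.6f" % float(np.min(ph)),
        "##MAXY= %.6f" % float(np.max(ph)),
        "##$SHAPE_EXMODE= None",
        "##$SHAPE_TOTROT= 0.000000",
        "##$SHAPE_TYPE= None",
        "##$SHAPE_MODE= 0",
        "$$ MAX_AMPLITUDE_HZ= %.9e" % amax,
        "$$ DWELL_S= %.9e" % pulse.dt,
        f"##NPOINTS= {pulse.n_points}",
        "##XYPOINTS= (XY..XY)",
    ]
    lines += [f" {a:.6f}, {p:.6f}" for a, p in zip(rel, ph)]
    if pulse.offset_track is not None:
        lines.append("$$ OFFSET_TRACK_HZ")
        lines += [f"$$ {v:.9e}" for v in pulse.offset_track]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_shape(path) -> ShapedPulse:
    """Read a shape file written by `write_shape` back into a ShapedPulse."""
    npoints = None
    amax = None
    dwell = None
    body: list[tuple[float, float]] = []
    track: list[float] = []
    in_body = False
    in_track = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("$$ MAX_AMPLITUDE_HZ="):
            amax = float(line.split("=", 1)[1])
        elif line.startswith("$$ DWELL_S="):
            dwell = float(line.split("=", 1)[1])
        elif line.startswith("##NPOINTS="):
            npoints = int(line.split("=", 1)[1])
        elif line.startswith("##XYPOINTS="):
            in_body = True
        elif line == "$$ OFFSET_TRACK_HZ":
            in_body = False
            in_track = True
        elif line.startswith("##END"):
            in_body = False
            in_track = False
        elif in_track and line.startswith("$$"):
            track.append(float(line[2:].strip()))
        elif in_body and not line.startswith("##"):
            parts = line.split(",")
            if len(parts) != 2:
                raise ShapeFileError(f"{path}:{lineno}: expected 'amplitude, phase', got {raw!r}")
            try:
                body.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ShapeFileError(f"{path}:{lineno}: {exc}") from exc
    if npoints is None or amax is None or dwell is None:
        raise ShapeFileError(f"{path}: missing NPOINTS, MAX_AMPLITUDE_HZ or DWELL_S header")
    if len(body) != npoints:
        raise ShapeFileError(f"{path}: header declares {npoints} points but body has {len(body)}")
    if track and len(track) != npoints:
        raise ShapeFileError(f"{path}: offset track has {len(track)} entries, expected {npoints}")
    rel = np.array([b[0] for b in body])
    phase = np.mod(np.array([b[1] for b in body]), 360.0)
    return ShapedPulse(
        dt=dwell,
        amplitude=rel * amax / 100.0,
        phase_deg=phase,
        offset_track=np.array(track) if track else None,
    )
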