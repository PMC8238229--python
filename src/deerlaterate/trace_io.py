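"""Reading, preprocessing and noise estimation for DEER time traces.

A DEER (double electron-electron resonance) experiment records a dipolar
echo decay as a complex signal sampled on a time axis. Files on disk use
the common ASCII dialect: whitespace-delimited columns ``time_ns real
[imag]``, with ``#``/``%`` comment lines. Internally time is kept in
microseconds and the real channel is normalized so its maximum is 1; the
imaginary channel, which ideally carries only noise after phase
correction, is rescaled by the same factor and used to estimate the
per-trace noise standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DeerTrace",
    "PairEntry",
    "read_trace",
    "write_trace",
    "truncate_trace",
    "estimate_noise",
    "read_manifest",
]

#: residue identifier: (chain, sequence number)
ResidueId = tuple[str, int]


def parse_residue_id(text: str | ResidueId) -> ResidueId:
    """Parse ``"A:131"`` (or a ready tuple) into a (chain, seqnum) pair."""
    if isinstance(text, tuple):
        chain, num = text
        return (str(chain), int(num))
    s = str(text).strip()
    if ":" in s:
        chain, _, num = s.partition(":")
    else:
        chain, num = "A", s
    return (chain, int(num))


def format_residue_id(rid: ResidueId) -> str:
    return f"{rid[0]}:{rid[1]}"


@dataclass
class DeerTrace:
    """One experimental or simulated dipolar decay.

    The constructor normalizes the real channel to a maximum of 1 and
    rescales the imaginary channel by the same factor, so the stored
    signal always satisfies ``max(real) == 1``.
    """

    trace_id: str
    residue_u: ResidueId
    residue_v: ResidueId
    time_us: np.ndarray
    real: np.ndarray
    imag: np.ndarray | None = None
    noise_sigma: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.time_us = np.asarray(self.time_us, dtype=float)
        self.real = np.asarray(self.real, dtype=float)
        self.residue_u = parse_residue_id(self.residue_u)
        self.residue_v = parse_residue_id(self.residue_v)
        if self.imag is not None:
            self.imag = np.asarray(self.imag, dtype=float)
            if self.imag.shape != self.time_us.shape:
                raise ValueError(f"{self.trace_id}: imag/time length mismatch")
        if self.real.shape != self.time_us.shape:
            raise ValueError(f"{self.trace_id}: real/time length mismatch")
        if self.time_us.size < 2:
            raise ValueError(f"{self.trace_id}: trace too short")
        if not np.all(np.diff(self.time_us) > 0):
            raise ValueError(f"{self.trace_id}: time axis not strictly increasing")
        if self.time_us[0] < 0:
            raise ValueError(f"{self.trace_id}: negative first time point")
        peak = float(np.max(self.real))
        if peak <= 0:
            raise ValueError(f"{self.trace_id}: non-positive real channel maximum")
        if abs(peak - 1.0) > 1e-12:
            self.real = self.real / peak
            if self.imag is not None:
                self.imag = self.imag / peak
        if self.noise_sigma is not None:
            self.noise_sigma = float(self.noise_sigma)
            if self.noise_sigma <= 0:
                raise ValueError(f"{self.trace_id}: noise_sigma must be positive")

    @property
    def n_points(self) -> int:
        return int(self.time_us.size)

    @property
    def span_us(self) -> float:
        return float(self.time_us[-1] - self.time_us[0])


def read_trace(
    path: str | Path,
    trace_id: str,
    residue_u: str | ResidueId,
    residue_v: str | ResidueId,
) -> DeerTrace:
    """Read a whitespace-delimited ASCII trace (time in ns, real, [imag]).

    Rows with non-numeric fields and comment lines (``#``/``%``) are
    skipped. Time is converted ns -> us; the real channel is rescaled to
    a maximum of 1 and the imaginary channel by the same factor.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(str(path))
    rows: list[list[float]] = []
    ncols: int | None = None
    for line in path.read_text().splitlines():
        s = line.strip()
        if not s or s[0] in "#%":
            continue
        fields = s.split()
        try:
            vals = [float(x) for x in fields]
        except ValueError:
            continue  # malformed row: reject, keep going
        if ncols is None:
            if len(vals) < 2:
                raise ValueError(f"{path}: fewer than 2 numeric columns")
            ncols = min(len(vals), 3)
        if len(vals) < ncols:
            continue
        rows.append(vals[:ncols])
    if ncols is None or len(rows) < 20:
        raise ValueError(f"{path}: fewer than 20 usable data rows")
    data = np.asarray(rows, dtype=float)
    time_us = data[:, 0] / 1000.0
    imag = data[:, 2] if ncols == 3 else None
    return DeerTrace(
        trace_id=trace_id,
        residue_u=parse_residue_id(residue_u),
        residue_v=parse_residue_id(residue_v),
        time_us=time_us,
        real=data[:, 1],
        imag=imag,
    )


def write_trace(trace: DeerTrace, path: str | Path) -> None:
    """Write a trace in the same ASCII dialect ``read_trace`` accepts."""
    cols = [trace.time_us * 1000.0, trace.real]
    if trace.imag is not None:
        cols.append(trace.imag)
    header = "time_ns real" + (" imag" if trace.imag is not None else "")
    np.savetxt(path, np.column_stack(cols), fmt="%.10g", header=header)


def truncate_trace(trace: DeerTrace, cut_ns: float = 500.0) -> DeerTrace:
    """Drop tail points with ``t > t_max - cut_ns`` (fitting-artifact guard).

    The late part of a DEER decay is distorted by the overlap of pump and
    observe pulses; discarding the last 500 ns is standard practice.
    """
    if cut_ns < 0:
        raise ValueError("cut_ns must be >= 0")
    cut_us = cut_ns / 1000.0
    if cut_us >= trace.span_us:
        raise ValueError(
            f"{trace.trace_id}: cut ({cut_ns} ns) >= trace span ({trace.span_us * 1000:.0f} ns)"
        )
    if cut_ns == 0:
        return replace(trace)
    keep = trace.time_us <= trace.time_us[-1] - cut_us + 1e-12
    return DeerTrace(
        trace_id=trace.trace_id,
        residue_u=trace.residue_u,
        residue_v=trace.residue_v,
        time_us=trace.time_us[keep],
        real=trace.real[keep],
        imag=trace.imag[keep] if trace.imag is not None else None,
        noise_sigma=trace.noise_sigma,
    )


def estimate_noise(trace: DeerTrace) -> float:
    """Estimate the noise s.d. from the imaginary channel.

    The complex signal is rotated by the phase angle that minimizes the
    RMS of the imaginary channel (standard phase correction), the rotated
    imaginary channel is mean-subtracted, and its standard deviation is
    returned and stored as ``trace.noise_sigma``. The estimate is
    invariant under global phase rotation of the input.
    """
    if trace.imag is None:
        raise ValueError(
            f"{trace.trace_id}: no imaginary channel; supply noise_sigma explicitly"
        )
    if trace.imag.size < 20:
        raise ValueError(f"{trace.trace_id}: need >= 20 points to estimate noise")
    re, im = trace.real, trace.imag
    # minimize sum(im')^2 with im' = im cos(phi) - re sin(phi):
    # quadratic form in (cos, sin) -> closed-form angle
    a = 0.5 * (np.dot(re, re) - np.dot(im, im))
    b = float(np.dot(re, im))
    phi = 0.5 * math.atan2(b, a) if (a != 0.0 or b != 0.0) else 0.0
    im_rot = im * math.cos(phi) - re * math.sin(phi)
    sigma = float(np.std(im_rot - im_rot.mean(), ddof=1))
    if sigma < 1e-12:
        raise ValueError(
            f"{trace.trace_id}: degenerate (noiseless) imaginary channel; "
            "supply noise_sigma explicitly"
        )
    trace.noise_sigma = sigma
    return sigma


@dataclass
class PairEntry:
    """One row of a pair manifest: a trace file and its labeled residues."""

    trace_path: str
    trace_id: str
    residue_u: ResidueId
    residue_v: ResidueId
    noise_sigma: float | None = None
    truncate_ns: float | None = None


def _entry_from_mapping(m: dict) -> PairEntry:
    try:
        return PairEntry(
            trace_path=str(m["trace_path"]),
            trace_id=str(m.get("trace_id", Path(str(m["trace_path"])).stem)),
            residue_u=parse_residue_id(m["residue_u"]),
            residue_v=parse_residue_id(m["residue_v"]),
            noise_sigma=float(m["noise_sigma"]) if m.get("noise_sigma") not in (None, "") else None,
            truncate_ns=float(m["truncate_ns"]) if m.get("truncate_ns") not in (None, "") else None,
        )
    except KeyError as exc:
        raise ValueError(f"manifest entry missing field {exc}") from exc


def read_manifest(path: str | Path) -> list[PairEntry]:
    """Read a pair manifest (YAML list/mapping, or TSV with a header row)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
        entries = doc["pairs"] if isinstance(doc, dict) else doc
        return [_entry_from_mapping(e) for e in entries]
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        out.append(_entry_from_mapping(dict(zip(header, ln.split("\t")))))
    return out
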