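"""Text file formats for schemes, signals and run configuration.

Scheme files are tab-separated with one row per measurement.  Two dialects
are supported:

* pair format (written by default), header
  ``b1 n1x n1y n1z b2 n2x n2y n2z`` — the two gradient-pair weightings
  (ms/um^2) and unit directions; zero rows encode b = 0 measurements;
* general b-tensor format, header ``bxx byy bzz bxy bxz byz`` — the six
  independent components with trace = total b.

Signal files are tab-separated with one aligned row per measurement, column
``signal`` for a noise-free set or ``rep_0001 ...`` for noisy realizations.
Floats are written with repr-round-trip precision so write/read cycles are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import AcquisitionScheme, BTensor, Measurement, btensor_from_pair

__all__ = ["read_scheme", "write_scheme", "read_signals", "write_signals", "RunConfig"]

_PAIR_HEADER = ["b1", "n1x", "n1y", "n1z", "b2", "n2x", "n2y", "n2z"]
_BT_HEADER = ["bxx", "byy", "bzz", "bxy", "bxz", "byz"]


def _fmt(x: float) -> str:
    return repr(float(x))


def _pair_of(measurement: Measurement):
    """The stored gradient pair, or a deterministic realization from the tensor."""
    if measurement.pair is not None:
        return measurement.pair
    bt = measurement.btensor
    if bt.shape == "zero":
        z = np.zeros(3)
        return (0.0, z, 0.0, z)
    if bt.shape == "linear":
        ax = bt.principal_axis
        return (bt.b / 2, ax, bt.b / 2, ax)
    if bt.shape == "planar":
        v = bt.planar_normal
        ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = ref - np.dot(ref, v) * v
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)
        return (bt.b / 2, e1, bt.b / 2, e2)
    raise ValueError("general b-tensors have no canonical gradient pair; use the 6-component dialect")


def write_scheme(scheme: AcquisitionScheme, path, dialect: str = "pair") -> None:
    path = Path(path)
    lines = []
    if dialect == "pair":
        lines.append("\t".join(_PAIR_HEADER))
        for m in scheme:
            b1, n1, b2, n2 = _pair_of(m)
            lines.append(
                "\t".join(
                    [_fmt(b1), *(_fmt(x) for x in n1), _fmt(b2), *(_fmt(x) for x in n2)]
                )
            )
    elif dialect == "btensor":
        lines.append("\t".join(_BT_HEADER))
        for m in scheme:
            t = m.btensor.matrix
            lines.append(
                "\t".join(
                    _fmt(v)
                    for v in (t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2])
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def _parse_row(cells, n_expected, lineno, path):
    if len(cells) != n_expected:
        raise ValueError(f"{path}:{lineno}: expected {n_expected} columns, got {len(cells)}")
    try:
        return [float(c) for c in cells]
    except ValueError as e:
        raise ValueError(f"{path}:{lineno}: {e}") from None


def read_scheme(path, name: str = "") -> AcquisitionScheme:
    """Read either scheme dialect; validates units and direction norms."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty scheme file")
    header = lines[0].split()
    measurements: list[Measurement] = []
    shells: dict[float, int] = {}

    def shell_of(b: float) -> int:
        if b <= 1e-12:
            return 0
        key = round(b, 9)
        if key not in shells:
            shells[key] = len(shells) + 1
        return shells[key]

    if header == _PAIR_HEADER:
        for i, ln in enumerate(lines[1:], start=2):
            vals = _parse_row(ln.split("\t"), 8, i, path)
            b1, n1 = vals[0], np.array(vals[1:4])
            b2, n2 = vals[4], np.array(vals[5:8])
            if b1 == 0.0 and b2 == 0.0:
                measurements.append(Measurement(BTensor.zero(), pair=None, shell=0))
                continue
            for b, n in ((b1, n1), (b2, n2)):
                if b > 0 and abs(np.linalg.norm(n) - 1.0) > 1e-6:
                    raise ValueError(f"{path}:{i}: non-unit direction {n}")
            bt = btensor_from_pair(b1, n1, b2, n2)
            measurements.append(
                Measurement(bt, pair=(b1, n1, b2, n2), shell=shell_of(bt.b))
            )
    elif header == _BT_HEADER:
        for i, ln in enumerate(lines[1:], start=2):
            bxx, byy, bzz, bxy, bxz, byz = _parse_row(ln.split("\t"), 6, i, path)
            mat = np.array([[bxx, bxy, bxz], [bxy, byy, byz], [bxz, byz, bzz]])
            bt = BTensor.zero() if np.all(mat == 0) else BTensor(mat)
            measurements.append(Measurement(bt, pair=None, shell=shell_of(bt.b)))
    else:
        raise ValueError(
            f"{path}:1: unrecognized header {header!r}; expected {_PAIR_HEADER} or {_BT_HEADER}"
        )
    return AcquisitionScheme(measurements, name=name or path.stem)


def write_signals(signals, path, scheme=None) -> None:
    """Write a SignalSet or values array; columns rep_#### for realizations."""
    from .forward_model import SignalSet

    values = signals.values if isinstance(signals, SignalSet) else np.asarray(signals, float)
    path = Path(path)
    if values.ndim == 1:
        header = ["signal"]
        rows = ([_fmt(v)] for v in values)
    else:
        header = [f"rep_{i + 1:04d}" for i in range(values.shape[1])]
        rows = ([_fmt(v) for v in row] for row in values)
    lines = ["\t".join(header)]
    lines.extend("\t".join(r) for r in rows)
    path.write_text("\n".join(lines) + "\n")


def read_signals(path, scheme: AcquisitionScheme | None = None):
    """Read a signal table; validates the length against ``scheme`` if given."""
    from .forward_model import SignalSet

    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    data = np.array(
        [_parse_row(ln.split("\t"), len(header), i, path) for i, ln in enumerate(lines[1:], start=2)]
    )
    if header == ["signal"]:
        data = data[:, 0]
    if scheme is not None:
        if data.shape[0] != len(scheme):
            raise ValueError(
                f"{path}: {data.shape[0]} rows but scheme has {len(scheme)} measurements"
            )
        return SignalSet(scheme, data)
    return data


@dataclass
class RunConfig:
    """Declarative description of one simulation/fit run (JSON round-trip)."""

    protocol: str = "DDE30+30"
    params: dict = field(default_factory=dict)
    snr: float | None = 50.0
    n_reps: int = 1
    seed: int = 0
    n_starts: int = 30
    scheme_seed: int = 0
    outputs: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
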