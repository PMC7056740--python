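"""FCS 3.0/3.1 list-mode I/O, spillover compensation, and axis transforms.

Reads $DATATYPE F/D/I list-mode files (3.0 and 3.1), writes FCS 3.1 with
$DATATYPE F.  A sample moves through a strict state machine
raw -> compensated -> transformed; compensation is linear unmixing in raw
intensity space and always precedes transformation.

The logicle transform follows the published biexponential formulation
(T/W/M/A parameterization); the forward map is evaluated on a dense
monotone grid of the closed-form inverse, which keeps it strictly
increasing and fast for large event matrices.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (
    ConfigurationError,
    FormatError,
    NumericalError,
    UnsupportedDialectError,
    ValidationError,
)

__all__ = [
    "ChannelInfo",
    "FlowSample",
    "SpilloverMatrix",
    "TransformSpec",
    "read_fcs",
    "write_fcs",
    "compensate",
    "transform",
    "read_spillover_csv",
]

_STATES = ("raw", "compensated", "transformed")


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one acquisition channel."""

    index: int  # 1-based channel number
    short_name: str  # $PnN
    marker: str = ""  # $PnS, may be empty
    range: float = 262144.0  # $PnR

    def __post_init__(self) -> None:
        if not self.short_name:
            raise ValidationError("channel short_name must be non-empty")
        if self.index < 1:
            raise ValidationError("channel index is 1-based")

    @property
    def label(self) -> str:
        """Marker name when stained, detector name otherwise."""
        return self.marker or self.short_name


@dataclass
class SpilloverMatrix:
    """Square spillover matrix keyed by detector (or marker) names."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("spillover matrix must be square")
        if m.shape[0] != len(self.names):
            raise ValidationError("spillover names/matrix size mismatch")
        if not np.allclose(np.diag(m), 1.0):
            raise ValidationError("spillover diagonal must be unit")
        self.matrix = m
        self.names = tuple(self.names)

    def to_keyword(self) -> str:
        vals = ",".join(repr(float(v)) for v in self.matrix.ravel())
        return f"{len(self.names)},{','.join(self.names)},{vals}"

    @classmethod
    def from_keyword(cls, text: str) -> "SpilloverMatrix":
        parts = [p.strip() for p in text.split(",")]
        try:
            n = int(parts[0])
            names = tuple(parts[1 : 1 + n])
            vals = np.asarray([float(v) for v in parts[1 + n :]], dtype=float)
            return cls(names, vals.reshape(n, n))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"malformed $SPILLOVER keyword: {exc}") from exc


@dataclass
class FlowSample:
    """Channel metadata plus an event x channel intensity matrix."""

    channels: list[ChannelInfo]
    events: np.ndarray
    spillover: SpilloverMatrix | None = None
    transform_state: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValidationError("events must be a 2-D matrix")
        if self.events.shape[1] != len(self.channels):
            raise ValidationError(
                f"events have {self.events.shape[1]} columns but "
                f"{len(self.channels)} channels are declared"
            )
        idx = [c.index for c in self.channels]
        if len(set(idx)) != len(idx):
            raise ValidationError("channel indices must be unique")
        if self.transform_state not in _STATES:
            raise ValidationError(f"unknown transform_state {self.transform_state!r}")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.channels)

    def column_of(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if name in (c.label, c.short_name):
                return i
        raise ConfigurationError(f"channel {name!r} not found in sample")

    def copy(self) -> "FlowSample":
        return FlowSample(
            channels=list(self.channels),
            events=self.events.copy(),
            spillover=self.spillover,
            transform_state=self.transform_state,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Transforms


def _logicle_params(T: float, W: float, M: float, A: float) -> dict:
    if T <= 0 or M <= 0 or W < 0 or A < 0:
        raise ValidationError("logicle requires T>0, M>0, W>=0, A>=0")
    b = (M + A) * np.log(10.0)
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    if w == 0:
        d = b
    else:
        # root of  2 (ln d - ln b) + w (b + d) = 0  in (0, b)
        func = lambda d: 2.0 * (np.log(d) - np.log(b)) + w * (b + d)
        d = brentq(func, 1e-12, b, xtol=1e-14)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
    a = T / ((np.exp(b) - mf_a) - c_a / np.exp(d))
    c = c_a * a
    f = -mf_a * a
    return {"a": a, "b": b, "c": c, "d": d, "f": f, "x1": x1, "T": T,
            "M": M, "A": A, "W": W}


def _logicle_inverse(y_norm: np.ndarray, p: dict) -> np.ndarray:
    """Closed-form biexponential: normalized display y in ~[0,1] -> raw."""
    y = np.asarray(y_norm, dtype=float)
    neg = y < p["x1"]
    yy = np.where(neg, 2.0 * p["x1"] - y, y)
    val = p["a"] * np.exp(p["b"] * yy) - p["c"] * np.exp(-p["d"] * yy) + p["f"]
    return np.where(neg, -val, val)


@dataclass
class TransformSpec:
    """Monotone axis transform: logicle, asinh, or linear.

    logicle output is in display decades (0 .. M+A); asinh output is
    asinh(x / cofactor); linear output is x / scale.
    """

    kind: str = "logicle"
    parameters: dict = field(default_factory=dict)

    _GRID_N = 30001

    def __post_init__(self) -> None:
        if self.kind not in ("logicle", "asinh", "linear"):
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        defaults = {
            "logicle": {"T": 262144.0, "W": 0.5, "M": 4.5, "A": 0.0},
            "asinh": {"cofactor": 150.0},
            "linear": {"scale": 1.0},
        }[self.kind]
        self.parameters = {**defaults, **self.parameters}
        if self.kind == "asinh" and self.parameters["cofactor"] <= 0:
            raise ValidationError("asinh cofactor must be positive")
        if self.kind == "linear" and self.parameters["scale"] == 0:
            raise ValidationError("linear scale must be nonzero")
        self._grid = None

    def _logicle_grid(self):
        if self._grid is None:
            p = _logicle_params(**{k: self.parameters[k] for k in "TWMA"})
            span = p["M"] + p["A"]
            y = np.linspace(p["x1"] - 0.6, 1.2, self._GRID_N)
            x = _logicle_inverse(y, p)
            self._grid = (x, y * span, p)
        return self._grid

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "asinh":
            return np.arcsinh(v / self.parameters["cofactor"])
        if self.kind == "linear":
            return v / self.parameters["scale"]
        x, y, p = self._logicle_grid()
        span = p["M"] + p["A"]
        yn = np.interp(v, x, y) / span  # grid seed, then Newton-polish
        for _ in range(4):
            resid = _logicle_inverse(yn, p) - v
            yy = np.where(yn < p["x1"], 2.0 * p["x1"] - yn, yn)
            deriv = p["a"] * p["b"] * np.exp(p["b"] * yy) + p["c"] * p["d"] * np.exp(
                -p["d"] * yy
            )
            yn = yn - resid / deriv
        return yn * span

    def inverse(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "asinh":
            return np.sinh(v) * self.parameters["cofactor"]
        if self.kind == "linear":
            return v * self.parameters["scale"]
        x, y, _ = self._logicle_grid()
        return np.interp(v, y, x)

    def to_jsonable(self) -> dict:
        return {"kind": self.kind, "parameters": dict(self.parameters)}

    @classmethod
    def from_jsonable(cls, raw: Mapping) -> "TransformSpec":
        return cls(kind=raw["kind"], parameters=dict(raw.get("parameters", {})))


# ---------------------------------------------------------------------------
# FCS reading


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    # a doubled delimiter escapes a literal delimiter and splits into an
    # empty piece; FCS forbids genuinely empty values, so rejoin on them
    tokens: list[str] = []
    cur = parts[0]
    i = 1
    while i < len(parts):
        if parts[i] == b"" and i + 1 < len(parts):
            cur = cur + delim + parts[i + 1]
            i += 2
        else:
            tokens.append(cur.decode("latin-1"))
            cur = parts[i]
            i += 1
    tokens.append(cur.decode("latin-1"))
    if len(tokens) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of tokens")
    out: dict[str, str] = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        out[k.strip().upper() if k.startswith("$") else k.strip()] = v
    return out


def _header_offset(header: bytes, start: int) -> int:
    field_ = header[start : start + 8].decode("ascii", "replace").strip()
    if field_ == "":
        return 0
    try:
        return int(field_)
    except ValueError as exc:
        raise FormatError(f"malformed HEADER offset field {field_!r}") from exc


def read_fcs(path) -> FlowSample:
    """Read an FCS 3.0/3.1 list-mode file into a raw FlowSample."""
    with open(path, "rb") as fh:
        content = fh.read()
    if len(content) < 58:
        raise FormatError("file too short to contain an FCS HEADER")
    version = content[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedDialectError(f"unsupported FCS version {version!r}")
    text_start = _header_offset(content, 10)
    text_end = _header_offset(content, 18)
    data_start = _header_offset(content, 26)
    data_end = _header_offset(content, 34)
    if text_start <= 0 or text_end <= text_start:
        raise FormatError("invalid TEXT offsets in HEADER")
    text = _parse_text_segment(content[text_start : text_end + 1])

    def req(key: str) -> str:
        if key not in text:
            raise FormatError(f"required keyword {key} missing from TEXT segment")
        return text[key]

    mode = req("$MODE").upper()
    if mode != "L":
        raise UnsupportedDialectError(f"unsupported $MODE {mode!r} (need list mode)")
    datatype = req("$DATATYPE").upper()
    if datatype not in ("F", "D", "I"):
        raise UnsupportedDialectError(f"unsupported $DATATYPE {datatype!r}")
    byteord = req("$BYTEORD")
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2"):
        endian = ">"
    else:
        raise FormatError(f"malformed $BYTEORD {byteord!r}")
    n_par = int(req("$PAR"))
    n_tot = int(req("$TOT"))
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    if data_start <= 0 or data_end < data_start:
        raise FormatError("invalid DATA offsets ($BEGINDATA/$ENDDATA)")

    channels: list[ChannelInfo] = []
    widths: list[int] = []
    for i in range(1, n_par + 1):
        pnn = text.get(f"$P{i}N")
        if not pnn:
            raise FormatError(f"required keyword $P{i}N missing or empty")
        pns = text.get(f"$P{i}S", "")
        pnr = float(text.get(f"$P{i}R", 262144))
        pnb = int(text.get(f"$P{i}B", 32))
        if pnb not in (8, 16, 32, 64):
            raise UnsupportedDialectError(f"unsupported $P{i}B width {pnb}")
        widths.append(pnb)
        channels.append(ChannelInfo(index=i, short_name=pnn, marker=pns, range=pnr))

    raw = content[data_start : data_end + 1]
    if datatype == "F":
        if any(w != 32 for w in widths):
            raise UnsupportedDialectError("$DATATYPE F requires $PnB 32")
        arr = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=endian + "f4")
    elif datatype == "D":
        if any(w != 64 for w in widths):
            raise UnsupportedDialectError("$DATATYPE D requires $PnB 64")
        arr = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=endian + "f8")
    else:  # integer, possibly mixed widths
        if len(set(widths)) == 1:
            dt = {8: "u1", 16: "u2", 32: "u4", 64: "u8"}[widths[0]]
            arr = np.frombuffer(
                raw[: widths[0] // 8 * n_par * n_tot], dtype=endian + dt
            )
        else:
            row_bytes = sum(w // 8 for w in widths)
            arr = np.empty(n_tot * n_par, dtype=float)
            off = 0
            pos = 0
            fmt = {8: "B", 16: "H", 32: "I", 64: "Q"}
            for _ in range(n_tot):
                for w in widths:
                    arr[pos] = struct.unpack_from(
                        endian + fmt[w], raw, off
                    )[0]
                    off += w // 8
                    pos += 1
    if arr.size < n_par * n_tot:
        raise FormatError(
            f"DATA segment truncated: expected {n_par * n_tot} values, got {arr.size}"
        )
    events = np.asarray(arr[: n_par * n_tot], dtype=float).reshape(n_tot, n_par)

    spill = None
    for key in ("$SPILLOVER", "SPILL", "$COMP"):
        if key in text:
            spill = SpilloverMatrix.from_keyword(text[key])
            break

    return FlowSample(
        channels=channels,
        events=events,
        spillover=spill,
        transform_state="raw",
        metadata=dict(text),
    )


# ---------------------------------------------------------------------------
# FCS writing


def write_fcs(sample: FlowSample, path) -> None:
    """Write a FlowSample as FCS 3.1, $DATATYPE F (float32), little-endian."""
    if sample.n_events < 1 or len(sample.channels) < 1:
        raise ValidationError("refusing to write an empty sample")
    n_tot, n_par = sample.events.shape
    delim = "/"

    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
    }
    for i, ch in enumerate(sample.channels, start=1):
        kw[f"$P{i}N"] = ch.short_name
        if ch.marker:
            kw[f"$P{i}S"] = ch.marker
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = repr(float(ch.range))
    if sample.spillover is not None:
        kw["$SPILLOVER"] = sample.spillover.to_keyword()
    # carry custom (non-$) metadata keywords through round trips
    for key, val in sample.metadata.items():
        if not key.startswith("$") and key not in kw:
            kw[key] = str(val)
    kw["TCD4_TRANSFORM_STATE"] = sample.transform_state

    data = np.ascontiguousarray(sample.events, dtype="<f4").tobytes()

    def render_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = f"{begin_data:010d}"
        items["$ENDDATA"] = f"{end_data:010d}"
        parts = [delim]
        for k, v in items.items():
            sv = str(v).replace(delim, delim + delim) or " "
            parts.append(f"{k}{delim}{sv}{delim}")
        return "".join(parts).encode("latin-1")

    header_len = 58
    text = render_text(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1
    # offsets are rendered at fixed width, so re-rendering keeps the length
    text = render_text(data_start, data_end)
    assert text_end == text_start + len(text) - 1

    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + (f"{data_start:8d}".encode() if data_end < 10**8 else b"       0")
        + (f"{data_end:8d}".encode() if data_end < 10**8 else b"       0")
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


# ---------------------------------------------------------------------------
# Compensation and transformation


def compensate(
    sample: FlowSample, spillover: SpilloverMatrix | None = None
) -> FlowSample:
    """Apply linear spillover unmixing: events <- events @ inverse(S)."""
    if sample.transform_state != "raw":
        raise ValidationError(
            f"cannot compensate a sample in state {sample.transform_state!r}"
        )
    spill = spillover if spillover is not None else sample.spillover
    if spill is None:
        raise ValidationError(
            "no spillover matrix supplied and none embedded in the sample"
        )
    cols = []
    for name in spill.names:
        try:
            cols.append(sample.column_of(name))
        except ConfigurationError as exc:
            raise ConfigurationError(
                f"spillover column {name!r} does not map to any detector"
            ) from exc
    cond = np.linalg.cond(spill.matrix)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(
            f"spillover matrix is numerically singular (condition number {cond:.3g})"
        )
    out = sample.copy()
    sub = out.events[:, cols]
    # column convention: observed_i = sum_j S[i,j] * true_j
    out.events[:, cols] = np.linalg.solve(spill.matrix, sub.T).T
    out.transform_state = "compensated"
    return out


def _default_fluorescence_columns(sample: FlowSample) -> list[str]:
    skip_prefixes = ("FSC", "SSC", "TIME")
    return [
        c.label
        for c in sample.channels
        if not c.short_name.upper().startswith(skip_prefixes)
    ]


def transform(
    sample: FlowSample,
    spec: TransformSpec,
    channels: Sequence[str] | None = None,
) -> FlowSample:
    """Map the listed channels through ``spec``; scatter stays linear.

    Allowed from state 'compensated', or directly from 'raw' when the sample
    has no spillover to apply.
    """
    if sample.transform_state == "transformed":
        raise ValidationError("sample is already transformed")
    if sample.transform_state == "raw" and sample.spillover is not None:
        raise ValidationError(
            "sample has an embedded spillover matrix; compensate first"
        )
    names = channels if channels is not None else _default_fluorescence_columns(sample)
    out = sample.copy()
    for name in names:
        col = out.column_of(name)  # raises lookup error for unknown names
        out.events[:, col] = spec.apply(out.events[:, col])
    out.transform_state = "transformed"
    out.metadata["TCD4_TRANSFORM"] = spec.kind
    return out


def read_spillover_csv(path) -> SpilloverMatrix:
    """Spillover as CSV with a header row and index column of detector names."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("spillover CSV must have identical row/column names")
    return SpilloverMatrix(tuple(df.columns), df.to_numpy(dtype=float))
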