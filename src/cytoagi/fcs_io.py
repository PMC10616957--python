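"""Event-level flow cytometry I/O: FCS 3.1 and CSV, compensation, transforms.

The analysis pipeline works on an :class:`EventMatrix` whose values move
through three stages: ``raw`` (instrument units as read from disk),
``compensated`` (after spillover correction of the fluorescence channels)
and ``transformed`` (inverse-hyperbolic-sine scaled fluorescence plus
linearly rescaled scatter), in that order only.

The FCS support here is a deliberately small, self-contained implementation
of the FCS 3.1 list-mode container (float32, little-endian) sufficient for
round-tripping panel data and per-event labels.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PANEL_MARKERS",
    "SCATTER_CHANNELS",
    "ChannelInfo",
    "EventMatrix",
    "SpilloverMatrix",
    "TransformSpec",
    "PanelMismatchError",
    "FCSParseError",
    "ConfigError",
    "default_panel",
    "read_events",
    "write_events",
    "read_labels",
    "compensate",
    "apply_transform",
]

#: The 18 antibody markers of the B-cell / plasma-cell immune-monitoring panel.
PANEL_MARKERS = (
    "CD19", "CD45", "CD38", "CD20", "CD24", "CD21", "CD27", "CD5",
    "CD62L", "CD138", "IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgG4",
    "IgA1", "IgA2",
)

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")
TIME_CHANNEL = "Time"

LABEL_CHANNEL = "LABEL"
LABEL_KEYWORD = "CYTOAGI_LABELS"


class PanelMismatchError(ValueError):
    """A file channel cannot be resolved against the declared panel."""


class FCSParseError(ValueError):
    """The file is not a readable FCS 3.x container."""


class ConfigError(ValueError):
    """Invalid panel / transform / threshold configuration."""


@dataclass(frozen=True)
class ChannelInfo:
    """One acquisition channel: detector name, marker it reports, and kind."""

    detector_name: str
    marker: str
    kind: str  # "scatter" | "fluorescence" | "time"

    def __post_init__(self):
        if self.kind not in ("scatter", "fluorescence", "time"):
            raise ConfigError(f"unknown channel kind {self.kind!r}")


def default_panel(include_time: bool = True) -> list[ChannelInfo]:
    """Scatter + 18 fluorescence markers (+ Time), detector name == marker."""
    chans = [ChannelInfo(c, c, "scatter") for c in SCATTER_CHANNELS]
    chans += [ChannelInfo(m, m, "fluorescence") for m in PANEL_MARKERS]
    if include_time:
        chans.append(ChannelInfo(TIME_CHANNEL, TIME_CHANNEL, "time"))
    _validate_panel(chans)
    return chans


def _validate_panel(channels: list[ChannelInfo]) -> None:
    markers = [c.marker for c in channels]
    if len(set(markers)) != len(markers):
        raise ConfigError("marker names must be unique within a panel")
    if sum(c.kind == "time" for c in channels) > 1:
        raise ConfigError("at most one time channel per panel")


_STAGES = ("raw", "compensated", "transformed")


@dataclass
class EventMatrix:
    """Events x channels intensity matrix plus channel metadata.

    ``stage`` only ever advances raw -> compensated -> transformed.
    """

    values: np.ndarray
    channels: list[ChannelInfo]
    stage: str = "raw"
    sample_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (events x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("event matrix contains non-finite values")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise PanelMismatchError(f"marker {marker!r} not in panel") from None

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index(marker)]

    def submatrix(self, markers: list[str]) -> np.ndarray:
        idx = [self.marker_index(m) for m in markers]
        return self.values[:, idx]

    def fluorescence_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.kind == "fluorescence"]

    def time_index(self) -> int | None:
        for i, c in enumerate(self.channels):
            if c.kind == "time":
                return i
        return None

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "EventMatrix":
        return EventMatrix(values, list(self.channels), stage or self.stage,
                           self.sample_id)


@dataclass
class SpilloverMatrix:
    """Square spillover matrix over fluorescence detectors; unit diagonal."""

    coefficients: np.ndarray
    detectors: list[str]

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        k = len(self.detectors)
        if self.coefficients.shape != (k, k):
            raise ConfigError("spillover matrix must be square over its detectors")
        if not np.allclose(np.diag(self.coefficients), 1.0):
            raise ConfigError("spillover diagonal must be exactly 1")
        if (not np.isfinite(np.linalg.cond(self.coefficients))
                or np.linalg.matrix_rank(self.coefficients) < k):
            raise ConfigError("spillover matrix is singular")

    @classmethod
    def identity(cls, detectors: list[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(detectors)), list(detectors))

    @classmethod
    def read_csv(cls, path: str) -> "SpilloverMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header = rows[0][1:]
        mat = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(mat, header)

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + self.detectors)
            for name, row in zip(self.detectors, self.coefficients):
                w.writerow([name] + [repr(float(v)) for v in row])


DEFAULT_COFACTOR = 150.0
#: Raw-unit span that maps scatter onto the [0, ~5] analysis scale.
SCATTER_SCALE = 10000.0


@dataclass
class TransformSpec:
    """Per-channel display/analysis transform.

    Fluorescence channels use asinh(x / cofactor); scatter channels a linear
    rescale x / scale; the time channel is left untouched. All transforms are
    strictly monotone.
    """

    cofactors: dict = field(default_factory=dict)  # marker -> cofactor
    scatter_scale: float = SCATTER_SCALE
    identity: bool = False

    def __post_init__(self):
        for m, c in self.cofactors.items():
            if c <= 0:
                raise ConfigError(f"non-positive cofactor for {m!r}")
        if self.scatter_scale <= 0:
            raise ConfigError("non-positive scatter scale")

    @classmethod
    def default(cls, channels: list[ChannelInfo],
                cofactor: float = DEFAULT_COFACTOR) -> "TransformSpec":
        return cls({c.marker: cofactor for c in channels
                    if c.kind == "fluorescence"})

    def forward(self, em: "EventMatrix") -> np.ndarray:
        out = em.values.copy()
        if self.identity:
            return out
        for i, ch in enumerate(em.channels):
            if ch.kind == "fluorescence":
                cf = self.cofactors.get(ch.marker, DEFAULT_COFACTOR)
                out[:, i] = np.arcsinh(out[:, i] / cf)
            elif ch.kind == "scatter":
                out[:, i] = out[:, i] / self.scatter_scale
        return out

    def inverse(self, em: "EventMatrix") -> np.ndarray:
        """Map transformed-space values back to raw units."""
        out = em.values.copy()
        if self.identity:
            return out
        for i, ch in enumerate(em.channels):
            if ch.kind == "fluorescence":
                cf = self.cofactors.get(ch.marker, DEFAULT_COFACTOR)
                out[:, i] = np.sinh(out[:, i]) * cf
            elif ch.kind == "scatter":
                out[:, i] = out[:, i] * self.scatter_scale
        return out


# ---------------------------------------------------------------------------
# FCS 3.1 container (float32 list mode)
# ---------------------------------------------------------------------------

def _build_text_segment(keywords: dict, text_start: int) -> bytes:
    """Serialise TEXT with '/' delimiter, resolving the chicken-and-egg
    between segment length and the $BEGINDATA/$ENDDATA offsets by padding
    the offset values to fixed width."""
    delim = "/"
    parts = [delim]
    for k, v in keywords.items():
        parts.append(f"{k}{delim}{v}{delim}")
    return "".join(parts).encode("latin-1")


def write_events(em: EventMatrix, path: str, labels=None) -> None:
    """Write an :class:`EventMatrix` to FCS 3.1 (.fcs) or CSV (.csv).

    With ``labels`` (length = event count), FCS output gains one extra
    integer channel ``LABEL`` whose code table is stored in the
    ``CYTOAGI_LABELS`` keyword; CSV output gains a trailing ``LABEL``
    column holding the label text.
    """
    if labels is not None and len(labels) != em.n_events:
        raise ValueError("labels length must equal event count")
    if path.lower().endswith(".csv"):
        _write_csv(em, path, labels)
    else:
        _write_fcs(em, path, labels)


def _write_csv(em: EventMatrix, path: str, labels) -> None:
    header = [c.detector_name for c in em.channels]
    vals = em.values.astype(np.float32)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if labels is None:
            w.writerow(header)
            for row in vals:
                w.writerow([repr(float(v)) for v in row])
        else:
            w.writerow(header + [LABEL_CHANNEL])
            for row, lab in zip(vals, labels):
                w.writerow([repr(float(v)) for v in row] + [str(lab)])


def _write_fcs(em: EventMatrix, path: str, labels) -> None:
    values = em.values.astype("<f4")
    channels = list(em.channels)
    label_table = ""
    if labels is not None:
        names = sorted(set(str(x) for x in labels))
        code = {n: i for i, n in enumerate(names)}
        col = np.array([code[str(x)] for x in labels], dtype="<f4")
        values = np.column_stack([values, col])
        channels = channels + [ChannelInfo(LABEL_CHANNEL, LABEL_CHANNEL, "fluorescence")]
        label_table = "|".join(names)

    n, p = values.shape
    keywords = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0", "$TOT": str(n), "$PAR": str(p),
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        # placeholders, fixed width so TEXT length is stable
        "$BEGINDATA": "%012d" % 0, "$ENDDATA": "%012d" % 0,
        "CYTOAGI_STAGE": em.stage, "CYTOAGI_SAMPLE": em.sample_id or "",
    }
    if label_table:
        keywords[LABEL_KEYWORD] = label_table
    for i, ch in enumerate(channels, start=1):
        rng = float(np.max(values[:, i - 1])) if n else 0.0
        keywords[f"$P{i}N"] = ch.detector_name
        keywords[f"$P{i}S"] = ch.marker
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "%d" % (int(rng) + 1)

    header_len = 58
    text = _build_text_segment(keywords, header_len)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + values.nbytes - 1
    keywords["$BEGINDATA"] = "%012d" % data_start
    keywords["$ENDDATA"] = "%012d" % data_end
    text = _build_text_segment(keywords, header_len)
    assert text_start + len(text) - 1 == text_end

    def off(v):  # header offsets; 0 if they do not fit in 8 ASCII digits
        return b"%8d" % v if v <= 99999999 else b"%8d" % 0

    header = b"FCS3.1    " + off(text_start) + off(text_end)
    header += off(data_start) + off(data_end) + off(0) + off(0)
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def _parse_fcs(path: str):
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:6].startswith(b"FCS3"):
        raise FCSParseError(f"{path}: not an FCS 3.x file")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FCSParseError(f"{path}: malformed header") from exc
    if text_end >= len(raw):
        raise FCSParseError(f"{path}: truncated TEXT segment")
    text = raw[text_start:text_end + 1].decode("latin-1")
    delim = text[0]
    toks = text[1:].split(delim)
    kw = {toks[i]: toks[i + 1] for i in range(0, len(toks) - 1, 2)}

    data_start = int(kw.get("$BEGINDATA", raw[26:34] or 0))
    data_end = int(kw.get("$ENDDATA", raw[34:42] or 0))
    n = int(kw["$TOT"])
    p = int(kw["$PAR"])
    if kw.get("$DATATYPE") != "F":
        raise FCSParseError(f"{path}: only $DATATYPE F is supported")
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    nbytes = n * p * 4
    if data_end - data_start + 1 < nbytes or data_end >= len(raw):
        raise FCSParseError(f"{path}: truncated DATA segment")
    values = np.frombuffer(raw[data_start:data_start + nbytes],
                           dtype=order + "f4").reshape(n, p).astype(np.float64)
    names = [kw.get(f"$P{i}N", "") for i in range(1, p + 1)]
    markers = [kw.get(f"$P{i}S", kw.get(f"$P{i}N", "")) for i in range(1, p + 1)]
    return values, names, markers, kw


def _resolve_panel(names, markers, panel):
    """Map file channels onto the declared panel; unknown channel -> error."""
    by_detector = {c.detector_name: c for c in panel}
    by_marker = {c.marker: c for c in panel}
    resolved = []
    for det, mark in zip(names, markers):
        if det == LABEL_CHANNEL or mark == LABEL_CHANNEL:
            resolved.append(None)
            continue
        ch = by_detector.get(det) or by_marker.get(mark)
        if ch is None:
            raise PanelMismatchError(
                f"channel {det!r} (marker {mark!r}) is not in the panel")
        resolved.append(ch)
    return resolved


def read_events(path: str, panel: list[ChannelInfo] | None = None) -> EventMatrix:
    """Read an FCS 3.x or CSV file into a stage=raw :class:`EventMatrix`.

    Event order is preserved as stored. A ``LABEL`` channel/column, if
    present, is dropped here (see :func:`read_labels`).
    """
    panel = panel if panel is not None else default_panel()
    if path.lower().endswith(".csv"):
        values, names = _read_csv_values(path)
        markers = names
        sample_id = os.path.splitext(os.path.basename(path))[0]
    else:
        values, names, markers, kw = _parse_fcs(path)
        sample_id = kw.get("CYTOAGI_SAMPLE") or os.path.splitext(
            os.path.basename(path))[0]
    resolved = _resolve_panel(names, markers, panel)
    keep = [i for i, ch in enumerate(resolved) if ch is not None]
    channels = [resolved[i] for i in keep]
    return EventMatrix(values[:, keep], channels, "raw", sample_id)


def _read_csv_values(path: str):
    with open(path, newline="") as fh:
        rdr = csv.reader(fh)
        header = next(rdr)
        rows = list(rdr)
    has_label = header and header[-1] == LABEL_CHANNEL
    ncol = len(header) - (1 if has_label else 0)
    if rows:
        values = np.array([[float(v) for v in r[:ncol]] for r in rows])
    else:
        values = np.empty((0, ncol))
    return values, header[:ncol]


def read_labels(path: str) -> list[str] | None:
    """Recover the per-event label vector written by :func:`write_events`."""
    if path.lower().endswith(".csv"):
        with open(path, newline="") as fh:
            rdr = csv.reader(fh)
            header = next(rdr)
            if not header or header[-1] != LABEL_CHANNEL:
                return None
            return [r[-1] for r in rdr]
    values, names, markers, kw = _parse_fcs(path)
    if LABEL_KEYWORD not in kw or LABEL_CHANNEL not in names:
        return None
    table = kw[LABEL_KEYWORD].split("|")
    col = values[:, names.index(LABEL_CHANNEL)].astype(int)
    return [table[i] for i in col]


# ---------------------------------------------------------------------------
# Compensation and transform stages
# ---------------------------------------------------------------------------

def compensate(em: EventMatrix, spill: SpilloverMatrix) -> EventMatrix:
    """Undo fluorescence spillover: observed = true @ S, so true = observed @ S^-1.

    Scatter and time channels are untouched; stage becomes ``compensated``.
    """
    if em.stage != "raw":
        raise ValueError(f"compensate expects stage=raw, got {em.stage}")
    fluor_idx = em.fluorescence_indices()
    det_names = [em.channels[i].detector_name for i in fluor_idx]
    missing = [d for d in spill.detectors if d not in det_names]
    if missing:
        raise PanelMismatchError(f"spillover detectors not in file: {missing}")
    cols = [fluor_idx[det_names.index(d)] for d in spill.detectors]
    try:
        inv = np.linalg.inv(spill.coefficients)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("spillover matrix is not invertible") from exc
    out = em.values.copy()
    out[:, cols] = out[:, cols] @ inv
    return em.with_values(out, "compensated")


def apply_transform(em: EventMatrix, spec: TransformSpec) -> EventMatrix:
    """Apply the per-channel monotone analysis transform (stage -> transformed)."""
    if em.stage != "compensated":
        raise ValueError(f"apply_transform expects stage=compensated, got {em.stage}")
    return em.with_values(spec.forward(em), "transformed")


def raw_from_transformed(em: EventMatrix, spec: TransformSpec | None = None) -> EventMatrix:
    """Inverse of the analysis transform, used when exporting simulated data."""
    if em.stage != "transformed":
        raise ValueError("expects stage=transformed")
    spec = spec or TransformSpec.default(em.channels)
    out = spec.inverse(em)
    return EventMatrix(out, list(em.channels), "raw", em.sample_id)
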