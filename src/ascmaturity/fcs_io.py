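"""Reading and writing cytometry event data in FCS 3.0/3.1 format.

The unit of data is the :class:`EventMatrix`: an events x detectors matrix of
linear intensities together with detector names (``$PnN``), optional marker
names (``$PnS``), a platform tag (flow vs. mass cytometry) and the raw TEXT
segment keywords. Spillover matrices stored in the file (``$SPILLOVER`` /
``SPILL`` / ``$COMP``) can be extracted and applied as a linear compensation
``x_comp = x_raw @ inv(S)``.

Only FCS versions 3.0 and 3.1 are supported; list-mode data of type ``F``
(float32), ``D`` (float64) and ``I`` (unsigned integers of 8/16/32/64 bit)
are read. Files are written as FCS 3.1 with ``$DATATYPE/F``, which
round-trips at float32 precision. No intensity transformation (arcsinh,
logicle, ...) is applied at I/O time; gating operates on linear values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Platform",
    "EventMatrix",
    "SpilloverMatrix",
    "FCSParseError",
    "read_fcs",
    "write_fcs",
    "extract_spillover",
    "apply_compensation",
    "rename_channels",
]

#: Standard marker vocabulary used throughout the pipeline.
STANDARD_MARKERS = frozenset(
    {
        "CD3", "CD19", "CD20", "CD27", "CD28", "CD38", "CD45", "CD56",
        "CD138", "HLA-DR", "Ki67", "viability", "DNA1", "DNA2",
        "FSC-A", "FSC-H", "SSC-A",
    }
)


class Platform(str, enum.Enum):
    flow = "flow"
    mass = "mass"


class FCSParseError(ValueError):
    """Raised when an FCS file violates the parts of the standard we rely on."""


@dataclass
class EventMatrix:
    """Per-sample event data: rows are cells/events, columns are detectors."""

    events: np.ndarray
    detector_names: list[str]
    marker_names: list[str]
    platform: Platform
    keywords: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix")
        n_chan = self.events.shape[1]
        if len(self.detector_names) != n_chan or len(self.marker_names) != n_chan:
            raise ValueError(
                "detector_names and marker_names must match the column count"
            )
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValueError("event intensities must be finite")
        self.platform = Platform(self.platform)

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def column_for_marker(self, marker: str) -> int:
        """Index of the channel carrying *marker* (marker name, then detector)."""
        if marker in self.marker_names:
            return self.marker_names.index(marker)
        if marker in self.detector_names:
            return self.detector_names.index(marker)
        raise KeyError(f"marker {marker!r} not present in this sample")

    def marker_values(self, marker: str) -> np.ndarray:
        return self.events[:, self.column_for_marker(marker)]


@dataclass
class SpilloverMatrix:
    """Square spillover matrix over a subset of detectors; diagonal is 1."""

    detectors: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.detectors)
        if self.matrix.shape != (n, n):
            raise ValueError("spillover matrix must be square over its detectors")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover diagonal must be 1")


def infer_platform(detector_names: list[str], marker_names: list[str]) -> Platform:
    """Flow if scatter channels are present, otherwise mass cytometry."""
    names = set(detector_names) | set(marker_names)
    if any(n.startswith(("FSC", "SSC")) for n in names):
        return Platform.flow
    return Platform.mass


# ---------------------------------------------------------------------------
# TEXT segment helpers


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # A doubled delimiter is an escaped literal delimiter character.
    parts = body.split(delim)
    tokens: list[bytes] = []
    buf = parts[0]
    j = 1
    while j < len(parts):
        if parts[j] == b"" and j + 1 < len(parts):
            buf += delim + parts[j + 1]
            j += 2
        else:
            tokens.append(buf)
            buf = parts[j]
            j += 1
    tokens.append(buf)
    if len(tokens) % 2 != 0:
        raise FCSParseError("TEXT segment has an odd number of tokens")
    kw: dict[str, str] = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        kw[k.decode("latin-1").strip()] = v.decode("latin-1")
    return kw


def _require(kw: dict[str, str], key: str) -> str:
    if key not in kw:
        raise FCSParseError(f"required keyword {key} missing from TEXT segment")
    return kw[key]


# ---------------------------------------------------------------------------
# Reader


def read_fcs(path) -> EventMatrix:
    """Read an FCS 3.0/3.1 file into an :class:`EventMatrix`.

    Detector names come from ``$PnN``; marker names from ``$PnS`` (empty
    string when absent). All TEXT keywords are preserved verbatim on the
    returned object. Raises :class:`FCSParseError` naming the offending
    keyword on malformed input.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    version = data[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSParseError(
            f"unsupported FCS version {version!r}: only FCS 3.0/3.1 are handled"
        )
    try:
        text_begin = int(data[10:18])
        text_end = int(data[18:26])
        data_begin = int(data[26:34])
        data_end = int(data[34:42])
    except ValueError as exc:
        raise FCSParseError(f"malformed HEADER offsets: {exc}") from exc
    kw = _parse_text_segment(data[text_begin : text_end + 1])

    if data_begin == 0 or data_end == 0:
        data_begin = int(_require(kw, "$BEGINDATA"))
        data_end = int(_require(kw, "$ENDDATA"))

    n_par = int(_require(kw, "$PAR"))
    n_tot = int(_require(kw, "$TOT"))
    datatype = _require(kw, "$DATATYPE").strip().upper()
    byteord = _require(kw, "$BYTEORD").strip()
    endian = "<" if byteord.startswith("1") else ">"

    detector_names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    marker_names = [kw.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    raw = data[data_begin : data_end + 1]
    if datatype == "F":
        dt = np.dtype(f"{endian}f4")
        events = np.frombuffer(raw[: n_tot * n_par * 4], dtype=dt)
    elif datatype == "D":
        dt = np.dtype(f"{endian}f8")
        events = np.frombuffer(raw[: n_tot * n_par * 8], dtype=dt)
    elif datatype == "I":
        widths = set(bits)
        if len(widths) != 1 or widths.pop() not in (8, 16, 32, 64):
            raise FCSParseError(
                "$PnB: only uniform 8/16/32/64-bit integer data are supported"
            )
        nbytes = bits[0] // 8
        dt = np.dtype(f"{endian}u{nbytes}")
        events = np.frombuffer(raw[: n_tot * n_par * nbytes], dtype=dt)
    else:
        raise FCSParseError(f"unsupported $DATATYPE {datatype!r}")
    if events.size != n_tot * n_par:
        raise FCSParseError(
            f"DATA segment holds {events.size} values, "
            f"but $TOT={n_tot} x $PAR={n_par} were declared"
        )
    events = events.reshape(n_tot, n_par).astype(np.float64)

    platform = infer_platform(detector_names, marker_names)
    return EventMatrix(
        events=events,
        detector_names=detector_names,
        marker_names=marker_names,
        platform=platform,
        keywords=kw,
    )


# ---------------------------------------------------------------------------
# Writer


def write_fcs(em: EventMatrix, path) -> None:
    """Write *em* as FCS 3.1, ``$DATATYPE/F`` (float32), little-endian.

    ``read_fcs(write_fcs(em))`` reproduces the event values at float32
    precision and preserves user keywords.
    """
    n_tot, n_par = em.events.shape
    delim = "/"

    def esc(s: str) -> str:
        return s.replace(delim, delim + delim)

    kw_pairs: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i in range(n_par):
        kw_pairs.append((f"$P{i + 1}N", em.detector_names[i]))
        kw_pairs.append((f"$P{i + 1}B", "32"))
        kw_pairs.append((f"$P{i + 1}E", "0,0"))
        kw_pairs.append((f"$P{i + 1}R", "262144"))
        if em.marker_names[i]:
            kw_pairs.append((f"$P{i + 1}S", em.marker_names[i]))
    reserved = {k for k, _ in kw_pairs} | {"$BEGINDATA", "$ENDDATA"}
    for k, v in em.keywords.items():
        if k not in reserved and v != "":
            kw_pairs.append((k, v))

    header_len = 58
    data_nbytes = n_tot * n_par * 4

    def render_text(begin_data: int, end_data: int) -> bytes:
        parts = [delim]
        pairs = kw_pairs + [
            ("$BEGINDATA", str(begin_data)),
            ("$ENDDATA", str(end_data)),
        ]
        for k, v in pairs:
            parts.append(esc(k) + delim + esc(v) + delim)
        return "".join(parts).encode("latin-1")

    # Fixed-point iteration on offsets (digit counts can shift the layout).
    begin_data = header_len + len(render_text(0, 0))
    for _ in range(6):
        text = render_text(begin_data, begin_data + max(data_nbytes - 1, 0))
        new_begin = header_len + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    end_data = begin_data + max(data_nbytes - 1, 0)
    text = render_text(begin_data, end_data)

    text_begin = header_len
    text_end = text_begin + len(text) - 1
    head = "FCS3.1    "
    # Offsets in the 58-byte header are 8-char right-justified ASCII; the
    # standard allows 0 there when the true offsets exceed 8 digits.
    def off(x: int) -> str:
        s = str(x)
        return s.rjust(8) if len(s) <= 8 else "0".rjust(8)

    data_off_begin = begin_data if data_nbytes else 0
    data_off_end = end_data if data_nbytes else 0
    header = (
        head
        + off(text_begin)
        + off(text_end)
        + off(data_off_begin)
        + off(data_off_end)
        + off(0)
        + off(0)
    ).encode("ascii")
    assert len(header) == header_len

    body = np.ascontiguousarray(em.events, dtype="<f4").tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(body)


# ---------------------------------------------------------------------------
# Spillover / compensation


def extract_spillover(em: EventMatrix) -> SpilloverMatrix | None:
    """Parse the spillover keyword if present, else return ``None``.

    Accepts the ``$SPILLOVER`` (FCS 3.1), ``SPILL`` and ``$COMP`` spellings,
    all in the ``"n,det1,...,detn,v11,...,vnn"`` format.
    """
    raw = None
    for key in ("$SPILLOVER", "SPILL", "$SPILL", "$COMP", "COMP"):
        if key in em.keywords:
            raw = em.keywords[key]
            break
    if raw is None:
        return None
    tokens = [t.strip() for t in raw.split(",")]
    try:
        n = int(tokens[0])
    except (ValueError, IndexError) as exc:
        raise FCSParseError(f"spillover keyword does not start with a count: {raw!r}") from exc
    if len(tokens) != 1 + n + n * n:
        raise FCSParseError(
            f"spillover keyword declares n={n} but holds {len(tokens)} tokens"
        )
    detectors = tokens[1 : 1 + n]
    values = np.array([float(t) for t in tokens[1 + n :]], dtype=float).reshape(n, n)
    return SpilloverMatrix(detectors=detectors, matrix=values)


def apply_compensation(em: EventMatrix, s: SpilloverMatrix) -> EventMatrix:
    """Compensate spillover: ``x_comp = x_raw @ inv(S)`` on the named detectors.

    Rows of ``S`` are source detectors (the flowCore convention). Channels not
    named in ``S`` are left untouched.
    """
    cols = []
    for det in s.detectors:
        if det not in em.detector_names:
            raise KeyError(f"spillover detector {det!r} not present in sample")
        cols.append(em.detector_names.index(det))
    if abs(np.linalg.det(s.matrix)) < 1e-12:
        raise np.linalg.LinAlgError("spillover matrix is singular")
    inv = np.linalg.inv(s.matrix)
    events = em.events.copy()
    events[:, cols] = em.events[:, cols] @ inv
    return replace(em, events=events)


def rename_channels(em: EventMatrix, mapping: dict[str, str]) -> EventMatrix:
    """Assign standard marker names to detectors (step: channel harmonization).

    ``mapping`` maps detector name -> marker name; unmapped channels keep
    their existing marker annotation. Two detectors mapped to the same marker
    is an error, as is an unknown detector.
    """
    unknown = set(mapping) - set(em.detector_names)
    if unknown:
        raise KeyError(f"unknown detectors in channel map: {sorted(unknown)}")
    targets = list(mapping.values())
    dupes = {t for t in targets if targets.count(t) > 1}
    if dupes:
        raise ValueError(f"multiple detectors mapped to the same marker: {sorted(dupes)}")
    marker_names = list(em.marker_names)
    for det, marker in mapping.items():
        marker_names[em.detector_names.index(det)] = marker
    return replace(em, marker_names=marker_names)
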