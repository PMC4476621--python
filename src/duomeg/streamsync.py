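"""Trigger-channel timestamp codec and clock-map fitting.

Two MEG sites record on free-running local clocks.  Each site's acquisition
computer injects serially encoded GPS timestamps into a spare trigger
channel; decoding those codewords and fitting an affine clock model
(offset + linear drift) co-registers the two recordings on the common GPS
timeline with sub-millisecond accuracy.

Codeword format (an original convention for this package; the wire format
is not standardized):

* start marker: level 255 held for 10 samples;
* payload: 48 bits — 32-bit integer seconds then 16-bit milliseconds,
  least-significant bit first, each bit held for 5 samples at level 1/0;
* checksum: 8 bits, the modular sum of the six payload bytes, same bit
  timing.

One codeword spans 290 samples (< 0.5 s at 1 kHz).  Bit cells are decoded
by majority vote with a uniformity check, so any single corrupted sample
inside a codeword is detected and flags the stamp rather than silently
corrupting it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MARKER_LEVEL",
    "MARKER_SAMPLES",
    "SAMPLES_PER_BIT",
    "PAYLOAD_BITS",
    "CHECKSUM_BITS",
    "CODEWORD_SAMPLES",
    "TriggerTrace",
    "DecodedStamp",
    "ClockMap",
    "encode_timestamps",
    "decode_timestamps",
    "fit_clock_map",
    "map_times",
    "to_common_timeline",
]

MARKER_LEVEL = 255
MARKER_SAMPLES = 10
SAMPLES_PER_BIT = 5
PAYLOAD_BITS = 48  # 32-bit seconds + 16-bit milliseconds, LSB first
CHECKSUM_BITS = 8
CODEWORD_SAMPLES = MARKER_SAMPLES + (PAYLOAD_BITS + CHECKSUM_BITS) * SAMPLES_PER_BIT


@dataclass
class TriggerTrace:
    """Trigger-line levels sampled at ``fs_hz``."""

    fs_hz: float
    samples: np.ndarray  # (N,) non-negative integer levels
    site: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("trigger trace must be 1-D")
        if np.any(self.samples < 0):
            raise ValueError("trigger levels must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class DecodedStamp:
    """One decoded codeword: where it sits in the trace and what it encodes."""

    sample_index: int  # first sample of the start marker
    encoded_time_s: float  # GPS time carried by the payload
    checksum_ok: bool


@dataclass
class ClockMap:
    """Affine map from local sample index to the common (GPS) timeline:
    ``t_common = offset_s + (1 + drift) * sample_index / fs_hz``."""

    offset_s: float
    drift: float  # slope - 1, dimensionless
    fs_hz: float
    rms_residual_ms: float = 0.0
    n_stamps: int = 0

    @property
    def drift_ppm(self) -> float:
        return self.drift * 1e6

    def sample_to_common(self, sample_index) -> np.ndarray:
        return self.offset_s + (1.0 + self.drift) * np.asarray(sample_index) / self.fs_hz

    def local_to_common(self, t_local_s) -> np.ndarray:
        return self.offset_s + (1.0 + self.drift) * np.asarray(t_local_s)


# ---------------------------------------------------------------------------
# codec


def _time_to_fields(t_s: float) -> tuple[int, int]:
    total_ms = int(round(t_s * 1000.0))
    if total_ms < 0:
        raise ValueError("timestamps must be non-negative")
    sec, ms = divmod(total_ms, 1000)
    if sec >= 2**32:
        raise ValueError("seconds field overflows 32 bits")
    return sec, ms


def _payload_bits(sec: int, ms: int) -> np.ndarray:
    word = sec | (ms << 32)  # 48-bit payload, seconds in the low 32 bits
    bits = np.array([(word >> i) & 1 for i in range(PAYLOAD_BITS)], dtype=np.uint8)
    return bits


def _checksum(bits: np.ndarray) -> int:
    by = np.packbits(bits.reshape(-1, 8), axis=1, bitorder="little").ravel()
    return int(by.sum()) % 256


def encode_timestamps(
    times_s,
    fs_hz: float,
    n_samples: int | None = None,
    site: str = "",
) -> TriggerTrace:
    """Render GPS timestamps as trigger-channel codewords.

    Each time is placed with its marker starting at the sample nearest the
    stamp's position in the trace; the payload carries the time itself,
    rounded to the millisecond.  Codewords must not overlap.
    """
    times_s = np.sort(np.asarray(times_s, dtype=float))
    starts = np.round(times_s * fs_hz).astype(np.int64)
    if np.any(np.diff(starts) < CODEWORD_SAMPLES):
        raise ValueError(
            f"codewords overlap: stamps closer than {CODEWORD_SAMPLES} samples"
        )
    if n_samples is None:
        n_samples = int(starts[-1]) + CODEWORD_SAMPLES if starts.size else 0
    trace = np.zeros(n_samples, dtype=np.int64)
    for t, s in zip(times_s, starts):
        word = _render_codeword(float(t))
        if s < 0 or s + CODEWORD_SAMPLES > n_samples:
            raise ValueError("codeword falls outside the trace")
        trace[s : s + CODEWORD_SAMPLES] = word
    return TriggerTrace(fs_hz=fs_hz, samples=trace, site=site)


def _render_codeword(t_s: float) -> np.ndarray:
    sec, ms = _time_to_fields(t_s)
    bits = _payload_bits(sec, ms)
    chk = _checksum(bits)
    chk_bits = np.array([(chk >> i) & 1 for i in range(CHECKSUM_BITS)], dtype=np.uint8)
    word = np.empty(CODEWORD_SAMPLES, dtype=np.int64)
    word[:MARKER_SAMPLES] = MARKER_LEVEL
    cells = np.repeat(np.concatenate([bits, chk_bits]).astype(np.int64),
                      SAMPLES_PER_BIT)
    word[MARKER_SAMPLES:] = cells
    return word


def _marker_starts(samples: np.ndarray) -> np.ndarray:
    is_marker = samples == MARKER_LEVEL
    edges = np.diff(np.concatenate([[0], is_marker.view(np.uint8)]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(np.diff(np.concatenate([is_marker.view(np.uint8), [0]])) == -1)
    good = (ends - starts + 1) >= MARKER_SAMPLES
    return starts[good]


def decode_timestamps(tt: TriggerTrace) -> list[DecodedStamp]:
    """Decode every codeword present in a trigger trace.

    Well-formed codewords yield ``checksum_ok=True`` stamps; corrupted bit
    cells (non-uniform or failing the checksum) flag the stamp instead of
    dropping it, and a truncated trailing codeword is reported via the log
    and skipped.  Raises if the checksum-valid stamps are not strictly
    increasing in both sample index and encoded time.
    """
    samples = np.asarray(tt.samples)
    stamps: list[DecodedStamp] = []
    for s in _marker_starts(samples):
        s = int(s)
        if s + CODEWORD_SAMPLES > samples.size:
            logger.warning("truncated codeword at sample %d skipped", s)
            continue
        body = samples[s + MARKER_SAMPLES : s + CODEWORD_SAMPLES]
        cells = body.reshape(PAYLOAD_BITS + CHECKSUM_BITS, SAMPLES_PER_BIT)
        ones = (cells > 0).sum(axis=1)
        bits = (ones * 2 > SAMPLES_PER_BIT).astype(np.uint8)
        uniform = np.all(cells == cells[:, :1], axis=1)
        payload = bits[:PAYLOAD_BITS]
        chk_bits = bits[PAYLOAD_BITS:]
        chk = int(np.packbits(chk_bits, bitorder="little")[0])
        ok = bool(np.all(uniform)) and chk == _checksum(payload)
        word = 0
        for i in range(PAYLOAD_BITS):
            word |= int(payload[i]) << i
        sec = word & 0xFFFFFFFF
        ms = word >> 32
        stamps.append(DecodedStamp(s, sec + ms / 1000.0, ok))
    good = [st for st in stamps if st.checksum_ok]
    for prev, cur in zip(good, good[1:]):
        if not (cur.sample_index > prev.sample_index
                and cur.encoded_time_s > prev.encoded_time_s):
            raise ValueError(
                "decoded timestamps are not strictly increasing "
                f"({prev.encoded_time_s} -> {cur.encoded_time_s})"
            )
    return stamps


# ---------------------------------------------------------------------------
# clock fitting


def fit_clock_map(stamps: list[DecodedStamp], fs_hz: float) -> ClockMap:
    """Least-squares affine fit of encoded GPS time against local sample time.

    Stamps failing the checksum are excluded, never interpolated.  Requires
    at least two valid stamps.
    """
    good = [st for st in stamps if st.checksum_ok]
    if len(good) < 2:
        raise ValueError(f"need >= 2 checksum-valid stamps, got {len(good)}")
    t_local = np.array([st.sample_index for st in good], dtype=float) / fs_hz
    t_enc = np.array([st.encoded_time_s for st in good])
    # centre the regressor for numerical stability at hour-scale offsets
    t0 = t_local.mean()
    slope, intercept = np.polyfit(t_local - t0, t_enc, 1)
    offset = intercept - slope * t0
    resid = t_enc - (offset + slope * t_local)
    return ClockMap(
        offset_s=float(offset),
        drift=float(slope - 1.0),
        fs_hz=fs_hz,
        rms_residual_ms=float(np.sqrt(np.mean(resid**2)) * 1000.0),
        n_stamps=len(good),
    )


def map_times(times_local_s, cm: ClockMap) -> np.ndarray:
    """Re-express local times (seconds since the recording start) on the
    common timeline."""
    return cm.local_to_common(times_local_s)


def to_common_timeline(rec, cm: ClockMap):
    """Return a copy of a recording or event series on the common timeline.

    Supports :class:`~duomeg.behavior.AccelRecording` (start time remapped)
    and :class:`~duomeg.behavior.EventSeries` (event times remapped); plain
    arrays go through :func:`map_times`.
    """
    from dataclasses import replace

    from .behavior import AccelRecording, EventSeries

    if isinstance(rec, EventSeries):
        return EventSeries(cm.local_to_common(rec.times_s), rec.site)
    if isinstance(rec, AccelRecording):
        return replace(rec, samples=rec.samples.copy(),
                       start_time_s=float(cm.local_to_common(rec.start_time_s)))
    return map_times(rec, cm)
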