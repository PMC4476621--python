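"""Small shared utilities."""

from __future__ import annotations

import hashlib
import json

__all__ = ["frame_duration_ms", "config_hash"]


def frame_duration_ms(n_samples: int, fs_hz: float) -> float:
    """Duration of one frame of ``n_samples`` at ``fs_hz``, in milliseconds.

    E.g. one 96-sample audio frame at 48 kHz lasts 2 ms.
    """
    if n_samples <= 0 or fs_hz <= 0:
        raise ValueError("n_samples and fs_hz must be positive")
    return n_samples / fs_hz * 1000.0


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
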