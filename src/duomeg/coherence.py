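"""Inter-subject sensor-space coherence mapping for paired MEG recordings.

Given simultaneously recorded 204-channel planar-gradiometer arrays from two
subjects, this module estimates the magnitude-squared coherence (MSC) between
every channel of one site and every channel of the other with Welch's
method, averages it over a low-frequency band covering the movement rhythm
(0.5–2 Hz by default), collapses the 204x204 matrix to per-channel and
per-module topography vectors, and renders flattened-helmet maps.

The Neuromag/Vectorview array has 102 sensor modules of 2 orthogonal planar
gradiometers each; module values are the mean of the two channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.signal as sps

__all__ = [
    "N_GRAD",
    "N_MODULES",
    "GradiometerRecording",
    "CoherenceMatrix",
    "TopoVector",
    "vectorview_grad_info",
    "msc_spectrum",
    "band_mean",
    "inter_subject_matrix",
    "collapse_to_sites",
    "render_topomap",
]

N_GRAD = 204
N_MODULES = 102

_DEF_WINDOW_LEN = 8096  # samples; ~8 s at 1 kHz, ~0.12-Hz resolution
_DEF_BAND = (0.5, 2.0)  # Hz


def vectorview_grad_info():
    """Standard Vectorview gradiometer names, module map and 2-D layout.

    Returns ``(channel_names, module_map, layout_2d)``: 204 channel names,
    an integer array mapping each channel to its module (0..101), and the
    flattened-helmet (x, y) position of each module.  Channels ``MEG xxx2``
    and ``MEG xxx3`` form one module at a common helmet location.
    """
    import mne

    lay = mne.channels.read_layout("Vectorview-grad")
    names = list(lay.names)
    keys = [n.split()[-1][:-1] for n in names]  # 'MEG 0113' -> '011'... '011'
    module_keys = sorted(set(keys), key=keys.index)
    key_to_mod = {k: i for i, k in enumerate(module_keys)}
    module_map = np.array([key_to_mod[k] for k in keys])
    pos = np.zeros((len(module_keys), 2))
    for m in range(len(module_keys)):
        pos[m] = lay.pos[module_map == m, :2].mean(axis=0)
    return names, module_map, pos


@dataclass
class GradiometerRecording:
    """One site's 204-channel planar-gradiometer array.

    ``module_map`` maps each channel to its sensor module (two channels per
    module); ``layout_2d`` holds the flattened-helmet positions of the 102
    modules.  Input data are assumed already interference-suppressed
    upstream (e.g. by signal-space separation); ``sss_applied`` records
    whether that preprocessing was done.
    """

    site: str
    fs_hz: float
    data: np.ndarray  # (204, N)
    channel_names: list[str]
    module_map: np.ndarray  # (204,) -> 0..101
    layout_2d: np.ndarray  # (102, 2)
    sss_applied: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_GRAD:
            raise ValueError(f"data must have shape ({N_GRAD}, N)")
        counts = np.bincount(np.asarray(self.module_map), minlength=N_MODULES)
        if not np.all(counts == 2):
            raise ValueError("module_map must assign exactly 2 channels per module")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class CoherenceMatrix:
    """Band-averaged inter-subject MSC between two gradiometer arrays.

    Entry ``values[i, j]`` is the band-averaged MSC between channel *i* of
    the rows site and channel *j* of the columns site (convention: rows =
    second/HUCH-role site, columns = first/Aalto-role site).
    """

    values: np.ndarray  # (204, 204) in [0, 1]
    band_hz: tuple[float, float]
    window_len: int
    rows_site: str
    cols_site: str
    overlap: float = 0.5
    taper: str = "hann"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("coherence values outside [0, 1]")


@dataclass
class TopoVector:
    """Per-channel and per-module average-coherence topography of one site."""

    per_channel: np.ndarray  # (204,)
    per_module: np.ndarray  # (102,)
    site: str


# ---------------------------------------------------------------------------
# Welch spectra


def _segment_view(x: np.ndarray, nperseg: int, noverlap: int) -> np.ndarray:
    """Complete Welch segments of ``x`` along the last axis, shape
    (..., n_segments, nperseg).  Incomplete trailing samples are discarded,
    matching scipy's convention."""
    step = nperseg - noverlap
    n = x.shape[-1]
    n_seg = (n - noverlap) // step
    if n_seg < 1:
        raise ValueError("signal shorter than one segment")
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    return x[..., idx]


def _segment_ffts(
    x: np.ndarray,
    window_len: int,
    overlap: float,
    taper: str,
) -> np.ndarray:
    """Per-segment one-sided FFTs with constant detrend and taper applied.

    Constant (mean) detrending only: the 0.5-Hz lower band edge sits near
    the segment fundamental, which linear detrending would distort.
    """
    noverlap = int(window_len * overlap)
    win = sps.get_window(taper, window_len)
    seg = _segment_view(np.asarray(x, dtype=float), window_len, noverlap)
    seg = seg - seg.mean(axis=-1, keepdims=True)
    return np.fft.rfft(seg * win, axis=-1)


def msc_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs_hz: float,
    window_len: int = _DEF_WINDOW_LEN,
    overlap: float = 0.5,
    taper: str = "hann",
):
    """Welch magnitude-squared coherence ``|Sxy|^2 / (Sxx Syy)`` per bin.

    Bin spacing is ``fs_hz / window_len`` (8096 samples at 1 kHz gives about
    0.12 Hz).  At least two segments are required: with a single segment the
    estimator degenerates to exactly 1 at every bin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    if x.size < 2 * window_len:
        raise ValueError(
            f"need >= {2 * window_len} samples (>= 2 Welch segments); with one "
            "segment the coherence estimate degenerates to 1 everywhere"
        )
    noverlap = int(window_len * overlap)
    freqs, cxy = sps.coherence(
        x, y, fs=fs_hz, window=taper, nperseg=window_len,
        noverlap=noverlap, detrend="constant",
    )
    return freqs, np.clip(cxy, 0.0, 1.0)


def band_mean(
    freqs: np.ndarray,
    msc: np.ndarray,
    band_hz: tuple[float, float] = _DEF_BAND,
) -> float:
    """Arithmetic mean of the MSC over bins inside ``band_hz`` (inclusive)."""
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(mask):
        raise ValueError(f"no frequency bins inside band {band_hz}")
    return float(np.mean(np.asarray(msc)[..., mask], axis=-1))


def band_bins(fs_hz: float, window_len: int,
              band_hz: tuple[float, float] = _DEF_BAND) -> np.ndarray:
    """Indices of the one-sided FFT bins inside ``band_hz`` (inclusive)."""
    freqs = np.fft.rfftfreq(window_len, 1.0 / fs_hz)
    idx = np.flatnonzero((freqs >= band_hz[0]) & (freqs <= band_hz[1]))
    if idx.size == 0:
        raise ValueError(f"no frequency bins inside band {band_hz}")
    return idx


def inter_subject_matrix(
    a: GradiometerRecording,
    b: GradiometerRecording,
    band_hz: tuple[float, float] = _DEF_BAND,
    window_len: int = _DEF_WINDOW_LEN,
    overlap: float = 0.5,
    taper: str = "hann",
) -> CoherenceMatrix:
    """Full 204x204 band-averaged inter-subject coherence matrix.

    ``values[i, j]`` equals ``band_mean(msc_spectrum(b.data[i], a.data[j]))``.
    Per-channel segment spectra are computed once and reused across the
    204x204 grid; the result is identical to the naive pairwise Welch
    computation (window scaling and one-sided doubling cancel inside the
    MSC ratio).
    """
    if a.n_samples != b.n_samples or a.fs_hz != b.fs_hz:
        raise ValueError("recordings must be aligned: equal length and rate")
    if a.n_samples < 2 * window_len:
        raise ValueError(f"need >= {2 * window_len} samples per channel")
    bins = band_bins(a.fs_hz, window_len, band_hz)

    def _banded_ffts(data: np.ndarray) -> np.ndarray:
        # chunk channels so the full-spectrum intermediate stays small
        parts = [
            _segment_ffts(data[i : i + 32], window_len, overlap, taper)[..., bins]
            for i in range(0, data.shape[0], 32)
        ]
        return np.concatenate(parts, axis=0)

    fa = _banded_ffts(a.data)
    fb = _banded_ffts(b.data)
    n_seg = fa.shape[1]
    paa = (fa.real**2 + fa.imag**2).mean(axis=1)  # (204, B)
    pbb = (fb.real**2 + fb.imag**2).mean(axis=1)
    acc = np.zeros((N_GRAD, N_GRAD))
    for k in range(bins.size):
        pxy = fb[:, :, k].conj() @ fa[:, :, k].T / n_seg  # rows=b, cols=a
        acc += (pxy.real**2 + pxy.imag**2) / (pbb[:, None, k] * paa[None, :, k])
    values = np.clip(acc / bins.size, 0.0, 1.0)
    return CoherenceMatrix(
        values=values,
        band_hz=tuple(band_hz),
        window_len=window_len,
        rows_site=b.site,
        cols_site=a.site,
        overlap=overlap,
        taper=taper,
    )


def collapse_to_sites(
    cm: CoherenceMatrix,
    module_map: np.ndarray | None = None,
) -> tuple[TopoVector, TopoVector]:
    """Collapse the matrix to one topography vector per site.

    Row means give the rows site's per-channel average coherence, column
    means the columns site's; each module's value is the mean of its two
    channels.  Returns ``(rows_site_vector, cols_site_vector)``.
    """
    if module_map is None:
        _, module_map, _ = vectorview_grad_info()
    module_map = np.asarray(module_map)

    def _collapse(per_channel: np.ndarray, site: str) -> TopoVector:
        sums = np.bincount(module_map, weights=per_channel, minlength=N_MODULES)
        counts = np.bincount(module_map, minlength=N_MODULES)
        return TopoVector(per_channel, sums / counts, site)

    return (
        _collapse(cm.values.mean(axis=1), cm.rows_site),
        _collapse(cm.values.mean(axis=0), cm.cols_site),
    )


def render_topomap(
    tv: TopoVector,
    layout_2d: np.ndarray,
    path: str | Path | None = None,
    grid_res: int = 64,
    title: str | None = None,
):
    """Flattened-helmet map of per-module coherence.

    Interpolates the 102 module values onto a regular grid, overlays the
    module positions, and (optionally) writes the figure.  Returns
    ``(fig, grid)`` where ``grid`` is the interpolated image array so the
    rendered maximum can be located programmatically.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    layout_2d = np.asarray(layout_2d, dtype=float)
    if layout_2d.shape != (N_MODULES, 2):
        raise ValueError(f"layout must have shape ({N_MODULES}, 2)")
    vals = np.asarray(tv.per_module, dtype=float)
    xi = np.linspace(layout_2d[:, 0].min(), layout_2d[:, 0].max(), grid_res)
    yi = np.linspace(layout_2d[:, 1].min(), layout_2d[:, 1].max(), grid_res)
    gx, gy = np.meshgrid(xi, yi)
    grid = griddata(layout_2d, vals, (gx, gy), method="linear")
    nearest = griddata(layout_2d, vals, (gx, gy), method="nearest")
    grid = np.where(np.isnan(grid), nearest, grid)

    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax - vmin < 1e-15:  # degenerate uniform map
        vmin, vmax = vmin - 1e-12, vmax + 1e-12
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(
        grid, origin="lower", vmin=vmin, vmax=vmax, cmap="viridis",
        extent=(xi[0], xi[-1], yi[0], yi[-1]), aspect="equal",
    )
    ax.scatter(layout_2d[:, 0], layout_2d[:, 1], s=4, c="k", alpha=0.4)
    ax.set_axis_off()
    ax.set_title(title or f"{tv.site}: average coherence")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig, grid
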