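"""Track smoothers: 3-bin moving average and Epanechnikov kernel smoothing.

The moving average (used upstream of peak marking and clustering) replaces
each bin by the mean of itself and its two neighbours, truncating the
window at chromosome ends.  The kernel smoother (used for display and for
matching cumulative profiles between data sets) convolves the binned
frequencies with an Epanechnikov kernel, K(u) = 0.75·(1 − u²) for |u| < 1,
of bandwidth h (default 30 bp), evaluated on the same bin grid.  By
default the kernel-smoothed track is rescaled to conserve total frequency
mass so absolute values stay comparable across data sets; downstream
per-window normalisation removes any residual scale anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from nucparticle.track import KDE, MOVING_AVERAGE, BinnedTrack


@dataclass(frozen=True)
class KernelSpec:
    kernel: str = "epanechnikov"
    bandwidth: float = 30.0
    mass_preserving: bool = True

    def __post_init__(self) -> None:
        if self.kernel != "epanechnikov":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def epanechnikov(u: np.ndarray | float) -> np.ndarray | float:
    """K(u) = 0.75 (1 - u^2) on |u| < 1, else 0."""
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u * u), 0.0)
    return out if out.ndim else float(out)


def _conv_same(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    # centered convolution of length len(v), valid even when len(w) > len(v)
    full = np.convolve(v, w, mode="full")
    start = (w.size - 1) // 2
    return full[start : start + v.size]


def moving_average_3(track: BinnedTrack) -> BinnedTrack:
    """3-bin moving average; edge bins average over the 2 available terms."""
    v = track.values
    if v.size < 1:
        raise ValueError("moving_average_3 requires at least one bin")
    kernel = np.ones(3)
    sums = _conv_same(v, kernel)
    counts = _conv_same(np.ones_like(v), kernel)
    return track.with_values(sums / counts, MOVING_AVERAGE, window_bins=3)


def _kernel_weights(bin_width: int, spec: KernelSpec) -> np.ndarray:
    # bin centers are bin_width apart; kernel support is |offset| < h
    max_d = int(np.ceil(spec.bandwidth / bin_width))
    d = np.arange(-max_d, max_d + 1)
    u = d * bin_width / spec.bandwidth
    w = np.asarray(epanechnikov(u)) / spec.bandwidth
    return w[w > 0] if np.any(w > 0) else w


def kernel_smooth(track: BinnedTrack, spec: KernelSpec | None = None) -> BinnedTrack:
    """Epanechnikov kernel smoothing on the bin grid.

    s[j] = Σ_i v[i] · K((x_j − x_i)/h) / h with x the bin centers, then
    (if ``mass_preserving``) rescaled so Σ s = Σ v.
    """
    spec = spec or KernelSpec()
    v = track.values
    w = _kernel_weights(track.bin_width, spec)
    s = _conv_same(v, w)
    total = v.sum()
    if spec.mass_preserving and s.sum() > 0:
        s = s * (total / s.sum())
    s = np.clip(s, 0.0, None)  # guard tiny negative round-off
    return track.with_values(
        s, KDE, kernel=spec.kernel, bandwidth=spec.bandwidth,
        mass_preserving=spec.mass_preserving,
    )


def smooth_tracks(
    tracks: Mapping[str, BinnedTrack], method: str, spec: KernelSpec | None = None
) -> dict[str, BinnedTrack]:
    """Apply a named smoother ('ma3' or 'epanechnikov') to every track."""
    if method == "ma3":
        return {c: moving_average_3(t) for c, t in tracks.items()}
    if method == "epanechnikov":
        return {c: kernel_smooth(t, spec) for c, t in tracks.items()}
    raise ValueError(f"unknown smoothing method {method!r}")
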