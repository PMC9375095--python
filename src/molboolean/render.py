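"""Rendering of molecular events into synthetic fluorescence images.

Produces a 3-channel stack (nuclear, detection A, detection B): nuclei as
soft-edged filled shapes in the nuclear channel, each rolling-circle product
(RCP) as a diffraction-limited isotropic Gaussian spot in the detection
channel(s) of its tag set. A dual-tag RCP is a single DNA ball and is rendered
at one shared centroid in both channels, with per-channel brightness coupled
through a common ball-size factor. Photon (Poisson) shot noise and Gaussian
read noise are applied on top of a constant background.

Physical placement: every RCP is displaced from its source molecule by an
isotropic Gaussian jitter (the ~0.5 um product ball settles around its
anchor). When two RCPs share one source molecule (padlock mode: each probe of
a complex amplifies its own ball) the two balls exclude each other sterically
and are rendered back-to-back, separated by a truncated-normal distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import Field, _as_rng

__all__ = ["RenderParams", "render_field"]

CHANNEL_ORDER = ("nuclear", "det_a", "det_b")


@dataclass(frozen=True)
class RenderParams:
    """Optical and noise model of the synthetic microscope.

    Amplitudes are Gaussian peak heights in counts. A spot's brightness is
    ``amplitude_mean * size_factor * channel_factor`` with both factors
    lognormal (median 1): the size factor is shared between the two channels
    of a dual-tag spot (one ball, tightly coupled A/B content), the channel
    factor models per-dye labeling variability.
    """

    psf_sigma_nm: float = 120.0
    amplitude_mean: float = 600.0
    size_sigma: float = 0.35
    channel_sigma: float = 0.10
    background: tuple[float, float, float] = (10.0, 50.0, 50.0)
    nuclear_amplitude: float = 300.0
    nuclear_smooth_px: float = 2.0
    read_noise_sd: float = 3.0
    rcp_jitter_nm: float = 150.0
    pair_separation_mean_nm: float = 600.0
    pair_separation_sd_nm: float = 150.0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be > 0")


def _stamp_gaussian(img: np.ndarray, y: float, x: float, sigma: float, amp: float) -> None:
    """Add an isotropic Gaussian of peak ``amp`` at (y, x), in place."""
    r = int(np.ceil(4 * sigma))
    H, W = img.shape
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0c, y1c = max(0, y0), min(H, y1)
    x0c, x1c = max(0, x0), min(W, x1)
    if y0c >= y1c or x0c >= x1c:
        return
    yy = np.arange(y0c, y1c)[:, None] - y
    xx = np.arange(x0c, x1c)[None, :] - x
    img[y0c:y1c, x0c:x1c] += amp * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def _event_positions_px(
    events: pd.DataFrame, params: RenderParams, pixel_size_nm: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rendered (y, x) pixel positions: molecule position + ball placement."""
    y = events["y_nm"].to_numpy(float).copy()
    x = events["x_nm"].to_numpy(float).copy()
    n = len(events)
    jitter = rng.normal(0.0, params.rcp_jitter_nm, size=(n, 2))
    # two balls anchored to one molecule exclude each other sterically
    src = events["source_ids"].to_numpy()
    order = np.argsort(src, kind="stable")
    k = 0
    while k < len(order) - 1:
        i, j = order[k], order[k + 1]
        if src[i] == src[j]:
            d = max(rng.normal(params.pair_separation_mean_nm, params.pair_separation_sd_nm), 0.0)
            theta = rng.uniform(0, 2 * np.pi)
            vec = np.array([np.sin(theta), np.cos(theta)]) * d / 2
            jitter[i] = vec
            jitter[j] = -vec
            k += 2
        else:
            k += 1
    y += jitter[:, 0]
    x += jitter[:, 1]
    return y / pixel_size_nm - 0.5, x / pixel_size_nm - 0.5


def render_field(
    events: pd.DataFrame,
    field: Field,
    params: RenderParams = RenderParams(),
    rng: "np.random.Generator | int" = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render events into a (3, H, W) uint16 stack plus a ground-truth table.

    Channel order is ``(nuclear, det_a, det_b)``. The ground-truth table
    records, per event, the rendered pixel position (after ball placement),
    tag set, truth category and cell id; it is the reference against which
    spot detection and classification are scored.
    """
    rng = _as_rng(rng)
    H, W = field.config.shape
    px = field.config.pixel_size_nm
    sigma_px = params.psf_sigma_nm / px

    nuclear = np.zeros((H, W), dtype=float)
    nuclear[field.nucleus_labels > 0] = params.nuclear_amplitude
    if params.nuclear_smooth_px > 0:
        nuclear = ndimage.gaussian_filter(nuclear, params.nuclear_smooth_px)
    det_a = np.zeros((H, W), dtype=float)
    det_b = np.zeros((H, W), dtype=float)

    y_px, x_px = _event_positions_px(events, params, px, rng)
    n = len(events)
    size = np.exp(rng.normal(0.0, params.size_sigma, n)) if n else np.empty(0)
    fac_a = np.exp(rng.normal(0.0, params.channel_sigma, n)) if n else np.empty(0)
    fac_b = np.exp(rng.normal(0.0, params.channel_sigma, n)) if n else np.empty(0)
    tags = events["tags"].to_numpy() if n else np.empty(0)
    for i in range(n):
        amp = params.amplitude_mean * size[i]
        if "A" in tags[i]:
            _stamp_gaussian(det_a, y_px[i], x_px[i], sigma_px, amp * fac_a[i])
        if "B" in tags[i]:
            _stamp_gaussian(det_b, y_px[i], x_px[i], sigma_px, amp * fac_b[i])

    stack = np.stack([nuclear, det_a, det_b])
    stack += np.asarray(params.background)[:, None, None]
    if params.noise:
        stack = rng.poisson(stack).astype(float)
        stack += rng.normal(0.0, params.read_noise_sd, stack.shape)
    stack = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    truth = pd.DataFrame(
        {
            "event_id": events["event_id"].to_numpy() if n else np.empty(0, int),
            "cell_id": events["cell_id"].to_numpy() if n else np.empty(0, int),
            "x_px": x_px,
            "y_px": y_px,
            "tags": tags,
            "category": events["category"].to_numpy() if n else np.empty(0, object),
        }
    )
    return stack, truth
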