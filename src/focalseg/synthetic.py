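"""Synthetic focal stacks with known ground-truth in-focus masks.

Real widefield focal stacks of bulk specimens are rarely released with
per-pixel in-focus annotations, so this module fabricates stacks whose
ground truth is known by construction: a textured scene sits on a
per-pixel depth surface ``d(y, x)``; slice ``z`` (focal depth
``z * z_step_um``) renders every pixel blurred with a Gaussian whose
sigma grows linearly with the pixel's defocus distance
``|z * z_step_um - d(y, x)|``.  A pixel counts as in focus on a slice
when that sigma stays below a perceptibility bound, so the ground-truth
masks of one pixel always form a contiguous run of slices.

The geometry emulates a low-numerical-aperture stereomicroscope
acquisition: 20 focal planes 8.55 um apart, gentle blur growth
(depth of field spanning several z-steps), a depth surface arranged so
the first slice is mostly out of focus and the last mostly in focus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .focusmap import FocalStack
from .masking import InFocusMask

__all__ = ["SyntheticStackSpec", "shepp_logan", "blur_image", "generate_focal_stack"]

# Standard head phantom: 10 ellipses as (a, b, x0, y0, phi_deg, intensity),
# half-axes and centres in [-1, 1] coordinates (high-contrast variant).
_SHEPP_LOGAN_ELLIPSES = (
    (0.69, 0.92, 0.0, 0.0, 0.0, 1.0),
    (0.6624, 0.874, 0.0, -0.0184, 0.0, -0.8),
    (0.11, 0.31, 0.22, 0.0, -18.0, -0.2),
    (0.16, 0.41, -0.22, 0.0, 18.0, -0.2),
    (0.21, 0.25, 0.0, 0.35, 0.0, 0.1),
    (0.046, 0.046, 0.0, 0.1, 0.0, 0.1),
    (0.046, 0.046, 0.0, -0.1, 0.0, 0.1),
    (0.046, 0.023, -0.08, -0.605, 0.0, 0.1),
    (0.023, 0.023, 0.0, -0.606, 0.0, 0.1),
    (0.023, 0.046, 0.06, -0.605, 0.0, 0.1),
)


@dataclass
class SyntheticStackSpec:
    """Parameters of the synthetic focal-stack generator.

    Attributes
    ----------
    height, width:
        Lateral image dimensions in pixels.
    n_slices:
        Number of focal planes (>= 2).
    z_step_um:
        Axial spacing between focal planes, in micrometres.
    depth_surface:
        ``smooth_random`` (the default: a low-frequency random surface,
        quantized into a few large depth strata — the terraced geometry
        of a bulk specimen whose structures sit at distinct depths),
        ``tilted_plane`` (depth ramps linearly across the field, then
        plateaus at the deepest plane) or ``flat`` (single depth
        everywhere).
    surface_params:
        For ``smooth_random``: ``corr_px`` — correlation length of the
        random surface (default 96, giving a few compact strata on a
        256-px field, like the bulky anatomy of a specimen head); ``level_fracs`` — depth of each
        stratum as a fraction of the full range (default (0, 0.5, 1));
        ``level_areas`` — area fraction of each stratum (default
        (0.25, 0.20, 0.55), which leaves the first slice mostly out of
        focus and the last mostly in focus); ``n_levels=0`` disables
        quantization (continuous surface).  For ``tilted_plane``:
        ``ramp_frac`` — fraction of the lateral coordinate over which
        the ramp spans the full depth range before plateauing (default
        0.6).  For ``flat``: ``depth_frac`` — depth as a fraction of
        the full range (default 1.0).
    sigma_per_um:
        Gaussian blur growth per micrometre of defocus, in px/um.  The
        default 0.05 models a low-NA stereomicroscope: one z-step of
        defocus adds ~0.4 px of blur, the far end of the stack ~8 px.
    sigma_in_focus:
        Blur sigma (px) below which a pixel counts as in focus.  The
        default 2.25 px together with ``sigma_per_um`` yields a depth
        of field of about +-45 um (+-5 z-steps), so each stratum stays
        in focus over a run of several consecutive slices.
    texture:
        ``filtered_noise`` (band-limited white noise, textured
        everywhere; the default, since focus is only observable where
        there is texture) or ``shepp_logan``.
    noise_sd:
        Additive Gaussian read-out noise, as a fraction of the dynamic
        range (default 0.01).
    n_blur_levels:
        Size of the pre-blurred image bank used to approximate
        spatially varying blur (nearest-sigma assignment).
    seed:
        Seed for all randomness; identical specs generate bit-identical
        stacks and masks.
    """

    height: int = 256
    width: int = 256
    n_slices: int = 20
    z_step_um: float = 8.55
    pixel_size_um: float = 0.79
    depth_surface: str = "smooth_random"
    surface_params: dict = field(default_factory=dict)
    sigma_per_um: float = 0.05
    sigma_in_focus: float = 2.25
    texture: str = "filtered_noise"
    noise_sd: float = 0.01
    n_blur_levels: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")
        if self.height < 8 or self.width < 8:
            raise ValueError("stack must be at least 8x8")
        if self.sigma_per_um <= 0 or self.sigma_in_focus <= 0:
            raise ValueError("sigma_per_um and sigma_in_focus must be > 0")
        if self.depth_surface not in ("tilted_plane", "smooth_random", "flat"):
            raise ValueError(f"unknown depth_surface {self.depth_surface!r}")
        if self.texture not in ("filtered_noise", "shepp_logan"):
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.noise_sd < 0 or self.n_blur_levels < 2:
            raise ValueError("noise_sd must be >= 0 and n_blur_levels >= 2")

    @property
    def depth_range_um(self) -> float:
        return (self.n_slices - 1) * self.z_step_um

    @property
    def dof_um(self) -> float:
        """Half-width of the in-focus depth band."""
        return self.sigma_in_focus / self.sigma_per_um


def shepp_logan(size: int) -> np.ndarray:
    """Rasterize the standard 10-ellipse head phantom at ``size x size``.

    Values are clipped to [0, 1]; the background outside the outer
    ellipse is exactly 0.
    """
    if size < 16:
        raise ValueError("phantom size must be >= 16")
    coords = np.linspace(-1.0, 1.0, size)
    x, y = np.meshgrid(coords, -coords)  # row 0 = top, y axis up
    img = np.zeros((size, size))
    for a, b, x0, y0, phi_deg, intensity in _SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
        yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += intensity
    return np.clip(img, 0.0, 1.0)


def blur_image(image: np.ndarray, kernel_size: int) -> np.ndarray:
    """Gaussian blur parameterized by square kernel support.

    A ``k x k`` kernel is rendered as a Gaussian with ``sigma = k / 4``
    (so the support holds about +-2 sigma), reflect-padded.
    ``kernel_size=1`` is the identity.
    """
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    if kernel_size == 1:
        return img.copy()
    return gaussian_filter(img, sigma=kernel_size / 4.0, mode="reflect", radius=kernel_size // 2)


def _make_texture(spec: SyntheticStackSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.texture == "shepp_logan":
        if spec.height != spec.width:
            raise ValueError("shepp_logan texture needs a square stack")
        return shepp_logan(spec.height)
    noise = rng.standard_normal((spec.height, spec.width))
    tex = gaussian_filter(noise, sigma=1.0, mode="reflect")
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / (hi - lo)


def _depth_surface(spec: SyntheticStackSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel focal depth in micrometres, in [0, depth_range_um]."""
    d_max = spec.depth_range_um
    p = spec.surface_params
    if spec.depth_surface == "flat":
        frac = float(p.get("depth_frac", 1.0))
        return np.full((spec.height, spec.width), frac * d_max)
    if spec.depth_surface == "tilted_plane":
        ramp_frac = float(p.get("ramp_frac", 0.6))
        if not 0.0 < ramp_frac <= 1.0:
            raise ValueError("ramp_frac must be in (0, 1]")
        u = np.tile(np.linspace(0.0, 1.0, spec.width), (spec.height, 1))
        return d_max * np.minimum(u / ramp_frac, 1.0)

    # smooth_random: low-frequency surface, optionally quantized into strata
    corr = float(p.get("corr_px", 96))
    field_ = gaussian_filter(rng.standard_normal((spec.height, spec.width)), sigma=corr, mode="reflect")
    lo, hi = field_.min(), field_.max()
    u = (field_ - lo) / (hi - lo) if hi > lo else np.zeros_like(field_)
    level_fracs = tuple(p.get("level_fracs", (0.0, 0.5, 1.0)))
    level_areas = tuple(p.get("level_areas", (0.25, 0.20, 0.55)))
    n_levels = int(p.get("n_levels", len(level_fracs)))
    if n_levels == 0:
        return d_max * u
    if len(level_fracs) != n_levels or len(level_areas) != n_levels:
        raise ValueError("level_fracs and level_areas must both have n_levels entries")
    if abs(sum(level_areas) - 1.0) > 1e-9 or any(a <= 0 for a in level_areas):
        raise ValueError("level_areas must be positive and sum to 1")
    # area-quantile cuts assign each stratum its requested share of pixels
    cuts = np.quantile(u, np.cumsum(level_areas)[:-1])
    depth = np.full(u.shape, level_fracs[0] * d_max)
    for frac, cut in zip(level_fracs[1:], cuts):
        depth[u > cut] = frac * d_max
    return depth


def generate_focal_stack(spec: SyntheticStackSpec) -> tuple:
    """Render a focal stack and its ground-truth in-focus masks.

    Per-pixel spatially varying blur is approximated by rendering a
    bank of ``n_blur_levels`` uniformly blurred copies of the texture
    and assigning each pixel the copy with the nearest sigma; the
    quantization step is ``sigma_max / (n_blur_levels - 1)`` px.
    Ground-truth masks use the exact (unquantized) sigma.

    Returns ``(FocalStack, [InFocusMask, ...])``.
    """
    rng = np.random.default_rng(spec.seed)
    texture = _make_texture(spec, rng)
    depth = _depth_surface(spec, rng)

    sigma_max = spec.sigma_per_um * spec.depth_range_um
    levels = np.linspace(0.0, sigma_max, spec.n_blur_levels)
    bank = np.stack(
        [texture if s == 0.0 else gaussian_filter(texture, sigma=s, mode="reflect") for s in levels]
    )
    step = levels[1] - levels[0]

    slices = np.empty((spec.n_slices, spec.height, spec.width))
    masks = []
    for z in range(spec.n_slices):
        defocus_um = np.abs(z * spec.z_step_um - depth)
        sigma = spec.sigma_per_um * defocus_um
        smin, smax = float(sigma.min()), float(sigma.max())
        if smin == smax:
            # spatially uniform blur (flat surface): render exactly
            rendered = texture if smin == 0.0 else gaussian_filter(texture, sigma=smin, mode="reflect")
        else:
            idx = np.clip(np.rint(sigma / step).astype(np.intp), 0, spec.n_blur_levels - 1)
            rendered = np.take_along_axis(bank, idx[np.newaxis], axis=0)[0]
        slices[z] = rendered + rng.normal(0.0, spec.noise_sd, rendered.shape)
        masks.append(InFocusMask(sigma <= spec.sigma_in_focus, slice_index=z, origin="synthetic_gt"))

    stack = FocalStack(
        slices,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
        source_path=f"synthetic(seed={spec.seed})",
    )
    return stack, masks
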