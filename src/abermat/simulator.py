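"""Synthetic data generation: aberration screens, phantoms, forward models
and the multi-layer tissue model with time-gated reflection.

Thin targets follow the convolution model

    E_out = P_out * [(E_in * P_in) S],

thick targets replace S by multi-slice (split-step) propagation through a
refractive-index volume, which produces the finite angular memory-effect
range of real 3D objects.  The tissue model stacks statistically calibrated
random phase screens: the screen variance fixes the ballistic attenuation
(scattering mean free path l_s) and the screen correlation length fixes the
angular diffusion (transport mean free path l_t); weak random reflection
screens provide the single-backscatter signal for reflection imaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lattice import (
    FieldStack,
    Grid2D,
    TiltGroup,
    fft2_centered,
    ifft2_centered,
    pupil_mask,
)
from .aberration import AberrationFunction
from .tomography import propagate_single

__all__ = [
    "ZernikeSpec",
    "CorrelatedRandomSpec",
    "AberrationScreen",
    "make_aberration_screen",
    "correlated_random_phase",
    "Phantom",
    "letter_target",
    "make_tilt_groups",
    "forward_thin",
    "forward_thick",
    "TissueModelConfig",
    "LayerStack",
    "generate_layer_screens",
    "bpm_propagate",
    "collect_reflections",
    "GateSpec",
    "gate_axial_response",
    "time_gated_reflection",
    "focusing_experiment",
    "brownian_bead_sequence",
]


# --------------------------------------------------------------------------
# aberration screens
# --------------------------------------------------------------------------

_ZERNIKE = {
    # name -> function of (rho, theta), normalised to the unit pupil
    "piston": lambda r, t: np.ones_like(r),
    "tip": lambda r, t: r * np.cos(t),
    "tilt": lambda r, t: r * np.sin(t),
    "defocus": lambda r, t: 2.0 * r**2 - 1.0,
    "astig_0": lambda r, t: r**2 * np.cos(2 * t),
    "astig_45": lambda r, t: r**2 * np.sin(2 * t),
    "coma_x": lambda r, t: (3.0 * r**3 - 2.0 * r) * np.cos(t),
    "coma_y": lambda r, t: (3.0 * r**3 - 2.0 * r) * np.sin(t),
    "trefoil_x": lambda r, t: r**3 * np.cos(3 * t),
    "trefoil_y": lambda r, t: r**3 * np.sin(3 * t),
    "spherical": lambda r, t: 6.0 * r**4 - 6.0 * r**2 + 1.0,
}


@dataclass
class ZernikeSpec:
    """Zernike coefficient list (radians) by aberration name."""

    coeffs: dict

    def __post_init__(self) -> None:
        unknown = set(self.coeffs) - set(_ZERNIKE)
        if unknown:
            raise ValueError(f"unknown Zernike terms: {sorted(unknown)}")


@dataclass
class CorrelatedRandomSpec:
    """Correlated Gaussian random phase: RMS (rad) and 1/e autocorrelation
    half-width (k-pixels)."""

    rms: float
    corr_length_px: float

    def __post_init__(self) -> None:
        if self.rms > 20.0:
            raise ValueError("requested RMS above 20 rad is unphysical for a pupil screen")
        if self.rms < 0 or self.corr_length_px <= 0:
            raise ValueError("rms must be >= 0 and corr_length_px > 0")


@dataclass
class AberrationScreen:
    """Ground-truth pupil phase screen with its generating spec and seed."""

    function: AberrationFunction
    spec: object
    seed: int | None

    @property
    def phase(self) -> np.ndarray:
        return self.function.phase

    @property
    def support(self) -> np.ndarray:
        return self.function.support


def correlated_random_phase(
    shape: tuple[int, int], rms: float, corr_length_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian random field with Gaussian autocorrelation of 1/e half-width
    ``corr_length_px``, normalised to the exact requested RMS."""
    noise = rng.normal(size=shape)
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    q2 = (2 * np.pi) ** 2 * (fx**2 + fy**2)  # rad^2 per pixel^2
    envelope = np.exp(-q2 * corr_length_px**2 / 8.0)
    phase = np.real(np.fft.ifft2(np.fft.fft2(noise) * envelope))
    phase -= phase.mean()
    std = phase.std()
    if std > 0 and rms > 0:
        phase *= rms / std
    else:
        phase[:] = 0.0
    return phase


def make_aberration_screen(spec, grid: Grid2D, seed: int | None = None) -> AberrationScreen:
    """Deterministic pupil phase screen from a Zernike or correlated-random spec."""
    support = pupil_mask(grid, grid.na_det)
    ky, kx = grid.k_mesh()
    if isinstance(spec, ZernikeSpec):
        rho = np.hypot(kx, ky) / grid.k_na_det
        theta = np.arctan2(ky, kx)
        phase = np.zeros(grid.shape)
        for name, c in spec.coeffs.items():
            phase += float(c) * _ZERNIKE[name](rho, theta)
    elif isinstance(spec, CorrelatedRandomSpec):
        rng = np.random.default_rng(seed)
        phase = correlated_random_phase(
            grid.shape, spec.rms, spec.corr_length_px, rng
        )
        # renormalise the RMS on the pupil support
        on = phase[support]
        if on.std() > 0 and spec.rms > 0:
            phase = phase * (spec.rms / on.std())
    else:
        raise ValueError(f"unknown screen spec {type(spec).__name__}")
    func = AberrationFunction(
        grid=grid, phase=np.where(support, phase, 0.0), support=support, side="outgoing"
    )
    return AberrationScreen(function=func, spec=spec, seed=seed)


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

@dataclass
class Phantom:
    """Target object: thin 2D transmittance, 3D RI volume, or beads.

    thin2d: ``values`` complex S(r) with |S| <= 1 on the grid.
    volume3d: ``values`` real n(z, y, x), slice pitch ``dz_slice`` (um).
    beads: ``positions`` (n, 2) um, ``radius`` um, ``delta_n``,
    ``diffusion`` um^2/s.
    """

    kind: str
    values: np.ndarray | None = None
    dz_slice: float = 0.5
    positions: np.ndarray | None = None
    radius: float = 1.0
    delta_n: float = 0.02
    diffusion: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("thin2d", "volume3d", "beads"):
            raise ValueError("phantom kind must be thin2d, volume3d or beads")
        if self.kind == "thin2d":
            self.values = np.asarray(self.values, dtype=np.complex128)
            if np.max(np.abs(self.values)) > 1.0 + 1e-9:
                raise ValueError("thin2d transmittance must satisfy |S| <= 1")
        if self.kind == "volume3d":
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 3:
                raise ValueError("volume3d values must be (z, y, x)")
            if np.min(self.values) < 1.0 - 1e-9:
                raise ValueError("volume3d refractive index must be >= 1")


def letter_target(grid: Grid2D, height_um: float = 8.0, center=(0.0, 0.0)) -> np.ndarray:
    """Binary 'A'-shaped mask drawn from three bars, for reflection targets."""
    yy, xx = grid.r_mesh()
    cy, cx = center[1], center[0]
    h = height_um
    w = 0.12 * h  # stroke width
    y = (yy - cy) / h + 0.5  # 0 at bottom, 1 at top
    x = (xx - cx) / h
    mask = np.zeros(grid.shape, dtype=bool)
    # two legs from apex (0, 1) to (-0.35, 0) / (0.35, 0)
    for sgn in (-1.0, 1.0):
        d = np.abs(x - sgn * 0.35 * (1.0 - y))
        mask |= (d < w / h) & (y >= 0) & (y <= 1)
    # crossbar at y ~ 0.35
    mask |= (np.abs(y - 0.35) < 0.6 * w / h) & (np.abs(x) < 0.35 * 0.7)
    return mask


def make_tilt_groups(
    grid: Grid2D,
    n_groups: int = 24,
    delta_k: float | None = None,
    rng: np.random.Generator | None = None,
    na_fraction: float = 0.85,
    on_grid: bool = True,
) -> list[TiltGroup]:
    """Fermat-spiral arrangement of illumination groups within the NA.

    Each group carries a central incidence plus two tilts of magnitude
    ``delta_k`` (default: one k-pixel) along x and y, mirroring the
    experimental geometry of one central and two tilted angles per group.
    """
    if delta_k is None:
        delta_k = grid.dkx
    k_max = na_fraction * grid.k_na_ill
    golden = np.pi * (3.0 - np.sqrt(5.0))
    groups = []
    for i in range(n_groups):
        r = k_max * np.sqrt((i + 0.5) / n_groups)
        th = i * golden
        kc = np.array([r * np.cos(th), r * np.sin(th)])
        if on_grid:
            kc = np.array(
                [np.round(kc[0] / grid.dkx) * grid.dkx, np.round(kc[1] / grid.dky) * grid.dky]
            )
        groups.append(
            TiltGroup(
                k_center=tuple(kc),
                tilt_offsets=((delta_k, 0.0), (0.0, delta_k)),
            )
        )
    return groups


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def _pupil_scalar(screen: AberrationFunction | None, k_in, grid: Grid2D) -> complex:
    """e^{i phi_in(k_in)} by bilinear interpolation of the unit phasor."""
    if screen is None:
        return 1.0 + 0.0j
    phasor = np.where(screen.support, np.exp(1j * screen.phase), 0.0)
    kx = grid.kx_coords()
    ky = grid.ky_coords()
    fx = (k_in[0] - kx[0]) / grid.dkx
    fy = (k_in[1] - ky[0]) / grid.dky
    ix0, iy0 = int(np.floor(fx)), int(np.floor(fy))
    wx, wy = fx - ix0, fy - iy0
    val = 0.0 + 0.0j
    for dy, wy2 in ((0, 1 - wy), (1, wy)):
        for dx, wx2 in ((0, 1 - wx), (1, wx)):
            jy = int(np.clip(iy0 + dy, 0, grid.ny - 1))
            jx = int(np.clip(ix0 + dx, 0, grid.nx - 1))
            val += wy2 * wx2 * phasor[jy, jx]
    if np.abs(val) < 1e-9:
        return 0.0 + 0.0j
    return val / np.abs(val)


def _apply_pupil_out(field: np.ndarray, screen: AberrationFunction | None, grid: Grid2D):
    """Band-limit to the detection pupil and apply the outgoing pupil phase."""
    mask = pupil_mask(grid, grid.na_det)
    if screen is None:
        pf = mask.astype(np.complex128)
    else:
        pf = np.where(screen.support & mask, np.exp(1j * screen.phase), 0.0)
    return ifft2_centered(fft2_centered(field, grid) * pf, grid)


def _add_noise(data: np.ndarray, snr: float | None, rng: np.random.Generator):
    if snr is None:
        return data
    sig = np.sqrt(np.mean(np.abs(data) ** 2))
    sigma = sig / snr / np.sqrt(2.0)
    return data + rng.normal(scale=sigma, size=data.shape) + 1j * rng.normal(
        scale=sigma, size=data.shape
    )


def forward_thin(
    groups: list[TiltGroup],
    screen_in: AberrationFunction | None,
    screen_out: AberrationFunction | None,
    phantom: Phantom,
    grid: Grid2D,
    noise_snr: float | None = None,
    seed: int | None = None,
) -> FieldStack:
    """Exact discrete thin-target model: E_out = P_out * [(E_in * P_in) S]."""
    if phantom.kind != "thin2d":
        raise ValueError("forward_thin requires a thin2d phantom")
    s_map = phantom.values
    yy, xx = grid.r_mesh()
    rng = np.random.default_rng(seed)
    n_slots = groups[0].n_slots
    data = np.empty((len(groups), n_slots, *grid.shape), dtype=np.complex128)
    for g, grp in enumerate(groups):
        for s in range(n_slots):
            k_in = grp.k_in(s)
            c_in = _pupil_scalar(screen_in, k_in, grid)
            inner = c_in * np.exp(1j * (k_in[0] * xx + k_in[1] * yy)) * s_map
            data[g, s] = _apply_pupil_out(inner, screen_out, grid)
    data = _add_noise(data, noise_snr, rng)
    return FieldStack(grid=grid, groups=list(groups), data=data)


def forward_thick(
    groups: list[TiltGroup],
    screen_in: AberrationFunction | None,
    screen_out: AberrationFunction | None,
    phantom: Phantom,
    grid: Grid2D,
    noise_snr: float | None = None,
    seed: int | None = None,
) -> FieldStack:
    """Multi-slice (split-step) thick-target model.

    The volume is centred on the focal plane z = 0; slices are modulated at
    their centres and the output is referenced back to z = 0, so a
    single-slice volume reduces exactly to the thin model.  Data generated
    this way exhibit a finite angular memory-effect range.
    """
    if phantom.kind != "volume3d":
        raise ValueError("forward_thick requires a volume3d phantom")
    vol = phantom.values
    nz = vol.shape[0]
    dz = phantom.dz_slice
    k0 = 2.0 * np.pi / grid.wavelength
    dn_max = float(np.max(np.abs(vol - grid.n_medium)))
    if dn_max > 0 and dz > grid.wavelength / (4.0 * dn_max):
        warnings.warn(
            "slice thickness exceeds lambda / (4 dn_max); split-step accuracy "
            "is degraded",
            stacklevel=2,
        )
    z_first = -(nz - 1) * dz / 2.0
    yy, xx = grid.r_mesh()
    km = grid.k_medium
    rng = np.random.default_rng(seed)
    n_slots = groups[0].n_slots
    data = np.empty((len(groups), n_slots, *grid.shape), dtype=np.complex128)
    masks = [np.exp(1j * k0 * (vol[j] - grid.n_medium) * dz) for j in range(nz)]
    for g, grp in enumerate(groups):
        for s in range(n_slots):
            k_in = grp.k_in(s)
            kz_in = np.sqrt(max(km**2 - k_in[0] ** 2 - k_in[1] ** 2, 0.0))
            c_in = _pupil_scalar(screen_in, k_in, grid)
            fld = c_in * np.exp(1j * (k_in[0] * xx + k_in[1] * yy)) * np.exp(
                1j * kz_in * z_first
            )
            for j in range(nz):
                fld = fld * masks[j]
                if j < nz - 1:
                    fld = propagate_single(fld, dz, grid)
            # reference the output back to the focal plane z = 0
            fld = propagate_single(fld, -(z_first + (nz - 1) * dz), grid)
            data[g, s] = _apply_pupil_out(fld, screen_out, grid)
    data = _add_noise(data, noise_snr, rng)
    return FieldStack(grid=grid, groups=list(groups), data=data)


# --------------------------------------------------------------------------
# multi-layer tissue model
# --------------------------------------------------------------------------

@dataclass
class TissueModelConfig:
    """Scattering parameters of the layered tissue model.

    Defaults reproduce typical biological tissue: layers every 10 um with
    scattering mean free path 53 um and transport mean free path 1.1 mm.
    ``total_reflectance`` caps the summed single-backscatter reflectance of
    the stack.  ``surface_deflection_rms``/``_corr_um`` add a smooth random
    phase to the first layer emulating refraction at the tissue boundary.
    """

    n_layers: int = 10
    dz_layer: float = 10.0
    l_s: float = 53.0
    l_t: float = 1100.0
    total_reflectance: float = 0.03
    surface_deflection_rms: float = 0.0
    surface_deflection_corr_um: float = 4.0


@dataclass
class LayerStack:
    """Per-layer complex transmission/reflection screens (at the reference
    wavelength of ``grid``)."""

    grid: Grid2D
    t_screens: np.ndarray  # (n_layers, ny, nx) complex, |t| <= 1
    r_screens: np.ndarray  # (n_layers, ny, nx) complex
    dz_layer: float
    config: TissueModelConfig
    calibration: dict = field(default_factory=dict)
    surface_deflection: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.max(np.abs(self.t_screens)) > 1.0 + 1e-9:
            raise ValueError("|t| must not exceed 1")

    @property
    def n_layers(self) -> int:
        return self.t_screens.shape[0]

    @property
    def thickness(self) -> float:
        return self.n_layers * self.dz_layer

    def t_phase(self) -> np.ndarray:
        return np.angle(self.t_screens)


def _screen_mean_k2(shape, corr_px: float) -> float:
    """Second moment <|q|^2> (rad^2/px^2) of the screen power spectrum."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    q2 = (2 * np.pi) ** 2 * (fx**2 + fy**2)
    w2 = np.exp(-q2 * corr_px**2 / 4.0)
    return float(np.sum(q2 * w2) / np.sum(w2))


def generate_layer_screens(
    config: TissueModelConfig, grid: Grid2D, seed: int | None = None
) -> LayerStack:
    """Random layer screens calibrated to (l_s, l_t) on the actual grid.

    The per-layer phase variance follows from the ballistic attenuation of
    a Gaussian phase screen, <e^{i phi}> = e^{-sigma^2/2}, giving
    sigma^2 = dz / l_s.  The correlation length is solved (bisection) so
    that the per-layer angular variance sigma^2 <|q|^2> / k_m^2, evaluated
    with the screen spectrum realised on this grid, equals the small-angle
    diffusion rate 2 dz / l_t.  Reflection screens are white complex
    Gaussian fields scaled so the summed stack reflectance meets the
    configured total.
    """
    if config.l_s <= 0 or config.l_t <= 0:
        raise ValueError("l_s and l_t must be positive")
    rng = np.random.default_rng(seed)
    sigma2 = config.dz_layer / config.l_s
    km = grid.k_medium
    target_q2 = 2.0 * config.dz_layer / config.l_t * km**2 / sigma2  # rad^2/um^2
    target_q2_px = target_q2 * grid.dx**2  # rad^2 / pixel^2

    lo, hi = 1e-3, float(min(grid.nx, grid.ny))
    q2_lo = _screen_mean_k2(grid.shape, lo)
    q2_hi = _screen_mean_k2(grid.shape, hi)
    if not (q2_hi <= target_q2_px <= q2_lo):
        raise ValueError(
            "requested (l_s, l_t) pair is unreachable on this grid: the "
            f"per-layer angular variance {target_q2_px:.3e} rad^2/px^2 must "
            f"lie within [{q2_hi:.3e}, {q2_lo:.3e}]; adjust dx, l_s or l_t"
        )
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if _screen_mean_k2(grid.shape, mid) > target_q2_px:
            lo = mid
        else:
            hi = mid
    corr_px = np.sqrt(lo * hi)

    sigma = np.sqrt(sigma2)
    t_screens = np.empty((config.n_layers, *grid.shape), dtype=np.complex128)
    for j in range(config.n_layers):
        phi = correlated_random_phase(grid.shape, sigma, corr_px, rng)
        t_screens[j] = np.exp(1j * phi)

    surface = None
    if config.surface_deflection_rms > 0:
        corr_surface_px = config.surface_deflection_corr_um / grid.dx
        surface = correlated_random_phase(
            grid.shape, config.surface_deflection_rms, corr_surface_px, rng
        )
        t_screens[0] = t_screens[0] * np.exp(1j * surface)

    # complex Gaussian reflection screens band-limited to propagating k
    # (backscatter outside |k| <= k_m would be evanescent and unobservable);
    # per-layer reflectance total/n_layers so the stack sums to the cap
    r_rms = np.sqrt(config.total_reflectance / config.n_layers)
    prop_disc = grid.k_radius() <= grid.k_medium
    disc_centered = np.fft.ifftshift(prop_disc)
    r_screens = np.empty((config.n_layers, *grid.shape), dtype=np.complex128)
    for j in range(config.n_layers):
        white = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
        filt = np.fft.ifft2(np.fft.fft2(white) * disc_centered)
        filt *= r_rms / np.sqrt(np.mean(np.abs(filt) ** 2))
        r_screens[j] = filt

    return LayerStack(
        grid=grid,
        t_screens=t_screens,
        r_screens=r_screens,
        dz_layer=config.dz_layer,
        config=config,
        calibration={
            "sigma_phi": sigma,
            "corr_length_px": float(corr_px),
            "corr_length_um": float(corr_px * grid.dx),
            "per_layer_reflectance": r_rms**2,
        },
        surface_deflection=surface,
    )


def _scaled_screens(layers: LayerStack, wavelength: float) -> np.ndarray:
    """Transmission screens at another wavelength (path-delay scaling)."""
    if abs(wavelength - layers.grid.wavelength) < 1e-12:
        return layers.t_screens
    scale = layers.grid.wavelength / wavelength
    return np.exp(1j * np.angle(layers.t_screens) * scale)


def bpm_propagate(
    field: np.ndarray,
    layers: LayerStack,
    grid: Grid2D,
    direction: str = "forward",
    return_layers: bool = True,
):
    """Split-step propagation through the layer stack.

    Layers sit at z = 0, dz, ..., (n-1) dz.  ``forward`` starts with the
    supplied field incident on layer 0 and returns the per-layer incident
    fields plus the field just after the last layer propagated one spacing
    further (z = n dz).  ``backward`` propagates the supplied field (given
    at z = n dz, travelling in -z) up through the stack, transmitting
    through each screen, and returns the field at z = 0.  Multiple
    inter-layer reflections are neglected by construction.
    """
    t = _scaled_screens(layers, grid.wavelength)
    dz = layers.dz_layer
    if direction == "forward":
        per_layer = []
        fld = field
        for j in range(layers.n_layers):
            per_layer.append(fld)
            fld = fld * t[j]
            fld = propagate_single(fld, dz, grid)
        if return_layers:
            return fld, per_layer
        return fld
    if direction == "backward":
        fld = field
        for j in range(layers.n_layers - 1, -1, -1):
            fld = propagate_single(fld, dz, grid)
            fld = fld * t[j]
        return fld
    raise ValueError("direction must be 'forward' or 'backward'")


def collect_reflections(
    incident: np.ndarray,
    layers: LayerStack,
    grid: Grid2D,
    target_reflectivity: np.ndarray | None = None,
    target_depth: float | None = None,
    include_layer_reflections: bool = True,
):
    """Single-backscatter reflection of an incident field off the stack.

    Returns ``(reflected_at_surface, forward_at_target)``: the total
    backward-travelling field referenced to z = 0 and the forward field at
    the target depth.  The backward sweep accumulates ``r_j`` times the
    forward incident field at every layer (each reflection transmits
    through the layers above it on the way out), plus the target reflection
    ``R(r) x E_fwd(z_t)`` if a target is given.
    """
    t = _scaled_screens(layers, grid.wavelength)
    dz = layers.dz_layer
    n = layers.n_layers
    z_layers = np.arange(n) * dz
    if target_depth is None:
        target_depth = n * dz

    # forward sweep, recording incidents
    fwd = incident
    incidents = []
    for j in range(n):
        incidents.append(fwd)
        fwd = fwd * t[j]
        if j < n - 1:
            fwd = propagate_single(fwd, dz, grid)
    # continue to the target depth
    fwd_target = propagate_single(fwd, target_depth - z_layers[-1], grid)

    # backward sweep from the target up
    if target_reflectivity is not None:
        back = fwd_target * target_reflectivity
    else:
        back = np.zeros(grid.shape, dtype=np.complex128)
    back = propagate_single(back, target_depth - z_layers[-1], grid)
    for j in range(n - 1, -1, -1):
        if include_layer_reflections:
            back = back + layers.r_screens[j] * incidents[j]
        back = back * t[j]
        if j > 0:
            back = propagate_single(back, dz, grid)
    return back, fwd_target


# --------------------------------------------------------------------------
# time gating
# --------------------------------------------------------------------------

@dataclass
class GateSpec:
    """Spectral gate: wavelength count and Gaussian bandwidth.

    ``sigma_lambda`` is the Gaussian standard deviation of the vacuum
    wavelength distribution (um); the default produces an axial intensity
    gate of roughly 11 um FWHM in the tissue medium.  Wavelengths sample
    +-2.5 sigma.
    """

    n_wavelengths: int = 40
    sigma_lambda: float = 0.00255
    span_sigmas: float = 2.5

    def wavelengths(self, center: float) -> np.ndarray:
        if self.n_wavelengths == 1:
            return np.array([center])
        return center + np.linspace(
            -self.span_sigmas, self.span_sigmas, self.n_wavelengths
        ) * self.sigma_lambda

    def weights(self, center: float) -> np.ndarray:
        lam = self.wavelengths(center)
        w = np.exp(-((lam - center) ** 2) / (2.0 * self.sigma_lambda**2))
        return w / w.sum()


def gate_axial_response(gate: GateSpec, grid: Grid2D, z: np.ndarray) -> np.ndarray:
    """Normalised gated intensity versus defocus of a mirror from the
    reference depth (round-trip phase 2 k_m z per wavelength)."""
    lam = gate.wavelengths(grid.wavelength)
    w = gate.weights(grid.wavelength)
    km = 2.0 * np.pi * grid.n_medium / lam
    resp = np.abs(np.sum(w[None, :] * np.exp(2j * km[None, :] * z[:, None]), axis=1)) ** 2
    return resp / resp.max()


def time_gated_reflection(
    groups: list[TiltGroup],
    layers: LayerStack,
    target_reflectivity: np.ndarray,
    target_depth: float,
    grid: Grid2D,
    gate: GateSpec | None = None,
    include_layer_reflections: bool = True,
    reference_depth: float | None = None,
) -> FieldStack:
    """Time-gated reflection-mode acquisition of a target inside the stack.

    For every illumination and wavelength the incident plane wave is
    propagated forward through the layers, reflected at the target (and at
    every layer in the single-backscatter model), propagated back to the
    surface, refocused to the target depth, and referenced to a mirror at
    the target depth; the coherent spectrally weighted sum gates out
    reflections away from the target depth.
    """
    gate = gate or GateSpec()
    if reference_depth is None:
        reference_depth = target_depth
    lam0 = grid.wavelength
    lams = gate.wavelengths(lam0)
    wts = gate.weights(lam0)
    yy, xx = grid.r_mesh()
    n_slots = groups[0].n_slots
    data = np.zeros((len(groups), n_slots, *grid.shape), dtype=np.complex128)
    for li, (lam, w) in enumerate(zip(lams, wts)):
        grid_l = grid.replace(wavelength=lam)
        km_l = grid_l.k_medium
        ref_phase = np.exp(-2j * km_l * reference_depth)
        for g, grp in enumerate(groups):
            for s in range(n_slots):
                k_in = grp.k_in(s)
                inc = np.exp(1j * (k_in[0] * xx + k_in[1] * yy))
                back, _ = collect_reflections(
                    inc,
                    layers,
                    grid_l,
                    target_reflectivity=target_reflectivity,
                    target_depth=target_depth,
                    include_layer_reflections=include_layer_reflections,
                )
                # coherence gating happens at the detector plane: weight and
                # reference each wavelength's surface field first
                data[g, s] += w * back * ref_phase
    # numerical refocusing of the gated field to the target depth is a
    # post-processing step at the centre wavelength (undo the target-to-
    # surface propagation of the backward sum)
    for g in range(len(groups)):
        for s in range(n_slots):
            data[g, s] = propagate_single(data[g, s], -target_depth, grid)
    return FieldStack(grid=grid, groups=list(groups), data=data)


# --------------------------------------------------------------------------
# focusing experiments
# --------------------------------------------------------------------------

def focusing_experiment(
    layers: LayerStack | None,
    target_depth: float,
    grid: Grid2D,
    phi_in: AberrationFunction | None = None,
    r_c=(0.0, 0.0),
):
    """Wavefront-shaped focus versus the guide-star ideal focus.

    The test beam is an aberration-corrected converging wave: the free-space
    focusing pupil (illumination NA) multiplied by e^{-i phi_in}, propagated
    through the layers to the target depth.  The ideal is phase conjugation
    of a point source at the target propagated backwards through the same
    realisation.  Both inputs are normalised to unit power; returns
    ``(focus_field, ideal_field)`` at the target plane.
    """
    mask = pupil_mask(grid, grid.na_ill)
    kz, _ = _kz_focus(grid)
    ky, kx = grid.k_mesh()
    spec = np.where(
        mask, np.exp(-1j * kz * target_depth) * np.exp(-1j * (kx * r_c[0] + ky * r_c[1])), 0.0
    )
    if phi_in is not None:
        corr = np.where(phi_in.support, np.exp(-1j * phi_in.phase), 1.0)
        spec = spec * corr
    e_in = ifft2_centered(spec, grid)

    # guide star: point source at the target propagated up through the stack
    delta = np.zeros(grid.shape, dtype=np.complex128)
    iy = grid.ny // 2 + int(round(r_c[1] / grid.dx))
    ix = grid.nx // 2 + int(round(r_c[0] / grid.dx))
    delta[iy, ix] = 1.0
    if layers is not None:
        up = propagate_single(delta, target_depth - (layers.n_layers - 1) * layers.dz_layer, grid)
        t = _scaled_screens(layers, grid.wavelength)
        for j in range(layers.n_layers - 1, -1, -1):
            up = up * t[j]
            if j > 0:
                up = propagate_single(up, layers.dz_layer, grid)
    else:
        up = propagate_single(delta, target_depth, grid)
    ideal_in = np.conj(up)
    # band-limit the conjugated wavefront to the physical illumination pupil
    ideal_in = ifft2_centered(
        np.where(mask, fft2_centered(ideal_in, grid), 0.0), grid
    )

    def _norm(f):
        p = np.sqrt(np.sum(np.abs(f) ** 2))
        return f / p if p > 0 else f

    e_in = _norm(e_in)
    ideal_in = _norm(ideal_in)

    def _to_target(f):
        if layers is None:
            return propagate_single(f, target_depth, grid)
        out, _ = bpm_propagate(f, layers, grid, direction="forward")
        extra = target_depth - layers.n_layers * layers.dz_layer
        return propagate_single(out, extra, grid)

    return _to_target(e_in), _to_target(ideal_in)


def _kz_focus(grid: Grid2D):
    k2 = grid.k_radius() ** 2
    km2 = grid.k_medium**2
    prop = k2 <= km2
    return np.sqrt(np.maximum(km2 - k2, 0.0)), prop


# --------------------------------------------------------------------------
# moving samples
# --------------------------------------------------------------------------

def brownian_bead_sequence(
    beads: Phantom,
    grid: Grid2D,
    screen_out: AberrationFunction | None,
    n_groups: int = 12,
    frame_interval_s: float = 1.0 / 60.0,
    delta_k: float | None = None,
    seed: int | None = None,
) -> tuple[FieldStack, dict]:
    """Tilt-series acquisition of beads undergoing Brownian motion.

    Frames are captured sequentially (central, +dk x, +dk y per group) with
    the bead positions taking an independent Gaussian step of per-axis
    standard deviation sqrt(2 D dt) between frames.  Beads are rendered as
    thin phase objects (projected spherical thickness).  Returns the stack
    and a motion report comparing the RMS inter-frame displacement against
    the diffraction limit lambda / (2 NA); a displacement beyond it warns
    that the method's validity bound is exceeded.
    """
    if beads.kind != "beads":
        raise ValueError("phantom kind must be 'beads'")
    rng = np.random.default_rng(seed)
    groups = make_tilt_groups(grid, n_groups=n_groups, delta_k=delta_k)
    step_sigma = np.sqrt(2.0 * beads.diffusion * frame_interval_s)
    diffraction_limit = grid.wavelength / (2.0 * grid.na_det)
    rms_step = step_sigma * np.sqrt(2.0)  # 2D displacement RMS
    if rms_step > diffraction_limit:
        warnings.warn(
            f"RMS inter-frame displacement {rms_step:.3f} um exceeds the "
            f"diffraction limit {diffraction_limit:.3f} um; aberration "
            "recovery from consecutive frames will degrade",
            stacklevel=2,
        )
    pos = np.array(beads.positions, dtype=float)
    yy, xx = grid.r_mesh()
    k0 = 2.0 * np.pi / grid.wavelength
    n_slots = groups[0].n_slots
    data = np.empty((len(groups), n_slots, *grid.shape), dtype=np.complex128)
    times = np.empty((len(groups), n_slots))
    frame = 0
    for g, grp in enumerate(groups):
        for s in range(n_slots):
            thickness = np.zeros(grid.shape)
            for p in pos:
                rho2 = (xx - p[0]) ** 2 + (yy - p[1]) ** 2
                thickness += 2.0 * np.sqrt(np.maximum(beads.radius**2 - rho2, 0.0))
            s_map = np.exp(1j * k0 * beads.delta_n * thickness)
            k_in = grp.k_in(s)
            inner = np.exp(1j * (k_in[0] * xx + k_in[1] * yy)) * s_map
            data[g, s] = _apply_pupil_out(inner, screen_out, grid)
            times[g, s] = frame * frame_interval_s
            frame += 1
            pos = pos + rng.normal(scale=step_sigma, size=pos.shape)
    stack = FieldStack(grid=grid, groups=list(groups), data=data, acquisition_times=times)
    report = {
        "rms_step_um": float(rms_step),
        "diffraction_limit_um": float(diffraction_limit),
        "within_tolerance": bool(rms_step <= diffraction_limit),
    }
    return stack, report
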