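"""Quantitative evaluation: tilt-tilt correlation, memory-effect range,
3D phase correlation and Strehl ratio.

The tilt-tilt (g1) field correlation compares the k-space field measured
with a tilted incidence, sampled on the tilt-shifted lattice, against the
untilted measurement; both averages run over the detection pupil
intersected with its shifted copy.  Its 1/e crossing defines the
memory-effect range.  The 3D phase correlation propagates two 2D fields
through a z range, restricts the unit-modulus cross-spectrum to a
one-voxel-thick Ewald shell and inverse transforms; for fields scattered by
the same object it reduces to the 3D intensity PSF of the aberration,
normalised by the ideal (empty-shell) peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lattice import FieldStack, Grid2D, fft2_centered, pupil_mask, shift_sample_kspace
from .tomography import angular_spectrum_propagate

__all__ = [
    "CorrelationCurve",
    "field_correlation",
    "memory_effect_range",
    "phase_correlation_3d",
    "phase_correlation_peak",
    "strehl_ratio",
]


@dataclass
class CorrelationCurve:
    """|C| and arg C versus tilt magnitude, in spatial-frequency units."""

    delta_u: np.ndarray  # |delta_k| / 2 pi  (1/um)
    values: np.ndarray  # complex C per point
    n_pairs: np.ndarray  # samples averaged per point

    def __post_init__(self) -> None:
        self.delta_u = np.asarray(self.delta_u, dtype=float)
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        order = np.argsort(self.delta_u)
        self.delta_u = self.delta_u[order]
        self.values = self.values[order]
        self.n_pairs = self.n_pairs[order]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def to_csv(self, path) -> None:
        arr = np.column_stack(
            [self.delta_u, np.abs(self.values), np.angle(self.values), self.n_pairs]
        )
        np.savetxt(
            path,
            arr,
            delimiter=",",
            header="delta_u,abs_C,arg_C,n_pairs",
            comments="",
        )


def field_correlation(stack: FieldStack, slots=None) -> CorrelationCurve:
    """Tilt-tilt correlation C(dk) averaged over k and groups.

    For every requested tilt slot: per group, the numerator is the k-average
    of the shifted-spectrum x conjugate-unshifted product over the pupil
    intersected with its dk-shifted copy, normalised by the two k-averaged
    powers; the per-group correlations are then averaged.  Slot 0 (the
    trivial dk = 0 pairing, C = 1 exactly) is always included as the first
    point.
    """
    grid = stack.grid
    if slots is None:
        slots = list(range(1, stack.n_slots))
    mask = pupil_mask(grid, grid.na_det)
    ky, kx = grid.k_mesh()

    du, vals, npairs = [0.0], [1.0 + 0.0j], [stack.n_groups]
    for slot in slots:
        dk = stack.tilt_offset(slot)
        # pupil intersect its shifted copy: |k| <= kNA and |k + dk| <= kNA
        m = mask & (np.hypot(kx + dk[0], ky + dk[1]) <= grid.k_na_det)
        if stack.n_groups < 2:
            warnings.warn(
                "fewer than 2 groups per tilt point: high-variance estimate",
                stacklevel=2,
            )
        acc = []
        for g in range(stack.n_groups):
            s0 = fft2_centered(stack.data[g, 0], grid)
            st = shift_sample_kspace(stack.data[g, slot], dk, grid)
            num = np.mean(st[m] * np.conj(s0[m]))
            p0 = np.mean(np.abs(s0[m]) ** 2)
            pt = np.mean(np.abs(st[m]) ** 2)
            if p0 > 0 and pt > 0:
                acc.append(num / np.sqrt(p0 * pt))
        du.append(float(np.hypot(*dk)) / (2 * np.pi))
        vals.append(complex(np.mean(acc)))
        npairs.append(len(acc))
    return CorrelationCurve(
        delta_u=np.array(du), values=np.array(vals), n_pairs=np.array(npairs)
    )


def memory_effect_range(curve: CorrelationCurve, threshold: float = np.exp(-1.0)):
    """Tilt magnitude where |C| first crosses the 1/e threshold.

    Linear interpolation between the bracketing samples, in the curve's
    delta_u units.  If the curve never drops below the threshold the upper
    sampled bound is returned with ``bounded=False``.
    """
    mag = curve.magnitude()
    du = curve.delta_u
    below = np.nonzero(mag < threshold)[0]
    if below.size == 0:
        return float(du[-1]), False
    j = int(below[0])
    if j == 0:
        return float(du[0]), True
    x0, x1 = du[j - 1], du[j]
    y0, y1 = mag[j - 1], mag[j]
    t = (threshold - y0) / (y1 - y0)
    return float(x0 + t * (x1 - x0)), True


# --------------------------------------------------------------------------
# 3D phase correlation
# --------------------------------------------------------------------------

def phase_correlation_3d(
    field_a: np.ndarray,
    field_b: np.ndarray,
    grid: Grid2D,
    z_range: tuple[float, float, int] = (-8.0, 8.0, 32),
) -> np.ndarray:
    """Squared-modulus 3D phase correlation of two band-limited 2D fields.

    Both fields are propagated through the z range by the angular spectrum
    method, the unit-modulus cross-spectrum is restricted to the pupil-
    truncated Ewald shell (one z-voxel thick) and inverse transformed; the
    result is normalised by the ideal peak of the same shell filled with
    unit phase, so identical aberration-free fields give a peak of exactly 1
    at the origin.
    """
    if field_a.shape != grid.shape or field_b.shape != grid.shape:
        raise ValueError("fields must match the grid")
    z0, z1, nz = z_range
    z = np.linspace(z0, z1, int(nz), endpoint=False)
    dz = z[1] - z[0]
    if (z1 - z0) < 2.0 * grid.wavelength / grid.n_medium:
        warnings.warn("z range may be too small to localise the peak", stacklevel=2)
    ea = angular_spectrum_propagate(field_a, z, grid, warn_evanescent=False)
    eb = angular_spectrum_propagate(field_b, z, grid, warn_evanescent=False)
    fa = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(ea)))
    fb = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(eb)))
    cross = fa * np.conj(fb)

    km = grid.k_medium
    dkz = 2.0 * np.pi / (int(nz) * dz)
    kz1 = (np.arange(int(nz)) - int(nz) // 2) * dkz
    ky, kx = grid.k_mesh()
    k3 = np.sqrt(kx[None] ** 2 + ky[None] ** 2 + kz1[:, None, None] ** 2)
    # one-voxel-thick shell, truncated to the detection pupil and kz > 0
    shell = (
        (np.abs(k3 - km) < dkz / 2.0)
        & (np.hypot(kx, ky)[None] <= grid.k_na_det)
        & (kz1[:, None, None] > 0)
    )
    phase = np.where(shell & (np.abs(cross) > 0), np.exp(1j * np.angle(cross)), 0.0)
    ideal = shell.astype(np.complex128)
    corr = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(phase)))
    ref = np.fft.ifftn(np.fft.ifftshift(ideal))  # value at r=0 is [0,0,0]
    peak_ideal = np.abs(ref[0, 0, 0])
    if peak_ideal == 0:
        raise ValueError("empty Ewald shell on this lattice; increase nz or z range")
    return np.abs(corr / peak_ideal) ** 2


def _shell_phase(field_a, field_b, grid, z_range):
    """Ewald-shell coordinates and unit cross-spectrum phasors (helper)."""
    z0, z1, nz = z_range
    z = np.linspace(z0, z1, int(nz), endpoint=False)
    dz = z[1] - z[0]
    ea = angular_spectrum_propagate(field_a, z, grid, warn_evanescent=False)
    eb = angular_spectrum_propagate(field_b, z, grid, warn_evanescent=False)
    fa = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(ea)))
    fb = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(eb)))
    cross = fa * np.conj(fb)
    km = grid.k_medium
    dkz = 2.0 * np.pi / (int(nz) * dz)
    kz1 = (np.arange(int(nz)) - int(nz) // 2) * dkz
    ky, kx = grid.k_mesh()
    k3 = np.sqrt(kx[None] ** 2 + ky[None] ** 2 + kz1[:, None, None] ** 2)
    shell = (
        (np.abs(k3 - km) < dkz / 2.0)
        & (np.hypot(kx, ky)[None] <= grid.k_na_det)
        & (kz1[:, None, None] > 0)
    )
    sel = shell & (np.abs(cross) > 0)
    iz, iy, ix = np.nonzero(sel)
    phasors = np.exp(1j * np.angle(cross[sel]))
    coords = np.stack([kx[iy, ix], ky[iy, ix], kz1[iz]], axis=1)
    return coords, phasors, int(shell.sum()), dkz


def phase_correlation_peak(
    field_a: np.ndarray,
    field_b: np.ndarray,
    grid: Grid2D,
    z_range: tuple[float, float, int] = (-8.0, 8.0, 32),
    refine: int = 6,
) -> float:
    """Sub-voxel peak of the 3D phase correlation.

    The correlation peak generally falls between lattice sites (any residual
    tip/tilt between the fields is a lateral shift of the peak), so the
    voxel map systematically understates it.  The peak is refined by direct
    evaluation of the shell sum on a fine local r-grid around the coarse
    maximum.
    """
    coords, phasors, n_shell, dkz = _shell_phase(field_a, field_b, grid, z_range)
    if n_shell == 0:
        raise ValueError("empty Ewald shell on this lattice")
    coarse = phase_correlation_3d(field_a, field_b, grid, z_range=z_range)
    nz = coarse.shape[0]
    pk = np.unravel_index(np.argmax(coarse), coarse.shape)
    dz_r = 2.0 * np.pi / (nz * dkz) / nz  # one z voxel in r-space... use pitch
    # r-space pitches of the correlation lattice
    dy = grid.dx
    dx = grid.dx
    z0, z1, nzz = z_range
    dzv = (z1 - z0) / int(nzz)
    r0 = np.array([
        (pk[2] - grid.nx // 2) * dx,
        (pk[1] - grid.ny // 2) * dy,
        (pk[0] - int(nzz) // 2) * dzv,
    ])
    def value(r):
        return float(np.abs(np.sum(phasors * np.exp(1j * (coords @ r)))) / n_shell)

    # two-stage local search: half-voxel then fine steps around the best
    best_r = r0
    best = value(r0)
    for step in (0.5, 0.5 / refine):
        offs = np.array([-2, -1, 0, 1, 2]) * step
        centre = best_r.copy()
        for oz in offs * dzv:
            for oy in offs * dy:
                for ox in offs * dx:
                    r = centre + np.array([ox, oy, oz])
                    v = value(r)
                    if v > best:
                        best, best_r = v, r
    return best**2


def strehl_ratio(focus_field: np.ndarray, ideal_field: np.ndarray) -> float:
    """Peak focus intensity relative to the ideal (guide-star) focus."""
    if focus_field.shape != ideal_field.shape:
        raise ValueError("fields must share the grid")
    peak_ideal = float(np.max(np.abs(ideal_field) ** 2))
    if peak_ideal == 0:
        raise ValueError("ideal field is zero")
    return float(np.max(np.abs(focus_field) ** 2)) / peak_ideal
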