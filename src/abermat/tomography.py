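"""Gradient-based Rytov tomography and angular-spectrum propagation.

The scattering potential follows the convention

    V(r) = k0^2 (n(r)^2 - n_medium^2),      k0 = 2 pi / lambda  (vacuum),

recorded in the tomogram metadata.  The inversion uses the gradient form of
the Rytov field: instead of unwrapping arg(E/E_in) globally, the per-pixel
finite differences of the log-modulus and the *wrapped* finite differences
of the phase are mapped onto the Ewald-sphere cap of the spectrum of
grad V, which stays single-valued even across phase vortices.  The DC
gradient component is irrecoverable by construction; the global offset of V
is set so that the background refractive index equals the medium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

from .lattice import FieldStack, Grid2D, fft2_centered, ifft2_centered
from .aberration import wrap_phase

__all__ = [
    "Tomogram",
    "angular_spectrum_propagate",
    "rytov_gradient_data",
    "reconstruct_tomogram",
    "save_tomogram",
]


@dataclass
class Tomogram:
    """Real 3D refractive-index volume, axes ordered (z, y, x)."""

    values: np.ndarray
    voxel_pitch: tuple[float, float, float]  # (dz, dy, dx) um
    n_medium: float
    z_offset: float = 0.0  # focal-plane offset of the first z slice (um)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tomogram must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tomogram contains non-finite values")

    @property
    def z_coords(self) -> np.ndarray:
        nz = self.values.shape[0]
        return self.z_offset + (np.arange(nz) - nz // 2) * self.voxel_pitch[0]

    def copy(self) -> "Tomogram":
        return Tomogram(
            values=self.values.copy(),
            voxel_pitch=self.voxel_pitch,
            n_medium=self.n_medium,
            z_offset=self.z_offset,
            meta=dict(self.meta),
        )


# --------------------------------------------------------------------------
# angular spectrum propagation
# --------------------------------------------------------------------------

def _kz_map(grid: Grid2D) -> tuple[np.ndarray, np.ndarray]:
    """(kz, propagating-mask) on the centred k-grid; evanescent kz set to 0."""
    k2 = grid.k_radius() ** 2
    km2 = grid.k_medium**2
    prop = k2 <= km2
    kz = np.sqrt(np.maximum(km2 - k2, 0.0))
    return kz, prop


def angular_spectrum_propagate(
    field2d: np.ndarray, z_planes, grid: Grid2D, warn_evanescent: bool = True
) -> np.ndarray:
    """Propagate a monochromatic field to one or many z planes.

    Returns ``E(z, y, x)`` with ``E(r, z) = IFT[E~(k) e^{i kz(k) z}]`` and
    ``kz = sqrt(k_medium^2 - |k|^2)``; evanescent components are zeroed.
    """
    z_planes = np.atleast_1d(np.asarray(z_planes, dtype=float))
    spec = fft2_centered(field2d, grid)
    kz, prop = _kz_map(grid)
    if warn_evanescent:
        power = np.abs(spec) ** 2
        tot = power.sum()
        if tot > 0 and power[~prop].sum() > 1e-9 * tot:
            warnings.warn(
                "field carries evanescent components beyond k_medium; they "
                "are zeroed before propagation",
                stacklevel=2,
            )
    spec = np.where(prop, spec, 0.0)
    out = np.empty((z_planes.size, *grid.shape), dtype=np.complex128)
    for i, z in enumerate(z_planes):
        out[i] = ifft2_centered(spec * np.exp(1j * kz * z), grid)
    return out


def propagate_single(field2d: np.ndarray, z: float, grid: Grid2D) -> np.ndarray:
    """One-plane convenience wrapper around the angular spectrum kernel."""
    return angular_spectrum_propagate(field2d, [z], grid, warn_evanescent=False)[0]


# --------------------------------------------------------------------------
# Rytov gradient data
# --------------------------------------------------------------------------

def rytov_gradient_data(
    field2d: np.ndarray,
    k_in,
    grid: Grid2D,
    amplitude_floor: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient of the complex Rytov phase, without unwrapping.

    For the normalised field ratio q = E / E_in (E_in the unit plane wave
    e^{i k_in . r} at the focal plane) returns the pair ``(data_x, data_y)``

        data = diff(log|q|) + i wrap(diff(arg q))

    using forward finite differences with periodic wrap-around (consistent
    with the FFT lattice).  An amplitude floor of ``amplitude_floor *
    max|E|`` guards the logarithm at near-zeros.
    """
    k_in = np.asarray(k_in, dtype=float)
    yy, xx = grid.r_mesh()
    e_in = np.exp(1j * (k_in[0] * xx + k_in[1] * yy))
    q = field2d * np.conj(e_in)  # |E_in| = 1
    floor = amplitude_floor * np.max(np.abs(field2d))
    amp = np.maximum(np.abs(q), floor)
    n_floored = int(np.count_nonzero(np.abs(q) < floor))
    if n_floored > 0.2 * q.size:
        warnings.warn(
            "amplitude floor engaged on more than 20% of the pixels; the "
            "Rytov weak-scattering assumption is questionable",
            stacklevel=2,
        )
    log_amp = np.log(amp)
    phase = np.angle(q)

    def diff(arr, axis):
        return np.roll(arr, -1, axis=axis) - arr

    data_x = diff(log_amp, 1) + 1j * wrap_phase(diff(phase, 1))
    data_y = diff(log_amp, 0) + 1j * wrap_phase(diff(phase, 0))
    return data_x, data_y


# --------------------------------------------------------------------------
# reconstruction
# --------------------------------------------------------------------------

def reconstruct_tomogram(
    stack: FieldStack,
    nz: int = 64,
    dz: float | None = None,
    amplitude_floor: float = 1e-3,
    use_gradient: bool = True,
    psi_override=None,
) -> Tomogram:
    """Rytov reconstruction from corrected angle-resolved fields.

    For each illumination the complex Rytov phase spectrum is recovered
    from the gradient data (dividing by the exact finite-difference spectral
    symbol where defined; the DC component is dropped), mapped onto the
    Ewald-sphere cap

        V~(k - k_in, kz(k) - kz_in) = -2 i kz(k) psi~(k - k_in)

    and accumulated with hit-count averaging.  ``psi_override`` lets a
    caller supply precomputed complex Rytov phases (one 2D array per group),
    used by the unwrap-based cross-check path.
    """
    grid = stack.grid
    if dz is None:
        dz = grid.dx
    ny, nx = grid.shape
    km = grid.k_medium
    kz2d, prop = _kz_map(grid)
    det_mask = (grid.k_radius() <= grid.k_na_det) & prop

    dkz = 2.0 * np.pi / (nz * dz)
    v_spec = np.zeros((nz, ny, nx), dtype=np.complex128)
    hits = np.zeros((nz, ny, nx), dtype=np.int64)

    kx1 = grid.kx_coords()
    ky1 = grid.ky_coords()

    any_coverage = False
    for g in range(stack.n_groups):
        k_in = stack.groups[g].k_in(0)
        kz_in = np.sqrt(max(km**2 - k_in[0] ** 2 - k_in[1] ** 2, 0.0))
        if psi_override is not None:
            psi = psi_override[g]
            psi_spec = fft2_centered(psi, grid)
        else:
            data_x, data_y = rytov_gradient_data(
                stack.data[g, 0], k_in, grid, amplitude_floor=amplitude_floor
            )
            # spectral symbols of the periodic forward difference
            sym_x = np.exp(1j * kx1[None, :] * grid.dx) - 1.0
            sym_y = np.exp(1j * ky1[:, None] * grid.dx) - 1.0
            fx = fft2_centered(data_x, grid)
            fy = fft2_centered(data_y, grid)
            denom = np.abs(sym_x) ** 2 + np.abs(sym_y) ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                psi_spec = (np.conj(sym_x) * fx + np.conj(sym_y) * fy) / denom
            psi_spec[denom < 1e-20] = 0.0  # DC of the Rytov phase is lost

        # Ewald mapping: q = k - k_in on the same 2D lattice (k_in is not
        # necessarily on-grid; the cap is indexed by the measured k)
        # detection wavevector k = q + k_in
        qx = kx1[None, :]
        qy = ky1[:, None]
        k_abs2 = (qx + k_in[0]) ** 2 + (qy + k_in[1]) ** 2
        ok = (k_abs2 <= grid.k_na_det**2) & (k_abs2 < km**2)
        if not np.any(ok):
            continue
        any_coverage = True
        kz_det = np.sqrt(np.maximum(km**2 - k_abs2, 0.0))
        qz = kz_det - kz_in
        iz = np.round(qz / dkz).astype(int) + nz // 2
        ok &= (iz >= 0) & (iz < nz)
        vals = -2j * kz_det * psi_spec
        iy_idx, ix_idx = np.nonzero(ok)
        np.add.at(v_spec, (iz[ok], iy_idx, ix_idx), vals[ok])
        np.add.at(hits, (iz[ok], iy_idx, ix_idx), 1)

    if not any_coverage:
        raise ValueError("empty spectral coverage: no illumination maps into the pupil")

    nonzero = hits > 0
    v_spec[nonzero] /= hits[nonzero]

    # inverse 3D transform with the same continuous convention per axis
    v_r = np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(v_spec))
    ) * (nx * ny * nz) * (grid.dkx * grid.dky * dkz) / (2.0 * np.pi) ** 3
    v_r = np.real(v_r)

    k0 = 2.0 * np.pi / grid.wavelength
    n2 = grid.n_medium**2 + v_r / k0**2
    n_vol = np.sqrt(np.maximum(n2, 0.0))
    # the lost DC sets an arbitrary offset: pin the background at n_medium
    n_vol = n_vol - np.median(n_vol) + grid.n_medium
    return Tomogram(
        values=n_vol,
        voxel_pitch=(dz, grid.dx, grid.dx),
        n_medium=grid.n_medium,
        meta={
            "potential_convention": "V = k0^2 (n^2 - n_medium^2)",
            "inversion": "gradient-rytov" if psi_override is None else "psi-override",
        },
    )


def save_tomogram(path_h5, tomo: Tomogram, path_tiff=None) -> None:
    """Write a tomogram to HDF5 (and optionally a 32-bit float TIFF stack)."""
    with h5py.File(path_h5, "w") as f:
        d = f.create_dataset("tomogram", data=tomo.values.astype(np.float32))
        d.attrs["voxel_pitch"] = tomo.voxel_pitch
        d.attrs["n_medium"] = tomo.n_medium
        d.attrs["z_offset"] = tomo.z_offset
        for k, v in tomo.meta.items():
            d.attrs[k] = v
    if path_tiff is not None:
        tifffile.imwrite(path_tiff, tomo.values.astype(np.float32))
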