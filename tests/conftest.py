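"""Shared fixtures: small grids and synthetic angle-resolved acquisitions."""

import numpy as np
import pytest

from abermat.lattice import (
    FieldStack,
    Grid2D,
    TiltGroup,
    fft2_centered,
    ifft2_centered,
    pupil_mask,
)


@pytest.fixture
def grid64():
    return Grid2D(nx=64, ny=64, dx=0.2, wavelength=0.532,
                  n_medium=1.336, na_det=1.15, na_ill=1.0)


@pytest.fixture
def grid96():
    return Grid2D(nx=96, ny=96, dx=0.2, wavelength=0.532,
                  n_medium=1.336, na_det=1.15, na_ill=0.9)


def smooth_pupil_phase(grid, which="out"):
    """Low-order pupil phase (defocus + coma + astigmatism), ~2 rad RMS."""
    ky, kx = grid.k_mesh()
    kn = grid.k_na_det
    r2 = (kx**2 + ky**2) / kn**2
    if which == "out":
        phase = 2.0 * (2 * r2 - 1) + 1.2 * (3 * r2 - 2) * kx / kn + 2.4 * (kx**2 - ky**2) / kn**2
    else:
        phase = 1.4 * (2 * r2 - 1) - 0.8 * (3 * r2 - 2) * ky / kn + 1.5 * kx * ky / kn**2
    return np.where(pupil_mask(grid, grid.na_det), phase, 0.0)


def make_thin_stack(grid, phi_out=None, phi_in=None, n_groups=30, seed=1,
                    delta_k_px=1.0, target=None):
    """Memory-effect-perfect thin-target acquisition with known screens.

    Every group carries a central incidence and two tilts (x and y) of
    ``delta_k_px`` k-pixels.  Spectra are built exactly from the thin-target
    factorisation, so the tilt-pair identity holds to machine precision for
    integer-pixel incidences.
    """
    rng = np.random.default_rng(seed)
    mask = pupil_mask(grid, grid.na_det)
    p_out = np.where(mask, np.exp(1j * (phi_out if phi_out is not None else 0.0)), 0)
    yy, xx = grid.r_mesh()
    if target is None:
        target = np.exp(1j * rng.uniform(-2, 2, grid.shape)) * (
            1 + 0.5 * np.cos(xx) * np.sin(yy)
        )
    dk1 = np.array([delta_k_px * grid.dkx, 0.0])
    dk2 = np.array([0.0, delta_k_px * grid.dky])
    pts = []
    step = max(2, grid.nx // 16)
    for i in range(-grid.nx // 3, grid.nx // 3 + 1, step):
        for j in range(-grid.ny // 3, grid.ny // 3 + 1, step):
            k = np.array([i * grid.dkx, j * grid.dky])
            if np.hypot(*k) < 0.8 * grid.k_na_ill:
                pts.append(k)
    pts = pts[:n_groups]
    groups = [
        TiltGroup(k_center=tuple(k), tilt_offsets=(tuple(dk1), tuple(dk2)))
        for k in pts
    ]

    def phi_in_at(k):
        if phi_in is None:
            return 1.0
        ix = int(round(k[0] / grid.dkx)) + grid.nx // 2
        iy = int(round(k[1] / grid.dky)) + grid.ny // 2
        return np.exp(1j * phi_in[iy, ix])

    data = np.empty((len(groups), 3, *grid.shape), dtype=np.complex128)
    for g, grp in enumerate(groups):
        for s in range(3):
            k_in = grp.k_in(s)
            pw = np.exp(1j * (k_in[0] * xx + k_in[1] * yy))
            spec = fft2_centered(target * pw * phi_in_at(k_in), grid)
            data[g, s] = ifft2_centered(spec * p_out, grid)
    return FieldStack(grid=grid, groups=groups, data=data), target
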