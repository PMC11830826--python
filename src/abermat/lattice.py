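"""Coordinate systems, Fourier conventions, pupil geometry and field containers.

All physical lengths are micrometres and wave vectors are rad/um.  The
forward two-dimensional transform follows the convention

    f~(k) = integral f(r) exp(-i k . r) dr

discretised with the continuous normalisation (a factor ``dx**2`` on the
forward transform).  k-space arrays are *centred*: on an even-sized axis of
length ``n`` the zero frequency sits at index ``n // 2``.

A parallel "spatial frequency" accessor ``u = k / (2 pi)`` is provided on
:class:`Grid2D` because tilt magnitudes are often quoted in inverse
wavelengths.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
import yaml

__all__ = [
    "Grid2D",
    "TiltGroup",
    "FieldStack",
    "PupilField",
    "fft2_centered",
    "ifft2_centered",
    "shift_sample_kspace",
    "pupil_mask",
    "save_fieldstack",
    "load_fieldstack",
    "import_tiff_stack",
]


# --------------------------------------------------------------------------
# grids
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid2D:
    """Sample-plane lattice and the optical parameters tied to it.

    Parameters
    ----------
    nx, ny:
        Pixel counts along x (last array axis) and y (second-to-last).
    dx:
        Pixel pitch in the sample plane (um).
    wavelength:
        Vacuum wavelength (um).
    n_medium:
        Refractive index of the immersion / background medium.
    na_det, na_ill:
        Detection and illumination numerical apertures.
    """

    nx: int
    ny: int
    dx: float
    wavelength: float
    n_medium: float = 1.336
    na_det: float = 1.15
    na_ill: float = 1.1

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8 pixels")
        if self.na_ill > self.na_det + 1e-12:
            raise ValueError("na_ill must not exceed na_det")
        if self.k_na_det > np.pi / self.dx + 1e-9:
            raise ValueError(
                "detection pupil exceeds the Nyquist rate: "
                f"k_NA={self.k_na_det:.3f} > pi/dx={np.pi / self.dx:.3f}"
            )

    # -- k-space geometry --------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def dkx(self) -> float:
        """k-space pitch along x (rad/um)."""
        return 2.0 * np.pi / (self.nx * self.dx)

    @property
    def dky(self) -> float:
        return 2.0 * np.pi / (self.ny * self.dx)

    @property
    def k_na_det(self) -> float:
        """Detection pupil radius 2 pi NA / lambda (rad/um)."""
        return 2.0 * np.pi * self.na_det / self.wavelength

    @property
    def k_na_ill(self) -> float:
        return 2.0 * np.pi * self.na_ill / self.wavelength

    @property
    def k_medium(self) -> float:
        """Wavenumber in the medium, 2 pi n / lambda (rad/um)."""
        return 2.0 * np.pi * self.n_medium / self.wavelength

    def x_coords(self) -> np.ndarray:
        return (np.arange(self.nx) - self.nx // 2) * self.dx

    def y_coords(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.dx

    def r_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(Y, X) real-space mesh in um."""
        return np.meshgrid(self.y_coords(), self.x_coords(), indexing="ij")

    def kx_coords(self) -> np.ndarray:
        return (np.arange(self.nx) - self.nx // 2) * self.dkx

    def ky_coords(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.dky

    def k_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(KY, KX) centred k-space mesh in rad/um."""
        return np.meshgrid(self.ky_coords(), self.kx_coords(), indexing="ij")

    def u_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatial-frequency mesh u = k / (2 pi), in 1/um."""
        ky, kx = self.k_mesh()
        return ky / (2 * np.pi), kx / (2 * np.pi)

    def k_radius(self) -> np.ndarray:
        ky, kx = self.k_mesh()
        return np.hypot(kx, ky)

    def replace(self, **kwargs) -> "Grid2D":
        return dataclasses.replace(self, **kwargs)


# --------------------------------------------------------------------------
# centred transforms
# --------------------------------------------------------------------------

def fft2_centered(fld: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Forward transform with e^{-ik.r} sign and continuous normalisation.

    Operates on the trailing two axes, which must match ``grid.shape``.
    """
    if fld.shape[-2:] != grid.shape:
        raise ValueError(f"field shape {fld.shape[-2:]} != grid shape {grid.shape}")
    out = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(fld, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    )
    return out * grid.dx**2


def ifft2_centered(spec: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Inverse of :func:`fft2_centered`."""
    if spec.shape[-2:] != grid.shape:
        raise ValueError(f"spectrum shape {spec.shape[-2:]} != grid shape {grid.shape}")
    out = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(spec, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    )
    return out / grid.dx**2


def shift_sample_kspace(fld: np.ndarray, delta_k, grid: Grid2D) -> np.ndarray:
    """Sample the spectrum of ``fld`` on the lattice shifted by ``delta_k``.

    Returns f~(k + delta_k) evaluated on the centred k-grid, exact for any
    sub-pixel shift: the real-space field is multiplied by e^{-i delta_k . r}
    before the forward transform (a k-space translation by the modulation
    theorem), never by integer rolling.
    """
    delta_k = np.asarray(delta_k, dtype=float)
    if np.hypot(*delta_k) >= grid.k_na_det:
        warnings.warn(
            "delta_k exceeds the detection pupil radius; the shifted samples "
            "fall outside the support where the correlation is undefined",
            stacklevel=2,
        )
    if delta_k[0] == 0.0 and delta_k[1] == 0.0:
        return fft2_centered(fld, grid)
    yy, xx = grid.r_mesh()
    ramp = np.exp(-1j * (delta_k[0] * xx + delta_k[1] * yy))
    return fft2_centered(fld * ramp, grid)


def pupil_mask(grid: Grid2D, na: float) -> np.ndarray:
    """Boolean k-space mask of the disc |k| <= 2 pi na / lambda."""
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    if na > grid.n_medium + 1e-9:
        raise ValueError("na cannot exceed the medium index for propagating waves")
    k_na = 2.0 * np.pi * na / grid.wavelength
    return grid.k_radius() <= k_na + 1e-12


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TiltGroup:
    """One illumination group: a central incidence plus tilted companions.

    ``k_center`` is the 2D incident wave vector (rad/um); ``tilt_offsets``
    holds one 2D shift per extra measurement slot.
    """

    k_center: tuple[float, float]
    tilt_offsets: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_center", tuple(float(v) for v in self.k_center))
        object.__setattr__(
            self,
            "tilt_offsets",
            tuple(tuple(float(v) for v in off) for off in self.tilt_offsets),
        )

    @property
    def n_slots(self) -> int:
        return 1 + len(self.tilt_offsets)

    def k_in(self, slot: int) -> np.ndarray:
        """Incident wave vector of a measurement slot (slot 0 is central)."""
        k = np.asarray(self.k_center, dtype=float)
        if slot == 0:
            return k
        return k + np.asarray(self.tilt_offsets[slot - 1], dtype=float)

    def validate(self, grid: Grid2D) -> None:
        for s in range(self.n_slots):
            if np.hypot(*self.k_in(s)) > grid.k_na_ill + 1e-9:
                raise ValueError(
                    f"incidence of slot {s} falls outside the illumination NA"
                )


@dataclass
class FieldStack:
    """Angle-resolved complex fields organised in tilt groups.

    ``data`` has shape ``(n_groups, n_slots, ny, nx)``; slot 0 carries the
    central incidence of each group.  ``acquisition_times`` (seconds, shape
    ``(n_groups, n_slots)``) is optional and only used by moving-sample
    bookkeeping.
    """

    grid: Grid2D
    groups: list[TiltGroup]
    data: np.ndarray
    acquisition_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.data.ndim != 4:
            raise ValueError("data must be (group, slot, y, x)")
        if self.data.shape[2:] != self.grid.shape:
            raise ValueError("field shape does not match grid")
        if self.data.shape[0] != len(self.groups):
            raise ValueError("group count mismatch")
        for g, grp in enumerate(self.groups):
            if grp.n_slots != self.data.shape[1]:
                raise ValueError(
                    f"group {g} declares {grp.n_slots} slots, data has "
                    f"{self.data.shape[1]}"
                )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("fields contain non-finite values")

    @property
    def n_groups(self) -> int:
        return self.data.shape[0]

    @property
    def n_slots(self) -> int:
        return self.data.shape[1]

    def k_in_table(self) -> np.ndarray:
        """Incident wave vectors, shape (n_groups, n_slots, 2)."""
        tab = np.empty((self.n_groups, self.n_slots, 2))
        for g, grp in enumerate(self.groups):
            for s in range(self.n_slots):
                tab[g, s] = grp.k_in(s)
        return tab

    def tilt_offset(self, slot: int) -> np.ndarray:
        """Common tilt offset of a slot, checked homogeneous across groups."""
        if slot < 1 or slot >= self.n_slots:
            raise IndexError(f"tilt slot {slot} out of range 1..{self.n_slots - 1}")
        offs = np.array([grp.tilt_offsets[slot - 1] for grp in self.groups])
        if np.max(np.abs(offs - offs[0])) > 1e-6:
            raise ValueError(f"tilt slot {slot} has heterogeneous offsets across groups")
        return offs[0]

    def copy(self) -> "FieldStack":
        return FieldStack(
            grid=self.grid,
            groups=list(self.groups),
            data=self.data.copy(),
            acquisition_times=None
            if self.acquisition_times is None
            else np.array(self.acquisition_times),
        )


@dataclass
class PupilField:
    """Complex samples on the centred k-grid, confined to a pupil support."""

    grid: Grid2D
    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.support = np.asarray(self.support, dtype=bool)
        if self.values.shape != self.grid.shape or self.support.shape != self.grid.shape:
            raise ValueError("pupil arrays must match the grid shape")
        det = pupil_mask(self.grid, self.grid.na_det)
        if np.any(self.support & ~det):
            raise ValueError("support extends beyond the detection pupil")
        self.values = np.where(self.support, self.values, 0.0)


# --------------------------------------------------------------------------
# HDF5 / TIFF I/O
# --------------------------------------------------------------------------

_GRID_ATTRS = ("nx", "ny", "dx", "wavelength", "n_medium", "na_det", "na_ill")


def save_fieldstack(path, stack: FieldStack) -> None:
    """Write a stack to the HDF5 container (bit-exact for complex128)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("fields")
        grp.create_dataset("data", data=stack.data)
        grp.create_dataset("k_in", data=stack.k_in_table())
        g = f.create_group("grid")
        for name in _GRID_ATTRS:
            g.attrs[name] = getattr(stack.grid, name)
        if stack.acquisition_times is not None:
            f.create_dataset("times", data=np.asarray(stack.acquisition_times))


def load_fieldstack(path) -> FieldStack:
    with h5py.File(path, "r") as f:
        data = f["fields/data"][()]
        k_in = f["fields/k_in"][()]
        attrs = {name: f["grid"].attrs[name] for name in _GRID_ATTRS}
        times = f["times"][()] if "times" in f else None
    grid = Grid2D(
        nx=int(attrs["nx"]),
        ny=int(attrs["ny"]),
        dx=float(attrs["dx"]),
        wavelength=float(attrs["wavelength"]),
        n_medium=float(attrs["n_medium"]),
        na_det=float(attrs["na_det"]),
        na_ill=float(attrs["na_ill"]),
    )
    groups = [
        TiltGroup(
            k_center=tuple(k_in[g, 0]),
            tilt_offsets=tuple(tuple(k_in[g, s] - k_in[g, 0]) for s in range(1, k_in.shape[1])),
        )
        for g in range(k_in.shape[0])
    ]
    return FieldStack(grid=grid, groups=groups, data=data, acquisition_times=times)


def import_tiff_stack(real_path, imag_path, sidecar_path) -> FieldStack:
    """Import paired real/imag multi-page TIFFs plus a YAML sidecar.

    The sidecar must define ``grid`` (the :class:`Grid2D` fields), a
    ``k_in`` table of shape (n_groups, n_slots, 2) and optionally ``shape``
    ``[n_groups, n_slots]`` describing how the flat page sequence folds into
    (group, slot) order.
    """
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    grid = Grid2D(**meta["grid"])
    k_in = np.asarray(meta["k_in"], dtype=float)
    re = tifffile.imread(real_path)
    im = tifffile.imread(imag_path)
    if re.shape != im.shape:
        raise ValueError("real and imaginary stacks disagree in shape")
    n_groups, n_slots = k_in.shape[:2]
    data = (re.astype(np.float64) + 1j * im.astype(np.float64)).reshape(
        n_groups, n_slots, *re.shape[-2:]
    )
    groups = [
        TiltGroup(
            k_center=tuple(k_in[g, 0]),
            tilt_offsets=tuple(tuple(k_in[g, s] - k_in[g, 0]) for s in range(1, n_slots)),
        )
        for g in range(n_groups)
    ]
    return FieldStack(grid=grid, groups=groups, data=data)
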