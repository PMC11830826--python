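"""Windowing for spatially varying aberrations, per-patch detection, stitching.

An aberrating medium is only described by a single pupil phase within an
isoplanatic patch.  Outgoing waves are windowed by direct multiplication in
the sample plane; incoming plane waves cannot be windowed directly because
the illumination is sampled sparsely in angle, so a window is synthesised
by superposing measurements taken on a small scan grid of extra incident
angles around each nominal incidence (a discrete Fourier synthesis of the
window), with coefficient moduli 4/2/1 on the rings |k| = 0, dk_scan,
sqrt(2) dk_scan and phases chosen so all terms agree at the patch centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .lattice import FieldStack, Grid2D, TiltGroup
from .aberration import AberrationFunction, DetectorConfig, detect_aberration
from .tomography import Tomogram

__all__ = [
    "WindowSpec",
    "ScannedFieldStack",
    "IncomingWindowSynthesis",
    "window_outgoing",
    "window_incoming",
    "detect_per_patch",
    "stitch_tomograms",
    "correlation_length",
]


# --------------------------------------------------------------------------
# window specification
# --------------------------------------------------------------------------

@dataclass
class WindowSpec:
    """Real-space window: an isotropic Gaussian or a supplied array.

    ``sigma`` and ``center`` are sample-plane micrometres.
    """

    kind: str = "gaussian"  # "gaussian" | "array"
    sigma: float = 5.0
    center: tuple[float, float] = (0.0, 0.0)
    array: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "array"):
            raise ValueError("window kind must be 'gaussian' or 'array'")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("window sigma must be positive")

    def evaluate(self, grid: Grid2D) -> np.ndarray:
        if self.kind == "array":
            arr = np.asarray(self.array, dtype=float)
            if arr.shape != grid.shape:
                raise ValueError("supplied window array does not match the grid")
            return arr
        x_half = grid.nx * grid.dx / 2.0
        y_half = grid.ny * grid.dx / 2.0
        cx, cy = self.center
        if not (-x_half <= cx <= x_half and -y_half <= cy <= y_half):
            raise ValueError("window centre lies outside the field of view")
        yy, xx = grid.r_mesh()
        return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * self.sigma**2))

    def shifted(self, center) -> "WindowSpec":
        return WindowSpec(kind=self.kind, sigma=self.sigma, center=tuple(center), array=self.array)


def window_outgoing(stack: FieldStack, window: WindowSpec) -> FieldStack:
    """Multiply every field by the real-space window (outgoing-side patch select)."""
    w = window.evaluate(stack.grid)
    out = stack.copy()
    out.data = out.data * w[None, None, :, :]
    return out


# --------------------------------------------------------------------------
# incoming-side window synthesis from scanned incidences
# --------------------------------------------------------------------------

@dataclass
class IncomingWindowSynthesis:
    """3x3 scan grid with the 4/2/1 ring moduli of the synthesised window."""

    dk_scan: float

    def scan_offsets(self) -> np.ndarray:
        """(9, 2) k-offsets of the scan grid, centre first."""
        pts = [(0, 0)]
        pts += [(1, 0), (-1, 0), (0, 1), (0, -1)]
        pts += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
        return np.array(pts, dtype=float) * self.dk_scan

    def moduli(self) -> np.ndarray:
        """Coefficient moduli per offset: 4 (centre), 2 (edge ring), 1 (corner)."""
        return np.array([4.0, 2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0])


@dataclass
class ScannedFieldStack:
    """Angle-resolved fields measured on a scan grid around every incidence.

    ``data`` has shape (n_groups, n_slots, n_scan, ny, nx); scan index 0 is
    the nominal (unshifted) incidence, matching
    :meth:`IncomingWindowSynthesis.scan_offsets`.
    """

    grid: Grid2D
    groups: list[TiltGroup]
    synthesis: IncomingWindowSynthesis
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 5:
            raise ValueError("data must be (group, slot, scan, y, x)")
        n_scan = self.synthesis.scan_offsets().shape[0]
        if self.data.shape[2] != n_scan:
            missing = [
                (g, s)
                for g in range(self.data.shape[0])
                for s in range(n_scan)
                if s >= self.data.shape[2]
            ]
            raise ValueError(f"missing scan offsets for (group, offset) pairs: {missing}")
        if self.data.shape[3:] != self.grid.shape:
            raise ValueError("field shape does not match grid")

    @property
    def n_groups(self) -> int:
        return self.data.shape[0]

    @property
    def n_slots(self) -> int:
        return self.data.shape[1]


def window_incoming(
    scanned: ScannedFieldStack,
    r_c,
    w_out: WindowSpec | None = None,
) -> FieldStack:
    """Synthesise incoming-windowed fields centred at ``r_c``.

    Per (group, slot): coefficient phases are set so every scan term shares
    the phase of the unshifted term at the patch centre, then the 4/2/1
    weighted superposition is formed.  If ``w_out`` is given the outgoing
    window (recentred at r_c) is applied as well.
    """
    grid = scanned.grid
    r_c = np.asarray(r_c, dtype=float)
    ix = int(np.argmin(np.abs(grid.x_coords() - r_c[0])))
    iy = int(np.argmin(np.abs(grid.y_coords() - r_c[1])))
    w = scanned.synthesis.moduli()
    out_data = np.empty(
        (scanned.n_groups, scanned.n_slots, *grid.shape), dtype=np.complex128
    )
    for g in range(scanned.n_groups):
        for s in range(scanned.n_slots):
            fields = scanned.data[g, s]  # (n_scan, ny, nx)
            ref = fields[0, iy, ix]
            centre_vals = fields[:, iy, ix]
            # phase matching at the patch centre (Fourier-coefficient phases)
            with np.errstate(invalid="ignore", divide="ignore"):
                phases = np.where(
                    np.abs(centre_vals) > 0,
                    np.exp(1j * (np.angle(ref) - np.angle(centre_vals))),
                    1.0,
                )
            coeffs = w * phases
            out_data[g, s] = np.tensordot(coeffs, fields, axes=1) / w.sum()
    stack = FieldStack(grid=grid, groups=list(scanned.groups), data=out_data)
    if w_out is not None:
        stack = window_outgoing(stack, w_out.shifted(r_c))
    return stack


# --------------------------------------------------------------------------
# per-patch detection
# --------------------------------------------------------------------------

def detect_per_patch(
    scanned: ScannedFieldStack,
    patch_centers,
    window: WindowSpec,
    detector_config: DetectorConfig | None = None,
):
    """Run the detection pipeline on every patch of a layout.

    Returns ``(aberrations, relative_phases, failures)``: per-patch outgoing
    :class:`AberrationFunction` (or None on failure), phases relative to the
    central patch of the list, and the recorded failure reasons.
    """
    centers = [np.asarray(c, dtype=float) for c in patch_centers]
    aberrations: list[AberrationFunction | None] = []
    failures: dict[int, str] = {}
    for i, r_c in enumerate(centers):
        try:
            stack = window_incoming(scanned, r_c, w_out=window)
            phi, _ = detect_aberration(stack, detector_config)
            aberrations.append(phi)
        except Exception as exc:  # per-patch failures are recorded, not fatal
            failures[i] = str(exc)
            aberrations.append(None)
    # relative maps vs the central patch
    i_mid = len(centers) // 2
    rel = []
    ref = aberrations[i_mid]
    for ab in aberrations:
        if ab is None or ref is None:
            rel.append(None)
        else:
            rel.append(np.where(ab.support & ref.support, ab.phase - ref.phase, 0.0))
    return aberrations, rel, failures


# --------------------------------------------------------------------------
# tomogram stitching
# --------------------------------------------------------------------------

def stitch_tomograms(
    patch_tomograms: list[Tomogram],
    patch_centers,
    patch_pitch: tuple[float, float],
    background_sigma: float = 0.25,
    gauge_patch: int | None = None,
) -> Tomogram:
    """Blend per-patch tomograms after solving their constant RI offsets.

    All patches share the same voxel lattice (full-FOV reconstructions each
    corrected with its own PSF).  The per-patch constant offsets produced by
    the global phase ambiguity are solved by least squares over pairwise
    overlap means on the patch-adjacency graph (gauge fixed at the central
    patch), the patches are blended with cosine-tapered weights around the
    patch midlines, and the slowly varying background is removed with a
    Gaussian high-pass of width ``background_sigma`` (1/um, default 1/4).
    """
    n = len(patch_tomograms)
    if n == 0:
        raise ValueError("no patches to stitch")
    shape = patch_tomograms[0].values.shape
    pitch = patch_tomograms[0].voxel_pitch
    for t in patch_tomograms:
        if t.values.shape != shape or t.voxel_pitch != pitch:
            raise ValueError("patch tomograms must share the voxel lattice")
    centers = [np.asarray(c, dtype=float) for c in patch_centers]
    if gauge_patch is None:
        gauge_patch = n // 2

    nz, ny, nx = shape
    dz, dy, dx = pitch
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    yy, xx = np.meshgrid(y, x, indexing="ij")

    # cosine-tapered membership weight per patch (soft crop at midlines)
    px, py = patch_pitch

    def weight(c):
        wx = np.clip(1.0 - np.abs(xx - c[0]) / px, 0.0, 1.0)
        wy = np.clip(1.0 - np.abs(yy - c[1]) / py, 0.0, 1.0)
        return (0.5 - 0.5 * np.cos(np.pi * wx)) * (0.5 - 0.5 * np.cos(np.pi * wy))

    weights = np.stack([weight(c) for c in centers])  # (n, ny, nx)

    if n > 1:
        # pairwise offsets from overlap means -> sparse least squares
        rows, cols, vals, rhs = [], [], [], []
        eq = 0
        adjacency = 0
        for i in range(n):
            for j in range(i + 1, n):
                ov = (weights[i] > 1e-3) & (weights[j] > 1e-3)
                if ov.sum() < 4:
                    continue
                adjacency += 1
                mi = patch_tomograms[i].values[:, ov].mean()
                mj = patch_tomograms[j].values[:, ov].mean()
                rows += [eq, eq]
                cols += [i, j]
                vals += [1.0, -1.0]
                rhs.append(mi - mj)
                eq += 1
        if adjacency == 0:
            raise ValueError("patch graph is disconnected: no overlapping pairs")
        # gauge: offset of the central patch = 0
        rows.append(eq)
        cols.append(gauge_patch)
        vals.append(1.0)
        rhs.append(0.0)
        A = sp.csr_matrix((vals, (rows, cols)), shape=(eq + 1, n))
        sol = spla.lsqr(A, np.asarray(rhs), atol=1e-14, btol=1e-14)[0]
        offsets = sol
        # verify connectivity: every patch must be reachable (finite solve)
        if not np.all(np.isfinite(offsets)):
            raise ValueError("patch graph is disconnected")
    else:
        offsets = np.zeros(1)

    num = np.zeros(shape)
    den = np.zeros((ny, nx))
    for i, t in enumerate(patch_tomograms):
        num += (t.values - offsets[i]) * weights[i][None, :, :]
        den += weights[i]
    den = np.maximum(den, 1e-12)
    stitched = num / den[None, :, :]

    if background_sigma and n > 1:
        # Gaussian high-pass: subtract a low-pass of width sigma (1/um)
        low = np.empty_like(stitched)
        for z in range(nz):
            spec = np.fft.fftshift(np.fft.fft2(stitched[z]))
            uy = (np.arange(ny) - ny // 2)[:, None] / (ny * dy)
            ux = (np.arange(nx) - nx // 2)[None, :] / (nx * dx)
            gauss = np.exp(-(ux**2 + uy**2) / (2.0 * background_sigma**2))
            low[z] = np.real(np.fft.ifft2(np.fft.ifftshift(spec * gauss)))
        stitched = stitched - low + patch_tomograms[0].n_medium

    return Tomogram(
        values=stitched,
        voxel_pitch=pitch,
        n_medium=patch_tomograms[0].n_medium,
        meta={"stitched_patches": n, "offsets": offsets.tolist()},
    )


# --------------------------------------------------------------------------
# isoplanatic-patch theory
# --------------------------------------------------------------------------

def correlation_length(l_t: float, L: float, wavelength_in_medium: float) -> float:
    """Isoplanatic correlation length l_c = (lambda / sqrt 2) sqrt(l_t / L).

    ``l_t`` is the transport mean free path and ``L`` the medium thickness
    (both um); valid in the anisotropic regime L << l_t (warns otherwise).
    """
    if l_t <= 0 or L <= 0 or wavelength_in_medium <= 0:
        raise ValueError("l_t, L and wavelength must be positive")
    if L > l_t:
        warnings.warn(
            "L > l_t: outside the anisotropic-scattering regime where the "
            "correlation-length estimate is valid",
            stacklevel=2,
        )
    return wavelength_in_medium / np.sqrt(2.0) * np.sqrt(l_t / L)
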