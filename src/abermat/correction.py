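"""Applying detected aberrations to field stacks.

Correction is phase-only: the detected aberration functions are phases of
unit-modulus pupil transfer functions, so deconvolution reduces to
multiplying each field spectrum by e^{-i phi_out(k)} (outgoing side) and
each group by the scalar e^{-i phi_in(k_in)} (incoming side; under plane
wave illumination the incoming aberration only contributes a constant
phase offset per incidence, which matters for tomographic synthesis but
not for viewing a single field).

For media whose isoplanatic patch is smaller than the aberrated PSF, a
single windowed detection is unreliable; the iterative windowed loop
alternates (i) detecting from windowed fields, (ii) correcting the original
fields with the accumulated phase, (iii) re-windowing, which sharpens the
field inside the window and shrinks the effective PSF each round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lattice import FieldStack, fft2_centered, ifft2_centered
from .aberration import (
    AberrationFunction,
    DetectorConfig,
    detect_aberration,
    wrap_phase,
)
from .patchwise import WindowSpec, window_outgoing

__all__ = [
    "CorrectionRecord",
    "correct_outgoing",
    "correct_incoming",
    "iterative_windowed_correction",
]


@dataclass
class CorrectionRecord:
    """Bookkeeping of an iterative correction run."""

    phi_out: AberrationFunction
    n_outer_iterations: int
    residual_history: list  # final UQP objective per outer iteration
    update_rms: list = field(default_factory=list)
    failed: bool = False


def correct_outgoing(stack: FieldStack, phi_out: AberrationFunction) -> FieldStack:
    """Phase-only deconvolution of the outgoing pupil aberration.

    Every field spectrum is multiplied by e^{-i phi_out} on the support
    (unity elsewhere), which conserves the spectral energy exactly.
    """
    if phi_out.grid.shape != stack.grid.shape:
        raise ValueError("aberration support does not match the stack grid")
    corr = np.where(phi_out.support, np.exp(-1j * phi_out.phase), 1.0)
    out = stack.copy()
    spec = fft2_centered(out.data, stack.grid)
    out.data = ifft2_centered(spec * corr, stack.grid)
    return out


def correct_incoming(stack: FieldStack, phi_in: AberrationFunction) -> FieldStack:
    """Cancel the per-incidence constant phase offsets e^{i phi_in(k_in)}.

    phi_in is sampled at each group's central incidence by bilinear
    interpolation of the unit phasor e^{i phi_in}; incidences outside the
    support fall back to the nearest supported pixel with a warning.
    """
    grid = stack.grid
    phasor = np.where(phi_in.support, np.exp(1j * phi_in.phase), 0.0)
    kx = grid.kx_coords()
    ky = grid.ky_coords()
    out = stack.copy()
    warned = False
    for g, grp in enumerate(stack.groups):
        for s in range(stack.n_slots):
            k_in = grp.k_in(s)
            fx = (k_in[0] - kx[0]) / grid.dkx
            fy = (k_in[1] - ky[0]) / grid.dky
            ix0, iy0 = int(np.floor(fx)), int(np.floor(fy))
            wx, wy = fx - ix0, fy - iy0
            val = 0.0 + 0.0j
            for dy2, wy2 in ((0, 1 - wy), (1, wy)):
                for dx2, wx2 in ((0, 1 - wx), (1, wx)):
                    jy = np.clip(iy0 + dy2, 0, grid.ny - 1)
                    jx = np.clip(ix0 + dx2, 0, grid.nx - 1)
                    val += wy2 * wx2 * phasor[jy, jx]
            if np.abs(val) < 1e-6:
                if not warned:
                    warnings.warn(
                        "incidence outside the phi_in support; using the "
                        "nearest supported sample",
                        stacklevel=2,
                    )
                    warned = True
                kyg, kxg = grid.k_mesh()
                d = np.where(
                    phi_in.support,
                    np.hypot(kxg - k_in[0], kyg - k_in[1]),
                    np.inf,
                )
                jy, jx = np.unravel_index(np.argmin(d), d.shape)
                val = phasor[jy, jx]
            out.data[g, s] = out.data[g, s] * np.exp(-1j * np.angle(val))
    return out


def iterative_windowed_correction(
    stack: FieldStack,
    window: WindowSpec,
    n_iter: int = 3,
    detector_config: DetectorConfig | None = None,
    rms_stop: float = 0.01,
    gain: float = 1.0,
    window_schedule: list[float] | None = None,
) -> tuple[FieldStack, CorrectionRecord]:
    """Window -> detect -> correct the *original* stack, repeated.

    The accumulated outgoing phase is returned; the loop stops early when
    the per-iteration pupil-phase update RMS falls below ``rms_stop`` (rad).
    ``gain`` under-relaxes each update (useful when the per-pass estimate is
    noisy); ``window_schedule`` optionally overrides the window width per
    iteration (coarse-to-fine), keeping the window centre.  A factorization
    failure mid-loop returns the last good state flagged.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    detector_config = detector_config or DetectorConfig()
    grid = stack.grid
    phi_acc = None
    corrected = stack
    history: list[float] = []
    update_rms: list[float] = []
    failed = False
    n_done = 0
    for it in range(n_iter):
        win = window
        if window_schedule is not None:
            win = WindowSpec(
                kind=window.kind,
                sigma=window_schedule[min(it, len(window_schedule) - 1)],
                center=window.center,
                array=window.array,
            )
        try:
            windowed = window_outgoing(corrected, win)
            phi_step, info = detect_aberration(windowed, detector_config)
        except Exception as exc:
            warnings.warn(
                f"factorization failed at outer iteration {it}: {exc}; "
                "returning the last good state",
                stacklevel=2,
            )
            failed = True
            break
        n_done = it + 1
        history.append(float(np.nansum(info["objective"])))
        rms = float(
            np.sqrt(np.mean(wrap_phase(phi_step.phase[phi_step.support]) ** 2))
        )
        update_rms.append(rms)
        step = gain * phi_step.phase
        if phi_acc is None:
            phi_acc = AberrationFunction(
                grid=grid,
                phase=np.where(phi_step.support, step, 0.0),
                support=phi_step.support,
                side="outgoing",
                gauge=phi_step.gauge,
            )
        else:
            support = phi_acc.support | phi_step.support
            phi_acc = AberrationFunction(
                grid=grid,
                phase=np.where(support, phi_acc.phase + step, 0.0),
                support=support,
                side="outgoing",
                gauge=phi_acc.gauge,
            )
        corrected = correct_outgoing(stack, phi_acc)
        if rms < rms_stop:
            break
    if phi_acc is None:
        # nothing succeeded: identity correction
        phi_acc = AberrationFunction(
            grid=grid,
            phase=np.zeros(grid.shape),
            support=np.ones(grid.shape, dtype=bool),
            side="outgoing",
        )
        corrected = stack.copy()
        failed = True
    record = CorrectionRecord(
        phi_out=phi_acc,
        n_outer_iterations=n_done,
        residual_history=history,
        update_rms=update_rms,
        failed=failed,
    )
    return corrected, record
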