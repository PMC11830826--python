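"""Matrix-based adaptive-optics baseline (CLASS / distortion-matrix method).

The reference method assumes a *thin* target: the angle-resolved spectrum
factorizes as E~(k_out; k_in) = P~_out(k_out) S~(k_out - k_in) P~_in(k_in),
so summing e^{-i phi_out} E~ e^{-i phi_in} over all (k_out, k_in) pairs
sharing K = k_out - k_in and maximising the resulting 2D-image intensity

    L(phi_out, phi_in) = sum_K | sum_{k_out-k_in=K} e^{-i phi_out} E~ e^{-i phi_in} |^2

recovers both pupil phases by alternating unimodular (projection power)
updates.  The triangle inequality bounds L by the incoherent sum of moduli,
with equality at the true phases.  For volumetric targets the factorisation
premise fails and the method can raise L without improving the field - the
behaviour this implementation is used to demonstrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lattice import FieldStack, Grid2D, fft2_centered, pupil_mask
from .aberration import AberrationFunction

__all__ = [
    "DistortionMatrixView",
    "class_objective",
    "class_iterate",
    "synthesize_2d_image",
]


@dataclass
class DistortionMatrixView:
    """K-indexed (distortion-matrix) view of an angle-resolved stack.

    ``rolled`` holds, per group, the 2D spectrum re-indexed by
    K = k_out - k_in (an integer-pixel roll of the centred spectrum; the
    central incidences are snapped to the k-lattice, with the maximum
    rounding error recorded).
    """

    grid: Grid2D
    rolled: np.ndarray  # (n_groups, ny, nx), index K
    kin_pixels: np.ndarray  # (n_groups, 2) integer (ix, iy) offsets from centre
    max_rounding_error: float

    @property
    def n_groups(self) -> int:
        return self.rolled.shape[0]


def _build_view(stack: FieldStack) -> DistortionMatrixView:
    grid = stack.grid
    rolled = np.empty((stack.n_groups, *grid.shape), dtype=np.complex128)
    kin_px = np.empty((stack.n_groups, 2), dtype=int)
    max_err = 0.0
    for g, grp in enumerate(stack.groups):
        kc = np.asarray(grp.k_center)
        ix = int(round(kc[0] / grid.dkx))
        iy = int(round(kc[1] / grid.dky))
        err = np.hypot(kc[0] - ix * grid.dkx, kc[1] - iy * grid.dky)
        max_err = max(max_err, float(err))
        spec = fft2_centered(stack.data[g, 0], grid)
        # spectrum indexed by K = k_out - k_in: shift k_in to the origin
        rolled[g] = np.roll(spec, (-iy, -ix), axis=(0, 1))
        kin_px[g] = (ix, iy)
    return DistortionMatrixView(
        grid=grid, rolled=rolled, kin_pixels=kin_px, max_rounding_error=max_err
    )


def _phase_maps(stack: FieldStack, phi_out, phi_in):
    """Resolve pupil-phase inputs (AberrationFunction | array | None)."""
    grid = stack.grid

    def as_map(p):
        if p is None:
            return np.zeros(grid.shape)
        if isinstance(p, AberrationFunction):
            return np.where(p.support, p.phase, 0.0)
        return np.asarray(p, dtype=float)

    return as_map(phi_out), as_map(phi_in)


def _phi_in_per_group(view: DistortionMatrixView, phi_in_map: np.ndarray) -> np.ndarray:
    ny, nx = view.grid.shape
    vals = np.empty(view.n_groups)
    for g, (ix, iy) in enumerate(view.kin_pixels):
        vals[g] = phi_in_map[ny // 2 + iy, nx // 2 + ix]
    return vals


def _coherent_sum(view: DistortionMatrixView, phi_out_map, phi_in_groups) -> np.ndarray:
    """S~(K) = sum_g e^{-i phi_out(K + k_in_g)} E~_g(K + k_in_g) e^{-i phi_in_g}."""
    acc = np.zeros(view.grid.shape, dtype=np.complex128)
    corr_out = np.exp(-1j * phi_out_map)
    for g, (ix, iy) in enumerate(view.kin_pixels):
        corr = np.roll(corr_out, (-iy, -ix), axis=(0, 1))
        acc += view.rolled[g] * corr * np.exp(-1j * phi_in_groups[g])
    return acc


def class_objective(stack: FieldStack, phi_out=None, phi_in=None) -> float:
    """Image-intensity objective L of the thin-target model.

    By Parseval, L equals (up to the transform normalisation) the intensity
    of the synthesized 2D image; for a single group it is phase-independent.
    """
    view = _build_view(stack)
    phi_out_map, phi_in_map = _phase_maps(stack, phi_out, phi_in)
    s = _coherent_sum(view, phi_out_map, _phi_in_per_group(view, phi_in_map))
    return float(np.sum(np.abs(s) ** 2))


def class_upper_bound(stack: FieldStack) -> float:
    """Triangle-inequality bound: sum_K (sum |E~|)^2 >= L for any phases."""
    view = _build_view(stack)
    return float(np.sum(np.sum(np.abs(view.rolled), axis=0) ** 2))


def synthesize_2d_image(stack: FieldStack, phi_out=None, phi_in=None) -> np.ndarray:
    """Coherently synthesized 2D image S(r) at the given correction phases."""
    view = _build_view(stack)
    phi_out_map, phi_in_map = _phase_maps(stack, phi_out, phi_in)
    s = _coherent_sum(view, phi_out_map, _phi_in_per_group(view, phi_in_map))
    grid = stack.grid
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(s))) / grid.dx**2
    return img


def class_iterate(
    stack: FieldStack,
    n_iter: int = 50,
    tol: float = 1e-9,
    inner_iter: int = 10,
):
    """Alternating unimodular maximisation of the image-intensity objective.

    Starting from flat phases, phi_in and phi_out are updated in turn by
    projection power iterations on their respective quadratic forms; the
    objective trace is non-decreasing (asserted) and iteration stops when
    its relative change falls below ``tol``.

    Returns ``(phi_out, phi_in, trace)`` with the phases as
    :class:`AberrationFunction` (phi_in sampled on the pupil at the group
    incidences, zero elsewhere).
    """
    view = _build_view(stack)
    grid = stack.grid
    det_mask = pupil_mask(grid, grid.na_det)
    phi_out_map = np.zeros(grid.shape)
    phi_in_g = np.zeros(view.n_groups)
    trace = [class_objective_from(view, phi_out_map, phi_in_g)]

    for _ in range(n_iter):
        # --- phi_in update: power iteration on the group-by-group form
        v = np.exp(-1j * phi_in_g)
        D = np.empty_like(view.rolled)
        corr_out = np.exp(-1j * phi_out_map)
        for g, (ix, iy) in enumerate(view.kin_pixels):
            D[g] = view.rolled[g] * np.roll(corr_out, (-iy, -ix), axis=(0, 1))
        Dm = D.reshape(view.n_groups, -1)
        M = Dm @ Dm.conj().T  # (n_groups, n_groups), Hermitian PSD
        for _ in range(inner_iter):
            Mv = M @ np.conj(v)
            v_new = np.where(np.abs(Mv) > 0, np.exp(-1j * np.angle(Mv)), v)
            if np.max(np.abs(v_new - v)) < 1e-12:
                v = v_new
                break
            v = v_new
        phi_in_g = -np.angle(v)  # v converges to e^{-i phi_in}
        obj = class_objective_from(view, phi_out_map, phi_in_g)
        _assert_monotone(trace, obj)
        trace.append(obj)

        # --- phi_out update: u(k_out) <- e^{i arg(sum_K D_out s*)}
        s = _coherent_sum(view, phi_out_map, phi_in_g)
        for _ in range(inner_iter):
            grad = np.zeros(grid.shape, dtype=np.complex128)
            for g, (ix, iy) in enumerate(view.kin_pixels):
                # D_out(k_out; K): unroll the K-indexed arrays back to k_out
                d_out = np.roll(
                    view.rolled[g] * np.exp(-1j * phi_in_g[g]), (iy, ix), axis=(0, 1)
                )
                grad += d_out * np.conj(np.roll(s, (iy, ix), axis=(0, 1)))
            new_phase = np.where(det_mask & (np.abs(grad) > 0), np.angle(grad), 0.0)
            if np.max(np.abs(new_phase - phi_out_map)) < 1e-12:
                phi_out_map = new_phase
                break
            phi_out_map = new_phase
            s = _coherent_sum(view, phi_out_map, phi_in_g)
        obj = class_objective_from(view, phi_out_map, phi_in_g)
        _assert_monotone(trace, obj)
        trace.append(obj)
        if len(trace) > 2 and abs(trace[-1] - trace[-3]) <= tol * max(abs(trace[-3]), 1e-30):
            break

    # package the phases; pin the gauge at the pupil centre
    cy, cx = grid.ny // 2, grid.nx // 2
    phi_out_map = np.where(det_mask, phi_out_map - phi_out_map[cy, cx], 0.0)
    phi_out = AberrationFunction(
        grid=grid, phase=phi_out_map, support=det_mask, side="outgoing"
    )
    phi_in_map = np.zeros(grid.shape)
    in_supp = np.zeros(grid.shape, dtype=bool)
    for g, (ix, iy) in enumerate(view.kin_pixels):
        phi_in_map[cy + iy, cx + ix] = phi_in_g[g]
        in_supp[cy + iy, cx + ix] = True
    phi_in = AberrationFunction(
        grid=grid, phase=phi_in_map, support=in_supp, side="incoming"
    )
    return phi_out, phi_in, np.asarray(trace)


def class_objective_from(view: DistortionMatrixView, phi_out_map, phi_in_groups) -> float:
    s = _coherent_sum(view, phi_out_map, phi_in_groups)
    return float(np.sum(np.abs(s) ** 2))


def _assert_monotone(trace, obj) -> None:
    if obj < trace[-1] * (1.0 - 1e-9) - 1e-12:
        raise AssertionError(
            "alternating maximisation decreased the objective "
            f"({trace[-1]:.6e} -> {obj:.6e}); numerical failure"
        )
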