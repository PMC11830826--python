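"""Aberration-matrix construction, factorization and pupil-phase recovery.

The tilt-tilt (angular memory-effect) correlation of angle-resolved fields
makes the conjugate product of a tilted and an untilted k-space measurement
separable: its argument is the sum of an outgoing phase difference indexed
by the detection pixel and an incoming phase difference indexed by the
illumination group,

    arg A(k_out; k_in) = [phi_out(k_out + dk) - phi_out(k_out)]
                       + [phi_in(k_in + dk) - phi_in(k_in)].

Factorizing the matrix therefore yields directional finite differences of
the two pupil aberration functions; two linearly independent tilt
directions give the full gradient, which is integrated over the (generally
non-rectangular) pupil support by masked least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .lattice import (
    FieldStack,
    Grid2D,
    fft2_centered,
    ifft2_centered,
    pupil_mask,
    shift_sample_kspace,
)

__all__ = [
    "AberrationMatrix",
    "PhaseDifferenceField",
    "AberrationFunction",
    "DetectorConfig",
    "detect_aberration",
    "build_aberration_matrix",
    "threshold_reweight",
    "mask_offdiagonal",
    "factorize_svd",
    "factorize_projection_power",
    "integrate_gradients",
    "retrieve_psf",
    "time_reversed_incoming",
    "wrap_phase",
    "circular_correlation",
    "align_piston_tilt",
]


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap values into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2.0 * np.pi)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class AberrationMatrix:
    """Complex matrix over (detection-pupil pixel, illumination group).

    ``entries`` has shape ``(n_rows, n_groups)`` where rows enumerate the
    ``True`` pixels of ``row_mask`` in C order.  ``weight_state`` tracks
    whether the raw moduli (the target's angular spectrum squared) are still
    present or have been replaced by unit moduli after thresholding.
    """

    grid: Grid2D
    delta_k: np.ndarray
    entries: np.ndarray
    row_mask: np.ndarray
    kin_table: np.ndarray  # (n_groups, 2) central incidences
    weight_state: str = "raw"

    def __post_init__(self) -> None:
        self.delta_k = np.asarray(self.delta_k, dtype=float)
        self.row_mask = np.asarray(self.row_mask, dtype=bool)
        self.kin_table = np.asarray(self.kin_table, dtype=float)
        if self.entries.shape != (int(self.row_mask.sum()), self.kin_table.shape[0]):
            raise ValueError("entries shape inconsistent with row mask / groups")
        if self.weight_state not in ("raw", "thresholded"):
            raise ValueError("weight_state must be 'raw' or 'thresholded'")

    @property
    def n_groups(self) -> int:
        return self.entries.shape[1]

    def row_k_coords(self) -> np.ndarray:
        """(n_rows, 2) array of (kx, ky) for each pupil row."""
        ky, kx = self.grid.k_mesh()
        return np.stack([kx[self.row_mask], ky[self.row_mask]], axis=1)

    def to_grid(self, column: np.ndarray) -> np.ndarray:
        """Scatter a row-indexed vector back onto the 2D k-grid."""
        out = np.zeros(self.grid.shape, dtype=column.dtype)
        out[self.row_mask] = column
        return out

    def copy(self) -> "AberrationMatrix":
        return AberrationMatrix(
            grid=self.grid,
            delta_k=self.delta_k.copy(),
            entries=self.entries.copy(),
            row_mask=self.row_mask.copy(),
            kin_table=self.kin_table.copy(),
            weight_state=self.weight_state,
        )


@dataclass
class PhaseDifferenceField:
    """Directional phase difference phi(k + dk) - phi(k), wrapped to (-pi, pi].

    For the outgoing side ``values`` lives densely on the detection-pupil
    ``support``; for the incoming side it is scattered from the sparse group
    incidences (the exact samples are kept in ``samples``).
    """

    grid: Grid2D
    direction: np.ndarray
    side: str  # "incoming" | "outgoing"
    values: np.ndarray
    support: np.ndarray
    samples: tuple[np.ndarray, np.ndarray] | None = None  # (k_points, values)
    weights: np.ndarray | None = None  # per-pixel reliability in [0, 1]

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        self.values = np.where(self.support, wrap_phase(self.values), 0.0)
        if self.weights is not None:
            self.weights = np.where(self.support, np.clip(self.weights, 0.0, 1.0), 0.0)
        if self.side not in ("incoming", "outgoing"):
            raise ValueError("side must be 'incoming' or 'outgoing'")


@dataclass
class AberrationFunction:
    """Pupil aberration phase phi(k) on a support, with its gauge record."""

    grid: Grid2D
    phase: np.ndarray
    support: np.ndarray
    side: str
    gauge: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool)
        self.phase = np.where(self.support, self.phase, 0.0)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("aberration phase contains non-finite values")

    def pupil_function(self) -> np.ndarray:
        """Unit-modulus pupil transfer function e^{i phi} on the support."""
        return np.where(self.support, np.exp(1j * self.phase), 0.0)


# --------------------------------------------------------------------------
# matrix construction and reweighting
# --------------------------------------------------------------------------

def build_aberration_matrix(stack: FieldStack, tilt_slot: int) -> AberrationMatrix:
    """Column-per-group conjugate product of tilted and untilted spectra.

    For every group the column is the spectrum of the tilted-incidence field
    sampled on the lattice shifted by the (possibly sub-pixel) tilt, times
    the conjugate of the untilted spectrum, restricted to the detection
    pupil.
    """
    delta_k = stack.tilt_offset(tilt_slot)  # raises on heterogeneity / bad slot
    grid = stack.grid
    mask = pupil_mask(grid, grid.na_det)
    n_rows = int(mask.sum())
    entries = np.empty((n_rows, stack.n_groups), dtype=np.complex128)
    for g in range(stack.n_groups):
        spec0 = fft2_centered(stack.data[g, 0], grid)
        spec_t = shift_sample_kspace(stack.data[g, tilt_slot], delta_k, grid)
        entries[:, g] = (spec_t * np.conj(spec0))[mask]
    kin = np.array([grp.k_center for grp in stack.groups])
    return AberrationMatrix(
        grid=grid,
        delta_k=delta_k,
        entries=entries,
        row_mask=mask,
        kin_table=kin,
        weight_state="raw",
    )


def _keep_mask(entries: np.ndarray, threshold) -> np.ndarray:
    """Survivor mask for a numeric or quantile ('q:0.6' / {'q': 0.6}) spec.

    A quantile spec keeps exactly ``ceil((1 - q) * n_nonzero)`` entries of
    largest modulus (top-k selection, robust to ties)."""
    if isinstance(threshold, str):
        if not threshold.startswith("q:"):
            raise ValueError(f"unrecognized threshold spec {threshold!r}")
        threshold = {"q": float(threshold[2:])}
    mags = np.abs(entries)
    if isinstance(threshold, dict):
        q = float(threshold["q"])
        if not 0.0 <= q < 1.0:
            raise ValueError("quantile must be in [0, 1)")
        nz_flat = np.flatnonzero(mags)
        if nz_flat.size == 0:
            return np.zeros(entries.shape, dtype=bool)
        n_keep = int(np.ceil(round((1.0 - q) * nz_flat.size, 9)))
        order = np.argsort(mags.ravel()[nz_flat], kind="stable")
        keep_flat = nz_flat[order[-n_keep:]]
        keep = np.zeros(entries.size, dtype=bool)
        keep[keep_flat] = True
        return keep.reshape(entries.shape)
    return mags > float(threshold)


def threshold_reweight(A: AberrationMatrix, threshold=("q", 0.6)) -> AberrationMatrix:
    """Replace entries above the noise floor by their unit-modulus phase.

    Entries with ``|A| > threshold`` become ``e^{i arg A}``; the rest are
    zeroed.  ``threshold`` may be a number, the string ``"q:0.6"`` or a dict
    ``{"q": 0.6}`` selecting a modulus quantile (the reproducible default).
    """
    if A.weight_state != "raw":
        # idempotent: thresholding a thresholded matrix keeps unit moduli
        out = A.copy()
        return out
    if isinstance(threshold, tuple):
        threshold = {threshold[0]: threshold[1]}
    keep = _keep_mask(A.entries, threshold)
    n_nonzero = int(np.count_nonzero(A.entries))
    if n_nonzero and keep.sum() < 0.01 * n_nonzero:
        warnings.warn(
            "threshold removes more than 99% of the entries; the "
            "factorization is likely ill-posed",
            stacklevel=2,
        )
    out = A.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        phases = np.where(keep, np.exp(1j * np.angle(A.entries)), 0.0)
    out.entries = phases
    out.weight_state = "thresholded"
    return out


def mask_offdiagonal(A: AberrationMatrix, radius_na: float) -> AberrationMatrix:
    """Zero entries with |k_out - k_in| beyond a radius given in NA units.

    The documented default band for low-scattering samples is 0.3-0.4 NA; a
    radius at or beyond the detection NA is a no-op.
    """
    if radius_na <= 0:
        raise ValueError("radius_na must be positive")
    k_rad = 2.0 * np.pi * radius_na / A.grid.wavelength
    kc = A.row_k_coords()  # (n_rows, 2)
    d = kc[:, None, :] - A.kin_table[None, :, :]
    keep = np.hypot(d[..., 0], d[..., 1]) <= k_rad + 1e-12
    out = A.copy()
    out.entries = np.where(keep, A.entries, 0.0)
    return out


# --------------------------------------------------------------------------
# factorization
# --------------------------------------------------------------------------

def _gauge_index(A: AberrationMatrix, u: np.ndarray) -> int:
    """Row index used to pin the global phase: the pupil-centre pixel."""
    kc = A.row_k_coords()
    centre = int(np.argmin(np.hypot(kc[:, 0], kc[:, 1])))
    if np.abs(u[centre]) < 1e-12:
        centre = int(np.argmax(np.abs(u)))
    return centre


def _package(A: AberrationMatrix, u: np.ndarray, v: np.ndarray, row_weight=None):
    """Gauge-fix and wrap factor vectors into PhaseDifferenceFields.

    ``u``/``v`` are complex vectors whose arguments estimate the outgoing /
    incoming phase differences (convention A ~ e^{i dphi_out} e^{i dphi_in}^T).
    ``row_weight`` is an optional per-row reliability in [0, 1] (the
    coherence of the survivors behind each row estimate).
    """
    g_idx = _gauge_index(A, u)
    alpha = np.angle(u[g_idx])
    dphi_out_rows = wrap_phase(np.angle(u) - alpha)
    dphi_in = wrap_phase(np.angle(v) + alpha)

    row_support = A.to_grid(np.abs(u) > 0).astype(bool) & A.row_mask
    out_field = PhaseDifferenceField(
        grid=A.grid,
        direction=A.delta_k,
        side="outgoing",
        values=A.to_grid(dphi_out_rows),
        support=row_support,
        weights=None if row_weight is None else A.to_grid(row_weight),
    )
    # scatter incoming samples onto nearest k-grid pixels
    kx = A.grid.kx_coords()
    ky = A.grid.ky_coords()
    in_vals = np.zeros(A.grid.shape)
    in_supp = np.zeros(A.grid.shape, dtype=bool)
    for g, (kcx, kcy) in enumerate(A.kin_table):
        ix = int(np.argmin(np.abs(kx - kcx)))
        iy = int(np.argmin(np.abs(ky - kcy)))
        in_vals[iy, ix] = dphi_in[g]
        in_supp[iy, ix] = True
    in_field = PhaseDifferenceField(
        grid=A.grid,
        direction=A.delta_k,
        side="incoming",
        values=in_vals,
        support=in_supp,
        samples=(A.kin_table.copy(), dphi_in),
    )
    return out_field, in_field


def factorize_svd(A: AberrationMatrix):
    """Rank-1 phase factorization through the leading singular pair."""
    if not np.any(A.entries):
        raise ValueError("cannot factorize an all-zero aberration matrix")
    U, s, Vh = np.linalg.svd(A.entries, full_matrices=False)
    u = U[:, 0]
    v = Vh[0, :]  # A ~ s0 * outer(u, v)
    # zero rows of A must stay outside the support
    u = np.where(np.abs(A.entries).sum(axis=1) > 0, u, 0.0)
    # row reliability: leading-vector energy relative to its typical level
    mag = np.abs(u)
    typ = np.median(mag[mag > 0]) if np.any(mag > 0) else 1.0
    weight = np.clip(mag / max(typ, 1e-30), 0.0, 1.0)
    return _package(A, u, v, row_weight=weight)


def factorize_projection_power(
    A: AberrationMatrix,
    max_iter: int = 100,
    tol: float = 1e-10,
    return_objective: bool = False,
):
    """Unimodular quadratic programming by projection power iteration.

    The incoming phase differences solve ``max v^H M v`` with ``M = A^H A``
    subject to unit-modulus entries, iterated as ``v <- e^{i arg(M v)}``
    from the all-ones start; the outgoing differences then follow in closed
    form as ``arg(A v)``.  The UQP objective is non-decreasing across
    iterations (asserted); non-convergence returns the best iterate with a
    warning.
    """
    if not np.any(A.entries):
        raise ValueError("cannot factorize an all-zero aberration matrix")
    M = A.entries.conj().T @ A.entries
    v = np.ones(A.n_groups, dtype=np.complex128)
    obj_prev = float(np.real(v.conj() @ (M @ v)))
    objective = [obj_prev]
    converged = False
    for _ in range(max_iter):
        Mv = M @ v
        v_new = np.where(np.abs(Mv) > 0, np.exp(1j * np.angle(Mv)), v)
        obj = float(np.real(v_new.conj() @ (M @ v_new)))
        if obj < obj_prev * (1.0 - 1e-12) - 1e-12:
            raise AssertionError("UQP objective decreased during power iteration")
        step = np.max(np.abs(wrap_phase(np.angle(v_new) - np.angle(v))))
        v = v_new
        objective.append(obj)
        obj_prev = obj
        if step < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"projection power iteration did not converge in {max_iter} "
            "iterations; returning the best iterate",
            stacklevel=2,
        )
    # v approximates e^{-i dphi_in}; outgoing side from the closed form.
    # The coherence of each row sum (|sum| / n_survivors, unimodular terms)
    # measures how well the rank-1 phase model fits that detection pixel.
    u_raw = A.entries @ v
    n_surv = np.count_nonzero(A.entries, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(n_surv > 0, np.abs(u_raw) / np.maximum(n_surv, 1), 0.0)
    u = np.where(np.abs(u_raw) > 0, np.exp(1j * np.angle(u_raw)), 0.0)
    out_field, in_field = _package(A, u, np.conj(v), row_weight=coherence)
    if return_objective:
        return out_field, in_field, np.asarray(objective)
    return out_field, in_field


# --------------------------------------------------------------------------
# gradient integration
# --------------------------------------------------------------------------

def integrate_gradients(
    dphi_1: PhaseDifferenceField,
    dphi_2: PhaseDifferenceField,
    support: np.ndarray | None = None,
    remove_tilt: bool = False,
    cg_tol: float = 1e-10,
    extra_fields: list[PhaseDifferenceField] | None = None,
) -> AberrationFunction:
    """Integrate two directional phase differences into a pupil phase.

    The wrapped differences along tilt directions dk1, dk2 are converted to
    Cartesian gradient components by a per-pixel 2x2 solve (no unwrapping),
    then integrated over the masked support by conjugate-gradient least
    squares with free boundaries; the per-edge targets are wrapped so that
    differences near +-pi do not corrupt the solve.  Piston is fixed at the
    pupil-centre pixel; tip/tilt is retained unless ``remove_tilt``.
    """
    grid = dphi_1.grid
    dk1 = dphi_1.direction
    dk2 = dphi_2.direction
    det = dk1[0] * dk2[1] - dk1[1] * dk2[0]
    scale = float(np.hypot(*dk1) * np.hypot(*dk2))
    if abs(det) < 1e-9 * max(scale, 1e-30):
        raise ValueError("tilt directions are (nearly) linearly dependent")
    fields = [dphi_1, dphi_2] + list(extra_fields or [])
    if support is None:
        support = fields[0].support.copy()
        for f in fields[1:]:
            support &= f.support
    support = np.asarray(support, dtype=bool)

    # per-pixel reliability: geometric mean of the available field weights
    weight = np.ones(support.shape)
    n_w = 0
    for f in fields:
        if f.weights is not None:
            weight = weight * np.maximum(f.weights, 1e-6)
            n_w += 1
    weight = weight ** (1.0 / n_w) if n_w else None

    if len(fields) == 2:
        # per-pixel 2x2 inversion: [dk1; dk2] . grad = [d1; d2]
        d1 = dphi_1.values
        d2 = dphi_2.values
        gx = (dk2[1] * d1 - dk1[1] * d2) / det
        gy = (-dk2[0] * d1 + dk1[0] * d2) / det
    else:
        # >2 tilt directions: per-pixel least squares over all of them
        D = np.array([f.direction for f in fields])  # (m, 2)
        rhs = np.stack([f.values for f in fields])  # (m, ny, nx)
        G = np.linalg.pinv(D)  # (2, m)
        gx = np.tensordot(G[0], rhs, axes=1)
        gy = np.tensordot(G[1], rhs, axes=1)
    if remove_tilt:
        gx = gx - gx[support].mean()
        gy = gy - gy[support].mean()

    phi = _masked_poisson_integrate(gx, gy, support, grid, cg_tol=cg_tol, weight=weight)

    # pin piston at the pupil-centre pixel (or nearest in-support pixel)
    ky, kx = grid.k_mesh()
    rad = np.hypot(kx, ky)
    rad_masked = np.where(support, rad, np.inf)
    gy_idx, gx_idx = np.unravel_index(np.argmin(rad_masked), rad.shape)
    phi = np.where(support, phi - phi[gy_idx, gx_idx], 0.0)
    return AberrationFunction(
        grid=grid,
        phase=phi,
        support=support,
        side=dphi_1.side,
        gauge={
            "piston_pixel": (int(gy_idx), int(gx_idx)),
            "tilt_removed": bool(remove_tilt),
        },
    )


def _masked_poisson_integrate(
    gx: np.ndarray,
    gy: np.ndarray,
    support: np.ndarray,
    grid: Grid2D,
    cg_tol: float = 1e-10,
    weight: np.ndarray | None = None,
) -> np.ndarray:
    """(Weighted) least-squares integration of a gradient over a mask.

    Unknowns are phi at the support pixels; every pair of x- or y-adjacent
    support pixels contributes one difference equation with the wrapped
    midpoint-gradient target, weighted by the geometric mean of the pixel
    reliabilities when given.  Solved by CG on the normal equations with a
    deterministic zero start.
    """
    idx = -np.ones(support.shape, dtype=np.int64)
    idx[support] = np.arange(int(support.sum()))
    n = int(support.sum())
    if n == 0:
        raise ValueError("empty support")

    a_list, b_list, t_list, w_list = [], [], [], []

    def add_edges(ok, sl_a, sl_b, g, dk):
        a_list.append(idx[sl_a][ok])
        b_list.append(idx[sl_b][ok])
        # the gradient samples are forward differences anchored at the
        # left/upper pixel, so that pixel's value is the exact edge target
        t_list.append(wrap_phase(g[sl_a][ok] * dk))
        if weight is not None:
            w_list.append(np.sqrt((weight[sl_a] * weight[sl_b])[ok]))

    sl_l = (slice(None), slice(None, -1))
    sl_r = (slice(None), slice(1, None))
    add_edges(support[sl_l] & support[sl_r], sl_l, sl_r, gx, grid.dkx)
    sl_u = (slice(None, -1), slice(None))
    sl_d = (slice(1, None), slice(None))
    add_edges(support[sl_u] & support[sl_d], sl_u, sl_d, gy, grid.dky)

    a_idx = np.concatenate(a_list)
    b_idx = np.concatenate(b_list)
    t_vec = np.concatenate(t_list)
    m = t_vec.size
    if m == 0:
        return np.zeros(support.shape)
    w_vec = np.concatenate(w_list) if weight is not None else np.ones(m)

    eq = np.arange(m)
    D = sp.csr_matrix(
        (
            np.concatenate([-w_vec, w_vec]),
            (np.concatenate([eq, eq]), np.concatenate([a_idx, b_idx])),
        ),
        shape=(m, n),
    )
    b_vec = w_vec * t_vec
    L = (D.T @ D).tocsr()
    # pin the nullspace (constant vector) with a tiny Tikhonov term
    L = L + sp.eye(n, format="csr") * 1e-12
    sol, info = spla.cg(L, D.T @ b_vec, rtol=cg_tol, atol=0.0, maxiter=20 * n)
    if info != 0:
        warnings.warn("CG integration did not fully converge", stacklevel=2)
    out = np.zeros(support.shape)
    out[support] = sol
    return out


# --------------------------------------------------------------------------
# high-level detector
# --------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    """Options of the matrix-based aberration detector.

    ``tilt_slots`` selects the two (or more) tilt slots whose directions
    span the gradient; ``threshold`` is a modulus threshold or quantile spec
    ("q:0.6"); ``mask_radius_na`` optionally zeroes far-off-diagonal entries
    (0.3-0.4 NA is the usual band for low-scattering samples); ``solver``
    chooses the UQP projection power iteration or plain SVD.

    ``support_na`` restricts detection to the pupil disc of that NA.  This
    matters for aberrating layers far from the focal plane on coarse
    k-lattices: the layer phase seen by a detection pixel k maps to the
    surface position z k / kz, whose per-pixel step diverges towards the
    pupil rim; rows beyond the NA where that step exceeds the layer
    correlation length carry aliased gradients and must be excluded.
    """

    tilt_slots: tuple[int, ...] = (1, 2)
    threshold: object = "q:0.6"
    mask_radius_na: float | None = None
    support_na: float | None = None
    solver: str = "power"
    remove_tilt: bool = False
    max_iter: int = 100
    tol: float = 1e-8


def detect_aberration(stack: FieldStack, config: DetectorConfig | None = None):
    """Full detection pipeline: matrices -> factorization -> integration.

    Returns ``(phi_out, info)`` where ``phi_out`` is the integrated outgoing
    :class:`AberrationFunction` and ``info`` carries the per-direction
    phase-difference fields (outgoing and incoming) and the final UQP
    objective values.
    """
    config = config or DetectorConfig()
    if len(config.tilt_slots) < 2:
        raise ValueError("at least two tilt slots are required for a 2D gradient")
    out_fields, in_fields, objectives = [], [], []
    for slot in config.tilt_slots:
        A = build_aberration_matrix(stack, slot)
        A = threshold_reweight(A, config.threshold)
        if config.mask_radius_na is not None:
            A = mask_offdiagonal(A, config.mask_radius_na)
        if config.support_na is not None:
            disc = pupil_mask(A.grid, config.support_na)
            A.entries = A.entries * disc[A.row_mask][:, None]
        if config.solver == "svd":
            d_out, d_in = factorize_svd(A)
            objectives.append(float("nan"))
        elif config.solver == "power":
            d_out, d_in, obj = factorize_projection_power(
                A, max_iter=config.max_iter, tol=config.tol, return_objective=True
            )
            objectives.append(float(obj[-1]))
        else:
            raise ValueError(f"unknown solver {config.solver!r}")
        out_fields.append(d_out)
        in_fields.append(d_in)
    phi_out = integrate_gradients(
        out_fields[0],
        out_fields[1],
        remove_tilt=config.remove_tilt,
        extra_fields=out_fields[2:] or None,
    )
    info = {
        "dphi_out": out_fields,
        "dphi_in": in_fields,
        "objective": objectives,
    }
    return phi_out, info


# --------------------------------------------------------------------------
# PSF and phase comparison helpers
# --------------------------------------------------------------------------

def retrieve_psf(phi: AberrationFunction) -> np.ndarray:
    """Complex PSF of a pupil phase: IFT of e^{i phi} on the support, unit L2."""
    if not np.any(phi.support):
        raise ValueError("empty pupil support")
    psf = ifft2_centered(phi.pupil_function(), phi.grid)
    return psf / np.sqrt(np.sum(np.abs(psf) ** 2))


def time_reversed_incoming(phi_out: AberrationFunction) -> AberrationFunction:
    """Incoming aberration from the outgoing one via time-reversal symmetry,
    phi_in(k) = phi_out(-k).

    On the even-sized centred lattice the k -> -k map is an index reversal
    followed by a one-pixel roll (k = 0 sits at index n // 2).
    """

    def neg_k(arr):
        return np.roll(arr[::-1, ::-1], 1, axis=(0, 1))

    return AberrationFunction(
        grid=phi_out.grid,
        phase=neg_k(phi_out.phase).copy(),
        support=neg_k(phi_out.support).copy(),
        side="incoming",
        gauge=dict(phi_out.gauge),
    )


def circular_correlation(phi_a: np.ndarray, phi_b: np.ndarray, support: np.ndarray) -> float:
    """|< e^{i (phi_a - phi_b)} >| over the support (1 = identical phases)."""
    d = np.asarray(phi_a)[support] - np.asarray(phi_b)[support]
    return float(np.abs(np.mean(np.exp(1j * d))))


def align_piston_tilt(
    phi: np.ndarray,
    phi_ref: np.ndarray,
    support: np.ndarray,
    grid: Grid2D,
    n_refine: int = 3,
) -> np.ndarray:
    """Remove the piston/tip/tilt gauge difference between two pupil phases.

    The tilt is first located as the Fourier peak of e^{i(phi - phi_ref)}
    on a 4x zero-padded lattice (robust to wrapping), then refined by a
    weighted linear fit of the wrapped residual.  Returns phi with the gauge
    plane subtracted, zero outside the support.
    """
    support = np.asarray(support, dtype=bool)
    diff_c = np.where(support, np.exp(1j * (phi - phi_ref)), 0.0)
    pad = 4
    ny, nx = diff_c.shape
    big = np.zeros((pad * ny, pad * nx), dtype=np.complex128)
    big[:ny, :nx] = diff_c  # embedding offset only shifts the spectral phase
    # coarse tilt from the DFT peak (in cycles per k-pixel)
    spec = np.fft.fft2(big)
    peak = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
    fy = np.fft.fftfreq(pad * ny)[peak[0]]  # cycles per k-pixel
    fx = np.fft.fftfreq(pad * nx)[peak[1]]
    ky, kx = grid.k_mesh()
    ix = kx / grid.dkx
    iy = ky / grid.dky
    plane = 2 * np.pi * (fx * ix + fy * iy)
    for _ in range(n_refine):
        resid = wrap_phase(phi - phi_ref - plane)
        # small-residual linear fit on the support
        A = np.stack(
            [np.ones(int(support.sum())), ix[support], iy[support]], axis=1
        )
        coef, *_ = np.linalg.lstsq(A, resid[support], rcond=None)
        plane = plane + coef[0] + coef[1] * ix + coef[2] * iy
    return np.where(support, wrap_phase(phi - plane), 0.0)
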