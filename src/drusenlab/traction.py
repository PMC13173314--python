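"""Bead-displacement PIV and Fourier-space traction reconstruction.

The displacement of fiducial beads between a loaded and a relaxed reference
image is estimated by windowed normalized cross-correlation with sub-pixel
parabolic peak refinement. Tractions are recovered on the same grid by
inverting the flat elastic half-space (Boussinesq) relation in Fourier space
with zeroth-order Tikhonov regularization; the identical Green's tensor run
forwards turns a known traction field into a displacement field, which is how
the synthetic generator produces bead pairs with ground truth.

Units: positions and displacements in µm, tractions and Young's modulus in
Pa. The half-space kernel assumes a flat substrate surface — a recorded
simplification when the gel is locally bulged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .geometry import OUTSIDE_NAME, DrusenGeometry, RegionSpec

__all__ = [
    "DisplacementField",
    "TractionField",
    "forward_displacement",
    "piv_displacement",
    "fttc_traction",
    "region_traction_summary",
    "project_and_align",
]

#: Default Tikhonov parameter, chosen by L-curve sweep on the phantom suite.
DEFAULT_LAMBDA = 2e-5
DEFAULT_POISSON = 0.5  # incompressible hydrogel
DEFAULT_YOUNG = 4000.0  # Pa, substrate characterization default


@dataclass
class DisplacementField:
    """Regular grid of 2D displacement vectors.

    ``x``/``y`` are 1D physical grid coordinates (µm); ``u``/``v`` the
    displacement components (µm) on the ``(len(y), len(x))`` grid. ``quality``
    is the correlation peak ratio per vector and ``flagged`` marks vectors
    that were replaced by a local median.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    quality: np.ndarray | None = None
    flagged: np.ndarray | None = None
    window: int = 0
    overlap: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        expected = (self.y.size, self.x.size)
        if self.u.shape != expected or self.v.shape != expected:
            raise ValueError(
                f"u/v must have shape {expected}, got {self.u.shape}/{self.v.shape}"
            )
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacement vectors must be finite")

    @property
    def spacing(self) -> float:
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        if dx.size and (np.ptp(dx) > 1e-9 * abs(dx[0]) or abs(dx[0] - dy[0]) > 1e-9):
            raise ValueError("grid must be regular and square")
        return float(dx[0]) if dx.size else float(dy[0])


@dataclass
class TractionField:
    """Traction vectors (Pa) on a regular grid, with elastic parameters."""

    x: np.ndarray
    y: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    E: float = DEFAULT_YOUNG
    nu: float = DEFAULT_POISSON
    lam: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        if not (np.all(np.isfinite(self.tx)) and np.all(np.isfinite(self.ty))):
            raise ValueError("traction vectors must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)


def _greens_tensor(
    kx: np.ndarray, ky: np.ndarray, E: float, nu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier-space Boussinesq tensor mapping traction to surface displacement.

    G(k) = 2(1+nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2,  -nu kx ky],
                                [-nu kx ky,  (1-nu) k^2 + nu kx^2]]

    The k = 0 entry is zeroed: the uniform mode carries no information for a
    half-space and both forward and inverse transforms enforce zero mean.
    """
    k2 = kx**2 + ky**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k**3)
        gxx = pref * ((1.0 - nu) * k2 + nu * ky**2)
        gyy = pref * ((1.0 - nu) * k2 + nu * kx**2)
        gxy = pref * (-nu * kx * ky)
    for g in (gxx, gxy, gyy):
        g[k2 == 0] = 0.0
    # The off-diagonal term is odd in each component separately; at the
    # (self-conjugate) Nyquist frequency its sign is ambiguous and it would
    # break Hermitian symmetry, so it is zeroed there.
    if kx.size:
        nyq_x = kx.min()
        nyq_y = ky.min()
        gxy[(kx == nyq_x) | (ky == nyq_y)] = 0.0
    return gxx, gxy, gyy


def _wavevectors(ny: int, nx: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing)
    return np.meshgrid(kx, ky)


def forward_displacement(
    tx: np.ndarray,
    ty: np.ndarray,
    spacing: float,
    E: float = DEFAULT_YOUNG,
    nu: float = DEFAULT_POISSON,
    pad: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface displacement (µm) produced by a traction field (Pa).

    Evaluates ``u = G * T`` per Fourier mode on a grid with physical spacing
    ``spacing`` µm. With ``pad`` the field is zero-padded to twice its size
    first, which suppresses wrap-around from the periodic transform.
    """
    tx = np.asarray(tx, dtype=float)
    ty = np.asarray(ty, dtype=float)
    ny, nx = tx.shape
    if pad:
        py, px = ny, nx
        tx = np.pad(tx, ((0, py), (0, px)))
        ty = np.pad(ty, ((0, py), (0, px)))
    kxg, kyg = _wavevectors(*tx.shape, spacing)
    gxx, gxy, gyy = _greens_tensor(kxg, kyg, E, nu)
    ftx = np.fft.fft2(tx)
    fty = np.fft.fft2(ty)
    ux = np.real(np.fft.ifft2(gxx * ftx + gxy * fty))
    uy = np.real(np.fft.ifft2(gxy * ftx + gyy * fty))
    return ux[:ny, :nx], uy[:ny, :nx]


def fttc_traction(
    displacement: DisplacementField,
    E: float = DEFAULT_YOUNG,
    nu: float = DEFAULT_POISSON,
    lam: float = DEFAULT_LAMBDA,
) -> TractionField:
    """Recover tractions from a displacement field by regularized inversion.

    Solves, independently per wavevector, the 2x2 Tikhonov system
    ``(G^T G + lam^2 I) T = G^T u``. The displacement field is made zero-mean
    (the uniform mode is not invertible on a half-space) and transformed
    periodically without padding — padding with zeros would inject a step
    that the high-pass inverse kernel amplifies into edge artifacts. Output
    is on the input grid.
    """
    if lam < 0:
        raise ValueError(f"regularization lam must be >= 0, got {lam}")
    spacing = displacement.spacing
    u = displacement.u - displacement.u.mean()
    v = displacement.v - displacement.v.mean()
    ny, nx = u.shape
    kxg, kyg = _wavevectors(*u.shape, spacing)
    gxx, gxy, gyy = _greens_tensor(kxg, kyg, E, nu)

    fu = np.fft.fft2(u)
    fv = np.fft.fft2(v)
    # normal equations, G symmetric: A = G G + lam^2 I, rhs = G u
    axx = gxx * gxx + gxy * gxy + lam**2
    axy = gxy * (gxx + gyy)
    ayy = gyy * gyy + gxy * gxy + lam**2
    bx = gxx * fu + gxy * fv
    by = gxy * fu + gyy * fv
    det = axx * ayy - axy * axy
    with np.errstate(divide="ignore", invalid="ignore"):
        ftx = (ayy * bx - axy * by) / det
        fty = (axx * by - axy * bx) / det
    zero = det == 0
    ftx[zero] = 0.0
    fty[zero] = 0.0
    tx = np.real(np.fft.ifft2(ftx))[:ny, :nx]
    ty = np.real(np.fft.ifft2(fty))[:ny, :nx]
    return TractionField(displacement.x, displacement.y, tx, ty, E=E, nu=nu, lam=lam)


def _subpixel_offset(c_minus: float, c_zero: float, c_plus: float) -> float:
    """Parabolic three-point peak interpolation; 0 if degenerate."""
    denom = c_minus - 2.0 * c_zero + c_plus
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    return float(np.clip(0.5 * (c_minus - c_plus) / denom, -1.0, 1.0))


def piv_displacement(
    reference: np.ndarray,
    deformed: np.ndarray,
    window: int = 32,
    overlap: int = 16,
    search: int = 8,
    pixel_pitch: float = 1.0,
    min_peak: float = 0.2,
    min_peak_ratio: float = 1.15,
) -> DisplacementField:
    """Block-matching PIV between a reference and a deformed bead image.

    For each interrogation window the deformed patch is located inside a
    search margin of the reference by normalized cross-correlation
    (template matching); the correlation peak is refined to sub-pixel
    precision by parabolic interpolation. Vectors whose peak is weak or
    ambiguous (peak-to-second-peak ratio below ``min_peak_ratio``) are
    flagged and replaced by the median of their 3x3 neighborhood.
    """
    reference = np.asarray(reference, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if reference.shape != deformed.shape:
        raise ValueError("reference and deformed images must have equal shape")
    if overlap >= window:
        raise ValueError("overlap must be smaller than window")
    step = window - overlap
    nrows, ncols = reference.shape
    row_starts = np.arange(0, nrows - window + 1, step)
    col_starts = np.arange(0, ncols - window + 1, step)
    if row_starts.size == 0 or col_starts.size == 0:
        raise ValueError("image smaller than one interrogation window")

    u = np.zeros((row_starts.size, col_starts.size))
    v = np.zeros_like(u)
    quality = np.zeros_like(u)
    flagged = np.zeros(u.shape, dtype=bool)

    for i, r0 in enumerate(row_starts):
        for j, c0 in enumerate(col_starts):
            template = deformed[r0 : r0 + window, c0 : c0 + window]
            rlo = max(r0 - search, 0)
            clo = max(c0 - search, 0)
            rhi = min(r0 + window + search, nrows)
            chi = min(c0 + window + search, ncols)
            region = reference[rlo:rhi, clo:chi]
            if template.std() == 0 or region.std() == 0:
                flagged[i, j] = True
                continue
            corr = match_template(region, template)
            pk = np.unravel_index(np.argmax(corr), corr.shape)
            peak_val = corr[pk]
            # displacement of the deformed patch relative to the reference:
            # the template was found at (rlo + pk) in the reference, so the
            # material moved by (r0 - rlo - pk).
            dr = r0 - (rlo + pk[0])
            dc = c0 - (clo + pk[1])
            if 0 < pk[0] < corr.shape[0] - 1:
                dr -= _subpixel_offset(
                    corr[pk[0] - 1, pk[1]], peak_val, corr[pk[0] + 1, pk[1]]
                )
            if 0 < pk[1] < corr.shape[1] - 1:
                dc -= _subpixel_offset(
                    corr[pk[0], pk[1] - 1], peak_val, corr[pk[0], pk[1] + 1]
                )
            masked = corr.copy()
            rmask = slice(max(pk[0] - 2, 0), pk[0] + 3)
            cmask = slice(max(pk[1] - 2, 0), pk[1] + 3)
            masked[rmask, cmask] = -np.inf
            second = masked.max()
            ratio = peak_val / second if second > 0 else np.inf
            quality[i, j] = ratio
            if peak_val < min_peak or ratio < min_peak_ratio:
                flagged[i, j] = True
            else:
                u[i, j] = dc * pixel_pitch
                v[i, j] = dr * pixel_pitch

    _fill_flagged(u, v, flagged)
    x = (col_starts + window / 2.0) * pixel_pitch
    y = (row_starts + window / 2.0) * pixel_pitch
    return DisplacementField(
        x=x, y=y, u=u, v=v, quality=quality, flagged=flagged,
        window=window, overlap=overlap,
    )


def _fill_flagged(u: np.ndarray, v: np.ndarray, flagged: np.ndarray) -> None:
    """Replace flagged vectors in-place with their 3x3 neighborhood median."""
    if not flagged.any():
        return
    uu = np.where(flagged, np.nan, u)
    vv = np.where(flagged, np.nan, v)
    for i, j in zip(*np.nonzero(flagged)):
        sl = (slice(max(i - 1, 0), i + 2), slice(max(j - 1, 0), j + 2))
        nbr_u = uu[sl]
        if np.all(np.isnan(nbr_u)):
            u[i, j] = 0.0
            v[i, j] = 0.0
        else:
            u[i, j] = np.nanmedian(nbr_u)
            v[i, j] = np.nanmedian(vv[sl])


def region_traction_summary(
    traction: TractionField, geometry: DrusenGeometry, spec: RegionSpec
) -> dict[str, dict]:
    """Per-region traction magnitude statistics and deltas vs Outside.

    Pools ``|T|`` over grid points by the region of each grid position and
    reports ``n``, ``mean``, ``median`` per region plus
    ``delta_mean_vs_outside = mean(region) - mean(Outside)``. Regions without
    grid points are flagged ``no_data``.
    """
    xg, yg = np.meshgrid(traction.x, traction.y)
    r = np.hypot(xg - geometry.center_xy[0], yg - geometry.center_xy[1])
    mag = traction.magnitude
    pooled: dict[str, np.ndarray] = {}
    for annulus in spec.annuli:
        sel = (r >= annulus.inner) & (r < annulus.outer)
        pooled[annulus.name] = mag[sel]
    outside = pooled.get(OUTSIDE_NAME, np.array([]))
    outside_mean = float(outside.mean()) if outside.size else np.nan
    summary: dict[str, dict] = {}
    for name, values in pooled.items():
        if values.size == 0:
            summary[name] = {
                "n": 0, "mean": np.nan, "median": np.nan,
                "delta_mean_vs_outside": np.nan, "no_data": True,
            }
            continue
        mean = float(values.mean())
        summary[name] = {
            "n": int(values.size),
            "mean": mean,
            "median": float(np.median(values)),
            "delta_mean_vs_outside": mean - outside_mean,
            "no_data": False,
        }
    return summary


def project_and_align(reference, deformed) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-intensity projection and integer-pixel rigid alignment.

    Projects both stacks along z, then shifts the deformed projection by the
    integer cross-correlation offset that best aligns it to the reference
    (values rolled in are zeroed).
    """
    ref = _project(reference)
    dfm = _project(deformed)
    ref0 = ref - ref.mean()
    dfm0 = dfm - dfm.mean()
    corr = np.real(np.fft.ifft2(np.fft.fft2(ref0) * np.conj(np.fft.fft2(dfm0))))
    pk = np.unravel_index(np.argmax(corr), corr.shape)
    shift = [p if p <= s // 2 else p - s for p, s in zip(pk, corr.shape)]
    aligned = np.roll(dfm, shift, axis=(0, 1))
    if shift[0] > 0:
        aligned[: shift[0], :] = 0
    elif shift[0] < 0:
        aligned[shift[0] :, :] = 0
    if shift[1] > 0:
        aligned[:, : shift[1]] = 0
    elif shift[1] < 0:
        aligned[:, shift[1] :] = 0
    return ref, aligned


def _project(stack) -> np.ndarray:
    arr = getattr(stack, "voxels", stack)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        return arr.max(axis=0)
    return arr
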