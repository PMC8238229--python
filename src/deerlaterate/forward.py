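"""Forward model: distance distributions -> simulated DEER decays.

The chain is: weighted pairwise-distance histogram between two
pseudo-rotamer clouds, Gaussian broadening by the pair RMSF (backbone
heterogeneity from B-factors), powder-averaged dipolar kernel giving the
intramolecular form factor (distances below 15 A excluded as
uninformative), and a stretched-exponential intermolecular background
with modulation depth:

    V_sim(t) = B(t) * (1 - lambda * (1 - V_intra(t))),
    B(t) = exp(-(k t)^(d/3)).

Distances are in Angstrom on the histogram grid, nanometers inside the
kernel, time in microseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import constants
from scipy.optimize import least_squares
from scipy.special import fresnel

from .rotamers import PseudoRotamerCloud

__all__ = [
    "DistanceDistribution",
    "BackgroundModel",
    "DistanceGrid",
    "default_grid",
    "distance_distribution",
    "broaden",
    "dipolar_kernel",
    "omega_dd",
    "form_factor",
    "background",
    "compose_trace",
    "fit_background",
    "OMEGA_RAD_PER_US_AT_1NM",
    "R_MIN_ANGSTROM",
]

# dipolar angular frequency at 1 nm: mu0 muB^2 g^2 / (4 pi hbar r^3), rad/us
_G_E = abs(constants.physical_constants["electron g factor"][0])
OMEGA_RAD_PER_US_AT_1NM = (
    constants.mu_0
    / (4.0 * math.pi)
    * constants.physical_constants["Bohr magneton"][0] ** 2
    * _G_E**2
    / constants.hbar
    / (1e-9) ** 3
    * 1e-6
)

#: distances below this contribute negligibly to the decay and are excluded
R_MIN_ANGSTROM = 15.0


@dataclass(frozen=True)
class DistanceGrid:
    """Uniform distance grid (A). Default: 0.5 A bins spanning 10-100 A."""

    r_min: float = 10.0
    r_max: float = 100.0
    dr: float = 0.5

    @property
    def centers(self) -> np.ndarray:
        n = int(round((self.r_max - self.r_min) / self.dr))
        return self.r_min + self.dr * (np.arange(n) + 0.5)

    @property
    def n_bins(self) -> int:
        return int(round((self.r_max - self.r_min) / self.dr))

    def bin_index(self, distances: np.ndarray) -> np.ndarray:
        """Nearest-center bin index, clipped to the grid."""
        c = self.centers
        idx = np.rint((np.asarray(distances) - c[0]) / self.dr).astype(np.int64)
        return np.clip(idx, 0, c.size - 1)


def default_grid() -> DistanceGrid:
    return DistanceGrid()


@dataclass
class DistanceDistribution:
    """Binned probability over inter-label distance, optional bands."""

    bin_centers: np.ndarray
    probabilities: np.ndarray
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_centers.shape != self.probabilities.shape:
            raise ValueError("bin_centers/probabilities shape mismatch")
        steps = np.diff(self.bin_centers)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("bin spacing must be uniform")
        if np.any(self.probabilities < -1e-12):
            raise ValueError("negative probabilities")
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")
        for band in (self.band_lo, self.band_hi):
            if band is not None and np.asarray(band).shape != self.bin_centers.shape:
                raise ValueError("band shape mismatch")

    @property
    def dr(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def mean(self) -> float:
        return float(np.dot(self.probabilities, self.bin_centers))

    def variance(self) -> float:
        m = self.mean()
        return float(np.dot(self.probabilities, (self.bin_centers - m) ** 2))


@dataclass
class BackgroundModel:
    """Stretched-exponential intermolecular background per trace.

    ``mod_depth`` is the modulation depth lambda in (0, 1]; ``k`` the
    decay rate in us^-1 on the (k t)^(d/3) scale; ``d`` the
    dimensionality of background coupling (3 for soluble proteins, 2-3.5
    for membrane proteins).
    """

    mod_depth: float
    k: float
    d: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.mod_depth <= 1.0):
            raise ValueError(f"mod_depth must be in (0, 1], got {self.mod_depth}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not (2.0 <= self.d <= 3.5):
            raise ValueError(f"d must be in [2.0, 3.5], got {self.d}")


def distance_distribution(
    cloud_u: PseudoRotamerCloud,
    cloud_v: PseudoRotamerCloud,
    grid: DistanceGrid | None = None,
) -> DistanceDistribution:
    """Weighted histogram of all pairwise inter-cloud distances.

    Each (rotamer_u, rotamer_v) pair contributes the product of the
    normalized weights; distances are assigned to the nearest bin center
    (clipped to the grid, so total probability is conserved).
    """
    grid = grid or default_grid()
    if cloud_u.residue.residue_id == cloud_v.residue.residue_id:
        raise ValueError("clouds belong to the same residue")
    pu = cloud_u.probabilities  # raises on all-zero weights
    pv = cloud_v.probabilities
    diff = cloud_u.positions[:, None, :] - cloud_v.positions[None, :, :]
    dists = np.sqrt(np.sum(diff * diff, axis=-1))
    idx = grid.bin_index(dists.ravel())
    w = np.outer(pu, pv).ravel()
    probs = np.bincount(idx, weights=w, minlength=grid.n_bins)
    return DistanceDistribution(bin_centers=grid.centers, probabilities=probs)


def broadening_matrix(centers: np.ndarray, sigma: float) -> np.ndarray:
    """Column-normalized discrete Gaussian kernel (mass-preserving)."""
    n = centers.size
    if sigma <= 0:
        return np.eye(n)
    d2 = (centers[:, None] - centers[None, :]) ** 2
    g = np.exp(-d2 / (2.0 * sigma * sigma))
    return g / g.sum(axis=0, keepdims=True)


def broaden(dist: DistanceDistribution, rmsf_uv: float) -> DistanceDistribution:
    """Convolve with a Gaussian of s.d. ``rmsf_uv`` (A) on the same grid."""
    if rmsf_uv < 0:
        raise ValueError("rmsf_uv must be >= 0")
    if rmsf_uv == 0:
        return replace(dist)
    g = broadening_matrix(dist.bin_centers, rmsf_uv)
    probs = g @ dist.probabilities
    probs /= probs.sum()
    return DistanceDistribution(bin_centers=dist.bin_centers, probabilities=probs)


def omega_dd(r_nm: np.ndarray | float) -> np.ndarray | float:
    """Dipolar angular frequency (rad/us) at inter-spin distance r (nm)."""
    r = np.asarray(r_nm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    return OMEGA_RAD_PER_US_AT_1NM / r**3


def dipolar_kernel(
    r_nm: np.ndarray | float,
    t_us: np.ndarray | float,
    n_quad: int | None = None,
) -> np.ndarray | float:
    """Powder-averaged dipolar kernel.

    K(r, t) = int_0^{pi/2} sin(x) cos((1 - 3 cos^2 x) w_dd(r) t) dx with
    the polar angle x between field and inter-spin vector. Evaluated in
    closed form via Fresnel integrals by default; pass ``n_quad`` for a
    fixed-order trapezoid quadrature instead (both deterministic).
    Broadcasts over ``r_nm`` and ``t_us``; K(r, 0) = 1.
    """
    w = omega_dd(r_nm)
    t = np.asarray(t_us, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    phi = np.asarray(w * t, dtype=float)
    if n_quad is not None:
        x = np.linspace(0.0, math.pi / 2.0, int(n_quad))
        integrand = np.sin(x) * np.cos(
            (1.0 - 3.0 * np.cos(x) ** 2)[(None,) * phi.ndim] * phi[..., None]
        )
        out = np.trapezoid(integrand, x, axis=-1)
        return out if out.ndim else float(out)
    small = phi < 1e-10
    phi_safe = np.where(small, 1.0, phi)
    z = np.sqrt(6.0 * phi_safe / math.pi)
    s_f, c_f = fresnel(z)
    out = np.sqrt(math.pi / (6.0 * phi_safe)) * (
        np.cos(phi_safe) * c_f + np.sin(phi_safe) * s_f
    )
    out = np.where(small, 1.0, out)
    return out if out.ndim else float(out)


def form_factor(
    dist: DistanceDistribution,
    time_us: np.ndarray,
    r_min: float = R_MIN_ANGSTROM,
    pair_id: str = "",
) -> np.ndarray:
    """Intramolecular form factor V_intra(t) = sum_j P(r_j) K(r_j, t).

    Bins with centers below ``r_min`` (default 15 A) are excluded and the
    surviving probability renormalized, so V_intra(0) = 1 is preserved.
    """
    keep = dist.bin_centers >= r_min
    mass = float(dist.probabilities[keep].sum())
    if mass <= 0:
        raise ValueError(
            f"pair {pair_id or '?'}: all probability mass below {r_min} A "
            "(restraint uninformative)"
        )
    p = dist.probabilities[keep] / mass
    r_nm = dist.bin_centers[keep] / 10.0
    kmat = dipolar_kernel(r_nm[None, :], np.asarray(time_us, dtype=float)[:, None])
    return kmat @ p


def background(t_us: np.ndarray | float, bg: BackgroundModel) -> np.ndarray | float:
    """Stretched-exponential background B(t) = exp(-(k t)^(d/3))."""
    t = np.asarray(t_us, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-((bg.k * t) ** (bg.d / 3.0)))
    return out if out.ndim else float(out)


def compose_trace(
    v_intra: np.ndarray,
    bg: BackgroundModel,
    time_us: np.ndarray,
) -> np.ndarray:
    """Full simulated decay V_sim(t) = B(t) (1 - lambda (1 - V_intra))."""
    v_intra = np.asarray(v_intra, dtype=float)
    time_us = np.asarray(time_us, dtype=float)
    if v_intra.shape != time_us.shape:
        raise ValueError("v_intra/time length mismatch")
    return np.asarray(background(time_us, bg)) * (1.0 - bg.mod_depth * (1.0 - v_intra))


_LAM_LO, _LAM_HI = 1e-4, 1.0
_D_LO, _D_HI = 2.0, 3.5


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return math.log(p / (1.0 - p))


def fit_background(
    trace,
    v_intra: np.ndarray,
    d_policy: str = "fixed",
) -> BackgroundModel:
    """Fit (mod_depth, k[, d]) by grid search + Levenberg-Marquardt.

    ``d_policy`` is ``"fixed"`` (d = 3.0) or ``"free"`` (d in [2.0, 3.5]).
    A coarse grid over mod_depth in {0.05..0.6} and log-spaced k seeds an
    LM refinement run in smoothly bounded parameters (logit/log
    transforms), which keeps the parameters inside their physical ranges.
    Deterministic for fixed inputs.
    """
    if d_policy not in ("fixed", "free"):
        raise ValueError("d_policy must be 'fixed' or 'free'")
    t = np.asarray(trace.time_us, dtype=float)
    y = np.asarray(trace.real, dtype=float)
    v = np.asarray(v_intra, dtype=float)
    if t.shape != v.shape or t.shape != y.shape:
        raise ValueError(f"{trace.trace_id}: trace and v_intra share no time axis")

    def model(lam: float, k: float, d: float) -> np.ndarray:
        return np.exp(-((k * t) ** (d / 3.0))) * (1.0 - lam * (1.0 - v))

    lam_grid = np.linspace(0.05, 0.6, 12)
    k_grid = np.concatenate([[1e-6], np.geomspace(1e-3, 3.0, 16)])
    d_grid = np.array([3.0]) if d_policy == "fixed" else np.array([2.0, 2.5, 3.0, 3.5])
    best, best_ssr = None, np.inf
    for d0 in d_grid:
        for lam0 in lam_grid:
            for k0 in k_grid:
                ssr = float(np.sum((y - model(lam0, k0, d0)) ** 2))
                if ssr < best_ssr:
                    best, best_ssr = (lam0, k0, d0), ssr
    lam0, k0, d0 = best

    free_d = d_policy == "free"

    def unpack(p: np.ndarray) -> tuple[float, float, float]:
        lam = _LAM_LO + (_LAM_HI - _LAM_LO) * _sigmoid(p[0])
        k = math.exp(p[1])
        d = _D_LO + (_D_HI - _D_LO) * _sigmoid(p[2]) if free_d else 3.0
        return lam, k, d

    def resid(p: np.ndarray) -> np.ndarray:
        return y - model(*unpack(p))

    # grid optima on a box corner would saturate the sigmoid (zero gradient);
    # start the logit-parametrized coordinates strictly inside the box
    p0 = [np.clip(_logit((lam0 - _LAM_LO) / (_LAM_HI - _LAM_LO)), -4.0, 4.0),
          math.log(max(k0, 1e-8))]
    if free_d:
        p0.append(np.clip(_logit((d0 - _D_LO) / (_D_HI - _D_LO)), -4.0, 4.0))
    sol = least_squares(resid, np.asarray(p0), method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success and float(np.sum(sol.fun**2)) > best_ssr:
        raise RuntimeError(f"{trace.trace_id}: background fit failed to converge")
    lam, k, d = unpack(sol.x)
    return BackgroundModel(mod_depth=min(lam, 1.0), k=k, d=d)
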