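"""Small-angle X-ray scattering toolkit for magnetosome sizing.

Implements 1-D curve reduction (normalization to accumulation time, sample
thickness and transmission, then buffer subtraction), the homogeneous-sphere
form factor with Gaussian diameter polydispersity, Guinier analyses (solid
sphere and flake/platelet variants), and the membrane/core decomposition:
the overall magnetosome radius R = R_core + R_membrane is obtained from the
sphere fit, the membrane contribution from a Guinier fit of magnetite-free
(aerobically grown) samples via R = sqrt(5/3) * Rg, and the core diameter by
subtracting the membrane thickness twice from the overall diameter.

q is always in 1/Angstrom at the interfaces; fitted lengths are reported in
nm (conversion is centralized in ``A_PER_NM``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "SAXSCurve",
    "SphereFitResult",
    "GuinierResult",
    "DiscGuinierResult",
    "reduce_curve",
    "sphere_form_factor",
    "polydisperse_intensity",
    "fit_sphere",
    "first_minimum_radius",
    "guinier_fit",
    "radius_from_rg",
    "core_diameter",
    "disc_guinier",
    "disc_form_factor",
    "find_first_minimum",
    "synth_curve",
    "FIRST_SPHERE_ZERO",
]

A_PER_NM = 10.0
#: First positive root of tan(x) = x: location of the sphere form-factor zero
#: at q*R = x1.
FIRST_SPHERE_ZERO = 4.493409457909064
#: Standard Guinier validity bound on q_max * Rg.
GUINIER_QMAX_RG = 1.3


@dataclass
class SAXSCurve:
    """A reduced or raw 1-D scattering curve I(q) with uncertainties."""

    q: np.ndarray                      # 1/Angstrom, strictly increasing
    intensity: np.ndarray              # arbitrary units
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is None:
            self.sigma = np.zeros_like(self.q)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.q) == 0:
            raise ValueError("empty curve")
        if self.q[0] <= 0 or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class SphereFitResult:
    diameter_nm: float        # mean 2R of the Gaussian diameter distribution
    sd_nm: float              # Gaussian sd of the diameter
    scale: float
    background: float
    chi2_reduced: float

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0 or self.sd_nm < 0:
            raise ValueError("non-physical sphere fit result")


@dataclass
class GuinierResult:
    rg_nm: float
    q_range: tuple[float, float]
    intercept: float          # ln I(0)
    sphere_radius_nm: float   # sqrt(5/3) * Rg
    valid: bool               # q_max * Rg <= 1.3


@dataclass
class DiscGuinierResult:
    radius_nm: float
    thickness_nm: float
    rg_total_nm: float
    flake_like: bool          # thickness clearly smaller than the radius


def _norm_factor(meta: dict) -> float:
    f = 1.0
    for key in ("accumulation_time", "thickness", "transmission"):
        v = float(meta.get(key, 1.0))
        if v <= 0:
            raise ValueError(f"normalization metadata {key!r} must be positive")
        f *= v
    return f


def reduce_curve(sample: SAXSCurve, buffer: SAXSCurve) -> SAXSCurve:
    """Normalize sample and buffer, subtract, propagate sigma in quadrature.

    The buffer is interpolated onto the sample grid; its q range must cover
    the sample's.
    """
    if buffer.q[0] > sample.q[0] + 1e-12 or buffer.q[-1] < sample.q[-1] - 1e-12:
        raise ValueError(
            "buffer q range does not cover the sample curve "
            f"({buffer.q[0]:.4g}-{buffer.q[-1]:.4g} vs {sample.q[0]:.4g}-{sample.q[-1]:.4g})"
        )
    fs = _norm_factor(sample.metadata)
    fb = _norm_factor(buffer.metadata)
    ib = np.interp(sample.q, buffer.q, buffer.intensity / fb)
    sb = np.interp(sample.q, buffer.q, buffer.sigma / fb)
    out = sample.intensity / fs - ib
    sig = np.sqrt((sample.sigma / fs) ** 2 + sb**2)
    meta = {"reduced": True, "sample": dict(sample.metadata), "buffer": dict(buffer.metadata)}
    return SAXSCurve(sample.q.copy(), out, sig, meta)


def sphere_form_factor(q: np.ndarray | float, radius: float) -> np.ndarray | float:
    """Normalized sphere form factor P(q) = [3 (sin x - x cos x)/x^3]^2.

    ``radius`` in Angstrom, q in 1/Angstrom; P(0) = 1 by the analytic limit.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    x = q * radius
    small = x < 1e-3
    amp = np.empty_like(x)
    xs = x[small]
    amp[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    amp[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    out = amp**2
    return out if out.shape else float(out)


def polydisperse_intensity(
    q: np.ndarray,
    mean_diameter_nm: float,
    sd_nm: float,
    scale: float = 1.0,
    background: float = 0.0,
    n_nodes: int = 101,
) -> np.ndarray:
    """Sphere scattering with a Gaussian diameter distribution.

    Volume-square (R^6) weighted average of the form factor over a Gaussian
    in diameter, truncated at +/- 4 sd with non-positive diameters excluded,
    normalized so that I(q -> 0) = scale + background.  ``sd_nm = 0`` reduces
    exactly to the monodisperse sphere.
    """
    if mean_diameter_nm <= 0:
        raise ValueError("mean diameter must be positive")
    if sd_nm < 0:
        raise ValueError("sd must be non-negative")
    q = np.asarray(q, dtype=float)
    if sd_nm == 0.0:
        r = mean_diameter_nm * A_PER_NM / 2.0
        return scale * sphere_form_factor(q, r) + background
    n_nodes = max(int(n_nodes), 51)
    d = np.linspace(mean_diameter_nm - 4 * sd_nm, mean_diameter_nm + 4 * sd_nm, n_nodes)
    keep = d > 0
    if keep.sum() < n_nodes * 0.9:
        warnings.warn("more than 10% of the Gaussian size weight truncated at 0")
    d = d[keep]
    w = np.exp(-0.5 * ((d - mean_diameter_nm) / sd_nm) ** 2)
    r = d * A_PER_NM / 2.0
    w6 = w * r**6
    pf = np.array([sphere_form_factor(q, ri) for ri in r])  # (nodes, nq)
    avg = w6 @ pf / np.sum(w6)
    return scale * avg + background


def first_minimum_radius(q_min: float) -> float:
    """Sphere radius (Angstrom) from the first form-factor minimum position."""
    if q_min <= 0:
        raise ValueError("q_min must be positive")
    return FIRST_SPHERE_ZERO / q_min


def find_first_minimum(q: np.ndarray, i: np.ndarray) -> float | None:
    """Locate the first (possibly smeared) form-factor minimum.

    Polydispersity fills the sharp zero of the sphere form factor; the
    oscillation survives in the Porod-scaled curve I*q^4, whose first local
    minimum is used (after light smoothing) as the estimate of q_min.
    Returns ``None`` when no interior minimum is found.
    """
    q = np.asarray(q, dtype=float)
    i = np.asarray(i, dtype=float)
    n = len(i)
    if n < 7:
        return None
    porod = np.log(np.clip(i, 1e-300, None) * q**4)
    k = max(3, n // 60) | 1
    pad = k // 2
    sm = np.convolve(porod, np.ones(k) / k, mode="same")
    for j in range(pad + 1, n - pad - 1):
        if sm[j] < sm[j - 1] and sm[j] <= sm[j + 1]:
            return float(q[j])
    return None


def fit_sphere(
    curve: SAXSCurve,
    init_diameter_nm: float | None = None,
    init_sd_nm: float | None = None,
    fit_background: bool = True,
) -> SphereFitResult:
    """Fit the Gaussian-polydisperse sphere model to a reduced curve.

    Initialization uses the first form-factor minimum when visible; residuals
    are relative (log-free) so the result is invariant to intensity scaling.
    """
    q, i = curve.q, curve.intensity
    pos = i > 0
    if pos.sum() < 6:
        raise ValueError("too few positive intensities to fit")
    if init_diameter_nm is None:
        qm = find_first_minimum(q[pos], i[pos])
        init_diameter_nm = (
            2.0 * first_minimum_radius(qm) / A_PER_NM if qm else 30.0
        )
    if init_sd_nm is None:
        init_sd_nm = 0.18 * init_diameter_nm
    bg0 = float(np.median(i[-max(3, len(i) // 20):])) if fit_background else 0.0
    scale0 = max(float(i[pos][0]) - bg0, 1e-12)

    def residuals(p):
        d, sd, log_scale, bg = p
        model = polydisperse_intensity(q, d, sd, math.exp(log_scale), bg)
        sig = np.where(curve.sigma > 0, curve.sigma, np.abs(i) * 0.01 + 1e-12)
        return (model - i) / sig

    p0 = [init_diameter_nm, init_sd_nm, math.log(scale0), bg0]
    lo = [1e-3, 0.0, math.log(scale0) - 20, -abs(bg0) * 10 - 1e-9]
    hi = [1e4, init_diameter_nm * 2.0, math.log(scale0) + 20, abs(bg0) * 10 + abs(scale0)]
    res = optimize.least_squares(residuals, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    d, sd, log_scale, bg = res.x
    dof = max(len(q) - 4, 1)
    return SphereFitResult(float(d), float(sd), math.exp(log_scale), float(bg),
                           float(2 * res.cost / dof))


def guinier_fit(curve: SAXSCurve, q_range: tuple[float, float]) -> GuinierResult:
    """Guinier analysis: ln I vs q^2 over ``q_range``; Rg = sqrt(-3 slope).

    Rejects windows with fewer than five positive points or a non-negative
    slope (no decay).  Validity (q_max * Rg <= 1.3) is flagged post hoc, not
    enforced.
    """
    lo, hi = q_range
    mask = (curve.q >= lo) & (curve.q <= hi) & (curve.intensity > 0)
    if mask.sum() < 5:
        raise ValueError(f"need >= 5 positive points in q range, got {int(mask.sum())}")
    q2 = curve.q[mask] ** 2
    res = stats.linregress(q2, np.log(curve.intensity[mask]))
    if res.slope >= 0:
        raise ValueError("non-decaying intensity in window: not Guinier-like")
    rg_a = math.sqrt(-3.0 * res.slope)
    q_max = float(curve.q[mask][-1])
    rg_nm = rg_a / A_PER_NM
    return GuinierResult(
        rg_nm,
        (float(curve.q[mask][0]), q_max),
        float(res.intercept),
        radius_from_rg(rg_nm),
        valid=q_max * rg_a <= GUINIER_QMAX_RG + 1e-9,
    )


def radius_from_rg(rg: float) -> float:
    """Solid-sphere radius from the radius of gyration: R = sqrt(5/3) Rg."""
    if rg <= 0:
        raise ValueError("Rg must be positive")
    return math.sqrt(5.0 / 3.0) * rg


def core_diameter(overall_2r_nm: float, membrane_thickness_nm: float) -> float:
    """Magnetite-core diameter: overall diameter minus membrane on both sides."""
    if membrane_thickness_nm < 0:
        raise ValueError("membrane thickness must be non-negative")
    if overall_2r_nm <= 2.0 * membrane_thickness_nm:
        raise ValueError(
            f"membrane ({membrane_thickness_nm} nm) >= radius: non-physical"
        )
    return overall_2r_nm - 2.0 * membrane_thickness_nm


def disc_form_factor(q: np.ndarray, radius: float, thickness: float, n_alpha: int = 200) -> np.ndarray:
    """Orientation-averaged flat-cylinder (platelet) form factor.

    ``radius`` and ``thickness`` in Angstrom.  Used as the generator for
    flake-like scatterers and as the oracle for :func:`disc_guinier`.
    """
    if radius <= 0 or thickness <= 0:
        raise ValueError("radius and thickness must be positive")
    q = np.asarray(q, dtype=float)
    # Gauss-Legendre nodes on alpha in (0, pi/2)
    x, w = np.polynomial.legendre.leggauss(n_alpha)
    alpha = (x + 1.0) * (math.pi / 4.0)
    wa = w * (math.pi / 4.0) * np.sin(alpha)
    qa = np.outer(q, np.sin(alpha)) * radius
    qh = np.outer(q, np.cos(alpha)) * thickness / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.where(qa > 1e-8, 2.0 * special.j1(qa) / qa, 1.0 - qa**2 / 8.0)
        slab = np.where(np.abs(qh) > 1e-8, np.sin(qh) / qh, 1.0 - qh**2 / 6.0)
    amp2 = (disc * slab) ** 2
    return amp2 @ wa / np.sum(wa)


def disc_guinier(
    curve: SAXSCurve,
    low_q_window: tuple[float, float] | None = None,
    thickness_window: tuple[float, float] | None = None,
) -> DiscGuinierResult:
    """Flake/platelet Guinier decomposition: (radius, thickness) in nm.

    Thickness from the cross-section Guinier ln(I q^2) vs q^2
    (T = sqrt(12) Rg_t); radius from the overall low-q Rg via
    R = sqrt(2 (Rg^2 - Rg_t^2)).  Windows are auto-selected when not given:
    the overall Guinier window is iterated to q <= 1/Rg, the thickness window
    spans q in [3/R_est, 0.9/Rg_t].  A sphere-like input (thickness
    comparable to the diameter) clears the ``flake_like`` flag.
    """
    q, i = curve.q, curve.intensity
    pos = i > 0
    if pos.sum() < 10:
        raise ValueError("window too narrow: need >= 10 positive points")
    q, i = q[pos], i[pos]
    work = SAXSCurve(q, i, metadata={})

    # overall Rg, iterated
    if low_q_window is None:
        qhi = q[min(9, len(q) - 1)]
        for _ in range(3):
            g = guinier_fit(work, (q[0], qhi))
            qhi = max(1.0 / (g.rg_nm * A_PER_NM), q[4])
        low_q_window = (q[0], qhi)
    g_tot = guinier_fit(work, low_q_window)
    rg_tot = g_tot.rg_nm * A_PER_NM

    r_est = math.sqrt(2.0) * rg_tot
    cross = SAXSCurve(q, i * q**2, metadata={})

    def _thickness(window):
        mask = (q >= window[0]) & (q <= window[1])
        if mask.sum() < 5:
            raise ValueError(f"window too narrow for thickness fit: {window}")
        res = stats.linregress(q[mask] ** 2, np.log(cross.intensity[mask]))
        if res.slope >= 0:
            raise ValueError("no cross-section decay: not flake-like")
        return math.sqrt(-res.slope)  # Rg_t in Angstrom

    if thickness_window is None:
        thickness_window = (3.0 / r_est, min(6.0 / r_est, q[-1]))
        rg_t = _thickness(thickness_window)
        thickness_window = (3.0 / r_est, min(max(0.9 / rg_t, 4.0 / r_est), q[-1]))
    rg_t = _thickness(thickness_window)

    thickness = math.sqrt(12.0) * rg_t
    radial_sq = 2.0 * (rg_tot**2 - rg_t**2)
    radius = math.sqrt(radial_sq) if radial_sq > 0 else 0.0
    flake = radius > 0 and thickness < radius
    return DiscGuinierResult(
        radius / A_PER_NM, thickness / A_PER_NM, g_tot.rg_nm, flake
    )


def synth_curve(
    q: np.ndarray,
    model: str = "sphere",
    mean_diameter_nm: float = 39.0,
    sd_nm: float = 7.0,
    radius_nm: float = 10.0,
    thickness_nm: float = 3.5,
    scale: float = 1.0,
    background: float = 0.0,
    noise_floor: float = 0.0,
    noise_fraction: float = 0.0,
    seed: int = 0,
    metadata: dict | None = None,
) -> SAXSCurve:
    """Generate a synthetic scattering curve with truthful sigma column.

    ``model`` is ``"sphere"`` (Gaussian-polydisperse spheres, the
    magnetosome-like case) or ``"disc"`` (flake-like platelet).  Noise is
    Gaussian with sd = max(noise_floor, noise_fraction * I).
    """
    q = np.asarray(q, dtype=float)
    if model == "sphere":
        ideal = polydisperse_intensity(q, mean_diameter_nm, sd_nm, scale, background)
    elif model == "disc":
        ideal = scale * disc_form_factor(q, radius_nm * A_PER_NM, thickness_nm * A_PER_NM) + background
    else:
        raise ValueError(f"unknown model {model!r}")
    sigma = np.maximum(noise_floor, noise_fraction * np.abs(ideal))
    rng = np.random.default_rng(seed)
    noisy = ideal + np.where(sigma > 0, rng.normal(0.0, np.where(sigma > 0, sigma, 1.0)), 0.0)
    meta = {"model": model, "seed": seed}
    if metadata:
        meta.update(metadata)
    return SAXSCurve(q, noisy, sigma, meta)
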