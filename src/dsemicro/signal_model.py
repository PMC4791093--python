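"""Three-compartment DSE diffusion signal model.

The diffusion-weighted signal in coherent white matter is modelled as a
weighted sum over three water pools:

    S / S0 = f_i * S_iso + f_r * S_restricted + (1 - f_i - f_r) * S_hindered

* ``S_iso``   -- free (CSF-like) water, exp(-b * D_i);
* ``S_hindered`` -- extracellular water, a cylindrically symmetric Gaussian
  with diffusivities D_par along and D_perp across the bundle;
* ``S_restricted`` -- water inside parallel impermeable cylinders of radius
  R.  Along the axis diffusion is free with D_par; across the axis the
  attenuation follows the Gaussian phase distribution (GPD) approximation
  with the cylinder eigenmode (Bessel-root) expansion, evaluated in closed
  form for any balanced piecewise-constant effective gradient waveform, so
  the same code covers both pulsed-gradient and dual spin-echo trains.

All diffusivities are in m^2/s, radii in meters, b-values in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.special import jnp_zeros

from .protocol import (
    GYROMAGNETIC_RATIO,
    EffectiveWaveform,
    Protocol,
    build_effective_waveform,
    infer_polarities,
)

FREE_WATER_DIFFUSIVITY = 3.0e-9  # m^2/s, D_i fixed during fitting


@dataclass(frozen=True)
class TissueParams:
    """Full tissue parameter set Phi = {S0, f_i, f_r, D_i, D_par, D_perp, R, theta, phi}.

    ``theta`` is the inclination of the cylinder axis from +z and ``phi`` its
    azimuth (physics convention), both in radians.
    """

    S0: float = 1.0
    f_i: float = 0.0
    f_r: float = 0.7
    D_i: float = FREE_WATER_DIFFUSIVITY
    D_par: float = 1.7e-9
    D_perp: float = 1.2e-9
    R: float = 5e-6
    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_i and 0.0 <= self.f_r and self.f_i + self.f_r <= 1.0 + 1e-12):
            raise ValueError("volume fractions must satisfy 0 <= f_i + f_r <= 1")
        if min(self.S0, self.D_i, self.D_par, self.D_perp, self.R) <= 0:
            raise ValueError("S0, diffusivities and R must be positive")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the cylinder axis."""
        st = np.sin(self.theta)
        return np.array(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )

    def replace(self, **kw) -> "TissueParams":
        return _dc_replace(self, **kw)


@dataclass(frozen=True)
class BesselRootTable:
    """First M positive roots of J1'(alpha) = 0 for the cylinder eigenmodes."""

    roots: np.ndarray

    @classmethod
    def generate(cls, m: int = 20) -> "BesselRootTable":
        return cls(roots=jnp_zeros(1, m))

    def __post_init__(self) -> None:
        r = np.asarray(self.roots, dtype=float)
        object.__setattr__(self, "roots", r)
        if np.any(np.diff(r) <= 0) or abs(r[0] - 1.8412) > 1e-4:
            raise ValueError("invalid Bessel root table")


# 30 roots keeps the series tail below 1e-8 in ln S up to R = 15 um for the
# timing/diffusivity regimes of interest (adding 10 more roots changes
# nothing at that precision)
_DEFAULT_ROOTS = BesselRootTable.generate(30)


def isotropic_signal(b, D_i: float = FREE_WATER_DIFFUSIVITY):
    """Free-water attenuation exp(-b * D_i); b in s/mm^2."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    return np.exp(-b * 1e6 * D_i)


def hindered_signal(b, alpha, D_par: float, D_perp: float):
    """Extracellular attenuation exp(-b (cos^2 a (D_par - D_perp) + D_perp)).

    ``alpha`` is the angle between gradient direction and bundle axis (rad).
    """
    b = np.asarray(b, dtype=float)
    c2 = np.cos(alpha) ** 2
    return np.exp(-b * 1e6 * (c2 * (D_par - D_perp) + D_perp))


def _pair_integrals(segments, lam):
    """sum over ordered segment pairs of g_i g_j int int exp(-lam (t-t')).

    ``segments`` is a list of (start, end, level); ``lam`` an array of decay
    rates (one per eigenmode).  Same-segment (triangle) and cross-segment
    (rectangle) contributions are both analytic for piecewise-constant g.
    """
    lam = np.asarray(lam)
    total = np.zeros_like(lam)
    for i, (a1, a2, gi) in enumerate(segments):
        # triangle: t, t' within one segment
        x = lam * (a2 - a1)
        small = x < 1e-4
        with np.errstate(over="ignore"):
            core = np.where(
                small, x**2 / 2 - x**3 / 6 + x**4 / 24, x - 1 + np.exp(-x)
            )
        total += gi * gi * core / lam**2
        for b1, b2, gj in segments[i + 1 :]:
            # rectangle: t' in earlier segment, t in later one
            e = (
                np.exp(-lam * (b1 - a2))
                - np.exp(-lam * (b1 - a1))
                - np.exp(-lam * (b2 - a2))
                + np.exp(-lam * (b2 - a1))
            )
            total += gi * gj * e / lam**2
    return total


def restricted_perp_lnsignal(
    wf: EffectiveWaveform,
    g_perp_scale: float,
    R: float,
    D: float,
    roots: BesselRootTable = _DEFAULT_ROOTS,
    gamma: float = GYROMAGNETIC_RATIO,
) -> float:
    """ln of the GPD attenuation perpendicular to the cylinder axis.

    ``g_perp_scale`` is the fraction of the gradient amplitude perpendicular
    to the axis (sin of the gradient/axis angle); the GPD phase variance is
    quadratic in the gradient, so ln S scales with its square.

    The phase-variance double integral over the effective waveform is
    evaluated in closed form per segment pair using the equilibrium
    position autocorrelation of diffusion in a disk,

        <x(t) x(t')> = sum_m c_m exp(-lam_m |t - t'|),
        c_m = 2 R^2 / (alpha_m^2 (alpha_m^2 - 1)),  lam_m = D alpha_m^2 / R^2,

    which reduces to the classical van Gelderen expression in the
    pulsed-gradient special case.
    """
    if R <= 0 or D <= 0:
        raise ValueError("R and D must be positive")
    if abs(wf.net_area()) > 1e-9 * (max(abs(l) for l in wf.levels) + 1e-300):
        from .protocol import UnbalancedWaveformError

        raise UnbalancedWaveformError("waveform must be balanced")
    if g_perp_scale == 0.0:
        return 0.0
    segs = [(a, b, g * g_perp_scale) for a, b, g in wf.segments()]
    if not segs:
        return 0.0
    alpha = roots.roots
    lam = D * alpha**2 / R**2
    c = 2 * R**2 / (alpha**2 * (alpha**2 - 1))
    return float(-(gamma**2) * np.sum(c * _pair_integrals(segs, lam)))


def vangelderen_pgse_lnsignal(
    delta: float,
    Delta: float,
    G: float,
    R: float,
    D: float,
    roots: BesselRootTable = _DEFAULT_ROOTS,
    gamma: float = GYROMAGNETIC_RATIO,
) -> float:
    """Published pulsed-gradient closed form for cylinders (oracle/reference).

    ln S = -2 gamma^2 G^2 sum_m [2 lam d - 2 + 2 e^{-lam d} + 2 e^{-lam D}
           - e^{-lam (D - d)} - e^{-lam (D + d)}] / (lam^2 alpha^2 (alpha^2 - 1) / R^2)

    with lam_m = D alpha_m^2 / R^2, d = delta, D = Delta.
    """
    alpha = roots.roots
    lam = D * alpha**2 / R**2
    num = (
        2 * lam * delta
        - 2
        + 2 * np.exp(-lam * delta)
        + 2 * np.exp(-lam * Delta)
        - np.exp(-lam * (Delta - delta))
        - np.exp(-lam * (Delta + delta))
    )
    den = lam**2 * alpha**2 * (alpha**2 - 1) / R**2
    return float(-2 * gamma**2 * G**2 * np.sum(num / den))


def restricted_signal(
    wf: EffectiveWaveform,
    direction: np.ndarray,
    params: TissueParams,
    roots: BesselRootTable = _DEFAULT_ROOTS,
    gamma: float = GYROMAGNETIC_RATIO,
) -> float:
    """Intracylinder signal: free axial Gaussian x perpendicular GPD factor.

    The axial factor uses the axis-projected waveform with D_par (cylinders
    are unbounded along their axis); the perpendicular factor is the GPD
    attenuation with the perpendicular gradient projection.
    """
    from .protocol import compute_bvalue

    u = np.asarray(direction, dtype=float)
    cos_a = float(np.dot(u, params.axis))
    sin2 = max(0.0, 1.0 - cos_a**2)
    b = compute_bvalue(wf, gamma)  # s/mm^2
    ln_axial = -b * 1e6 * cos_a**2 * params.D_par
    ln_perp = restricted_perp_lnsignal(
        wf, np.sqrt(sin2), params.R, params.D_par, roots, gamma
    )
    return float(np.exp(ln_axial + ln_perp))


class ProtocolCache:
    """Precomputed per-arrangement quantities for fast repeated prediction.

    Stores segment lists, b-values and direction tables once per protocol,
    caches the unit-direction perpendicular GPD factor per unique
    arrangement for the last (R, D) queried (MCMC proposals frequently leave
    the diffusivity/radius block untouched).
    """

    def __init__(self, protocol: Protocol, roots: BesselRootTable = _DEFAULT_ROOTS):
        self.protocol = protocol
        self.roots = roots
        self.gamma = protocol.gyromagnetic_ratio
        b_arr = protocol.bvalues()
        self.weighted = protocol.weighted_indices
        self.segments = {}
        self.b = {}
        self.dirs = {}
        self._sig = {}  # arrangement idx -> hashable segment signature
        for i in self.weighted:
            a = protocol.arrangements[i]
            if a.polarities is None:
                a = infer_polarities(a)
            wf = build_effective_waveform(a)
            self.segments[i] = wf.segments()
            self.b[i] = b_arr[i]
            self.dirs[i] = protocol.directions[i]
            self._sig[i] = tuple(map(tuple, self.segments[i]))
        self.n_b0 = protocol.n_b0
        self.n_meas = protocol.n_measurements
        self._gpd_key = None
        self._gpd_val = {}

    def _ln_perp_full(self, R: float, D: float) -> dict:
        """ln S_perp at full amplitude, perpendicular axis, per arrangement."""
        key = (R, D)
        if key != self._gpd_key:
            alpha = self.roots.roots
            lam = D * alpha**2 / R**2
            c = 2 * R**2 / (alpha**2 * (alpha**2 - 1))
            by_sig = {}
            for i in self.weighted:
                sig = self._sig[i]
                if sig not in by_sig:
                    by_sig[sig] = float(
                        -(self.gamma**2)
                        * np.sum(c * _pair_integrals(self.segments[i], lam))
                    )
            self._gpd_val = {i: by_sig[self._sig[i]] for i in self.weighted}
            self._gpd_key = key
        return self._gpd_val

    def predict(self, params: TissueParams) -> np.ndarray:
        """Model signal for every measurement of the protocol."""
        if params.f_i + params.f_r > 1.0 + 1e-12:
            raise ValueError("f_i + f_r must not exceed 1")
        out = np.empty(self.n_meas)
        out[: self.n_b0] = params.S0
        axis = params.axis
        ln_perp = self._ln_perp_full(params.R, params.D_par)
        f_h = 1.0 - params.f_i - params.f_r
        pos = self.n_b0
        for i in self.weighted:
            u = self.dirs[i]
            n_k = len(u)
            b_si = self.b[i] * 1e6
            cos2 = (u @ axis) ** 2
            sin2 = np.clip(1.0 - cos2, 0.0, 1.0)
            s_i = np.exp(-b_si * params.D_i)
            s_h = np.exp(
                -b_si * (cos2 * (params.D_par - params.D_perp) + params.D_perp)
            )
            s_r = np.exp(-b_si * cos2 * params.D_par + sin2 * ln_perp[i])
            out[pos : pos + n_k] = params.S0 * (
                params.f_i * s_i + params.f_r * s_r + f_h * s_h
            )
            pos += n_k
        return out


def model_signal(protocol: Protocol, index: int, params: TissueParams) -> float:
    """Predicted signal for one measurement index of the protocol."""
    cache = ProtocolCache(protocol)
    if not 0 <= index < cache.n_meas:
        raise IndexError("measurement index out of range")
    return float(cache.predict(params)[index])
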