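"""Dual spin-echo (DSE) pulse arrangements and diffusion-weighting physics.

A DSE sequence refocuses twice, so up to four diffusion gradients can be
placed around the two 180-degree pulses.  Diffusion weighting depends only on
the *effective* gradient waveform -- the physical train with the sign flipped
after each refocusing pulse -- so arrangements are represented here by their
pulse onsets/lengths plus effective polarities, and all quantities (b-value,
effective diffusion time, eddy-current residual, CRLB) are derived from the
piecewise-constant effective waveform.

Times in the public API are in milliseconds (as printed on scanner consoles);
internal integrals are carried out in SI units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

GYROMAGNETIC_RATIO = 2.6752e8  # rad s^-1 T^-1, proton

# Final optimized protocol timings (ms) at 35 mT/m, TE = 118.54 ms.
# Arrangement 1 carries no diffusion gradients (b = 0).  Arrangements 2 and 4
# are identical by design.
_TABLE1 = {
    1: {"onsets": [], "lengths": []},
    2: {"onsets": [0.00, 91.76], "lengths": [7.34, 7.34]},
    3: {"onsets": [24.47, 46.45], "lengths": [21.97, 21.97]},
    4: {"onsets": [0.00, 91.76], "lengths": [7.34, 7.34]},
    5: {"onsets": [0.00, 20.60, 79.86], "lengths": [13.01, 6.83, 19.84]},
}
TABLE1_ECHO_TIME_MS = 118.54
TABLE1_AMPLITUDE = 0.035  # T/m
_T90_MS = 2.56   # time needed for a 90 degree RF pulse
_T180_MS = 7.56  # time needed for a 180 degree pulse + crushers


class UnbalancedWaveformError(ValueError):
    """Raised when no effective-sign assignment gives zero net gradient area."""


@dataclass(frozen=True)
class PulseArrangement:
    """One diffusion-sensitizing pulse arrangement of a DSE sequence.

    Parameters
    ----------
    onsets, lengths : tuple of float
        Pulse start times and durations in milliseconds.
    amplitude : float
        Gradient magnitude in T/m (same for every pulse).
    echo_time : float
        Echo time in milliseconds.
    polarities : tuple of int or None
        Effective sign (+1/-1) of each pulse after accounting for the
        refocusing pulses.  ``None`` until assigned (see
        :func:`infer_polarities`).
    """

    onsets: tuple[float, ...]
    lengths: tuple[float, ...]
    amplitude: float
    echo_time: float
    polarities: tuple[int, ...] | None = None
    refocus_windows: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        onsets = tuple(float(o) for o in self.onsets)
        lengths = tuple(float(l) for l in self.lengths)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "lengths", lengths)
        if len(onsets) != len(lengths):
            raise ValueError("onsets and lengths must have equal length")
        if any(o < 0 for o in onsets) or any(l <= 0 for l in lengths):
            if lengths:  # empty (b=0) arrangement is fine
                raise ValueError("onsets must be >= 0 and lengths > 0")
        ends = [o + l for o, l in zip(onsets, lengths)]
        for i in range(len(onsets) - 1):
            if ends[i] > onsets[i + 1] + 1e-9:
                raise ValueError("pulses overlap or are out of order")
        if lengths and self.echo_time <= ends[-1]:
            raise ValueError("echo_time must exceed the last pulse end")
        if self.polarities is not None:
            pol = tuple(int(p) for p in self.polarities)
            object.__setattr__(self, "polarities", pol)
            if len(pol) != len(onsets):
                raise ValueError("polarities length mismatch")
            if any(p not in (-1, 1) for p in pol):
                raise ValueError("polarities must be +1 or -1")

    @property
    def n_pulses(self) -> int:
        return len(self.onsets)

    @property
    def is_weighted(self) -> bool:
        return self.n_pulses > 0 and self.amplitude > 0

    def net_area(self) -> float:
        """Signed effective gradient area, T/m * ms (zero when balanced)."""
        if self.polarities is None:
            raise ValueError("polarities not assigned")
        return sum(
            p * l * self.amplitude for p, l in zip(self.polarities, self.lengths)
        )


@dataclass(frozen=True)
class EffectiveWaveform:
    """Piecewise-constant effective gradient waveform on [0, echo_time].

    ``breakpoints`` are ordered times in seconds (first 0, last the echo
    time); ``levels[i]`` is the gradient value in T/m on
    ``[breakpoints[i], breakpoints[i+1])``.
    """

    breakpoints: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        lv = tuple(float(g) for g in self.levels)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)
        if len(bp) != len(lv) + 1:
            raise ValueError("need one more breakpoint than levels")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    @property
    def echo_time(self) -> float:
        return self.breakpoints[-1]

    def net_area(self) -> float:
        dt = np.diff(self.breakpoints)
        return float(np.dot(dt, self.levels))

    def segments(self) -> list[tuple[float, float, float]]:
        """Nonzero segments as (start, end, level) in SI units."""
        return [
            (t0, t1, g)
            for t0, t1, g in zip(self.breakpoints, self.breakpoints[1:], self.levels)
            if g != 0.0
        ]

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Evaluate g_eff at times ``t`` (s); right-open intervals."""
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.levels) - 1)
        out = np.asarray(self.levels)[idx]
        out = np.where((t < 0) | (t >= self.echo_time), 0.0, out)
        return out

    def integrate(self, t0: float, t1: float) -> float:
        """Exact integral of g_eff over [t0, t1] (seconds)."""
        total = 0.0
        for a, b, g in zip(self.breakpoints, self.breakpoints[1:], self.levels):
            lo, hi = max(a, t0), min(b, t1)
            if hi > lo:
                total += g * (hi - lo)
        return total


@dataclass(frozen=True)
class Protocol:
    """An ordered set of pulse arrangements with their gradient directions.

    The measurement index runs over ``n_b0`` unweighted volumes first, then
    the directions of each weighted arrangement in order.
    """

    arrangements: tuple[PulseArrangement, ...]
    directions: tuple[np.ndarray, ...]  # one (n_k, 3) array per arrangement
    n_b0: int = 0
    gyromagnetic_ratio: float = GYROMAGNETIC_RATIO

    def __post_init__(self) -> None:
        dirs = []
        for d in self.directions:
            d = np.atleast_2d(np.asarray(d, dtype=float))
            if d.size and d.shape[1] != 3:
                raise ValueError("directions must be 3-vectors")
            norms = np.linalg.norm(d, axis=1) if d.size else np.array([])
            if d.size and np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("directions must have unit norm")
            dirs.append(d)
        object.__setattr__(self, "directions", tuple(dirs))
        if len(self.directions) != len(self.arrangements):
            raise ValueError("one direction table per arrangement required")

    @property
    def weighted_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.arrangements) if a.is_weighted]

    @property
    def n_measurements(self) -> int:
        return self.n_b0 + sum(
            len(self.directions[i]) for i in self.weighted_indices
        )

    def measurement_table(self) -> list[tuple[int, np.ndarray | None]]:
        """Bijective measurement index -> (arrangement index, direction)."""
        table: list[tuple[int, np.ndarray | None]] = [
            (-1, None) for _ in range(self.n_b0)
        ]
        for i in self.weighted_indices:
            for d in self.directions[i]:
                table.append((i, d))
        return table

    def bvalues(self) -> np.ndarray:
        """b-value (s mm^-2) of each arrangement (0 for unweighted)."""
        out = []
        for a in self.arrangements:
            if not a.is_weighted:
                out.append(0.0)
            else:
                wf = build_effective_waveform(
                    a if a.polarities is not None else infer_polarities(a)
                )
                out.append(compute_bvalue(wf, self.gyromagnetic_ratio))
        return np.array(out)

    def measurement_bvalues(self) -> np.ndarray:
        b_arr = self.bvalues()
        return np.array(
            [0.0 if i < 0 else b_arr[i] for i, _ in self.measurement_table()]
        )


def infer_polarities(arr: PulseArrangement) -> PulseArrangement:
    """Assign effective pulse signs from the zero-net-area (balance) condition.

    The refocusing-pulse placements determine the signs physically, but only
    the effective waveform matters for diffusion weighting, and the balance
    condition pins it down: we enumerate sign patterns (first pulse +1 by
    convention) and keep the one with zero net area.  Idempotent when
    polarities are already set and balanced.
    """
    if arr.polarities is not None:
        if abs(arr.net_area()) > 1e-9 * arr.amplitude * max(arr.lengths):
            raise UnbalancedWaveformError("assigned polarities do not balance")
        return arr
    if arr.n_pulses < 2:
        raise UnbalancedWaveformError(
            "a single gradient pulse can never have zero net area"
        )
    tol = 1e-6 * max(arr.lengths)
    solutions = []
    for signs in itertools.product((1, -1), repeat=arr.n_pulses - 1):
        pattern = (1,) + signs
        area = sum(p * l for p, l in zip(pattern, arr.lengths))
        if abs(area) <= tol:
            solutions.append(pattern)
    if not solutions:
        raise UnbalancedWaveformError(
            f"no sign assignment balances pulse lengths {arr.lengths}"
        )
    # deterministic: prefer the lexicographically first (+1-leading) solution
    return replace(arr, polarities=solutions[0])


def build_effective_waveform(arr: PulseArrangement) -> EffectiveWaveform:
    """Effective waveform: polarity*amplitude inside pulses, 0 elsewhere (SI)."""
    if arr.n_pulses == 0 or arr.amplitude == 0.0:
        te = arr.echo_time * 1e-3
        return EffectiveWaveform(breakpoints=(0.0, te), levels=(0.0,))
    if arr.polarities is None:
        arr = infer_polarities(arr)
    if abs(arr.net_area()) > 1e-9 * arr.amplitude * max(arr.lengths):
        raise UnbalancedWaveformError("arrangement is not balanced")
    bp = [0.0]
    lv = []
    for o, l, p in zip(arr.onsets, arr.lengths, arr.polarities):
        start, end = o * 1e-3, (o + l) * 1e-3
        if start > bp[-1]:
            bp.append(start)
            lv.append(0.0)
        elif start < bp[-1] - 1e-12:
            raise ValueError("pulse overlap while building waveform")
        bp.append(end)
        lv.append(p * arr.amplitude)
    te = arr.echo_time * 1e-3
    if te > bp[-1]:
        bp.append(te)
        lv.append(0.0)
    return EffectiveWaveform(breakpoints=tuple(bp), levels=tuple(lv))


def compute_bvalue(
    wf: EffectiveWaveform, gamma: float = GYROMAGNETIC_RATIO
) -> float:
    """b-value (s mm^-2) of a balanced effective waveform.

    b = gamma^2 * integral of q(t)^2 over [0, TE], with q the running integral
    of g_eff.  q is piecewise linear, so each interval contributes the exact
    polynomial integral (q0^2 + q0*q1 + q1^2) * dt / 3 -- no quadrature.
    """
    bp = np.asarray(wf.breakpoints)
    lv = np.asarray(wf.levels)
    dt = np.diff(bp)
    q = np.concatenate([[0.0], np.cumsum(lv * dt)])
    scale = max(abs(lv).max() * dt.sum(), np.finfo(float).tiny)
    if abs(q[-1]) > 1e-9 * scale:
        raise UnbalancedWaveformError("q(TE) != 0: waveform is not balanced")
    q0, q1 = q[:-1], q[1:]
    integral = np.sum((q0 * q0 + q0 * q1 + q1 * q1) * dt / 3.0)
    return float(gamma**2 * integral / 1e6)  # s/m^2 -> s/mm^2


def effective_diffusion_time(arr: PulseArrangement) -> float:
    """Onset-to-onset separation (ms) of the outermost pulses.

    The DSE sequence has no unique diffusion time; this convention (analogous
    to the Delta of a pulsed-gradient pair) reproduces the short/long
    diffusion-time classification of the optimized arrangements.
    """
    if arr.n_pulses < 2:
        raise ValueError("need at least two pulses for a diffusion time")
    return arr.onsets[-1] - arr.onsets[0]


def eddy_residual(wf: EffectiveWaveform, tau: float) -> float:
    """Normalized residual eddy-current amplitude at the echo.

    Each gradient slew event (a step change of the waveform by Delta-g)
    launches an exponentially decaying eddy field; the residual at TE is
    |sum_e Delta-g_e * exp(-(TE - t_e)/tau)| / max|g|.  For a balanced
    waveform the residual vanishes as tau -> infinity.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    bp = np.asarray(wf.breakpoints)
    lv = np.concatenate([[0.0], np.asarray(wf.levels), [0.0]])
    edges = np.diff(lv)  # slew at each breakpoint (incl. start and TE)
    times = np.concatenate([bp, [bp[-1]]])[: len(edges)]
    te = wf.echo_time
    amp = max(np.abs(wf.levels).max(), np.finfo(float).tiny)
    resid = np.sum(edges * np.exp(-(te - times) / tau))
    return float(abs(resid) / amp)


def heid_time_constant(arrangements) -> float:
    """Design eddy time constant: 0.7 times the maximal summed pulse length."""
    tmax = max(
        (sum(a.lengths) for a in arrangements if a.is_weighted), default=0.0
    )
    return 0.7 * tmax * 1e-3  # s


def fisher_bounds(predict, x0, sigma: float, scales=None) -> np.ndarray:
    """Cramer-Rao variance bounds for a deterministic signal model.

    Under independent Gaussian noise of s.d. ``sigma``, the Fisher
    information is F = J^T J / sigma^2 with J the Jacobian of
    ``predict(x)`` (central finite differences, step 1e-4 of each
    parameter's scale).  Returns the diagonal of F^-1; a numerically
    singular Fisher matrix yields infinite bounds (non-identifiable), not
    an error.
    """
    x0 = np.asarray(x0, dtype=float)
    if scales is None:
        scales = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    n_par = len(x0)
    f0 = None
    cols = []
    for j in range(n_par):
        h = 1e-4 * scales[j]
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        # central differences, falling back to one-sided at domain edges
        try:
            fp = np.asarray(predict(xp))
        except ValueError:
            fp = None
        try:
            fm = np.asarray(predict(xm))
        except ValueError:
            fm = None
        if fp is not None and fm is not None:
            cols.append((fp - fm) / (2 * h))
        else:
            if f0 is None:
                f0 = np.asarray(predict(x0))
            if fp is not None:
                cols.append((fp - f0) / h)
            elif fm is not None:
                cols.append((f0 - fm) / h)
            else:
                raise ValueError(f"model not evaluable around parameter {j}")
    jac = np.stack(cols, axis=1)
    # invert in scale-normalized coordinates so disparate parameter units
    # (diffusivities ~1e-9, fractions ~1) do not masquerade as singularity
    jac_s = jac * scales[None, :]
    fisher_s = jac_s.T @ jac_s / sigma**2
    cond = np.linalg.cond(fisher_s)
    if not np.isfinite(cond) or cond > 1e12:
        return np.full(n_par, np.inf)
    return np.diag(np.linalg.inv(fisher_s)) * scales**2


def crlb_objective(protocol: Protocol, params, sigma: float) -> dict:
    """Cramer-Rao variance bounds for the tissue parameters under a protocol.

    Evaluates :func:`fisher_bounds` for the three-compartment model over all
    measurements of the protocol; this is the objective used to rank
    candidate protocols (the stochastic design search itself is out of
    scope here).  Returns {parameter name: variance bound}.
    """
    from . import signal_model as sm

    free = ["S0", "f_i", "f_r", "D_par", "D_perp", "R", "theta", "phi"]
    x0 = np.array([getattr(params, k) for k in free])
    cache = sm.ProtocolCache(protocol)

    def predict(x):
        p = params.replace(**dict(zip(free, x)))
        return cache.predict(p)

    return dict(zip(free, fisher_bounds(predict, x0, sigma)))


def uniform_sphere_directions(
    n: int, seed: int = 0, antipodal: bool = True, n_iter: int = 300
) -> np.ndarray:
    """n unit vectors spread over the sphere by electrostatic repulsion.

    Minimizes the Coulomb energy of the point set (including antipodal images
    when ``antipodal`` is true, appropriate for gradient directions, which
    are axes) by projected gradient descent from a seeded random start.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        d2 = np.sum(diff**2, axis=-1) + np.eye(n)
        force = np.sum(diff / d2[..., None] ** 1.5, axis=1)
        if antipodal:
            sdiff = x[:, None, :] + x[None, :, :]
            s2 = np.sum(sdiff**2, axis=-1) + 1e-12
            force += np.sum(sdiff / s2[..., None] ** 1.5, axis=1)
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        x += step * force / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def table1_protocol(
    n_b0: int = 9, n_directions: int = 90, direction_seed: int = 20150520
) -> Protocol:
    """The optimized five-arrangement 35 mT/m protocol as a Protocol object.

    ``n_b0`` defaults to 9: ten b = 0 volumes are acquired but the first is a
    dummy and is discarded before analysis.  The same ``n_directions``
    electrostatically spread directions are used for every weighted
    arrangement, as acquired.
    """
    arrs = []
    for k in sorted(_TABLE1):
        t = _TABLE1[k]
        a = PulseArrangement(
            onsets=tuple(t["onsets"]),
            lengths=tuple(t["lengths"]),
            amplitude=TABLE1_AMPLITUDE if t["onsets"] else 0.0,
            echo_time=TABLE1_ECHO_TIME_MS,
        )
        if a.n_pulses:
            a = infer_polarities(a)
        arrs.append(a)
    dirs90 = uniform_sphere_directions(n_directions, seed=direction_seed)
    directions = tuple(
        dirs90 if a.is_weighted else np.empty((0, 3)) for a in arrs
    )
    return Protocol(
        arrangements=tuple(arrs), directions=directions, n_b0=n_b0
    )
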