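"""Voxelwise Bayesian fitting of the three-compartment model.

The measured magnitude signal in each voxel is modelled with a Rician
likelihood around the model prediction, combined with structured informative
priors on the tissue parameters:

    f_i            ~ Beta(1.2, 1.2)
    f_r / (1-f_i)  ~ Beta(5, 5)
    D_par          ~ LogNormal(-20.69, 1)    (mean 1.7e-9 m^2/s)
    D_perp         ~ LogNormal(-21.04, 1)    (mean 1.2e-9 m^2/s)
    R              ~ Gamma(3.562, 1.404e-6)  (mean 5 um)

(SI units throughout).  Sampling uses a blocked Metropolis--Hastings
algorithm on transformed coordinates -- logs for positive parameters,
logits for bounded fractions -- with a tuned multivariate Gaussian proposal
per block: (S0), (f_i, f_r), (D_par, D_perp, R), (theta, phi), (sigma).
Chains are initialized from an ordinary-least-squares tensor fit.  The
per-voxel summary of interest is the axon radius index: the median of the
posterior samples of R.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betaln, gammaln, i0e

from .protocol import Protocol
from .signal_model import FREE_WATER_DIFFUSIVITY, ProtocolCache, TissueParams

_LOG_2PI = np.log(2.0 * np.pi)

# transformed-coordinate layout
_NAMES = ["S0", "f_i", "f_rp", "D_par", "D_perp", "R", "theta", "phi", "sigma"]
_BLOCKS = [["S0"], ["f_i", "f_rp"], ["D_par", "D_perp", "R"], ["theta", "phi"], ["sigma"]]
_IDX = {n: i for i, n in enumerate(_NAMES)}


@dataclass(frozen=True)
class PriorSet:
    """The informative priors, with per-parameter disable switches.

    Disabling a prior reverts that coordinate to a flat prior on its
    transformed (log/logit) scale.  The sigma prior is flat on log sigma
    over a broad bounded support.
    """

    f_i_ab: tuple[float, float] = (1.2, 1.2)
    f_rp_ab: tuple[float, float] = (5.0, 5.0)
    D_par_lognorm: tuple[float, float] = (-20.69, 1.0)
    D_perp_lognorm: tuple[float, float] = (-21.04, 1.0)
    R_gamma: tuple[float, float] = (3.562, 1.404e-6)  # shape, scale (m)
    log_sigma_bounds: tuple[float, float] = (-30.0, 30.0)
    enabled: frozenset[str] = frozenset({"f_i", "f_rp", "D_par", "D_perp", "R"})

    def disable(self, *names: str) -> "PriorSet":
        return replace(self, enabled=self.enabled - set(names))

    @property
    def R_mean(self) -> float:
        return self.R_gamma[0] * self.R_gamma[1]

    @property
    def D_par_mean(self) -> float:
        mu, sd = self.D_par_lognorm
        return float(np.exp(mu + 0.5 * sd**2))

    @property
    def D_perp_mean(self) -> float:
        mu, sd = self.D_perp_lognorm
        return float(np.exp(mu + 0.5 * sd**2))


def rician_loglik(x, S, sigma: float):
    """Log Rician density of measurements ``x`` around predictions ``S``.

    Overflow-safe via the exponentially scaled Bessel function:
    log I0(z) = log(i0e(z)) + z.  Summing over measurements gives the joint
    log-likelihood under independent noise.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x < 0):
        raise ValueError("magnitude measurements must be non-negative")
    s2 = sigma**2
    z = x * S / s2
    with np.errstate(divide="ignore"):
        return np.log(x / s2) - (x**2 + S**2) / (2 * s2) + np.log(i0e(z)) + z


def _beta_logpdf(x, a, b):
    if not 0.0 < x < 1.0:
        return -np.inf
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def _lognorm_logpdf(x, mu, sd):
    if x <= 0:
        return -np.inf
    lx = np.log(x)
    return -lx - np.log(sd) - 0.5 * _LOG_2PI - 0.5 * ((lx - mu) / sd) ** 2


def _gamma_logpdf(x, shape, scale):
    if x <= 0:
        return -np.inf
    return (
        (shape - 1) * np.log(x)
        - x / scale
        - gammaln(shape)
        - shape * np.log(scale)
    )


def log_prior(params: TissueParams, sigma: float, priors: PriorSet) -> float:
    """Sum of the enabled component log prior densities in natural space.

    Out-of-support values return -inf (so the sampler rejects them) rather
    than raising.
    """
    total = 0.0
    if "f_i" in priors.enabled:
        total += _beta_logpdf(params.f_i, *priors.f_i_ab)
    if "f_rp" in priors.enabled:
        if params.f_i >= 1.0:
            return -np.inf
        total += _beta_logpdf(params.f_r / (1.0 - params.f_i), *priors.f_rp_ab)
    if "D_par" in priors.enabled:
        total += _lognorm_logpdf(params.D_par, *priors.D_par_lognorm)
    if "D_perp" in priors.enabled:
        total += _lognorm_logpdf(params.D_perp, *priors.D_perp_lognorm)
    if "R" in priors.enabled:
        total += _gamma_logpdf(params.R, *priors.R_gamma)
    lo, hi = priors.log_sigma_bounds
    if not lo <= np.log(sigma) <= hi:
        return -np.inf
    return float(total)


# ---------------------------------------------------------------------------
# coordinate transforms


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def to_transformed(params: TissueParams, sigma: float) -> np.ndarray:
    f_rp = params.f_r / (1.0 - params.f_i) if params.f_i < 1.0 else 0.5
    f_rp = np.clip(f_rp, 1e-12, 1 - 1e-12)
    return np.array(
        [
            np.log(params.S0),
            _logit(np.clip(params.f_i, 1e-12, 1 - 1e-12)),
            _logit(f_rp),
            np.log(params.D_par),
            np.log(params.D_perp),
            np.log(params.R),
            params.theta,
            params.phi,
            np.log(sigma),
        ]
    )


def to_natural(x: np.ndarray) -> tuple[TissueParams, float]:
    f_i = _expit(x[_IDX["f_i"]])
    f_rp = _expit(x[_IDX["f_rp"]])
    params = TissueParams(
        S0=np.exp(x[_IDX["S0"]]),
        f_i=f_i,
        f_r=f_rp * (1.0 - f_i),
        D_i=FREE_WATER_DIFFUSIVITY,
        D_par=np.exp(x[_IDX["D_par"]]),
        D_perp=np.exp(x[_IDX["D_perp"]]),
        R=np.exp(x[_IDX["R"]]),
        theta=x[_IDX["theta"]],
        phi=x[_IDX["phi"]],
    )
    return params, float(np.exp(x[_IDX["sigma"]]))


def log_jacobian(x: np.ndarray, enabled: frozenset) -> float:
    """log |d natural / d transformed| for the enabled prior coordinates.

    Priors are stated in natural space; the sampler works on transformed
    coordinates, so each enabled component contributes its change-of-variable
    term.  Disabled components are flat on the transformed scale and
    contribute nothing.  sigma's flat-on-log prior likewise contributes
    nothing.
    """
    total = 0.0
    if "f_i" in enabled:
        p = _expit(x[_IDX["f_i"]])
        total += np.log(p) + np.log1p(-p)
    if "f_rp" in enabled:
        p = _expit(x[_IDX["f_rp"]])
        total += np.log(p) + np.log1p(-p)
    if "D_par" in enabled:
        total += x[_IDX["D_par"]]
    if "D_perp" in enabled:
        total += x[_IDX["D_perp"]]
    if "R" in enabled:
        total += x[_IDX["R"]]
    return float(total)


# ---------------------------------------------------------------------------
# tensor initialization


def ols_tensor_fit(signals: np.ndarray, protocol: Protocol):
    """Ordinary-least-squares diffusion tensor fit.

    Regresses log signal on the b-matrix; returns (eigenvalues descending,
    FA, principal axis, log S0 intercept, rms residual in signal units).
    Non-positive signals are excluded; at least 7 usable measurements
    (including b = 0) are required.
    """
    signals = np.asarray(signals, dtype=float)
    b = protocol.measurement_bvalues()
    table = protocol.measurement_table()
    n = len(table)
    if len(signals) != n:
        raise ValueError("signal vector length does not match protocol")
    X = np.zeros((n, 7))
    X[:, 0] = 1.0
    for k, (i, d) in enumerate(table):
        if d is not None:
            gx, gy, gz = d
            bk = b[k] * 1e6  # s/m^2
            X[k, 1:] = [
                -bk * gx * gx,
                -bk * gy * gy,
                -bk * gz * gz,
                -2 * bk * gx * gy,
                -2 * bk * gx * gz,
                -2 * bk * gy * gz,
            ]
    usable = signals > 0
    if usable.sum() < 7 or not np.any(usable & (b == 0)):
        raise ValueError("fewer than 7 usable measurements for the tensor fit")
    coef, *_ = np.linalg.lstsq(X[usable], np.log(signals[usable]), rcond=None)
    Dxx, Dyy, Dzz, Dxy, Dxz, Dyz = coef[1:]
    tensor = np.array([[Dxx, Dxy, Dxz], [Dxy, Dyy, Dyz], [Dxz, Dyz, Dzz]])
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    principal = evecs[:, order[0]]
    md = evals.mean()
    denom = np.sqrt(np.sum(evals**2))
    fa = 0.0 if denom == 0 else float(
        np.sqrt(1.5 * np.sum((evals - md) ** 2)) / denom
    )
    resid = signals[usable] - np.exp(X[usable] @ coef)
    rms = float(np.sqrt(np.mean(resid**2)))
    return evals, fa, principal, float(coef[0]), rms


def initialize_params(
    evals: np.ndarray,
    principal: np.ndarray,
    log_s0: float,
    priors: PriorSet | None = None,
) -> TissueParams:
    """Chain start from the tensor fit.

    f_i ~ lam3^2/(lam1 lam2) (clipped), f_r = 0.7 (1 - f_i), D_par = lam1,
    D_perp = (lam2 + lam3)/2, R = 5 um; the axis comes from the principal
    eigenvector.  Negative eigenvalues are clamped; a degenerate tensor
    falls back to the prior means.
    """
    priors = priors or PriorSet()
    ev = np.maximum(np.asarray(evals, dtype=float), 1e-12)
    degenerate = np.any(np.asarray(evals) <= 0) and ev.max() / ev.min() > 1e6
    if degenerate:
        f_i = 1e-3
        d_par, d_perp = priors.D_par_mean, priors.D_perp_mean
        axis = np.array([0.0, 0.0, 1.0])
    else:
        f_i = float(np.clip(ev[2] ** 2 / (ev[0] * ev[1]), 1e-3, 1 - 1e-3))
        d_par, d_perp = float(ev[0]), float((ev[1] + ev[2]) / 2.0)
        axis = np.asarray(principal, dtype=float)
    theta = float(np.arccos(np.clip(axis[2] / np.linalg.norm(axis), -1, 1)))
    phi = float(np.arctan2(axis[1], axis[0]))
    return TissueParams(
        S0=float(np.exp(log_s0)),
        f_i=f_i,
        f_r=0.7 * (1.0 - f_i),
        D_par=d_par,
        D_perp=d_perp,
        R=5e-6,
        theta=theta,
        phi=phi,
    )


# ---------------------------------------------------------------------------
# sampler


@dataclass
class ChainState:
    """Current transformed coordinates plus per-block proposal state."""

    x: np.ndarray
    block_indices: list[np.ndarray]
    proposal_chol: list[np.ndarray]        # Cholesky factors, one per block
    accept_counts: np.ndarray = field(default=None)
    propose_counts: np.ndarray = field(default=None)

    def __post_init__(self):
        nb = len(self.block_indices)
        if self.accept_counts is None:
            self.accept_counts = np.zeros(nb)
        if self.propose_counts is None:
            self.propose_counts = np.zeros(nb)

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.accept_counts / np.maximum(self.propose_counts, 1)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings: total iterations = burn_in + n_samples * thin."""

    burn_in: int = 50_000
    n_samples: int = 50
    thin: int = 100
    tune_epoch: int = 250
    max_tune_epochs: int = 30
    target_acceptance: float = 0.23
    acceptance_band: tuple[float, float] = (0.15, 0.35)
    seed: int = 0
    fix: dict = field(default_factory=dict)  # e.g. {"f_i": 0.0}


@dataclass
class PosteriorSamples:
    """Retained draws per parameter (natural space) with diagnostics."""

    samples: dict[str, np.ndarray]
    acceptance_rates: np.ndarray
    block_names: list[list[str]]
    settings: MCMCSettings
    flagged: bool = False

    @property
    def n(self) -> int:
        return len(next(iter(self.samples.values())))


class VoxelPosterior:
    """Log-posterior on transformed coordinates for one voxel.

    Caches the model prediction so blocks that do not change tissue
    parameters (the sigma block) skip the forward model.
    """

    def __init__(self, signals, cache: ProtocolCache, priors: PriorSet,
                 use_likelihood: bool = True):
        self.signals = np.asarray(signals, dtype=float)
        self.cache = cache
        self.priors = priors
        self.use_likelihood = use_likelihood
        self._pred_key = None
        self._pred = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        key = tuple(x[:8])
        if key != self._pred_key:
            params, _ = to_natural(x)
            self._pred = self.cache.predict(params)
            self._pred_key = key
        return self._pred

    def __call__(self, x: np.ndarray) -> float:
        params, sigma = to_natural(x)
        lp = log_prior(params, sigma, self.priors)
        if not np.isfinite(lp):
            return -np.inf
        lp += log_jacobian(x, self.priors.enabled)
        if self.use_likelihood:
            pred = self.predict(x)
            lp += float(np.sum(rician_loglik(self.signals, pred, sigma)))
        return lp


def _make_blocks(fix: dict) -> tuple[list[np.ndarray], list[list[str]]]:
    indices, names = [], []
    for block in _BLOCKS:
        free = [n for n in block if n not in fix]
        if free:
            indices.append(np.array([_IDX[n] for n in free]))
            names.append(free)
    return indices, names


_DEFAULT_SCALES = {
    "S0": 0.02, "f_i": 0.2, "f_rp": 0.2, "D_par": 0.1, "D_perp": 0.1,
    "R": 0.2, "theta": 0.1, "phi": 0.1, "sigma": 0.1,
}


def make_chain_state(x0: np.ndarray, fix: dict) -> ChainState:
    indices, names = _make_blocks(fix)
    chols = [
        np.diag([_DEFAULT_SCALES[n] for n in blk]) for blk in names
    ]
    return ChainState(x=x0.copy(), block_indices=indices, proposal_chol=chols)


def _mh_sweep(state: ChainState, logpost, lp_cur, rng, n_iter: int):
    """n_iter blocked MH sweeps, updating state in place; returns final lp."""
    for _ in range(n_iter):
        for bi, (idx, chol) in enumerate(
            zip(state.block_indices, state.proposal_chol)
        ):
            prop = state.x.copy()
            prop[idx] = prop[idx] + chol @ rng.standard_normal(len(idx))
            lp_prop = logpost(prop)
            state.propose_counts[bi] += 1
            if np.log(rng.uniform()) < lp_prop - lp_cur:
                state.x = prop
                lp_cur = lp_prop
                state.accept_counts[bi] += 1
    return lp_cur


def tune_proposals(
    state: ChainState,
    logpost,
    settings: MCMCSettings,
    rng,
) -> tuple[ChainState, bool]:
    """Adapt each block's proposal scale until acceptance is in band.

    Robbins--Monro-style: after each epoch the block scale is multiplied by
    exp(acceptance - target).  Adaptation stops once every block is inside
    the band (or after max_tune_epochs) and the proposal is frozen, so
    subsequent sampling satisfies detailed balance.  Returns the state and a
    flag marking chains whose acceptance stayed at zero.
    """
    lo, hi = settings.acceptance_band
    lp = logpost(state.x)
    for _ in range(settings.max_tune_epochs):
        state.accept_counts[:] = 0
        state.propose_counts[:] = 0
        lp = _mh_sweep(state, logpost, lp, rng, settings.tune_epoch)
        rates = state.acceptance_rates
        if np.all((rates >= lo) & (rates <= hi)):
            return state, False
        for bi, rate in enumerate(rates):
            state.proposal_chol[bi] = state.proposal_chol[bi] * np.exp(
                rate - settings.target_acceptance
            )
    return state, bool(np.any(state.acceptance_rates == 0.0))


def run_chain(
    signals,
    protocol: Protocol,
    priors: PriorSet | None = None,
    settings: MCMCSettings | None = None,
    init: TissueParams | None = None,
    sigma_init: float | None = None,
    cache: ProtocolCache | None = None,
    use_likelihood: bool = True,
) -> PosteriorSamples:
    """Full voxel fit: tensor init, proposal tuning, burn-in, sampling.

    ``settings.fix`` maps parameter names to fixed natural values (e.g.
    ``{"f_i": 0.0}`` for synthetic data, where there is no CSF pool).
    ``use_likelihood=False`` samples the prior alone (diagnostics).
    """
    priors = priors or PriorSet()
    settings = settings or MCMCSettings()
    rng = np.random.default_rng(settings.seed)
    cache = cache or ProtocolCache(protocol)

    if init is None:
        evals, _, principal, log_s0, rms = ols_tensor_fit(signals, protocol)
        init = initialize_params(evals, principal, log_s0, priors)
        if sigma_init is None:
            sigma_init = max(rms, 1e-6 * init.S0)
    if sigma_init is None:
        sigma_init = 0.05 * init.S0

    x0 = to_transformed(init, sigma_init)
    fix = dict(settings.fix)
    for name, value in fix.items():
        if name == "f_i":
            x0[_IDX[name]] = _logit(np.clip(value, 1e-12, 1 - 1e-12))
        elif name in ("S0", "D_par", "D_perp", "R", "sigma"):
            x0[_IDX[name]] = np.log(value)
        else:
            x0[_IDX[name]] = value

    state = make_chain_state(x0, fix)
    logpost = VoxelPosterior(signals, cache, priors, use_likelihood)

    lp0 = logpost(state.x)
    retries = 0
    while not np.isfinite(lp0) and retries < 20:
        # re-initialize from a prior-ish draw on the transformed scale
        jitter = rng.standard_normal(len(x0)) * 0.5
        state.x = x0 + jitter
        for name in fix:
            state.x[_IDX[name]] = x0[_IDX[name]]
        lp0 = logpost(state.x)
        retries += 1
    if not np.isfinite(lp0):
        raise RuntimeError("could not find a finite posterior starting point")

    # short pre-adaptation phase so tuning sees the posterior's scale,
    # not the initialization point's
    lp0 = _mh_sweep(state, logpost, lp0, rng, min(500, settings.burn_in // 5))
    state, flagged = tune_proposals(state, logpost, settings, rng)

    lp = logpost(state.x)
    lp = _mh_sweep(state, logpost, lp, rng, settings.burn_in)

    state.accept_counts[:] = 0
    state.propose_counts[:] = 0
    draws = np.empty((settings.n_samples, len(_NAMES)))
    for s in range(settings.n_samples):
        lp = _mh_sweep(state, logpost, lp, rng, settings.thin)
        draws[s] = state.x

    out: dict[str, np.ndarray] = {}
    nat = [to_natural(row) for row in draws]
    out["S0"] = np.array([p.S0 for p, _ in nat])
    out["f_i"] = np.array([p.f_i for p, _ in nat])
    out["f_r"] = np.array([p.f_r for p, _ in nat])
    out["D_par"] = np.array([p.D_par for p, _ in nat])
    out["D_perp"] = np.array([p.D_perp for p, _ in nat])
    out["R"] = np.array([p.R for p, _ in nat])
    out["theta"] = np.array([p.theta for p, _ in nat])
    out["phi"] = np.array([p.phi for p, _ in nat])
    out["sigma"] = np.array([s_ for _, s_ in nat])

    _, block_names = _make_blocks(fix)
    return PosteriorSamples(
        samples=out,
        acceptance_rates=state.acceptance_rates.copy(),
        block_names=block_names,
        settings=settings,
        flagged=flagged,
    )


def fold_axis(theta: np.ndarray, phi: np.ndarray):
    """Fold sampled axes to the upper hemisphere (antipodal symmetry)."""
    theta = np.mod(np.asarray(theta), 2 * np.pi)
    phi = np.asarray(phi).copy()
    # bring theta into [0, pi]
    over = theta > np.pi
    theta = np.where(over, 2 * np.pi - theta, theta)
    phi = np.where(over, phi + np.pi, phi)
    # fold lower hemisphere up
    lower = theta > np.pi / 2
    theta = np.where(lower, np.pi - theta, theta)
    phi = np.where(lower, phi + np.pi, phi)
    return theta, np.mod(phi, 2 * np.pi)


def summarize(samples: PosteriorSamples) -> dict:
    """Posterior medians (the R median is the axon radius index) and spreads."""
    if samples.n < 1:
        raise ValueError("no retained samples")
    out = {}
    theta_f, phi_f = fold_axis(samples.samples["theta"], samples.samples["phi"])
    vals = dict(samples.samples)
    vals["theta"], vals["phi"] = theta_f, phi_f
    for name, v in vals.items():
        out[name + "_median"] = float(np.median(v))
        out[name + "_q25"] = float(np.quantile(v, 0.25))
        out[name + "_q75"] = float(np.quantile(v, 0.75))
        out[name + "_mean"] = float(np.mean(v))
        out[name + "_sd"] = float(np.std(v, ddof=1)) if samples.n > 1 else 0.0
    out["radius_index"] = out["R_median"]
    return out
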