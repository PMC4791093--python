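"""Monte-Carlo random-walk synthesis of DSE signals from cylinder substrates.

Spins random-walk in the cross-sectional plane of a periodic packed-cylinder
substrate (axial motion is free: the cylinders are invariant along their
axis), accumulating phase under the effective gradient waveform of each
pulse arrangement.  Membranes are impermeable in both directions; wall
collisions are resolved by elastic specular reflection with repeated
sub-step resolution.  The magnitude signal is |mean over spins of
exp(i phase)|, and Rician noise is added to emulate magnitude MRI at a
target SNR.

One trajectory per substrate serves every arrangement and direction of the
protocol: the phase of a spin is gamma * u . integral(g_eff(t) x(t) dt), so
it suffices to accumulate the vector integral of g_eff against the
(unwrapped) position, then project onto each gradient direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .protocol import Protocol, build_effective_waveform, infer_polarities


@dataclass(frozen=True)
class Substrate:
    """Packed parallel cylinders in a periodic rectangular cell.

    ``centers`` are 2-D cross-section coordinates (m) in [0, cell) x [0,
    cell); ``axis`` is the cylinder axis orientation in the laboratory frame.
    """

    centers: np.ndarray        # (n, 2)
    radii: np.ndarray          # (n,)
    cell: tuple[float, float]  # (Lx, Ly), m
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    diffusivity: float = 1.7e-9

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        r = np.atleast_1d(np.asarray(self.radii, dtype=float))
        ax = np.asarray(self.axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "axis", ax)
        if len(c) != len(r):
            raise ValueError("centers/radii length mismatch")
        if np.any(r <= 0) or self.diffusivity <= 0:
            raise ValueError("radii and diffusivity must be positive")
        # pairwise overlap check with the periodic minimum image
        L = np.asarray(self.cell)
        for i in range(len(c)):
            d = c[i + 1 :] - c[i]
            d -= np.round(d / L) * L
            if np.any(np.hypot(d[:, 0], d[:, 1]) < r[i + 1 :] + r[i] - 1e-12):
                raise ValueError("cylinders overlap")

    @property
    def intracellular_fraction(self) -> float:
        return float(np.sum(np.pi * self.radii**2) / (self.cell[0] * self.cell[1]))


def make_hex_substrate(
    R: float,
    spacing_factor: float = 2.3,
    D: float = 1.7e-9,
    min_span_diameters: float = 10.0,
) -> Substrate:
    """Hexagonally packed fixed-radius cylinders.

    Center-to-center separation is ``spacing_factor * R``; at the default
    2.3 the intracellular area fraction is 2*pi/(sqrt(3)*2.3^2) ~= 0.69 for
    any radius.  The periodic cell is the smallest lattice-commensurate
    rectangle spanning at least ``min_span_diameters`` cylinder diameters.
    """
    if spacing_factor <= 2.0:
        raise ValueError("spacing_factor must exceed 2 (cylinders would overlap)")
    s = spacing_factor * R
    nx = max(1, int(np.ceil(min_span_diameters * 2 * R / s)))
    ny = max(1, int(np.ceil(min_span_diameters * 2 * R / (s * np.sqrt(3)))))
    centers = []
    for i in range(nx):
        for j in range(ny):
            centers.append((i * s, j * s * np.sqrt(3)))
            centers.append(((i + 0.5) * s, (j + 0.5) * s * np.sqrt(3)))
    return Substrate(
        centers=np.array(centers),
        radii=np.full(2 * nx * ny, R),
        cell=(nx * s, ny * s * np.sqrt(3)),
        diffusivity=D,
    )


def make_gamma_substrate(
    mean_R: float,
    var_R: float,
    target_fraction: tuple[float, float] = (0.65, 0.70),
    seed: int = 0,
    D: float = 1.7e-9,
    max_attempts: int = 40,
) -> Substrate:
    """Randomly placed cylinders with gamma-distributed radii.

    Radii are drawn from Gamma(shape = mean^2/var, scale = var/mean).
    Cylinders are placed by dart-throwing with overlap rejection
    (largest-first); because sequential random placement jams below the
    target density, the cell is then contracted gradually with short
    repulsive relaxation sweeps until the intracellular fraction enters
    ``target_fraction``.  Raises if no attempt succeeds.
    """
    if mean_R <= 0 or var_R < 0:
        raise ValueError("mean_R must be positive and var_R non-negative")
    lo, hi = target_fraction
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        L = 20.0 * mean_R
        area_target = 0.5 * (lo + hi) * L * L
        radii = []
        total = 0.0
        while total < area_target:
            if var_R == 0:
                r = mean_R
            else:
                r = rng.gamma(mean_R**2 / var_R, var_R / mean_R)
            radii.append(r)
            total += np.pi * r * r
        radii = np.sort(np.asarray(radii))[::-1]
        n = len(radii)
        centers = np.empty((n, 2))
        placed = 0
        # dart throwing at a dilute start (larger cell), largest first
        L0 = L * 1.35
        for i in range(n):
            ok = False
            for _try in range(2000):
                p = rng.uniform(0, L0, 2)
                d = centers[:placed] - p
                d -= np.round(d / L0) * L0
                if placed == 0 or np.all(
                    np.hypot(d[:, 0], d[:, 1]) >= radii[:placed] + radii[i]
                ):
                    centers[i] = p
                    placed += 1
                    ok = True
                    break
            if not ok:
                break
        if placed < n:
            continue
        # contract the cell toward the target fraction, relaxing overlaps
        cur = L0
        failed = False
        disk_area = np.sum(np.pi * radii**2)
        while disk_area / cur**2 < lo:
            # shrink faster while dilute, gently near the target density
            step = 0.99 if disk_area / cur**2 < 0.58 else 0.997
            new = cur * step
            centers *= new / cur
            cur = new
            if not _relax(centers, radii, cur, rng):
                failed = True
                break
        frac = np.sum(np.pi * radii**2) / cur**2
        if not failed and lo <= frac <= hi:
            return Substrate(
                centers=np.mod(centers, cur),
                radii=radii,
                cell=(cur, cur),
                diffusivity=D,
            )
    raise RuntimeError(
        f"could not pack gamma substrate to fraction in [{lo}, {hi}]"
    )


def _relax(centers: np.ndarray, radii: np.ndarray, L: float, rng, sweeps: int = 600) -> bool:
    """Push overlapping cylinders apart (periodic); True if overlap-free."""
    rsum = radii[:, None] + radii[None, :]
    for s in range(sweeps):
        d = centers[:, None, :] - centers[None, :, :]
        d -= np.round(d / L) * L
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        over = dist < rsum - 1e-15
        if not over.any():
            return True
        gap = np.where(over, rsum - dist, 0.0)
        unit = d / (dist[..., None] + 1e-300)
        centers += np.sum(unit * gap[..., None] * 0.4, axis=1)
        if s % 60 == 59:  # jitter to escape jammed configurations
            centers += rng.normal(0.0, 0.02 * radii.min(), centers.shape)
        np.mod(centers, L, out=centers)
    return False


@njit(cache=True)
def _walk(pos0, inside0, centers, radii, Lx, Ly, sigma_step, n_steps, g_int, noise):
    """Reflecting random walk; accumulates sum_j g_int[a, j] * x_j per spin.

    pos0: (n, 2) wrapped start positions; inside0: (n,) cylinder index or -1.
    g_int: (n_arr, n_steps) exact integral of g_eff over each step interval.
    noise: (n, n_steps, 3) standard normal increments (z is the free axis).
    Returns (w, crossings): w is (n, n_arr, 3) with the accumulated vector
    integral using unwrapped positions; crossings counts membrane
    violations (should be zero).
    """
    n = pos0.shape[0]
    n_arr = g_int.shape[0]
    n_cyl = centers.shape[0]
    w = np.zeros((n, n_arr, 3))
    crossings = 0
    for sp in range(n):
        wx, wy = pos0[sp, 0], pos0[sp, 1]   # wrapped (geometry)
        ux, uy, uz = wx, wy, 0.0            # unwrapped (phase)
        own = inside0[sp]
        for st in range(n_steps):
            ux0, uy0, uz0 = ux, uy, uz
            dx = sigma_step * noise[sp, st, 0]
            dy = sigma_step * noise[sp, st, 1]
            uz += sigma_step * noise[sp, st, 2]
            for _ref in range(16):
                # find earliest wall hit along (dx, dy) from (wx, wy)
                tbest = 2.0
                nxb = 0.0
                nyb = 0.0
                if own >= 0:
                    # inside: only its own cylinder wall can be hit (exit)
                    ccx = centers[own, 0]
                    ccy = centers[own, 1]
                    rx = wx - ccx - np.round((wx - ccx) / Lx) * Lx
                    ry = wy - ccy - np.round((wy - ccy) / Ly) * Ly
                    a = dx * dx + dy * dy
                    if a > 0.0:
                        bq = 2.0 * (rx * dx + ry * dy)
                        cq = rx * rx + ry * ry - radii[own] * radii[own]
                        disc = bq * bq - 4.0 * a * cq
                        if disc > 0.0:
                            t = (-bq + np.sqrt(disc)) / (2.0 * a)
                            if 0.0 <= t <= 1.0:
                                tbest = t
                                nxb = rx + t * dx
                                nyb = ry + t * dy
                else:
                    for k in range(n_cyl):
                        rx = wx - centers[k, 0]
                        rx -= np.round(rx / Lx) * Lx
                        ry = wy - centers[k, 1]
                        ry -= np.round(ry / Ly) * Ly
                        a = dx * dx + dy * dy
                        if a == 0.0:
                            continue
                        bq = 2.0 * (rx * dx + ry * dy)
                        cq = rx * rx + ry * ry - radii[k] * radii[k]
                        if cq < 0.0:
                            continue  # numerically inside another: skip
                        disc = bq * bq - 4.0 * a * cq
                        if disc <= 0.0:
                            continue
                        t = (-bq - np.sqrt(disc)) / (2.0 * a)
                        if 0.0 <= t < tbest:
                            tbest = t
                            nxb = rx + t * dx
                            nyb = ry + t * dy
                if tbest > 1.0:
                    wx += dx
                    wy += dy
                    ux += dx
                    uy += dy
                    break
                # advance to wall, reflect remainder about the normal
                hx = tbest * dx
                hy = tbest * dy
                wx += hx
                wy += hy
                ux += hx
                uy += hy
                rem_x = (1.0 - tbest) * dx
                rem_y = (1.0 - tbest) * dy
                nn = np.sqrt(nxb * nxb + nyb * nyb)
                if nn == 0.0:
                    dx = 0.0
                    dy = 0.0
                    break
                nxb /= nn
                nyb /= nn
                dot = rem_x * nxb + rem_y * nyb
                dx = rem_x - 2.0 * dot * nxb
                dy = rem_y - 2.0 * dot * nyb
                # nudge off the wall to avoid an immediate re-hit
                eps = 1e-9 * radii[0]
                if own >= 0:
                    # stay strictly inside: pull inward off the wall
                    wx -= eps * nxb
                    wy -= eps * nyb
                    ux -= eps * nxb
                    uy -= eps * nyb
                else:
                    wx += eps * nxb
                    wy += eps * nyb
                    ux += eps * nxb
                    uy += eps * nyb
            # wrap for geometry
            wx -= np.floor(wx / Lx) * Lx
            wy -= np.floor(wy / Ly) * Ly
            # membrane-violation audit
            now = -1
            for k in range(n_cyl):
                rx = wx - centers[k, 0]
                rx -= np.round(rx / Lx) * Lx
                ry = wy - centers[k, 1]
                ry -= np.round(ry / Ly) * Ly
                if rx * rx + ry * ry < radii[k] * radii[k]:
                    now = k
                    break
            if (own >= 0) != (now >= 0):
                crossings += 1
                own = now
            # trapezoidal phase accumulation over the step interval
            for a_i in range(n_arr):
                gi = g_int[a_i, st]
                if gi != 0.0:
                    w[sp, a_i, 0] += gi * 0.5 * (ux0 + ux)
                    w[sp, a_i, 1] += gi * 0.5 * (uy0 + uy)
                    w[sp, a_i, 2] += gi * 0.5 * (uz0 + uz)
        _ = own
    return w, crossings


def _locate(substrate: Substrate, pos: np.ndarray) -> np.ndarray:
    """Cylinder index containing each position (-1 outside), minimum image."""
    L = np.asarray(substrate.cell)
    idx = np.full(len(pos), -1, dtype=np.int64)
    for k, (c, r) in enumerate(zip(substrate.centers, substrate.radii)):
        d = pos - c
        d -= np.round(d / L) * L
        hit = (d[:, 0] ** 2 + d[:, 1] ** 2 < r**2) & (idx < 0)
        idx[hit] = k
    return idx


def _init_positions(substrate, n_spins, rng, init="uniform"):
    L = np.asarray(substrate.cell)
    if init == "uniform":
        pos = rng.uniform(0, 1, (n_spins, 2)) * L
        return pos, _locate(substrate, pos)
    if init == "intra":
        pos = np.empty((n_spins, 2))
        idx = np.empty(n_spins, dtype=np.int64)
        got = 0
        while got < n_spins:
            cand = rng.uniform(0, 1, (4 * n_spins, 2)) * L
            loc = _locate(substrate, cand)
            keep = loc >= 0
            take = min(n_spins - got, keep.sum())
            pos[got : got + take] = cand[keep][:take]
            idx[got : got + take] = loc[keep][:take]
            got += take
        return pos, idx
    raise ValueError("init must be 'uniform' or 'intra'")


def _rotation_to_axis_frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping lab vectors into a frame with axis -> +z."""
    z = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def run_walk(
    substrate: Substrate,
    protocol: Protocol,
    n_spins: int,
    n_steps: int,
    seed: int,
    init: str = "uniform",
):
    """One trajectory ensemble; returns (w, gamma, crossings).

    ``w`` has shape (n_spins, n_weighted_arrangements, 3) in the substrate
    frame: the accumulated integral of g_eff * x(t) dt for each weighted
    arrangement, from which the phase for any direction follows by
    projection.
    """
    rng = np.random.default_rng(seed)
    arrs = protocol.weighted_indices
    te = protocol.arrangements[arrs[0]].echo_time * 1e-3
    dt = te / n_steps
    sigma_step = np.sqrt(2.0 * substrate.diffusivity * dt)
    if sigma_step > 0.2 * substrate.radii.min():
        warnings.warn(
            "step length exceeds 0.2 x min radius: geometry under-resolved",
            stacklevel=2,
        )
    edges = np.linspace(0.0, te, n_steps + 1)
    g_int = np.empty((len(arrs), n_steps))
    for row, i in enumerate(arrs):
        a = protocol.arrangements[i]
        if a.polarities is None:
            a = infer_polarities(a)
        wf = build_effective_waveform(a)
        for j in range(n_steps):
            g_int[row, j] = wf.integrate(edges[j], edges[j + 1])
    pos, inside = _init_positions(substrate, n_spins, rng, init)
    noise = rng.standard_normal((n_spins, n_steps, 3))
    w, crossings = _walk(
        pos,
        inside,
        substrate.centers,
        substrate.radii,
        substrate.cell[0],
        substrate.cell[1],
        sigma_step,
        n_steps,
        g_int,
        noise,
    )
    return w, protocol.gyromagnetic_ratio, crossings


def signal_from_walk(
    w: np.ndarray, gamma: float, arr_row: int, direction_local: np.ndarray
) -> float:
    """|mean exp(i phase)| for one arrangement row and substrate-frame direction."""
    phase = gamma * (w[:, arr_row, :] @ np.asarray(direction_local))
    return float(np.abs(np.mean(np.exp(1j * phase))))


def simulate_signal(
    substrate: Substrate,
    protocol: Protocol,
    arrangement_id: int,
    direction: np.ndarray,
    n_spins: int = 10_000,
    n_steps: int = 1_000,
    seed: int = 0,
    init: str = "uniform",
) -> float:
    """Noise-free normalized signal for one arrangement and direction.

    ``arrangement_id`` is the index into ``protocol.arrangements``;
    ``direction`` is given in the laboratory frame.
    """
    a = protocol.arrangements[arrangement_id]
    if not a.is_weighted:
        return 1.0
    w, gamma, _ = run_walk(substrate, protocol, n_spins, n_steps, seed, init)
    row = protocol.weighted_indices.index(arrangement_id)
    rot = _rotation_to_axis_frame(substrate.axis)
    return signal_from_walk(w, gamma, row, rot @ np.asarray(direction, float))


def simulate_dataset(
    substrate: Substrate,
    protocol: Protocol,
    n_spins: int = 10_000,
    n_steps: int = 1_000,
    seed: int = 0,
    init: str = "uniform",
) -> np.ndarray:
    """Noise-free signals for every measurement of the protocol (b0 = 1)."""
    w, gamma, _ = run_walk(substrate, protocol, n_spins, n_steps, seed, init)
    rot = _rotation_to_axis_frame(substrate.axis)
    out = np.ones(protocol.n_measurements)
    pos = protocol.n_b0
    for row, i in enumerate(protocol.weighted_indices):
        dirs_local = protocol.directions[i] @ rot.T
        phases = gamma * np.einsum("dk,sk->sd", dirs_local, w[:, row, :])
        out[pos : pos + len(dirs_local)] = np.abs(np.mean(np.exp(1j * phases), axis=0))
        pos += len(dirs_local)
    return out


def add_rician_noise(signal, S0: float, snr: float, seed: int = 0) -> np.ndarray:
    """Rician noise at the given b = 0 SNR: v -> sqrt((v+n1)^2 + n2^2).

    n1, n2 are independent zero-mean Gaussians of s.d. S0/snr, the magnitude
    noise model of MRI.  Positively biased at low SNR.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    v = np.asarray(signal, dtype=float)
    sd = S0 / snr
    n1 = rng.normal(0.0, sd, v.shape)
    n2 = rng.normal(0.0, sd, v.shape)
    return np.sqrt((v + n1) ** 2 + n2**2)


def mc_standard_error(w, gamma, arr_row, direction_local, n_boot=200, seed=0):
    """Bootstrap (over spins) standard error of the magnitude signal."""
    rng = np.random.default_rng(seed)
    phase = gamma * (w[:, arr_row, :] @ np.asarray(direction_local))
    z = np.exp(1j * phase)
    n = len(z)
    stats = np.abs(
        np.mean(z[rng.integers(0, n, (n_boot, n))], axis=1)
    )
    return float(np.std(stats))


def generate_experiment(
    radii,
    n_orientations: int,
    protocol: Protocol,
    snr: float = 19.0,
    seed: int = 0,
    n_spins: int = 10_000,
    n_steps: int = 1_000,
    spacing_factor: float = 2.3,
    D: float = 1.7e-9,
):
    """Synthetic study: one noisy dataset per (radius, orientation).

    Orientations are spread over the sphere; each dataset records its
    generative parameters and derived seed in a manifest.  Returns a list of
    dicts with keys ``signals`` (noisy), ``clean``, and ``manifest``.
    """
    from .protocol import uniform_sphere_directions

    orientations = uniform_sphere_directions(
        n_orientations, seed=seed + 1, antipodal=False
    )
    ss = np.random.SeedSequence(seed)
    datasets = []
    for r_i, R in enumerate(radii):
        substrate = make_hex_substrate(R, spacing_factor, D)
        for o_i in range(n_orientations):
            sub = Substrate(
                centers=substrate.centers,
                radii=substrate.radii,
                cell=substrate.cell,
                axis=orientations[o_i],
                diffusivity=D,
            )
            child = int(
                np.random.SeedSequence([seed, r_i, o_i]).generate_state(1)[0]
                % (2**31)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clean = simulate_dataset(
                    sub, protocol, n_spins, n_steps, seed=child
                )
            noisy = add_rician_noise(clean, 1.0, snr, seed=child + 1)
            datasets.append(
                {
                    "signals": noisy,
                    "clean": clean,
                    "manifest": {
                        "radius_m": float(R),
                        "orientation": orientations[o_i].tolist(),
                        "spacing_factor": spacing_factor,
                        "diffusivity": D,
                        "snr": snr,
                        "n_spins": n_spins,
                        "n_steps": n_steps,
                        "seed": child,
                    },
                }
            )
    _ = ss
    return datasets
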