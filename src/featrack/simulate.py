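"""Self-propelled-rod (SPR) simulator and grow-divide colony fixture.

Generates ground-truthed synthetic feature tables that emulate dense
bacterial collectives.  Rods are stiff chains of evenly spaced, mutually
repulsive Yukawa point charges on a doubly periodic square domain, driven
along their axis by a constant propulsion force and integrated with the
overdamped midpoint (RK2) method:

    f_T . dr/dt  = -dU/dr + nu * u,        f_phi . dphi/dt = -dU/dphi,

with the translational friction tensor f_T = f0 (g_par u u^T +
g_perp (1 - u u^T)) and rotational friction f_phi built from standard
slender-rod (Tirado-type) friction factors.  Units are non-dimensional: one
rod width is the unit length, and the friction factors are normalized so an
isolated rod of the reference aspect ratio with nu = 1 travels one rod width
per unit time.

Aspect ratios are drawn from Gamma(shape 15.3, scale 0.248) and fluorescence
intensities from Normal(63.1, 8.83), matching distributions fitted to
experimental rod-shaped bacteria.  Observations add independent zero-mean
Gaussian measurement noise per feature, report orientation modulo pi
(nematic, as a segmenter would) and shuffle object ids each frame so a
tracker cannot exploit id continuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import yukawa_forces
from .features import CIRCULAR, LINEAR, FeatureSpec, FeatureTable
from .tracker import LINK_COLUMNS, LinkSet

SIM_FEATURE_NAMES = ("x", "y", "orientation", "length", "intensity")

#: reference aspect ratio for the time-unit normalization (gamma mean)
A_REF = 15.3 * 0.248


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the baseline parameter set."""

    A: float = 10_000.0          # domain area, rod-width^2
    f0: float = 1.0              # Stokesian friction coefficient
    n_rods: int = 700
    nu: float = 1.0              # self-propulsion force
    dT: float = 10.0             # sampling interval
    dt: float = 0.05             # integration step
    n_frames: int = 40
    burn_in: float = 50.0
    sigma_r: float = 0.02        # positional noise sd (per coordinate)
    sigma_phi: float = 0.02      # orientational noise sd, radians
    sigma_a: float = 0.1         # length noise sd
    sigma_I: float = 1.0         # intensity noise sd, A.U.
    gamma_shape: float = 15.3
    gamma_scale: float = 0.248
    norm_mean: float = 63.1
    norm_sd: float = 8.83
    U0: float = 1.0              # Yukawa prefactor
    lam: float = 1.0             # Yukawa screening length (rod widths)
    cutoff: float = 4.0          # interaction cutoff, in units of lam
    seed: int = 0

    def __post_init__(self):
        for name in ("A", "f0", "nu", "dT", "dt", "U0", "lam", "cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dt > self.dT:
            raise ValueError("integration step dt must not exceed dT")

    @property
    def side(self) -> float:
        return math.sqrt(self.A)


@dataclass
class RodState:
    """Instantaneous state of the rod collection."""

    r: np.ndarray      # (n, 2) positions
    phi: np.ndarray    # (n,) polar orientations, radians
    a: np.ndarray      # (n,) aspect ratios (>= 1)
    I: np.ndarray      # (n,) fluorescence intensities

    def copy(self) -> "RodState":
        return RodState(self.r.copy(), self.phi.copy(), self.a.copy(), self.I.copy())

    @property
    def n(self) -> int:
        return len(self.phi)

    @property
    def u(self) -> np.ndarray:
        return np.column_stack([np.cos(self.phi), np.sin(self.phi)])


@dataclass
class GroundTruthDataset:
    """Noisy observations plus the exact identity links (and lineage)."""

    frames: list
    gt_links: LinkSet
    spec: FeatureSpec
    config: object
    gt_lineage: object | None = None


# ---------------------------------------------------------------------------
# initial conditions and bookkeeping
# ---------------------------------------------------------------------------

def sample_rod_properties(config: SimConfig, count: int, rng: np.random.Generator):
    """Draw aspect ratios (gamma, clipped >= 1) and intensities (normal)."""
    a = rng.gamma(config.gamma_shape, config.gamma_scale, size=count)
    a = np.maximum(a, 1.0)
    intensity = rng.normal(config.norm_mean, config.norm_sd, size=count)
    return a, intensity


def packing_fraction(state: RodState, A: float) -> float:
    """Fraction of the domain covered: (1/A) sum[(a_i - 1) + pi/4]."""
    return float(np.sum((state.a - 1.0) + math.pi / 4) / A)


def lattice_state(config: SimConfig, rng: np.random.Generator) -> RodState:
    """Rods on a square lattice with random orientations."""
    n = config.n_rods
    a, intensity = sample_rod_properties(config, n, rng)
    cols = math.ceil(math.sqrt(n))
    pitch = config.side / cols
    idx = np.arange(n)
    r = np.column_stack([(idx % cols + 0.5) * pitch,
                         (idx // cols + 0.5) * pitch])
    phi = rng.uniform(0, 2 * math.pi, size=n)
    return RodState(r, phi, a, intensity)


# ---------------------------------------------------------------------------
# forces and friction
# ---------------------------------------------------------------------------

def _segments(state: RodState):
    """Flat arrays of segment positions/offsets for the force kernel.

    Rod i carries n_seg = max(2, ceil(a_i)) charges evenly spaced along its
    axis, spanning the rod length minus one width (so end charges sit half a
    width inside the tips).
    """
    nseg = np.maximum(2, np.ceil(state.a).astype(np.int64))
    total = int(nseg.sum())
    seg_rod = np.repeat(np.arange(state.n, dtype=np.int64), nseg)
    seg_s = np.empty(total)
    pos = 0
    for i in range(state.n):
        k = nseg[i]
        half = (state.a[i] - 1.0) / 2.0
        seg_s[pos:pos + k] = np.linspace(-half, half, k)
        pos += k
    u = state.u
    seg_x = state.r[seg_rod, 0] + seg_s * u[seg_rod, 0]
    seg_y = state.r[seg_rod, 1] + seg_s * u[seg_rod, 1]
    return seg_x, seg_y, seg_rod, seg_s


def pair_forces(state: RodState, config: SimConfig):
    """Per-rod forces and torques from all segment-pair Yukawa repulsions.

    Returns ``(forces, torques, potential)``; the potential is the total
    pair energy, used by energy diagnostics and gradient tests.
    """
    seg_x, seg_y, seg_rod, seg_s = _segments(state)
    u = state.u
    fx, fy, tau, pot = yukawa_forces(
        seg_x % config.side, seg_y % config.side, seg_rod, seg_s,
        np.ascontiguousarray(u[:, 0]), np.ascontiguousarray(u[:, 1]),
        state.n, config.side, config.U0, config.lam,
        config.cutoff * config.lam)
    return np.column_stack([fx, fy]), tau, float(pot)


def potential_energy(state: RodState, config: SimConfig) -> float:
    return pair_forces(state, config)[2]


def _tirado(a: np.ndarray):
    """Slender-rod friction factors (parallel, perpendicular, rotational)."""
    a = np.maximum(a, 1.0)
    ln = np.log(a)
    g_par = 2 * math.pi * a / (ln - 0.207 + 0.980 / a - 0.133 / a ** 2)
    g_perp = 4 * math.pi * a / (ln + 0.839 + 0.185 / a + 0.233 / a ** 2)
    g_rot = math.pi * a ** 3 / (3 * (ln - 0.662 + 0.917 / a - 0.050 / a ** 2))
    return g_par, g_perp, g_rot


_F_PAR_REF = float(_tirado(np.array([A_REF]))[0][0])


def friction_factors(a: np.ndarray, f0: float = 1.0):
    """Friction factors normalized to the package's time-unit convention.

    Scaled so an isolated rod with the reference aspect ratio and nu = 1,
    f0 = 1 translates exactly one rod width per unit time.
    """
    g_par, g_perp, g_rot = _tirado(np.asarray(a, dtype=float))
    return (f0 * g_par / _F_PAR_REF, f0 * g_perp / _F_PAR_REF,
            f0 * g_rot / _F_PAR_REF)


def _rhs(state: RodState, config: SimConfig):
    """Overdamped velocities (dr/dt, dphi/dt)."""
    F, tau, _ = pair_forces(state, config)
    u = state.u
    g = F + config.nu * u
    f_par, f_perp, f_rot = friction_factors(state.a, config.f0)
    g_par = (g * u).sum(axis=1)
    v = (g_par / f_par)[:, None] * u + ((g - g_par[:, None] * u) / f_perp[:, None])
    return v, tau / f_rot


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

MAX_STEP_DISPLACEMENT = 0.25  # rod widths; larger steps are auto-halved
_MIN_DT_FACTOR = 64


def _midpoint_step(state: RodState, config: SimConfig, dt: float) -> RodState:
    v1, w1 = _rhs(state, config)
    mid = RodState(state.r + 0.5 * dt * v1, state.phi + 0.5 * dt * w1,
                   state.a, state.I)
    v2, w2 = _rhs(mid, config)
    new = RodState((state.r + dt * v2) % config.side,
                   state.phi + dt * w2, state.a, state.I)
    if not (np.all(np.isfinite(new.r)) and np.all(np.isfinite(new.phi))):
        raise FloatingPointError("simulation diverged: non-finite state")
    disp = np.abs(dt * v2).max() if len(v2) else 0.0
    if disp > MAX_STEP_DISPLACEMENT and dt > config.dt / _MIN_DT_FACTOR:
        half = _midpoint_step(state, config, dt / 2)
        return _midpoint_step(half, config, dt / 2)
    return new


def integrate(state: RodState, config: SimConfig, duration: float) -> RodState:
    """Advance the state by ``duration`` time units in steps of ``dt``.

    Runs entirely inside a compiled kernel; each step applies the same
    midpoint update and auto-halving rule as :func:`step`.
    """
    from ._kernels import integrate_steps

    n_steps = int(round(duration / config.dt))
    if n_steps == 0:
        return state
    _, _, seg_rod, seg_s = _segments(state)
    f_par, f_perp, f_rot = friction_factors(state.a, config.f0)
    r = state.r.copy()
    phi = state.phi.copy()
    ok = integrate_steps(r, phi, seg_rod, seg_s, f_par, f_perp, f_rot,
                         config.nu, config.side, config.U0, config.lam,
                         config.cutoff * config.lam, config.dt, n_steps,
                         MAX_STEP_DISPLACEMENT, _MIN_DT_FACTOR)
    if not ok:
        raise FloatingPointError("simulation diverged: non-finite state")
    return RodState(r, phi, state.a, state.I)


def step(state: RodState, config: SimConfig, dt: float | None = None) -> RodState:
    """One midpoint step (exposed for convergence and physics tests)."""
    return _midpoint_step(state, config, config.dt if dt is None else dt)


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def sim_feature_spec(config) -> FeatureSpec:
    side = config.side if hasattr(config, "side") else math.sqrt(config.A)
    return FeatureSpec(
        names=SIM_FEATURE_NAMES,
        kinds=(LINEAR, LINEAR, CIRCULAR, LINEAR, LINEAR),
        circular_period=(None, None, math.pi, None, None),
        units=("rod widths", "rod widths", "radians", "rod widths", "A.U."),
        domain_size=(side, side),
        periodic=True,
    )


def observe(state: RodState, config, frame: int, rng: np.random.Generator,
            ids: np.ndarray | None = None) -> FeatureTable:
    """Noisy measurement of one frame.

    Adds independent zero-mean Gaussian noise (sd sigma_r per coordinate,
    sigma_phi, sigma_a, sigma_I), re-wraps positions into the domain and
    reports orientation modulo pi — the nematic ambiguity a segmenter of
    rod-shaped cells produces.  ``ids`` gives the observed id of each rod
    (callers shuffle them per frame).
    """
    n = state.n
    side = config.side if hasattr(config, "side") else math.sqrt(config.A)
    x = (state.r[:, 0] + rng.normal(0, config.sigma_r, n)) % side
    y = (state.r[:, 1] + rng.normal(0, config.sigma_r, n)) % side
    phi = (state.phi + rng.normal(0, config.sigma_phi, n)) % math.pi
    a = state.a + rng.normal(0, config.sigma_a, n)
    intensity = state.I + rng.normal(0, config.sigma_I, n)
    if ids is None:
        ids = np.arange(n)
    X = np.column_stack([x, y, phi, a, intensity])
    order = np.argsort(ids)
    return FeatureTable(frame, ids[order], X[order])


def _gt_links_frame(frame: int, ids_t: np.ndarray, ids_t1: np.ndarray):
    import pandas as pd

    return pd.DataFrame({
        "frame_from": frame, "id_from": ids_t,
        "frame_to": frame + 1, "id_to": ids_t1,
        "score": 0.0, "kind": "primary",
    })


def simulate(config: SimConfig) -> GroundTruthDataset:
    """Burn in from a lattice, then sample noisy frames plus true links."""
    rng = np.random.default_rng(config.seed)
    state = lattice_state(config, rng)
    rho = packing_fraction(state, config.A)
    if rho > 0.9:
        raise ValueError(f"packing fraction {rho:.2f} > 0.9: unphysical jamming")
    state = integrate(state, config, config.burn_in)

    frames = []
    links = []
    prev_ids = None
    for f in range(config.n_frames):
        if f > 0:
            state = integrate(state, config, config.dT)
        ids = rng.permutation(state.n)
        frames.append(observe(state, config, f, rng, ids))
        if prev_ids is not None:
            links.append(_gt_links_frame(f - 1, prev_ids, ids))
        prev_ids = ids
    import pandas as pd

    gt = LinkSet(pd.concat(links, ignore_index=True)) if links else LinkSet.empty()
    return GroundTruthDataset(frames, gt, sim_feature_spec(config), config)


# ---------------------------------------------------------------------------
# grow-divide fixture
# ---------------------------------------------------------------------------

@dataclass
class GrowDivideConfig:
    """Non-motile elongating/dividing colony used to test lineage recovery."""

    n_founders: int = 1
    A: float = 10_000.0
    f0: float = 1.0
    nu: float = 0.0
    growth_rate: float = 0.1     # per unit time; da/dt = g*a
    a0: float = 2.5              # founder aspect ratio
    a_div: float = 5.0           # division length
    division_gap: float = 0.3    # septum gap between daughters
    jitter_pos: float = 0.02     # placement jitter of daughter centroids
    jitter_phi: float = 0.02     # placement jitter of daughter orientations
    intensity_cv: float = 0.02   # multiplicative intensity inheritance noise
    dT: float = 1.0
    dt: float = 0.05
    n_frames: int = 24
    sigma_r: float = 0.02
    sigma_phi: float = 0.02
    sigma_a: float = 0.1
    sigma_I: float = 1.0
    norm_mean: float = 63.1
    norm_sd: float = 8.83
    U0: float = 1.0
    lam: float = 1.0
    cutoff: float = 4.0
    seed: int = 0

    @property
    def side(self) -> float:
        return math.sqrt(self.A)


def grow_divide_fixture(config: GrowDivideConfig) -> GroundTruthDataset:
    """Grow a colony of non-motile rods; record true links and parentage.

    Cells elongate exponentially and divide at a >= a_div into two
    end-to-end daughters of length (a - gap)/2; the first daughter inherits
    the mother's identity (the mother continues as one daughter), the second
    gets a fresh id with the parentage recorded at the first frame on which
    it is observed.  Steric overlap from growth is relaxed by the same
    Yukawa force machinery as the motility model.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    side = config.side
    n0 = config.n_founders
    spacing = side / max(1, math.ceil(math.sqrt(n0)))
    cols = max(1, math.ceil(math.sqrt(n0)))
    r = np.column_stack([(np.arange(n0) % cols + 0.5) * spacing,
                         (np.arange(n0) // cols + 0.5) * spacing])
    phi = rng.uniform(0, math.pi, n0)
    a = np.full(n0, config.a0, dtype=float)
    intensity = rng.normal(config.norm_mean, config.norm_sd, n0)
    cell_ids = list(range(n0))
    next_id = n0
    state = RodState(r, phi, a, intensity)
    sim_cfg = SimConfig(A=config.A, f0=config.f0, nu=0.0, dT=config.dT,
                        dt=config.dt, n_frames=config.n_frames,
                        U0=config.U0, lam=config.lam, cutoff=config.cutoff,
                        sigma_r=config.sigma_r, sigma_phi=config.sigma_phi,
                        sigma_a=config.sigma_a, sigma_I=config.sigma_I)

    lineage_rows = []   # (child_cell, mother_cell, frame, child_obs, parent_obs)
    pending = []        # divisions awaiting this frame's observed ids
    frames = []
    links = []
    prev_ids_by_cell = None

    def divide(next_frame: int):
        nonlocal state, cell_ids, next_id
        while True:
            ripe = np.nonzero(state.a >= config.a_div)[0]
            if len(ripe) == 0:
                return
            i = int(ripe[0])
            a_m = state.a[i]
            ld = (a_m - config.division_gap) / 2.0
            off = (a_m + config.division_gap) / 4.0
            u = np.array([math.cos(state.phi[i]), math.sin(state.phi[i])])
            jit = lambda: rng.normal(0, config.jitter_pos, 2)
            r1 = (state.r[i] + off * u + jit()) % side
            r2 = (state.r[i] - off * u + jit()) % side
            p1 = state.phi[i] + rng.normal(0, config.jitter_phi)
            p2 = state.phi[i] + rng.normal(0, config.jitter_phi)
            i1 = state.I[i] * (1 + rng.normal(0, config.intensity_cv))
            i2 = state.I[i] * (1 + rng.normal(0, config.intensity_cv))
            state.r = np.vstack([np.delete(state.r, i, axis=0), r1[None], r2[None]])
            state.phi = np.append(np.delete(state.phi, i), [p1, p2])
            state.a = np.append(np.delete(state.a, i), [ld, ld])
            state.I = np.append(np.delete(state.I, i), [i1, i2])
            mother = cell_ids[i]
            child = next_id
            next_id += 1
            cell_ids = cell_ids[:i] + cell_ids[i + 1:] + [mother, child]
            pending.append((child, mother, next_frame))

    for f in range(config.n_frames):
        if f > 0:
            n_steps = int(round(config.dT / config.dt))
            growth = math.exp(config.growth_rate * config.dt)
            for _ in range(n_steps):
                state.a = state.a * growth
                state = _midpoint_step(state, sim_cfg, config.dt)
            divide(f)
        obs_ids = rng.permutation(len(cell_ids))
        frames.append(observe(state, sim_cfg, f, rng, ids=obs_ids))
        obs_of_cell = {cid: int(obs_ids[k]) for k, cid in enumerate(cell_ids)}
        for child, mother, df_frame in pending:
            lineage_rows.append((child, mother, df_frame,
                                 obs_of_cell[child],
                                 prev_ids_by_cell[mother] if prev_ids_by_cell else -1))
        pending = []
        if prev_ids_by_cell is not None:
            common = [c for c in prev_ids_by_cell if c in obs_of_cell]
            links.append(pd.DataFrame({
                "frame_from": f - 1,
                "id_from": [prev_ids_by_cell[c] for c in common],
                "frame_to": f,
                "id_to": [obs_of_cell[c] for c in common],
                "score": 0.0, "kind": "primary",
            }))
        prev_ids_by_cell = obs_of_cell

    gt_links = LinkSet(pd.concat(links, ignore_index=True)) if links else LinkSet.empty()
    lineage = pd.DataFrame(lineage_rows, columns=["child_cell", "parent_cell",
                                                  "division_frame",
                                                  "child_obs_id", "parent_obs_id"])
    return GroundTruthDataset(frames, gt_links, sim_feature_spec(config),
                              config, gt_lineage=lineage)
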