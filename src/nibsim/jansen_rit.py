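"""Jansen-Rit whole-brain network simulation with lambda*E stimulation coupling.

Each node is a Jansen-Rit neural mass: three interacting populations
(pyramidal cells, excitatory and inhibitory interneurons) whose
post-synaptic potentials follow second-order synaptic kinetics, closed by
the sigmoidal potential-to-rate function

    S(v) = 2 e0 / (1 + exp(r (v0 - v))).

With PSP states y0 (excitatory feedback on interneurons), y1 (excitatory
PSP on pyramidal cells), y2 (inhibitory PSP on pyramidal cells) and their
rates y3..y5, the node equations are

    dy0 = y3;  dy3 = A a S(v_p + s)            - 2 a y3 - a^2 y0
    dy1 = y4;  dy4 = A a (p + u + C2 S(C1 y0)) - 2 a y4 - a^2 y1
    dy2 = y5;  dy5 = B b C4 S(C3 y0)           - 2 b y5 - b^2 y2

where v_p = y1 - y2 is the pyramidal membrane potential (the EEG-generating
signal), p the background input rate, u the network input (delayed
long-range coupling G * sum_j w_ij S(v_p,j(t - tau_ij)) plus, in surface
mode, an undelayed Gaussian local-kernel term), and s the stimulation term.

Stimulation couples through the lambda*E model: the field component along
the cortical normal, scaled by the effective membrane space constant
(1 V/m x 1 mm = 1 mV), perturbs the pyramidal membrane potential — s is
added inside every sigmoid argument that takes v_p, both locally and in the
transmitted rate.  Interneuron coupling is omitted by default (their field
sensitivity is much weaker); an input-current entry mode is kept behind a
flag for sensitivity checks.

Integration is a stochastic Heun (predictor-corrector trapezoidal) scheme
with additive noise on the excitatory rate state y4, seeded and
reproducible; delays are handled with per-pair ring buffers of transmitted
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse as sp

from .phantom import Connectome, CorticalMesh

__all__ = ["JRParams", "NetworkModel", "StimulusDrive", "SimOutput",
           "sigmoid", "build_network", "simulate", "make_drive",
           "fixed_point", "DEFAULT_PARAMS"]


@dataclass(frozen=True)
class JRParams:
    """Jansen-Rit and network parameters.

    Synaptic gains A, B are in mV; rate constants a, b in 1/s; C1..C4 are
    dimensionless connectivity constants; v0 (mV), e0 (1/s) and r (1/mV)
    shape the sigmoid.  ``mean_input`` is the background pyramidal input
    rate p (1/s); the default 260 lies in the upper part of the model's
    physiological 120-320 pulse range, where both a single node and the
    G-coupled network express alpha-band (8-12 Hz) rhythms — below ~140
    the model instead falls into a large-amplitude ~3 Hz spike cycle, and
    below ~90 it rests at a stable equilibrium.  ``G`` scales long-range
    coupling,
    ``noise_sigma`` is the additive-noise intensity on the excitatory rate
    state, ``conduction_speed`` (mm/ms) sets axonal delays, and
    ``lambda_mm`` is the effective membrane space constant of the
    stimulation coupling (a placeholder magnitude: quantitative use
    requires tuning it against measured data).
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    C1: float = 135.0
    C2: float = 0.8 * 135.0
    C3: float = 0.25 * 135.0
    C4: float = 0.25 * 135.0
    v0: float = 5.52
    e0: float = 2.5
    r: float = 0.56
    mean_input: float = 260.0
    G: float = 7.0
    noise_sigma: float = 1e-7
    conduction_speed: float = 3.0      # mm/ms
    local_width_mm: float = 10.0
    local_amplitude: float = 1.0
    local_cutoff_mm: float = 20.0
    lambda_mm: float = 1.0

    def __post_init__(self):
        for name in ("A", "B", "a", "b", "C1", "C2", "C3", "C4", "e0", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")


DEFAULT_PARAMS = JRParams()


def sigmoid(v, params: JRParams = DEFAULT_PARAMS):
    """Population potential-to-rate sigmoid S(v), 1/s; S(v0) = e0."""
    return 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.v0 - np.asarray(v, float))))


@dataclass
class NetworkModel:
    """Node geometry plus long-range (delayed) and local coupling."""

    positions: np.ndarray          # (n, 3) mm
    normals: np.ndarray | None     # (n, 3) unit, surface mode
    mode: str                      # "region" | "surface"
    weights: np.ndarray            # (R, R) long-range, zero diagonal
    delay_s: np.ndarray            # (R, R) seconds, region granularity
    region_of_node: np.ndarray     # (n,) region index
    local: sp.csr_matrix | None = None  # (n, n) Gaussian kernel, surface mode

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_regions(self) -> int:
        return len(self.weights)

    def delay_steps(self, dt: float) -> np.ndarray:
        """Integer delay steps tau_ij = round(length / speed / dt)."""
        return np.round(self.delay_s / dt).astype(int)


@dataclass
class StimulusDrive:
    """Per-node stimulation amplitudes (mV) with a temporal waveform.

    ``amplitudes`` are lambda * (E . n); the waveform is a sinusoid, DC or
    envelope-modulated sinusoid gated by an on/off window in seconds.
    """

    amplitudes: np.ndarray
    freq_Hz: float = 0.0
    window_s: tuple[float, float] = (0.0, np.inf)
    shape: str = "sinusoid"          # sinusoid | dc | envelope
    envelope_Hz: float = 0.0

    def waveform(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        gate = (t >= self.window_s[0]) & (t < self.window_s[1])
        if self.shape == "dc":
            w = np.ones_like(t)
        elif self.shape == "sinusoid":
            w = np.sin(2 * np.pi * self.freq_Hz * t)
        elif self.shape == "envelope":
            w = np.sin(np.pi * self.envelope_Hz * t) ** 2 \
                * np.sin(2 * np.pi * self.freq_Hz * t)
        else:
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        return np.where(gate, w, 0.0)


@dataclass
class SimOutput:
    """Pyramidal potential traces after burn-in removal."""

    time: np.ndarray           # (T,) seconds
    v_pyr: np.ndarray          # (n_nodes, T) mV
    dt: float
    seed: int
    burn_in_s: float
    params: JRParams
    meta: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


# ---------------------------------------------------------------------------
# Network construction


def _gaussian_local_kernel(mesh: CorticalMesh, params: JRParams) -> sp.csr_matrix:
    """Gaussian local-connectivity kernel on the cortical surface.

    Distances are geodesic (great-circle arcs for the spherical cortex);
    weights are amplitude * exp(-d^2 / (2 width^2)) up to the cutoff, with
    no self-coupling.
    """
    v = mesh.vertices
    r = np.linalg.norm(v, axis=1).mean()
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    cosang = np.clip(u @ u.T, -1.0, 1.0)
    d = r * np.arccos(cosang)
    w = params.local_amplitude * np.exp(-d**2 / (2 * params.local_width_mm**2))
    w[d > params.local_cutoff_mm] = 0.0
    np.fill_diagonal(w, 0.0)
    return sp.csr_matrix(w)


def build_network(source: Connectome | CorticalMesh, params: JRParams = DEFAULT_PARAMS,
                  mode: str | None = None,
                  connectome: Connectome | None = None) -> NetworkModel:
    """Assemble a region- or surface-based network model.

    Region mode (from a :class:`Connectome`): one node per region at its
    centroid, long-range weights and distance-based delays from the
    connectome.  Surface mode (from a :class:`CorticalMesh`, plus a
    connectome for the long-range part): one node per mesh vertex, a
    Gaussian local kernel, and region-granular long-range coupling mapped
    to member vertices.
    """
    if mode is None:
        mode = "region" if isinstance(source, Connectome) else "surface"
    speed_mm_s = params.conduction_speed * 1e3
    if mode == "region":
        con = source if isinstance(source, Connectome) else connectome
        if con is None:
            raise ValueError("region mode needs a connectome")
        return NetworkModel(
            positions=con.centroids.copy(), normals=None, mode="region",
            weights=con.weights.copy(), delay_s=con.lengths / speed_mm_s,
            region_of_node=np.arange(con.n_regions), local=None)
    if mode != "surface":
        raise ValueError(f"unknown mode {mode!r}")
    mesh = source
    if not isinstance(mesh, CorticalMesh) or connectome is None:
        raise ValueError("surface mode needs a CorticalMesh and a connectome")
    occupied = np.unique(mesh.region_of_vertex)
    if occupied.max() >= connectome.n_regions:
        raise ValueError("mesh regions exceed connectome regions")
    return NetworkModel(
        positions=mesh.vertices.copy(), normals=mesh.normals.copy(),
        mode="surface", weights=connectome.weights.copy(),
        delay_s=connectome.lengths / speed_mm_s,
        region_of_node=mesh.region_of_vertex.copy(),
        local=_gaussian_local_kernel(mesh, params))


# ---------------------------------------------------------------------------
# Stimulus construction


def make_drive(efield: np.ndarray, spacing_mm, origin_mm, mesh: CorticalMesh,
               lambda_mm: float, freq_Hz: float = 0.0,
               window_s: tuple[float, float] = (0.0, np.inf),
               shape: str = "sinusoid") -> StimulusDrive:
    """lambda*E stimulus amplitudes at mesh vertices.

    ``efield`` is a (3, nx, ny, nz) V/m volume (e.g. a basis pair field at
    the intended current); the amplitude at vertex i is
    ``lambda_mm * (E(r_i) . n_i)`` in mV (1 V/m x 1 mm = 1 mV).
    """
    from .em import sample_field
    Ev = sample_field(efield, np.asarray(spacing_mm, float),
                      np.asarray(origin_mm, float), mesh.vertices)
    amp = lambda_mm * np.einsum("ij,ij->i", Ev, mesh.normals)
    return StimulusDrive(amplitudes=amp, freq_Hz=freq_Hz, window_s=window_s,
                         shape=shape)


def region_average_drive(drive: StimulusDrive, region_of_vertex: np.ndarray,
                         n_regions: int) -> StimulusDrive:
    """Aggregate a vertex-level drive to region level (mean amplitude)."""
    sums = np.bincount(region_of_vertex, weights=drive.amplitudes,
                       minlength=n_regions)
    cnt = np.bincount(region_of_vertex, minlength=n_regions)
    amp = np.where(cnt > 0, sums / np.maximum(cnt, 1), 0.0)
    return replace(drive, amplitudes=amp)


# ---------------------------------------------------------------------------
# Fixed point (for oracle tests and diagnostics)


def fixed_point(params: JRParams, input_rate: float | None = None,
                which: str = "stable") -> np.ndarray:
    """Equilibrium of the uncoupled, noise-free, unstimulated node.

    The stationary equations reduce to a scalar root problem in the
    pyramidal potential v = y1 - y2:
    y0 = (A/a) S(v), y1 = (A/a)(p + C2 S(C1 y0)), y2 = (B/b) C4 S(C3 y0).
    The node can have up to three equilibria; ``which="stable"`` returns the
    most stable one (smallest leading Jacobian real part — for mid-range
    inputs, where no linearly stable equilibrium exists and the attractor
    is the alpha-band limit cycle, this is the weakly unstable focus the
    cycle surrounds), ``"all"`` returns every root as an array of states.
    """
    from scipy.optimize import brentq

    p = params.mean_input if input_rate is None else input_rate
    Aa_r = params.A / params.a
    Bb_r = params.B / params.b

    def v_residual(v):
        y0 = Aa_r * float(sigmoid(v, params))
        y1 = Aa_r * (p + params.C2 * float(sigmoid(params.C1 * y0, params)))
        y2 = Bb_r * params.C4 * float(sigmoid(params.C3 * y0, params))
        return (y1 - y2) - v

    def state(v):
        y0 = Aa_r * float(sigmoid(v, params))
        y1 = Aa_r * (p + params.C2 * float(sigmoid(params.C1 * y0, params)))
        y2 = y1 - v
        return np.array([y0, y1, y2, 0.0, 0.0, 0.0])

    grid = np.linspace(-30.0, 60.0, 18001)
    resid = np.array([v_residual(v) for v in grid])
    sign = np.sign(resid)
    roots = [brentq(v_residual, grid[i], grid[i + 1], xtol=1e-13)
             for i in np.flatnonzero(sign[:-1] != sign[1:])]
    if not roots:
        raise RuntimeError("no equilibrium found in the scanned range")
    states = [state(v) for v in roots]
    if which == "all":
        return np.array(states)
    lead = [np.max(np.linalg.eigvals(_jacobian(params, s, p)).real) for s in states]
    return states[int(np.argmin(lead))]


def _jacobian(params: JRParams, y: np.ndarray, p: float) -> np.ndarray:
    """Jacobian of the single-node drift at a state (stability analysis)."""
    A, a, B, b = params.A, params.a, params.B, params.b

    def dS(v):
        s = float(sigmoid(v, params))
        return params.r * s * (1.0 - s / (2.0 * params.e0))

    y0, y1, y2 = y[:3]
    J = np.zeros((6, 6))
    J[0, 3] = J[1, 4] = J[2, 5] = 1.0
    g = A * a * dS(y1 - y2)
    J[3, 0] = -a * a; J[3, 1] = g; J[3, 2] = -g; J[3, 3] = -2 * a
    J[4, 0] = A * a * params.C2 * params.C1 * dS(params.C1 * y0)
    J[4, 1] = -a * a; J[4, 4] = -2 * a
    J[5, 0] = B * b * params.C4 * params.C3 * dS(params.C3 * y0)
    J[5, 2] = -b * b; J[5, 5] = -2 * b
    return J


# ---------------------------------------------------------------------------
# Simulation


def simulate(
    network: NetworkModel,
    params: JRParams = DEFAULT_PARAMS,
    drive: StimulusDrive | None = None,
    duration_s: float = 30.0,
    dt: float = 5e-4,
    seed: int = 0,
    burn_in_s: float = 1.0,
    stim_mode: str = "sigmoid",
    couple_rate: bool = True,
    initial_state: np.ndarray | None = None,
) -> SimOutput:
    """Integrate the network with stochastic Heun; returns post-burn-in v_pyr.

    ``stim_mode="sigmoid"`` perturbs the pyramidal membrane potential inside
    every sigmoid (the lambda*E entry point); ``"current"`` adds the drive as
    an input-current term instead (sensitivity checks).  ``couple_rate``
    transmits S(v_pyr) over long-range connections (flag kept for the raw
    v_pyr alternative).
    """
    if dt > 1e-3:
        raise ValueError("dt must be <= 1 ms")
    if duration_s <= burn_in_s:
        raise ValueError("duration must exceed the burn-in")
    if stim_mode not in ("sigmoid", "current"):
        raise ValueError(f"unknown stim_mode {stim_mode!r}")
    n = network.n_nodes
    nreg = network.n_regions
    rng = np.random.default_rng(seed)
    A, a, B, b = params.A, params.a, params.B, params.b
    Aa, Bb = A * a, B * b

    tau = network.delay_steps(dt)          # (R, R)
    buflen = int(tau.max()) + 2
    n_steps = int(round(duration_s / dt))
    if buflen > n_steps:
        raise ValueError("delays exceed the simulation length")

    amp = np.zeros(n)
    wave = np.zeros(n_steps + 1)
    if drive is not None:
        if len(drive.amplitudes) != n:
            raise ValueError(
                f"drive has {len(drive.amplitudes)} amplitudes for {n} nodes")
        if not np.all(np.isfinite(drive.amplitudes)):
            raise ValueError("drive amplitudes must be finite")
        amp = np.asarray(drive.amplitudes, float)
        wave = drive.waveform(np.arange(n_steps + 1) * dt)

    reg = network.region_of_node
    cnt = np.maximum(np.bincount(reg, minlength=nreg), 1)
    W = params.G * network.weights          # (R, R)
    local = network.local

    # ring buffer of region-level transmitted rates
    if initial_state is not None:
        y = np.array(initial_state, float).reshape(6, n).copy()
    else:
        y = np.zeros((6, n))
        y[:3] = fixed_point(params, params.mean_input)[:3, None]
    v0_pyr = y[1] - y[2]
    s0 = sigmoid(v0_pyr, params) if couple_rate else v0_pyr
    reg_rate0 = np.bincount(reg, weights=s0, minlength=nreg) / cnt
    buf = np.tile(reg_rate0[:, None], (1, buflen))

    # gather indices: for row i, delayed rate of region j at t - tau[i, j]
    jj = np.broadcast_to(np.arange(nreg), (nreg, nreg))

    burn_steps = int(round(burn_in_s / dt))
    n_keep = n_steps - burn_steps
    out = np.empty((n, n_keep))
    sq = np.sqrt(2.0 * params.noise_sigma * dt)

    def drift(y, s_stim, u_net):
        v_p = y[1] - y[2] + s_stim
        S_p = sigmoid(v_p, params)
        S_e = sigmoid(params.C1 * y[0], params)
        S_i = sigmoid(params.C3 * y[0], params)
        d = np.empty_like(y)
        d[0] = y[3]
        d[1] = y[4]
        d[2] = y[5]
        d[3] = Aa * S_p - 2 * a * y[3] - a * a * y[0]
        d[4] = Aa * (params.mean_input + u_net + params.C2 * S_e) \
            - 2 * a * y[4] - a * a * y[1]
        d[5] = Bb * params.C4 * S_i - 2 * b * y[5] - b * b * y[2]
        return d

    for t in range(n_steps):
        pos = np.mod(t - tau, buflen)
        delayed = buf[jj, pos]                       # (R, R)
        u_reg = np.einsum("ij,ij->i", W, delayed)    # (R,)
        u = u_reg[reg]
        s_now = amp * wave[t]
        s_next = amp * wave[t + 1]
        if local is not None:
            vloc = y[1] - y[2] + (s_now if stim_mode == "sigmoid" else 0.0)
            u = u + local @ sigmoid(vloc, params)
        if stim_mode == "current":
            u = u + amp * wave[t]

        noise = np.zeros((6, n))
        noise[4] = sq * rng.standard_normal(n)

        s_arg_now = s_now if stim_mode == "sigmoid" else 0.0
        s_arg_next = s_next if stim_mode == "sigmoid" else 0.0
        d1 = drift(y, s_arg_now, u)
        y_pred = y + dt * d1 + noise
        d2 = drift(y_pred, s_arg_next, u)
        y = y + 0.5 * dt * (d1 + d2) + noise

        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"non-finite state at step {t} (t = {t * dt:.4f} s)")

        v_p = y[1] - y[2]
        sig_arg = v_p + (s_next if stim_mode == "sigmoid" else 0.0)
        tx = sigmoid(sig_arg, params) if couple_rate else sig_arg
        buf[:, (t + 1) % buflen] = np.bincount(reg, weights=tx, minlength=nreg) / cnt

        if t >= burn_steps:
            out[:, t - burn_steps] = v_p

    time = (burn_steps + 1 + np.arange(n_keep)) * dt
    return SimOutput(time=time, v_pyr=out, dt=dt, seed=seed, burn_in_s=burn_in_s,
                     params=params, meta={"mode": network.mode,
                                          "stim_mode": stim_mode,
                                          "duration_s": duration_s})
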