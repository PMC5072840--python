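"""ODE dynamics of an inferred regulatory network.

Each node i contributes two state variables,

    dm_i/dt = s_i(p_j, ...) - delta_i * m_i
    dp_i/dt = lam_i * (m_i - p_i)

where s_i is the node's fitted regulation function evaluated on the
protein levels of its inputs (other nodes, itself, or declared external
drivers such as a cyclin).  mRNA degradation rates delta_i are constant;
the steady-state-consistent initialization is delta_i = <s_i>/<m_i>.

External drivers are supplied as measured series turned into protein
signals; beyond the end of the measurement the policy decides whether the
drive drops to zero, holds its time average, or holds the last value.
Knockouts clamp both m and p of the named genes to zero, so direct and
indirect effects propagate through the network.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .dataio import GeneTimeSeries, Kind, TimeSeriesSet
from .grf_models import GRFSpec, N_MAX, N_MIN, evaluate, grf_gradient
from .network_inference import NetworkModel
from .protein_proxy import Propagator

__all__ = ["AfterEnd", "ExternalInputPolicy", "ODESystem", "SimulationResult",
           "assemble_ode", "simulate", "knockout", "global_refit",
           "RefitConfig", "initialize_delta", "initial_state_from_data",
           "dominant_period", "classify_oscillation"]


class AfterEnd(str, enum.Enum):
    zero = "zero"
    constant_average = "constant_average"
    hold_last = "hold_last"


@dataclass(frozen=True)
class ExternalInputPolicy:
    """Protein drive for one external species.

    ``series`` is the measured trace on the measurement grid; mRNA-level
    series are filtered into a protein proxy with rate ``lam`` first,
    protein_proxy series are used directly.  ``after_end`` governs the
    signal beyond the last measured time.
    """

    series: GeneTimeSeries
    after_end: AfterEnd = AfterEnd.constant_average
    lam: float = math.log(2) / 15.0

    def protein_function(self):
        if self.series.kind == Kind.mrna_level:
            trace = Propagator(self.series, lam_min=self.lam)(self.lam)
        else:
            trace = self.series
        t = trace.grid.times
        spline = CubicSpline(t, trace.values, bc_type="not-a-knot")
        t_end = float(t[-1])
        mode = AfterEnd(self.after_end)
        if mode == AfterEnd.zero:
            tail = 0.0
        elif mode == AfterEnd.constant_average:
            tail = float(trace.values.mean())
        else:
            tail = float(trace.values[-1])

        def p_ext(time: float) -> float:
            if time <= t_end:
                return max(float(spline(min(max(time, float(t[0])), t_end))), 0.0)
            return tail

        return p_ext, t_end


@dataclass
class SimulationResult:
    times: np.ndarray
    m: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    inputs_used: dict[str, str] = field(default_factory=dict)
    events: list[str] = field(default_factory=list)

    def mrna(self, gene: str) -> np.ndarray:
        return self.m[gene]


class ODESystem:
    """Right-hand side (and analytic Jacobian) of the network equations."""

    def __init__(self, network: NetworkModel,
                 externals: dict[str, ExternalInputPolicy] | None = None,
                 clamped: frozenset[str] = frozenset()):
        self.network = network
        self.genes = sorted(network.nodes)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.n = len(self.genes)
        self.clamped = frozenset(clamped)
        for g in self.clamped:
            if g not in self.index:
                raise ValueError(f"cannot knock out unknown gene {g!r}")
        externals = externals or {}
        for g in self.genes:
            if g not in network.lam:
                raise ValueError(f"no protein degradation rate lam for node {g!r}")
            if g not in network.delta:
                raise ValueError(f"no mRNA degradation rate delta for node {g!r}")
        self.lam = np.array([network.lam[g] for g in self.genes])
        self.delta = np.array([network.delta[g] for g in self.genes])
        self._ext_funcs: dict[str, tuple] = {}
        self.switch_times: list[float] = []
        for name, policy in externals.items():
            fn, t_end = policy.protein_function()
            self._ext_funcs[name] = (fn, policy)
            self.switch_times.append(t_end)
        # resolve each node's inputs to state indices or external callables
        self._inputs: list[list] = []
        for g in self.genes:
            fit = network.nodes[g]
            resolved = []
            for inp in fit.inputs:
                if inp in self.index:
                    resolved.append(("node", self.index[inp]))
                elif inp in self._ext_funcs:
                    resolved.append(("ext", self._ext_funcs[inp][0]))
                else:
                    raise ValueError(f"unresolved input {inp!r} of node {g!r}: "
                                     "not a node and no external policy given")
            self._inputs.append(resolved)
        self._specs = [network.nodes[g].spec for g in self.genes]
        self._clamp_idx = np.array([self.index[g] for g in sorted(self.clamped)],
                                   dtype=int)

    def _input_levels(self, t: float, p: np.ndarray, i: int) -> list[float]:
        out = []
        for kind, ref in self._inputs[i]:
            if kind == "node":
                out.append(max(float(p[ref]), 0.0))
            else:
                out.append(max(float(ref(t)), 0.0))
        return out

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        m, p = y[:n], y[n:]
        dm = np.empty(n)
        for i in range(n):
            dm[i] = evaluate(self._specs[i], self._input_levels(t, p, i)) \
                - self.delta[i] * m[i]
        dp = self.lam * (m - p)
        if self._clamp_idx.size:
            dm[self._clamp_idx] = 0.0
            dp[self._clamp_idx] = 0.0
        return np.concatenate([dm, dp])

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        p = y[n:]
        J = np.zeros((2 * n, 2 * n))
        for i in range(n):
            J[i, i] = -self.delta[i]
            levels = self._input_levels(t, p, i)
            grad = grf_gradient(self._specs[i], levels)
            for (kind, ref), g in zip(self._inputs[i], grad):
                if kind == "node":
                    J[i, n + ref] += g
            J[n + i, i] = self.lam[i]
            J[n + i, n + i] = -self.lam[i]
        for i in self._clamp_idx:
            J[i, :] = 0.0
            J[n + i, :] = 0.0
            J[:, i] = 0.0          # clamped state contributes nothing
            J[:, n + i] = 0.0
        return J

    def initial_state(self, m0: dict[str, float], p0: dict[str, float]) -> np.ndarray:
        y0 = np.empty(2 * self.n)
        for g, i in self.index.items():
            y0[i] = 0.0 if g in self.clamped else m0[g]
            y0[self.n + i] = 0.0 if g in self.clamped else p0[g]
        return y0


def assemble_ode(network: NetworkModel,
                 externals: dict[str, ExternalInputPolicy] | None = None) -> ODESystem:
    """Close the network into an integrable dynamical system (2 states per
    node).  Every node input must resolve to another node, the node itself,
    or an external policy."""
    return ODESystem(network, externals)


def knockout(system: ODESystem, genes: list[str]) -> ODESystem:
    """Clamp the named genes' mRNA and protein to zero for the whole
    simulation; downstream GRFs see zero input and indirect effects
    propagate."""
    return ODESystem(system.network,
                     {name: policy for name, (fn, policy) in system._ext_funcs.items()},
                     clamped=system.clamped | frozenset(genes))


def simulate(system: ODESystem, m0: dict[str, float], p0: dict[str, float],
             t_end: float, t_start: float = 0.0, output_dt: float = 1.0,
             rtol: float = 1e-8) -> SimulationResult:
    """Integrate the network with a stiff-capable method (LSODA, analytic
    Jacobian), splitting at external-input switch times so the policy
    discontinuity never sits inside an integrator step."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    y0 = system.initial_state(m0, p0)
    breaks = sorted({t for t in system.switch_times if t_start < t < t_end})
    spans = list(zip([t_start] + breaks, breaks + [t_end]))
    times_all, ys_all = [], []
    events = [f"external input switch at t={b:g} min" for b in breaks]
    y = y0
    for lo, hi in spans:
        t_eval = np.arange(lo, hi, output_dt)
        if t_eval.size == 0 or t_eval[0] > lo:
            t_eval = np.insert(t_eval, 0, lo)
        if t_eval[-1] < hi:
            t_eval = np.append(t_eval, hi)
        sol = solve_ivp(system.rhs, (lo, hi), y, method="LSODA",
                        jac=system.jacobian, t_eval=t_eval,
                        rtol=rtol, atol=1e-10 * max(1.0, float(np.max(np.abs(y0)))))
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1]:g}: {sol.message}")
        keep = slice(None) if not times_all else slice(1, None)
        times_all.append(sol.t[keep])
        ys_all.append(sol.y[:, keep])
        y = sol.y[:, -1]
    t = np.concatenate(times_all)
    Y = np.concatenate(ys_all, axis=1)
    n = system.n
    return SimulationResult(
        times=t,
        m={g: Y[system.index[g]] for g in system.genes},
        p={g: Y[n + system.index[g]] for g in system.genes},
        inputs_used={name: AfterEnd(pol.after_end).value
                     for name, (fn, pol) in system._ext_funcs.items()},
        events=events)


def initialize_delta(network: NetworkModel, data: TimeSeriesSet,
                     replicate: str = "1") -> dict[str, float]:
    """Steady-state-consistent mRNA decay rates delta = <s>/<m> per node."""
    out = {}
    for g in network.nodes:
        s = data.get(g, Kind.synthesis_rate, replicate).values
        m = data.get(g, Kind.mrna_level, replicate).values
        out[g] = float(s.mean() / m.mean())
    return out


def initial_state_from_data(network: NetworkModel, data: TimeSeriesSet,
                            replicate: str = "1"):
    """Measured mRNA and inferred protein proxies at t = 0 as initial values."""
    m0, p0 = {}, {}
    for g in network.nodes:
        mrna = data.get(g, Kind.mrna_level, replicate)
        m0[g] = float(mrna.values[0])
        lam = network.lam[g]
        p0[g] = float(Propagator(mrna, lam_min=lam).values(lam)[0])
    return m0, p0


# --- global refit --------------------------------------------------------------

@dataclass(frozen=True)
class RefitConfig:
    max_iter: int = 25
    fd_step: float = 1e-4            # relative finite-difference step
    initial_step: float = 0.05       # gradient-descent step in transformed space
    backtrack: float = 0.5
    grow: float = 1.5
    min_step: float = 1e-7
    tol: float = 1e-8                # stop when relative objective gain < tol
    refit_delta: bool = True
    rtol: float = 1e-6               # integration tolerance during refit


def _network_theta(network: NetworkModel, refit_delta: bool):
    """Flatten all node GRF shape parameters (log b, log alpha, log K, n)
    plus optionally log delta into one vector."""
    theta, layout = [], []
    for g in sorted(network.nodes):
        spec = network.nodes[g].spec
        vals = [math.log(max(spec.b, 1e-300)), math.log(max(spec.alpha, 1e-300))]
        vals += [math.log(k) for k in spec.K] + list(spec.n)
        if refit_delta:
            vals.append(math.log(network.delta[g]))
        layout.append((g, spec.arity))
        theta.extend(vals)
    return np.array(theta), layout


def _network_from_theta(network: NetworkModel, theta: np.ndarray, layout,
                        refit_delta: bool) -> NetworkModel:
    nodes = dict(network.nodes)
    delta = dict(network.delta)
    pos = 0
    for g, ar in layout:
        k = 2 + 2 * ar + (1 if refit_delta else 0)
        block = theta[pos:pos + k]
        pos += k
        spec = network.nodes[g].spec
        new_spec = GRFSpec(
            form=spec.form,
            b=math.exp(block[0]), alpha=math.exp(block[1]),
            K=tuple(math.exp(x) for x in block[2:2 + ar]),
            n=tuple(float(np.clip(x, N_MIN, N_MAX)) for x in block[2 + ar:2 + 2 * ar]),
            inputs=spec.inputs)
        nodes[g] = replace(network.nodes[g], spec=new_spec)
        if refit_delta:
            delta[g] = math.exp(block[-1])
    return NetworkModel(nodes=nodes, lam=dict(network.lam), delta=delta,
                        externals=network.externals)


def global_refit(network: NetworkModel, data: TimeSeriesSet,
                 externals: dict[str, ExternalInputPolicy] | None = None,
                 config: RefitConfig | None = None, replicate: str = "1"):
    """Re-fit the assembled ODE model's output to the measured mRNA levels.

    Individually fitted nodes propagate their errors downstream in a
    simulation, so all GRF shape parameters (and delta) are adjusted
    jointly by finite-difference gradient descent with a backtracking line
    search, starting from the single-node fits.  The objective is the sum
    over nodes of squared mRNA residuals normalized by each gene's data
    variance.  Returns (refitted network, report) where the report lists
    the objective trace and per-parameter relative changes; the refit
    objective never exceeds the starting one.
    """
    config = config or RefitConfig()
    grid = data.get(sorted(network.nodes)[0], Kind.mrna_level, replicate).grid
    t_obs = grid.times
    obs = {g: data.get(g, Kind.mrna_level, replicate).values
           for g in network.nodes}
    var = {g: float(np.mean((v - v.mean()) ** 2)) for g, v in obs.items()}
    m0, p0 = initial_state_from_data(network, data, replicate)

    def objective_of(net: NetworkModel) -> float:
        system = assemble_ode(net, externals)
        try:
            sim = simulate(system, m0, p0, t_end=float(t_obs[-1]),
                           t_start=float(t_obs[0]), output_dt=float(np.diff(t_obs).min()),
                           rtol=config.rtol)
        except RuntimeError:
            return np.inf
        total = 0.0
        for g in net.nodes:
            m_sim = np.interp(t_obs, sim.times, sim.m[g])
            total += float(np.mean((m_sim - obs[g]) ** 2) / var[g])
        return total

    theta0, layout = _network_theta(network, config.refit_delta)
    theta = theta0.copy()
    f = objective_of(network)
    f0 = f
    trace = [f]
    step = config.initial_step
    for _ in range(config.max_iter):
        # forward-difference gradient in transformed coordinates
        grad = np.zeros_like(theta)
        for j in range(theta.size):
            bump = theta.copy()
            h = config.fd_step * max(abs(theta[j]), 1.0)
            bump[j] += h
            fj = objective_of(_network_from_theta(network, bump, layout,
                                                  config.refit_delta))
            grad[j] = (fj - f) / h
        gnorm = float(np.linalg.norm(grad))
        if gnorm == 0 or not np.isfinite(gnorm):
            break
        improved = False
        while step >= config.min_step:
            trial = theta - step * grad / gnorm
            ft = objective_of(_network_from_theta(network, trial, layout,
                                                  config.refit_delta))
            if ft < f:
                theta, f = trial, ft
                step *= config.grow
                improved = True
                break
            step *= config.backtrack
        trace.append(f)
        if not improved or (trace[-2] - f) < config.tol * max(f, 1.0):
            break
    refitted = _network_from_theta(network, theta, layout, config.refit_delta)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_change = np.abs(theta - theta0) / np.maximum(np.abs(theta0), 1e-12)
    report = {"objective_start": f0, "objective_end": min(f, f0),
              "objective_trace": trace,
              "relative_parameter_change": rel_change.tolist()}
    if f > f0:  # line search failed outright; keep the starting model
        refitted = network
    return refitted, report


# --- oscillation utilities -----------------------------------------------------

def _autocorr(values: np.ndarray) -> np.ndarray:
    """Unbiased normalized autocorrelation (each lag divided by its overlap
    count, so a perfectly sustained oscillation gives unit-height peaks)."""
    v = values - values.mean()
    c = np.correlate(v, v, mode="full")[v.size - 1:]
    c = c / (v.size - np.arange(v.size))
    # the unbiased estimate gets noisy beyond half the window
    c = c[: v.size // 2 + 1]
    return c / c[0] if c[0] > 0 else c


def _local_maxima(c: np.ndarray) -> list[int]:
    return [k for k in range(1, c.size - 1)
            if c[k] >= c[k - 1] and c[k] > c[k + 1]]


def dominant_period(times: np.ndarray, values: np.ndarray) -> float:
    """Dominant oscillation period from the first autocorrelation peak."""
    dt = float(np.mean(np.diff(times)))
    c = _autocorr(np.asarray(values, float))
    peaks = _local_maxima(c)
    if not peaks:
        raise ValueError("no autocorrelation peak: signal not oscillatory")
    return peaks[0] * dt


def classify_oscillation(times: np.ndarray, values: np.ndarray,
                         tol: float = 0.05) -> str:
    """Classify a free-running trajectory as 'sustained' or 'damped' from
    the envelope of successive autocorrelation maxima (a decaying envelope
    means the oscillation loses amplitude cycle over cycle)."""
    c = _autocorr(np.asarray(values, float))
    heights = [c[k] for k in _local_maxima(c) if c[k] > 0]
    if not heights:
        return "damped"
    if len(heights) == 1:
        return "sustained" if heights[0] >= 1.0 - tol else "damped"
    ratios = [heights[i + 1] / heights[i] for i in range(len(heights) - 1)]
    return "sustained" if min(heights[0], float(np.median(ratios))) >= 1.0 - tol \
        else "damped"
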