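"""Ground-truth networks and synthetic DTA-like observations.

Emulates the structure of a dynamic-transcriptome experiment on a
synchronized cell population: total mRNA levels and mRNA synthesis rates
for every gene, on a 42-point grid at 5-min spacing (0-205 min), in two
replicates, oscillating with a period near 60 min.  Two observation
effects are modelled on top of the noiseless truth:

* population-desynchronization damping — each series' deviation from its
  time mean shrinks by exp(-gamma_sync * t), a first-order surrogate for
  phase diffusion that affects inputs and outputs alike;
* multiplicative log-normal measurement noise exp(sigma * Z), i.i.d. per
  data point and replicate.

The truth network is integrated with the package's own ODE machinery, so
the truth GRFs evaluated on the truth protein traces reproduce the clean
synthesis-rate series exactly at the grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .dataio import GeneTimeSeries, Kind, TimeGrid, TimeSeriesSet
from .fitting import FitResult
from .grf_models import GRFForm, GRFSpec
from .network_dynamics import (AfterEnd, ExternalInputPolicy, assemble_ode,
                               classify_oscillation, simulate)
from .network_inference import NetworkModel

__all__ = ["SynthConfig", "SyntheticDataset", "generate", "make_fixture",
           "FIXTURE_NAMES", "driver_series", "ring_network",
           "driven_chain_network"]

FIXTURE_NAMES = ("single_activator", "two_input_and", "two_input_xor",
                 "ring_oscillator_5", "driven_oscillator_10")

# rates spanning the biologically inferred 5-50 min protein half-life range
LAM_RANGE = (math.log(2) / 50.0, math.log(2) / 5.0)
DELTA_RANGE = (math.log(2) / 30.0, math.log(2) / 5.0)


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator; defaults mirror the emulated dataset."""

    n_nodes: int = 5
    lam_range: tuple[float, float] = LAM_RANGE
    delta_range: tuple[float, float] = DELTA_RANGE
    period: float = 60.0            # target oscillation period, min
    gamma_sync: float = 0.0         # desynchronization damping rate, 1/min
    noise_sigma: float = 0.05       # log-normal noise scale
    n_timepoints: int = 42
    dt: float = 5.0
    replicates: int = 2
    transient: float = 400.0        # burn-in before the measurement window, min
    require_oscillation: bool = False
    retry_budget: int = 5
    seed: int = 0

    def grid(self) -> TimeGrid:
        return TimeGrid(np.arange(self.n_timepoints) * self.dt)


@dataclass
class SyntheticDataset:
    """Truth network plus observed (noisy, damped) and clean series."""

    truth: NetworkModel
    observed: TimeSeriesSet
    clean: TimeSeriesSet
    externals: dict[str, ExternalInputPolicy] = field(default_factory=dict)
    config: SynthConfig | None = None


def driver_series(grid: TimeGrid, period: float = 60.0, mean: float = 1.0,
                  amplitude: float = 0.8, phase: float = 0.0,
                  gene: str = "DRIVER", kind: Kind = Kind.mrna_level,
                  replicate: str = "1") -> GeneTimeSeries:
    """Sinusoidal external-driver trace (e.g. a cyclin mRNA surrogate)."""
    t = grid.times
    v = mean + amplitude * np.sin(2 * np.pi * t / period + phase)
    return GeneTimeSeries(gene, kind, np.clip(v, 0.0, None), grid, replicate)


def _fit_stub(gene: str, spec: GRFSpec, lam: tuple[float, ...]) -> FitResult:
    """Wrap a truth GRF in the FitResult container (score 0: exact model)."""
    return FitResult(gene=gene, inputs=spec.inputs, spec=spec, lam=lam,
                     score=0.0)


def ring_network(n_nodes: int = 5, lam: float = math.log(2) / 2.5,
                 delta: float = math.log(2) / 2.0, b: float = 0.02,
                 alpha: float = 1.0, K: float = 0.5, n_hill: float = 4.0,
                 prefix: str = "R") -> NetworkModel:
    """Cyclic repression ring (odd length oscillates: a repressilator).

    Default rates are faster than the biological half-life range: a
    free-running 5-ring needs short stage delays to hit a ~60 min period.
    """
    genes = [f"{prefix}{i}" for i in range(n_nodes)]
    nodes = {}
    for i, g in enumerate(genes):
        pred = genes[(i - 1) % n_nodes]
        spec = GRFSpec(form=GRFForm.REP, b=b, alpha=alpha, K=(K,), n=(n_hill,),
                       inputs=(pred,))
        nodes[g] = _fit_stub(g, spec, (lam,))
    return NetworkModel(nodes=nodes,
                        lam={g: lam for g in genes},
                        delta={g: delta for g in genes})


def driven_chain_network(n_nodes: int = 10, driver: str = "CLN",
                         lam: float = math.log(2) / 15.0,
                         delta: float = math.log(2) / 8.0,
                         rep_targets: tuple[int, ...] = (2, 4, 6, 8),
                         rep_offset: int = 3) -> NetworkModel:
    """Forward-activation ring with backward repressions and one external
    driver, mimicking a transcription-wave cell-cycle module.

    Node i is activated by node i-1 (ring closure keeps the module strongly
    connected); nodes in ``rep_targets`` carry a second, repressing input
    from the node ``rep_offset`` ahead (ANDNOT logic).  The driver acts as
    an additional activator on node 0 via OR logic.
    """
    genes = [f"G{i}" for i in range(n_nodes)]
    nodes = {}
    # amplitudes sized so mRNA levels stay of order the K thresholds
    for i, g in enumerate(genes):
        act = genes[(i - 1) % n_nodes]
        if i == 0:
            spec = GRFSpec(form=GRFForm.OR, b=0.005, alpha=0.045,
                           K=(0.8, 1.0), n=(2.5, 2.5), inputs=(act, driver))
        elif i in rep_targets:
            rep = genes[(i + rep_offset) % n_nodes]
            spec = GRFSpec(form=GRFForm.ANDNOT, b=0.01, alpha=0.16,
                           K=(0.8, 0.9), n=(2.5, 2.5), inputs=(act, rep))
        else:
            spec = GRFSpec(form=GRFForm.ACT, b=0.01, alpha=0.13,
                           K=(0.8,), n=(2.5,), inputs=(act,))
        nodes[g] = _fit_stub(g, spec, (lam,) * spec.arity)
    return NetworkModel(nodes=nodes,
                        lam={g: lam for g in genes},
                        delta={g: delta for g in genes},
                        externals=(driver,))


def _simulate_truth(truth: NetworkModel, externals, config: SynthConfig):
    """Integrate the truth from a washed-out transient and sample the grid."""
    grid = config.grid()
    genes = sorted(truth.nodes)
    # start near mid-activity, staggered per node: a perfectly symmetric
    # state can sit on an unstable fixed point of a ring forever
    rng = np.random.default_rng([config.seed, 3])
    guess = {}
    for g in genes:
        spec = truth.nodes[g].spec
        mid = (spec.b + 0.5 * spec.alpha) / truth.delta[g]
        guess[g] = mid * float(rng.uniform(0.6, 1.4))
    system = assemble_ode(truth, externals)
    sim = simulate(system, guess, dict(guess), t_end=float(grid.times[-1]),
                   t_start=-config.transient, output_dt=1.0, rtol=1e-8)
    idx = np.searchsorted(sim.times, grid.times)
    assert np.allclose(sim.times[idx], grid.times)
    m = {g: sim.m[g][idx] for g in genes}
    p = {g: sim.p[g][idx] for g in genes}
    # synthesis rate = truth GRF on truth protein levels, exactly
    ext_fn = {name: pol.protein_function()[0] for name, pol in (externals or {}).items()}
    s = {}
    for g in genes:
        fit = truth.nodes[g]
        levels = []
        for inp in fit.inputs:
            if inp in p:
                levels.append(p[inp])
            else:
                levels.append(np.array([max(ext_fn[inp](t), 0.0)
                                        for t in grid.times]))
        from .grf_models import evaluate
        s[g] = np.asarray(evaluate(fit.spec, levels), float)
    return grid, m, p, s, sim


def generate(config: SynthConfig, truth: NetworkModel | None = None,
             externals: dict[str, ExternalInputPolicy] | None = None) -> SyntheticDataset:
    """Simulate a truth network and emit DTA-like observations.

    Without an explicit ``truth``, an odd repression ring of
    ``config.n_nodes`` genes is built with rates drawn from the configured
    ranges.  When ``require_oscillation`` is set, non-oscillatory draws are
    redrawn up to ``retry_budget`` times before failing.
    """
    rng = np.random.default_rng(config.seed)
    last_error = None
    for attempt in range(max(config.retry_budget, 1)):
        if truth is None:
            n = config.n_nodes if config.n_nodes % 2 == 1 else config.n_nodes + 1
            lam = float(rng.uniform(*config.lam_range))
            delta = float(rng.uniform(*config.delta_range))
            candidate = ring_network(n, lam=lam, delta=delta,
                                     K=float(rng.uniform(0.4, 0.7)),
                                     n_hill=float(rng.uniform(3.0, 6.0)))
        else:
            candidate = truth
        grid, m, p, s, sim = _simulate_truth(candidate, externals, config)
        if config.require_oscillation:
            probe = sorted(candidate.nodes)[0]
            # judge on the settled part of the whole run, not just the
            # short measurement window
            window = sim.times >= sim.times[0] + 200.0
            if classify_oscillation(sim.times[window], sim.m[probe][window]) != "sustained":
                last_error = "non-oscillatory draw"
                if truth is not None:
                    raise RuntimeError(
                        "provided truth network does not oscillate as required")
                continue
        return _assemble_dataset(candidate, externals, config, grid, m, p, s, rng)
    raise RuntimeError(
        f"no oscillatory network found in {config.retry_budget} attempts "
        f"({last_error})")


def _assemble_dataset(truth, externals, config, grid, m, p, s, rng):
    clean = TimeSeriesSet()
    observed = TimeSeriesSet()
    t = grid.times
    damp = np.exp(-config.gamma_sync * t)
    ext_series = {}
    for name, pol in (externals or {}).items():
        fn = pol.protein_function()[0]
        # external drive exposed on the measurement grid, mRNA-like
        ext_series[name] = np.array([max(fn(tt), 0.0) for tt in t]) \
            if pol.series.kind != Kind.mrna_level else None

    def observe(values, rep_rng):
        out = values
        if config.gamma_sync > 0:
            out = values.mean() + (values - values.mean()) * damp
        noise = rep_rng.standard_normal(values.size)  # drawn even if unused,
        if config.noise_sigma > 0:                    # to keep streams aligned
            out = out * np.exp(config.noise_sigma * noise)
        return np.clip(out, 0.0, None)

    for r in range(config.replicates):
        rep = str(r + 1)
        rep_rng = np.random.default_rng([config.seed, 7, r])
        for g in sorted(truth.nodes):
            clean.add(GeneTimeSeries(g, Kind.mrna_level, m[g], grid, rep))
            clean.add(GeneTimeSeries(g, Kind.synthesis_rate, s[g], grid, rep))
            clean.add(GeneTimeSeries(g, Kind.protein_proxy, p[g], grid, rep))
            observed.add(GeneTimeSeries(g, Kind.mrna_level,
                                        observe(m[g], rep_rng), grid, rep))
            observed.add(GeneTimeSeries(g, Kind.synthesis_rate,
                                        observe(s[g], rep_rng), grid, rep))
        for name, pol in (externals or {}).items():
            if pol.series.kind == Kind.mrna_level:
                base = pol.series
                vals = np.interp(t, base.grid.times, base.values)
            else:
                vals = ext_series[name]
            clean.add(GeneTimeSeries(name, Kind.mrna_level, vals, grid, rep))
            observed.add(GeneTimeSeries(name, Kind.mrna_level,
                                        observe(vals, rep_rng), grid, rep))
    return SyntheticDataset(truth=truth, observed=observed, clean=clean,
                            externals=dict(externals or {}), config=config)


# --- canonical fixtures --------------------------------------------------------

def _extended_driver(period: float, phase: float = 0.0, lead: float = 600.0,
                     gene: str = "E1") -> GeneTimeSeries:
    """Driver defined well before t=0 so the generation transient is driven."""
    grid = TimeGrid(np.arange(-lead, 210.0, 5.0))
    return driver_series(grid, period=period, phase=phase, gene=gene)


def _cascade_network(specs: dict[str, GRFSpec], lam: dict[str, float],
                     delta: dict[str, float], externals: tuple[str, ...]):
    nodes = {g: _fit_stub(g, sp, tuple(lam.get(i, math.log(2) / 15.0)
                                       for i in sp.inputs))
             for g, sp in specs.items()}
    return NetworkModel(nodes=nodes, lam=lam, delta=delta, externals=externals)


def make_fixture(name: str, seed: int = 0, noise_sigma: float = 0.05,
                 gamma_sync: float = 0.0) -> SyntheticDataset:
    """Canonical seeded datasets used across the test suite.

    single_activator     2 genes: driver-fed TF A activating target B.
    two_input_and        3 genes: phase-shifted TFs A, B; C = A AND B.
    two_input_xor        as above with XOR logic.
    ring_oscillator_5    free-running 5-gene repression ring (~60 min period).
    driven_oscillator_10 10-gene forward-activation / backward-repression
                         module driven by an external cyclin-like input.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    lam_a = math.log(2) / 12.0
    lam_b = math.log(2) / 25.0
    delta = math.log(2) / 8.0
    cfg = SynthConfig(seed=seed, noise_sigma=noise_sigma, gamma_sync=gamma_sync)

    if name == "single_activator":
        # TF A sweeps widely through B's threshold so all four GRF shape
        # parameters of B are identifiable from the 42-point series
        specs = {
            "A": GRFSpec(GRFForm.ACT, b=0.01, alpha=0.32, K=(1.0,), n=(4.0,),
                         inputs=("E1",)),
            "B": GRFSpec(GRFForm.ACT, b=0.01, alpha=0.15, K=(0.67,), n=(3.0,),
                         inputs=("A",)),
        }
        net = _cascade_network(specs, {"A": math.log(2) / 5.0, "B": lam_a},
                               {"A": math.log(2) / 3.0, "B": delta}, ("E1",))
        ext = {"E1": ExternalInputPolicy(_extended_driver(60.0),
                                         AfterEnd.constant_average,
                                         lam=math.log(2) / 5.0)}
        return generate(cfg, truth=net, externals=ext)

    if name in ("two_input_and", "two_input_xor"):
        form = GRFForm.AND if name == "two_input_and" else GRFForm.XOR
        # anti-phased TFs exercise the AND corners; a partial phase lag
        # makes the XOR signature (double-frequency output) visible.
        # Thresholds sit at the realized protein mid-levels so the data
        # sweep both flanks of each Hill term.
        phase = math.pi if name == "two_input_and" else 0.8
        K_C = (0.67, 0.72) if name == "two_input_and" else (0.67, 0.69)
        lam_fast, lam_slow = math.log(2) / 5.0, math.log(2) / 10.0
        delta_ab = math.log(2) / 3.0
        specs = {
            "A": GRFSpec(GRFForm.ACT, b=0.01, alpha=0.32, K=(1.0,), n=(4.0,),
                         inputs=("E1",)),
            "B": GRFSpec(GRFForm.ACT, b=0.01, alpha=0.32, K=(1.0,), n=(4.0,),
                         inputs=("E2",)),
            "C": GRFSpec(form, b=0.02, alpha=0.30, K=K_C, n=(5.0, 5.0),
                         inputs=("A", "B")),
        }
        net = _cascade_network(specs,
                               {"A": lam_fast, "B": lam_slow,
                                "C": math.log(2) / 15.0},
                               {"A": delta_ab, "B": delta_ab, "C": delta},
                               ("E1", "E2"))
        ext = {"E1": ExternalInputPolicy(_extended_driver(60.0, gene="E1"),
                                         AfterEnd.constant_average, lam=lam_fast),
               "E2": ExternalInputPolicy(_extended_driver(60.0, phase=phase, gene="E2"),
                                         AfterEnd.constant_average, lam=lam_slow)}
        return generate(cfg, truth=net, externals=ext)

    if name == "ring_oscillator_5":
        net = ring_network(5)
        cfg5 = dc_replace(cfg, require_oscillation=True, transient=600.0)
        return generate(cfg5, truth=net)

    # driven_oscillator_10
    net = driven_chain_network()
    ext = {"CLN": ExternalInputPolicy(_extended_driver(60.0, gene="CLN"),
                                      AfterEnd.constant_average,
                                      lam=math.log(2) / 10.0)}
    return generate(cfg, truth=net, externals=ext)
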