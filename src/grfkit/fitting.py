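"""Scoring and global fitting of gene regulation functions.

The fit quality of a candidate GRF is the normalized score

    S = mean((s_d - s_m)^2) / mean((s_d - <s_d>)^2)

i.e. the fraction of the variance of the measured synthesis-rate series
that the model leaves unexplained: 0 for a perfect fit, 1 for the
constant time-average model.  Scores are therefore comparable across
genes and can be averaged into network scores.

Global optimization uses simulated annealing with a self-adapting cooling
schedule (geometric cooling; per-temperature step-size adaptation toward a
target acceptance ratio), several independent restarts, and an optional
derivative-free simplex polish.  Scale parameters (b, alpha, K, lam) are
searched in log-space; the Hill sensitivity n on a linear [1, 8] range.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize

from .dataio import DegenerateInputError, GeneTimeSeries, Kind
from .grf_models import (GRFForm, GRFSpec, N_MAX, N_MIN, arity_of,
                         enumerate_forms, evaluate, parameter_count)
from .protein_proxy import LAM_MAX, LAM_MIN, Propagator

__all__ = ["FitConfig", "FitResult", "score", "fit_grf", "select_best_form",
           "select_best_inputs", "data_collapse_residual", "fast_config"]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Annealing and bound settings for GRF fitting."""

    n_restarts: int = 5
    chain_length: int = 100          # moves per temperature level
    cooling: float = 0.85            # geometric temperature factor
    t_floor_ratio: float = 1e-5      # stop when T < T0 * ratio
    target_acceptance: float = 0.44  # step sizes adapt toward this
    init_acceptance: float = 0.8     # sets the initial temperature
    polish: bool = True              # Nelder-Mead simplex refinement
    seed: int = 0
    lam_bounds: tuple[float, float] = (LAM_MIN, LAM_MAX)
    n_bounds: tuple[float, float] = (N_MIN, N_MAX)
    rate_floor_ratio: float = 1e-6   # lower bound for b, alpha as fraction of max s
    rate_ceil_factor: float = 10.0   # upper bound for b, alpha as multiple of max s
    K_margin: float = 10.0           # K in [min p / margin, max p * margin]


def fast_config(seed: int = 0, **kw) -> FitConfig:
    """Reduced-effort settings for batch (network) fitting: fewer restarts
    and shorter chains.  Adequate when lam is fixed and only the 4-6 shape
    parameters are free."""
    defaults = dict(n_restarts=2, chain_length=60, cooling=0.80,
                    t_floor_ratio=1e-4, seed=seed)
    defaults.update(kw)
    return FitConfig(**defaults)


@dataclass(frozen=True)
class FitResult:
    """Best fit of one GRF form to one target gene."""

    gene: str
    inputs: tuple[str, ...]
    spec: GRFSpec
    lam: tuple[float, ...]
    score: float
    replicate: str = "1"
    seed: int = 0
    n_restarts: int = 1

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be nonnegative")
        if len(self.inputs) != self.spec.arity:
            raise ValueError("spec arity must match number of inputs")

    def to_dict(self) -> dict:
        return {"gene": self.gene, "inputs": list(self.inputs),
                "spec": self.spec.to_dict(), "lam": list(self.lam),
                "score": self.score, "replicate": self.replicate,
                "seed": self.seed, "n_restarts": self.n_restarts}

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(gene=d["gene"], inputs=tuple(d["inputs"]),
                   spec=GRFSpec.from_dict(d["spec"]), lam=tuple(d["lam"]),
                   score=d["score"], replicate=d.get("replicate", "1"),
                   seed=d.get("seed", 0), n_restarts=d.get("n_restarts", 1))


def score(observed: GeneTimeSeries | np.ndarray, model: GeneTimeSeries | np.ndarray) -> float:
    """Normalized unexplained-variance score of a model series."""
    d = observed.values if isinstance(observed, GeneTimeSeries) else np.asarray(observed, float)
    m = model.values if isinstance(model, GeneTimeSeries) else np.asarray(model, float)
    if d.shape != m.shape:
        raise ValueError("observed and model series must share one grid")
    var = np.mean((d - d.mean()) ** 2)
    if var == 0:
        raise DegenerateInputError("constant observed series has zero variance")
    return float(np.mean((d - m) ** 2) / var)


# --- parameter vector <-> GRFSpec ---------------------------------------------

class _Problem:
    """Objective closure: theta -> score, with log-space transforms and
    per-input protein propagators shared across evaluations."""

    def __init__(self, target: GeneTimeSeries, inputs: list[GeneTimeSeries],
                 form: GRFForm, config: FitConfig,
                 fixed_lam: tuple[float, ...] | None):
        self.form = GRFForm(form)
        self.arity = arity_of(self.form)
        if len(inputs) != self.arity:
            raise ValueError(f"{self.form.value} takes {self.arity} inputs, "
                             f"got {len(inputs)}")
        if target.kind != Kind.synthesis_rate:
            raise ValueError("target must be a synthesis_rate series")
        self.target = target
        self.d = target.values
        self.var = np.mean((self.d - self.d.mean()) ** 2)
        if self.var == 0:
            raise DegenerateInputError(f"{target.gene}: constant synthesis rate")
        self.config = config
        self.fixed_lam = None if fixed_lam is None else tuple(float(x) for x in fixed_lam)
        self.propagators = [Propagator(m, lam_min=config.lam_bounds[0]) for m in inputs]
        if self.fixed_lam is not None:
            self._p_fixed = [prop.values(l)
                             for prop, l in zip(self.propagators, self.fixed_lam)]
        self._build_bounds()

    def _build_bounds(self):
        cfg = self.config
        smax = float(self.d.max())
        lo, hi = [], []
        lo.append(math.log(cfg.rate_floor_ratio * smax))   # b
        hi.append(math.log(cfg.rate_ceil_factor * smax))
        lo.append(math.log(cfg.rate_floor_ratio * smax))   # alpha
        hi.append(math.log(cfg.rate_ceil_factor * smax))
        for prop in self.propagators:                      # K per input
            # protein proxies live on the mRNA scale (nu/lam = 1)
            pv = prop.series.values
            pmin = max(float(pv[pv > 0].min()) if np.any(pv > 0) else 1e-12, 1e-12)
            lo.append(math.log(pmin / cfg.K_margin))
            hi.append(math.log(max(float(pv.max()), pmin) * cfg.K_margin))
        for _ in range(self.arity):                        # n per input
            lo.append(cfg.n_bounds[0])
            hi.append(cfg.n_bounds[1])
        if self.fixed_lam is None:                         # lam per input
            for _ in range(self.arity):
                lo.append(math.log(cfg.lam_bounds[0]))
                hi.append(math.log(cfg.lam_bounds[1]))
        self.lower = np.array(lo)
        self.upper = np.array(hi)
        self.dim = self.lower.size

    def unpack(self, theta: np.ndarray):
        a = self.arity
        b = math.exp(theta[0])
        alpha = math.exp(theta[1])
        K = tuple(math.exp(x) for x in theta[2:2 + a])
        n = tuple(theta[2 + a:2 + 2 * a])
        if self.fixed_lam is not None:
            lam = self.fixed_lam
        else:
            lam = tuple(math.exp(x) for x in theta[2 + 2 * a:2 + 3 * a])
        return b, alpha, K, n, lam

    def spec_of(self, theta: np.ndarray) -> GRFSpec:
        b, alpha, K, n, _ = self.unpack(theta)
        n = tuple(min(max(v, N_MIN), N_MAX) for v in n)
        return GRFSpec(form=self.form, b=b, alpha=alpha, K=K, n=n,
                       inputs=tuple(p.series.gene for p in self.propagators))

    def lam_of(self, theta: np.ndarray) -> tuple[float, ...]:
        return self.unpack(theta)[4]

    def model_series(self, theta: np.ndarray) -> np.ndarray:
        b, alpha, K, n, lam = self.unpack(theta)
        if self.fixed_lam is not None:
            proteins = self._p_fixed
        else:
            proteins = [prop.values(l) for prop, l in zip(self.propagators, lam)]
        spec = GRFSpec(form=self.form, b=b, alpha=alpha, K=K,
                       n=tuple(min(max(v, N_MIN), N_MAX) for v in n))
        return evaluate(spec, proteins)

    def __call__(self, theta: np.ndarray) -> float:
        if np.any(theta < self.lower) or np.any(theta > self.upper):
            return np.inf
        m = self.model_series(theta)
        return float(np.mean((self.d - m) ** 2) / self.var)


def _anneal(problem: _Problem, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    cfg = problem.config
    span = problem.upper - problem.lower
    theta = problem.lower + rng.random(problem.dim) * span
    energy = problem(theta)
    best_theta, best_energy = theta.copy(), energy

    # probe moves calibrate the initial temperature to ~init_acceptance
    step = 0.3 * span
    uphill = []
    for _ in range(30):
        d = rng.integers(problem.dim)
        trial = theta.copy()
        trial[d] = np.clip(trial[d] + rng.normal(0.0, step[d]),
                           problem.lower[d], problem.upper[d])
        delta = problem(trial) - energy
        if delta > 0 and np.isfinite(delta):
            uphill.append(delta)
    t0 = (np.median(uphill) / -math.log(cfg.init_acceptance)) if uphill else 1.0
    t0 = max(t0, 1e-12)

    temp = t0
    while temp > t0 * cfg.t_floor_ratio:
        accepted = 0
        for _ in range(cfg.chain_length):
            d = rng.integers(problem.dim)
            trial = theta.copy()
            trial[d] = np.clip(trial[d] + rng.normal(0.0, step[d]),
                               problem.lower[d], problem.upper[d])
            e = problem(trial)
            if e <= energy or rng.random() < math.exp(-(e - energy) / temp):
                theta, energy = trial, e
                accepted += 1
                if e < best_energy:
                    best_theta, best_energy = trial.copy(), e
        ratio = accepted / cfg.chain_length
        # self-adapting step size: expand when too hot, shrink when stuck
        step = np.clip(step * math.exp(ratio - cfg.target_acceptance),
                       1e-4 * span, span)
        temp *= cfg.cooling
    return best_theta, best_energy


def _polish(problem: _Problem, theta: np.ndarray, energy: float):
    res = minimize(problem, theta, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12,
                            "maxiter": 400 * problem.dim})
    if res.fun < energy:
        return np.clip(res.x, problem.lower, problem.upper), float(res.fun)
    return theta, energy


def fit_grf(target: GeneTimeSeries, inputs: list[GeneTimeSeries],
            form: GRFForm, config: FitConfig | None = None,
            fixed_lam: tuple[float, ...] | None = None) -> FitResult:
    """Globally fit one GRF form to a target synthesis-rate series.

    ``inputs`` are mRNA-level series of the regulators; their protein
    proxies are part of the model.  With ``fixed_lam`` the degradation
    rates are pinned (network mode) and only shape parameters are fitted.
    Deterministic given ``config.seed``; more restarts never worsen the
    returned score (the best restart is kept).
    """
    config = config or FitConfig()
    problem = _Problem(target, inputs, form, config, fixed_lam)
    best_theta, best_energy = None, np.inf
    form_id = list(GRFForm).index(GRFForm(form))
    for r in range(config.n_restarts):
        rng = np.random.default_rng([config.seed, form_id, r])
        theta, energy = _anneal(problem, rng)
        if energy < best_energy:
            best_theta, best_energy = theta, energy
    if config.polish:
        best_theta, best_energy = _polish(problem, best_theta, best_energy)
    return FitResult(gene=target.gene,
                     inputs=tuple(m.gene for m in inputs),
                     spec=problem.spec_of(best_theta),
                     lam=problem.lam_of(best_theta),
                     score=best_energy,
                     replicate=target.replicate,
                     seed=config.seed,
                     n_restarts=config.n_restarts)


def _better(a: FitResult, b: FitResult) -> bool:
    """True if a beats b: lower score; near-ties favor fewer parameters,
    then the fixed form-menu order."""
    if abs(a.score - b.score) > _TIE_TOL:
        return a.score < b.score
    pa, pb = parameter_count(a.spec.form), parameter_count(b.spec.form)
    if pa != pb:
        return pa < pb
    order = list(GRFForm)
    return order.index(a.spec.form) < order.index(b.spec.form)


def select_best_form(target: GeneTimeSeries, inputs: list[GeneTimeSeries],
                     config: FitConfig | None = None,
                     fixed_lam: tuple[float, ...] | None = None,
                     return_all: bool = False):
    """Fit every form of the matching arity and return the best result.

    Arity 1 tries activation and repression; arity 2 tries all ten analog
    logic forms.  With ``return_all`` also returns the per-form results.
    """
    forms = enumerate_forms(len(inputs))
    results = [fit_grf(target, inputs, f, config, fixed_lam) for f in forms]
    best = results[0]
    for r in results[1:]:
        if _better(r, best):
            best = r
    return (best, results) if return_all else best


def select_best_inputs(target: GeneTimeSeries,
                       candidate_inputs: list[GeneTimeSeries],
                       config: FitConfig | None = None,
                       fixed_lam: dict[str, float] | None = None):
    """Try every single input and every unordered pair of candidates;
    return (best FitResult, ranked list over input sets)."""
    if len(candidate_inputs) < 2:
        raise ValueError("need at least two candidate inputs")
    by_name = {m.gene: m for m in candidate_inputs}
    sets: list[tuple[str, ...]] = [(g,) for g in by_name]
    sets += [tuple(c) for c in itertools.combinations(by_name, 2)]
    ranked: list[FitResult] = []
    for names in sets:
        series = [by_name[g] for g in names]
        fl = None
        if fixed_lam is not None:
            fl = tuple(fixed_lam[g] for g in names)
        ranked.append(select_best_form(target, series, config, fixed_lam=fl))
    ranked.sort(key=lambda r: r.score)
    return ranked[0], ranked


def data_collapse_residual(target: GeneTimeSeries, mrna: GeneTimeSeries,
                           lam_grid: np.ndarray, window: int = 5) -> np.ndarray:
    """Single-valuedness statistic of the (p, s) scatter per candidate lam.

    For the correct degradation rate, synthesis rate plotted against the
    protein proxy collapses to a curve; we quantify the residual around a
    running-mean smooth of s ordered by p.  Minimizing over the lam grid
    locates the collapse.
    """
    prop = Propagator(mrna, lam_min=float(np.min(lam_grid)))
    s = target.values
    out = np.empty(len(lam_grid))
    for i, lam in enumerate(lam_grid):
        p = prop.values(float(lam))
        order = np.argsort(p)
        s_sorted = s[order]
        smooth = uniform_filter1d(s_sorted, size=window, mode="nearest")
        out[i] = np.mean((s_sorted - smooth) ** 2)
    return out
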