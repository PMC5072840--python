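"""Consensus estimation of a TF's effective protein degradation rate.

The degradation rate lam is a property of the TF, not of any one target,
so estimates from different target genes must agree.  For each suitable
target (periodic, well fitted by the TF, fitted with the literature
regulatory sign) a Metropolis chain samples the fit-score landscape with
stationary density proportional to exp(-S / T_mc), the marginal over lam
is histogrammed on a shared log-spaced grid, and the per-target histograms
are multiplied bin-wise.  The consensus lam is the center of the highest
bin of the product histogram.

T_mc acts as a sharpness knob for the pseudo-posterior; the default 0.05
is on the order of the score difference that separates competing fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import GeneTimeSeries
from .fitting import FitConfig, FitResult, _Problem
from .grf_models import MONOTONE_SIGNS
from .protein_proxy import LAM_MAX, LAM_MIN

__all__ = ["PosteriorHistogram", "ConsensusResult", "MCMCConfig",
           "default_bin_edges", "select_lambda_targets",
    "sample_lambda_posterior", "combine_posteriors", "SCORE_CUTOFF"]

# a target counts as "well fitted" by the TF below this score
SCORE_CUTOFF = 0.5

N_BINS = 100


def default_bin_edges() -> np.ndarray:
    """100 log-spaced bins spanning half-lives of 1-120 min."""
    return np.geomspace(LAM_MIN, LAM_MAX, N_BINS + 1)


@dataclass(frozen=True)
class PosteriorHistogram:
    """Binned marginal density over lam; density sums to 1 over bins."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.bin_edges, float)
        d = np.asarray(self.density, float)
        if not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if d.size != e.size - 1:
            raise ValueError("density needs one entry per bin")
        if np.any(d < 0):
            raise ValueError("density must be nonnegative")
        total = d.sum()
        if total > 0 and not math.isclose(total, 1.0, rel_tol=1e-9):
            d = d / total
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "density", d)

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])  # log-space centers

    @property
    def mode(self) -> float:
        return float(self.centers[int(np.argmax(self.density))])

    def variance(self) -> float:
        c = self.centers
        mean = float((self.density * c).sum())
        return float((self.density * (c - mean) ** 2).sum())


@dataclass(frozen=True)
class ConsensusResult:
    tf: str
    lam_hat: float
    per_target: dict[str, PosteriorHistogram]
    product: PosteriorHistogram
    targets_used: tuple[str, ...] = ()


@dataclass(frozen=True)
class MCMCConfig:
    n_steps: int = 20_000
    burn_in_fraction: float = 0.25
    temperature: float = 0.05        # T_mc of the pseudo-posterior exp(-S/T)
    initial_step_scale: float = 0.1  # in units of each parameter's bound span
    seed: int = 0
    bin_edges: np.ndarray | None = None


def tf_sign_in_fit(fit: FitResult, tf: str) -> int:
    """Monotone direction (+1 activator, -1 repressor, 0 non-monotone) of a
    TF within a fitted form."""
    if tf not in fit.inputs:
        raise ValueError(f"{tf!r} is not an input of this fit")
    return MONOTONE_SIGNS[fit.spec.form][fit.inputs.index(tf)]


def select_lambda_targets(tf: str, fits: list[FitResult],
                          periodic_flags: dict[str, bool],
                          sign_reference: dict[str, int]) -> list[str]:
    """Targets usable for lam consensus: periodically expressed, fitted with
    the TF at score < 0.5, and with the TF's fitted regulatory sign matching
    the literature reference (+1 activator / -1 repressor)."""
    targets = []
    for fit in fits:
        if tf not in fit.inputs:
            continue
        if not periodic_flags.get(fit.gene, False):
            continue
        if fit.score >= SCORE_CUTOFF:
            continue
        ref = sign_reference.get(fit.gene)
        if ref is not None and tf_sign_in_fit(fit, tf) != ref:
            continue
        if fit.gene not in targets:
            targets.append(fit.gene)
    if not targets:
        warnings.warn(f"no suitable consensus targets for TF {tf!r}",
                      stacklevel=2)
    return targets


def sample_lambda_posterior(target: GeneTimeSeries, inputs: list[GeneTimeSeries],
                            fit: FitResult, tf: str,
                            config: MCMCConfig | None = None,
                            fit_config: FitConfig | None = None) -> PosteriorHistogram:
    """Metropolis sampling of all fit parameters around a converged fit;
    returns the marginal histogram over the TF's lam on the shared bin grid.

    The chain lives in the same transformed coordinates as the optimizer
    (log for scale parameters, linear for n) with per-parameter Gaussian
    proposals whose scale adapts during burn-in only, keeping the
    post-burn-in kernel fixed and the sampler reproducible.
    """
    config = config or MCMCConfig()
    problem = _Problem(target, inputs, fit.spec.form, fit_config or FitConfig(),
                       fixed_lam=None)
    if tf not in fit.inputs:
        raise ValueError(f"{tf!r} is not an input of this fit")
    a = problem.arity
    lam_index = 2 + 2 * a + fit.inputs.index(tf)

    # start from the converged fit, in transformed coordinates
    theta = np.concatenate([
        [math.log(fit.spec.b), math.log(fit.spec.alpha)],
        np.log(fit.spec.K), fit.spec.n, np.log(fit.lam)])
    theta = np.clip(theta, problem.lower, problem.upper)
    energy = problem(theta)

    rng = np.random.default_rng(config.seed)
    span = problem.upper - problem.lower
    step = config.initial_step_scale * span
    burn = int(config.n_steps * config.burn_in_fraction)
    samples = np.empty(config.n_steps - burn)
    accepted_total = 0
    accepted_window = 0
    for i in range(config.n_steps):
        d = rng.integers(problem.dim)
        trial = theta.copy()
        trial[d] = np.clip(trial[d] + rng.normal(0.0, step[d]),
                           problem.lower[d], problem.upper[d])
        e = problem(trial)
        if e <= energy or rng.random() < math.exp(-(e - energy) / config.temperature):
            theta, energy = trial, e
            accepted_total += 1
            accepted_window += 1
        if i < burn and (i + 1) % 200 == 0:
            ratio = accepted_window / 200
            step = np.clip(step * math.exp(ratio - 0.3), 1e-4 * span, span)
            accepted_window = 0
        if i >= burn:
            samples[i - burn] = math.exp(theta[lam_index])

    rate = accepted_total / config.n_steps
    if not 0.05 <= rate <= 0.8:
        warnings.warn(f"MCMC acceptance rate {rate:.2f} outside [0.05, 0.8]; "
                      "check temperature/step settings", stacklevel=2)

    edges = config.bin_edges if config.bin_edges is not None else default_bin_edges()
    counts, _ = np.histogram(samples, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no lam samples fell inside the histogram support")
    return PosteriorHistogram(bin_edges=edges, density=counts / total)


def combine_posteriors(histograms: list[PosteriorHistogram],
                       tf: str = "", targets: tuple[str, ...] = ()) -> ConsensusResult:
    """Multiply per-target marginals bin-wise and take the product's mode.

    Disjoint supports (identically zero product) indicate mutually
    inconsistent targets and raise instead of being smoothed away.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if not np.array_equal(h.bin_edges, edges):
            raise ValueError("histograms must share bin edges")
    product = np.ones_like(histograms[0].density)
    for h in histograms:
        product = product * h.density
    if product.sum() == 0:
        raise ValueError("inconsistent targets: product histogram is zero everywhere")
    prod_hist = PosteriorHistogram(bin_edges=edges, density=product / product.sum())
    per_target = {t: h for t, h in zip(targets, histograms)} if targets else \
        {str(i): h for i, h in enumerate(histograms)}
    return ConsensusResult(tf=tf, lam_hat=prod_hist.mode,
                           per_target=per_target, product=prod_hist,
                           targets_used=tuple(per_target))
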