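"""Gene regulation function (GRF) forms: Hill-term combinatorial logic.

A GRF maps input TF protein concentrations to a target's mRNA synthesis
rate.  Building blocks are the activating Hill term
h(p; K, n) = p^n / (K^n + p^n) and its repressing complement
r(p; K, n) = K^n / (K^n + p^n) = 1 - h.  One-input genes are either
activated (ACT) or repressed (REP); two inputs combine through the ten
non-trivial analog logic forms (AND, OR, ANDNOT, NOTAND, ORNOT, NOTOR,
NOR, NAND, XOR, EQ).  Every form reads

    s = b + alpha * [bracket of Hill terms]

with basal rate b and regulation amplitude alpha.  Additive brackets
(OR family, SUM_OF_ANDS) can reach 2, so their maximal fold change is
b + 2*alpha; they are deliberately not renormalized and alpha is the
per-branch amplitude.

SUM_OF_ANDS is the composite four-input form used for a gene repressed by
two factors and additively activated by two others (cyclin drive plus
autoactivation): s = b + alpha * [r1*r2 + h3*h4].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["GRFForm", "GRFSpec", "hill_act", "hill_rep", "evaluate",
           "evaluate_swi4", "enumerate_forms", "parameter_count",
           "grf_gradient", "N_MIN", "N_MAX"]

# Sensitivity bounds used during fitting: n < 1 is non-sigmoidal, n > 8 is
# indistinguishable from a step at 42-point sampling.
N_MIN, N_MAX = 1.0, 8.0


class GRFForm(str, enum.Enum):
    ACT = "ACT"
    REP = "REP"
    AND = "AND"
    OR = "OR"
    ANDNOT = "ANDNOT"      # p1 AND NOT p2
    NOTAND = "NOTAND"      # NOT p1 AND p2
    ORNOT = "ORNOT"        # p1 OR NOT p2
    NOTOR = "NOTOR"        # NOT p1 OR p2
    NOR = "NOR"
    NAND = "NAND"
    XOR = "XOR"
    EQ = "EQ"
    SUM_OF_ANDS = "SUM_OF_ANDS"


ONE_INPUT_FORMS = (GRFForm.ACT, GRFForm.REP)
TWO_INPUT_FORMS = (GRFForm.AND, GRFForm.OR, GRFForm.ANDNOT, GRFForm.NOTAND,
                   GRFForm.ORNOT, GRFForm.NOTOR, GRFForm.NOR, GRFForm.NAND,
                   GRFForm.XOR, GRFForm.EQ)

_ARITY = {f: 1 for f in ONE_INPUT_FORMS}
_ARITY.update({f: 2 for f in TWO_INPUT_FORMS})
_ARITY[GRFForm.SUM_OF_ANDS] = 4

# analytic maximum of the bracketed term
_BRACKET_MAX = {f: 1.0 for f in GRFForm}
for _f in (GRFForm.OR, GRFForm.ORNOT, GRFForm.NOTOR, GRFForm.NAND,
           GRFForm.SUM_OF_ANDS):
    _BRACKET_MAX[_f] = 2.0

# monotonic direction per input (+1 increasing, -1 decreasing, 0 neither)
MONOTONE_SIGNS = {
    GRFForm.ACT: (1,), GRFForm.REP: (-1,),
    GRFForm.AND: (1, 1), GRFForm.OR: (1, 1),
    GRFForm.ANDNOT: (1, -1), GRFForm.NOTAND: (-1, 1),
    GRFForm.ORNOT: (1, -1), GRFForm.NOTOR: (-1, 1),
    GRFForm.NOR: (-1, -1), GRFForm.NAND: (-1, -1),
    GRFForm.XOR: (0, 0), GRFForm.EQ: (0, 0),
    GRFForm.SUM_OF_ANDS: (-1, -1, 1, 1),
}

SYMMETRIC_FORMS = (GRFForm.AND, GRFForm.OR, GRFForm.NOR, GRFForm.NAND,
                   GRFForm.XOR, GRFForm.EQ)


def arity_of(form: GRFForm) -> int:
    return _ARITY[GRFForm(form)]


def bracket_max(form: GRFForm) -> float:
    """Analytic maximum of the bracketed Hill combination for the form."""
    return _BRACKET_MAX[GRFForm(form)]


def hill_act(p, K: float, n: float):
    """Activating Hill term p^n/(K^n + p^n), overflow-free for large n.

    Evaluated as a logistic in log-concentration: expit(n*(ln p - ln K)).
    p = 0 maps to 0 exactly (n >= 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("protein concentrations must be nonnegative")
    with np.errstate(divide="ignore"):
        out = expit(n * (np.log(p) - np.log(K)))
    out = np.where(p == 0, 0.0, out)
    return out if out.ndim else float(out)


def hill_rep(p, K: float, n: float):
    """Repressing Hill term K^n/(K^n + p^n) = 1 - hill_act."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("protein concentrations must be nonnegative")
    with np.errstate(divide="ignore"):
        out = expit(n * (np.log(K) - np.log(p)))
    out = np.where(p == 0, 1.0, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GRFSpec:
    """A regulation form plus its parameters.

    K and n carry one entry per input, in input order; b and alpha are
    global.  ``inputs`` names the regulators (order matters for the
    asymmetric forms).
    """

    form: GRFForm
    b: float
    alpha: float
    K: tuple[float, ...]
    n: tuple[float, ...]
    inputs: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        form = GRFForm(self.form)
        object.__setattr__(self, "form", form)
        object.__setattr__(self, "K", tuple(float(k) for k in self.K))
        object.__setattr__(self, "n", tuple(float(v) for v in self.n))
        object.__setattr__(self, "inputs", tuple(self.inputs))
        ar = arity_of(form)
        if len(self.K) != ar or len(self.n) != ar:
            raise ValueError(f"{form.value} needs {ar} (K, n) pairs")
        if self.inputs and len(self.inputs) != ar:
            raise ValueError(f"{form.value} needs {ar} inputs, got {len(self.inputs)}")
        if self.b < 0 or self.alpha < 0:
            raise ValueError("b and alpha must be nonnegative")
        if any(k <= 0 for k in self.K):
            raise ValueError("thresholds K must be positive")
        if any(v < 1 for v in self.n):
            raise ValueError("sensitivities n must be >= 1")

    @property
    def arity(self) -> int:
        return arity_of(self.form)

    def to_dict(self) -> dict:
        return {"form": self.form.value, "b": self.b, "alpha": self.alpha,
                "K": list(self.K), "n": list(self.n), "inputs": list(self.inputs)}

    @classmethod
    def from_dict(cls, d: dict) -> "GRFSpec":
        return cls(form=GRFForm(d["form"]), b=d["b"], alpha=d["alpha"],
                   K=tuple(d["K"]), n=tuple(d["n"]), inputs=tuple(d.get("inputs", ())))


def _bracket(form: GRFForm, terms_act, terms_rep):
    h, r = terms_act, terms_rep
    if form == GRFForm.ACT:
        return h[0]
    if form == GRFForm.REP:
        return r[0]
    if form == GRFForm.AND:
        return h[0] * h[1]
    if form == GRFForm.OR:
        return h[0] + h[1]
    if form == GRFForm.ANDNOT:
        return h[0] * r[1]
    if form == GRFForm.NOTAND:
        return r[0] * h[1]
    if form == GRFForm.ORNOT:
        return h[0] + r[1]
    if form == GRFForm.NOTOR:
        return r[0] + h[1]
    if form == GRFForm.NOR:
        return r[0] * r[1]
    if form == GRFForm.NAND:
        return r[0] + r[1]
    if form == GRFForm.XOR:
        return h[0] * r[1] + r[0] * h[1]
    if form == GRFForm.EQ:
        return h[0] * h[1] + r[0] * r[1]
    if form == GRFForm.SUM_OF_ANDS:
        return r[0] * r[1] + h[2] * h[3]
    raise ValueError(f"unknown form {form}")  # pragma: no cover


def evaluate(spec: GRFSpec, p):
    """Evaluate a GRF at protein concentrations ``p`` (one scalar or array
    per input, in spec input order).  Returns the model synthesis rate."""
    ar = spec.arity
    if len(p) != ar:
        raise ValueError(f"{spec.form.value} takes {ar} inputs, got {len(p)}")
    h = [hill_act(p[i], spec.K[i], spec.n[i]) for i in range(ar)]
    r = [hill_rep(p[i], spec.K[i], spec.n[i]) for i in range(ar)]
    return spec.b + spec.alpha * _bracket(spec.form, h, r)


def evaluate_swi4(spec: GRFSpec, p_rep1, p_rep2, p_act1, p_act2):
    """Composite additive-AND GRF: two repressors times two additive
    activators, s = b + alpha*[r1*r2 + h3*h4].  Input order is
    (repressor1, repressor2, activator1, activator2)."""
    if spec.form != GRFForm.SUM_OF_ANDS:
        raise ValueError("spec must use the SUM_OF_ANDS form")
    return evaluate(spec, [p_rep1, p_rep2, p_act1, p_act2])


def _hill_derivative(p: float, K: float, n: float) -> float:
    """d/dp of the activating Hill term at a scalar p >= 0."""
    if p == 0.0:
        return 1.0 / K if n == 1.0 else 0.0
    h = hill_act(p, K, n)
    return n / p * h * (1.0 - h)


def grf_gradient(spec: GRFSpec, p) -> np.ndarray:
    """Partial derivatives of the synthesis rate w.r.t. each scalar input.

    Used for analytic ODE Jacobians; computed by product/sum rules on the
    Hill terms of the form's bracket.
    """
    ar = spec.arity
    if len(p) != ar:
        raise ValueError(f"{spec.form.value} takes {ar} inputs, got {len(p)}")
    h = [float(hill_act(p[i], spec.K[i], spec.n[i])) for i in range(ar)]
    r = [1.0 - hi for hi in h]
    dh = [_hill_derivative(float(p[i]), spec.K[i], spec.n[i]) for i in range(ar)]
    grad = np.zeros(ar)
    for i in range(ar):
        bumped_h = list(h)
        bumped_r = list(r)
        # d(bracket)/dh_i, evaluated by linearity of the bracket in each h_i
        bumped_h[i], bumped_r[i] = 1.0, 0.0
        hi_one = _bracket(spec.form, bumped_h, bumped_r)
        bumped_h[i], bumped_r[i] = 0.0, 1.0
        hi_zero = _bracket(spec.form, bumped_h, bumped_r)
        grad[i] = spec.alpha * (hi_one - hi_zero) * dh[i]
    return grad


def enumerate_forms(arity: int) -> list[GRFForm]:
    """All regulation forms of the given arity: 2 one-input directions or
    the 10 non-trivial two-input analog logic operations."""
    if arity == 1:
        return list(ONE_INPUT_FORMS)
    if arity == 2:
        return list(TWO_INPUT_FORMS)
    raise ValueError(f"no systematic form menu for arity {arity}")


def parameter_count(form: GRFForm, include_protein: bool = False) -> int:
    """Number of free parameters: b, alpha plus (K, n) per input; with
    ``include_protein`` add one degradation rate per input."""
    ar = arity_of(form)
    count = 2 + 2 * ar
    if include_protein:
        count += ar
    return count
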