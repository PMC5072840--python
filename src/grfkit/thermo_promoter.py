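"""Thermodynamic-ensemble regulation function for a configurable promoter.

Occupancy states of the promoter's binding sites are Boltzmann-weighted:
a state's weight is the product of per-site affinity*concentration terms
and pairwise cooperativity factors; each state carries a fold-activation F
describing how strongly the bound configuration attracts RNA polymerase
(F = 1 for the empty promoter).  The synthesis rate is

    s = basal + scale * (<F> - 1),   <F> = sum_states W*F / sum_states W

so an empty promoter (all concentrations zero) transcribes at the basal
rate and a single activating site reduces exactly to a Hill function with
n = 1.  Overlapping sites are expressed as mutual-exclusion groups;
recruited factors (cofactors without intrinsic DNA affinity for the bare
promoter) bind only when at least one of their platform sites is occupied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PromoterArchitecture", "ThermoParams", "enumerate_states",
           "evaluate_thermo", "state_probabilities", "project_grf",
           "kip2_architecture", "kip2_parameter_names", "kip2_params"]


@dataclass(frozen=True)
class PromoterArchitecture:
    """Binding sites (site name -> bound TF), exclusion groups, recruitments."""

    sites: dict[str, str]
    exclusions: tuple[frozenset[str], ...] = ()
    recruitments: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "exclusions",
                           tuple(frozenset(e) for e in self.exclusions))
        object.__setattr__(self, "recruitments",
                           {k: frozenset(v) for k, v in self.recruitments.items()})
        declared = set(self.sites)
        for group in self.exclusions:
            if not group <= declared:
                raise ValueError(f"exclusion group {set(group)} references unknown sites")
        for rec, platforms in self.recruitments.items():
            if rec not in declared or not platforms <= declared:
                raise ValueError(f"recruitment for {rec!r} references unknown sites")
        self._check_acyclic()

    def _check_acyclic(self):
        # edge platform -> recruited; a cycle would make occupancy ill-defined
        color: dict[str, int] = {}

        def visit(site: str):
            if color.get(site) == 1:
                raise ValueError("cyclic recruitment chain detected")
            if color.get(site) == 2:
                return
            color[site] = 1
            for rec, platforms in self.recruitments.items():
                if site in platforms:
                    visit(rec)
            color[site] = 2

        for s in self.sites:
            visit(s)

    @property
    def tfs(self) -> list[str]:
        seen: list[str] = []
        for tf in self.sites.values():
            if tf not in seen:
                seen.append(tf)
        return seen


@dataclass(frozen=True)
class ThermoParams:
    """Boltzmann weights of the promoter ensemble.

    affinity: per-site statistical weight per unit TF concentration.
    cooperativity: extra weight factor for site pairs bound simultaneously.
    polymerase_attraction: fold-activation F per occupancy state
    (frozenset of site names); unlisted states have F = 1.
    """

    affinity: dict[str, float]
    cooperativity: dict[frozenset[str], float] = field(default_factory=dict)
    polymerase_attraction: dict[frozenset[str], float] = field(default_factory=dict)
    basal: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "cooperativity",
                           {frozenset(k): float(v) for k, v in self.cooperativity.items()})
        object.__setattr__(self, "polymerase_attraction",
                           {frozenset(k): float(v)
                            for k, v in self.polymerase_attraction.items()})
        if any(a <= 0 for a in self.affinity.values()):
            raise ValueError("affinities must be positive")
        if any(w <= 0 for w in self.cooperativity.values()):
            raise ValueError("cooperativities must be positive")


def enumerate_states(arch: PromoterArchitecture) -> list[frozenset[str]]:
    """All occupancy states consistent with exclusions and recruitments,
    including the empty promoter (brute-force subset filter; <= 12 sites)."""
    sites = sorted(arch.sites)
    if len(sites) > 12:
        raise ValueError("state enumeration limited to 12 sites")
    states = []
    for r in range(len(sites) + 1):
        for combo in itertools.combinations(sites, r):
            occ = frozenset(combo)
            if any(len(occ & group) > 1 for group in arch.exclusions):
                continue
            if any(rec in occ and not (platforms & occ)
                   for rec, platforms in arch.recruitments.items()):
                continue
            states.append(occ)
    return states


def _weights(arch, params, p: dict[str, float], states):
    w = np.empty(len(states))
    for i, state in enumerate(states):
        wi = 1.0
        for site in state:
            tf = arch.sites[site]
            if tf not in p:
                raise ValueError(f"missing concentration for TF {tf!r}")
            if p[tf] < 0:
                raise ValueError(f"negative concentration for TF {tf!r}")
            wi *= params.affinity[site] * p[tf]
        for pair, coop in params.cooperativity.items():
            if pair <= state:
                wi *= coop
        w[i] = wi
    return w


def state_probabilities(arch: PromoterArchitecture, params: ThermoParams,
                        p: dict[str, float]) -> dict[frozenset[str], float]:
    """Equilibrium occupancy probabilities; they sum to one."""
    states = enumerate_states(arch)
    w = _weights(arch, params, p, states)
    w /= w.sum()
    return dict(zip(states, w))


def evaluate_thermo(arch: PromoterArchitecture, params: ThermoParams,
                    p: dict[str, float]) -> float:
    """Synthesis rate basal + scale*(<F> - 1) with <F> the ensemble-averaged
    polymerase fold-activation."""
    states = enumerate_states(arch)
    w = _weights(arch, params, p, states)
    F = np.array([params.polymerase_attraction.get(s, 1.0) for s in states])
    return float(params.basal + params.scale * ((w * F).sum() / w.sum() - 1.0))


def project_grf(arch: PromoterArchitecture, params: ThermoParams,
                fixed: dict[str, float], free: tuple[str, str],
                grid1: np.ndarray, grid2: np.ndarray) -> np.ndarray:
    """2-D GRF surface over a lattice of the two free TF concentrations,
    all other TFs held at ``fixed``.  Returns shape (len(grid1), len(grid2))."""
    tf1, tf2 = free
    known = set(fixed) | {tf1, tf2}
    missing = [tf for tf in arch.tfs if tf not in known]
    if tf1 not in arch.tfs or tf2 not in arch.tfs:
        raise ValueError(f"free TFs {free} not in architecture")
    if missing:
        raise ValueError(f"no concentration for TFs {missing}")
    out = np.empty((len(grid1), len(grid2)))
    for i, c1 in enumerate(grid1):
        for j, c2 in enumerate(grid2):
            conc = dict(fixed)
            conc[tf1], conc[tf2] = float(c1), float(c2)
            out[i, j] = evaluate_thermo(arch, params, conc)
    return out


# --- the three-input G2/M promoter (Kip2-like architecture) -------------------

def kip2_architecture() -> PromoterArchitecture:
    """Promoter with three dynamic inputs: Fkh2 (binding as a complex with
    the constant platform factor Mcm1), Fkh1 on a site that overlaps the
    Mcm1/Fkh2 region, and the coactivator Ndd1, recruited by either
    forkhead platform.  Mcm1 occupies its own site but is not a dynamic
    input; its concentration is held constant by the caller."""
    return PromoterArchitecture(
        sites={"mcm1": "Mcm1", "fkh2": "Fkh2", "fkh1": "Fkh1", "ndd1": "Ndd1"},
        exclusions=(frozenset({"mcm1", "fkh1"}), frozenset({"fkh2", "fkh1"})),
        recruitments={"ndd1": frozenset({"fkh2", "fkh1"})},
    )


def kip2_parameter_names() -> list[str]:
    """The 12 free parameters of the three-input promoter model: 3 affinities,
    2 recruitment cooperativities, 2 proximal-pair interactions, 3 polymerase
    attractions (one per activating configuration class), basal and scale.
    The constant Mcm1 site weight is folded to 1."""
    return [
        "affinity_fkh2", "affinity_fkh1", "affinity_ndd1",
        "coop_fkh2_ndd1", "coop_fkh1_ndd1",
        "coop_mcm1_fkh2", "coop_mcm1_ndd1",
        "pol_fkh2_ndd1", "pol_fkh1_ndd1", "pol_fkh1",
        "basal", "scale",
    ]


def kip2_params(values: dict[str, float]) -> ThermoParams:
    """Assemble :class:`ThermoParams` for :func:`kip2_architecture` from the
    named 12-parameter vector of :func:`kip2_parameter_names`.

    The two Ndd1-bound forkhead-platform classes and the lone Fkh1 state
    activate transcription; all other configurations are basal.
    """
    missing = set(kip2_parameter_names()) - set(values)
    if missing:
        raise ValueError(f"missing parameters: {sorted(missing)}")
    v = values
    return ThermoParams(
        affinity={"mcm1": 1.0, "fkh2": v["affinity_fkh2"],
                  "fkh1": v["affinity_fkh1"], "ndd1": v["affinity_ndd1"]},
        cooperativity={
            frozenset({"fkh2", "ndd1"}): v["coop_fkh2_ndd1"],
            frozenset({"fkh1", "ndd1"}): v["coop_fkh1_ndd1"],
            frozenset({"mcm1", "fkh2"}): v["coop_mcm1_fkh2"],
            frozenset({"mcm1", "ndd1"}): v["coop_mcm1_ndd1"],
        },
        polymerase_attraction={
            frozenset({"fkh2", "ndd1"}): v["pol_fkh2_ndd1"],
            frozenset({"mcm1", "fkh2", "ndd1"}): v["pol_fkh2_ndd1"],
            frozenset({"fkh1", "ndd1"}): v["pol_fkh1_ndd1"],
            frozenset({"fkh1"}): v["pol_fkh1"],
        },
        basal=v["basal"], scale=v["scale"],
    )
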