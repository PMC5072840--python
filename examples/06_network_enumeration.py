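"""Combinatorial enumeration of strongly connected candidate networks.

Once every node's possible regulations are pre-fitted, whole networks are
just combinations of per-node choices, scored by the mean node score and
filtered to strongly connected wirings (a closed oscillator module must
let every gene influence every other).  This example pre-fits all input
sets of the driven 10-gene oscillator fixture and prints the top-3
networks; rank 1 should reproduce the true wiring.
"""

import math

from grfkit import (Kind, NodeCandidateSet, enumerate_networks, fast_config,
                    make_fixture, rank_report, select_best_form)

ds = make_fixture("driven_oscillator_10", seed=0)
truth = ds.truth

candidates = {}
for g in sorted(truth.nodes):
    allowed = list(truth.nodes[g].inputs)
    target = ds.observed.get(g, Kind.synthesis_rate, "1")
    input_sets = [(a,) for a in allowed]
    if len(allowed) == 2:
        input_sets.append(tuple(allowed))
    menu = []
    for names in input_sets:
        series = [ds.observed.get(i, Kind.mrna_level, "1") for i in names]
        lam = tuple(truth.lam.get(i, math.log(2) / 10.0) for i in names)
        menu.append(select_best_form(target, series, fast_config(seed=0),
                                     fixed_lam=lam))
    candidates[g] = NodeCandidateSet(g, menu)

report = rank_report(enumerate_networks(candidates, lam=truth.lam,
                                        delta=truth.delta,
                                        externals=truth.externals), top_k=3)
true_topology = {g: sorted(f.inputs) for g, f in truth.nodes.items()}
for entry in report:
    wiring = {g: n["inputs"] for g, n in entry["nodes"].items()}
    print(f"rank {entry['rank']}: score {entry['score']:.3f}  "
          f"matches truth: {wiring == true_topology}  "
          f"differs at: {entry['differs_from_rank1_at'] or '-'}")
print("\nLower-ranked networks drop one input at a repressed node; the")
print("score gap quantifies how much that regulation explains.")
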