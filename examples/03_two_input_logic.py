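"""Selecting combinatorial regulatory logic for a two-input gene.

Target C is regulated by TFs A and B through AND logic (both inputs must
be present).  All ten non-trivial analog logic forms are fitted and ranked
by score; AND should win and the competing forms quantify how sharply the
data discriminate between logics.
"""

from grfkit import Kind, fast_config, make_fixture, select_best_form

ds = make_fixture("two_input_and", seed=0)
target = ds.observed.get("C", Kind.synthesis_rate, "1")
inputs = [ds.observed.get(g, Kind.mrna_level, "1") for g in ("A", "B")]
lam = (ds.truth.lam["A"], ds.truth.lam["B"])

best, results = select_best_form(target, inputs, fast_config(seed=0),
                                 fixed_lam=lam, return_all=True)

print("form ranking (score = unexplained variance fraction):")
for r in sorted(results, key=lambda r: r.score):
    marker = " <- selected" if r.spec.form == best.spec.form else ""
    print(f"  {r.spec.form.value:7s} {r.score:6.3f}{marker}")
print(f"\ntrue logic: {ds.truth.nodes['C'].spec.form.value}")
print("AND wins clearly; EQ (its closest analog neighbour) trails, and")
print("forms with the wrong monotonicity explain almost nothing.")
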