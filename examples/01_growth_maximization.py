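"""Assemble a mini-cell ME model and maximize its growth rate.

Generates a seeded synthetic organism, expands it into a
metabolism-and-expression model, and finds the maximum feasible growth
rate by bisection over LP feasibility. The printed census shows how the
expression layer dwarfs the metabolic core, and the decoupled (M-like)
variant shows how much growth the expression burden costs.
"""

from mecell import (
    assemble_me_model,
    decouple_model,
    generate_minicell,
    maximize_growth,
)

spec = generate_minicell(seed=7)
model = assemble_me_model(spec)

print("reaction census:")
for rtype, n in sorted(model.census().items()):
    print(f"  {rtype:18s} {n}")

result = maximize_growth(model)
print(f"\nmax growth rate mu* = {result.mu_star:.4f} 1/h "
      f"({result.iterations} bisection steps, "
      f"bracket width {result.bracket[1] - result.bracket[0]:.1e})")
print(f"glucose uptake  {-result.solution['EX_glc_e']:.2f} mmol/gDW/h")
print(f"reporter secretion {result.solution['translocation_g_amy']:.2e} "
      "mmol/gDW/h")

decoupled = maximize_growth(decouple_model(model))
print(f"\ndecoupled (M-like) mu* = {decoupled.mu_star:.4f} 1/h — "
      "removing expression costs inflates growth and lets the futile "
      f"cycle run at {decoupled.solution['FC1']:.0f} mmol/gDW/h "
      f"(coupled: {result.solution['FC1']:.0f}).")
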