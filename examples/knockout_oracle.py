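"""Exhaustive knockout enumeration as ground truth for the grid design.

On networks with few unprotected reactions every knockout subset can be
scored directly; the grid search must never report a better production rate
than this oracle.
"""

import gridprod as gp

toy = gp.build_toy_network()
oracle = gp.brute_force_design(toy, medium=gp.toy_medium())
print(f"toy network optimum: knock out {sorted(oracle.best_knockouts)} "
      f"-> GR = {oracle.gr:g}, PR = {oracle.pr:g}")

print("\nrandom small networks (grid score vs exhaustive optimum):")
for seed in (3, 9, 14, 15):
    model = gp.random_network(3, 8 + seed % 4, seed=seed)
    grid = gp.run_gridprod(model, grid=gp.GridConfig(p_inv=5))
    best = gp.brute_force_design(model)
    flag = "dominated, as required" if grid.pr <= best.pr + 1e-6 else "VIOLATION"
    print(f"  seed {seed:2d} ({len(model.reactions)} reactions): "
          f"grid PR = {grid.pr:5.2f}   oracle PR = {best.pr:5.2f}   ({flag})")
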