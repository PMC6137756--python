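"""Walk through the design procedure on the 8-reaction toy network.

Shows why a grid over (growth, production) space is needed: at maximal
growth the intact network produces nothing, and only removing the direct
growth route (R3) couples growth to production.
"""

import gridprod as gp

toy = gp.build_toy_network()
medium = gp.toy_medium()  # minimum viable growth rate 1

tmgr = gp.compute_tmgr(toy)
tmpr = gp.compute_tmpr(toy)
print(f"theoretical maximum growth rate  TMGR = {tmgr:g}")
print(f"theoretical maximum production   TMPR = {tmpr:g}")

# What the intact network does at its growth optimum: nothing for us.
sec = gp.second_lp(toy, set(), medium)
print(f"intact network at max growth: GR = {sec.gr:g}, PR = {sec.pr:g}")

# Knock out R3 (the direct growth route): growth drops to 1 but every
# remaining flux pattern must push 4 units through the target exchange.
sec = gp.second_lp(toy, {"R3"}, medium)
print(f"R3 knocked out:               GR = {sec.gr:g}, PR = {sec.pr:g}")

# The full grid search at 5x5 resolution.  On this network the parsimonious
# first LP always keeps R3 active, so no cell discovers the design — the
# sharp case that motivates comparing against the exhaustive oracle.
result = gp.run_gridprod(toy, grid=gp.GridConfig(p_inv=5), medium=medium)
print(f"grid search best score: PR = {result.pr:g} "
      f"(matrix max over {result.pr_matrix.size} cells)")
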