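"""Model-implied development vector field from a fitted bivariate model.

Each arrow starts at a hypothetical pair of wave-1 scores and points to the
model-implied expected wave-2 position: E[change] evaluated exactly from the
fitted change equations.  With positive couplings, arrows in the high-
vocabulary column point further up (more reasoning gain), and arrows in the
high-reasoning rows point further right (more vocabulary gain).
"""

import numpy as np

import lcspanel as L

data = L.simulate_panel(L.nspn_like_preset(), 785, seed=1)
fit = L.fit_model(L.build_bivariate_lcs(), data)

voc_grid = np.linspace(45, 72, 7)
mat_grid = np.linspace(23, 34, 6)
field = L.expected_change_field(fit, voc_grid, mat_grid)

print("Expected reasoning change as vocabulary varies (at reasoning = 28.6):")
j = 3
for i, v in enumerate(field.voc_grid):
    print(f"  voc1 = {v:5.1f}  ->  E[d mat] = {field.dmat[i, j]:+.2f}")
print()
print("Expected vocabulary change as reasoning varies (at vocabulary = 58.5):")
i = 3
for j, m in enumerate(field.mat_grid):
    print(f"  mat1 = {m:5.1f}  ->  E[d voc] = {field.dvoc[i, j]:+.2f}")

try:
    import matplotlib

    matplotlib.use("Agg")
    ax = field.plot(color="tab:blue", width=0.003)
    ax.figure.savefig("vector_field.png", dpi=150, bbox_inches="tight")
    print("\nSaved quiver plot to vector_field.png")
except ImportError:
    print("\n(matplotlib not installed; skipping the quiver plot)")
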