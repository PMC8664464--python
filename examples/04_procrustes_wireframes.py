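"""Generalized Procrustes analysis and species mean-shape wireframes.

Superimposes a jittered cohort of Nv male heads, extracts the consensus
shape, and exports the head wireframe — the overlay used to compare species
mean head shapes.
"""

import numpy as np

from waspmorph import GeneratorConfig, gpa, wireframe_export
from waspmorph.synthetic import make_templates, sample_head

cfg = GeneratorConfig(seed=42)
rng = np.random.default_rng(42)
template = make_templates()[("Nv", "male")]
cohort = [sample_head(template, rng, cfg, f"nv-{i}").config for i in range(30)]

mean, aligned = gpa(cohort)
print(f"GPA on {mean.n_specimens} Nv male heads: converged={mean.converged} "
      f"in {mean.iterations} iteration(s)")

resid = np.mean([((a.coords - mean.coords) ** 2).sum() for a in aligned])
print(f"mean Procrustes residual about the consensus: {resid:.6f}")

segments = wireframe_export(mean)
print(f"\nwireframe: {len(segments)} segments (consensus coordinates, unit centroid size)")
for a, b, pa, pb in segments[:4]:
    print(f"  {a} -> {b}: length {np.linalg.norm(pa - pb):.4f}")

print(
    "\nThe consensus is the iteratively refit mean shape; wireframe segment"
    "\nlengths are in consensus units (centroid size 1) and overlaying the"
    "\nwireframes of different species shows where their heads diverge."
)
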