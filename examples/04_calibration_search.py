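"""Constraint-based calibration: screening random rate constants.

Samples parameter sets log-uniformly around the shipped defaults, screens
them with the fast mean-field model against the behavioural constraints
(peak timing, return to baseline, group orderings, PP2 reversal,
activation pattern), and confirms the leaders with SSA ensembles.  This
is a small demonstration run; the shipped defaults were produced by the
same procedure at larger sample counts.
"""

from mechanoscx import (ConstraintSet, bounds_around, constraint_search,
                        default_parameters)

params = default_parameters()
result = constraint_search(bounds_around(params, span=2.0), ConstraintSet(),
                           n_samples=100, seed=1, base=params,
                           n_confirm=3, n_reps_confirm=100)

print(f"samples screened:        {len(result.samples)}")
print(f"acceptance fraction:     {result.acceptance_fraction:.3f}")
print(f"best sample index:       {result.best_index}")
best = result.samples.loc[result.best_index]
for name in result.constraint_names:
    print(f"  {name:16s} margin {best[f'{name}_margin']:+.3f}")

# The acceptance fraction is the share of random sets satisfying every
# constraint; margins are signed distances to each pass boundary
# (positive = satisfied with room to spare).
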