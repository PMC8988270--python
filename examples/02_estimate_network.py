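"""Estimate one regularized partial-correlation network per group.

Each group's item scores are residualized on age and sex, correlated, and
fitted with the graphical LASSO along a penalty path; the EBIC picks the
final sparsity level.
"""
from symptomnet import estimate_network, four_group_fixture, residualize_items
from symptomnet.simulate import concat_cohorts

cohorts, models = four_group_fixture(seed=1)
resid = residualize_items(concat_cohorts(cohorts))

print(f"{'group':>6} {'n':>4} {'true':>5} {'estimated':>9} {'lambda':>8}")
for g in ("CD", "RD", "SD", "HC"):
    net = estimate_network(resid.for_group(g))
    print(f"{g:>6} {net.n:>4} {len(models[g].edge_set):>5} "
          f"{net.nonzero_edge_count:>9} {net.lambda_selected:>8.4f}")

print("\nEstimated nonzero-edge counts follow the generating structure:")
print("dense for CD and RD, sparse for SD, empty for HC — severity does not")
print("drive density, connectivity does.")
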