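"""Run the somatic filtering cascade on a simulated tumor/normal pair.

Simulates a paired exome at the study operating point (purity 0.88, mean
depth 47x) with known ground truth, runs the four-stage cascade, and scores
the call set against the truth labels.
"""

from somaticmz import (
    SimulationConfig,
    blacklist_from_truth,
    run_cascade,
    simulate_pair,
    variant_key,
)
from somaticmz.synthetic_cohort import GERMLINE, SOMATIC

cfg = SimulationConfig(
    n_germline_het=2000, n_somatic=100, n_artifacts=100, n_polymorphisms=50, seed=11
)
pairs, truth = simulate_pair(cfg)
called, report = run_cascade(pairs, blacklist=blacklist_from_truth(pairs, truth))

print("per-stage attrition:", report.to_dict())

called_keys = {variant_key(p) for p in called}
by_key = {variant_key(p): t for p, t in zip(pairs, truth)}
clonal = [k for k, t in by_key.items() if t.origin == SOMATIC and t.ccf == 1.0]
subclonal = [k for k, t in by_key.items() if t.origin == SOMATIC and t.ccf == 0.25]
germline = [k for k, t in by_key.items() if t.origin == GERMLINE]

print(f"clonal (CCF 1.0) recovery:   {sum(k in called_keys for k in clonal)}/{len(clonal)}")
print(f"subclonal (CCF 0.25) recovery: {sum(k in called_keys for k in subclonal)}/{len(subclonal)}")
print(f"germline leaking through:    {sum(k in called_keys for k in germline)}/{len(germline)}")
print(
    "-> clonal variants are recovered essentially completely, deep subclones "
    "fall below the VAF floor, germline hets are caught by the normal-VAF rule."
)
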