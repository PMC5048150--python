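#!/usr/bin/env python
"""Generate the default synthetic cohort with its ground-truth tables."""

from pathlib import Path

from ki_audit.synthetic_cohort import SimulationConfig, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

config = SimulationConfig(seed=1)
data = simulate(config)
data.write(OUT)

n_survive = sum(t.should_survive_filter for t in data.truth)
by_class = {}
for t in data.truth:
    by_class[t.planted_class] = by_class.get(t.planted_class, 0) + 1

print(f"reference: {len(data.reference)} genes, "
      f"{sum(len(s) for s in data.reference.values())} bp")
print(f"planted off-target sites: "
      f"{[(s.mismatches, s.with_pam) for s in data.planted_sites]}")
print(f"cohort: {len(data.cohort.variants)} variants over "
      f"{len(data.cohort.samples)} samples")
print(f"planted classes: {by_class}")
print(f"{n_survive} variants should survive the six-rule filter")
print(f"outputs written under {OUT}")
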