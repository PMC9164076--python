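"""Two-stage target intersection on a synthetic study.

The generator plants the case study's cardinalities: prediction sources of
332 and 660 targets sharing exactly 198, and a 622-gene disease set sharing
exactly 15 with that consensus.  The pipeline recovers the planted numbers.
"""

from netpharm import TargetSet, two_stage_overlap
from netpharm.simulate import SynthConfig, gen_disease_set, gen_prediction_sources

cfg = SynthConfig(seed=42)
source_a, source_b = gen_prediction_sources(cfg)
set_a = TargetSet("sourceA", source_a.targets)
set_b = TargetSet("sourceB", source_b.targets)
consensus = TargetSet("consensus", set_a.members & set_b.members)
disease = gen_disease_set(cfg, consensus)

result = two_stage_overlap(set_a, set_b, disease)
print("source A targets:      ", result.stage1.size_a)
print("source B targets:      ", result.stage1.size_b)
print("union (raw targets):   ", result.union_size)
print("stage 1 consensus:     ", result.stage1.intersection_size)
print("disease set size:      ", len(disease))
print("final (disease) overlap:", result.stage2.intersection_size)
print("final targets:", ", ".join(result.final_targets.sorted_members()[:5]), "...")
# Stage 1 keeps targets both predictors agree on; stage 2 keeps the subset
# also implicated in the disease — the candidate therapeutic targets.
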