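"""Generate a synthetic behavioural cohort and write its data tables.

The simulated study mirrors the real design: 16 participants each arrange
30 cell stimuli (6 per class) twice on a 60 x 60 cm workbench and rate each
stimulus along 8 visual feature dimensions (240 ratings per participant).
"""

from pathlib import Path

from morphorsa import SimulationConfig, simulate_cohort
from morphorsa.io import write_arrangements, write_manifest, write_ratings

cfg = SimulationConfig(seed=0)
stimset, arrangements, ratings = simulate_cohort(cfg)

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)
write_manifest(stimset, out / "manifest.tsv")
write_arrangements(arrangements, stimset, out / "arrangements.tsv")
write_ratings(ratings, out / "ratings.tsv")

print(f"stimuli: {stimset.n_stimuli} ({stimset.class_labels.count('BC')} per class)")
print(f"arrangements: {len(arrangements)} "
      f"({cfg.n_participants} participants x {cfg.n_sessions} sessions)")
print(f"ratings per participant: {ratings.values.shape[1] * ratings.values.shape[2]}")
print(f"tables written to {out}/")
# Each arrangement is a 2D point configuration whose spatial proximities
# encode perceived shape similarity; the analyses only ever consume the
# pairwise distances, never the absolute placement on the workbench.
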