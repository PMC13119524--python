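"""Enumerate the serial-passage experimental design and its dosing schedules.

Builds the default 72-population survey (sequential, cocktail, monophage and
control arms), prints the replicate structure, and expands one arm into its
concrete dosing events.
"""

import phagesteer as ps

design = ps.enumerate_design(ps.initial_experiment_arms())
print(f"initial experiment: {len(design)} replicate populations")
print(design.groupby("strategy").size().to_string(), "\n")

followup = ps.enumerate_design(ps.followup_arms())
print(f"follow-up experiment: {len(followup)} populations "
      "(12 replicates per multi-phage treatment)\n")

spec = ps.TreatmentSpec("cocktail", "BOTH", "late", "BOTH", 3)
print("cocktail, late second dose, 1e6 PFU per dose:")
for event in ps.dose_schedule(spec, 1e6):
    print(f"  day {event.day}: {event.pfu_by_phage}")
print("Each cocktail dose splits its 1e6 PFU equally between T2 and lambda;")
print("the 'late' second dose lands at the start of day 3 (72 h).")
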