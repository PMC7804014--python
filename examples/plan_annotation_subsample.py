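"""Plan a systematic random subsample of a year of hourly recordings.

Selects ~200 of 8760 hourly chunks with a spacing coprime with 24 so every
clock hour is represented, then reports the spacing, clock-hour coverage and
total audio hours (here for a 25 min/h duty-cycled instrument).
"""

from bluefin.subsampling import (
    RecordingInventory,
    audio_hours,
    coverage_by_clock_hour,
    plan_subsample,
)

inventory = RecordingInventory.hourly(
    "2014-01-01T00:00", 8760, recorded_s=25 * 60.0, site_year="Maud-Rise-like 2014"
)
plan = plan_subsample(inventory, target_n=200, seed=5)
hist = coverage_by_clock_hour(plan, inventory)

print(f"inventory: {len(inventory)} hourly chunks, 25 min recorded per hour")
print(f"plan: spacing {plan.spacing} chunks, random start {plan.start} "
      f"-> {len(plan)} chunks selected")
print("clock-hour coverage (hour: count):")
print("  " + "  ".join(f"{h:02d}:{c}" for h, c in enumerate(hist)))
print(f"selected audio: {audio_hours(plan, inventory):.1f} h")
print("every clock hour appears 5-10 times, so diel call patterns are")
print("represented; ~200 chunks x 25 min is ~83 h of audio to annotate.")
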