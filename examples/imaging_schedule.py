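"""Serialize a multi-well, multi-interval imaging schedule.

One camera images one well at a time (about 5 s per well), so captures
requested at the same interval are serialized; the schedule reports when
each capture actually happens and which intervals are too tight to honour.
"""

from beadsim import schedule_imaging

wells = ["A1", "A2", "A3"]
intervals = [20, 40, 60, 300, 600, 900, 1200, 1500, 1800]  # s after dispense
result = schedule_imaging(wells, intervals, per_well_time=5.0)

print(f"{len(result.captures)} captures over {len(intervals)} intervals:")
for (realized, well), (requested, _) in list(zip(result.captures, result.requested))[:6]:
    shift = realized - requested
    print(f"  t={realized:7.1f}s  {well}  (requested {requested:.0f}s, shifted {shift:.0f}s)")
print("  ...")
print(f"total duration: {result.total_duration:.0f} s")
print(f"infeasible intervals: {result.infeasible_intervals or 'none'}")

# A full 96-well plate at the same nine intervals: early 20 s gaps cannot fit
# a 480 s sweep, so those intervals are flagged and captures slide later.
full = schedule_imaging([f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)], intervals)
print(f"\nfull plate: {len(full.captures)} captures, "
      f"{len(full.infeasible_intervals)} intervals infeasible, "
      f"total {full.total_duration / 3600:.2f} h")
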