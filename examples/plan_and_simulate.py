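"""Plan and simulate the demo hydrogel screen.

Plans the two-pipette protocol (CaCl2 distribution, tool pick-up,
air-gapped alginate droplets, coalescence dispensing, per-well imaging),
simulates it against the pipette state machines, and prints the event log
and the liquid-conservation ledger.
"""

from beadsim import ProtocolConfig, default_deck, plan_hydrogel_screen, simulate
from beadsim.protocol import volume_ledger

deck = default_deck()
plan = plan_hydrogel_screen(ProtocolConfig(), deck)
print(f"planned {len(plan)} steps; first five:")
for step in plan[:5]:
    print("  ", step.describe())

captures = []
log = simulate(plan, deck, camera=lambda well, slot, t: captures.append((str(well), t)))
print(f"\nsimulated {len(log)} events, all ok: {all(ev.outcome == 'ok' for ev in log)}")
print(f"camera fired for wells: {[w for w, _ in captures]}")
print("\nliquid ledger (aspirated = dispensed + residual for every label):")
print(volume_ledger(log).to_string(index=False))
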