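"""Deck layout and screening capacity.

Builds the demo deck (plate, tip racks, vial rack, camera-tool holder) and
a full six-plate screening deck, then prints how many unique formulation
conditions each can monitor in one unattended run.
"""

from beadsim import DeckLayout, builtin_definition, condition_capacity, default_deck, well_position

deck = default_deck()
print("Demo deck:")
for slot in range(1, 12):
    lw = deck.labware_at(slot)
    print(f"  slot {slot:>2}: {lw.name if lw else '(empty)'}")
print(f"  -> capacity: {condition_capacity(deck)} conditions")

screen = DeckLayout()
plate = builtin_definition("plate_96_wellplate_360ul")
for slot in (1, 2, 3, 4, 5, 6):
    screen.load(slot, plate)
print(f"Six-plate screening deck -> capacity: {condition_capacity(screen)} conditions")

x, y = well_position(deck, 1, "H12")
print(f"Well H12 of the slot-1 plate sits at deck position ({x:.2f}, {y:.2f}) mm")
# Capacity counts microplate wells only; each well is one alginate/CaCl2 pairing.
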