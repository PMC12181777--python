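"""Protocol engine: plan and simulate the two-pipette hydrogel screen.

The demo workflow it reproduces: the right pipette dispenses CaCl2
crosslinker into target wells, drops its tip, then picks up the
camera-carrying pick-and-place tool by friction fit; the left pipette
aspirates several alginate droplets separated by air gaps and, well by
well, dispenses each droplet in two sub-steps (partial dispense, then a
touch-and-coalesce into the well liquid), after which the camera is
positioned over the well for an image.  Execution is fully simulated
against per-pipette state machines with a monotone simulated clock and
an auditable event log; nothing touches hardware.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import pandas as pd

from .labware import AddressError, DeckLayout, WellAddress, default_deck

__all__ = [
    "StepOp",
    "Step",
    "PipetteConfig",
    "PipetteState",
    "Segment",
    "ProtocolConfig",
    "Event",
    "EventLog",
    "PlanError",
    "CapacityError",
    "StateMachineError",
    "plan_hydrogel_screen",
    "simulate",
    "schedule_imaging",
    "ScheduleResult",
    "volume_ledger",
    "random_protocol_config",
]


class StepOp(str, enum.Enum):
    PICK_UP_TIP = "pick_up_tip"
    DROP_TIP = "drop_tip"
    PICK_UP_TOOL = "pick_up_tool"
    RETURN_TOOL = "return_tool"
    ASPIRATE = "aspirate"
    DISPENSE = "dispense"
    DISPENSE_PARTIAL = "dispense_partial"
    TOUCH_COALESCE = "touch_coalesce"
    MOVE_TO_WELL = "move_to_well"
    CAPTURE_IMAGE = "capture_image"
    DELAY = "delay"


# Default simulated durations, seconds.  Only the 5 s per-well image figure
# is an observed instrument property; the rest are plausible motion times and
# are configurable through ProtocolConfig.durations.
DEFAULT_DURATIONS = {
    StepOp.PICK_UP_TIP: 5.0,
    StepOp.DROP_TIP: 5.0,
    StepOp.PICK_UP_TOOL: 10.0,
    StepOp.RETURN_TOOL: 10.0,
    StepOp.ASPIRATE: 2.0,
    StepOp.DISPENSE: 2.0,
    StepOp.DISPENSE_PARTIAL: 2.0,
    StepOp.TOUCH_COALESCE: 2.0,
    StepOp.MOVE_TO_WELL: 2.0,
    StepOp.CAPTURE_IMAGE: 5.0,
    StepOp.DELAY: 0.0,
}

AIR_LABEL = "air"


class PlanError(ValueError):
    """The protocol cannot be planned on the given deck."""


class CapacityError(PlanError):
    """A pipette load exceeds its maximum volume."""


class StateMachineError(RuntimeError):
    """A step violates pipette state invariants during simulation."""


@dataclass(frozen=True)
class Step:
    op: StepOp
    mount: str  # "left" or "right"
    target: Optional[tuple[int, WellAddress]] = None  # (slot, well)
    volume: Optional[float] = None  # µL
    label: Optional[str] = None  # liquid label; AIR_LABEL for air gaps
    nominal_duration: float = 0.0  # s

    def describe(self) -> str:
        parts = [self.op.value, self.mount]
        if self.target is not None:
            parts.append(f"{self.target[0]}:{self.target[1]}")
        if self.volume is not None:
            parts.append(f"{self.volume:g}uL")
        if self.label:
            parts.append(self.label)
        return " ".join(parts)


@dataclass(frozen=True)
class PipetteConfig:
    mount: str
    max_volume: float  # µL
    role: str  # "liquid_handling" or "tool_carrier"


@dataclass(frozen=True)
class Segment:
    kind: str  # "liquid" or "air"
    volume: float  # µL
    label: str


@dataclass
class PipetteState:
    """Mutable simulation state of one mounted pipette."""

    config: PipetteConfig
    tip_attached: bool = False
    tool_attached: bool = False
    contents: list[Segment] = field(default_factory=list)

    @property
    def held_volume(self) -> float:
        return sum(s.volume for s in self.contents)

    def aspirate(self, volume: float, label: str) -> None:
        if self.tool_attached:
            raise StateMachineError("tool held: cannot aspirate")
        if not self.tip_attached:
            raise StateMachineError("no tip attached: cannot aspirate")
        if self.held_volume + volume > self.config.max_volume + 1e-9:
            raise StateMachineError(
                f"aspirating {volume} µL would exceed max {self.config.max_volume} µL"
            )
        kind = "air" if label == AIR_LABEL else "liquid"
        self.contents.append(Segment(kind, volume, label))

    @property
    def liquid_volume(self) -> float:
        return sum(s.volume for s in self.contents if s.kind == "liquid")

    def dispense(self, volume: float) -> list[Segment]:
        """Expel `volume` µL of liquid from the tip end (last aspirated first).

        Air segments reached at the tip end are blown out for free, as a
        physical air gap would be; returns all segments expelled.
        """
        if self.tool_attached:
            raise StateMachineError("tool held: cannot dispense")
        if volume > self.liquid_volume + 1e-9:
            raise StateMachineError(
                f"dispense {volume} µL exceeds held liquid {self.liquid_volume} µL"
            )
        out: list[Segment] = []
        remaining = volume
        while self.contents and self.contents[-1].kind == "air":
            out.append(self.contents.pop())
        while remaining > 1e-12 and self.contents:
            seg = self.contents[-1]
            if seg.kind == "air":
                out.append(self.contents.pop())
                continue
            if seg.volume <= remaining + 1e-12:
                out.append(self.contents.pop())
                remaining -= seg.volume
            else:
                self.contents[-1] = replace(seg, volume=seg.volume - remaining)
                out.append(replace(seg, volume=remaining))
                remaining = 0.0
        return out


@dataclass
class ProtocolConfig:
    """Configuration of the demo hydrogel screen.

    ``cacl2_wells`` lists (slot, well, concentration %w/v, volume µL)
    crosslinker targets; ``alginate_droplets`` lists (concentration %w/v,
    volume µL) droplets aspirated with air gaps in between, dispensed one
    per target well in order.  ``imaging_intervals`` are seconds after each
    well's dispense at which a follow-up image is requested (used by
    :func:`schedule_imaging`; the plan itself captures one image per well
    immediately after coalescence, as in the demo protocol).
    """

    cacl2_wells: list[tuple[int, WellAddress, float, float]] = field(
        default_factory=lambda: [
            (1, WellAddress("A", 1), 1.0, 200.0),
            (1, WellAddress("A", 2), 1.0, 200.0),
            (1, WellAddress("A", 3), 1.0, 200.0),
        ]
    )
    alginate_droplets: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.5, 20.0)] * 3
    )
    imaging_intervals: list[float] = field(
        default_factory=lambda: [20, 40, 60, 300, 600, 900, 1200, 1500, 1800]
    )
    per_well_image_time: float = 5.0  # s
    air_gap_volume: float = 10.0  # µL between droplets
    tip_rack_1000_slot: int = 8
    tip_rack_300_slot: int = 9
    vial_rack_slot: int = 10
    tool_holder_slot: int = 11
    right_pipette: PipetteConfig = field(
        default_factory=lambda: PipetteConfig("right", 1000.0, "tool_carrier")
    )
    left_pipette: PipetteConfig = field(
        default_factory=lambda: PipetteConfig("left", 300.0, "liquid_handling")
    )
    camera_working_height: float = 120.0  # mm above deck while carrying the tool
    durations: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))

    def __post_init__(self):
        if any(v <= 0 for _, _, _, v in self.cacl2_wells):
            raise PlanError("cacl2 volumes must be > 0")
        if any(v <= 0 for _, v in self.alginate_droplets):
            raise PlanError("alginate droplet volumes must be > 0")
        ivals = list(self.imaging_intervals)
        if any(b <= a for a, b in zip(ivals, ivals[1:])):
            raise PlanError("imaging_intervals must be strictly increasing")
        if self.per_well_image_time <= 0:
            raise PlanError("per_well_image_time must be > 0")
        if {self.right_pipette.mount, self.left_pipette.mount} != {"left", "right"}:
            raise PlanError("exactly one pipette per mount")
        roles = {self.right_pipette.role, self.left_pipette.role}
        if "tool_carrier" not in roles:
            raise PlanError("exactly one tool_carrier pipette required")


@dataclass(frozen=True)
class Event:
    sim_time: float
    step: Step
    outcome: str  # ok | skipped | error
    detail: str = ""


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def append(self, event: Event) -> None:
        if self.events and event.sim_time < self.events[-1].sim_time - 1e-9:
            raise ValueError("sim_time must be non-decreasing")
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            slot, well = (None, None)
            if ev.step.target is not None:
                slot, well = ev.step.target[0], str(ev.step.target[1])
            rows.append(
                {
                    "sim_time": ev.sim_time,
                    "op": ev.step.op.value,
                    "mount": ev.step.mount,
                    "slot": slot,
                    "well": well,
                    "volume": ev.step.volume,
                    "label": ev.step.label,
                    "outcome": ev.outcome,
                    "detail": ev.detail,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sim_time", "op", "mount", "slot", "well",
                "volume", "label", "outcome", "detail",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Planning

def _check_collisions(config: ProtocolConfig, layout: DeckLayout, plate_slots: set[int]) -> None:
    # While the camera tool is carried, its working height must clear every
    # occupied labware except the plate being imaged and the tool's own holder.
    for slot, lw in layout.slots.items():
        if slot in plate_slots or slot == config.tool_holder_slot:
            continue
        if lw.height >= config.camera_working_height:
            raise PlanError(
                f"collision risk: {lw.name} in slot {slot} (height {lw.height} mm) "
                f"reaches camera working height {config.camera_working_height} mm"
            )


def plan_hydrogel_screen(config: ProtocolConfig, layout: Optional[DeckLayout] = None) -> list[Step]:
    """Plan the demo screen; returns an ordered, hardware-agnostic step list.

    Order: right tip pick-up; CaCl2 aspirate + per-well dispense; right tip
    drop; left tip pick-up; right tool pick-up; left multi-droplet aspirate
    with air gaps; per well dispense_partial + touch_coalesce + capture;
    tool return and left tip drop.
    """
    if layout is None:
        layout = default_deck()
    cfg = config
    dur = {**DEFAULT_DURATIONS, **cfg.durations}

    def need(slot: int, kind: str, what: str):
        lw = layout.labware_at(slot)
        if lw is None or lw.kind != kind:
            raise PlanError(f"{what} expected in slot {slot} (kind {kind}), found "
                            f"{lw.name if lw else 'nothing'}")
        return lw

    need(cfg.tip_rack_1000_slot, "tip_rack", "1000 µL tip rack")
    need(cfg.tip_rack_300_slot, "tip_rack", "300 µL tip rack")
    vials = need(cfg.vial_rack_slot, "vial_rack", "vial rack")
    need(cfg.tool_holder_slot, "tool_holder", "camera tool holder")

    plate_slots = {slot for slot, _, _, _ in cfg.cacl2_wells}
    for slot, well, _, _ in cfg.cacl2_wells:
        plate = layout.labware_at(slot)
        if plate is None or plate.kind != "microplate":
            raise PlanError(f"target slot {slot} holds no microplate")
        plate.validate_address(well)
    _check_collisions(cfg, layout, plate_slots)

    n_droplets = len(cfg.alginate_droplets)
    droplet_load = sum(v for _, v in cfg.alginate_droplets)
    gap_load = cfg.air_gap_volume * max(0, n_droplets - 1)
    if droplet_load + gap_load > cfg.left_pipette.max_volume:
        raise CapacityError(
            f"alginate load {droplet_load + gap_load} µL exceeds left pipette "
            f"max {cfg.left_pipette.max_volume} µL"
        )
    cacl2_total = sum(v for _, _, _, v in cfg.cacl2_wells)
    if cacl2_total > cfg.right_pipette.max_volume:
        raise CapacityError(
            f"CaCl2 load {cacl2_total} µL exceeds right pipette max "
            f"{cfg.right_pipette.max_volume} µL"
        )

    right, left = cfg.right_pipette.mount, cfg.left_pipette.mount
    tip_a1 = WellAddress("A", 1)
    steps: list[Step] = []

    def add(op: StepOp, mount: str, **kw):
        steps.append(Step(op=op, mount=mount, nominal_duration=dur[op], **kw))

    if not cfg.cacl2_wells:
        return steps

    # (1) crosslinker distribution with the right (liquid-capable) pipette
    add(StepOp.PICK_UP_TIP, right, target=(cfg.tip_rack_1000_slot, tip_a1))
    vial = vials.validate_address(WellAddress("A", 1))
    add(StepOp.ASPIRATE, right, target=(cfg.vial_rack_slot, vial),
        volume=cacl2_total, label="cacl2")
    for slot, well, conc, vol in cfg.cacl2_wells:
        add(StepOp.MOVE_TO_WELL, right, target=(slot, well))
        add(StepOp.DISPENSE, right, target=(slot, well), volume=vol,
            label="cacl2")
    add(StepOp.DROP_TIP, right, target=(cfg.tip_rack_1000_slot, tip_a1))

    # (2) left pipette tips up, right pipette fetches the camera tool
    add(StepOp.PICK_UP_TIP, left, target=(cfg.tip_rack_300_slot, tip_a1))
    add(StepOp.PICK_UP_TOOL, right, target=(cfg.tool_holder_slot, tip_a1))

    # (3) air-gapped multi-droplet aspiration of the polymer solution
    alginate_vial = vials.validate_address(WellAddress("B", 1))
    for i, (conc, vol) in enumerate(cfg.alginate_droplets):
        add(StepOp.ASPIRATE, left, target=(cfg.vial_rack_slot, alginate_vial),
            volume=vol, label=f"alginate[{i}]")
        if i < n_droplets - 1:
            add(StepOp.ASPIRATE, left, volume=cfg.air_gap_volume, label=AIR_LABEL)

    # (4) per-well two-sub-step coalescence dispensing + in-situ image.
    # Droplets come back out tip-end first, so the last aspirated droplet
    # goes into the first well.
    droplet_order = list(reversed(range(n_droplets)))
    for k, (slot, well, conc, vol) in enumerate(cfg.cacl2_wells if n_droplets else []):
        di = droplet_order[k % n_droplets]
        dvol = cfg.alginate_droplets[di][1]
        add(StepOp.MOVE_TO_WELL, left, target=(slot, well))
        add(StepOp.DISPENSE_PARTIAL, left, target=(slot, well), volume=dvol,
            label=f"alginate[{di}]")
        add(StepOp.TOUCH_COALESCE, left, target=(slot, well), volume=dvol,
            label=f"alginate[{di}]")
        add(StepOp.CAPTURE_IMAGE, right, target=(slot, well))
        if k + 1 >= n_droplets:
            break

    # (5) stow the tool, shed the tip
    add(StepOp.RETURN_TOOL, right, target=(cfg.tool_holder_slot, tip_a1))
    add(StepOp.DROP_TIP, left, target=(cfg.tip_rack_300_slot, tip_a1))
    return steps


# ---------------------------------------------------------------------------
# Simulation

def simulate(
    plan: Sequence[Step],
    layout: Optional[DeckLayout] = None,
    camera: Optional[Callable[[WellAddress, int, float], None]] = None,
    clock_start: float = 0.0,
) -> EventLog:
    """Execute a plan against pipette state machines; returns the event log.

    ``camera(well, slot, sim_time)`` is invoked for every capture_image step.
    The first invariant violation is logged as an error event and halts the
    run (remaining steps are logged as skipped).  Deterministic: identical
    plan and layout give an identical log.
    """
    if layout is None:
        layout = default_deck()
    mounts: dict[str, PipetteState] = {}
    for step in plan:
        if step.mount not in mounts:
            # max volume inferred lazily; generous default when a mount only moves
            mounts[step.mount] = PipetteState(
                PipetteConfig(step.mount, 1000.0, "liquid_handling")
            )
    log = EventLog()
    t = clock_start
    halted = False
    # pending partial dispense per mount: (slot, well, volume, label)
    pending: dict[str, Optional[tuple]] = {m: None for m in mounts}

    for step in plan:
        if halted:
            log.append(Event(t, step, "skipped", "simulation halted"))
            continue
        state = mounts[step.mount]
        t += step.nominal_duration
        try:
            op = step.op
            if op == StepOp.PICK_UP_TIP:
                if state.tip_attached or state.tool_attached:
                    raise StateMachineError("cannot pick up tip: shaft occupied")
                state.tip_attached = True
            elif op == StepOp.DROP_TIP:
                if not state.tip_attached:
                    raise StateMachineError("no tip to drop")
                if state.liquid_volume > 1e-9:
                    raise StateMachineError("dropping a tip still holding liquid")
                state.tip_attached = False
                state.contents.clear()  # residual air goes with the tip
            elif op == StepOp.PICK_UP_TOOL:
                if state.tip_attached:
                    raise StateMachineError("cannot pick up tool while tip attached")
                if state.tool_attached:
                    raise StateMachineError("tool already held")
                state.tool_attached = True
            elif op == StepOp.RETURN_TOOL:
                if not state.tool_attached:
                    raise StateMachineError("no tool to return")
                state.tool_attached = False
            elif op == StepOp.ASPIRATE:
                state.aspirate(step.volume or 0.0, step.label or "unlabelled")
            elif op == StepOp.DISPENSE:
                state.dispense(step.volume or 0.0)
            elif op == StepOp.DISPENSE_PARTIAL:
                # droplet pushed to just before detachment; still on the tip
                if state.tool_attached:
                    raise StateMachineError("tool held: cannot dispense")
                if (step.volume or 0.0) > state.held_volume + 1e-9:
                    raise StateMachineError("partial dispense exceeds held volume")
                pending[step.mount] = (step.target, step.volume, step.label)
            elif op == StepOp.TOUCH_COALESCE:
                pend = pending.get(step.mount)
                if pend is None:
                    raise StateMachineError("touch_coalesce without pending droplet")
                if pend[0] != step.target:
                    raise StateMachineError("touch_coalesce target mismatch")
                state.dispense(pend[1] or 0.0)
                pending[step.mount] = None
            elif op == StepOp.MOVE_TO_WELL:
                if step.target is not None:
                    layout.require(step.target[0]).validate_address(step.target[1])
            elif op == StepOp.CAPTURE_IMAGE:
                if camera is not None and step.target is not None:
                    camera(step.target[1], step.target[0], t)
            elif op == StepOp.DELAY:
                pass  # time already advanced by nominal_duration
            log.append(Event(t, step, "ok"))
        except (StateMachineError, AddressError) as exc:
            log.append(Event(t, step, "error", str(exc)))
            halted = True
    return log


# ---------------------------------------------------------------------------
# Imaging schedule

@dataclass
class ScheduleResult:
    captures: list[tuple[float, str]]  # (realized sim_time, well)
    requested: list[tuple[float, str]]  # (requested sim_time, well)
    total_duration: float
    infeasible_intervals: list[float]  # intervals whose captures overflowed


def schedule_imaging(
    wells: Sequence[Union[str, WellAddress]],
    intervals: Sequence[float],
    per_well_time: float = 5.0,
) -> ScheduleResult:
    """Serialize per-interval captures of many wells onto one camera.

    Each well gets one capture per interval.  The camera is exclusive for
    ``per_well_time`` seconds per capture, so colliding requests shift later
    wells by multiples of ``per_well_time``; a realized time is never earlier
    than requested.  An interval is reported infeasible when some capture in
    it is delayed by more than (n_wells - 1) x per_well_time, i.e. the
    previous interval's sweep was still running.
    """
    ivals = list(intervals)
    if any(b <= a for a, b in zip(ivals, ivals[1:])):
        raise ValueError("intervals must be strictly increasing")
    if per_well_time <= 0:
        raise ValueError("per_well_time must be > 0")
    names = [str(w) for w in wells]
    captures: list[tuple[float, str]] = []
    requested: list[tuple[float, str]] = []
    infeasible: list[float] = []
    camera_free = float("-inf")
    n = len(names)
    for interval in ivals:
        worst_delay = 0.0
        for w in names:
            req = float(interval)
            realized = max(req, camera_free)
            captures.append((realized, w))
            requested.append((req, w))
            worst_delay = max(worst_delay, realized - req)
            camera_free = realized + per_well_time
        if n and worst_delay > (n - 1) * per_well_time + 1e-9:
            infeasible.append(float(interval))
    total = captures[-1][0] if captures else 0.0
    return ScheduleResult(captures, requested, total, infeasible)


# ---------------------------------------------------------------------------
# Liquid accounting

def volume_ledger(log: EventLog) -> pd.DataFrame:
    """Per-label liquid balance from an event log.

    Columns: label, aspirated, dispensed, residual (= aspirated - dispensed),
    balanced (residual >= 0 and conservation holds).  Air segments are
    accounted like liquids; a dispense drawing on never-aspirated volume shows
    up as a negative residual with balanced=False.
    """
    totals: dict[str, dict[str, float]] = {}

    def bucket(label: str) -> dict[str, float]:
        return totals.setdefault(label, {"aspirated": 0.0, "dispensed": 0.0})

    for ev in log:
        if ev.outcome != "ok" or ev.step.volume is None:
            continue
        label = ev.step.label or "unlabelled"
        if ev.step.op == StepOp.ASPIRATE:
            bucket(label)["aspirated"] += ev.step.volume
        elif ev.step.op in (StepOp.DISPENSE, StepOp.TOUCH_COALESCE):
            bucket(label)["dispensed"] += ev.step.volume
    rows = []
    for label in sorted(totals):
        asp = totals[label]["aspirated"]
        disp = totals[label]["dispensed"]
        residual = asp - disp
        rows.append(
            {
                "label": label,
                "aspirated": asp,
                "dispensed": disp,
                "residual": residual,
                "balanced": residual >= -1e-9,
            }
        )
    return pd.DataFrame(rows, columns=["label", "aspirated", "dispensed", "residual", "balanced"])


# ---------------------------------------------------------------------------
# Randomized valid configs (property tests / shakedown)

def random_protocol_config(seed: int) -> ProtocolConfig:
    """A random but valid ProtocolConfig on the default deck; seeded."""
    rng = random.Random(seed)
    n_wells = rng.randint(1, 8)
    wells = []
    cols = rng.sample(range(1, 13), n_wells)
    row = rng.choice("ABCDEFGH")
    for c in sorted(cols):
        wells.append((1, WellAddress(row, c), rng.uniform(0.1, 10.0),
                      rng.uniform(20.0, 120.0)))
    n_drops = n_wells
    drop_vol = rng.uniform(5.0, 25.0)
    gap = rng.uniform(2.0, 10.0)
    # keep the left pipette load feasible
    while drop_vol * n_drops + gap * (n_drops - 1) > 300.0:
        drop_vol *= 0.5
    k = rng.randint(2, 5)
    intervals = sorted(rng.sample(range(20, 2000), k))
    return ProtocolConfig(
        cacl2_wells=wells,
        alginate_droplets=[(rng.uniform(0.5, 2.0), drop_vol)] * n_drops,
        imaging_intervals=[float(i) for i in intervals],
        air_gap_volume=gap,
    )
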