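"""Life-state codes shared by the engine, motility and mortality modules."""

CYCLING = 0            # progressing through the cell cycle, free to move
ARRESTED = 1           # completely surrounded: clock paused, no movement (reversible)
BOUNDARY_ARRESTED = 2  # touched the domain boundary: clock paused, no movement
DYING = 3              # scheduled for removal; occupies space but is inert

STATE_NAMES = {
    CYCLING: "cycling",
    ARRESTED: "arrested",
    BOUNDARY_ARRESTED: "boundary_arrested",
    DYING: "dying",
}
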