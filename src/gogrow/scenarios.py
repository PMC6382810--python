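"""Named scenario presets spanning the study's experimental grid.

The grid crosses the three tradeoff boundaries (open, convex, concave) with
three demographic death levels (none, low = 1/14 per day, high = 1/7 per day)
and, at the high death rate, three catastrophic shares (0%, 50%, 100%).
``*_small`` variants shrink the domain to a 500 um radius for desk-scale
work; full-domain growth/turnover runs are hour-scale computations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .engine import SimConfig
from .mortality import MortalityRegime

_DEATH_LEVELS = {"none": 0.0, "low": 1.0 / 14.0, "high": 1.0 / 7.0}
SMALL_RADIUS = 500.0  # um
SMALL_DURATION = 90.0  # days


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    boundary: str            # tradeoff kind
    death_level: str         # none | low | high
    cat_fraction: float      # fraction of deaths that are catastrophic
    duration_days: float
    domain_radius: float = 1350.0
    initial_phenotype: tuple = (40.0, 0.0)
    snapshot_days: float = 5.0

    @property
    def p_death(self) -> float:
        return _DEATH_LEVELS[self.death_level]

    def to_config(self, seed: int = 0, **overrides) -> SimConfig:
        cfg = SimConfig(
            duration_days=self.duration_days,
            domain_radius=self.domain_radius,
            boundary=self.boundary,
            regime=MortalityRegime(self.p_death, self.cat_fraction),
            initial_phenotype=self.initial_phenotype,
            seed=seed,
            snapshot_days=self.snapshot_days,
        )
        return replace(cfg, **overrides) if overrides else cfg


def _build_presets() -> dict[str, ScenarioPreset]:
    presets: dict[str, ScenarioPreset] = {}

    def add(p: ScenarioPreset):
        presets[p.name] = p

    for b in ("open", "convex", "concave"):
        # pure growth until space fills (no mortality)
        add(ScenarioPreset(f"growth_{b}", b, "none", 0.0, duration_days=150.0))
        # demographic turnover at two rates, 12-month horizon
        for lvl in ("low", "high"):
            add(ScenarioPreset(f"turnover_{lvl}_{b}", b, lvl, 0.0, duration_days=365.0))
        # catastrophic share sweep at the high death rate
        for frac, tag in ((0.5, "half"), (1.0, "full")):
            add(ScenarioPreset(f"catastrophe_{tag}_{b}", b, "high", frac,
                               duration_days=365.0))
    # desk-scale variants: 500 um-radius domain, 90 days
    for name, p in list(presets.items()):
        add(replace(p, name=f"{name}_small", domain_radius=SMALL_RADIUS,
                    duration_days=SMALL_DURATION))
    return presets


PRESETS: dict[str, ScenarioPreset] = _build_presets()


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown scenario {name!r}; known: {known}") from None


def list_presets() -> list[str]:
    return sorted(PRESETS)
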