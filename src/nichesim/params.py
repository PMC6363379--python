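"""Simulation parameter set for the agent-based niche model.

The model places a static spherical ureteric-tip attractor at the origin.
Cap (progenitor) cells migrate stochastically, are attracted to / repelled
from the tip, accumulate inductive signal while below a y-coordinate cutoff
(the induction zone), and commit irreversibly once the accumulated signal
reaches a threshold.  Two variants differ only in what happens to the
accumulated signal outside the zone: the *primed* variant retains it
(re-entry value 0) while the *return-to-ground* variant decays it by a
fixed decrement per step (re-entry value >= 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError, ParameterError

VARIANTS = ("primed", "return_to_ground")


@dataclass
class SimParams:
    """Complete parameter set of one simulation run.

    Parameters
    ----------
    tip_size:
        Radius of the tip attractor, in niche units. Cells closer than the
        (scaled) tip size are repelled; cells at or beyond it are attracted.
    induction_cutoff:
        y-coordinate below which cells accumulate inductive signal
        (negative: the zone sits below the tip centre).
    tip_attraction:
        Magnitude scale of the tip interaction displacement per step.
    random_migration:
        Standard deviation of the per-step random displacement magnitude.
    state_threshold:
        Number of accumulated in-zone steps required to commit.
    mitotic_index:
        Per-step probability that a cap cell divides.
    reentry_value:
        Per-step decrement of accumulated signal outside the zone.
        ``None`` resolves from the variant (primed -> 0, return_to_ground -> 1).
    n_steps:
        Number of simulation steps.
    niche_scale:
        Dimensionless multiplier applied to ``tip_size`` and
        ``induction_cutoff`` only (migration and attraction are not scaled).
    variant:
        ``"primed"`` or ``"return_to_ground"``.
    n_init:
        Initial population size (all cap, state 0, unlabelled).
    seed:
        Seed for the single per-simulation random generator.
    allow_variant_mismatch:
        Relax the variant <-> reentry_value pairing (for exploratory runs).
    """

    tip_size: float = 5.0
    induction_cutoff: float = -2.0
    tip_attraction: float = 0.5
    random_migration: float = 0.5
    state_threshold: int = 30
    mitotic_index: float = 0.01
    reentry_value: int | None = None
    n_steps: int = 400
    niche_scale: float = 1.0
    variant: str = "primed"
    n_init: int = 200
    seed: int = 0
    allow_variant_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.reentry_value is None:
            self.reentry_value = 0 if self.variant == "primed" else 1
        if self.tip_size <= 0:
            raise ParameterError("tip_size must be > 0")
        if self.niche_scale <= 0:
            raise ParameterError("niche_scale must be > 0")
        if self.state_threshold < 1:
            raise ParameterError("state_threshold must be >= 1")
        if not 0.0 <= self.mitotic_index <= 1.0:
            raise ParameterError("mitotic_index must lie in [0, 1]")
        if self.reentry_value < 0:
            raise ParameterError("reentry_value must be >= 0")
        if self.random_migration < 0:
            raise ParameterError("random_migration must be >= 0")
        if self.tip_attraction < 0:
            raise ParameterError("tip_attraction must be >= 0")
        if self.n_steps < 0:
            raise ParameterError("n_steps must be >= 0")
        if self.n_init < 1:
            raise ParameterError("n_init must be >= 1")
        if not self.allow_variant_mismatch:
            if self.variant == "primed" and self.reentry_value != 0:
                raise ParameterError(
                    "primed variant requires reentry_value == 0 "
                    "(set allow_variant_mismatch=True to override)"
                )
            if self.variant == "return_to_ground" and self.reentry_value < 1:
                raise ParameterError(
                    "return_to_ground variant requires reentry_value >= 1 "
                    "(set allow_variant_mismatch=True to override)"
                )

    # Scaling applies to tip_size and induction_cutoff only.
    @property
    def scaled_tip_size(self) -> float:
        return self.tip_size * self.niche_scale

    @property
    def scaled_induction_cutoff(self) -> float:
        return self.induction_cutoff * self.niche_scale

    def replace(self, **changes: Any) -> "SimParams":
        """Return a validated copy with ``changes`` applied."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SimParams":
        """Build from a config mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        try:
            return cls(**dict(mapping))
        except TypeError as exc:  # wrong value type slipped through
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "SimParams":
        """Load from a JSON or YAML file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        try:
            if path.suffix.lower() == ".json":
                data = json.loads(text)
            else:
                data = yaml.safe_load(text)
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)
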