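"""Run configuration and fidelity presets.

Two presets ship with the package.  ``paper`` uses the method's canonical
full-scale budgets: 10^4 permutations per screen (escalating
10^4 -> 10^5 -> 10^6 for pairs), 10^4 cross-validation splits, 100 bootstrap
rounds at a 90% subsample, candidate threshold 200.  ``desk`` is a
scaled-down configuration with the same structure that finishes on a single
workstation core; budgets only change Monte-Carlo resolution, not the
procedure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    preset: str = "desk"
    # screening budgets (full-data stage)
    screen_B: int = 999
    screen_splits: int = 500
    broad_B: int = 199
    broad_splits: int = 100
    pair_schedule: tuple = (999, 9_999)
    # bootstrap accumulation
    rounds: int = 20
    fraction: float = 0.9
    round_B: int = 199
    round_splits: int = 100
    threshold: int | None = None      # None -> 2 * rounds
    # pool shaping
    pair_shortlist: int = 50
    probe_shortlist: int | None = None  # cap probes entering pair enumeration
    max_pairs: int = 20_000
    # projection / CV behaviour
    train_fraction: float = 0.7
    refit_in_cv: bool = False
    # affirmation
    k_cliques: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValidationError("rounds must be >= 1")
        if not (0.0 < self.fraction <= 1.0):
            raise ValidationError("fraction must lie in (0, 1]")
        self.pair_schedule = tuple(int(b) for b in self.pair_schedule)

    @property
    def effective_threshold(self) -> int:
        return 2 * self.rounds if self.threshold is None else self.threshold

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        return cls(preset="desk", **overrides)

    @classmethod
    def paper(cls, **overrides) -> "RunConfig":
        base = dict(
            preset="paper",
            screen_B=10_000, screen_splits=10_000,
            broad_B=10_000, broad_splits=10_000,
            pair_schedule=(10_000, 100_000, 1_000_000),
            rounds=100, fraction=0.9,
            round_B=10_000, round_splits=10_000,
            threshold=200, pair_shortlist=50,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        if name == "desk":
            return cls.desk(**overrides)
        if name == "paper":
            return cls.paper(**overrides)
        raise ValidationError(f"unknown preset {name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pair_schedule"] = list(self.pair_schedule)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
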