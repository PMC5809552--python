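"""Study configuration loading and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["StudyConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised with the full list of schema violations found in a config."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in self.problems))


@dataclass
class StudyConfig:
    """Validated settings for one simulation study run."""

    study: str = "point"  # point | interval | bayes
    model: str = "single"  # single | two
    x_type: str = "continuous"  # continuous | binary
    ns: list = field(default_factory=list)  # empty -> study default grid
    reps: int = 1000
    B: int = 1000
    level: float = 0.95
    n_iter: int = 2500
    burn_in: int = 500
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1

    _CHOICES = {
        "study": ("point", "interval", "bayes"),
        "model": ("single", "two"),
        "x_type": ("continuous", "binary"),
    }

    def validate(self) -> "StudyConfig":
        problems = []
        for name, choices in self._CHOICES.items():
            if getattr(self, name) not in choices:
                problems.append(f"{name} must be one of {choices}, got {getattr(self, name)!r}")
        for name, minimum in (("reps", 2), ("B", 100), ("n_iter", 2)):
            v = getattr(self, name)
            if not isinstance(v, int) or v < minimum:
                problems.append(f"{name} must be an integer >= {minimum}, got {v!r}")
        if not isinstance(self.burn_in, int) or self.burn_in < 0:
            problems.append(f"burn_in must be a non-negative integer, got {self.burn_in!r}")
        elif isinstance(self.n_iter, int) and self.burn_in >= self.n_iter:
            problems.append("burn_in must be smaller than n_iter")
        if not isinstance(self.seed, int) or self.seed < 0:
            problems.append(f"seed must be a non-negative integer, got {self.seed!r}")
        if not (isinstance(self.level, (int, float)) and 0.0 < self.level < 1.0):
            problems.append(f"level must be in (0, 1), got {self.level!r}")
        if not isinstance(self.ns, list) or any(
            not isinstance(n, int) or n < 10 for n in self.ns
        ):
            problems.append(f"ns must be a list of integers >= 10, got {self.ns!r}")
        if problems:
            raise ConfigError(problems)
        return self


def load_config(path) -> StudyConfig:
    """Load a YAML (or JSON) config file, filling defaults and validating.

    Unknown keys are rejected by name; every violation found is reported.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a mapping"])
    known = {f.name for f in fields(StudyConfig) if not f.name.startswith("_")}
    unknown = sorted(set(raw) - known)
    problems = [f"unknown key {k!r}" for k in unknown]
    cfg = StudyConfig(**{k: v for k, v in raw.items() if k in known})
    try:
        cfg.validate()
    except ConfigError as err:
        problems.extend(err.problems)
    if problems:
        raise ConfigError(problems)
    return cfg
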