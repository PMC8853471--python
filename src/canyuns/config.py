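"""Shared defaults, run configuration, and logging helpers.

Every numerical default that influences a reconstruction lives here so that a
run can log a complete, auditable record of its parameters.  Values mirror the
conventions of the method: reaction bounds of 0/±1000, a biomass flux of 0.1
as both the training requirement and the growth-call threshold, and a bitscore
of 500 as the zero-crossing of the evidence weight transform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

#: Magnitude used for unconstrained reaction bounds (mmol gDW^-1 h^-1).
DEFAULT_BOUND = 1000.0

#: Flux below this magnitude is treated as numerically zero.
DEFAULT_EPS = 1e-6

#: Bitscore that maps to weight 0 in the evidence transform.
DEFAULT_B_ZERO = 500.0

#: Bitscore at (and above) which the evidence weight saturates at 1.
DEFAULT_B_SAT = 1000.0

#: Minimum biomass flux enforced during a data-guided FBA solve.
DEFAULT_BIOMASS_MIN = 0.1

#: FBA biomass flux above which a condition is called as growth (strict >).
DEFAULT_GROWTH_THRESHOLD = 0.1

#: Default uptake limit applied to carbon sources in minimal-media simulations.
DEFAULT_UPTAKE = 10.0

#: Upper bound on each artificial sink in the free-mass scan.
DEFAULT_SINK_CAP = 1000.0

#: Number of random condition subsets drawn per subset size in rarefaction.
DEFAULT_RAREFACTION_SAMPLES = 10_000

logger = logging.getLogger("canyuns")


@dataclass
class RunConfig:
    """Bundle of tunable parameters for a reconstruction run.

    Defaults are logged at startup so that no parameter is silently assumed.
    """

    b_zero: float = DEFAULT_B_ZERO
    b_sat: float = DEFAULT_B_SAT
    biomass_min: float = DEFAULT_BIOMASS_MIN
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD
    eps: float = DEFAULT_EPS
    default_uptake: float = DEFAULT_UPTAKE
    sink_cap: float = DEFAULT_SINK_CAP
    n_rarefaction_samples: int = DEFAULT_RAREFACTION_SAMPLES
    seed: int | None = None
    solver: str = "highs"
    extracellular: str = "e"
    explicit: set[str] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.b_zero < self.b_sat):
            raise ValueError("require 0 < b_zero < b_sat")

    def log_parameters(self) -> None:
        """Emit one log line per parameter, flagging defaulted values."""
        for f in dataclasses.fields(self):
            if f.name == "explicit":
                continue
            value = getattr(self, f.name)
            origin = "set" if f.name in self.explicit else "default"
            logger.info("config %s=%r (%s)", f.name, value, origin)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance records."""
        payload = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "explicit"
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def file_digest(path: str | Path) -> str:
    """SHA-256 digest (truncated) of an input file, for provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
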