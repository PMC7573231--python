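"""SUIT protocol definitions: ordered titration steps and their states.

The default four-protocol table ships with the package as
``data/protocols.yaml``; users can supply their own file with the same
schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError

VALID_AGENTS = frozenset(
    {"OC", "P", "M", "G", "S", "ADP", "CytC", "OM", "CCCP", "Rot", "Mal", "REOX"}
)
STATE_LABELS = frozenset(
    {"baseline", "Ln", "OXPHOS", "LOmy", "ETS", "CI", "CII", "cytc_check", "none"}
)
#: States measured in more than one protocol; aggregated as plain means.
REPEATED_STATES = ("Ln", "OXPHOS", "ETS")
#: States measured once per sample; standardized to the sample-mean OXPHOS.
SINGLE_STATES = ("LOmy", "CI", "CII")


@dataclass(frozen=True)
class ProtocolStep:
    """One titration step: the agents added and the state it establishes."""

    agents: frozenset[str]
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATE_LABELS:
            raise ConfigError(f"unknown state label {self.state!r}")
        bad = set(self.agents) - VALID_AGENTS
        if bad:
            raise ConfigError(f"unknown agents {sorted(bad)}")


@dataclass(frozen=True)
class SuitProtocol:
    """An ordered SUIT titration protocol.

    The first step must be an agent-free baseline; every protocol must
    contain an OXPHOS step and a cytochrome-c integrity check.
    """

    protocol_id: str
    steps: tuple[ProtocolStep, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigError(f"protocol {self.protocol_id}: no steps")
        if self.steps[0].state != "baseline" or self.steps[0].agents:
            raise ConfigError(
                f"protocol {self.protocol_id}: first step must be an "
                "agent-free baseline"
            )
        states = [s.state for s in self.steps]
        if "OXPHOS" not in states:
            raise ConfigError(f"protocol {self.protocol_id}: missing OXPHOS step")
        if "cytc_check" not in states:
            raise ConfigError(f"protocol {self.protocol_id}: missing CytC step")

    @property
    def titration_steps(self) -> tuple[ProtocolStep, ...]:
        """Steps after the baseline, each paired with one titration event."""
        return self.steps[1:]

    @property
    def measured_states(self) -> tuple[str, ...]:
        return tuple(
            s.state for s in self.steps if s.state not in ("none", "cytc_check")
        )


def _parse(doc: dict) -> dict[str, SuitProtocol]:
    try:
        raw = doc["protocols"]
    except (KeyError, TypeError):
        raise ConfigError("protocol file must contain a 'protocols' mapping")
    out: dict[str, SuitProtocol] = {}
    for pid, body in raw.items():
        steps = tuple(
            ProtocolStep(frozenset(step.get("agents", [])), step["state"])
            for step in body["steps"]
        )
        out[str(pid)] = SuitProtocol(str(pid), steps)
    return out


def load_protocols(path: str | Path | None = None) -> dict[str, SuitProtocol]:
    """Load a protocol table from *path*, or the packaged default."""
    if path is None:
        text = (
            resources.files("sealmito").joinpath("data/protocols.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return _parse(yaml.safe_load(text))


def default_protocols() -> dict[str, SuitProtocol]:
    return load_protocols(None)
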