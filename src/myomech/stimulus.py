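"""Stimulation protocols: per-motor-unit firing schedules and pulse shapes.

A pulse is a rectangular current of given amplitude (uA/cm^2) and width (ms)
injected at the neuromuscular-junction node.  Discharge times are either a
regular frequency or an explicit, sorted list per motor unit; they are
precomputed and never depend on the mechanical state (unidirectional drive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = ["StimulusProtocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Firing schedule for ``n_mus`` motor units plus the MU->fiber map.

    ``frequency_hz`` applies to every MU unless ``firing_times`` (a tuple of
    per-MU sorted time tuples, ms) overrides it.  ``mu_of_fiber[i]`` gives
    the motor unit driving fiber ``i``; an empty map means every fiber
    belongs to MU 0.
    """

    frequency_hz: float = 100.0
    amplitude: float = 700.0      # uA/cm^2
    width: float = 0.5            # ms
    start: float = 0.0            # ms, first discharge
    n_mus: int = 1
    firing_times: tuple = ()      # optional explicit per-MU schedules
    mu_of_fiber: tuple = ()

    def __post_init__(self):
        if self.firing_times:
            if len(self.firing_times) != self.n_mus:
                raise ConfigError("firing_times must have one entry per MU")
            for times in self.firing_times:
                if any(b < a for a, b in zip(times, times[1:])):
                    raise ConfigError("firing times must be sorted")
        elif not self.frequency_hz > 0:
            raise ConfigError("stimulation frequency must be > 0")
        if self.amplitude < 0 or self.width <= 0:
            raise ConfigError("pulse amplitude must be >= 0 and width > 0")

    def mu_for(self, fiber_index: int) -> int:
        if not self.mu_of_fiber:
            return 0
        return self.mu_of_fiber[fiber_index]

    def is_active(self, mu: int, t: float) -> bool:
        """Whether MU ``mu`` is delivering current at time ``t`` (ms)."""
        if self.firing_times:
            times = self.firing_times[mu]
            i = np.searchsorted(times, t, side="right") - 1
            return i >= 0 and t - times[i] < self.width
        if t < self.start:
            return False
        period = 1000.0 / self.frequency_hz
        return (t - self.start) % period < self.width

    def current(self, mu: int, t: float) -> float:
        """Stimulus current (uA/cm^2) delivered by MU ``mu`` at time ``t``."""
        return self.amplitude if self.is_active(mu, t) else 0.0
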