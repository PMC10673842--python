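"""Hardware abstraction seam.

Anything that implements this contract -- the simulated twin or a driver
for the physical instrument -- can sit under the calibration, spectroscopy
and control layers.  ``batch_read`` must return exactly 96 values in
A1..H12 row-major order; ``set_intensity`` must reject settings above 4095.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .twin import PWM_MAX
from .wells import N_WELLS


@runtime_checkable
class HardwareBackend(Protocol):
    def set_intensity(self, role: str, well: str, pwm_setting: int) -> None: ...

    def set_intensity_array(self, role: str, pwm_settings) -> None: ...

    def batch_read(self, channel: str, n_avg: int = 100) -> np.ndarray: ...

    def pause_shaker(self) -> None: ...

    def resume_shaker(self) -> None: ...


class ReplayBackend:
    """Backend replaying pre-recorded 96-well count frames.

    Useful for re-running analysis code against counts captured from a real
    instrument, and for testing that the upper layers depend only on the
    hardware contract.
    """

    def __init__(self, frames: dict[str, list[np.ndarray]]) -> None:
        self._frames = {ch: [np.asarray(f, dtype=float) for f in fs]
                        for ch, fs in frames.items()}
        for ch, fs in self._frames.items():
            for f in fs:
                if f.shape != (N_WELLS,):
                    raise ValueError(f"{ch}: frames must have 96 values")
        self._cursor = {ch: 0 for ch in self._frames}
        self.settings_log: list[tuple] = []
        self.shaker_log: list[tuple[str, ...]] = []

    def set_intensity(self, role: str, well: str, pwm_setting: int) -> None:
        if not 0 <= int(pwm_setting) <= PWM_MAX:
            raise ValueError(f"PWM setting out of range 0..{PWM_MAX}")
        self.settings_log.append((role, well, int(pwm_setting)))

    def set_intensity_array(self, role: str, pwm_settings) -> None:
        arr = np.asarray(pwm_settings)
        if arr.shape != (N_WELLS,):
            raise ValueError("expected 96 settings")
        if arr.min() < 0 or arr.max() > PWM_MAX:
            raise ValueError(f"PWM settings out of range 0..{PWM_MAX}")
        self.settings_log.append((role, "ALL", arr.astype(int)))

    def batch_read(self, channel: str, n_avg: int = 100) -> np.ndarray:
        frames = self._frames.get(channel)
        if not frames:
            raise KeyError(f"no recorded frames for channel {channel!r}")
        i = min(self._cursor[channel], len(frames) - 1)
        self._cursor[channel] += 1
        return frames[i].copy()

    def pause_shaker(self) -> None:
        self.shaker_log.append(("pause",))

    def resume_shaker(self) -> None:
        self.shaker_log.append(("resume",))
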