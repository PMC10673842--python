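"""96-well plate addressing.

Wells are addressed A1..H12 in row-major order everywhere in this package;
no 0-based indices are exposed to users.
"""

from __future__ import annotations

ROWS = "ABCDEFGH"
N_COLS = 12
N_WELLS = 96

WELLS: tuple[str, ...] = tuple(f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1))
_WELL_INDEX = {w: i for i, w in enumerate(WELLS)}


def well_index(well: str) -> int:
    """Row-major index (0..95) of a well name such as 'A1' or 'H12'."""
    try:
        return _WELL_INDEX[well.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown well {well!r}: expected A1..H12") from None


def well_name(index: int) -> str:
    if not 0 <= index < N_WELLS:
        raise ValueError(f"well index {index} out of range 0..95")
    return WELLS[index]
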