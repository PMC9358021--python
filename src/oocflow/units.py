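"""Unit conversions at the config boundary.

Configs speak the bench vocabulary (mm, ml/min, µl/hr, hours); everything
internal is SI (m, m³/s, s). Conversion factors are exact rationals, so
round-tripping is lossless to machine precision.
"""

from __future__ import annotations

# length → metres
_LENGTH = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
}

# volume → cubic metres
_VOLUME = {
    "m3": 1.0,
    "ml": 1e-6,
    "ul": 1e-9,
}

# time → seconds
_TIME = {
    "s": 1.0,
    "min": 60.0,
    "hr": 3600.0,
    "h": 3600.0,
}


def length_to_si(value: float, unit: str) -> float:
    return value * _LENGTH[unit]


def volume_to_si(value: float, unit: str) -> float:
    return value * _VOLUME[unit]


def time_to_si(value: float, unit: str) -> float:
    return value * _TIME[unit]


def flow_rate_to_si(value: float, unit: str) -> float:
    """Convert a volumetric flow rate like ``"ml/min"`` to m³/s."""
    vol, _, time = unit.partition("/")
    if not time:
        raise ValueError(f"flow-rate unit must look like 'ml/min', got {unit!r}")
    return value * _VOLUME[vol] / _TIME[time]


def convert_flow_rate(value: float, unit_from: str, unit_to: str) -> float:
    """Convert a flow rate between two human units (e.g. µl/hr → µl/min)."""
    si = flow_rate_to_si(value, unit_from)
    vol, _, time = unit_to.partition("/")
    if not time:
        raise ValueError(f"flow-rate unit must look like 'ml/min', got {unit_to!r}")
    return si * _TIME[time] / _VOLUME[vol]
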