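"""Environmental heat-load covariates.

Wet bulb globe temperature (WBGT) is the composite heat-stress index used to
characterise the environmental load on an exercising horse.  On-course WBGT
is rarely measured directly, so it is approximated from daily maximum air
temperature and relative humidity:

* wet-bulb temperature via Stull's arctangent approximation (valid for
  standard sea-level pressure, humidity entered in percent, angles in
  radians);
* black-globe temperature via a linear function of air temperature
  calibrated for equine sports settings;
* WBGT as the 0.7/0.3 weighted sum of the two (no direct solar or wind-speed
  input).

The module also derives the acclimatisation covariate: the mean of the daily
maximum temperature over the five days strictly before the race day.
"""

from __future__ import annotations

import math
from datetime import date as _date, timedelta
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "wet_bulb_temperature",
    "black_globe_temperature",
    "wbgt_index",
    "wbgt_from_weather",
    "preceding_average",
    "MISSING",
]

#: Marker for a covariate that cannot be computed (e.g. incomplete
#: preceding-temperature window).  Rows carrying it are later excluded.
MISSING = float("nan")

_T_MIN, _T_MAX = -20.0, 50.0


def wet_bulb_temperature(T, H):
    """Approximate wet-bulb temperature (°C) from air temperature and RH.

    Parameters
    ----------
    T : float or array-like
        Air temperature in °C; plausible range (-20, 50).
    H : float or array-like
        Relative humidity in percent (0-100).  Note the formula takes H on
        the percent scale (50, not 0.5).

    Returns
    -------
    float or ndarray
        Wet-bulb temperature in °C.

    Raises
    ------
    ValueError
        If any humidity value lies outside [0, 100] or any temperature is
        physically implausible.
    """
    T = np.asarray(T, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any((H < 0) | (H > 100)):
        raise ValueError("relative humidity must lie in [0, 100] percent")
    if np.any((T < _T_MIN) | (T > _T_MAX)):
        raise ValueError(f"air temperature outside plausible range ({_T_MIN}, {_T_MAX}) °C")
    twb = (
        T * np.arctan(0.151977 * np.sqrt(H + 8.313659))
        + np.arctan(T + H)
        - np.arctan(H - 1.676331)
        + 0.00391838 * H ** 1.5 * np.arctan(0.023101 * H)
        - 4.686035
    )
    return float(twb) if twb.ndim == 0 else twb


def black_globe_temperature(T):
    """Approximate black-globe temperature (°C): 1.54 * T + 8.65."""
    T = np.asarray(T, dtype=float)
    tg = 1.54 * T + 8.65
    return float(tg) if tg.ndim == 0 else tg


def wbgt_index(Twb, Tg):
    """WBGT = 0.7 * Twb + 0.3 * Tg (°C)."""
    out = 0.7 * np.asarray(Twb, dtype=float) + 0.3 * np.asarray(Tg, dtype=float)
    return float(out) if out.ndim == 0 else out


def wbgt_from_weather(T, H):
    """Full composition: (air temperature, RH %) -> WBGT in °C."""
    return wbgt_index(wet_bulb_temperature(T, H), black_globe_temperature(T))


def preceding_average(
    weather: Mapping[tuple, float] | Iterable,
    course_id,
    date: _date,
    window: int = 5,
) -> float:
    """Mean daily maximum temperature over the ``window`` days before ``date``.

    The race day itself is excluded: the window is [date - window, date - 1].
    If any day in the window is missing for the course the result is the
    missing-covariate marker (NaN) rather than a shortened mean, so that an
    incomplete acclimatisation history never silently biases the covariate.

    ``weather`` is either a mapping {(course_id, date): tmax} or an iterable
    of objects with ``course_id``, ``date`` and ``tmax`` attributes.
    """
    if not isinstance(weather, Mapping):
        weather = {(w.course_id, w.date): w.tmax for w in weather}
    vals = []
    for back in range(1, window + 1):
        key = (course_id, date - timedelta(days=back))
        if key not in weather:
            return MISSING
        vals.append(weather[key])
    return float(math.fsum(vals) / window)
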