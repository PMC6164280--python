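"""Published worked-example measurements shipped as package data.

The three reference tables below are the printed measurement records for
three adult Qinchuan steers (ear tags Q0521, Q0145, Q0159): per body
dimension, the manual tape/stick measurement, the uncorrected (initial)
scan-derived value, the distance-corrected value, and the resulting relative
deviations.  They drive the worked-example and regression checks: deviation
arithmetic, per-scene corrected/initial ratio constancy, and the distance
correction fit.
"""

from __future__ import annotations

import pandas as pd

from .measurement import DIMENSION_NAMES

__all__ = ["reference_measurements", "reference_scene_distances"]

# photographic distance (m) per scene
_DISTANCES = {"Q0521": 1.57047, "Q0145": 1.78572, "Q0159": 1.54938}

# per scene: dimension -> (manual, initial, corrected, initial_dev_pct, final_dev_pct)
_TABLES = {
    "Q0521": {
        "withers_height": (1.56900, 1.41508, 1.58461, 9.81, 1.00),
        "chest_depth":    (0.65300, 0.57622, 0.64525, 11.76, 1.19),
        "back_height":    (1.55600, 1.38628, 1.55236, 10.91, 0.23),
        "body_length":    (1.59100, 1.39373, 1.56071, 12.40, 1.90),
        "waist_height":   (1.59800, 1.43797, 1.61025, 10.01, 0.77),
    },
    "Q0145": {
        "withers_height": (1.53400, 1.27672, 1.52120, 16.77, 0.83),
        "chest_depth":    (0.75800, 0.64814, 0.77225, 14.49, 1.88),
        "back_height":    (1.51600, 1.26818, 1.51103, 16.35, 0.33),
        "body_length":    (1.58400, 1.35469, 1.61410, 14.48, 1.90),
        "waist_height":   (1.55800, 1.31889, 1.57145, 15.35, 0.86),
    },
    "Q0159": {
        "withers_height": (1.12200, 0.98878, 1.10256, 11.87, 1.73),
        "chest_depth":    (0.54100, 0.48211, 0.53759, 10.89, 0.63),
        "back_height":    (1.10100, 0.97186, 1.08370, 11.73, 1.57),
        "body_length":    (1.19600, 1.07749, 1.20149, 9.91, 0.46),
        "waist_height":   (1.14300, 1.00453, 1.12013, 12.11, 2.00),
    },
}


def reference_scene_distances() -> dict[str, float]:
    """Photographic distance (m) of each reference scene, keyed by ear tag."""
    return dict(_DISTANCES)


def reference_measurements() -> pd.DataFrame:
    """All 15 published dimension records as a tidy DataFrame.

    Columns: scene, distance_m, dimension, manual_m, initial_m, corrected_m,
    initial_dev_pct, final_dev_pct.
    """
    rows = []
    for scene, table in _TABLES.items():
        for dim in DIMENSION_NAMES:
            manual, initial, corrected, idev, fdev = table[dim]
            rows.append({
                "scene": scene,
                "distance_m": _DISTANCES[scene],
                "dimension": dim,
                "manual_m": manual,
                "initial_m": initial,
                "corrected_m": corrected,
                "initial_dev_pct": idev,
                "final_dev_pct": fdev,
            })
    return pd.DataFrame(rows)
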