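"""Published reference vorticity summaries for the Weimen reach.

Band means (left / middle / right, 1/s) of cross-sectional vorticity reported
for eight transects of the Weimen reach of the upper Minjiang River, a natural
Schizothorax prenanti spawning ground: three spawning sections (A-A, B-B,
C-C), two transition sections (N-N, M-M) and three non-spawning sections
(D-D, E-E, F-F). ``NEAR_BED`` covers the bed-to-1.3-m layer, ``FULL_SECTION``
the entire wetted section. ``printed_mean`` is the mean column as published
(the section mean is the unweighted average of the three band means; the
published full-section B-B mean carries a one-unit rounding slip in the
fifth decimal).

These values are study outputs used as arithmetic reference inputs; they are
not recomputed from physics here.
"""

from __future__ import annotations

__all__ = [
    "SECTION_LABELS",
    "NEAR_BED",
    "FULL_SECTION",
    "SPAWNING_INTERVAL",
    "NONSPAWNING_BASELINE_PRINTED",
]

#: Habitat label of each reference section.
SECTION_LABELS = {
    "A-A": "spawning",
    "B-B": "spawning",
    "C-C": "spawning",
    "N-N": "transition",
    "M-M": "transition",
    "D-D": "nonspawning",
    "E-E": "nonspawning",
    "F-F": "nonspawning",
}

#: Bed-to-1.3-m layer: {section: (left, middle, right, printed_mean)} in 1/s.
NEAR_BED = {
    "A-A": (0.23973, 0.35652, 0.29233, 0.29619),
    "B-B": (0.28246, 0.41803, 0.31754, 0.33934),
    "C-C": (0.22054, 0.37016, 0.28911, 0.29327),
    "N-N": (0.17135, 0.24331, 0.15274, 0.18913),
    "M-M": (0.14402, 0.23257, 0.13245, 0.16968),
    "D-D": (0.10002, 0.11131, 0.10034, 0.10389),
    "E-E": (0.10001, 0.10101, 0.10001, 0.10034),
    "F-F": (0.10001, 0.10001, 0.10001, 0.10001),
}

#: Entire wetted section: {section: (left, middle, right, printed_mean)} in 1/s.
FULL_SECTION = {
    "A-A": (0.21135, 0.27012, 0.30157, 0.26101),
    "B-B": (0.27951, 0.33086, 0.30378, 0.30471),
    "C-C": (0.18927, 0.26458, 0.22615, 0.22667),
    "N-N": (0.16366, 0.21985, 0.14781, 0.17711),
    "M-M": (0.14006, 0.20174, 0.12988, 0.15723),
    "D-D": (0.10001, 0.10003, 0.10001, 0.10002),
    "E-E": (0.10001, 0.10001, 0.10001, 0.10001),
    "F-F": (0.10001, 0.10001, 0.10001, 0.10001),
}

#: Suitable cross-sectional mean vorticity interval of natural spawning
#: grounds, 1/s.
SPAWNING_INTERVAL = (0.17, 0.35)

#: Reported non-spawning baseline mean vorticity, 1/s.
NONSPAWNING_BASELINE_PRINTED = 0.10001
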