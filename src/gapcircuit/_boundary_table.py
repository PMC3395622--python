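"""Packaged mRNA boundary positions for the trunk gap genes.

Median positions (in % A-P, 0 = anterior pole) of the starting points of the
boundary-approximating splines, per gene, expression domain, boundary side
(A = anterior/rising into the domain, P = posterior/falling) and time class
(C13, then T1-T8 subdividing C14A).  ``None`` marks a boundary that is not
present at that time point.
"""

# (gene, domain, side) in anterior-to-posterior domain order
BOUNDARY_TABLE_COLUMNS = (
    ("hb", "anterior", "P"),
    ("gt", "anterior", "A"),
    ("gt", "anterior", "P"),
    ("Kr", "central", "A"),
    ("Kr", "central", "P"),
    ("kni", "abdominal", "A"),
    ("kni", "abdominal", "P"),
    ("gt", "posterior", "A"),
    ("gt", "posterior", "P"),
    ("hb", "posterior", "A"),
    ("hb", "posterior", "P"),
)

MRNA_BOUNDARY_TABLE = {
    "C13": (45.8, 19.3, 39.8, 46.7, 59.4, 58.3, 72.0, 74.0, None, 89.5, None),
    "T1": (43.8, 20.7, 39.3, 45.3, 57.8, 56.5, 70.1, 69.8, 82.2, 85.0, None),
    "T2": (44.4, 20.0, 38.2, 44.3, 57.3, 57.9, 70.1, 69.8, 79.4, 81.2, 92.2),
    "T3": (45.1, 18.7, 37.8, 45.5, 59.8, 58.0, 70.0, 67.5, 76.9, 80.1, 89.3),
    "T4": (47.0, 18.2, 37.7, 44.0, 57.8, 56.9, 67.1, 67.0, 77.0, 78.9, 88.0),
    "T5": (45.9, 18.3, 37.7, 43.9, 56.7, 56.0, 66.0, 66.8, 76.5, 76.9, 87.7),
    "T6": (45.8, 18.8, 37.3, 43.5, 56.4, 54.5, 64.8, 65.6, 75.1, 75.0, 86.6),
    "T7": (45.8, 19.7, 37.6, 43.0, 52.5, 54.5, 63.0, 64.5, 72.1, 75.6, 86.1),
    "T8": (45.0, 20.5, 37.2, 42.7, 52.5, 54.7, 63.6, 65.3, 72.8, 75.5, 85.8),
}
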