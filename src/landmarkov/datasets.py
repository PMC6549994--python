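"""Published validation fixtures from the Wales 2007-2015 land-cover study.

These are the printed tables of a published Wales case study (CEH Land Cover
Maps 2007/2015, 25 m, projected to 2030): the business-as-usual and
ecosystem-conservation transition probability matrices, and the driver
screening table of 20 Cramer's V values.  The underlying rasters are not
redistributable, so these printed numbers serve as ground truth for the
scenario-edit arithmetic and the screening rule.
"""

from __future__ import annotations

import numpy as np

from .drivers import DriverVariable
from .grid import Legend
from .markov import ScenarioEdit, TransitionProbabilityMatrix

__all__ = [
    "WALES_LEGEND",
    "wales_bau_matrix",
    "wales_ec_matrix",
    "wales_ec_edits",
    "wales_screening_table",
    "WALES_BASE_YEARS",
    "WALES_TARGET_YEARS",
]

WALES_LEGEND = Legend([
    (1, "broadleaf forest"),
    (2, "conifer forest"),
    (3, "arable land"),
    (4, "improved grassland"),
    (5, "semi-natural grassland"),
    (6, "mountain, heath and bog"),
])

#: observation window (2007-2015) and projection horizon (2015-2030), years
WALES_BASE_YEARS = 8.0
WALES_TARGET_YEARS = 15.0

_BAU = np.array([
    [0.570, 0.142, 0.019, 0.191, 0.062, 0.013],
    [0.188, 0.754, 0.003, 0.029, 0.020, 0.004],
    [0.052, 0.009, 0.098, 0.752, 0.079, 0.007],
    [0.040, 0.008, 0.057, 0.784, 0.103, 0.006],
    [0.073, 0.049, 0.034, 0.411, 0.381, 0.051],
    [0.061, 0.088, 0.019, 0.167, 0.452, 0.211],
])

_EC = np.array([
    [1.000, 0.000, 0.000, 0.000, 0.000, 0.000],
    [0.282, 0.659, 0.003, 0.029, 0.020, 0.004],
    [0.052, 0.009, 0.098, 0.752, 0.079, 0.007],
    [0.040, 0.008, 0.057, 0.784, 0.103, 0.006],
    [0.073, 0.049, 0.034, 0.411, 0.381, 0.051],
    [0.061, 0.088, 0.019, 0.167, 0.347, 0.316],
])


def wales_bau_matrix() -> TransitionProbabilityMatrix:
    """Printed business-as-usual transition matrix (2015 -> 2030, 3 d.p.)."""
    return TransitionProbabilityMatrix(_BAU.copy(), WALES_TARGET_YEARS, WALES_LEGEND)


def wales_ec_matrix() -> TransitionProbabilityMatrix:
    """Printed ecosystem-conservation transition matrix (2015 -> 2030, 3 d.p.).

    Note: the published conifer persistence cell is 0.659, while exact donor
    arithmetic on the printed B-a-U row yields 0.660 — a 0.001 rounding
    residue of the study's unpublished internal precision.
    """
    return TransitionProbabilityMatrix(_EC.copy(), WALES_TARGET_YEARS, WALES_LEGEND)


def wales_ec_edits() -> list[ScenarioEdit]:
    """The three ecosystem-conservation rules, in publication order:
    conifer-to-broadleaf conversion +50% (donor: persistence), mountain/
    heath/bog persistence +50% (donor: largest off-diagonal), and broadleaf
    loss forbidden."""
    return [
        ScenarioEdit("scale_cell", "conifer forest", "broadleaf forest", 1.5,
                     donor="diagonal"),
        ScenarioEdit("scale_diagonal", "mountain, heath and bog", factor=1.5,
                     donor="largest_offdiagonal"),
        ScenarioEdit("fix_row_identity", "broadleaf forest"),
    ]


#: (name, printed Cramer's V, dynamic?, retained-in-published-model?)
_SCREENING_ROWS: list[tuple[str, float, bool, bool]] = [
    ("altitude", 0.345, False, True),
    ("aspect", 0.077, False, False),
    ("slope", 0.168, False, True),
    ("hillshade", 0.135, False, False),
    ("distance from access points", 0.224, False, True),
    ("distance from green spaces", 0.223, False, True),
    ("distance from water channels", 0.011, False, False),
    ("distance from roads", 0.254, False, True),
    ("distance from hydronodes", 0.065, False, False),
    ("distance from motorway junctions", 0.161, False, True),
    ("distance from broadleaf forest", 0.155, True, True),
    ("distance from conifer forest", 0.081, True, False),
    ("distance from arable land", 0.210, True, True),
    ("distance from improved grassland", 0.155, True, True),
    ("distance from semi-natural grassland", 0.161, True, True),
    ("distance from mountain, heath and bog", 0.013, True, False),
    ("evidence likelihood broadleaf-to-all (past transitions)", 0.249, False, True),
    ("evidence likelihood all-to-broadleaf (past transitions)", 0.533, False, True),
    ("evidence likelihood broadleaf-to-all (soil type)", 0.251, False, True),
    ("evidence likelihood all-to-broadleaf (soil type)", 0.256, False, True),
]


def wales_screening_table() -> tuple[list[DriverVariable], list[str]]:
    """The 20 published driver variables with their printed Cramer's V.

    Returns ``(variables, published_retained_names)`` — the variables carry
    no raster (the source rasters are not redistributable), only the
    statistic needed to replay the screening decision.
    """
    variables = [
        DriverVariable(name=name, raster=None, dynamic=dyn, cramers_v=v)  # type: ignore[arg-type]
        for name, v, dyn, _ in _SCREENING_ROWS
    ]
    retained = [name for name, _, _, kept in _SCREENING_ROWS if kept]
    return variables, retained
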