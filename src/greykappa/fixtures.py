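"""Packaged worked-example tables: breast-cancer film classification.

The ``original`` table records two radiologists' diagnostic classification
of 85 xeromammography films into four ordered categories (Normal, Benign
disease, Suspected cancer, Cancer).  The adjacent middle categories form a
grey zone: Radiologist A over-uses "Suspected cancer" (29 vs B's 16) while
Radiologist B over-uses "Benign disease" (38 vs A's 22), inflating the
(Suspected, Benign) cell to 9 against a single (Benign, Suspected) rating.

Three hypothetical scenarios remove the grey-zone tendency by relocating
Radiologist A's borderline "Suspected cancer" ratings into "Benign disease"
while holding Radiologist B's column totals fixed:

* ``scenario1`` — the bulk of the (Suspected, Suspected) diagonal (13 of 15)
  moves up a row to (Benign, Suspected): agreement on Benign rises, on
  Suspected collapses.
* ``scenario2`` — the off-diagonal (Suspected, Benign) count of 9 moves up
  to the (Benign, Benign) diagonal: agreement rises across the board.
* ``scenario3`` — scenario 2 plus 3 ratings moved off the (Suspected,
  Suspected) diagonal to (Benign, Suspected).

Provenance note: the published source marks the changed cells of scenarios
1 and 3 inconsistently (marked cells, row totals and the accompanying
Cohen's kappa values cannot all hold at once).  The tables above are the
unique reconstructions that keep Radiologist B's column totals at
(28, 38, 16, 3), match the printed row totals, and reproduce the published
Cohen's kappa rows to 3 decimals.

A second, "additive" realization of each scenario is also packaged
(``scenario1_additive`` ...), in which the relocated counts are added to
their destination cells without decrementing the sources (N grows from 85
to 94).  These are not probability-conserving edits of the original table,
but they are exactly the tables behind the published cross-scenario
sensitivity analysis (the per-measure coefficient sets and their
coefficients of variation reproduce to 3 decimals only from these), so both
realizations ship.
"""

from __future__ import annotations

import numpy as np

from .measures import ContingencyTable

#: Ordered category labels of the worked example.
CATEGORIES = ("Normal", "Benign disease", "Suspected cancer", "Cancer")

_ORIGINAL = (
    (21, 12, 0, 0),
    (4, 17, 1, 0),
    (3, 9, 15, 2),
    (0, 0, 0, 1),
)


def _edit(base, changes):
    m = [list(row) for row in base]
    for (i, j), v in changes.items():
        m[i][j] = v
    return tuple(tuple(row) for row in m)


_TABLES: dict[str, tuple] = {
    "original": _ORIGINAL,
    # Marginal-consistent reconstructions (N = 85).
    "scenario1": _edit(_ORIGINAL, {(1, 2): 14, (2, 2): 2}),
    "scenario2": _edit(_ORIGINAL, {(1, 1): 26, (2, 1): 0}),
    "scenario3": _edit(_ORIGINAL, {(1, 1): 26, (2, 1): 0, (1, 2): 4, (2, 2): 12}),
    # Additive realizations behind the published sensitivity analysis (N = 94).
    "scenario1_additive": _edit(_ORIGINAL, {(1, 1): 26, (1, 2): 14, (2, 2): 2}),
    "scenario2_additive": _edit(_ORIGINAL, {(1, 1): 26}),
    "scenario3_additive": _edit(_ORIGINAL, {(1, 1): 26, (1, 2): 3, (2, 2): 13}),
}

#: Fixture names, in canonical order.
FIXTURE_NAMES = tuple(_TABLES)

#: The four tables entering the cross-scenario CV sensitivity summary.
CV_SET = ("original", "scenario1_additive", "scenario2_additive", "scenario3_additive")


def load_fixture(name: str) -> ContingencyTable:
    """Return a packaged worked-example table by name."""
    try:
        return ContingencyTable(np.array(_TABLES[name], dtype=np.int64))
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
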