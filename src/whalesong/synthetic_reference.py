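"""Synthetic reconstruction of the published two-population theme table.

The study's deposited per-theme presence table is not redistributable, so
this module carries a *synthetic* stand-in: a per-theme presence layout
constructed to be consistent with every published aggregate — 40 themes
numbered 1-40 across six song types (Purple, Light Purple, Brown, Light
Brown, Teal, Orange; the "Light" types are the two evolution lineages), 29
themes shared between the east Australian (EA) and New Caledonian (NC)
populations and 11 recorded in a single population, single-population themes
concentrated in the evolution song types and in NC, Theme 6 (Light Purple)
unique to EA and Theme 28 (Light Brown) unique to one population.  The
row-level layout within those constraints is a construction, not data.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["synthetic_theme_presence"]

# (song_type, theme_id, in_EA, in_NC)
_ROWS = [
    # Purple (revolution): all 5 themes shared
    ("Purple", 1, True, True),
    ("Purple", 2, True, True),
    ("Purple", 3, True, True),
    ("Purple", 4, True, True),
    ("Purple", 5, True, True),
    # Light Purple (evolution): Theme 6 unique to EA; 11, 12 unique to NC
    ("Light Purple", 6, True, False),
    ("Light Purple", 7, True, True),
    ("Light Purple", 8, True, True),
    ("Light Purple", 9, True, True),
    ("Light Purple", 10, True, True),
    ("Light Purple", 11, False, True),
    ("Light Purple", 12, False, True),
    # Brown (revolution): one NC-unique theme
    ("Brown", 13, True, True),
    ("Brown", 14, True, True),
    ("Brown", 15, True, True),
    ("Brown", 16, True, True),
    ("Brown", 17, True, True),
    ("Brown", 18, True, True),
    ("Brown", 19, False, True),
    # Light Brown (evolution): Theme 28 unique to EA; 25-27 unique to NC
    ("Light Brown", 20, True, True),
    ("Light Brown", 21, True, True),
    ("Light Brown", 22, True, True),
    ("Light Brown", 23, True, True),
    ("Light Brown", 24, True, True),
    ("Light Brown", 25, False, True),
    ("Light Brown", 26, False, True),
    ("Light Brown", 27, False, True),
    ("Light Brown", 28, True, False),
    # Teal (revolution): one NC-unique theme
    ("Teal", 29, True, True),
    ("Teal", 30, True, True),
    ("Teal", 31, True, True),
    ("Teal", 32, True, True),
    ("Teal", 33, True, True),
    ("Teal", 34, False, True),
    # Orange (revolution): two NC-unique themes
    ("Orange", 35, True, True),
    ("Orange", 36, True, True),
    ("Orange", 37, True, True),
    ("Orange", 38, True, True),
    ("Orange", 39, False, True),
    ("Orange", 40, False, True),
]


def synthetic_theme_presence() -> pd.DataFrame:
    """Presence table with columns song_type, theme_id, in_EA, in_NC."""
    return pd.DataFrame(
        _ROWS, columns=["song_type", "theme_id", "in_EA", "in_NC"]
    )
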