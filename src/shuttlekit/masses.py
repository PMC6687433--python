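"""Pinned monoisotopic mass table.

The table is frozen (CODATA-2018 / AME-2020 values, truncated to 10
significant figures) and carries a version tag so that exact-mass arithmetic
is reproducible to the fourth decimal regardless of dependency drift.
Isotopically labelled species are distinct symbols: ``D`` (²H) and ``[15N]``.
"""

from __future__ import annotations

MASS_TABLE_VERSION = "pinned-2020.1"

#: Monoisotopic masses in Da (most abundant isotope unless labelled).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825032,
    "D": 2.014101778,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "Na": 22.98976928,
    "S": 31.97207117,
    "P": 30.97376200,
    "[15N]": 15.00010890,
}

#: Electron rest mass in Da.
ELECTRON_MASS = 0.000548579909

#: Exact mass difference gained per H → D exchange, Da.
DEUTERIUM_SHIFT = MONOISOTOPIC_MASS["D"] - MONOISOTOPIC_MASS["H"]
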