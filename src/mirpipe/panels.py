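"""MicroRNA identifier normalization and the default analysis panel.

Published tables write microRNA ids in dot form (``miR.146a.5p``) while raw
instrument exports and miRBase use dash form (``hsa-miR-146a-5p``).  Everything
in this package canonicalizes to the dash form without the species prefix,
e.g. ``miR-146a-5p``.
"""

from __future__ import annotations

import re

__all__ = [
    "normalize_mir_id",
    "DEFAULT_MIR_PANEL",
    "HOUSEKEEPER_ID",
    "HOUSEKEEPER_ALIASES",
    "TOPOGRAPHY_TISSUES",
]

_MIR_RE = re.compile(r"^(?:hsa[-._])?(mir|let)[-._]?(.+)$", re.IGNORECASE)


def normalize_mir_id(mir_id: str) -> str:
    """Canonicalize a microRNA identifier.

    Accepts dot-separated table forms (``miR.146a.5p``), miRBase forms
    (``hsa-miR-146a-5p``) and case variants; returns ``miR-146a-5p``.
    Unrecognized strings are returned stripped but otherwise unchanged.
    """
    s = str(mir_id).strip()
    m = _MIR_RE.match(s)
    if m is None:
        return s
    prefix = "let" if m.group(1).lower() == "let" else "miR"
    body = m.group(2).replace(".", "-").replace("_", "-")
    return f"{prefix}-{body}"


#: The 24-microRNA qualitative analysis panel (housekeeper handled separately).
DEFAULT_MIR_PANEL: tuple[str, ...] = (
    "miR-324-5p",
    "miR-9",
    "miR-21",
    "miR-31",
    "miR-33b",
    "miR-96",
    "miR-105",
    "miR-146a-5p",
    "miR-182-5p",
    "miR-196b",
    "miR-199b-5p",
    "miR-200a",
    "miR-200b",
    "miR-205",
    "miR-212",
    "miR-221",
    "miR-345",
    "miR-429",
    "miR-767",
    "miR-944",
    "miR-1269a",
    "miR-1293",
    "miR-1910",
    "miR-3662",
)

#: Housekeeping transcript used for qualitative QC and delta-Ct normalization.
HOUSEKEEPER_ID = "miR-423-3p"

#: Both arms of miR-423 are accepted as housekeeper ids (source reports are
#: internally inconsistent about which arm was used); neither belongs in the
#: analysis panel.
HOUSEKEEPER_ALIASES: frozenset[str] = frozenset({"miR-423-3p", "miR-423-5p"})

#: Airway sampling levels, deep lung to mouth: exhaled breath condensate,
#: bronchoalveolar lavage, bronchial brush, sputum, mouthwash.
TOPOGRAPHY_TISSUES: tuple[str, ...] = ("EBC", "BAL", "BB", "SP", "MW")
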