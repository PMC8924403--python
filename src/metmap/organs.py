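"""The 13 organ sites of the structured CT report template.

Chest/abdomen/pelvis CT reports written against the structured template
carry one free-text "Findings" paragraph per organ site plus an overall
"Impression".  The enum below fixes the canonical site list and the
headings used in the plain-text dialect.
"""

from __future__ import annotations

import enum


class OrganSite(enum.Enum):
    """One of the 13 organ sections of the report template."""

    LUNGS = "lungs"
    PLEURA = "pleura"
    THORACIC_NODES = "thoracic_nodes"
    LIVER = "liver"
    SPLEEN = "spleen"
    ADRENAL_GLANDS = "adrenal_glands"
    RENAL = "renal"
    ABDOMINOPELVIC_NODES = "abdominopelvic_nodes"
    PELVIC_ORGANS = "pelvic_organs"
    BOWEL = "bowel"
    PERITONEUM = "peritoneum"
    BONES = "bones"
    SOFT_TISSUES = "soft_tissues"

    @property
    def heading(self) -> str:
        """Human-readable heading as it appears in a rendered report."""
        return self.value.replace("_", " ").title()

    @classmethod
    def from_heading(cls, text: str) -> "OrganSite":
        """Resolve a heading string (case-insensitive) to a site.

        Raises
        ------
        KeyError
            If the heading does not name one of the 13 sites.
        """
        key = text.strip().strip(":").strip().lower().replace(" ", "_")
        return cls(key)


#: The three sites modeled in the classification study: the two most common
#: metastatic sites (lungs, liver) and one of the least common (adrenals).
TARGET_ORGANS = (OrganSite.LUNGS, OrganSite.LIVER, OrganSite.ADRENAL_GLANDS)
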