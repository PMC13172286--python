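"""Coil-element naming for the torso and head-and-neck arrays.

Element labels follow the vendor convention: VAS (ventral anterior
superior), VPS (ventral posterior superior), VAP (ventral anterior
posterior), VPP (ventral posterior posterior), each numbered from 1.
The torso array has 12 elements (three per group); the head-and-neck
array has 10 (VAP and VPP stop at 2).
"""

import re

ELEMENT_PATTERN = re.compile(r"V(A|P)(S|P)\d", re.IGNORECASE)

TORSO_ELEMENTS: tuple[str, ...] = (
    "VAS1", "VAS2", "VAS3",
    "VPS1", "VPS2", "VPS3",
    "VAP1", "VAP2", "VAP3",
    "VPP1", "VPP2", "VPP3",
)

HEAD_NECK_ELEMENTS: tuple[str, ...] = (
    "VAS1", "VAS2", "VAS3",
    "VPS1", "VPS2", "VPS3",
    "VAP1", "VAP2",
    "VPP1", "VPP2",
)

COIL_ELEMENTS: dict[str, tuple[str, ...]] = {
    "torso": TORSO_ELEMENTS,
    "head_neck": HEAD_NECK_ELEMENTS,
}


def extract_element_label(text: str) -> str | None:
    """Return the first element label found in ``text``, uppercased, or None."""
    m = ELEMENT_PATTERN.search(text or "")
    return m.group(0).upper() if m else None
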