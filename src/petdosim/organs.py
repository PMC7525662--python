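"""Controlled organ vocabulary.

Region-of-interest names exported by image-analysis software vary
(``Kidney L``/``Kidney R``, ``whole-body`` vs ``Total Body`` ...).  All
inputs are mapped onto one canonical, lower-snake-case vocabulary at read
time; unknown names raise :class:`~petdosim.errors.UnknownOrganError`
rather than being silently dropped.  Paired organs (kidneys, lungs) are
summed into the single phantom organ the dose phantoms use.
"""

from __future__ import annotations

from .errors import UnknownOrganError

WHOLE_BODY = "whole_body"
REMAINDER = "remainder"
LLI_WALL = "lli_wall"

#: Source organs delineated in a rodent whole-body scan.
SOURCE_ORGANS = (
    "brain",
    "heart",
    "lungs",
    "liver",
    "kidneys",
    "intestine",
    "urinary_bladder",
)

#: Phantom target organs, superset of sources (the LLI wall receives dose
#: but is not delineated as a rodent source).
TARGET_ORGANS = SOURCE_ORGANS + (LLI_WALL,)

#: Extended target list used when simulating clinical dose tables.
EXTENDED_TARGETS = TARGET_ORGANS + (
    "spleen",
    "pancreas",
    "stomach_wall",
    "red_marrow",
    "thyroid",
    "muscle",
    "skin",
    "bone_surface",
)

# alias -> (canonical name, paired flag). Paired members are summed.
_ALIASES: dict[str, str] = {
    "whole-body": WHOLE_BODY,
    "wholebody": WHOLE_BODY,
    "total_body": WHOLE_BODY,
    "total body": WHOLE_BODY,
    "kidney_left": "kidneys",
    "kidney_right": "kidneys",
    "kidney l": "kidneys",
    "kidney r": "kidneys",
    "kidney": "kidneys",
    "lung_left": "lungs",
    "lung_right": "lungs",
    "lung l": "lungs",
    "lung r": "lungs",
    "lung": "lungs",
    "bladder": "urinary_bladder",
    "urinary bladder": "urinary_bladder",
    "lli wall": LLI_WALL,
    "lli": LLI_WALL,
    "lower_large_intestine": LLI_WALL,
    "remaining": REMAINDER,
}

_KNOWN = set(EXTENDED_TARGETS) | {WHOLE_BODY, REMAINDER}


def canonical_organ(name: str) -> str:
    """Map a free-form organ label to the canonical vocabulary.

    Raises
    ------
    UnknownOrganError
        If the label is not recognised.
    """
    key = name.strip().lower().replace("-", "_")
    key = _ALIASES.get(key, _ALIASES.get(name.strip().lower(), key))
    if key not in _KNOWN:
        raise UnknownOrganError(
            f"organ label {name!r} is not in the controlled vocabulary"
        )
    return key
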