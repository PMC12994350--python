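"""Tissue class legend shared across the package.

Nine tissue classes are segmented in H&E rectal-cancer histology; a tenth
``background`` code marks unstained glass / lumen and is assigned only by
masking, never predicted by the classifier.
"""

from __future__ import annotations

from enum import IntEnum


class TissueClass(IntEnum):
    """Class codes for the 9 tissue types plus background.

    Codes are stable across the whole package: masks on disk, model
    outputs and TSR bookkeeping all use these integers.
    """

    TUMOR = 0
    STROMA = 1
    NECROSIS = 2
    MUSCLE = 3
    HEALTHY_EPITHELIUM = 4
    FAT = 5
    MUCUS = 6
    LYMPHOCYTES = 7
    BLOOD = 8
    BACKGROUND = 9


#: The nine classes a trained segmenter may predict (background excluded).
TISSUE_CLASSES: tuple[TissueClass, ...] = tuple(
    c for c in TissueClass if c is not TissueClass.BACKGROUND
)

#: code -> lower-case name, e.g. {0: "tumor", ...}
CLASS_LEGEND: dict[int, str] = {int(c): c.name.lower() for c in TissueClass}

#: name -> code
CLASS_BY_NAME: dict[str, int] = {v: k for k, v in CLASS_LEGEND.items()}


def validate_class_codes(codes) -> None:
    """Raise ``InvalidClassError`` if any code is not a known class."""
    from .errors import InvalidClassError

    valid = set(CLASS_LEGEND)
    bad = sorted(set(int(c) for c in codes) - valid)
    if bad:
        raise InvalidClassError(f"unknown tissue class code(s): {bad}")
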