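"""Tissue classes used to label plaque cross-section regions and elements."""

from enum import IntEnum


class TissueLabel(IntEnum):
    """CTA-derived plaque tissue classes.

    MATX: fibrous/cellular matrix; CALC: macro-calcification;
    LRNC: lipid-rich necrotic core. Integer values are stable and are what
    mesh files store in their ``tissue_label`` cell field.
    """

    MATX = 1
    CALC = 2
    LRNC = 3

    @classmethod
    def from_any(cls, value) -> "TissueLabel":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls[value.upper()]
        return cls(int(value))
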