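"""Unit conventions, centralized.

Internal lengths are micrometres (um); optical coefficients are per
millimetre (mm^-1); thermal quantities are SI.  Every conversion between
those systems goes through the constants below so that a silent 10x error
cannot hide in two places at once.
"""

UM_PER_MM = 1000.0
MM_PER_UM = 1.0 / UM_PER_MM
M_PER_UM = 1e-6
UM_PER_CM = 1e4
CM2_PER_M2 = 1e4


def um_to_mm(x_um: float) -> float:
    return x_um * MM_PER_UM


def mm_to_um(x_mm: float) -> float:
    return x_mm * UM_PER_MM
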