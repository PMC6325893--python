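"""Published wild-type gamma parameters for *S. cerevisiae* cell size.

Maximum-likelihood gamma fits (shape α, rate β per fL) reported for
Coulter-channelyzer cell-size distributions of the standard laboratory
backgrounds: BY4743 diploids across carbon sources, and the two BY4741
haploid samples of the genome-wide deletion-collection screen.  The
average of the two BY4741 fits defines the fixed reference null used to
rank deletion strains by their departure from the wild-type gamma pattern.
"""

from __future__ import annotations

import pandas as pd

# (strain, carbon source, gamma shape, gamma rate)
WILDTYPE_GAMMA_FITS: tuple[tuple[str, str, float, float], ...] = (
    ("BY4743", "Dextrose(2%)", 6.624628, 0.060432),
    ("BY4743", "Dextrose(2%)", 6.839326, 0.0613),
    ("BY4743", "Dextrose(2%)", 7.939692, 0.062422),
    ("BY4743", "Dextrose(2%)", 6.327387, 0.051845),
    ("BY4743", "Dextrose(0.5%)", 6.631854, 0.056427),
    ("BY4743", "Dextrose(0.5%)", 7.028829, 0.059809),
    ("BY4743", "Dextrose(0.5%)", 6.523879, 0.056879),
    ("BY4743", "Dextrose(0.5%)", 6.682971, 0.05811),
    ("BY4743", "Dextrose(0.5%)", 6.92371, 0.059789),
    ("BY4743", "Dextrose(0.5%)", 7.118115, 0.060818),
    ("BY4743", "Dextrose(0.1%)", 5.491663, 0.051904),
    ("BY4743", "Dextrose(0.1%)", 5.502986, 0.050511),
    ("BY4743", "Dextrose(0.1%)", 5.038751, 0.050269),
    ("BY4743", "Dextrose(0.1%)", 4.987775, 0.049489),
    ("BY4743", "Dextrose(0.05%)", 4.084743, 0.043347),
    ("BY4743", "Dextrose(0.05%)", 4.601468, 0.047501),
    ("BY4743", "Dextrose(0.05%)", 4.13688, 0.046411),
    ("BY4743", "Dextrose(0.05%)", 4.137698, 0.046938),
    ("BY4743", "Dextrose(0.05%)", 4.936219, 0.052235),
    ("BY4743", "Dextrose(0.05%)", 4.86957, 0.04992),
    ("BY4743", "Galactose(2%)", 4.352128, 0.049247),
    ("BY4743", "Galactose(2%)", 4.34835, 0.048053),
    ("BY4743", "Galactose(2%)", 4.460477, 0.050979),
    ("BY4743", "Galactose(2%)", 4.651173, 0.053049),
    ("BY4743", "Galactose(2%)", 4.561268, 0.0503),
    ("BY4743", "Galactose(2%)", 4.886206, 0.053239),
    ("BY4743", "Glycerol(2%)", 4.576071, 0.046215),
    ("BY4743", "Glycerol(2%)", 4.19207, 0.046484),
    ("BY4743", "Glycerol(2%)", 4.243508, 0.04657),
    ("BY4741", "Dextrose(2%)", 3.651767, 0.074363),
    ("BY4741", "Dextrose(2%)", 4.003634, 0.083534),
)

#: Fixed gamma null for the haploid deletion-collection screen: the average
#: of the two BY4741 wild-type fits.
BY4741_REFERENCE_SHAPE = 3.8277
BY4741_REFERENCE_RATE = 0.078949


def wildtype_table() -> pd.DataFrame:
    """The reference fits as a DataFrame (strain, condition, shape, rate)."""
    return pd.DataFrame(WILDTYPE_GAMMA_FITS, columns=["strain", "condition", "shape", "rate"])
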