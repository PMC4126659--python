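"""Published reference values for Antarctic krill (*Euphausia superba*).

These constants reproduce the morphometric and selectivity relationships
estimated for krill caught off the South Orkney Islands: cross-section
shape families, bilinear coefficient models linking cross-section width
``b`` and height ``h`` to shape parameters, linear body-length
regressions for ``b`` and ``h`` at the two decisive cross sections, and
the experimentally estimated selection curve of a 15.4 mm commercial
diamond-mesh trawl against a 7 mm macroplankton control trawl.  They
serve as package defaults; every fitting routine accepts freshly
estimated replacements.
"""

from __future__ import annotations

from .morphology import (
    BilinearCoefficientModel,
    CoefficientModelSet,
    LengthDimensionRegression,
    default_residual_sds,
)
from .selectivity import SelectionCurve

#: Best-fitting cross-section curve family per cross section.
KRILL_SHAPE_FAMILIES = {
    "CS1": "flexellipse_1",
    "CS2": "flexellipse_3",
    "CS3": "flexdrope_2",
}

#: Bilinear coefficient models c(b, h), CS1 (anterior, maximum-width section).
KRILL_CS1_COEFFS = CoefficientModelSet(
    c1=BilinearCoefficientModel({"a1": 0.5224}, r2=0.9892, df_resid=29),
    c2=BilinearCoefficientModel({"a1": 0.4403, "a2": 0.2069}, r2=0.9887, df_resid=28),
    c3=BilinearCoefficientModel({"a2": 0.1584, "a3": -0.0190}, r2=0.6831, df_resid=28),
    family="flexellipse_1",
    b_range=(1.96, 5.57),  # implied by the length regressions over 19-54 mm
    h_range=(3.47, 8.53),
)

#: Bilinear coefficient models c(b, h), CS2 (posterior section).
KRILL_CS2_COEFFS = CoefficientModelSet(
    c1=BilinearCoefficientModel({"a1": 0.2768, "a2": 0.1473}, r2=0.9929, df_resid=28),
    c2=BilinearCoefficientModel({"a1": 0.3456, "a2": 0.2126}, r2=0.9902, df_resid=28),
    c3=BilinearCoefficientModel({"a2": 0.1247, "a3": -0.0129}, r2=0.8713, df_resid=28),
    family="flexellipse_3",
    b_range=(1.97, 5.46),
    h_range=(2.68, 7.17),
)

KRILL_COEFF_MODELS = {"CS1": KRILL_CS1_COEFFS, "CS2": KRILL_CS2_COEFFS}

#: Length (mm) -> dimension (mm) regressions: (slope, intercept, R^2).
KRILL_LENGTH_REGRESSIONS = LengthDimensionRegression({
    ("CS1", "width"): (0.1031, 0.0033, 0.8478),
    ("CS1", "height"): (0.1444, 0.7278, 0.8220),
    ("CS2", "width"): (0.0995, 0.0833, 0.8822),
    ("CS2", "height"): (0.1282, 0.2461, 0.8419),
})

#: Length statistics of the fresh reference sample (mm).
KRILL_LENGTH_MEAN = 44.7
KRILL_LENGTH_SD = 7.7

#: Residual sds (mm) per (cross section, dimension) consistent with the
#: regression R^2 values at the reference length spread.
KRILL_RESIDUAL_SDS = default_residual_sds(KRILL_LENGTH_REGRESSIONS, KRILL_LENGTH_SD)

#: Commercial trawl netting: stretched inside mesh size (mm).
COMMERCIAL_MESH_MM = 15.4

#: Experimental paired-gear selection estimate for the 15.4 mm trawl.
EXPERIMENTAL_CURVE = SelectionCurve(l50=32.72, sr=4.85)
EXPERIMENTAL_SP = 0.55
EXPERIMENTAL_TEST_TOTAL = 393
EXPERIMENTAL_CONTROL_TOTAL = 416
EXPERIMENTAL_N_HAULS = 4

#: Opening-angle grid (degrees) used for mixture calibration.
DEFAULT_OA_GRID = (15, 20, 25, 30, 35, 40, 45, 50)
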