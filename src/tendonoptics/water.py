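"""Pure-water absorption spectrum, 400-1600 nm.

A compact knot table of the absorption coefficient of pure water
[mm^-1], after the Hale & Querry (1973) compilation as commonly tabulated in
tissue optics.  The knots reproduce the familiar features of the spectrum --
the minimum near 500 nm, the shoulders at 750 and 840 nm, the 970 nm and
1200 nm overtone bands, and the strong 1450 nm band.  Between knots the
package interpolates log-linearly (absorption spans five decades over this
range).  Digitizations of this spectrum differ at the tens-of-percent level
between published tabulations; for tendon work the consequence is small
because attenuation is scattering-dominated everywhere except inside the
water bands.
"""

import numpy as np

# wavelength [nm], mua_water [mm^-1]
WATER_KNOTS = np.array(
    [
        (400.0, 6.63e-5),
        (425.0, 4.78e-5),
        (450.0, 3.70e-5),
        (475.0, 3.22e-5),
        (500.0, 2.51e-5),
        (525.0, 2.91e-5),
        (550.0, 4.48e-5),
        (575.0, 6.69e-5),
        (600.0, 2.283e-4),
        (625.0, 2.795e-4),
        (650.0, 3.170e-4),
        (675.0, 4.152e-4),
        (700.0, 6.014e-4),
        (725.0, 1.586e-3),
        (750.0, 2.614e-3),
        (775.0, 2.400e-3),
        (800.0, 1.963e-3),
        (810.0, 2.050e-3),
        (825.0, 2.772e-3),
        (850.0, 4.332e-3),
        (875.0, 5.616e-3),
        (900.0, 6.786e-3),
        (925.0, 1.440e-2),
        (950.0, 3.875e-2),
        (975.0, 4.486e-2),
        (1000.0, 3.631e-2),
        (1050.0, 1.675e-2),
        (1100.0, 1.691e-2),
        (1150.0, 5.33e-2),
        (1200.0, 1.036e-1),
        (1250.0, 8.54e-2),
        (1300.0, 1.112e-1),
        (1350.0, 3.00e-1),
        (1400.0, 1.239),
        (1450.0, 2.86),
        (1500.0, 1.92),
        (1550.0, 0.97),
        (1600.0, 0.672),
    ]
)
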