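"""Physical constants and scanner conventions.

All ppm <-> Hz conversions in this package use a fixed 13C reference
frequency of 75.0 MHz (nominal 7 T), so 1 ppm = 75.0 Hz.  The value is
configurable where it matters (pulse design, spectrum axes) but every
default routes through these module-level constants.
"""

#: 13C gyromagnetic ratio, MHz/T.
GAMMA_13C_MHZ_PER_T = 10.7084

#: 13C gyromagnetic ratio, Hz/Gauss (1 T = 1e4 G).
GAMMA_13C_HZ_PER_G = GAMMA_13C_MHZ_PER_T * 1e6 / 1e4

#: 13C carrier frequency at nominal 7 T, MHz.  1 ppm == F0_MHZ Hz.
F0_MHZ = 75.0

#: Hz per ppm at the reference field.
HZ_PER_PPM = F0_MHZ

#: Gradient raster time, s.
RASTER_S = 4e-6

#: Maximum gradient slew rate, Gauss/cm/s (2000 T/m/s).
MAX_SLEW_G_CM_S = 2e5

#: Peak gradient amplitude cap, Gauss/cm (400 mT/m system).
MAX_GRAD_G_CM = 40.0

#: Default peak-B1 hardware cap, Gauss (0.2 mT; within reach of
#: small-animal volume transmit coils at the 13C frequency).
MAX_B1_GAUSS = 2.0
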