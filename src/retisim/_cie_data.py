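"""CIE 1931 2-degree standard observer CMFs and D65 illuminant, 380-780 nm at 5 nm steps."""

# wavelengths in nanometres
CIE_WAVELENGTHS_NM = [
    380.0, 385.0, 390.0, 395.0, 400.0, 405.0, 410.0, 415.0, 420.0, 425.0, 430.0, 435.0, 440.0, 445.0, 450.0, 455.0, 460.0, 465.0, 470.0, 475.0, 480.0, 485.0, 490.0, 495.0, 500.0, 505.0, 510.0, 515.0, 520.0, 525.0, 530.0, 535.0, 540.0, 545.0, 550.0, 555.0, 560.0, 565.0, 570.0, 575.0, 580.0, 585.0, 590.0, 595.0, 600.0, 605.0, 610.0, 615.0, 620.0, 625.0, 630.0, 635.0, 640.0, 645.0, 650.0, 655.0, 660.0, 665.0, 670.0, 675.0, 680.0, 685.0, 690.0, 695.0, 700.0, 705.0, 710.0, 715.0, 720.0, 725.0, 730.0, 735.0, 740.0, 745.0, 750.0, 755.0, 760.0, 765.0, 770.0, 775.0, 780.0,
]

# columns: x_bar, y_bar, z_bar
CMF_XYZ_1931_2DEG = [
    (1.368000e-03, 3.900000e-05, 6.450001e-03),
    (2.236000e-03, 6.400000e-05, 1.054999e-02),
    (4.243000e-03, 1.200000e-04, 2.005001e-02),
    (7.650000e-03, 2.170000e-04, 3.621000e-02),
    (1.431000e-02, 3.960000e-04, 6.785001e-02),
    (2.319000e-02, 6.400000e-04, 1.102000e-01),
    (4.351000e-02, 1.210000e-03, 2.074000e-01),
    (7.763000e-02, 2.180000e-03, 3.713000e-01),
    (1.343800e-01, 4.000000e-03, 6.456000e-01),
    (2.147700e-01, 7.300000e-03, 1.039050e+00),
    (2.839000e-01, 1.160000e-02, 1.385600e+00),
    (3.285000e-01, 1.684000e-02, 1.622960e+00),
    (3.482800e-01, 2.300000e-02, 1.747060e+00),
    (3.480600e-01, 2.980000e-02, 1.782600e+00),
    (3.362000e-01, 3.800000e-02, 1.772110e+00),
    (3.187000e-01, 4.800000e-02, 1.744100e+00),
    (2.908000e-01, 6.000000e-02, 1.669200e+00),
    (2.511000e-01, 7.390000e-02, 1.528100e+00),
    (1.953600e-01, 9.098000e-02, 1.287640e+00),
    (1.421000e-01, 1.126000e-01, 1.041900e+00),
    (9.564000e-02, 1.390200e-01, 8.129501e-01),
    (5.795001e-02, 1.693000e-01, 6.162000e-01),
    (3.201000e-02, 2.080200e-01, 4.651800e-01),
    (1.470000e-02, 2.586000e-01, 3.533000e-01),
    (4.900000e-03, 3.230000e-01, 2.720000e-01),
    (2.400000e-03, 4.073000e-01, 2.123000e-01),
    (9.300000e-03, 5.030000e-01, 1.582000e-01),
    (2.910000e-02, 6.082000e-01, 1.117000e-01),
    (6.327000e-02, 7.100000e-01, 7.824999e-02),
    (1.096000e-01, 7.932000e-01, 5.725001e-02),
    (1.655000e-01, 8.620000e-01, 4.216000e-02),
    (2.257499e-01, 9.148501e-01, 2.984000e-02),
    (2.904000e-01, 9.540000e-01, 2.030000e-02),
    (3.597000e-01, 9.803000e-01, 1.340000e-02),
    (4.334499e-01, 9.949501e-01, 8.749999e-03),
    (5.120501e-01, 1.000000e+00, 5.749999e-03),
    (5.945000e-01, 9.950000e-01, 3.900000e-03),
    (6.784000e-01, 9.786000e-01, 2.749999e-03),
    (7.621000e-01, 9.520000e-01, 2.100000e-03),
    (8.425000e-01, 9.154000e-01, 1.800000e-03),
    (9.163000e-01, 8.700000e-01, 1.650001e-03),
    (9.786000e-01, 8.163000e-01, 1.400000e-03),
    (1.026300e+00, 7.570000e-01, 1.100000e-03),
    (1.056700e+00, 6.949000e-01, 1.000000e-03),
    (1.062200e+00, 6.310000e-01, 8.000000e-04),
    (1.045600e+00, 5.668000e-01, 6.000000e-04),
    (1.002600e+00, 5.030000e-01, 3.400000e-04),
    (9.384000e-01, 4.412000e-01, 2.400000e-04),
    (8.544499e-01, 3.810000e-01, 1.900000e-04),
    (7.514000e-01, 3.210000e-01, 1.000000e-04),
    (6.424000e-01, 2.650000e-01, 4.999999e-05),
    (5.419000e-01, 2.170000e-01, 3.000000e-05),
    (4.479000e-01, 1.750000e-01, 2.000000e-05),
    (3.608000e-01, 1.382000e-01, 1.000000e-05),
    (2.835000e-01, 1.070000e-01, -1.905824e-21),
    (2.187000e-01, 8.160000e-02, 0.000000e+00),
    (1.649000e-01, 6.100000e-02, 0.000000e+00),
    (1.212000e-01, 4.458000e-02, 0.000000e+00),
    (8.740000e-02, 3.200000e-02, 0.000000e+00),
    (6.360000e-02, 2.320000e-02, 0.000000e+00),
    (4.677000e-02, 1.700000e-02, 0.000000e+00),
    (3.290000e-02, 1.192000e-02, 0.000000e+00),
    (2.270000e-02, 8.210000e-03, 0.000000e+00),
    (1.584000e-02, 5.723000e-03, 0.000000e+00),
    (1.135916e-02, 4.102000e-03, 0.000000e+00),
    (8.110916e-03, 2.929000e-03, 0.000000e+00),
    (5.790346e-03, 2.091000e-03, 0.000000e+00),
    (4.109457e-03, 1.484000e-03, 0.000000e+00),
    (2.899327e-03, 1.047000e-03, 0.000000e+00),
    (2.049190e-03, 7.400000e-04, 0.000000e+00),
    (1.439971e-03, 5.200000e-04, 0.000000e+00),
    (9.999493e-04, 3.611000e-04, 0.000000e+00),
    (6.900786e-04, 2.492000e-04, 0.000000e+00),
    (4.760213e-04, 1.719000e-04, 0.000000e+00),
    (3.323011e-04, 1.200000e-04, 0.000000e+00),
    (2.348261e-04, 8.480000e-05, 0.000000e+00),
    (1.661505e-04, 6.000000e-05, 0.000000e+00),
    (1.174130e-04, 4.240000e-05, 0.000000e+00),
    (8.307527e-05, 3.000000e-05, 0.000000e+00),
    (5.870652e-05, 2.120000e-05, 0.000000e+00),
    (4.150994e-05, 1.499000e-05, 0.000000e+00),
]

# relative spectral power distribution, normalised to 100 at 560 nm
D65_SPD = [
    49.9755, 52.3118, 54.6482, 68.7015, 82.7549, 87.1204,
    91.4860, 92.4589, 93.4318, 90.0570, 86.6823, 95.7736,
    104.8650, 110.9360, 117.0080, 117.4100, 117.8120, 116.3360,
    114.8610, 115.3920, 115.9230, 112.3670, 108.8110, 109.0820,
    109.3540, 108.5780, 107.8020, 106.2960, 104.7900, 106.2390,
    107.6890, 106.0470, 104.4050, 104.2250, 104.0460, 102.0230,
    100.0000, 98.1671, 96.3342, 96.0611, 95.7880, 92.2368,
    88.6856, 89.3459, 90.0062, 89.8026, 89.5991, 88.6489,
    87.6987, 85.4936, 83.2886, 83.4939, 83.6992, 81.8630,
    80.0268, 80.1207, 80.2146, 81.2462, 82.2778, 80.2810,
    78.2842, 74.0027, 69.7213, 70.6652, 71.6091, 72.9790,
    74.3490, 67.9765, 61.6040, 65.7448, 69.8856, 72.4863,
    75.0870, 69.3398, 63.5927, 55.0054, 46.4182, 56.6118,
    66.8054, 65.0941, 63.3828,
]
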