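"""LG amino-acid replacement model constants (Le & Gascuel 2008).

Exchangeabilities are given as the strict upper triangle of the symmetric
rate matrix in alphabetical one-letter amino-acid order
(A C D E F G H I K L M N P Q R S T V W Y), row by row. Values are the
published LG estimates as distributed with standard ML phylogenetics
software.
"""

LG_ORDER = "ACDEFGHIKLMNPQRSTVWY"

LG_FREQS = [
    0.079066, 0.012937, 0.053052, 0.071586, 0.042302, 0.057337, 0.022355,
    0.062157, 0.064600, 0.099081, 0.022951, 0.041977, 0.044040, 0.040767,
    0.055941, 0.061197, 0.053287, 0.069147, 0.012066, 0.034155,
]

LG_UPPER = [
    2.066040, 2.489084, 2.139501, 1.105251, 0.534551, 6.326067, 0.170887,
    0.523386, 2.145078, 0.425860, 0.276818, 1.672569, 0.536518, 0.425093,
    0.018811, 0.129836, 0.165001, 0.159069, 1.702745,
    0.395337, 0.751878, 0.670128, 2.426601, 0.858151, 0.541712, 0.010690,
    4.008358, 0.084808, 0.149830, 1.080136, 4.727182, 0.358858, 0.077852,
    0.108882, 1.338132, 0.064105, 0.748683,
    2.547870, 1.143480, 0.390192, 0.332533, 1.695752, 0.927114, 0.161787,
    0.037967, 1.038545, 1.223828, 1.177651, 0.969894, 0.604545, 0.076701,
    0.654683, 0.078281, 0.390322,
    1.959291, 0.301848, 0.593607, 4.509238, 0.282959, 0.045376, 0.569265,
    0.218959, 0.257336, 0.123954, 0.180717, 0.245034, 0.697264, 0.095131,
    0.111660, 0.049906,
    4.128591, 0.267959, 4.813505, 0.582457, 0.072854, 3.234294, 2.784478,
    0.173735, 1.165532, 0.075382, 0.196961, 5.306834, 0.140825, 0.182287,
    0.696175,
    0.314440, 0.191503, 0.025548, 0.612025, 0.640543, 0.363970, 0.210332,
    0.126991, 2.807908, 0.311484, 0.442472, 0.089613, 0.232523, 0.131932,
    0.068427, 0.017416, 0.083688, 0.320627, 0.052722, 0.348847, 0.578987,
    0.484133, 0.008705, 0.682139, 0.296501, 10.649107, 0.185202,
    0.394456, 0.062556, 0.594007, 0.528768, 0.423881, 1.437645, 5.076149,
    0.044261, 0.508851, 6.472279, 0.137500, 1.798853,
    1.240275, 0.893680, 0.844926, 0.069673, 0.015076, 5.243870, 0.139538,
    0.584262, 0.400547, 2.592692, 0.346960,
    0.013266, 0.089525, 0.044265, 2.000679, 0.371004, 0.296636, 0.990012,
    0.248862, 6.312358, 0.099849,
    0.135107, 1.807177, 0.003499, 0.029890, 0.089586, 0.597054, 0.098369,
    0.249060, 2.020366,
    0.624294, 0.253701, 0.395144, 0.611973, 0.054679, 7.803902, 1.112727,
    0.023918,
    0.236199, 0.035855, 1.739990, 0.119013, 0.245841, 0.302936, 0.481306,
    1.124035, 0.120037, 0.366317, 0.571468, 1.033739, 1.136863,
    0.419409, 0.268491, 2.457121, 4.273607, 0.656604,
    4.145067, 2.188158, 0.619632, 1.898718,
    3.151815, 0.299648, 0.094464,
    0.189510, 0.249313,
    0.361819,
]
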