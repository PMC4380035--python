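"""Empirical amino-acid replacement model data.

Each entry maps a model name to ``(exchangeabilities, frequencies)``:
190 lower-triangle exchangeabilities in column-major order over the PAML
state order ARNDCQEGHILKMFPSTWYV, and the model's 20 stationary
frequencies, as published by the models' original authors (Dayhoff et al.
1978; Kosiol & Goldman 2005 [DCMut/JTT-DCMut]; Jones et al. 1992; Adachi &
Hasegawa 1996 [mtREV24]; Whelan & Goldman 2001 [WAG]; Dimmic et al. 2002
[RtREV]; Adachi et al. 2000 [cpREV]; Mueller & Vingron 2000 [VT]; Henikoff
& Henikoff 1992 [Blosum62]; Yang et al. 1998 [mtMam]; Le & Gascuel 2008
[LG]; Abascal et al. 2007 [mtArt]; Rota-Stabelli et al. 2009 [MtZoa];
Nickle et al. 2007 [HIVb/HIVw]; Dang et al. 2010 [FLU]).

PMB is an exception: the published Probability Matrix from Blocks
(Veerassamy et al. 2003) is not bundled here.  The ``PMB`` entry is a
synthetic stand-in that reuses the Blosum62 rate model (both are derived
from the Blocks database); it satisfies all structural invariants but its
values are NOT the published PMB matrix.  ``SYNTHETIC_MODELS`` lists such
stand-ins so callers can warn.
"""

SYNTHETIC_MODELS = frozenset({"PMB"})

AA_MODEL_DATA = {
"WAG": (
    [0.551571, 0.509848, 0.738998, 1.02704, 0.908598, 1.58285, 1.41672, 0.316954, 0.193335, 0.397915, 0.906265, 0.893496, 0.210494, 1.43855, 3.37079, 2.12111, 0.113133, 0.240735, 2.00601, 0.635346, 0.147304, 0.528191, 3.0355, 0.439157, 0.584665, 2.13715, 0.186979, 0.497671, 5.35142, 0.683162, 0.102711, 0.679489, 1.22419, 0.554413, 1.16392, 0.381533, 0.251849, 5.42942, 0.265256, 1.54364, 0.947198, 1.12556, 3.95629, 0.554236, 0.131528, 3.01201, 0.198221, 0.0961621, 0.195081, 3.97423, 2.03006, 0.0719167, 1.086, 0.196246, 0.0302949, 0.616783, 6.17416, 0.865584, 0.930676, 0.039437, 0.0848047, 0.479855, 0.103754, 0.0467304, 0.423984, 1.07176, 0.374866, 0.129767, 0.325711, 0.152335, 0.0988179, 0.021352, 0.306674, 0.248972, 0.170135, 0.384287, 0.0740339, 0.390482, 0.39802, 0.109404, 1.40766, 0.512984, 0.71707, 0.543833, 1.00214, 5.46947, 0.330052, 4.29411, 0.113917, 0.869489, 3.8949, 1.54526, 0.0999208, 0.933372, 1.02887, 0.857928, 0.215737, 0.22771, 0.301281, 0.567717, 0.570025, 0.127395, 0.154263, 2.58443, 0.315124, 0.0811339, 0.682355, 0.704939, 0.822765, 0.156557, 0.196303, 0.588731, 0.24941, 0.0304501, 0.0613037, 0.373558, 0.1741, 0.049931, 0.24357, 1.34182, 0.225833, 0.336983, 0.103604, 0.187247, 0.13819, 0.499462, 0.890432, 0.404141, 0.679371, 0.696198, 0.740169, 0.473307, 0.262569, 3.87344, 0.118358, 3.17097, 0.323832, 4.25746, 1.05947, 0.0999288, 0.31944, 1.45816, 0.212483, 0.42017, 7.8213, 0.257555, 4.85402, 2.11517, 0.415844, 0.344739, 0.326622, 0.665309, 0.398618, 1.80034, 0.934276, 0.088836, 0.556896, 0.96713, 1.38698, 0.137505, 0.133264, 0.305434, 1.19063, 0.171329, 0.493905, 1.51612, 0.515706, 0.428437, 2.05845, 0.161444, 0.545931, 0.171903, 1.52964, 6.45428, 0.649892, 1.61328, 0.795384, 0.139405, 0.216046, 0.314887, 4.37802, 0.523742, 0.786993, 0.232739, 0.110864, 0.291148, 1.38823, 2.48539, 0.365369, 0.31473],
    [0.086627909, 0.043972004, 0.039089404, 0.057045106, 0.019307802, 0.036728104, 0.058058906, 0.083251808, 0.024431302, 0.048466005, 0.086209009, 0.062028606, 0.019502702, 0.038431904, 0.045763105, 0.069517907, 0.061012706, 0.014385901, 0.035274204, 0.070895607]),
"JTT": (
    [58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62, 285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16],
    [0.076747923, 0.051690948, 0.042644957, 0.051543948, 0.01980298, 0.040751959, 0.061829938, 0.073151927, 0.022943977, 0.053760946, 0.091903908, 0.058675941, 0.023825976, 0.04012596, 0.050900949, 0.068764931, 0.058564941, 0.014260986, 0.032101968, 0.066004934]),
"LG": (
    [0.425093, 0.276818, 0.395144, 2.489084, 0.969894, 1.038545, 2.06604, 0.358858, 0.14983, 0.395337, 0.536518, 1.124035, 0.253701, 1.177651, 4.727182, 2.139501, 0.180717, 0.218959, 2.54787, 0.751878, 0.123954, 0.534551, 2.807908, 0.36397, 0.390192, 2.426601, 0.126991, 0.301848, 6.326067, 0.484133, 0.052722, 0.332533, 0.858151, 0.578987, 0.593607, 0.31444, 0.170887, 5.076149, 0.528768, 1.695752, 0.541712, 1.437645, 4.509238, 0.191503, 0.068427, 2.145078, 0.371004, 0.089525, 0.161787, 4.008358, 2.000679, 0.045376, 0.612025, 0.083688, 0.062556, 0.523386, 5.24387, 0.844926, 0.927114, 0.01069, 0.015076, 0.282959, 0.025548, 0.017416, 0.394456, 1.240275, 0.42586, 0.02989, 0.135107, 0.037967, 0.084808, 0.003499, 0.569265, 0.640543, 0.320627, 0.594007, 0.013266, 0.89368, 1.105251, 0.075382, 2.784478, 1.14348, 0.670128, 1.165532, 1.959291, 4.128591, 0.267959, 4.813505, 0.072854, 0.582457, 3.234294, 1.672569, 0.035855, 0.624294, 1.223828, 1.080136, 0.236199, 0.257336, 0.210332, 0.348847, 0.423881, 0.044265, 0.069673, 1.807177, 0.173735, 0.018811, 0.419409, 0.611973, 0.604545, 0.077852, 0.120037, 0.245034, 0.311484, 0.008705, 0.044261, 0.296636, 0.139538, 0.089586, 0.196961, 1.73999, 0.129836, 0.268491, 0.054679, 0.076701, 0.108882, 0.366317, 0.697264, 0.442472, 0.682139, 0.508851, 0.990012, 0.584262, 0.597054, 5.306834, 0.119013, 4.145067, 0.159069, 4.273607, 1.112727, 0.078281, 0.064105, 1.033739, 0.11166, 0.232523, 10.649107, 0.1375, 6.312358, 2.592692, 0.24906, 0.182287, 0.302936, 0.619632, 0.299648, 1.702745, 0.656604, 0.023918, 0.390322, 0.748683, 1.136863, 0.049906, 0.131932, 0.185202, 1.798853, 0.099849, 0.34696, 2.020366, 0.696175, 0.481306, 1.898718, 0.094464, 0.361819, 0.165001, 2.457121, 7.803902, 0.654683, 1.338132, 0.571468, 0.095131, 0.089613, 0.296501, 6.472279, 0.248862, 0.400547, 0.098369, 0.140825, 0.245841, 2.188158, 3.151815, 0.18951, 0.249313],
    [0.079065921, 0.055940944, 0.041976958, 0.053051947, 0.012936987, 0.040766959, 0.071585928, 0.057336943, 0.022354978, 0.062156938, 0.099080901, 0.064599935, 0.022950977, 0.042301958, 0.044039956, 0.061196939, 0.053286947, 0.012065988, 0.034154966, 0.069146931]),
"DAYHOFF": (
    [27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371, 0, 24, 208, 32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154, 26, 201, 8, 24, 905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42, 495, 229, 23, 95, 15, 0, 134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95, 66, 0, 0, 18, 0, 0, 11, 28, 44, 0, 0, 0, 0, 19, 161, 16, 0, 96, 49, 716, 28, 606, 18, 73, 153, 114, 0, 153, 56, 53, 0, 0, 35, 81, 43, 61, 11, 83, 30, 0, 51, 79, 34, 0, 22, 37, 10, 0, 7, 27, 17, 15, 34, 234, 30, 0, 0, 54, 7, 44, 26, 0, 48, 94, 35, 22, 27, 127, 44, 257, 46, 336, 196, 12, 24, 192, 0, 37, 889, 18, 527, 157, 32, 17, 33, 46, 28, 175, 243, 0, 33, 96, 136, 0, 13, 10, 92, 17, 62, 104, 0, 0, 258, 11, 46, 13, 76, 698, 12, 245, 78, 0, 0, 48, 550, 75, 34, 30, 0, 42, 157, 61, 0, 28],
    [0.087126913, 0.040903959, 0.04043196, 0.046871953, 0.033473967, 0.038254962, 0.04952995, 0.088611911, 0.033617966, 0.036885963, 0.085356915, 0.08048192, 0.014752985, 0.03977196, 0.050679949, 0.06957693, 0.058541941, 0.01049399, 0.02991597, 0.064717935]),
"CPREV": (
    [105, 227, 175, 669, 157, 499, 665, 66, 145, 197, 236, 185, 68, 490, 2440, 1340, 14, 56, 968, 357, 43, 823, 1745, 152, 243, 715, 136, 203, 4482, 125, 53, 87, 385, 314, 230, 323, 92, 4435, 538, 768, 1055, 653, 1405, 168, 113, 2430, 61, 97, 173, 2085, 1393, 40, 754, 83, 10, 400, 3691, 431, 331, 10, 10, 412, 47, 22, 170, 590, 266, 18, 281, 75, 10, 10, 303, 441, 280, 396, 48, 159, 726, 285, 2331, 576, 435, 1466, 592, 3122, 133, 1269, 92, 286, 3313, 202, 10, 323, 396, 241, 53, 391, 54, 379, 162, 148, 82, 2629, 113, 145, 185, 568, 369, 63, 142, 200, 19, 40, 20, 263, 21, 25, 28, 691, 92, 82, 10, 91, 29, 66, 305, 10, 127, 152, 303, 32, 69, 1971, 25, 1745, 345, 1772, 454, 117, 216, 1040, 42, 89, 4797, 218, 1351, 1268, 219, 516, 156, 159, 189, 865, 193, 72, 302, 868, 918, 10, 247, 249, 327, 100, 93, 645, 86, 215, 475, 43, 487, 148, 468, 2370, 317, 1202, 260, 49, 97, 122, 2151, 73, 522, 167, 29, 71, 760, 346, 10, 119],
    [0.0755, 0.0621, 0.041, 0.0371, 0.0091, 0.0382, 0.0495, 0.0838, 0.0246, 0.0806, 0.1011, 0.0504, 0.022, 0.0506, 0.0431, 0.0622, 0.0543, 0.0181, 0.0307, 0.066]),
"MTMAM": (
    [32, 2, 11, 0, 0, 0, 78, 8, 75, 21, 0, 76, 0, 53, 342, 681, 5, 0, 398, 4, 0, 186, 246, 0, 18, 232, 0, 6, 50, 0, 0, 9, 3, 0, 16, 0, 0, 864, 0, 8, 0, 47, 458, 19, 0, 408, 21, 6, 33, 446, 110, 6, 156, 0, 0, 49, 569, 79, 11, 0, 0, 0, 0, 5, 2, 16, 0, 0, 0, 10, 0, 0, 0, 305, 41, 27, 0, 0, 7, 0, 347, 114, 65, 530, 0, 274, 0, 550, 0, 20, 242, 22, 0, 51, 30, 0, 0, 54, 33, 22, 22, 0, 0, 215, 0, 0, 0, 21, 4, 0, 0, 20, 0, 0, 0, 0, 0, 0, 0, 112, 0, 0, 1, 5, 0, 26, 0, 0, 0, 53, 20, 1, 0, 1525, 0, 232, 6, 378, 57, 5, 0, 360, 0, 16, 2220, 4, 609, 246, 43, 74, 34, 12, 25, 100, 59, 0, 18, 65, 50, 0, 67, 0, 11, 0, 47, 691, 13, 0, 832, 17, 90, 8, 0, 682, 6, 202, 78, 7, 8, 0, 614, 17, 107, 0, 0, 0, 237, 14, 0, 0],
    [0.0692, 0.0184, 0.04, 0.0186, 0.0065, 0.0238, 0.0236, 0.0557, 0.0277, 0.0905, 0.1675, 0.0221, 0.0561, 0.0611, 0.0536, 0.0725, 0.087, 0.0293, 0.034, 0.0428]),
"MTART": (
    [0.2, 0.2, 1, 254, 0.2, 0.2, 200, 0.2, 26, 4, 0.2, 121, 13, 49, 673, 244, 0.2, 1, 340, 0.2, 4, 36, 154, 0.2, 0.2, 41, 2, 2, 209, 5, 5, 0.2, 3, 0.2, 0.2, 4, 0.2, 500, 98, 262, 183, 121, 180, 21, 13, 467, 79, 20, 17, 398, 166, 8, 251, 23, 11, 0.2, 862, 12, 0.2, 7, 1, 2, 0.2, 0.2, 0.2, 44, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 81, 12, 63, 79, 0.2, 312, 184, 0.2, 664, 183, 22, 72, 350, 262, 3, 314, 11, 16, 349, 67, 0.2, 39, 52, 44, 7, 87, 0.2, 44, 15, 7, 2, 106, 0.2, 0.2, 8, 31, 43, 11, 8, 14, 0.2, 3, 1, 0.2, 56, 1, 0.2, 226, 0.2, 2, 9, 3, 0.2, 6, 0.2, 0.2, 14, 1, 11, 19, 0.2, 191, 0.2, 515, 3, 515, 118, 0.2, 7, 204, 0.2, 12, 1855, 4, 885, 263, 12, 8, 48, 21, 20, 85, 106, 11, 17, 144, 70, 16, 117, 26, 322, 5, 112, 289, 71, 71, 281, 15, 36, 14, 54, 792, 52, 87, 47, 0.2, 18, 32, 660, 2, 30, 61, 0.2, 46, 544, 38, 0.2, 2],
    [0.054116, 0.018227, 0.039903, 0.02016, 0.009709, 0.018781, 0.024289, 0.068183, 0.024518, 0.092638, 0.148658, 0.021718, 0.061453, 0.088668, 0.041826, 0.09103, 0.049194, 0.029786, 0.039443, 0.0577]),
"MTZOA": (
    [3.3, 1.7, 16.1, 272.5, 7.3, 17.1, 289.3, 2.3, 33.2, 15.6, 0.2, 136.5, 26.5, 61.8, 644.9, 378.1, 3.1, 2.1, 321.9, 33.6, 3.2, 61.1, 231, 6.4, 7.2, 61.7, 0.2, 4.1, 292.3, 3.8, 0.2, 7.5, 11.8, 3.2, 16.9, 13.8, 5.1, 617, 94.6, 190.3, 174, 99.3, 228.9, 24.3, 7.9, 413.4, 73.7, 12.9, 22.6, 420.2, 184.6, 6.4, 141.6, 7.1, 9.5, 19.3, 883.6, 26, 55.6, 1.5, 0.5, 0.2, 0.2, 2, 0.2, 51.4, 2.3, 0.2, 13.9, 3.7, 49.1, 3.4, 82.4, 37.5, 48.8, 59.7, 0.2, 264.8, 167.8, 8.1, 656.3, 199, 36.1, 76.7, 243.8, 349.4, 8.9, 421.8, 0.2, 23, 334, 83.9, 9.5, 52.2, 96.4, 39.4, 6.1, 52.3, 9, 43.1, 14.9, 7.3, 1, 163.2, 0.2, 0.2, 20.6, 38.4, 34.5, 3.5, 10, 16.3, 7.4, 3.4, 3.5, 10.1, 52.2, 5.8, 1.3, 257.1, 5.2, 12.3, 4.3, 23.7, 1.6, 6.6, 23.9, 7.1, 13.1, 15.6, 23.1, 19.4, 4.5, 266.5, 0.3, 425.2, 8.4, 449.7, 90.3, 2.6, 7.2, 222.3, 9.7, 13.1, 1710.6, 6.7, 636.3, 234.2, 11.4, 15.2, 50, 27.2, 5.7, 126.1, 83, 16.3, 24.3, 144.9, 75.5, 6.6, 45, 11.1, 215.6, 5.4, 95.3, 305.1, 48.7, 41.4, 279.6, 10.5, 32.2, 19.3, 58.2, 590.5, 59.6, 79.7, 56.9, 1.3, 4.2, 17.9, 666.3, 10.3, 29.7, 49.5, 3.6, 29, 396.4, 79.8, 13.7, 15.6],
    [0.068879931, 0.021036979, 0.03038997, 0.020695979, 0.00996599, 0.018622981, 0.024988975, 0.071967928, 0.026813973, 0.085071915, 0.15671684, 0.019275981, 0.050651949, 0.081711918, 0.044802955, 0.080534919, 0.056385944, 0.027997972, 0.037403963, 0.066082934]),
"MTREV": (
    [23.18, 26.95, 17.67, 59.93, 1.9, 9.77, 120.71, 13.9, 96.49, 25.46, 8.36, 141.88, 6.37, 54.31, 387.86, 480.72, 1.9, 6.48, 195.06, 13.24, 1.9, 103.33, 220.99, 1.9, 23.03, 165.23, 1.9, 15.58, 141.4, 1.9, 4.69, 23.64, 6.04, 2.08, 21.95, 1.9, 7.64, 794.38, 58.94, 173.56, 63.05, 53.3, 496.13, 27.1, 15.16, 608.7, 65.41, 15.2, 73.31, 494.39, 238.46, 10.68, 191.36, 1.9, 1.9, 55.28, 583.55, 56.77, 113.99, 4.34, 1.9, 2.31, 1.9, 4.98, 13.43, 69.02, 28.01, 19.86, 21.21, 1.9, 75.24, 1.9, 30.71, 141.49, 62.73, 25.65, 1.9, 6.18, 70.8, 31.26, 277.05, 179.97, 33.6, 254.77, 1.9, 313.56, 6.75, 582.4, 8.34, 39.7, 465.58, 47.37, 19.11, 137.29, 54.11, 94.93, 1.9, 38.82, 19, 28.28, 49.12, 3.31, 1.9, 313.86, 1.9, 2.67, 12.83, 54.71, 14.82, 1.9, 13.12, 21.14, 1.9, 5.98, 2.41, 22.73, 1.9, 1.9, 1.9, 125.93, 11.17, 10.92, 3.21, 2.53, 12.26, 11.49, 127.67, 11.97, 48.16, 60.97, 77.46, 44.78, 7.08, 670.14, 1.9, 329.09, 19.57, 517.98, 84.67, 20.63, 47.7, 368.43, 1.9, 25.01, 1222.94, 14.88, 537.53, 216.06, 40.1, 73.61, 126.4, 32.44, 44.15, 91.67, 91.37, 6.44, 50.1, 105.79, 136.33, 24, 51.17, 1.9, 90.82, 18.84, 111.16, 528.17, 21.71, 39.96, 387.54, 17.31, 64.29, 33.85, 7.84, 465.58, 6.35, 169.9, 128.22, 4.21, 16.21, 8.23, 597.21, 38.58, 64.92, 1.9, 9.99, 38.73, 204.54, 26.25, 5.37, 1.9],
    [0.072, 0.019, 0.039, 0.019, 0.006, 0.025, 0.024, 0.056, 0.028, 0.088, 0.169, 0.023, 0.054, 0.061, 0.054, 0.072, 0.086, 0.029, 0.033, 0.043]),
"VT": (
    [0.233108, 0.199097, 0.265145, 0.227333, 0.310084, 0.567957, 0.876213, 0.078692, 0.222972, 0.42463, 0.393245, 0.21155, 0.116646, 0.399143, 1.817198, 0.877877, 0.030309, 0.087061, 1.230985, 0.210797, 0.105191, 0.031726, 0.493763, 0.25524, 0.156945, 0.213164, 0.08151, 0.192364, 1.755838, 0.08793, 0.042569, 0.12848, 0.292327, 0.204109, 0.046417, 0.09701, 0.113146, 0.883422, 0.027495, 0.2757, 0.270417, 0.362028, 0.290006, 0.087225, 0.069245, 0.50306, 0.05742, 0.039769, 0.083956, 0.847049, 0.471268, 0.010459, 0.093268, 0.049824, 0.010313, 0.205842, 1.599461, 0.311718, 0.134252, 0.01172, 0.060863, 0.261101, 0.012182, 0.016577, 0.160063, 0.461519, 0.178197, 0.011393, 0.051664, 0.048769, 0.004315, 0.005321, 0.050876, 0.016695, 0.046398, 0.091709, 0.004067, 0.02369, 0.051127, 0.011137, 0.17527, 0.079511, 0.007732, 0.042823, 0.163831, 0.960976, 0.12866, 0.315521, 0.054602, 0.24353, 0.738208, 0.120801, 0.026235, 0.15657, 0.358017, 0.248992, 0.021248, 0.062544, 0.112027, 0.250447, 0.104458, 0.046589, 0.151924, 0.88863, 0.058643, 0.028168, 0.205134, 0.406035, 0.321028, 0.018844, 0.0552, 0.205868, 0.058131, 0.051089, 0.087056, 0.193243, 0.04656, 0.050143, 0.124492, 0.612843, 0.136266, 0.02399, 0.037568, 0.082579, 0.020039, 0.103552, 0.153323, 0.021157, 0.079807, 0.078892, 0.167406, 0.101117, 0.020009, 0.286027, 0.068575, 2.08989, 0.093181, 0.493845, 0.32102, 0.054797, 0.081567, 0.376588, 0.034954, 0.086237, 3.65443, 0.201204, 1.105667, 0.946499, 0.169784, 0.214977, 0.243227, 0.083439, 0.189842, 1.337571, 0.096474, 0.038261, 0.212302, 0.400072, 0.446646, 0.023321, 0.068689, 0.144587, 0.173052, 0.010363, 0.090515, 0.184609, 0.022019, 0.073223, 0.307309, 0.042564, 0.138119, 0.08587, 0.12805, 0.898663, 0.247329, 0.430431, 0.207143, 0.014584, 0.032043, 0.129315, 1.767766, 0.035933, 0.121979, 0.1277, 0.020437, 0.094617, 0.740372, 0.124746, 0.022134, 0.125733],
    [0.078836921, 0.051237949, 0.042312958, 0.053065947, 0.015174985, 0.036712963, 0.061923938, 0.070851929, 0.023081977, 0.062055938, 0.096370904, 0.057323943, 0.023770976, 0.043295957, 0.043910956, 0.063402937, 0.055896944, 0.013271987, 0.034398966, 0.073100927]),
"RTREV": (
    [34, 51, 10, 439, 32, 81, 135, 30, 1, 45, 38, 235, 1, 97, 460, 258, 5, 55, 197, 35, 30, 92, 221, 10, 41, 90, 24, 18, 593, 57, 7, 24, 102, 64, 13, 47, 29, 384, 128, 236, 79, 94, 320, 35, 15, 123, 1, 49, 33, 294, 148, 16, 28, 21, 1, 78, 542, 61, 91, 1, 5, 20, 1, 1, 55, 136, 55, 1, 1, 6, 70, 1, 48, 124, 104, 110, 16, 156, 70, 1, 75, 117, 55, 131, 295, 372, 18, 387, 33, 54, 309, 158, 1, 68, 225, 146, 10, 45, 36, 70, 34, 1, 21, 141, 1, 1, 52, 95, 82, 17, 1, 35, 68, 1, 3, 30, 37, 7, 17, 152, 7, 23, 21, 3, 34, 51, 76, 116, 141, 44, 183, 49, 48, 307, 1, 385, 34, 375, 64, 10, 4, 72, 39, 26, 1048, 23, 581, 179, 22, 24, 25, 47, 64, 112, 134, 14, 43, 77, 110, 6, 1, 19, 247, 1, 1, 131, 111, 74, 236, 11, 20, 69, 182, 1017, 92, 134, 62, 9, 14, 25, 671, 14, 31, 39, 1, 34, 196, 176, 26, 59],
    [0.0646, 0.0453, 0.0376, 0.0422, 0.0114, 0.0606, 0.0607, 0.0639, 0.0273, 0.0679, 0.1018, 0.0751, 0.015, 0.0287, 0.0681, 0.0488, 0.0622, 0.0251, 0.0318, 0.0619]),
"HIVW": (
    [0.0744808, 0.617509, 4.43521, 0.167653, 0.005, 5.56325, 1.8685, 0.005, 0.005, 0.16024, 0.592784, 0.005, 0.597923, 1.00981, 8.5942, 24.1422, 0.005, 0.005, 24.8094, 0.16024, 0.0674539, 2.86364, 10.6746, 0.0251632, 13.4379, 6.84405, 1.34069, 0.586757, 39.8897, 3.28652, 0.005, 0.404723, 8.35024, 0.928203, 5.96564, 0.005, 0.279425, 29.4087, 0.0604932, 0.342068, 0.201526, 0.0604932, 8.59876, 0.987028, 0.005, 10.6655, 0.201526, 0.005, 0.344848, 14.5699, 4.54206, 0.005, 5.06475, 0.0744808, 0.005, 0.005, 12.1233, 10.3969, 2.31779, 0.145124, 0.005, 0.894313, 0.005, 0.005, 0.005, 0.427881, 0.630395, 0.005, 2.28154, 2.91786, 0.005, 0.005, 0.0489798, 0.005, 0.005, 0.005, 0.005, 0.005, 0.362959, 0.005, 1.12195, 0.005, 5.49894, 8.34835, 0.005, 3.20656, 0.0604932, 18.5465, 0.0342252, 2.89048, 13.0705, 0.005, 0.005, 3.04502, 0.16024, 0.203091, 0.0443298, 0.005, 0.005, 14.7801, 0.005, 0.0390512, 0.129839, 23.9626, 0.005, 0.005, 0.005, 0.005, 0.458743, 0.005, 0.005, 2.19952, 0.005, 0.005, 0.0489798, 0.279425, 0.0489798, 0.005, 0.005, 6.27966, 0.0489798, 2.8258, 0.005, 2.79622, 0.005, 1.76382, 0.22406, 0.005, 0.005, 13.9444, 0.725157, 0.95956, 0.005, 47.4889, 0.827479, 9.10246, 0.817481, 17.3064, 1.48288, 0.005, 0.740091, 9.36345, 0.005, 0.114512, 24.8231, 0.005, 11.3839, 7.48781, 9.83095, 6.14396, 0.005, 1.37031, 0.005, 2.95344, 4.09564, 0.005, 0.111928, 0.005, 4.04802, 0.005, 0.005, 0.128065, 0.005, 0.005, 0.392575, 7.41313, 0.005, 0.579198, 14.7683, 0.0342252, 4.27939, 0.114512, 0.005, 4.12728, 2.28, 14.249, 4.33701, 0.005, 0.005, 0.005, 6.34079, 1.10156, 0.933142, 0.862637, 0.005, 0.490608, 0.005, 0.005, 0.005, 1.35482],
    [0.037749396, 0.057320994, 0.089112891, 0.034203397, 0.024010498, 0.043782396, 0.061860594, 0.083849592, 0.015607598, 0.09836409, 0.057786694, 0.064168194, 0.015841898, 0.042274096, 0.045860095, 0.055084594, 0.081377392, 0.019596998, 0.020584698, 0.051563895]),
"HIVB": (
    [0.307507, 0.005, 1.45504, 0.123758, 0.0551128, 1.48135, 2.13536, 0.0847613, 0.005, 0.215256, 0.005, 0.0186643, 0.0141269, 2.12217, 2.46633, 15.9183, 0.005, 0.005, 7.61428, 0.295543, 0.005, 0.351721, 3.4215, 0.0749218, 3.65345, 9.04044, 0.677289, 0.701427, 20.45, 2.51394, 0.005, 1.28355, 3.4791, 2.86868, 0.991338, 0.00991826, 0.0812454, 17.6612, 0.0860642, 0.672052, 0.0792633, 0.323401, 7.64585, 0.680565, 0.005, 7.90443, 0.005, 0.005, 0.00739578, 13.1447, 6.88667, 0.005, 1.76417, 0.026656, 0.005, 0.005, 10.5872, 2.83806, 1.9169, 0.0176792, 0.00876048, 0.005, 0.005, 0.005, 0.0342658, 0.52823, 0.274724, 0.005, 0.674653, 1.04793, 0.005, 0.005, 0.897871, 0.240073, 0.005, 0.129777, 0.005, 0.005, 9.29815, 0.005, 4.69314, 0.739969, 2.63277, 7.57932, 0.420027, 2.5602, 0.0619137, 7.05545, 0.005, 1.49456, 6.54737, 0.303676, 0.005, 4.47211, 0.116311, 0.243589, 0.026656, 0.113033, 0.0209153, 3.92775, 0.11974, 0.00609079, 0.005, 4.61482, 0.175789, 0.005, 0.0120226, 0.005, 0.289774, 0.005, 0.0792633, 1.02847, 0.005, 0.005, 0.005, 0.521705, 0.005, 0.291561, 0.005, 4.38041, 0.369615, 1.21674, 0.005, 0.953155, 0.103111, 1.74171, 0.005, 0.005, 0.145558, 2.45318, 0.382747, 0.711594, 0.0695179, 18.6943, 0.005, 5.95879, 0.322319, 11.2065, 3.39836, 0.0410593, 1.21803, 8.61217, 0.005, 0.148168, 17.7389, 0.0814995, 5.31961, 8.52484, 2.07757, 0.927656, 0.0437673, 0.748843, 0.111986, 1.41036, 1.28246, 0.0342658, 0.0313862, 0.504111, 4.67142, 0.005, 0.005, 0.265829, 0.188025, 0.005, 0.005, 4.94026, 0.089078, 0.005, 6.8532, 0.005, 0.956472, 0.0141269, 0.829343, 15.34, 0.723274, 5.37762, 2.01417, 0.0444506, 0.0304381, 0.005, 8.93107, 0.0248728, 0.648024, 0.0749218, 0.005, 0.105652, 0.709226, 1.28022, 0.005, 0.0410593],
    [0.060490222, 0.066039665, 0.044127815, 0.042109048, 0.020075899, 0.053606488, 0.071567447, 0.072308239, 0.022293943, 0.069730629, 0.098851122, 0.056968211, 0.019768318, 0.028809447, 0.046025282, 0.05060433, 0.053636813, 0.033011601, 0.028350243, 0.061625237]),
"FLU": (
    [0.13865876, 0.053366579, 0.58485231, 0.026447095, 0.35375398, 1.4842345, 1.1323131, 0.21475786, 0.14992673, 0.023116952, 0.47433361, 0.058745423, 0.080490909, 0.65931148, 3.0113445, 5.4182982, 0.19596635, 0.018289288, 3.5320053, 0.16100089, 0.0067718425, 0.16720701, 3.2927169, 0.12489762, 1.1906245, 1.8795699, 0.24611717, 0.29604556, 15.300097, 0.89016235, 0.016055031, 0.15402718, 0.95013841, 0.18307691, 1.3694294, 0.099855497, 0.10396439, 7.7373929, 1.3024986e-05, 0.53064266, 0.061652192, 0.32252465, 1.387096, 0.21857198, 0.00083587317, 2.646848, 0.0052516878, 0.00083644562, 0.036441772, 3.8813105, 2.1403323, 0.00053628404, 0.37310193, 0.010257517, 0.014132063, 0.14546939, 5.3705113, 1.9348328, 0.88757055, 0.014085917, 0.0057306821, 0.29004298, 0.041762964, 1.0600103e-06, 0.18853946, 0.33837218, 0.13548123, 1.4893874e-05, 0.52539854, 0.29712398, 0.002547334, 3.9110699e-11, 0.11694146, 0.021844617, 0.0011121581, 0.0056136272, 3.8322812e-06, 0.11145731, 0.10405367, 1.5931206e-13, 0.33626334, 0.011975266, 0.09410668, 0.60169243, 0.054904564, 1.1956291, 0.10805134, 5.3303134, 0.02883995, 1.020367, 2.5595872, 0.19025918, 0.032680657, 0.7127696, 0.4878225, 0.60234096, 0.04402052, 0.072205935, 0.40669781, 1.5930988, 0.25649186, 0.014210712, 0.016499536, 3.8814888, 0.31397435, 0.0010035008, 0.31955883, 0.3071403, 0.2801249, 0.15524549, 0.10409287, 0.28504795, 0.058774527, 1.6266228e-05, 0.0065162294, 0.26414893, 0.0015004669, 0.001236645, 0.038631761, 1.5856466, 0.01880803, 0.19648645, 0.074814997, 0.33722962, 0.24319014, 0.32161169, 0.34730279, 0.0012735089, 0.11902851, 0.92446691, 0.58070425, 0.36871357, 0.022372919, 6.4489544, 0.098631355, 3.5120723, 0.227708, 9.0179542, 1.4633573, 0.080543327, 0.29038108, 2.9040523, 0.03213215, 0.27393426, 14.394052, 0.12922364, 6.7469365, 2.9868, 0.63430852, 0.57076669, 0.044926357, 0.43127766, 0.34005847, 0.89059858, 1.3312916, 0.3198959, 0.19575063, 0.28380767, 1.5269642, 4.9764145e-05, 0.012416222, 0.07312793, 0.27991051, 0.056869322, 0.0070265883, 2.0315113, 0.070460039, 0.87427217, 4.9048422, 0.0071324305, 0.99668567, 0.00013490624, 0.81475309, 5.3939242, 0.59258799, 2.0873853, 0.54225109, 0.0004310207, 0.00018229488, 0.058971975, 2.2068599, 0.099835753, 0.39255224, 0.088256423, 0.20706621, 0.12489802, 0.65410911, 0.42775543, 0.25690046, 0.16758165],
    [0.047071805, 0.050910205, 0.074214307, 0.047859605, 0.025021603, 0.033303603, 0.054587405, 0.076373408, 0.019964202, 0.067133607, 0.071498107, 0.056784506, 0.018150702, 0.030496103, 0.050656105, 0.088409109, 0.074338607, 0.018523702, 0.031474103, 0.063229206]),
"BLOSUM62": (
    [0.73579039, 0.48539106, 0.54316182, 1.4599953, 1.1997057, 1.170949, 1.9558836, 0.71624144, 0.605899, 0.80001653, 1.2952013, 1.2537583, 0.49296468, 1.1732759, 4.3250927, 1.729178, 0.46583937, 0.7182067, 2.1877745, 1.2974467, 0.50096441, 0.22782657, 3.0208336, 1.3605742, 0.41876331, 1.4561412, 0.23203645, 0.62271167, 5.4111151, 0.98369299, 0.37164469, 0.44813366, 1.1227831, 0.91466595, 0.42638231, 0.72051744, 0.43838834, 3.1801, 0.39735895, 1.8392161, 1.2404885, 1.3558723, 2.4145014, 0.28301733, 0.21188816, 1.593137, 0.64844128, 0.35486125, 0.49488704, 2.9041017, 1.8981736, 0.19148205, 0.53822252, 0.3128588, 0.24083661, 1.1909457, 3.7616252, 0.79847325, 0.77814266, 0.41855573, 0.21813158, 1.0324479, 0.2226219, 0.28173069, 0.73062827, 1.5827541, 0.93418751, 0.14534505, 0.26142221, 0.25812929, 0.3298015, 0.14074889, 0.41820319, 0.35405811, 0.77489402, 0.83184264, 0.2850788, 0.76768882, 0.44133747, 0.3560085, 1.1971884, 1.1198314, 0.52766442, 0.47023773, 1.1163525, 5.5289192, 0.60984631, 2.4353411, 0.23620245, 0.58073709, 3.9452777, 2.4948961, 0.14435696, 0.85857058, 1.9348709, 1.2774803, 0.75865381, 0.95898974, 0.53078579, 0.42357999, 1.6268911, 0.18684805, 0.37262518, 2.8024272, 0.5554154, 0.29140908, 0.92656393, 1.7698932, 1.0710972, 0.40763565, 0.5967193, 0.52425385, 0.53985912, 0.18929629, 0.21772116, 0.75204244, 0.45943617, 0.36816646, 0.5040866, 1.5093263, 0.64143601, 0.50835892, 0.30805574, 0.25334079, 0.25271845, 0.34807221, 1.022507, 0.98431153, 0.7145337, 0.52700734, 1.1170298, 0.58540709, 0.3012486, 4.218954, 0.20155597, 3.8909638, 0.40619359, 3.3647978, 1.5173593, 0.38835541, 0.35754441, 1.1790912, 0.34198579, 0.67461709, 8.3118394, 0.44557027, 6.0305594, 2.0648397, 0.37455569, 0.35296918, 0.91525986, 0.69147463, 0.81124586, 2.2314057, 1.0730612, 0.26692475, 1.0473835, 1.7521659, 1.3038752, 0.33224304, 0.71799349, 0.49813848, 1.7738552, 0.45412363, 0.91872342, 1.4885481, 0.8881011, 0.95168216, 2.5758508, 0.23359791, 0.54002764, 0.48820612, 2.0743249, 6.7472604, 0.83811961, 1.1691296, 1.0054517, 0.25221483, 0.36940532, 0.49690841, 5.1515563, 0.38792562, 0.79675152, 0.56192546, 0.51312813, 0.80101024, 2.2530741, 4.054419, 0.26650873, 1],
    [0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068, 0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073]),
"DCMUT": (
    [0.267828, 0.984474, 1.199805, 0.360016, 0.887753, 1.961167, 2.386111, 0.228116, 0.653416, 0.406431, 0.258635, 0.71784, 0.183641, 2.48592, 4.05187, 3.680365, 0, 0.244139, 2.059564, 0.327059, 0, 0.232374, 2.439939, 0, 0.087791, 2.383148, 0.632629, 0.154924, 4.610124, 0.896321, 0.136906, 1.028313, 1.53159, 0.265745, 2.001375, 0.078012, 0.240368, 8.931515, 0, 1.028509, 1.493409, 1.385352, 5.290024, 0.768024, 0.341113, 3.148371, 0, 0.138503, 0.419244, 4.885892, 2.271697, 0.224968, 0.94694, 0.158067, 0, 1.348551, 11.388659, 1.240981, 0.868241, 0.239248, 0, 0.716913, 0, 0, 0.13394, 0.956097, 0.66093, 0, 0, 0.178316, 0, 0, 0.107278, 0.282729, 0.438074, 0, 0, 0, 0, 0.18755, 1.598356, 0.162366, 0, 0.953164, 0.484678, 7.086022, 0.281581, 6.011613, 0.180393, 0.730772, 1.519078, 1.127499, 0, 1.526188, 0.561828, 0.525651, 0, 0, 0.346983, 0.811907, 0.439469, 0.609526, 0.11288, 0.830078, 0.304803, 0, 0.507003, 0.793999, 0.340156, 0, 0.214717, 0.36725, 0.106802, 0, 0.071514, 0.267683, 0.170372, 0.153478, 0.347153, 2.322243, 0.306662, 0, 0, 0.538165, 0.076981, 0.443504, 0.270475, 0, 0.475927, 0.933709, 0.353643, 0.226333, 0.270564, 1.2654, 0.438715, 2.556685, 0.460857, 3.332732, 1.951951, 0.119152, 0.247955, 1.900739, 0, 0.374834, 8.810038, 0.180629, 5.230115, 1.56516, 0.316258, 0.171432, 0.33109, 0.461776, 0.286572, 1.745156, 2.411739, 0, 0.335419, 0.954557, 1.350599, 0, 0.132142, 0.10385, 0.92186, 0.170205, 0.619951, 1.031534, 0, 0, 2.565955, 0.110506, 0.459901, 0.136655, 0.762354, 6.952629, 0.123606, 2.427202, 0.782857, 0, 0, 0.485026, 5.436674, 0.740819, 0.336289, 0.303836, 0, 0.417839, 1.561997, 0.60807, 0, 0.279379],
    [0.087126913, 0.040903959, 0.04043196, 0.046871953, 0.033473967, 0.038254962, 0.04952995, 0.088611911, 0.033618966, 0.036885963, 0.085356915, 0.08048092, 0.014752985, 0.03977196, 0.050679949, 0.06957693, 0.058541941, 0.01049399, 0.02991597, 0.064717935]),
"JTTDCMUT": (
    [0.531678, 0.557967, 0.827445, 0.574478, 0.556725, 1.066681, 1.740159, 0.21997, 0.361684, 0.310007, 0.369437, 0.469395, 0.138293, 1.959599, 3.887095, 4.582565, 0.084329, 0.139492, 2.924161, 0.451095, 0.154899, 1.019843, 3.021995, 0.318483, 1.359652, 3.210671, 0.239195, 0.372261, 6.529255, 0.431045, 0.065314, 0.710489, 1.001551, 0.650282, 1.257961, 0.235601, 0.171995, 5.54953, 0.313311, 0.768834, 0.578115, 0.773313, 4.025778, 0.491003, 0.137289, 2.529517, 0.33072, 0.073481, 0.121804, 5.057964, 2.351311, 0.0277, 0.700693, 0.164525, 0.105625, 0.521646, 7.766557, 1.272434, 1.032342, 0.115968, 0.061486, 0.282466, 0.190001, 0.032522, 0.127164, 0.589268, 0.425159, 0.057466, 0.453952, 0.315261, 0.091304, 0.053907, 0.546389, 0.724998, 0.150559, 0.164593, 0.049009, 0.409202, 0.678335, 0.123653, 2.155331, 0.469823, 1.104181, 2.114852, 0.621323, 3.417706, 0.231294, 5.68408, 0.07827, 0.709004, 2.966732, 0.456901, 0.045683, 1.608126, 0.548807, 0.523825, 0.172206, 0.254745, 0.179771, 1.115632, 0.243768, 0.111773, 0.097485, 1.731684, 0.175084, 0.043829, 0.191994, 0.312449, 0.331584, 0.114381, 0.063452, 0.465271, 0.201696, 0.053769, 0.069492, 0.26984, 0.130379, 0.050212, 0.208081, 1.874296, 0.316862, 0.54418, 0.0525, 0.47014, 0.181788, 0.540571, 0.525096, 0.32966, 0.453428, 1.141961, 0.743458, 0.477355, 0.128193, 5.8484, 0.121827, 2.335139, 0.202562, 4.831666, 0.77709, 0.09858, 0.405119, 2.553806, 0.13451, 0.303445, 9.533943, 0.146481, 3.856906, 2.500294, 1.060504, 0.592511, 0.272514, 0.530324, 0.241094, 1.761439, 0.624581, 0.024521, 0.216345, 0.474478, 0.965641, 0.089134, 0.087904, 0.124066, 0.436181, 0.164215, 0.285564, 2.114728, 0.201334, 0.18987, 3.038533, 0.148483, 0.943971, 0.138904, 0.537922, 5.484236, 0.593478, 2.788406, 1.176961, 0.069965, 0.11385, 0.211561, 4.777647, 0.310927, 0.628608, 0.408532, 0.080556, 0.201094, 1.14398, 0.747889, 0.239697, 0.165473],
    [0.076861923, 0.051056949, 0.042545957, 0.051268949, 0.02027898, 0.041060959, 0.061819938, 0.074713925, 0.022982977, 0.052568947, 0.091110909, 0.059497941, 0.023413977, 0.040529959, 0.050531949, 0.068224932, 0.058517941, 0.014335986, 0.032302968, 0.066373934]),
}

# synthetic stand-in: Blosum62 values under the PMB name (see module docstring)
AA_MODEL_DATA["PMB"] = AA_MODEL_DATA["BLOSUM62"]
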