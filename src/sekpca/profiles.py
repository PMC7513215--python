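"""Published per-component variance-contribution profiles from a two-session,
30-electrode driving-fatigue EEG study (sample-entropy features; 600x30 and
900x30 epoch matrices).

Each profile lists the 30 contribution rates C_i = lambda_i / sum(lambda) in
descending order, to the 4 decimals at which they were reported. They serve
as regression fixtures for :func:`sekpca.decomposition.cvc_select`: the
component counts retained at thresholds 0.90 / 0.95 / 0.99 are reproducible
from these printed entries alone.

Keys: ``("pca", 1)`` and ``("pca", 2)`` are the linear-PCA profiles of the
first (10-subject) and second (15-subject) sessions; ``("poly", P, session)``
are the kernel-PCA profiles for the P-order polynomial kernel.
"""

from __future__ import annotations

CONTRIBUTION_PROFILES: dict[tuple, list[float]] = {
    ("pca", 1): [
        0.5664, 0.0721, 0.0633, 0.0486, 0.0425, 0.0306, 0.0275, 0.0209,
        0.0191, 0.0154, 0.0138, 0.0125, 0.0097, 0.0086, 0.0079, 0.0065,
        0.0051, 0.0044, 0.0043, 0.0038, 0.0031, 0.0027, 0.0023, 0.0018,
        0.0016, 0.0013, 0.0012, 0.0011, 0.0011, 0.0008,
    ],
    ("pca", 2): [
        0.6286, 0.0960, 0.0470, 0.0350, 0.0322, 0.0266, 0.0197, 0.0163,
        0.0145, 0.0107, 0.0104, 0.0080, 0.0068, 0.0060, 0.0056, 0.0050,
        0.0046, 0.0040, 0.0033, 0.0030, 0.0028, 0.0027, 0.0024, 0.0019,
        0.0017, 0.0014, 0.0012, 0.0009, 0.0008, 0.0007,
    ],
    ("poly", 2.0, 1): [
        0.7026, 0.0534, 0.0412, 0.0318, 0.0269, 0.0213, 0.0190, 0.0157,
        0.0141, 0.0093, 0.0077, 0.0073, 0.0059, 0.0057, 0.0048, 0.0037,
        0.0034, 0.0030, 0.0027, 0.0023, 0.0019, 0.0018, 0.0016, 0.0015,
        0.0013, 0.0013, 0.0011, 0.0010, 0.0009, 0.0008,
    ],
    ("poly", 2.0, 2): [
        0.7171, 0.0679, 0.0359, 0.0313, 0.0214, 0.0183, 0.0156, 0.0131,
        0.0118, 0.0089, 0.0070, 0.0064, 0.0052, 0.0042, 0.0037, 0.0034,
        0.0030, 0.0028, 0.0024, 0.0023, 0.0020, 0.0019, 0.0017, 0.0016,
        0.0013, 0.0011, 0.0009, 0.0009, 0.0008, 0.0006,
    ],
    ("poly", 1.0, 1): [
        0.5977, 0.0809, 0.0557, 0.0434, 0.0355, 0.0284, 0.0257, 0.0208,
        0.0197, 0.0127, 0.0104, 0.0097, 0.0087, 0.0079, 0.0065, 0.0051,
        0.0044, 0.0041, 0.0034, 0.0030, 0.0026, 0.0022, 0.0021, 0.0019,
        0.0017, 0.0016, 0.0013, 0.0011, 0.0010, 0.0009,
    ],
    ("poly", 1.0, 2): [
        0.6255, 0.1035, 0.0456, 0.0390, 0.0288, 0.0255, 0.0205, 0.0177,
        0.0139, 0.0112, 0.0091, 0.0076, 0.0066, 0.0055, 0.0046, 0.0046,
        0.0042, 0.0042, 0.0033, 0.0031, 0.0026, 0.0025, 0.0023, 0.0021,
        0.0016, 0.0013, 0.0012, 0.0009, 0.0008, 0.0006,
    ],
    ("poly", 0.5, 1): [
        0.5055, 0.1051, 0.0685, 0.0552, 0.0424, 0.0353, 0.0314, 0.0250,
        0.0238, 0.0157, 0.0128, 0.0128, 0.0107, 0.0097, 0.0079, 0.0062,
        0.0054, 0.0051, 0.0041, 0.0036, 0.0032, 0.0027, 0.0025, 0.0023,
        0.0020, 0.0019, 0.0015, 0.0013, 0.0012, 0.0010,
    ],
    ("poly", 0.5, 2): [
        0.5343, 0.1374, 0.0562, 0.0476, 0.0366, 0.0330, 0.0249, 0.0224,
        0.0159, 0.0135, 0.0112, 0.0089, 0.0081, 0.0069, 0.0061, 0.0058,
        0.0052, 0.0051, 0.0041, 0.0039, 0.0033, 0.0030, 0.0028, 0.0026,
        0.0020, 0.0016, 0.0014, 0.0011, 0.0009, 0.0007,
    ],
}

# Component counts reported for these profiles at the standard thresholds.
REPORTED_COMPONENT_COUNTS: dict[tuple, dict[float, int]] = {
    ("pca", 1): {0.90: 10, 0.95: 14, 0.99: 23},
    ("pca", 2): {0.90: 8, 0.95: 13, 0.99: 23},
    ("poly", 2.0, 1): {0.90: 8, 0.95: 12, 0.99: 26},
    ("poly", 2.0, 2): {0.90: 7, 0.95: 12, 0.99: 25},
    ("poly", 1.0, 1): {0.90: 9, 0.95: 14, 0.99: 23},
    ("poly", 1.0, 2): {0.90: 8, 0.95: 13, 0.99: 23},
    ("poly", 0.5, 1): {0.90: 10, 0.95: 14, 0.99: 22},
    ("poly", 0.5, 2): {0.90: 9, 0.95: 13, 0.99: 21},
}
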