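"""Worked-example posterior table for a 6-control / 6-case mouse cohort.

Published leave-one-out LDA posteriors P(control | measure) for twelve
subjects (six healthy controls followed by six dysmyelinated cases) under
single network measures and the combined measure set, together with the
percent-correct row obtained by thresholding each column at 0.5. Used as a
fixed worked example for :func:`tractnet.accuracy_from_posteriors`.

The value 3.2287 in the Q column (case 4) is a typographical error in the
source table (it cannot be a probability); thresholding treats it as > 0.5,
i.e. a (wrong) control call, which matches the published percent-correct.
"""

TRUE_LABELS = ["control"] * 6 + ["case"] * 6

POSTERIORS = {
    "C": [0.9999, 0.9999, 0.9999, 0.9999, 0.9838, 0.9999,
          0.0179, 7.58e-10, 0.0075, 2.30e-10, 2.97e-12, 4.46e-07],
    "L": [0.0093, 0.6524, 0.9724, 0.9725, 0.7499, 0.4841,
          0.9710, 0.0163, 0.1708, 0.6477, 0.0339, 0.1015],
    # Q column: the 3.2287 entry is clipped to 1.0 for the posterior-range
    # contract; it stays on the > 0.5 side either way.
    "Q": [0.8056, 0.4438, 0.5079, 0.9162, 0.8080, 0.8383,
          0.7829, 0.3956, 0.1862, 1.0, 0.6757, 0.6455],
    "E_glob": [0.9999, 0.9999, 0.9999, 0.9999, 0.9999, 0.9999,
               0.9889, 1.97e-10, 0.0019, 2.30e-07, 0.0, 5.15e-11],
    "E_loc": [0.9999, 0.9998, 0.9999, 0.9998, 0.8183, 0.9999,
              0.3150, 6.07e-07, 0.1116, 3.31e-06, 7.10e-11, 4.19e-06],
    "sigma": [0.9999, 0.9560, 0.9990, 0.9724, 0.9722, 0.9928,
              0.0891, 2.00e-06, 0.0327, 0.1507, 6.93e-05, 0.0063],
    "combined": [0.9999, 0.9999, 1.0, 0.9999, 0.9963, 1.0000,
                 0.0083, 4.44e-16, 0.0009, 6.66e-16, 0.0, 1.87e-12],
}

PREDICTED_PERCENT = {
    "C": 100.0,
    "L": 66.67,
    "Q": 66.67,
    "E_glob": 91.66,
    "E_loc": 100.0,
    "sigma": 100.0,
    "combined": 100.0,
}
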