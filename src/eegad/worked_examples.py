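"""Worked-example inputs for the selection and metric arithmetic.

These small tables are published screening summaries from a
representative AD-versus-control qEEG study: significance counts of
channels per band feature and of band features per channel, the
per-channel p-values of one feature family, and one printed
performance row.  They exercise the Bonferroni, distribution-ratio and
cumulative-selection arithmetic end to end without any EEG data.
"""

from __future__ import annotations

import pandas as pd

# Per-channel p-values for one (method, band-ratio) family tested over the
# 19 montage channels (theta/alpha ratio, Tsallis entropy family).
THETA_ALPHA_TSEN_PVALUES = {
    "Fp1": 0.0264, "Fp2": 0.0394, "F7": 0.4883, "F3": 0.5511, "FZ": 0.3612,
    "F4": 0.1582, "F8": 0.3105, "T3": 0.1352, "C3": 0.2859, "CZ": 0.8901,
    "C4": 0.5549, "T4": 0.2418, "T5": 0.0010, "P3": 0.0048, "PZ": 0.0207,
    "P4": 0.0036, "T6": 0.0002, "O1": 0.0028, "O2": 0.0035,
}

# Number of channels at which each band feature met the p <= 0.001
# criterion, per analysis method (columns: ApEn, LZC, HFD, TsEn, band
# power, amplitude change rate, zero-crossing interval, coherence), with
# the published row total last.  A few published totals differ from their
# cell sums (transcription quirks in the source summary); the published
# totals are kept as the ranking weights, since the derived ratio and
# cumulative columns are tallied from them and they sum to 475.
_FEATURE_COUNT_ROWS = [
    # band_spec,        APEN LZC HFD TSEN DPS DEEGA ZCI COH  total
    ("theta/alpha",       12,  5,  9,  2, 18, 12, 15,  1,  74),
    ("alpha/theta",       12,  7,  0,  2, 17, 15, 15,  0,  68),
    ("alpha/delta",        0,  0,  0,  0, 18, 11,  8,  0,  37),
    ("beta/theta",        13,  0,  0,  0,  2, 10,  9,  1,  35),
    ("theta/beta",        12,  0,  3,  0,  4,  5,  9,  0,  33),
    ("alpha",              2,  0,  4,  0, 19,  3,  4,  0,  32),
    ("delta/alpha",        1,  0,  0,  0, 18,  4,  7,  0,  30),
    ("delta",              0,  0,  0,  0, 19,  0,  0,  3,  22),
    ("theta",              0,  0,  0,  0, 18,  0,  0,  3,  19),
    ("theta/delta",        0,  0,  0,  0, 17,  0,  0,  0,  18),
    ("delta/theta",        8,  0,  0,  1,  0,  4,  4,  0,  17),
    ("gamma/theta",        0,  0,  0,  0, 16,  0,  0,  0,  17),
    ("beta/delta",         0,  0,  0,  0,  2,  7,  3,  2,  14),
    ("beta",               2,  0,  4,  0,  1,  1,  3,  2,  13),
    ("theta/gamma",        6,  0,  0,  1,  0,  0,  4,  0,  11),
    ("alpha/beta",         0,  4,  0,  0,  4,  0,  0,  0,   8),
    ("gamma/delta",        3,  0,  0,  0,  1,  3,  1,  0,   8),
    ("delta/beta",         0,  0,  0,  0,  2,  0,  2,  0,   4),
    ("alpha/gamma",        0,  4,  0,  0,  0,  0,  0,  0,   4),
    ("gamma",              0,  2,  0,  0,  1,  0,  0,  2,   3),
    ("gamma/alpha",        0,  0,  1,  0,  2,  0,  0,  0,   3),
    ("gamma/beta",         0,  1,  0,  0,  1,  0,  0,  0,   3),
    ("beta/alpha",         0,  0,  0,  0,  1,  0,  0,  0,   2),
    ("delta/gamma",        0,  0,  0,  0,  0,  0,  0,  0,   0),
    ("beta/gamma",         0,  0,  0,  0,  0,  0,  0,  0,   0),
]

FEATURE_COUNT_COLUMNS = ["APEN", "LZC", "HFD", "TSEN", "DPS", "DEEGA",
                         "ZCI", "COH"]


def feature_count_table() -> pd.DataFrame:
    """Band-feature significance counts (25 features x 8 methods).

    The ``total`` column holds the published ranking weights, which sum
    to 475 over all eight methods.
    """
    df = pd.DataFrame([r[1:-1] for r in _FEATURE_COUNT_ROWS],
                      index=[r[0] for r in _FEATURE_COUNT_ROWS],
                      columns=FEATURE_COUNT_COLUMNS)
    df["total"] = [r[-1] for r in _FEATURE_COUNT_ROWS]
    return df


# Number of band features per channel meeting the criterion, over the
# seven single-channel methods (coherence is tallied separately by pair).
_CHANNEL_COUNT_ROWS = [
    # channel, APEN LZC HFD TSEN DPS DEEGA ZCI
    ("P4",  7, 5, 4, 0, 10, 10, 12),
    ("P3",  9, 2, 4, 0,  9,  8, 13),
    ("PZ",  8, 2, 3, 2, 11,  9, 10),
    ("T6",  3, 6, 2, 2,  9,  7,  7),
    ("T5",  2, 3, 4, 2,  9,  6,  7),
    ("C4",  6, 0, 0, 0, 11,  6,  4),
    ("T4",  4, 2, 1, 0,  8,  7,  3),
    ("T3",  4, 0, 1, 0, 14,  3,  2),
    ("C3",  4, 0, 0, 0, 12,  4,  4),
    ("CZ",  6, 0, 0, 0,  9,  3,  6),
    ("O2",  3, 3, 1, 0, 10,  3,  4),
    ("O1",  4, 0, 1, 0,  8,  3,  4),
    ("F8",  2, 0, 0, 0, 12,  1,  2),
    ("F7",  3, 0, 0, 0,  9,  2,  2),
    ("F3",  3, 0, 0, 0,  9,  1,  2),
    ("FZ",  3, 0, 0, 0,  7,  2,  2),
    ("Fp1", 0, 0, 0, 0,  9,  0,  0),
    ("F4",  0, 0, 0, 0,  9,  0,  0),
    ("Fp2", 0, 0, 0, 0,  6,  0,  0),
]

CHANNEL_COUNT_COLUMNS = ["APEN", "LZC", "HFD", "TSEN", "DPS", "DEEGA", "ZCI"]


def channel_count_table() -> pd.DataFrame:
    """Per-channel significance counts (19 channels x 7 methods, total 461)."""
    df = pd.DataFrame([r[1:] for r in _CHANNEL_COUNT_ROWS],
                      index=[r[0] for r in _CHANNEL_COUNT_ROWS],
                      columns=CHANNEL_COUNT_COLUMNS)
    df["total"] = df.sum(axis=1)
    return df


# Coherence channel pairs with at least one significant band feature.
PAIR_COUNTS = {
    "F4-F8": 3, "FZ-F8": 2, "T3-T4": 2, "Fp2-F4": 1, "F4-T3": 1,
    "F4-T4": 1, "F8-P4": 1, "T3-P4": 1, "T3-T6": 1, "T4-P3": 1,
}

# One printed cross-validated performance row of a two-channel panel
# (sensitivity, specificity, accuracy, F-measure, MCC, PPV, NPV).
PRINTED_PANEL_ROW = {
    "sensitivity": 83.33, "specificity": 81.82, "accuracy": 82.35,
    "f_measure": 76.92, "mcc": 0.63, "ppv": 71.43, "npv": 90.00,
}
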