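"""Statistical screening of biomarkers and channels.

Each feature column gets a two-sample AD-vs-control p-value; features
and channels are then ranked by how many locations reach the
significance threshold, expressed as probability-distribution ratios
(each item's share of all significant tests), and the top items covering
a cumulative share of at least 80% are selected.  Bonferroni-corrected
p-values and the family-wise critical value are reported alongside but
do not gate the selection, which uses the raw p <= 0.001 rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import BiomarkerTable
from .io import GROUP_AD, GROUP_NOLD
from .montage import (
    ALL_METHODS,
    COHERENCE_METHOD,
    FeatureId,
    SINGLE_CHANNEL_METHODS,
    band_specs,
)

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.001
CUMULATIVE_THRESHOLD = 80.0
FAMILYWISE_ALPHA = 0.05


def group_pvalue(values_ad: np.ndarray, values_nold: np.ndarray,
                 test: str = "welch") -> float:
    """Two-sided two-sample p-value between the AD and control groups.

    ``test`` is ``"welch"`` (unequal-variance t-test, the default) or
    ``"mannwhitney"``.  Non-finite values are dropped; fewer than two
    finite values in either group yields NaN (feature excluded).
    """
    a = np.asarray(values_ad, dtype=float)
    b = np.asarray(values_nold, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value, ``min(1, p * n_tests)``."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def bonferroni_critical(n_tests: int, alpha: float = FAMILYWISE_ALPHA) -> float:
    """Per-test critical value controlling the family-wise error rate."""
    return alpha / n_tests


def distribution_ratio(counts: pd.Series) -> pd.DataFrame:
    """Probability-distribution ratios and the cumulative ranking.

    Each item's ratio is ``100 * x_i / sum(x)``.  Items are ranked by
    descending ratio (ties broken by count, then identifier) and the
    cumulative column accumulates the ratios rounded to three decimals,
    the tallying convention of the printed screening tables this module
    mirrors.  All-zero counts are an error.
    """
    counts = pd.Series(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all counts are zero; nothing to rank")
    ratio = 100.0 * counts / total
    order = sorted(counts.index,
                   key=lambda i: (-ratio[i], -counts[i], str(i)))
    out = pd.DataFrame({"count": counts.astype(int), "ratio_pct": ratio})
    out = out.loc[order]
    out["cumulative_pct"] = out["ratio_pct"].round(3).cumsum()
    return out


def cumulative_select(ranked: pd.DataFrame,
                      threshold: float = CUMULATIVE_THRESHOLD) -> list:
    """Shortest ranking prefix whose cumulative ratio reaches the threshold.

    ``ranked`` is a :func:`distribution_ratio` table.  The item that
    carries the cumulative total across the threshold is included.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    cum = ranked["cumulative_pct"].to_numpy()
    # first index at which the cumulative share reaches the threshold
    idx = int(np.argmax(cum >= threshold))
    if cum[idx] < threshold:  # never reached (rounding artefacts)
        idx = len(cum) - 1
    return list(ranked.index[: idx + 1])


@dataclass
class SelectionReport:
    """Outcome of the statistical screening stage.

    ``pvalues`` is the long-form per-feature test table; the three count
    tables rank band features (over all 8 methods), channels (over the 7
    single-channel methods) and coherence channel pairs.  Selected sets
    are prefixes of the respective rankings.
    """

    pvalues: pd.DataFrame
    feature_table: pd.DataFrame
    channel_table: pd.DataFrame
    pair_table: pd.DataFrame | None
    selected_features: list[str]
    selected_channels: list[str]
    selected_pairs: list[str]
    thresholds: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pvalues.to_csv(outdir / "pvalues.csv", index=False)
        self.feature_table.to_csv(outdir / "feature_ranking.csv",
                                  index_label="band_spec")
        self.channel_table.to_csv(outdir / "channel_ranking.csv",
                                  index_label="channel")
        if self.pair_table is not None:
            self.pair_table.to_csv(outdir / "pair_ranking.csv",
                                   index_label="pair")


def compute_pvalues(table: BiomarkerTable, test: str = "welch") -> pd.DataFrame:
    """Per-feature group p-values with per-family Bonferroni correction.

    The correction family is the set of locations tested for one
    (method, band_spec): 19 channels for single-channel methods, 171
    pairs for coherence on the full montage.
    """
    ad = table.groups == GROUP_AD
    nold = table.groups == GROUP_NOLD
    if ad.sum() < 2 or nold.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for col in table.values.columns:
        fid = FeatureId.from_column(col)
        vals = table.values[col].to_numpy()
        p = group_pvalue(vals[ad.to_numpy()], vals[nold.to_numpy()], test)
        rows.append((col, fid.method, fid.band_spec, fid.location, p))
    df = pd.DataFrame(rows, columns=["column", "method", "band_spec",
                                     "location", "p"])
    n_dropped = int(df["p"].isna().sum())
    if n_dropped:
        logger.warning("%d features excluded from testing (too few finite values)",
                       n_dropped)
    family_n = df.groupby(["method", "band_spec"])["p"].transform("size")
    df["n_tests"] = family_n
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * family_n)
    df["critical"] = FAMILYWISE_ALPHA / family_n
    df["significant"] = df["p"] <= P_THRESHOLD
    return df


def significance_counts(pvalues: pd.DataFrame,
                        p_threshold: float = P_THRESHOLD
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Count tables of locations meeting the p-value criterion.

    Returns (feature x method counts over all methods, channel x method
    counts over the single-channel methods, coherence pair counts).
    """
    sig = pvalues[pvalues["p"] <= p_threshold]
    specs = [s for s in band_specs() if s in set(pvalues["band_spec"])]

    feat = pd.DataFrame(0, index=specs, columns=list(ALL_METHODS))
    for (spec, method), grp in sig.groupby(["band_spec", "method"]):
        feat.loc[spec, method] = len(grp)
    feat["total"] = feat.sum(axis=1)

    single = sig[sig["method"] != COHERENCE_METHOD]
    channels = sorted(set(pvalues.loc[pvalues["method"] != COHERENCE_METHOD,
                                      "location"]))
    chan = pd.DataFrame(0, index=channels, columns=list(SINGLE_CHANNEL_METHODS))
    for (loc, method), grp in single.groupby(["location", "method"]):
        chan.loc[loc, method] = len(grp)
    chan["total"] = chan.sum(axis=1)

    pairs_sig = sig[sig["method"] == COHERENCE_METHOD]
    pair = pairs_sig.groupby("location").size().rename("total").to_frame()
    return feat, chan, pair


def select(table: BiomarkerTable, test: str = "welch",
           p_threshold: float = P_THRESHOLD,
           cumulative_threshold: float = CUMULATIVE_THRESHOLD
           ) -> SelectionReport:
    """Run the full screening stage on a biomarker table."""
    pvalues = compute_pvalues(table, test)
    feat, chan, pair = significance_counts(pvalues, p_threshold)

    feature_rank = _ranked(feat, feat["total"])
    channel_rank = _ranked(chan, chan["total"])
    selected_features = (cumulative_select(feature_rank, cumulative_threshold)
                         if feat["total"].sum() else [])
    selected_channels = (cumulative_select(channel_rank, cumulative_threshold)
                         if chan["total"].sum() else [])

    pair_rank = None
    selected_pairs: list[str] = []
    if len(pair) and pair["total"].sum() > 0:
        pair_rank = _ranked(pair, pair["total"])
        selected_pairs = list(pair_rank.index)  # pairs meeting the p-rule
    return SelectionReport(
        pvalues=pvalues,
        feature_table=feature_rank,
        channel_table=channel_rank,
        pair_table=pair_rank,
        selected_features=selected_features,
        selected_channels=selected_channels,
        selected_pairs=selected_pairs,
        thresholds={"p": p_threshold, "cumulative_pct": cumulative_threshold,
                    "test": test},
    )


def _ranked(counts_table: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    nonzero_total = totals.sum()
    if nonzero_total == 0:
        out = counts_table.copy()
        out["ratio_pct"] = 0.0
        out["cumulative_pct"] = 0.0
        return out
    rank = distribution_ratio(totals)
    out = counts_table.loc[rank.index].copy()
    out["ratio_pct"] = rank["ratio_pct"]
    out["cumulative_pct"] = rank["cumulative_pct"]
    return out
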