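"""Group inference on peak-window responses: ROI and channel t-tests.

Participant-level responses (one value per participant x channel) are
aggregated into regions of interest and tested with one-sample one-tailed
t-tests -- HbO for an increase, HbR for a decrease -- with
Benjamini-Hochberg FDR across units, Cohen's d (mean/SD) and post hoc power
from the noncentral t distribution at alpha = 0.05.

The module also exposes a statsmodels-style front end:
``SustainedAttentionModel(responses, roi_map=..., adjacency=...).fit()``
returns a :class:`SustainedAttentionResults` carrying the ROI table, the
channel table, the permutation-cluster outcome, and a ``summary()``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_roi_map",
    "roi_aggregate",
    "one_sample_t",
    "cohens_d",
    "posthoc_power",
    "fdr_adjust",
    "unit_stats",
    "channelwise_stats",
    "roi_stats",
    "SustainedAttentionModel",
    "SustainedAttentionResults",
]


def load_roi_map(path=None) -> dict[str, list[int]]:
    """ROI name -> channel index list; defaults to the packaged illustrative map."""
    if path is None:
        ref = importlib.resources.files("natattn.data") / "roi_map.yaml"
        with importlib.resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    roi_map = {str(k): [int(c) for c in v] for k, v in raw.items()}
    seen: set[int] = set()
    for name, chans in roi_map.items():
        if not chans:
            raise ValueError(f"ROI {name!r} is empty")
        dup = seen.intersection(chans)
        if dup:
            raise ValueError(f"channels {sorted(dup)} appear in multiple ROIs")
        seen.update(chans)
    return roi_map


def roi_aggregate(responses: pd.DataFrame, roi_map: dict[str, list[int]]) -> pd.DataFrame:
    """Participant-level ROI values: mean of that participant's available channels.

    ``responses`` is tidy (participant, channel, response).  A participant
    with no surviving channel in an ROI is omitted from that ROI only, which
    is what produces unequal degrees of freedom across ROIs.  Returns a tidy
    frame (participant, roi, value, n_channels).
    """
    rows = []
    for roi, chans in roi_map.items():
        if not chans:
            raise ValueError(f"ROI {roi!r} is empty")
        sub = responses[responses["channel"].isin(chans)]
        for pid, grp in sub.groupby("participant"):
            vals = grp["response"].dropna()
            if len(vals):
                rows.append({"participant": pid, "roi": roi, "value": vals.mean(), "n_channels": len(vals)})
    return pd.DataFrame(rows, columns=["participant", "roi", "value", "n_channels"])


def one_sample_t(values, alternative: str = "greater") -> tuple[float, int, float]:
    """One-sample t-test of mean 0: returns (t, df, one-tailed p).

    t = mean / (sd / sqrt(n)) with the sample SD (ddof=1); p is the upper
    tail for ``alternative='greater'`` (HbO increase) or lower tail for
    ``'less'`` (HbR decrease).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    t = x.mean() / (sd / np.sqrt(n))
    df = n - 1
    if alternative == "greater":
        p = sps.t.sf(t, df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return float(t), df, float(p)


def cohens_d(values) -> float:
    """One-sample Cohen's d: mean divided by the sample SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return float(x.mean() / sd)


def posthoc_power(d: float, n: int, alpha: float = 0.05, alternative: str = "greater") -> float:
    """Post hoc power of the one-tailed one-sample t-test at effect size d.

    Under the alternative the t statistic is noncentral t with df = n - 1
    and noncentrality d * sqrt(n); power is the probability it exceeds the
    central-t critical value.  For d = 0 this equals alpha.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    ncp = d * np.sqrt(n)
    if alternative == "less":
        ncp = -ncp
    elif alternative != "greater":
        raise ValueError("alternative must be 'greater' or 'less'")
    t_crit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(t_crit, df, ncp))


def fdr_adjust(pvalues, method: str = "bh", pi0: float | None = None) -> np.ndarray:
    """FDR-adjusted q-values.

    ``method='bh'`` is the Benjamini-Hochberg step-up.  ``method='storey'``
    multiplies BH q-values by a *user-supplied* ``pi0`` (the null proportion);
    no pi0 smoother is fitted -- with a handful of tests such estimators are
    unstable.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        if pi0 is None or not 0 < pi0 <= 1:
            raise ValueError("storey mode needs a fixed pi0 in (0, 1]")
        return np.minimum(q * pi0, 1.0)
    raise ValueError("method must be 'bh' or 'storey'")


def _stats_table(groups: dict, alternative: str, unit_name: str) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2 or x.std(ddof=1) == 0:
            raise ValueError(f"{unit_name} {name!r}: need >= 2 values with nonzero SD")
        t, df, p = one_sample_t(x, alternative)
        d = cohens_d(x)
        rows.append(
            {
                unit_name: name,
                "n": x.size,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
                "d": d,
                "power": posthoc_power(d, x.size, alternative=alternative),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = fdr_adjust(table["p"].to_numpy())
    return table


def roi_stats(
    responses: pd.DataFrame,
    roi_map: dict[str, list[int]],
    alternative: str = "greater",
) -> pd.DataFrame:
    """ROI-level one-tailed t-table with FDR across ROIs.

    Columns mirror the usual report layout: n, mean, sd, t, df, p, q, d,
    power.  ``alternative='greater'`` tests an HbO increase; pass ``'less'``
    for HbR.
    """
    agg = roi_aggregate(responses, roi_map)
    groups = {roi: grp["value"].to_numpy() for roi, grp in agg.groupby("roi")}
    for roi in roi_map:
        if roi not in groups:
            raise ValueError(f"ROI {roi!r} has no data")
    ordered = {roi: groups[roi] for roi in roi_map}
    return _stats_table(ordered, alternative, "roi")


def channelwise_stats(responses: pd.DataFrame, alternative: str = "greater") -> pd.DataFrame:
    """Per-channel one-tailed t-table with FDR across channels."""
    groups = {}
    for ch, grp in responses.groupby("channel"):
        vals = grp["response"].dropna().to_numpy()
        if vals.size >= 2 and vals.std(ddof=1) > 0:
            groups[int(ch)] = vals
    if not groups:
        raise ValueError("no channel has enough responses")
    return _stats_table(groups, alternative, "channel")


def unit_stats(values, alternative: str = "greater") -> dict:
    """Single-sample summary: t, df, p, d, power for one unit (ROI or channel)."""
    t, df, p = one_sample_t(values, alternative)
    d = cohens_d(values)
    return {"t": t, "df": df, "p": p, "d": d, "power": posthoc_power(d, df + 1, alternative=alternative)}


# ---------------------------------------------------------------------------
# model front end


class SustainedAttentionModel:
    """Group-level model of peak-window responses.

    Parameters
    ----------
    responses
        Tidy per-participant, per-channel response table (columns
        participant, channel, response), typically from
        :func:`natattn.epoching.peak_window_mean`.
    roi_map
        ROI name -> channel list; defaults to the packaged map.
    adjacency
        Channel adjacency (``{channel: set(neighbors)}``) enabling the
        cluster permutation test; optional.
    chromophore
        'hbo' (tests an increase) or 'hbr' (tests a decrease).
    """

    def __init__(
        self,
        responses: pd.DataFrame,
        roi_map: dict[str, list[int]] | None = None,
        adjacency: dict[int, set[int]] | None = None,
        chromophore: str = "hbo",
    ) -> None:
        if chromophore not in ("hbo", "hbr"):
            raise ValueError("chromophore must be 'hbo' or 'hbr'")
        self.responses = responses
        self.roi_map = roi_map if roi_map is not None else load_roi_map()
        self.adjacency = adjacency
        self.chromophore = chromophore
        self.alternative = "greater" if chromophore == "hbo" else "less"

    @classmethod
    def from_blocks(cls, blocks, params=None, **kwargs) -> "SustainedAttentionModel":
        """Build directly from epoched blocks via the peak-window statistic."""
        from .epoching import EpochParams, peak_window_mean

        params = params or EpochParams()
        chromophore = kwargs.get("chromophore", "hbo")
        responses = peak_window_mean(blocks, params, chromophore)
        return cls(responses, **kwargs)

    def fit(
        self,
        cluster_threshold: float = 2.0,
        n_perm: int = 1000,
        seed: int | None = None,
    ) -> "SustainedAttentionResults":
        """Run ROI tests, channel tests, and (if adjacency given) the cluster test."""
        roi_table = roi_stats(self.responses, self.roi_map, self.alternative)
        channel_table = channelwise_stats(self.responses, self.alternative)
        clusters = None
        if self.adjacency is not None:
            from .cluster import cluster_test

            clusters = cluster_test(
                self.responses,
                self.adjacency,
                threshold=cluster_threshold,
                n_perm=n_perm,
                seed=seed,
                alternative=self.alternative,
            )
        return SustainedAttentionResults(self, roi_table, channel_table, clusters)


@dataclass
class SustainedAttentionResults:
    """Fitted group-level results with a printable summary."""

    model: SustainedAttentionModel
    roi_table: pd.DataFrame
    channel_table: pd.DataFrame
    clusters: list | None = None

    def significant_rois(self, alpha: float = 0.05, corrected: bool = False) -> list[str]:
        col = "q" if corrected else "p"
        return list(self.roi_table.loc[self.roi_table[col] < alpha, "roi"])

    def summary(self) -> str:
        chrom = self.model.chromophore.upper()
        direction = "increase" if self.model.alternative == "greater" else "decrease"
        lines = [
            f"Sustained-attention group inference ({chrom}, one-tailed {direction})",
            "=" * 68,
            "ROI results (FDR across ROIs):",
        ]
        tab = self.roi_table.copy()
        for col, fmt in (("mean", "{:.3e}"), ("sd", "{:.3e}")):
            tab[col] = tab[col].map(fmt.format)
        for col in ("t", "d", "power"):
            tab[col] = tab[col].map("{:.3f}".format)
        for col in ("p", "q"):
            tab[col] = tab[col].map("{:.3f}".format)
        lines.append(tab.to_string(index=False))
        sig = self.channel_table[self.channel_table["p"] < 0.05]
        lines.append("")
        lines.append(
            f"Channels with uncorrected p < 0.05: "
            f"{sorted(sig['channel'].tolist()) if len(sig) else 'none'}"
        )
        if self.clusters is not None:
            lines.append("")
            if self.clusters:
                for c in self.clusters:
                    lines.append(
                        f"Cluster {sorted(c.channels)}: mass={c.mass:.2f}, "
                        f"p={c.p_cluster:.4g} ({c.n_perm} permutations)"
                    )
            else:
                lines.append("No supra-threshold cluster.")
        return "\n".join(lines)
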