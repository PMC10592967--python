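"""Dose-response analysis of intron-specific inhibitor resistance.

Raw splicing efficiencies at each inhibitor dose are normalised to the
no-drug (DMSO) control so each intron's uninhibited efficiency reads as
100%; introns are then ranked within each non-zero dose (rank 1 = most
resistant), the per-dose ranks averaged into an "average rank", split
into quintiles by intrinsic efficiency, and hierarchically clustered on
their relative dose-response profiles into sensitivity groups.

The model object follows the statsmodels convention: build a
:class:`DoseResponseModel` from a long-format SE table, call ``fit()``,
and read estimates off the returned :class:`DoseResponseResults`.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "DoseResponseModel",
    "DoseResponseResults",
    "relative_se",
    "rank_resistance",
    "assign_quintiles",
    "cluster_profiles",
    "bp_variant_rank_summary",
    "drug_delta",
    "covariate_correlation",
    "uncentered_correlation_distance",
]

logger = logging.getLogger(__name__)

GROUP_MOST_RESISTANT = "most_resistant"
GROUP_INTERMEDIATE = "intermediate"
GROUP_MOST_SENSITIVE = "most_sensitive"


def relative_se(se_dose: float, se_dmso: float) -> float:
    """Relative SE: 100 * SE(dose) / SE(DMSO).

    Values above 100 (splicing improved under drug) are legitimate and
    preserved. Undefined (NaN) when the DMSO efficiency is zero.
    """
    se_dose = np.asarray(se_dose, dtype=float)
    se_dmso = np.asarray(se_dmso, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(se_dmso > 0, 100.0 * se_dose / se_dmso, np.nan)
    return float(out) if out.ndim == 0 else out


def rank_resistance(rel_se: pd.DataFrame) -> pd.DataFrame:
    """Rank introns by resistance within each dose and average the ranks.

    ``rel_se`` is a wide table (index = event_id, one column per non-zero
    dose of relative SE). Rank 1 = highest relative SE (most resistant);
    ties receive the mean rank. Events missing any dose are excluded.
    Returns a frame with per-dose ``rank_<col>`` columns and
    ``average_rank``, sorted by average rank.
    """
    complete = rel_se.dropna()
    excluded = rel_se.index.difference(complete.index)
    if len(excluded):
        logger.info("rank_resistance: %d events missing a dose, excluded", len(excluded))
    ranks = pd.DataFrame(index=complete.index)
    for col in complete.columns:
        ranks[f"rank_{col}"] = stats.rankdata(-complete[col].to_numpy(), method="average")
    ranks["average_rank"] = ranks.mean(axis=1)
    return ranks.sort_values("average_rank")


def assign_quintiles(values: pd.Series) -> pd.Series:
    """Split events into 5 equal-frequency bins (1 = highest values).

    Ties are broken by average rank before binning so every event gets a
    label even with duplicated values. Refuses fewer than 5 events.
    """
    values = values.dropna()
    if len(values) < 5:
        raise ValueError("need at least 5 events to form quintiles")
    # rank descending so quintile 1 = most efficient
    r = stats.rankdata(-values.to_numpy(), method="ordinal")
    q = np.ceil(5 * r / len(values)).astype(int)
    return pd.Series(q, index=values.index, name="quintile")


def uncentered_correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed pairwise distance 1 - <xi, xj> / (|xi| |xj|).

    The uncentered Pearson distance of classic gene-expression clustering
    tools: cosine distance without mean-centering, so profiles with the
    same shape *and* magnitude cluster together.
    """
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0] = 1.0
    xn = x / norms[:, None]
    sim = np.clip(xn @ xn.T, -1.0, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return squareform(d, checks=False)


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 3,
    metric: str = "uncentered",
    method: str = "average",
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchically cluster relative-SE profiles and cut into k groups.

    metric='uncentered' (default) uses uncentered-Pearson distance;
    'euclidean' is offered as an alternative. Groups are named by their
    mean relative SE: the highest-mean group is 'most_resistant', the
    lowest 'most_sensitive', any others 'intermediate'.

    Returns (linkage matrix, group labels indexed like profiles).
    """
    x = profiles.to_numpy(dtype=float)
    n = len(profiles)
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles n={n}")
    if metric == "uncentered":
        dist = uncentered_correlation_distance(x)
        z = hierarchy.linkage(dist, method=method)
    else:
        z = hierarchy.linkage(x, method=method, metric=metric)
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    means = (
        pd.Series(x.mean(axis=1), index=profiles.index)
        .groupby(flat)
        .mean()
        .sort_values(ascending=False)
    )
    names = {}
    ordered = list(means.index)
    for i, cl in enumerate(ordered):
        if i == 0:
            names[cl] = GROUP_MOST_RESISTANT
        elif i == len(ordered) - 1:
            names[cl] = GROUP_MOST_SENSITIVE
        elif len(ordered) == 3:
            names[cl] = GROUP_INTERMEDIATE
        else:
            names[cl] = f"{GROUP_INTERMEDIATE}_{i}"
    labels = pd.Series(
        [names[c] for c in flat], index=profiles.index, name="cluster_group"
    )
    return z, labels


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialise a SciPy linkage matrix as a Newick tree string."""
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(z, leaf_names)
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def bp_variant_rank_summary(
    ranks: pd.Series, is_variant: pd.Series
) -> dict:
    """Summarise where variant-branch-point introns fall in the resistance ranking.

    Counts how many variant-BP introns have an average rank in the bottom
    third of all ranked introns (rank > ceil(2n/3)) and attaches a
    hypergeometric tail probability for observing at least that many —
    the test is an addition beyond the raw count and is labelled as such.
    """
    ranks = ranks.dropna()
    is_variant = is_variant.reindex(ranks.index).fillna(False).astype(bool)
    n = len(ranks)
    n_variant = int(is_variant.sum())
    if n_variant == 0:
        return {"n_ranked": n, "n_variant": 0}
    boundary = int(np.ceil(2 * n / 3))
    in_bottom = ranks > boundary
    n_bottom_total = int(in_bottom.sum())
    count = int((in_bottom & is_variant).sum())
    # P(X >= count) for X ~ Hypergeom(N=n, K=n_variant, n=n_bottom_total)
    p_tail = float(stats.hypergeom.sf(count - 1, n, n_variant, n_bottom_total))
    return {
        "n_ranked": n,
        "n_variant": n_variant,
        "bottom_third_boundary_rank": boundary,
        "n_variant_in_bottom_third": count,
        "hypergeometric_tail_p": p_tail,
        "note": "tail probability is an addition beyond the raw count",
    }


def drug_delta(rel_se_a: pd.Series, rel_se_b: pd.Series) -> pd.Series:
    """Per-intron difference in relative SE between two drugs (A - B).

    Negative values mean drug A is the more potent inhibitor on that
    intron. Events missing either measurement are skipped.
    """
    joined = pd.concat([rel_se_a, rel_se_b], axis=1, join="inner").dropna()
    out = joined.iloc[:, 0] - joined.iloc[:, 1]
    out.name = "drug_delta"
    return out


def covariate_correlation(
    resistance: pd.Series, covariate: pd.Series, method: str = "spearman_rho"
) -> dict:
    """Correlate a resistance measure with a per-gene covariate.

    method='pearson_r2' returns the squared Pearson correlation;
    'spearman_rho' returns Spearman's rho. Pairs with missing values are
    dropped and counted; zero variance in either vector yields NaN with a
    flag.
    """
    joined = pd.concat([resistance, covariate], axis=1, join="inner")
    n_dropped = int(joined.isna().any(axis=1).sum())
    joined = joined.dropna()
    x = joined.iloc[:, 0].to_numpy(float)
    y = joined.iloc[:, 1].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    out = {"n": len(x), "n_dropped": n_dropped, "method": method}
    if np.std(x) == 0 or np.std(y) == 0:
        out.update(statistic=float("nan"), p_value=float("nan"), degenerate=True)
        return out
    if method == "pearson_r2":
        res = stats.pearsonr(x, y)
        out.update(statistic=float(res.statistic**2), p_value=float(res.pvalue))
    elif method == "spearman_rho":
        res = stats.spearmanr(x, y)
        out.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    else:
        raise ValueError("method must be 'pearson_r2' or 'spearman_rho'")
    out["degenerate"] = False
    return out


class DoseResponseModel:
    """Dose-response resistance model for a set of single-intron events.

    Parameters
    ----------
    se_table : long-format frame with columns event_id, dose_uM, SE
        (one row per event per dose; replicates already averaged).
    doses : the dose grid in uM; the first must be 0 (DMSO).
    annotations : optional per-event frame (indexed by event_id) carrying
        ``n_introns`` (multi-intron genes are quantified upstream but
        excluded here) and ``bp_is_consensus`` for the variant-BP summary.
    """

    def __init__(
        self,
        se_table: pd.DataFrame,
        doses: tuple[float, ...] = (0.0, 0.5, 5.0),
        annotations: pd.DataFrame | None = None,
    ):
        doses = tuple(float(d) for d in doses)
        if doses[0] != 0.0:
            raise ValueError("doses[0] must be the 0 uM (DMSO) control")
        self.doses = doses
        self.annotations = annotations
        required = {"event_id", "dose_uM", "SE"}
        missing = required - set(se_table.columns)
        if missing:
            raise ValueError(f"se_table missing columns: {sorted(missing)}")
        self.se_wide = (
            se_table.pivot_table(index="event_id", columns="dose_uM", values="SE")
            .reindex(columns=list(doses))
        )
        if annotations is not None and "n_introns" in annotations.columns:
            multi = annotations.index[annotations["n_introns"] > 1]
            dropped = self.se_wide.index.intersection(multi)
            if len(dropped):
                logger.info(
                    "excluding %d multi-intron events from dose-response", len(dropped)
                )
            self.se_wide = self.se_wide.drop(index=dropped)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "DoseResponseModel":
        from intronsens.cli_io import read_table

        return cls(read_table(path), **kwargs)

    def fit(
        self,
        k: int = 3,
        metric: str = "uncentered",
        linkage_method: str = "average",
    ) -> "DoseResponseResults":
        """Normalise, rank, bin and cluster; returns the results object."""
        se = self.se_wide
        dmso = se[self.doses[0]]
        quantifiable = dmso > 0
        n_excluded = int((~quantifiable | dmso.isna()).sum())
        if n_excluded:
            logger.info(
                "%d events with zero/missing DMSO SE excluded from normalisation",
                n_excluded,
            )
        se = se.loc[quantifiable.fillna(False)]
        dmso = se[self.doses[0]]

        prof = pd.DataFrame(index=se.index)
        prof["SE_0"] = dmso
        rel_cols = []
        for d in self.doses[1:]:
            tag = str(d).rstrip("0").rstrip(".").replace(".", "")
            prof[f"SE_{tag}"] = se[d]
            rel = relative_se(se[d].to_numpy(), dmso.to_numpy())
            prof[f"relSE_{tag}"] = rel
            rel_cols.append(f"relSE_{tag}")
        if len(self.doses) >= 2:
            low_tag = str(self.doses[1]).rstrip("0").rstrip(".").replace(".", "")
            prof["dSE_05" if low_tag == "05" else f"dSE_{low_tag}"] = (
                prof["SE_0"] - prof[f"SE_{low_tag}"]
            )
        prof["improved_flag"] = (prof[rel_cols] > 100).any(axis=1)

        ranks = rank_resistance(prof[rel_cols])
        prof = prof.join(ranks)
        prof["quintile"] = assign_quintiles(prof["SE_0"])

        clusterable = prof[rel_cols].dropna()
        z, labels = cluster_profiles(
            clusterable, k=k, metric=metric, method=linkage_method
        )
        prof["cluster_group"] = labels

        return DoseResponseResults(
            model=self,
            profiles=prof,
            rel_cols=rel_cols,
            linkage=z,
            linkage_index=list(clusterable.index),
            k=k,
        )


@dataclass
class DoseResponseResults:
    """Fitted dose-response profiles, ranks, quintiles and cluster groups."""

    model: DoseResponseModel
    profiles: pd.DataFrame
    rel_cols: list[str]
    linkage: np.ndarray
    linkage_index: list[str]
    k: int
    _bp_summary: dict | None = field(default=None, repr=False)

    @property
    def average_rank(self) -> pd.Series:
        return self.profiles["average_rank"]

    def newick(self) -> str:
        """The cluster dendrogram in Newick format."""
        return linkage_to_newick(self.linkage, self.linkage_index)

    def bp_variant_summary(self, bp_is_consensus: pd.Series | None = None) -> dict:
        """Where do variant-branch-point introns fall in the ranking?"""
        if bp_is_consensus is None:
            ann = self.model.annotations
            if ann is None or "bp_is_consensus" not in ann.columns:
                raise ValueError("bp_is_consensus flags not provided")
            bp_is_consensus = ann["bp_is_consensus"]
        is_variant = ~bp_is_consensus.astype(bool)
        return bp_variant_rank_summary(self.profiles["average_rank"], is_variant)

    def plot_profiles(self, ax=None):
        """Relative-SE dose-response lines coloured by cluster group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        doses = self.model.doses
        palette = {
            GROUP_MOST_RESISTANT: "goldenrod",
            GROUP_INTERMEDIATE: "black",
            GROUP_MOST_SENSITIVE: "steelblue",
        }
        for _, row in self.profiles.iterrows():
            ys = [100.0] + [row[c] for c in self.rel_cols]
            color = palette.get(row["cluster_group"], "grey")
            ax.plot(doses, ys, color=color, alpha=0.25, lw=0.8)
        ax.set_xlabel("dose (uM)")
        ax.set_ylabel("relative SE (%)")
        ax.set_title("dose-response by cluster group")
        return ax

    def summary(self) -> str:
        prof = self.profiles
        lines = [
            "Dose-response resistance summary",
            "=" * 38,
            f"events analysed:        {len(prof)}",
            f"doses (uM):             {list(self.model.doses)}",
            f"cluster groups (k={self.k}):",
        ]
        for g, cnt in prof["cluster_group"].value_counts().items():
            sub = prof.loc[prof["cluster_group"] == g, self.rel_cols]
            lines.append(
                f"  {g:<16} n={cnt:<5d} mean relSE={sub.mean().mean():6.1f}%"
            )
        top = prof.nsmallest(5, "average_rank")
        lines.append("most resistant introns (by average rank):")
        for ev, row in top.iterrows():
            lines.append(
                f"  {ev:<16} avg rank {row['average_rank']:6.1f}  "
                + "  ".join(f"{c}={row[c]:6.1f}" for c in self.rel_cols)
            )
        return "\n".join(lines)
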