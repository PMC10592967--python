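"""Co-transcriptional splicing curves from single-molecule intron tracking.

SMIT reads report, for one nascent transcript, the Pol II 3'-end position
(taken as the polymerase's position, in nt relative to the 3' splice
site) and whether the intron has been excised. Binning reads by position
gives the raw fraction spliced versus polymerase position. Because the
library captures molecules with probability depending on insert length,
and a spliced molecule is shorter than an unspliced one at the same
polymerase position by exactly the intron length, the raw fraction is
biased; it is corrected by re-weighting with the insert-length
probability law evaluated at the two product lengths.

Resistance to an inhibitor is quantified as the area under the corrected
curve within a 200-nt window anchored at the gene-specific onset of
splicing, compared between treated and control conditions:
``delta_AUC = 1 - AUC_treated / AUC_control`` and co-transcriptional
resistance ``CTX = (1 - delta_AUC) * 100%``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsertLengthDist",
    "SmitCurve",
    "SmitComparison",
    "SmitModel",
    "SmitResults",
    "raw_fraction_spliced",
    "estimate_insert_dist",
    "normalize_fraction_spliced",
    "detect_onset",
    "windowed_auc",
    "delta_auc",
    "wilcoxon_paired",
    "average_comparisons",
]

logger = logging.getLogger(__name__)


@dataclass
class InsertLengthDist:
    """Probability mass per insert length over a bounded support [L_min, L_max]."""

    lengths: np.ndarray
    pmf: np.ndarray
    source_reads: int = 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.pmf = np.asarray(self.pmf, dtype=float)
        if np.any(self.pmf < 0):
            raise ValueError("probability masses must be non-negative")
        total = self.pmf.sum()
        if not np.isclose(total, 1.0):
            self.pmf = self.pmf / total

    @property
    def support(self) -> tuple[int, int]:
        return int(self.lengths[0]), int(self.lengths[-1])

    def prob(self, length):
        """P(insert length); zero outside the support."""
        scalar = np.isscalar(length)
        idx = np.atleast_1d(np.asarray(length, dtype=int)) - self.support[0]
        valid = (idx >= 0) & (idx < len(self.pmf))
        out = np.where(valid, self.pmf[np.clip(idx, 0, len(self.pmf) - 1)], 0.0)
        return float(out[0]) if scalar else out

    @classmethod
    def from_normal(
        cls, mean: float, sd: float, support: tuple[int, int]
    ) -> "InsertLengthDist":
        lo, hi = support
        lengths = np.arange(lo, hi + 1)
        pmf = stats.norm.pdf(lengths, loc=mean, scale=sd)
        return cls(lengths, pmf / pmf.sum())


def estimate_insert_dist(
    reads: pd.DataFrame,
    support: tuple[int, int] | None = None,
    pseudocount: float = 0.5,
    min_reads: int = 200,
) -> InsertLengthDist:
    """Estimate the insert-length law from observed reads.

    Histogram over the support (default: observed min..max insert length)
    with pseudocount smoothing, normalised to sum to 1. Reads are pooled
    across genes and conditions; refuses fewer than ``min_reads``.
    """
    ins = reads["insert_len"].to_numpy(int)
    if len(ins) < min_reads:
        raise ValueError(
            f"need >= {min_reads} reads to estimate insert-length law, got {len(ins)}"
        )
    if support is None:
        support = (int(ins.min()), int(ins.max()))
    lo, hi = support
    lengths = np.arange(lo, hi + 1)
    counts = np.bincount(np.clip(ins, lo, hi) - lo, minlength=len(lengths)).astype(float)
    counts += pseudocount
    return InsertLengthDist(lengths, counts / counts.sum(), source_reads=len(ins))


@dataclass
class SmitCurve:
    """Fraction-spliced-versus-position curve for one gene and condition.

    ``bins`` columns: position (bin centre, nt relative to the 3'SS),
    raw (raw fraction spliced, NaN where empty), norm (bias-corrected
    fraction, filled by :func:`normalize_fraction_spliced`), n_spliced,
    n_unspliced, n (reads per bin), reliable (capture weights above
    floor).
    """

    gene_id: str
    condition: str
    bin_width: int
    bins: pd.DataFrame

    @property
    def positions(self) -> np.ndarray:
        return self.bins["position"].to_numpy()


def raw_fraction_spliced(
    reads: pd.DataFrame, bin_width: int = 10
) -> SmitCurve:
    """Bin reads of one gene/condition by Pol II position; raw fraction per bin.

    Reads flagged spliced at positions upstream of the 3'SS are physically
    impossible (the splice site has not been transcribed); they are
    counted and excluded. Empty bins carry NaN.
    """
    if reads.empty:
        return SmitCurve(
            gene_id="", condition="", bin_width=bin_width,
            bins=pd.DataFrame(
                columns=["position", "raw", "norm", "n_spliced", "n_unspliced", "n", "reliable"]
            ),
        )
    gene = str(reads["gene_id"].iloc[0])
    cond = str(reads["condition"].iloc[0])
    bad = (reads["polII_pos"] < 0) & (reads["spliced"] == 1)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning(
            "%s/%s: %d spliced reads upstream of the 3'SS excluded", gene, cond, n_bad
        )
    reads = reads.loc[~bad]
    pos = reads["polII_pos"].to_numpy(int)
    spl = reads["spliced"].to_numpy(int)
    bin_idx = np.floor_divide(pos, bin_width)
    lo, hi = bin_idx.min(), bin_idx.max()
    rows = []
    for b in range(lo, hi + 1):
        m = bin_idx == b
        n = int(m.sum())
        ns = int(spl[m].sum())
        rows.append(
            {
                "position": b * bin_width + bin_width / 2.0,
                "raw": (ns / n) if n else np.nan,
                "norm": np.nan,
                "n_spliced": ns,
                "n_unspliced": n - ns,
                "n": n,
                "reliable": True,
            }
        )
    return SmitCurve(gene_id=gene, condition=cond, bin_width=bin_width,
                     bins=pd.DataFrame(rows))


def normalize_fraction_spliced(
    curve: SmitCurve,
    dist: InsertLengthDist,
    intron_length: int,
    primer_offset: int,
    weight_floor: float = 1e-3,
    max_weight_ratio: float = 10.0,
    max_se: float = 0.02,
) -> SmitCurve:
    """Invert the insert-length capture bias on a raw curve.

    At polymerase position x the unspliced product has length
    ``L_u = primer_offset + x`` and the spliced product
    ``L_s = L_u - intron_length``. Their capture weights are the
    insert-law masses summed over the integer positions of the bin. The
    corrected fraction is the odds inversion

        f = f_raw * w_u / (f_raw * w_u + (1 - f_raw) * w_s),

    which undoes over-capture of the shorter (spliced) product; raw
    fractions of exactly 0 or 1 are fixed points of the inversion.

    A corrected value is computed only where it is identifiable: both
    capture weights at least ``weight_floor`` of the law's peak mass,
    within ``max_weight_ratio``-fold of each other, and a positive
    spliced-product length. Elsewhere the bin gets NaN; the
    windowed-AUC step interpolates across such bins or withholds the
    gene when too much of the window is missing.

    A computed bin is additionally flagged *reliable* when its
    delta-method standard error (binomial noise in the raw fraction
    amplified through the inversion, assessed at the Jeffreys midpoint
    so raw fractions of exactly 0/1 are not treated as noiseless) is at
    most ``max_se`` — i.e. when the point estimate itself, not just the
    procedure, can be trusted.
    """
    bins = curve.bins.copy()
    half = curve.bin_width / 2.0
    peak = dist.pmf.max()
    floor = weight_floor * peak
    norm = np.full(len(bins), np.nan)
    norm_se = np.full(len(bins), np.nan)
    reliable = np.ones(len(bins), dtype=bool)
    for i, row in enumerate(bins.itertuples(index=False)):
        n = row.n
        xs = np.arange(int(np.floor(row.position - half)), int(np.floor(row.position + half)))
        l_u = primer_offset + xs
        l_s = l_u - intron_length
        if np.all(l_s <= 0):
            reliable[i] = False
            continue
        w_u = float(np.sum(dist.prob(l_u)))
        w_s = float(np.sum(dist.prob(l_s[l_s > 0])))
        if (
            w_u < floor
            or w_s < floor
            or w_u <= 0
            or w_s <= 0
            or max(w_u, w_s) > max_weight_ratio * min(w_u, w_s)
            or n == 0
            or np.isnan(row.raw)
        ):
            reliable[i] = False
            continue
        f_raw = row.raw
        denom = f_raw * w_u + (1.0 - f_raw) * w_s
        norm[i] = f_raw * w_u / denom
        # delta method at the Jeffreys midpoint: d(norm)/d(raw) = w_u w_s / denom^2
        f_j = (row.n_spliced + 0.5) / (n + 1.0)
        denom_j = f_j * w_u + (1.0 - f_j) * w_s
        se = (w_u * w_s / denom_j**2) * np.sqrt(f_j * (1.0 - f_j) / n)
        norm_se[i] = se
        if se > max_se:
            reliable[i] = False
    bins["norm"] = norm
    bins["norm_se"] = norm_se
    bins["reliable"] = reliable
    return SmitCurve(curve.gene_id, curve.condition, curve.bin_width, bins)


def detect_onset(
    curve: SmitCurve, theta: float = 0.05, w: int = 2
) -> float | None:
    """Gene-specific onset of splicing on a normalised control curve.

    The smallest bin centre x >= 0 whose corrected fraction exceeds
    ``theta`` for ``w`` consecutive non-missing bins. Returns None when
    no bin qualifies (gene excluded from AUC analysis).
    """
    bins = curve.bins
    sel = bins["position"] >= 0
    pos = bins.loc[sel, "position"].to_numpy()
    f = bins.loc[sel, "norm"].to_numpy()
    above = f > theta  # NaN compares False
    for i in range(len(pos) - w + 1):
        if above[i : i + w].all():
            return float(pos[i])
    return None


def windowed_auc(
    curve: SmitCurve,
    onset: float,
    window_len: float = 200.0,
    max_missing_frac: float = 0.5,
) -> float | None:
    """Trapezoidal area under the corrected curve over [onset, onset+window].

    Missing bins inside the window are linearly interpolated when they
    make up at most ``max_missing_frac`` of the window; otherwise the
    gene is flagged and the AUC withheld (None). Units: nt * fraction.
    """
    bins = curve.bins
    m = (bins["position"] >= onset) & (bins["position"] <= onset + window_len)
    pos = bins.loc[m, "position"].to_numpy(float)
    f = bins.loc[m, "norm"].to_numpy(float)
    if len(pos) < 2:
        return None
    missing = np.isnan(f)
    if missing.mean() > max_missing_frac:
        logger.warning(
            "%s/%s: %.0f%% of window bins missing; AUC withheld",
            curve.gene_id, curve.condition, 100 * missing.mean(),
        )
        return None
    # integrate over the exact window: curve value at the bounds comes from
    # interpolation across all non-missing bins (constant beyond the ends)
    all_pos = bins["position"].to_numpy(float)
    all_f = bins["norm"].to_numpy(float)
    known = ~np.isnan(all_f)
    grid = np.concatenate(([onset], pos, [onset + window_len]))
    grid = np.unique(grid)
    vals = np.interp(grid, all_pos[known], all_f[known])
    return float(np.trapezoid(vals, grid))


def delta_auc(auc_control: float, auc_treated: float) -> tuple[float, float]:
    """Fractional AUC loss and co-transcriptional resistance.

    ``delta = 1 - AUC_treated / AUC_control``;
    ``ctx_resistance = (AUC_treated / AUC_control) * 100`` percent.
    Resistance above 100% (treated curve larger) is legitimate and
    preserved. Undefined when the control AUC is zero.
    """
    if auc_control is None or auc_control <= 0:
        raise ValueError("control AUC must be positive")
    ratio = auc_treated / auc_control
    return 1.0 - ratio, 100.0 * ratio


def wilcoxon_paired(
    curve_a: SmitCurve,
    curve_b: SmitCurve,
    onset: float,
    window_len: float = 200.0,
    min_pairs: int = 5,
) -> tuple[float | None, int]:
    """Two-sided Wilcoxon signed-rank p over paired per-bin fractions.

    Pairs bins by position within the window; zero differences are
    dropped (their count is reflected in the returned pair count). Exact
    null for n <= 25, normal approximation with continuity correction
    beyond. Returns (p, n_pairs_used); p is None with fewer than
    ``min_pairs`` usable pairs.
    """
    a = curve_a.bins.set_index("position")["norm"]
    b = curve_b.bins.set_index("position")["norm"]
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    joined = joined.loc[
        (joined.index >= onset) & (joined.index <= onset + window_len)
    ]
    diffs = (joined.iloc[:, 0] - joined.iloc[:, 1]).to_numpy()
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n < min_pairs:
        return None, n
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(
        diffs, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return float(res.pvalue), n


def average_comparisons(ctx_values) -> tuple[float, bool]:
    """Best-estimate resistance: mean of the (ideally three) pairings.

    The full design compares the treated humanized strain against three
    uninhibited references (same strain + carrier, control strain +
    carrier, control strain + drug). Returns (mean, partial_flag) where
    partial marks fewer than three available comparisons.
    """
    vals = [v for v in ctx_values if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("no comparisons available")
    return float(np.mean(vals)), len(vals) < 3


@dataclass
class SmitComparison:
    """Onset/AUC/resistance summary for one gene under one condition pair."""

    gene_id: str
    condition_control: str
    condition_treated: str
    onset_pos: float
    auc_control: float
    auc_treated: float
    delta_auc: float
    ctx_resistance: float
    wilcoxon_p: float | None
    n_paired_bins: int


class SmitModel:
    """SMIT analysis model: reads + gene annotation -> curves and comparisons.

    Parameters
    ----------
    reads : frame with columns gene_id, condition, polII_pos, spliced,
        insert_len.
    genes : frame indexed by gene_id with columns intron_length and
        primer_offset.
    insert_dist : insert-length law; estimated from the pooled reads when
        None.
    """

    def __init__(
        self,
        reads: pd.DataFrame,
        genes: pd.DataFrame,
        insert_dist: InsertLengthDist | None = None,
    ):
        required = {"gene_id", "condition", "polII_pos", "spliced", "insert_len"}
        missing = required - set(reads.columns)
        if missing:
            raise ValueError(f"reads missing columns: {sorted(missing)}")
        self.reads = reads
        self.genes = genes
        self.insert_dist = insert_dist

    def fit(
        self,
        pairs: list[tuple[str, str]] | None = None,
        bin_width: int = 10,
        theta: float = 0.05,
        w: int = 2,
        window_len: float = 200.0,
    ) -> "SmitResults":
        """Build curves for every gene/condition and compare the given pairs.

        ``pairs`` lists (control_condition, treated_condition); defaults
        to pairing the first condition seen (assumed control) with each
        other condition. The splicing onset is detected on the control
        curve only, so both members of a pair share one window.
        """
        dist = self.insert_dist or estimate_insert_dist(self.reads)
        conditions = list(dict.fromkeys(self.reads["condition"]))
        if pairs is None:
            pairs = [(conditions[0], c) for c in conditions[1:]]

        curves: dict[tuple[str, str], SmitCurve] = {}
        for (gene, cond), sub in self.reads.groupby(["gene_id", "condition"], sort=False):
            if gene not in self.genes.index:
                logger.warning("gene %s absent from annotation; skipped", gene)
                continue
            raw = raw_fraction_spliced(sub, bin_width=bin_width)
            g = self.genes.loc[gene]
            curves[(gene, cond)] = normalize_fraction_spliced(
                raw, dist,
                intron_length=int(g["intron_length"]),
                primer_offset=int(g["primer_offset"]),
            )

        comparisons: list[SmitComparison] = []
        excluded: list[dict] = []
        genes_seen = list(dict.fromkeys(g for g, _ in curves))
        for gene in genes_seen:
            for ctrl, trt in pairs:
                c_ctrl = curves.get((gene, ctrl))
                c_trt = curves.get((gene, trt))
                if c_ctrl is None or c_trt is None:
                    excluded.append({"gene_id": gene, "pair": (ctrl, trt),
                                     "reason": "missing curve"})
                    continue
                onset = detect_onset(c_ctrl, theta=theta, w=w)
                if onset is None:
                    excluded.append({"gene_id": gene, "pair": (ctrl, trt),
                                     "reason": "no splicing onset"})
                    continue
                auc_c = windowed_auc(c_ctrl, onset, window_len)
                auc_t = windowed_auc(c_trt, onset, window_len)
                if auc_c is None or auc_t is None or auc_c <= 0:
                    excluded.append({"gene_id": gene, "pair": (ctrl, trt),
                                     "reason": "AUC withheld"})
                    continue
                d_auc, ctx = delta_auc(auc_c, auc_t)
                p, n_pairs = wilcoxon_paired(c_ctrl, c_trt, onset, window_len)
                comparisons.append(
                    SmitComparison(
                        gene_id=gene,
                        condition_control=ctrl,
                        condition_treated=trt,
                        onset_pos=onset,
                        auc_control=auc_c,
                        auc_treated=auc_t,
                        delta_auc=d_auc,
                        ctx_resistance=ctx,
                        wilcoxon_p=p,
                        n_paired_bins=n_pairs,
                    )
                )
        return SmitResults(
            model=self, insert_dist=dist, curves=curves,
            comparisons=comparisons, excluded=excluded,
            window_len=window_len,
        )


@dataclass
class SmitResults:
    """Fitted SMIT curves and per-gene resistance comparisons."""

    model: SmitModel
    insert_dist: InsertLengthDist
    curves: dict[tuple[str, str], SmitCurve]
    comparisons: list[SmitComparison]
    excluded: list[dict]
    window_len: float
    _table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def comparison_table(self) -> pd.DataFrame:
        if self._table is None:
            self._table = pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "control": c.condition_control,
                        "treated": c.condition_treated,
                        "onset": c.onset_pos,
                        "auc_control": c.auc_control,
                        "auc_treated": c.auc_treated,
                        "delta_auc": c.delta_auc,
                        "ctx_resistance": c.ctx_resistance,
                        "wilcoxon_p": c.wilcoxon_p,
                        "n_paired_bins": c.n_paired_bins,
                    }
                    for c in self.comparisons
                ]
            )
        return self._table

    def best_estimate(self, gene_id: str) -> tuple[float, bool]:
        """Mean CTX resistance over this gene's available comparisons."""
        vals = [
            c.ctx_resistance for c in self.comparisons if c.gene_id == gene_id
        ]
        return average_comparisons(vals)

    def plot_gene(self, gene_id: str, ax=None):
        """Raw and corrected fraction-spliced curves for one gene."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for (g, cond), curve in self.curves.items():
            if g != gene_id:
                continue
            b = curve.bins
            ax.plot(b["position"], b["raw"], ":", alpha=0.6, label=f"{cond} raw")
            ax.plot(b["position"], b["norm"], "-", label=f"{cond} corrected")
        ax.set_xlabel("Pol II position rel. 3'SS (nt)")
        ax.set_ylabel("fraction spliced")
        ax.set_ylim(-0.05, 1.05)
        ax.legend(fontsize=7)
        ax.set_title(gene_id)
        return ax

    def summary(self) -> str:
        tbl = self.comparison_table
        lines = [
            "SMIT co-transcriptional splicing summary",
            "=" * 44,
            f"genes with comparisons:   {tbl['gene_id'].nunique() if len(tbl) else 0}",
            f"comparisons computed:     {len(tbl)}",
            f"genes excluded:           {len(self.excluded)}",
            f"AUC window length (nt):   {self.window_len:.0f}",
        ]
        if len(tbl):
            lines.append(
                f"median CTX resistance:    {tbl['ctx_resistance'].median():.1f}%"
            )
            lines.append("per-gene comparisons:")
            for _, r in tbl.iterrows():
                p = "NA" if r["wilcoxon_p"] is None or np.isnan(r["wilcoxon_p"]) else f"{r['wilcoxon_p']:.3g}"
                lines.append(
                    f"  {r['gene_id']:<10} {r['control']}->{r['treated']:<10} "
                    f"onset={r['onset']:6.1f}  dAUC={r['delta_auc']:+.3f}  "
                    f"CTX={r['ctx_resistance']:6.1f}%  p={p}"
                )
        return "\n".join(lines)
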