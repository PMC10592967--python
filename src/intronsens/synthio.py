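"""Synthetic junction-count tables and SMIT read sets with known ground truth.

The generator emulates, at desk scale, the statistical structure of two
experiment types:

* bulk RNA-seq junction counting: per intron, per dose, per replicate, a
  negative-binomial total read count split binomially between exon-exon
  junction reads (spliced) and intron-exon boundary reads (unspliced),
  with the spliced probability equal to the intron's intrinsic splicing
  efficiency attenuated by a per-dose multiplicative inhibition factor;

* SMIT (single-molecule intron tracking): nascent-transcript molecules
  whose Pol II 3'-end position is sampled along the gene, whose spliced
  state follows a position-dependent logistic splicing curve, and whose
  capture probability depends on the molecule (insert) length through a
  unimodal insert-length law — the bias the analysis-side normaliser
  inverts.

All randomness flows from ``SimConfig.seed``; identical configs yield
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "simulate_junction_counts",
    "simulate_smit_reads",
    "designed_smit_panel",
]

#: consensus yeast branch-point sequence (DNA alphabet)
BP_CONSENSUS = "TACTAAC"


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic generator.

    Junction-count truth
    --------------------
    n_introns : number of single-intron events to simulate.
    doses : ascending inhibitor concentrations in uM; the first must be 0
        (the DMSO carrier control).
    n_replicates : biological replicates per dose.
    expression_depth : expected total informative read count per event
        (scalar or per-intron array); negative-binomial mean.
    dispersion : negative-binomial dispersion alpha (var = mu + alpha mu^2);
        0 gives Poisson totals.
    intrinsic_se : per-intron uninhibited splicing efficiency in percent,
        in (0, 100]; drawn Uniform(30, 95) when None.
    sensitivity : per-intron, per-dose inhibition fraction in [0, 1]
        (0 = unaffected, 1 = fully blocked), shape (n_introns, n_doses);
        dose 0 is forced to 0. Drawn non-decreasing in dose when None.

    SMIT truth
    ----------
    n_genes : number of SMIT-primed genes.
    reads_per_gene : retained molecules to aim for per gene and condition.
    midpoint, slope, f_max : logistic splicing-curve parameters per gene
        (nt downstream of the 3'SS, nt, fraction); drawn when None.
    intron_length : per-gene intron length in nt; drawn Uniform(100, 400)
        when None (typical yeast single-intron genes).
    primer_offset : distance in transcript coordinates from the
        gene-specific capture primer to the 3'SS, nt.
    insert_mean, insert_sd, insert_support : discretised-normal
        insert-length law (capture bias); support bounds in nt.
    pol_window : Pol II positions sampled uniformly over this window
        relative to the 3'SS, covering pre-3'SS (necessarily unspliced)
        territory and the 200-nt analysis window with margin.
    smit_conditions : mapping condition name -> multiplicative factor
        applied to the true splicing curve (1.0 = uninhibited control).
    """

    n_introns: int = 50
    doses: tuple[float, ...] = (0.0, 0.5, 5.0)
    n_replicates: int = 2
    expression_depth: float | np.ndarray = 1000.0
    dispersion: float = 0.05
    intrinsic_se: np.ndarray | None = None
    sensitivity: np.ndarray | None = None
    strain: str = "hsh155-ds"
    treatment: str = "Plad-B"

    n_genes: int = 8
    reads_per_gene: int = 3000
    midpoint: np.ndarray | None = None
    slope: np.ndarray | None = None
    f_max: np.ndarray | None = None
    intron_length: np.ndarray | None = None
    primer_offset: int = 150
    insert_mean: float = 250.0
    insert_sd: float = 60.0
    insert_support: tuple[int, int] = (100, 600)
    pol_window: tuple[int, int] = (-100, 500)
    smit_conditions: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "treated": 0.5}
    )

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_introns <= 0:
            raise ValueError("n_introns must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        doses = tuple(float(d) for d in self.doses)
        if list(doses) != sorted(doses):
            raise ValueError("doses must be sorted ascending")
        if doses[0] != 0.0:
            raise ValueError("doses[0] must be 0 (DMSO control)")
        depth = np.atleast_1d(np.asarray(self.expression_depth, dtype=float))
        if np.any(depth <= 0):
            raise ValueError("expression_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.intrinsic_se is not None:
            se = np.asarray(self.intrinsic_se, dtype=float)
            if np.any(se <= 0) or np.any(se > 100):
                raise ValueError("intrinsic_se must lie in (0, 100]")
        if self.sensitivity is not None:
            s = np.asarray(self.sensitivity, dtype=float)
            if np.any(s < 0) or np.any(s > 1):
                raise ValueError("sensitivity must lie in [0, 1]")
        if self.f_max is not None:
            fm = np.asarray(self.f_max, dtype=float)
            if np.any(fm <= 0) or np.any(fm > 1):
                raise ValueError("f_max must lie in (0, 1]")
        lo, hi = self.insert_support
        if not lo < hi:
            raise ValueError("insert support requires L_min < L_max")

    def to_json(self) -> str:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            d[f.name] = v
        return json.dumps(d, sort_keys=True, default=list)


def _draw_junction_truth(config: SimConfig, rng: np.random.Generator):
    """Fill any unspecified per-intron truth arrays. Returns (se, sens, depth)."""
    n, n_doses = config.n_introns, len(config.doses)
    if config.intrinsic_se is None:
        se = rng.uniform(30.0, 95.0, size=n)
    else:
        se = np.broadcast_to(np.asarray(config.intrinsic_se, float), (n,)).copy()
    if config.sensitivity is None:
        # non-decreasing in dose: each non-zero dose pushes inhibition upward
        sens = np.zeros((n, n_doses))
        prev = np.zeros(n)
        for j in range(1, n_doses):
            prev = prev + (1.0 - prev) * rng.uniform(0.1, 0.9, size=n)
            sens[:, j] = prev
    else:
        sens = np.asarray(config.sensitivity, float)
        if sens.shape != (n, n_doses):
            raise ValueError(
                f"sensitivity must have shape ({n}, {n_doses}), got {sens.shape}"
            )
        sens = sens.copy()
    sens[:, 0] = 0.0
    depth = np.broadcast_to(
        np.atleast_1d(np.asarray(config.expression_depth, float)), (n,)
    ).copy()
    return se, sens, depth


def _sample_totals(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial totals with mean mu and var mu + dispersion*mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_junction_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-intron junction-count records across doses and replicates.

    For intron *i* at dose *d*, replicate *r*, the total informative count
    is negative-binomial with mean ``expression_depth[i]``; the exon-exon
    count is Binomial(total, SE_i(d)/100) with
    ``SE_i(d) = intrinsic_se[i] * (1 - sensitivity[i, d])``; the
    intron-exon count is the remainder, so ``N_EE + N_IE = total`` holds
    exactly for every record.

    Returns
    -------
    (counts, truth) :
        ``counts`` has one row per (event, dose, replicate) with columns
        event_id, strain, treatment, dose_uM, replicate, N_EE, N_IE;
        ``truth`` has one row per (event, dose) with the intrinsic SE,
        inhibition fraction and expected SE used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    se, sens, depth = _draw_junction_truth(config, rng)
    event_ids = [f"intron{i:04d}" for i in range(config.n_introns)]

    rows = []
    truth_rows = []
    for i, ev in enumerate(event_ids):
        for j, dose in enumerate(config.doses):
            se_true = se[i] * (1.0 - sens[i, j])
            truth_rows.append(
                {
                    "event_id": ev,
                    "dose_uM": dose,
                    "intrinsic_SE": se[i],
                    "sensitivity": sens[i, j],
                    "expected_SE": se_true,
                    "expression_depth": depth[i],
                }
            )
            totals = _sample_totals(
                rng, np.full(config.n_replicates, depth[i]), config.dispersion
            )
            n_ee = rng.binomial(totals, se_true / 100.0)
            for r in range(config.n_replicates):
                rows.append(
                    {
                        "event_id": ev,
                        "strain": config.strain,
                        "treatment": "DMSO" if dose == 0 else config.treatment,
                        "dose_uM": dose,
                        "replicate": r + 1,
                        "N_EE": int(n_ee[r]),
                        "N_IE": int(totals[r] - n_ee[r]),
                    }
                )
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return counts, truth


def logistic_splicing_curve(
    x: np.ndarray, midpoint: float, slope: float, f_max: float
) -> np.ndarray:
    """True fraction spliced at Pol II position x (nt relative to the 3'SS).

    Logistic in x for x >= 0, exactly 0 upstream of the 3'SS (an intron
    cannot be excised before its 3' splice site has been transcribed).
    ``slope -> 0`` degenerates to a step at the midpoint.
    """
    x = np.asarray(x, dtype=float)
    if slope <= 0:
        f = np.where(x >= midpoint, f_max, 0.0)
    else:
        f = f_max / (1.0 + np.exp(-(x - midpoint) / slope))
    return np.where(x < 0, 0.0, f)


def _draw_smit_truth(config: SimConfig, rng: np.random.Generator):
    n = config.n_genes
    mid = (
        rng.uniform(80.0, 250.0, n)
        if config.midpoint is None
        else np.broadcast_to(np.asarray(config.midpoint, float), (n,)).copy()
    )
    slope = (
        rng.uniform(10.0, 40.0, n)
        if config.slope is None
        else np.broadcast_to(np.asarray(config.slope, float), (n,)).copy()
    )
    fmax = (
        rng.uniform(0.7, 1.0, n)
        if config.f_max is None
        else np.broadcast_to(np.asarray(config.f_max, float), (n,)).copy()
    )
    ilen = (
        np.round(rng.uniform(100.0, 400.0, n))
        if config.intron_length is None
        else np.broadcast_to(np.asarray(config.intron_length, float), (n,)).copy()
    )
    return mid, slope, fmax, ilen


def insert_length_pmf(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discretised-normal insert-length law on the configured support.

    Returns (lengths, pmf) with the pmf normalised to sum to 1.
    """
    lo, hi = config.insert_support
    lengths = np.arange(lo, hi + 1)
    pmf = stats.norm.pdf(lengths, loc=config.insert_mean, scale=config.insert_sd)
    return lengths, pmf / pmf.sum()


def simulate_smit_reads(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate SMIT reads under position-dependent splicing with capture bias.

    Per molecule: Pol II position x ~ Uniform(pol_window); spliced state ~
    Bernoulli(factor * f_true(x)) where f_true is the gene's logistic
    splicing curve and factor is the condition's inhibition multiplier;
    molecule length = primer_offset + x, minus intron_length if spliced.
    The molecule is retained with probability proportional to the
    insert-length law's density at its length (length-capture bias);
    retained molecules are emitted with insert_length = molecule length.

    Returns
    -------
    (reads, truth) :
        ``reads`` columns: gene_id, condition, polII_pos, spliced {0,1},
        insert_len. ``truth`` has per-gene curve parameters, intron
        length, primer offset and per-condition factors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    mid, slope, fmax, ilen = _draw_smit_truth(config, rng)
    lengths, pmf = insert_length_pmf(config)
    pmf_max = pmf.max()
    lo, hi = config.insert_support
    x_lo, x_hi = config.pol_window

    rows = []
    truth_rows = []
    for g in range(config.n_genes):
        gene = f"gene{g:03d}"
        for cond, factor in config.smit_conditions.items():
            truth_rows.append(
                {
                    "gene_id": gene,
                    "condition": cond,
                    "midpoint": mid[g],
                    "slope": slope[g],
                    "f_max": fmax[g],
                    "factor": factor,
                    "intron_length": ilen[g],
                    "primer_offset": config.primer_offset,
                }
            )
            # oversample to compensate for capture-bias rejection
            n_try = int(config.reads_per_gene * 4)
            x = rng.integers(x_lo, x_hi + 1, size=n_try)
            f_true = np.clip(
                factor * logistic_splicing_curve(x, mid[g], slope[g], fmax[g]),
                0.0,
                1.0,
            )
            spliced = rng.random(n_try) < f_true
            mol_len = config.primer_offset + x - spliced * ilen[g].astype(int)
            in_support = (mol_len >= lo) & (mol_len <= hi)
            capture_p = np.zeros(n_try)
            capture_p[in_support] = pmf[(mol_len[in_support] - lo).astype(int)] / pmf_max
            keep = rng.random(n_try) < capture_p
            keep_idx = np.flatnonzero(keep)[: config.reads_per_gene]
            for k in keep_idx:
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": cond,
                        "polII_pos": int(x[k]),
                        "spliced": int(spliced[k]),
                        "insert_len": int(mol_len[k]),
                    }
                )
    reads = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def designed_smit_panel(
    seed: int = 0,
    reads_per_gene: int = 5000,
    smit_conditions: dict[str, float] | None = None,
) -> SimConfig:
    """A three-gene SMIT panel with assay-friendly geometry.

    Real SMIT panels are built around gene-specific capture primers
    placed so that both the spliced and the unspliced product stay
    within the library's capturable size range across the positions of
    interest; without that, one product class is invisible and the
    fraction spliced cannot be corrected. This panel encodes that
    design: short introns (90-110 nt), the primer 120 nt upstream of
    the 3'SS, and splicing-onset midpoints 90-130 nt downstream of the
    3'SS, so the default insert-length law covers both products over
    the 200-nt analysis window.
    """
    if smit_conditions is None:
        smit_conditions = {"control": 1.0, "treated": 0.5}
    return SimConfig(
        n_genes=3,
        reads_per_gene=reads_per_gene,
        midpoint=np.array([90.0, 110.0, 130.0]),
        slope=np.array([15.0, 20.0, 25.0]),
        f_max=np.array([0.9, 0.9, 0.85]),
        intron_length=np.array([100.0, 110.0, 90.0]),
        primer_offset=120,
        smit_conditions=smit_conditions,
        seed=seed,
    )
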