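"""Count containers, normalization and differential expression.

Expression data travel through the pipeline as :class:`ExpressionMatrix`
objects: a features x samples count (or normalized-value) table plus the
sample sheet describing the two-group (Sham vs ICH), two-timepoint
(day7 vs day28) replicate design.

Normalization follows the read-count conventions of bulk RNA-seq:
TPM-style library-size scaling for circRNA and miRNA counts
(value = count * 1e6 / libsize, libsize being the per-sample sum of that
species' counts) and FPKM for mRNA (value = count * 1e9 / (length * libsize)).

Differential expression is a negative-binomial Wald test per feature and
timepoint: counts are scaled by median-of-ratios size factors, per-feature
dispersions are estimated by method of moments and shrunk halfway toward a
mean-dispersion trend, and the log fold change is tested against zero with
a standard-normal Wald reference. Raw p-values
are Benjamini-Hochberg adjusted per species and timepoint; features with
adjusted p below alpha are called up or down by the sign of the fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUPS = ("Sham", "ICH")
TIMEPOINTS = ("day7", "day28")

__all__ = [
    "ExpressionMatrix",
    "DeRecord",
    "tpm_normalize",
    "fpkm_normalize",
    "bh_adjust",
    "de_test",
    "de_summary",
    "ddct_fold_change",
]


@dataclass
class ExpressionMatrix:
    """Features x samples values with sample metadata.

    Parameters
    ----------
    species : str
        One of ``circRNA``, ``miRNA``, ``mRNA``.
    counts : pandas.DataFrame
        Non-negative values, index = feature ids, columns = sample ids.
    samples : pandas.DataFrame
        Sample sheet indexed by sample id with columns ``group``,
        ``timepoint``, ``replicate``; must cover every count column.
    lengths : pandas.Series, optional
        Feature lengths in bp (required for FPKM; mRNA only).
    """

    species: str
    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.counts, dtype=float) < 0).any():
            raise ValueError("negative values in count matrix")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        if self.lengths is not None:
            lens = self.lengths.reindex(self.counts.index)
            if lens.isna().any():
                absent = list(self.counts.index[lens.isna()])[:3]
                raise ValueError(f"missing feature lengths, e.g. {absent}")
            if (lens <= 0).any():
                raise ValueError("feature lengths must be positive")
            self.lengths = lens

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def timepoint_samples(self, timepoint: str, group: str | None = None) -> list[str]:
        """Sample ids at a timepoint, optionally restricted to one group."""
        meta = self.samples.loc[list(self.counts.columns)]
        mask = meta["timepoint"] == timepoint
        if group is not None:
            mask &= meta["group"] == group
        return list(meta.index[mask])

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(self.species, values, self.samples, self.lengths)


@dataclass
class DeRecord:
    """Per-feature differential expression call (ICH vs Sham)."""

    feature_id: str
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str  # up | down | ns


def tpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalization: value = count * 1e6 / column sum.

    Every output column sums to 1e6 (to float tolerance). The library size
    is the per-sample sum of the same species' counts.
    """
    libsize = matrix.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return matrix.with_values(matrix.counts * 1e6 / libsize)


def fpkm_normalize(matrix: ExpressionMatrix, lengths: pd.Series | None = None) -> ExpressionMatrix:
    """FPKM: value = count * 1e9 / (length_bp * libsize)."""
    lens = lengths if lengths is not None else matrix.lengths
    if lens is None:
        raise ValueError("feature lengths required for FPKM")
    lens = lens.reindex(matrix.counts.index)
    if lens.isna().any():
        absent = list(matrix.counts.index[lens.isna()])[:3]
        raise ValueError(f"missing feature lengths, e.g. {absent}")
    libsize = matrix.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    values = matrix.counts.mul(1e9, axis=0).div(libsize, axis=1).div(lens, axis=0)
    out = matrix.with_values(values)
    out.lengths = lens
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (features x samples array)."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        # every feature has a zero somewhere; fall back to library-size ratios
        lib = counts.sum(axis=0)
        return lib / np.exp(np.mean(np.log(lib)))
    ratios = log_counts[usable] - log_geomean[usable, None]
    return np.exp(np.median(ratios, axis=0))


def _dispersion_estimates(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersions shrunk 50/50 toward an a0 + a1/mean trend."""
    mu = norm.mean(axis=1)
    # pooled within-group variance so planted group differences do not inflate it
    wvar = np.zeros(norm.shape[0])
    dof = 0
    for idx in group_idx:
        wvar += norm[:, idx].var(axis=1, ddof=1) * (len(idx) - 1)
        dof += len(idx) - 1
    wvar /= max(dof, 1)
    mu_safe = np.maximum(mu, 1e-8)
    alpha_mom = (wvar - mu_safe) / mu_safe**2
    alpha_mom = np.maximum(alpha_mom, 1e-8)
    # trend fit alpha ~ a0 + a1/mu on features with informative estimates
    informative = alpha_mom > 1e-8
    if informative.sum() >= 10:
        x = np.column_stack([np.ones(informative.sum()), 1.0 / mu_safe[informative]])
        coef, *_ = np.linalg.lstsq(x, alpha_mom[informative], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:
        a0, a1 = float(np.median(alpha_mom)), 0.0
    trend = a0 + a1 / mu_safe
    return np.maximum(0.5 * alpha_mom + 0.5 * trend, 1e-8)


def de_test(
    matrix: ExpressionMatrix,
    timepoint: str,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> list[DeRecord]:
    """Negative-binomial Wald test of ICH vs Sham at one timepoint.

    Counts are normalized by median-of-ratios size factors; per-feature
    dispersions come from :func:`_dispersion_estimates`. The Wald statistic
    divides the log fold change (with pseudocount) by its delta-method
    standard error and is referred to the standard normal distribution.
    Raw two-sided p-values are BH-adjusted across the features of this
    species/timepoint; direction is up/down only when p_adj < alpha.
    """
    sham = matrix.timepoint_samples(timepoint, "Sham")
    ich = matrix.timepoint_samples(timepoint, "ICH")
    if len(sham) < 2 or len(ich) < 2:
        raise ValueError(
            f"need >=2 replicates per group at {timepoint}; "
            f"got {len(sham)} Sham, {len(ich)} ICH"
        )
    cols = sham + ich
    counts = matrix.counts[cols].to_numpy(dtype=float)
    s = _size_factors(counts)
    norm = counts / s
    idx_a = np.arange(len(sham))
    idx_b = np.arange(len(sham), len(cols))
    disp = _dispersion_estimates(norm, [idx_a, idx_b])

    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    lfc = np.log2(mu_b + pseudocount) - np.log2(mu_a + pseudocount)

    # Var(ln mean of K_j/s_j) ~ (1/n^2) sum_j 1/(mu s_j) + alpha/n, delta method
    def _log_mean_var(mu: np.ndarray, idx: np.ndarray) -> np.ndarray:
        n = len(idx)
        mu_safe = np.maximum(mu, pseudocount)
        return (1.0 / (mu_safe[:, None] * s[idx][None, :])).sum(axis=1) / n**2 + disp / n

    se = np.sqrt(_log_mean_var(mu_a, idx_a) + _log_mean_var(mu_b, idx_b)) / np.log(2)
    z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = bh_adjust(p_raw)

    records = []
    for fid, l2, pr, pa in zip(matrix.feature_ids, lfc, p_raw, p_adj):
        if pa < alpha:
            direction = "up" if l2 > 0 else "down"
        else:
            direction = "ns"
        records.append(DeRecord(str(fid), float(l2), float(pr), float(pa), direction))
    return records


def de_summary(records: list[DeRecord]) -> dict:
    """Counts of down/up/total differentially expressed features."""
    n_down = sum(1 for r in records if r.direction == "down")
    n_up = sum(1 for r in records if r.direction == "up")
    return {"n_down": n_down, "n_up": n_up, "n_total": n_down + n_up}


def ddct_fold_change(delta_ct_treated: float, delta_ct_control: float) -> float:
    """Relative qPCR fold change 2^-(ddCT), ddCT = dCT_treated - dCT_control."""
    ddct = float(delta_ct_treated) - float(delta_ct_control)
    if not np.isfinite(ddct):
        raise ValueError("delta-CT inputs must be finite")
    return float(2.0 ** (-ddct))


def de_table(records: list[DeRecord]) -> pd.DataFrame:
    """DE records as a tidy DataFrame (feature_id, log2fc, p_raw, p_adj, direction)."""
    return pd.DataFrame(
        [(r.feature_id, r.log2fc, r.p_raw, r.p_adj, r.direction) for r in records],
        columns=["feature_id", "log2fc", "p_raw", "p_adj", "direction"],
    )
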