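"""Expression-signature discrimination of experimental groups.

Quantifies how well the differentially expressed features of each RNA
species (or a row-concatenation of several species) separate the
Sham/ICH x day-7/day-28 samples: per-feature z-scored log2(normalized + 1)
profiles are clustered hierarchically (Euclidean distance, average linkage,
dendrogram cut at k) and the accuracy is the best cluster-to-class
agreement under Hungarian matching. PCA on the same signature reports PC1
and PC2 scores and the percentage of variance they explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .expression import DeRecord, ExpressionMatrix

__all__ = [
    "SignatureMatrix",
    "DiscriminationResult",
    "build_signature",
    "cluster_accuracy",
    "pca_variance",
    "species_comparison",
]


@dataclass
class SignatureMatrix:
    """Z-scored DE-feature profiles (rows = features, columns = samples)."""

    label: str
    values: pd.DataFrame
    sample_labels: pd.Series  # class label per sample (e.g. group_timepoint)


@dataclass
class DiscriminationResult:
    """Clustering accuracy and PCA variance for one species combination."""

    label: str
    k: int
    accuracy: float
    n_correct: dict[str, int]
    pc1_pct: float
    pc2_pct: float


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    sd = sd.replace(0.0, 1.0)  # constant rows become all-zero, not NaN
    return values.sub(mean, axis=0).div(sd, axis=0)


def build_signature(
    matrices: dict[str, ExpressionMatrix],
    de_tables: dict[str, list[DeRecord]],
    species_set: tuple[str, ...],
    samples: list[str] | None = None,
) -> SignatureMatrix:
    """Row-concatenate each species' DE features, z-scored per feature.

    ``de_tables`` maps species to DE records (union over timepoints is the
    caller's responsibility when both contrasts matter). Values are
    log2(normalized + 1) before z-scoring.
    """
    blocks = []
    ref = matrices[species_set[0]]
    cols = samples if samples is not None else list(ref.sample_ids)
    for sp in species_set:
        de_ids = [r.feature_id for r in de_tables[sp] if r.direction != "ns"]
        de_ids = [f for f in dict.fromkeys(de_ids) if f in matrices[sp].counts.index]
        if not de_ids:
            continue
        block = np.log2(matrices[sp].counts.loc[de_ids, cols] + 1.0)
        block.index = [f"{sp}:{f}" for f in de_ids]
        blocks.append(block)
    if not blocks:
        raise ValueError(f"no DE features for species {species_set}")
    values = _zscore_rows(pd.concat(blocks, axis=0))
    meta = ref.samples.loc[cols]
    labels = meta["group"].astype(str) + "_" + meta["timepoint"].astype(str)
    return SignatureMatrix("+".join(species_set), values, labels)


def cluster_accuracy(signature: SignatureMatrix, k: int) -> DiscriminationResult:
    """Hierarchical clustering at k clusters scored against sample classes.

    Agglomerative, Euclidean distance, average linkage; accuracy is the
    fraction of samples correctly assigned under the optimal (Hungarian)
    cluster-to-class matching. Deterministic.
    """
    x = signature.values.to_numpy().T  # samples x features
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    z = linkage(x, method="average", metric="euclidean")
    clusters = fcluster(z, t=k, criterion="maxclust")
    labels = signature.sample_labels.to_numpy()
    classes = sorted(set(labels))
    cluster_ids = sorted(set(clusters))
    contingency = np.zeros((len(cluster_ids), len(classes)), dtype=int)
    for c, lab in zip(clusters, labels):
        contingency[cluster_ids.index(c), classes.index(lab)] += 1
    rows, cols = linear_sum_assignment(-contingency)
    n_correct = {classes[j]: int(contingency[i, j]) for i, j in zip(rows, cols)}
    accuracy = sum(n_correct.values()) / n
    pc = pca_variance(signature)
    return DiscriminationResult(
        signature.label, k, accuracy, n_correct, pc["variance_pct"][0], pc["variance_pct"][1]
    )


def pca_variance(signature: SignatureMatrix) -> dict:
    """PCA over samples (features as dimensions): scores + % variance.

    Returns ``{"scores": DataFrame (samples x PCs), "variance_pct": list}``
    with PC1% >= PC2%. All-equal samples yield zero variance and are
    flagged with a warning.
    """
    x = signature.values.to_numpy().T
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    centered = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    # identical samples leave rounding residuals ~eps after centering, so the
    # degeneracy test must be relative to the data scale, not exact zero
    scale = max(float(np.abs(x).max(initial=0.0)), 1.0)
    if total <= (1e-9 * scale) ** 2 * x.size:
        total = 0.0
    if total == 0:
        warnings.warn("degenerate signature: all samples identical, zero variance")
        pct = np.zeros(len(var))
    else:
        pct = 100.0 * var / total
    scores = u * s
    n_pc = min(2, scores.shape[1])
    frame = pd.DataFrame(
        scores[:, :n_pc],
        index=signature.values.columns,
        columns=[f"PC{i+1}" for i in range(n_pc)],
    )
    pct_out = [float(pct[i]) if i < len(pct) else 0.0 for i in range(2)]
    return {"scores": frame, "variance_pct": pct_out}


_COMBOS: tuple[tuple[str, ...], ...] = (
    ("circRNA",),
    ("mRNA",),
    ("miRNA",),
    ("mRNA", "miRNA"),
    ("circRNA", "miRNA"),
    ("circRNA", "mRNA", "miRNA"),
)


def species_comparison(
    matrices: dict[str, ExpressionMatrix],
    de_tables: dict[str, list[DeRecord]],
) -> pd.DataFrame:
    """Clustering accuracy for each species combination.

    Runs k=4 over all samples (Sham/ICH x day7/day28) and k=2 within each
    timepoint; combinations whose species have no DE features are skipped
    with a warning. Returns a table ranked by the k=4 accuracy.
    """
    ref = next(iter(matrices.values()))
    rows = []
    for combo in _COMBOS:
        try:
            sig_all = build_signature(matrices, de_tables, combo)
        except ValueError as err:
            warnings.warn(f"skipping {'+'.join(combo)}: {err}")
            continue
        res4 = cluster_accuracy(sig_all, k=4)
        row = {
            "combination": sig_all.label,
            "accuracy_k4": res4.accuracy,
            "pc1_pct": res4.pc1_pct,
            "pc2_pct": res4.pc2_pct,
        }
        for tp in ("day7", "day28"):
            samples = ref.timepoint_samples(tp)
            sig_tp = build_signature(matrices, de_tables, combo, samples=samples)
            row[f"accuracy_k2_{tp}"] = cluster_accuracy(sig_tp, k=2).accuracy
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values("accuracy_k4", ascending=False).reset_index(drop=True)
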