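"""Synthetic RNA-seq data with known ground truth.

Emulates the inputs of a two-group (Sham vs ICH), two-timepoint (day 7 vs
day 28) rat-brain profiling design with 4 replicates per group: negative-
binomial count matrices for circRNA, miRNA and mRNA; mature-miRNA, circRNA
exonic and mRNA 3'UTR sequences; and two callers' back-splice-junction
tables with a matching gene annotation. Every planted signal (differential
features, ceRNA sponge triplets, circRNA genomic classes, seed-site
offsets) is recorded in a :class:`GroundTruth` so downstream stages can be
tested without any external data.

The sponge signal is a per-sample latent activity z ~ N(0, 1), drawn
independently within each timepoint, that multiplies the expected counts of
a planted triplet's circRNA and mRNA by 2^(+strength*z) and of its miRNA by
2^(-strength*z), inducing the negative circ-miR and miR-mRNA correlations a
ceRNA decoy/core/target trio shows in co-expression analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import GROUPS, TIMEPOINTS, ExpressionMatrix

DNA = "ACGT"
RNA = "ACGU"
_RC = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_counts",
    "emit_sequences",
    "emit_caller_tables",
    "reverse_complement_dna",
]


def reverse_complement_dna(seq: str) -> str:
    """DNA reverse complement of an RNA or DNA string (U pairs as A)."""
    return "".join(_RC[c] for c in reversed(seq.upper()))


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults follow the 4-replicates-per-group design and bulk RNA-seq
    conventions: log-normal baseline abundances, NB dispersion 0.05,
    one-million-read libraries varying +/-20% between samples, planted
    log2 fold changes drawn from [1, 3].
    """

    n_circ: int = 100
    n_mirna: int = 40
    n_mrna: int = 150
    n_reps: int = 4
    de_fraction: float = 0.1
    log2fc_range: tuple[float, float] = (1.0, 3.0)
    nb_dispersion: float = 0.05
    depth_mean: float = 1e6
    n_triplets: int = 5
    sponge_strength: float = 0.9
    seed: int = 0
    frac_exonic: float = 0.8283
    frac_intronic: float = 0.0628
    frac_intergenic: float = 0.1089
    # caller-table realism knobs
    fp_frac_a: float = 0.1
    fp_frac_b: float = 0.1
    lowcount_frac: float = 0.1
    # sequence lengths (nt)
    mirna_len: int = 22
    circ_seq_len: int = 500
    utr_len: int = 1000

    def __post_init__(self) -> None:
        frac_sum = self.frac_exonic + self.frac_intronic + self.frac_intergenic
        if abs(frac_sum - 1.0) > 1e-9:
            raise ValueError(f"circRNA class fractions sum to {frac_sum}, not 1")
        if self.n_triplets > min(self.n_circ, self.n_mirna, self.n_mrna):
            raise ValueError("n_triplets exceeds the smallest species size")
        if not 0.0 <= self.sponge_strength <= 1.0:
            raise ValueError("sponge_strength must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates per group")
        if not 18 <= self.mirna_len <= 26:
            raise ValueError("miRNA length must lie in 18-26 nt")
        if min(self.circ_seq_len, self.utr_len) < 8:
            raise ValueError("target sequences must be at least 8 nt")

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for tp, grp in itertools.product(TIMEPOINTS, GROUPS):
            for r in range(1, self.n_reps + 1):
                rows.append((f"{grp}_{tp}_r{r}", grp, tp, r))
        return pd.DataFrame(
            rows, columns=["sample_id", "group", "timepoint", "replicate"]
        ).set_index("sample_id")


@dataclass
class GroundTruth:
    """Planted signals of one simulated dataset.

    ``de_labels[species][feature_id]`` is +1 (up in ICH) or -1 (down);
    ``triplets`` lists (circ_id, mir_id, mrna_id) sponge trios;
    ``circ_classes`` maps circ_id to exonic/intronic/intergenic;
    ``site_offsets[(mir_id, target_id)]`` lists 0-based planted site starts;
    ``circ_loci`` maps circ_id to (chrom, start, end, strand), filled in by
    :func:`emit_caller_tables`.
    """

    de_labels: dict[str, dict[str, int]]
    triplets: list[tuple[str, str, str]]
    circ_classes: dict[str, str]
    site_offsets: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    circ_loci: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    lowcount_circ: set[str] = field(default_factory=set)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:04d}" for i in range(1, n + 1)]


def _plant_de(
    rng: np.random.Generator,
    ids: list[str],
    de_fraction: float,
    lfc_range: tuple[float, float],
    forced: dict[str, int],
) -> tuple[dict[str, int], dict[str, float]]:
    """Choose DE features and signed log2 fold changes; triplet members first."""
    labels = dict(forced)
    n_de = int(round(de_fraction * len(ids)))
    pool = [f for f in ids if f not in labels]
    extra = max(0, n_de - len(labels))
    for fid in rng.permutation(pool)[:extra]:
        labels[str(fid)] = int(rng.choice([-1, 1]))
    lo, hi = lfc_range
    lfc = {fid: sign * float(rng.uniform(lo, hi)) for fid, sign in labels.items()}
    return labels, lfc


def simulate_counts(
    config: SimConfig,
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Simulate circRNA/miRNA/mRNA count matrices with planted truth.

    Returns a dict keyed ``circRNA``/``miRNA``/``mRNA`` and the
    :class:`GroundTruth`. Deterministic given ``config.seed``.
    """
    rng = _rng(config, 1)
    samples = config.sample_sheet()
    circ_ids = _feature_ids("circ", config.n_circ)
    mir_ids = _feature_ids("mir", config.n_mirna)
    mrna_ids = _feature_ids("mrna", config.n_mrna)

    # sponge triplets: members drawn without replacement, coherent directions
    trip_circ = [str(f) for f in rng.permutation(circ_ids)[: config.n_triplets]]
    trip_mir = [str(f) for f in rng.permutation(mir_ids)[: config.n_triplets]]
    trip_mrna = [str(f) for f in rng.permutation(mrna_ids)[: config.n_triplets]]
    triplets = list(zip(trip_circ, trip_mir, trip_mrna))
    forced: dict[str, dict[str, int]] = {"circRNA": {}, "miRNA": {}, "mRNA": {}}
    for c, m, g in triplets:
        mirror = int(rng.choice([-1, 1]))  # decoy/target up & core down, or flipped
        forced["circRNA"][c] = mirror
        forced["miRNA"][m] = -mirror
        forced["mRNA"][g] = mirror

    de_labels: dict[str, dict[str, int]] = {}
    lfcs: dict[str, dict[str, float]] = {}
    for species, ids in (("circRNA", circ_ids), ("miRNA", mir_ids), ("mRNA", mrna_ids)):
        de_labels[species], lfcs[species] = _plant_de(
            rng, ids, config.de_fraction, config.log2fc_range, forced[species]
        )

    libsizes = config.depth_mean * rng.uniform(0.8, 1.2, size=len(samples))
    is_ich = (samples["group"] == "ICH").to_numpy()
    # latent sponge activity, one draw per (triplet, sample); day-7 and day-28
    # samples never share a draw, matching per-timepoint network construction
    z = rng.standard_normal((config.n_triplets, len(samples)))

    member_role = {
        "circRNA": dict(zip(trip_circ, range(config.n_triplets))),
        "miRNA": dict(zip(trip_mir, range(config.n_triplets))),
        "mRNA": dict(zip(trip_mrna, range(config.n_triplets))),
    }
    sponge_sign = {"circRNA": +1.0, "miRNA": -1.0, "mRNA": +1.0}

    matrices: dict[str, ExpressionMatrix] = {}
    mrna_lengths = None
    for species, ids in (("circRNA", circ_ids), ("miRNA", mir_ids), ("mRNA", mrna_ids)):
        weights = rng.lognormal(mean=0.0, sigma=1.5, size=len(ids))
        rel = weights / weights.sum()
        mean = rel[:, None] * libsizes[None, :]
        log2_shift = np.zeros_like(mean)
        for k, fid in enumerate(ids):
            if fid in lfcs[species]:
                log2_shift[k, is_ich] += lfcs[species][fid]
            t = member_role[species].get(fid)
            if t is not None and config.sponge_strength > 0:
                log2_shift[k, :] += sponge_sign[species] * config.sponge_strength * z[t]
        mean = mean * 2.0**log2_shift
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
        frame = pd.DataFrame(counts, index=ids, columns=samples.index)
        lengths = None
        if species == "mRNA":
            mrna_lengths = pd.Series(
                rng.integers(500, 5000, size=len(ids)), index=ids, name="length"
            ).astype(float)
            lengths = mrna_lengths
        matrices[species] = ExpressionMatrix(species, frame, samples, lengths)

    class_labels = _assign_classes(rng, circ_ids, config)
    low_n = int(round(config.lowcount_frac * config.n_circ))
    lowcount = {str(f) for f in rng.permutation(circ_ids)[:low_n]}
    truth = GroundTruth(
        de_labels=de_labels,
        triplets=triplets,
        circ_classes=class_labels,
        lowcount_circ=lowcount,
    )
    return matrices, truth


def _assign_classes(
    rng: np.random.Generator, circ_ids: list[str], config: SimConfig
) -> dict[str, str]:
    n = len(circ_ids)
    n_ex = int(round(config.frac_exonic * n))
    n_in = int(round(config.frac_intronic * n))
    n_in = min(n_in, n - n_ex)
    labels = (
        ["exonic"] * n_ex + ["intronic"] * n_in + ["intergenic"] * (n - n_ex - n_in)
    )
    order = rng.permutation(n)
    return {circ_ids[i]: labels[j] for j, i in enumerate(order)}


# ---------------------------------------------------------------------------
# sequences


def emit_sequences(
    truth: GroundTruth, config: SimConfig
) -> dict[str, dict[str, str]]:
    """Random-background sequences with planted seed-complementary sites.

    Returns ``{"miRNA": {...}, "circRNA": {...}, "mRNA": {...}}`` mapping ids
    to sequences: RNA for miRNAs, DNA for circRNA exonic and mRNA 3'UTR
    targets. For every planted triplet the DNA reverse complement of the
    miRNA seed (positions 2-8) is embedded in both target sequences; the
    0-based site offsets are recorded in ``truth.site_offsets``.
    """
    rng = _rng(config, 2)
    mir_ids = _feature_ids("mir", config.n_mirna)
    mirna = {
        m: "".join(rng.choice(list(RNA), size=config.mirna_len)) for m in mir_ids
    }
    circ_seqs = {
        c: "".join(rng.choice(list(DNA), size=config.circ_seq_len))
        for c in sorted(truth.circ_classes)
    }
    utr_seqs = {
        g: "".join(rng.choice(list(DNA), size=config.utr_len))
        for g in _feature_ids("mrna", config.n_mrna)
    }

    truth.site_offsets.clear()
    for c, m, g in truth.triplets:
        site = reverse_complement_dna(mirna[m][1:8])
        for target_id, seqs in ((c, circ_seqs), (g, utr_seqs)):
            seq = seqs[target_id]
            if len(seq) < len(site) + 1:
                raise ValueError(f"sequence {target_id} shorter than a seed site")
            offset = int(rng.integers(0, len(seq) - len(site)))
            # non-A base 3' of the site keeps the planted type a clean 7mer-m8
            seqs[target_id] = (
                seq[:offset] + site + "C" + seq[offset + len(site) + 1 :]
            )
            truth.site_offsets.setdefault((m, target_id), []).append(offset)
    return {"miRNA": mirna, "circRNA": circ_seqs, "mRNA": utr_seqs}


# ---------------------------------------------------------------------------
# caller tables + annotation


def emit_caller_tables(
    truth: GroundTruth,
    config: SimConfig,
    matrices: dict[str, ExpressionMatrix] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two callers' BSJ tables plus a matching gene annotation.

    True circRNAs appear in both tables at identical coordinates; each
    caller additionally reports its own false positives (fractions
    ``fp_frac_a``/``fp_frac_b`` of n_circ). A ``lowcount_frac`` subset of
    true circRNAs is drawn so that every replicate set contains a sample
    with fewer than 2 junction reads, i.e. they fail the replicate filter.
    The annotation places exonic circRNAs on exon boundaries, intronic ones
    strictly inside introns and intergenic ones between genes.

    Returns (table_A, table_B, gtf) as DataFrames; caller tables have
    columns chrom, start, end, strand, caller, reads_<sample>; the GTF
    frame has the standard 9 columns, 1-based inclusive coordinates.
    """
    rng = _rng(config, 3)
    samples = config.sample_sheet()
    rep_sets = [
        list(samples.index[(samples["group"] == g) & (samples["timepoint"] == t)])
        for g, t in itertools.product(GROUPS, TIMEPOINTS)
    ]

    gtf_rows: list[tuple] = []
    cursor = 1000
    chrom = "chr1"
    truth.circ_loci.clear()
    gene_counter = 0

    def _new_gene(n_exons: int) -> tuple[str, list[tuple[int, int]], str]:
        nonlocal cursor, gene_counter
        gene_counter += 1
        gid = f"gene_{gene_counter:04d}"
        strand = str(rng.choice(["+", "-"]))
        exons = []
        pos = cursor + int(rng.integers(5000, 20000))  # intergenic gap
        for _ in range(n_exons):
            length = int(rng.integers(150, 300))
            exons.append((pos, pos + length - 1))
            pos = pos + length + int(rng.integers(500, 2000))  # intron
        cursor = exons[-1][1]
        gene_span = (exons[0][0], exons[-1][1])
        tid = gid + ".t1"
        attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
        gtf_rows.append((chrom, "sim", "gene", gene_span[0], gene_span[1], ".", strand, ".", f'gene_id "{gid}";'))
        gtf_rows.append((chrom, "sim", "transcript", gene_span[0], gene_span[1], ".", strand, ".", attrs))
        for s, e in exons:
            gtf_rows.append((chrom, "sim", "exon", s, e, ".", strand, ".", attrs))
        return gid, exons, strand

    for circ_id in sorted(truth.circ_classes):
        cls = truth.circ_classes[circ_id]
        if cls == "exonic":
            _, exons, strand = _new_gene(int(rng.integers(3, 7)))
            i = int(rng.integers(0, len(exons) - 1))
            j = int(rng.integers(i + 1, len(exons)))
            locus = (chrom, exons[i][0], exons[j][1], strand)
        elif cls == "intronic":
            _, exons, strand = _new_gene(int(rng.integers(2, 5)))
            k = int(rng.integers(0, len(exons) - 1))
            intron = (exons[k][1] + 1, exons[k + 1][0] - 1)
            locus = (chrom, intron[0] + 10, intron[1] - 10, strand)
        else:  # intergenic: claim a gap well beyond the last gene
            start = cursor + int(rng.integers(6000, 12000))
            end = start + int(rng.integers(200, 800))
            cursor = end
            locus = (chrom, start, end, str(rng.choice(["+", "-"])))
        truth.circ_loci[circ_id] = locus

    def _junction_reads(fails_filter: bool) -> dict[str, int]:
        reads = {s: int(rng.poisson(8)) for s in samples.index}
        if fails_filter:
            for rs in rep_sets:  # knock one sample below 2 in every set
                victim = str(rng.choice(rs))
                reads[victim] = int(rng.integers(0, 2))
        else:
            rs = rep_sets[int(rng.integers(0, len(rep_sets)))]
            for s in rs:  # guarantee one fully supported replicate set
                reads[s] = max(reads[s], 2)
        return reads

    def _rows(caller: str) -> list[dict]:
        rows = []
        for circ_id, (c, s, e, st) in truth.circ_loci.items():
            reads = true_reads[circ_id]
            rows.append({"chrom": c, "start": s, "end": e, "strand": st, "caller": caller, **{f"reads_{k}": v for k, v in reads.items()}})
        return rows

    true_reads = {
        circ_id: _junction_reads(circ_id in truth.lowcount_circ)
        for circ_id in truth.circ_loci
    }

    def _fp_rows(caller: str, n_fp: int, base_shift: int) -> list[dict]:
        rows = []
        used = {(c, s, e) for c, s, e, _ in truth.circ_loci.values()}
        base = cursor + 50000 + base_shift  # A/B false positives never collide
        for k in range(n_fp):
            start = base + k * 3000 + int(rng.integers(0, 1000))
            end = start + int(rng.integers(200, 600))
            if (chrom, start, end) in used:
                continue
            reads = {s: int(rng.poisson(4)) for s in samples.index}
            rows.append({"chrom": chrom, "start": start, "end": end, "strand": str(rng.choice(["+", "-"])), "caller": caller, **{f"reads_{k2}": v for k2, v in reads.items()}})
        return rows

    cols = ["chrom", "start", "end", "strand", "caller"] + [
        f"reads_{s}" for s in samples.index
    ]
    table_a = pd.DataFrame(
        _rows("callerA")
        + _fp_rows("callerA", int(round(config.fp_frac_a * config.n_circ)), 0),
        columns=cols,
    )
    table_b = pd.DataFrame(
        _rows("callerB")
        + _fp_rows("callerB", int(round(config.fp_frac_b * config.n_circ)), 1500),
        columns=cols,
    )
    gtf = pd.DataFrame(
        gtf_rows,
        columns=["seqname", "source", "feature", "start", "end", "score", "strand", "frame", "attribute"],
    )
    return table_a, table_b, gtf
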