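"""miRNA seed-match target prediction.

Sites are the canonical seed classes: the target is scanned (sense strand,
5'->3', DNA alphabet) for the reverse complement of the miRNA seed
(positions 2-7, the 6mer core); each core match is then extended to

* 8mer      — position-8 complement matches AND an A faces position 1,
* 7mer-m8   — position-8 complement matches only,
* 7mer-A1   — an A faces position 1 only,

and bare 6mers are not reported. Scores rank the classes (8mer=3,
7mer-m8=2, 7mer-A1=1). G:U wobble pairing is off by default; enabling it
lets the core and the m8 extension tolerate wobble pairs.

Pair candidates for the ceRNA stage keep a (circRNA, miRNA) or
(miRNA, mRNA) pair only when a site exists and both members are
differentially expressed, collapsing multiple sites into a site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import DeRecord
from .simdata import reverse_complement_dna

__all__ = ["MirnaSeq", "TargetSite", "find_seed_sites", "pair_candidates"]

@dataclass
class MirnaSeq:
    """A mature miRNA sequence (RNA alphabet, 18-26 nt)."""

    mir_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(f"{self.mir_id}: length {len(self.sequence)} outside 18-26 nt")
        if set(self.sequence) - set("ACGU"):
            raise ValueError(f"{self.mir_id}: not an RNA sequence")

    @property
    def seed(self) -> str:
        """Positions 2-8 (1-based), i.e. a 7-nt substring at offset 1."""
        return self.sequence[1:8]


@dataclass
class TargetSite:
    """One predicted binding site on a target transcript."""

    mir_id: str
    target_id: str
    target_kind: str  # circ | mrna
    offset: int  # 0-based start of the site in the target
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1
    score: int

    @property
    def length(self) -> int:
        return 8 if self.site_type == "8mer" else 7


def _pairs_with(target_base: str, mir_base: str, allow_wobble: bool) -> bool:
    """Does the DNA target base pair with the RNA miRNA base (antiparallel)?"""
    watson = {"A": "U", "T": "A", "G": "C", "C": "G"}
    if watson[target_base] == mir_base:
        return True
    if allow_wobble:
        # G:U wobble — target G pairs miRNA U, target T pairs miRNA G
        return (target_base, mir_base) in {("G", "U"), ("T", "G")}
    return False


def _core_positions(seq: str, core_mir: str, allow_wobble: bool) -> list[int]:
    """Start positions of 6mer-core matches in the target.

    Without wobble the core has a single exact DNA representation, so plain
    substring search does the scan; with wobble each position is checked
    base by base.
    """
    k = len(core_mir)
    if not allow_wobble:
        core_dna = reverse_complement_dna(core_mir)
        hits, q = [], seq.find(core_dna)
        while q != -1:
            hits.append(q)
            q = seq.find(core_dna, q + 1)
        return hits
    return [
        q
        for q in range(len(seq) - k + 1)
        if all(_pairs_with(seq[q + j], core_mir[k - 1 - j], True) for j in range(k))
    ]


def find_seed_sites(
    mir: MirnaSeq,
    target_id: str,
    target_seq: str,
    target_kind: str = "mrna",
    allow_wobble: bool = False,
) -> list[TargetSite]:
    """All canonical seed sites for one miRNA in one target sequence."""
    seq = target_seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"{target_id}: not a DNA sequence")
    if target_kind not in ("circ", "mrna"):
        raise ValueError(f"unknown target kind {target_kind!r}")

    # 6mer core = reverse complement of seed positions 2-7; on the target it
    # reads 3'->5' relative to the miRNA, so core[0] faces position 7
    core_mir = mir.sequence[1:7]
    sites: list[TargetSite] = []
    n, k = len(seq), 6
    for q in _core_positions(seq, core_mir, allow_wobble):
        m8 = q >= 1 and _pairs_with(seq[q - 1], mir.sequence[7], allow_wobble)
        a1 = q + k < n and seq[q + k] == "A"
        if m8 and a1:
            sites.append(TargetSite(mir.mir_id, target_id, target_kind, q - 1, "8mer", 3))
        elif m8:
            sites.append(TargetSite(mir.mir_id, target_id, target_kind, q - 1, "7mer-m8", 2))
        elif a1:
            sites.append(TargetSite(mir.mir_id, target_id, target_kind, q, "7mer-A1", 1))
    return sites


def scan_targets(
    mirnas: dict[str, str],
    targets: dict[str, str],
    target_kind: str,
    allow_wobble: bool = False,
) -> list[TargetSite]:
    """Scan every miRNA against every target sequence."""
    sites = []
    for mir_id in sorted(mirnas):
        mir = MirnaSeq(mir_id, mirnas[mir_id])
        for target_id in sorted(targets):
            sites.extend(
                find_seed_sites(mir, target_id, targets[target_id], target_kind, allow_wobble)
            )
    return sites


def _de_ids(records: list[DeRecord]) -> set[str]:
    return {r.feature_id for r in records if r.direction != "ns"}


def pair_candidates(
    sites: list[TargetSite],
    de_circ: list[DeRecord],
    de_mir: list[DeRecord],
    de_mrna: list[DeRecord],
    timepoints: tuple[str, str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE-filtered, deduplicated (circ, miR) and (miR, mRNA) pair tables.

    A pair is kept iff a binding site exists and both members are
    differentially expressed (direction != ns). Multiple sites for the same
    pair collapse to one row with a ``site_count``. When the contrasts'
    timepoint labels are supplied they must agree.
    """
    if timepoints is not None and len(set(timepoints)) != 1:
        raise ValueError(f"DE tables come from different timepoints: {timepoints}")
    circ_de, mir_de, mrna_de = _de_ids(de_circ), _de_ids(de_mir), _de_ids(de_mrna)
    counts: dict[tuple[str, str, str], int] = {}
    for s in sites:
        if s.mir_id not in mir_de:
            continue
        if s.target_kind == "circ" and s.target_id in circ_de:
            key = ("circ", s.target_id, s.mir_id)
        elif s.target_kind == "mrna" and s.target_id in mrna_de:
            key = ("mrna", s.mir_id, s.target_id)
        else:
            continue
        counts[key] = counts.get(key, 0) + 1

    circ_rows = sorted(
        (a, b, n) for (kind, a, b), n in counts.items() if kind == "circ"
    )
    mrna_rows = sorted(
        (a, b, n) for (kind, a, b), n in counts.items() if kind == "mrna"
    )
    circ_mir = pd.DataFrame(circ_rows, columns=["circ_id", "mir_id", "site_count"])
    mir_mrna = pd.DataFrame(mrna_rows, columns=["mir_id", "mrna_id", "site_count"])
    return circ_mir, mir_mrna
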