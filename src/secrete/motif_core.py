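"""Detection and scoring of triplet-periodic nucleotide-class runs (SECReTE motifs).

A SECReTE motif is an uninterrupted run of nucleotide triplets carrying a
pyrimidine (Y = C/T) at a fixed position of every triplet.  Within a coding
sequence the three possible positions correspond to the codon positions and
are written YNN (phase 0), NYN (phase 1) and NNY (phase 2).  The same scan
generalises to the other two-letter IUPAC classes (R, K, M, S, W), giving the
NNX motif family.

The scanner reports *maximal* runs only: a run cannot be extended by one more
triplet on either side while keeping the checked base in-class.  A transcript
may carry several motifs, each potentially in a different phase; the SECReTE
count of a transcript is the number of such maximal runs at or above the
length threshold across the configured regions and phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NT_CLASSES",
    "REGIONS",
    "ScanConfig",
    "MotifHit",
    "find_runs",
    "scan_transcript",
    "secrete_count",
    "max_run_length",
    "rry_score",
    "pyrimidine_content",
]

#: Two-letter IUPAC nucleotide classes accepted as the checked-base class.
NT_CLASSES: dict[str, frozenset[str]] = {
    "Y": frozenset("CT"),
    "R": frozenset("AG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
}

#: Recognised scan regions.  FULL concatenates 5'UTR + CDS + 3'UTR and anchors
#: offsets at the transcript 5' end (whole-transcript profiles).
REGIONS = ("5UTR", "CDS", "3UTR", "FULL")


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of a motif scan.

    min_triplets is the SECReTE threshold: 10 selects SECReTE10, the default
    motif definition.  phases restricts the CDS scan to the given codon
    positions; UTRs are always scanned at all three offsets from their own
    5' end because no reading frame applies there.
    """

    min_triplets: int = 10
    nt_class: str = "Y"
    regions: frozenset[str] = frozenset({"CDS"})
    phases: frozenset[int] = frozenset({0, 1, 2})

    def __post_init__(self) -> None:
        if self.min_triplets < 2:
            raise ValueError(f"min_triplets must be >= 2, got {self.min_triplets}")
        if self.nt_class not in NT_CLASSES:
            raise ValueError(f"unknown nucleotide class {self.nt_class!r}")
        object.__setattr__(self, "regions", frozenset(self.regions))
        object.__setattr__(self, "phases", frozenset(self.phases))
        bad = self.regions - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region(s) {sorted(bad)}")
        if not self.phases <= {0, 1, 2}:
            raise ValueError(f"phases must be within {{0,1,2}}, got {sorted(self.phases)}")
        if not self.regions or not self.phases:
            raise ValueError("regions and phases must be non-empty")


@dataclass
class MotifHit:
    """One maximal triplet-periodic run.

    start_nt is the 0-based position, within the scanned region, of the start
    of the first triplet (i.e. the first checked base lies at
    ``start_nt + phase``).  The checked bases are ``start_nt + phase + 3k``
    for ``0 <= k < n_triplets``.  ``sequence`` spans complete triplets from
    ``start_nt`` and is truncated at the region end when fewer than 3 nt
    remain after the last checked base.
    """

    gene_id: str
    region: str
    phase: int
    start_nt: int
    n_triplets: int
    sequence: str
    rry_score: float = math.nan
    overlaps_tmd: bool = False

    def checked_positions(self) -> range:
        """Region-local positions of the in-class bases of this run."""
        first = self.start_nt + self.phase
        return range(first, first + 3 * self.n_triplets, 3)


def _class_mask(seq: str, nt_class: str) -> np.ndarray:
    """Boolean mask over ``seq``: True where the base belongs to ``nt_class``.

    N (and any base outside the class) is False, so an N at a checked
    position breaks a run.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    members = NT_CLASSES[nt_class]
    mask = np.zeros(arr.shape, dtype=bool)
    for base in members:
        mask |= arr == ord(base)
    return mask


def _true_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (half-open) of maximal True stretches."""
    if flags.size == 0:
        return []
    padded = np.empty(flags.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = flags
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def find_runs(
    seq: str,
    phase: int,
    nt_class: str = "Y",
    min_triplets: int = 10,
    *,
    gene_id: str = "",
    region: str = "CDS",
) -> list[MotifHit]:
    """All maximal runs of >= ``min_triplets`` triplets in one phase.

    The checked bases are ``seq[phase::3]``; a run is a maximal stretch of
    consecutive checked bases inside ``nt_class``.  Runs are returned left to
    right and never overlap within a phase.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    if min_triplets < 1:
        raise ValueError("min_triplets must be >= 1")
    if len(seq) <= phase:
        return []
    checked = _class_mask(seq, nt_class)[phase::3]
    hits = []
    for s, e in _true_runs(checked):
        n = e - s
        if n < min_triplets:
            continue
        start_nt = 3 * s
        hits.append(
            MotifHit(
                gene_id=gene_id,
                region=region,
                phase=phase,
                start_nt=start_nt,
                n_triplets=n,
                sequence=seq[start_nt : min(start_nt + 3 * n, len(seq))],
            )
        )
    return hits


def max_run_length(seq: str, phase: int, nt_class: str = "Y") -> int:
    """Length in triplets of the longest maximal run (0 if none).

    This is the per-gene statistic used by the codon-shuffle permutation
    test (the observed motif length).
    """
    if len(seq) <= phase:
        return 0
    checked = _class_mask(seq, nt_class)[phase::3]
    runs = _true_runs(checked)
    return max((e - s for s, e in runs), default=0)


def _tmd_overlap(hit: MotifHit, tmd_intervals: Sequence[tuple[int, int]]) -> bool:
    # Checked bases at region-local positions start+phase+3k fall in codon
    # (pos // 3), i.e. residues s+1 .. s+n (1-based) for a phase-anchored CDS.
    if not tmd_intervals:
        return False
    first_res = hit.start_nt // 3 + 1
    last_res = first_res + hit.n_triplets - 1
    return any(a <= last_res and first_res <= b for a, b in tmd_intervals)


def scan_transcript(transcript, cfg: ScanConfig) -> list[MotifHit]:
    """Scan the configured regions of a transcript.

    The CDS is scanned in the reading frame (phases restricted to
    ``cfg.phases``); each UTR is scanned independently at all three offsets
    from its own 5' end; FULL concatenates 5'UTR + CDS + 3'UTR with offsets
    anchored at the transcript 5' end.  An empty requested region silently
    yields no hits.  ``overlaps_tmd`` is set on CDS hits whose checked bases
    fall in a codon covered by an annotated transmembrane interval, and the
    RRY score of every hit is filled in.
    """
    hits: list[MotifHit] = []
    if "CDS" in cfg.regions and transcript.cds:
        for phase in sorted(cfg.phases):
            for hit in find_runs(
                transcript.cds,
                phase,
                cfg.nt_class,
                cfg.min_triplets,
                gene_id=transcript.gene_id,
                region="CDS",
            ):
                hit.overlaps_tmd = _tmd_overlap(hit, transcript.tmd_intervals)
                hits.append(hit)
    for region, seq in (("5UTR", transcript.utr5), ("3UTR", transcript.utr3)):
        if region in cfg.regions and seq:
            for offset in (0, 1, 2):
                hits.extend(
                    find_runs(
                        seq,
                        offset,
                        cfg.nt_class,
                        cfg.min_triplets,
                        gene_id=transcript.gene_id,
                        region=region,
                    )
                )
    if "FULL" in cfg.regions:
        full = transcript.utr5 + transcript.cds + transcript.utr3
        if full:
            for offset in (0, 1, 2):
                hits.extend(
                    find_runs(
                        full,
                        offset,
                        cfg.nt_class,
                        cfg.min_triplets,
                        gene_id=transcript.gene_id,
                        region="FULL",
                    )
                )
    for hit in hits:
        hit.rry_score = rry_score(hit.sequence)
    return hits


def secrete_count(transcript, cfg: ScanConfig) -> int:
    """Number of maximal motifs at or above the threshold (the SECReTE count)."""
    return len(scan_transcript(transcript, cfg))


_RRY_TEMPLATE = ("R", "R", "Y")


def rry_score(motif_seq: str) -> float:
    """Fraction of bases matching a cyclic purine-purine-pyrimidine template.

    Each base scores 1 when it matches the template letter (R at template
    positions 0 and 1, Y at position 2) and 0 otherwise; the mean is taken
    over the whole motif and the maximum over the three possible template
    offsets is returned.  Distinguishes genuinely RRY-patterned motifs from
    motifs that are merely pyrimidine-rich: a poly-Y stretch conforms to NNY
    yet scores only 1/3 here.
    """
    if not motif_seq:
        raise ValueError("rry_score of an empty sequence is undefined")
    y_mask = _class_mask(motif_seq, "Y")
    r_mask = _class_mask(motif_seq, "R")
    n = len(motif_seq)
    best = 0.0
    for offset in range(3):
        matches = 0
        for i in range(n):
            if _RRY_TEMPLATE[(i + offset) % 3] == "Y":
                matches += bool(y_mask[i])
            else:
                matches += bool(r_mask[i])
        best = max(best, matches / n)
    return best


def pyrimidine_content(seq: str) -> float:
    """(#C + #T) / length; N counts in the denominator only."""
    if not seq:
        raise ValueError("pyrimidine content of an empty sequence is undefined")
    return int(_class_mask(seq, "Y").sum()) / len(seq)
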