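"""Excision of TMD- and signal-sequence-coding regions before rescanning.

Motif enrichment in membrane-protein transcripts could in principle be an
artefact of the hydrophobic codons of transmembrane domains (second-position
pyrimidines) or of signal peptides.  These operations remove the codons for
annotated TMD intervals and/or the signal-sequence coding region (SSCR) and
rescan the concatenated remainder, so that enrichment can be re-assessed
without those segments.  Excision works on whole codons in protein
coordinates; concatenating the flanks may create new runs across the
junction, which are reported as-is.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .motif_core import MotifHit, ScanConfig, scan_transcript

__all__ = ["merge_intervals", "excise_protein_intervals", "remove_sscr", "rescan_after_excision"]


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def excise_protein_intervals(cds: str, intervals: Sequence[tuple[int, int]]) -> str:
    """Remove the codons covered by 1-based inclusive residue intervals.

    Flanks are concatenated in order; overlapping intervals are merged first.
    The output length is the input length minus 3x the number of covered
    residues.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n_res = len(cds) // 3
    merged = merge_intervals(intervals)
    for a, b in merged:
        if a < 1 or b > n_res:
            raise ValueError(f"interval {a}-{b} outside protein of {n_res} residues")
    kept = []
    pos = 0
    for a, b in merged:
        kept.append(cds[pos * 3 : (a - 1) * 3])
        pos = b
    kept.append(cds[pos * 3 :])
    return "".join(kept)


def remove_sscr(cds: str, sscr_len: int) -> str:
    """Drop the first ``sscr_len`` codons (the signal-sequence coding region)."""
    if sscr_len < 0 or 3 * sscr_len > len(cds):
        raise ValueError(f"sscr_len {sscr_len} outside protein length")
    return cds[3 * sscr_len :]


def rescan_after_excision(transcript, mode: str, cfg: ScanConfig) -> list[MotifHit]:
    """Scan the CDS after removing TMD codons, the SSCR, or both.

    mode is one of "TMD", "SSCR", "both".  Hit coordinates are reported in
    excised-sequence space and each hit's region is tagged with the mode
    (e.g. ``CDS-TMD``).  Only the CDS is scanned.
    """
    if mode not in ("TMD", "SSCR", "both"):
        raise ValueError(f"mode must be TMD, SSCR or both, got {mode!r}")
    cds = transcript.cds
    intervals: list[tuple[int, int]] = []
    if mode in ("TMD", "both"):
        intervals.extend(transcript.tmd_intervals)
    if mode in ("SSCR", "both") and transcript.sscr_len:
        intervals.append((1, transcript.sscr_len))
    cds = excise_protein_intervals(cds, intervals)
    shadow = replace_cds(transcript, cds)
    hits = scan_transcript(shadow, ScanConfig(cfg.min_triplets, cfg.nt_class, {"CDS"}, cfg.phases))
    tag = f"CDS-{mode}"
    return [replace(h, region=tag, overlaps_tmd=False) for h in hits]


def replace_cds(transcript, new_cds: str):
    """Copy of a transcript with a different CDS and no interval annotations."""
    from .sequence_io import Transcript

    return Transcript(
        gene_id=transcript.gene_id,
        cds=new_cds,
        utr5=transcript.utr5,
        utr3=transcript.utr3,
        is_secretome=transcript.is_secretome,
        groups=set(transcript.groups),
    )
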