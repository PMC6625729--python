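"""Synthetic labelled transcriptomes with planted, exactly recoverable motifs.

The generator emulates the contrasts the statistics layer is meant to
detect: a "secretome" gene class carrying planted triplet-periodic NNY runs
(and optionally hydrophobic TMD-like codon stretches producing NYN runs) and
a "non-secretome" class carrying shorter decoy runs.  Coding sequences are
codon-composed from a usage table (ATG start, single terminal stop, no
internal stops); planted CDS runs at the third codon position are produced
by the same synonymous third-position substitutions the recoder applies, so
the planted window stays a plausible protein.  UTRs are random nucleotide
stretches; UTR runs are planted by direct substitution.

Two properties make the truth table exact rather than approximate:

* flank enforcement - the checked base immediately before and after every
  planted run is forced to a purine, so the scanner reports exactly the
  planted coordinates and length;
* background capping - any accidental in-class run longer than
  ``background_max_run`` triplets (in any phase/offset, outside planted
  structure) is broken by resampling one codon/base, so planted runs are the
  only runs at or above the decoy threshold.

All randomness flows through per-gene streams derived from (seed, gene_id),
so generation is deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .motif_core import _class_mask, _true_runs
from .recoder import CodonUsageTable, _codon_to_aa, _PLUS_SUB, default_yeast_usage
from .sequence_io import Transcript, write_fasta
from .stats import gene_rng

__all__ = [
    "PlantedMotifSpec",
    "PlantedTMDSpec",
    "SimulationSpec",
    "generate_transcriptome",
    "plant_tmd",
    "null_transcriptome",
    "write_dataset",
    "HYDROPHOBIC_PURINE3_POOL",
]

_PYR = "CT"
_PUR = "AG"

#: Hydrophobic codons with a pyrimidine second base and a purine third base:
#: a TMD-like stretch of these yields an NYN run without an NNY run.
HYDROPHOBIC_PURINE3_POOL = ("CTA", "CTG", "TTA", "TTG", "GTA", "GTG", "ATA")


@dataclass(frozen=True)
class PlantedMotifSpec:
    """Distribution of planted runs for one gene class.

    phase is the CDS codon position of the checked base; for UTR regions the
    scan offset is drawn at random per gene when phase is None.
    """

    min_triplets: int = 10
    max_triplets: int = 14
    phase: int | None = 2
    region: str = "CDS"
    prob: float = 1.0

    def __post_init__(self):
        if not 2 <= self.min_triplets <= self.max_triplets:
            raise ValueError("need 2 <= min_triplets <= max_triplets")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must lie in [0, 1]")
        if self.region not in ("CDS", "5UTR", "3UTR"):
            raise ValueError(f"unknown planting region {self.region!r}")


@dataclass(frozen=True)
class PlantedTMDSpec:
    """A planted stretch of hydrophobic codons (transmembrane-domain mimic)."""

    length: int = 21
    prob: float = 0.0
    pool: tuple[str, ...] = HYDROPHOBIC_PURINE3_POOL

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("length must be non-negative")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions of one synthetic transcriptome.

    Defaults: 400 secretome genes carrying one planted 10-14-triplet NNY run
    each, 400 non-secretome genes carrying one 5-9-triplet decoy each, CDS
    lengths of 150-600 codons drawn on budding-yeast codon usage, and
    background runs capped at 4 triplets.
    """

    n_secretome: int = 400
    n_non_secretome: int = 400
    cds_len_range: tuple[int, int] = (150, 600)
    utr5_len_range: tuple[int, int] = (30, 150)
    utr3_len_range: tuple[int, int] = (50, 300)
    usage: CodonUsageTable = field(default_factory=default_yeast_usage)
    motif_secretome: PlantedMotifSpec = PlantedMotifSpec(10, 14, 2, "CDS", 1.0)
    motif_non_secretome: PlantedMotifSpec = PlantedMotifSpec(5, 9, 2, "CDS", 1.0)
    tmd_secretome: PlantedTMDSpec = PlantedTMDSpec(21, 0.0)
    tmd_non_secretome: PlantedTMDSpec = PlantedTMDSpec(21, 0.0)
    background_max_run: int = 4
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.cds_len_range, self.utr5_len_range, self.utr3_len_range):
            if lo < 0 or lo > hi:
                raise ValueError("length ranges must satisfy 0 <= lo <= hi")
        if self.cds_len_range[0] < 10:
            raise ValueError("CDS length range too short for planting")
        if self.background_max_run < 1:
            raise ValueError("background_max_run must be >= 1")


class _Pools:
    """Usage-weighted codon pools, filtered on per-position base-class needs."""

    def __init__(self, usage: CodonUsageTable):
        self.usage = usage
        codon_aa = _codon_to_aa(usage.table_id)
        self.sense = sorted(c for c, aa in codon_aa.items() if aa != "*")
        self.stops = sorted(c for c, aa in codon_aa.items() if aa == "*")
        self.codon_aa = codon_aa
        # codons whose synonymous plus-edit ends in a pyrimidine
        self.plus_editable = [c for c in self.sense if self.plus_edit(c)[2] in _PYR]
        self._cache: dict[tuple, tuple[list[str], np.ndarray]] = {}

    def plus_edit(self, codon: str) -> str:
        third = codon[2]
        if third in _PLUS_SUB:
            cand = codon[:2] + _PLUS_SUB[third]
            if self.codon_aa[cand] == self.codon_aa[codon]:
                return cand
        return codon

    def _weights(self, codons) -> np.ndarray:
        w = np.array([self.usage.freq[c] for c in codons], dtype=float)
        total = w.sum()
        if total <= 0:  # degenerate usage table: fall back to uniform
            return np.full(len(codons), 1.0 / len(codons))
        return w / total

    def draw(self, rng, codons) -> str:
        key = tuple(codons)
        if key not in self._cache:
            self._cache[key] = (list(codons), self._weights(codons))
        pool, probs = self._cache[key]
        return pool[rng.choice(len(pool), p=probs)]

    def constrained(self, need: dict[int, str]) -> list[str]:
        """Sense codons with the required base class at each given position."""
        out = []
        for c in self.sense:
            ok = True
            for j, cls in need.items():
                if c[j] not in (_PYR if cls == "Y" else _PUR):
                    ok = False
                    break
            if ok:
                out.append(c)
        return out


def _break_cds_runs(codons, constraints, max_run, pools, rng) -> None:
    """Resample codons until no unplanted in-class run exceeds max_run.

    constraints maps absolute nt positions to a required class ("Y" for
    planted checked bases, "R" for enforced flanks); constrained positions
    are never altered, and a replacement codon must honour every constrained
    position it covers.  The start and stop codons are left untouched.
    """
    n = len(codons)
    for _ in range(300):
        changed = False
        seq = "".join(codons)
        mask = _class_mask(seq, "Y")
        for q in range(3):
            for s, e in _true_runs(mask[q::3]):
                if e - s <= max_run:
                    continue
                cand = [k for k in range(s, e)
                        if (3 * k + q) not in constraints and 0 < k < n - 1]
                if not cand:
                    continue  # planted run: protected
                k = cand[len(cand) // 2]
                need = {q: "R"}
                for j in range(3):
                    if j != q and (3 * k + j) in constraints:
                        need[j] = constraints[3 * k + j]
                pool = pools.constrained(need)
                if not pool:
                    continue
                codons[k] = pools.draw(rng, pool)
                changed = True
        if not changed:
            return
    raise RuntimeError("background capping did not converge")


def _break_utr_runs(bases, constraints, max_run, rng) -> None:
    """UTR analogue of _break_cds_runs: flip one unconstrained base per run."""
    for _ in range(300):
        changed = False
        seq = "".join(bases)
        mask = _class_mask(seq, "Y")
        for off in range(3):
            for s, e in _true_runs(mask[off::3]):
                if e - s <= max_run:
                    continue
                cand = [k for k in range(s, e) if (off + 3 * k) not in constraints]
                if not cand:
                    continue
                k = cand[len(cand) // 2]
                bases[off + 3 * k] = rng.choice(list(_PUR))
                changed = True
        if not changed:
            return
    raise RuntimeError("background capping did not converge")


def _plant_cds_motif(codons, constraints, forbidden, mspec, pools, rng):
    """Plant one exact NNY/NYN/YNN run of L triplets; returns a truth record."""
    n = len(codons)
    L = int(rng.integers(mspec.min_triplets, mspec.max_triplets + 1))
    p = mspec.phase if mspec.phase is not None else int(rng.integers(0, 3))
    w_min = 2 if p == 1 else 1  # ATG carries a pyrimidine at codon position 1
    w_max = (n - 2 if p == 0 else n - 1) - L  # stop codons start with T
    if w_max < w_min:
        raise ValueError(
            f"cannot plant a {L}-triplet run in a {n}-codon CDS (phase {p})"
        )
    for _ in range(200):
        w = int(rng.integers(w_min, w_max + 1))
        span = set(range(w - 1, w + L + 1))
        if not span & forbidden:
            break
    else:
        raise ValueError("no room to plant motif clear of the TMD interval")
    for k in range(w, w + L):
        if p == 2:
            codons[k] = pools.plus_edit(pools.draw(rng, pools.plus_editable))
        else:
            codons[k] = pools.draw(rng, pools.constrained({p: "Y"}))
        constraints[3 * k + p] = "Y"
    for k in (w - 1, w + L):
        if 0 < k < n - 1:
            need = {p: "R"}
            for j in range(3):
                if j != p and (3 * k + j) in constraints:
                    need[j] = constraints[3 * k + j]
            codons[k] = pools.draw(rng, pools.constrained(need))
        constraints[3 * k + p] = "R"
    forbidden |= set(range(w - 1, w + L + 1))
    return {"region": "CDS", "phase": p, "start_nt": 3 * w, "n_triplets": L}


def _plant_cds_tmd(codons, constraints, tspec, pools, rng):
    """Replace an interior codon stretch with hydrophobic NYN-pool codons."""
    n = len(codons)
    Lt = tspec.length
    if Lt == 0:
        return None, set()
    s_max = n - 2 - Lt
    if s_max < 2:
        raise ValueError(f"CDS of {n} codons too short for a {Lt}-residue TMD")
    s = int(rng.integers(2, s_max + 1))
    for k in range(s, s + Lt):
        codons[k] = pools.draw(rng, list(tspec.pool))
        constraints[3 * k + 1] = "Y"
    for k in (s - 1, s + Lt):
        if 0 < k < n - 1:
            need = {1: "R"}
            codons[k] = pools.draw(rng, pools.constrained(need))
        constraints[3 * k + 1] = "R"
    interval = (s + 1, s + Lt)  # 1-based inclusive residues
    return interval, set(range(s - 1, s + Lt + 1))


def _random_utr(length: int, rng) -> list[str]:
    # AT-rich background, loosely mimicking yeast untranslated regions
    return list(rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3]))


def _plant_utr_motif(bases, constraints, mspec, rng):
    length = len(bases)
    L = int(rng.integers(mspec.min_triplets, mspec.max_triplets + 1))
    off = mspec.phase if mspec.phase is not None else int(rng.integers(0, 3))
    # need flank checked positions on both sides: off+3(s-1) >= 0, off+3(s+L) < len
    s_max = (length - 1 - off) // 3 - L
    if s_max < 1:
        raise ValueError(f"cannot plant a {L}-triplet run in a {length}-nt UTR")
    s = int(rng.integers(1, s_max + 1))
    for k in range(s, s + L):
        pos = off + 3 * k
        bases[pos] = rng.choice(list(_PYR))
        constraints[pos] = "Y"
    for k in (s - 1, s + L):
        pos = off + 3 * k
        bases[pos] = rng.choice(list(_PUR))
        constraints[pos] = "R"
    return {"phase": off, "start_nt": 3 * s, "n_triplets": L}


def _make_gene(gene_id, is_secretome, mspec, tspec, spec, pools, rng):
    n = int(rng.integers(spec.cds_len_range[0], spec.cds_len_range[1] + 1))
    codons = (
        ["ATG"]
        + [pools.draw(rng, pools.sense) for _ in range(n - 2)]
        + [pools.draw(rng, pools.stops)]
    )
    constraints: dict[int, str] = {}
    truth_rows = []
    tmd_interval = None
    forbidden: set[int] = set()
    if tspec.length > 0 and rng.random() < tspec.prob:
        tmd_interval, tmd_span = _plant_cds_tmd(codons, constraints, tspec, pools, rng)
        forbidden |= tmd_span
        if tmd_interval is not None:
            truth_rows.append(
                {"gene_id": gene_id, "kind": "tmd", "region": "CDS", "phase": 1,
                 "start_nt": 3 * (tmd_interval[0] - 1), "n_triplets": tspec.length}
            )
    plant_motif = rng.random() < mspec.prob
    if plant_motif and mspec.region == "CDS":
        rec = _plant_cds_motif(codons, constraints, forbidden, mspec, pools, rng)
        truth_rows.append({"gene_id": gene_id, "kind": "motif", **rec})
    _break_cds_runs(codons, constraints, spec.background_max_run, pools, rng)

    utrs = {}
    for region, rng_range in (("5UTR", spec.utr5_len_range), ("3UTR", spec.utr3_len_range)):
        lo, hi = rng_range
        length = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        bases = _random_utr(length, rng)
        u_constraints: dict[int, str] = {}
        if plant_motif and mspec.region == region:
            rec = _plant_utr_motif(bases, u_constraints, mspec, rng)
            truth_rows.append({"gene_id": gene_id, "kind": "motif", "region": region, **rec})
        if length:
            _break_utr_runs(bases, u_constraints, spec.background_max_run, rng)
        utrs[region] = "".join(bases)

    groups = set()
    if is_secretome:
        groups.add("TMD" if tmd_interval else "SS")
    elif tmd_interval:
        groups.add("TMD")
    transcript = Transcript(
        gene_id=gene_id,
        cds="".join(codons),
        utr5=utrs["5UTR"],
        utr3=utrs["3UTR"],
        is_secretome=is_secretome,
        groups=groups,
        tmd_intervals=[tmd_interval] if tmd_interval else [],
    )
    return transcript, truth_rows


_TRUTH_COLUMNS = ["gene_id", "kind", "region", "phase", "start_nt", "n_triplets"]


def generate_transcriptome(spec: SimulationSpec) -> tuple[list[Transcript], pd.DataFrame]:
    """Generate the labelled transcriptome and its planted-structure truth table.

    The truth table has one row per planted motif/TMD with exact region-local
    coordinates (0-based ``start_nt`` of the first triplet, as MotifHit
    reports them), phase/offset and triplet length.  Identical specs produce
    byte-identical output.
    """
    pools = _Pools(spec.usage)
    transcripts: list[Transcript] = []
    rows: list[dict] = []
    jobs = [(f"SEC{i:04d}", True, spec.motif_secretome, spec.tmd_secretome)
            for i in range(spec.n_secretome)]
    jobs += [(f"NSC{i:04d}", False, spec.motif_non_secretome, spec.tmd_non_secretome)
             for i in range(spec.n_non_secretome)]
    for gene_id, is_sec, mspec, tspec in jobs:
        rng = gene_rng(spec.seed, gene_id)
        transcript, truth_rows = _make_gene(gene_id, is_sec, mspec, tspec, spec, pools, rng)
        transcripts.append(transcript)
        rows.extend(truth_rows)
    truth = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return transcripts, truth


def plant_tmd(
    transcript: Transcript,
    length: int,
    rng: np.random.Generator,
    pool: tuple[str, ...] = HYDROPHOBIC_PURINE3_POOL,
    usage: CodonUsageTable | None = None,
) -> tuple[Transcript, tuple[int, int] | None]:
    """Insert a hydrophobic codon stretch into a transcript's CDS.

    Replaces ``length`` interior codons with draws from ``pool`` and records
    the 1-based inclusive protein interval.  length 0 returns the transcript
    unchanged.
    """
    if length == 0:
        return transcript, None
    pools = _Pools(usage or default_yeast_usage())
    codons = [transcript.cds[i: i + 3] for i in range(0, len(transcript.cds), 3)]
    n = len(codons)
    if n - 2 - length < 1:
        raise ValueError(f"CDS of {n} codons too short for a {length}-residue stretch")
    s = int(rng.integers(1, n - 1 - length))
    for k in range(s, s + length):
        codons[k] = pools.draw(rng, list(pool))
    interval = (s + 1, s + length)
    return (
        replace(
            transcript,
            cds="".join(codons),
            tmd_intervals=transcript.tmd_intervals + [interval],
        ),
        interval,
    )


def null_transcriptome(spec: SimulationSpec) -> tuple[list[Transcript], pd.DataFrame]:
    """As generate_transcriptome, but with class labels randomly permuted.

    Sequences keep whatever was planted for their original class; labels are
    then reassigned independently of sequence, giving the calibration null
    for AUC (~0.5) and chi-squared (uniform p).
    """
    transcripts, truth = generate_transcriptome(spec)
    rng = np.random.default_rng([spec.seed, 0x5EC7E7E])
    labels = [t.is_secretome for t in transcripts]
    perm = rng.permutation(len(labels))
    for t, i in zip(transcripts, perm):
        t.is_secretome = labels[i]
    return transcripts, truth


def write_dataset(
    transcripts: list[Transcript], truth: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Emit the dataset in the formats sequence_io reads.

    Writes cds.fasta, utr5.fasta, utr3.fasta (non-empty records only),
    annotations.tsv and truth.tsv under ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds": outdir / "cds.fasta",
        "utr5": outdir / "utr5.fasta",
        "utr3": outdir / "utr3.fasta",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta({t.gene_id: t.cds for t in transcripts}, paths["cds"])
    write_fasta({t.gene_id: t.utr5 for t in transcripts if t.utr5}, paths["utr5"])
    write_fasta({t.gene_id: t.utr3 for t in transcripts if t.utr3}, paths["utr3"])
    with open(paths["annotations"], "w") as fh:
        fh.write("gene_id\tis_secretome\tgroups\ttmd_intervals\tsscr_len\n")
        for t in transcripts:
            intervals = ";".join(f"{a}-{b}" for a, b in t.tmd_intervals)
            fh.write(
                f"{t.gene_id}\t{int(t.is_secretome)}\t{';'.join(sorted(t.groups))}\t"
                f"{intervals}\t{t.sscr_len}\n"
            )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
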