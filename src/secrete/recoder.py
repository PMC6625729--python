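"""Synonymous (+)/(-)SECReTE recoding of coding sequences and CAI bookkeeping.

(+)SECReTE recoding raises the NNY signal of a CDS by substituting every
third-codon-position A with T and G with C wherever the substitution is
synonymous; (-)SECReTE applies the mirror substitution (T -> A, C -> G).
Because the synonymy guard skips any substitution that would change the
encoded amino acid, the protein sequence is invariant by construction and
stop codons are never touched.  Some motifs can survive (-) recoding where
synonymy blocks the substitution (e.g. NYN-based runs through hydrophobic
stretches).

The Codon Adaptation Index (CAI) is the geometric mean over codons of the
relative adaptiveness w(c) = f(c) / max f among the codon's synonyms,
excluding the single-synonym codons ATG and TGG and the stop codons
(Sharp & Li convention).  It is reported before and after recoding so that
variants can be kept within a similar codon-optimality range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Data import CodonTable

from .motif_core import ScanConfig, find_runs

__all__ = [
    "CodonUsageTable",
    "RecodeResult",
    "default_yeast_usage",
    "plus_secrete",
    "minus_secrete",
    "cai",
    "recode_report",
    "recode_utr",
    "translate",
]

# S. cerevisiae codon usage, frequencies per 1,000 codons (standard reference
# values).  Used as the default background for CAI and for the synthetic
# transcriptome generator.
_YEAST_USAGE_PER_1000 = {
    "TTT": 26.1, "TTC": 18.4, "TTA": 26.2, "TTG": 27.2,
    "CTT": 12.3, "CTC": 5.4, "CTA": 13.4, "CTG": 10.5,
    "ATT": 30.1, "ATC": 17.2, "ATA": 17.8, "ATG": 20.9,
    "GTT": 22.1, "GTC": 11.8, "GTA": 11.8, "GTG": 10.8,
    "TCT": 23.5, "TCC": 14.2, "TCA": 18.7, "TCG": 8.6,
    "CCT": 13.5, "CCC": 6.8, "CCA": 18.3, "CCG": 5.3,
    "ACT": 20.3, "ACC": 12.7, "ACA": 17.8, "ACG": 8.0,
    "GCT": 21.2, "GCC": 12.6, "GCA": 16.2, "GCG": 6.2,
    "TAT": 18.8, "TAC": 14.8, "TAA": 1.1, "TAG": 0.5,
    "CAT": 13.6, "CAC": 7.8, "CAA": 27.3, "CAG": 12.1,
    "AAT": 35.7, "AAC": 24.8, "AAA": 41.9, "AAG": 30.8,
    "GAT": 37.6, "GAC": 20.2, "GAA": 45.6, "GAG": 19.2,
    "TGT": 8.1, "TGC": 4.8, "TGA": 0.7, "TGG": 10.4,
    "CGT": 6.4, "CGC": 2.6, "CGA": 3.0, "CGG": 1.7,
    "AGT": 14.2, "AGC": 9.8, "AGA": 21.3, "AGG": 9.2,
    "GGT": 23.9, "GGC": 9.8, "GGA": 10.9, "GGG": 6.0,
}


def _codon_to_aa(table_id: int = 1) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass
class CodonUsageTable:
    """Codon frequencies and derived relative adaptiveness w(c).

    w(c) = f(c) / max frequency among the codon's synonyms; stop codons are
    kept in the frequency map but excluded from w.
    """

    freq: dict[str, float]
    table_id: int = 1
    w: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        codon_aa = _codon_to_aa(self.table_id)
        sense = [c for c, aa in codon_aa.items() if aa != "*"]
        missing = [c for c in sense if c not in self.freq]
        if missing:
            raise ValueError(f"usage table lacks sense codon(s) {missing}")
        if any(f < 0 for f in self.freq.values()):
            raise ValueError("codon frequencies must be non-negative")
        by_aa: dict[str, float] = {}
        for c in sense:
            aa = codon_aa[c]
            by_aa[aa] = max(by_aa.get(aa, 0.0), self.freq[c])
        self.w = {}
        for c in sense:
            m = by_aa[codon_aa[c]]
            if m <= 0:
                raise ValueError(f"all synonyms of codon {c} have zero frequency")
            self.w[c] = self.freq[c] / m

    @classmethod
    def from_tsv(cls, path: str | Path, table_id: int = 1) -> "CodonUsageTable":
        """Read a TSV with columns codon, frequency."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"codon", "frequency"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns codon, frequency")
        return cls(
            freq={str(c).upper().replace("U", "T"): float(f)
                  for c, f in zip(df["codon"], df["frequency"])},
            table_id=table_id,
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tfrequency\n")
            for codon in sorted(self.freq):
                fh.write(f"{codon}\t{self.freq[codon]}\n")


def default_yeast_usage() -> CodonUsageTable:
    """The built-in budding-yeast codon usage table."""
    return CodonUsageTable(freq=dict(_YEAST_USAGE_PER_1000))


@dataclass
class RecodeResult:
    """Outcome of one (+)/(-) recoding of a CDS."""

    original: str
    recoded: str
    direction: str
    n_substitutions: int
    n_blocked: int
    motif_count_before: int
    motif_count_after: int
    cai_before: float = math.nan
    cai_after: float = math.nan
    protein: str = ""

    def summary(self) -> dict:
        return {
            "direction": self.direction,
            "length_nt": len(self.original),
            "n_substitutions": self.n_substitutions,
            "n_blocked": self.n_blocked,
            "motif_count_before": self.motif_count_before,
            "motif_count_after": self.motif_count_after,
            "cai_before": self.cai_before,
            "cai_after": self.cai_after,
        }


_PLUS_SUB = {"A": "T", "G": "C"}
_MINUS_SUB = {"T": "A", "C": "G"}


def translate(cds: str, table_id: int = 1) -> str:
    """Protein sequence including a trailing '*' for a terminal stop codon."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codon_aa = _codon_to_aa(table_id)
    try:
        return "".join(codon_aa[cds[i : i + 3]] for i in range(0, len(cds), 3))
    except KeyError as exc:
        raise ValueError(f"cannot translate codon {exc.args[0]!r}") from None


def _check_cds(cds: str, table_id: int) -> str:
    protein = translate(cds, table_id)
    if "*" in protein[:-1]:
        pos = protein.index("*") + 1
        raise ValueError(f"internal stop codon at residue {pos}")
    return protein


def _recode(cds: str, substitution: Mapping[str, str], table_id: int) -> tuple[str, int, int]:
    codon_aa = _codon_to_aa(table_id)
    out = []
    n_sub = n_blocked = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        third = codon[2]
        if third in substitution:
            candidate = codon[:2] + substitution[third]
            if codon_aa[candidate] == codon_aa[codon]:
                out.append(candidate)
                n_sub += candidate != codon
                continue
            n_blocked += 1
        out.append(codon)
    return "".join(out), n_sub, n_blocked


def _motif_count(cds: str, cfg: ScanConfig) -> int:
    return sum(
        len(find_runs(cds, p, cfg.nt_class, cfg.min_triplets)) for p in sorted(cfg.phases)
    )


_DEFAULT_CFG = ScanConfig(min_triplets=10, nt_class="Y", regions=frozenset({"CDS"}),
                          phases=frozenset({2}))


def plus_secrete(
    cds: str,
    table_id: int = 1,
    usage: CodonUsageTable | None = None,
    cfg: ScanConfig = _DEFAULT_CFG,
) -> RecodeResult:
    """Raise the NNY signal: third-position A -> T and G -> C where synonymous."""
    protein = _check_cds(cds, table_id)
    recoded, n_sub, n_blocked = _recode(cds, _PLUS_SUB, table_id)
    return _build_result(cds, recoded, "plus", n_sub, n_blocked, protein, usage, cfg)


def minus_secrete(
    cds: str,
    table_id: int = 1,
    usage: CodonUsageTable | None = None,
    cfg: ScanConfig = _DEFAULT_CFG,
) -> RecodeResult:
    """Lower the NNY signal: third-position T -> A and C -> G where synonymous."""
    protein = _check_cds(cds, table_id)
    recoded, n_sub, n_blocked = _recode(cds, _MINUS_SUB, table_id)
    return _build_result(cds, recoded, "minus", n_sub, n_blocked, protein, usage, cfg)


def _build_result(cds, recoded, direction, n_sub, n_blocked, protein, usage, cfg):
    result = RecodeResult(
        original=cds,
        recoded=recoded,
        direction=direction,
        n_substitutions=n_sub,
        n_blocked=n_blocked,
        motif_count_before=_motif_count(cds, cfg),
        motif_count_after=_motif_count(recoded, cfg),
        protein=protein,
    )
    if usage is not None:
        result.cai_before = cai(cds, usage)
        result.cai_after = cai(recoded, usage)
    return result


def cai(cds: str, usage: CodonUsageTable) -> float:
    """Codon Adaptation Index: geometric mean of w over the CDS.

    ATG, TGG and stop codons are excluded.  A CDS consisting only of excluded
    codons has an undefined CAI and raises.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codon_aa = _codon_to_aa(usage.table_id)
    log_sum = 0.0
    n = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in codon_aa:
            raise ValueError(f"unknown codon {codon!r}")
        if codon in ("ATG", "TGG") or codon_aa[codon] == "*":
            continue
        w = usage.w.get(codon)
        if w is None:
            raise ValueError(f"codon {codon!r} absent from usage table")
        if w <= 0:
            raise ValueError(f"codon {codon!r} has zero adaptiveness; CAI undefined")
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError("CAI undefined: no informative codons")
    return math.exp(log_sum / n)


def recode_report(
    transcript,
    direction: str,
    cfg: ScanConfig = _DEFAULT_CFG,
    usage: CodonUsageTable | None = None,
    table_id: int = 1,
) -> tuple[RecodeResult, dict]:
    """Recode a transcript's CDS and summarise motif/CAI changes.

    Besides the motif counts at the configured threshold, the summary carries
    per-triplet counts (threshold 1) before and after, i.e. the number of
    maximal NNY runs of any length, for whole-gene profile comparisons.
    """
    usage = usage if usage is not None else default_yeast_usage()
    fn = {"plus": plus_secrete, "minus": minus_secrete}.get(direction)
    if fn is None:
        raise ValueError(f"direction must be 'plus' or 'minus', got {direction!r}")
    result = fn(transcript.cds, table_id=table_id, usage=usage, cfg=cfg)
    profile_before = sum(
        len(find_runs(result.original, p, cfg.nt_class, 1)) for p in sorted(cfg.phases)
    )
    profile_after = sum(
        len(find_runs(result.recoded, p, cfg.nt_class, 1)) for p in sorted(cfg.phases)
    )
    summary = {"gene_id": transcript.gene_id, **result.summary(),
               "runs_any_length_before": profile_before,
               "runs_any_length_after": profile_after}
    return result, summary


def recode_utr(seq: str, direction: str) -> str:
    """Unconditional (+)/(-) substitution for untranslated regions.

    No synonymy constraint applies outside a reading frame, so every A/G
    (plus) or T/C (minus) is substituted at every position.
    """
    sub = {"plus": _PLUS_SUB, "minus": _MINUS_SUB}.get(direction)
    if sub is None:
        raise ValueError(f"direction must be 'plus' or 'minus', got {direction!r}")
    return "".join(sub.get(b, b) for b in seq)
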