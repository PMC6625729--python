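"""Reading transcript sequences and annotations; writing motif and stats tables.

Input sequences arrive as multi-record FASTA (one file per region: CDS, 5'UTR,
3'UTR, keyed by gene id) or as a genome FASTA plus GFF3 feature annotations.
Gene-level metadata (secretome flag, group labels, transmembrane intervals,
signal-sequence length) comes from a tab-separated table.

All coordinates are 0-based half-open internally; emitted tables are 1-based
inclusive and say so in a header comment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .motif_core import MotifHit

logger = logging.getLogger("secrete")

__all__ = [
    "Transcript",
    "GeneValueTable",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "assemble_transcripts",
    "read_gff3_transcripts",
    "write_motif_table",
    "read_motif_table",
    "read_gene_values",
]

# IUPAC nucleotide codes; ambiguity codes other than N are collapsed to N at
# ingest so downstream code only ever sees A/C/G/T/N.
_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIG_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHV"})


@dataclass
class Transcript:
    """A gene's sequences plus the annotations the analyses need.

    tmd_intervals are 1-based inclusive protein coordinates; sscr_len is the
    number of signal-peptide residues (0 if none).
    """

    gene_id: str
    cds: str
    utr5: str = ""
    utr3: str = ""
    is_secretome: bool = False
    groups: set[str] = field(default_factory=set)
    tmd_intervals: list[tuple[int, int]] = field(default_factory=list)
    sscr_len: int = 0

    def __post_init__(self) -> None:
        n_res = len(self.cds) // 3
        for a, b in self.tmd_intervals:
            if not (1 <= a <= b <= n_res):
                raise ValueError(
                    f"{self.gene_id}: TMD interval {a}-{b} outside protein of {n_res} residues"
                )
        if not 0 <= self.sscr_len <= n_res:
            raise ValueError(f"{self.gene_id}: sscr_len {self.sscr_len} exceeds protein length")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    @property
    def length(self) -> int:
        return len(self.utr5) + len(self.cds) + len(self.utr3)


@dataclass
class GeneValueTable:
    """Per-gene numeric values (e.g. an ER-enrichment log-ratio) from one source."""

    values: dict[str, float]
    source: str = ""

    def split_by(self, gene_ids: Iterable[str]) -> tuple[list[float], list[float]]:
        """Values for genes in the given set vs all remaining genes."""
        members = set(gene_ids)
        inside = [v for g, v in self.values.items() if g in members]
        outside = [v for g, v in self.values.items() if g not in members]
        return inside, outside


def _normalize(seq: str, record_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(
            f"record {record_id!r}: non-IUPAC character(s) {sorted(bad)} in sequence"
        )
    return seq.replace("U", "T").translate(_AMBIG_TO_N)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Sequences are uppercased, U is mapped to T and ambiguity codes other
    than N are collapsed to N.  Duplicate ids and non-IUPAC characters are
    hard errors.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        out[record.id] = _normalize(str(record.seq), record.id)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write an id -> sequence map as wrapped FASTA (insertion order preserved)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")


def _parse_intervals(text: str, line_no: int) -> list[tuple[int, int]]:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return []
    intervals = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            a_s, b_s = chunk.split("-")
            a, b = int(a_s), int(b_s)
        except ValueError:
            raise ValueError(f"line {line_no}: malformed interval {chunk!r}") from None
        if a < 1 or a > b:
            raise ValueError(f"line {line_no}: invalid interval {chunk!r} (start > end or < 1)")
        intervals.append((a, b))
    return intervals


_ANNOT_REQUIRED = ("gene_id", "is_secretome")
_ANNOT_OPTIONAL = ("groups", "tmd_intervals", "sscr_len")


def read_annotations(path: str | Path) -> dict[str, dict]:
    """Read the gene annotation TSV into gene_id -> record dicts.

    Required columns: gene_id, is_secretome.  Optional: groups
    (semicolon/comma separated labels), tmd_intervals ("s1-e1;s2-e2",
    1-based inclusive protein coordinates), sscr_len.  Unknown columns are
    ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _ANNOT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks required column(s) {missing}")
    unknown = [c for c in df.columns if c not in _ANNOT_REQUIRED + _ANNOT_OPTIONAL]
    if unknown:
        logger.warning("annotation table %s: ignoring unknown column(s) %s", path, unknown)
    out: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        gene = row["gene_id"]
        if gene in out:
            raise ValueError(f"line {line_no}: duplicate gene_id {gene!r}")
        groups_text = row.get("groups", "")
        groups = set()
        if isinstance(groups_text, str) and groups_text:
            groups = {g.strip() for g in groups_text.replace(",", ";").split(";") if g.strip()}
        sscr = row.get("sscr_len", "")
        out[gene] = {
            "is_secretome": str(row["is_secretome"]).strip() in ("1", "True", "true", "yes"),
            "groups": groups,
            "tmd_intervals": _parse_intervals(row.get("tmd_intervals", ""), line_no),
            "sscr_len": int(sscr) if isinstance(sscr, str) and sscr.strip() else 0,
        }
    return out


def assemble_transcripts(
    cds_map: Mapping[str, str],
    utr5_map: Mapping[str, str] | None = None,
    utr3_map: Mapping[str, str] | None = None,
    annotations: Mapping[str, dict] | None = None,
) -> tuple[list[Transcript], int]:
    """Join per-region sequences and annotations into Transcript records.

    Genes whose CDS length is not a multiple of 3 are excluded (per-codon
    analyses are undefined for them); the exclusion count is returned and
    logged.  Annotated genes missing a CDS are an error; genes without an
    annotation row default to non-secretome with no intervals.
    """
    utr5_map = utr5_map or {}
    utr3_map = utr3_map or {}
    annotations = annotations or {}
    missing = sorted(set(annotations) - set(cds_map))
    if missing:
        raise ValueError(f"annotated gene(s) missing a CDS: {missing}")
    transcripts: list[Transcript] = []
    excluded = 0
    for gene, cds in cds_map.items():
        if len(cds) % 3 != 0:
            logger.info("excluding %s: CDS length %d not divisible by 3", gene, len(cds))
            excluded += 1
            continue
        ann = annotations.get(gene, {})
        transcripts.append(
            Transcript(
                gene_id=gene,
                cds=cds,
                utr5=utr5_map.get(gene, ""),
                utr3=utr3_map.get(gene, ""),
                is_secretome=ann.get("is_secretome", False),
                groups=set(ann.get("groups", set())),
                tmd_intervals=list(ann.get("tmd_intervals", [])),
                sscr_len=ann.get("sscr_len", 0),
            )
        )
    if excluded:
        logger.info("excluded %d gene(s) with CDS length not divisible by 3", excluded)
    return transcripts, excluded


def read_gff3_transcripts(
    gff_path: str | Path,
    genome_fasta: str | Path,
    annotations: Mapping[str, dict] | None = None,
) -> tuple[list[Transcript], int]:
    """Assemble transcripts from a genome FASTA + GFF3 feature annotations.

    Uses feature types CDS / five_prime_UTR / three_prime_UTR; the gene id is
    taken from the Parent (or ID) attribute.  Multi-part features are
    concatenated in coordinate order and reverse-complemented for minus-strand
    genes.  This is the optional alternative to per-region FASTA input.
    """
    import gffutils
    from Bio.Seq import Seq

    genome = read_fasta(genome_fasta)
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    parts: dict[str, dict[str, list]] = {}
    type_map = {"CDS": "cds", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}
    for feat in db.all_features():
        if feat.featuretype not in type_map:
            continue
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            continue
        gene = parents[0]
        seq = genome[feat.seqid][feat.start - 1 : feat.end]
        entry = parts.setdefault(gene, {"cds": [], "utr5": [], "utr3": [], "strand": feat.strand})
        entry[type_map[feat.featuretype]].append((feat.start, seq))
    cds_map, utr5_map, utr3_map = {}, {}, {}
    for gene, entry in parts.items():
        for key, target in (("cds", cds_map), ("utr5", utr5_map), ("utr3", utr3_map)):
            if not entry[key]:
                continue
            joined = "".join(s for _, s in sorted(entry[key]))
            if entry["strand"] == "-":
                joined = str(Seq(joined).reverse_complement())
            target[gene] = joined
    return assemble_transcripts(cds_map, utr5_map, utr3_map, annotations)


_MOTIF_COLUMNS = [
    "gene_id",
    "region",
    "phase",
    "start",
    "n_triplets",
    "sequence",
    "rry_score",
    "overlaps_tmd",
]
_MOTIF_HEADER = (
    "# motif table: start is 1-based (first nucleotide of the first triplet, "
    "region-local); phase 0/1/2 = YNN/NYN/NNY for CDS, 5'-anchored offset for UTRs\n"
)


def write_motif_table(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Serialize motif hits as TSV, sorted by (gene_id, region, start, phase)."""
    rows = sorted(hits, key=lambda h: (h.gene_id, h.region, h.start_nt, h.phase))
    with open(path, "w") as fh:
        fh.write(_MOTIF_HEADER)
        fh.write("\t".join(_MOTIF_COLUMNS) + "\n")
        for h in rows:
            fh.write(
                f"{h.gene_id}\t{h.region}\t{h.phase}\t{h.start_nt + 1}\t"
                f"{h.n_triplets}\t{h.sequence}\t{h.rry_score!r}\t{int(h.overlaps_tmd)}\n"
            )


def read_motif_table(path: str | Path) -> list[MotifHit]:
    """Inverse of write_motif_table (coordinates converted back to 0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "sequence": str})
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            MotifHit(
                gene_id=row.gene_id,
                region=row.region,
                phase=int(row.phase),
                start_nt=int(row.start) - 1,
                n_triplets=int(row.n_triplets),
                sequence=row.sequence,
                rry_score=float(row.rry_score),
                overlaps_tmd=bool(row.overlaps_tmd),
            )
        )
    return hits


def read_gene_values(path: str | Path, source: str = "") -> GeneValueTable:
    """Read a per-gene value TSV with columns gene_id, value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, value")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene id(s) {dupes}")
    return GeneValueTable(
        values=dict(zip(df["gene_id"].astype(str), df["value"].astype(float))),
        source=source or str(path),
    )
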