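"""Readers and writers for the formats the pipeline touches, plus basic assembly statistics.

Coordinates are 0-based half-open everywhere inside the package (BED
convention); VCF positions are converted at the I/O boundary.

Alignments are held as :class:`ProbAlignment`, a column-indexed container
whose rows are either concrete sequences (extant genomes) or probabilistic
rows (reconstructed internal nodes carrying a posterior base distribution
per column).  Probabilistic rows serialize to a small text dialect,
"pFASTA": FASTA-style headers, whitespace-separated column tokens, each
token one of ``-`` (gap), a single base letter, or ``pA,pC,pG,pT`` with
6-decimal fixed-point floats.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# Base codes used throughout the package.
A, C, G, T, GAP, NBASE = 0, 1, 2, 3, 4, 5
BASES = "ACGT"
_CODE = {"A": A, "C": C, "G": G, "T": T, "-": GAP, "N": NBASE,
         "a": A, "c": C, "g": G, "t": T, "n": NBASE}
_LETTER = np.array(list("ACGT-N"))


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class VariantRecord:
    """Biallelic substitution variant with per-haplotype genotypes.

    ``pos`` is 0-based. ``genotypes`` holds one entry per haplotype
    (0 = ref, 1 = alt, -1 = missing). ``aa`` is the ancestral allele
    ("N" when unresolved), ``daf`` the derived allele frequency once
    polarized.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    vid: str | None = None
    aa: str | None = None
    daf: float | None = None

    @property
    def n_alleles(self) -> int:
        return int(np.sum(self.genotypes >= 0))

    @property
    def alt_count(self) -> int:
        return int(np.sum(self.genotypes == 1))


@dataclass
class BaseRow:
    """Concrete sequence row: int8 codes (0-3 bases, 4 gap, 5 N)."""

    codes: np.ndarray

    @property
    def present(self) -> np.ndarray:
        return self.codes < 4

    def to_string(self) -> str:
        return "".join(_LETTER[self.codes])


@dataclass
class ProbRow:
    """Probabilistic row: per-column posterior over A,C,G,T plus presence."""

    probs: np.ndarray   # (n_columns, 4) float64; undefined where absent
    present: np.ndarray  # (n_columns,) bool


Row = BaseRow | ProbRow


def row_from_string(seq: str) -> BaseRow:
    try:
        codes = np.array([_CODE[ch] for ch in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"unexpected sequence character {exc.args[0]!r}") from exc
    return BaseRow(codes)


class ProbAlignment:
    """Column-indexed alignment anchored to a reference coordinate system.

    The first row is the reference; it may contain gaps (columns inserted
    relative to the reference) but never posterior vectors.
    ``ref_coord_map[i]`` is the alignment column of reference base ``i``.
    """

    def __init__(self, reference_name: str, rows: dict[str, Row]):
        if reference_name not in rows:
            raise ValueError(f"reference row {reference_name!r} missing")
        lengths = {self.row_length(r) for r in rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        ref = rows[reference_name]
        if not isinstance(ref, BaseRow):
            raise FormatError("reference row must be a concrete sequence")
        self.reference_name = reference_name
        self.rows = dict(rows)
        self.n_columns = lengths.pop()
        self.ref_coord_map = np.flatnonzero(ref.codes != GAP)

    @staticmethod
    def row_length(row: Row) -> int:
        return len(row.codes) if isinstance(row, BaseRow) else len(row.present)

    @property
    def ref_length(self) -> int:
        return len(self.ref_coord_map)

    def names(self) -> list[str]:
        return list(self.rows)

    def __getitem__(self, name: str) -> Row:
        return self.rows[name]

    def add_row(self, name: str, row: Row) -> None:
        if self.row_length(row) != self.n_columns:
            raise FormatError("row length does not match alignment")
        self.rows[name] = row


# ---------------------------------------------------------------------------
# FASTA / pFASTA

def _parse_records(text: str) -> list[tuple[str, list[str]]]:
    records: list[tuple[str, list[str]]] = []
    name = None
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, tokens))
            name = line[1:].split()[0]
            tokens = []
        else:
            if name is None:
                raise FormatError("sequence data before first header")
            tokens.append(line)
    if name is not None:
        records.append((name, tokens))
    return records


def _parse_pfasta_tokens(tokens: Iterable[str]) -> Row:
    codes: list[int] = []
    probs: list[tuple[float, float, float, float]] = []
    for tok in tokens:
        if "," in tok:
            parts = tok.split(",")
            if len(parts) != 4:
                raise FormatError(f"bad probability token {tok!r}")
            try:
                vec = tuple(float(p) for p in parts)
            except ValueError as exc:
                raise FormatError(f"bad probability token {tok!r}") from exc
            codes.append(-1)
            probs.append(vec)
        elif tok in _CODE:
            codes.append(_CODE[tok])
            probs.append((0.0, 0.0, 0.0, 0.0))
        else:
            raise FormatError(f"token {tok!r} is neither gap, base nor 4-float vector")
    arr = np.array(codes, dtype=np.int8)
    if np.any(arr == -1):
        p = np.array(probs, dtype=np.float64)
        present = arr != GAP
        # concrete bases inside a probabilistic row become point masses
        concrete = (arr >= 0) & (arr < 4)
        p[concrete] = np.eye(4)[arr[concrete]]
        return ProbRow(probs=p, present=present)
    return BaseRow(arr)


def read_alignment(path: str | os.PathLike | io.StringIO,
                   format: str = "pfasta") -> ProbAlignment:
    """Read a multi-FASTA or pFASTA alignment; the first record is the reference."""
    if format not in {"multi-fasta", "pfasta"}:
        raise ValueError(f"unknown format {format!r}")
    if isinstance(path, io.StringIO):
        text = path.getvalue()
    else:
        with open(path) as fh:
            text = fh.read()
    records = _parse_records(text)
    if not records:
        raise FormatError("no records found")
    rows: dict[str, Row] = {}
    for name, tokens in records:
        if format == "multi-fasta":
            rows[name] = row_from_string("".join(tokens))
        else:
            flat: list[str] = []
            for line in tokens:
                flat.extend(line.split())
            rows[name] = _parse_pfasta_tokens(flat)
    return ProbAlignment(records[0][0], rows)


def write_alignment(aln: ProbAlignment, path: str | os.PathLike,
                    format: str = "pfasta", wrap: int = 100) -> None:
    with open(path, "w") as fh:
        for name, row in aln.rows.items():
            fh.write(f">{name}\n")
            if format == "multi-fasta":
                if isinstance(row, ProbRow):
                    raise FormatError("cannot write probabilistic row as plain FASTA")
                s = row.to_string()
                for i in range(0, len(s), wrap):
                    fh.write(s[i:i + wrap] + "\n")
            else:
                toks = _row_tokens(row)
                for i in range(0, len(toks), 20):
                    fh.write(" ".join(toks[i:i + 20]) + "\n")


def _row_tokens(row: Row) -> list[str]:
    if isinstance(row, BaseRow):
        return [str(x) for x in _LETTER[row.codes]]
    toks = []
    for present, vec in zip(row.present, row.probs):
        if not present:
            toks.append("-")
        else:
            toks.append(",".join(f"{p:.6f}" for p in vec))
    return toks


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"BED line with {len(f)} fields: {line!r}")
            name = f[3] if len(f) > 3 else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, score))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """Read CHROM/POS/REF/ALT/INFO-AA/GT columns of a VCF into VariantRecords.

    Positions are converted to 0-based. Multi-allelic records are kept as-is
    (one alt per cyvcf2 record split is not applied); downstream polarization
    rejects them.
    """
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(path)):
        gts = np.asarray(v.genotype.array())[:, :-1].reshape(-1)
        alt = v.ALT[0] if len(v.ALT) == 1 else ",".join(v.ALT)
        aa = v.INFO.get("AA")
        out.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS - 1, ref=v.REF, alt=alt,
            genotypes=gts.astype(np.int8), vid=v.ID, aa=aa))
    return out


def write_vcf(variants: Sequence[VariantRecord], path: str | os.PathLike,
              n_samples: int | None = None) -> None:
    """Write variants as a minimal diploid VCF (AA and DAF in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=DAF,Number=1,Type=Float,Description="Derived allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if variants:
            n_hap = len(variants[0].genotypes)
        else:
            n_hap = 0
        n_smp = n_samples if n_samples is not None else (n_hap + 1) // 2
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += [f"S{i}" for i in range(n_smp)]
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            info = []
            if v.aa is not None:
                info.append(f"AA={v.aa}")
            if v.daf is not None:
                info.append(f"DAF={v.daf:.6g}")
            gt_fields = []
            g = v.genotypes
            for i in range(0, len(g), 2):
                pair = g[i:i + 2]
                gt_fields.append("|".join("." if x < 0 else str(int(x)) for x in pair))
            fh.write("\t".join([
                v.chrom, str(v.pos + 1), v.vid or ".", v.ref, v.alt, ".", "PASS",
                ";".join(info) or ".", "GT"] + gt_fields) + "\n")


# ---------------------------------------------------------------------------
# GTF (CDS features only)

@dataclass(frozen=True)
class CdsFeature:
    """One CDS block. ``frame`` counts bases to skip before the first codon."""

    chrom: str
    start: int   # 0-based
    end: int     # exclusive
    strand: str  # '+' or '-'
    frame: int   # 0, 1 or 2
    transcript_id: str | None = None


def read_gtf_cds(path: str | os.PathLike) -> list[CdsFeature]:
    """Extract CDS features (with frame and strand) from a GTF file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] != "CDS":
                continue
            tid = None
            if len(f) > 8 and 'transcript_id "' in f[8]:
                tid = f[8].split('transcript_id "', 1)[1].split('"', 1)[0]
            out.append(CdsFeature(
                chrom=f[0], start=int(f[3]) - 1, end=int(f[4]),
                strand=f[6], frame=int(f[7]), transcript_id=tid))
    return out


# ---------------------------------------------------------------------------
# WIG

def write_wig(path: str | os.PathLike, chrom: str, start: int,
              values: Sequence[float], step: int, span: int | None = None) -> None:
    """Fixed-step WIG writer (1-based start per WIG convention)."""
    with open(path, "w") as fh:
        header = f"fixedStep chrom={chrom} start={start + 1} step={step}"
        if span is not None:
            header += f" span={span}"
        fh.write(header + "\n")
        for v in values:
            fh.write(f"{v:g}\n")


# ---------------------------------------------------------------------------
# Assembly statistics

def assembly_stats(contig_lengths: Sequence[int]) -> tuple[int, int]:
    """Return (contig count, N50).

    N50 is the largest length L such that contigs of length >= L sum to at
    least half the assembly total.
    """
    if len(contig_lengths) == 0:
        raise ValueError("contig length list is empty")
    lengths = np.sort(np.asarray(contig_lengths))[::-1]
    if np.any(lengths <= 0):
        raise ValueError("contig lengths must be positive")
    half = lengths.sum() / 2
    cum = np.cumsum(lengths)
    idx = int(np.searchsorted(cum, half))
    return len(lengths), int(lengths[idx])
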