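"""Reference sequences, candidate SNVs, and one-hot sequence windows.

Candidate single-nucleotide variants (SNVs) called from RNA-seq are the raw
input of the classifier.  This module reads the reference (FASTA) and the
candidate lists (VCF or TSV), extracts a fixed-width nucleotide window
centred on each candidate, one-hot encodes it, and classifies the ref→alt
mismatch type.

Coordinates are 1-based and fully closed throughout, matching VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("editnet")

VALID_BASES = frozenset("ACGT")
#: Channel order of the one-hot encoding.  A→(1,0,0,0), T→(0,1,0,0),
#: C→(0,0,1,0), G→(0,0,0,1); N and out-of-contig padding → all-zero row.
CHANNEL_ORDER = "ATCG"

_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNEL_ORDER)}


class FileFormatError(ValueError):
    """A reference or candidate file violated its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSNV:
    """A candidate single-nucleotide variant at a 1-based genomic position.

    ``total_coverage`` / ``alt_coverage`` are read-depth counts carried
    through from the variant caller when available; they only matter for
    :func:`coverage_filter`.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    total_coverage: int | None = None
    alt_coverage: int | None = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref}) at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        for name in ("total_coverage", "alt_coverage"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if (
            self.total_coverage is not None
            and self.alt_coverage is not None
            and self.alt_coverage > self.total_coverage
        ):
            raise ValueError(
                f"alt_coverage {self.alt_coverage} exceeds total_coverage "
                f"{self.total_coverage} at {self.contig}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the site: (contig, pos, ref, alt)."""
        return (self.contig, self.pos, self.ref, self.alt)


class MismatchType(Enum):
    """One of the 12 ordered ref→alt substitutions over {A,C,G,T}."""

    A_TO_C = ("A", "C")
    A_TO_G = ("A", "G")
    A_TO_T = ("A", "T")
    C_TO_A = ("C", "A")
    C_TO_G = ("C", "G")
    C_TO_T = ("C", "T")
    G_TO_A = ("G", "A")
    G_TO_C = ("G", "C")
    G_TO_T = ("G", "T")
    T_TO_A = ("T", "A")
    T_TO_C = ("T", "C")
    T_TO_G = ("T", "G")

    @property
    def ref(self) -> str:
        return self.value[0]

    @property
    def alt(self) -> str:
        return self.value[1]

    def is_a_to_i(self, collapse_revcomp_a2i: bool = False) -> bool:
        """Whether this mismatch is consistent with A-to-I editing.

        A-to-I editing reads out as A→G.  With ``collapse_revcomp_a2i``
        the reverse-complement readout T→C also counts, for candidate
        lists produced by unstranded callers.
        """
        if self is MismatchType.A_TO_G:
            return True
        return collapse_revcomp_a2i and self is MismatchType.T_TO_C

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ref}>{self.alt}"


_MISMATCH_BY_PAIR = {m.value: m for m in MismatchType}


def classify_mismatch(snv: CandidateSNV) -> MismatchType:
    """Return the ref→alt mismatch type of a candidate."""
    return _MISMATCH_BY_PAIR[(snv.ref, snv.alt)]


@dataclass
class GenomeSequence:
    """Uppercased reference sequences keyed by contig name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")

    def base_at(self, contig: str, pos: int) -> str:
        """Single base at a 1-based position."""
        seq = self._contig(contig)
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside contig {contig!r} (length {len(seq)})")
        return seq[pos - 1]

    def _contig(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class SequenceWindow:
    """A (2·flank+1)-base window centred on a candidate, plus its one-hot matrix."""

    snv: CandidateSNV
    flank: int
    seq: str
    onehot: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.seq) != 2 * self.flank + 1:
            raise ValueError(
                f"window length {len(self.seq)} != 2*{self.flank}+1"
            )

    @property
    def centre_base(self) -> str:
        return self.seq[self.flank]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> GenomeSequence:
    """Load a (multi-record, possibly line-wrapped) FASTA into memory.

    Sequences are uppercased.  Duplicate record names and empty files are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FileFormatError(f"duplicate contig name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - (VALID_BASES | {"N"})
        if bad:
            raise FileFormatError(
                f"contig {record.id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        contigs[record.id] = seq
    if not contigs:
        raise FileFormatError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def _dedup(candidates: list[CandidateSNV]) -> list[CandidateSNV]:
    seen: set[tuple] = set()
    out = []
    dups = 0
    for c in candidates:
        if c.key in seen:
            dups += 1
            continue
        seen.add(c.key)
        out.append(c)
    if dups:
        logger.warning("dropped %d duplicate candidate records", dups)
    return out


def _read_candidates_vcf(path: Path) -> list[CandidateSNV]:
    candidates: list[CandidateSNV] = []
    n_indels = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            total = rec.info.get("DP", None)
            alt_cov = rec.info.get("AD", None)
            if isinstance(alt_cov, tuple):  # Number=A/R style
                alt_cov = alt_cov[-1]
            for alt in alts:
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    n_indels += 1
                    continue
                try:
                    candidates.append(
                        CandidateSNV(
                            rec.chrom,
                            rec.pos,
                            rec.ref.upper(),
                            alt.upper(),
                            total_coverage=int(total) if total is not None else None,
                            alt_coverage=int(alt_cov) if alt_cov is not None else None,
                        )
                    )
                except ValueError as exc:
                    raise FileFormatError(f"{path}: bad record at {rec.chrom}:{rec.pos}: {exc}")
    if n_indels:
        logger.info("skipped %d non-SNV (indel) alleles in %s", n_indels, path)
    return candidates


def _read_candidates_tsv(path: Path) -> list[CandidateSNV]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 4:
        raise FileFormatError(f"{path}: expected >=4 tab-separated columns, got {df.shape[1]}")
    candidates: list[CandidateSNV] = []
    n_indels = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        contig, pos, ref, alt = row[0], row[1], str(row[2]).upper(), str(row[3]).upper()
        if len(ref) != 1 or len(alt) != 1:
            n_indels += 1
            continue
        try:
            total = int(row[4]) if df.shape[1] > 4 and not pd.isna(row[4]) else None
            altc = int(row[5]) if df.shape[1] > 5 and not pd.isna(row[5]) else None
            candidates.append(CandidateSNV(str(contig), int(pos), ref, alt, total, altc))
        except (ValueError, TypeError) as exc:
            raise FileFormatError(f"{path}: unparseable row {i}: {exc}")
    if n_indels:
        logger.info("skipped %d non-SNV rows in %s", n_indels, path)
    return candidates


def read_candidates(path: str | Path, fmt: str | None = None) -> list[CandidateSNV]:
    """Read candidate SNVs from a VCF 4.x or tab-separated file.

    The TSV dialect is ``contig<TAB>pos<TAB>ref<TAB>alt[<TAB>total<TAB>alt_reads]``.
    Multiallelic VCF records are split into independent candidates; indel
    rows are skipped with a logged count; duplicate (contig, pos, ref, alt)
    records are deduplicated with a warning.  Contig names are *not*
    validated here — that happens at window extraction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "vcf":
        candidates = _read_candidates_vcf(path)
    elif fmt == "tsv":
        candidates = _read_candidates_tsv(path)
    else:
        raise ValueError(f"unknown candidate format {fmt!r}")
    return _dedup(candidates)


# ---------------------------------------------------------------------------
# Filtering, windows, encoding
# ---------------------------------------------------------------------------

def coverage_filter(
    candidates: Iterable[CandidateSNV],
    min_total: int = 5,
    min_alt: int = 3,
) -> list[CandidateSNV]:
    """Keep candidates with total coverage ≥ ``min_total`` and supporting
    (alt) coverage ≥ ``min_alt``.

    The defaults are the read-depth filter commonly applied before editing
    calling (total ≥ 5, supporting ≥ 3).  Candidates lacking coverage
    fields are an error — disable the filter rather than guessing.
    """
    if min_total < 0 or min_alt < 0:
        raise ValueError("coverage thresholds must be nonnegative")
    kept = []
    for c in candidates:
        if c.total_coverage is None or c.alt_coverage is None:
            raise ValueError(
                f"candidate {c.contig}:{c.pos} lacks coverage fields; "
                "cannot apply coverage_filter"
            )
        if c.total_coverage >= min_total and c.alt_coverage >= min_alt:
            kept.append(c)
    return kept


def extract_window(genome: GenomeSequence, snv: CandidateSNV, flank: int) -> SequenceWindow:
    """Extract the 2·flank+1 window centred at the candidate position.

    Positions beyond the contig ends are padded with N so the window width
    is invariant; padding encodes as all-zero one-hot rows.
    """
    if flank < 0:
        raise ValueError(f"flank must be nonnegative, got {flank}")
    contig_seq = genome._contig(snv.contig)
    if not 1 <= snv.pos <= len(contig_seq):
        raise IndexError(
            f"candidate position {snv.pos} outside contig {snv.contig!r} "
            f"(length {len(contig_seq)})"
        )
    lo = snv.pos - 1 - flank  # 0-based inclusive
    hi = snv.pos + flank  # 0-based exclusive
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(contig_seq))
    core = contig_seq[max(lo, 0) : min(hi, len(contig_seq))]
    seq = "N" * left_pad + core + "N" * right_pad
    return SequenceWindow(snv=snv, flank=flank, seq=seq, onehot=one_hot_encode(seq))


def extract_windows(
    genome: GenomeSequence, candidates: Iterable[CandidateSNV], flank: int
) -> list[SequenceWindow]:
    """Vector convenience wrapper over :func:`extract_window`."""
    return [extract_window(genome, c, flank) for c in candidates]


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an (L, 4) binary matrix.

    Channel order is A, T, C, G; N encodes as the all-zero row.  The
    row-major (by position) flattening of this matrix is the model input.
    """
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    for i, base in enumerate(seq):
        if base == "N":
            continue
        try:
            mat[i, _CHANNEL_INDEX[base]] = 1.0
        except KeyError:
            raise ValueError(f"invalid nucleotide {base!r} at position {i}") from None
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (all-zero rows decode to N)."""
    out = []
    for row in np.asarray(mat):
        s = row.sum()
        if s == 0:
            out.append("N")
        else:
            out.append(CHANNEL_ORDER[int(np.argmax(row))])
    return "".join(out)
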