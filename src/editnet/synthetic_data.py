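"""Synthetic genomes and labelled candidate SNVs with plantable editing signal.

The generator emulates the statistical structure that makes editing-site
classification learnable from sequence alone, so the full training and
evaluation stack runs without any external download:

* class composition — positives (editing sites) are predominantly A→G
  (default 86.3%), negatives (SNPs and artifacts) much less so (34.8%);
* the ADAR neighbour preference — G depleted immediately 5′ of an edited
  adenosine and enriched immediately 3′ of it;
* a positional signal concentrated near the candidate that decays
  linearly out to ±``decay_halfwidth`` (default 25) and vanishes beyond.

Biological realism is deliberately minimal (i.i.d. background, linear
decay, no reads): the generator's job is recoverable structure, not
genome realism.  Outputs are byte-deterministic under ``master_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .model_core import ClassLabel, stack_windows
from .sequence_windows import (
    CandidateSNV,
    GenomeSequence,
    extract_windows,
)

_BASES = np.array(list("ACGT"))
_NON_A = np.array(list("CGT"))
_NON_G = np.array(list("ACT"))

#: the 11 ref→alt pairs other than A→G
_NON_A2G_PAIRS = [
    (r, a) for r in "ACGT" for a in "ACGT" if r != a and (r, a) != ("A", "G")
]


@dataclass(frozen=True)
class MotifModel:
    """Neighbour-preference and positional-decay parameters for positives.

    ``p_g_minus1_pos`` / ``p_g_plus1_pos`` set the G frequency at the 5′ /
    3′ neighbour of a planted editing site (depleted / enriched relative
    to background).  ``None`` for the negative-class probabilities means
    "background".  Positions 2..``decay_halfwidth`` on each side carry a
    class-informative base bias whose strength decays linearly with
    distance, scaled by ``signal_strength``.
    """

    p_g_minus1_pos: float = 0.05
    p_g_plus1_pos: float = 0.70
    p_g_minus1_neg: float | None = None
    p_g_plus1_neg: float | None = None
    decay_halfwidth: int = 25
    signal_strength: float = 0.9

    def __post_init__(self) -> None:
        for name in ("p_g_minus1_pos", "p_g_plus1_pos", "signal_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def signature_prob(self, offset: int) -> float:
        """Probability of writing the class-signature base at an offset."""
        o = abs(offset)
        if o < 2 or o > self.decay_halfwidth:
            return 0.0
        return self.signal_strength * 0.5 * (1.0 - (o - 1) / self.decay_halfwidth)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic dataset.

    ``genome_length`` is per contig.  The A→G fractions default to the
    composition of real positive/negative gold sets (86.3% / 34.8%).
    Coverage counts exist only to exercise the read-depth filter and are
    drawn from a negative binomial with the given mean and dispersion.
    """

    genome_length: int = 600_000
    n_contigs: int = 4
    gc_content: float = 0.5
    n_positives: int = 1000
    n_snps: int = 1000
    n_others: int = 1000
    frac_a2g_positive: float = 0.863
    frac_a2g_negative: float = 0.348
    flank: int = 100
    snp_transition_bias: float = 0.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_positives, self.n_snps, self.n_others) <= 0:
            raise ValueError("all three class counts must be positive")
        for name in ("gc_content", "frac_a2g_positive", "frac_a2g_negative", "snp_transition_bias"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.genome_length < 2 * self.flank + 1:
            raise ValueError("contigs shorter than one window are infeasible")


@dataclass
class SyntheticDataset:
    """A generated genome plus labelled candidates and their provenance."""

    genome: GenomeSequence
    candidates: list[CandidateSNV]
    labels: np.ndarray  # ClassLabel ints aligned with candidates
    manifest: dict
    gold_sets: list[np.ndarray] = field(default_factory=list)

    @property
    def truth(self) -> dict[tuple, ClassLabel]:
        """Map site key → class label."""
        return {c.key: ClassLabel(int(l)) for c, l in zip(self.candidates, self.labels)}

    def training_arrays(
        self, flank: int | None = None, subset: Sequence[int] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """One-hot tensor and label vector ready for model training."""
        flank = self.manifest["config"]["flank"] if flank is None else flank
        idx = np.arange(len(self.candidates)) if subset is None else np.asarray(subset)
        windows = extract_windows(self.genome, [self.candidates[i] for i in idx], flank)
        return stack_windows(windows), self.labels[idx]

    def gold_set_arrays(self, flank: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
        return [self.training_arrays(flank, subset=g) for g in self.gold_sets]


# ---------------------------------------------------------------------------
# Genome background
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    # order A, C, G, T
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _simulate_contig(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_BASES, size=length, p=_base_probs(gc))


def simulate_genome(config: SimulationConfig, seed: int | None = None) -> GenomeSequence:
    """An i.i.d. random genome at the configured GC content."""
    rng = np.random.default_rng(config.master_seed if seed is None else seed)
    arrays = _genome_arrays(config, rng)
    return GenomeSequence({k: "".join(v) for k, v in arrays.items()})


def _genome_arrays(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        f"contig{i + 1}": _simulate_contig(config.genome_length, config.gc_content, rng)
        for i in range(config.n_contigs)
    }


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _draw_g_or_background(p_g: float, gc: float, rng: np.random.Generator) -> str:
    """G with probability p_g, else background renormalized over A/C/T."""
    if rng.random() < p_g:
        return "G"
    probs = _base_probs(gc)[[0, 1, 3]]  # A, C, T
    return str(rng.choice(_NON_G, p=probs / probs.sum()))


def plant_positive(
    arrays: dict[str, np.ndarray],
    contig: str,
    pos: int,
    motif: MotifModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CandidateSNV:
    """Write an editing site into the genome at a 1-based position.

    The centre base becomes A (the edited adenosine); the immediate
    neighbours follow the 5′-depleted / 3′-enriched G preference; flanking
    positions out to ``decay_halfwidth`` get the class-signature base (C on
    the 5′ side, G on the 3′ side) with linearly decaying probability.
    ``signal_strength`` interpolates every planted probability between the
    genome background (0) and its target value (1).  The alt allele is G
    with probability ``frac_a2g_positive``.
    """
    seq = arrays[contig]
    i = pos - 1
    if i - config.flank < 0 or i + config.flank >= len(seq):
        raise ValueError(f"position {pos} leaves no room for flank {config.flank}")
    bg_g = config.gc_content / 2
    ss = motif.signal_strength
    seq[i] = "A"
    seq[i - 1] = _draw_g_or_background(
        bg_g + ss * (motif.p_g_minus1_pos - bg_g), config.gc_content, rng)
    seq[i + 1] = _draw_g_or_background(
        bg_g + ss * (motif.p_g_plus1_pos - bg_g), config.gc_content, rng)
    for o in range(2, motif.decay_halfwidth + 1):
        if rng.random() < motif.signature_prob(o):
            seq[i - o] = "C"
        if rng.random() < motif.signature_prob(o):
            seq[i + o] = "G"
    alt = "G" if rng.random() < config.frac_a2g_positive else str(rng.choice(np.array(list("CT"))))
    total, altc = _draw_coverage(config, rng)
    return CandidateSNV(contig, pos, "A", alt, total, altc)


def plant_negative(
    arrays: dict[str, np.ndarray],
    contig: str,
    pos: int,
    label: ClassLabel,
    config: SimulationConfig,
    rng: np.random.Generator,
    motif: MotifModel | None = None,
) -> CandidateSNV:
    """Write a SNP or artifact site: background flanks, negative A→G mix.

    By default SNP and OTHER are distributionally identical (labels
    differ only); ``snp_transition_bias`` > 0 skews SNP alts toward
    transitions so the three-class problem becomes non-degenerate.
    """
    seq = arrays[contig]
    i = pos - 1
    if i - config.flank < 0 or i + config.flank >= len(seq):
        raise ValueError(f"position {pos} leaves no room for flank {config.flank}")
    if rng.random() < config.frac_a2g_negative:
        ref, alt = "A", "G"
    elif label is ClassLabel.SNP and rng.random() < config.snp_transition_bias:
        ref, alt = [("G", "A"), ("C", "T"), ("T", "C")][int(rng.integers(3))]
    else:
        ref, alt = _NON_A2G_PAIRS[int(rng.integers(len(_NON_A2G_PAIRS)))]
    seq[i] = ref
    if motif is not None and motif.p_g_minus1_neg is not None:
        seq[i - 1] = _draw_g_or_background(motif.p_g_minus1_neg, config.gc_content, rng)
    if motif is not None and motif.p_g_plus1_neg is not None:
        seq[i + 1] = _draw_g_or_background(motif.p_g_plus1_neg, config.gc_content, rng)
    total, altc = _draw_coverage(config, rng)
    return CandidateSNV(contig, pos, ref, alt, total, altc)


def _draw_coverage(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, int]:
    n = config.coverage_dispersion
    p = n / (n + config.coverage_mean)
    total = int(rng.negative_binomial(n, p)) + 1
    alt = int(rng.binomial(total, 0.5))
    return total, alt


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

_MAX_PLACEMENT_TRIES = 500


def _place_nonoverlapping(
    trees: dict[str, IntervalTree],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Rejection-sample a window position overlapping no planted window."""
    names = sorted(trees)
    for _ in range(_MAX_PLACEMENT_TRIES):
        contig = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(config.flank + 1, config.genome_length - config.flank + 1))
        if not trees[contig].overlap(pos - config.flank, pos + config.flank + 1):
            trees[contig].addi(pos - config.flank, pos + config.flank + 1)
            return contig, pos
    raise RuntimeError(
        "could not place a non-overlapping window; increase genome_length or "
        "n_contigs, or reduce the candidate counts"
    )


def generate_dataset(
    config: SimulationConfig,
    motif: MotifModel | None = None,
    n_gold_sets: int = 1,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a labelled three-class dataset on a fresh random genome.

    Candidates are planted at non-overlapping window positions (rejection
    sampling), positives first, then SNPs, then artifacts.  With
    ``n_gold_sets`` > 1 the candidates are partitioned class-stratified
    into that many gold sets, to exercise component-level training.  When
    ``out_dir`` is given, writes genome.fa, candidates.vcf, labels.tsv and
    manifest.json there (byte-deterministic under ``master_seed``).
    """
    motif = MotifModel() if motif is None else motif
    if motif.decay_halfwidth > config.flank:
        raise ValueError("decay_halfwidth cannot exceed the window flank")
    rng = np.random.default_rng(config.master_seed)
    arrays = _genome_arrays(config, rng)
    trees = {name: IntervalTree() for name in arrays}

    candidates: list[CandidateSNV] = []
    labels: list[int] = []
    for label, count in (
        (ClassLabel.EDITING, config.n_positives),
        (ClassLabel.SNP, config.n_snps),
        (ClassLabel.OTHER, config.n_others),
    ):
        for _ in range(count):
            contig, pos = _place_nonoverlapping(trees, config, rng)
            if label is ClassLabel.EDITING:
                snv = plant_positive(arrays, contig, pos, motif, config, rng)
            else:
                snv = plant_negative(arrays, contig, pos, label, config, rng, motif)
            candidates.append(snv)
            labels.append(int(label))

    genome = GenomeSequence({k: "".join(v) for k, v in arrays.items()})
    y = np.array(labels, dtype=np.int64)
    gold_sets = _partition_gold_sets(y, n_gold_sets)
    manifest = {
        "config": asdict(config),
        "motif": asdict(motif),
        "n_gold_sets": n_gold_sets,
        "class_counts": {l.name: int((y == l).sum()) for l in ClassLabel},
    }
    dataset = SyntheticDataset(genome, candidates, y, manifest, gold_sets)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def _partition_gold_sets(y: np.ndarray, m: int) -> list[np.ndarray]:
    """Class-stratified round-robin partition into m index sets."""
    if m < 1:
        raise ValueError("n_gold_sets must be >= 1")
    sets: list[list[int]] = [[] for _ in range(m)]
    for label in ClassLabel:
        for j, idx in enumerate(np.flatnonzero(y == label)):
            sets[j % m].append(int(idx))
    return [np.array(sorted(s), dtype=np.int64) for s in sets]


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fa, candidates.vcf, labels.tsv and manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "genome.fa",
        "vcf": out_dir / "candidates.vcf",
        "labels": out_dir / "labels.tsv",
        "manifest": out_dir / "manifest.json",
    }
    dataset.genome.to_fasta(paths["fasta"])
    write_vcf(dataset.candidates, dataset.genome, paths["vcf"])
    with open(paths["labels"], "w") as fh:
        fh.write("contig\tpos\tref\talt\tlabel\n")
        for c, l in zip(dataset.candidates, dataset.labels):
            fh.write(f"{c.contig}\t{c.pos}\t{c.ref}\t{c.alt}\t{ClassLabel(int(l)).name}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(dataset.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def write_vcf(
    candidates: Sequence[CandidateSNV],
    genome: GenomeSequence | None,
    path: str | Path,
) -> None:
    """Write candidates as a sorted, minimally headed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if genome is not None:
            for name, seq in genome.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Reads supporting the alternate allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(candidates, key=lambda c: (c.contig, c.pos, c.ref, c.alt)):
            info = []
            if c.total_coverage is not None:
                info.append(f"DP={c.total_coverage}")
            if c.alt_coverage is not None:
                info.append(f"AD={c.alt_coverage}")
            fh.write(
                f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{';'.join(info) or '.'}\n"
            )


def read_labels(path: str | Path) -> dict[tuple, ClassLabel]:
    """Read a labels.tsv back into a site-key → label map."""
    out: dict[tuple, ClassLabel] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig"):
            raise ValueError(f"{path}: expected a labels.tsv header line")
        for line in fh:
            contig, pos, ref, alt, label = line.rstrip("\n").split("\t")
            out[(contig, int(pos), ref, alt)] = ClassLabel[label]
    return out
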