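"""Hexamer binding-motif detection and inverted-repeat architecture analysis.

Type Ia partition ATPases (ParA) autoregulate their operon by binding short
hexamer motifs (consensus 5'-CTTTGC for the F plasmid) in the promoter
region.  Pairs of motifs on opposite strands separated by a large spacer
(26-29 bp, about three helical turns between motif centers) form inverted
repeats (IRs) that each accommodate one ParA dimer via its two winged-HTH
domains.  This module scans promoter sequences for motif occurrences on both
strands, pairs them into IRs under spacer constraints, classifies the
overlapping-IR architecture, and quantifies motif conservation with a
position frequency matrix and per-column information content.

Coordinates are 0-based, half-open, on the plus strand throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "MotifHit",
    "IRPair",
    "ArchitectureReport",
    "PFM",
    "LogoProfile",
    "reverse_complement",
    "hamming",
    "scan_motifs",
    "find_inverted_repeats",
    "classify_architecture",
    "build_pfm",
    "information_content",
    "read_fasta",
    "hits_to_bed",
    "write_hits_bed",
    "write_pfm_tsv",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved; N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length DNA strings.

    Comparison is case-insensitive.  Any character outside {A,C,G,T} in
    either string counts as a mismatch against everything (ambiguity codes
    are treated as universal mismatches).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    d = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _BASES or y not in _BASES or x != y:
            d += 1
    return d


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on a scanned sequence.

    Attributes
    ----------
    seq_id : str
        Identifier of the scanned sequence.
    start : int
        0-based start on plus-strand coordinates.
    strand : str
        ``"+"`` or ``"-"``.
    observed : str
        The site as read 5'->3' on its own strand (reverse complement of the
        plus-strand window for minus-strand hits).
    mismatches : int
        Hamming distance to the consensus.
    """

    seq_id: str
    start: int
    strand: str
    observed: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError("start must be >= 0")

    @property
    def end(self) -> int:
        """Exclusive end coordinate on the plus strand."""
        return self.start + len(self.observed)

    @property
    def center(self) -> float:
        return self.start + len(self.observed) / 2


@dataclass(frozen=True)
class IRPair:
    """An inverted-repeat pair: a plus-strand motif and a downstream
    minus-strand motif separated by ``spacer`` bp.

    ``center_distance`` is the base-pair distance between motif centers,
    identically ``spacer + motif_len``.  The pair is *perfect* when both
    half-sites match the consensus exactly, *degenerate* otherwise.
    """

    left: MotifHit
    right: MotifHit
    spacer: int

    def __post_init__(self) -> None:
        if self.left.strand != "+" or self.right.strand != "-":
            raise ValueError("IR pair requires a + left and a - right half-site")
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")
        if self.right.start < self.left.start:
            raise ValueError("left half-site must precede right half-site")

    @property
    def motif_len(self) -> int:
        return len(self.left.observed)

    @property
    def center_distance(self) -> int:
        return self.spacer + self.motif_len

    @property
    def total_mismatches(self) -> int:
        return self.left.mismatches + self.right.mismatches

    @property
    def irclass(self) -> str:
        return "perfect" if self.total_mismatches == 0 else "degenerate"

    @property
    def span(self) -> tuple[int, int]:
        """Footprint interval [left.start, right.end) on the plus strand."""
        return (self.left.start, self.right.end)


@dataclass
class ArchitectureReport:
    """Promoter architecture summary: IR pairs, overlaps, unpaired motifs.

    ``overlaps`` holds index pairs (i, j), i < j, of IR pairs whose
    footprints intersect; the relation is symmetric and stored once per
    unordered pair.  ``min_left_margin_bp`` is the distance from the 5' end
    of the sequence to the first paired motif — if it falls below the
    threshold the promoter is flagged, mirroring the observation that an IR
    placed mid-fragment without enough upstream DNA does not support the
    assembly of three dimers.
    """

    ir_pairs: list[IRPair]
    singletons: list[MotifHit]
    overlaps: list[tuple[int, int]]
    min_left_margin_bp: int | None
    left_margin_threshold_bp: int
    insufficient_left_margin: bool

    def overlapping(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in set(self.overlaps)

    def to_dict(self) -> dict:
        return {
            "ir_pairs": [
                {
                    "left_start": p.left.start,
                    "right_start": p.right.start,
                    "spacer": p.spacer,
                    "center_distance": p.center_distance,
                    "irclass": p.irclass,
                    "total_mismatches": p.total_mismatches,
                }
                for p in self.ir_pairs
            ],
            "singletons": [
                {"start": h.start, "strand": h.strand, "observed": h.observed}
                for h in self.singletons
            ],
            "overlaps": [list(o) for o in self.overlaps],
            "min_left_margin_bp": self.min_left_margin_bp,
            "left_margin_threshold_bp": self.left_margin_threshold_bp,
            "insufficient_left_margin": self.insufficient_left_margin,
        }


def scan_motifs(
    seq: str,
    consensus: str = "CTTTGC",
    max_mismatch: int = 0,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Find all occurrences of ``consensus`` on both strands of ``seq``.

    Every window of length ``len(consensus)`` is compared to the consensus:
    plus-strand windows as-is, minus-strand windows after reverse
    complementation (i.e. the site as read 5'->3' on the minus strand).
    Windows within ``max_mismatch`` Hamming distance are reported, sorted by
    start then strand ("+" before "-").  Matching is case-insensitive;
    ambiguity codes in the sequence never match.

    Parameters
    ----------
    seq : str
        DNA sequence (plus strand).
    consensus : str
        Motif consensus over {A,C,G,T}.
    max_mismatch : int
        Maximum Hamming distance; must be smaller than the motif length.
    seq_id : str
        Identifier recorded on each hit.

    Returns
    -------
    list of MotifHit
    """
    cons = consensus.upper()
    if not cons or any(b not in _BASES for b in cons):
        raise ValueError(f"consensus must be non-empty over ACGT, got {consensus!r}")
    if max_mismatch >= len(cons):
        raise ValueError("max_mismatch must be < motif length")
    L = len(cons)
    hits: list[MotifHit] = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        d_plus = hamming(window, cons)
        if d_plus <= max_mismatch:
            hits.append(MotifHit(seq_id, start, "+", window.upper(), d_plus))
        site_minus = reverse_complement(window)
        d_minus = hamming(site_minus, cons)
        if d_minus <= max_mismatch:
            hits.append(MotifHit(seq_id, start, "-", site_minus.upper(), d_minus))
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def find_inverted_repeats(
    hits: Sequence[MotifHit],
    spacer_min: int = 26,
    spacer_max: int = 29,
    max_total_mismatch: int = 2,
    require_perfect_half: bool = True,
) -> list[IRPair]:
    """Pair plus-strand motifs with downstream minus-strand motifs into IRs.

    For every (+ hit, downstream - hit) combination the spacer
    ``right.start - (left.start + motif_len)`` is computed; pairs whose
    spacer falls in ``[spacer_min, spacer_max]`` are kept.  By default a
    degenerate pair is tolerated only when the two half-sites accumulate at
    most ``max_total_mismatch`` mismatches and at least one half-site is a
    perfect consensus match (the promoter's degenerate IR pairs a 2-mismatch
    half-site with a perfect one).

    Returns pairs sorted by left start.
    """
    if spacer_min > spacer_max:
        raise ValueError("spacer_min must be <= spacer_max")
    pairs: list[IRPair] = []
    plus = [h for h in hits if h.strand == "+"]
    minus = [h for h in hits if h.strand == "-"]
    for left in plus:
        for right in minus:
            spacer = right.start - left.end
            if spacer < spacer_min or spacer > spacer_max:
                continue
            total_mm = left.mismatches + right.mismatches
            if total_mm > max_total_mismatch:
                continue
            if require_perfect_half and min(left.mismatches, right.mismatches) > 0:
                continue
            pairs.append(IRPair(left, right, spacer))
    pairs.sort(key=lambda p: (p.left.start, p.right.start))
    return pairs


def classify_architecture(
    hits: Sequence[MotifHit],
    ir_pairs: Sequence[IRPair],
    seq_len: int,
    left_margin_threshold: int = 40,
) -> ArchitectureReport:
    """Summarize the overlapping-IR promoter architecture.

    Reports which IR pairs overlap (footprint intervals intersect), which
    motif hits belong to no pair (candidate half-site anchors for a dimer
    bound through a single wHTH), and whether enough DNA is available
    5' of the first paired motif for a three-dimer assembly.
    """
    paired: set[tuple[int, str]] = set()
    for p in ir_pairs:
        paired.add((p.left.start, p.left.strand))
        paired.add((p.right.start, p.right.strand))
    singletons = [h for h in hits if (h.start, h.strand) not in paired]

    overlaps: list[tuple[int, int]] = []
    for i in range(len(ir_pairs)):
        a0, a1 = ir_pairs[i].span
        for j in range(i + 1, len(ir_pairs)):
            b0, b1 = ir_pairs[j].span
            if a0 < b1 and b0 < a1:
                overlaps.append((i, j))

    if ir_pairs:
        margin: int | None = min(p.left.start for p in ir_pairs)
        insufficient = margin < left_margin_threshold
    else:
        margin = None
        insufficient = False
    return ArchitectureReport(
        ir_pairs=list(ir_pairs),
        singletons=singletons,
        overlaps=overlaps,
        min_left_margin_bp=margin,
        left_margin_threshold_bp=left_margin_threshold,
        insufficient_left_margin=insufficient,
    )


@dataclass
class PFM:
    """Position frequency matrix: base x column counts over n sites.

    Rows follow alphabet order A, C, G, T.  Every column sums to ``n``.
    """

    counts: np.ndarray  # (4, L) integer counts
    n: int
    alphabet: str = _BASES

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n


@dataclass
class LogoProfile:
    """Per-column information content (bits) and per-base letter heights."""

    ic: np.ndarray  # (L,) bits
    heights: np.ndarray  # (4, L), p * IC
    alphabet: str = _BASES


def build_pfm(motifs: Iterable[str]) -> PFM:
    """Count a 4 x L position frequency matrix from equal-length sites.

    Raises on empty input, unequal lengths, or characters outside ACGT.
    """
    sites = [m.upper() for m in motifs]
    if not sites:
        raise ValueError("need at least one motif")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("motifs must have equal lengths")
    counts = np.zeros((4, L), dtype=int)
    for s in sites:
        for j, b in enumerate(s):
            k = _BASES.find(b)
            if k < 0:
                raise ValueError(f"non-ACGT character {b!r} in motif {s!r}")
            counts[k, j] += 1
    return PFM(counts=counts, n=len(sites))


def information_content(pfm: PFM, small_sample_correction: bool = False) -> LogoProfile:
    """Shannon information content per column, in bits.

    IC_j = 2 + sum_b p_bj log2 p_bj with 0*log0 = 0; letter heights are
    p_bj * IC_j (the usual sequence-logo stack).  With
    ``small_sample_correction`` the Schneider e_n = 3 / (2 ln2 n) term is
    subtracted (clipped at zero); off by default since motif sets here can
    be as small as three sites and the uncorrected IC is what the stacked
    logos display.
    """
    p = pfm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    if small_sample_correction:
        ic = ic - 3.0 / (2.0 * np.log(2) * pfm.n)
    ic = np.clip(ic, 0.0, 2.0)
    return LogoProfile(ic=ic, heights=p * ic)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def hits_to_bed(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """BED-like 6-column table: seq_id, start, end, name, mismatches, strand."""
    return pd.DataFrame(
        {
            "seq_id": [h.seq_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": [h.observed for h in hits],
            "mismatches": [h.mismatches for h in hits],
            "strand": [h.strand for h in hits],
        }
    )


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    hits_to_bed(hits).to_csv(path, sep="\t", header=False, index=False)


def write_pfm_tsv(pfm: PFM, path: str | Path) -> None:
    pd.DataFrame(pfm.counts, index=list(pfm.alphabet)).to_csv(path, sep="\t")


def write_architecture_json(report: ArchitectureReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
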