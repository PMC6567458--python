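"""Bisulfite read placement and per-cytosine methylation calling.

Alignment is unique-best by exhaustive scan in three-letter (C->T) space:
the read and both genome strands are reduced C->T, every placement within
the mismatch budget is enumerated, and a read is reported only when one
placement has strictly fewer mismatches than all others.  Ambiguous reads
(ties at the best count) are discarded — multi-mapping reads carry no
trustworthy methylation evidence.

Methylation calls: at every reference cytosine covered on the read's
originating strand, a read C is a methylated call and a read T an
unmethylated call; any other base is ignored.  Context (CpG / CHG / CHH,
H = A, C or T) is determined solely by the reference sequence.  The
bisulfite conversion rate is estimated from calls on the unmethylated
spike-in contig, where every C call is a conversion failure.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .simgen import Genome, Read, ReadSet, revcomp

__all__ = [
    "Placement",
    "CytosineCall",
    "CytosineCallSet",
    "BisulfiteAligner",
    "align_bisulfite",
    "align_genomic",
    "classify_context",
    "call_methylation",
    "conversion_rate",
    "methylation_fractions_by_context",
]

CONTEXTS = ("CpG", "CHG", "CHH", "CN_unknown")


@dataclass(frozen=True)
class Placement:
    """A unique-best read placement. ``strand`` is OT (original top, read
    matches the forward strand) or OB (original bottom)."""

    read_id: str
    contig: str
    start: int
    strand: str
    mismatches: int
    read_index: int = -1


@dataclass
class CytosineCall:
    contig: str
    pos: int
    strand: str
    context: str
    count_methylated: int = 0
    count_unmethylated: int = 0

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def percent_methylated(self) -> float:
        cov = self.coverage
        return 100.0 * self.count_methylated / cov if cov else float("nan")


class CytosineCallSet:
    """Per-sample aggregation of cytosine calls keyed by (contig, pos, strand)."""

    def __init__(self, sample: str = "sample"):
        self.sample = sample
        self.calls: dict[tuple[str, int, str], CytosineCall] = {}

    def get(self, contig: str, pos: int, strand: str) -> CytosineCall | None:
        return self.calls.get((contig, pos, strand))

    def add(self, contig: str, pos: int, strand: str, context: str, methylated: bool) -> None:
        key = (contig, pos, strand)
        call = self.calls.get(key)
        if call is None:
            call = CytosineCall(contig, pos, strand, context)
            self.calls[key] = call
        if methylated:
            call.count_methylated += 1
        else:
            call.count_unmethylated += 1

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls.values())

    def to_dataframe(self):
        import pandas as pd

        rows = [
            (c.contig, c.pos, c.strand, c.context, c.count_methylated, c.count_unmethylated)
            for c in sorted(self.calls.values(), key=lambda c: (c.contig, c.pos, c.strand))
        ]
        return pd.DataFrame(
            rows,
            columns=["contig", "pos", "strand", "context", "count_methylated", "count_unmethylated"],
        )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class BisulfiteAligner:
    """Exhaustive unique-best aligner over both original strands.

    With ``convert=True`` (bisulfite mode) read and genome are reduced C->T
    before comparison; with ``convert=False`` raw sequences are compared
    (used for the untreated SNP-discovery libraries).  Runtime is
    O(genome x read length) per read — appropriate for desk-scale synthetic
    genomes, and exchangeable for an indexed implementation with identical
    output.
    """

    def __init__(self, genome: Genome, max_mismatch: int = 2, convert: bool = True):
        self.genome = genome
        self.max_mismatch = max_mismatch
        self.convert = convert
        self._fwd: dict[str, np.ndarray] = {}
        self._rev: dict[str, np.ndarray] = {}
        for name, seq in genome.contigs.items():
            fwd, rev = seq, revcomp(seq)
            if convert:
                fwd, rev = fwd.replace("C", "T"), rev.replace("C", "T")
            self._fwd[name] = _encode(fwd)
            self._rev[name] = _encode(rev)

    def _scan(self, arr: np.ndarray, read: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        L, k = len(arr), len(read)
        if k > L:
            return np.array([], int), np.array([], int)
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        mism = (windows != read).sum(axis=1)
        hits = np.nonzero(mism <= self.max_mismatch)[0]
        return hits, mism[hits]

    def align(self, read: Read) -> Placement | None:
        seq = read.sequence
        if self.convert:
            seq = seq.replace("C", "T")
        r = _encode(seq)
        best: tuple[int, str, str, int] | None = None  # (mism, contig, strand, start)
        best_count = 0
        for contig in self.genome.names:
            for strand, arr in (("OT", self._fwd[contig]), ("OB", self._rev[contig])):
                hits, mism = self._scan(arr, r)
                for pos, m in zip(hits, mism):
                    m = int(m)
                    if strand == "OB":
                        start = len(arr) - int(pos) - len(r)
                    else:
                        start = int(pos)
                    if best is None or m < best[0]:
                        best = (m, contig, strand, start)
                        best_count = 1
                    elif m == best[0]:
                        best_count += 1
        if best is None or best_count > 1:
            return None
        m, contig, strand, start = best
        return Placement(read_id=read.read_id, contig=contig, start=start, strand=strand, mismatches=m)

    def align_all(self, reads: ReadSet) -> list[Placement]:
        placements = []
        for i, read in enumerate(reads):
            p = self.align(read)
            if p is not None:
                placements.append(
                    Placement(p.read_id, p.contig, p.start, p.strand, p.mismatches, read_index=i)
                )
        return placements


def align_bisulfite(read: Read, genome: Genome, max_mismatch: int = 2) -> Placement | None:
    """Unique-best bisulfite placement of a single read (C->T space)."""
    return BisulfiteAligner(genome, max_mismatch=max_mismatch, convert=True).align(read)


def align_genomic(read: Read, genome: Genome, max_mismatch: int = 2) -> Placement | None:
    """Unique-best placement of an untreated read (no C->T reduction)."""
    return BisulfiteAligner(genome, max_mismatch=max_mismatch, convert=False).align(read)


# ---------------------------------------------------------------------------
# Context classification and methylation calling
# ---------------------------------------------------------------------------


def classify_context(genome: Genome, contig: str, pos: int, strand: str) -> str:
    """Sequence context of a cytosine: the next two bases downstream on its
    strand give CpG (G_), CHG (HG) or CHH (HH); fewer than the required
    bases remaining yields CN_unknown (contig-edge truncation)."""
    seq = genome[contig]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{contig}:{pos}:+ is not a cytosine")
        n1 = seq[pos + 1] if pos + 1 < len(seq) else None
        n2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{contig}:{pos}:- is not a cytosine")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        n1 = comp[seq[pos - 1]] if pos - 1 >= 0 else None
        n2 = comp[seq[pos - 2]] if pos - 2 >= 0 else None
    else:
        raise ValueError(f"bad strand {strand!r}")
    if n1 is None:
        return "CN_unknown"
    if n1 == "G":
        return "CpG"
    if n2 is None:
        return "CN_unknown"
    return "CHG" if n2 == "G" else "CHH"


def call_methylation(
    placements: list[Placement],
    reads: ReadSet,
    genome: Genome,
    sample: str = "sample",
) -> CytosineCallSet:
    """Aggregate per-cytosine methylation evidence from unique-best placements.

    OT reads report forward-strand cytosines; OB reads report reverse-strand
    cytosines (reference G on the forward strand).  Read bases other than
    C/T at a reference cytosine are ignored (sequencing error or SNP).
    """
    callset = CytosineCallSet(sample=sample)
    ctx_cache: dict[tuple[str, int, str], str] = {}
    for p in placements:
        read = reads[p.read_index]
        seq = genome[p.contig]
        k = len(read.sequence)
        if p.start < 0 or p.start + k > len(seq):
            raise ValueError(f"placement of {p.read_id} outside {p.contig} (corrupt inputs)")
        if p.strand == "OT":
            for j in range(k):
                g = p.start + j
                if seq[g] != "C":
                    continue
                b = read.sequence[j]
                if b not in "CT":
                    continue
                key = (p.contig, g, "+")
                ctx = ctx_cache.get(key)
                if ctx is None:
                    ctx = ctx_cache[key] = classify_context(genome, p.contig, g, "+")
                callset.add(p.contig, g, "+", ctx, methylated=(b == "C"))
        else:
            for j in range(k):
                g = p.start + k - 1 - j  # read pos j on bottom strand
                if seq[g] != "G":
                    continue
                b = read.sequence[j]
                if b not in "CT":
                    continue
                key = (p.contig, g, "-")
                ctx = ctx_cache.get(key)
                if ctx is None:
                    ctx = ctx_cache[key] = classify_context(genome, p.contig, g, "-")
                callset.add(p.contig, g, "-", ctx, methylated=(b == "C"))
    return callset


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def conversion_rate(callset: CytosineCallSet, spikein_names: set[str]) -> float | None:
    """Bisulfite conversion rate from the unmethylated spike-in: converted
    (unmethylated) calls over all calls at spike-in cytosines, all contexts.

    Returns None (with a warning) when the spike-in has zero coverage."""
    import warnings

    meth = unmeth = 0
    for call in callset:
        if call.contig in spikein_names:
            meth += call.count_methylated
            unmeth += call.count_unmethylated
    total = meth + unmeth
    if total == 0:
        warnings.warn("no spike-in coverage: conversion rate undefined", stacklevel=2)
        return None
    return unmeth / total


def methylation_fractions_by_context(callset: CytosineCallSet) -> dict[str, float]:
    """Global percentage of methylated calls per sequence context.

    Contexts with zero coverage are absent from the result."""
    if len(callset) == 0:
        raise ValueError("empty callset")
    meth: dict[str, int] = defaultdict(int)
    cov: dict[str, int] = defaultdict(int)
    for call in callset:
        meth[call.context] += call.count_methylated
        cov[call.context] += call.coverage
    return {ctx: 100.0 * meth[ctx] / cov[ctx] for ctx in meth if cov[ctx] > 0}
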