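"""Synthetic data generation for reduced-representation bisulfite sequencing (RRBS).

This module builds every input the analysis pipeline consumes: genomes with
CpG-enriched island blocks and a fully unmethylated spike-in contig, gene
annotations, per-group true methylomes with designated differential CpG
sites, SNPs injected at CpG positions, MspI/TaqI double-digested and
size-selected restriction fragments, single-end bisulfite-converted and
untreated (genomic) read sets, and a two-group expression matrix whose
differential genes can be sign-linked to nearby differential methylation.

All generators are deterministic for a fixed (parameters, seed) pair; the
ground truth of every stochastic decision is recorded so downstream
statistics can be scored against it.

Coordinates are 0-based half-open throughout; 1-based coordinates appear
only in emitted text formats.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genome",
    "GeneRecord",
    "GeneAnnotation",
    "TrueMethylome",
    "Variant",
    "VariantSet",
    "Fragment",
    "FragmentSet",
    "Read",
    "ReadSet",
    "ExpressionMatrix",
    "ENZYMES",
    "SPIKEIN_NAME",
    "simulate_genome",
    "simulate_annotation",
    "digest",
    "size_select",
    "cpg_positions",
    "simulate_methylome",
    "simulate_origin_methylome",
    "inject_variants",
    "simulate_bisulfite_reads",
    "simulate_genomic_reads",
    "simulate_count_matrix",
    "simulate_expression",
    "revcomp",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Restriction enzymes as (recognition site, cut offset on the forward
#: strand).  MspI cuts C^CGG and TaqI cuts T^CGA; both sites are
#: palindromic, so forward-strand scanning finds every site.
ENZYMES: dict[str, tuple[str, int]] = {
    "MspI": ("CCGG", 1),
    "TaqI": ("TCGA", 1),
}

SPIKEIN_NAME = "spikein_lambda"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Named contigs plus the set of contigs acting as unmethylated spike-in.

    ``islands`` records the CpG-enriched block intervals laid down by
    :func:`simulate_genome` (half-open, per contig) so that enrichment can be
    audited.
    """

    contigs: dict[str, str]
    spikein_names: set[str] = field(default_factory=set)
    islands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome must contain at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name!r} contains non-ACGT characters")
        unknown = self.spikein_names - set(self.contigs)
        if unknown:
            raise ValueError(f"spike-in names not in genome: {sorted(unknown)}")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    @property
    def names(self) -> list[str]:
        return list(self.contigs)


@dataclass
class GeneRecord:
    """A gene model: TSS is the 5' end of the first exon on the gene strand."""

    gene_id: str
    contig: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        self.exons = ex
        expected_tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} does not match 5' exon end {expected_tss}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


class GeneAnnotation:
    """Ordered collection of :class:`GeneRecord` with per-contig lookup."""

    def __init__(self, records: list[GeneRecord]):
        self.records = list(records)
        self._by_contig: dict[str, list[GeneRecord]] = {}
        for r in self.records:
            self._by_contig.setdefault(r.contig, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genes_on(self, contig: str) -> list[GeneRecord]:
        return self._by_contig.get(contig, [])

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def by_id(self, gene_id: str) -> GeneRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)


@dataclass
class TrueMethylome:
    """Per-cytosine, per-group true methylation probabilities.

    ``levels`` maps (contig, position, strand) to an array of length
    ``len(groups)``.  ``differential`` records the designated differential
    CpG sites with the signed effect applied to the second group relative to
    the first, in percentage points.  ``clipped`` lists sites where the
    requested effect could not be applied exactly and was truncated.
    """

    groups: list[str]
    levels: dict[tuple[str, int, str], np.ndarray]
    differential: dict[tuple[str, int, str], float] = field(default_factory=dict)
    carrier: dict[tuple[str, int, str], str] = field(default_factory=dict)
    clipped: set[tuple[str, int, str]] = field(default_factory=set)

    def level(self, site: tuple[str, int, str], group: str) -> float:
        return float(self.levels[site][self.groups.index(group)])

    def group_delta(self, site: tuple[str, int, str], group1: str, group2: str) -> float:
        """True methylation difference group2 - group1 in percentage points."""
        lv = self.levels[site]
        return 100.0 * float(lv[self.groups.index(group2)] - lv[self.groups.index(group1)])


@dataclass
class Variant:
    contig: str
    pos: int
    ref: str
    alt: str
    freq: float

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt equals ref")
        if not 0 < self.freq <= 1:
            raise ValueError("allele frequency must be in (0, 1]")


class VariantSet:
    def __init__(self, variants: list[Variant], genome: Genome | None = None):
        if genome is not None:
            for v in variants:
                if genome[v.contig][v.pos] != v.ref:
                    raise ValueError(
                        f"variant ref {v.ref} does not match genome at {v.contig}:{v.pos}"
                    )
        self.variants = list(variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def positions(self) -> set[tuple[str, int]]:
        return {(v.contig, v.pos) for v in self.variants}


@dataclass(frozen=True)
class Fragment:
    """Restriction fragment, half-open; boundary provenance names the enzyme
    whose cut produced each end (None at contig ends)."""

    contig: str
    start: int
    end: int
    left_enzyme: str | None = None
    right_enzyme: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")

    def __len__(self) -> int:
        return self.end - self.start


class FragmentSet:
    def __init__(self, fragments: list[Fragment]):
        self.fragments = list(fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]


@dataclass
class Read:
    """A sequencing read with its simulation truth tags."""

    read_id: str
    sequence: str
    quality: str
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")


class ReadSet:
    def __init__(self, reads: list[Read]):
        self.reads = list(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __getitem__(self, i):
        return self.reads[i]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table (log2-scale) with group labels and the
    generator's differential-expression truth (signed shifts)."""

    values: "object"  # pandas.DataFrame, genes x samples
    groups: dict[str, str]
    true_shifts: dict[str, float] = field(default_factory=dict)
    linked_genes: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------


def simulate_genome(
    n_contigs: int,
    contig_length: int,
    cpg_enrichment: float = 1.0,
    seed: int = 0,
    spikein_length: int = 3000,
    island_block: int = 200,
    island_period: int = 5,
) -> Genome:
    """Simulate a random A/C/G/T genome plus one unmethylated spike-in contig.

    Every ``island_period``-th block of ``island_block`` bases is designated
    a CpG island: within islands the CpG dinucleotide frequency is
    multiplied by ``cpg_enrichment`` by explicit CG placement.  RRBS targets
    exactly such CpG-dense fractions, so enrichment > 1 concentrates
    restriction sites and CpGs where the assay looks.

    Parameters mirror a desk-scale stand-in for a real reference genome; the
    spike-in contig models the unmethylated lambda-phage control added to
    each library at ~1% mass.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    if cpg_enrichment < 1:
        raise ValueError("cpg_enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    islands: dict[str, list[tuple[int, int]]] = {}

    # base CG dinucleotide rate under iid uniform bases is 1/16
    island_cg_rate = min(0.45, cpg_enrichment / 16.0)

    for i in range(n_contigs):
        name = f"contig_{i + 1}"
        seq = rng.choice(_BASES, size=contig_length).tobytes().decode()
        blocks = []
        for b0 in range(0, contig_length - island_block + 1, island_block * island_period):
            blocks.append((b0, b0 + island_block))
        if cpg_enrichment > 1:
            arr = bytearray(seq, "ascii")
            for b0, b1 in blocks:
                # place CG dinucleotides at the island rate
                n_cg = rng.binomial(island_block // 2, island_cg_rate * 2)
                starts = rng.choice(
                    np.arange(b0, b1 - 1, 2), size=min(n_cg, (b1 - b0) // 2), replace=False
                )
                for s in starts:
                    arr[s : s + 2] = b"CG"
            seq = arr.decode()
        contigs[name] = seq
        islands[name] = blocks

    spike = rng.choice(_BASES, size=max(1000, spikein_length)).tobytes().decode()
    contigs[SPIKEIN_NAME] = spike
    return Genome(contigs=contigs, spikein_names={SPIKEIN_NAME}, islands=islands)


def simulate_annotation(
    genome: Genome,
    genes_per_contig: int = 4,
    n_exons: int = 3,
    exon_len: int = 300,
    intron_len: int = 500,
    seed: int = 0,
) -> GeneAnnotation:
    """Lay non-overlapping multi-exon gene models on each non-spike-in contig.

    Genes alternate strand; the TSS of each gene is the 5' end of its first
    exon on the annotated strand.
    """
    rng = np.random.default_rng(seed)
    records = []
    k = 0
    for contig, seq in genome.contigs.items():
        if contig in genome.spikein_names:
            continue
        gene_span = n_exons * exon_len + (n_exons - 1) * intron_len
        gap = max(1, (len(seq) - genes_per_contig * gene_span) // (genes_per_contig + 1))
        pos = gap
        for g in range(genes_per_contig):
            if pos + gene_span > len(seq):
                break
            start = pos + int(rng.integers(0, max(1, gap // 4)))
            if start + gene_span > len(seq):
                start = pos
            exons = []
            e = start
            for _ in range(n_exons):
                exons.append((e, e + exon_len))
                e += exon_len + intron_len
            strand = "+" if k % 2 == 0 else "-"
            tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
            records.append(
                GeneRecord(
                    gene_id=f"gene_{k + 1:04d}",
                    contig=contig,
                    strand=strand,
                    tss=tss,
                    exons=exons,
                )
            )
            k += 1
            pos = start + gene_span + gap
    return GeneAnnotation(records)


# ---------------------------------------------------------------------------
# Restriction digestion and size selection
# ---------------------------------------------------------------------------


def _resolve_enzymes(enzymes) -> list[tuple[str, str, int]]:
    out = []
    for enz in enzymes:
        if isinstance(enz, str):
            if enz not in ENZYMES:
                raise ValueError(f"unknown enzyme {enz!r}; give (name, site, offset)")
            site, offset = ENZYMES[enz]
            out.append((enz, site, offset))
        else:
            name, site, offset = enz
            out.append((name, site, offset))
    return out


def digest(genome: Genome, enzymes=("MspI", "TaqI")) -> FragmentSet:
    """In-silico double digestion: cut at every forward-strand recognition
    site at the enzyme's offset; fragments partition each contig.

    The union of all enzymes' cut positions is used, emulating complete
    double digestion of the library.  Both default sites (MspI C^CGG, TaqI
    T^CGA) are palindromic, so forward-strand scanning is exhaustive.
    """
    enz = _resolve_enzymes(enzymes)
    fragments: list[Fragment] = []
    for contig, seq in genome.contigs.items():
        cuts: dict[int, str] = {}
        for name, site, offset in enz:
            start = seq.find(site)
            while start != -1:
                cut = start + offset
                if 0 < cut < len(seq):
                    cuts.setdefault(cut, name)
                start = seq.find(site, start + 1)
        bounds = sorted(cuts)
        prev = 0
        prev_enz: str | None = None
        for cut in bounds:
            fragments.append(Fragment(contig, prev, cut, prev_enz, cuts[cut]))
            prev, prev_enz = cut, cuts[cut]
        fragments.append(Fragment(contig, prev, len(seq), prev_enz, None))
    return FragmentSet(fragments)


def size_select(fragments: FragmentSet, min_len: int = 40, max_len: int = 240) -> FragmentSet:
    """Keep fragments with min_len <= length <= max_len (inclusive), in order.

    Defaults reproduce the 40-240 bp gel size-selection window.
    """
    if min_len < 0 or max_len < 0:
        raise ValueError("size bounds must be non-negative")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return FragmentSet([f for f in fragments if min_len <= len(f) <= max_len])


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------


def cpg_positions(genome: Genome, contig: str) -> list[tuple[int, str]]:
    """All cytosines in CpG context on both strands of a contig.

    Forward-strand C of a CG dinucleotide at pos i pairs with the
    reverse-strand C at i+1 (the forward G).
    """
    seq = genome[contig]
    out = []
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            out.append((i, "+"))
            out.append((i + 1, "-"))
    return out


def _default_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    # mid-heavy baseline keeps per-site tests informative at desk-scale depth
    return rng.beta(2.0, 2.0, size=n)


def simulate_methylome(
    genome: Genome,
    groups: list[str],
    diff_fraction: float = 0.0,
    delta: float = 30.0,
    baseline_dist=None,
    seed: int = 0,
    chg_level: float = 0.01,
    chh_level: float = 0.008,
    sign_window: int = 20_000,
) -> TrueMethylome:
    """Assign true methylation probabilities per cytosine and group.

    CpG cytosines draw a shared baseline level per CpG dyad (both strands of
    a CpG carry the same level, as symmetric maintenance methylation
    implies).  A random ``diff_fraction`` of CpG dyads become differential.
    With two groups the second group's level differs from the first by
    exactly ``delta`` percentage points (direction chosen to stay inside
    [0, 1]; if neither direction fits the effect is clipped and the site
    flagged).  With more than two groups each differential site is carried
    by one group chosen uniformly at random — that group shifts by
    ``delta`` while the rest stay at baseline — so every pairwise
    comparison receives signal and parental-inheritance patterns arise
    naturally in an F2 design.

    The direction of the shift is coherent within ``sign_window``-bp
    blocks of each contig: methylation gains and losses occur over
    domain-scale regions rather than flipping site by site, which also
    gives promoter-proximal differential CpGs of one gene a common
    direction.  When a differential dyad's baseline cannot accommodate the
    block's direction, its baseline is redrawn uniformly from the feasible
    range so the designated effect stays exact.

    Non-CpG cytosines get low constant levels (``chg_level``/``chh_level``),
    mirroring the near-zero CHG/CHH methylation of mammalian somatic tissue.
    Spike-in contigs are fully unmethylated everywhere, serving as the
    bisulfite-conversion control.
    """
    if not 0 <= diff_fraction <= 1:
        raise ValueError("diff_fraction must be in [0, 1]")
    if not groups:
        raise ValueError("at least one group required")
    rng = np.random.default_rng(seed)
    draw = baseline_dist or _default_baseline
    ng = len(groups)
    levels: dict[tuple[str, int, str], np.ndarray] = {}
    differential: dict[tuple[str, int, str], float] = {}
    carrier: dict[tuple[str, int, str], str] = {}
    clipped: set[tuple[str, int, str]] = set()
    d = delta / 100.0

    for contig, seq in genome.contigs.items():
        spike = contig in genome.spikein_names
        n = len(seq)
        dyads = []  # forward positions of CG dinucleotides
        for i in range(n):
            base = seq[i]
            if base == "C":
                if i + 1 < n and seq[i + 1] == "G":
                    dyads.append(i)
                else:
                    levels[(contig, i, "+")] = np.zeros(ng) if spike else np.full(
                        ng, chg_level if i + 2 < n and seq[i + 2] == "G" else chh_level
                    )
            elif base == "G":
                if not (i - 1 >= 0 and seq[i - 1] == "C"):
                    # reverse-strand cytosine outside CpG context
                    rc_next = _COMPLEMENT[seq[i - 1]] if i - 1 >= 0 else None
                    rc_next2 = _COMPLEMENT[seq[i - 2]] if i - 2 >= 0 else None
                    lvl = chg_level if rc_next2 == "G" and rc_next != "G" else chh_level
                    levels[(contig, i, "-")] = np.zeros(ng) if spike else np.full(ng, lvl)

        if spike:
            for i in dyads:
                levels[(contig, i, "+")] = np.zeros(ng)
                levels[(contig, i + 1, "-")] = np.zeros(ng)
            continue

        n_dyads = len(dyads)
        base_levels = np.asarray(draw(rng, n_dyads), dtype=float)
        if ((base_levels < 0) | (base_levels > 1)).any():
            raise ValueError("baseline_dist produced levels outside [0, 1]")
        n_diff = int(round(diff_fraction * n_dyads))
        diff_idx = set(rng.choice(n_dyads, size=n_diff, replace=False)) if n_diff else set()
        block_signs: dict[int, float] = {}

        for j, i in enumerate(dyads):
            base = base_levels[j]
            lv = np.full(ng, base)
            if j in diff_idx and ng >= 2:
                block = i // max(sign_window, 1)
                if block not in block_signs:
                    block_signs[block] = 1.0 if rng.random() < 0.5 else -1.0
                sign = block_signs[block]
                flagged = False
                if not 0 <= base + sign * d <= 1:
                    if d > 1:
                        flagged = True
                    else:
                        # redraw a baseline compatible with the block direction
                        base = float(rng.uniform(0, 1 - d) if sign > 0 else rng.uniform(d, 1))
                        lv = np.full(ng, base)
                shifted = base + sign * d
                if flagged:
                    shifted = float(np.clip(shifted, 0.0, 1.0))
                gi = 1 if ng == 2 else int(rng.integers(0, ng))
                lv[gi] = shifted
                eff = (shifted - base) * 100.0
                for s in ((contig, i, "+"), (contig, i + 1, "-")):
                    differential[s] = eff
                    carrier[s] = groups[gi]
                    if flagged:
                        clipped.add(s)
            levels[(contig, i, "+")] = lv
            levels[(contig, i + 1, "-")] = lv.copy()

    return TrueMethylome(
        groups=list(groups), levels=levels, differential=differential,
        carrier=carrier, clipped=clipped,
    )


def simulate_origin_methylome(
    genome: Genome,
    diff_fraction: float = 0.1,
    delta: float = 40.0,
    baseline_dist=None,
    seed: int = 0,
    groups: tuple[str, str, str, str] = ("DuPi", "Duroc", "PiPP", "PiNN"),
) -> TrueMethylome:
    """Four-group methylome with explicit parental-inheritance structure.

    At each differential CpG dyad the donor breed (second group, "Duroc")
    shifts by ``delta`` and the F2 (first group) copies the donor's level,
    while both remaining groups stay at baseline — the pattern that should
    be attributed to donor origin downstream.  ``carrier`` records the
    donor group at the constructed sites.
    """
    methylome = simulate_methylome(
        genome, list(groups), diff_fraction=diff_fraction, delta=delta,
        baseline_dist=baseline_dist, seed=seed,
    )
    f2_i, donor_i = 0, 1
    for site in methylome.differential:
        lv = methylome.levels[site]
        vals, counts = np.unique(lv, return_counts=True)
        base = float(vals[np.argmax(counts)])  # baseline shared by non-carriers
        shifted_candidates = [float(v) for v in lv if v != base]
        shifted = shifted_candidates[0] if shifted_candidates else base
        lv[:] = base
        lv[donor_i] = shifted
        lv[f2_i] = shifted
        methylome.carrier[site] = groups[donor_i]
    return methylome


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def inject_variants(
    genome: Genome,
    cpg_sites: list[tuple[str, int]],
    snp_fraction: float,
    seed: int = 0,
) -> VariantSet:
    """Pick round(snp_fraction * len(cpg_sites)) CpG positions and assign an
    alternate allele, emulating segregating SNPs that confound methylation
    calls at CpG sites."""
    if not 0 <= snp_fraction <= 1:
        raise ValueError("snp_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(snp_fraction * len(cpg_sites)))
    idx = rng.choice(len(cpg_sites), size=n, replace=False) if n else np.array([], int)
    variants = []
    for i in sorted(idx):
        contig, pos = cpg_sites[i]
        ref = genome[contig][pos]
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(0, 3))]
        freq = float(rng.uniform(0.1, 0.5))
        variants.append(Variant(contig, pos, ref, alt, freq))
    return VariantSet(variants, genome)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _quality_string(rng: np.random.Generator, n: int, degraded_tail: bool) -> str:
    if not degraded_tail:
        return "I" * n  # constant Q40
    # linear decay over the last third of the read down to ~Q10
    q = np.full(n, 40)
    tail = n // 3
    if tail:
        q[-tail:] = np.linspace(40, 10, tail).astype(int)
    return "".join(chr(33 + int(v)) for v in q)


def _apply_errors(seq: list[str], error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        others = [b for b in "ACGT" if b != seq[i]]
        seq[i] = others[int(rng.integers(0, 3))]


def _fragment_weights(fragments: FragmentSet, genome: Genome, spikein_mass: float) -> np.ndarray:
    """Sampling weights giving spike-in fragments a fixed share of read mass."""
    is_spike = np.array([f.contig in genome.spikein_names for f in fragments])
    w = np.ones(len(fragments.fragments))
    if is_spike.any() and (~is_spike).any():
        w[is_spike] = spikein_mass / is_spike.sum() if spikein_mass > 0 else 0.0
        w[~is_spike] = (1 - spikein_mass) / (~is_spike).sum()
    return w / w.sum()


def simulate_bisulfite_reads(
    genome: Genome,
    fragments: FragmentSet,
    methylome: TrueMethylome,
    group: str,
    conversion_rate: float = 0.995,
    read_len: int = 114,
    depth: int = 30,
    error_rate: float = 0.001,
    seed: int = 0,
    sample: str = "sample",
    spikein_mass: float = 0.01,
    degraded_tail: bool = False,
) -> ReadSet:
    """Simulate single-end directional bisulfite reads from size-selected
    fragments.

    Each fragment yields ``depth`` reads on average (multinomial over
    fragments, with spike-in fragments collectively receiving
    ``spikein_mass`` of the read mass, emulating the 1% spike-in control).
    Each read picks an original strand (OT/OB) uniformly and reports the
    fragment 5' end on that strand, truncated to ``read_len``.

    Bisulfite chemistry: each cytosine on the read strand is drawn
    methylated with its site's true probability; methylated cytosines always
    read C (no over-conversion), unmethylated cytosines read T unless
    conversion fails (probability 1 - conversion_rate), in which case they
    read C.  Uniform sequencing errors are applied after conversion.
    """
    if not 0 <= conversion_rate <= 1:
        raise ValueError("conversion_rate must be in [0, 1]")
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    gi = methylome.groups.index(group)
    frags = fragments.fragments
    if not frags:
        return ReadSet([])
    weights = _fragment_weights(fragments, genome, spikein_mass)
    counts = rng.multinomial(depth * len(frags), weights)
    reads = []
    rid = 0
    for frag, n_reads in zip(frags, counts):
        seq = genome[frag.contig][frag.start : frag.end]
        for _ in range(n_reads):
            ot = rng.random() < 0.5
            template = seq if ot else revcomp(seq)
            template = template[:read_len]
            out = list(template)
            for j, b in enumerate(out):
                if b != "C":
                    continue
                if ot:
                    site = (frag.contig, frag.start + j, "+")
                else:
                    site = (frag.contig, frag.end - 1 - j, "-")
                level = methylome.levels.get(site)
                p = float(level[gi]) if level is not None else 0.0
                methylated = rng.random() < p
                if methylated:
                    continue  # protected, stays C
                if rng.random() < conversion_rate:
                    out[j] = "T"
            _apply_errors(out, error_rate, rng)
            read_seq = "".join(out)
            reads.append(
                Read(
                    read_id=f"{sample}:bs:{rid}",
                    sequence=read_seq,
                    quality=_quality_string(rng, len(read_seq), degraded_tail),
                    tags={
                        "contig": frag.contig,
                        "frag_start": frag.start,
                        "frag_end": frag.end,
                        "strand": "OT" if ot else "OB",
                        "bisulfite": True,
                    },
                )
            )
            rid += 1
    return ReadSet(reads)


def simulate_genomic_reads(
    genome: Genome,
    fragments: FragmentSet,
    variants: VariantSet | None = None,
    depth: int = 30,
    error_rate: float = 0.001,
    read_len: int = 114,
    seed: int = 0,
    sample: str = "pool",
    alt_prob: float = 0.5,
    degraded_tail: bool = False,
) -> ReadSet:
    """Simulate untreated (non-bisulfite) reads for SNP discovery.

    Reads carry injected variant alleles: each read covering a variant
    position shows the alternate allele with probability ``alt_prob``
    (0.5 models a heterozygote or a balanced pool)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    var_by_pos: dict[tuple[str, int], str] = {}
    if variants is not None:
        for v in variants:
            var_by_pos[(v.contig, v.pos)] = v.alt
    reads = []
    rid = 0
    for frag in fragments:
        seq = genome[frag.contig][frag.start : frag.end]
        for _ in range(depth):
            ot = rng.random() < 0.5
            out = list(seq)
            for j in range(len(out)):
                alt = var_by_pos.get((frag.contig, frag.start + j))
                if alt is not None and rng.random() < alt_prob:
                    out[j] = alt
            template = "".join(out)
            if not ot:
                template = revcomp(template)
            template = template[:read_len]
            out_l = list(template)
            _apply_errors(out_l, error_rate, rng)
            read_seq = "".join(out_l)
            reads.append(
                Read(
                    read_id=f"{sample}:gen:{rid}",
                    sequence=read_seq,
                    quality=_quality_string(rng, len(read_seq), degraded_tail),
                    tags={
                        "contig": frag.contig,
                        "frag_start": frag.start,
                        "frag_end": frag.end,
                        "strand": "OT" if ot else "OB",
                        "bisulfite": False,
                    },
                )
            )
            rid += 1
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# Direct count simulation (methylome -> per-sample counts)
# ---------------------------------------------------------------------------


def simulate_count_matrix(
    methylome: TrueMethylome,
    genome: Genome,
    samples: dict[str, str],
    coverage: int = 30,
    seed: int = 0,
    cpg_only: bool = True,
):
    """Draw per-sample methylated/total counts directly from the true
    methylome at a fixed mean coverage (Poisson per sample and site,
    binomial methylated calls).

    This bypasses read simulation and alignment; it is the statistical
    sampling model those stages induce at a reference CpG and is the
    appropriate scale for simulation studies of the differential-testing
    stage.  Returns a :class:`rrbspipe.diffmeth.MethylMatrix`.
    """
    from .diffmeth import MethylMatrix

    rng = np.random.default_rng(seed)
    sample_names = list(samples)
    sites = []
    for (contig, pos, strand), lv in methylome.levels.items():
        if contig in genome.spikein_names:
            continue
        if cpg_only:
            seq = genome[contig]
            if strand == "+":
                if not (pos + 1 < len(seq) and seq[pos + 1] == "G"):
                    continue
            else:
                if not (pos - 1 >= 0 and seq[pos - 1] == "C"):
                    continue
            if strand == "-":
                continue  # one record per dyad: forward strand carries it
        sites.append((contig, pos, strand))
    sites.sort()
    n_sites, n_samp = len(sites), len(sample_names)
    cov = rng.poisson(coverage, size=(n_sites, n_samp)).astype(np.int64)
    cov = np.maximum(cov, 1)
    meth = np.empty_like(cov)
    for k, s in enumerate(sample_names):
        gi = methylome.groups.index(samples[s])
        p = np.array([methylome.levels[site][gi] for site in sites])
        meth[:, k] = rng.binomial(cov[:, k], p)
    return MethylMatrix(sites=sites, meth=meth, cov=cov, samples=sample_names, groups=dict(samples))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    annotation: GeneAnnotation,
    groups: dict[str, str],
    de_fraction: float = 0.1,
    effect_size: float = 2.0,
    link_to_methylome: TrueMethylome | None = None,
    link_fraction: float = 1.0,
    link_window: int = 10_000,
    noise_sd: float = 0.5,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate a two-group log2-scale expression matrix (microarray-like).

    A random ``de_fraction`` of genes are differential with group-mean shift
    ``effect_size``.  When ``link_to_methylome`` is given, genes whose TSS
    lies within ``link_window`` of a designated differential CpG are, with
    probability ``link_fraction``, forced to be differential with shift of
    opposite sign to the methylation effect — promoter methylation
    repressing expression.  Truth (signed shifts, linked genes) is recorded.
    """
    import pandas as pd

    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = annotation.gene_ids()
    sample_names = list(groups)
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError("expression simulation requires exactly two groups")

    # methylation effect sign near each gene's TSS, measured between the two
    # expression groups when they exist in the methylome (else its first two)
    meth_sign: dict[str, float] = {}
    if link_to_methylome is not None:
        mg = link_to_methylome.groups
        if set(group_names) <= set(mg):
            g1, g2 = group_names
        else:
            g1, g2 = mg[0], mg[1]
        for rec in annotation:
            for (contig, pos, strand) in link_to_methylome.differential:
                if contig != rec.contig or abs(pos - rec.tss) > link_window:
                    continue
                eff = link_to_methylome.group_delta((contig, pos, strand), g1, g2)
                if eff != 0.0:
                    meth_sign[rec.gene_id] = math.copysign(1.0, eff)
                    break

    shifts: dict[str, float] = {}
    linked: dict[str, float] = {}
    n_de = int(round(de_fraction * len(gene_ids)))
    de_idx = set(rng.choice(len(gene_ids), size=n_de, replace=False)) if n_de else set()
    for j, g in enumerate(gene_ids):
        if g in meth_sign and rng.random() < link_fraction:
            shifts[g] = -meth_sign[g] * abs(effect_size)
            linked[g] = shifts[g]
        elif j in de_idx:
            shifts[g] = abs(effect_size) * (1.0 if rng.random() < 0.5 else -1.0)

    base = rng.normal(baseline_mean, baseline_sd, size=len(gene_ids))
    data = np.empty((len(gene_ids), len(sample_names)))
    for k, s in enumerate(sample_names):
        second = groups[s] == group_names[1]
        mu = base.copy()
        if second:
            for j, g in enumerate(gene_ids):
                mu[j] += shifts.get(g, 0.0)
        data[:, k] = mu + rng.normal(0.0, noise_sd, size=len(gene_ids))
    values = pd.DataFrame(data, index=gene_ids, columns=sample_names)
    return ExpressionMatrix(values=values, groups=dict(groups), true_shifts=shifts, linked_genes=linked)
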