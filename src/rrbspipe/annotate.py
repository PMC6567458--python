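"""Genomic-feature annotation of CpG sites and breed-origin attribution.

Feature assignment uses the precedence promoter > exon > intron >
intergenic (classes overlap, so precedence is required): a site is promoter
when it lies within 2 kb of any transcription start site (two-sided), exon
or intron by containment in a gene body otherwise, and intergenic when
neither applies.  Distances to the nearest TSS are signed on the gene
strand — negative upstream of the TSS.

Breed-origin attribution labels a CpG in an F2 cross (here the Duroc x
Pietrain DuPi population) by the pattern of its three F2-vs-purebred
comparisons: a site inherited from Duroc is indistinguishable from Duroc
but differentially methylated against at least one Pietrain group; a site
inherited from Pietrain differs from Duroc but is indistinguishable from at
least one Pietrain group.  The full eight-row truth table is frozen in
``ORIGIN_TRUTH_TABLE``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .simgen import GeneAnnotation

__all__ = [
    "AnnotatedSite",
    "OriginCall",
    "annotate_site",
    "annotate_sites",
    "feature_distribution",
    "attribute_origin",
    "attribute_origins",
    "ORIGIN_TRUTH_TABLE",
    "FEATURES",
]

FEATURES = ("promoter", "exon", "intron", "intergenic")

DUROC_ORIGIN = "Duroc_origin"
PIETRAIN_ORIGIN = "Pietrain_origin"
UNASSIGNED = "unassigned"

#: (dm vs Duroc, dm vs PiPP, dm vs PiNN) -> origin label.  Duroc-origin: no
#: difference to Duroc but different to a Pietrain group; Pietrain-origin:
#: different to Duroc but not to at least one Pietrain group.
ORIGIN_TRUTH_TABLE: dict[tuple[bool, bool, bool], str] = {
    (False, False, False): UNASSIGNED,
    (False, False, True): DUROC_ORIGIN,
    (False, True, False): DUROC_ORIGIN,
    (False, True, True): DUROC_ORIGIN,
    (True, False, False): PIETRAIN_ORIGIN,
    (True, False, True): PIETRAIN_ORIGIN,
    (True, True, False): PIETRAIN_ORIGIN,
    (True, True, True): UNASSIGNED,
}


@dataclass
class AnnotatedSite:
    site: tuple[str, int, str]
    feature: str
    gene_id: str | None
    dist_to_tss: int | None  # signed on gene strand; None when no gene on contig


@dataclass
class OriginCall:
    site: tuple[str, int, str]
    label: str


def _signed_dist(pos: int, tss: int, strand: str) -> int:
    return pos - tss if strand == "+" else tss - pos


def annotate_site(
    site: tuple[str, int, str],
    annotation: GeneAnnotation,
    promoter_bp: int = 2000,
) -> AnnotatedSite:
    """Classify one site against the gene annotation.

    ``gene_id``/``dist_to_tss`` always refer to the nearest TSS on the
    site's contig; they are None on a contig without genes (the site is then
    intergenic)."""
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    contig, pos, _strand = site
    genes = annotation.genes_on(contig)
    if not genes:
        return AnnotatedSite(site=site, feature="intergenic", gene_id=None, dist_to_tss=None)

    nearest = min(genes, key=lambda g: (abs(pos - g.tss), g.gene_id))
    dist = _signed_dist(pos, nearest.tss, nearest.strand)

    if any(abs(pos - g.tss) <= promoter_bp for g in genes):
        feature = "promoter"
    else:
        feature = "intergenic"
        for g in genes:
            lo, hi = g.span
            if lo <= pos < hi:
                feature = "exon" if any(s <= pos < e for s, e in g.exons) else "intron"
                if feature == "exon":
                    break
    return AnnotatedSite(site=site, feature=feature, gene_id=nearest.gene_id, dist_to_tss=dist)


def annotate_sites(sites, annotation: GeneAnnotation, promoter_bp: int = 2000) -> list[AnnotatedSite]:
    return [annotate_site(s, annotation, promoter_bp) for s in sites]


def feature_distribution(annotated: list[AnnotatedSite]) -> dict[str, float]:
    """Percentage of sites per feature class (sums to 100 up to rounding)."""
    if not annotated:
        raise ValueError("no annotated sites")
    counts = Counter(a.feature for a in annotated)
    total = len(annotated)
    return {f: 100.0 * counts.get(f, 0) / total for f in FEATURES}


def attribute_origin(
    dm_vs_duroc: bool | None,
    dm_vs_pipp: bool | None,
    dm_vs_pinn: bool | None,
) -> str:
    """Origin label from the three F2-vs-purebred differential flags.

    A missing comparison (None) yields 'unassigned' with a warning — origin
    is only defined for sites tested in all three comparisons."""
    flags = (dm_vs_duroc, dm_vs_pipp, dm_vs_pinn)
    if any(f is None for f in flags):
        warnings.warn("origin attribution requires all three comparisons", stacklevel=2)
        return UNASSIGNED
    return ORIGIN_TRUTH_TABLE[tuple(bool(f) for f in flags)]


def attribute_origins(
    sig_vs_duroc: set,
    sig_vs_pipp: set,
    sig_vs_pinn: set,
    tested_sites,
) -> list[OriginCall]:
    """Attribute origin for every site tested in all three comparisons.

    ``sig_vs_*`` are the significant-site keys of each F2-vs-purebred
    comparison; ``tested_sites`` is the common tested universe."""
    out = []
    for site in tested_sites:
        label = ORIGIN_TRUTH_TABLE[
            (site in sig_vs_duroc, site in sig_vs_pipp, site in sig_vs_pinn)
        ]
        out.append(OriginCall(site=site, label=label))
    return out
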