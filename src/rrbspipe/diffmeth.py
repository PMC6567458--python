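"""Differential CpG methylation: uniting, filtering, per-site logistic
regression, FDR control, effect-size selection, variant screening and
sample clustering.

The statistical core is a per-CpG binomial logistic regression of
methylated counts on group membership.  With a single binary covariate the
maximum-likelihood fit has a closed form — the fitted proportion in each
group is the pooled (coverage-weighted) within-group proportion — so the
likelihood-ratio statistic against the null of a common proportion is
computed analytically and referred to chi-square with 1 df.  Complete
separation (a group entirely methylated or unmethylated) is handled by
bounding fitted logits at +/-15, keeping p-values finite and conservative.

Site filtering follows the pipeline order: coverage (>= 10x in every
sample, CpG context only), zero-variance removal (subsumes all-0% and
all-100% sites), then exclusion of CpGs flagged polymorphic by the
untreated-library pileup screen.  Multiple testing is controlled with the
Benjamini-Hochberg step-up; significance requires q < 0.05 and a
methylation difference strictly greater than 25 percentage points.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bscall import CytosineCallSet, Placement
from .simgen import Genome, ReadSet

__all__ = [
    "MethylMatrix",
    "DiffMethRecord",
    "VariantScreen",
    "unite",
    "drop_invariant",
    "call_variants_pileup",
    "exclude_snp_sites",
    "test_site",
    "adjust_fdr",
    "diff_test",
    "significant_sites",
    "cluster_samples",
    "Dendrogram",
]

LOGIT_BOUND = 15.0  # |logit| cap for separated fits
_P_LO = 1.0 / (1.0 + np.exp(LOGIT_BOUND))
_P_HI = 1.0 - _P_LO


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class MethylMatrix:
    """Site x sample methylated/total count table with group labels."""

    sites: list[tuple[str, int, str]]
    meth: np.ndarray  # (n_sites, n_samples) methylated counts
    cov: np.ndarray  # (n_sites, n_samples) total coverage
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.cov = np.asarray(self.cov, dtype=np.int64)
        if self.meth.shape != self.cov.shape:
            raise ValueError("meth and cov shapes differ")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("matrix shape does not match sites x samples")
        if (self.meth > self.cov).any():
            raise ValueError("methylated counts exceed coverage")
        if not set(self.samples) <= set(self.groups):
            raise ValueError("every sample needs a group label")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def percent(self) -> np.ndarray:
        """Per-site per-sample methylation percentages (NaN at zero coverage)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.meth / self.cov

    def group_columns(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if self.groups[s] == group]

    def subset(self, keep: np.ndarray) -> "MethylMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        else:
            idx = keep
        return MethylMatrix(
            sites=[self.sites[i] for i in idx],
            meth=self.meth[idx],
            cov=self.cov[idx],
            samples=list(self.samples),
            groups=dict(self.groups),
        )


@dataclass
class DiffMethRecord:
    site: tuple[str, int, str]
    p_value: float
    q_value: float
    meth_diff: float  # group2 mean - group1 mean, percentage points
    hyper_group: str
    significant: bool


@dataclass
class VariantScreen:
    """Positions flagged polymorphic by the untreated-library pileup."""

    positions: set[tuple[str, int]] = field(default_factory=set)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# Uniting and filtering
# ---------------------------------------------------------------------------


def unite(
    callsets: dict[str, CytosineCallSet],
    groups: dict[str, str],
    min_coverage: int = 10,
) -> MethylMatrix:
    """Join per-sample callsets on CpG-context sites covered >= min_coverage
    in every sample.

    An empty intersection yields an empty matrix with a warning, not an
    error — small libraries legitimately share no deep sites."""
    if len(callsets) < 2:
        raise ValueError("unite requires at least 2 samples")
    samples = list(callsets)
    common: set[tuple[str, int, str]] | None = None
    for s in samples:
        keys = {
            k
            for k, c in callsets[s].calls.items()
            if c.context == "CpG" and c.coverage >= min_coverage
        }
        common = keys if common is None else (common & keys)
    sites = sorted(common or set())
    if not sites:
        warnings.warn("no CpG site passes the coverage filter in all samples", stacklevel=2)
    meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
    cov = np.zeros_like(meth)
    for j, s in enumerate(samples):
        for i, key in enumerate(sites):
            c = callsets[s].calls[key]
            meth[i, j] = c.count_methylated
            cov[i, j] = c.coverage
    return MethylMatrix(sites=sites, meth=meth, cov=cov, samples=samples, groups=dict(groups))


def drop_invariant(matrix: MethylMatrix) -> MethylMatrix:
    """Remove sites whose per-sample methylation percentages are identical
    across all samples (zero variance), which subsumes the all-0% and
    all-100% cases."""
    if matrix.n_sites == 0:
        return matrix
    pct = matrix.percent()
    keep = ~np.all(np.isclose(pct, pct[:, [0]]), axis=1)
    return matrix.subset(keep)


def call_variants_pileup(
    placements: list[Placement],
    reads: ReadSet,
    genome: Genome,
    min_cov: int = 10,
    min_alt_frac: float = 0.2,
    min_alt_count: int = 2,
) -> VariantScreen:
    """Simple pileup variant screen over uniquely placed untreated reads.

    A position is flagged when coverage >= min_cov, the most frequent
    non-reference allele reaches min_alt_frac of the pileup, and its count
    is >= min_alt_count.  OB placements contribute the complement of the
    read base at the forward-strand position."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for p in placements:
        read = reads[p.read_index]
        k = len(read.sequence)
        for j, b in enumerate(read.sequence):
            if b not in "ACGT":
                continue
            if p.strand == "OT":
                counts[(p.contig, p.start + j)][b] += 1
            else:
                counts[(p.contig, p.start + k - 1 - j)][comp[b]] += 1
    screen = VariantScreen()
    for (contig, pos), c in counts.items():
        cov = sum(c.values())
        if cov < min_cov:
            continue
        ref = genome[contig][pos]
        alts = [(n, b) for b, n in c.items() if b != ref]
        if not alts:
            continue
        n_alt, _ = max(alts)
        if n_alt >= min_alt_count and n_alt / cov >= min_alt_frac:
            screen.positions.add((contig, pos))
    return screen


def exclude_snp_sites(
    matrix: MethylMatrix, screen: VariantScreen, genome: Genome | None = None
) -> tuple[MethylMatrix, int]:
    """Drop sites whose position — or whose CpG-partner position — is
    flagged polymorphic; returns the filtered matrix and the removal count.

    The partner of a forward-strand CpG cytosine is the base immediately
    downstream (its paired reverse-strand cytosine), and conversely: a SNP
    on either side of the dyad corrupts calls on both."""
    if len(screen) == 0:
        return matrix, 0
    keep = np.ones(matrix.n_sites, dtype=bool)
    for i, (contig, pos, strand) in enumerate(matrix.sites):
        partner = pos + 1 if strand == "+" else pos - 1
        if (contig, pos) in screen or (contig, partner) in screen:
            keep[i] = False
    removed = int((~keep).sum())
    return matrix.subset(keep), removed


# ---------------------------------------------------------------------------
# Per-site logistic regression
# ---------------------------------------------------------------------------


def _binom_ll(m: float, n: float, p: float) -> float:
    p = min(max(p, _P_LO), _P_HI)
    return m * np.log(p) + (n - m) * np.log1p(-p)


def test_site(
    counts1: list[tuple[int, int]], counts2: list[tuple[int, int]]
) -> tuple[float, float]:
    """Likelihood-ratio test of equal methylation proportion between two
    groups under the binomial logistic model.

    ``counts*`` are per-sample (methylated, unmethylated) pairs.  Returns
    (p_value, meth_diff) with meth_diff = 100 * (pooled proportion of group
    2 minus group 1).  The MLE under logit(p_i) = b0 + b1 * group_i pools
    counts within groups; fitted logits are bounded at +/-15 under
    separation.
    """
    for grp in (counts1, counts2):
        for m, u in grp:
            if m + u < 1:
                raise ValueError("zero-coverage sample; filter upstream")
    m1 = sum(m for m, _ in counts1)
    n1 = sum(m + u for m, u in counts1)
    m2 = sum(m for m, _ in counts2)
    n2 = sum(m + u for m, u in counts2)
    p1, p2, p0 = m1 / n1, m2 / n2, (m1 + m2) / (n1 + n2)
    lrt = 2.0 * (
        _binom_ll(m1, n1, p1)
        + _binom_ll(m2, n2, p2)
        - _binom_ll(m1, n1, p0)
        - _binom_ll(m2, n2, p0)
    )
    p_value = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return p_value, 100.0 * (p2 - p1)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m * p_(j) / j, capped
    at 1; monotone non-decreasing in p."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def diff_test(
    matrix: MethylMatrix,
    group1: str,
    group2: str,
    q_threshold: float = 0.05,
    diff_threshold: float = 25.0,
) -> list[DiffMethRecord]:
    """Run the per-site test across a united matrix for one group pair and
    attach BH q-values, hypermethylated-group labels and significance."""
    c1 = matrix.group_columns(group1)
    c2 = matrix.group_columns(group2)
    if not c1 or not c2:
        raise ValueError("both groups need at least one sample")
    ps, diffs = [], []
    for i in range(matrix.n_sites):
        counts1 = [(int(matrix.meth[i, j]), int(matrix.cov[i, j] - matrix.meth[i, j])) for j in c1]
        counts2 = [(int(matrix.meth[i, j]), int(matrix.cov[i, j] - matrix.meth[i, j])) for j in c2]
        p, d = test_site(counts1, counts2)
        ps.append(p)
        diffs.append(d)
    qs = adjust_fdr(ps) if ps else np.array([])
    records = []
    for site, p, q, d in zip(matrix.sites, ps, qs, diffs):
        hyper = group2 if d > 0 else group1
        sig = bool(q < q_threshold and abs(d) > diff_threshold)
        records.append(
            DiffMethRecord(
                site=site, p_value=float(p), q_value=float(q), meth_diff=float(d),
                hyper_group=hyper, significant=sig,
            )
        )
    return records


def significant_sites(
    records: list[DiffMethRecord],
    q_threshold: float = 0.05,
    diff_threshold: float = 25.0,
) -> tuple[list[DiffMethRecord], dict[str, int]]:
    """Strict selection (q < threshold AND |diff| > threshold) plus a
    per-hypermethylated-group tally."""
    kept = [r for r in records if r.q_value < q_threshold and abs(r.meth_diff) > diff_threshold]
    tally = Counter(r.hyper_group for r in kept)
    return kept, dict(tally)


# ---------------------------------------------------------------------------
# Hierarchical clustering (Ward on 1 - Pearson correlation)
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    members: tuple[int, ...]
    height: float
    left: "_Node | None" = None
    right: "_Node | None" = None
    label: str | None = None


class Dendrogram:
    """Agglomeration result: nested grouping with merge heights."""

    def __init__(self, root: _Node, labels: list[str], merges: list[tuple[int, int, float]]):
        self.root = root
        self.labels = labels
        self.merges = merges  # (cluster index a, cluster index b, height)

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels (0..k-1) obtained by undoing the last k-1 merges."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValueError("k out of range")
        parent = list(range(2 * n - 1))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t, (a, b, _) in enumerate(self.merges[: n - k]):
            parent[find(a)] = n + t
            parent[find(b)] = n + t
        roots: dict[int, int] = {}
        out = {}
        for i, lab in enumerate(self.labels):
            r = find(i)
            out[lab] = roots.setdefault(r, len(roots))
        return out

    def to_newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.label is not None:
                return f"{node.label}:{length:.6g}"
            return f"({fmt(node.left, node.height)},{fmt(node.right, node.height)}):{length:.6g}"

        r = self.root
        return f"({fmt(r.left, r.height)},{fmt(r.right, r.height)});" if r.left else f"({r.label});"


def cluster_samples(matrix: MethylMatrix) -> Dendrogram:
    """Ward-linkage hierarchical clustering of samples on 1 - Pearson
    correlation of their methylation-percentage profiles.

    Distances follow the Lance-Williams Ward recurrence on squared
    distances; ties break toward the lowest cluster-index pair, making the
    merge order deterministic for a given sample order.  A sample with a
    constant methylation vector has undefined correlation and raises."""
    n = len(matrix.samples)
    if n < 3:
        raise ValueError("clustering needs at least 3 samples")
    if matrix.n_sites < 2:
        raise ValueError("clustering needs at least 2 sites")
    pct = matrix.percent()
    for j, s in enumerate(matrix.samples):
        if np.isclose(pct[:, j].std(), 0.0):
            raise ValueError(f"sample {s!r} has constant methylation; correlation undefined")
    corr = np.corrcoef(pct.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return _ward(d, list(matrix.samples))


def _ward(d: np.ndarray, labels: list[str]) -> Dendrogram:
    n = len(labels)
    d2 = d.astype(float) ** 2
    active = {i: _Node(members=(i,), height=0.0, label=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d2[i, j]
    merges = []
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        best = None
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                i, j = ids[a], ids[b]
                key = (min(i, j), max(i, j))
                v = dist[key]
                if best is None or v < best[0] - 1e-15:
                    best = (v, i, j)
        v, i, j = best
        h = float(np.sqrt(max(v, 0.0)))
        node = _Node(members=active[i].members + active[j].members, height=h,
                     left=active[i], right=active[j])
        si, sj = sizes[i], sizes[j]
        for k in ids:
            if k in (i, j):
                continue
            sk = sizes[k]
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dij = dist[(min(i, j), max(i, j))]
            new = ((si + sk) * dik + (sj + sk) * djk - sk * dij) / (si + sj + sk)
            dist[(min(k, next_id), max(k, next_id))] = new
        merges.append((i, j, h))
        active[next_id] = node
        sizes[next_id] = si + sj
        ids = [k for k in ids if k not in (i, j)] + [next_id]
        next_id += 1
    root = active[ids[0]]
    return Dendrogram(root=root, labels=labels, merges=merges)
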