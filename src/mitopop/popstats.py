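"""Forensic population statistics over mtDNA haplotypes.

Pairwise haplotype matching under the two forensic policies (literal: an
IUPAC symbol only matches itself; pattern: symbols match when their
expansions intersect), clustering into a haplotype frequency spectrum, and
the statistics derived from it:

* observed random match probability  RMP_obs = sum_i p_i^2  with
  p_i = n_i / n (probability two draws with replacement share a haplotype);
* empirical random match probability
  RMP_emp = sum_i n_i (n_i - 1) / (n (n - 1)) (fraction of distinct sample
  pairs that match);
* haplotype diversity  H = (n / (n - 1)) (1 - sum_i p_i^2), the power of
  discrimination of the marker system.

Also: de-duplication of maternal relatives sharing a haplotype, chi-squared
comparison of haplogroup distributions with Yates's continuity correction,
and dataset-level summary reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .refmodel import (
    IUPAC_EXPANSION,
    Haplotype,
    MITOGENOME_RANGE,
    RangeSpec,
    iupac_match,
    restrict_to_range,
)

MatchMode = Literal["literal", "pattern"]


@dataclass(frozen=True)
class MatchPolicy:
    """How two haplotypes are compared: matching mode, whether indels are
    ignored (the forensic default), and the range restriction."""

    mode: MatchMode = "literal"
    ignore_indels: bool = True
    range: RangeSpec = MITOGENOME_RANGE


# ---------------------------------------------------------------------------
# Matching and clustering
# ---------------------------------------------------------------------------


def _comparison_profile(
    h: Haplotype, policy: MatchPolicy, *, drop_n: bool = False
) -> dict[int, str]:
    """Substitution map used for comparison, restricted to the policy range.

    N calls are retained by default so that pairwise comparison can skip
    the position in *both* samples (missing data); exact-key clustering
    drops them instead (see :func:`cluster_haplotypes`).
    """
    h = restrict_to_range(h, policy.range)
    return {
        v.position: v.observed
        for v in h.variants
        if v.kind == "substitution" and not (drop_n and v.observed == "N")
    }


def _indel_key(h: Haplotype, policy: MatchPolicy) -> tuple:
    h = restrict_to_range(h, policy.range)
    return tuple(v.token() for v in h.variants if v.is_indel)


def haplotypes_match(h1: Haplotype, h2: Haplotype, policy: MatchPolicy) -> bool:
    """True when the two haplotypes are indistinguishable under the policy.

    After range restriction (and dropping indels when ignored), the
    substitution maps must cover the same positions and agree at each under
    the policy's IUPAC matching mode; positions where either sample reports
    N are skipped as missing data.
    """
    p1 = _comparison_profile(h1, policy)
    p2 = _comparison_profile(h2, policy)
    for pos in set(p1) | set(p2):
        a, b = p1.get(pos), p2.get(pos)
        if a == "N" or b == "N":
            continue  # missing data: position skipped entirely
        if a is None or b is None:
            return False
        if not iupac_match(a, b, policy.mode):
            return False
    if not policy.ignore_indels and _indel_key(h1, policy) != _indel_key(h2, policy):
        return False
    return True


@dataclass(frozen=True)
class FrequencySpectrum:
    """Multiplicity -> number of haplotype classes observed that many times.

    The spectrum is the sufficient statistic for all the match-probability
    and diversity computations.
    """

    n: int
    classes: dict[int, int]

    def __post_init__(self):
        if any(m < 1 for m in self.classes):
            raise ValueError("multiplicities must be >= 1")
        total = sum(m * c for m, c in self.classes.items())
        if total != self.n:
            raise ValueError(
                f"spectrum accounts for {total} samples, expected {self.n}"
            )

    @classmethod
    def from_class_sizes(cls, sizes: Iterable[int]) -> "FrequencySpectrum":
        sizes = list(sizes)
        classes: dict[int, int] = {}
        for s in sizes:
            classes[s] = classes.get(s, 0) + 1
        return cls(n=sum(sizes), classes=classes)

    @property
    def total_classes(self) -> int:
        return sum(self.classes.values())

    @property
    def n_unique(self) -> int:
        return self.classes.get(1, 0)

    def class_sizes(self) -> list[int]:
        out: list[int] = []
        for m, c in sorted(self.classes.items(), reverse=True):
            out.extend([m] * c)
        return out


def cluster_haplotypes(
    hs: Sequence[Haplotype], policy: MatchPolicy
) -> tuple[FrequencySpectrum, list[int]]:
    """Group haplotypes into match classes under the policy.

    Literal mode groups by exact comparison key (matching is transitive).
    Pattern-mode IUPAC matching is not transitive, so clusters are built by
    a deterministic greedy pass in input order: each haplotype joins the
    first existing cluster whose representative (its first member) it
    matches, else founds a new cluster.

    Returns the frequency spectrum and, per input haplotype, its cluster
    index.
    """
    assignments: list[int] = []
    if policy.mode == "literal":
        keys: dict[tuple, int] = {}
        sizes: list[int] = []
        for h in hs:
            profile = _comparison_profile(h, policy, drop_n=True)
            key = tuple(sorted(profile.items()))
            if not policy.ignore_indels:
                key = (key, _indel_key(h, policy))
            idx = keys.setdefault(key, len(sizes))
            if idx == len(sizes):
                sizes.append(0)
            sizes[idx] += 1
            assignments.append(idx)
    else:
        representatives: list[Haplotype] = []
        sizes = []
        for h in hs:
            for idx, rep in enumerate(representatives):
                if haplotypes_match(h, rep, policy):
                    sizes[idx] += 1
                    assignments.append(idx)
                    break
            else:
                representatives.append(h)
                sizes.append(1)
                assignments.append(len(sizes) - 1)
    spectrum = FrequencySpectrum.from_class_sizes(sizes) if sizes else (
        FrequencySpectrum(0, {})
    )
    return spectrum, assignments


# ---------------------------------------------------------------------------
# Forensic statistics
# ---------------------------------------------------------------------------


def observed_rmp(s: FrequencySpectrum) -> float:
    """Sum of squared haplotype sample frequencies (match probability for
    two draws with replacement)."""
    if s.n < 1:
        raise ValueError("empty spectrum")
    return float(
        sum(c * (m / s.n) ** 2 for m, c in s.classes.items())
    )


def empirical_rmp(s: FrequencySpectrum) -> float:
    """Fraction of distinct sample pairs sharing a haplotype."""
    if s.n < 2:
        raise ValueError("empirical RMP requires n >= 2")
    return float(
        sum(c * m * (m - 1) for m, c in s.classes.items()) / (s.n * (s.n - 1))
    )


def haplotype_diversity(s: FrequencySpectrum) -> float:
    """(n/(n-1)) * (1 - sum p_i^2): the power of discrimination."""
    if s.n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    return float(s.n / (s.n - 1) * (1.0 - observed_rmp(s)))


@dataclass(frozen=True)
class PopStatsResult:
    """Table-2-style summary for one range and matching mode."""

    total_haplotypes: int
    unique_haplotypes: int
    proportion_unique: float
    observed_rmp: float
    empirical_rmp: float
    haplotype_diversity: float

    def as_printed(self) -> dict[str, float]:
        """Values on the printed scale: RMPs as percentages at two
        decimals, proportion unique as a percentage at one decimal,
        diversity at four decimals (round-half-even)."""
        return {
            "total_haplotypes": self.total_haplotypes,
            "unique_haplotypes": self.unique_haplotypes,
            "proportion_unique_pct": round(100 * self.proportion_unique, 1),
            "observed_rmp_pct": round(100 * self.observed_rmp, 2),
            "empirical_rmp_pct": round(100 * self.empirical_rmp, 2),
            "haplotype_diversity": round(self.haplotype_diversity, 4),
        }


def population_stats(s: FrequencySpectrum) -> PopStatsResult:
    return PopStatsResult(
        total_haplotypes=s.total_classes,
        unique_haplotypes=s.n_unique,
        proportion_unique=s.n_unique / s.total_classes if s.total_classes else 0.0,
        observed_rmp=observed_rmp(s),
        empirical_rmp=empirical_rmp(s),
        haplotype_diversity=haplotype_diversity(s),
    )


def solve_sharing_split(
    *,
    n: int,
    total_classes: int,
    singletons: int,
    known_classes: dict[int, int],
    ambiguous_multiplicities: tuple[int, int],
    ambiguous_total: int,
) -> FrequencySpectrum:
    """Reconstruct a frequency spectrum when the split between two adjacent
    sharing multiplicities is only reported as a combined class count.

    Given the sample size, total and singleton class counts, the fully
    known classes, and that ``ambiguous_total`` further classes have
    multiplicity ``a`` or ``b``, the split solves the 2x2 linear system
    (class-count and sample-count conservation).  Raises if the counts are
    inconsistent or non-integral.
    """
    a, b = ambiguous_multiplicities
    known_samples = sum(m * c for m, c in known_classes.items())
    known_count = sum(known_classes.values())
    if known_count + singletons + ambiguous_total != total_classes:
        raise ValueError("class counts do not add up")
    remaining = n - singletons - known_samples
    # x classes of multiplicity a, y of b:  x + y = ambiguous_total,
    # a x + b y = remaining
    y_num = remaining - a * ambiguous_total
    if y_num % (b - a) != 0:
        raise ValueError("sharing counts have no integral solution")
    y = y_num // (b - a)
    x = ambiguous_total - y
    if x < 0 or y < 0:
        raise ValueError("sharing counts have no non-negative solution")
    classes = dict(known_classes)
    classes[a] = classes.get(a, 0) + x
    classes[b] = classes.get(b, 0) + y
    classes[1] = classes.get(1, 0) + singletons
    return FrequencySpectrum(n=n, classes={m: c for m, c in classes.items() if c})


# ---------------------------------------------------------------------------
# Relative de-duplication
# ---------------------------------------------------------------------------


def dedup_related(
    hs: Sequence[Haplotype],
    relatedness: Iterable[tuple[str, str, str]],
) -> list[Haplotype]:
    """Keep one sample per cluster of close maternal relatives that share a
    haplotype.

    Sharing is assessed ignoring indels and heteroplasmy (ambiguous IUPAC
    calls are excluded from the comparison profile).  ``relatedness`` lists
    ``(sample_a, sample_b, degree)`` pairs flagged as first or second
    degree.  Within each shared-haplotype group, related samples are
    clustered transitively and the lowest sample_id of each cluster is
    retained; unrelated samples are always kept.
    """
    ids = {h.sample_id for h in hs}
    related_pairs = set()
    for a, b, _degree in relatedness:
        if a not in ids or b not in ids:
            warnings.warn(f"relatedness pair ({a}, {b}) references unknown sample")
            continue
        related_pairs.add(frozenset((a, b)))

    def share_key(h: Haplotype) -> tuple:
        return tuple(
            sorted(
                (v.position, v.observed)
                for v in h.variants
                if v.kind == "substitution"
                and len(IUPAC_EXPANSION[v.observed]) == 1
            )
        )

    groups: dict[tuple, list[Haplotype]] = {}
    for h in hs:
        groups.setdefault(share_key(h), []).append(h)

    drop: set[str] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        # union-find over the related pairs within this shared group
        parent = {h.sample_id: h.sample_id for h in members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for pair in related_pairs:
            a, b = tuple(pair)
            if a in parent and b in parent:
                parent[find(a)] = find(b)
        clusters: dict[str, list[str]] = {}
        for h in members:
            clusters.setdefault(find(h.sample_id), []).append(h.sample_id)
        for cluster in clusters.values():
            if len(cluster) > 1:
                keep = min(cluster)
                drop.update(s for s in cluster if s != keep)
    return [h for h in hs if h.sample_id not in drop]


# ---------------------------------------------------------------------------
# Haplogroup distribution comparison
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """Dataset x haplogroup-bin counts for distribution comparison."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any() or (
            self.counts.sum(axis=0) == 0
        ).any():
            raise ValueError("contingency table has an all-zero row or column")


def chisq_yates(table) -> tuple[float, int, float]:
    """Chi-squared test of homogeneity with Yates's continuity correction.

    Per-cell statistic sum (|O - E| - 0.5)^2 / E (the correction clipped at
    zero), (r-1)(c-1) degrees of freedom, upper-tail p-value.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(
        table, dtype=float
    )
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = row @ col / counts.sum()
    corrected = np.maximum(np.abs(counts - expected) - 0.5, 0.0)
    statistic = float((corrected**2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    # a single row or column has no free cells: distributions are trivially
    # identical
    p = 1.0 if df == 0 else float(sps.chi2.sf(statistic, df))
    return statistic, df, p


# ---------------------------------------------------------------------------
# Summary helpers (Table 1 / Table 2 style reporting)
# ---------------------------------------------------------------------------


def proportion_pct(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage at the given precision (round-half-even); 0 for an empty
    denominator."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, ndigits)


def php_haplotype_summary(php_distribution: dict[int, int], n: int) -> dict:
    """Summaries of the per-haplotype PHP count distribution
    ``{k PHPs: number of haplotypes}`` (k >= 1) in a sample of ``n``."""
    n_with_php = sum(php_distribution.values())
    n_php_total = sum(k * c for k, c in php_distribution.items())
    return {
        "haplotypes_with_php": n_with_php,
        "total_php": n_php_total,
        "php_haplotype_pct": proportion_pct(n_with_php, n),
        "single_php_share_pct": proportion_pct(
            php_distribution.get(1, 0), n_with_php
        ),
        "max_php_per_haplotype": max(php_distribution, default=0),
    }


def classify_php_symbol(symbol: str) -> str:
    """Classify a two-base IUPAC PHP symbol as transition / transversion."""
    expansion = IUPAC_EXPANSION.get(symbol)
    if expansion is None or len(expansion) != 2:
        raise ValueError(f"{symbol!r} is not a two-base IUPAC symbol")
    if expansion in (frozenset("AG"), frozenset("CT")):
        return "transition"
    return "transversion"


def summarize_dataset(
    results: Optional[Sequence] = None,
    haplotypes: Optional[Sequence[Haplotype]] = None,
    policies: Optional[Sequence[MatchPolicy]] = None,
) -> dict:
    """Dataset-level report: coverage-class tallies, depth and average-VF
    means, variant and heteroplasmy summaries, and per-policy population
    statistics.

    ``results`` are per-sample call results (QC metrics); ``haplotypes``
    default to the called haplotypes.  The report is a plain dict so it can
    be serialized to JSON/TSV as Table-1/2-style output.
    """
    report: dict = {}
    results = list(results or [])
    if haplotypes is None:
        haplotypes = [r.haplotype for r in results]
    haplotypes = list(haplotypes)
    n = len(haplotypes)
    report["n_samples"] = n
    if n == 0:
        return report

    if results:
        coverage: dict[str, int] = {}
        for r in results:
            coverage[r.coverage_class] = coverage.get(r.coverage_class, 0) + 1
        report["coverage_classes"] = coverage
        report["mean_depth"] = float(np.mean([r.mean_depth for r in results]))
        mapped = [r.mapped_reads for r in results if r.mapped_reads is not None]
        if mapped:
            report["mean_mapped_reads"] = float(np.mean(mapped))
        vf_all = [r.avg_vf_all for r in results if r.avg_vf_all is not None]
        vf_nohp = [
            r.avg_vf_excluding_hp
            for r in results
            if r.avg_vf_excluding_hp is not None
        ]
        if vf_all:
            report["avg_vf_all_pct"] = round(100 * float(np.mean(vf_all)), 1)
        if vf_nohp:
            report["avg_vf_no_hp_pct"] = round(100 * float(np.mean(vf_nohp)), 1)
        depths = np.array([r.mean_depth for r in results], dtype=float)
        reads = np.array(
            [r.mapped_reads if r.mapped_reads is not None else np.nan for r in results]
        )
        ok = ~np.isnan(reads)
        if ok.sum() >= 3 and np.std(depths[ok]) > 0:
            lr = sps.linregress(reads[ok], depths[ok])
            report["reads_depth_r_squared"] = round(float(lr.rvalue**2), 3)
        report["n_mixture_flagged"] = sum(bool(r.mixture_flag) for r in results)
        report["n_numt_flagged_variants"] = sum(len(r.numt_flags) for r in results)

    # variants per haplotype
    n_variants = [len(h.variants) for h in haplotypes]
    report["total_variants"] = int(np.sum(n_variants))
    report["mean_variants_per_haplotype"] = round(float(np.mean(n_variants)), 1)
    report["max_variants_per_haplotype"] = int(np.max(n_variants))

    # PHP distribution and substitution-class tallies
    php_distribution: dict[int, int] = {}
    php_class = {"transition": 0, "transversion": 0, "other": 0}
    for h in haplotypes:
        k = h.n_php
        if k:
            php_distribution[k] = php_distribution.get(k, 0) + 1
        for v in h.variants:
            if v.is_heteroplasmic and v.kind == "substitution":
                exp = IUPAC_EXPANSION[v.observed]
                if len(exp) == 2:
                    php_class[classify_php_symbol(v.observed)] += 1
                else:
                    php_class["other"] += 1
    report["php_distribution"] = dict(sorted(php_distribution.items()))
    report.update(php_haplotype_summary(php_distribution, n))
    total_php = sum(php_class.values())
    report["php_classes"] = php_class
    if total_php:
        report["php_transition_share_pct"] = proportion_pct(
            php_class["transition"], total_php
        )

    # LHP tallies
    lhp_counts: dict[str, int] = {}
    n_lhp = 0
    for h in haplotypes:
        if h.lhp_regions:
            n_lhp += 1
            for region in h.lhp_regions:
                lhp_counts[region] = lhp_counts.get(region, 0) + 1
    report["lhp_haplotypes"] = n_lhp
    report["lhp_prevalence_pct"] = proportion_pct(n_lhp, n, 0)
    report["lhp_region_counts"] = dict(sorted(lhp_counts.items()))

    # population statistics per policy
    if policies:
        stats_rows = {}
        for policy in policies:
            spectrum, _ = cluster_haplotypes(haplotypes, policy)
            key = f"{policy.range.name}/{policy.mode}"
            row = population_stats(spectrum).as_printed()
            row["most_common_frequency_pct"] = proportion_pct(
                max(spectrum.classes, default=0), n
            )
            stats_rows[key] = row
        report["population_stats"] = stats_rows
    return report
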