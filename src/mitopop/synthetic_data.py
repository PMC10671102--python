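"""Synthetic mtDNA populations and read-evidence tables.

Generates (a) populations of true haplotypes with a configurable haplotype
frequency spectrum (a labelled-clade model: the spectrum, not a genealogy,
is what the downstream statistics consume) and (b) per-sample pileup tables
with the statistical structure of WGS-derived mtDNA read evidence:

* per-sample mean depth drawn log-uniformly over a wide range (roughly
  500X-3000X), per-position counts negative-binomial around it;
* per-base miscall noise well below the 2% background level;
* point heteroplasmy (PHP) as two-allele mixtures at 10-50% minor fraction;
* length heteroplasmy (LHP) as mixtures of length molecules in homopolymer
  C-stretches;
* NUMT contamination concentrated in hotspot blocks (nps 12,501-13,105 and
  np 16,496), raising low-frequency alleles in proportion to the
  contamination fraction;
* coverage dropout in homopolymer windows.

Every draw flows from a single seeded generator, so outputs are
deterministic given the seed.  Ground truth is returned alongside the data
for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .caller import BASES, PileupTable, _BASE_INDEX
from .refmodel import (
    HOMOPOLYMER_REGIONS,
    Haplotype,
    IUPAC_EXPANSION,
    IUPAC_FROM_PAIR,
    ReferenceGenome,
    SeqVariant,
    TRANSITIONS,
    synthetic_reference,
)

#: Haplotype-sharing structure of a large published Swedish mitogenome
#: population sample (n = 934): one haplotype seen 7, 6 and 5 times, five
#: seen 4 times, 16 tripletons, 51 doubletons and 746 singletons.
EXAMPLE_CLADE_SIZES: tuple[int, ...] = (
    (7,) + (6,) + (5,) + (4,) * 5 + (3,) * 16 + (2,) * 51 + (1,) * 746
)

#: Reporting anchors for insertion molecules in each homopolymer region.
LHP_ANCHORS: dict[str, int] = {
    "HVS2-C": 315,
    "HVS1-C": 16_193,
    "HVS3-C": 573,
    "AC-513": 524,
    "C-460": 459,
    "C-960": 960,
    "C-5899": 5_898,
    "C-8276": 8_275,
    "C-356": 355,
    "C-498": 497,
    "C-7471": 7_470,
}


@dataclass
class NumtBlock:
    """A nuclear-mtDNA segment whose reads co-align to a reference block.

    ``variants`` maps positions inside the interval to the NUMT allele;
    ``fraction`` is the expected frequency the NUMT alleles reach in the
    contaminated pileup (the mtDNA:nuclear read proportion is monotone in
    it)."""

    interval: tuple[int, int]
    variants: dict[int, str]
    fraction: float

    def __post_init__(self):
        if not 0 <= self.fraction < 1:
            raise ValueError("contamination fraction must be in [0, 1)")
        lo, hi = self.interval
        for pos in self.variants:
            if not lo <= pos <= hi:
                raise ValueError(f"NUMT variant {pos} outside block {self.interval}")


def default_numt_blocks(
    reference: ReferenceGenome, fraction: float = 0.0, n_variants: int = 6
) -> list[NumtBlock]:
    """Hotspot-shaped NUMT blocks: evenly spaced transition variants across
    nps 12,501-13,105 plus one at np 16,496."""
    positions = np.linspace(12_510, 13_100, n_variants).astype(int)
    variants = {
        int(p): TRANSITIONS[reference.base_at(int(p))] for p in positions
    }
    return [
        NumtBlock((12_501, 13_105), variants, fraction),
        NumtBlock(
            (16_496, 16_496),
            {16_496: TRANSITIONS[reference.base_at(16_496)]},
            fraction,
        ),
    ]


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate the WGS population study
    conditions the analysis is designed for."""

    n_samples: int = 100
    seed: int = 0
    clade_sizes: Optional[Sequence[int]] = None  # default: all singletons
    mean_mutations: float = 25.5        # variants per lineage vs reference
    ts_tv_weight: float = 15.0          # transition:transversion odds
    depth_range: tuple[float, float] = (500.0, 3000.0)  # per-sample mean, log-uniform
    depth_dispersion: float = 100.0     # negative-binomial size parameter
    error_rate: float = 0.005           # per-base miscall probability
    php_rate: float = 0.219             # probability a sample carries >=1 PHP
    php_count_probs: tuple[float, ...] = (0.863, 0.122, 0.015)  # 1, 2, 3 PHPs
    php_fraction_range: tuple[float, float] = (0.10, 0.50)
    lhp_region_probs: dict[str, float] = field(
        default_factory=lambda: {
            "HVS2-C": 0.64,
            "HVS1-C": 0.18,
            "HVS3-C": 0.05,
            "AC-513": 0.02,
        }
    )
    numt_fraction: float = 0.0          # contamination fraction for all samples
    numt_sample_rate: float = 0.0       # probability a sample is contaminated
    dropout_multiplier: float = 0.5     # depth multiplier in homopolymer windows
    dropout_windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(HOMOPOLYMER_REGIONS)
    )

    def __post_init__(self):
        if self.clade_sizes is not None:
            sizes = list(self.clade_sizes)
            if any(s < 1 for s in sizes):
                raise ValueError("clade sizes must be positive")
            if sum(sizes) != self.n_samples:
                raise ValueError(
                    f"clade sizes sum to {sum(sizes)}, expected {self.n_samples}"
                )
        lo, hi = self.php_fraction_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("PHP minor fractions must lie in (0, 0.5]")
        if not 0 <= self.numt_fraction < 1:
            raise ValueError("contamination fraction must be in [0, 1)")


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    clade: int
    haplotype: Haplotype
    php: list[tuple[int, str, float]] = field(default_factory=list)
    lhp: dict[str, dict[str, float]] = field(default_factory=dict)
    numt_fraction: float = 0.0
    mean_depth: float = 0.0


@dataclass
class GroundTruth:
    """Population-level ground truth emitted next to the synthetic data."""

    samples: list[SampleTruth]
    reference: ReferenceGenome
    config: SimConfig

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        if cfg.get("clade_sizes") is not None:
            cfg["clade_sizes"] = list(cfg["clade_sizes"])
        return {
            "seed": self.config.seed,
            "n_samples": self.config.n_samples,
            "reference": self.reference.name,
            "config": cfg,
        }


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def _forbidden_positions(config: SimConfig) -> set[int]:
    """Positions excluded from random substitution placement: homopolymer
    windows (plus one flank) and the PHP-suppressed error positions."""
    out: set[int] = {302, 16_182, 16_183}
    for lo, hi in HOMOPOLYMER_REGIONS.values():
        out.update(range(lo - 1, hi + 2))
    return out


#: NUMT hotspot blocks: heteroplasmy injected there would be annotated as
#: potential NUMT signal by the caller, so simulated PHPs avoid them.
_NUMT_HOTSPOT_POSITIONS: frozenset[int] = frozenset(
    range(12_501, 13_106)
) | {16_496}


def simulate_population(
    config: SimConfig, reference: Optional[ReferenceGenome] = None
) -> tuple[list[Haplotype], GroundTruth]:
    """Draw a population of true haplotypes with the configured sharing
    structure.

    Each clade receives a distinct substitution profile (so the realized
    frequency spectrum equals the configured clade sizes when per-clade
    haplotypes are identical, i.e. with PHP injection disabled); PHPs, LHP
    regions and NUMT contamination are then assigned per sample.
    """
    rng = np.random.default_rng(config.seed)
    reference = reference or synthetic_reference()
    sizes = (
        list(config.clade_sizes)
        if config.clade_sizes is not None
        else [1] * config.n_samples
    )
    forbidden = _forbidden_positions(config)
    candidates = np.array(
        [p for p in range(1, reference.length + 1) if p not in forbidden]
    )
    p_ts = config.ts_tv_weight / (config.ts_tv_weight + 2.0)

    clade_profiles: list[dict[int, str]] = []
    seen_profiles: set[frozenset] = set()
    for _ in sizes:
        while True:
            k = int(rng.poisson(config.mean_mutations))
            positions = rng.choice(candidates, size=min(k, candidates.size), replace=False)
            profile: dict[int, str] = {}
            for pos in sorted(int(p) for p in positions):
                ref_base = reference.base_at(pos)
                if rng.random() < p_ts:
                    alt = TRANSITIONS[ref_base]
                else:
                    tv = [b for b in BASES if b != ref_base and b != TRANSITIONS[ref_base]]
                    alt = tv[int(rng.integers(len(tv)))]
                profile[pos] = alt
            key = frozenset(profile.items())
            if key not in seen_profiles:
                seen_profiles.add(key)
                clade_profiles.append(profile)
                break

    haplotypes: list[Haplotype] = []
    truths: list[SampleTruth] = []
    sample_no = 0
    for clade_idx, size in enumerate(sizes):
        for _ in range(size):
            sample_no += 1
            sample_id = f"S{sample_no:04d}"
            profile = dict(clade_profiles[clade_idx])
            variants = [
                SeqVariant(pos, "substitution", alt, reference_base=reference.base_at(pos))
                for pos, alt in profile.items()
            ]
            truth = SampleTruth(sample_id=sample_id, clade=clade_idx, haplotype=Haplotype())

            # --- point heteroplasmy ---------------------------------------
            if rng.random() < config.php_rate:
                probs = np.array(config.php_count_probs)
                n_php = int(rng.choice(np.arange(1, len(probs) + 1), p=probs / probs.sum()))
                free = [
                    int(p)
                    for p in candidates
                    if int(p) not in profile
                    and int(p) not in _NUMT_HOTSPOT_POSITIONS
                ]
                php_positions = rng.choice(free, size=n_php, replace=False)
                for pos in sorted(int(p) for p in php_positions):
                    major = reference.base_at(pos)
                    minor = TRANSITIONS[major]
                    symbol = IUPAC_FROM_PAIR[frozenset((major, minor))]
                    frac = float(rng.uniform(*config.php_fraction_range))
                    truth.php.append((pos, symbol, frac))
                    variants.append(
                        SeqVariant(pos, "substitution", symbol, reference_base=major)
                    )

            # --- length heteroplasmy --------------------------------------
            for region, p_region in config.lhp_region_probs.items():
                if rng.random() < p_region:
                    # major molecule well clear of the runner-up so the
                    # major-length-molecule rule is stable under sampling
                    major_frac = float(rng.uniform(0.55, 0.70))
                    second_frac = float(rng.uniform(0.18, 0.28))
                    rest = 1.0 - major_frac - second_frac
                    fill = "AC" if region.startswith("AC") else "C"
                    truth.lhp[region] = {
                        fill: major_frac,       # major length molecule: +1 unit
                        "": second_frac,        # reference-length molecules
                        fill * 2: rest,         # minor longer molecule
                    }
                    anchor = LHP_ANCHORS[region]
                    for k, base in enumerate(fill, start=1):
                        variants.append(
                            SeqVariant(anchor, "insertion", base, insertion_index=k)
                        )

            # --- NUMT contamination ---------------------------------------
            if config.numt_fraction > 0 and (
                config.numt_sample_rate >= 1.0
                or rng.random() < config.numt_sample_rate
            ):
                truth.numt_fraction = config.numt_fraction

            truth.mean_depth = float(
                np.exp(rng.uniform(*np.log(config.depth_range)))
            )
            truth.haplotype = Haplotype(
                sample_id=sample_id,
                variants=tuple(variants),
                lhp_regions=frozenset(truth.lhp),
            )
            haplotypes.append(truth.haplotype)
            truths.append(truth)

    return haplotypes, GroundTruth(samples=truths, reference=reference, config=config)


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------


def _negative_binomial(rng, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_pileup(
    truth: SampleTruth,
    reference: ReferenceGenome,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PileupTable:
    """Emit per-position read evidence consistent with a sample's ground
    truth.

    Depth is negative-binomial around the sample mean (reduced in dropout
    windows); base counts are multinomial around the true allele(s) with
    the configured miscall rate; PHP positions mix two alleles at the
    stated minor fraction; LHP regions emit insertion-molecule mixtures;
    NUMT contamination is layered on by :func:`inject_numt`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = reference.length
    e = config.error_rate

    mean_depth = truth.mean_depth or float(np.mean(config.depth_range))
    multiplier = np.ones(L)
    for lo, hi in config.dropout_windows.values():
        multiplier[lo - 1 : hi] = config.dropout_multiplier
    depth = _negative_binomial(rng, mean_depth * multiplier, config.depth_dispersion)
    depth = np.maximum(depth, 1)

    # allele probabilities: truth base keeps 1-e, each other base e/3
    probs = np.full((L, 4), e / 3.0)
    truth_idx = np.fromiter(
        (_BASE_INDEX[b] for b in reference.bases), dtype=np.int64, count=L
    )
    subs = {
        v.position: v.observed
        for v in truth.haplotype.variants
        if v.kind == "substitution"
    }
    php_by_pos = {pos: (symbol, frac) for pos, symbol, frac in truth.php}
    del_positions = [
        v.position for v in truth.haplotype.variants if v.kind == "deletion"
    ]
    for pos, obs in subs.items():
        if pos in php_by_pos:
            continue
        truth_idx[pos - 1] = _BASE_INDEX[obs]
    rows = np.arange(L)
    probs[rows, truth_idx] = 1.0 - e
    for pos, (symbol, frac) in php_by_pos.items():
        major = reference.base_at(pos)
        minor = next(iter(IUPAC_EXPANSION[symbol] - {major}))
        row = np.full(4, e / 3.0)
        row[_BASE_INDEX[major]] = (1.0 - e) * (1.0 - frac)
        row[_BASE_INDEX[minor]] = (1.0 - e) * frac
        probs[pos - 1] = row
    probs /= probs.sum(axis=1, keepdims=True)

    base_counts = rng.multinomial(depth, probs)
    del_counts = np.zeros(L, dtype=np.int64)
    for pos in del_positions:
        d = depth[pos - 1]
        del_counts[pos - 1] = rng.binomial(d, 1.0 - e)
        remainder = d - del_counts[pos - 1]
        base_counts[pos - 1] = rng.multinomial(remainder, np.full(4, 0.25))

    insertions: dict[int, dict[str, int]] = {}
    # true (non-LHP) insertions are near-fixed
    ins_variants: dict[int, list[SeqVariant]] = {}
    lhp_anchors = {LHP_ANCHORS[r] for r in truth.lhp}
    for v in truth.haplotype.variants:
        if v.kind == "insertion" and v.position not in lhp_anchors:
            ins_variants.setdefault(v.position, []).append(v)
    for pos, vs in ins_variants.items():
        seq = "".join(
            v.observed for v in sorted(vs, key=lambda v: v.sort_key)
        )
        n = int(rng.binomial(depth[pos - 1], 1.0 - e))
        if n:
            insertions[pos] = {seq: n}
    # LHP molecule mixtures
    for region, molecules in truth.lhp.items():
        anchor = LHP_ANCHORS[region]
        names = list(molecules)
        fracs = np.array([molecules[m] for m in names], dtype=float)
        fracs /= fracs.sum()
        counts = rng.multinomial(int(depth[anchor - 1]), fracs)
        events = {
            name: int(c) for name, c in zip(names, counts) if name and c > 0
        }
        if events:
            insertions[anchor] = events

    pileup = PileupTable(
        sample_id=truth.sample_id,
        depth=depth,
        base_counts=base_counts,
        del_counts=del_counts,
        insertions=insertions,
        mapped_reads=float(mean_depth * L / 150.0 * rng.lognormal(0.0, 0.02)),
    )
    if truth.numt_fraction > 0:
        blocks = default_numt_blocks(reference, truth.numt_fraction)
        pileup = inject_numt(pileup, blocks, rng)
    return pileup


def inject_numt(
    pileup: PileupTable,
    blocks: Sequence[NumtBlock],
    rng: Optional[np.random.Generator] = None,
) -> PileupTable:
    """Add NUMT reads to a pileup.

    Within each block, reads carrying the NUMT allele are added so its
    expected frequency equals the block's contamination fraction; depth
    increases accordingly.  A zero fraction leaves the pileup unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    depth = pileup.depth.copy()
    base_counts = pileup.base_counts.copy()
    L = depth.shape[0]
    for block in blocks:
        lo, hi = block.interval
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"NUMT block {block.interval} outside reference")
        f = block.fraction
        if f == 0:
            continue
        for pos, allele in block.variants.items():
            d = depth[pos - 1]
            extra = int(rng.poisson(d * f / (1.0 - f)))
            base_counts[pos - 1, _BASE_INDEX[allele]] += extra
            depth[pos - 1] += extra
    return PileupTable(
        sample_id=pileup.sample_id,
        depth=depth,
        base_counts=base_counts,
        del_counts=pileup.del_counts.copy(),
        insertions={p: dict(ev) for p, ev in pileup.insertions.items()},
        mapped_reads=pileup.mapped_reads,
    )


def simulate_dataset(
    config: SimConfig, reference: Optional[ReferenceGenome] = None
) -> tuple[list[PileupTable], GroundTruth]:
    """Population plus one pileup per sample, all from the configured seed."""
    haplotypes, truth = simulate_population(config, reference)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pileups = [
        simulate_pileup(s, truth.reference, config, rng) for s in truth.samples
    ]
    return pileups, truth
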