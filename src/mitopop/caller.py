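"""Forensic mtDNA haplotype calling from per-position read evidence.

Implements thresholded calling in the style used for mitogenome haplotyping
of whole-genome-sequencing data, where low-level variants from co-aligning
nuclear mtDNA segments (NUMTs) must not enter the reported haplotype:

* a minimum read depth (default 100X, with a 20X fallback for otherwise
  incomplete samples) and a 10% minimum variant frequency (VF) threshold;
* point heteroplasmy (PHP) reported as a two-base IUPAC symbol when exactly
  two bases exceed the VF threshold;
* length heteroplasmy (LHP) in homopolymer regions handled by reporting the
  major length molecule and flagging the region;
* PHP suppression at positions dominated by post-homopolymer sequencing
  error (302, 16182, 16183), where the major nucleotide is reported;
* NUMT hotspot annotation (nps 12,501-13,105 and 16,496) with sub-threshold
  signal detection above the background-noise floor;
* per-haplotype QC: coverage class, average major-nucleotide frequency
  (average VF) with and without heteroplasmic positions, mixture flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .refmodel import (
    DELETION_MARKER,
    HOMOPOLYMER_REGIONS,
    IUPAC_FROM_PAIR,
    CoverageClass,
    Haplotype,
    ReferenceGenome,
    SeqVariant,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# Read-evidence container
# ---------------------------------------------------------------------------


@dataclass
class PileupTable:
    """Per-position read evidence for one sample.

    ``depth`` is total read depth; ``base_counts`` has one column per base
    (A, C, G, T); ``del_counts`` counts reads spanning the position with a
    deletion; ``insertions`` maps an anchor position to a tally of inserted
    sequences observed immediately after it.  Rows cover positions
    ``1..len(depth)``.
    """

    sample_id: str
    depth: np.ndarray
    base_counts: np.ndarray
    del_counts: np.ndarray
    insertions: dict[int, dict[str, int]] = field(default_factory=dict)
    mapped_reads: Optional[float] = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.base_counts = np.asarray(self.base_counts, dtype=np.int64)
        self.del_counts = np.asarray(self.del_counts, dtype=np.int64)
        L = self.depth.shape[0]
        if self.base_counts.shape != (L, 4):
            raise ValueError("base_counts must have shape (L, 4)")
        if self.del_counts.shape != (L,):
            raise ValueError("del_counts must have shape (L,)")
        if (self.base_counts < 0).any() or (self.del_counts < 0).any() or (
            self.depth < 0
        ).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_positions(self) -> int:
        return int(self.depth.shape[0])

    def to_frame(self) -> pd.DataFrame:
        ins_col = []
        for pos in range(1, self.n_positions + 1):
            events = self.insertions.get(pos)
            ins_col.append(
                ";".join(f"{seq}:{n}" for seq, n in sorted(events.items()))
                if events
                else "."
            )
        return pd.DataFrame(
            {
                "position": np.arange(1, self.n_positions + 1),
                "depth": self.depth,
                "count_A": self.base_counts[:, 0],
                "count_C": self.base_counts[:, 1],
                "count_G": self.base_counts[:, 2],
                "count_T": self.base_counts[:, 3],
                "count_del": self.del_counts,
                "insertions": ins_col,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: Optional[str] = None) -> "PileupTable":
        df = pd.read_csv(path, sep="\t")
        required = {
            "position", "depth", "count_A", "count_C", "count_G", "count_T",
            "count_del", "insertions",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
        df = df.sort_values("position")
        positions = df["position"].to_numpy()
        expected = np.arange(1, len(df) + 1)
        if not np.array_equal(positions, expected):
            gaps = sorted(set(expected) - set(positions))
            raise ValueError(f"pileup missing positions: {gaps[:10]}")
        insertions: dict[int, dict[str, int]] = {}
        for pos, cell in zip(positions, df["insertions"].astype(str)):
            if cell in (".", "nan", ""):
                continue
            events = {}
            for item in cell.split(";"):
                seq, n = item.rsplit(":", 1)
                events[seq] = int(n)
            insertions[int(pos)] = events
        if sample_id is None:
            import os

            sample_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(
            sample_id=sample_id,
            depth=df["depth"].to_numpy(),
            base_counts=df[["count_A", "count_C", "count_G", "count_T"]].to_numpy(),
            del_counts=df["count_del"].to_numpy(),
            insertions=insertions,
        )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_hotspots() -> list[tuple[int, int]]:
    return [(12_501, 13_105), (16_496, 16_496)]


def _default_suppressed() -> frozenset[int]:
    return frozenset({302, 16_182, 16_183})


@dataclass
class CallConfig:
    """Thresholds and reporting rules for haplotype calling.

    ``min_depth`` (100X) is the primary coverage requirement; samples left
    incomplete under it may be re-called under ``fallback_min_depth`` (20X).
    ``min_vf`` (10%) is the minimum variant frequency for any call — the
    primary defence against NUMT interference.  ``noise_floor`` (2%) is the
    background-noise level above which sub-threshold NUMT signal is
    considered detectable.
    """

    min_depth: int = 100
    fallback_min_depth: int = 20
    min_vf: float = 0.10
    noise_floor: float = 0.02
    numt_hotspots: list[tuple[int, int]] = field(default_factory=_default_hotspots)
    homopolymer_regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(HOMOPOLYMER_REGIONS)
    )
    suppressed_php_positions: frozenset[int] = field(default_factory=_default_suppressed)
    nearly_complete_max_low_positions: int = 4
    mixture_php_cap: int = 3          # > cap PHP-like positions => mixture
    mixture_min_avg_vf: float = 0.98  # avg VF (no HP) below this => mixture
    exclude_flagged_numt: bool = True

    def __post_init__(self):
        if not (0 < self.noise_floor < self.min_vf < 0.5):
            raise ValueError("require 0 < noise_floor < min_vf < 0.5")
        if not self.fallback_min_depth < self.min_depth:
            raise ValueError("fallback_min_depth must be below min_depth")

    def in_hotspot(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.numt_hotspots)

    def homopolymer_region_of(self, position: int) -> Optional[str]:
        for region_id, (lo, hi) in self.homopolymer_regions.items():
            if lo <= position <= hi:
                return region_id
        return None


# ---------------------------------------------------------------------------
# Per-position calls
# ---------------------------------------------------------------------------


@dataclass
class PositionCall:
    """Outcome of thresholded calling at one reference position."""

    position: int
    ref_base: str
    major_base: str
    major_fraction: float
    observed: str                       # base or two-base IUPAC symbol
    minor_fraction: Optional[float] = None
    is_php: bool = False
    deletion_called: bool = False
    deletion_fraction: float = 0.0
    deletion_major: bool = False
    insertions_called: list[tuple[str, float]] = field(default_factory=list)
    n_alleles_above_threshold: int = 0
    below_depth: bool = False
    uncovered: bool = False
    in_homopolymer: Optional[str] = None
    suppressed_php: bool = False


def call_position(
    position: int,
    depth: int,
    base_counts,
    del_count: int,
    ref_base: str,
    config: CallConfig,
    insertion_events: Optional[dict[str, int]] = None,
    min_depth: Optional[int] = None,
) -> PositionCall:
    """Apply the VF threshold to one position's read evidence.

    Exactly two bases at or above ``min_vf`` yield a two-base IUPAC PHP
    symbol with the minor fraction recorded; three or more count as
    mixture-indicative and only the major base is called.  Deletions and
    each distinct inserted sequence are called at the same threshold.  Zero
    depth marks the position uncovered.
    """
    active_min_depth = config.min_depth if min_depth is None else min_depth
    counts = np.asarray(base_counts, dtype=float)
    if depth <= 0:
        return PositionCall(
            position=position, ref_base=ref_base, major_base=ref_base,
            major_fraction=0.0, observed=ref_base, uncovered=True,
            below_depth=True,
        )
    freqs = counts / depth
    above = np.flatnonzero(freqs >= config.min_vf)
    major_idx = int(np.argmax(counts))
    major_base = BASES[major_idx]
    major_fraction = float(freqs[major_idx])
    call = PositionCall(
        position=position,
        ref_base=ref_base,
        major_base=major_base,
        major_fraction=major_fraction,
        observed=major_base,
        n_alleles_above_threshold=int(above.size),
        below_depth=depth < active_min_depth,
        in_homopolymer=config.homopolymer_region_of(position),
    )
    if above.size == 2:
        pair = frozenset(BASES[i] for i in above)
        call.observed = IUPAC_FROM_PAIR[pair]
        call.is_php = True
        minor_idx = above[np.argmin(freqs[above])]
        call.minor_fraction = float(freqs[minor_idx])
    del_fraction = del_count / depth
    if del_fraction >= config.min_vf:
        call.deletion_called = True
        call.deletion_fraction = float(del_fraction)
        if del_fraction > call.major_fraction:
            # the deletion is the major allele: no base-level call applies
            call.deletion_major = True
            call.major_fraction = float(del_fraction)
            call.observed = call.ref_base
            call.is_php = False
            call.minor_fraction = None
    if insertion_events:
        for seq, n in sorted(insertion_events.items()):
            frac = n / depth
            if frac >= config.min_vf:
                call.insertions_called.append((seq, float(frac)))
    return call


# ---------------------------------------------------------------------------
# Haplotype assembly
# ---------------------------------------------------------------------------


@dataclass
class CallResult:
    """A called haplotype plus the QC metrics used for forensic review."""

    haplotype: Haplotype
    coverage_class: CoverageClass
    n_positions_below_min_depth: int
    avg_vf_all: Optional[float]
    avg_vf_excluding_hp: Optional[float]
    numt_flags: list[tuple[int, str, float]]
    sub_threshold_numt_signal: bool
    mixture_flag: bool
    mean_depth: float
    mapped_reads: Optional[float] = None
    n_mixed_positions: int = 0
    calls: list[PositionCall] = field(default_factory=list)
    uncovered_positions: list[int] = field(default_factory=list)


def classify_coverage(n_below: int, config: CallConfig) -> CoverageClass:
    """Coverage class from the number of positions below the depth
    threshold: 0 -> complete, 1-4 -> nearly complete, >=5 -> incomplete
    (with the default cap of 4)."""
    if n_below < 0:
        raise ValueError("n_below must be >= 0")
    if n_below == 0:
        return "complete"
    if n_below <= config.nearly_complete_max_low_positions:
        return "nearly_complete"
    return "incomplete"


def average_vf(calls: list[PositionCall], exclude_hp: bool) -> Optional[float]:
    """Mean major-nucleotide frequency across variant positions.

    ``exclude_hp`` drops PHP positions and positions inside homopolymer
    regions (where length heteroplasmy depresses the major fraction),
    mirroring the "No HP" QC metric.  Returns ``None`` when no variant
    position exists.
    """
    fracs = []
    for c in calls:
        if exclude_hp and (c.is_php or c.suppressed_php or c.in_homopolymer):
            continue
        fracs.append(c.major_fraction)
    if not fracs:
        return None
    return float(np.mean(fracs))


def flag_mixture(
    n_mixed_positions: int,
    avg_vf_excluding_hp: Optional[float],
    config: CallConfig,
) -> bool:
    """Mixture evidence: more PHP-like (multi-allelic, non-hotspot)
    positions than the configured cap, or a depressed average VF."""
    if n_mixed_positions > config.mixture_php_cap:
        return True
    if (
        avg_vf_excluding_hp is not None
        and avg_vf_excluding_hp < config.mixture_min_avg_vf
    ):
        return True
    return False


def call_haplotype(
    pileup: PileupTable,
    ref: ReferenceGenome,
    config: Optional[CallConfig] = None,
    *,
    min_depth: Optional[int] = None,
) -> CallResult:
    """Assemble a forensic haplotype from a pileup.

    Applies the per-position VF threshold, the major-length-molecule rule in
    homopolymer regions, PHP suppression at post-homopolymer error
    positions, and NUMT hotspot annotation; computes coverage class,
    average VF metrics and the mixture flag.
    """
    config = config or CallConfig()
    if pileup.n_positions != ref.length:
        raise ValueError(
            f"pileup covers {pileup.n_positions} positions, reference has "
            f"{ref.length}"
        )
    active_min_depth = config.min_depth if min_depth is None else min_depth

    depth = pileup.depth
    counts = pileup.base_counts
    ref_idx = np.fromiter(
        (_BASE_INDEX[b] for b in ref.bases), dtype=np.int64, count=ref.length
    )

    covered = depth > 0
    safe_depth = np.where(covered, depth, 1)
    freqs = counts / safe_depth[:, None]
    del_freq = pileup.del_counts / safe_depth

    n_above = (freqs >= config.min_vf).sum(axis=1)
    major_idx = np.argmax(counts, axis=1)
    # positions needing a detailed look: non-reference major, multi-allelic,
    # deletion signal, insertion events, or hotspot sub-threshold signal
    interesting = (
        (major_idx != ref_idx)
        | (n_above >= 2)
        | (del_freq >= config.min_vf)
        | ~covered
    )
    for pos in pileup.insertions:
        interesting[pos - 1] = True

    hotspot_mask = np.zeros(ref.length, dtype=bool)
    for lo, hi in config.numt_hotspots:
        hotspot_mask[lo - 1 : hi] = True

    # sub-threshold NUMT signal: any hotspot position where a non-major
    # allele sits between the noise floor and the VF threshold
    nonmajor = freqs.copy()
    nonmajor[np.arange(ref.length), major_idx] = 0.0
    sub_signal_mask = (
        hotspot_mask
        & covered
        & ((nonmajor.max(axis=1) >= config.noise_floor)
           & (nonmajor.max(axis=1) < config.min_vf))
    )
    sub_threshold_numt_signal = bool(sub_signal_mask.any())

    variants: list[SeqVariant] = []
    calls: list[PositionCall] = []
    numt_flags: list[tuple[int, str, float]] = []
    uncovered_positions: list[int] = []
    n_mixed_positions = 0
    lhp_regions: set[str] = set()
    lhp_hp_positions: set[int] = set()

    # region -> {molecule sequence ("" = reference length): fraction}
    region_molecules: dict[str, dict[str, float]] = {}

    for i in np.flatnonzero(interesting):
        pos = int(i) + 1
        call = call_position(
            pos,
            int(depth[i]),
            counts[i],
            int(pileup.del_counts[i]),
            BASES[ref_idx[i]],
            config,
            insertion_events=pileup.insertions.get(pos),
            min_depth=active_min_depth,
        )
        if call.uncovered:
            uncovered_positions.append(pos)
            calls.append(call)
            continue

        hotspot = bool(hotspot_mask[i])
        suppressed = pos in config.suppressed_php_positions
        region = call.in_homopolymer

        # --- PHP / substitution logic -----------------------------------
        observed = call.observed
        if call.n_alleles_above_threshold >= 3 and not hotspot:
            n_mixed_positions += 1
        if call.is_php:
            if suppressed:
                # post-homopolymer error position: report major base only
                call.suppressed_php = True
                observed = call.major_base
            elif hotspot:
                # NUMT hotspot: always flag; optionally keep out of the
                # haplotype (major base reported instead)
                # recover the minor base from the thresholded pair
                pair = [
                    b for b in BASES
                    if freqs[i, _BASE_INDEX[b]] >= config.min_vf
                ]
                minor = next(b for b in pair if b != call.major_base)
                numt_flags.append((pos, minor, float(freqs[i, _BASE_INDEX[minor]])))
                if config.exclude_flagged_numt:
                    observed = call.major_base
                    call.suppressed_php = True
            else:
                n_mixed_positions += 1
        if region is not None and call.is_php and not suppressed:
            lhp_hp_positions.add(pos)

        if observed != BASES[ref_idx[i]] or (
            call.is_php and not call.suppressed_php
        ):
            if len(observed) == 1:
                # plain substitution (or major-base call where major != ref)
                if observed != BASES[ref_idx[i]]:
                    # a near-fixed non-reference major is a genuine variant
                    # even inside a hotspot; NUMT interference shows up as a
                    # minor allele and is flagged through the PHP branch
                    variants.append(
                        SeqVariant(pos, "substitution", observed,
                                   reference_base=BASES[ref_idx[i]])
                    )
            else:
                variants.append(
                    SeqVariant(pos, "substitution", observed,
                               reference_base=BASES[ref_idx[i]])
                )
        call.observed = observed
        calls.append(call)

        # --- deletions ---------------------------------------------------
        if call.deletion_called:
            if region is not None:
                mol = region_molecules.setdefault(region, {})
                mol["-"] = mol.get("-", 0.0) + call.deletion_fraction
                # decided with the region's length molecules below
                if call.deletion_fraction > 0.5:
                    variants.append(SeqVariant(pos, "deletion", DELETION_MARKER))
            else:
                variants.append(SeqVariant(pos, "deletion", DELETION_MARKER))

        # --- insertions --------------------------------------------------
        if pos in pileup.insertions:
            events = pileup.insertions[pos]
            total_ins = sum(events.values())
            if region is not None:
                # length-molecule accounting: reference-length molecules are
                # the reads without an insertion at this anchor
                mol = region_molecules.setdefault(region, {})
                mol[""] = mol.get("", 0.0) + max(depth[i] - total_ins, 0) / depth[i]
                for seq, n in events.items():
                    mol[seq] = mol.get(seq, 0.0) + n / depth[i]
                mol["_anchor"] = pos  # type: ignore[assignment]
            else:
                for seq, frac in call.insertions_called:
                    for k, base in enumerate(seq, start=1):
                        variants.append(
                            SeqVariant(pos, "insertion", base, insertion_index=k)
                        )

    # --- homopolymer regions: major length molecule + LHP flag -----------
    for region, molecules in region_molecules.items():
        anchor = molecules.pop("_anchor", None)
        above = {m: f for m, f in molecules.items() if f >= config.min_vf}
        if len(above) >= 2:
            lhp_regions.add(region)
        if not above:
            continue
        major_mol = max(above, key=lambda m: (above[m], m))
        if major_mol in ("", "-"):
            continue  # reference length (or deletion handled above)
        if anchor is not None:
            for k, base in enumerate(major_mol, start=1):
                variants.append(
                    SeqVariant(int(anchor), "insertion", base, insertion_index=k)
                )

    n_below = int((depth < active_min_depth).sum())
    coverage_class = classify_coverage(n_below, config)

    # average VF over variant positions; LHP-region calls are excluded from
    # the "no HP" figure via their in_homopolymer tag
    variant_calls = [
        c for c in calls
        if not c.uncovered and (
            c.observed != c.ref_base
            or c.is_php
            or c.suppressed_php
            or c.deletion_called
            or c.position in pileup.insertions
        )
    ]
    avg_all = average_vf(variant_calls, exclude_hp=False)
    avg_no_hp = average_vf(variant_calls, exclude_hp=True)

    haplotype = Haplotype(
        sample_id=pileup.sample_id,
        variants=tuple(variants),
        coverage_class=coverage_class,
        lhp_regions=frozenset(lhp_regions),
    )
    return CallResult(
        haplotype=haplotype,
        coverage_class=coverage_class,
        n_positions_below_min_depth=n_below,
        avg_vf_all=avg_all,
        avg_vf_excluding_hp=avg_no_hp,
        numt_flags=numt_flags,
        sub_threshold_numt_signal=sub_threshold_numt_signal,
        mixture_flag=flag_mixture(n_mixed_positions, avg_no_hp, config),
        mean_depth=float(depth.mean()),
        mapped_reads=pileup.mapped_reads,
        n_mixed_positions=n_mixed_positions,
        calls=calls,
        uncovered_positions=uncovered_positions,
    )


def call_with_fallback(
    pileup: PileupTable,
    ref: ReferenceGenome,
    config: Optional[CallConfig] = None,
) -> CallResult:
    """Call under the primary depth threshold; if the sample comes out
    incomplete, re-call under the fallback threshold (the 20X rescue rule
    for otherwise incomplete samples)."""
    config = config or CallConfig()
    result = call_haplotype(pileup, ref, config)
    if result.coverage_class == "incomplete":
        result = call_haplotype(
            pileup, ref, config, min_depth=config.fallback_min_depth
        )
    return result
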