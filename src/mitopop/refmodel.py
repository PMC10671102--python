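"""Reference model for forensic mitogenome haplotypes.

Coordinates are 1-based positions on the revised Cambridge Reference
Sequence (rCRS) numbering system; the mitogenome is circular, 16,569 bp.
Haplotypes are expressed EMPOP-style as differences from the reference:
substitutions (``263G``), insertions (``315.1C``, wildcard index ``309.xC``)
and deletions (``8281DEL``, reader also accepts ``8281-``).  Point
heteroplasmy is encoded with two-base IUPAC symbols (``16093Y`` = C/T
mixture); ``N`` is accepted on parse but treated as missing data in
comparisons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np

MITOGENOME_LENGTH = 16_569

#: IUPAC nucleotide codes mapped to their expansion sets.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: two-base expansion -> ambiguity symbol (for PHP calls).
IUPAC_FROM_PAIR: dict[frozenset[str], str] = {
    exp: sym for sym, exp in IUPAC_EXPANSION.items() if len(exp) == 2
}

DELETION_MARKER = "DEL"

#: Transition partner for each base (purine<->purine, pyrimidine<->pyrimidine).
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


class NotationError(ValueError):
    """Malformed or inconsistent haplotype notation."""


# ---------------------------------------------------------------------------
# Ranges
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangeSpec:
    """A named union of closed 1-based intervals on the mtDNA coordinate
    system.

    The circular origin is handled by expressing wrap-around ranges as an
    explicit union (the control region is ``16,024-16,569 + 1-576``), so the
    intervals themselves are plain linear intervals.
    """

    name: str
    intervals: tuple[tuple[int, int], ...]

    def __init__(self, name: str, intervals: Iterable[Sequence[int]]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "intervals", _normalize_intervals(intervals))

    def __contains__(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.intervals)

    def __len__(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.intervals)

    def intersect(self, other: "RangeSpec") -> "RangeSpec":
        out = []
        for a_lo, a_hi in self.intervals:
            for b_lo, b_hi in other.intervals:
                lo, hi = max(a_lo, b_lo), min(a_hi, b_hi)
                if lo <= hi:
                    out.append((lo, hi))
        return RangeSpec(f"{self.name}&{other.name}", out)

    def issubset(self, other: "RangeSpec") -> bool:
        return len(self.intersect(other)) == len(self)

    def positions(self) -> np.ndarray:
        """All member positions as a sorted integer array."""
        return np.concatenate(
            [np.arange(lo, hi + 1) for lo, hi in self.intervals]
        ) if self.intervals else np.empty(0, dtype=int)


def _normalize_intervals(
    intervals: Iterable[Sequence[int]],
) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(lo), int(hi)) for lo, hi in intervals)
    for lo, hi in ivs:
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid interval ({lo}, {hi})")
    merged: list[list[int]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


#: Hypervariable segments HVS1 (16,024-16,365) and HVS2 (73-340).
HVS_RANGE = RangeSpec("HVS", [(16_024, 16_365), (73, 340)])
#: Control region, spanning the circular origin as an explicit union.
CR_RANGE = RangeSpec("CR", [(16_024, 16_569), (1, 576)])
#: The entire mitogenome.
MITOGENOME_RANGE = RangeSpec("mitogenome", [(1, MITOGENOME_LENGTH)])

NAMED_RANGES = {
    "hvs": HVS_RANGE,
    "cr": CR_RANGE,
    "mitogenome": MITOGENOME_RANGE,
}


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceGenome:
    """Circular 1-based mtDNA reference sequence."""

    name: str
    bases: str

    def __post_init__(self):
        if set(self.bases) - set("ACGT"):
            raise ValueError("reference may contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.bases)

    def normalize_position(self, position: int) -> int:
        """Map a coordinate onto 1..length (circular arithmetic)."""
        return (position - 1) % self.length + 1

    def base_at(self, position: int) -> str:
        return self.bases[self.normalize_position(position) - 1]

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single FASTA record, got {len(records)}")
        rec = records[0]
        return cls(name=rec.id, bases=str(rec.seq).upper())

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            seq = self.bases
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


#: Homopolymer C-stretch coordinates used when building the synthetic
#: reference and as default length-heteroplasmy regions for the caller.
#: Keys are the identifiers used in LHP reporting.
HOMOPOLYMER_REGIONS: dict[str, tuple[int, int]] = {
    "HVS2-C": (303, 315),      # CCCCCCCTCCCCC around np 310
    "HVS1-C": (16_184, 16_193),
    "HVS3-C": (568, 573),
    "AC-513": (513, 524),      # AC dinucleotide repeat
    "C-460": (456, 459),
    "C-960": (956, 960),
    "C-5899": (5_895, 5_898),
    "C-8276": (8_272, 8_275),
    "C-356": (352, 355),
    "C-498": (494, 497),
    "C-7471": (7_466, 7_470),
}


def synthetic_reference(seed: int = 0, name: str = "synthetic-mtref") -> ReferenceGenome:
    """Build a synthetic 16,569-bp stand-in for the rCRS.

    The true rCRS sequence is not shipped; this fixture reproduces the
    coordinate system and places homopolymer runs at the canonical C-stretch
    coordinates so that length-heteroplasmy and coverage-dropout behaviour
    can be simulated realistically.  It is labelled synthetic and must not
    be mistaken for the real reference.
    """
    rng = np.random.default_rng(seed)
    # mtDNA heavy strand is pyrimidine-rich; mildly skew composition.
    bases = rng.choice(list("ACGT"), size=MITOGENOME_LENGTH, p=[0.31, 0.31, 0.13, 0.25])
    seq = bases.copy()
    for region_id, (lo, hi) in HOMOPOLYMER_REGIONS.items():
        fill = "AC" if region_id.startswith("AC") else "C"
        run = (fill * (hi - lo + 1))[: hi - lo + 1]
        seq[lo - 1 : hi] = list(run)
    return ReferenceGenome(name=name, bases="".join(seq))


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

VariantKind = Literal["substitution", "insertion", "deletion"]

_TOKEN_RE = re.compile(
    r"^(?P<pos>\d+)"
    r"(?:\.(?P<idx>\d+|[xX]))?"
    r"(?P<obs>[ACGTRYSWKMBDHVNacgtryswkmbdhvn]+|DEL|del|-)"
    r"(?P<back>!?)$"
)

_KIND_ORDER = {"substitution": 0, "deletion": 1, "insertion": 2}


@dataclass(frozen=True, order=False)
class SeqVariant:
    """A single rCRS-relative sequence difference.

    ``insertion_index`` is the 1-based position within the inserted run
    (``315.1C``) or the wildcard ``"x"`` (``309.xC``) when the run length
    varies; it is ``None`` for substitutions and deletions.  ``observed`` is
    an IUPAC symbol (ambiguity codes denote point heteroplasmy) or the
    deletion marker.
    """

    position: int
    kind: VariantKind
    observed: str
    insertion_index: Optional[Union[int, str]] = None
    reference_base: Optional[str] = None
    back_mutation: bool = False

    def __post_init__(self):
        if self.position < 1:
            raise NotationError(f"position must be >= 1, got {self.position}")
        if self.kind == "deletion":
            if self.observed != DELETION_MARKER:
                raise NotationError("deletion must observe the deletion marker")
        elif self.observed not in IUPAC_EXPANSION:
            raise NotationError(f"invalid observed symbol {self.observed!r}")
        if self.kind == "insertion":
            ok = self.insertion_index == "x" or (
                isinstance(self.insertion_index, int) and self.insertion_index >= 1
            )
            if not ok:
                raise NotationError(
                    f"insertion index must be >= 1 or 'x', got {self.insertion_index!r}"
                )
        elif self.insertion_index is not None:
            raise NotationError("insertion_index only valid for insertions")
        if (
            self.kind == "substitution"
            and self.reference_base is not None
            and self.observed == self.reference_base
        ):
            raise NotationError(
                f"substitution at {self.position} observes the reference base"
            )

    @property
    def is_indel(self) -> bool:
        return self.kind != "substitution"

    @property
    def is_heteroplasmic(self) -> bool:
        """True when the observed symbol expands to more than one base (PHP)."""
        return (
            self.kind != "deletion" and len(IUPAC_EXPANSION[self.observed]) > 1
        )

    @property
    def sort_key(self) -> tuple:
        idx = self.insertion_index
        # wildcard 'x' sorts after numbered insertion indices
        idx_key = (1, 0) if idx == "x" else (0, idx or 0)
        return (self.position, _KIND_ORDER[self.kind], idx_key)

    @property
    def key(self) -> tuple:
        """Identity key: no two variants of a haplotype may share it."""
        return (self.position, self.kind, self.insertion_index)

    def token(self) -> str:
        bang = "!" if self.back_mutation else ""
        if self.kind == "deletion":
            return f"{self.position}{DELETION_MARKER}{bang}"
        if self.kind == "insertion":
            return f"{self.position}.{self.insertion_index}{self.observed}{bang}"
        return f"{self.position}{self.observed}{bang}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def parse_variant_token(
    token: str, *, allow_back_mutation: bool = False
) -> SeqVariant:
    """Parse one EMPOP-style variant token.

    Accepts ``263G`` (substitution), ``315.1C`` / ``309.xC`` (insertion),
    ``8281DEL`` or ``8281-`` (deletion) and, when ``allow_back_mutation`` is
    set, a trailing ``!`` marking a phylogenetic back mutation.
    """
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise NotationError(f"malformed variant token {token!r}")
    if m.group("back") and not allow_back_mutation:
        raise NotationError(f"back-mutation token {token!r} not allowed here")
    pos = int(m.group("pos"))
    obs = m.group("obs").upper()
    idx_raw = m.group("idx")
    back = bool(m.group("back"))
    if obs in (DELETION_MARKER, "-"):
        if idx_raw is not None:
            raise NotationError(f"deletion token {token!r} cannot carry an index")
        return SeqVariant(pos, "deletion", DELETION_MARKER, back_mutation=back)
    if len(obs) != 1:
        raise NotationError(f"malformed variant token {token!r}")
    if idx_raw is not None:
        idx: Union[int, str] = "x" if idx_raw.lower() == "x" else int(idx_raw)
        return SeqVariant(pos, "insertion", obs, insertion_index=idx, back_mutation=back)
    return SeqVariant(pos, "substitution", obs, back_mutation=back)


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

CoverageClass = Literal["complete", "nearly_complete", "incomplete"]


@dataclass(frozen=True)
class Haplotype:
    """A sample's mtDNA profile: an ordered set of rCRS differences plus QC
    metadata.  An rCRS-identical sample has an empty variant set."""

    sample_id: str = ""
    variants: tuple[SeqVariant, ...] = ()
    covered_range: RangeSpec = MITOGENOME_RANGE
    coverage_class: CoverageClass = "complete"
    lhp_regions: frozenset[str] = frozenset()
    haplogroup: Optional[str] = None

    def __post_init__(self):
        ordered = tuple(sorted(self.variants, key=lambda v: v.sort_key))
        object.__setattr__(self, "variants", ordered)
        seen = set()
        for v in ordered:
            if v.key in seen:
                raise NotationError(
                    f"duplicate variant at {v.position} ({v.kind}, "
                    f"index {v.insertion_index})"
                )
            seen.add(v.key)
            if v.position > MITOGENOME_LENGTH:
                raise NotationError(
                    f"position {v.position} beyond mitogenome length"
                )

    @property
    def substitutions(self) -> dict[int, str]:
        """position -> observed symbol, substitutions only."""
        return {
            v.position: v.observed
            for v in self.variants
            if v.kind == "substitution"
        }

    @property
    def n_php(self) -> int:
        return sum(v.is_heteroplasmic for v in self.variants)

    def with_(self, **kwargs) -> "Haplotype":
        return replace(self, **kwargs)


def parse_haplotype_string(
    text: str,
    range_spec: RangeSpec = MITOGENOME_RANGE,
    *,
    sample_id: str = "",
    out_of_range: Literal["error", "drop", "keep"] = "error",
) -> Haplotype:
    """Parse a whitespace-separated list of variant tokens into a Haplotype.

    Tokens whose position falls outside ``range_spec`` are rejected
    (default), silently dropped, or kept, per ``out_of_range``.
    """
    variants = []
    for token in text.split():
        v = parse_variant_token(token)
        if v.position not in range_spec:
            if out_of_range == "error":
                raise NotationError(
                    f"token {token!r} outside range {range_spec.name}"
                )
            if out_of_range == "drop":
                continue
        variants.append(v)
    return Haplotype(
        sample_id=sample_id, variants=tuple(variants), covered_range=range_spec
    )


def serialize_haplotype(h: Haplotype) -> str:
    """Canonical serialization: tokens sorted by position then insertion
    index; ``parse_haplotype_string(serialize_haplotype(h))`` reproduces
    the variant set."""
    return " ".join(v.token() for v in h.variants)


def restrict_to_range(h: Haplotype, range_spec: RangeSpec) -> Haplotype:
    """Drop variants outside ``range_spec``; the covered range becomes the
    intersection.  Idempotent and monotone."""
    kept = tuple(v for v in h.variants if v.position in range_spec)
    return h.with_(
        variants=kept, covered_range=h.covered_range.intersect(range_spec)
    )


# ---------------------------------------------------------------------------
# IUPAC matching
# ---------------------------------------------------------------------------


def iupac_match(a: str, b: str, policy: Literal["literal", "pattern"]) -> bool:
    """Compare two IUPAC symbols under the forensic matching policies.

    ``literal``: symbols must be identical (a Y only matches a Y).
    ``pattern``: expansion sets must intersect (a Y matches a C or a T).
    """
    if a not in IUPAC_EXPANSION:
        raise ValueError(f"invalid IUPAC symbol {a!r}")
    if b not in IUPAC_EXPANSION:
        raise ValueError(f"invalid IUPAC symbol {b!r}")
    if policy == "literal":
        return a == b
    if policy == "pattern":
        return bool(IUPAC_EXPANSION[a] & IUPAC_EXPANSION[b])
    raise ValueError(f"unknown matching policy {policy!r}")
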