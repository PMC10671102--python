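"""Haplogroup assignment from a rooted tree of defining variants.

A haplogroup tree (Phylotree-style, at reduced scale) is a rooted hierarchy
whose nodes carry defining substitutions in rCRS-relative notation.
Back-mutation tokens (``263A!``) revert the position to the reference state
along the root-to-node path — this is how the reference haplotype itself
(which sits deep inside haplogroup H2a2a1) accumulates an *empty* expected
variant set at its own node.

Assignment scores each node by the expected substitutions along its path:
``score = matches - 0.5 * missing``, with private variants (in the sample
but expected nowhere on the path) unpenalized.  The maximal-score node
wins; ties break to the shallower node, then lexicographically, and are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .refmodel import (
    Haplotype,
    NotationError,
    RangeSpec,
    MITOGENOME_RANGE,
    iupac_match,
    parse_variant_token,
    restrict_to_range,
)


@dataclass
class HaplogroupNode:
    """One named clade: its defining substitutions and children."""

    name: str
    defining_variants: list = field(default_factory=list)
    children: list["HaplogroupNode"] = field(default_factory=list)
    parent: Optional["HaplogroupNode"] = None
    depth: int = 0


class HaplogroupTree:
    """Rooted haplogroup hierarchy supporting range-restricted assignment."""

    def __init__(self, root: HaplogroupNode):
        self.root = root
        self.nodes: dict[str, HaplogroupNode] = {}
        # accumulated expected substitution map (position -> base) per node
        self._expected: dict[str, dict[int, str]] = {}
        self._index(root, {}, 0)

    def _index(self, node: HaplogroupNode, inherited: dict[int, str], depth: int):
        if node.name in self.nodes:
            raise ValueError(f"duplicate haplogroup name {node.name!r}")
        node.depth = depth
        self.nodes[node.name] = node
        expected = dict(inherited)
        for v in node.defining_variants:
            if v.back_mutation:
                expected.pop(v.position, None)
            else:
                expected[v.position] = v.observed
        self._expected[node.name] = expected
        for child in node.children:
            child.parent = node
            self._index(child, expected, depth + 1)

    def __len__(self) -> int:
        return len(self.nodes)

    def expected_variants(
        self, name: str, range_spec: RangeSpec = MITOGENOME_RANGE
    ) -> dict[int, str]:
        return {
            pos: base
            for pos, base in self._expected[name].items()
            if pos in range_spec
        }

    def is_ancestor_or_equal(self, ancestor: str, descendant: str) -> bool:
        node: Optional[HaplogroupNode] = self.nodes[descendant]
        while node is not None:
            if node.name == ancestor:
                return True
            node = node.parent
        return False


def load_tree(text: str) -> HaplogroupTree:
    """Parse an indented plain-text tree.

    One node per line, ``name<TAB>variant tokens`` (tokens optional), with
    nesting expressed by leading spaces (two per level).  Back mutations
    carry a trailing ``!``.  Blank lines and ``#`` comments are skipped.
    """
    stack: list[tuple[int, HaplogroupNode]] = []
    root: Optional[HaplogroupNode] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        stripped = raw.lstrip(" ")
        indent = len(raw) - len(stripped)
        if indent % 2:
            raise ValueError(f"line {lineno}: odd indentation")
        level = indent // 2
        parts = stripped.replace("\t", " ").split()
        name, tokens = parts[0], parts[1:]
        variants = []
        for token in tokens:
            try:
                v = parse_variant_token(token, allow_back_mutation=True)
            except NotationError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            if v.kind != "substitution":
                raise ValueError(
                    f"line {lineno}: defining variants must be substitutions, "
                    f"got {token!r}"
                )
            variants.append(v)
        node = HaplogroupNode(name=name, defining_variants=variants)
        if level == 0:
            if root is not None:
                raise ValueError(f"line {lineno}: multiple root nodes")
            root = node
            stack = [(0, node)]
        else:
            while stack and stack[-1][0] >= level:
                stack.pop()
            if not stack or stack[-1][0] != level - 1:
                raise ValueError(f"line {lineno}: orphan indentation level")
            stack[-1][1].children.append(node)
            stack.append((level, node))
    if root is None:
        raise ValueError("empty tree file")
    return HaplogroupTree(root)


def load_tree_file(path) -> HaplogroupTree:
    with open(path) as fh:
        return load_tree(fh.read())


@dataclass
class AssignmentResult:
    """Best-scoring haplogroup with the evidence behind the call."""

    best: str
    score: float
    matched: list[int]
    missing: list[int]
    private: list[int]
    ties: list[str] = field(default_factory=list)


def assign(
    h: Haplotype,
    tree: HaplogroupTree,
    range_spec: RangeSpec = MITOGENOME_RANGE,
) -> AssignmentResult:
    """Score the haplotype against every node and return the best.

    The haplotype is first restricted to ``range_spec``; only substitutions
    participate (indels and N calls are ignored).  Expected variants match
    under pattern-mode IUPAC comparison, so a heteroplasmic sample symbol
    still supports the clade carrying either component base.
    """
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    h = restrict_to_range(h, range_spec)
    profile = {
        pos: sym for pos, sym in h.substitutions.items() if sym != "N"
    }

    scored: list[tuple[float, int, str, list[int], list[int]]] = []
    for name, node in tree.nodes.items():
        expected = tree.expected_variants(name, range_spec)
        matched, missing = [], []
        for pos, base in expected.items():
            obs = profile.get(pos)
            if obs is not None and iupac_match(obs, base, "pattern"):
                matched.append(pos)
            else:
                missing.append(pos)
        score = len(matched) - 0.5 * len(missing)
        scored.append((score, node.depth, name, matched, missing))

    best_score = max(s[0] for s in scored)
    contenders = sorted(
        (s for s in scored if s[0] == best_score),
        key=lambda s: (s[1], s[2]),  # shallower depth, then name
    )
    score, _depth, best, matched, missing = contenders[0]
    expected_best = tree.expected_variants(best, range_spec)
    private = sorted(pos for pos in profile if pos not in expected_best)
    return AssignmentResult(
        best=best,
        score=score,
        matched=sorted(matched),
        missing=sorted(missing),
        private=private,
        ties=[s[2] for s in contenders[1:]],
    )


#: 25-node synthetic mini-tree.  The topology follows the standard human
#: mtDNA nomenclature (R0/HV/H, U/U5/U8, JT, W) but the defining-variant
#: lists are a reduced synthetic fixture derived to be mutually consistent
#: with the haplotypes used in the test-suite; it is not the published
#: Phylotree build.
EXAMPLE_TREE_TEXT = """\
mt-ancestor\t73G 263G 750G 1438G 2706G 4769G 7028T 8860G 11719A 14766T 15326G
  R0\t73A! 11719G!
    HV\t14766C!
      V\t4580A 15904T 16298C
      H\t2706A! 7028C!
        H1\t3010A
          H1c1a\t477C 9150G
        H2\t1438A!
          H2a\t4769A!
            H2a1n\t146C 951A 4659A 16354T
            H2a5\t4336C 16354T
            H2a2a1\t263A! 750A! 8860A! 15326A!
  U\t11467G 12308G 12372A
    U5\t3197C 9477A 13617C 16270T
      U5b\t150T 7768G 14182C
        U5b1\t5656G 16189C
          U5b1b1a\t7385G 10927C 12618A 16144C
    U8a1a1a\t282C 1811G 3738T 4129G 5240G 6392C 6455T 7055G 9365T 9698C 10733T 11150A 12135A 13145A 16209C 16342C
    K\t1811G 3480G 9055A 16224C 16311C
  JT\t4216C 11251G 15452A 16126C
    T\t709A 1888A 4917G 8697A 10463C 13368A 14905A 15607G 15928A 16294T
      T2\t11812G 14233G 16296T
    J\t295T 489C 10398G 12612G 13708A 16069T
      J1\t228A 462T
  W1a\t119C 204C 1243C 3505G 8994A 11947G 15884C 16292T
"""


def example_tree() -> HaplogroupTree:
    """Load the packaged 25-node mini-tree fixture."""
    return load_tree(EXAMPLE_TREE_TEXT)
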