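"""Core data types for protein feature architectures.

A *feature architecture* is the arrangement of annotated features
(functional domains, secondary-structure elements, compositional
properties) along one protein sequence.  Every scoring function operates
on profiles derived from an architecture:

* :class:`CountProfile` — how many instances of each feature type occur,
* :class:`ClanProfile` — instance counts aggregated over Pfam clans,
* :class:`PositionProfile` — the relative center position of every
  instance, normalised by protein length.

Coordinates are 1-based and inclusive throughout, matching Pfam/HMMER
reporting.  Feature identity is a namespaced accession with any version
suffix stripped (``PF00043.19`` becomes ``pfam:PF00043``); structural and
compositional annotations use one canonical id per predictor output class
(``tmhmm:TM``, ``signalp:SP``, ``coils:CC``, ``phd:H``, ``phd:E``,
``seg:LC``, ``cast:<residue>``).  Overlapping instances are kept verbatim:
none of the scoring functions uses feature order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

__all__ = [
    "FeatureInstance",
    "FeatureArchitecture",
    "CountProfile",
    "ClanProfile",
    "PositionProfile",
    "FeatureCatalog",
    "count_profile",
    "shared_features",
    "clan_profile",
    "position_profile",
    "validate_architecture",
    "restrict_namespaces",
    "strip_version",
]

#: Namespaces treated as Pfam for clan lookup and for pfam-only mode.
DEFAULT_PFAM_NAMESPACES = frozenset({"pfam"})


def strip_version(accession: str) -> str:
    """Drop a trailing ``.NN`` version suffix from a Pfam/SMART accession."""
    head, sep, tail = accession.partition(".")
    if sep and tail.isdigit():
        return head
    return accession


@dataclass(frozen=True)
class FeatureInstance:
    """One located occurrence of a feature on a protein (1-based, inclusive)."""

    feature_id: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class FeatureArchitecture:
    """A protein's length plus its multiset of feature instances.

    ``sequence`` is optional; when present its length must equal ``length``
    (needed only for the embedded amino-acid dotplot).
    """

    protein_id: str
    length: int
    instances: List[FeatureInstance] = field(default_factory=list)
    sequence: Optional[str] = None

    @property
    def feature_ids(self) -> Set[str]:
        return {inst.feature_id for inst in self.instances}

    def namespace_of(self, feature_id: str) -> str:
        return feature_id.partition(":")[0]

    def __eq__(self, other) -> bool:
        # instance order is irrelevant: no scoring function uses it
        if not isinstance(other, FeatureArchitecture):
            return NotImplemented
        key = lambda i: (i.feature_id, i.start, i.end)
        return (
            self.protein_id == other.protein_id
            and self.length == other.length
            and self.sequence == other.sequence
            and sorted(self.instances, key=key) == sorted(other.instances, key=key)
        )


@dataclass
class CountProfile:
    """Instance count per feature type (the per-architecture N_i values)."""

    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        """Number of distinct feature types (N)."""
        return len(self.counts)

    @property
    def total_instances(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, feature_id: str) -> int:
        return self.counts.get(feature_id, 0)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.counts

    def __iter__(self):
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class ClanProfile:
    """Instance count per Pfam clan (the per-architecture C_i values)."""

    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def n_clans(self) -> int:
        return len(self.counts)

    def __getitem__(self, clan_id: str) -> int:
        return self.counts.get(clan_id, 0)

    def __iter__(self):
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class PositionProfile:
    """Per feature, the sorted relative center positions in (0, 1].

    Each value is ``((start + end) / 2) / length`` — the instance center
    normalised by protein length, so C-terminal features of proteins of
    different lengths still lie close together.
    """

    positions: Dict[str, List[float]] = field(default_factory=dict)

    def __getitem__(self, feature_id: str) -> List[float]:
        return self.positions.get(feature_id, [])

    def __iter__(self):
        return iter(self.positions)


class FeatureCatalog:
    """Maps Pfam feature ids to clan ids; knows which namespaces are Pfam.

    Lookups for features without a clan assignment return ``None``
    ("no clan"); features outside the Pfam namespaces never map to a clan.
    """

    def __init__(
        self,
        clan_of: Optional[Dict[str, str]] = None,
        pfam_namespaces: Iterable[str] = DEFAULT_PFAM_NAMESPACES,
    ) -> None:
        self._clan_of: Dict[str, str] = dict(clan_of or {})
        self.pfam_namespaces: Set[str] = set(pfam_namespaces)

    def clan(self, feature_id: str) -> Optional[str]:
        ns = feature_id.partition(":")[0]
        if ns not in self.pfam_namespaces:
            return None
        return self._clan_of.get(feature_id)

    def is_pfam(self, feature_id: str) -> bool:
        return feature_id.partition(":")[0] in self.pfam_namespaces

    @property
    def clans(self) -> Set[str]:
        return set(self._clan_of.values())

    def __len__(self) -> int:
        return len(self._clan_of)

    def items(self):
        return self._clan_of.items()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureCatalog)
            and self._clan_of == other._clan_of
            and self.pfam_namespaces == other.pfam_namespaces
        )


# ---------------------------------------------------------------------------
# Profile derivation


def count_profile(arch: FeatureArchitecture) -> CountProfile:
    """Tally instances per feature type. Overlapping instances do not merge."""
    counts: Dict[str, int] = {}
    for inst in arch.instances:
        counts[inst.feature_id] = counts.get(inst.feature_id, 0) + 1
    return CountProfile(counts)


def shared_features(p: CountProfile, q: CountProfile) -> Set[str]:
    """Feature types present in both architectures (cardinality N^PQ)."""
    return set(p.counts) & set(q.counts)


def clan_profile(arch: FeatureArchitecture, catalog: FeatureCatalog) -> ClanProfile:
    """Aggregate Pfam-domain instance counts by clan.

    Features without a clan assignment (and all non-Pfam features) are
    ignored, so a clan's count is the sum of the instance counts of its
    member domains present in the architecture.
    """
    counts: Dict[str, int] = {}
    for inst in arch.instances:
        clan = catalog.clan(inst.feature_id)
        if clan is not None:
            counts[clan] = counts.get(clan, 0) + 1
    return ClanProfile(counts)


def position_profile(arch: FeatureArchitecture) -> PositionProfile:
    """Relative center position of every instance, sorted per feature."""
    positions: Dict[str, List[float]] = {}
    for inst in arch.instances:
        positions.setdefault(inst.feature_id, []).append(
            inst.center() / arch.length
        )
    for vals in positions.values():
        vals.sort()
    return PositionProfile(positions)


def validate_architecture(arch: FeatureArchitecture) -> List[str]:
    """Return human-readable invariant violations; empty list means valid.

    Validation never raises — a malformed architecture yields one message
    per broken rule, each naming the protein and feature involved.
    """
    violations: List[str] = []
    if not arch.protein_id:
        violations.append("architecture has empty protein_id")
    pid = arch.protein_id or "<unnamed>"
    if arch.length <= 0:
        violations.append(f"{pid}: length {arch.length} is not positive")
    if arch.sequence is not None and len(arch.sequence) != arch.length:
        violations.append(
            f"{pid}: sequence length {len(arch.sequence)} != declared length "
            f"{arch.length}"
        )
    for inst in arch.instances:
        if inst.start < 1:
            violations.append(
                f"{pid}: {inst.feature_id} start {inst.start} below 1-based "
                "minimum"
            )
        if inst.start > inst.end:
            violations.append(
                f"{pid}: {inst.feature_id} start {inst.start} > end {inst.end}"
            )
        if arch.length > 0 and inst.end > arch.length:
            violations.append(
                f"{pid}: {inst.feature_id} end {inst.end} exceeds protein "
                f"length {arch.length}"
            )
    return violations


def restrict_namespaces(
    arch: FeatureArchitecture, namespaces: Iterable[str]
) -> FeatureArchitecture:
    """Copy of ``arch`` keeping only instances whose namespace is listed.

    Used for pfam-only scoring: restricting the feature set to Pfam domains
    reproduces the coarser, tie-prone behaviour of domain-content-only
    comparison.
    """
    allowed = set(namespaces)
    kept = [i for i in arch.instances if i.feature_id.partition(":")[0] in allowed]
    return FeatureArchitecture(
        protein_id=arch.protein_id,
        length=arch.length,
        instances=kept,
        sequence=arch.sequence,
    )
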