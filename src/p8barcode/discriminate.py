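"""Species discrimination by restriction-site profiles and region length.

A taxon is *discriminated* under a criterion when no other taxon shares
its exact profile under that criterion — equality of sorted site-position
lists per enzyme (equivalently, identical rows of the binary matrix),
equality of P8 length, or both.  No similarity threshold is involved:
indistinguishability is exact profile identity.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Hashable, Sequence

from .scan import SiteProfile

__all__ = [
    "DiscriminationReport",
    "site_key",
    "discriminate_by_sites",
    "discriminate_by_length",
    "discriminate_combined",
    "length_distribution",
]


@dataclass(frozen=True)
class DiscriminationReport:
    """Partition of taxa into unique singletons and tied groups.

    ``discriminated`` counts taxa unique under the criterion; ``groups``
    are the indistinguishable classes of size >= 2, each sorted
    alphabetically, groups ordered by first member.
    """

    criterion: str
    n_taxa: int
    discriminated: int
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        grouped = sum(len(g) for g in self.groups)
        if self.discriminated + grouped != self.n_taxa:
            raise ValueError(
                f"partition mismatch: {self.discriminated} singletons + "
                f"{grouped} grouped != {self.n_taxa} taxa"
            )
        if any(len(g) < 2 for g in self.groups):
            raise ValueError("groups must have size >= 2")
        members = [t for g in self.groups for t in g]
        if len(members) != len(set(members)):
            raise ValueError("groups must be disjoint")

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "n_taxa": self.n_taxa,
            "discriminated": self.discriminated,
            "groups": [list(g) for g in self.groups],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            f"Criterion: {self.criterion}",
            f"Taxa analysed: {self.n_taxa}",
            f"Discriminated (unique profiles): {self.discriminated}",
            f"Indistinguishable groups: {len(self.groups)}",
        ]
        for g in self.groups:
            lines.append("  - " + "; ".join(g))
        return "\n".join(lines)


def site_key(profile: SiteProfile, enzyme_subset: Sequence[str]) -> tuple:
    """Canonical hashable key of a profile restricted to an enzyme subset.

    Two taxa are indistinguishable by sites iff their keys are equal.  The
    subset is canonicalised by sorting, so key equality does not depend on
    the order enzymes were requested in.
    """
    if not enzyme_subset:
        raise ValueError("enzyme_subset must be non-empty")
    return tuple((enz, profile.sites.get(enz, ())) for enz in sorted(set(enzyme_subset)))


def _partition(
    profiles: Sequence[SiteProfile], keys: Sequence[Hashable], criterion: str
) -> DiscriminationReport:
    classes: dict[Hashable, list[str]] = defaultdict(list)
    for profile, key in zip(profiles, keys):
        classes[key].append(profile.taxon_name)
    singles = sum(1 for members in classes.values() if len(members) == 1)
    groups = sorted(
        (tuple(sorted(members)) for members in classes.values() if len(members) >= 2),
        key=lambda g: g[0],
    )
    return DiscriminationReport(
        criterion=criterion,
        n_taxa=len(profiles),
        discriminated=singles,
        groups=tuple(groups),
    )


def discriminate_by_sites(
    profiles: Sequence[SiteProfile], enzyme_subset: Sequence[str]
) -> DiscriminationReport:
    """Partition taxa by exact equality of site positions over a subset of
    enzymes."""
    if not profiles:
        raise ValueError("need at least one profile")
    subset = sorted(set(enzyme_subset))
    keys = [site_key(p, subset) for p in profiles]
    return _partition(profiles, keys, criterion=f"sites:{'+'.join(subset)}")


def discriminate_by_length(profiles: Sequence[SiteProfile]) -> DiscriminationReport:
    """Partition taxa by exact P8 length."""
    if not profiles:
        raise ValueError("need at least one profile")
    keys = [p.p8_length for p in profiles]
    return _partition(profiles, keys, criterion="length")


def discriminate_combined(
    profiles: Sequence[SiteProfile], enzyme_subset: Sequence[str]
) -> DiscriminationReport:
    """Partition taxa by site profile AND P8 length jointly.

    The combined criterion refines both single criteria: taxa stay
    grouped only when they agree on every site position of every selected
    enzyme and on region length.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    subset = sorted(set(enzyme_subset))
    keys = [(site_key(p, subset), p.p8_length) for p in profiles]
    return _partition(profiles, keys, criterion=f"sites:{'+'.join(subset)}+length")


def length_distribution(profiles: Sequence[SiteProfile]) -> dict[int, int]:
    """Histogram of exact P8 lengths: length -> number of taxa."""
    return dict(sorted(Counter(p.p8_length for p in profiles).items()))
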