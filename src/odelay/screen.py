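"""Inhibitor-candidate screen: Venn partition and the three-criterion filter.

Compounds detected in both conditioned media but not in fresh medium form
the candidate region; candidates must further (1) leave the post-delay
growth rate unchanged, (2) have little effect on growth in the presence of
glucose, and (3) cause a shorter delay in already-adapted cells.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import CompoundRecord

__all__ = ["VennPartition", "venn_partition", "candidate_filter"]

REGIONS = (
    "mm_only",
    "wt_only",
    "fbp1_only",
    "mm_wt",
    "mm_fbp1",
    "wt_fbp1",
    "all_three",
)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint membership regions over (fresh MM, WT CM, fbp1 CM)."""

    members: dict[str, tuple[str, ...]]

    @property
    def counts(self) -> dict[str, int]:
        return {region: len(names) for region, names in self.members.items()}

    @property
    def candidate_region(self) -> tuple[str, ...]:
        """Compounds in both CMs but not fresh medium (the hatching area)."""
        return self.members["wt_fbp1"]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def venn_partition(records: list[CompoundRecord]) -> VennPartition:
    """Partition compounds into the 7 Venn regions of the three media.

    Compounds absent from every medium are ignored; duplicate compound
    names are an error.
    """
    names = [r.compound for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate compound names: {dupes}")
    members: dict[str, list[str]] = {region: [] for region in REGIONS}
    key_by_pattern = {
        (True, False, False): "mm_only",
        (False, True, False): "wt_only",
        (False, False, True): "fbp1_only",
        (True, True, False): "mm_wt",
        (True, False, True): "mm_fbp1",
        (False, True, True): "wt_fbp1",
        (True, True, True): "all_three",
    }
    for r in records:
        pattern = (r.in_mm, r.in_wt_cm, r.in_fbp1_cm)
        if pattern == (False, False, False):
            continue
        members[key_by_pattern[pattern]].append(r.compound)
    return VennPartition(
        members={region: tuple(v) for region, v in members.items()}
    )


def candidate_filter(candidates: list[CompoundRecord]) -> list[CompoundRecord]:
    """Keep compounds passing all three candidate criteria, order-stable.

    A record with any criterion flag unset (``None``) is an error: the
    filter refuses to guess missing annotations.
    """
    for r in candidates:
        if None in (
            r.changes_postdelay_growth,
            r.affects_growth_with_glucose,
            r.delays_adapted_cells,
        ):
            raise ValueError(f"compound {r.compound!r} is missing criterion flags")
    return [
        r
        for r in candidates
        if not r.changes_postdelay_growth
        and not r.affects_growth_with_glucose
        and not r.delays_adapted_cells
    ]
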