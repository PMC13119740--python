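"""Marker panel container with selection bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IdentityError

__all__ = ["MarkerPanel"]


@dataclass
class MarkerPanel:
    """An ordered list of selected markers.

    ``newly_resolved[i]`` is the number of accession pairs first discriminated
    by ``markers[i]`` during selection (forced markers included).  For a panel
    built by :func:`minmark.selection.select_minimal_markers` on ``n``
    accessions, ``sum(newly_resolved) + unresolved_pairs_remaining`` equals
    ``n(n−1)/2``.
    """

    markers: list[str]
    newly_resolved: list[int] | None = None
    unresolved_pairs_remaining: int | None = None
    resolved_fraction: float | None = None
    forced: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = [str(m) for m in self.markers]
        seen: set[str] = set()
        for m in self.markers:
            if m in seen:
                raise IdentityError(f"duplicate marker identifier in panel: {m!r}")
            seen.add(m)
        if self.newly_resolved is not None:
            if len(self.newly_resolved) != len(self.markers):
                raise ValueError("newly_resolved length must match panel length")
            if any(c < 0 for c in self.newly_resolved):
                raise ValueError("newly_resolved counts must be non-negative")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)
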