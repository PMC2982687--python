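"""Vertex labels, the global total order over them, and label bags.

Every compression run works over a totally ordered label set L.  Original
labels are the ones present on the input graph; each contraction introduces a
*derived* label that is strictly greater than everything existing at that
moment.  Because derived labels carry no structural meaning of their own,
tie-breaking during contraction is driven by *label bags*: the multiset of
original labels a (possibly derived) label expands to.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

ORIGINAL = "original"
DERIVED = "derived"


@functools.total_ordering
@dataclass(frozen=True)
class Label:
    """A vertex label with its rank in the run-wide total order.

    ``ordinal`` defines the strict total order; ``display`` is the
    human-readable form used in files and rule listings; ``origin`` records
    whether the label existed on the input graph or was created by a
    contraction rule.
    """

    ordinal: int
    display: str
    origin: str = ORIGINAL

    def __lt__(self, other: "Label") -> bool:
        return self.ordinal < other.ordinal

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Label):
            return NotImplemented
        return self.ordinal == other.ordinal

    def __hash__(self) -> int:
        return hash(self.ordinal)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Label({self.ordinal}, {self.display!r}, {self.origin})"


def _original_sort_key(display: str):
    # Numeric labels (e.g. Morgan indices) order numerically and before
    # arbitrary strings; everything else orders lexicographically.
    try:
        return (0, int(display), display)
    except ValueError:
        return (1, 0, display)


class LabelOrder:
    """Registry holding the total order over labels for one compression run.

    Original labels get ordinals ``0..k-1`` from a deterministic sort of
    their display strings, so two isomorphic graphs (same label multiset)
    always induce the same order.  ``derive`` mints labels whose ordinal
    exceeds every existing one, as contraction requires.
    """

    def __init__(self, displays: Iterable[str]):
        uniq = sorted(set(displays), key=_original_sort_key)
        self._labels: list[Label] = [
            Label(i, d, ORIGINAL) for i, d in enumerate(uniq)
        ]
        self._by_display: dict[str, Label] = {l.display: l for l in self._labels}
        # bag: descending-sorted tuple of original ordinals
        self._bags: dict[int, tuple[int, ...]] = {
            l.ordinal: (l.ordinal,) for l in self._labels
        }

    def __contains__(self, display: str) -> bool:
        return display in self._by_display

    def __iter__(self) -> Iterator[Label]:
        return iter(self._labels)

    def get(self, display: str) -> Label:
        """Return the original label registered for ``display``."""
        return self._by_display[display]

    def bag(self, label: Label) -> tuple[int, ...]:
        """The label bag of ``label`` as a descending tuple of ordinals."""
        return self._bags[label.ordinal]

    def bag_display(self, bag: tuple[int, ...]) -> str:
        parts = [self._labels[o].display for o in sorted(bag)]
        if all(len(p) == 1 for p in parts):
            return "".join(parts)
        return "+".join(parts)

    def derive(self, bag: tuple[int, ...]) -> Label:
        """Create a fresh derived label greater than every existing label.

        ``bag`` is the multiset union of the bags of the labels being
        contracted, as a descending tuple of original ordinals.
        """
        ordinal = len(self._labels)
        label = Label(ordinal, self.bag_display(bag), DERIVED)
        self._labels.append(label)
        self._bags[ordinal] = bag
        return label

    def union_bags(self, *labels: Label) -> tuple[int, ...]:
        merged: list[int] = []
        for l in labels:
            merged.extend(self._bags[l.ordinal])
        return tuple(sorted(merged, reverse=True))


def as_bag(labels: Iterable[Label | int]) -> tuple[int, ...]:
    """Normalize a collection of labels/ordinals to a descending bag tuple."""
    ords = [l.ordinal if isinstance(l, Label) else int(l) for l in labels]
    return tuple(sorted(ords, reverse=True))


def label_bag_less(s1: Iterable[Label | int], s2: Iterable[Label | int]) -> bool:
    """Strict "smaller" test between two label bags.

    Both bags are sorted in descending label order and compared element by
    element; the first position where they differ decides.  If one bag is a
    strict prefix of the other, the shorter bag is the smaller one.
    """
    return as_bag(s1) < as_bag(s2)
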