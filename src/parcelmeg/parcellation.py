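"""Cortical parcellation metadata: labels, hemispheres, homologue pairs, ROI groups.

A parcellation here is purely the bookkeeping layer of a reduced cortical
atlas: an ordered list of parcel labels, a hemisphere assignment for each,
a symmetric left/right homologue pairing, and named regions of interest
(sensorimotor, frontal, temporal, occipital) used to plant and test
regional effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Parcellation", "make_parcellation"]

_DEFAULT_ROI_NAMES = ("sensorimotor", "frontal", "temporal", "occipital")


@dataclass(frozen=True)
class Parcellation:
    """Ordered parcel labels with hemisphere, homologue and ROI structure.

    Attributes
    ----------
    labels
        Ordered parcel names; index into this list is the row index of every
        parcels-by-samples matrix downstream.
    hemisphere
        ``"left"`` or ``"right"`` per parcel, same order as ``labels``.
    homologue
        Total mapping parcel label -> contralateral partner label.
    roi_groups
        Named subsets of labels, e.g. ``{"sensorimotor": [...]}``.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    homologue: dict[str, str] = field(default_factory=dict)
    roi_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("parcel labels must be unique")
        if len(self.hemisphere) != len(self.labels):
            raise ValueError("hemisphere assignment length mismatch")
        bad = sorted(set(self.hemisphere) - {"left", "right"})
        if bad:
            raise ValueError(f"unknown hemisphere values: {bad}")
        for p, q in self.homologue.items():
            if p not in self.labels or q not in self.labels:
                raise ValueError(f"homologue pair ({p}, {q}) references unknown parcel")
            if self.homologue.get(q) != p:
                raise ValueError(f"homologue mapping not symmetric at {p!r}")
        for name, members in self.roi_groups.items():
            unknown = sorted(set(members) - set(self.labels))
            if unknown:
                raise ValueError(f"roi_group {name!r} references unknown parcels {unknown}")

    @property
    def n_parcels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def hemisphere_indices(self, side: str) -> list[int]:
        return [i for i, h in enumerate(self.hemisphere) if h == side]

    def roi_indices(self, roi: str) -> list[int]:
        members = self.roi_groups[roi]
        return [self.labels.index(m) for m in members]


def make_parcellation(n_pairs: int, roi_names: tuple[str, ...] = _DEFAULT_ROI_NAMES) -> Parcellation:
    """Build a mirrored left/right parcellation with ``2 * n_pairs`` parcels.

    Parcels are named ``left_<i>`` / ``right_<i>`` with ``homologue``
    linking each pair.  ROI groups are assigned by cycling homologue pairs
    through ``roi_names``, so every default ROI receives at least one full
    left/right pair whenever ``n_pairs >= len(roi_names)``; with fewer pairs
    the leading ROIs are populated first.

    Parameters
    ----------
    n_pairs
        Number of homologue pairs; must be at least 2 so that both
        hemispheres contain more than one parcel (otherwise the
        intra-hemispheric connectivity summaries are undefined).
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2: hemispheric summaries are undefined otherwise")
    labels: list[str] = []
    hemisphere: list[str] = []
    homologue: dict[str, str] = {}
    for i in range(n_pairs):
        left, right = f"left_{i}", f"right_{i}"
        labels += [left, right]
        hemisphere += ["left", "right"]
        homologue[left] = right
        homologue[right] = left
    roi_groups: dict[str, list[str]] = {name: [] for name in roi_names}
    for i in range(n_pairs):
        roi = roi_names[i % len(roi_names)]
        roi_groups[roi] += [f"left_{i}", f"right_{i}"]
    return Parcellation(
        labels=tuple(labels),
        hemisphere=tuple(hemisphere),
        homologue=homologue,
        roi_groups={k: tuple(v) for k, v in roi_groups.items() if v},
    )
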