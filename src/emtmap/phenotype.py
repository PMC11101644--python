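"""Phenotype calling from marker node states.

A state (or a binarised activity window) is labelled epithelial,
mesenchymal, hybrid or undetermined from the ON-fractions of two disjoint
marker sets.  With threshold τ (default 0.75):

* epithelial    — epithelial fraction ≥ τ and mesenchymal fraction ≤ 1−τ
* mesenchymal   — the mirror condition
* hybrid        — both fractions ≥ 1−τ with at least one marker ON per side
* undetermined  — anything else

The pure labels are checked before hybrid, so a state that satisfies both a
pure condition and the hybrid floor gets the pure label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

LABELS = ("epithelial", "mesenchymal", "hybrid", "undetermined")


@dataclass(frozen=True)
class MarkerConfig:
    """Epithelial / mesenchymal marker node sets and the call threshold."""

    epithelial_markers: tuple[str, ...]
    mesenchymal_markers: tuple[str, ...]
    phenotype_node: str | None = None
    majority_threshold: float = 0.75

    def __post_init__(self) -> None:
        epi = tuple(self.epithelial_markers)
        mes = tuple(self.mesenchymal_markers)
        object.__setattr__(self, "epithelial_markers", epi)
        object.__setattr__(self, "mesenchymal_markers", mes)
        if not epi or not mes:
            raise ValueError("both marker lists must be non-empty")
        if set(epi) & set(mes):
            raise ValueError("marker lists must be disjoint")
        if not 0.5 < self.majority_threshold <= 1.0:
            raise ValueError("majority_threshold must lie in (0.5, 1]")

    def swapped(self) -> "MarkerConfig":
        return MarkerConfig(
            self.mesenchymal_markers,
            self.epithelial_markers,
            self.phenotype_node,
            self.majority_threshold,
        )


@dataclass(frozen=True)
class PhenotypeCall:
    label: str
    epithelial_fraction: Fraction
    mesenchymal_fraction: Fraction


def default_marker_config() -> MarkerConfig:
    """Marker sets for the packaged EMT-core fixture."""
    return MarkerConfig(
        epithelial_markers=("Ecadherin", "ZO1", "miR200", "GRHL2", "OVOL2"),
        mesenchymal_markers=("SNAIL", "ZEB", "TWIST", "Goosecoid", "Ncadherin"),
        phenotype_node="EMT",
        majority_threshold=0.75,
    )


def classify_state(state: Mapping[str, int], config: MarkerConfig) -> PhenotypeCall:
    """Label one binary state from its marker ON-fractions."""
    for marker in (*config.epithelial_markers, *config.mesenchymal_markers):
        if marker not in state:
            raise KeyError(f"marker {marker!r} missing from state")
    epi_on = sum(int(state[m]) for m in config.epithelial_markers)
    mes_on = sum(int(state[m]) for m in config.mesenchymal_markers)
    ef = Fraction(epi_on, len(config.epithelial_markers))
    mf = Fraction(mes_on, len(config.mesenchymal_markers))
    tau = Fraction(config.majority_threshold).limit_denominator(10**6)
    if ef >= tau and mf <= 1 - tau:
        label = "epithelial"
    elif mf >= tau and ef <= 1 - tau:
        label = "mesenchymal"
    elif ef >= 1 - tau and mf >= 1 - tau and epi_on >= 1 and mes_on >= 1:
        label = "hybrid"
    else:
        label = "undetermined"
    return PhenotypeCall(label, ef, mf)


@dataclass
class PhenotypeCourse:
    calls: list[PhenotypeCall]
    transitions: list[tuple[int, str]]  # (index of first state/window, new label)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.calls]


def phenotype_course(
    course: Sequence[Mapping[str, int]] | "object",
    config: MarkerConfig,
    binarize_at: float = 0.5,
) -> PhenotypeCourse:
    """Classify every state of a trajectory or every window of a profile.

    Accepts either a sequence of binary states or an object with a
    ``binarized(threshold)`` method (an activity profile); window means are
    cut at ``binarize_at`` before classification.
    """
    if hasattr(course, "binarized"):
        states: Sequence[Mapping[str, int]] = course.binarized(binarize_at)
    else:
        states = course  # type: ignore[assignment]
    if len(states) == 0:
        raise ValueError("empty trajectory/profile cannot be classified")
    calls = [classify_state(s, config) for s in states]
    transitions: list[tuple[int, str]] = [(0, calls[0].label)]
    for idx in range(1, len(calls)):
        if calls[idx].label != calls[idx - 1].label:
            transitions.append((idx, calls[idx].label))
    return PhenotypeCourse(calls=calls, transitions=transitions)
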