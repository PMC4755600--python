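"""Additive Cu(I) cluster capacity from modular architecture.

Model-compound chemistry identifies [Cu4S6] and [Cu5S7] as the stable
flexible Cu(I)-thiolate cores relevant to Cu-thioneins. The capacity
model here assumes each 7-Cys box folds an independent Cu5 cluster and
each 6-Cys box a Cu4 cluster, with additive behavior across tandem
boxes; Cys left outside every box can each bind at most one extra
Cu(I) (the loosest bound compatible with Cu:S <= 1 in those cores).
For the six 7-Cys + two 6-Cys + three unassigned Cys architecture this
predicts a base capacity of 38 and a ceiling of 41 Cu(I).

Stepwise Cu(I) titration of the Zn-protein populates predominant
species in a characteristic loading series of doublets: (4,5), (8,9),
(12,13), then +5 per step — (17,18), (22,23), (27,28), (32,33) ... The
first steps read as 6-Cys boxes filling with Cu4 (each with a minor
+1 species), the later +5 steps as successive 7-Cys boxes folding Cu5
clusters; the series itself is architecture-independent here because
the doublet-to-box mapping is an interpretation, not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cysbox import ModuleArchitecture
from .errors import ModmtError, UnknownBoxKindError

#: Optimal Cu(I) load per box kind.
BOX_CU_CAPACITY: dict[str, int] = {"seven_cys": 5, "six_cys": 4}


@dataclass(frozen=True)
class CapacityPrediction:
    """Per-box Cu capacities and architecture totals."""

    per_box: tuple[tuple[str, int], ...]
    base_total: int
    extra_cys: int

    @property
    def max_total(self) -> int:
        return self.base_total + self.extra_cys

    @property
    def predicted_major_range(self) -> tuple[int, int]:
        return (self.base_total, self.max_total)

    def to_dict(self) -> dict:
        return {
            "per_box": [{"kind": k, "cu_capacity": c} for k, c in self.per_box],
            "base_total": self.base_total,
            "extra_cys": self.extra_cys,
            "max_total": self.max_total,
            "predicted_major_range": list(self.predicted_major_range),
        }


def cu_capacity(arch: ModuleArchitecture) -> CapacityPrediction:
    """Predict Cu(I) capacity of an architecture: 7-Cys box -> 5, 6-Cys -> 4.

    Box-unassigned Cys contribute between 0 and 1 Cu(I) each, so the
    predicted predominant species lie in [base_total, max_total].
    """
    per_box = []
    for box in arch.boxes:
        if box.kind not in BOX_CU_CAPACITY:
            raise UnknownBoxKindError(
                f"no Cu capacity rule for box kind {box.kind!r}"
            )
        per_box.append((box.kind, BOX_CU_CAPACITY[box.kind]))
    base = sum(c for _, c in per_box)
    return CapacityPrediction(
        per_box=tuple(per_box), base_total=base,
        extra_cys=len(arch.unassigned_cys),
    )


@dataclass(frozen=True)
class LoadingSeries:
    """Predominant Cu(I) loadings as (lower, lower+1) doublets."""

    doublets: tuple[tuple[int, int], ...]
    rule: str = ("doublets 1-3 at (4k, 4k+1); each later doublet adds 5 "
                 "Cu(I) to the previous one")


def loading_series(n_doublets: int) -> LoadingSeries:
    """The predominant-species series of a stepwise Cu(I) titration.

    Doublets 1-3 are (4, 5), (8, 9), (12, 13); each subsequent doublet
    adds 5 to both members: (17, 18), (22, 23), (27, 28), (32, 33), ...
    The experimental series lists the 7th predominant species as a lone
    Cu33; the generator follows the +5 rule and emits (32, 33), which
    consistency reports should note.
    """
    if n_doublets < 1:
        raise ModmtError(f"n_doublets must be >= 1, got {n_doublets}")
    doublets = []
    lower = 0
    for k in range(1, n_doublets + 1):
        lower = 4 * k if k <= 3 else lower + 5
        doublets.append((lower, lower + 1))
    return LoadingSeries(doublets=tuple(doublets))


@dataclass(frozen=True)
class ConsistencyEntry:
    observed: int
    inside: bool
    offset_from_base: int


def capacity_consistency(prediction: CapacityPrediction,
                         observed_majors: list[int]) -> list[ConsistencyEntry]:
    """Compare observed major stoichiometries with the predicted window.

    An observed major is "inside" when it lies in
    [base_total, max_total + 1]; the +1 allows the minor satellite one
    Cu above the optimum seen throughout the loading series.
    """
    if not observed_majors:
        raise ModmtError("observed_majors must be non-empty")
    lo, hi = prediction.base_total, prediction.max_total + 1
    return [
        ConsistencyEntry(observed=n, inside=lo <= n <= hi,
                         offset_from_base=n - prediction.base_total)
        for n in observed_majors
    ]
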