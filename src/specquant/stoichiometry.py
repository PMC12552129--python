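"""Complex masses, metallocluster iron inventories and activity arithmetic.

Bookkeeping for nitrogenase-like two-component systems: theoretical
masses of subunit assemblies (e.g. the MarH2 reductase homodimer or the
Mar(DK)2 catalytic heterotetramer), iron counts implied by a metallocluster
inventory, consistency of those counts with ICP-OES measurements, and
specific-activity rates. All arithmetic is exact; rounding (half-up to
integer kDa) happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "Subunit",
    "ComplexModel",
    "ClusterInventory",
    "FE_PER_CLUSTER",
    "theoretical_mass",
    "fe_count",
    "icp_consistency",
    "specific_activity",
]

#: Iron atoms per cluster type. FeMoco counts 7 Fe: molybdenum occupies
#: the eighth metal site of the [MoFe7S9C-(R)-homocitrate] cofactor.
FE_PER_CLUSTER = {
    "Fe4S4": 4,  # [Fe4S4] cubane (reductase component)
    "P_Fe8S7": 8,  # P-cluster, [Fe8S7]
    "L_Fe8S9C": 8,  # L-cluster, [Fe8S9C] (FeMoco precursor / Mar active site)
    "FeMoco": 7,  # [MoFe7S9C-homocitrate]
}


@dataclass(frozen=True)
class Subunit:
    name: str
    mass_kda: float
    copies: int = 1

    def __post_init__(self) -> None:
        if self.mass_kda <= 0:
            raise ValueError(f"subunit {self.name}: mass must be positive")
        if self.copies < 1:
            raise ValueError(f"subunit {self.name}: copies must be >= 1")


@dataclass(frozen=True)
class ComplexModel:
    """Subunit composition of a protein complex."""

    subunits: tuple
    label: str = ""

    def __post_init__(self) -> None:
        subs = tuple(
            s if isinstance(s, Subunit) else Subunit(*s) for s in self.subunits
        )
        object.__setattr__(self, "subunits", subs)


def theoretical_mass(model: ComplexModel) -> tuple[float, int]:
    """Exact and half-up-rounded theoretical mass in kDa.

    Returns ``(exact_kda, rounded_kda)``; e.g. two 31.9 kDa protomers give
    (63.8, 64).
    """
    if not model.subunits:
        raise ValueError("complex model has no subunits")
    exact = sum(s.mass_kda * s.copies for s in model.subunits)
    rounded = int(Decimal(str(exact)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return float(exact), rounded


@dataclass
class ClusterInventory:
    """Counts of metalloclusters carried by one complex."""

    clusters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ctype, count in self.clusters.items():
            if ctype not in FE_PER_CLUSTER:
                raise ValueError(
                    f"unknown cluster type {ctype!r}; known: {sorted(FE_PER_CLUSTER)}"
                )
            if count < 0 or int(count) != count:
                raise ValueError(f"cluster count for {ctype} must be a non-negative integer")

    def __add__(self, other: "ClusterInventory") -> "ClusterInventory":
        merged = dict(self.clusters)
        for ctype, count in other.clusters.items():
            merged[ctype] = merged.get(ctype, 0) + count
        return ClusterInventory(merged)


def fe_count(inventory: ClusterInventory) -> int:
    """Total iron atoms implied by the cluster inventory (exact integer)."""
    return sum(FE_PER_CLUSTER[t] * int(c) for t, c in inventory.clusters.items())


def icp_consistency(
    expected_fe: float, measured_mean: float, measured_sd: float
) -> tuple[float, bool]:
    """z-score of a measured metal count against the structural expectation.

    Returns ``(z, within_1_sd)`` with ``z = (measured − expected)/sd``.
    """
    if measured_sd <= 0:
        raise ValueError("measured_sd must be positive")
    z = (measured_mean - expected_fe) / measured_sd
    return float(z), bool(abs(z) <= 1.0)


def specific_activity(product_nmol: float, enzyme_mg: float, minutes: float) -> float:
    """Specific activity in nmol product per mg enzyme per minute."""
    if enzyme_mg <= 0 or minutes <= 0:
        raise ValueError("enzyme_mg and minutes must be positive")
    if product_nmol < 0:
        raise ValueError("product_nmol must be >= 0")
    return product_nmol / (enzyme_mg * minutes)
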