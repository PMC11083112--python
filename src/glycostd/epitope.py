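"""STD NMR epitope maps and DEEP-STD differential factors.

The fractional STD intensity of a proton is (I0 - Isat)/I0, where I0 and
Isat are its intensities in the off- and on-resonance spectra.  Relative
epitope maps normalize these fractions against the most intense signal
(assigned 100%) and classify protons into semi-quantitative bins.  The
DEEP-STD factor of a proton is the mean-centered ratio of its STD
intensities between two experimental conditions (here two solvents,
D2O and H2O); factors exceeding 0.1 in magnitude are conventionally
considered significant.  The sum of absolute STD percentages over all
protons of one condition ("total saturation") discriminates high- from
medium/low-affinity binding when compared across solvents: gaining total
saturation on going from D2O to H2O points to a long-lived complex that
protects exchangeable protein protons from the bulk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from glycostd.errors import ValidationError
from glycostd.structures import StdTable

__all__ = [
    "BinClass", "EpitopeMap", "DeepStdResult", "SaturationComparison",
    "std_intensities", "relativize_and_bin", "deep_std", "compare_total_saturation",
]


class BinClass(str, Enum):
    STRONG = "strong"    # relative STD in [80, 100]
    MEDIUM = "medium"    # [60, 80)
    LOW = "low"          # [40, 60)
    BELOW = "below"      # < 40


@dataclass
class EpitopeMap:
    """Per-proton absolute STD fractions, relative percentages and bins."""

    condition_label: str
    abs_std: dict[str, float]
    rel_std: dict[str, float] = field(default_factory=dict)
    bins: dict[str, BinClass] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition_label": self.condition_label,
            "abs_std": dict(self.abs_std),
            "rel_std": dict(self.rel_std),
            "bins": {k: v.value for k, v in self.bins.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpitopeMap":
        return cls(
            condition_label=d["condition_label"],
            abs_std={k: float(v) for k, v in d["abs_std"].items()},
            rel_std={k: float(v) for k, v in d.get("rel_std", {}).items()},
            bins={k: BinClass(v) for k, v in d.get("bins", {}).items()},
        )


@dataclass
class DeepStdResult:
    """Differential epitope map between two conditions."""

    delta_std: dict[str, float]
    ratios: dict[str, float]
    n: int
    significant: list[str]
    threshold: float
    excluded: list[str] = field(default_factory=list)  # zero-denominator or uncommon

    def to_dict(self) -> dict:
        return {
            "delta_std": dict(self.delta_std),
            "ratios": dict(self.ratios),
            "n": self.n,
            "significant": list(self.significant),
            "threshold": self.threshold,
            "excluded": list(self.excluded),
        }


class AffinityVerdict(str, Enum):
    HIGH = "suggests_high_affinity"
    MEDIUM_LOW = "suggests_medium_low_affinity"


@dataclass
class SaturationComparison:
    total_d2o: float   # percent
    total_h2o: float   # percent
    verdict: AffinityVerdict
    tie: bool = False

    def to_dict(self) -> dict:
        return {
            "total_d2o": self.total_d2o,
            "total_h2o": self.total_h2o,
            "verdict": self.verdict.value,
            "tie": self.tie,
        }


def std_intensities(table: StdTable) -> EpitopeMap:
    """Absolute fractional STD intensities, (I0 - Isat)/I0, per proton.

    Negative values (Isat > I0) propagate with a warning: they carry
    diagnostic information and are never clipped.
    """
    abs_std: dict[str, float] = {}
    for label, (i0, isat) in table.rows.items():
        val = (i0 - isat) / i0
        if val < 0:
            warnings.warn(
                f"proton {label}: negative STD intensity {val:.4g}", stacklevel=2
            )
        abs_std[label] = val
    return EpitopeMap(condition_label=table.condition_label, abs_std=abs_std)


def _bin_for(rel: float) -> BinClass:
    # intervals closed on the lower edge: [80,100] strong, [60,80) medium,
    # [40,60) low, below otherwise
    if rel >= 80.0:
        return BinClass.STRONG
    if rel >= 60.0:
        return BinClass.MEDIUM
    if rel >= 40.0:
        return BinClass.LOW
    return BinClass.BELOW


def relativize_and_bin(epitope: EpitopeMap) -> EpitopeMap:
    """Normalize against the most intense signal (100%) and bin.

    Requires at least one positive absolute STD; the normalization is
    scale-invariant, so the bins depend only on intensity ratios.
    """
    if not epitope.abs_std:
        raise ValidationError("empty epitope map")
    peak = max(epitope.abs_std.values())
    if peak <= 0:
        raise ValidationError("all absolute STD values are <= 0; cannot normalize")
    rel = {p: 100.0 * v / peak for p, v in epitope.abs_std.items()}
    bins = {p: _bin_for(r) for p, r in rel.items()}
    return EpitopeMap(epitope.condition_label, dict(epitope.abs_std), rel, bins)


def deep_std(
    map1: EpitopeMap, map2: EpitopeMap, threshold: float = 0.1
) -> DeepStdResult:
    """DEEP-STD factors between two conditions.

    For each proton i common to both maps the ratio STD1_i/STD2_i is
    formed; the factor is the ratio minus the mean of all ratios, so the
    factors sum to zero by construction.  Protons present in only one
    condition, or with zero intensity in the denominator condition, are
    excluded and listed in the result.
    """
    common = [p for p in map1.abs_std if p in map2.abs_std]
    excluded = sorted(
        set(map1.abs_std).symmetric_difference(map2.abs_std)
    )
    usable = []
    for p in common:
        if map2.abs_std[p] == 0:
            warnings.warn(f"proton {p}: zero STD in condition 2, excluded", stacklevel=2)
            excluded.append(p)
        else:
            usable.append(p)
    if len(usable) < 2:
        raise ValidationError(
            f"need at least 2 common protons with nonzero denominators, got {len(usable)}"
        )
    ratios = {p: map1.abs_std[p] / map2.abs_std[p] for p in usable}
    mean_ratio = float(np.mean(list(ratios.values())))
    delta = {p: r - mean_ratio for p, r in ratios.items()}
    significant = [p for p, d in delta.items() if abs(d) > threshold]
    return DeepStdResult(
        delta_std=delta,
        ratios=ratios,
        n=len(usable),
        significant=significant,
        threshold=threshold,
        excluded=excluded,
    )


def compare_total_saturation(
    map_d2o: EpitopeMap, map_h2o: EpitopeMap
) -> SaturationComparison:
    """Compare total saturation (sum of absolute STD percentages) across solvents.

    A higher total in H2O than in D2O suggests a high-affinity interaction;
    the converse (or a tie) suggests medium/low affinity.
    """
    if not map_d2o.abs_std or not map_h2o.abs_std:
        raise ValidationError("both epitope maps must be nonempty")
    total_d2o = 100.0 * sum(map_d2o.abs_std.values())
    total_h2o = 100.0 * sum(map_h2o.abs_std.values())
    tie = total_h2o == total_d2o
    verdict = (
        AffinityVerdict.HIGH if total_h2o > total_d2o else AffinityVerdict.MEDIUM_LOW
    )
    return SaturationComparison(total_d2o, total_h2o, verdict, tie)
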