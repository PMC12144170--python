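"""Baseline-vs-revision comparison reports.

A report pairs the evaluated mechanics of two treatment variants of the
same case — peak von Mises stress per region and healing-zone fractions —
and derives the deltas the surgeon cares about: percent stress reduction
relative to baseline, the baseline/revised stress ratio, and zone-fraction
differences. A full provenance block (thresholds, materials, calibration,
seeds, mesh sizes) makes every report re-runnable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanobiology import ZONES, HealingWindowResult
from .solver import FESolution


@dataclass
class VariantSummary:
    """Evaluated metrics of one treatment variant."""

    name: str
    peak_vm: dict[str, float]  # region -> MPa
    peak_vm_element: dict[str, int]
    zone_volume_fractions: dict[str, float]
    zone_count_fractions: dict[str, float]
    healing_window_volume_fraction: float
    healing_window_count_fraction: float
    n_elements: int
    n_nodes: int
    load_case: str

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "peak_vm_MPa": self.peak_vm,
            "peak_vm_element": self.peak_vm_element,
            "zone_volume_fractions": self.zone_volume_fractions,
            "zone_count_fractions": self.zone_count_fractions,
            "healing_window_volume_fraction": self.healing_window_volume_fraction,
            "healing_window_count_fraction": self.healing_window_count_fraction,
            "n_elements": self.n_elements,
            "n_nodes": self.n_nodes,
            "load_case": self.load_case,
        }


@dataclass
class ComparisonReport:
    case: str
    baseline: VariantSummary
    revised: VariantSummary
    stress_reduction_percent: dict[str, float]
    stress_ratio: dict[str, float]
    zone_volume_fraction_delta: dict[str, float]
    zone_count_fraction_delta: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "baseline": self.baseline.to_dict(),
            "revised": self.revised.to_dict(),
            "stress_reduction_percent": self.stress_reduction_percent,
            "stress_ratio": self.stress_ratio,
            "zone_volume_fraction_delta": self.zone_volume_fraction_delta,
            "zone_count_fraction_delta": self.zone_count_fraction_delta,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, path=None):
        rows = []
        for variant in (self.baseline, self.revised):
            for region, peak in variant.peak_vm.items():
                rows.append({"case": self.case, "variant": variant.name,
                             "metric": f"peak_vm_MPa[{region}]", "value": peak})
            for z in ZONES:
                rows.append({"case": self.case, "variant": variant.name,
                             "metric": f"zone_volume_fraction[{z}]",
                             "value": variant.zone_volume_fractions[z]})
            rows.append({"case": self.case, "variant": variant.name,
                         "metric": "healing_window_volume_fraction",
                         "value": variant.healing_window_volume_fraction})
        for region, red in self.stress_reduction_percent.items():
            rows.append({"case": self.case, "variant": "delta",
                         "metric": f"stress_reduction_percent[{region}]",
                         "value": red})
        df = pd.DataFrame(rows)
        if path is not None:
            df.to_csv(path, index=False)
        return df


def summarize_variant(
    name: str,
    solution: FESolution,
    healing: HealingWindowResult,
    regions: list[str],
) -> VariantSummary:
    from .mechanobiology import peak_stress

    peaks, elems = {}, {}
    for region in regions:
        vm, eid = peak_stress(solution, region)
        peaks[region] = vm
        elems[region] = eid
    return VariantSummary(
        name=name,
        peak_vm=peaks,
        peak_vm_element=elems,
        zone_volume_fractions=dict(healing.volume_fractions),
        zone_count_fractions=dict(healing.count_fractions),
        healing_window_volume_fraction=healing.healing_window_volume_fraction,
        healing_window_count_fraction=healing.healing_window_count_fraction,
        n_elements=solution.mesh.n_elements,
        n_nodes=solution.mesh.n_nodes,
        load_case=solution.load_case.name if solution.load_case else "",
    )


def compare_treatments(
    case: str,
    baseline: tuple[FESolution, HealingWindowResult],
    revised: tuple[FESolution, HealingWindowResult],
    regions: list[str],
    provenance: dict | None = None,
    names: tuple[str, str] = ("baseline", "revised"),
) -> ComparisonReport:
    """Build the paired report for two variants of one case definition."""
    sol_b, heal_b = baseline
    sol_r, heal_r = revised
    if heal_b.config.to_dict() != heal_r.config.to_dict():
        raise ValueError("variants use different healing-zone configs; incomparable")
    if sol_b.load_case and sol_r.load_case and (
        sol_b.load_case.name != sol_r.load_case.name
    ):
        raise ValueError("variants were solved under different load cases")

    vb = summarize_variant(names[0], sol_b, heal_b, regions)
    vr = summarize_variant(names[1], sol_r, heal_r, regions)

    reduction, ratio = {}, {}
    for region in regions:
        pb, pr = vb.peak_vm[region], vr.peak_vm[region]
        reduction[region] = 100.0 * (pb - pr) / pb if pb != 0 else float("nan")
        ratio[region] = pb / pr if pr != 0 else float("inf")
    zone_vol_delta = {
        z: vr.zone_volume_fractions[z] - vb.zone_volume_fractions[z] for z in ZONES
    }
    zone_cnt_delta = {
        z: vr.zone_count_fractions[z] - vb.zone_count_fractions[z] for z in ZONES
    }
    return ComparisonReport(
        case=case,
        baseline=vb,
        revised=vr,
        stress_reduction_percent=reduction,
        stress_ratio=ratio,
        zone_volume_fraction_delta=zone_vol_delta,
        zone_count_fraction_delta=zone_cnt_delta,
        provenance=provenance or {},
    )
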