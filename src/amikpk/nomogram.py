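"""Initial-dose nomogram: regimen recommendation per renal-function level.

Given an attainment grid and an MIC, the nomogram recommends, for each
creatinine-clearance level, the regimen meeting the joint PK/PD target
(Cmax/MIC >= 8 and Cmin < 4 mg/L) in at least the threshold percentage
of virtual subjects — preferring the lowest dose and, among equal
doses, the longest interval (the extended-interval convention for
aminoglycosides).  Levels where no regimen qualifies map to NA.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pta import PTAGrid, Regimen

__all__ = ["Nomogram", "build_nomogram", "RENAL_FUNCTION_LABELS"]

#: Display labels per CCr decade (mL/min).
RENAL_FUNCTION_LABELS = {
    10.0: "Kidney failure",
    20.0: "Kidney failure",
    30.0: "Severe impairment",
    40.0: "Severe impairment",
    50.0: "Moderate impairment",
    60.0: "Moderate impairment",
    70.0: "Mild impairment",
    80.0: "Mild impairment",
    90.0: "Normal",
}


@dataclass(frozen=True)
class Nomogram:
    """Ordered CCr -> recommended regimen (or None) mapping."""

    recommendations: dict[float, Regimen | None]
    mic: float
    pta_threshold: float
    fta_threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "renal_function": RENAL_FUNCTION_LABELS.get(ccr, ""),
                "ccr": ccr,
                "regimen": reg.label if reg is not None else "NA",
            }
            for ccr, reg in self.recommendations.items()
        ]
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [
            f"Recommended initial regimens (MIC {self.mic:g} mg/L, "
            f"joint attainment >= {self.pta_threshold:g}%)",
            "",
            "| Renal function | CCr (mL/min) | Recommended regimen |",
            "| --- | --- | --- |",
        ]
        for _, row in self.to_frame().iterrows():
            lines.append(
                f"| {row.renal_function} | {row.ccr:g} | {row.regimen} |"
            )
        return "\n".join(lines) + "\n"


def build_nomogram(
    grid: PTAGrid,
    mic: float,
    pta_threshold: float = 90.0,
    fta_threshold: float | None = None,
    fta_table: pd.DataFrame | None = None,
) -> Nomogram:
    """Select a recommended regimen per CCr level from an attainment grid.

    Among regimens whose joint attainment at ``mic`` meets
    ``pta_threshold``, the lowest dose wins, ties broken by the longest
    interval.  When ``fta_threshold`` is given, candidates must also
    reach it in ``fta_table`` (columns ccr, dose_mg, interval_h,
    fta_pct).  A level with no qualifying regimen maps to None.
    """
    t = grid.table
    if t.empty:
        raise ValueError("attainment grid is empty")
    sub = t[t["mic"] == mic]
    if sub.empty:
        raise ValueError(f"grid has no entries for MIC {mic}")
    if fta_threshold is not None:
        if fta_table is None:
            raise ValueError("fta_threshold given without an fta_table")
        sub = sub.merge(fta_table, on=["ccr", "dose_mg", "interval_h"])
    recs: dict[float, Regimen | None] = {}
    for ccr in sorted(sub["ccr"].unique()):
        ok = sub[(sub["ccr"] == ccr) & (sub["joint_pct"] >= pta_threshold)]
        if fta_threshold is not None:
            ok = ok[ok["fta_pct"] >= fta_threshold]
        if ok.empty:
            recs[float(ccr)] = None
            continue
        best = ok.sort_values(
            ["dose_mg", "interval_h"], ascending=[True, False]
        ).iloc[0]
        recs[float(ccr)] = Regimen(float(best.dose_mg), float(best.interval_h))
    return Nomogram(
        recommendations=recs,
        mic=mic,
        pta_threshold=pta_threshold,
        fta_threshold=fta_threshold,
    )
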