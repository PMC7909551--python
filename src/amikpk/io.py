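"""Cohort file format: one CSV row per dose or observation event.

Columns: id, time_h, event_type (dose|obs), amount_mg, infusion_h,
conc_mg_L, blq_flag, ccr, age, sex, weight_kg, height_m, scr.  Dose
rows leave the observation columns empty and vice versa; covariates
repeat on every row of a subject.  The writer emits shortest-repr
floats so that a write -> read -> write cycle is bit-stable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .cohort_sim import Covariates, Subject
from .pk_model import DoseEvent

__all__ = ["read_cohort", "write_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "id", "time_h", "event_type", "amount_mg", "infusion_h",
    "conc_mg_L", "blq_flag", "ccr", "age", "sex", "weight_kg",
    "height_m", "scr",
]


class CohortFormatError(ValueError):
    """Raised for malformed cohort files; messages name the CSV row."""


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_cohort(cohort: list[Subject], path: str | Path) -> None:
    """Write a cohort to the event-per-row CSV dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for s in cohort:
            c = s.covariates
            cov = [_fmt(c.ccr), _fmt(c.age), c.sex, _fmt(c.weight),
                   _fmt(c.height), _fmt(c.serum_creatinine)]
            events: list[tuple[float, int, list[str]]] = []
            for d in s.doses:
                events.append(
                    (d.start_time, 0,
                     [s.id, _fmt(d.start_time), "dose", _fmt(d.amount),
                      _fmt(d.infusion_duration), "", ""] + cov)
                )
            for t, conc, blq in zip(s.times, s.concentrations, s.blq):
                events.append(
                    (float(t), 1,
                     [s.id, _fmt(float(t)), "obs", "", "",
                      _fmt(float(conc)), str(int(blq))] + cov)
                )
            for _, _, row in sorted(events, key=lambda e: (e[0], e[1])):
                w.writerow(row)


def read_cohort(path: str | Path) -> list[Subject]:
    """Read a cohort CSV, validating structure row by row.

    Raises :class:`CohortFormatError` naming the offending row for
    missing columns, unsorted times within a subject, or observations
    that precede the subject's first dose.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        if reader.fieldnames is None:
            raise CohortFormatError("empty file: header row is mandatory")
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortFormatError(f"missing columns: {sorted(missing)}")
        per_subject: dict[str, dict] = {}
        order: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            sid = row["id"]
            if sid not in per_subject:
                per_subject[sid] = {"doses": [], "obs": [], "cov": None,
                                    "last_t": -np.inf}
                order.append(sid)
            rec = per_subject[sid]
            try:
                t = float(row["time_h"])
            except ValueError as exc:
                raise CohortFormatError(f"row {lineno}: bad time_h") from exc
            if t < rec["last_t"]:
                raise CohortFormatError(
                    f"row {lineno}: times not sorted for subject {sid!r}"
                )
            rec["last_t"] = t
            if rec["cov"] is None:
                try:
                    rec["cov"] = Covariates(
                        age=float(row["age"]), sex=row["sex"],
                        weight=float(row["weight_kg"]),
                        height=float(row["height_m"]),
                        serum_creatinine=float(row["scr"]),
                        ccr=float(row["ccr"]),
                    )
                except ValueError as exc:
                    raise CohortFormatError(
                        f"row {lineno}: bad covariates ({exc})"
                    ) from exc
            kind = row["event_type"]
            if kind == "dose":
                try:
                    rec["doses"].append(
                        DoseEvent(t, float(row["amount_mg"]),
                                  float(row["infusion_h"]))
                    )
                except ValueError as exc:
                    raise CohortFormatError(
                        f"row {lineno}: bad dose event ({exc})"
                    ) from exc
            elif kind == "obs":
                if not rec["doses"]:
                    raise CohortFormatError(
                        f"row {lineno}: observation before any dose for "
                        f"subject {sid!r}"
                    )
                try:
                    conc = float(row["conc_mg_L"])
                except ValueError as exc:
                    raise CohortFormatError(
                        f"row {lineno}: bad concentration"
                    ) from exc
                rec["obs"].append((t, conc, row["blq_flag"] in ("1", "True")))
            else:
                raise CohortFormatError(
                    f"row {lineno}: unknown event_type {kind!r}"
                )
    cohort = []
    for sid in order:
        rec = per_subject[sid]
        if not rec["doses"]:
            raise CohortFormatError(f"subject {sid!r} has no dose events")
        obs = rec["obs"]
        cohort.append(
            Subject(
                id=sid, covariates=rec["cov"], doses=rec["doses"],
                times=np.array([o[0] for o in obs]),
                concentrations=np.array([o[1] for o in obs]),
                blq=np.array([o[2] for o in obs], dtype=bool),
            )
        )
    return cohort
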