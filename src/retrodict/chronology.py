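"""Molecular-clock ages and interaction anchoring.

Node distances from rooted trees are converted to geological ages (Gy,
gigayears before present) through a linear clock fitted to calibration
points.  RNA substructures, which have no clock of their own, are anchored
through their interactions with protein domains: the age of an interaction
is bounded by its components, so a substructure is at least as old as the
oldest domain it interacts with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

#: Default age ceiling (Gy): no prediction may exceed the age of origin.
AGE_CEILING_GY = 4.2


class ChronologyError(ValueError):
    """Raised for invalid calibrations or unresolvable identifiers."""


@dataclass(frozen=True)
class ClockModel:
    """Linear clock ``age = slope * x + intercept`` with OLS diagnostics.

    ``x`` is by convention a relative age (1 - nd/nd_max), making the
    calibration transferable across trees of different depth; raw node
    distances can be used instead as long as calibration and application
    agree.
    """

    slope: float
    intercept: float
    r_squared: float
    stderr: float
    points: tuple[tuple[float, float], ...]

    @property
    def x_range(self) -> tuple[float, float]:
        xs = [x for x, _ in self.points]
        return (min(xs), max(xs))

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class TimelineEntry:
    """One dated unit: a protein domain or an RNA substructure."""

    unit: str
    kind: str  # "domain" | "substructure"
    age_gy: float
    provenance: str  # "clock" | "interaction-anchor"
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class InteractionRecord:
    domain: str
    substructure: str
    evidence: str = ""


@dataclass
class Timeline:
    """Ages with provenance; supports lookup and TSV/JSON export."""

    entries: list[TimelineEntry] = field(default_factory=list)

    def age(self, unit: str) -> float:
        for e in self.entries:
            if e.unit == unit:
                return e.age_gy
        raise ChronologyError(f"no age for unit {unit!r}")

    def __contains__(self, unit: str) -> bool:
        return any(e.unit == unit for e in self.entries)

    def to_tsv(self) -> str:
        lines = ["unit\tkind\tage_gy\tprovenance\tflags"]
        for e in self.entries:
            lines.append(
                f"{e.unit}\t{e.kind}\t{e.age_gy:.6g}\t{e.provenance}\t"
                + (";".join(e.flags) if e.flags else "-")
            )
        return "\n".join(lines) + "\n"

    def to_records(self) -> list[dict]:
        return [
            {
                "unit": e.unit,
                "kind": e.kind,
                "age_gy": e.age_gy,
                "provenance": e.provenance,
                "flags": list(e.flags),
            }
            for e in self.entries
        ]


def calibrate_clock(points: Sequence[tuple[float, float]]) -> ClockModel:
    """Ordinary least-squares fit of age (Gy) against node-distance x.

    Requires at least two distinct x values.
    """
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    if len(set(xs.tolist())) < 2:
        raise ChronologyError("calibration needs >= 2 distinct x values")
    fit = sps.linregress(xs, ys)
    return ClockModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        stderr=float(fit.stderr),
        points=tuple((float(x), float(y)) for x, y in points),
    )


def apply_clock(
    clock: ClockModel,
    units: Mapping[str, float],
    kind: str = "domain",
    ceiling: float = AGE_CEILING_GY,
) -> Timeline:
    """Date units from their x values; clamping and extrapolation flagged.

    Predictions are clamped to ``[0, ceiling]`` Gy, never silently: each
    clamped entry carries a flag, as does any x outside the calibration
    range.
    """
    lo, hi = clock.x_range
    tl = Timeline()
    for unit, x in units.items():
        age = clock.predict(x)
        flags: list[str] = []
        if x < lo or x > hi:
            flags.append("extrapolated")
        if age < 0.0:
            age = 0.0
            flags.append("clamped-to-0")
        elif age > ceiling:
            age = ceiling
            flags.append(f"clamped-to-{ceiling}")
        tl.entries.append(
            TimelineEntry(
                unit=unit, kind=kind, age_gy=age, provenance="clock", flags=tuple(flags)
            )
        )
    return tl


def interaction_age(component_ages: Iterable[float]) -> float:
    """Age of an interaction: the youngest component limits coexistence."""
    ages = list(component_ages)
    if not ages:
        raise ChronologyError("interaction with no components")
    return min(ages)


def anchor_substructures(
    domain_ages: Timeline,
    interactions: Sequence[InteractionRecord],
    relative_ages: Mapping[str, float] | None = None,
) -> Timeline:
    """Date substructures from the domains they interact with.

    Each substructure receives the maximum age among its interacting
    domains — the oldest partner sets a lower bound on the substructure's
    true age.  When ``relative_ages`` (e.g. from a substructure tree) are
    supplied, a consistency flag is raised on any substructure pair whose
    anchored-age order contradicts the relative-age order; both values stay
    reported.
    """
    by_sub: dict[str, list[float]] = {}
    for rec in interactions:
        if rec.domain not in domain_ages:
            raise ChronologyError(f"unresolvable domain id {rec.domain!r}")
        by_sub.setdefault(rec.substructure, []).append(domain_ages.age(rec.domain))
    anchored = {sub: max(ages) for sub, ages in by_sub.items()}

    inconsistent: set[str] = set()
    if relative_ages is not None:
        subs = [s for s in anchored if s in relative_ages]
        for i, a in enumerate(subs):
            for b in subs[i + 1 :]:
                d_anchor = anchored[a] - anchored[b]
                d_rel = relative_ages[a] - relative_ages[b]
                if d_anchor * d_rel < 0:
                    inconsistent.update((a, b))

    tl = Timeline()
    for sub in sorted(anchored):
        flags: list[str] = []
        if sub in inconsistent:
            flags.append(
                f"order-conflict-with-relative-age-{relative_ages[sub]:.3g}"
            )
        tl.entries.append(
            TimelineEntry(
                unit=sub,
                kind="substructure",
                age_gy=anchored[sub],
                provenance="interaction-anchor",
                flags=tuple(flags),
            )
        )
    return tl


def read_calibration_tsv(path_or_buf) -> list[tuple[float, float]]:
    """Calibration TSV with columns ``x`` and ``age_gy``."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t")
    if not {"x", "age_gy"} <= set(df.columns):
        raise ChronologyError("calibration TSV needs columns x, age_gy")
    return [(float(r.x), float(r.age_gy)) for r in df.itertuples()]


def read_interactions_tsv(path_or_buf) -> list[InteractionRecord]:
    """Interaction TSV with columns ``domain_id``, ``substructure``, ``evidence``."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t")
    need = {"domain_id", "substructure"}
    if not need <= set(df.columns):
        raise ChronologyError("interaction TSV needs columns domain_id, substructure")
    return [
        InteractionRecord(
            domain=str(r.domain_id),
            substructure=str(r.substructure),
            evidence=str(getattr(r, "evidence", "")),
        )
        for r in df.itertuples()
    ]
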