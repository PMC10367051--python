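"""Reaction free-energy profiles: assembly, stitching, barriers, RDS.

A profile is an ordered list of stationary points with free energies on a
common scale.  Within a contiguous segment minima and transition states
alternate; two adjacent minima mark a segment break (a rearrangement or an
association/dissociation event joining two surfaces).  Profiles for
successive hydrolytic steps, computed on separate model systems, are
stitched onto a single absolute scale through the free energy of the
linking event (water association, difluoroacetate dissociation).

The elementary barrier of a transition state is measured from the nearest
preceding minimum; the rate-determining step is the largest such barrier.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .energy_model import ProtocolTag, composite_free_energy
from .records import (
    MINIMUM, TRANSITION_STATE, StationaryPointRecord, ValidationError,
)
from .thermochem import standard_state_correction

__all__ = [
    "ProfilePoint",
    "ReactionProfile",
    "StitchEvent",
    "Barrier",
    "RateDeterminingStep",
    "build_profile",
    "stitch_profiles",
    "elementary_barriers",
    "barrier_between",
    "rate_determining_step",
    "export_diagram",
]


@dataclass(frozen=True)
class ProfilePoint:
    label: str
    role: str
    g: float  # kcal/mol relative to the profile reference


Barrier = namedtuple("Barrier", "from_minimum ts delta_g_act")


@dataclass(frozen=True)
class RateDeterminingStep:
    from_minimum: str
    ts: str
    delta_g_act: float
    #: all barriers tying the maximum (including the returned one), in order
    ties: tuple[Barrier, ...] = ()


@dataclass(frozen=True)
class ReactionProfile:
    """Ordered stationary points with relative free energies (kcal/mol)."""

    points: tuple[ProfilePoint, ...]
    reference_label: str
    scale: str = "local"  # "local" | "absolute"

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if not pts:
            raise ValidationError("a profile needs at least one point")
        labels = [p.label for p in pts]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate stationary-point labels in profile")
        for a, b in zip(pts, pts[1:]):
            if a.role == TRANSITION_STATE and b.role == TRANSITION_STATE:
                raise ValidationError(
                    f"two consecutive transition states ({a.label}, {b.label})"
                )
        if pts[0].role != MINIMUM or pts[-1].role != MINIMUM:
            raise ValidationError("a profile must start and end at minima")
        if self.scale not in ("local", "absolute"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        ref = self._find(self.reference_label)
        if ref.role != MINIMUM:
            raise ValidationError("the reference point must be a minimum")
        if self.scale == "local" and abs(ref.g) > 1e-9:
            raise ValidationError("reference energy must be 0 on a local scale")

    def _find(self, label: str) -> ProfilePoint:
        for p in self.points:
            if p.label == label:
                return p
        raise ValidationError(f"label {label!r} not found in profile")

    def g(self, label: str) -> float:
        return self._find(label).g

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.points)

    @classmethod
    def from_values(cls, labels: Sequence[str], roles: Sequence[str],
                    values: Sequence[float], reference_label: str | None = None,
                    scale: str = "local") -> "ReactionProfile":
        """Build a profile directly from tabulated relative energies."""
        if not (len(labels) == len(roles) == len(values)):
            raise ValidationError("labels, roles and values must align")
        if reference_label is None:
            reference_label = labels[0]
        pts = tuple(
            ProfilePoint(l, r, float(v)) for l, r, v in zip(labels, roles, values)
        )
        return cls(pts, reference_label, scale)

    def shifted(self, offset: float, scale: str | None = None,
                reference_label: str | None = None) -> "ReactionProfile":
        pts = tuple(replace(p, g=p.g + offset) for p in self.points)
        return ReactionProfile(
            pts,
            reference_label or self.reference_label,
            scale or self.scale,
        )

    def re_reference(self, label: str) -> "ReactionProfile":
        """Return a local-scale copy with *label* (a minimum) set to zero."""
        ref = self._find(label)
        if ref.role != MINIMUM:
            raise ValidationError("can only re-reference to a minimum")
        return self.shifted(-ref.g, scale="local", reference_label=label)

    def segment(self, first_label: str, last_label: str) -> "ReactionProfile":
        """Contiguous sub-profile between two labels (inclusive), local scale
        referenced to its first minimum."""
        labels = self.labels
        i, j = labels.index(first_label), labels.index(last_label)
        if j < i:
            raise ValidationError("segment labels out of order")
        sub = ReactionProfile(self.points[i:j + 1], self.points[i].label,
                              scale="absolute")
        return sub.re_reference(self.points[i].label)


@dataclass(frozen=True)
class StitchEvent:
    """Association/dissociation event joining two per-step profiles.

    ``delta_g_link`` is the free-energy change of the event from
    ``from_label`` (terminal minimum of the upstream profile) to ``to_label``
    (reference minimum of the downstream profile); ``delta_n`` is the molar
    change, used only when a standard-state term is requested.
    """

    from_label: str
    to_label: str
    delta_g_link: float
    species: str = ""
    delta_n: int = 0


def build_profile(records: Sequence[StationaryPointRecord], tag: ProtocolTag,
                  reference_label: str, T: float = 298.15,
                  **qrrho_kwargs) -> ReactionProfile:
    """Assemble a local-scale profile from stationary-point records.

    Records must appear in reaction order with valid role alternation; the
    reference must be one of the minima.  Energies are protocol composite
    free energies minus the reference value.
    """
    if not records:
        raise ValidationError("no records supplied")
    values = {
        r.label: composite_free_energy(r, tag, T, **qrrho_kwargs) for r in records
    }
    if reference_label not in values:
        raise ValidationError(f"reference label {reference_label!r} not in records")
    ref = values[reference_label]
    pts = tuple(
        ProfilePoint(r.label, r.role, values[r.label] - ref) for r in records
    )
    return ReactionProfile(pts, reference_label, scale="local")


def stitch_profiles(p1: ReactionProfile, p2: ReactionProfile, link: StitchEvent,
                    apply_standard_state: bool = False,
                    T: float = 298.15) -> ReactionProfile:
    """Place *p2* on *p1*'s scale through the linking event.

    The downstream reference lands at G(p1, from_label) + ΔG_link, plus the
    1.9Δn-style standard-state term when *apply_standard_state* is set (off
    by default: tabulated link free energies normally include it already).
    The result is on the absolute scale of *p1*.
    """
    last = p1.points[-1]
    if link.from_label != last.label:
        raise ValidationError(
            f"stitch must leave from the terminal minimum {last.label!r}, "
            f"got {link.from_label!r}"
        )
    first = p2.points[0]
    if link.to_label != first.label:
        raise ValidationError(
            f"stitch must land on the first minimum {first.label!r} of the "
            f"downstream profile, got {link.to_label!r}"
        )
    dg = link.delta_g_link
    if apply_standard_state:
        dg += standard_state_correction(link.delta_n, T)
    offset = p1.g(link.from_label) + dg - p2.g(link.to_label)
    shifted = tuple(replace(p, g=p.g + offset) for p in p2.points)
    return ReactionProfile(
        p1.points + shifted, p1.reference_label, scale="absolute"
    )


def elementary_barriers(p: ReactionProfile) -> list[Barrier]:
    """Forward barrier of every transition state from its nearest preceding
    minimum; negative apparent barriers are flagged with a warning."""
    barriers: list[Barrier] = []
    last_min: ProfilePoint | None = None
    for pt in p.points:
        if pt.role == MINIMUM:
            last_min = pt
        else:
            if last_min is None:
                raise ValidationError(f"transition state {pt.label!r} has no "
                                      "preceding minimum")
            dg = pt.g - last_min.g
            if dg <= 0:
                warnings.warn(
                    f"transition state {pt.label} lies below its preceding "
                    f"minimum {last_min.label} (ΔG‡ = {dg:.2f} kcal/mol)",
                    stacklevel=2,
                )
            barriers.append(Barrier(last_min.label, pt.label, float(dg)))
    return barriers


def barrier_between(p: ReactionProfile, from_label: str, ts_label: str) -> float:
    """Activation free energy from an explicitly chosen minimum to a TS.

    Exposes alternatively referenced barriers, e.g. the step-2 first barrier
    measured from the global-minimum water complex rather than from the
    rearranged reactive complex."""
    start = p._find(from_label)
    ts = p._find(ts_label)
    if start.role != MINIMUM or ts.role != TRANSITION_STATE:
        raise ValidationError("barrier must run from a minimum to a transition state")
    return float(ts.g - start.g)


def rate_determining_step(p: ReactionProfile) -> RateDeterminingStep:
    """Largest elementary barrier; ties are broken by earliest position and
    reported in the result's ``ties`` tuple."""
    barriers = elementary_barriers(p)
    if not barriers:
        raise ValidationError("profile contains no transition state")
    best = max(b.delta_g_act for b in barriers)
    tied = tuple(b for b in barriers if abs(b.delta_g_act - best) < 1e-12)
    top = tied[0]
    return RateDeterminingStep(top.from_minimum, top.ts, top.delta_g_act, tied)


def profile_to_frame(p: ReactionProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [pt.label for pt in p.points],
            "role": [pt.role for pt in p.points],
            "g_kcal_mol": [pt.g for pt in p.points],
        }
    )


def export_diagram(p: ReactionProfile, path, csv_path=None) -> None:
    """Render a ladder diagram (minima as plateaus, TS as peaks) and write a
    machine-readable CSV next to it.  Output is deterministic."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(p.points) + 1, 4))
    half = 0.3
    prev = None
    for i, pt in enumerate(p.points):
        ax.hlines(pt.g, i - half, i + half,
                  colors="tab:blue" if pt.role == MINIMUM else "tab:red",
                  linewidth=2.5)
        ax.annotate(pt.label, (i, pt.g), textcoords="offset points",
                    xytext=(0, 6), ha="center", fontsize=8)
        if prev is not None:
            dashed = prev.role == MINIMUM and pt.role == MINIMUM
            ax.plot([i - 1 + half, i - half], [prev.g, pt.g],
                    linestyle="--" if dashed else "-", color="gray",
                    linewidth=0.8)
        prev = pt
    ax.set_xticks([])
    ax.set_ylabel("ΔG (kcal/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    if csv_path is None:
        csv_path = str(path).rsplit(".", 1)[0] + ".csv"
    profile_to_frame(p).to_csv(csv_path, index=False, float_format="%.6f")
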