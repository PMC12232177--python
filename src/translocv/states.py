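"""State assignment, transition counting and pathway classification.

Frames are labeled PRE / INT1 / INT2 / POST when they fall inside a fixed
radius of the corresponding reference point (latent coordinates for the
surrogate; for real data the two axes would be primer- and template-strand
displacement metrics against the PRE reference), and TRANSIT otherwise.
A transition between the two end states is recorded when the trajectory
leaves one end state and next settles in the other; the intermediate it
passed through classifies the pathway (1 = via INT1, primer strand first;
2 = via INT2, template strand first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .errors import ConfigurationError, InputError, UndefinedResultError
from .surrogate import BASIN_CENTERS, Trajectory
from .tables import DescriptorTable

__all__ = [
    "StateReference",
    "TransitionRecord",
    "assign_states",
    "count_transitions",
    "state_distance_distributions",
    "pathway_preference",
]

TRANSIT = "TRANSIT"
_END_STATES = ("PRE", "POST")


@dataclass(frozen=True)
class StateReference:
    """Reference points and assignment radii in the chosen metric space."""

    points: dict = field(default_factory=lambda: {k: tuple(v) for k, v in BASIN_CENTERS.items()})
    radius: float = 0.25

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("assignment radius must be positive")
        names = list(self.points)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d = np.linalg.norm(np.asarray(self.points[a]) - np.asarray(self.points[b]))
                if d <= 2.0 * self.radius:
                    raise ConfigurationError(
                        f"state spheres {a} and {b} overlap (separation {d:.3f})"
                    )


def assign_states(trajectory, reference: StateReference | None = None) -> np.ndarray:
    """Per-frame state labels; a pure function of the coordinates."""
    reference = reference or StateReference()
    coords = trajectory.latent if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    coords = np.atleast_2d(coords)
    labels = np.full(len(coords), TRANSIT, dtype=object)
    for state, point in reference.points.items():
        d = np.linalg.norm(coords - np.asarray(point)[None, :], axis=1)
        labels[d <= reference.radius] = state
    return labels


@dataclass(frozen=True)
class TransitionRecord:
    """One settled excursion between the two end states."""

    start_state: str
    end_state: str
    start_frame: int
    end_frame: int
    intermediate: str | None
    pathway: int | None  # 1 via INT1, 2 via INT2, None if no intermediate

    def __post_init__(self):
        if self.start_state == self.end_state:
            raise ConfigurationError("transition endpoints must differ")


def _settled_visits(labels: np.ndarray, settle: int) -> list[tuple[str, int]]:
    """(state, entry_frame) for every run of >= settle consecutive same labels."""
    visits = []
    run_state, run_start = None, 0
    labels = list(labels) + [None]  # sentinel flush
    for i, lab in enumerate(labels):
        if lab != run_state:
            if run_state not in (None, TRANSIT) and i - run_start >= settle:
                if not visits or visits[-1][0] != run_state:
                    visits.append((run_state, run_start))
            run_state, run_start = lab, i
    return visits


def count_transitions(label_sequence, settle: int = 10) -> list[TransitionRecord]:
    """Emit ordered, non-overlapping PRE<->POST transition records.

    A state counts as visited once it holds for ``settle`` consecutive
    frames (recrossing suppression).  The intermediate of a record is the
    last settled non-end-state strictly between the two end-state visits.
    """
    labels = np.asarray(list(label_sequence), dtype=object)
    if len(labels) == 0:
        raise InputError("empty label sequence")
    records: list[TransitionRecord] = []
    last_end: tuple[str, int] | None = None
    for state, frame in _settled_visits(labels, settle):
        if state not in _END_STATES:
            continue
        if last_end is not None and state != last_end[0]:
            # intermediate: last raw (unsettled) non-end-state label between
            # the two end-state visits — fast passages still count
            between = labels[last_end[1] + 1: frame]
            inters = between[(between != TRANSIT) & (between != "PRE") & (between != "POST")]
            inter = str(inters[-1]) if len(inters) else None
            records.append(
                TransitionRecord(
                    start_state=last_end[0],
                    end_state=state,
                    start_frame=last_end[1],
                    end_frame=frame,
                    intermediate=inter,
                    pathway={"INT1": 1, "INT2": 2}.get(inter),
                )
            )
        last_end = (state, frame)
    return records


def state_distance_distributions(
    table: DescriptorTable,
    labels=None,
    states=None,
    bins: int = 50,
) -> tuple[dict, pd.DataFrame]:
    """Per-descriptor, per-state distance histograms and mean ± SD summaries.

    Histograms are normalized to unit area.  Returns
    ``({(descriptor_id, state): (density, edges)}, summary_frame)``.
    """
    labels = table.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise InputError("no state labels available")
    if len(labels) != len(table):
        raise InputError("labels do not align with table frames")
    states = list(states) if states is not None else sorted(set(labels) - {TRANSIT})
    for s in states:
        if s not in labels:
            raise InputError(f"requested state {s!r} absent from labels")
    hists = {}
    rows = []
    for state in states:
        sub = table.data.loc[labels == state]
        for col in table.descriptor_ids:
            vals = sub[col].to_numpy()
            lo, hi = vals.min(), vals.max()
            if lo == hi:  # degenerate point mass: one unit-area bin
                edges = np.array([lo - 0.5, lo + 0.5])
                dens = np.array([1.0])
            else:
                dens, edges = np.histogram(vals, bins=bins, density=True)
            hists[(col, state)] = (dens, edges)
            rows.append(
                {"descriptor_id": col, "state": state,
                 "mean": vals.mean(), "sd": vals.std(), "n_frames": len(vals)}
            )
    return hists, pd.DataFrame(rows)


def pathway_preference(
    records: list[TransitionRecord], confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of PRE-origin transitions routed via INT1, with exact CI.

    Only PRE -> POST records with a defined intermediate enter the count;
    the interval is Clopper-Pearson at the given confidence level.
    """
    origin = [r for r in records if r.start_state == "PRE" and r.pathway is not None]
    if not origin:
        raise UndefinedResultError("no PRE-origin transitions with a defined pathway")
    k = sum(1 for r in origin if r.pathway == 1)
    n = len(origin)
    ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return k / n, (float(ci.low), float(ci.high))
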