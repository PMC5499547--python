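"""Comparative statistics over populations and reactivity matrices.

* roadblocking efficiency: stalled / (stalled + run-off), terminated and
  aborted species excluded;
* Delta-rho matrices between two roadblocking strategies;
* footprint-shift estimation from the stripe of negative Delta-rho
  adjacent to the protected 3' edge;
* folding-transition onset/completion detection on region-mean reactivity
  traces across transcript lengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .pipeline import ReactivityMatrix
from .tec import FATE_RUNOFF, FATE_STALLED, Population, RoadblockKind

log = logging.getLogger(__name__)

DIRECTION_DECREASE = "decrease"
DIRECTION_INCREASE = "increase"


def roadblock_efficiency(
    population: Population,
    count_terminal_as_runoff: bool = True,
) -> float:
    """Roadblocking efficiency: stalled / (stalled + run-off).

    Terminated species are excluded from the calculation (as are aborted
    products, which the simulator does not model).  TECs held only by a
    terminal roadblock are counted as run-off equivalents by default,
    since they passed every internal roadblock.
    """
    stalled_mask = population.fate == FATE_STALLED
    terminal_mask = stalled_mask & (population.roadblock == RoadblockKind.TERMINAL_SAV)
    internal = int((stalled_mask & ~terminal_mask).sum())
    runoff = int((population.fate == FATE_RUNOFF).sum())
    if count_terminal_as_runoff:
        runoff += int(terminal_mask.sum())
    else:
        internal += int(terminal_mask.sum())
    denom = internal + runoff
    if denom == 0:
        raise ValueError("no roadblocked or run-off products")
    return internal / denom


@dataclass
class DeltaMatrix:
    """Elementwise rho difference A - B over common lengths/positions."""

    data: pd.DataFrame
    name_a: str = "A"
    name_b: str = "B"

    @property
    def lengths(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def row(self, L: int) -> np.ndarray:
        return self.data.loc[L].to_numpy()[:L]

    def per_length_summary(self) -> pd.Series:
        """Mean |Delta-rho| per length."""
        return self.data.abs().mean(axis=1, skipna=True).rename("mean_abs_delta_rho")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# cotshape delta-rho matrix ({self.name_a} - {self.name_b}); "
                "rows = transcript length, columns = 1-based position\n"
            )
            self.data.to_csv(fh, sep="\t", na_rep="NA", index_label="length")


def delta_rho(
    matrix_a: ReactivityMatrix,
    matrix_b: ReactivityMatrix,
    skip_low_signal: bool = True,
) -> DeltaMatrix:
    """Delta-rho = rho_A - rho_B over intersecting lengths and positions."""
    la = set(matrix_a.good_lengths() if skip_low_signal else map(int, matrix_a.lengths))
    lb = set(matrix_b.good_lengths() if skip_low_signal else map(int, matrix_b.lengths))
    common = sorted(la & lb)
    if not common:
        raise ValueError("matrices share no transcript lengths")
    cols = matrix_a.data.columns.intersection(matrix_b.data.columns)
    diff = matrix_a.data.loc[common, cols] - matrix_b.data.loc[common, cols]
    return DeltaMatrix(
        data=diff,
        name_a=str(matrix_a.metadata.get("name", "A")),
        name_b=str(matrix_b.metadata.get("name", "B")),
    )


def estimate_footprint_shift(
    delta: DeltaMatrix,
    reference: ReactivityMatrix,
    tau: float = defaults.FOOTPRINT_TAU,
) -> tuple[float, pd.Series]:
    """Width of the negative Delta-rho stripe adjacent to the RNAP edge.

    ``delta`` must be computed as (backtracking-prone) - (reference), with
    ``reference`` the matrix whose protected edge defines the anchor (the
    last position with reference rho > tau).  Per length, the stripe is
    the maximal contiguous run of Delta-rho < -tau ending at that anchor.
    Lengths where the edge abuts an unreactive region carry no width
    information and are excluded from the mean; if no length has a
    qualifying run the mean is 0 with a warning.
    """
    widths = {}
    for L in delta.lengths:
        L = int(L)
        if L not in reference.data.index:
            continue
        ref_row = reference.rho(L)
        drow = delta.row(L)
        n = min(len(ref_row), len(drow))
        anchor = -1
        for k in range(n - 1, -1, -1):
            if np.isfinite(ref_row[k]) and ref_row[k] > tau:
                anchor = k
                break
        if anchor < 0:
            continue
        w = 0
        k = anchor
        while k >= 0 and np.isfinite(drow[k]) and drow[k] < -tau:
            w += 1
            k -= 1
        widths[L] = w
    widths = pd.Series(widths, name="stripe_width", dtype=float)
    qualifying = widths[widths >= 1]
    if len(qualifying) == 0:
        warnings.warn("no qualifying negative stripe in any length", stacklevel=2)
        return 0.0, widths
    return float(qualifying.mean()), widths


@dataclass
class TransitionCall:
    """A detected structural transition along the folding pathway."""

    element: str
    region: tuple[int, int]
    direction: str
    onset: int | None
    completion: int | None
    trace: pd.Series = field(repr=False, default=None)

    @property
    def called(self) -> bool:
        return self.onset is not None


def region_trace(
    matrix: ReactivityMatrix,
    region: tuple[int, int],
    lengths: tuple[int, int] | None = None,
    exclude_lengths: tuple[int, ...] = (),
) -> pd.Series:
    """Region-mean rho trace across transcript lengths."""
    lo, hi = region
    use = []
    for L in matrix.good_lengths():
        if L < hi:
            continue
        if lengths is not None and not (lengths[0] <= L <= lengths[1]):
            continue
        if L in exclude_lengths:
            continue
        use.append(L)
    if not use:
        raise ValueError("no usable lengths for the requested region")
    cols = list(range(lo, hi + 1))
    return matrix.data.loc[use, cols].mean(axis=1).sort_index()


def detect_transition(
    matrix: ReactivityMatrix,
    region: tuple[int, int],
    direction: str,
    element: str = "element",
    lengths: tuple[int, int] | None = None,
    exclude_lengths: tuple[int, ...] = (),
    plateau: int = defaults.TRANSITION_PLATEAU,
    persistence: int = defaults.TRANSITION_PERSISTENCE,
) -> TransitionCall:
    """Detect a reactivity transition of a region across lengths.

    The region-mean trace is min-max normalised between the medians of
    the first and last ``plateau`` defined lengths.  The onset is the
    first length at which the normalised trace passes 0.5 toward the
    post-transition plateau and remains past it for >= ``persistence``
    consecutive lengths; completion requires passing 0.9 likewise.  A
    trace whose plateaus do not move in the stated direction yields a
    no-call.
    """
    if direction not in (DIRECTION_DECREASE, DIRECTION_INCREASE):
        raise ValueError(f"bad direction {direction!r}")
    trace = region_trace(matrix, region, lengths=lengths, exclude_lengths=exclude_lengths)
    if len(trace) < 2 * max(plateau, persistence):
        raise ValueError(
            f"need at least {2 * max(plateau, persistence)} lengths on the trace, "
            f"have {len(trace)}"
        )
    pre = float(trace.iloc[:plateau].median())
    post = float(trace.iloc[-plateau:].median())
    moved_down = post < pre
    if (direction == DIRECTION_DECREASE) != moved_down or pre == post:
        return TransitionCall(element, region, direction, None, None, trace)
    norm = (trace - pre) / (post - pre)  # 0 at pre-plateau, 1 at post-plateau

    def first_sustained(threshold: float) -> int | None:
        passed = (norm >= threshold).to_numpy()
        for i in range(len(passed) - persistence + 1):
            if passed[i : i + persistence].all():
                return int(norm.index[i])
        return None

    onset = first_sustained(0.5)
    completion = first_sustained(0.9)
    if onset is None:
        return TransitionCall(element, region, direction, None, None, trace)
    if completion is not None and completion < onset:
        completion = onset
    return TransitionCall(element, region, direction, onset, completion, trace)


def transition_table(calls: list[TransitionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element": c.element,
                "region_start": c.region[0],
                "region_end": c.region[1],
                "direction": c.direction,
                "onset": c.onset,
                "completion": c.completion,
            }
            for c in calls
        ]
    )
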