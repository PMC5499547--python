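"""Single-round transcription over roadblocked templates.

Each template molecule yields at most one transcription elongation complex
(TEC); rifampicin in the modelled reaction blocks re-initiation.  A TEC
traverses its roadblocks in order of the stall positions they would
impose, stalls at each with a per-roadblock Bernoulli probability, may
terminate at the intrinsic terminator (fluoride-dependent), and otherwise
runs off the template end (or is held by a terminal biotin-SAv roadblock).

Stalled TECs backtrack.  Biotin-SAv roadblocks, tethered through a
flexible linker, permit backtracking of up to 4 nt from the primary stall
position (up to 7 nt total for TECs that pushed the roadblock before
stopping), while the rigid Gln111 roadblock permits at most 1 nt.  A
folded hairpin immediately behind RNAP blocks backtracking (cap 1 nt).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from . import defaults
from .folding import FoldingPathway
from .templates import TemplateSpec

log = logging.getLogger(__name__)

FATE_STALLED = "stalled"
FATE_RUNOFF = "runoff"
FATE_TERMINATED = "terminated"


class RoadblockKind(str, Enum):
    SAV_TEMPLATE = "SAv_template"
    SAV_NONTEMPLATE = "SAv_nontemplate"
    GLN111 = "Gln111"
    TERMINAL_SAV = "terminal_SAv"


_OFFSET_SUPPORTS = {
    RoadblockKind.SAV_TEMPLATE: (7, 13),
    RoadblockKind.SAV_NONTEMPLATE: (7, 13),
    RoadblockKind.GLN111: (14, 14),
    RoadblockKind.TERMINAL_SAV: (0, 0),
}


def _check_dist(dist: dict[int, float], name: str) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative probabilities")


@dataclass(frozen=True)
class RoadblockModel:
    """One roadblock: kind, site, stall probability and offset/backtrack laws.

    ``site`` is the transcript coordinate of the biotinylated base (SAv),
    of the first base of GAATTC (Gln111) or of the template end (terminal).
    A stall leaves the RNA 3' end at length ``site - d`` with the offset
    ``d`` drawn from ``offset_dist``.
    """

    kind: RoadblockKind
    site: int
    stall_prob: float
    offset_dist: dict[int, float]
    backtrack_dist: dict[int, float]

    def __post_init__(self):
        if not 0.0 <= self.stall_prob <= 1.0:
            raise ValueError("stall_prob outside [0, 1]")
        _check_dist(self.offset_dist, "offset_dist")
        _check_dist(self.backtrack_dist, "backtrack_dist")
        lo, hi = _OFFSET_SUPPORTS[self.kind]
        for d in self.offset_dist:
            if not lo <= d <= hi:
                raise ValueError(
                    f"{self.kind.value} offset {d} outside printed support [{lo}, {hi}]"
                )

    @property
    def max_offset(self) -> int:
        return max(self.offset_dist)

    @property
    def modal_offset(self) -> int:
        return max(self.offset_dist, key=self.offset_dist.get)

    # -- constructors with field defaults ---------------------------------

    @classmethod
    def sav_template(cls, site: int, **kw) -> "RoadblockModel":
        kw.setdefault("stall_prob", defaults.SAV_TEMPLATE_STALL_PROB)
        kw.setdefault("offset_dist", dict(defaults.SAV_TEMPLATE_OFFSETS))
        kw.setdefault("backtrack_dist", dict(defaults.SAV_BACKTRACK_DIST))
        return cls(kind=RoadblockKind.SAV_TEMPLATE, site=site, **kw)

    @classmethod
    def sav_nontemplate(cls, site: int, **kw) -> "RoadblockModel":
        kw.setdefault("stall_prob", defaults.SAV_NONTEMPLATE_STALL_PROB)
        kw.setdefault("offset_dist", dict(defaults.SAV_NONTEMPLATE_OFFSETS))
        kw.setdefault("backtrack_dist", dict(defaults.SAV_BACKTRACK_DIST))
        return cls(kind=RoadblockKind.SAV_NONTEMPLATE, site=site, **kw)

    @classmethod
    def gln111(cls, site: int, **kw) -> "RoadblockModel":
        kw.setdefault("stall_prob", defaults.GLN111_STALL_PROB)
        kw.setdefault("offset_dist", dict(defaults.GLN111_OFFSETS))
        kw.setdefault("backtrack_dist", dict(defaults.GLN111_BACKTRACK_DIST))
        return cls(kind=RoadblockKind.GLN111, site=site, **kw)

    @classmethod
    def terminal(cls, site: int, **kw) -> "RoadblockModel":
        kw.setdefault("stall_prob", defaults.TERMINAL_STALL_PROB)
        kw.setdefault("offset_dist", dict(defaults.TERMINAL_OFFSETS))
        kw.setdefault("backtrack_dist", dict(defaults.SAV_BACKTRACK_DIST))
        return cls(kind=RoadblockKind.TERMINAL_SAV, site=site, **kw)


@dataclass
class TECState:
    """One elongation complex after the simulation has resolved its fate."""

    template_id: int
    L: int  # RNA 3'-end length, nt
    b: int = 0  # backtrack depth; active site at L - b
    fate: str = FATE_STALLED
    bound: bool = True  # still template-associated (bead-bound if immobilised)
    pushed: int = 0  # nt advanced past the primary stall position
    roadblock: RoadblockKind | None = None
    run_through: bool = False  # passed a Gln111 roadblock (aberrant 3' sequence)

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("negative backtrack depth")


def _draw(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def stall_outcome(
    roadblock: RoadblockModel, rng: np.random.Generator
) -> tuple[bool, int | None, int]:
    """Bernoulli stall at one roadblock.

    Returns ``(stalled, L, pushed)``: on a stall, the RNA 3'-end length L
    is ``site - d`` with d drawn from the offset distribution, and
    ``pushed`` is how far past the modal (primary) stop the TEC advanced.
    On a non-stall the TEC continues downstream.
    """
    if roadblock.site - roadblock.max_offset < 1:
        raise ValueError(
            f"roadblock at site {roadblock.site} is too close to +1 "
            f"(max offset {roadblock.max_offset})"
        )
    if rng.random() >= roadblock.stall_prob:
        return False, None, 0
    d = _draw(roadblock.offset_dist, rng)
    pushed = max(0, roadblock.modal_offset - d)
    return True, roadblock.site - d, pushed


def apply_backtracking(
    tec: TECState,
    roadblock: RoadblockModel,
    rng: np.random.Generator,
    pathway: FoldingPathway | None = None,
    condition: str = "+F",
) -> TECState:
    """Set the backtrack depth of a stalled TEC.

    SAv kinds draw from the SAv backtrack distribution and add the push
    (total depth <= 7 from the most advanced register); Gln111 draws from
    {0, 1}.  If the folding ground truth places a folded hairpin within 4
    nt of the RNAP back edge at this length, the depth is capped at 1.
    Depths exceeding L - 1 clamp with a warning.
    """
    if tec.fate != FATE_STALLED:
        raise ValueError("backtracking applies to stalled TECs only")
    if roadblock.kind is RoadblockKind.GLN111:
        b = _draw(roadblock.backtrack_dist, rng)
        b = min(b, 1)
    else:
        b = _draw(roadblock.backtrack_dist, rng)
        b = min(b, defaults.SAV_MAX_BACKTRACK_PRIMARY)
        b = min(b + tec.pushed, defaults.SAV_MAX_BACKTRACK_TOTAL)
    if pathway is not None:
        cap = pathway.backtrack_cap(tec.L, condition)
        if cap is not None:
            b = min(b, cap)
    if b > tec.L - 1:
        warnings.warn(f"backtrack {b} exceeds L-1={tec.L - 1}; clamped", stacklevel=2)
        b = tec.L - 1
    return replace(tec, b=b)


def greb_cleavage_register(tec: TECState) -> int:
    """RNA length after GreB-stimulated cleavage of a backtracked TEC.

    GreB trims the nascent RNA back to the active-site register, L - b.
    """
    if tec.fate != FATE_STALLED:
        raise ValueError("GreB cleavage applies to stalled TECs only")
    return tec.L - tec.b


def exo3_protection(
    tec: TECState, rng: np.random.Generator, jitter: bool = True
) -> int:
    """nt of template-strand DNA protected from ExoIII upstream of the
    position templating the RNA 3' nt.

    protection = f_dna + b + delta with delta a uniform 0/1 nt jitter on
    the digestion endpoint.
    """
    if tec.fate != FATE_STALLED:
        raise ValueError("ExoIII footprinting applies to stalled TECs only")
    delta = int(rng.integers(defaults.EXO3_JITTER[0], defaults.EXO3_JITTER[1] + 1)) if jitter else 0
    return defaults.F_DNA + tec.b + delta


@dataclass
class TerminatorModel:
    """Intrinsic terminator: fires on encounter with fluoride-dependent
    probability, releasing the RNA at a length in the termination window."""

    window: tuple[int, int] = defaults.TERMINATION_WINDOW
    p_term_no_fluoride: float = defaults.P_TERM_NO_FLUORIDE
    p_term_fluoride: float = defaults.P_TERM_FLUORIDE

    def p_term(self, fluoride_mM: float) -> float:
        return self.p_term_fluoride if fluoride_mM > 0 else self.p_term_no_fluoride


class Population:
    """Vector-of-arrays container for many simulated TECs."""

    COLUMNS = ("template_id", "L", "b", "fate", "bound", "pushed", "roadblock", "run_through")

    def __init__(self, template_id, L, b, fate, bound, pushed, roadblock, run_through):
        self.template_id = np.asarray(template_id, dtype=np.int64)
        self.L = np.asarray(L, dtype=np.int64)
        self.b = np.asarray(b, dtype=np.int64)
        self.fate = np.asarray(fate, dtype=object)
        self.bound = np.asarray(bound, dtype=bool)
        self.pushed = np.asarray(pushed, dtype=np.int64)
        self.roadblock = np.asarray(roadblock, dtype=object)
        self.run_through = np.asarray(run_through, dtype=bool)

    def __len__(self) -> int:
        return len(self.L)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i) -> TECState:
        if isinstance(i, (int, np.integer)):
            return TECState(
                template_id=int(self.template_id[i]),
                L=int(self.L[i]),
                b=int(self.b[i]),
                fate=str(self.fate[i]),
                bound=bool(self.bound[i]),
                pushed=int(self.pushed[i]),
                roadblock=self.roadblock[i],
                run_through=bool(self.run_through[i]),
            )
        raise TypeError("Population indices must be integers")

    def subset(self, mask: np.ndarray) -> "Population":
        return Population(
            self.template_id[mask], self.L[mask], self.b[mask], self.fate[mask],
            self.bound[mask], self.pushed[mask], self.roadblock[mask],
            self.run_through[mask],
        )

    @property
    def stalled(self) -> np.ndarray:
        return self.fate == FATE_STALLED

    def fate_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.fate.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "template_id": self.template_id,
                "L": self.L,
                "b": self.b,
                "fate": self.fate.astype(str),
                "bound": self.bound,
                "pushed": self.pushed,
                "roadblock": [r.value if r is not None else "NA" for r in self.roadblock],
                "run_through": self.run_through,
            }
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write("# cotshape population table; coordinates 1-based, +1 frame\n")
            df.to_csv(fh, sep="\t", index=False)

    @staticmethod
    def concatenate(parts: list["Population"]) -> "Population":
        return Population(*[
            np.concatenate([getattr(p, c) for p in parts]) for c in Population.COLUMNS
        ])


def simulate_population(
    spec: TemplateSpec,
    roadblocks: list[RoadblockModel],
    n_molecules: int,
    seed: int | np.random.Generator,
    fluoride_mM: float = 10.0,
    terminator: TerminatorModel | None = None,
    pathway: FoldingPathway | None = None,
    template_id: int = 0,
) -> Population:
    """Simulate ``n_molecules`` single-round TECs on one template.

    Every molecule traverses the roadblocks in order of the stall position
    each would impose; run-through molecules may stall at later roadblocks
    (indistinguishable downstream).  Without fluoride, molecules reaching
    the terminator terminate with probability ``p_term`` at a length drawn
    uniformly from the termination window; antitermination dominates at
    10 mM fluoride.  Molecules passing everything run off at the template
    end (or stall there if a terminal roadblock is supplied).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    condition = "+F" if fluoride_mM > 0 else "-F"
    n = n_molecules

    # Candidate stall events, vectorised per roadblock.
    event_pos = np.full((len(roadblocks) + 1, n), np.iinfo(np.int64).max, dtype=np.int64)
    event_pushed = np.zeros_like(event_pos)
    event_rb = np.full((len(roadblocks) + 1, n), -1, dtype=np.int64)
    gln_sites = [rb.site for rb in roadblocks if rb.kind is RoadblockKind.GLN111]
    for j, rb in enumerate(roadblocks):
        if rb.site - rb.max_offset < 1:
            raise ValueError(f"roadblock at site {rb.site} too close to +1")
        success = rng.random(n) < rb.stall_prob
        ds = np.array(sorted(rb.offset_dist))
        ps = np.array([rb.offset_dist[d] for d in ds], dtype=float)
        d = rng.choice(ds, size=n, p=ps / ps.sum())
        pos = rb.site - d
        event_pos[j, success] = pos[success]
        event_pushed[j] = np.maximum(0, rb.modal_offset - d)
        event_rb[j, success] = j

    # Terminator as one more event.
    TERM_J = len(roadblocks)
    if terminator is not None:
        lo, hi = terminator.window
        fire = rng.random(n) < terminator.p_term(fluoride_mM)
        tpos = rng.integers(lo, hi + 1, size=n)
        event_pos[TERM_J, fire] = tpos[fire]
        event_rb[TERM_J, fire] = TERM_J

    # First successful event along the template wins.  Ties between a
    # roadblock stall and the terminator at the same position go to the
    # roadblock (RNAP stalls while still upstream of the release point).
    order = np.argsort(event_pos, axis=0, kind="stable")
    first = order[0]
    cols = np.arange(n)
    win_pos = event_pos[first, cols]
    win_j = event_rb[first, cols]

    L = np.empty(n, dtype=np.int64)
    fate = np.empty(n, dtype=object)
    rb_kind = np.empty(n, dtype=object)
    pushed = np.zeros(n, dtype=np.int64)
    b = np.zeros(n, dtype=np.int64)
    bound = np.ones(n, dtype=bool)

    none_mask = win_j < 0
    term_mask = (win_j == TERM_J) & ~none_mask
    stall_mask = ~none_mask & ~term_mask

    # run-through flag: at least one Gln111 roadblock upstream of the final
    # 3' end was passed without stalling
    run_through = np.zeros(n, dtype=bool)

    L[none_mask] = spec.target_length
    fate[none_mask] = FATE_RUNOFF
    rb_kind[none_mask] = None
    bound[none_mask] = False

    L[term_mask] = win_pos[term_mask]
    fate[term_mask] = FATE_TERMINATED
    rb_kind[term_mask] = None
    bound[term_mask] = False

    if stall_mask.any():
        idx = np.flatnonzero(stall_mask)
        L[idx] = win_pos[idx]
        fate[idx] = FATE_STALLED
        pushed[idx] = event_pushed[win_j[idx], idx]
        for j, rb in enumerate(roadblocks):
            sel = idx[win_j[idx] == j]
            if len(sel) == 0:
                continue
            rb_kind[np.asarray(sel)] = rb.kind
            # backtracking, vectorised over this roadblock's stalls
            ks = np.array(sorted(rb.backtrack_dist))
            ps = np.array([rb.backtrack_dist[k] for k in ks], dtype=float)
            draw = rng.choice(ks, size=len(sel), p=ps / ps.sum())
            if rb.kind is RoadblockKind.GLN111:
                bb = np.minimum(draw, 1)
            else:
                bb = np.minimum(draw, defaults.SAV_MAX_BACKTRACK_PRIMARY)
                bb = np.minimum(bb + pushed[sel], defaults.SAV_MAX_BACKTRACK_TOTAL)
            if pathway is not None:
                caps = np.array(
                    [pathway.backtrack_cap(int(l), condition) for l in L[sel]],
                    dtype=object,
                )
                has_cap = np.array([c is not None for c in caps])
                if has_cap.any():
                    capvals = np.array([c if c is not None else 0 for c in caps])
                    bb = np.where(has_cap, np.minimum(bb, capvals), bb)
            bb = np.minimum(bb, L[sel] - 1)
            b[sel] = bb

    # run-through bookkeeping for Gln111 experiments
    if gln_sites:
        for j, rb in enumerate(roadblocks):
            if rb.kind is not RoadblockKind.GLN111:
                continue
            passed = (event_rb[j] < 0) & (L >= rb.site)
            run_through |= passed

    return Population(
        template_id=np.full(n, template_id),
        L=L, b=b, fate=fate, bound=bound, pushed=pushed,
        roadblock=rb_kind, run_through=run_through,
    )


def pellet_partition(
    population: Population,
    rng: np.random.Generator | int,
    p_bound: float = defaults.P_BOUND,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition RNAs of a bead-immobilised reaction into pellet and
    supernatant index arrays.

    Stalled TECs pellet with probability ``p_bound``; terminated and
    run-off RNAs are released and always fractionate to the supernatant.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    stalled = population.stalled
    keep = rng.random(len(population)) < p_bound
    pellet = np.flatnonzero(stalled & keep)
    supernatant = np.flatnonzero(~(stalled & keep))
    return pellet, supernatant
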