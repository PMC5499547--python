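"""Cotranscriptional folding ground truth for a fluoride riboswitch.

The pathway is encoded as a table of structural elements, each switching
the flexibility class of a set of positions once a threshold amount of RNA
has *emerged* from RNAP.  Only the last ``f_rna + b`` nt of a nascent RNA
are inside the polymerase (RNA footprint ``f_rna`` plus backtrack depth
``b``); everything upstream is free to fold and accessible to the probe.

Thresholds are calibrated from observed Gln111 transition lengths using
f_rna = 14: a transition printed at transcript length T corresponds to an
emergence threshold E = T - 14, and reappears for a roadblock with
backtrack depth b at apparent length E + f_rna + b.

Default pathway (crcB-like coordinates):

* P1 stem (2-9 / 17-24) pairs as soon as both sides have emerged (E=25).
* P1 loop (11-16) is reactive until its pseudoknot partner, the lower
  terminator stem (42-47), emerges: PK1 forms at E=43 in both conditions.
  A10 and A22 report aptamer folding with the same threshold.
* 0 mM fluoride: the terminator hairpin winds at E=62, quenching the upper
  stem (52-55) and disrupting PK1 (P1 loop returns to high).  The folded
  hairpin abuts RNAP and blocks backtracking beyond 1 nt.
* 10 mM fluoride: the aptamer sequesters the lower stem; only a partial
  upper terminator stem forms at E=74 (52-55 drop to medium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from . import defaults

CLASSES = ("low", "medium", "high")
CLASS_CODE = {c: i for i, c in enumerate(CLASSES)}

CONDITION_PLUS = "+F"
CONDITION_MINUS = "-F"
_CONDITIONS = (CONDITION_PLUS, CONDITION_MINUS, "both")


def _positions(spans) -> tuple[int, ...]:
    """Expand a list of ints / [start, end] pairs into positions."""
    out: list[int] = []
    for item in spans:
        if isinstance(item, int):
            out.append(item)
        else:
            a, b = item
            out.extend(range(a, b + 1))
    return tuple(out)


@dataclass(frozen=True)
class StructuralElement:
    """One step of the folding pathway.

    When ``emerged >= threshold`` (and the condition matches), every
    position in ``effects`` switches to the stated flexibility class.
    ``caps_backtracking`` marks hairpins that, once folded, prevent RNAP
    from backtracking into them; ``fold_back_edge`` is the 3'-most paired
    position of the folded element.
    """

    name: str
    threshold: int
    effects: dict[int, str]
    condition: str = "both"
    caps_backtracking: bool = False
    fold_back_edge: int | None = None

    def __post_init__(self):
        if self.condition not in _CONDITIONS:
            raise ValueError(f"bad condition {self.condition!r}")
        for cls in self.effects.values():
            if cls not in CLASSES:
                raise ValueError(f"bad class {cls!r}")

    def active(self, emerged: int, condition: str) -> bool:
        if self.condition != "both" and self.condition != condition:
            return False
        return emerged >= self.threshold


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-position flexibility classes and modification rates."""

    classes: tuple[str, ...]
    rates: np.ndarray

    def __len__(self) -> int:
        return len(self.classes)


@dataclass
class FoldingPathway:
    """Element table plus class -> modification-rate mapping."""

    length: int
    elements: list[StructuralElement]
    rates: dict[str, float] = field(
        default_factory=lambda: dict(defaults.MODIFICATION_RATES)
    )
    baseline: str = "high"
    f_rna: int = defaults.F_RNA
    name: str = "pathway"

    def __post_init__(self):
        r = self.rates
        if not (0 < r["low"] < r["medium"] < r["high"] <= 0.2):
            raise ValueError("rates must satisfy 0 < low < medium < high <= 0.2")
        for el in self.elements:
            for pos in el.effects:
                if not 1 <= pos <= self.length:
                    raise ValueError(f"{el.name}: position {pos} outside [1, n]")

    # -- core queries ------------------------------------------------------

    def structure_at(self, emerged_length: int, condition: str) -> FlexibilityProfile:
        """Flexibility profile over positions 1..emerged_length.

        Deterministic: elements are applied in increasing threshold order,
        so later steps overwrite earlier ones on shared positions.
        """
        if emerged_length <= 0:
            return FlexibilityProfile(classes=(), rates=np.empty(0))
        n = min(emerged_length, self.length)
        classes = [self.baseline] * n
        for el in sorted(self.elements, key=lambda e: e.threshold):
            if el.active(emerged_length, condition):
                for pos, cls in el.effects.items():
                    if pos <= n:
                        classes[pos - 1] = cls
        rates = np.array([self.rates[c] for c in classes])
        return FlexibilityProfile(classes=tuple(classes), rates=rates)

    def rate_vector(self, emerged_length: int, condition: str) -> np.ndarray:
        return self.structure_at(emerged_length, condition).rates

    def backtrack_cap(self, L: int, condition: str) -> int | None:
        """Backtrack cap for a TEC stalled at 3'-end length ``L``.

        If a folded backtrack-blocking hairpin lies within
        ``STRUCTURE_CAP_WINDOW`` nt of the RNAP back edge (evaluated at the
        un-backtracked register), returns the capped depth; else None.
        """
        e0 = L - self.f_rna
        for el in self.elements:
            if not el.caps_backtracking:
                continue
            if not el.active(e0, condition):
                continue
            edge = el.fold_back_edge if el.fold_back_edge is not None else max(el.effects)
            if 0 <= e0 - edge <= defaults.STRUCTURE_CAP_WINDOW:
                return defaults.STRUCTURE_CAPPED_BACKTRACK
            return None
        return None


def emerged_length(L: int, b: int = 0, f_rna: int = defaults.F_RNA) -> int:
    """nt of nascent RNA that has emerged from RNAP.

    The last ``f_rna + b`` nt are sequestered inside the (possibly
    backtracked) enzyme; results below zero clamp to 0.
    """
    return max(0, L - (f_rna + b))


# -- element-table I/O ----------------------------------------------------


def pathway_from_dict(doc: dict) -> FoldingPathway:
    elements = []
    for item in doc["elements"]:
        effects = {}
        for eff in item["effects"]:
            for pos in _positions(eff["positions"]):
                effects[pos] = eff["class"]
        elements.append(
            StructuralElement(
                name=item["name"],
                threshold=int(item["threshold"]),
                effects=effects,
                condition=item.get("condition", "both"),
                caps_backtracking=bool(item.get("caps_backtracking", False)),
                fold_back_edge=item.get("fold_back_edge"),
            )
        )
    return FoldingPathway(
        length=int(doc["length"]),
        elements=elements,
        rates=dict(doc.get("rates", defaults.MODIFICATION_RATES)),
        baseline=doc.get("baseline", "high"),
        f_rna=int(doc.get("f_rna", defaults.F_RNA)),
        name=doc.get("name", "pathway"),
    )


def load_pathway(path) -> FoldingPathway:
    """Load a user element table (YAML)."""
    with open(path) as fh:
        return pathway_from_dict(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def fluoride_riboswitch_pathway() -> FoldingPathway:
    """The bundled fluoride-riboswitch-like pathway fixture."""
    text = resources.files("cotshape.data").joinpath("fluoride_riboswitch.yaml").read_text()
    return pathway_from_dict(yaml.safe_load(text))
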