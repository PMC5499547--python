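"""Biotinylated DNA template design.

Randomly biotinylated templates are produced by spiking biotin-11-dNTPs
into a PCR at a stoichiometry chosen to introduce, on average, ``m``
biotins per template:

    dNTP_bio(N) = m * dNTP_comb / (4 * N_count)

where ``N_count`` is the number of occurrences of base N across *both*
strands of the target-encoding region (reverse-primer span excluded) and
``dNTP_comb`` is the combined (biotinylated + plain) nmol of that dNTP.
Each incorporation of base N is then biotinylated independently with
probability ``m / (4 * N_count)``, so the total biotin count per template
is approximately Poisson with mean ``m``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import defaults
from .sequences import complement

log = logging.getLogger(__name__)

BASES = "ACGT"

TEMPLATE_STRAND = "template"
NONTEMPLATE_STRAND = "nontemplate"


@dataclass
class TemplateSpec:
    """A linear transcription template.

    ``nontemplate_sequence`` is the full nontemplate (sense) strand,
    including the promoter.  ``txn_start`` is the 1-based index of the +1
    nucleotide within that string; transcript coordinates count from +1.
    """

    nontemplate_sequence: str
    txn_start: int
    target_length: int
    terminal_biotin: bool = False
    ecoRI_pos: int | None = None  # transcript coord of the first G of GAATTC
    biotin_sites: list[tuple[int, str]] = field(default_factory=list)
    reverse_primer_length: int = defaults.REVERSE_PRIMER_LENGTH
    name: str = "template"

    def __post_init__(self) -> None:
        self.nontemplate_sequence = self.nontemplate_sequence.upper()
        if self.txn_start < 1 or self.txn_start > len(self.nontemplate_sequence):
            raise ValueError("txn_start outside sequence")
        if self.txn_start + self.target_length - 1 > len(self.nontemplate_sequence):
            raise ValueError("target_length overruns template sequence")
        for pos, strand in self.biotin_sites:
            if not 1 <= pos <= self.target_length:
                raise ValueError(f"biotin site {pos} outside [1, n]")
            if strand not in (TEMPLATE_STRAND, NONTEMPLATE_STRAND):
                raise ValueError(f"bad strand {strand!r}")

    # -- coordinate helpers ------------------------------------------------

    def transcript(self, length: int | None = None) -> str:
        """Sense sequence of the transcript (DNA alphabet), 1..length."""
        if length is None:
            length = self.target_length
        start = self.txn_start - 1
        return self.nontemplate_sequence[start : start + length]

    def target_region(self) -> str:
        """Nontemplate strand of the target-encoding region used for
        biotin bookkeeping: transcript coordinates 1..n minus the
        reverse-primer span at the 3' end."""
        end = max(0, self.target_length - self.reverse_primer_length)
        return self.transcript(end)


@dataclass
class BiotinRecipe:
    """Per-base biotin-11-dNTP amounts for a randomly biotinylated PCR."""

    n_count: dict[str, int]
    dntp_comb: float  # nmol, per base
    dntp_bio: dict[str, float]  # nmol
    multiplicity: float

    @property
    def dntp_plain(self) -> dict[str, float]:
        return {b: self.dntp_comb - self.dntp_bio[b] for b in BASES}

    def incorporation_probability(self, base: str) -> float:
        """Probability that a single incorporation of ``base`` is biotinylated."""
        n = self.n_count[base]
        if n == 0:
            return 0.0
        return self.multiplicity / (4.0 * n)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "base": list(BASES),
                "N_count": [self.n_count[b] for b in BASES],
                "dNTP_bio_nmol": [self.dntp_bio[b] for b in BASES],
                "dNTP_plain_nmol": [self.dntp_plain[b] for b in BASES],
            }
        )


def count_bases_both_strands(region: str) -> dict[str, int]:
    """Occurrences of each base across both strands of ``region``.

    Counting the complement strand is equivalent to adding the count of the
    complementary base on the given strand: N_count(A) = #A + #T.
    """
    region = region.upper()
    both = region + complement(region)
    return {b: both.count(b) for b in BASES}


def compute_biotin_recipe(region: str, dntp_comb: float, m: float) -> BiotinRecipe:
    """Per-base biotin-11-dNTP amounts for target multiplicity ``m``.

    ``region`` is the nontemplate strand of the target-encoding region
    (both strands are counted internally).  ``dntp_comb`` is the combined
    nmol of each dNTP fixed by the PCR condition.
    """
    if not region:
        raise ValueError("empty region")
    if dntp_comb <= 0:
        raise ValueError("dntp_comb must be positive")
    if m < 0:
        raise ValueError("multiplicity must be >= 0")
    n_count = count_bases_both_strands(region)
    dntp_bio: dict[str, float] = {}
    for b in BASES:
        if n_count[b] == 0:
            warnings.warn(
                f"base {b} absent from both strands of the region; "
                f"dNTP_bio({b}) set to 0",
                stacklevel=2,
            )
            dntp_bio[b] = 0.0
            continue
        amount = m * dntp_comb / (4.0 * n_count[b])
        if amount > dntp_comb:
            raise ValueError(
                f"multiplicity {m} demands {amount:.3g} nmol biotin-11-d{b}TP, "
                f"more than the {dntp_comb:.3g} nmol combined pool"
            )
        dntp_bio[b] = amount
    return BiotinRecipe(n_count=n_count, dntp_comb=dntp_comb, dntp_bio=dntp_bio, multiplicity=m)


def _eligible_positions(spec: TemplateSpec) -> list[tuple[int, str, str]]:
    """(transcript coord, strand, incorporated base) for every eligible
    incorporation.  Eligible positions are both strands of the
    target-encoding region; the promoter (forward primer, -45..-1) and the
    reverse-primer span are covered by unmodified primers and excluded."""
    region = spec.target_region()
    out = []
    for i, base in enumerate(region, start=1):
        out.append((i, NONTEMPLATE_STRAND, base))
        # the template strand incorporates the complement at this duplex position
        out.append((i, TEMPLATE_STRAND, complement(base)))
    return out


def sample_biotin_positions(
    spec: TemplateSpec,
    m: float,
    rng: np.random.Generator | int,
) -> TemplateSpec:
    """Sample random biotin incorporations onto one template molecule.

    Each eligible incorporation of base N is biotinylated independently
    with probability m / (4 * N_count(N)), giving an expected total of m
    biotins per template.  Returns a copy of ``spec`` with
    ``biotin_sites`` filled; deterministic for a fixed seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if m < 0:
        raise ValueError("multiplicity must be >= 0")
    region = spec.target_region()
    n_count = count_bases_both_strands(region)
    probs = {}
    for b in BASES:
        if n_count[b] == 0:
            probs[b] = 0.0
            continue
        p = m / (4.0 * n_count[b])
        if p > 1.0:
            raise ValueError(
                f"multiplicity {m} implies per-incorporation probability "
                f"{p:.3g} > 1 for base {b}"
            )
        probs[b] = p
    sites: list[tuple[int, str]] = []
    if m > 0:
        eligible = _eligible_positions(spec)
        draws = rng.random(len(eligible))
        for (pos, strand, base), u in zip(eligible, draws):
            if u < probs[base]:
                sites.append((pos, strand))
    return replace(spec, biotin_sites=sites)


def load_template_fasta(path, **kwargs) -> TemplateSpec:
    """Read a single-record FASTA as a TemplateSpec.

    The record is taken as the full nontemplate strand.  ``txn_start`` and
    ``target_length`` may be passed as keyword arguments; by default the
    whole record minus a 45-nt promoter prefix is the target.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single-record FASTA, found {len(records)}")
    seq = str(records[0].seq).upper()
    txn_start = kwargs.pop("txn_start", 46 if len(seq) > 45 else 1)
    target_length = kwargs.pop("target_length", len(seq) - txn_start + 1)
    return TemplateSpec(
        nontemplate_sequence=seq,
        txn_start=txn_start,
        target_length=target_length,
        name=records[0].id,
        **kwargs,
    )
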