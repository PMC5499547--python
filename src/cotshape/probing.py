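"""Single-hit SHAPE probing and paired-end read simulation.

Nascent RNAs are treated with a fast-acting acylating probe ((+) channel)
or solvent only ((-) channel).  Each unprotected position is modified
independently at its flexibility-class rate; the last ``f_rna + b`` nt of
a stalled TEC's RNA sit inside RNAP and are never modified.  Reverse
transcription initiates on a 3'-ligated linker and halts one nt 3' of the
most 3' modification it encounters; at every position it may also stop
spuriously at a background rate shared by both channels.  Stop position
k = 0 denotes full-length extension to +1.

The single-hit regime is enforced by the rate magnitudes, not by
truncating to one modification: RT's 3'-most-stop rule makes extra hits
invisible, mirroring the chemistry.

Reads follow the 3'-linker-anchored paired-end layout: read 1 starts at
the cDNA terminus (sense sequence from position k+1, running into the
linker for short fragments) and read 2 starts with the reverse complement
of the linker followed by the transcript 3' sequence, anchoring the
transcript length.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np

from . import defaults
from .folding import FoldingPathway, emerged_length
from .sequences import revcomp

log = logging.getLogger(__name__)

CHANNEL_PLUS = "plus"
CHANNEL_MINUS = "minus"


@dataclass
class ProbeConfig:
    """Probing and library-construction parameters."""

    background_rate: float = defaults.BACKGROUND_STOP_RATE
    linker: str = defaults.LINKER
    read_length: int = defaults.READ_LENGTH
    ligation_bias_sigma: float = defaults.LIGATION_BIAS_SIGMA
    #: optional uniform per-base substitution rate for robustness tests
    sequencing_error_rate: float = 0.0

    def __post_init__(self):
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate outside [0, 1)")

    def ligation_weights(
        self, lengths: np.ndarray, rng: np.random.Generator
    ) -> dict[int, float]:
        """Per-transcript-length ligation efficiencies.

        Relative efficiencies are log-normal (median 1, sigma on the log
        scale) clipped at 1, modelling lengths that ligate at the maximum
        achievable efficiency alongside disfavoured ones.
        """
        lengths = np.unique(np.asarray(lengths))
        if self.ligation_bias_sigma <= 0:
            return {int(L): 1.0 for L in lengths}
        w = np.exp(rng.normal(0.0, self.ligation_bias_sigma, size=len(lengths)))
        w = np.minimum(w, 1.0)
        return {int(L): float(x) for L, x in zip(lengths, w)}


# -- single-molecule operations (reference implementations) ----------------


def modify(
    length: int,
    protected: int,
    rates: np.ndarray,
    rng: np.random.Generator,
    channel: str = CHANNEL_PLUS,
) -> np.ndarray:
    """Positions (1-based) modified on one molecule.

    ``protected`` is the number of 3'-terminal nt inside RNAP; ``rates``
    gives the per-position modification rate over the emerged prefix.
    (-) channel molecules carry no modifications.
    """
    if channel == CHANNEL_MINUS:
        return np.empty(0, dtype=np.int64)
    n_open = max(0, length - protected)
    r = np.zeros(length)
    r[:n_open] = rates[:n_open]
    hits = rng.random(length) < r
    return np.flatnonzero(hits) + 1


def reverse_transcribe(
    length: int,
    modified: np.ndarray,
    background_rate: float,
    rng: np.random.Generator,
) -> int:
    """RT stop position k in {0..L} for one molecule.

    RT proceeds from the 3' end toward +1, halting at the 3'-most modified
    position encountered; at every position it may also stop spuriously at
    the background rate.  k = 0 is full-length extension.
    """
    spurious = np.flatnonzero(rng.random(length) < background_rate) + 1
    stops = np.concatenate([np.asarray(modified, dtype=np.int64), spurious])
    return int(stops.max()) if len(stops) else 0


def stop_distribution(hazards: np.ndarray) -> np.ndarray:
    """Exact distribution of the RT stop position given per-position
    stop hazards h_1..h_L: P(k) = h_k * prod_{j>k}(1 - h_j), P(0) is the
    full-length survival.  Index 0 of the result is k = 0."""
    L = len(hazards)
    surv = np.ones(L + 1)
    if L:
        surv[:-1] = np.cumprod((1.0 - hazards)[::-1])[::-1]
    p = np.empty(L + 1)
    p[0] = surv[0]
    p[1:] = hazards * surv[1:]
    return p


def combined_hazards(
    length: int, protected: int, rates: np.ndarray, background: float
) -> np.ndarray:
    """Per-position RT stop hazards for a (+) channel molecule: chemistry
    on the emerged prefix plus background everywhere."""
    h = np.full(length, background, dtype=float)
    n_open = max(0, length - protected)
    r = rates[:n_open]
    h[:n_open] = 1.0 - (1.0 - r) * (1.0 - background)
    return h


# -- population-scale stop sampling ---------------------------------------


@dataclass
class MoleculeRecord:
    """Per-molecule data carried into FASTQ generation."""

    seq: str  # sense sequence of the full nascent RNA (1..L)
    L: int
    stop: int  # RT stop k, 0..L
    channel: str


def sample_stop_counts(
    groups: list[tuple[np.ndarray, int]],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Multinomial RT-stop counts for groups of identical molecules.

    ``groups`` is a list of (hazard vector, n_molecules); returns one
    count vector (length L+1, index 0 = full length) per group.  Exact
    because molecules within a group are iid.
    """
    out = []
    for hazards, n in groups:
        p = stop_distribution(hazards)
        out.append(rng.multinomial(n, p))
    return out


def molecule_hazards(
    L: int,
    b: int,
    stalled: bool,
    pathway: FoldingPathway,
    condition: str,
    config: ProbeConfig,
    channel: str,
) -> np.ndarray:
    """Stop-hazard vector for one molecule class.

    Stalled TECs expose only the emerged prefix (protection f_rna + b);
    released RNAs (terminated / run-off) are probed in full.
    """
    if channel == CHANNEL_MINUS:
        return np.full(L, config.background_rate)
    protected = (pathway.f_rna + b) if stalled else 0
    emerged = emerged_length(L, b, pathway.f_rna) if stalled else L
    rates = np.full(L, pathway.rates[pathway.baseline])
    prof = pathway.rate_vector(emerged, condition)
    k = min(len(prof), L)
    rates[:k] = prof[:k]
    return combined_hazards(L, protected, rates, config.background_rate)


# -- FASTQ emission --------------------------------------------------------


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = rng.choice([c for c in "ACGT" if c != chars[i]])
    return "".join(chars)


def read_pair(molecule: MoleculeRecord, config: ProbeConfig) -> tuple[str, str]:
    """Sequences of the two mates for one molecule.

    The sequenced insert is RNA[k+1..L] + linker.  Read 1 reads the insert
    in sense orientation from position k+1; read 2 reads it from the
    linker end in reverse complement.  Reads truncate pad-free when the
    insert is shorter than the read length.
    """
    insert = molecule.seq[molecule.stop : molecule.L] + config.linker
    r1 = insert[: config.read_length]
    r2 = revcomp(insert)[: config.read_length]
    return r1, r2


def generate_fastq(
    molecules: list[MoleculeRecord],
    config: ProbeConfig,
    out_prefix,
    rng: np.random.Generator,
    bias_weights: dict[int, float] | None = None,
    gz: bool = False,
) -> dict[str, tuple[str, str]]:
    """Write paired FASTQ for each channel; returns {channel: (r1, r2)}.

    Molecules are subsampled per transcript length by the ligation-bias
    weights (probability = relative ligation efficiency).  Qualities are
    fixed.  Deterministic under a fixed generator state.
    """
    if bias_weights is None:
        lengths = np.array([m.L for m in molecules], dtype=np.int64)
        bias_weights = config.ligation_weights(lengths, rng)
    keep_u = rng.random(len(molecules))
    err_rng = rng

    paths: dict[str, tuple[str, str]] = {}
    handles = {}
    opener = gzip.open if gz else open
    suffix = ".fastq.gz" if gz else ".fastq"
    for channel, tag in ((CHANNEL_PLUS, "plus"), (CHANNEL_MINUS, "minus")):
        p1 = f"{out_prefix}_{tag}_R1{suffix}"
        p2 = f"{out_prefix}_{tag}_R2{suffix}"
        handles[channel] = (opener(p1, "wt"), opener(p2, "wt"))
        paths[channel] = (p1, p2)

    n_written = 0
    for i, mol in enumerate(molecules):
        if keep_u[i] >= bias_weights.get(mol.L, 1.0):
            continue
        r1, r2 = read_pair(mol, config)
        if config.sequencing_error_rate > 0:
            r1 = _mutate(r1, config.sequencing_error_rate, err_rng)
            r2 = _mutate(r2, config.sequencing_error_rate, err_rng)
        h1, h2 = handles[mol.channel]
        name = f"@cotshape:{i}"
        h1.write(f"{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
        h2.write(f"{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
        n_written += 1

    for h1, h2 in handles.values():
        h1.close()
        h2.close()
    log.info("wrote %d read pairs (of %d molecules)", n_written, len(molecules))
    return paths
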