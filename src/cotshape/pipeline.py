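"""Demultiplexing, RT-stop counting and reactivity estimation.

Paired reads are resolved into (transcript length L, RT stop k) pairs:
read 2 is linker-stripped and matched to the target 3' sequence to fix L,
and read 1 fixes the cDNA terminus at k+1.  Stops are accumulated per
length into (+) and (-) channel tables, and per-length reactivities are
estimated with a log-survival maximum-likelihood estimator: positional
stop hazards

    beta_k = c+_k / (c+_0 + sum_{j<=k} c+_j)     (and gamma_k from c-)

combine into raw reactivities theta~_k = max(0, ln(1-gamma_k) -
ln(1-beta_k)), normalised so that sum(theta) = 1; rho_k = L * theta_k has
mean 1 over the transcript.  Because each length is normalised
internally, per-length read abundances (ligation bias) cannot change a
profile.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import defaults
from .sequences import ECORI_SITE, hamming, revcomp

log = logging.getLogger(__name__)

DROP_NO_LINKER = "no_linker"
DROP_NO_MATCH = "no_match"
DROP_RUN_THROUGH = "run_through"
DROP_SHORT = "too_short"


@dataclass
class StopCountTable:
    """RT-stop counts per transcript length for one channel.

    ``counts[L]`` is a vector over k = 0..L; k = 0 is the full-length
    cDNA bucket.
    """

    channel: str
    counts: dict[int, np.ndarray] = field(default_factory=dict)
    dropped: Counter = field(default_factory=Counter)

    def add(self, L: int, k: int, n: int = 1) -> None:
        if L not in self.counts:
            self.counts[L] = np.zeros(L + 1, dtype=np.int64)
        self.counts[L][k] += n

    def lengths(self) -> list[int]:
        return sorted(self.counts)

    def total_assigned(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for L in self.lengths():
            for k, c in enumerate(self.counts[L]):
                if c:
                    rows.append((L, k, int(c)))
        return pd.DataFrame(rows, columns=["length", "stop", "count"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# cotshape stop counts; 1-based transcript coordinates, +1 frame; "
                "stop=0 is the full-length cDNA bucket\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, channel: str = "?") -> "StopCountTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        table = cls(channel=channel)
        for _, row in df.iterrows():
            table.add(int(row["length"]), int(row["stop"]), int(row["count"]))
        return table


class _TargetIndex:
    """Exact k-mer lookup tables over the target, built lazily per width."""

    def __init__(self, target: str):
        self.target = target
        self._starts: dict[int, dict[str, list[int]]] = {}
        self._suffixes: dict[int, dict[str, list[int]]] = {}

    def starts(self, w: int) -> dict[str, list[int]]:
        if w not in self._starts:
            idx: dict[str, list[int]] = {}
            for i in range(len(self.target) - w + 1):
                idx.setdefault(self.target[i : i + w], []).append(i)
            self._starts[w] = idx
        return self._starts[w]

    def suffix_ends(self, w: int) -> dict[str, list[int]]:
        """Map w-mer -> list of lengths L with target[L-w:L] == w-mer."""
        if w not in self._suffixes:
            idx: dict[str, list[int]] = {}
            for L in range(w, len(self.target) + 1):
                idx.setdefault(self.target[L - w : L], []).append(L)
            self._suffixes[w] = idx
        return self._suffixes[w]


def _resolve_length(
    payload: str, index: _TargetIndex, max_mismatch: int
) -> tuple[int | None, int]:
    """Transcript length from the linker-stripped read-2 payload.

    The reverse complement of the payload is the transcript 3' sequence
    ending at L.  Ties are broken by fewest mismatches, then longest L.
    Returns (L, mismatches) or (None, -1).
    """
    rc = revcomp(payload)
    w = len(rc)
    hits = index.suffix_ends(w).get(rc)
    if hits:
        return max(hits), 0
    if max_mismatch > 0:
        target = index.target
        best, best_mm = None, max_mismatch + 1
        for L in range(w, len(target) + 1):
            mm = hamming(target[L - w : L], rc)
            if mm < best_mm or (mm == best_mm and best is not None and L > best):
                if mm <= max_mismatch:
                    best, best_mm = L, mm
        if best is not None:
            return best, best_mm
    return None, -1


def _resolve_stop(
    read1: str, L: int, index: _TargetIndex, linker: str, max_mismatch: int
) -> tuple[int | None, int]:
    """RT stop k from read 1 given the transcript length L.

    Read 1 is the sense sequence from position k+1, running into the
    linker when the insert is shorter than the read.  Returns (k, mm).
    """
    target = index.target
    w = len(read1)
    # Exact pure-target case: fragment at least as long as the read.
    if w <= L:
        hits = index.starts(w).get(read1)
        if hits:
            cands = [p for p in hits if p + w <= L]
            if cands:
                return min(cands), 0
    # Exact junction case: read1 = target[L-f:L] + linker[:w-f], fragment f.
    fmin = max(1, w - len(linker))
    fmax = min(w, L)
    for f in range(fmin, fmax + 1):
        if target[L - f : L] + linker[: w - f] == read1:
            return L - f, 0
    if max_mismatch <= 0:
        return None, -1
    # Mismatch-tolerant fallbacks (rare; only with sequencing errors).
    best, best_mm = None, max_mismatch + 1
    for f in range(fmin, fmax + 1):
        expect = target[L - f : L] + linker[: w - f]
        if len(expect) != w:
            continue
        mm = hamming(expect, read1)
        if mm < best_mm:
            best, best_mm = L - f, mm
    if best_mm > 0 and w <= L:
        for p in range(0, L - w + 1):
            mm = hamming(target[p : p + w], read1)
            if mm < best_mm:
                best, best_mm = p, mm
    if best is not None and best_mm <= max_mismatch:
        return best, best_mm
    return None, -1


def demultiplex(
    fastq1,
    fastq2,
    target: str,
    linker: str = defaults.LINKER,
    max_mismatch: int = 1,
    channel: str = "?",
    gln111_mode: bool = False,
    min_payload: int = 12,
) -> StopCountTable:
    """Resolve a paired FASTQ into an RT-stop count table.

    Pairs failing the linker check or the mismatch budget are dropped and
    tallied by cause.  Payloads shorter than ``min_payload`` (RT stops a
    few nt from the 3' end, inside the RNAP-protected span) are dropped as
    unmappable rather than risk a spurious length assignment.  In Gln111
    mode, reads whose sequence crosses into the EcoRI cassette (roadblock
    run-through products carrying non-native sequence) fail to match the
    target and are tallied as run-through.
    """
    target = target.upper()
    index = _TargetIndex(target)
    rc_linker = revcomp(linker)
    table = StopCountTable(channel=channel)

    with open(fastq1) as f1, open(fastq2) as f2:
        for (t1, s1, _q1), (t2, s2, _q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            if t1.split("/")[0] != t2.split("/")[0]:
                raise ValueError(f"mate-pair order broken at {t1} / {t2}")
            head = s2[: len(rc_linker)]
            if head != rc_linker and (
                len(head) < len(rc_linker) or hamming(head, rc_linker) > max_mismatch
            ):
                table.dropped[DROP_NO_LINKER] += 1
                continue
            payload = s2[len(rc_linker) :]
            if len(payload) < min_payload:
                table.dropped[DROP_SHORT] += 1
                continue
            L, _mm2 = _resolve_length(payload, index, max_mismatch)
            if L is None:
                if gln111_mode and (
                    ECORI_SITE in revcomp(payload) or ECORI_SITE in s1
                ):
                    table.dropped[DROP_RUN_THROUGH] += 1
                else:
                    table.dropped[DROP_NO_MATCH] += 1
                continue
            k, _mm1 = _resolve_stop(s1, L, index, linker, max_mismatch)
            if k is None:
                table.dropped[DROP_NO_MATCH] += 1
                continue
            table.add(L, k)
    return table


# -- reactivity estimation -------------------------------------------------


@dataclass
class ReactivityProfile:
    """Normalised reactivities for one transcript length."""

    length: int
    theta: np.ndarray  # k = 1..L
    low_signal: bool = False

    @property
    def rho(self) -> np.ndarray:
        return self.length * self.theta


def estimate_reactivity(
    c_plus: np.ndarray,
    c_minus: np.ndarray,
    L: int | None = None,
    min_reads: int = defaults.MIN_READS_PER_LENGTH,
) -> ReactivityProfile:
    """Log-survival ML reactivity estimate from (+)/(-) stop counts.

    ``c_plus`` and ``c_minus`` are vectors over k = 0..L.  Hazards with no
    surviving reads (beta = 1) are clamped with a half-count pseudocount.
    A profile with no differential signal, or with fewer than
    ``min_reads`` in either channel, is returned all-zero and flagged.
    """
    c_plus = np.asarray(c_plus, dtype=float)
    c_minus = np.asarray(c_minus, dtype=float)
    if L is None:
        L = len(c_plus) - 1
    if len(c_plus) != L + 1 or len(c_minus) != L + 1:
        raise ValueError("count vectors must have length L + 1")
    tot_p, tot_m = c_plus.sum(), c_minus.sum()
    if tot_p == 0 or tot_m == 0:
        raise ValueError("each channel needs at least one read")

    def hazards(c):
        reached = c[0] + np.cumsum(c[1:])  # reads that reached position k
        h = np.zeros(L)
        nz = reached > 0
        h[nz] = c[1:][nz] / reached[nz]
        sat = h >= 1.0
        if sat.any():
            warnings.warn(
                "saturated hazard (no surviving reads); clamped with pseudocount",
                stacklevel=3,
            )
            h[sat] = c[1:][sat] / (reached[sat] + 0.5)
        return h

    beta = hazards(c_plus)
    gamma = hazards(c_minus)
    raw = np.log1p(-gamma) - np.log1p(-beta)
    raw = np.maximum(raw, 0.0)
    total = raw.sum()
    low = (total == 0.0) or (tot_p < min_reads) or (tot_m < min_reads)
    theta = raw / total if total > 0 else np.zeros(L)
    return ReactivityProfile(length=L, theta=theta, low_signal=low)


@dataclass
class ReactivityMatrix:
    """Stacked per-length rho profiles: lengths x positions, NA above the
    diagonal.  ``data`` rows are indexed by transcript length."""

    data: pd.DataFrame
    low_signal: dict[int, bool] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def lengths(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def rho(self, L: int) -> np.ndarray:
        return self.data.loc[L].to_numpy()[:L]

    def good_lengths(self) -> list[int]:
        return [int(L) for L in self.lengths if not self.low_signal.get(int(L), False)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cond = self.metadata.get("condition", "NA")
            fh.write(
                f"# cotshape reactivity matrix (rho); rows = transcript length, "
                f"columns = 1-based position (+1 frame); condition={cond}\n"
            )
            df = self.data.copy()
            df.insert(0, "low_signal", [int(self.low_signal.get(int(L), False)) for L in df.index])
            df.to_csv(fh, sep="\t", na_rep="NA", index_label="length")

    @classmethod
    def from_tsv(cls, path) -> "ReactivityMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="length")
        low = {int(L): bool(v) for L, v in df["low_signal"].items()}
        df = df.drop(columns=["low_signal"])
        df.columns = df.columns.astype(int)
        return cls(data=df, low_signal=low)


def assemble_matrix(
    profiles: list[ReactivityProfile],
    metadata: dict | None = None,
    drop_low_signal: bool = False,
) -> ReactivityMatrix:
    """Stack per-length profiles into a reactivity matrix.

    Rows are sorted by length; cells above the diagonal are NA.  Duplicate
    lengths are an error.  Low-signal rows are kept and flagged by
    default.
    """
    if not profiles:
        raise ValueError("no profiles to assemble")
    lengths = [p.length for p in profiles]
    if len(set(lengths)) != len(lengths):
        raise ValueError("duplicate transcript lengths")
    if drop_low_signal:
        profiles = [p for p in profiles if not p.low_signal]
    profiles = sorted(profiles, key=lambda p: p.length)
    n = max(p.length for p in profiles)
    data = np.full((len(profiles), n), np.nan)
    for i, p in enumerate(profiles):
        data[i, : p.length] = p.rho
    df = pd.DataFrame(data, index=[p.length for p in profiles], columns=range(1, n + 1))
    missing = sorted(set(range(min(lengths), max(lengths) + 1)) - set(lengths))
    meta = dict(metadata or {})
    meta["missing_lengths"] = missing
    return ReactivityMatrix(
        data=df,
        low_signal={p.length: p.low_signal for p in profiles},
        metadata=meta,
    )


def matrix_from_tables(
    plus: StopCountTable,
    minus: StopCountTable,
    metadata: dict | None = None,
    min_reads: int = defaults.MIN_READS_PER_LENGTH,
) -> ReactivityMatrix:
    """Estimate every common length and assemble the reactivity matrix."""
    profiles = []
    for L in sorted(set(plus.counts) & set(minus.counts)):
        profiles.append(
            estimate_reactivity(plus.counts[L], minus.counts[L], L, min_reads=min_reads)
        )
    return assemble_matrix(profiles, metadata=metadata)


def aligned_read_distribution(
    table: StopCountTable, full_length: int | None = None
) -> pd.Series:
    """%Aligned reads per transcript length from the (-) channel.

    Unmodified-channel reads aligned at each length divided by total
    unmodified reads aligned, as a percentage.  The terminally
    roadblocked (full-template) length is reported as the separate
    category ``full_length`` so internal stops remain visible.
    """
    total = table.total_assigned()
    if total == 0:
        raise ValueError("no aligned reads")
    pct = {}
    for L in table.lengths():
        key = "full_length" if (full_length is not None and L == full_length) else L
        pct[key] = pct.get(key, 0.0) + 100.0 * table.counts[L].sum() / total
    return pd.Series(pct, name="pct_aligned")


def rmdb_export(matrix: ReactivityMatrix, path, name: str = "cotshape") -> None:
    """Flat-text reactivity export in an RMDB-flavoured layout: one line
    per transcript length with tab-separated rho values."""
    with open(path, "w") as fh:
        fh.write(f"NAME\t{name}\n")
        fh.write("COMMENT\tcotranscriptional reactivity matrix; rho per position\n")
        for L in matrix.lengths:
            vals = "\t".join(f"{v:.4f}" for v in matrix.rho(int(L)))
            fh.write(f"REACTIVITY:{int(L)}\t{vals}\n")
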