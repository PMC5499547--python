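"""Experiment-level simulation and the end-to-end pipeline.

Two library designs are modelled:

* **SAv**: every template molecule carries its own random biotin
  incorporations (both strands, Poisson-like count with mean ``m``) plus
  an optional terminal template-strand biotin; streptavidin roadblocks
  distribute stalled TECs across all transcript lengths.
* **Gln111**: a template library places an EcoRI site after every native
  prefix; the catalytically dead EcoRI(E111Q) roadblock stalls RNAP 14 nt
  upstream of the site.  Run-through TECs transcribe into the non-native
  cassette and their reads are discarded at alignment.

Both feed the same probing, read-generation and analysis stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, defaults
from .folding import FoldingPathway, fluoride_riboswitch_pathway, load_pathway
from .pipeline import (
    ReactivityMatrix,
    StopCountTable,
    aligned_read_distribution,
    demultiplex,
    matrix_from_tables,
)
from .probing import (
    CHANNEL_MINUS,
    CHANNEL_PLUS,
    MoleculeRecord,
    ProbeConfig,
    generate_fastq,
    molecule_hazards,
    stop_distribution,
)
from .sequences import CASSETTE, SYNTHETIC_PROMOTER, SYNTHETIC_TARGET
from .tec import (
    FATE_RUNOFF,
    FATE_STALLED,
    FATE_TERMINATED,
    Population,
    RoadblockKind,
    TerminatorModel,
)
from .templates import count_bases_both_strands

log = logging.getLogger(__name__)

MODE_SAV = "sav"
MODE_GLN111 = "gln111"

#: Standard transition-detection settings for the bundled riboswitch
#: pathway.  Trace windows start once the region has fully emerged from
#: RNAP for the relevant roadblock chemistry (region end + f_rna + max
#: backtrack, rounded up to leave a clean pre-plateau); the terminator
#: window stops short of the sparsely covered post-termination lengths,
#: and terminated lengths are excluded because released RNAs are probed
#: without an RNAP footprint.
TRANSITION_PRESETS: dict[str, dict] = {
    "PK1": dict(region=(11, 16), direction="decrease", lengths=(40, 100)),
    "partial_terminator": dict(region=(52, 55), direction="decrease", lengths=(70, 100)),
    "terminator": dict(
        region=(52, 55),
        direction="decrease",
        lengths=(69, 85),
        exclude_lengths=(80, 81, 82),
    ),
}


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulated experiment."""

    mode: str = MODE_SAV
    fluoride_mM: float = 10.0
    n_molecules: int = 100_000
    biotin_multiplicity: float = 1.0
    terminal_biotin: bool = True
    #: Gln111 library stall coverage: EcoRI sites give stalls at every
    #: length in this inclusive range
    gln_length_range: tuple[int, int] = (21, 100)
    seeds: dict = field(default_factory=dict)
    target_fasta: str | None = None  # default: bundled synthetic target
    pathway_file: str | None = None  # default: bundled riboswitch pathway
    probe: dict = field(default_factory=dict)
    out_dir: str = "cotshape_out"
    name: str = "run"

    REQUIRED_SEEDS = ("biotin", "transcription", "probing", "ligation")

    def validate(self) -> None:
        if self.mode not in (MODE_SAV, MODE_GLN111):
            raise ValueError(f"mode must be '{MODE_SAV}' or '{MODE_GLN111}'")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.biotin_multiplicity < 0:
            raise ValueError("biotin_multiplicity must be >= 0")
        missing = [s for s in self.REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ValueError(f"missing explicit seeds for stages: {missing}")

    @classmethod
    def from_master_seed(cls, seed: int, **kwargs) -> "RunConfig":
        """Derive one explicit seed per stochastic stage from a master seed."""
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(cls.REQUIRED_SEEDS))
        seeds = {
            name: int(child.generate_state(1)[0] % (2**31 - 1))
            for name, child in zip(cls.REQUIRED_SEEDS, children)
        }
        return cls(seeds=seeds, **kwargs)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["gln_length_range"] = list(self.gln_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "gln_length_range" in doc:
            doc["gln_length_range"] = tuple(doc["gln_length_range"])
        return cls(**doc)

    # -- resolved resources ----------------------------------------------

    def resolve_target(self) -> tuple[str, str]:
        """(promoter, native target) sequences."""
        if self.target_fasta is None:
            return SYNTHETIC_PROMOTER, SYNTHETIC_TARGET
        from .templates import load_template_fasta

        spec = load_template_fasta(self.target_fasta)
        promoter = spec.nontemplate_sequence[: spec.txn_start - 1]
        return promoter, spec.transcript()

    def resolve_pathway(self) -> FoldingPathway:
        if self.pathway_file is None:
            return fluoride_riboswitch_pathway()
        return load_pathway(self.pathway_file)

    def probe_config(self) -> ProbeConfig:
        return ProbeConfig(**self.probe)

    @property
    def condition(self) -> str:
        return "+F" if self.fluoride_mM > 0 else "-F"


# --------------------------------------------------------------------------
# population simulation (vectorised experiment designs)
# --------------------------------------------------------------------------

_KIND_PRIORITY = {
    RoadblockKind.SAV_TEMPLATE: 0,
    RoadblockKind.SAV_NONTEMPLATE: 0,
    RoadblockKind.GLN111: 0,
    RoadblockKind.TERMINAL_SAV: 2,
}
_TERMINATOR_PRIORITY = 1  # roadblock stall wins a positional tie


def _first_event_population(
    n: int,
    mol: np.ndarray,
    pos: np.ndarray,
    kind: np.ndarray,
    pushed: np.ndarray,
    priority: np.ndarray,
    runoff_length: np.ndarray,
    pathway: FoldingPathway | None,
    condition: str,
    rng: np.random.Generator,
    gln_passed: np.ndarray | None = None,
) -> Population:
    """Resolve per-molecule candidate stall/termination events into fates.

    ``kind`` uses -1 for the terminator; other values index RoadblockKind.
    Molecules without any successful event run off at ``runoff_length``.
    """
    kinds = list(RoadblockKind)
    L = runoff_length.copy()
    fate = np.full(n, FATE_RUNOFF, dtype=object)
    rb = np.full(n, None, dtype=object)
    out_pushed = np.zeros(n, dtype=np.int64)
    b = np.zeros(n, dtype=np.int64)
    bound = np.zeros(n, dtype=bool)

    if len(mol):
        order = np.lexsort((priority, pos, mol))
        mol_s = mol[order]
        first_idx = order[np.unique(mol_s, return_index=True)[1]]
        win_mol = mol[first_idx]
        L[win_mol] = pos[first_idx]
        is_term = kind[first_idx] < 0
        term_mol = win_mol[is_term]
        fate[term_mol] = FATE_TERMINATED
        stall_mol = win_mol[~is_term]
        stall_evt = first_idx[~is_term]
        fate[stall_mol] = FATE_STALLED
        bound[stall_mol] = True
        out_pushed[stall_mol] = pushed[stall_evt]
        for code, k in enumerate(kinds):
            sel = stall_evt[kind[stall_evt] == code]
            if not len(sel):
                continue
            rb[mol[sel]] = k
            if k is RoadblockKind.GLN111:
                dist = defaults.GLN111_BACKTRACK_DIST
                draw = _vdraw(dist, len(sel), rng)
                bb = np.minimum(draw, 1)
            else:
                dist = defaults.SAV_BACKTRACK_DIST
                draw = _vdraw(dist, len(sel), rng)
                bb = np.minimum(draw, defaults.SAV_MAX_BACKTRACK_PRIMARY)
                bb = np.minimum(
                    bb + pushed[sel], defaults.SAV_MAX_BACKTRACK_TOTAL
                )
            if pathway is not None:
                Ls = pos[sel]
                caps = _cap_lookup(pathway, condition, Ls)
                bb = np.where(caps >= 0, np.minimum(bb, caps), bb)
            bb = np.minimum(bb, pos[sel] - 1)
            b[mol[sel]] = bb

    run_through = np.zeros(n, dtype=bool)
    if gln_passed is not None:
        run_through = gln_passed & (fate != FATE_STALLED)

    return Population(
        template_id=np.arange(n),
        L=L,
        b=b,
        fate=fate,
        bound=bound,
        pushed=out_pushed,
        roadblock=rb,
        run_through=run_through,
    )


def _vdraw(dist: dict[int, float], size: int, rng: np.random.Generator) -> np.ndarray:
    keys = np.array(sorted(dist))
    p = np.array([dist[k] for k in keys], dtype=float)
    return rng.choice(keys, size=size, p=p / p.sum())


def _cap_lookup(
    pathway: FoldingPathway, condition: str, Ls: np.ndarray
) -> np.ndarray:
    """Per-length structural backtrack caps; -1 where no cap applies."""
    table = {}
    for l in np.unique(Ls):
        cap = pathway.backtrack_cap(int(l), condition)
        table[int(l)] = -1 if cap is None else cap
    return np.array([table[int(l)] for l in Ls], dtype=np.int64)


def simulate_sav_experiment(
    native: str,
    n_molecules: int,
    m: float,
    fluoride_mM: float,
    seed: tuple[int, int] | int,
    pathway: FoldingPathway | None = None,
    terminal_biotin: bool = True,
    terminator: TerminatorModel | None = None,
    reverse_primer_length: int = defaults.REVERSE_PRIMER_LENGTH,
) -> Population:
    """Population of single-round TECs on randomly biotinylated templates.

    ``seed`` may be (biotin_seed, transcription_seed) or a single int.
    Each molecule samples its own biotin incorporations with probability
    m / (4 N_count) per eligible incorporation (both strands, promoter
    and reverse-primer spans excluded).
    """
    if isinstance(seed, (int, np.integer)):
        ss = np.random.SeedSequence(seed).spawn(2)
        rng_bio, rng_txn = (np.random.default_rng(s) for s in ss)
    else:
        rng_bio, rng_txn = (np.random.default_rng(s) for s in seed)
    if terminator is None:
        terminator = TerminatorModel()
    pathway = pathway or fluoride_riboswitch_pathway()
    condition = "+F" if fluoride_mM > 0 else "-F"
    n_t = len(native)
    region = native[: max(0, n_t - reverse_primer_length)]
    n_count = count_bases_both_strands(region)

    # biotin incorporations per molecule, by strand
    mol_list, pos_list, strand_list = [], [], []
    for strand, seq in (("nontemplate", region), ("template", region)):
        # template-strand incorporation of base N occurs where the
        # nontemplate base is complement(N); the per-incorporation
        # probability depends only on the base class
        for base in "ACGT":
            if n_count[base] == 0:
                continue
            q = m / (4.0 * n_count[base])
            if q > 1:
                raise ValueError(f"multiplicity {m} implies probability > 1 for {base}")
            if strand == "nontemplate":
                positions = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)) + 1
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                positions = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord(comp)) + 1
            if not len(positions):
                continue
            counts = rng_bio.binomial(len(positions), q, size=n_molecules)
            total = int(counts.sum())
            if total == 0:
                continue
            picks = rng_bio.integers(0, len(positions), size=total)
            mol_list.append(np.repeat(np.arange(n_molecules), counts))
            pos_list.append(positions[picks])
            strand_list.append(np.full(total, strand == "template"))

    if mol_list:
        mol = np.concatenate(mol_list)
        site = np.concatenate(pos_list)
        is_template = np.concatenate(strand_list)
    else:
        mol = np.empty(0, dtype=np.int64)
        site = np.empty(0, dtype=np.int64)
        is_template = np.empty(0, dtype=bool)

    # stall draws per biotin
    ev_mol, ev_pos, ev_kind, ev_push, ev_prio = [], [], [], [], []
    for templ, p_stall, offsets, code in (
        (True, defaults.SAV_TEMPLATE_STALL_PROB, defaults.SAV_TEMPLATE_OFFSETS,
         list(RoadblockKind).index(RoadblockKind.SAV_TEMPLATE)),
        (False, defaults.SAV_NONTEMPLATE_STALL_PROB, defaults.SAV_NONTEMPLATE_OFFSETS,
         list(RoadblockKind).index(RoadblockKind.SAV_NONTEMPLATE)),
    ):
        sel = np.flatnonzero(is_template == templ)
        if not len(sel):
            continue
        success = rng_txn.random(len(sel)) < p_stall
        d = _vdraw(offsets, len(sel), rng_txn)
        pos = site[sel] - d
        ok = success & (pos >= 1)
        sel = sel[ok]
        if not len(sel):
            continue
        ev_mol.append(mol[sel])
        ev_pos.append(pos[ok])
        ev_kind.append(np.full(len(sel), code))
        modal = max(offsets, key=offsets.get)
        ev_push.append(np.maximum(0, modal - d[ok]))
        ev_prio.append(np.zeros(len(sel), dtype=np.int64))

    # terminator
    fire = rng_txn.random(n_molecules) < terminator.p_term(fluoride_mM)
    tpos = rng_txn.integers(terminator.window[0], terminator.window[1] + 1, size=n_molecules)
    tm = np.flatnonzero(fire)
    if len(tm):
        ev_mol.append(tm)
        ev_pos.append(tpos[tm])
        ev_kind.append(np.full(len(tm), -1))
        ev_push.append(np.zeros(len(tm), dtype=np.int64))
        ev_prio.append(np.full(len(tm), _TERMINATOR_PRIORITY))

    # terminal roadblock
    if terminal_biotin:
        allm = np.arange(n_molecules)
        ev_mol.append(allm)
        ev_pos.append(np.full(n_molecules, n_t))
        ev_kind.append(np.full(n_molecules, list(RoadblockKind).index(RoadblockKind.TERMINAL_SAV)))
        ev_push.append(np.zeros(n_molecules, dtype=np.int64))
        ev_prio.append(np.full(n_molecules, _KIND_PRIORITY[RoadblockKind.TERMINAL_SAV]))

    cat = lambda parts, dtype: (
        np.concatenate(parts).astype(dtype) if parts else np.empty(0, dtype=dtype)
    )
    return _first_event_population(
        n_molecules,
        cat(ev_mol, np.int64),
        cat(ev_pos, np.int64),
        cat(ev_kind, np.int64),
        cat(ev_push, np.int64),
        cat(ev_prio, np.int64),
        runoff_length=np.full(n_molecules, n_t, dtype=np.int64),
        pathway=pathway,
        condition=condition,
        rng=rng_txn,
        gln_passed=None,
    )


def simulate_gln111_experiment(
    native: str,
    n_molecules: int,
    length_range: tuple[int, int],
    fluoride_mM: float,
    seed: int,
    pathway: FoldingPathway | None = None,
    terminator: TerminatorModel | None = None,
    stall_prob: float = defaults.GLN111_STALL_PROB,
) -> tuple[Population, np.ndarray]:
    """Population over a Gln111 template library.

    The library places an EcoRI site so that stalls land at every length
    in ``length_range``; molecules are assigned to library members
    uniformly.  Returns (population, per-molecule EcoRI site coordinate).
    Run-through molecules transcribe to the end of their own template
    (native prefix + EcoRI cassette).
    """
    rng = np.random.default_rng(seed)
    if terminator is None:
        terminator = TerminatorModel()
    pathway = pathway or fluoride_riboswitch_pathway()
    condition = "+F" if fluoride_mM > 0 else "-F"
    offset = next(iter(defaults.GLN111_OFFSETS))
    lo, hi = length_range
    sites = np.arange(lo + offset, hi + offset + 1)
    if sites.max() - 1 > len(native):
        raise ValueError("length_range demands EcoRI sites beyond the native sequence")
    assign = rng.integers(0, len(sites), size=n_molecules)
    mol_site = sites[assign]

    success = rng.random(n_molecules) < stall_prob
    ev_mol, ev_pos, ev_kind, ev_push, ev_prio = [], [], [], [], []
    sm = np.flatnonzero(success)
    ev_mol.append(sm)
    ev_pos.append(mol_site[sm] - offset)
    ev_kind.append(np.full(len(sm), list(RoadblockKind).index(RoadblockKind.GLN111)))
    ev_push.append(np.zeros(len(sm), dtype=np.int64))
    ev_prio.append(np.zeros(len(sm), dtype=np.int64))

    fire = rng.random(n_molecules) < terminator.p_term(fluoride_mM)
    tpos = rng.integers(terminator.window[0], terminator.window[1] + 1, size=n_molecules)
    # the terminator can only release molecules whose own stall point lies
    # at/beyond it; molecules stalled upstream never reach it, which the
    # first-event resolution handles by position ordering
    tm = np.flatnonzero(fire)
    ev_mol.append(tm)
    ev_pos.append(tpos[tm])
    ev_kind.append(np.full(len(tm), -1))
    ev_push.append(np.zeros(len(tm), dtype=np.int64))
    ev_prio.append(np.full(len(tm), _TERMINATOR_PRIORITY))

    runoff_length = (mol_site - 1) + len(CASSETTE)
    pop = _first_event_population(
        n_molecules,
        np.concatenate(ev_mol),
        np.concatenate(ev_pos),
        np.concatenate(ev_kind),
        np.concatenate(ev_push),
        np.concatenate(ev_prio),
        runoff_length=runoff_length,
        pathway=pathway,
        condition=condition,
        rng=rng,
        gln_passed=~success,
    )
    # a passed roadblock only leaves aberrant sequence in RNAs long enough
    # to have transcribed into the cassette
    pop.run_through &= pop.L >= mol_site
    return pop, mol_site


# --------------------------------------------------------------------------
# probing + reads
# --------------------------------------------------------------------------


def build_molecules(
    population: Population,
    native: str,
    pathway: FoldingPathway,
    condition: str,
    config: ProbeConfig,
    rng: np.random.Generator,
    gln_sites: np.ndarray | None = None,
) -> list[MoleculeRecord]:
    """Apply probing and reverse transcription to every molecule in both
    channels, returning per-molecule records ready for FASTQ emission.

    Molecules are grouped by (length, backtrack, fate class, sequence
    class); RT stop positions within a group are drawn from the exact
    multinomial stop distribution.
    """
    n = len(population)
    seq_cache: dict[int, str] = {0: native}

    def molecule_seq(i: int) -> str:
        if gln_sites is not None and population.run_through[i]:
            s = int(gln_sites[i])
            if s not in seq_cache:
                seq_cache[s] = native[: s - 1] + CASSETTE
            return seq_cache[s]
        return native

    groups: dict[tuple, list[int]] = {}
    for i in range(n):
        stalled = population.fate[i] == FATE_STALLED
        key = (
            int(population.L[i]),
            int(population.b[i]) if stalled else 0,
            stalled,
            int(gln_sites[i]) if (gln_sites is not None and population.run_through[i]) else 0,
        )
        groups.setdefault(key, []).append(i)

    molecules: list[MoleculeRecord] = []
    for (L, b, stalled, seq_key), members in sorted(groups.items()):
        seq_full = seq_cache[0] if seq_key == 0 else molecule_seq(members[0])
        seq = seq_full[:L]
        for channel in (CHANNEL_PLUS, CHANNEL_MINUS):
            hazards = molecule_hazards(L, b, stalled, pathway, condition, config, channel)
            counts = rng.multinomial(len(members), stop_distribution(hazards))
            stops = np.repeat(np.arange(L + 1), counts)
            for k in stops:
                molecules.append(MoleculeRecord(seq=seq, L=L, stop=int(k), channel=channel))
    return molecules


@dataclass
class RunResult:
    """Artifacts of one end-to-end run."""

    config: RunConfig
    population: Population
    fastq: dict[str, tuple[str, str]]
    stop_tables: dict[str, StopCountTable]
    matrix: ReactivityMatrix
    aligned_pct: "object"
    manifest: dict


def run_end_to_end(config: RunConfig, write_outputs: bool = True) -> RunResult:
    """Simulate, probe, sequence, demultiplex and estimate one experiment.

    Deterministic given the configured seeds.  Any stage failure aborts
    with the stage name; a manifest records versions, seeds and per-stage
    molecule/read accounting.
    """
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)  # FASTQ is always materialised
    promoter, native = config.resolve_target()
    pathway = config.resolve_pathway()
    probe_cfg = config.probe_config()
    manifest = {
        "version": __version__,
        "name": config.name,
        "mode": config.mode,
        "condition": config.condition,
        "seeds": dict(config.seeds),
        "stages": {},
    }

    stage = "simulate"
    try:
        if config.mode == MODE_SAV:
            pop = simulate_sav_experiment(
                native,
                config.n_molecules,
                config.biotin_multiplicity,
                config.fluoride_mM,
                (config.seeds["biotin"], config.seeds["transcription"]),
                pathway=pathway,
                terminal_biotin=config.terminal_biotin,
            )
            gln_sites = None
        else:
            pop, gln_sites = simulate_gln111_experiment(
                native,
                config.n_molecules,
                config.gln_length_range,
                config.fluoride_mM,
                config.seeds["transcription"],
                pathway=pathway,
            )
        manifest["stages"][stage] = {"molecules": len(pop), "fates": pop.fate_counts()}

        stage = "probe_and_reads"
        rng_probe = np.random.default_rng(config.seeds["probing"])
        molecules = build_molecules(
            pop, native, pathway, config.condition, probe_cfg, rng_probe, gln_sites
        )
        rng_lig = np.random.default_rng(config.seeds["ligation"])
        lengths = np.array([m.L for m in molecules], dtype=np.int64)
        bias = probe_cfg.ligation_weights(lengths, rng_lig)
        fastq = generate_fastq(
            molecules, probe_cfg, out / f"{config.name}", rng_lig, bias_weights=bias
        )
        manifest["stages"][stage] = {"molecules_probed": len(molecules)}

        stage = "demultiplex"
        tables = {}
        for channel in (CHANNEL_PLUS, CHANNEL_MINUS):
            f1, f2 = fastq[channel]
            tables[channel] = demultiplex(
                f1,
                f2,
                native,
                linker=probe_cfg.linker,
                channel=channel,
                gln111_mode=config.mode == MODE_GLN111,
            )
        manifest["stages"][stage] = {
            ch: {"assigned": t.total_assigned(), "dropped": dict(t.dropped)}
            for ch, t in tables.items()
        }

        stage = "reactivity"
        matrix = matrix_from_tables(
            tables[CHANNEL_PLUS],
            tables[CHANNEL_MINUS],
            metadata={
                "name": config.name,
                "condition": config.condition,
                "roadblock": config.mode,
                "seeds": dict(config.seeds),
            },
        )
        full_len = len(native) if (config.mode == MODE_SAV and config.terminal_biotin) else None
        aligned = aligned_read_distribution(tables[CHANNEL_MINUS], full_length=full_len)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(
            f"stage '{stage}' failed after {time.time() - t0:.1f}s "
            f"(accounting so far: {manifest['stages']})"
        ) from exc

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    if write_outputs:
        pop.to_tsv(out / f"{config.name}_population.tsv")
        for ch, t in tables.items():
            t.to_tsv(out / f"{config.name}_{ch}_stops.tsv")
        matrix.to_tsv(out / f"{config.name}_matrix.tsv")
        with open(out / f"{config.name}_aligned_pct.tsv", "w") as fh:
            fh.write("# %aligned unmodified reads per transcript length (1-based, +1 frame)\n")
            aligned.to_csv(fh, sep="\t", header=["pct_aligned"], index_label="length")
        with open(out / f"{config.name}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        config.to_yaml(out / f"{config.name}_config.yaml")
    return RunResult(
        config=config,
        population=pop,
        fastq=fastq,
        stop_tables=tables,
        matrix=matrix,
        aligned_pct=aligned,
        manifest=manifest,
    )
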