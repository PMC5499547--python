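"""Default model parameters shared across the package.

All coordinates are 1-based transcript coordinates: +1 is the first
transcribed nucleotide.  "d nt upstream of site X" means a nascent-RNA
3'-end length of X - d.
"""

# --- RNAP geometry ------------------------------------------------------
#: nt of nascent RNA held inside RNAP (unfoldable and SHAPE-protected)
F_RNA = 14
#: nt of template-strand DNA protected upstream of the position templating
#: the RNA 3' nt (ExoIII back border of a non-backtracked TEC)
F_DNA = 14

# --- Roadblock stalling -------------------------------------------------
#: per-encounter stall probability of a template-strand biotin-SAv roadblock
SAV_TEMPLATE_STALL_PROB = 0.85
#: per-encounter stall probability of a nontemplate-strand biotin-SAv roadblock
SAV_NONTEMPLATE_STALL_PROB = 0.30
#: per-encounter stall probability of an EcoRI(E111Q) "Gln111" roadblock
GLN111_STALL_PROB = 0.95
#: terminal (template 5'-end) biotin-SAv roadblock
TERMINAL_STALL_PROB = 1.0

#: offset distribution (nt upstream of the biotin base) for template-strand
#: SAv stalls; the cluster spans 7-13 nt with a modal stop at 10, and the
#: sub-modal offsets model TECs that "push" the roadblock before stopping
SAV_TEMPLATE_OFFSETS = {10: 0.75, 8: 0.125, 7: 0.125}
SAV_MODAL_OFFSET = 10
#: nontemplate-strand SAv stalls as a single defined stop
SAV_NONTEMPLATE_OFFSETS = {10: 1.0}
#: Gln111 stalls as a defined stop 14 nt upstream of the first base of GAATTC
GLN111_OFFSETS = {14: 1.0}
TERMINAL_OFFSETS = {0: 1.0}

# --- Backtracking -------------------------------------------------------
#: backtrack-depth distribution (nt) for SAv-stalled TECs at the primary
#: stall position; pushed TECs add their push to the drawn depth
SAV_BACKTRACK_DIST = {2: 0.1, 3: 0.3, 4: 0.6}
#: Gln111-stalled TECs backtrack at most 1 nt
GLN111_BACKTRACK_DIST = {0: 0.7, 1: 0.3}
#: absolute cap: backtrack from the primary position <= 4, total <= 7
SAV_MAX_BACKTRACK_PRIMARY = 4
SAV_MAX_BACKTRACK_TOTAL = 7
#: backtrack cap when a folded hairpin sits within this many nt of the
#: RNAP back edge (nascent structure blocks reverse translocation)
STRUCTURE_CAP_WINDOW = 4
STRUCTURE_CAPPED_BACKTRACK = 1

# --- Intrinsic terminator -----------------------------------------------
#: termination window (RNA 3'-end lengths) of the riboswitch terminator
TERMINATION_WINDOW = (80, 82)
#: per-encounter termination probability without / with fluoride
P_TERM_NO_FLUORIDE = 0.99
P_TERM_FLUORIDE = 0.01

# --- Bead partition -----------------------------------------------------
#: probability that a stalled TEC on an immobilised template pellets
P_BOUND = 0.965

# --- ExoIII footprinting ------------------------------------------------
#: uniform 0/1 nt jitter on the measured protection
EXO3_JITTER = (0, 1)

# --- Chemical probing ---------------------------------------------------
#: per-nt, per-pulse SHAPE modification rates by flexibility class
MODIFICATION_RATES = {"high": 0.04, "medium": 0.02, "low": 0.004}
#: spurious RT-stop rate per nt, shared by (+) and (-) channels
BACKGROUND_STOP_RATE = 0.002

# --- Sequencing / library -----------------------------------------------
READ_LENGTH = 36
#: synthetic 3' RNA linker (9-mer fixture; the real v2.1 linker differs)
LINKER = "GCCAAGCGA"
#: sigma of the log-normal per-length ligation-efficiency model
LIGATION_BIAS_SIGMA = 0.5

# --- Analysis -----------------------------------------------------------
#: Delta-rho threshold (rho units) for footprint-stripe calling
FOOTPRINT_TAU = 0.3
#: plateau window (lengths) and persistence (lengths) for transition calls
TRANSITION_PLATEAU = 5
TRANSITION_PERSISTENCE = 3
#: minimum reads per channel before a length's profile is trusted
MIN_READS_PER_LENGTH = 40

#: span of the promoter covered by the unmodified forward PCR primer
PROMOTER_SPAN = (-45, -1)
#: default reverse-primer length (excluded from biotinylation bookkeeping)
REVERSE_PRIMER_LENGTH = 20
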