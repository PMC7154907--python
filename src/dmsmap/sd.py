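"""Shine-Dalgarno strength via RNA-RNA nearest-neighbor hybridization.

The anti-SD of the 16S rRNA (5'-CCUCCU-3') is hybridized, ungapped and
antiparallel, at every offset against the -22..-2 window upstream of a start
codon. Each offset's free energy is the best contiguous complementary run
(Watson-Crick or G.U wobble, at least 2 pairs): the sum of Turner
nearest-neighbor stack terms dH - T*dS/1000, plus duplex initiation and a
terminal penalty for each helix end closed by an A.U or G.U pair. The
default temperature is 293.15 K (20 degC). Bulges, internal loops and
dangling ends are not modelled; this contiguous-helix duplex is a documented
simplification that is accurate for the long perfect matches that define
strong SDs.

Classification of the minimum dG over all offsets: strong (< -6 kcal/mol),
weak (-6 <= dG < 0), none (dG >= 0 or no duplex); boundary values fall in
the weaker class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .io import GeneAnnotation, Transcript
from .metrics import rel_to_abs

ANTI_SD = "CCUCCU"
T37 = 310.15
DEFAULT_TEMPERATURE_K = 293.15  # 20 degC
STRONG_MAX = -6.0  # kcal/mol, exclusive
WEAK_MAX = 0.0     # kcal/mol, exclusive

WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
AU_GU_PAIRS = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}

NO_DUPLEX = math.inf


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor helix parameters (dH kcal/mol, dS cal/(mol.K)).

    ``stacks`` is keyed by the canonical stack name 5'WX3'/3'ZY5'; ``init``
    and ``terminal_au`` are (dH, dS) for duplex initiation and the terminal
    A.U / G.U penalty. ``dg37`` holds the published 37 degC free energies for
    integrity checks.
    """

    name: str
    citation: str
    stacks: dict[str, tuple[float, float]]
    init: tuple[float, float]
    terminal_au: tuple[float, float]
    dg37: dict[str, float] = field(default_factory=dict)

    def stack_dG(self, key: str, temperature_K: float) -> float:
        dh, ds = self.stacks[canonical_stack(key)]
        return dh - temperature_K * ds / 1000.0

    def init_dG(self, temperature_K: float) -> float:
        dh, ds = self.init
        return dh - temperature_K * ds / 1000.0

    def terminal_dG(self, temperature_K: float) -> float:
        dh, ds = self.terminal_au
        return dh - temperature_K * ds / 1000.0


@dataclass(frozen=True)
class DuplexScanResult:
    """Anti-SD scan over one upstream window."""

    gene: str
    window: str
    offsets: tuple[int, ...]
    dG_per_offset: tuple[float, ...]
    min_dG: float
    sd_class: str
    truncated: bool = False


def canonical_stack(key: str) -> str:
    """A stack 5'WX3'/3'ZY5' equals its helix-reversed form 5'YZ3'/3'XW5';
    the lexicographically smaller name is canonical."""
    top, bottom = key.split("/")
    (w, x), (z, y) = top, bottom
    return min(key, f"{y}{z}/{x}{w}")


def load_nn_table(name: str = "turner2004") -> NNParameterTable:
    """Load the shipped nearest-neighbor parameter TSV."""
    fname = f"rna_stack_{name}.tsv"
    with resources.files("dmsmap.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    stacks, dg37 = {}, {}
    init = terminal = None
    for row in df.itertuples(index=False):
        if row.name == "init":
            init = (float(row.dH), float(row.dS))
        elif row.name == "terminal_au":
            terminal = (float(row.dH), float(row.dS))
        else:
            stacks[row.name] = (float(row.dH), float(row.dS))
        dg37[row.name] = float(row.dG37)
    if init is None or terminal is None:
        raise ValueError(f"parameter table {fname} lacks init/terminal_au rows")
    return NNParameterTable(
        name=name,
        citation="Turner & Mathews nearest-neighbor set (Xia et al. 1998; "
                 "Mathews et al. 1999/2004)",
        stacks=stacks, init=init, terminal_au=terminal, dg37=dg37,
    )


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    if set(seq) - set("ACGU"):
        raise ValueError(f"{what} contains non-ACGU characters: {seq!r}")
    return seq


def _pairs_ok(t: str, p: str, allow_wobble: bool) -> bool:
    pair = (t, p)
    return pair in WC_PAIRS or (allow_wobble and pair in WOBBLE_PAIRS)


def _score_alignment(target: str, probe_rev: str, params: NNParameterTable,
                     temperature_K: float, allow_wobble: bool) -> float:
    """Best contiguous run of >= 2 pairs for one fixed, fully-overlapping
    antiparallel alignment (target[i] against probe_rev[i])."""
    n = len(target)
    assert len(probe_rev) == n
    ok = [_pairs_ok(target[i], probe_rev[i], allow_wobble) for i in range(n)]
    best = NO_DUPLEX
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        if j > i:  # run of at least 2 pairs
            dG = params.init_dG(temperature_K)
            for k in range(i, j):
                key = f"{target[k]}{target[k + 1]}/{probe_rev[k]}{probe_rev[k + 1]}"
                dG += params.stack_dG(key, temperature_K)
            for end in (i, j):
                if (target[end], probe_rev[end]) in AU_GU_PAIRS:
                    dG += params.terminal_dG(temperature_K)
            best = min(best, dG)
        i = j + 1
    return best


def duplex_dG(target_subseq: str, probe: str = ANTI_SD,
              params: NNParameterTable | None = None,
              temperature_K: float = DEFAULT_TEMPERATURE_K,
              allow_wobble: bool = True) -> float:
    """Hybridization dG (kcal/mol) of probe against an equal-length target
    at a fixed offset, antiparallel and ungapped.

    Only the best single contiguous helix is scored (runs shorter than two
    pairs do not form a duplex; +inf is returned when no helix forms).
    """
    params = params or load_nn_table()
    target = _check_rna(target_subseq, "target")
    probe = _check_rna(probe, "probe")
    if len(target) != len(probe):
        raise ValueError("duplex_dG needs target and probe of equal length")
    return _score_alignment(target, probe[::-1], params, temperature_K, allow_wobble)


def scan_sd(utr_window: str, probe: str = ANTI_SD,
            params: NNParameterTable | None = None,
            temperature_K: float = DEFAULT_TEMPERATURE_K,
            allow_wobble: bool = True, gene: str = "") -> DuplexScanResult:
    """Slide the (reversed) probe along the window, allowing partial overlaps
    of at least 2 nt at the edges; report per-offset dG, the minimum and the
    SD class."""
    params = params or load_nn_table()
    window = _check_rna(utr_window, "window")
    probe = _check_rna(probe, "probe")
    if not window:
        raise ValueError("empty window")
    probe_rev = probe[::-1]
    lw, lp = len(window), len(probe)
    offsets, dgs = [], []
    for off in range(-(lp - 2), lw - 1):
        lo = max(0, off)
        hi = min(lw, off + lp)
        if hi - lo < 2:
            continue
        dG = _score_alignment(
            window[lo:hi], probe_rev[lo - off:hi - off],
            params, temperature_K, allow_wobble,
        )
        offsets.append(off)
        dgs.append(dG)
    min_dG = min(dgs) if dgs else NO_DUPLEX
    return DuplexScanResult(
        gene=gene, window=window, offsets=tuple(offsets),
        dG_per_offset=tuple(dgs), min_dG=min_dG, sd_class=classify_sd(min_dG),
    )


def classify_sd(min_dG: float) -> str:
    """strong < -6 kcal/mol; weak in [-6, 0); none otherwise (boundary values
    assigned to the weaker class)."""
    if min_dG < STRONG_MAX:
        return "strong"
    if min_dG < WEAK_MAX:
        return "weak"
    return "none"


def sd_window_sequence(annotation: GeneAnnotation, transcript: Transcript,
                       rel_start: int = -22, rel_end: int = -2) -> tuple[str, bool]:
    """Extract the -22..-2 window upstream of the start codon; truncated to
    the available 5' UTR when shorter. Returns (sequence, truncated)."""
    a = rel_to_abs(annotation.start_codon_pos, rel_start)
    b = rel_to_abs(annotation.start_codon_pos, rel_end)
    ta, tb = max(1, a), min(transcript.length, b)
    if tb < ta:
        return "", True
    return transcript.sequence[ta - 1:tb], (ta, tb) != (a, b)


def classify_plastome(annotations: list[GeneAnnotation],
                      transcripts: dict[str, Transcript],
                      params: NNParameterTable | None = None,
                      temperature_K: float = DEFAULT_TEMPERATURE_K,
                      probe: str = ANTI_SD) -> tuple[pd.DataFrame, dict[str, float]]:
    """SD class of every annotated gene plus class fractions.

    Genes with fewer than 2 nt of upstream sequence are reported as
    unclassifiable and excluded from the fractions.
    """
    params = params or load_nn_table()
    rows = []
    for ann in annotations:
        t = transcripts[ann.transcript_id]
        window, truncated = sd_window_sequence(ann, t)
        if len(window) < 2:
            rows.append({"gene": ann.gene, "min_dG": float("nan"),
                         "sd_class": "unclassifiable", "truncated": True})
            continue
        res = scan_sd(window, probe=probe, params=params,
                      temperature_K=temperature_K, gene=ann.gene)
        rows.append({"gene": ann.gene, "min_dG": res.min_dG,
                     "sd_class": res.sd_class, "truncated": truncated})
    table = pd.DataFrame(rows)
    usable = table[table["sd_class"] != "unclassifiable"]
    fractions = {
        cls: float((usable["sd_class"] == cls).mean()) if len(usable) else float("nan")
        for cls in ("strong", "weak", "none")
    }
    return table, fractions
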