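"""Reactivity-guided folding stand-in and arc-diagram export.

This is deliberately a maximum-pairing (Nussinov-style) dynamic program, not
a thermodynamic folder: its role is to make the soft-constraint logic
testable end-to-end and to produce arc tables for plotting. The guided
variant maximizes

    (#pairs) - lambda * #(paired A/C positions with normalized reactivity > theta)

so that, in the large-lambda limit, highly reactive A/C positions are never
paired (a hard constraint). Structures are nested, each position pairs at
most once, and hairpin loops have at least ``min_loop`` unpaired positions.
Production-grade minimum-free-energy folding with probing constraints should
be done with an external engine fed by the exported constraint files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CAN_PAIR = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class FoldConfig:
    min_loop: int = 3
    reactivity_threshold: float = 0.4   # theta: "highly reactive" cutoff
    pair_bonus: float = 1.0
    penalty: float = 2.0                # lambda, per paired high-reactivity A/C
    max_pair_distance: int | None = None  # optional |j - i| cap, default off

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.reactivity_threshold <= 0:
            raise ValueError("reactivity_threshold must be > 0")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")


@dataclass(frozen=True)
class FoldResult:
    pairs: tuple[tuple[int, int], ...]  # (i, j), 1-based, i < j
    score: float
    method: str

    def partner_array(self, n: int) -> np.ndarray:
        partner = np.zeros(n, dtype=int)
        for i, j in self.pairs:
            partner[i - 1], partner[j - 1] = j, i
        return partner


def _validate_fold(pairs, n: int, min_loop: int) -> None:
    seen: set[int] = set()
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise AssertionError(f"invalid pair ({i},{j})")
        if j - i <= min_loop:
            raise AssertionError(f"pair ({i},{j}) violates min_loop {min_loop}")
        if i in seen or j in seen:
            raise AssertionError(f"position reused in pair ({i},{j})")
        seen.update((i, j))
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise AssertionError(f"crossing pairs ({i},{j}) and ({k},{l})")


def _fold_dp(seq: str, pair_score, min_loop: int,
             max_dist: int | None) -> tuple[tuple[tuple[int, int], ...], float]:
    """Interval DP maximizing the sum of pair scores; negative-scoring pairs
    are simply never chosen. Traceback tie-break: prefer pairing the leftmost
    position with the smallest admissible partner."""
    n = len(seq)
    W = np.zeros((n + 2, n + 2))
    # W[i][j] over 1-based closed intervals; fill by increasing span
    for span in range(min_loop + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = W[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if max_dist is not None and k - i > max_dist:
                    break
                if (seq[i - 1], seq[k - 1]) in CAN_PAIR:
                    s = pair_score(i, k)
                    cand = s + W[i + 1][k - 1] + W[k + 1][j]
                    if cand > best:
                        best = cand
            W[i][j] = best

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            target = W[i][j]
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if max_dist is not None and k - i > max_dist:
                    break
                if (seq[i - 1], seq[k - 1]) in CAN_PAIR:
                    s = pair_score(i, k)
                    if abs(s + W[i + 1][k - 1] + W[k + 1][j] - target) < 1e-9 and (
                        s + W[i + 1][k - 1] + W[k + 1][j] >= W[i + 1][j] - 1e-9
                    ):
                        pairs.append((i, k))
                        trace(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    trace(1, n)
    return tuple(sorted(pairs)), float(W[1][n] if n >= 1 else 0.0)


def nussinov_fold(sequence: str, min_loop: int = 3,
                  max_pair_distance: int | None = None) -> FoldResult:
    """Maximum-pairing nested fold (Watson-Crick + G.U wobble)."""
    seq = sequence.upper().replace("T", "U")
    pairs, score = _fold_dp(seq, lambda i, j: 1.0, min_loop, max_pair_distance)
    _validate_fold(pairs, len(seq), min_loop)
    return FoldResult(pairs=pairs, score=score, method="nussinov")


def reactivity_penalties(sequence: str, profile: pd.DataFrame | np.ndarray | None,
                         config: FoldConfig,
                         transcript_id: str | None = None) -> np.ndarray:
    """Per-position indicator: A/C with normalized reactivity above theta.

    ``profile`` may be a reactivity DataFrame (single transcript unless
    ``transcript_id`` narrows it) or a plain per-position array of normalized
    values; masked / missing positions carry no penalty.
    """
    n = len(sequence)
    norm = np.full(n, np.nan)
    if profile is None:
        pass
    elif isinstance(profile, pd.DataFrame):
        sub = profile
        if transcript_id is not None:
            sub = sub[sub["transcript_id"] == transcript_id]
        pos = sub["pos"].to_numpy(dtype=int)
        if pos.size and (pos.max() > n or pos.min() < 1):
            raise ValueError("profile positions do not align with the sequence")
        ok = (sub["mask_reason"] == "none").to_numpy() & sub["normalized"].notna(
        ).to_numpy()
        norm[pos[ok] - 1] = sub["normalized"].to_numpy(dtype=float)[ok]
    else:
        arr = np.asarray(profile, dtype=float)
        if arr.size != n:
            raise ValueError("reactivity array length != sequence length")
        norm = arr
    is_ac = np.isin(list(sequence), ["A", "C"])
    with np.errstate(invalid="ignore"):
        return (is_ac & (norm > config.reactivity_threshold)).astype(float)


def guided_fold(sequence: str, profile, config: FoldConfig | None = None,
                transcript_id: str | None = None) -> FoldResult:
    """Reactivity-guided fold: pairs score ``pair_bonus`` minus
    ``penalty`` for each paired high-reactivity A/C endpoint."""
    config = config or FoldConfig()
    seq = sequence.upper().replace("T", "U")
    pen = reactivity_penalties(seq, profile, config)

    def pair_score(i: int, j: int) -> float:
        return config.pair_bonus - config.penalty * (pen[i - 1] + pen[j - 1])

    pairs, score = _fold_dp(seq, pair_score, config.min_loop,
                            config.max_pair_distance)
    _validate_fold(pairs, len(seq), config.min_loop)
    return FoldResult(pairs=pairs, score=score, method="nussinov_guided")


def fold_to_dotbracket(fold: FoldResult, n: int) -> str:
    out = ["."] * n
    for i, j in fold.pairs:
        out[i - 1], out[j - 1] = "(", ")"
    return "".join(out)


def pairs_to_arcs(fold: FoldResult, path, reactivity: np.ndarray | None = None) -> None:
    """Write the arc table (columns i, j and, when reactivities are supplied,
    react_i / react_j for coloring)."""
    rows = []
    for i, j in fold.pairs:
        row = {"i": i, "j": j}
        if reactivity is not None:
            row["react_i"] = reactivity[i - 1]
            row["react_j"] = reactivity[j - 1]
        rows.append(row)
    cols = ["i", "j"] + (["react_i", "react_j"] if reactivity is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_arcs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
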