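"""Per-position mutation counts -> normalized two-channel DMS reactivities.

The pipeline is: raw rate = (substitutions + deletions) / coverage for every
position that survives filtering (coverage >= 2500 by default, outside
primer-covered ranges, not an RNA-editing site, not a known modified
nucleotide); then per-transcript, per-channel scaling by the mean reactivity
of the 90th-99th percentile window (A/C and G/U separately, because DMS
modifies G/U far more weakly); then transcript-wise 99% winsorization of the
normalized values, channels pooled, to suppress extreme outliers.

Profiles are pandas DataFrames with columns
``transcript_id, pos, ref_base, channel, raw_rate, normalized, mask_reason``;
``mask_reason`` is one of none, low_coverage, primer, editing_site,
modified_site. Per-channel normalization bookkeeping (divisor or the reason a
channel could not be normalized) lives in ``profile.attrs["normalization"]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import REACTIVITY_COLUMNS, MaskSet

CHANNEL_OF = {"A": "AC", "C": "AC", "G": "GU", "U": "GU"}
MASK_NONE = "none"


@dataclass(frozen=True)
class ReactivityParams:
    """Tunables of the reactivity pipeline (defaults = the analysis' stated
    thresholds)."""

    min_coverage: int = 2500
    percentile_window: tuple[float, float] = (90.0, 99.0)
    winsor_level: float = 99.0
    min_positions: int = 20  # per (transcript, channel) to attempt normalization

    def __post_init__(self) -> None:
        lo, hi = self.percentile_window
        if not 0 <= lo < hi <= 100:
            raise ValueError("percentile window must satisfy 0 <= lo < hi <= 100")
        if not 0 < self.winsor_level <= 100:
            raise ValueError("winsor_level must be in (0, 100]")
        if self.min_coverage < 1 or self.min_positions < 1:
            raise ValueError("min_coverage and min_positions must be >= 1")


def compute_raw_rates(counts: pd.DataFrame, masks: dict[str, MaskSet] | None = None,
                      min_coverage: int = 2500) -> pd.DataFrame:
    """Raw mutation rates with mask bookkeeping.

    raw_rate = (sub_count + del_count) / coverage at unmasked positions.
    Masking precedence when several reasons apply: primer > editing_site >
    modified_site > low_coverage. A position listed twice for one transcript
    is an error.
    """
    masks = masks or {}
    dup = counts.duplicated(subset=["transcript_id", "pos"])
    if dup.any():
        row = counts[dup].iloc[0]
        raise ValueError(f"duplicate position {row.transcript_id}:{row.pos} in counts")
    df = counts.sort_values(["transcript_id", "pos"], kind="stable").reset_index(drop=True)

    reasons = np.full(len(df), MASK_NONE, dtype=object)
    low = (df["coverage"] < min_coverage).to_numpy()
    reasons[low] = "low_coverage"
    for tid, mask in masks.items():
        rows = (df["transcript_id"] == tid).to_numpy()
        pos = df["pos"].to_numpy()
        if mask.modified_sites:
            reasons[rows & np.isin(pos, mask.modified_sites)] = "modified_site"
        if mask.editing_sites:
            reasons[rows & np.isin(pos, mask.editing_sites)] = "editing_site"
        if mask.primer_ranges:
            in_primer = np.zeros(len(df), dtype=bool)
            for a, b in mask.primer_ranges:
                in_primer |= rows & (pos >= a) & (pos <= b)
            reasons[in_primer] = "primer"

    unmasked = reasons == MASK_NONE
    raw = np.full(len(df), np.nan)
    cov = df["coverage"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw[unmasked] = (
            (df["sub_count"] + df["del_count"]).to_numpy(dtype=float)[unmasked]
            / cov[unmasked]
        )
    out = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"],
            "pos": df["pos"],
            "ref_base": df["ref_base"],
            "channel": df["ref_base"].map(CHANNEL_OF),
            "raw_rate": raw,
            "normalized": np.nan,
            "mask_reason": reasons,
        }
    )
    out.attrs["normalization"] = {}
    return out


def _percentile_window_divisor(values: np.ndarray,
                               window: tuple[float, float]) -> tuple[float, str]:
    """Mean of values in the upper percentile window.

    The window is (strictly above the lower percentile, at or below the upper
    percentile), percentiles by linear interpolation. When ties make that
    exclusive window empty (e.g. an all-constant channel) the lower edge
    becomes inclusive, so a constant channel normalizes to 1.
    """
    lo = float(np.percentile(values, window[0]))
    hi = float(np.percentile(values, window[1]))
    sel = values[(values > lo) & (values <= hi)]
    if sel.size == 0:
        sel = values[(values >= lo) & (values <= hi)]
    if sel.size == 0:
        return np.nan, "empty_percentile_window"
    divisor = float(sel.mean())
    if divisor <= 0.0:
        return np.nan, "zero_divisor"
    return divisor, "ok"


def normalize_two_channel(profile: pd.DataFrame,
                          params: ReactivityParams | None = None) -> pd.DataFrame:
    """Scale raw rates per (transcript, channel) by the mean reactivity of
    the 90th-99th percentile window of that transcript-channel.

    Channels with fewer than ``min_positions`` unmasked positions, or whose
    percentile window has zero mean (no signal), are flagged in
    ``attrs["normalization"]`` and left unnormalized rather than silently
    scaled.
    """
    params = params or ReactivityParams()
    out = profile.copy()
    out["normalized"] = np.nan
    status: dict[tuple[str, str], dict] = {}
    unmasked = (out["mask_reason"] == MASK_NONE) & out["raw_rate"].notna()
    for (tid, channel), idx in out[unmasked].groupby(
        ["transcript_id", "channel"], sort=True
    ).groups.items():
        raw = out.loc[idx, "raw_rate"].to_numpy(dtype=float)
        if raw.size < params.min_positions:
            status[(tid, channel)] = {"status": "too_few_positions", "n": int(raw.size)}
            continue
        divisor, why = _percentile_window_divisor(raw, params.percentile_window)
        if why != "ok":
            status[(tid, channel)] = {"status": why, "n": int(raw.size)}
            continue
        out.loc[idx, "normalized"] = raw / divisor
        status[(tid, channel)] = {"status": "ok", "n": int(raw.size), "divisor": divisor}
    out.attrs["normalization"] = status
    return out


def winsorize_99(profile: pd.DataFrame,
                 params: ReactivityParams | None = None) -> pd.DataFrame:
    """Cap normalized values above the transcript-wise 99th percentile.

    Applied per transcript with both channels pooled; one-sided (upper only):
    values are capped at the percentile, never removed. The cap is the
    largest data value at or below the percentile rank (``method="lower"``),
    which makes winsorization idempotent.
    """
    params = params or ReactivityParams()
    out = profile.copy()
    out.attrs = dict(profile.attrs)
    has = out["normalized"].notna()
    for tid, idx in out[has].groupby("transcript_id").groups.items():
        vals = out.loc[idx, "normalized"].to_numpy(dtype=float)
        cap = float(np.percentile(vals, params.winsor_level, method="lower"))
        out.loc[idx, "normalized"] = np.minimum(vals, cap)
    return out


def reactivity_pipeline(counts: pd.DataFrame, masks: dict[str, MaskSet] | None = None,
                        params: ReactivityParams | None = None) -> pd.DataFrame:
    """Full profile: raw rates -> two-channel normalization -> winsorization."""
    params = params or ReactivityParams()
    if counts.empty:
        empty = pd.DataFrame(columns=REACTIVITY_COLUMNS)
        empty.attrs["normalization"] = {}
        return empty
    profile = compute_raw_rates(counts, masks, min_coverage=params.min_coverage)
    profile = normalize_two_channel(profile, params)
    return winsorize_99(profile, params)


def exclusion_counts(profile: pd.DataFrame) -> dict[str, int]:
    """How many positions each mask reason removed (plus 'analyzed'); the
    values partition the total position count."""
    counts = profile["mask_reason"].value_counts().to_dict()
    return {
        "analyzed": int(counts.pop(MASK_NONE, 0)),
        "low_coverage": int(counts.pop("low_coverage", 0)),
        "primer": int(counts.pop("primer", 0)),
        "editing_site": int(counts.pop("editing_site", 0)),
        "modified_site": int(counts.pop("modified_site", 0)),
    }
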