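"""Region-level structure statistics: regional mean reactivity, Gini index,
and ROC validation against a reference structure.

Regions are anchored on the first nucleotide of the start codon (+1), with no
position 0 (-1 abuts +1): the translation initiation region (TIR) spans -25
to +5 (30 nt), the Shine-Dalgarno search window -22 to -2 (21 nt), the start
codon +1 to +3, the CDS +1 to the end of the stop codon. A higher Gini index
of A/C reactivities means a more structured region (few highly reactive
positions dominate). ROC truth labels come from a reference structure:
positive = unpaired AND solvent-accessible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .io import GeneAnnotation, ReferenceStructure, Transcript

REGION_KINDS = ("start_codon", "sd_window", "tir", "cds")

# relative windows (no position 0; -1 abuts +1)
REL_WINDOWS = {"start_codon": (1, 3), "sd_window": (-22, -2), "tir": (-25, 5)}

BASE_SETS = {"A": ("A",), "C": ("C",), "G": ("G",), "U": ("U",),
             "AC": ("A", "C"), "GU": ("G", "U"), "ACGU": ("A", "C", "G", "U")}


@dataclass(frozen=True)
class RegionSpec:
    """One resolved analysis region of a gene (absolute 1-based inclusive)."""

    gene: str
    kind: str
    start: int
    end: int
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GiniResult:
    value: float
    n_used: int
    base_set: str


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int
    base_filter: str


def rel_to_abs(start_codon_pos: int, rel: int) -> int:
    """Relative-to-start-codon coordinate -> absolute 1-based position.

    There is no relative position 0: +1 is the first nucleotide of the start
    codon and -1 the nucleotide immediately upstream.
    """
    if rel == 0:
        raise ValueError("relative coordinate 0 does not exist")
    return start_codon_pos + rel - 1 if rel > 0 else start_codon_pos + rel


def resolve_regions(annotation: GeneAnnotation,
                    transcript: Transcript) -> list[RegionSpec]:
    """Start codon, SD window, TIR and CDS of one gene, clipped to the
    transcript with a truncation flag when a window runs off either end."""
    annotation.validate(transcript.length)
    s = annotation.start_codon_pos
    out = []
    for kind, (lo, hi) in REL_WINDOWS.items():
        a, b = rel_to_abs(s, lo), rel_to_abs(s, hi)
        ta, tb = max(1, a), min(transcript.length, b)
        out.append(RegionSpec(annotation.gene, kind, ta, tb,
                              truncated=(ta, tb) != (a, b)))
    out.append(RegionSpec(annotation.gene, "cds", s, annotation.cds_end_pos))
    return out


def _region_values(profile: pd.DataFrame, region: RegionSpec, base_set: str,
                   transcript_id: str | None = None) -> np.ndarray:
    bases = BASE_SETS[base_set]
    sub = profile
    if transcript_id is not None:
        sub = sub[sub["transcript_id"] == transcript_id]
    sel = (
        (sub["pos"] >= region.start)
        & (sub["pos"] <= region.end)
        & sub["ref_base"].isin(bases)
        & (sub["mask_reason"] == "none")
        & sub["normalized"].notna()
    )
    return sub.loc[sel, "normalized"].to_numpy(dtype=float)


def region_mean_reactivity(profile: pd.DataFrame, region: RegionSpec,
                           base_set: str = "AC",
                           transcript_id: str | None = None) -> tuple[float, int]:
    """Mean normalized reactivity over the region's unmasked positions whose
    base is in ``base_set``. Returns (mean, n contributing); (nan, 0) when no
    position contributes — never 0."""
    vals = _region_values(profile, region, base_set, transcript_id)
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def gini(values, base_set: str = "AC", form: str = "population") -> GiniResult:
    """Gini index of a set of reactivities.

    Population mean-absolute-difference form by default:
    G = sum_ij |x_i - x_j| / (2 n^2 xbar); ``form="sample"`` uses the
    bias-corrected 2 n (n-1) xbar denominator. Requires n >= 2, all values
    >= 0 and a positive mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("gini requires at least 2 values")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("gini undefined for zero-mean values")
    n = x.size
    xs = np.sort(x)
    # sum_ij |xi - xj| = 2 * sum_k (2k - n + 1) * x_(k)   (k 0-based, sorted)
    mad_sum = 2.0 * np.sum((2.0 * np.arange(n) - n + 1.0) * xs)
    if form == "population":
        denom = 2.0 * n * n * mean
    elif form == "sample":
        denom = 2.0 * n * (n - 1) * mean
    else:
        raise ValueError(f"unknown gini form {form!r}")
    return GiniResult(value=float(mad_sum / denom), n_used=int(n), base_set=base_set)


def region_gini(profile: pd.DataFrame, region: RegionSpec, base_set: str = "AC",
                form: str = "population",
                transcript_id: str | None = None) -> GiniResult | None:
    """Gini of the region's unmasked normalized reactivities (None when fewer
    than 2 usable positions or zero mean — masked positions are excluded,
    never imputed)."""
    vals = _region_values(profile, region, base_set, transcript_id)
    if vals.size < 2 or vals.mean() <= 0:
        return None
    return gini(vals, base_set=base_set, form=form)


def accessibility_labels(structure: ReferenceStructure) -> np.ndarray:
    """Truth labels for ROC: positive iff unpaired AND solvent-accessible."""
    return structure.unpaired & structure.solvent_accessible


def roc_auc(profile: pd.DataFrame, labels: np.ndarray, base_filter: str = "AC",
            transcript_id: str | None = None) -> RocResult:
    """ROC of normalized reactivity against structure-derived truth labels.

    ``labels`` is a per-position boolean array over the whole transcript
    (index 0 = position 1). Only unmasked positions whose base passes
    ``base_filter`` enter. The AUC is computed by the exact Mann-Whitney
    rank formula (ties counted half), which equals the trapezoidal area
    under the interpolated curve; the curve itself comes from
    sklearn.metrics.roc_curve.
    """
    bases = BASE_SETS[base_filter]
    sub = profile
    if transcript_id is not None:
        sub = sub[sub["transcript_id"] == transcript_id]
    sel = sub["ref_base"].isin(bases) & (sub["mask_reason"] == "none") & sub[
        "normalized"].notna()
    sub = sub[sel]
    labels = np.asarray(labels, dtype=bool)
    y = labels[sub["pos"].to_numpy(dtype=int) - 1]
    scores = sub["normalized"].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative position")
    fpr, tpr, _ = roc_curve(y, scores)
    ranks = rankdata(scores)  # average ranks: ties contribute 1/2 each
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return RocResult(
        auc=float(u / (n_pos * n_neg)),
        fpr=fpr, tpr=tpr, n_pos=n_pos, n_neg=n_neg, base_filter=base_filter,
    )


def compare_conditions(profile_vivo: pd.DataFrame, profile_vitro: pd.DataFrame,
                       regions: list[RegionSpec], gini_form: str = "population",
                       transcript_id: str | None = None) -> pd.DataFrame:
    """Per-region in vivo vs in vitro comparison table.

    One row per (gene, region kind) with mean reactivity and Gini in each
    condition and their (vivo - vitro) differences. Start-codon means use
    adenosines only; all other regions use A/C. Rows where either profile
    lacks usable positions are flagged.
    """
    rows = []
    for region in regions:
        base_set = "A" if region.kind == "start_codon" else "AC"
        mean_vv, n_vv = region_mean_reactivity(
            profile_vivo, region, base_set, transcript_id)
        mean_vt, n_vt = region_mean_reactivity(
            profile_vitro, region, base_set, transcript_id)
        g_vv = region_gini(profile_vivo, region, "AC", gini_form, transcript_id)
        g_vt = region_gini(profile_vitro, region, "AC", gini_form, transcript_id)
        rows.append(
            {
                "gene": region.gene,
                "region": region.kind,
                "base_set": base_set,
                "mean_vivo": mean_vv,
                "n_vivo": n_vv,
                "mean_vitro": mean_vt,
                "n_vitro": n_vt,
                "mean_diff": mean_vv - mean_vt,
                "gini_vivo": g_vv.value if g_vv else float("nan"),
                "gini_vitro": g_vt.value if g_vt else float("nan"),
                "gini_diff": (g_vv.value - g_vt.value) if (g_vv and g_vt)
                             else float("nan"),
                "flag": "ok" if (n_vv and n_vt) else "missing_data",
            }
        )
    return pd.DataFrame(rows)
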