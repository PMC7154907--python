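"""Structure-conditioned synthetic DMS-MaPseq data.

The generator emulates the statistical structure the downstream analysis
assumes: nucleotides that are both unpaired and solvent-accessible acquire a
high channel-specific modification rate (A/C much higher than G/U, mirroring
the chemistry of dimethyl sulfate), everything else a low background rate;
sequencing coverage varies negative-binomially; RNA-editing sites look like
constitutively high mutation rates regardless of structure; primer-covered
ranges have no usable coverage. Per-read effects (PCR bias, RT drop-off)
are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import MaskSet, ReferenceStructure, Transcript

AC_BASES = frozenset("AC")


@dataclass(frozen=True)
class SimulationConfig:
    """Modification-rate and coverage model.

    Default rates are chosen so that the A/C channel separates paired from
    unpaired positions strongly and the G/U channel only weakly, matching
    the relative reliability of the two channels in DMS probing. They are
    working values for testing the pipeline, not estimates of any measured
    per-nucleotide rate.
    """

    rate_unpaired_AC: float = 0.02
    rate_paired_AC: float = 0.002
    rate_unpaired_GU: float = 0.006
    rate_paired_GU: float = 0.002
    error_rate: float = 0.001
    editing_rate: float = 0.15       # apparent rate at an RNA-editing site
    coverage_mean: float = 5000.0
    coverage_dispersion: float = 50.0  # NB size parameter; var = m + m^2/size
    sub_fraction: float = 0.8        # fixed substitution share of mutations
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.rate_unpaired_AC, self.rate_paired_AC,
            self.rate_unpaired_GU, self.rate_paired_GU,
            self.error_rate, self.editing_rate,
        )
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must be probabilities in [0, 1]")
        if not (self.rate_unpaired_AC > self.rate_paired_AC
                and self.rate_unpaired_GU > self.rate_paired_GU):
            raise ValueError("unpaired rates must exceed paired rates per channel")
        if max(rates[:4]) + self.error_rate > 1.0:
            raise ValueError("rate + error_rate must not exceed 1")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if not 0.0 <= self.sub_fraction <= 1.0:
            raise ValueError("sub_fraction must be in [0, 1]")


@dataclass
class TrueRateTrack:
    """Ground-truth per-position modification probabilities.

    ``positive`` marks the DMS-accessible class (unpaired AND
    solvent-accessible), the truth labels later ROC validation is scored
    against.
    """

    transcript: Transcript
    rates: np.ndarray
    positive: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.positive = np.asarray(self.positive, dtype=bool)
        n = self.transcript.length
        if self.rates.size != n or self.positive.size != n:
            raise ValueError("track arrays must match transcript length")
        if ((self.rates < 0) | (self.rates > 1)).any():
            raise ValueError("rates must be in [0, 1]")


def assign_true_rates(transcript: Transcript, structure: ReferenceStructure,
                      config: SimulationConfig,
                      editing_sites: tuple[int, ...] = ()) -> TrueRateTrack:
    """Map structure + accessibility to per-position modification rates.

    A position gets its channel's unpaired rate iff it is unpaired AND
    solvent-accessible; otherwise the paired (background) rate. Declared
    editing sites get a fixed high apparent rate regardless of structure
    and are excluded from the positive class.
    """
    if structure.length != transcript.length:
        raise ValueError("structure length != transcript length")
    seq = np.frombuffer(transcript.sequence.encode(), dtype="S1").astype("U1")
    is_ac = np.isin(seq, ["A", "C"])
    accessible = structure.unpaired & structure.solvent_accessible
    rates = np.where(
        is_ac,
        np.where(accessible, config.rate_unpaired_AC, config.rate_paired_AC),
        np.where(accessible, config.rate_unpaired_GU, config.rate_paired_GU),
    )
    positive = accessible.copy()
    for p in editing_sites:
        rates[p - 1] = config.editing_rate
        positive[p - 1] = False
    return TrueRateTrack(transcript=transcript, rates=rates, positive=positive)


def simulate_counts(track: TrueRateTrack, config: SimulationConfig, seed: int,
                    primer_ranges: tuple[tuple[int, int], ...] = ()) -> pd.DataFrame:
    """Draw a per-position mutation-count table from a true-rate track.

    coverage ~ NegativeBinomial(mean=coverage_mean, size=coverage_dispersion),
    forced to 0 inside primer ranges; mutations ~ Binomial(coverage,
    rate + error_rate); the mutation count is split into substitutions and
    deletions at the fixed ``sub_fraction`` ratio (downstream analysis sums
    them again). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = track.transcript.length
    m, size = config.coverage_mean, config.coverage_dispersion
    coverage = rng.negative_binomial(n=size, p=size / (size + m), size=n)
    for a, b in primer_ranges:
        coverage[a - 1:b] = 0
    p = np.clip(track.rates + config.error_rate, 0.0, 1.0)
    mutations = rng.binomial(coverage, p)
    subs = np.rint(mutations * config.sub_fraction).astype(int)
    dels = mutations - subs
    seq = np.frombuffer(track.transcript.sequence.encode(), dtype="S1").astype("U1")
    return pd.DataFrame(
        {
            "transcript_id": track.transcript.id,
            "pos": np.arange(1, n + 1),
            "ref_base": seq,
            "coverage": coverage,
            "sub_count": subs,
            "del_count": dels,
        }
    )


def release_footprint(structure: ReferenceStructure,
                      footprint_range: tuple[int, int]) -> ReferenceStructure:
    """Remove every pair with at least one endpoint in the footprint.

    Models a bound protein preventing helix formation: both endpoints of a
    removed pair become unpaired and solvent-accessible.
    """
    a, b = footprint_range
    if a > b or a < 1 or b > structure.length:
        raise ValueError(f"invalid footprint range [{a},{b}]")
    partner = structure.partner.copy()
    accessible = structure.solvent_accessible.copy()
    for i in range(1, structure.length + 1):
        j = int(partner[i - 1])
        if j and (a <= i <= b or a <= j <= b):
            partner[i - 1] = 0
            partner[j - 1] = 0
            accessible[i - 1] = True
            accessible[j - 1] = True
    return ReferenceStructure(
        transcript_id=structure.transcript_id,
        partner=partner,
        solvent_accessible=accessible,
    )


def make_paired_conditions(transcript: Transcript, structure: ReferenceStructure,
                           footprint_range: tuple[int, int] | None,
                           config: SimulationConfig,
                           primer_ranges: tuple[tuple[int, int], ...] = (),
                           editing_sites: tuple[int, ...] = ()) -> dict[str, pd.DataFrame]:
    """Simulate an in vivo / in vitro condition pair.

    The in vitro table is drawn from the structure as-is (protein-free
    refolded RNA); the in vivo table from the structure with the protein
    footprint's helices released. An empty footprint (None) makes both
    conditions draws from identical rate tracks.
    """
    vitro_track = assign_true_rates(transcript, structure, config, editing_sites)
    vivo_struct = (
        structure if footprint_range is None
        else release_footprint(structure, footprint_range)
    )
    vivo_track = assign_true_rates(transcript, vivo_struct, config, editing_sites)
    seed_vivo, seed_vitro = derive_seeds(config.seed, 2)
    return {
        "in_vivo": simulate_counts(vivo_track, config, seed_vivo, primer_ranges),
        "in_vitro": simulate_counts(vitro_track, config, seed_vitro, primer_ranges),
    }


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (kept below 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def hairpin_transcript(transcript_id: str, n_hairpins: int, seed: int,
                       stem_len: int = 10, loop_len: int = 8, spacer_len: int = 12,
                       accessible_frac: float = 0.85,
                       paired_accessible_frac: float = 0.5) -> tuple[Transcript, ReferenceStructure]:
    """A hairpin-rich transcript with known structure.

    Alternates spacer / stem-loop units. Unpaired positions are
    solvent-accessible with probability ``accessible_frac`` (an unpaired but
    buried position belongs to the negative, DMS-inaccessible class), paired
    positions with probability ``paired_accessible_frac``.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    seq: list[str] = []
    partner_pairs: list[tuple[int, int]] = []

    def random_run(k):
        seq.extend(rng.choice(bases, size=k))

    for _ in range(n_hairpins):
        random_run(spacer_len)
        stem_start = len(seq) + 1
        stem = rng.choice(bases, size=stem_len)
        seq.extend(stem)
        random_run(loop_len)
        right_start = len(seq) + 1
        seq.extend(_COMPLEMENT[b] for b in stem[::-1])
        for k in range(stem_len):
            i = stem_start + k
            j = right_start + (stem_len - 1 - k)
            partner_pairs.append((i, j))
    random_run(spacer_len)

    n = len(seq)
    partner = np.zeros(n, dtype=int)
    for i, j in partner_pairs:
        partner[i - 1], partner[j - 1] = j, i
    unpaired = partner == 0
    accessible = np.where(
        unpaired,
        rng.random(n) < accessible_frac,
        rng.random(n) < paired_accessible_frac,
    )
    transcript = Transcript(id=transcript_id, sequence="".join(seq))
    structure = ReferenceStructure(
        transcript_id=transcript_id, partner=partner, solvent_accessible=accessible
    )
    return transcript, structure


def rrn16_like(seed: int = 0, n_hairpins: int = 37) -> tuple[Transcript, ReferenceStructure]:
    """A ~1.5 kb hairpin-rich transcript standing in for a 16S rRNA control:
    roughly half the positions paired, known pairing map, known
    accessibility mask."""
    return hairpin_transcript("rrn16_like", n_hairpins=n_hairpins, seed=seed)


def footprint_fixture(seed: int = 0) -> dict:
    """A small mRNA whose start codon is sequestered in a stem that a protein
    footprint releases in vivo.

    Layout (1-based): 5' UTR of 45 nt carrying an SD (GGAGG at -22..-18
    relative to the start codon, i.e. 24..28); a 9-bp stem pairing UTR
    positions 31..39 with 46..54, burying the start codon AUG at 46..48;
    CDS 46..120. Returns transcript, structure, annotation, footprint range
    and mask set.
    """
    from .io import GeneAnnotation

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    start = 46
    length = 120
    seq = list(rng.choice(bases, size=length))
    for p, b in zip(range(start - 22, start - 17), "GGAGG"):
        seq[p - 1] = b
    seq[start - 1:start + 2] = list("AUG")
    left = list(range(31, 40))
    right = list(range(46, 55))
    partner = np.zeros(length, dtype=int)
    # left arm is complement-determined by the right arm, so AUG survives
    for k, i in enumerate(left):
        j = right[len(right) - 1 - k]
        seq[i - 1] = _COMPLEMENT[seq[j - 1]]
        partner[i - 1], partner[j - 1] = j, i
    accessible = np.ones(length, dtype=bool)
    transcript = Transcript(id="clpP_like", sequence="".join(seq))
    structure = ReferenceStructure(
        transcript_id="clpP_like", partner=partner, solvent_accessible=accessible
    )
    annotation = GeneAnnotation(
        gene="clpP_like", transcript_id="clpP_like",
        start_codon_pos=start, cds_end_pos=length,
    )
    annotation.validate(transcript.length)
    return {
        "transcript": transcript,
        "structure": structure,
        "annotation": annotation,
        "footprint_range": (28, 42),
        "masks": MaskSet(),
    }
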