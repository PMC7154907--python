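import numpy as np
import pandas as pd
import pytest

import dmsmap as d


@pytest.fixture(scope="session")
def nn_params():
    return d.load_nn_table()


@pytest.fixture(scope="session")
def rrn16_sim():
    """One simulated probing run on the hairpin-rich control transcript."""
    transcript, structure = d.rrn16_like(seed=11)
    config = d.SimulationConfig(seed=11)
    track = d.assign_true_rates(transcript, structure, config)
    counts = d.simulate_counts(track, config, seed=23)
    profile = d.reactivity_pipeline(counts)
    return {
        "transcript": transcript,
        "structure": structure,
        "config": config,
        "track": track,
        "counts": counts,
        "profile": profile,
    }


def counts_from_rates(rates, ref_bases, coverage=100000, transcript_id="t1"):
    """Exact-rate counts table: raw_rate reproduces ``rates`` bit-for-bit."""
    rates = np.asarray(rates, dtype=float)
    subs = np.rint(rates * coverage).astype(int)
    return pd.DataFrame(
        {
            "transcript_id": transcript_id,
            "pos": np.arange(1, rates.size + 1),
            "ref_base": list(ref_bases),
            "coverage": coverage,
            "sub_count": subs,
            "del_count": 0,
        }
    )
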