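import numpy as np
import pandas as pd
import pytest


def make_survival(times, events, index=None, **cov):
    """Minimal valid survival table for tests."""
    n = len(times)
    idx = pd.Index(index if index is not None else [f"P{i+1:03d}" for i in range(n)],
                   name="patient_id")
    return pd.DataFrame(
        {
            "time_months": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "age": cov.get("age", np.full(n, 60.0)),
            "gender": cov.get("gender", ["male"] * n),
            "uN": cov.get("uN", np.ones(n, dtype=int)),
        },
        index=idx,
    )


@pytest.fixture
def toy_survival():
    """4 patients, 2 per group, all events, no ties."""
    return make_survival([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])


@pytest.fixture
def probe_map_small():
    import dmrsurv as ds

    return ds.generate_probe_map(
        seed=7, n_chrom=2, islands_per_chrom=10, probes_per_island=(2, 5)
    )


def brute_force_regions(probe_map, max_gap):
    """O(n^2)-flavoured reference run-finder for build_regions."""
    out = []
    for chrom in probe_map["chrom"].unique():
        sub = probe_map[probe_map["chrom"] == chrom].reset_index(drop=True)
        i = 0
        while i < len(sub):
            j = i
            while (
                j + 1 < len(sub)
                and sub.loc[j + 1, "start"] - sub.loc[j, "end"] <= max_gap
            ):
                j += 1
            if j > i:
                out.append(
                    (
                        chrom,
                        int(sub.loc[i, "start"]),
                        int(sub.loc[j, "end"]),
                        tuple(sub.loc[i:j, "probe_id"]),
                    )
                )
            i = j + 1
    return out


def brute_force_segment(pattern):
    """Reference for segment_supported on a boolean top-probe pattern."""
    pos = [i for i, t in enumerate(pattern) if t]
    return any(b - a <= 2 for a, b in zip(pos, pos[1:]))
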