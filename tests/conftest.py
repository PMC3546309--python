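import numpy as np
import pandas as pd
import pytest

from cpmap.simdata import SimConfig, TrueLG, TrueMap, simulate_progeny

#: reference per-LG sizes used by the recovery fixtures
LG_SIZES = [128.46, 138.92, 186.32, 89.49, 119.93, 99.80, 115.59, 118.03, 87.54]


def make_testcross_map(rng, markers_per_lg=20, lg_sizes=None, spacing="even"):
    """Truth map where parent 1 is heterozygous (A/B, random phase) at every
    marker and parent 2 is homozygous: a pure one-parent testcross frame."""
    lg_sizes = lg_sizes if lg_sizes is not None else LG_SIZES
    lgs, rows = [], []
    for i, L in enumerate(lg_sizes, start=1):
        if spacing == "even":
            pos = np.linspace(0.0, L, markers_per_lg)
        else:
            pos = np.sort(rng.uniform(0.0, L, markers_per_lg))
            while np.any(np.diff(pos) <= 1e-3):
                pos = np.sort(rng.uniform(0.0, L, markers_per_lg))
        names = [f"M{i}_{j + 1:02d}" for j in range(markers_per_lg)]
        lgs.append(TrueLG(f"LG{i}", names, pos))
        for nm, p in zip(names, pos):
            h = ("A", "B") if rng.random() < 0.5 else ("B", "A")
            rows.append({"marker": nm, "lg": f"LG{i}", "pos": p, "marker_class": "snp",
                         "p1_h1": h[0], "p1_h2": h[1], "p2_h1": "A", "p2_h2": "A"})
    return TrueMap(lgs, pd.DataFrame(rows).set_index("marker"))


def simulate_testcross(seed, n=156, markers_per_lg=20, lg_sizes=None,
                       error_rate=0.0, missing_rate=0.0, selection=None):
    rng = np.random.default_rng(seed)
    tm = make_testcross_map(rng, markers_per_lg, lg_sizes)
    gm, truth = simulate_progeny(
        tm, selection,
        SimConfig(n_progeny=n, genotyping_error_rate=error_rate,
                  missing_rate=missing_rate),
        rng,
    )
    return tm, gm, truth


@pytest.fixture(scope="session")
def small_testcross():
    """One 3-LG error-free testcross shared across fast tests."""
    return simulate_testcross(11, n=150, markers_per_lg=12, lg_sizes=[100.0, 90.0, 80.0])
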