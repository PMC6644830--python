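import numpy as np
import pytest

from locimap import (
    DnaModelParams,
    LocusTrack,
    PenaltySet,
    ProblemSpec,
    SpotField,
)
from locimap.io import RunConfig, SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def model():
    return DnaModelParams(n_l=0.3, l_p=300.0, rho=0.5)


def make_spec(loci_kb, loci_colors, spot_xyz, spot_colors, n_colors,
              model=None, q=None, q_miss=None, p_fn=0.1):
    """Small hand-built problem with explicit penalties (default: all ones)."""
    model = model or DnaModelParams(0.3, 300.0, 0.5)
    track = LocusTrack(np.asarray(loci_kb, float), np.asarray(loci_colors, int),
                       n_colors)
    spots = SpotField(np.asarray(spot_xyz, float).reshape(-1, 3),
                      np.asarray(spot_colors, int), n_colors)
    m = len(spot_colors)
    pen = PenaltySet(
        np.ones(m) if q is None else np.asarray(q, float),
        np.ones(n_colors) if q_miss is None else np.asarray(q_miss, float),
    )
    return ProblemSpec(track, spots, model, pen,
                       p_fn_targets=np.full(n_colors, p_fn))


@pytest.fixture
def unit_spec():
    """1 locus, 1 same-color spot, unit penalties."""
    return make_spec([0.0], [0], [[0.0, 0.0, 0.0]], [0], 1)


def toy_instance(seed, contour_kb=10_000.0, n_colors=3, **sim_kwargs):
    """One simulated toy experiment (paper-style parameters)."""
    cfg = RunConfig()
    cfg.sim = SimConfig(contour_kb=contour_kb, n_colors=n_colors, **sim_kwargs)
    return simulate_experiment(cfg, seed=seed)


def toy_batch(seeds, min_loci=4, max_loci=12, **sim_kwargs):
    """Simulated toy instances filtered to enumeration-friendly sizes."""
    out = []
    for seed in seeds:
        spec, truth, _ = toy_instance(seed, **sim_kwargs)
        if min_loci <= spec.n_loci <= max_loci and spec.n_spots >= 2:
            out.append((seed, spec, truth))
    return out
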